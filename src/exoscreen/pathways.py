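"""Per-condition metabolic pathway importance scoring.

A metabolite is *produced* in a condition when its normalized exudation
value exceeds a threshold (default: strictly above zero, i.e. above the
LOD after supplement masking).  Each pathway's importance score in a
condition is the number of produced metabolites belonging to the pathway
divided by the number of distinct produced metabolites that map to at
least one pathway in that condition; pathways are then ranked per
condition by this score.  A metabolite in several pathways counts once
in each pathway's numerator but once overall in the denominator; the
multiplicity-weighted denominator (sum of per-pathway counts) is
available behind ``denominator="multiplicity"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import NormalizedExometabolome, PathwayDB
from .errors import ValidationError


def score_pathways(norm: NormalizedExometabolome, db: PathwayDB,
                   produced_min: float = 0.0,
                   denominator: str = "distinct") -> pd.DataFrame:
    """Score and rank every pathway in every condition.

    Returns a DataFrame with columns condition_id, pathway_id,
    n_produced_in_pathway, score, rank, undefined.  Conditions with no
    produced pathway-mapped metabolite carry score NaN and
    ``undefined=True`` for every pathway.
    """
    if db.frame.empty:
        raise ValidationError("pathway database is empty")
    if denominator not in ("distinct", "multiplicity"):
        raise ValidationError(f"unknown denominator mode {denominator!r}")
    members: dict[str, set[str]] = {}
    for _, row in db.frame.iterrows():
        members.setdefault(str(row["pathway_id"]), set()).add(
            str(row["metabolite_id"]))
    pathway_ids = sorted(members)
    mapped = set(db.frame["metabolite_id"])

    rows = []
    for cond in norm.values.columns:
        produced = set(norm.values.index[norm.values[cond] > produced_min])
        produced_mapped = produced & mapped
        counts = {p: len(members[p] & produced) for p in pathway_ids}
        if denominator == "distinct":
            denom = len(produced_mapped)
        else:
            denom = sum(counts.values())
        undefined = denom == 0
        scored = []
        for p in pathway_ids:
            score = np.nan if undefined else counts[p] / denom
            scored.append((p, counts[p], score))
        # rank by score descending, ties by pathway id
        order = sorted(scored, key=lambda t: (-(t[2] if not undefined else 0.0),
                                              t[0]))
        rank_of = {p: i + 1 for i, (p, _, _) in enumerate(order)}
        for p, n, score in scored:
            rows.append({"condition_id": cond, "pathway_id": p,
                         "n_produced_in_pathway": n, "score": score,
                         "rank": rank_of[p], "undefined": undefined})
    return pd.DataFrame(rows)
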