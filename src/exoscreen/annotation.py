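"""Exact-mass annotation of ions against a metabolite mass table.

Ions are acquired in negative mode and assumed to be singly deprotonated
[M-H]- species, so the neutral mass is recovered by adding back one
proton per charge.  Metabolites whose neutral monoisotopic mass falls
within a ppm tolerance of an ion's inferred neutral mass are matched;
isobars indistinguishable by exact mass (e.g. leucine/isoleucine) are
collapsed into a single ambiguous label.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Mass of a proton in Da (CODATA).
PROTON_MASS = 1.007276466


def neutral_mass_from_mz(mz: float, charge: int = 1) -> float:
    """Neutral monoisotopic mass from an [M-H]- (or multiply deprotonated)
    m/z: M = mz * z + z * m_proton."""
    if charge < 1:
        raise ValidationError("charge must be >= 1")
    if mz <= 0:
        raise ValidationError("mz must be positive")
    return float(mz) * charge + charge * PROTON_MASS


def annotate_ions(ions: pd.DataFrame, masses, tol_ppm: float = 10.0,
                  charge: int = 1) -> pd.DataFrame:
    """Match every ion to all metabolites within ``tol_ppm`` of its neutral mass.

    Parameters
    ----------
    ions : DataFrame with columns ion_id, mz.
    masses : MassTable.
    tol_ppm : relative tolerance in parts per million, computed against
        the metabolite's neutral mass.

    Returns
    -------
    DataFrame with one row per ion: ion_id, mz, metabolite_ids (tuple,
    sorted), label (names joined with '/' for ambiguous isobars, '' if
    unmatched), ppm_errors (tuple, aligned with metabolite_ids).
    Unmatched ions are retained with an empty match set.
    """
    if tol_ppm <= 0:
        raise ValidationError("tol_ppm must be positive")
    met = masses.frame["metabolite_id"].to_numpy()
    met_mass = masses.frame["monoisotopic_mass_da"].to_numpy(dtype=float)
    rows = []
    for ion_id, mz in zip(ions["ion_id"], ions["mz"]):
        m = neutral_mass_from_mz(float(mz), charge=charge)
        ppm = (m - met_mass) / met_mass * 1e6
        hit = np.abs(ppm) <= tol_ppm
        order = np.argsort(met[hit])
        names = tuple(met[hit][order])
        rows.append({
            "ion_id": ion_id,
            "mz": float(mz),
            "metabolite_ids": names,
            "label": "/".join(names),
            "ppm_errors": tuple(float(p) for p in ppm[hit][order]),
        })
    return pd.DataFrame(rows, columns=["ion_id", "mz", "metabolite_ids",
                                       "label", "ppm_errors"])


def metabolite_ion_map(annotations: pd.DataFrame,
                       intensities: pd.DataFrame) -> dict[str, str]:
    """Choose one representative ion per metabolite.

    When several annotated ions match the same metabolite, the ion with
    the largest summed intensity across all samples represents it
    downstream.  Ties break by ion_id for determinism.
    """
    totals = intensities.sum(axis=1)
    best: dict[str, tuple[float, str]] = {}
    for _, row in annotations.iterrows():
        for met in row["metabolite_ids"]:
            key = (float(totals.get(row["ion_id"], 0.0)), row["ion_id"])
            # prefer larger total; on equal totals prefer smaller ion_id
            cur = best.get(met)
            if cur is None or key[0] > cur[0] or (key[0] == cur[0]
                                                  and key[1] < cur[1]):
                best[met] = key
    return {met: ion for met, (_, ion) in best.items()}


def write_annotations(annotations: pd.DataFrame, path) -> None:
    out = annotations.copy()
    out["metabolite_ids"] = out["metabolite_ids"].map("|".join)
    out["ppm_errors"] = out["ppm_errors"].map(
        lambda t: "|".join(f"{p:.4f}" for p in t))
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")
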