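"""Exometabolome normalization, consumption calling and exudate ranking.

The normalization follows a fixed pipeline per annotated metabolite:

1. **LOD thresholding** — a limit of detection is the mean background-medium
   intensity plus three background standard deviations; culture intensities
   below it are reassigned to the background mean.
2. **Supplement masking** — in conditions where the metabolite itself was
   supplemented, its intensity is reassigned to the background mean, so the
   leftover supplement cannot masquerade as exudation.
3. **0-1 scaling** — intensities are scaled as (I - mu_bg) / (I_max - mu_bg),
   where mu_bg is the background mean and I_max the highest post-masking
   intensity among individual culture supernatant samples; 0 therefore means
   "at background level" and 1 "the most concentrated sample".  Metabolites
   whose maximum never exceeds the LOD are never produced and map to all
   zeros.  Replicates are averaged per condition after scaling.

Consumption (mixotrophy) calling compares day-10 supernatant intensities of
the supplemented metabolite against sterile supplemented-medium reference
samples: a metabolite is called consumed at a concentration when the
reduction is statistically significant (two-sided Welch's t test,
p < alpha) and amounts to at least a 10% drop in readout; a metabolite is
mixotrophically used when the call holds at either concentration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (ExperimentDesign, FeatureMatrix,
                        NormalizedExometabolome)
from .errors import MissingReferenceError, ValidationError
from .growth import welch_t_test

FLAG_MEASURED = "measured"
FLAG_BELOW_LOD = "below_lod_reassigned"
FLAG_MASKED = "supplement_masked"


def compute_lod(features: FeatureMatrix, met_ion: dict[str, str]) -> pd.DataFrame:
    """Per-metabolite background mean, SD (n-1 denominator) and LOD.

    Parameters
    ----------
    met_ion : mapping metabolite_id -> representative ion_id
        (see :func:`exoscreen.annotation.metabolite_ion_map`).

    Returns a DataFrame indexed by metabolite_id with columns
    background_mean, background_sd, lod = mean + 3*SD.
    """
    bg_ids = features.sample_ids("background_medium")
    if len(bg_ids) < 2:
        raise ValidationError(
            "need >= 2 background_medium samples to define an SD")
    rows = {}
    for met, ion in met_ion.items():
        vals = features.intensities.loc[ion, bg_ids].to_numpy(dtype=float)
        mu = float(vals.mean())
        sd = float(vals.std(ddof=1))
        rows[met] = {"background_mean": mu, "background_sd": sd,
                     "lod": mu + 3.0 * sd}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "metabolite_id"
    return out


def normalize(features: FeatureMatrix, met_ion: dict[str, str],
              lod: pd.DataFrame,
              design: ExperimentDesign) -> NormalizedExometabolome:
    """Apply LOD reassignment, supplement masking and 0-1 scaling.

    Only day-10 culture supernatant samples enter the scaling (background
    samples define the zero; sterile reference samples exist solely for
    consumption calls).  Returns the metabolite x condition matrix of
    replicate-averaged normalized values with per-cell provenance flags.
    """
    sup = features.samples.loc[
        features.samples["sample_class"] == "supernatant_day10"]
    if sup.empty:
        raise ValidationError("no supernatant_day10 samples")
    sample_ids = list(sup["sample_id"])
    cond_of = dict(zip(sup["sample_id"], sup["condition_id"]))
    conditions = list(dict.fromkeys(sup["condition_id"]))  # keep order

    mets = sorted(met_ion)
    values = pd.DataFrame(0.0, index=pd.Index(mets, name="metabolite_id"),
                          columns=conditions)
    flags = pd.DataFrame(FLAG_MEASURED, index=values.index, columns=conditions)

    supplement_conditions: dict[str, set[str]] = {}
    for _, row in design.supplemented.iterrows():
        supplement_conditions.setdefault(
            str(row["metabolite_id"]), set()).add(str(row["condition_id"]))

    for met in mets:
        ion = met_ion[met]
        mu = float(lod.loc[met, "background_mean"])
        thr = float(lod.loc[met, "lod"])
        raw = features.intensities.loc[ion, sample_ids].to_numpy(dtype=float)

        below = raw < thr
        vals = np.where(below, mu, raw)

        masked_conds = supplement_conditions.get(met, set())
        masked = np.array([cond_of[s] in masked_conds for s in sample_ids])
        vals = np.where(masked, mu, vals)

        i_max = float(vals.max())
        if i_max <= thr:
            scaled = np.zeros_like(vals)  # never produced
            below = np.ones_like(below)
        else:
            scaled = np.clip((vals - mu) / (i_max - mu), 0.0, 1.0)

        per_sample = pd.Series(scaled, index=sample_ids)
        below_s = pd.Series(below, index=sample_ids)
        for cond in conditions:
            ids = [s for s in sample_ids if cond_of[s] == cond]
            values.loc[met, cond] = float(per_sample[ids].mean())
            if cond in masked_conds:
                flags.loc[met, cond] = FLAG_MASKED
                values.loc[met, cond] = 0.0
            elif bool(below_s[ids].all()):
                flags.loc[met, cond] = FLAG_BELOW_LOD
    return NormalizedExometabolome(values, flags)


def consumption(features: FeatureMatrix, met_ion: dict[str, str],
                design: ExperimentDesign, threshold: float = 0.10,
                alpha: float = 0.05) -> pd.DataFrame:
    """Fraction-consumed and mixotrophy call per (metabolite, concentration).

    fraction_consumed = max(0, 1 - mean(day-10 supernatant) / mean(sterile
    reference)); the call requires a significant reduction (Welch p < alpha
    with supernatant below reference) of at least ``threshold``.
    Metabolites flagged unmeasurable in the design are excluded.
    """
    rows = []
    supp = design.supplemented
    for _, drow in supp.iterrows():
        if bool(drow["unmeasurable"]):
            continue
        met = str(drow["metabolite_id"])
        cond = str(drow["condition_id"])
        if met not in met_ion:
            raise ValidationError(
                f"supplemented metabolite {met!r} not resolvable to an "
                "annotated ion and not flagged unmeasurable")
        ion = met_ion[met]
        ref_ids = features.sample_ids("supplemented_reference", cond)
        if len(ref_ids) < 2:
            raise MissingReferenceError(
                f"condition {cond!r} lacks supplemented_reference samples")
        sup_ids = features.sample_ids("supernatant_day10", cond)
        ref = features.intensities.loc[ion, ref_ids].to_numpy(dtype=float)
        day10 = features.intensities.loc[ion, sup_ids].to_numpy(dtype=float)
        frac = max(0.0, 1.0 - day10.mean() / ref.mean())
        res = welch_t_test(day10, ref)
        is_mixo = (frac >= threshold and res.p < alpha
                   and day10.mean() < ref.mean())
        rows.append({
            "metabolite_id": met,
            "concentration_uM": float(drow["concentration_uM"]),
            "condition_id": cond,
            "fraction_consumed": frac,
            "p_value": res.p,
            "is_mixotrophic": is_mixo,
        })
    return pd.DataFrame(rows)


def mixotrophic_metabolites(calls: pd.DataFrame) -> list[str]:
    """Metabolites consumed at either concentration."""
    if calls.empty:
        return []
    hit = calls.loc[calls["is_mixotrophic"], "metabolite_id"]
    return sorted(set(hit))


def rank_exudates(norm: NormalizedExometabolome) -> pd.DataFrame:
    """Rank metabolites by summed normalized intensity across conditions.

    Rank 1 is the largest sum; ties break lexicographically by
    metabolite_id.  ``n_producing_conditions`` counts conditions where the
    normalized value exceeds zero.
    """
    if norm.values.empty:
        raise ValidationError("normalized matrix is empty")
    sums = norm.values.sum(axis=1)
    n_prod = (norm.values > 0).sum(axis=1)
    out = pd.DataFrame({
        "metabolite_id": sums.index,
        "summed_normalized_intensity": sums.to_numpy(dtype=float),
        "n_producing_conditions": n_prod.to_numpy(dtype=int),
    })
    out = out.sort_values(
        ["summed_normalized_intensity", "metabolite_id"],
        ascending=[False, True], kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
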