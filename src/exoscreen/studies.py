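"""Simulation studies: test calibration and ground-truth recovery rates.

These functions measure operating characteristics of the pipeline on the
synthetic generator — the null rejection rate of the Welch test, the
probability of calling a planted substrate drawdown, and the recovery of
a planted condition-specific exudation signature from PCA loadings.
They are used both by the test suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import annotation as ann
from . import exometabolome as exo
from . import multivariate as mv
from . import synthetic as syn
from .growth import welch_t_test


def welch_null_rejection_rate(n_sims: int = 10_000, n: int = 3,
                              alpha: float = 0.05, seed: int = 0) -> float:
    """Empirical type-I error of the Welch test with both groups drawn
    from the same normal distribution."""
    rng = np.random.default_rng([seed, 101])
    hits = 0
    for _ in range(n_sims):
        a = rng.normal(0.0, 1.0, n)
        b = rng.normal(0.0, 1.0, n)
        if welch_t_test(a, b).p < alpha:
            hits += 1
    return hits / n_sims


def mixotrophy_call_rate(drawdown: float, noise_cv: float = 0.05,
                         n_runs: int = 200, n_replicates: int = 3,
                         seed: int = 0) -> float:
    """Fraction of seeded single-supplement screens in which the planted
    drawdown is called mixotrophic (p < 0.05 and >= 10% reduction)."""
    called = 0
    for s in range(n_runs):
        cfg = syn.SyntheticConfig(
            metabolites=("glucose",), concentrations_uM=(100.0,),
            n_replicates=n_replicates, n_ions=3, n_background_samples=3,
            noise_cv=noise_cv, seed=(seed * 100_003 + s) % (2 ** 31),
            planted_effects={syn.condition_id("glucose", 100.0):
                             syn.PlantedEffect(drawdown_fraction=drawdown)})
        design, truth, _, masses, fm = syn.generate_screen(cfg)
        ion = syn.ion_for_metabolite(fm, masses, "glucose")
        calls = exo.consumption(fm, {"glucose": ion}, design)
        called += int(calls["is_mixotrophic"].iloc[0])
    return called / n_runs


SIGNATURE = ("itaconate", "2-phosphoglycolate", "5-methyltetrahydrofolate",
             "formylglutathione", "dihydroneopterin")


def _signature_config(seed: int, noise_cv: float) -> syn.SyntheticConfig:
    mets = ("glucose", "proline", "serine", "arginine", "histidine",
            "taurine", "sucrose", "citrate")
    commons = ("glutathione", "cyanoalanine", "shikimate")
    effects = {}
    for k, m in enumerate(mets):
        cid = syn.condition_id(m, 5000.0)
        effects[cid] = syn.PlantedEffect(
            exuded_metabolite_ids=commons[: 1 + k % 3],
            exudation_fold=6.0 + 2.0 * (k % 4))
    sig_cond = syn.condition_id("glucose", 5000.0)
    effects[sig_cond] = syn.PlantedEffect(
        exuded_metabolite_ids=commons + SIGNATURE, exudation_fold=20.0)
    return syn.SyntheticConfig(
        metabolites=mets, concentrations_uM=(5000.0,), n_ions=60,
        n_background_samples=4, noise_cv=noise_cv, seed=seed,
        planted_effects=effects)


def pca_signature_recovery(seed: int, noise_cv: float = 0.05) -> int:
    """Plant a unique 5-metabolite exudation signature in one condition,
    run annotation -> LOD -> normalization -> PCA, locate the component
    separating that condition, and count how many signature metabolites
    appear among that component's top-5 loadings (0-5)."""
    cfg = _signature_config(seed, noise_cv)
    design, truth, _, masses, fm = syn.generate_screen(cfg)
    annotations = ann.annotate_ions(fm.ions, masses)
    met_ion = ann.metabolite_ion_map(annotations, fm.intensities)
    lod = exo.compute_lod(fm, met_ion)
    norm = exo.normalize(fm, met_ion, lod, design)
    res = mv.pca(norm, n_components=min(4, *norm.values.shape))

    sig_cond = syn.condition_id("glucose", 5000.0)
    sep, best = None, -np.inf
    for comp in res.scores.columns:
        others = res.scores.loc[res.scores.index != sig_cond, comp]
        gap = abs(res.scores.loc[sig_cond, comp] - others.median())
        spread = others.std() if others.std() > 0 else 1.0
        if gap / spread > best:
            best, sep = gap / spread, comp
    direction = np.sign(res.scores.loc[sig_cond, sep])
    pos, neg = mv.top_loadings(res, sep, k=5)
    top = pos if direction >= 0 else neg
    return len(set(top.index) & set(SIGNATURE))
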