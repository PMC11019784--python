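"""Synthetic screen generator with known ground truth.

Emulates the processed data level of a nutrient-supplementation screen
of a cyanobacterium: an experimental design (supplements x
concentrations + control), OD750 growth curves, and an LC-MS feature
table (ion x sample intensities) containing background-medium samples,
sterile supplemented-medium reference samples and day-10 culture
supernatants.  Growth effects, substrate drawdown and
condition-specific exudation signatures are *planted*, so every
downstream stage can be tested against a known truth.

The default metabolite panel mirrors a 32-compound screen (amino acids,
organic acids, monosaccharides, C1 compounds); five of the compounds
(urea, trimethylamine, methanol, ammonia, acetate) are flagged
unmeasurable by negative-mode LC-MS and excluded from consumption
analysis.

Growth model: logistic with shared rate and condition-specific carrying
capacity — exponential in the first days, plateauing by day 10.  Noise:
additive Gaussian on OD (SD = cv * OD) and mean-preserving multiplicative
log-normal on intensities (cv = ``noise_cv``); ``noise_cv = 0`` gives
noiseless output, used by closure tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics.mass import calculate_mass

from .annotation import PROTON_MASS
from .datatypes import (
    CONTROL_METABOLITE,
    ExperimentDesign,
    FeatureMatrix,
    GrowthCurves,
    MassTable,
)
from .errors import DesignError, ValidationError

GROWTH_CLASSES = ("enhanced", "inhibited", "none", "complete_inhibition")

# 32-compound supplementation panel with molecular formulas (neutral form).
DEFAULT_PANEL: dict[str, str] = {
    "glucose": "C6H12O6",
    "fructose": "C6H12O6",
    "sucrose": "C12H22O11",
    "glycerol": "C3H8O3",
    "gluconate": "C6H12O7",
    "malate": "C4H6O5",
    "citrate": "C6H8O7",
    "succinate": "C4H6O4",
    "glutarate": "C5H8O4",
    "propionate": "C3H6O2",
    "lactate": "C3H6O3",
    "acetate": "C2H4O2",
    "urea": "CH4N2O",
    "trimethylamine": "C3H9N",
    "methanol": "CH4O",
    "ammonia": "H3N",
    "alanine": "C3H7NO2",
    "arginine": "C6H14N4O2",
    "asparagine": "C4H8N2O3",
    "glutamate": "C5H9NO4",
    "glutamine": "C5H10N2O3",
    "glycine": "C2H5NO2",
    "histidine": "C6H9N3O2",
    "leucine": "C6H13NO2",
    "lysine": "C6H14N2O2",
    "methionine": "C5H11NO2S",
    "phenylalanine": "C9H11NO2",
    "proline": "C5H9NO2",
    "serine": "C3H7NO3",
    "threonine": "C4H9NO3",
    "valine": "C5H11NO2",
    "taurine": "C2H7NO3S",
}

# Compounds the negative-mode LC-MS method cannot measure.
UNMEASURABLE = frozenset(
    {"urea", "trimethylamine", "methanol", "ammonia", "acetate"})

# Exudate pool: metabolites the organism may release into the medium.
EXUDATE_FORMULAS: dict[str, str] = {
    "isopropylmalate": "C7H12O5",
    "ketovaline": "C5H8O3",
    "hydroxyglutarate": "C5H8O5",
    "isoleucine": "C6H13NO2",
    "itaconate": "C5H6O4",
    "2-phosphoglycolate": "C2H5O6P",
    "5-methyltetrahydrofolate": "C20H25N7O6",
    "formylglutathione": "C11H17N3O7S",
    "glutathione": "C10H17N3O6S",
    "lactoylglutathione": "C13H21N3O8S",
    "dihydroneopterin": "C9H13N5O4",
    "cyanoalanine": "C4H6N2O2",
    "hydroxy-formylkynurenine": "C11H12N2O5",
    "shikimate": "C7H10O5",
    "pantothenate": "C9H17NO5",
}


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth perturbation for one condition."""

    growth_class: str = "none"
    drawdown_fraction: float = 0.0
    exuded_metabolite_ids: tuple[str, ...] = ()
    capacity_fold: float | None = None  # overrides the class default
    exudation_fold: float = 10.0

    def __post_init__(self):
        if self.growth_class not in GROWTH_CLASSES:
            raise ValidationError(
                f"unknown growth_class {self.growth_class!r}")
        if not 0.0 <= self.drawdown_fraction <= 1.0:
            raise ValidationError("drawdown_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic screen.

    Defaults reproduce the study conditions the generator emulates:
    32 supplements x {100 uM, 5 mM} + control, triplicates, ~10^3 ions,
    background-medium samples, multiplicative log-normal intensity noise.
    """

    metabolites: tuple[str, ...] = tuple(DEFAULT_PANEL)
    concentrations_uM: tuple[float, ...] = (100.0, 5000.0)
    n_replicates: int = 3
    n_ions: int = 1000
    n_background_samples: int = 6
    n_reference_replicates: int = 3
    noise_cv: float = 0.05
    planted_effects: dict[str, PlantedEffect] = field(default_factory=dict)
    seed: int = 0
    unmeasurable: frozenset[str] = UNMEASURABLE
    # growth model
    od_start: float = 0.01
    growth_rate_per_day: float = 0.8
    control_capacity: float = 1.0
    enhanced_fold: float = 1.5
    inhibited_fold: float = 0.5
    days: tuple[float, ...] = tuple(float(d) for d in range(11))
    # intensity model
    baseline_range: tuple[float, float] = (100.0, 1000.0)
    supplement_intensity_per_uM: float = 20.0
    mz_range: tuple[float, float] = (50.0, 1700.0)
    extra_masses: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.metabolites)) != len(self.metabolites):
            raise DesignError("duplicate metabolite names in panel")
        for n, v in (("n_replicates", self.n_replicates),
                     ("n_ions", self.n_ions),
                     ("n_background_samples", self.n_background_samples),
                     ("n_reference_replicates", self.n_reference_replicates)):
            if v < 1:
                raise ValidationError(f"{n} must be >= 1")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if any(c <= 0 for c in self.concentrations_uM):
            raise ValidationError("concentrations must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent per-stage stream derived from the master seed."""
        return np.random.default_rng([int(self.seed), int(stream)])


def condition_id(metabolite: str, concentration_uM: float) -> str:
    c = float(concentration_uM)
    conc = str(int(c)) if c.is_integer() else repr(c)
    return f"{metabolite}_{conc}uM"

CONTROL_ID = "control"


@dataclass(frozen=True)
class GroundTruth:
    """One record per condition: true growth class, drawdown, exudates."""

    frame: pd.DataFrame  # condition_id, growth_class, drawdown_fraction
    exuded: dict[str, tuple[str, ...]]  # condition_id -> exuded metabolites
    effects: dict[str, PlantedEffect]

    def effect_of(self, cond: str) -> PlantedEffect:
        return self.effects.get(cond, PlantedEffect())


def generate_design(config: SyntheticConfig) -> ExperimentDesign:
    """Enumerate one condition per (metabolite, concentration) plus one control."""
    rows = [{
        "condition_id": CONTROL_ID,
        "metabolite_id": CONTROL_METABOLITE,
        "concentration_uM": np.nan,
        "n_replicates": config.n_replicates,
        "unmeasurable": False,
    }]
    for met in config.metabolites:
        for conc in config.concentrations_uM:
            rows.append({
                "condition_id": condition_id(met, conc),
                "metabolite_id": met,
                "concentration_uM": float(conc),
                "n_replicates": config.n_replicates,
                "unmeasurable": met in config.unmeasurable,
            })
    return ExperimentDesign(pd.DataFrame(rows))


def ground_truth(design: ExperimentDesign, config: SyntheticConfig) -> GroundTruth:
    """Materialize the planted effects into one record per condition."""
    unknown = set(config.planted_effects) - set(design.condition_ids)
    if unknown:
        raise DesignError(
            f"planted effect for unknown condition(s): {sorted(unknown)}")
    rows, exuded = [], {}
    for cond in design.condition_ids:
        eff = config.planted_effects.get(cond, PlantedEffect())
        rows.append({"condition_id": cond,
                     "growth_class": eff.growth_class,
                     "drawdown_fraction": eff.drawdown_fraction})
        exuded[cond] = tuple(eff.exuded_metabolite_ids)
    return GroundTruth(pd.DataFrame(rows), exuded,
                       dict(config.planted_effects))


def _capacity(eff: PlantedEffect, config: SyntheticConfig) -> float:
    if eff.growth_class == "complete_inhibition":
        return config.od_start
    base = {"enhanced": config.enhanced_fold,
            "inhibited": config.inhibited_fold,
            "none": 1.0}[eff.growth_class]
    fold = eff.capacity_fold if eff.capacity_fold is not None else base
    return config.control_capacity * fold


def logistic_od(t, od0, capacity, rate):
    """Logistic growth curve through OD(0) = od0 with carrying capacity."""
    t = np.asarray(t, dtype=float)
    return capacity * od0 / (od0 + (capacity - od0) * np.exp(-rate * t))


def generate_growth_curves(design: ExperimentDesign, truth: GroundTruth,
                           config: SyntheticConfig) -> GrowthCurves:
    """Daily OD750 for each condition x replicate under the logistic model."""
    missing = set(truth.frame["condition_id"]) - set(design.condition_ids)
    if missing:
        raise DesignError(f"truth mentions unknown condition(s): {sorted(missing)}")
    rng = config.rng(1)
    days = np.asarray(config.days, dtype=float)
    rows = []
    for cond in design.condition_ids:
        eff = truth.effect_of(cond)
        cap = _capacity(eff, config)
        clean = logistic_od(days, config.od_start, cap,
                            config.growth_rate_per_day)
        for rep in range(1, config.n_replicates + 1):
            noise = rng.normal(0.0, config.noise_cv * clean) \
                if config.noise_cv > 0 else 0.0
            od = np.maximum(clean + noise, 0.0)
            for d, o in zip(days, od):
                rows.append({"condition_id": cond, "replicate": rep,
                             "day": float(d), "od750": float(o)})
    return GrowthCurves(pd.DataFrame(rows))


def generate_mass_table(config: SyntheticConfig) -> MassTable:
    """Monoisotopic neutral masses for the panel plus the exudate pool."""
    entries: dict[str, float] = {}
    for name in config.metabolites:
        if name in DEFAULT_PANEL:
            entries[name] = calculate_mass(formula=DEFAULT_PANEL[name])
        elif name in config.extra_masses:
            entries[name] = float(config.extra_masses[name])
        else:
            raise ValidationError(
                f"no formula or mass known for metabolite {name!r}")
    for name, formula in EXUDATE_FORMULAS.items():
        entries.setdefault(name, calculate_mass(formula=formula))
    for name, mass in config.extra_masses.items():
        entries.setdefault(name, float(mass))
    frame = pd.DataFrame({"metabolite_id": list(entries),
                          "monoisotopic_mass_da": list(entries.values())})
    return MassTable(frame)


def _lognormal_factors(rng, cv, shape):
    """Mean-preserving multiplicative log-normal noise with the given CV."""
    if cv <= 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv * cv)
    return np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=shape))


def generate_feature_matrix(design: ExperimentDesign, truth: GroundTruth,
                            masses: MassTable,
                            config: SyntheticConfig) -> FeatureMatrix:
    """Ion x sample intensities with planted drawdown and exudation.

    One ion per distinct mass-table mass at its [M-H]- m/z — isobaric
    metabolites (e.g. glucose/fructose, leucine/isoleucine) share a
    single ion, as upstream feature alignment cannot separate species of
    identical exact mass without retention information — padded with
    unannotated decoy ions up to ``n_ions``.  Background samples carry a
    per-ion baseline; sterile reference samples carry the supplement ion
    at a concentration-proportional level; day-10 supernatants show the
    planted drawdown (supplement ion at ``level * (1 - drawdown)``,
    floored at baseline) and planted exudation (exudate ion at
    ``baseline * fold``).  Coinciding contributions to one cell combine
    by maximum.
    """
    if not len(masses.frame):
        raise ValidationError("mass table is empty")
    met_ids = masses.metabolite_ids
    for cond, exuded in truth.exuded.items():
        missing = set(exuded) - set(met_ids)
        if missing:
            raise ValidationError(
                f"planted exudate(s) {sorted(missing)} for condition "
                f"{cond!r} missing from mass table")

    rng = config.rng(2)
    # isobars collapse onto one ion (grouped by mass to 1e-6 Da)
    ion_of_met: dict[str, int] = {}
    annot_mz: list[float] = []
    for met, mass in zip(met_ids,
                         masses.frame["monoisotopic_mass_da"]):
        key = round(float(mass), 6)
        for i, existing in enumerate(annot_mz):
            if round(existing + PROTON_MASS, 6) == key:
                ion_of_met[met] = i
                break
        else:
            ion_of_met[met] = len(annot_mz)
            annot_mz.append(float(mass) - PROTON_MASS)
    n_annot = len(annot_mz)
    n_ions = max(config.n_ions, n_annot)
    ion_ids = [f"ion{i:04d}" for i in range(n_ions)]
    mz = np.empty(n_ions)
    mz[:n_annot] = annot_mz
    mz[n_annot:] = np.sort(rng.uniform(*config.mz_range, size=n_ions - n_annot))

    lo, hi = config.baseline_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_ions))

    sample_rows = []
    for _ in range(config.n_background_samples):
        i = len(sample_rows) + 1
        sample_rows.append(("bg%02d" % i, "", i, "background_medium"))
    supp = design.supplemented
    for _, row in supp.iterrows():
        for rep in range(1, config.n_reference_replicates + 1):
            sample_rows.append((f"ref_{row.condition_id}_r{rep}",
                                row.condition_id, rep, "supplemented_reference"))
    for cond in design.condition_ids:
        for rep in range(1, config.n_replicates + 1):
            sample_rows.append((f"sup_{cond}_r{rep}", cond, rep,
                                "supernatant_day10"))
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "condition_id",
                                                 "replicate", "sample_class"])

    clean = np.tile(baseline[:, None], (1, len(samples)))
    cls = samples["sample_class"].to_numpy()
    cond_of = samples["condition_id"].to_numpy()
    level = {}  # condition -> reference intensity of its supplement ion
    for _, row in supp.iterrows():
        level[row.condition_id] = (config.supplement_intensity_per_uM
                                   * float(row.concentration_uM))
    for j in range(len(samples)):
        cond = cond_of[j]
        if cls[j] == "supplemented_reference":
            met = design.supplement_of(cond)
            if met in ion_of_met:
                i = ion_of_met[met]
                clean[i, j] = max(clean[i, j], level[cond])
        elif cls[j] == "supernatant_day10" and cond != design.control_id:
            eff = truth.effect_of(cond)
            met = design.supplement_of(cond)
            if met and met in ion_of_met:
                i = ion_of_met[met]
                clean[i, j] = max(clean[i, j],
                                  level[cond] * (1.0 - eff.drawdown_fraction))
        if cls[j] == "supernatant_day10":
            eff = truth.effect_of(cond)
            for met in truth.exuded.get(cond, ()):
                i = ion_of_met[met]
                clean[i, j] = max(clean[i, j],
                                  baseline[i] * eff.exudation_fold)

    noisy = clean * _lognormal_factors(rng, config.noise_cv, clean.shape)
    intens = pd.DataFrame(noisy, index=pd.Index(ion_ids, name="ion_id"),
                          columns=samples["sample_id"])
    ions = pd.DataFrame({"ion_id": ion_ids, "mz": mz,
                         "polarity": "negative"})
    return FeatureMatrix(intens, ions, samples)


# Coarse pathway membership for the synthetic panel + exudate pool
# (loosely modelled on cyanobacterial central metabolism groupings; a
# metabolite may belong to several pathways).
SYNTHETIC_PATHWAYS: dict[str, tuple[str, ...]] = {
    "tca_cycle": ("citrate", "malate", "succinate", "glutarate", "itaconate",
                  "hydroxyglutarate"),
    "glycolysis_oxidative_pentose": ("glucose", "fructose", "sucrose",
                                     "gluconate", "lactate",
                                     "2-phosphoglycolate"),
    "branched_chain_aa": ("valine", "leucine", "isoleucine", "ketovaline",
                          "isopropylmalate"),
    "glutathione_metabolism": ("glutathione", "formylglutathione",
                               "lactoylglutathione", "glutamate", "glycine"),
    "one_carbon_folate": ("5-methyltetrahydrofolate", "dihydroneopterin",
                          "serine", "glycine", "methionine"),
    "aromatic_aa": ("phenylalanine", "shikimate",
                    "hydroxy-formylkynurenine"),
    "nitrogen_assimilation": ("glutamine", "glutamate", "arginine",
                              "asparagine", "urea", "ammonia",
                              "cyanoalanine"),
}


def generate_pathway_db():
    """Many-to-many metabolite -> pathway table for the synthetic panel."""
    from .datatypes import PathwayDB
    rows = [{"metabolite_id": met, "pathway_id": pw}
            for pw, mets in sorted(SYNTHETIC_PATHWAYS.items())
            for met in sorted(mets)]
    return PathwayDB(pd.DataFrame(rows))


def ion_for_metabolite(features: FeatureMatrix, masses: MassTable,
                       metabolite_id: str) -> str:
    """The generated ion whose m/z is closest to a metabolite's [M-H]- mass."""
    target = masses.mass_of(metabolite_id) - PROTON_MASS
    idx = (features.ions["mz"] - target).abs().idxmin()
    return str(features.ions.loc[idx, "ion_id"])


def paper_like_config(seed: int = 0, noise_cv: float = 0.05,
                      n_ions: int = 1000) -> SyntheticConfig:
    """Default screen scenario: a full 65-condition panel with planted
    enhancers, inhibitors, consumed substrates and two condition-specific
    exudation signatures (a glucose-like and a valine-like response),
    plus a set of broadly exuded stress metabolites."""
    mM5 = 5000.0
    uM100 = 100.0
    effects: dict[str, PlantedEffect] = {}

    common = ("hydroxy-formylkynurenine", "glutathione", "dihydroneopterin")

    def plant(met, conc, **kw):
        cid = condition_id(met, conc)
        kw.setdefault("exuded_metabolite_ids", common)
        effects[cid] = PlantedEffect(**kw)

    enhancers = [("glucose", 1.53), ("acetate", 1.40), ("proline", 1.30),
                 ("taurine", 1.25), ("serine", 1.15), ("alanine", 1.12),
                 ("glycine", 1.10)]
    for met, fold in enhancers:
        plant(met, mM5, growth_class="enhanced", capacity_fold=fold)

    dead_5mM = ["citrate", "fructose", "glutamine", "glutarate", "glutamate",
                "succinate", "malate", "methionine", "propionate", "threonine",
                "lysine", "histidine"]
    for met in dead_5mM:
        plant(met, mM5, growth_class="complete_inhibition",
              exuded_metabolite_ids=())
    for met in ("lysine", "propionate", "threonine"):
        plant(met, uM100, growth_class="complete_inhibition",
              exuded_metabolite_ids=())

    partial = ["valine", "leucine", "phenylalanine", "arginine", "asparagine",
               "gluconate", "lactate", "sucrose", "glycerol"]
    for met in partial:
        plant(met, mM5, growth_class="inhibited", capacity_fold=0.6)
    for met in partial[:6]:
        plant(met, uM100, growth_class="inhibited", capacity_fold=0.75)
    for met in ("citrate", "glutamate", "malate", "succinate", "glutarate",
                "glutamine"):
        plant(met, uM100, growth_class="inhibited", capacity_fold=0.7)

    consumed = ["glucose", "proline", "serine", "alanine", "glycine",
                "arginine", "asparagine", "glutamate", "glutamine",
                "leucine", "valine", "malate", "citrate", "gluconate",
                "sucrose"]
    for k, met in enumerate(consumed):
        frac = 0.3 + 0.04 * k  # 0.30 .. 0.86
        for conc in (uM100, mM5):
            cid = condition_id(met, conc)
            prev = effects.get(cid, PlantedEffect())
            if prev.growth_class == "complete_inhibition":
                continue  # dead cultures consume nothing
            effects[cid] = PlantedEffect(
                growth_class=prev.growth_class,
                drawdown_fraction=frac,
                exuded_metabolite_ids=prev.exuded_metabolite_ids or common,
                capacity_fold=prev.capacity_fold)

    glucose_sig = ("gluconate", "5-methyltetrahydrofolate", "formylglutathione",
                   "2-phosphoglycolate", "itaconate")
    valine_sig = ("isopropylmalate", "ketovaline", "hydroxyglutarate",
                  "isoleucine", "glutarate")
    for met, sig in (("glucose", glucose_sig), ("valine", valine_sig)):
        cid = condition_id(met, mM5)
        prev = effects[cid]
        effects[cid] = PlantedEffect(
            growth_class=prev.growth_class,
            drawdown_fraction=prev.drawdown_fraction,
            exuded_metabolite_ids=tuple(common) + sig,
            capacity_fold=prev.capacity_fold,
            exudation_fold=20.0)

    return SyntheticConfig(noise_cv=noise_cv, n_ions=n_ions, seed=seed,
                           planted_effects=effects)


def generate_screen(config: SyntheticConfig):
    """Convenience: design, truth, growth curves, mass table, feature matrix."""
    design = generate_design(config)
    truth = ground_truth(design, config)
    curves = generate_growth_curves(design, truth, config)
    masses = generate_mass_table(config)
    features = generate_feature_matrix(design, truth, masses, config)
    return design, truth, curves, masses, features
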