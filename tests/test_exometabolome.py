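"""Normalization (LOD, masking, 0-1 scaling), consumption calls and
exudate ranking, checked against an independent step-by-step oracle."""

import statistics

import numpy as np
import pandas as pd
import pytest

import exoscreen as xs
from exoscreen.datatypes import ExperimentDesign
from exoscreen.errors import MissingReferenceError, ValidationError
from exoscreen.exometabolome import (FLAG_BELOW_LOD, FLAG_MASKED,
                                     compute_lod, consumption,
                                     mixotrophic_metabolites, normalize,
                                     rank_exudates)
from exoscreen.synthetic import PlantedEffect, SyntheticConfig, condition_id

from conftest import tiny_feature_matrix


def _design(rows):
    """rows: list of (condition_id, metabolite_id, conc)."""
    frame = pd.DataFrame(
        [{"condition_id": c, "metabolite_id": m,
          "concentration_uM": conc, "n_replicates": 3,
          "unmeasurable": False} for c, m, conc in rows]
        + [{"condition_id": "control", "metabolite_id": "",
            "concentration_uM": np.nan, "n_replicates": 3,
            "unmeasurable": False}])
    return ExperimentDesign(frame)


class TestLod:
    def test_zero_sd_background(self):
        fm = tiny_feature_matrix([[100.0, 100.0, 100.0]],
                                 ["background_medium"] * 3, [""] * 3)
        lod = compute_lod(fm, {"m": "i0"})
        assert lod.loc["m", "lod"] == pytest.approx(100.0)

    def test_worked_sigma_example(self):
        # mean 103.33, sample SD 5.7735 -> LOD 120.66
        fm = tiny_feature_matrix([[100.0, 100.0, 110.0]],
                                 ["background_medium"] * 3, [""] * 3)
        lod = compute_lod(fm, {"m": "i0"})
        assert lod.loc["m", "background_mean"] == pytest.approx(103.3333,
                                                                abs=1e-3)
        assert lod.loc["m", "background_sd"] == pytest.approx(5.7735,
                                                              abs=1e-3)
        assert lod.loc["m", "lod"] == pytest.approx(103.3333 + 3 * 5.77350,
                                                    abs=1e-3)

    def test_lod_linear_in_sd(self):
        fm1 = tiny_feature_matrix([[100.0, 100.0, 110.0]],
                                  ["background_medium"] * 3, [""] * 3)
        # doubled deviations around the same mean
        fm2 = tiny_feature_matrix([[96.667, 96.667, 116.667]],
                                  ["background_medium"] * 3, [""] * 3)
        l1 = compute_lod(fm1, {"m": "i0"})
        l2 = compute_lod(fm2, {"m": "i0"})
        assert (l2.loc["m", "lod"] - l2.loc["m", "background_mean"]
                ) == pytest.approx(
            2 * (l1.loc["m", "lod"] - l1.loc["m", "background_mean"]),
            rel=1e-3)

    def test_single_background_sample_rejected(self):
        fm = tiny_feature_matrix([[100.0, 50.0]],
                                 ["background_medium", "supernatant_day10"],
                                 ["", "c1"])
        with pytest.raises(ValidationError, match="background"):
            compute_lod(fm, {"m": "i0"})


def _normalize_setup(intensities, sample_conditions, supplement_rows):
    n_samples = len(sample_conditions)
    classes = ["background_medium" if c == "" else "supernatant_day10"
               for c in sample_conditions]
    fm = tiny_feature_matrix(intensities, classes, sample_conditions)
    design = _design(supplement_rows)
    met_ion = {f"m{k}": f"i{k}" for k in range(np.shape(intensities)[0])}
    lod = compute_lod(fm, met_ion)
    return fm, design, met_ion, lod


class TestNormalize:
    def test_stated_formula(self):
        """mu_bg = 100, samples [100, 150, 200] -> [0, 0.5, 1.0]."""
        fm, design, met_ion, lod = _normalize_setup(
            [[100.0, 100.0, 100.0, 150.0, 200.0]],
            ["", "", "c1", "c2", "c3"],
            [("c1", "x", 100.0), ("c2", "x", 5000.0), ("c3", "y", 100.0)])
        norm = normalize(fm, met_ion, lod, design)
        assert norm.values.loc["m0", ["c1", "c2", "c3"]].to_numpy() \
            == pytest.approx([0.0, 0.5, 1.0])

    def test_below_lod_reassigned_to_background(self):
        """115 with LOD 120.66 is background-reassigned -> normalized 0."""
        fm, design, met_ion, lod = _normalize_setup(
            [[100.0, 100.0, 110.0, 115.0, 200.0]],
            ["", "", "", "c1", "c2"],
            [("c1", "x", 100.0), ("c2", "x", 5000.0)])
        norm = normalize(fm, met_ion, lod, design)
        assert norm.values.loc["m0", "c1"] == 0.0
        assert norm.flags.loc["m0", "c1"] == FLAG_BELOW_LOD
        assert norm.values.loc["m0", "c2"] == pytest.approx(1.0)

    def test_supplement_masked_to_zero(self):
        """The supplemented metabolite's own value is 0 in its conditions,
        whatever was measured."""
        fm, design, met_ion, lod = _normalize_setup(
            [[100.0, 100.0, 9999.0, 300.0]],
            ["", "", "g100", "c2"],
            [("g100", "m0", 100.0), ("c2", "y", 100.0)])
        norm = normalize(fm, met_ion, lod, design)
        assert norm.values.loc["m0", "g100"] == 0.0
        assert norm.flags.loc["m0", "g100"] == FLAG_MASKED

    def test_never_produced_metabolite_all_zero(self):
        # LOD = 120.65; both culture values sit below it
        fm, design, met_ion, lod = _normalize_setup(
            [[100.0, 100.0, 110.0, 115.0, 99.0]],
            ["", "", "", "c1", "c2"],
            [("c1", "x", 100.0), ("c2", "y", 100.0)])
        norm = normalize(fm, met_ion, lod, design)
        assert (norm.values.loc["m0"] == 0.0).all()

    @pytest.mark.parametrize("c", [0.01, 3.0, 1e4])
    def test_scale_invariance(self, c):
        base = np.array([[100.0, 105.0, 130.0, 400.0, 220.0]])
        fm1, design, met_ion, lod1 = _normalize_setup(
            base, ["", "", "c1", "c2", "c3"],
            [("c1", "x", 100.0), ("c2", "x", 5000.0), ("c3", "y", 100.0)])
        fm2, _, _, lod2 = _normalize_setup(
            base * c, ["", "", "c1", "c2", "c3"],
            [("c1", "x", 100.0), ("c2", "x", 5000.0), ("c3", "y", 100.0)])
        n1 = normalize(fm1, met_ion, lod1, design)
        n2 = normalize(fm2, met_ion, lod2, design)
        np.testing.assert_allclose(n1.values.to_numpy(),
                                   n2.values.to_numpy(), atol=1e-12)


def oracle_normalize(raw, bg_cols, cond_of_col, masked_conds):
    """Spreadsheet-style reference implementation for one metabolite.

    raw : per-sample intensity list (supernatant columns only)
    bg_cols : background intensities
    cond_of_col : condition of each supernatant column
    masked_conds : conditions where this metabolite was supplemented
    Returns dict condition -> normalized value.
    """
    mu = statistics.mean(bg_cols)
    sd = statistics.stdev(bg_cols)
    lod = mu + 3 * sd
    vals = [mu if v < lod else v for v in raw]
    vals = [mu if cond_of_col[j] in masked_conds else v
            for j, v in enumerate(vals)]
    imax = max(vals)
    if imax <= lod:
        scaled = [0.0] * len(vals)
    else:
        scaled = [min(1.0, max(0.0, (v - mu) / (imax - mu))) for v in vals]
    out = {}
    for cond in dict.fromkeys(cond_of_col):
        members = [scaled[j] for j, c in enumerate(cond_of_col) if c == cond]
        out[cond] = (0.0 if cond in masked_conds
                     else statistics.mean(members))
    return out


def random_norm_instance(seed):
    """<=5 ions x <=6 supernatant samples + backgrounds, random supplements."""
    rng = np.random.default_rng(seed)
    n_ions = rng.integers(1, 6)
    n_conds = rng.integers(2, 4)
    n_reps = rng.integers(1, 3)
    conds = [f"c{k}" for k in range(n_conds)]
    cond_of_col = [c for c in conds for _ in range(n_reps)][:6]
    n_bg = 3
    raw = rng.uniform(50, 500, size=(n_ions, n_bg + len(cond_of_col)))
    sample_conditions = [""] * n_bg + cond_of_col
    supplement_rows = [(c, f"m{rng.integers(0, n_ions)}", 100.0 * (k + 1))
                       for k, c in enumerate(conds)]
    return raw, n_bg, cond_of_col, sample_conditions, supplement_rows


@pytest.mark.parametrize("seed", range(25))
def test_normalize_matches_independent_oracle(seed):
    raw, n_bg, cond_of_col, sample_conditions, supplement_rows = \
        random_norm_instance(seed)
    fm, design, met_ion, lod = _normalize_setup(raw, sample_conditions,
                                                supplement_rows)
    norm = normalize(fm, met_ion, lod, design)
    masked_by_met = {}
    for c, m, _ in supplement_rows:
        masked_by_met.setdefault(m, set()).add(c)
    for k in range(raw.shape[0]):
        met = f"m{k}"
        expected = oracle_normalize(list(raw[k, n_bg:]), list(raw[k, :n_bg]),
                                    cond_of_col,
                                    masked_by_met.get(met, set()))
        for cond, v in expected.items():
            assert norm.values.loc[met, cond] == pytest.approx(v, abs=1e-12)
        assert (norm.values.loc[met] >= 0).all()
        assert (norm.values.loc[met] <= 1).all()


def _consumption_fm(day10_vals, ref_vals):
    vals = [[100.0, 100.0] + list(ref_vals) + list(day10_vals)]
    classes = (["background_medium"] * 2
               + ["supplemented_reference"] * len(ref_vals)
               + ["supernatant_day10"] * len(day10_vals))
    conds = ["", ""] + ["g100"] * (len(ref_vals) + len(day10_vals))
    return tiny_feature_matrix(vals, classes, conds)


class TestConsumption:
    def test_fraction_arithmetic(self):
        fm = _consumption_fm([400.0, 400.0, 400.0], [1000.0, 1000.0, 1000.0])
        design = _design([("g100", "m0", 100.0)])
        calls = consumption(fm, {"m0": "i0"}, design)
        row = calls.iloc[0]
        assert row["fraction_consumed"] == pytest.approx(0.6)
        assert row["is_mixotrophic"]  # constant groups, different means: p=0

    def test_small_reduction_not_called(self):
        fm = _consumption_fm([950.0, 950.0, 950.0], [1000.0, 1000.0, 1000.0])
        design = _design([("g100", "m0", 100.0)])
        calls = consumption(fm, {"m0": "i0"}, design)
        assert calls["fraction_consumed"].iloc[0] == pytest.approx(0.05)
        assert not calls["is_mixotrophic"].iloc[0]

    def test_increase_clipped_to_zero(self):
        fm = _consumption_fm([1500.0, 1400.0, 1450.0], [1000.0] * 3)
        design = _design([("g100", "m0", 100.0)])
        calls = consumption(fm, {"m0": "i0"}, design)
        assert calls["fraction_consumed"].iloc[0] == 0.0
        assert not calls["is_mixotrophic"].iloc[0]

    def test_missing_reference_errors(self):
        fm = tiny_feature_matrix(
            [[100.0, 100.0, 400.0]],
            ["background_medium", "background_medium", "supernatant_day10"],
            ["", "", "g100"])
        design = _design([("g100", "m0", 100.0)])
        with pytest.raises(MissingReferenceError, match="g100"):
            consumption(fm, {"m0": "i0"}, design)

    def test_unmeasurable_metabolite_excluded(self):
        fm = _consumption_fm([400.0] * 3, [1000.0] * 3)
        frame = _design([("g100", "m0", 100.0)]).frame.copy()
        frame.loc[frame["metabolite_id"] == "m0", "unmeasurable"] = True
        calls = consumption(fm, {}, ExperimentDesign(frame))
        assert calls.empty
        assert mixotrophic_metabolites(calls) == []

    def test_either_concentration_rule(self):
        """A metabolite consumed at one concentration only is still called
        mixotrophic overall."""
        cfg = SyntheticConfig(
            metabolites=("glucose",), n_ions=5, n_background_samples=3,
            noise_cv=0.02, seed=9,
            planted_effects={
                condition_id("glucose", 100.0): PlantedEffect(
                    drawdown_fraction=0.5)})
        design, truth, _, masses, fm = xs.generate_screen(cfg)
        met_ion = {"glucose": xs.synthetic.ion_for_metabolite(fm, masses,
                                                              "glucose")}
        calls = consumption(fm, met_ion, design)
        by_conc = calls.set_index("concentration_uM")
        assert by_conc.loc[100.0, "is_mixotrophic"]
        assert not by_conc.loc[5000.0, "is_mixotrophic"]
        assert mixotrophic_metabolites(calls) == ["glucose"]


def mixotrophy_call_rate(drawdown, noise_cv, n_runs, seed0=0):
    """Fraction of seeded single-metabolite screens where the planted
    drawdown is called at the 100 uM condition."""
    called = 0
    for s in range(n_runs):
        cfg = SyntheticConfig(
            metabolites=("glucose",), concentrations_uM=(100.0,),
            n_ions=3, n_background_samples=3, noise_cv=noise_cv,
            seed=seed0 + s,
            planted_effects={condition_id("glucose", 100.0): PlantedEffect(
                drawdown_fraction=drawdown)})
        design, truth, _, masses, fm = xs.generate_screen(cfg)
        met_ion = {"glucose": xs.synthetic.ion_for_metabolite(fm, masses,
                                                              "glucose")}
        calls = consumption(fm, met_ion, design)
        called += int(calls["is_mixotrophic"].iloc[0])
    return called / n_runs


def test_mixotrophy_recovery_quick():
    """Planted 30% drawdown at cv 5%, n=3 is almost always called; zero
    drawdown almost never (deep 200-run study in the acceptance suite)."""
    assert mixotrophy_call_rate(0.30, 0.05, 40) >= 0.95
    assert mixotrophy_call_rate(0.0, 0.05, 40) <= 0.05


class TestRankExudates:
    def _norm(self, values, conds):
        v = pd.DataFrame(values, columns=conds)
        v.index = pd.Index([f"m{k}" for k in range(len(v))],
                           name="metabolite_id")
        return xs.NormalizedExometabolome(v)

    def test_top_rank_and_sum(self):
        norm = self._norm([[1.0] * 10, [0.5] * 10, [0.0] * 10],
                          [f"c{k}" for k in range(10)])
        ranks = rank_exudates(norm).set_index("metabolite_id")
        assert ranks.loc["m0", "rank"] == 1
        assert ranks.loc["m0", "summed_normalized_intensity"] == \
            pytest.approx(10.0)
        assert ranks.loc["m0", "n_producing_conditions"] == 10
        assert ranks.loc["m2", "rank"] == 3  # all-zero metabolite is last
        assert ranks.loc["m2", "n_producing_conditions"] == 0
        assert sorted(ranks["rank"]) == [1, 2, 3]

    def test_condition_order_invariance(self):
        conds = [f"c{k}" for k in range(4)]
        vals = np.random.default_rng(1).uniform(0, 1, size=(5, 4))
        r1 = rank_exudates(self._norm(vals, conds))
        r2 = rank_exudates(self._norm(vals[:, ::-1], conds[::-1]))
        pd.testing.assert_frame_equal(r1, r2)

    def test_planted_high_exuders_recovered(self):
        """Top-10 extraction recovers 10 planted high exuders among 100."""
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 0.3, size=(100, 12))
        planted = rng.choice(100, size=10, replace=False)
        vals[planted] += 0.7
        ranks = rank_exudates(self._norm(vals, [f"c{k}" for k in range(12)]))
        top10 = set(ranks.head(10)["metabolite_id"])
        assert top10 == {f"m{k}" for k in planted}
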