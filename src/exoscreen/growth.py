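"""Growth-curve summaries and growth-effect classification.

Each supplemented condition's day-10 OD750 is compared to the
unsupplemented control with a two-sided Welch's t test (unequal
variances).  Conditions whose final OD stays below an absolute
no-growth threshold are labelled ``complete_inhibition`` regardless of
the test; otherwise significance at ``alpha`` together with the
direction of the mean difference yields ``enhanced`` / ``inhibited``,
and everything else is ``none``.  An exponential-phase sanity check
(R^2 of ln(OD) vs time over an early window, default days 0-4)
accompanies each summary.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GrowthCurves
from .errors import GroupSizeError, ValidationError


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


def welch_t_test(a, b) -> WelchResult:
    """Two-sided Welch's t test between two replicate groups.

    t = (mean(a) - mean(b)) / sqrt(s_a^2/n_a + s_b^2/n_b), with
    Welch-Satterthwaite degrees of freedom.  Degenerate zero-variance
    groups follow the documented conventions: p = 1 when both variances
    are zero and the means are equal, p = 0 (difference beyond machine
    resolution) when they differ.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise GroupSizeError("each group needs at least 2 replicates")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("non-finite replicate value")
    # constant groups detected by range, not variance: var([a, a, a]) can be
    # a tiny nonzero number through mean-cancellation rounding
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(a.size + b.size - 2), 1.0)
        t = np.inf if a.mean() > b.mean() else -np.inf
        return WelchResult(float(t), float(a.size + b.size - 2), 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def _log_linear_r2(days, od):
    """R^2 of ln(OD) against time; nonpositive ODs are excluded.

    Returns (r2, flagged): degenerate windows (fewer than 2 usable
    points, or zero variance in ln(OD) i.e. flat curves) report r2 = 0
    with the flag set.
    """
    days = np.asarray(days, dtype=float)
    od = np.asarray(od, dtype=float)
    keep = od > 0
    if keep.sum() < 2:
        return 0.0, True
    x, y = days[keep], np.log(od[keep])
    if np.ptp(x) == 0 or np.allclose(y, y[0]):
        return 0.0, True
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return 0.0, True
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot
    return max(0.0, min(1.0, r2)), bool(keep.sum() != od.size)


def summarize_growth(curves: GrowthCurves, day_final: float = 10.0,
                     exp_window: tuple[float, float] = (0.0, 4.0)
                     ) -> pd.DataFrame:
    """Per-condition day-final OD mean/SD and exponential-phase R^2.

    Returns a DataFrame with columns condition_id, final_od_mean,
    final_od_sd, final_od_values (tuple of replicate ODs at day_final),
    exp_phase_r2, exp_phase_flagged.
    """
    f = curves.frame
    lo, hi = exp_window
    rows = []
    for cond, grp in f.groupby("condition_id", sort=True):
        finals = grp.loc[grp["day"] == day_final, "od750"]
        if finals.empty:
            raise ValidationError(
                f"condition {cond!r} has no timepoint at day {day_final}")
        if len(finals) < 2:
            raise ValidationError(
                f"condition {cond!r} has fewer than 2 replicates at day "
                f"{day_final}")
        win = grp.loc[(grp["day"] >= lo) & (grp["day"] <= hi)]
        r2, flagged = _log_linear_r2(win["day"], win["od750"])
        rows.append({
            "condition_id": cond,
            "final_od_mean": float(finals.mean()),
            "final_od_sd": float(finals.std(ddof=1)),
            "final_od_values": tuple(float(v) for v in finals),
            "exp_phase_r2": r2,
            "exp_phase_flagged": flagged,
        })
    return pd.DataFrame(rows)


def classify_growth(summaries: pd.DataFrame, control_id: str,
                    alpha: float = 0.05,
                    no_growth_threshold_od: float = 0.05,
                    fdr: bool = False) -> pd.DataFrame:
    """Classify each condition's growth effect against the control.

    Returns a DataFrame (control excluded) with columns condition_id,
    p_value, fold_change, effect_class.  With ``fdr=True`` p-values are
    Benjamini-Hochberg adjusted before thresholding (off by default).
    """
    ctrl = summaries.loc[summaries["condition_id"] == control_id]
    if ctrl.empty:
        raise ValidationError(f"control condition {control_id!r} not present")
    ctrl_vals = np.asarray(ctrl["final_od_values"].iloc[0], dtype=float)
    ctrl_mean = float(ctrl["final_od_mean"].iloc[0])

    others = summaries.loc[summaries["condition_id"] != control_id]
    pvals, folds = [], []
    for _, row in others.iterrows():
        res = welch_t_test(np.asarray(row["final_od_values"], dtype=float),
                           ctrl_vals)
        pvals.append(res.p)
        folds.append(row["final_od_mean"] / ctrl_mean if ctrl_mean > 0
                     else np.inf)
    pvals = np.asarray(pvals, dtype=float)
    if fdr and len(pvals):
        pvals = stats.false_discovery_control(pvals, method="bh")

    classes = []
    for (_, row), p in zip(others.iterrows(), pvals):
        if row["final_od_mean"] < no_growth_threshold_od:
            classes.append("complete_inhibition")
        elif p < alpha and row["final_od_mean"] > ctrl_mean:
            classes.append("enhanced")
        elif p < alpha and row["final_od_mean"] < ctrl_mean:
            classes.append("inhibited")
        else:
            classes.append("none")
    return pd.DataFrame({
        "condition_id": others["condition_id"].to_numpy(),
        "p_value": pvals,
        "fold_change": folds,
        "effect_class": classes,
    })
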