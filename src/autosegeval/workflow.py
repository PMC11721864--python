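"""Secondary workflow endpoints: correction-time and confidence comparisons,
and Bonferroni family-wise multiplicity control.

Pairing conventions: correction times are totalled over the five organs per
delineation, averaged over observers within each patient and arm, and the
resulting per-patient pairs enter a classical paired t test. Confidence
scores are compared per organ on per-patient pairs after averaging over
observers; the signed-rank test then runs on those 20 pairs. Zero
differences are dropped before ranking (Wilcoxon's original rule, chosen
over Pratt's for exact-enumeration testability); for n <= 25 retained pairs
the exact null distribution of the signed-rank statistic is computed by
dynamic programming over (tie-adjusted) midranks, above that a normal
approximation with tie correction is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

EXACT_WILCOXON_MAX_N = 25


@dataclass
class TestResult:
    method: str
    statistic: float
    df: float | None
    p_value: float
    n: int
    estimate: float            # arm difference in native units
    degenerate: bool = False


def paired_ttest(x_hp, x_conv) -> TestResult:
    """Classical two-sided paired t test on matched per-patient values."""
    x_hp = np.asarray(x_hp, dtype=float)
    x_conv = np.asarray(x_conv, dtype=float)
    if x_hp.shape != x_conv.shape or x_hp.ndim != 1 or len(x_hp) < 2:
        raise ValueError("paired vectors of equal length >= 2 required")
    d = x_hp - x_conv
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        return TestResult("paired_t", 0.0 if d.mean() == 0 else np.inf, float(n - 1),
                          1.0 if d.mean() == 0 else 0.0, n, float(d.mean()),
                          degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return TestResult("paired_t", float(t), float(n - 1), p, n, float(d.mean()))


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for the signed-rank statistic under random signs.

    Enumerates the null distribution of W+ = sum of ranks with positive sign
    by dynamic programming over the (midrank) values, equivalent to summing
    over all 2^n sign patterns. Midranks are multiples of 1/2, so doubling
    gives an integer-support convolution.
    """
    scaled = [Fraction(r).limit_denominator(2) * 2 for r in ranks]
    scaled = [int(s) for s in scaled]
    total = sum(scaled)
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for s in scaled:
        nxt = dist.copy()
        nxt[s:] += dist[: total + 1 - s]
        dist = nxt
    dist /= dist.sum()
    w2 = int(round(2 * w_plus))
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(x_hp, x_conv) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on matched pairs.

    Zeros are dropped; exact enumeration for n <= 25 retained pairs, normal
    approximation with tie correction above.
    """
    x_hp = np.asarray(x_hp, dtype=float)
    x_conv = np.asarray(x_conv, dtype=float)
    if x_hp.shape != x_conv.shape or x_hp.ndim != 1 or len(x_hp) < 1:
        raise ValueError("paired vectors of equal length >= 1 required")
    d = x_hp - x_conv
    d = d[d != 0]
    n = len(d)
    estimate = float((x_hp - x_conv).mean())
    if n == 0:
        return TestResult("wilcoxon_signed_rank", np.nan, None, 1.0, 0, estimate,
                          degenerate=True)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_corr = np.sum(counts ** 3 - counts) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
        if var <= 0:
            return TestResult("wilcoxon_signed_rank", w_plus, None, 1.0, n, estimate,
                              degenerate=True)
        z = (w_plus - mu) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return TestResult("wilcoxon_signed_rank", w_plus, None, min(p, 1.0), n, estimate)


def bonferroni_level(alpha: float, m: int) -> float:
    """Per-test significance level alpha / m controlling the family-wise error."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# aggregation helpers from the cohort metadata table
# ---------------------------------------------------------------------------

def patient_arm_total_times(meta: pd.DataFrame) -> pd.DataFrame:
    """Per (patient, arm): total correction time over organs, averaged over
    observers; columns high_performance / conventional, one row per patient."""
    per_obs = (meta.groupby(["patient_id", "imaging_system", "observer_id"])
               ["correction_time_s"].sum())
    per_pat = per_obs.groupby(["patient_id", "imaging_system"]).mean()
    return per_pat.unstack("imaging_system")


def compare_correction_times(meta: pd.DataFrame) -> TestResult:
    wide = patient_arm_total_times(meta)
    return paired_ttest(wide["high_performance"].to_numpy(),
                        wide["conventional"].to_numpy())


def compare_confidence(meta: pd.DataFrame, organ: str) -> TestResult:
    """Per-organ confidence comparison on per-patient observer-mean scores."""
    sub = meta[meta["organ"] == organ]
    wide = (sub.groupby(["patient_id", "imaging_system"])["confidence"].mean()
            .unstack("imaging_system"))
    return wilcoxon_signed_rank(wide["high_performance"].to_numpy(),
                                wide["conventional"].to_numpy())


def confidence_summary(meta: pd.DataFrame) -> pd.DataFrame:
    """Mean [SD] confidence per organ and arm (the study's Table-4 layout)."""
    g = meta.groupby(["organ", "imaging_system"])["confidence"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"std": "sd", "count": "n"})
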