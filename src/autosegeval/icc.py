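"""Interobserver variability as a variance-ratio intraclass correlation.

The ICC here is the observer variance component divided by the total
(systematic + patient + observer) variance of a two-way crossed decomposition
y_ij = mu + p_i + o_j + e_ij fitted per imaging system, organ and metric.
An ICC near 0 means observers are consistent relative to the other sources
of variation — note this inverts the usual reliability reading of an ICC.
The "systematic" component of the total is identified with the residual of
the decomposition (a constant systematic offset has no variance, so the term
cannot mean the grand mean); this interpretation is deliberate and recorded.

Uncertainty is quantified by a stratified cluster bootstrap: within each
imaging-system stratum, patients are resampled with replacement carrying
their complete observer set (observers are a fixed crossed factor and are
never resampled), the ICC is recomputed per replicate, and percentile
intervals are read off the replicate distribution. Arms are compared with a
Welch two-sample t test on the two replicate vectors — the study's literal
procedure, not a calibrated test of the underlying ICC difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ICCEstimate:
    icc: float
    sigma2_observer: float
    sigma2_patient: float
    sigma2_systematic: float   # residual component of the two-way decomposition
    n_patients: int
    n_observers: int
    degenerate: bool = False   # total variance was (numerically) zero


@dataclass
class ICCComparison:
    icc_hp: float
    icc_conv: float
    boot_mean_hp: float
    boot_mean_conv: float
    delta_ci: tuple[float, float]   # percentile CI of (conv - hp) paired-index differences
    welch_t: float
    welch_df: float
    p_value: float
    B: int
    seed: int | None = None
    degenerate: bool = False
    boot_hp: np.ndarray = field(default=None, repr=False)
    boot_conv: np.ndarray = field(default=None, repr=False)


def _pivot_single_arm(table: pd.DataFrame, response: str) -> np.ndarray:
    if "imaging_system" in table.columns and table["imaging_system"].nunique() > 1:
        raise ValueError("icc_point expects data from a single imaging system")
    df = table.dropna(subset=[response])
    wide = df.pivot_table(index="patient_id", columns="observer_id", values=response,
                          aggfunc="mean", dropna=False)
    M = wide.to_numpy(dtype=float)
    complete = ~np.isnan(M).any(axis=1)
    M = M[complete]
    if M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need at least 2 complete patients and 2 observers")
    return M


def _components_from_matrix(M: np.ndarray):
    """Balanced two-way ANOVA closed form on an (patients x observers) matrix;
    components truncated at zero."""
    a, b = M.shape
    gm = M.mean()
    row = M.mean(axis=1)
    col = M.mean(axis=0)
    ms_p = b * np.sum((row - gm) ** 2) / (a - 1)
    ms_o = a * np.sum((col - gm) ** 2) / (b - 1)
    ss_e = np.sum((M - row[:, None] - col[None, :] + gm) ** 2)
    ms_e = ss_e / ((a - 1) * (b - 1))
    # snap floating-point dust to an exact zero so structural zero-variance
    # cases (identical observers, constant data) report ICC = 0 exactly
    tol = 1e-12 * max(ms_p, ms_o, ms_e, abs(gm) ** 2)
    s2p = max((ms_p - ms_e) / b, 0.0)
    s2o = max((ms_o - ms_e) / a, 0.0)
    s2e = max(ms_e, 0.0)
    return (0.0 if s2p < tol else s2p, 0.0 if s2o < tol else s2o,
            0.0 if s2e < tol else s2e)


def icc_point(table: pd.DataFrame, response: str = "value") -> ICCEstimate:
    """Point ICC for one imaging system, one organ, one metric.

    The balanced closed form is used when every retained (patient, observer)
    cell is observed once and the table is complete; when cells are missing
    (a patient only partially observed) the components come from a REML fit
    of y = mu + p_i + o_j + e_ij instead.
    """
    if "imaging_system" in table.columns and table["imaging_system"].nunique() > 1:
        raise ValueError("icc_point expects data from a single imaging system")
    df = table.dropna(subset=[response])
    wide = df.pivot_table(index="patient_id", columns="observer_id", values=response,
                          aggfunc="mean", dropna=False)
    M = wide.to_numpy(dtype=float)
    partial = np.isnan(M).any(axis=1) & ~np.isnan(M).all(axis=1)
    if partial.any():
        from .mixed_model import reml_variance_components

        pat, _ = pd.factorize(df["patient_id"], sort=True)
        obs, _ = pd.factorize(df["observer_id"], sort=True)
        s2p, s2o, s2e = reml_variance_components(
            df[response].to_numpy(dtype=float), pat, obs)
        total = s2p + s2o + s2e
        a, b = df["patient_id"].nunique(), df["observer_id"].nunique()
        if total <= 1e-30:
            return ICCEstimate(0.0, 0.0, 0.0, 0.0, a, b, degenerate=True)
        return ICCEstimate(float(s2o / total), s2o, s2p, s2e, a, b)
    M = M[~np.isnan(M).any(axis=1)]
    if M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need at least 2 complete patients and 2 observers")
    return icc_from_matrix(M)


def icc_from_matrix(M: np.ndarray) -> ICCEstimate:
    a, b = M.shape
    s2p, s2o, s2e = _components_from_matrix(M)
    total = s2p + s2o + s2e
    if total <= 1e-30:
        return ICCEstimate(icc=0.0, sigma2_observer=0.0, sigma2_patient=0.0,
                           sigma2_systematic=0.0, n_patients=a, n_observers=b,
                           degenerate=True)
    return ICCEstimate(icc=float(s2o / total), sigma2_observer=float(s2o),
                       sigma2_patient=float(s2p), sigma2_systematic=float(s2e),
                       n_patients=a, n_observers=b)


def icc_from_components(sigma2_patient: float, sigma2_observer: float,
                        sigma2_systematic: float) -> float:
    """The defining ratio on already-estimated (non-negative) components."""
    comps = np.maximum([sigma2_patient, sigma2_observer, sigma2_systematic], 0.0)
    total = comps.sum()
    if total <= 0:
        return 0.0
    return float(comps[1] / total)


def stratified_bootstrap_icc(table: pd.DataFrame, B: int = 10000,
                             seed: int | None = 0,
                             response: str = "value") -> np.ndarray:
    """Patient-cluster bootstrap replicate ICCs for one imaging-system stratum.

    Each replicate draws ``n_patients`` patients with replacement, carries
    each sampled patient's complete observer set, and recomputes the point
    ICC. Replicates with zero total variance contribute ICC = 0.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    M = _pivot_single_arm(table, response)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 909091]))
    return _bootstrap_matrix(M, B, rng)


def _bootstrap_matrix(M: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    a, b = M.shape
    idx = rng.integers(0, a, size=(B, a))
    Y = M[idx]                         # (B, a, b)
    gm = Y.mean(axis=(1, 2))
    row = Y.mean(axis=2)               # (B, a)
    col = Y.mean(axis=1)               # (B, b)
    ms_p = b * ((row - gm[:, None]) ** 2).sum(axis=1) / (a - 1)
    ms_o = a * ((col - gm[:, None]) ** 2).sum(axis=1) / (b - 1)
    resid = Y - row[:, :, None] - col[:, None, :] + gm[:, None, None]
    ms_e = (resid ** 2).sum(axis=(1, 2)) / ((a - 1) * (b - 1))
    tol = 1e-12 * np.maximum.reduce([ms_p, ms_o, ms_e, gm ** 2])
    s2p = np.maximum((ms_p - ms_e) / b, 0.0)
    s2o = np.maximum((ms_o - ms_e) / a, 0.0)
    s2e = np.maximum(ms_e, 0.0)
    s2p[s2p < tol] = 0.0
    s2o[s2o < tol] = 0.0
    s2e[s2e < tol] = 0.0
    total = s2p + s2o + s2e
    out = np.zeros(B)
    ok = total > 0
    out[ok] = s2o[ok] / total[ok]
    return out


def welch_test(x: np.ndarray, y: np.ndarray):
    """Welch two-sample t statistic, Welch-Satterthwaite df, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    # zero variance up to floating-point dust in both vectors -> degenerate
    tol = 1e-24 * (x.mean() ** 2 + y.mean() ** 2) + 1e-300
    if se2 <= tol:
        return 0.0, float("nan"), 1.0, True
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / (v1 ** 2 / (n1 ** 2 * (n1 - 1)) + v2 ** 2 / (n2 ** 2 * (n2 - 1)))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), float(df), p, False


def compare_icc(boot_hp: np.ndarray, boot_conv: np.ndarray,
                point_hp: float = np.nan, point_conv: float = np.nan,
                seed: int | None = None) -> ICCComparison:
    """Compare two arms' bootstrap replicate ICC vectors.

    The Welch t test runs on the two replicate vectors (the study's stated
    procedure); the delta 95% CI is the 2.5/97.5 percentile interval of
    paired-index differences (conventional minus high-performance).
    """
    boot_hp = np.asarray(boot_hp, dtype=float)
    boot_conv = np.asarray(boot_conv, dtype=float)
    if len(boot_hp) != len(boot_conv) or len(boot_hp) < 1:
        raise ValueError("replicate vectors must be non-empty and of equal length")
    t, df, p, degenerate = welch_test(boot_conv, boot_hp)
    delta = boot_conv - boot_hp
    lo, hi = np.percentile(delta, [2.5, 97.5])
    return ICCComparison(
        icc_hp=float(point_hp), icc_conv=float(point_conv),
        boot_mean_hp=float(boot_hp.mean()), boot_mean_conv=float(boot_conv.mean()),
        delta_ci=(float(lo), float(hi)), welch_t=t, welch_df=df, p_value=p,
        B=len(boot_hp), seed=seed, degenerate=degenerate,
        boot_hp=boot_hp, boot_conv=boot_conv)
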