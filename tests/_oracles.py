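"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithmic paths: distances by
all-pairs enumeration, percentiles by the explicit linear-interpolation
formula, variance components by the balanced expected-mean-squares closed
form, and the signed-rank null by exhaustive sign enumeration.
"""

import itertools

import numpy as np
import pandas as pd

from autosegeval.metrics import boundary_voxels


def percentile_linear(values, q):
    """Linear-interpolation percentile written out explicitly."""
    v = np.sort(np.asarray(values, dtype=float))
    if len(v) == 1:
        return float(v[0])
    pos = (q / 100.0) * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, len(v) - 1)
    frac = pos - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)


def brute_dice(a, b):
    A = {tuple(i) for i in np.argwhere(a.voxels)}
    B = {tuple(i) for i in np.argwhere(b.voxels)}
    return 2 * len(A & B) / (len(A) + len(B))


def brute_hd95(a, b):
    """All-pairs boundary distances, pooled, explicit percentile."""
    sp = np.asarray(a.spacing_mm)
    pa = np.argwhere(boundary_voxels(a)) * sp
    pb = np.argwhere(boundary_voxels(b)) * sp
    D = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2))
    pooled = np.concatenate([D.min(axis=1), D.min(axis=0)])
    return percentile_linear(pooled, 95.0)


def ems_components_three_way(table: pd.DataFrame, response: str):
    """Balanced expected-mean-squares estimators for the crossed design with
    an arm factor: y_ijk = mu + arm_k + p_i + o_j + e; truncated at zero."""
    y = table[response].to_numpy(dtype=float)
    pat, _ = pd.factorize(table["patient_id"], sort=True)
    obs, _ = pd.factorize(table["observer_id"], sort=True)
    arm, _ = pd.factorize(table["imaging_system"], sort=True)
    a, b = pat.max() + 1, obs.max() + 1
    gm = y.mean()
    ybp = np.array([y[pat == i].mean() for i in range(a)])
    ybo = np.array([y[obs == j].mean() for j in range(b)])
    ms_p = 2 * b * np.sum((ybp - gm) ** 2) / (a - 1)
    ms_o = 2 * a * np.sum((ybo - gm) ** 2) / (b - 1)
    ss_arm = a * b * sum((y[arm == k].mean() - gm) ** 2 for k in (0, 1))
    ss_e = (np.sum((y - gm) ** 2) - 2 * b * np.sum((ybp - gm) ** 2)
            - 2 * a * np.sum((ybo - gm) ** 2) - ss_arm)
    ms_e = ss_e / (2 * a * b - a - b)
    return (max((ms_p - ms_e) / (2 * b), 0.0),
            max((ms_o - ms_e) / (2 * a), 0.0),
            ms_e)


def exhaustive_signed_rank_p(diffs):
    """Two-sided signed-rank p by enumerating all 2^n sign patterns of the
    observed |d| midranks (zeros dropped)."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))
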