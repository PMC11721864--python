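"""Crossed random-intercepts model for the imaging-system effect.

Model:  y = beta0 + beta1 * x + u_patient + v_observer + eps, with
independent Gaussian random intercepts for patients and observers (crossed:
every observer corrects every patient) and x = 1 for the high-performance
arm, 0 for the conventional arm, so beta1 is reported as (high-performance
minus conventional): a positive DSC coefficient and a negative HD95
coefficient both favour the high-performance system.

Estimation is restricted maximum likelihood (REML): the profiled REML
criterion is minimised over the two variance ratios (sigma2_patient /
sigma2_residual, sigma2_observer / sigma2_residual) on the log scale by
bounded quasi-Newton from several deterministic starts, with all boundary
sub-models (either or both components removed) evaluated explicitly, which
realises truncation of negative variance estimates at zero with refit.

Inference on beta1: for balanced complete tables the package uses the exact
paired-contrast t test on the per-(patient, observer) arm differences, which
has exact size under the model (the behaviour small-sample corrections such
as Kenward-Roger aim to recover); for unbalanced tables a Satterthwaite-type
t test with degrees of freedom from the REML information matrix is used.
Both are available explicitly via the ``inference`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

_LOG_GAMMA_BOUNDS = (np.log(1e-8), np.log(1e8))


@dataclass
class ModelFit:
    beta0: float
    beta1: float
    se_beta1: float            # model-based (GLS) standard error
    t_statistic: float
    df: float
    p_value: float
    sigma2_patient: float
    sigma2_observer: float
    sigma2_residual: float
    reml_loglik: float
    converged: bool
    n_obs: int
    inference: str             # "paired" or "satterthwaite"
    response: str = ""
    organ: str = ""
    degenerate: bool = False
    message: str = ""


def _profiled_criterion(log_gammas, y, Zp, Zo, X, free):
    """-2 * profiled REML log-likelihood (up to a constant) at variance ratios
    gamma = sigma2_component / sigma2_residual; returns (criterion, aux)."""
    n, p = X.shape
    gp = np.exp(log_gammas[free.index("p")]) if "p" in free else 0.0
    go = np.exp(log_gammas[free.index("o")]) if "o" in free else 0.0
    V0 = np.eye(n)
    if gp > 0:
        V0 += gp * (Zp @ Zp.T)
    if go > 0:
        V0 += go * (Zo @ Zo.T)
    L = np.linalg.cholesky(V0)
    Xt = linalg.solve_triangular(L, X, lower=True)
    yt = linalg.solve_triangular(L, y, lower=True)
    XtX = Xt.T @ Xt
    beta = np.linalg.solve(XtX, Xt.T @ yt)
    r = yt - Xt @ beta
    q = float(r @ r)
    logdetV0 = 2.0 * float(np.sum(np.log(np.diag(L))))
    sign, logdetXtX = np.linalg.slogdet(XtX)
    crit = logdetV0 + logdetXtX + (n - p) * np.log(max(q, 1e-300))
    return crit, {"beta": beta, "q": q, "gp": gp, "go": go,
                  "logdetV0": logdetV0, "logdetXtX": logdetXtX, "XtX": XtX}


def _optimize_case(y, Zp, Zo, X, free, starts):
    if not free:
        crit, aux = _profiled_criterion(np.array([]), y, Zp, Zo, X, free)
        return crit, aux, True
    best = None
    ok = False
    for s in starts:
        res = optimize.minimize(
            lambda lg: _profiled_criterion(lg, y, Zp, Zo, X, free)[0],
            x0=np.asarray(s, dtype=float),
            method="L-BFGS-B",
            bounds=[_LOG_GAMMA_BOUNDS] * len(free),
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
        )
        ok = ok or res.success
        if best is None or res.fun < best.fun:
            best = res
    crit, aux = _profiled_criterion(best.x, y, Zp, Zo, X, free)
    return crit, aux, ok


def _balanced_anova_start(y, pat, obs, x):
    """Method-of-moments variance ratios from the balanced three-way EMS
    decomposition; used only to seed the optimiser."""
    a, b = pat.max() + 1, obs.max() + 1
    n = len(y)
    if n != 2 * a * b:
        return None
    gm = y.mean()
    ybar_p = np.array([y[pat == i].mean() for i in range(a)])
    ybar_o = np.array([y[obs == j].mean() for j in range(b)])
    ms_p = 2 * b * np.sum((ybar_p - gm) ** 2) / (a - 1)
    ms_o = 2 * a * np.sum((ybar_o - gm) ** 2) / (b - 1)
    ss_arm = a * b * sum((y[x == lv].mean() - gm) ** 2 for lv in (0, 1))
    ss_tot = np.sum((y - gm) ** 2)
    df_e = 2 * a * b - a - b
    ss_e = ss_tot - 2 * b * np.sum((ybar_p - gm) ** 2) - 2 * a * np.sum((ybar_o - gm) ** 2) - ss_arm
    ms_e = ss_e / df_e
    s2e = max(ms_e, 1e-12)
    s2p = max((ms_p - ms_e) / (2 * b), 0.0)
    s2o = max((ms_o - ms_e) / (2 * a), 0.0)
    return s2p / s2e, s2o / s2e


def fit_crossed_model(table: pd.DataFrame, response: str, organ: str | None = None,
                      inference: str = "auto") -> ModelFit:
    """Fit the crossed random-intercepts model for one organ and one metric.

    Parameters
    ----------
    table : DataFrame with columns patient_id, observer_id, imaging_system and
        the response column; rows with NaN response (missing records) are
        dropped, exercising the unbalanced path.
    response : name of the response column (e.g. "dsc" or "hd95_mm").
    organ : optional organ name to subset on (column "organ").
    inference : "auto" (paired when balanced complete, else Satterthwaite),
        "paired", or "satterthwaite".
    """
    df = table
    if organ is not None:
        df = df[df["organ"] == organ]
    df = df.dropna(subset=[response])
    if df.empty:
        raise ValueError("no usable observations")
    y = df[response].to_numpy(dtype=float)
    pat, pat_levels = pd.factorize(df["patient_id"], sort=True)
    obs, obs_levels = pd.factorize(df["observer_id"], sort=True)
    systems = sorted(df["imaging_system"].unique())
    if len(pat_levels) < 2 or len(obs_levels) < 2:
        raise ValueError("need at least 2 patients and 2 observers")
    if len(systems) != 2:
        raise ValueError("both imaging systems must be present")
    # x = 1 for the high-performance arm (beta1 = high-performance minus conventional)
    x = (df["imaging_system"] == "high_performance").to_numpy(dtype=float)
    if x.sum() == 0:  # labels other than the study's: code the second level as 1
        x = (df["imaging_system"] == systems[1]).to_numpy(dtype=float)
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    Zp = np.eye(len(pat_levels))[pat]
    Zo = np.eye(len(obs_levels))[obs]

    start_ratio = _balanced_anova_start(y, pat, obs, x)
    starts2 = [np.log([0.5, 0.5]), np.log([5.0, 0.2]), np.log([0.05, 0.05])]
    if start_ratio is not None and min(start_ratio) > 0:
        starts2.insert(0, np.log(np.maximum(start_ratio, 1e-6)))
    cases = {
        ("p", "o"): starts2,
        ("p",): [[s[0]] for s in starts2],
        ("o",): [[s[1]] for s in starts2],
        (): [[]],
    }
    results = {}
    converged_any = False
    for free, starts in cases.items():
        crit, aux, ok = _optimize_case(y, Zp, Zo, X, list(free), starts)
        # the moment-estimate point is itself a candidate: under balance it is
        # the exact stationary point of the REML criterion, so taking the
        # arg-min over {optimizer result, moment point} removes the residual
        # optimizer tolerance
        if free == ("p", "o") and start_ratio is not None and min(start_ratio) > 0:
            c2, a2 = _profiled_criterion(np.log(start_ratio), y, Zp, Zo, X, list(free))
            if c2 <= crit:
                crit, aux = c2, a2
                ok = True
        results[free] = (crit, aux, ok)
        converged_any = converged_any or ok or not free
    # prefer the simplest model whose criterion is within numerical tolerance
    # of the best (truncation-at-zero with refit)
    best_crit = min(c for c, _, _ in results.values())
    chosen = min((free for free, (c, _, _) in results.items()
                  if c <= best_crit + 1e-7), key=len)
    crit, aux, ok = results[chosen]

    p = X.shape[1]
    sigma2_e = aux["q"] / (n - p)
    sigma2_p = aux["gp"] * sigma2_e
    sigma2_o = aux["go"] * sigma2_e
    beta = aux["beta"]
    cov_beta = sigma2_e * np.linalg.inv(aux["XtX"])
    se1 = float(np.sqrt(max(cov_beta[1, 1], 0.0)))
    loglik = -0.5 * (crit - (n - p) * np.log(max(aux["q"], 1e-300))
                     + n * np.log(max(sigma2_e, 1e-300))
                     - p * np.log(max(sigma2_e, 1e-300))
                     + aux["q"] / max(sigma2_e, 1e-300)
                     + (n - p) * np.log(2 * np.pi))

    fit = ModelFit(
        beta0=float(beta[0]), beta1=float(beta[1]), se_beta1=se1,
        t_statistic=np.nan, df=np.nan, p_value=np.nan,
        sigma2_patient=float(sigma2_p), sigma2_observer=float(sigma2_o),
        sigma2_residual=float(sigma2_e), reml_loglik=float(loglik),
        converged=bool(converged_any and ok or not chosen), n_obs=n,
        inference="", response=response, organ=organ or "",
        message="" if ok or not chosen else "optimizer did not report convergence",
    )

    balanced = _is_balanced_complete(df)
    mode = inference
    if inference == "auto":
        mode = "paired" if balanced else "satterthwaite"
    if mode == "paired":
        if not balanced:
            raise ValueError("paired inference requires a balanced complete table")
        _paired_inference(fit, df, response)
    elif mode == "satterthwaite":
        _satterthwaite_inference(fit, y, X, Zp, Zo, chosen, aux, sigma2_e)
    else:
        raise ValueError(f"unknown inference mode '{mode}'")
    return fit


def _is_balanced_complete(df: pd.DataFrame) -> bool:
    counts = df.groupby(["patient_id", "observer_id", "imaging_system"], sort=False).size()
    a = df["patient_id"].nunique()
    b = df["observer_id"].nunique()
    return bool((counts == 1).all() and len(counts) == a * b * 2)


def _paired_inference(fit: ModelFit, df: pd.DataFrame, response: str) -> None:
    """Exact paired-contrast t test on per-(patient, observer) arm differences."""
    wide = df.pivot_table(index=["patient_id", "observer_id"],
                          columns="imaging_system", values=response)
    d = (wide["high_performance"] - wide["conventional"]).to_numpy() \
        if "high_performance" in wide.columns else \
        (wide[wide.columns[1]] - wide[wide.columns[0]]).to_numpy()
    m = len(d)
    sd = d.std(ddof=1)
    fit.inference = "paired"
    if sd == 0:
        fit.degenerate = True
        fit.t_statistic = 0.0 if d.mean() == 0 else np.inf
        fit.df = float(m - 1)
        fit.p_value = 1.0 if d.mean() == 0 else 0.0
        fit.message = (fit.message + "; " if fit.message else "") + "zero difference variance"
        return
    t = d.mean() / (sd / np.sqrt(m))
    fit.t_statistic = float(t)
    fit.df = float(m - 1)
    fit.p_value = float(2.0 * stats.t.sf(abs(t), m - 1))


def _satterthwaite_inference(fit: ModelFit, y, X, Zp, Zo, chosen, aux, sigma2_e) -> None:
    """t test with Satterthwaite df from the expected REML information."""
    fit.inference = "satterthwaite"
    n = len(y)
    if sigma2_e <= 1e-14:
        fit.degenerate = True
        fit.t_statistic = np.inf if fit.beta1 != 0 else 0.0
        fit.df = np.nan
        fit.p_value = 0.0 if fit.beta1 != 0 else 1.0
        fit.message = (fit.message + "; " if fit.message else "") + "zero residual variance"
        return
    Vdots = []
    if "p" in chosen:
        Vdots.append(Zp @ Zp.T)
    if "o" in chosen:
        Vdots.append(Zo @ Zo.T)
    Vdots.append(np.eye(n))
    V = sigma2_e * np.eye(n)
    if "p" in chosen:
        V = V + fit.sigma2_patient * (Zp @ Zp.T)
    if "o" in chosen:
        V = V + fit.sigma2_observer * (Zo @ Zo.T)
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    C = np.linalg.inv(XtVi @ X)
    P = Vi - XtVi.T @ C @ XtVi
    k = len(Vdots)
    info = np.empty((k, k))
    PV = [P @ Vd for Vd in Vdots]
    for i in range(k):
        for j in range(i, k):
            info[i, j] = info[j, i] = 0.5 * np.trace(PV[i] @ PV[j])
    var_beta1 = C[1, 1]
    g = np.array([(C @ (XtVi @ Vd @ XtVi.T) @ C)[1, 1] for Vd in Vdots])
    try:
        denom = float(g @ np.linalg.solve(info, g))
    except np.linalg.LinAlgError:
        denom = np.nan
    df = 2.0 * var_beta1 ** 2 / denom if denom and denom > 0 else np.nan
    se = float(np.sqrt(var_beta1))
    t = fit.beta1 / se
    fit.se_beta1 = se
    fit.t_statistic = float(t)
    fit.df = float(df)
    if np.isfinite(df) and df > 0:
        fit.p_value = float(2.0 * stats.t.sf(abs(t), df))
    else:
        fit.degenerate = True
        fit.p_value = float(2.0 * stats.norm.sf(abs(t)))
        fit.message = (fit.message + "; " if fit.message else "") + "df unavailable, normal fallback"


def reml_variance_components(y: np.ndarray, pat_codes: np.ndarray,
                             obs_codes: np.ndarray) -> tuple[float, float, float]:
    """REML (patient, observer, residual) variance components for
    y = mu + u_patient + v_observer + eps on possibly unbalanced data.

    Utility for the ICC module's unbalanced fallback; truncation at zero is
    realised by explicit boundary sub-models, as in :func:`fit_crossed_model`.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.ones((n, 1))
    Zp = np.eye(int(pat_codes.max()) + 1)[pat_codes]
    Zo = np.eye(int(obs_codes.max()) + 1)[obs_codes]
    starts2 = [np.log([0.5, 0.5]), np.log([5.0, 0.2]), np.log([0.05, 0.05])]
    cases = {("p", "o"): starts2, ("p",): [[s[0]] for s in starts2],
             ("o",): [[s[1]] for s in starts2], (): [[]]}
    results = {}
    for free, starts in cases.items():
        crit, aux, _ = _optimize_case(y, Zp, Zo, X, list(free), starts)
        results[free] = (crit, aux)
    best_crit = min(c for c, _ in results.values())
    chosen = min((f for f, (c, _) in results.items() if c <= best_crit + 1e-7), key=len)
    _, aux = results[chosen]
    s2e = aux["q"] / (n - 1)
    return float(aux["gp"] * s2e), float(aux["go"] * s2e), float(s2e)


def test_fixed_effect(fit: ModelFit) -> dict:
    """Package the imaging-system test from a fitted model."""
    if not fit.converged:
        raise ValueError(f"cannot test a non-converged fit: {fit.message}")
    return {"t_statistic": fit.t_statistic, "df": fit.df, "p_value": fit.p_value,
            "inference": fit.inference, "degenerate": fit.degenerate}
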