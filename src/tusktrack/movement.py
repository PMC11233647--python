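"""Time-varying move persistence and its environmental mixed models.

The move-persistence index gamma_t in (0, 1) measures the autocorrelation of
successive displacements of a regularized track: values near 1 mean directed
transit, values near 0 mean uncorrelated, area-restricted movement. The
latent model is a first-difference correlated random walk

    d_t = gamma_t * d_{t-1} + eps_t,      eps_t ~ N(0, sigma^2 I_2),

where d_t is the planar displacement over step t, with logit(gamma_t)
evolving as a Gaussian random walk of variance sigma_g^2. Estimation
maximizes the penalized likelihood over the logit-scale path (equivalent to
the posterior mode of the latent walk), with sigma profiled in closed form
and sigma_g chosen by a Laplace-approximate marginal likelihood over a grid.

Estimated gamma_t values, annotated with ice concentration and log-depth,
feed a linear mixed model on the logit scale with per-individual random
intercepts/slopes, fitted by maximum likelihood (statsmodels MixedLM) and
ranked by AIC across the candidate formula set.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cholesky_banded
import statsmodels.api as sm

from .preprocess import RegularTrack

GAMMA_EPS = 1e-9
SIGMA_G_GRID = np.exp(np.linspace(np.log(0.02), np.log(2.0), 8))
SIGMA_G_FLOOR = 1e-6


def _logistic(g):
    return 1.0 / (1.0 + np.exp(-g))


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def _penalized_path(d_prev, d_curr, sigma_g, n_outer=4):
    """Posterior-mode logit(gamma) path and profiled sigma for one segment.

    d_prev, d_curr: (T, 2) arrays of consecutive displacement pairs.
    Returns (g_path, sigma, laplace_marginal_loglik).
    """
    T = d_curr.shape[0]
    a2 = np.einsum("ij,ij->i", d_prev, d_prev)          # |d_{t-1}|^2
    cross = np.einsum("ij,ij->i", d_prev, d_curr)       # d_{t-1} . d_t
    b2 = np.einsum("ij,ij->i", d_curr, d_curr)

    g = np.zeros(T)
    sigma2 = max(float(np.mean(b2)) / 2.0, 1e-12)

    def obj(g, sigma2):
        gam = _logistic(g)
        resid = b2 - 2.0 * gam * cross + gam * gam * a2
        nll = resid.sum() / (2.0 * sigma2)
        pen = np.diff(g)
        nll += (pen @ pen) / (2.0 * sigma_g ** 2)
        dgam = gam * (1.0 - gam)
        grad = (2.0 * gam * a2 - 2.0 * cross) * dgam / (2.0 * sigma2)
        grad[:-1] -= pen / sigma_g ** 2
        grad[1:] += pen / sigma_g ** 2
        return nll, grad

    for _ in range(n_outer):
        res = optimize.minimize(obj, g, args=(sigma2,), jac=True,
                                method="L-BFGS-B",
                                options={"maxiter": 500, "ftol": 1e-12})
        g = res.x
        gam = _logistic(g)
        resid = b2 - 2.0 * gam * cross + gam * gam * a2
        sigma2 = max(float(resid.sum()) / (2.0 * T), 1e-12)

    # Laplace-approximate marginal likelihood for sigma_g selection.
    gam = _logistic(g)
    resid = b2 - 2.0 * gam * cross + gam * gam * a2
    loglik_obs = -resid.sum() / (2.0 * sigma2) - T * np.log(2.0 * np.pi * sigma2)
    pen = np.diff(g)
    logprior = (-(pen @ pen) / (2.0 * sigma_g ** 2)
                - 0.5 * (T - 1) * np.log(2.0 * np.pi * sigma_g ** 2))
    # Gauss-Newton Hessian of the negative joint: diagonal obs + RW tridiagonal
    dgam = gam * (1.0 - gam)
    diag = (dgam ** 2) * a2 / sigma2
    diag_rw = np.full(T, 2.0 / sigma_g ** 2)
    diag_rw[0] = diag_rw[-1] = 1.0 / sigma_g ** 2
    ab = np.zeros((2, T))
    ab[0, 1:] = -1.0 / sigma_g ** 2
    ab[1] = diag + diag_rw
    try:
        cb = cholesky_banded(ab, lower=False)
        logdet_h = 2.0 * np.log(cb[1]).sum()
    except np.linalg.LinAlgError:
        logdet_h = np.inf
    marginal = loglik_obs + logprior + 0.5 * T * np.log(2.0 * np.pi) - 0.5 * logdet_h
    return g, np.sqrt(sigma2), marginal


def estimate_move_persistence(track: RegularTrack,
                              sigma_g_grid=SIGMA_G_GRID) -> pd.DataFrame:
    """Estimate gamma_t for every within-segment step of a regular track.

    Returns a frame (id, timestamp, segment, gamma) with one row per step
    that has a preceding step in the same segment (gamma for step t uses the
    displacement pair ending at position t+1). Segments with fewer than 4
    positions, or with essentially no movement, yield NaN gamma flagged rows.
    """
    out = []
    for seg_id, seg in track.segments():
        x = seg["x"].to_numpy()
        y = seg["y"].to_numpy()
        t = seg["timestamp"].to_numpy()
        if len(x) < 4:
            continue
        d = np.column_stack([np.diff(x), np.diff(y)])
        d_prev, d_curr = d[:-1], d[1:]
        move_scale = float(np.hypot(d[:, 0], d[:, 1]).mean())
        if move_scale < 1e-6:
            gam = np.full(len(d_curr), np.nan)
        else:
            best = (None, -np.inf)
            for sg in np.maximum(np.asarray(sigma_g_grid), SIGMA_G_FLOOR):
                g, sigma, marg = _penalized_path(d_prev, d_curr, sg)
                if marg > best[1]:
                    best = (g, marg)
            gam = np.clip(_logistic(best[0]), GAMMA_EPS, 1.0 - GAMMA_EPS)
        out.append(pd.DataFrame({
            "id": seg["id"].iloc[0] if "id" in seg else "",
            "timestamp": t[1:-1],
            "segment": seg_id,
            "gamma": gam,
        }))
    if not out:
        raise ValueError("no segment with at least 4 positions")
    return pd.concat(out, ignore_index=True)


# --------------------------------------------------------------------------
# mixed models on logit(gamma)
# --------------------------------------------------------------------------

DEFAULT_CANDIDATES = (
    "~ ice * depth + (depth | id)",
    "~ ice + depth + (ice + depth | id)",
    "~ ice * depth + (1 | id)",
    "~ ice + depth + (ice | id)",
    "~ depth + (depth | id)",
    "~ depth + (1 | id)",
    "~ ice + (1 | id)",
    "~ ice + (ice | id)",
    "~ 1 + (1 | id)",
)

_FORMULA_RE = re.compile(r"^\s*~\s*(?P<fixed>[^(]+?)\s*\+\s*\(\s*(?P<re>[^|]+?)\s*\|\s*id\s*\)\s*$")


@dataclass
class MpmmFit:
    formula: str
    coefficients: pd.DataFrame    # term, estimate, se, ci_low, ci_high
    loglik: float
    aic: float
    df: int
    converged: bool
    result: object = None


def _parse_formula(formula: str):
    m = _FORMULA_RE.match(formula)
    if not m:
        raise ValueError(f"cannot parse model formula {formula!r}")
    fixed = [t.strip() for t in m.group("fixed").split("+")]
    if fixed == ["ice * depth"] or "ice * depth" in m.group("fixed"):
        fixed = ["ice", "depth", "ice:depth"]
    fixed = [t for t in fixed if t != "1"]
    rand = [t.strip() for t in m.group("re").split("+")]
    rand = [t for t in rand if t != "1"]
    return fixed, rand


def prepare_covariates(series: pd.DataFrame, depth_floor_m: float = 1.0
                       ) -> pd.DataFrame:
    """Scale covariates for modelling: ice to [0, 1], depth to log-metres
    (floored at 1 m), and gamma to the logit scale."""
    df = series.dropna(subset=["gamma", "ice_pct", "depth_m"]).copy()
    df["ice"] = df["ice_pct"] / 100.0
    df["depth"] = np.log(np.maximum(df["depth_m"], depth_floor_m))
    df["logit_gamma"] = logit(np.clip(df["gamma"], 1e-6, 1 - 1e-6))
    return df


def fit_mpmm(data: pd.DataFrame, formula: str) -> MpmmFit:
    """ML fit of logit(gamma) ~ fixed + (random | id).

    ``data`` needs columns logit_gamma, ice, depth, id (see
    :func:`prepare_covariates`). Fixed terms may include ice, depth and
    ice:depth; random terms are an intercept plus optional ice/depth slopes
    per individual.
    """
    fixed, rand = _parse_formula(formula)
    exog = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
    for term in fixed:
        if term == "ice:depth":
            exog[term] = data["ice"] * data["depth"]
        else:
            exog[term] = data[term]
    exog_re = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
    for term in rand:
        exog_re[term] = data[term]
    model = sm.MixedLM(data["logit_gamma"], exog, groups=data["id"],
                       exog_re=exog_re)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=False)
            if not (res.converged and np.isfinite(res.llf)):
                res = model.fit(reml=False, method="lbfgs")
            converged = bool(res.converged) and bool(np.isfinite(res.llf))
        except Exception:
            return MpmmFit(formula, pd.DataFrame(), -np.inf, np.inf, 0, False)
    k = exog.shape[1] + exog_re.shape[1] * (exog_re.shape[1] + 1) // 2 + 1
    aic = 2.0 * k - 2.0 * res.llf
    fe = res.fe_params
    se = res.bse_fe
    ci = res.conf_int().loc[fe.index]
    table = pd.DataFrame({
        "term": fe.index, "estimate": fe.to_numpy(), "se": se.to_numpy(),
        "ci_low": ci[0].to_numpy(), "ci_high": ci[1].to_numpy(),
    }).reset_index(drop=True)
    return MpmmFit(formula, table, float(res.llf), float(aic), int(k),
                   converged, res)


def rank_models(data: pd.DataFrame,
                candidates=DEFAULT_CANDIDATES) -> pd.DataFrame:
    """Fit all candidate formulas, drop non-converged fits, rank by AIC.

    Returns (formula, df, dAIC, dLR, converged) sorted by dAIC; dLR is twice
    the log-likelihood gap to the best model.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate models")
    fits = [fit_mpmm(data, f) for f in candidates]
    rows = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if not rows:
        raise RuntimeError(
            "no candidate model converged; log-likelihoods: "
            + ", ".join(f"{f.formula}: {f.loglik:.2f}" for f in fits)
        )
    best_aic = min(f.aic for f in rows)
    best_llf = max(f.loglik for f in rows)
    table = pd.DataFrame({
        "formula": [f.formula for f in rows],
        "df": [f.df for f in rows],
        "dAIC": [f.aic - best_aic for f in rows],
        "dLR": [2.0 * (best_llf - f.loglik) for f in rows],
        "converged": [f.converged for f in rows],
    }).sort_values("dAIC", kind="stable").reset_index(drop=True)
    return table
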