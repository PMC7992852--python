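"""Single-mediator path analysis: intervention -> ASI -> outcome.

Estimates the covariate-adjusted path coefficients of the standard
product-of-coefficients mediation model on a pooled two-trial dataset:

* a-path   : M_w ~ group + M_0 + study
* b, c'    : Y_w ~ group + M_w + [covariates per scheme]
* c (total): Y_w ~ group + Y_0 + study
* AB = a*b ; proportion mediated = 100 * AB / c

The mediated effect's 95% interval is a bias-corrected (BC, no
acceleration) bootstrap over whole participants, with type-6 empirical
quantiles.  Missing follow-ups are handled either by per-model complete
cases or by full-information maximum likelihood (FIML) on the joint
Gaussian of (M_0, Y_0, M_w, Y_w) given group and study.

Covariate schemes for the b/c' model:

* ``"table_footnote"`` (default): baseline mediator + baseline outcome + study.
* ``"methods_text"``: baseline outcome + study only.
* ``"matched"``: every model shares the covariate set {M_0, Y_0, study}, the
  configuration under which c = c' + a*b holds as an exact OLS identity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import ndtr, ndtri
from scipy.stats import norm

logger = logging.getLogger(__name__)

SCHEMES = ("table_footnote", "methods_text", "matched")

#: proportion mediated is unstable when the total effect is near zero
C_TOTAL_FLOOR = 1e-8


class MediationError(ValueError):
    pass


@dataclass(frozen=True)
class MediationSpec:
    mediator: str = "asi12"
    outcome: str = "dass_depression"
    wave: int = 3
    scheme: str = "table_footnote"
    boot: int = 5000
    confidence: float = 0.95
    seed: int | None = None
    missing: str = "fiml"  # "fiml" | "complete"

    def __post_init__(self) -> None:
        if self.wave not in (3, 6):
            raise MediationError("wave must be 3 or 6")
        if self.scheme not in SCHEMES:
            raise MediationError(f"unknown covariate scheme {self.scheme!r}")
        if self.boot < 1:
            raise MediationError("bootstrap replicates must be >= 1")
        if not 0.0 < self.confidence < 1.0:
            raise MediationError("confidence must be in (0, 1)")
        if self.missing not in ("fiml", "complete"):
            raise MediationError("missing must be 'fiml' or 'complete'")


@dataclass
class PathEstimates:
    a: float
    a_se: float
    b: float
    b_se: float
    c_prime: float
    c_prime_se: float
    c_total: float
    c_total_se: float
    ab: float
    ab_se: float | None = None
    ab_ci: tuple[float, float] | None = None
    proportion_mediated: float | None = None
    n_a: int = 0
    n_bc: int = 0
    n_c: int = 0
    method: str = "complete"

    def pvalues(self) -> dict[str, float]:
        """Large-sample z-test p-values for the individual paths."""
        out = {}
        for name, est, se in (
            ("a", self.a, self.a_se),
            ("b", self.b, self.b_se),
            ("c_prime", self.c_prime, self.c_prime_se),
            ("c_total", self.c_total, self.c_total_se),
        ):
            out[name] = float(2.0 * norm.sf(abs(est / se))) if se and se > 0 else np.nan
        return out


# ---------------------------------------------------------------------------
# OLS engine


def fit_linear_model(X: pd.DataFrame, y: pd.Series):
    """OLS with an explicit full-rank check.

    ``X`` must already contain its intercept column.  Rows with any missing
    value are excluded (complete-case engine).  Rank deficiency raises an
    error naming the collinear columns.
    """
    data = pd.concat([X, y.rename("__y__")], axis=1).dropna()
    if data.empty:
        raise MediationError("no usable rows after dropping missing values")
    Xc = data[X.columns].astype(float)
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        bad = _collinear_columns(Xc)
        raise MediationError(f"design matrix is rank deficient; collinear columns: {bad}")
    model = sm.OLS(data["__y__"].astype(float), Xc)
    return model.fit()


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    bad = []
    cols = list(X.columns)
    for i in range(1, len(cols) + 1):
        sub = X[cols[:i]].to_numpy()
        if np.linalg.matrix_rank(sub) < i - len(bad):
            bad.append(cols[i - 1])
    return bad or cols[-1:]


# ---------------------------------------------------------------------------
# wide layout

WIDE_COLS = ("group", "study", "m0", "y0", "mw", "yw")


def make_wide(data: pd.DataFrame, spec: MediationSpec) -> pd.DataFrame:
    """Pivot the long participant-by-wave table into one row per participant."""
    for col in ("pid", "wave", "group", "trial", spec.mediator, spec.outcome):
        if col not in data.columns:
            raise MediationError(f"dataset missing required column {col!r}")
    base = data[data["wave"] == 0].set_index("pid")
    fw = data[data["wave"] == spec.wave].set_index("pid")
    if base.empty or fw.empty:
        raise MediationError(f"no rows for baseline or wave {spec.wave}")
    fw = fw.reindex(base.index)
    trials = sorted(base["trial"].unique())
    wide = pd.DataFrame(
        {
            "group": base["group"].astype(float),
            "study": (base["trial"] == trials[-1]).astype(float) if len(trials) > 1 else 0.0,
            "m0": pd.to_numeric(base[spec.mediator], errors="coerce"),
            "y0": pd.to_numeric(base[spec.outcome], errors="coerce"),
            "mw": pd.to_numeric(fw[spec.mediator], errors="coerce"),
            "yw": pd.to_numeric(fw[spec.outcome], errors="coerce"),
        }
    )
    if wide[["group", "m0", "y0"]].isna().any().any():
        raise MediationError("baseline values or group indicator contain missing data")
    return wide


def _model_columns(spec: MediationSpec) -> dict[str, list[str]]:
    if spec.scheme == "table_footnote":
        return {"a": ["m0", "study"], "bc": ["m0", "y0", "study"], "c": ["y0", "study"]}
    if spec.scheme == "methods_text":
        return {"a": ["m0", "study"], "bc": ["y0", "study"], "c": ["y0", "study"]}
    return {"a": ["m0", "y0", "study"], "bc": ["m0", "y0", "study"], "c": ["m0", "y0", "study"]}


# ---------------------------------------------------------------------------
# complete-case estimation


def estimate_paths(data: pd.DataFrame, spec: MediationSpec) -> PathEstimates:
    """Point estimates of a, b, c', c, AB via per-model complete-case OLS.

    ``data`` may be the long table (pivoted internally) or an already-wide
    table with columns group/study/m0/y0/mw/yw.
    """
    wide = data if set(WIDE_COLS).issubset(data.columns) else make_wide(data, spec)
    cols = _model_columns(spec)

    def run(response: str, predictors: list[str]):
        X = wide[predictors].copy()
        X.insert(0, "const", 1.0)
        return fit_linear_model(X, wide[response])

    fit_a = run("mw", ["group"] + cols["a"])
    fit_bc = run("yw", ["group", "mw"] + cols["bc"])
    fit_c = run("yw", ["group"] + cols["c"])

    a, b = float(fit_a.params["group"]), float(fit_bc.params["mw"])
    c_prime, c_total = float(fit_bc.params["group"]), float(fit_c.params["group"])
    ab = a * b
    ab_se = float(np.sqrt(a**2 * fit_bc.bse["mw"] ** 2 + b**2 * fit_a.bse["group"] ** 2))
    return PathEstimates(
        a=a,
        a_se=float(fit_a.bse["group"]),
        b=b,
        b_se=float(fit_bc.bse["mw"]),
        c_prime=c_prime,
        c_prime_se=float(fit_bc.bse["group"]),
        c_total=c_total,
        c_total_se=float(fit_c.bse["group"]),
        ab=ab,
        ab_se=ab_se,
        proportion_mediated=proportion_mediated(ab, c_total),
        n_a=int(fit_a.nobs),
        n_bc=int(fit_bc.nobs),
        n_c=int(fit_c.nobs),
        method="complete",
    )


def proportion_mediated(ab: float, c_total: float) -> float | None:
    """100 * AB / c, reported only when the total effect is meaningfully nonzero."""
    if abs(c_total) <= C_TOTAL_FLOOR:
        return None
    if np.sign(ab) != np.sign(c_total):
        logger.info("AB and total effect have opposite signs; proportion mediated is unstable")
    return float(100.0 * ab / c_total)


# ---------------------------------------------------------------------------
# fast ab for the bootstrap


def _ab_arrays(wide: pd.DataFrame, spec: MediationSpec):
    cols = _model_columns(spec)
    g = wide["group"].to_numpy(float)
    arrays = {c: wide[c].to_numpy(float) for c in ("study", "m0", "y0", "mw", "yw")}
    Xa = np.column_stack([np.ones_like(g), g] + [arrays[c] for c in cols["a"]])
    Xb = np.column_stack([np.ones_like(g), g, arrays["mw"]] + [arrays[c] for c in cols["bc"]])
    return Xa, arrays["mw"], Xb, arrays["yw"]


def _ab_point(Xa, mw, Xb, yw, idx=None) -> float:
    if idx is not None:
        Xa, mw, Xb, yw = Xa[idx], mw[idx], Xb[idx], yw[idx]
    ok_a = ~np.isnan(mw)
    Aa = Xa[ok_a]
    beta_a = np.linalg.solve(Aa.T @ Aa, Aa.T @ mw[ok_a])
    ok_b = ~(np.isnan(yw) | np.isnan(Xb).any(axis=1))
    Ab = Xb[ok_b]
    beta_b = np.linalg.solve(Ab.T @ Ab, Ab.T @ yw[ok_b])
    return float(beta_a[1] * beta_b[2])  # a = coef on group, b = coef on mw


def bc_bootstrap_ci(
    data: pd.DataFrame,
    spec: MediationSpec,
    *,
    rng: np.random.Generator | None = None,
    estimator=None,
) -> tuple[float, float]:
    """Bias-corrected bootstrap interval for the mediated effect AB.

    Whole participants are resampled with replacement (both trials pooled,
    no stratification), AB recomputed each time, and the percentile
    endpoints shifted by the bias-correction constant
    ``z0 = ndtri(#{AB* < AB_hat} / B)`` (ties at AB_hat counted half below).
    """
    wide = data if set(WIDE_COLS).issubset(data.columns) else make_wide(data, spec)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = len(wide)
    if estimator is None:
        Xa, mw, Xb, yw = _ab_arrays(wide, spec)
        ab_hat = _ab_point(Xa, mw, Xb, yw)
        draws = np.empty(spec.boot)
        for i in range(spec.boot):
            draws[i] = _ab_point(Xa, mw, Xb, yw, idx=rng.integers(0, n, n))
    else:
        ab_hat = estimator(wide)
        draws = np.empty(spec.boot)
        for i in range(spec.boot):
            draws[i] = estimator(wide.iloc[rng.integers(0, n, n)])
    return bc_interval(draws, ab_hat, spec.confidence)


def bc_interval(draws: np.ndarray, point: float, confidence: float) -> tuple[float, float]:
    """BC percentile endpoints from a bootstrap sample of the statistic."""
    draws = np.asarray(draws, float)
    B = len(draws)
    if B == 1:
        return float(draws[0]), float(draws[0])
    if np.all(draws == draws[0]):
        warnings.warn("all bootstrap replicates identical; degenerate interval")
        return float(draws[0]), float(draws[0])
    prop = (np.sum(draws < point) + 0.5 * np.sum(draws == point)) / B
    if prop <= 0.0 or prop >= 1.0:
        raise MediationError(
            "all bootstrap replicates fall on one side of the point estimate; "
            "increase the number of bootstrap samples"
        )
    z0 = ndtri(prop)
    z_crit = ndtri((1.0 + confidence) / 2.0)
    p_lo = ndtr(2.0 * z0 - z_crit)
    p_hi = ndtr(2.0 * z0 + z_crit)
    lo = float(np.quantile(draws, p_lo, method="weibull"))
    hi = float(np.quantile(draws, p_hi, method="weibull"))
    return lo, hi


# ---------------------------------------------------------------------------
# FIML

_VARS = ("m0", "y0", "mw", "yw")


def _em_mvn(V: np.ndarray, X: np.ndarray, *, tol: float = 1e-10, max_iter: int = 2000):
    """ML estimation of V = X B + E, E ~ N(0, Sigma), with missing entries in V.

    EM over missingness patterns; every row of X must be complete.  Returns
    (B, Sigma, loglik).  With complete data the first M-step already lands on
    the multivariate-OLS MLE.
    """
    n, p = V.shape
    k = X.shape[1]
    obs = ~np.isnan(V)
    if not obs.any(axis=1).all():
        # rows with nothing observed carry no information
        keep = obs.any(axis=1)
        V, X, obs = V[keep], X[keep], obs[keep]
        n = len(V)
    # start from available-case moments
    Vfill = np.where(obs, V, 0.0)
    counts = obs.sum(axis=0).astype(float)
    means = Vfill.sum(axis=0) / np.maximum(counts, 1.0)
    B = np.zeros((k, p))
    B[0] = means
    resid = np.where(obs, V - means, 0.0)
    Sigma = (resid.T @ resid) / n + np.eye(p) * 1e-3
    # complete-case OLS start when enough complete rows (spec'd starting values)
    complete = obs.all(axis=1)
    if complete.sum() > k + p:
        Xc, Vc = X[complete], V[complete]
        B = np.linalg.lstsq(Xc, Vc, rcond=None)[0]
        R = Vc - Xc @ B
        Sigma = (R.T @ R) / complete.sum()

    patterns: dict[bytes, np.ndarray] = {}
    for key in np.unique(obs, axis=0):
        patterns[key.tobytes()] = np.where((obs == key).all(axis=1))[0]

    XtX = X.T @ X
    ll_old = -np.inf
    for _ in range(max_iter):
        mu = X @ B
        EV = np.array(V)
        S_corr = np.zeros((p, p))
        ll = 0.0
        for key, rows in patterns.items():
            mask = np.frombuffer(key, dtype=bool)
            o = np.where(mask)[0]
            m = np.where(~mask)[0]
            Soo = Sigma[np.ix_(o, o)]
            L = np.linalg.cholesky(Soo)
            diff = V[np.ix_(rows, o)] - mu[np.ix_(rows, o)]
            solved = np.linalg.solve(L, diff.T)
            ll += -0.5 * (
                len(rows) * (len(o) * np.log(2 * np.pi) + 2 * np.sum(np.log(np.diag(L))))
                + np.sum(solved**2)
            )
            if len(m):
                Smo = Sigma[np.ix_(m, o)]
                W = np.linalg.solve(Soo, Smo.T).T  # regression of missing on observed
                cond_mean = mu[np.ix_(rows, m)] + diff @ W.T
                EV[np.ix_(rows, m)] = cond_mean
                cond_cov = Sigma[np.ix_(m, m)] - W @ Smo.T
                C = np.zeros((p, p))
                C[np.ix_(m, m)] = cond_cov
                S_corr += len(rows) * C
        B_new = np.linalg.solve(XtX, X.T @ EV)
        R = EV - X @ B_new
        Sigma_new = (R.T @ R + S_corr) / n
        B, Sigma = B_new, Sigma_new
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            break
        ll_old = ll
    else:
        raise MediationError(f"FIML EM did not converge (last log-likelihood change {ll - ll_old:.3e})")
    return B, Sigma, ll


def _mvn_negloglik(theta: np.ndarray, V: np.ndarray, X: np.ndarray, p: int, k: int) -> float:
    B = theta[: k * p].reshape(k, p)
    L = np.zeros((p, p))
    tril = np.tril_indices(p)
    L[tril] = theta[k * p :]
    L[np.diag_indices(p)] = np.exp(np.diag(L))
    Sigma = L @ L.T
    mu = X @ B
    obs = ~np.isnan(V)
    nll = 0.0
    for key in np.unique(obs, axis=0):
        rows = np.where((obs == key).all(axis=1))[0]
        o = np.where(key)[0]
        Soo = Sigma[np.ix_(o, o)]
        try:
            Lc = np.linalg.cholesky(Soo)
        except np.linalg.LinAlgError:
            return np.inf
        diff = V[np.ix_(rows, o)] - mu[np.ix_(rows, o)]
        solved = np.linalg.solve(Lc, diff.T)
        nll += 0.5 * (
            len(rows) * (len(o) * np.log(2 * np.pi) + 2 * np.sum(np.log(np.diag(Lc))))
            + np.sum(solved**2)
        )
    return float(nll)


def _theta_from(B: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    p = Sigma.shape[0]
    L = np.linalg.cholesky(Sigma)
    Lp = np.array(L)
    Lp[np.diag_indices(p)] = np.log(np.diag(L))
    return np.concatenate([B.ravel(), Lp[np.tril_indices(p)]])


def _paths_from_moments(B: np.ndarray, Sigma: np.ndarray, spec: MediationSpec) -> dict[str, float]:
    """Path coefficients implied by the joint-Gaussian MLE.

    Conditioning a subset of (m0, y0, mw, yw) out of the joint model
    reproduces, at the MLE, exactly the OLS coefficients of the
    corresponding regression when the data are complete.
    """
    idx = {v: i for i, v in enumerate(_VARS)}
    cols = _model_columns(spec)

    def implied(response: str, conditioning: list[str], want: str | None = None):
        c = [idx[v] for v in conditioning if v in idx]  # "study" handled via B
        r = idx[response]
        if c:
            beta = np.linalg.solve(Sigma[np.ix_(c, c)], Sigma[c, r])
        else:
            beta = np.zeros(0)
        g_coef = B[1, r] - beta @ B[1, c] if c else B[1, r]
        slopes = dict(zip([(_VARS[i]) for i in c], beta))
        return float(g_coef), slopes

    a, _ = implied("mw", cols["a"])
    c_prime, slopes = implied("yw", ["mw"] + cols["bc"])
    b = slopes["mw"]
    c_total, _ = implied("yw", cols["c"])
    return {"a": a, "b": float(b), "c_prime": c_prime, "c_total": c_total, "ab": a * float(b)}


def fiml_fit(
    data: pd.DataFrame,
    spec: MediationSpec,
    *,
    compute_se: bool = True,
) -> PathEstimates:
    """Full-information ML path estimates using every observed wave.

    Missingness may affect the wave-3/6 mediator and outcome only; group,
    study and baseline values must be complete.  With zero missingness the
    estimates equal the complete-case OLS estimates exactly.
    """
    wide = data if set(WIDE_COLS).issubset(data.columns) else make_wide(data, spec)
    V = wide[list(_VARS)].to_numpy(float)
    X = np.column_stack([np.ones(len(wide)), wide["group"].to_numpy(float), wide["study"].to_numpy(float)])
    if np.isnan(X).any() or np.isnan(V[:, :2]).any():
        raise MediationError("FIML requires complete baseline values and covariates")
    B, Sigma, _ = _em_mvn(V, X)
    eigmin = np.linalg.eigvalsh(Sigma).min()
    if eigmin <= 0:
        raise MediationError("implied covariance is not positive definite")
    paths = _paths_from_moments(B, Sigma, spec)

    ses = {k: np.nan for k in ("a", "b", "c_prime", "c_total", "ab")}
    if compute_se:
        ses = _fiml_ses(B, Sigma, V, X, spec)

    ab = paths["ab"]
    # proportion mediated is only worth flagging on the primary fit, not on
    # the thousands of silent bootstrap refits
    prop = proportion_mediated(ab, paths["c_total"]) if compute_se else None
    return PathEstimates(
        a=paths["a"], a_se=ses["a"],
        b=paths["b"], b_se=ses["b"],
        c_prime=paths["c_prime"], c_prime_se=ses["c_prime"],
        c_total=paths["c_total"], c_total_se=ses["c_total"],
        ab=ab, ab_se=ses["ab"],
        proportion_mediated=prop,
        n_a=int(len(wide)), n_bc=int(len(wide)), n_c=int(len(wide)),
        method="fiml",
    )


def _fiml_ses(B, Sigma, V, X, spec) -> dict[str, float]:
    """Delta-method SEs from the numerical observed information."""
    p, k = Sigma.shape[0], X.shape[1]
    theta = _theta_from(B, Sigma)
    d = len(theta)
    h = 1e-4 * np.maximum(np.abs(theta), 1.0)

    def f(t):
        return _mvn_negloglik(t, V, X, p, k)

    H = np.empty((d, d))
    for i in range(d):
        for j in range(i, d):
            ti = np.array(theta)
            tj = np.array(theta)
            tij = np.array(theta)
            ti[i] += h[i]
            tj[j] += h[j]
            tij[i] += h[i]
            tij[j] += h[j]
            H[i, j] = H[j, i] = (f(tij) - f(ti) - f(tj) + f(theta)) / (h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return {key: np.nan for key in ("a", "b", "c_prime", "c_total", "ab")}

    def path_vec(t):
        Bt = t[: k * p].reshape(k, p)
        L = np.zeros((p, p))
        L[np.tril_indices(p)] = t[k * p :]
        L[np.diag_indices(p)] = np.exp(np.diag(L))
        pa = _paths_from_moments(Bt, L @ L.T, spec)
        return np.array([pa["a"], pa["b"], pa["c_prime"], pa["c_total"], pa["ab"]])

    G = np.empty((5, d))
    for i in range(d):
        tp = np.array(theta)
        tm = np.array(theta)
        tp[i] += h[i]
        tm[i] -= h[i]
        G[:, i] = (path_vec(tp) - path_vec(tm)) / (2 * h[i])
    var = np.einsum("id,de,ie->i", G, cov, G)
    var = np.where(var > 0, var, np.nan)
    keys = ("a", "b", "c_prime", "c_total", "ab")
    return dict(zip(keys, np.sqrt(var)))


# ---------------------------------------------------------------------------
# interaction check and top-level driver


def interaction_check(data: pd.DataFrame, spec: MediationSpec) -> dict[str, float]:
    """Test the no exposure-mediator interaction assumption.

    Augments the outcome model with a group x mediator product term and
    returns its coefficient, SE and p-value.
    """
    wide = data if set(WIDE_COLS).issubset(data.columns) else make_wide(data, spec)
    cols = _model_columns(spec)["bc"]
    X = wide[["group", "mw"] + cols].copy()
    X["group_x_mw"] = X["group"] * X["mw"]
    X.insert(0, "const", 1.0)
    fit = fit_linear_model(X, wide["yw"])
    return {
        "coef": float(fit.params["group_x_mw"]),
        "se": float(fit.bse["group_x_mw"]),
        "pvalue": float(fit.pvalues["group_x_mw"]),
        "n": int(fit.nobs),
    }


def mediate(data: pd.DataFrame, spec: MediationSpec) -> PathEstimates:
    """Full mediation analysis: point estimates plus BC bootstrap CI for AB."""
    wide = data if set(WIDE_COLS).issubset(data.columns) else make_wide(data, spec)
    if spec.missing == "fiml":
        est = fiml_fit(wide, spec)
        estimator = lambda w: fiml_fit(w, spec, compute_se=False).ab  # noqa: E731
        ci = bc_bootstrap_ci(wide, spec, estimator=estimator)
    else:
        est = estimate_paths(wide, spec)
        ci = bc_bootstrap_ci(wide, spec)
    est.ab_ci = ci
    return est
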