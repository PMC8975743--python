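"""Association models: proportional-odds, logistic, and random-intercept fits.

The statistical battery mirrors a patient-reported pharmacogenomic
association study:

* 3-level ordinal treatment efficacy — cumulative-logit
  (proportional-odds) regression, ``logit P(y <= k) = theta_k - x beta``;
* binary discontinuation-due-to-side-effects and any-side-effect —
  logistic regression;
* analyses pooled across drugs — the same likelihoods with a
  participant-level random intercept integrated out by adaptive
  Gauss–Hermite quadrature (maximum likelihood);
* crude 2x2 odds ratios with Woolf confidence intervals, and Bonferroni
  familywise thresholds.

All fits are Newton-type with step-halving, converge on an infinity-norm
gradient below 1e-8 (max 100 iterations), and report Wald standard
errors from the observed information.  Non-convergence and
non-identifiable data are flagged on the returned :class:`FitResult`,
never raised, so simulation loops can count them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import norm

logger = logging.getLogger(__name__)

GRAD_TOL = 1e-8
MAX_ITER = 100

STATUS_CONTRASTS: tuple[str, ...] = ("poor", "intermediate", "rapid", "ultrarapid")
REFERENCE_STATUS = "normal"
DRUGS: tuple[str, ...] = ("sertraline", "citalopram", "escitalopram")


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model.

    ``params``/``se`` are indexed by term name; threshold terms are
    named ``theta_1``, ``theta_2``, ....  ``sigma`` is the random-
    intercept SD for mixed fits (None for fixed-effect fits).
    """

    params: pd.Series
    se: pd.Series
    loglik: float
    converged: bool
    n_obs: int
    method: str
    sigma: float | None = None
    sigma_se: float | None = None
    message: str = ""
    n_groups: int | None = None

    def contrast(self, term: str) -> dict[str, float]:
        """Wald summary for one coefficient: beta, SE, OR, 95% CI, p."""
        beta = float(self.params[term])
        se = float(self.se[term])
        with np.errstate(over="ignore"):  # CI may overflow under separation
            return {
                "beta": beta,
                "se": se,
                "or": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - 1.96 * se)),
                "ci_high": float(np.exp(beta + 1.96 * se)),
                "p": float(2 * norm.sf(abs(beta) / se)) if se > 0 else np.nan,
            }

    def summary(self) -> pd.DataFrame:
        rows = []
        for term in self.params.index:
            c = self.contrast(term)
            rows.append({"term": term, **c})
        return pd.DataFrame(rows).set_index("term")


@dataclass
class CrudeOR:
    """Crude odds ratio from a 2x2 table with a Woolf (log-scale) 95% CI."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    log_or: float
    se: float
    corrected: bool = False  # Haldane–Anscombe 0.5 applied to zero cells


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------


def _clm_parts(params: np.ndarray, y: np.ndarray, X: np.ndarray, K: int):
    """Per-observation pieces of the cumulative-logit likelihood.

    Returns (loglik vector, D, F_hi, F_lo, f_hi, f_lo, z ok flag) where
    D = P(Y = y_i).  ``y`` is 1-based in {1..K}.
    """
    theta = params[: K - 1]
    beta = params[K - 1 :]
    eta = X @ beta
    # boundary thresholds: theta_0 = -inf, theta_K = +inf
    hi_idx = y  # category index c: upper threshold theta_c (1-based)
    lo_idx = y - 1
    F_hi = np.where(hi_idx >= K, 1.0, expit(theta[np.clip(hi_idx, 1, K - 1) - 1] - eta))
    F_lo = np.where(lo_idx <= 0, 0.0, expit(theta[np.clip(lo_idx, 1, K - 1) - 1] - eta))
    D = np.clip(F_hi - F_lo, 1e-150, None)
    f_hi = np.where(hi_idx >= K, 0.0, F_hi * (1 - F_hi))
    f_lo = np.where(lo_idx <= 0, 0.0, F_lo * (1 - F_lo))
    return np.log(D), D, F_hi, F_lo, f_hi, f_lo


def _clm_nll_grad_hess(
    params: np.ndarray, y: np.ndarray, X: np.ndarray, K: int, want_hess: bool = True
):
    """Negative log-likelihood, gradient and (optionally) Hessian of the CLM."""
    n, p = X.shape
    q = K - 1 + p
    ll, D, F_hi, F_lo, f_hi, f_lo = _clm_parts(params, y, X, K)

    # dense per-observation dz/dparam matrices for upper/lower thresholds
    U_hi = np.zeros((n, q))
    U_lo = np.zeros((n, q))
    rows = np.arange(n)
    mask_hi = y < K
    U_hi[rows[mask_hi], y[mask_hi] - 1] = 1.0
    mask_lo = y > 1
    U_lo[rows[mask_lo], y[mask_lo] - 2] = 1.0
    U_hi[:, K - 1 :] = -X
    U_lo[:, K - 1 :] = -X

    g_hi = f_hi / D
    g_lo = f_lo / D
    S = g_hi[:, None] * U_hi - g_lo[:, None] * U_lo  # per-obs score
    grad = S.sum(axis=0)

    if not want_hess:
        return -ll.sum(), -grad, None

    # f'(z) = f(z) (1 - 2 F(z))
    a = f_hi * (1 - 2 * F_hi) / D
    b = f_lo * (1 - 2 * F_lo) / D
    H = (
        U_hi.T @ (a[:, None] * U_hi)
        - U_lo.T @ (b[:, None] * U_lo)
        - S.T @ S
    )
    return -ll.sum(), -grad, -H


def _logit_nll_grad_hess(params, y, X, want_hess=True):
    eta = X @ params
    p = expit(eta)
    # stable bernoulli loglik
    ll = y * eta - np.logaddexp(0.0, eta)
    grad = X.T @ (y - p)
    if not want_hess:
        return -ll.sum(), -grad, None
    W = p * (1 - p)
    H = -(X.T @ (W[:, None] * X))
    return -ll.sum(), -grad, -H


def _newton(
    nll_grad_hess,
    x0: np.ndarray,
    valid=lambda x: True,
    tol: float = GRAD_TOL,
    max_iter: int = MAX_ITER,
):
    """Newton optimization with ridge fallback and step-halving line search."""
    x = np.asarray(x0, dtype=float)
    nll, grad, H = nll_grad_hess(x)
    converged = False
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        ridge = 0.0
        step = None
        for _attempt in range(8):
            try:
                step = np.linalg.solve(
                    H + ridge * np.eye(len(x)), grad
                )
                if np.all(np.isfinite(step)):
                    break
            except np.linalg.LinAlgError:
                pass
            ridge = 10.0 * ridge if ridge else 1e-6
        if step is None or not np.all(np.isfinite(step)):
            break
        t = 1.0
        accepted = False
        while t > 1e-12:
            x_new = x - t * step
            if valid(x_new):
                nll_new, grad_new, H_new = nll_grad_hess(x_new)
                if np.isfinite(nll_new) and nll_new <= nll + 1e-12:
                    x, nll, grad, H = x_new, nll_new, grad_new, H_new
                    accepted = True
                    break
            t *= 0.5
        if not accepted:
            break
    else:
        converged = np.max(np.abs(grad)) < tol
    if not converged:
        converged = np.max(np.abs(grad)) < tol
    return x, nll, grad, H, converged


def _wald_se(H_nll: np.ndarray) -> np.ndarray:
    """SEs from the observed information (Hessian of the nll)."""
    try:
        cov = np.linalg.inv(H_nll)
        d = np.diag(cov)
        return np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        return np.full(H_nll.shape[0], np.nan)


def _check_design(X: np.ndarray) -> None:
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")


# ---------------------------------------------------------------------------
# fixed-effect fits
# ---------------------------------------------------------------------------


def fit_cumulative_logit(
    y: np.ndarray, X: np.ndarray, names: list[str] | None = None
) -> FitResult:
    """ML proportional-odds fit of an ordinal response.

    Parameters
    ----------
    y
        Ordinal responses coded 1..K (K >= 2 levels observed).
    X
        Covariate matrix WITHOUT an intercept column (the thresholds act
        as category-specific intercepts); must have full column rank.
    names
        Column names for X; defaults to ``x1..xp``.

    The model is ``logit P(y <= k) = theta_k - x beta`` with increasing
    thresholds, so positive coefficients shift mass toward higher
    categories and ``exp(beta)`` is the cumulative odds ratio for a
    higher response.
    """
    y = np.asarray(y, dtype=int)
    X = np.asarray(X, dtype=float)
    _check_design(X)
    levels = np.unique(y)
    K = int(levels.max())
    names = list(names) if names is not None else [f"x{j+1}" for j in range(X.shape[1])]
    index = [f"theta_{k}" for k in range(1, K)] + names
    if len(levels) < 2:
        return FitResult(
            params=pd.Series(np.nan, index=index),
            se=pd.Series(np.nan, index=index),
            loglik=np.nan,
            converged=False,
            n_obs=len(y),
            method="clm",
            message="fewer than two observed response levels",
        )
    if not np.all(np.isin(y, np.arange(1, K + 1))):
        raise ValueError("y must be coded 1..K")

    # start: empirical cumulative logits, beta = 0
    cum = np.cumsum(np.bincount(y, minlength=K + 1)[1:K]) / len(y)
    cum = np.clip(cum, 1e-4, 1 - 1e-4)
    x0 = np.concatenate([logit(cum), np.zeros(X.shape[1])])

    def valid(params):
        theta = params[: K - 1]
        return bool(np.all(np.diff(theta) > 1e-10))

    est, nll, grad, H, converged = _newton(
        lambda p: _clm_nll_grad_hess(p, y, X, K), x0, valid=valid
    )
    se = _wald_se(H)
    return FitResult(
        params=pd.Series(est, index=index),
        se=pd.Series(se, index=index),
        loglik=-nll,
        converged=bool(converged),
        n_obs=len(y),
        method="clm",
        message="" if converged else "gradient tolerance not reached",
    )


def fit_logistic(
    y: np.ndarray, X: np.ndarray, names: list[str] | None = None
) -> FitResult:
    """ML logistic fit; ``X`` should include an intercept column.

    A constant outcome (all 0 or all 1) is non-identifiable and returns
    a flagged result rather than raising; quasi-separation surfaces as
    ``converged=False``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    _check_design(X)
    names = list(names) if names is not None else [f"x{j+1}" for j in range(X.shape[1])]
    if len(np.unique(y)) < 2:
        return FitResult(
            params=pd.Series(np.nan, index=names),
            se=pd.Series(np.nan, index=names),
            loglik=np.nan,
            converged=False,
            n_obs=len(y),
            method="logistic",
            message="outcome is constant; model non-identifiable",
        )
    est, nll, grad, H, converged = _newton(
        lambda p: _logit_nll_grad_hess(p, y, X), np.zeros(X.shape[1])
    )
    se = _wald_se(H)
    return FitResult(
        params=pd.Series(est, index=names),
        se=pd.Series(se, index=names),
        loglik=-nll,
        converged=bool(converged),
        n_obs=len(y),
        method="logistic",
        message="" if converged else "gradient tolerance not reached",
    )


# ---------------------------------------------------------------------------
# random-intercept (mixed) fits via adaptive Gauss–Hermite quadrature
# ---------------------------------------------------------------------------


def _cluster_loglik_terms(kind, params_fixed, y, X, K, u_per_record):
    """Per-record loglik and first/second derivatives w.r.t. the random effect."""
    if kind == "logistic":
        eta = X @ params_fixed + u_per_record
        p = expit(eta)
        ll = y * eta - np.logaddexp(0.0, eta)
        d1 = y - p
        d2 = -p * (1 - p)
        return ll, d1, d2
    theta = params_fixed[: K - 1]
    beta = params_fixed[K - 1 :]
    eta = X @ beta + u_per_record
    hi_idx = y
    lo_idx = y - 1
    F_hi = np.where(hi_idx >= K, 1.0, expit(theta[np.clip(hi_idx, 1, K - 1) - 1] - eta))
    F_lo = np.where(lo_idx <= 0, 0.0, expit(theta[np.clip(lo_idx, 1, K - 1) - 1] - eta))
    D = np.clip(F_hi - F_lo, 1e-150, None)
    f_hi = np.where(hi_idx >= K, 0.0, F_hi * (1 - F_hi))
    f_lo = np.where(lo_idx <= 0, 0.0, F_lo * (1 - F_lo))
    N = f_hi - f_lo
    # z = theta - eta - u, dz/du = -1
    d1 = -N / D
    fp_hi = np.where(hi_idx >= K, 0.0, f_hi * (1 - 2 * F_hi))
    fp_lo = np.where(lo_idx <= 0, 0.0, f_lo * (1 - 2 * F_lo))
    Np = -(fp_hi - fp_lo)
    d2 = -(Np * D + N**2) / D**2
    return np.log(D), d1, d2


def mixed_marginal_loglik(
    kind: str,
    params_fixed: np.ndarray,
    sigma: float,
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    K: int = 3,
    n_nodes: int = 15,
) -> float:
    """Marginal log-likelihood of a random-intercept model by adaptive GH.

    The per-cluster integral over the N(0, sigma^2) random intercept is
    centred at the mode of the integrand and scaled by its curvature
    (adaptive Gauss–Hermite, ``n_nodes`` nodes).  Exposed so the
    quadrature can be checked against direct numerical integration.

    ``kind`` is ``"logistic"`` or ``"clm"``; ``groups`` are 0..G-1
    cluster codes.
    """
    y = np.asarray(y)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups, dtype=int)
    G = groups.max() + 1
    if sigma <= 0:
        ll, _, _ = _cluster_loglik_terms(kind, params_fixed, y, X, K, 0.0)
        return float(ll.sum())

    # inner Newton for the per-cluster mode of h(u) - u^2 / (2 sigma^2)
    u = np.zeros(G)
    for _ in range(50):
        ll, d1, d2 = _cluster_loglik_terms(kind, params_fixed, y, X, K, u[groups])
        g1 = np.bincount(groups, weights=d1, minlength=G) - u / sigma**2
        g2 = np.bincount(groups, weights=d2, minlength=G) - 1.0 / sigma**2
        step = g1 / g2
        u = u - step
        if np.max(np.abs(step)) < 1e-10:
            break
    ll, d1, d2 = _cluster_loglik_terms(kind, params_fixed, y, X, K, u[groups])
    g2 = np.bincount(groups, weights=d2, minlength=G) - 1.0 / sigma**2
    tau = 1.0 / np.sqrt(-g2)

    z, w = hermgauss(n_nodes)
    # nodes: G x n_nodes
    U = u[:, None] + np.sqrt(2.0) * tau[:, None] * z[None, :]
    log_q = np.empty((G, n_nodes))
    for k in range(n_nodes):
        ll_k, _, _ = _cluster_loglik_terms(kind, params_fixed, y, X, K, U[groups, k])
        h = np.bincount(groups, weights=ll_k, minlength=G)
        log_q[:, k] = h - U[:, k] ** 2 / (2 * sigma**2)
    log_q += (
        np.log(w)[None, :]
        + z[None, :] ** 2
        + 0.5 * np.log(2.0)
        + np.log(tau)[:, None]
        - np.log(sigma)
        - 0.5 * np.log(2 * np.pi)
    )
    m = log_q.max(axis=1)
    log_L = m + np.log(np.exp(log_q - m[:, None]).sum(axis=1))
    return float(log_L.sum())


def fit_random_intercept(
    kind: str,
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    names: list[str] | None = None,
    n_nodes: int = 15,
) -> FitResult:
    """ML random-intercept fit (logistic or cumulative-logit likelihood).

    Parameters
    ----------
    kind
        ``"logistic"`` (X includes an intercept) or ``"clm"`` (X without
        intercept; thresholds estimated).
    groups
        Cluster labels (e.g. participant IDs); records sharing a label
        share one N(0, sigma^2) intercept.
    n_nodes
        Adaptive Gauss–Hermite node count (default 15).

    When every cluster has a single record the random intercept is not
    identified and the fit reduces to the corresponding fixed model with
    ``sigma = 0``.
    """
    y = np.asarray(y)
    X = np.asarray(X, dtype=float)
    codes, _ = pd.factorize(np.asarray(groups))
    sizes = np.bincount(codes)
    names = list(names) if names is not None else [f"x{j+1}" for j in range(X.shape[1])]

    if sizes.max() <= 1:
        fixed = (
            fit_logistic(y, X, names) if kind == "logistic" else fit_cumulative_logit(y, X, names)
        )
        fixed.sigma = 0.0
        fixed.method = f"mixed-{kind}(degenerate)"
        fixed.n_groups = len(sizes)
        return fixed

    K = int(np.max(y)) if kind == "clm" else 2
    start = (
        fit_logistic(y, X, names) if kind == "logistic" else fit_cumulative_logit(y, X, names)
    )
    x0_fixed = start.params.to_numpy()
    if not np.all(np.isfinite(x0_fixed)):
        x0_fixed = np.zeros(X.shape[1] + (K - 1 if kind == "clm" else 0))
    x0 = np.concatenate([x0_fixed, [np.log(0.5)]])

    def nll(phi):
        sigma = float(np.exp(phi[-1]))
        return -mixed_marginal_loglik(kind, phi[:-1], sigma, y, X, codes, K, n_nodes)

    res = minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=[(None, None)] * (len(x0) - 1) + [(np.log(1e-4), np.log(50.0))],
        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
    )
    est = res.x
    sigma = float(np.exp(est[-1]))

    # observed information by central finite differences
    q = len(est)
    h = 1e-4 * np.maximum(1.0, np.abs(est))
    H = np.empty((q, q))
    f0 = nll(est)
    for i in range(q):
        for j in range(i, q):
            ei = np.zeros(q)
            ej = np.zeros(q)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                H[i, i] = (nll(est + ei) - 2 * f0 + nll(est - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    nll(est + ei + ej)
                    - nll(est + ei - ej)
                    - nll(est - ei + ej)
                    + nll(est - ei - ej)
                ) / (4 * h[i] * h[j])
    se_all = _wald_se(H)

    index = (
        [f"theta_{k}" for k in range(1, K)] + names if kind == "clm" else names
    )
    sigma_se = sigma * se_all[-1] if np.isfinite(se_all[-1]) else np.nan
    return FitResult(
        params=pd.Series(est[:-1], index=index),
        se=pd.Series(se_all[:-1], index=index),
        loglik=-res.fun,
        converged=bool(res.success),
        n_obs=len(y),
        method=f"mixed-{kind}",
        sigma=sigma,
        sigma_se=float(sigma_se),
        message="" if res.success else str(res.message),
        n_groups=int(len(sizes)),
    )


# ---------------------------------------------------------------------------
# contingency helpers
# ---------------------------------------------------------------------------


def crude_or(a: float, b: float, c: float, d: float) -> CrudeOR:
    """Crude odds ratio (a*d)/(b*c) with a Woolf 95% CI.

    ``a, b`` are exposed-group event/non-event counts and ``c, d`` the
    reference-group counts.  Zero cells get the Haldane–Anscombe 0.5
    continuity correction, flagged via ``corrected``.
    """
    counts = np.array([a, b, c, d], dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    corrected = bool(np.any(counts == 0))
    if corrected:
        counts = counts + 0.5
    a_, b_, c_, d_ = counts
    log_or = float(np.log(a_ * d_ / (b_ * c_)))
    se = float(np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_))
    return CrudeOR(
        odds_ratio=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - 1.96 * se)),
        ci_high=float(np.exp(log_or + 1.96 * se)),
        log_or=log_or,
        se=se,
        corrected=corrected,
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Familywise significance threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# primary analysis battery
# ---------------------------------------------------------------------------


def bin_side_effect_count(n: np.ndarray) -> np.ndarray:
    """Bin a side-effect count into ordinal levels 1 (0), 2 (1–2), 3 (3+)."""
    n = np.asarray(n)
    return np.where(n <= 0, 1, np.where(n <= 2, 2, 3))


def _design(df: pd.DataFrame, pooled: bool) -> tuple[np.ndarray, list[str]]:
    """Status dummies (normal reference) + age + sex (+ drug dummies when pooled)."""
    cols = []
    names = []
    for status in STATUS_CONTRASTS:
        if (df["status"] == status).any():  # skip empty groups
            cols.append((df["status"] == status).to_numpy(float))
            names.append(status)
    cols.append(df["age"].to_numpy(float))
    names.append("age")
    cols.append(df["sex"].to_numpy(float))
    names.append("sex")
    if pooled:
        # dummies only for drugs present, first present drug as reference
        present = [d for d in DRUGS if (df["drug"] == d).any()]
        for drug in present[1:]:
            cols.append((df["drug"] == drug).to_numpy(float))
            names.append(f"drug_{drug}")
    return np.column_stack(cols), names


def _fit_outcome(
    df: pd.DataFrame,
    outcome: str,
    ordinal: bool,
    pooled: bool,
    n_nodes: int = 15,
) -> FitResult:
    if ordinal:
        y = df[outcome].to_numpy(int)
    else:
        y = df[outcome].to_numpy(float)
    X, names = _design(df, pooled)
    if pooled:
        groups = df["participant_id"].to_numpy()
        return fit_random_intercept(
            "clm" if ordinal else "logistic",
            y,
            np.column_stack([np.ones(len(df)), X]) if not ordinal else X,
            groups,
            names=(["const"] + names) if not ordinal else names,
            n_nodes=n_nodes,
        )
    if ordinal:
        return fit_cumulative_logit(y, X, names)
    return fit_logistic(y, np.column_stack([np.ones(len(df)), X]), ["const"] + names)


def run_primary_analysis(
    records: pd.DataFrame,
    alpha: float = 0.05,
    include_pooled: bool = True,
    include_side_effect_scan: bool = True,
    n_nodes: int = 15,
) -> pd.DataFrame:
    """Run the full association battery on a long-format cohort table.

    ``records`` needs columns participant_id, drug, status, age, sex,
    efficacy, discontinued, any_side_effect, and (for the side-effect
    analyses) n_side_effects plus ``se_*`` binaries.

    Families and Bonferroni thresholds:

    * efficacy — cumulative-logit per drug + pooled random-intercept;
      threshold alpha/4 (four status contrasts vs normal);
    * tolerability (discontinued) — logistic per drug + pooled mixed;
      threshold alpha/4;
    * side effects — any-side-effect, binned number of side effects
      (0 / 1–2 / 3+, ordinal) and each named side effect, per drug;
      family of 25 outcomes x 3 drugs x 4 contrasts = 300 tests,
      threshold alpha/300.  Any-side-effect and the count are also fit
      pooled.

    Returns one row per (family, outcome, scope, contrast) with OR,
    95% CI, p, and significance flags at the family threshold.
    """
    required = {"participant_id", "drug", "status", "age", "sex"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records table lacks required columns: {sorted(missing)}")

    se_cols = sorted(c for c in records.columns if c.startswith("se_"))
    thr_main = bonferroni_threshold(alpha, 4)
    thr_scan = bonferroni_threshold(alpha, 300)

    rows: list[dict] = []

    def emit(family, outcome, scope, fit: FitResult, threshold):
        for status in STATUS_CONTRASTS:
            if status in fit.params.index and np.isfinite(fit.params[status]):
                c = fit.contrast(status)
            else:
                c = {k: np.nan for k in ("beta", "se", "or", "ci_low", "ci_high", "p")}
            rows.append(
                {
                    "family": family,
                    "outcome": outcome,
                    "scope": scope,
                    "contrast": status,
                    "n": fit.n_obs,
                    **{
                        {"or": "odds_ratio"}.get(k, k): v for k, v in c.items()
                    },
                    "sigma": fit.sigma,
                    "converged": fit.converged,
                    "threshold": threshold,
                    "sig_nominal": bool(np.isfinite(c["p"]) and c["p"] < alpha),
                    "sig_corrected": bool(np.isfinite(c["p"]) and c["p"] < threshold),
                }
            )

    def scopes(df, outcome, ordinal, family, threshold, pooled_too=True):
        for drug in DRUGS:
            sub = df[(df["drug"] == drug) & df[outcome].notna()]
            if len(sub) == 0:
                continue
            fit = _fit_outcome(sub, outcome, ordinal, pooled=False)
            emit(family, outcome, drug, fit, threshold)
        if include_pooled and pooled_too:
            sub = df[df[outcome].notna()]
            fit = _fit_outcome(sub, outcome, ordinal, pooled=True, n_nodes=n_nodes)
            emit(family, outcome, "pooled", fit, threshold)

    df = records.copy()
    if "efficacy" in df.columns:
        scopes(df, "efficacy", ordinal=True, family="efficacy", threshold=thr_main)
    if "discontinued" in df.columns:
        scopes(df, "discontinued", ordinal=False, family="tolerability", threshold=thr_main)
    if "any_side_effect" in df.columns:
        scopes(
            df,
            "any_side_effect",
            ordinal=False,
            family="side_effects",
            threshold=thr_scan,
        )
    if "n_side_effects" in df.columns:
        df = df.assign(n_se_binned=bin_side_effect_count(df["n_side_effects"]))
        scopes(
            df, "n_se_binned", ordinal=True, family="side_effects", threshold=thr_scan
        )
    if include_side_effect_scan:
        for col in se_cols:
            scopes(
                df,
                col,
                ordinal=False,
                family="side_effects",
                threshold=thr_scan,
                pooled_too=False,
            )
    out = pd.DataFrame(rows)
    logger.info(
        "run_primary_analysis: n_rows=%d n_families=%d",
        len(out),
        out["family"].nunique() if len(out) else 0,
    )
    return out
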