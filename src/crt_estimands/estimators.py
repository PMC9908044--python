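"""Estimators for cluster-randomized trial treatment effects.

Four estimators are unbiased under informative cluster size, each targeting
a named estimand through its weighting:

* unweighted independence estimating equations (IEE) on participant-level
  data -> participant-average effect (equal weight per participant);
* size-weighted cluster-level regression -> participant-average effect
  (identical point estimates to unweighted IEE);
* inverse-cluster-size-weighted IEE -> cluster-average effect;
* unweighted cluster-level regression -> cluster-average effect.

Two common comparators are provided because their implicit inverse-variance
cluster weights ``w(n) = n / (1 + (n - 1) rho)`` match neither estimand and
bias them when cluster size is informative:

* a random-intercept linear mixed model fitted by REML (or ML);
* generalized estimating equations with an exchangeable working
  correlation.

All participant-level analyses report cluster-robust sandwich standard
errors; weighted cluster-level analyses report heteroskedasticity-robust
(HC0) standard errors, which the weighting requires.
"""

from __future__ import annotations

import dataclasses
import math
import warnings as _warnings
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .data import CRTDataset, ClusterSummaryTable, summarize_clusters

__all__ = [
    "FitOptions",
    "EstimateResult",
    "EstimatorError",
    "ConvergenceError",
    "fit_iee",
    "fit_cluster_level",
    "fit_mixed_random_intercept",
    "fit_gee_exchangeable",
    "cluster_robust_covariance",
    "fit_estimator",
    "ESTIMATOR_NAMES",
]


class EstimatorError(ValueError):
    """Raised when a fit is requested on data it cannot handle."""


class ConvergenceError(RuntimeError):
    """Raised when an iterative fit fails to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclasses.dataclass(frozen=True)
class FitOptions:
    """Inference options shared by all estimators.

    ``variance_correction`` scales the sandwich: CR0 is the plain
    estimator, CR1 multiplies it by G/(G-1) as a small-sample correction.
    ``df_method`` chooses between normal quantiles and a t distribution
    with G-2 degrees of freedom for confidence intervals.
    """

    variance_correction: str = "CR0"  # CR0 | CR1
    ci_level: float = 0.95
    df_method: str = "t_G_minus_2"  # normal | t_G_minus_2
    max_iter: int = 100
    tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.variance_correction not in ("CR0", "CR1"):
            raise ValueError("variance_correction must be CR0 or CR1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.df_method not in ("normal", "t_G_minus_2"):
            raise ValueError("df_method must be 'normal' or 't_G_minus_2'")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclasses.dataclass(frozen=True)
class EstimateResult:
    """A point estimate with uncertainty and provenance.

    ``estimand_target`` records which estimand the estimator's weighting
    corresponds to; the mixed model and exchangeable GEE are tagged
    ``model_based`` since their inverse-variance weighting targets neither
    average when cluster size is informative.  ``nuisance`` carries
    estimator-specific quantities such as the ICC ``rho`` or the working
    correlation ``alpha``.
    """

    estimator: str
    estimand_target: str  # participant_average | cluster_average | model_based
    estimate: float
    se: float
    ci: tuple[float, float]
    df: Optional[int]
    correction: str
    nuisance: dict = dataclasses.field(default_factory=dict)
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be >= 0")
        if not (self.ci[0] <= self.estimate <= self.ci[1]):
            raise ValueError("estimate must lie inside its confidence interval")


ESTIMATOR_NAMES = (
    "iee",
    "iee-weighted",
    "cl-weighted",
    "cl-unweighted",
    "mixed",
    "gee-exch",
)


# ---------------------------------------------------------------------------
# sandwich machinery


def cluster_robust_covariance(
    cluster_scores: np.ndarray, bread: np.ndarray, correction: str = "CR0"
) -> np.ndarray:
    """Cluster-robust sandwich covariance B^-1 (sum_i s_i s_i^T) B^-1.

    ``cluster_scores`` is (G, p) with scores summed within cluster; CR1
    multiplies the result by G / (G - 1).  With one observation per
    cluster this reduces to the HC0 heteroskedasticity-robust covariance.
    """
    s = np.atleast_2d(np.asarray(cluster_scores, float))
    bread = np.asarray(bread, float)
    g = s.shape[0]
    if g < 3:
        raise EstimatorError("cluster-robust covariance needs at least 3 clusters")
    meat = s.T @ s
    try:
        binv = np.linalg.inv(bread)
    except np.linalg.LinAlgError as exc:
        raise EstimatorError("singular bread matrix in sandwich") from exc
    cov = binv @ meat @ binv
    if correction == "CR1":
        cov = cov * (g / (g - 1.0))
    elif correction != "CR0":
        raise ValueError("correction must be CR0 or CR1")
    return cov


def _interval(
    estimate: float, se: float, opts: FitOptions, g: int
) -> tuple[tuple[float, float], Optional[int]]:
    if opts.df_method == "t_G_minus_2":
        df = max(g - 2, 1)
        q = stats.t.ppf(0.5 + opts.ci_level / 2.0, df)
    else:
        df = None
        q = stats.norm.ppf(0.5 + opts.ci_level / 2.0)
    return (estimate - q * se, estimate + q * se), df


def _require_fit_ready(data: CRTDataset) -> None:
    if data.n_clusters < 3:
        raise EstimatorError(
            "need at least 3 clusters: the cluster-robust sandwich is "
            "degenerate with fewer"
        )
    arms = set(data.cluster_arms.tolist())
    if arms != {0, 1}:
        raise EstimatorError("all clusters are in one arm; contrast undefined")


# ---------------------------------------------------------------------------
# GLM pieces for the independence estimating equations


def _link_funcs(family: str, link: str):
    """Return (mu(eta), dmu/deta(eta), variance(mu), link(mu))."""
    if family == "gaussian":
        if link != "identity":
            raise EstimatorError("gaussian family supports the identity link only")
        return (lambda e: e, lambda e: np.ones_like(e), lambda m: np.ones_like(m),
                lambda m: m)
    if family != "binomial":
        raise EstimatorError(f"unknown family {family!r}")
    if link == "logit":
        return (
            lambda e: 1.0 / (1.0 + np.exp(-e)),
            lambda e: (p := 1.0 / (1.0 + np.exp(-e))) * (1 - p),
            lambda m: m * (1 - m),
            lambda m: np.log(m / (1 - m)),
        )
    if link == "log":
        return (np.exp, np.exp, lambda m: m * (1 - m), np.log)
    if link == "identity":
        return (
            lambda e: e,
            lambda e: np.ones_like(e),
            lambda m: m * (1 - m),
            lambda m: m,
        )
    raise EstimatorError(f"unknown link {link!r}")


def _glm_weighted(
    x: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    family: str,
    link: str,
    opts: FitOptions,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve the weighted GLM estimating equation; return (beta, mu, bread)."""
    mu_f, dmu_f, var_f, link_f = _link_funcs(family, link)
    p = x.shape[1]
    if family == "gaussian":
        xtw = x.T * w
        bread = xtw @ x
        beta = np.linalg.solve(bread, xtw @ y)
        return beta, x @ beta, bread

    # binomial: Fisher scoring with step-halving to stay inside (0, 1)
    ybar = min(max(float(np.average(y, weights=w)), 1e-6), 1 - 1e-6)
    beta = np.zeros(p)
    beta[0] = link_f(np.array([ybar]))[0]

    def score_info(b):
        eta = x @ b
        mu = mu_f(eta)
        if family == "binomial" and (np.any(mu <= 0) or np.any(mu >= 1)):
            return None
        d = dmu_f(eta)
        v = var_f(mu)
        u = x.T @ (w * (y - mu) * d / v)
        info = (x.T * (w * d * d / v)) @ x
        return mu, u, info

    cur = score_info(beta)
    if cur is None:
        raise ConvergenceError("invalid starting point for binomial fit", beta)
    for _ in range(opts.max_iter):
        mu, u, info = cur
        if np.max(np.abs(u)) < opts.tol * max(1.0, float(np.sum(w))):
            break
        try:
            step = np.linalg.solve(info, u)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix", beta) from exc
        # step-halving: accept the first step that keeps mu in range
        for _ in range(30):
            nxt = score_info(beta + step)
            if nxt is not None:
                break
            step = step / 2.0
        else:
            raise ConvergenceError(
                f"step-halving failed to keep fitted probabilities in (0,1) for link {link!r}",
                beta,
            )
        beta = beta + step
        cur = nxt
    else:
        raise ConvergenceError("binomial fit did not converge", beta)
    mu, _, info = cur
    return beta, mu, info


def fit_iee(
    data: CRTDataset,
    weights: str = "none",
    opts: FitOptions = FitOptions(),
    family: str = "gaussian",
    link: str = "identity",
) -> EstimateResult:
    """Independence estimating equations with cluster-robust standard errors.

    ``weights='none'`` gives every participant equal weight and targets the
    participant-average effect; ``weights='inverse_cluster_size'`` weights
    each participant by 1/n_i, giving every cluster equal weight and
    targeting the cluster-average effect.  Weights enter the estimating
    equation unnormalized (point estimates are invariant to their scale).

    For binomial outcomes the link (logit/log/identity) selects the
    summary measure: odds ratio, risk ratio or risk difference on the
    linear-predictor scale.
    """
    _require_fit_ready(data)
    if weights not in ("none", "inverse_cluster_size"):
        raise ValueError("weights must be 'none' or 'inverse_cluster_size'")
    y = data.outcome
    x = np.column_stack([np.ones(len(y)), data.arm.astype(float)])
    if weights == "inverse_cluster_size":
        w = 1.0 / data.cluster_sizes[data.cluster_codes]
        target = "cluster_average"
        name = "iee-weighted"
    else:
        w = np.ones(len(y))
        target = "participant_average"
        name = "iee"

    mu_f, dmu_f, var_f, _ = _link_funcs(family, link)
    beta, mu, bread = _glm_weighted(x, y, w, family, link, opts)
    eta = x @ beta
    resid_score = w * (y - mu) * dmu_f(eta) / var_f(mu)
    g = data.n_clusters
    scores = np.zeros((g, x.shape[1]))
    for j in range(x.shape[1]):
        scores[:, j] = np.bincount(data.cluster_codes, weights=resid_score * x[:, j], minlength=g)
    cov = cluster_robust_covariance(scores, bread, opts.variance_correction)
    est = float(beta[1])
    se = float(math.sqrt(max(cov[1, 1], 0.0)))
    ci, df = _interval(est, se, opts, g)
    return EstimateResult(
        estimator=name,
        estimand_target=target,
        estimate=est,
        se=se,
        ci=ci,
        df=df,
        correction=opts.variance_correction,
        nuisance={"intercept": float(beta[0]), "family": family, "link": link},
    )


# ---------------------------------------------------------------------------
# cluster-level analyses


def fit_cluster_level(
    summary: ClusterSummaryTable,
    weighted: bool,
    opts: FitOptions = FitOptions(),
    robust: Optional[bool] = None,
) -> EstimateResult:
    """Regression of cluster means on arm.

    ``weighted=True`` weights each cluster mean by its size n_i, giving
    each participant equal weight (participant-average target); its point
    estimate is identical to unweighted IEE.  The weights make the
    regression heteroskedastic, so HC0 robust standard errors are always
    used.  ``weighted=False`` gives each cluster equal weight
    (cluster-average target) with classical homoskedastic standard errors
    by default (``robust=True`` switches to HC0, useful when cluster-mean
    variances differ).
    """
    g = summary.n_clusters
    if g < 3:
        raise EstimatorError("need at least 3 clusters")
    arms = set(np.unique(summary.arm).tolist())
    if arms != {0, 1}:
        raise EstimatorError("all clusters are in one arm; contrast undefined")
    x = np.column_stack([np.ones(g), summary.arm.astype(float)])
    y = summary.ybar.astype(float)
    w = summary.n.astype(float) if weighted else np.ones(g)
    xtw = x.T * w
    bread = xtw @ x
    beta = np.linalg.solve(bread, xtw @ y)
    resid = y - x @ beta

    use_robust = True if weighted else bool(robust)
    if use_robust:
        scores = (w * resid)[:, None] * x
        cov = cluster_robust_covariance(scores, bread, opts.variance_correction)
        corr = f"HC0+{opts.variance_correction}" if opts.variance_correction == "CR1" else "HC0"
    else:
        sigma2 = float(resid @ resid) / (g - 2)
        cov = sigma2 * np.linalg.inv(bread)
        corr = "classical"
    est = float(beta[1])
    se = float(math.sqrt(max(cov[1, 1], 0.0)))
    ci, df = _interval(est, se, opts, g)
    return EstimateResult(
        estimator="cl-weighted" if weighted else "cl-unweighted",
        estimand_target="participant_average" if weighted else "cluster_average",
        estimate=est,
        se=se,
        ci=ci,
        df=df,
        correction=corr,
        nuisance={"intercept": float(beta[0])},
    )


# ---------------------------------------------------------------------------
# random-intercept linear mixed model


def _cluster_suffstats(data: CRTDataset):
    g = data.n_clusters
    n = data.cluster_sizes.astype(float)
    s = np.bincount(data.cluster_codes, weights=data.outcome, minlength=g)
    ss = np.bincount(data.cluster_codes, weights=data.outcome**2, minlength=g)
    arm = data.cluster_arms.astype(float)
    return n, arm, s, ss


def _gls_beta(n, arm, s, rho):
    """GLS fixed effects under compound symmetry at correlation ``rho``.

    With a cluster-constant design the GLS normal equations collapse to a
    weighted cluster-level regression with weights w_i = n_i/(1+(n_i-1)rho)
    (up to a constant factor that cancels).
    """
    w = n / (1.0 + (n - 1.0) * rho)
    x = np.column_stack([np.ones(len(n)), arm])
    ybar = s / n
    a = (x.T * w) @ x
    b = (x.T * w) @ ybar
    beta = np.linalg.solve(a, b)
    return beta, w, a


def _rss_cs(n, s, ss, m, rho):
    """r' R^-1 r summed over clusters, R compound-symmetric, fitted mean m_i."""
    q = ss - 2.0 * m * s + n * m * m          # sum of squared residuals per cluster
    t = s - n * m                              # sum of residuals per cluster
    if rho == 0.0:
        return float(np.sum(q))
    return float(np.sum((q - rho / (1.0 + (n - 1.0) * rho) * t * t) / (1.0 - rho)))


def fit_mixed_random_intercept(
    data: CRTDataset,
    opts: FitOptions = FitOptions(),
    method: str = "reml",
    fixed_rho: Optional[float] = None,
) -> EstimateResult:
    """Linear mixed model y_ij = b0 + b1 arm_i + u_i + e_ij.

    The (restricted) likelihood is profiled over the intraclass
    correlation rho = sigma_b^2/(sigma_b^2+sigma_e^2) on [0, 0.999] with
    bounded scalar minimization; fixed effects are generalized least
    squares under the compound-symmetric covariance, which for a
    cluster-constant design weights each cluster by
    w_i = n_i / (1 + (n_i - 1) rho).  The reported standard error is
    model-based.  A ``rho`` pinned at either boundary is flagged in
    ``warnings``.

    ``fixed_rho`` skips estimation and fits GLS at a known intraclass
    correlation (useful for limit checks and for isolating the
    inverse-variance weighting mechanism from ICC estimation error).
    """
    _require_fit_ready(data)
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    n, arm, s, ss = _cluster_suffstats(data)
    n_tot = float(np.sum(n))
    p = 2
    denom = n_tot - p if method == "reml" else n_tot
    x = np.column_stack([np.ones(len(n)), arm])

    def neg2loglik(rho):
        beta, w, a = _gls_beta(n, arm, s, rho)
        m = x @ beta
        rss = _rss_cs(n, s, ss, m, rho)
        rss = max(rss, 1e-300)
        sigma2 = rss / denom
        logdet_r = float(np.sum((n - 1.0) * np.log1p(-rho) + np.log1p((n - 1.0) * rho)))
        val = denom * math.log(sigma2) + logdet_r
        if method == "reml":
            # a = X' R^-1 X up to the 1/(1-rho) factor folded into w
            sign, logdet_a = np.linalg.slogdet(a)
            val += logdet_a
        return val

    hi = 0.999
    warn: tuple[str, ...] = ()
    if fixed_rho is not None:
        if not 0.0 <= fixed_rho <= hi:
            raise ValueError(f"fixed_rho must lie in [0, {hi}]")
        rho = float(fixed_rho)
    else:
        res = optimize.minimize_scalar(
            neg2loglik, bounds=(0.0, hi), method="bounded",
            options={"xatol": 1e-8, "maxiter": 500},
        )
        if not res.success:
            raise ConvergenceError("profile optimization failed", res)
        rho = float(res.x)
        # the bounded minimizer never lands exactly on a bound; snap when flat
        for cand in (0.0, hi):
            if abs(rho - cand) < 1e-6 and neg2loglik(cand) <= res.fun + 1e-9:
                rho = cand
        if rho <= 1e-6 or rho >= hi - 1e-6:
            warn = ("icc_at_boundary",)

    beta, w, a = _gls_beta(n, arm, s, rho)
    m = x @ beta
    sigma2 = _rss_cs(n, s, ss, m, rho) / denom
    cov = sigma2 * np.linalg.inv(a)
    est = float(beta[1])
    se = float(math.sqrt(max(cov[1, 1], 0.0)))
    ci, df = _interval(est, se, opts, data.n_clusters)
    return EstimateResult(
        estimator="mixed",
        estimand_target="model_based",
        estimate=est,
        se=se,
        ci=ci,
        df=df,
        correction="model",
        nuisance={
            "rho": rho,
            "sigma_b2": rho * sigma2,
            "sigma_e2": (1.0 - rho) * sigma2,
            "method": method,
            "intercept": float(beta[0]),
        },
        warnings=warn,
    )


# ---------------------------------------------------------------------------
# exchangeable GEE


def fit_gee_exchangeable(
    data: CRTDataset,
    opts: FitOptions = FitOptions(),
    family: str = "gaussian",
    alpha: Optional[float] = None,
) -> EstimateResult:
    """GEE with an exchangeable working correlation and sandwich SEs.

    Alternates GLS/IRLS coefficient updates under the working correlation
    with the moment estimator of the common within-cluster correlation
    ``alpha`` (mean within-cluster pairwise Pearson-residual product over
    the Pearson dispersion) until coefficients move by less than
    ``opts.tol``.  ``alpha`` is clamped to [0, 0.999]; a negative moment
    estimate is clamped to 0 and flagged.  Passing ``alpha`` fixes the
    working correlation (no moment updates).

    Continuous outcomes use the identity link; ``family='binomial'`` uses
    the logit link.
    """
    _require_fit_ready(data)
    if family == "gaussian":
        link = "identity"
    elif family == "binomial":
        link = "logit"
    else:
        raise EstimatorError(f"unknown family {family!r}")
    mu_f, dmu_f, var_f, _ = _link_funcs(family, link)

    y = data.outcome
    x = np.column_stack([np.ones(len(y)), data.arm.astype(float)])
    codes = data.cluster_codes
    g = data.n_clusters
    sizes = data.cluster_sizes.astype(float)
    n_tot = float(len(y))
    p = x.shape[1]
    n_pairs = float(np.sum(sizes * (sizes - 1.0) / 2.0))

    # start from the independence fit
    beta, _, _ = _glm_weighted(x, y, np.ones(len(y)), family, link, opts)
    a_work = 0.0 if alpha is None else float(np.clip(alpha, 0.0, 0.999))
    warn: tuple[str, ...] = ()

    def exch_solve(v: np.ndarray, a: float) -> np.ndarray:
        """R(a)^-1 v blockwise: R^-1 = [I - a/(1+(n-1)a) J] / (1-a)."""
        if a == 0.0:
            return v
        tot = np.bincount(codes, weights=v, minlength=g)
        shrink = a / (1.0 + (sizes - 1.0) * a)
        return (v - (shrink * tot)[codes]) / (1.0 - a)

    def beta_update(beta, a):
        eta = x @ beta
        mu = mu_f(eta)
        d = dmu_f(eta)
        v = var_f(mu)
        sv = np.sqrt(v)
        # D' V^-1 = (d/sv) * R^-1 * A^-1/2 applied columnwise
        xd = x * (d / sv)[:, None]
        rinv_xd = np.column_stack([exch_solve(xd[:, j], a) for j in range(p)])
        rez = (y - mu) / sv
        info = xd.T @ rinv_xd
        u = rinv_xd.T @ rez
        step = np.linalg.solve(info, u)
        return beta + step, step

    def alpha_moment(beta):
        eta = x @ beta
        mu = mu_f(eta)
        e = (y - mu) / np.sqrt(var_f(mu))
        phi = float(e @ e) / (n_tot - p)
        if phi <= 0 or n_pairs <= p:
            return 0.0, False
        tot = np.bincount(codes, weights=e, minlength=g)
        sq = np.bincount(codes, weights=e * e, minlength=g)
        pair_sum = float(np.sum(tot * tot - sq)) / 2.0
        a = pair_sum / ((n_pairs - p) * phi)
        return a, a < 0.0

    converged = False
    for _ in range(opts.max_iter):
        if alpha is None:
            a_raw, neg = alpha_moment(beta)
            a_work = float(np.clip(a_raw, 0.0, 0.999))
            if neg and "alpha_clamped_to_zero" not in warn:
                warn = warn + ("alpha_clamped_to_zero",)
        beta_new, step = beta_update(beta, a_work)
        if not np.all(np.isfinite(beta_new)):
            raise ConvergenceError("GEE update produced non-finite coefficients", beta)
        beta = beta_new
        if np.max(np.abs(step)) < opts.tol * max(1.0, np.max(np.abs(beta))):
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"GEE did not converge in {opts.max_iter} iterations", beta
        )

    # sandwich at the converged working correlation
    eta = x @ beta
    mu = mu_f(eta)
    d = dmu_f(eta)
    v = var_f(mu)
    sv = np.sqrt(np.maximum(v, 1e-300))
    xd = x * (d / sv)[:, None]
    rinv_xd = np.column_stack([exch_solve(xd[:, j], a_work) for j in range(p)])
    bread = xd.T @ rinv_xd
    rez = (y - mu) / sv
    rinv_rez = exch_solve(rez, a_work)
    scores = np.zeros((g, p))
    for j in range(p):
        scores[:, j] = np.bincount(codes, weights=xd[:, j] * rinv_rez, minlength=g)
    cov = cluster_robust_covariance(scores, bread, opts.variance_correction)
    est = float(beta[1])
    se = float(math.sqrt(max(cov[1, 1], 0.0)))
    ci, df = _interval(est, se, opts, g)
    return EstimateResult(
        estimator="gee-exch",
        estimand_target="model_based",
        estimate=est,
        se=se,
        ci=ci,
        df=df,
        correction=opts.variance_correction,
        nuisance={"alpha": a_work, "family": family, "intercept": float(beta[0])},
        warnings=warn,
    )


# ---------------------------------------------------------------------------
# dispatch by name (used by the study runner and the CLI)


def fit_estimator(
    name: str, data: CRTDataset, opts: FitOptions = FitOptions()
) -> EstimateResult:
    """Fit one of the named estimators on participant-level data."""
    if name == "iee":
        return fit_iee(data, "none", opts)
    if name == "iee-weighted":
        return fit_iee(data, "inverse_cluster_size", opts)
    if name == "cl-weighted":
        return fit_cluster_level(summarize_clusters(data), True, opts)
    if name == "cl-unweighted":
        return fit_cluster_level(summarize_clusters(data), False, opts)
    if name == "mixed":
        return fit_mixed_random_intercept(data, opts)
    if name == "gee-exch":
        return fit_gee_exchangeable(data, opts)
    raise ValueError(f"unknown estimator {name!r}; choose from {ESTIMATOR_NAMES}")
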