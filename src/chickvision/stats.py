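"""Statistical procedures used by the analysis pipeline.

Every test statistic in the pipeline is computed here explicitly (closed
forms, or numerical likelihood maximization for the mixed models), so each
stage of the analysis is inspectable.  Only distribution tail functions
(``scipy.stats`` survival functions, ``scipy.special``) are delegated.

The two mixed models are the one-way random-intercept designs the behavioral
analysis calls for: a Bernoulli (logistic) model fitted by adaptive-free
Gauss-Hermite marginal maximum likelihood, and a Gaussian model fitted by
REML with the variance ratio profiled out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats as sps

__all__ = [
    "Chi2Result",
    "PearsonResult",
    "TTestResult",
    "AnovaResult",
    "OLSResult",
    "MixedFitResult",
    "chi_square_2x2",
    "binomial_tail_one_sided",
    "pearson_r_test",
    "one_sample_t",
    "one_way_anova",
    "ols",
    "fit_random_intercept_logistic",
    "fit_random_intercept_linear",
]


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class PearsonResult:
    r: float
    t: float
    df: int
    p_value: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_value: float


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float


@dataclass(frozen=True)
class OLSResult:
    intercept: float
    slope: float
    slope_se: float
    t: float
    df: int
    p_value: float


@dataclass(frozen=True)
class MixedFitResult:
    """Fit of an intercept-only model with a per-subject random intercept.

    ``stat`` is a Wald z for the logistic model and a t (with ``df``) for the
    linear model.  ``converged=False`` marks estimates as unreliable
    (optimizer failure, complete separation, or a singular information
    matrix).
    """

    b: float
    se: float
    stat: float
    stat_name: str  # "z" or "t"
    df: int | None
    p_value: float
    random_intercept_sd: float
    residual_sd: float | None
    converged: bool
    n_obs: int
    n_groups: int


def chi_square_2x2(table, correction: bool = False) -> Chi2Result:
    """Pearson chi-square on a 2x2 contingency table.

    ``table`` is [[a, b], [c, d]].  By default no Yates continuity
    correction is applied (the convention of the model-vs-subject
    comparisons this pipeline reproduces).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with nonnegative counts")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        raise ValueError("degenerate table: a marginal total is zero")
    num = abs(a * d - b * c)
    if correction:
        num = max(num - n / 2.0, 0.0)
    stat = n * num**2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return Chi2Result(float(stat), 1, float(sps.chi2.sf(stat, 1)))


def binomial_tail_one_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact upper tail P(X >= k) for X ~ Binomial(n, p0).

    Uses the regularized incomplete beta identity, which is numerically
    stable for large n.
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"invalid k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    if k == 0:
        return 1.0
    # P(X >= k) = I_{p0}(k, n - k + 1)
    return float(special.betainc(k, n - k + 1, p0))


def pearson_r_test(x, y) -> PearsonResult:
    """Pearson correlation with its two-sided t-test on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(yc**2))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance: correlation undefined")
    if np.array_equal(x, y):
        r = 1.0  # exact identity, avoid roundoff below 1
    else:
        r = float(np.clip(np.sum(xc * yc) / (sx * sy), -1.0, 1.0))
    df = n - 2
    if abs(r) == 1.0:
        return PearsonResult(r, np.inf if r > 0 else -np.inf, df, 0.0)
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return PearsonResult(r, float(t), df, float(p))


def one_sample_t(values, mu0: float = 0.0) -> TTestResult:
    """Two-sided one-sample t-test of mean(values) against mu0."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need at least 2 observations")
    n = v.size
    sd = v.std(ddof=1)
    if sd == 0.0:
        if np.allclose(v.mean(), mu0):
            return TTestResult(0.0, n - 1, 1.0)
        raise ValueError("zero variance: t undefined for mean != mu0")
    t = (v.mean() - mu0) / (sd / np.sqrt(n))
    return TTestResult(float(t), n - 1, float(2.0 * sps.t.sf(abs(t), n - 1)))


def one_way_anova(groups) -> AnovaResult:
    """One-way fixed-effects ANOVA over a sequence of groups of values."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 1 for g in gs):
        raise ValueError("need >= 2 groups each with >= 1 value")
    all_v = np.concatenate(gs)
    n = all_v.size
    k = len(gs)
    grand = all_v.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(np.sum((g - g.mean()) ** 2) for g in gs)
    dfb, dfw = k - 1, n - k
    if dfw < 1:
        raise ValueError("no within-group degrees of freedom")
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, dfb, dfw, 1.0)
        return AnovaResult(np.inf, dfb, dfw, 0.0)
    F = (ssb / dfb) / (ssw / dfw)
    return AnovaResult(float(F), dfb, dfw, float(sps.f.sf(F, dfb, dfw)))


def ols(x, y) -> OLSResult:
    """Simple linear regression y = a + b x with classical standard errors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-d arrays, n >= 3")
    n = x.size
    xc = x - x.mean()
    sxx = np.sum(xc**2)
    if sxx == 0.0:
        raise ValueError("zero variance in x")
    slope = float(np.sum(xc * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - intercept - slope * x
    df = n - 2
    s2 = np.sum(resid**2) / df
    se = float(np.sqrt(s2 / sxx))
    if se == 0.0:
        t = 0.0 if slope == 0.0 else np.inf * np.sign(slope)
        return OLSResult(intercept, slope, se, float(t), df, 0.0 if slope else 1.0)
    t = slope / se
    return OLSResult(intercept, slope, se, float(t), df, float(2.0 * sps.t.sf(abs(t), df)))


# ---------------------------------------------------------------------------
# Mixed models (intercept-only, subject random intercept)
# ---------------------------------------------------------------------------


def _group_binomial(outcomes, subject_ids):
    out = np.asarray(outcomes)
    subj = np.asarray(subject_ids)
    if out.shape != subj.shape or out.ndim != 1:
        raise ValueError("outcomes and subject_ids must be equal-length 1-d")
    if not np.isin(out, (0, 1)).all():
        raise ValueError("outcomes must be binary 0/1")
    labels, idx = np.unique(subj, return_inverse=True)
    k = np.bincount(idx, weights=out.astype(float))
    n = np.bincount(idx).astype(float)
    if labels.size < 2 or np.any(n < 2):
        raise ValueError("need >= 2 subjects with >= 2 trials each")
    return k, n


def _gh_loglik(b, s, k, n, z_nodes, log_w):
    """Marginal log-likelihood via adaptive Gauss-Hermite quadrature.

    The per-subject integrand is re-centered at its mode with curvature
    scaling (the integrand is far narrower than the random-effect prior
    when subjects contribute many trials, so non-adaptive quadrature is
    inaccurate).  Binomial-coefficient constants are dropped.
    """
    if s < 1e-8:
        log_p = -np.logaddexp(0.0, -b)
        log_q = -np.logaddexp(0.0, b)
        return float(np.sum(k * log_p + (n - k) * log_q))

    def h_parts(u):
        # u: (m, q); returns h(u) with subject stats broadcast over nodes
        eta = b + u
        log_p = -np.logaddexp(0.0, -eta)
        log_q = -np.logaddexp(0.0, eta)
        return (
            k[:, None] * log_p
            + (n - k)[:, None] * log_q
            - 0.5 * np.log(2.0 * np.pi * s * s)
            - u * u / (2.0 * s * s)
        )

    # Newton iterations for the per-subject mode of h (strictly concave)
    u = np.zeros_like(k)
    for _ in range(50):
        p = special.expit(b + u)
        grad = k - n * p - u / (s * s)
        curv = -n * p * (1.0 - p) - 1.0 / (s * s)
        step = grad / curv
        u = u - step
        if np.max(np.abs(step)) < 1e-12:
            break
    p = special.expit(b + u)
    c = n * p * (1.0 - p) + 1.0 / (s * s)  # -h'' at the mode
    scale = np.sqrt(2.0 / c)  # (m,)
    uq = u[:, None] + scale[:, None] * z_nodes[None, :]  # (m, q)
    hq = h_parts(uq)
    # log w already includes the 1/sqrt(pi); add back exp(z^2) and the scale
    a = (log_w + 0.5 * np.log(np.pi) + z_nodes**2)[None, :] + hq
    ll = np.log(scale) + special.logsumexp(a, axis=1)
    return float(ll.sum())


def fit_random_intercept_logistic(
    outcomes, subject_ids, n_quad: int = 21
) -> MixedFitResult:
    """Intercept-only mixed-effects logistic regression.

    Model: outcome_ij ~ Bernoulli(expit(b + u_i)), u_i ~ Normal(0, sigma_u^2).
    The marginal likelihood is maximized with fixed-order Gauss-Hermite
    quadrature (``n_quad`` nodes).  Returns a Wald z = b/SE with a two-sided
    normal p-value.
    """
    k, n = _group_binomial(outcomes, subject_ids)
    n_obs = int(n.sum())
    m = k.size
    z_nodes, w = np.polynomial.hermite.hermgauss(n_quad)
    log_w = np.log(w) - 0.5 * np.log(np.pi)

    total_k = k.sum()
    separated = total_k == 0 or total_k == n.sum()

    def nll(theta):
        return -_gh_loglik(theta[0], theta[1], k, n, z_nodes, log_w)

    p_hat = np.clip(total_k / n.sum(), 1e-6, 1 - 1e-6)
    b0 = np.log(p_hat / (1 - p_hat))
    p_i = np.clip(k / n, 1e-3, 1 - 1e-3)
    s0 = max(np.std(np.log(p_i / (1 - p_i)), ddof=1) * 0.7, 0.05)
    res = optimize.minimize(
        nll,
        x0=np.array([b0, s0]),
        method="L-BFGS-B",
        bounds=[(-15.0, 15.0), (0.0, 10.0)],
    )
    b_hat, s_hat = res.x
    converged = bool(res.success) and not separated

    # Observed information via central differences at the optimum.
    h = 1e-4
    at_boundary = s_hat < 1e-3

    def d2(f, x, i, j):
        ei = np.eye(2)[i] * h
        ej = np.eye(2)[j] * h
        return (f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)) / (
            4 * h * h
        )

    se = np.nan
    if at_boundary:
        # sigma pinned at 0: 1-d curvature in b only
        f = lambda bb: nll(np.array([bb, 0.0]))
        info = (f(b_hat + h) - 2 * f(b_hat) + f(b_hat - h)) / (h * h)
        if info > 0:
            se = 1.0 / np.sqrt(info)
    else:
        x = np.array([b_hat, s_hat])
        H = np.array(
            [[d2(nll, x, 0, 0), d2(nll, x, 0, 1)], [d2(nll, x, 0, 1), d2(nll, x, 1, 1)]]
        )
        try:
            cov = np.linalg.inv(H)
            if cov[0, 0] > 0:
                se = float(np.sqrt(cov[0, 0]))
        except np.linalg.LinAlgError:
            pass
    if not np.isfinite(se):
        converged = False
        se = np.nan
        z = np.nan
        p = np.nan
    else:
        z = b_hat / se
        p = 2.0 * sps.norm.sf(abs(z))
    return MixedFitResult(
        b=float(b_hat),
        se=float(se),
        stat=float(z),
        stat_name="z",
        df=None,
        p_value=float(p),
        random_intercept_sd=float(s_hat),
        residual_sd=None,
        converged=converged,
        n_obs=n_obs,
        n_groups=m,
    )


def fit_random_intercept_linear(y, subject_ids) -> MixedFitResult:
    """Intercept-only linear mixed model fitted by REML.

    Model: y_ij = b + u_i + e_ij, u_i ~ N(0, sigma_u^2), e_ij ~ N(0, sigma_e^2).
    The variance ratio lambda = sigma_u^2/sigma_e^2 is profiled and optimized
    on the log scale.  The Wald t uses df = N - n_subjects - 1 (the df
    convention here is package-dependent in the wild; see docs).
    """
    y = np.asarray(y, dtype=float)
    subj = np.asarray(subject_ids)
    if y.shape != subj.shape or y.ndim != 1:
        raise ValueError("y and subject_ids must be equal-length 1-d")
    labels, idx = np.unique(subj, return_inverse=True)
    m = labels.size
    n_i = np.bincount(idx).astype(float)
    if m < 2 or np.any(n_i < 2):
        raise ValueError("need >= 2 subjects with >= 2 observations each")
    N = y.size
    sums = np.bincount(idx, weights=y)
    ybar_i = sums / n_i
    ssw = float(np.sum((y - ybar_i[idx]) ** 2))

    def profile(lam):
        denom = 1.0 + n_i * lam
        w = n_i / denom
        b = np.sum(w * ybar_i) / np.sum(w)
        q = ssw + np.sum(n_i * (ybar_i - b) ** 2 / denom)
        sigma_e2 = q / (N - 1)
        return b, w, sigma_e2, denom

    def neg_reml(log_lam):
        lam = np.exp(log_lam)
        b, w, sigma_e2, denom = profile(lam)
        if sigma_e2 <= 0:
            return np.inf
        # -2 restricted log-likelihood up to an additive constant
        return (
            (N - 1) * np.log(sigma_e2)
            + np.sum(np.log(denom))
            + np.log(np.sum(w))
            + (N - 1)
        )

    res = optimize.minimize_scalar(
        neg_reml, bounds=(-20.0, 12.0), method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(np.exp(res.x))
    # a boundary solution at the lower bound is effectively sigma_u = 0
    if neg_reml(-30.0) <= res.fun:
        lam = 0.0
    b, w, sigma_e2, _ = profile(lam)
    sigma_u2 = lam * sigma_e2
    se = float(np.sqrt(sigma_e2 / np.sum(w)))
    df = int(N - m - 1)
    if se == 0.0:
        t = 0.0 if b == 0 else np.inf * np.sign(b)
        p = 1.0 if b == 0 else 0.0
    else:
        t = b / se
        p = 2.0 * sps.t.sf(abs(t), df)
    return MixedFitResult(
        b=float(b),
        se=se,
        stat=float(t),
        stat_name="t",
        df=df,
        p_value=float(p),
        random_intercept_sd=float(np.sqrt(sigma_u2)),
        residual_sd=float(np.sqrt(sigma_e2)),
        converged=bool(res.success),
        n_obs=int(N),
        n_groups=int(m),
    )
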