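"""Rubin's rules for combining per-imputation inbreeding estimates.

Given m per-imputation estimates Q_i with within-imputation variances U_i:

    q_bar = mean(Q_i)                     (pooled estimate)
    w_bar = mean(U_i)                     (average within-imputation variance)
    b     = sample variance of Q_i        (between-imputation variance, m-1 divisor)
    T     = w_bar + (1 + 1/m) b           (total variance)
    r     = (1 + 1/m) b / w_bar           (relative increase in variance)
    nu    = (m - 1) (1 + 1/r)^2           (Student-t degrees of freedom)
    lambda= (r + 2/(nu+3)) / (r + 1)      (fraction of missing information)

The null statistic q_bar / sqrt(T) is referred to a Student t with nu
degrees of freedom (equivalently its square to F(1, nu)); the CI is
q_bar +/- t_{nu} sqrt(T).  When b = 0 the result reduces to complete-data
inference on any one copy (r = 0, nu = inf, lambda -> 2/(nu+3) -> 0).

The inbreeding coefficient is an intraclass correlation, so pooling can
optionally be done on the Fisher-z scale z = atanh(f), where its
distribution is closer to normal; the within variance transforms by the
delta method, Var(z) = Var(f) / (1 - f^2)^2, and the pooled estimate and
CI are mapped back through tanh.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PooledResult:
    """Rubin-combined estimate with missing-information statistics."""

    q_bar: float
    w_bar: float
    b: float
    t_var: float
    r: float
    nu: float
    lmbda: float
    ci: tuple[float, float]
    p: float
    m: int
    level: float = 0.95
    scale: str = "identity"

    @property
    def se(self) -> float:
        return float(np.sqrt(self.t_var))


def pool(
    estimates: np.ndarray, variances: np.ndarray, level: float = 0.95
) -> PooledResult:
    """Combine m estimates and their variances by Rubin's rules."""
    q = np.asarray(estimates, float)
    u = np.asarray(variances, float)
    if q.size < 2:
        raise ValueError("pooling requires at least 2 imputations")
    if q.shape != u.shape:
        raise ValueError("estimates and variances must have equal length")
    if (u <= 0).any():
        raise ValueError("within-imputation variances must be positive")
    m = q.size
    q_bar = float(q.mean())
    w_bar = float(u.mean())
    b = float(q.var(ddof=1))
    t_var = w_bar + (1 + 1 / m) * b
    r = (1 + 1 / m) * b / w_bar
    if r > 0:
        # numpy arithmetic: a vanishing r gives nu = inf, not an overflow
        with np.errstate(over="ignore"):
            nu = float((m - 1) * np.square(1 + 1 / np.float64(r)))
        lmbda = (r + 2 / (nu + 3)) / (r + 1)
        tdist = stats.t(df=nu)
        p = 2 * float(tdist.sf(abs(q_bar) / np.sqrt(t_var)))
        tq = float(tdist.ppf(0.5 + level / 2))
    else:
        # b = 0: degenerate agreement across imputations -> complete-data z test
        nu = np.inf
        lmbda = 0.0
        p = 2 * float(stats.norm.sf(abs(q_bar) / np.sqrt(t_var)))
        tq = float(stats.norm.ppf(0.5 + level / 2))
    half = tq * np.sqrt(t_var)
    return PooledResult(
        q_bar=q_bar, w_bar=w_bar, b=b, t_var=float(t_var), r=float(r),
        nu=float(nu), lmbda=float(lmbda),
        ci=(q_bar - half, q_bar + half), p=p, m=m, level=level,
    )


def pool_fisher_z(
    estimates: np.ndarray, variances: np.ndarray, level: float = 0.95
) -> PooledResult:
    """Pool inbreeding estimates on the Fisher-z scale, back-transforming.

    Requires |f| < 1 for every imputation (z is infinite at the boundary);
    callers should fall back to the identity scale otherwise.
    """
    f = np.asarray(estimates, float)
    u = np.asarray(variances, float)
    if (np.abs(f) >= 1).any():
        raise ValueError("Fisher-z pooling undefined at |f| = 1")
    z = np.arctanh(f)
    var_z = u / (1 - f**2) ** 2
    res = pool(z, var_z, level=level)
    return PooledResult(
        q_bar=float(np.tanh(res.q_bar)),
        w_bar=res.w_bar, b=res.b, t_var=res.t_var, r=res.r, nu=res.nu,
        lmbda=res.lmbda,
        ci=(float(np.tanh(res.ci[0])), float(np.tanh(res.ci[1]))),
        p=res.p, m=res.m, level=res.level, scale="fisher-z",
    )


def pool_inbreeding(
    estimates: np.ndarray,
    variances: np.ndarray,
    level: float = 0.95,
    scale: str = "identity",
) -> PooledResult:
    """Pool with the requested scale, falling back to identity at |f| = 1."""
    if scale == "fisher-z":
        try:
            return pool_fisher_z(estimates, variances, level=level)
        except ValueError:
            warnings.warn(
                "estimate at |f| = 1: falling back to identity-scale pooling"
            )
    return pool(estimates, variances, level=level)


def mi_hwp_test(panel, spec, method: str = "chained",
                level: float = 0.95, scale: str = "identity") -> PooledResult:
    """End-to-end HWP inference for one marker under multiple imputation.

    Imputes the target marker's missing calls (chained equations, or
    marginal random draws for the MCAR baseline), estimates the
    inbreeding coefficient and its variance on each completed dataset —
    at the completed sample size, i.e. all individuals — and combines the
    m estimates by Rubin's rules.  A marker with no missing calls yields
    complete-case inference (b = 0).
    """
    from .genodata import tabulate
    from .hwp import estimate_inbreeding
    from .impute import impute_chained, impute_random

    if method == "chained":
        imputed = impute_chained(panel, spec)
    elif method == "random":
        imputed = impute_random(panel, m=spec.m, seed=spec.seed)
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    return pool_imputed(imputed, spec.target, level=level, scale=scale)


def pool_imputed(imputed, target: str, level: float = 0.95,
                 scale: str = "identity") -> PooledResult:
    """Pool per-imputation inbreeding estimates of one marker.

    When every completed copy sits on the boundary f_hat = +/-1 (e.g. a
    marker with no observed heterozygotes, which can never receive an
    imputed one), the large-sample variance degenerates to zero; the
    result is then reported as the all-missing-information limit
    (w_bar = 0, lambda = 1) rather than an error.
    """
    from .genodata import GenotypeVector, tabulate
    from .hwp import estimate_inbreeding

    ests, variances = [], []
    for i in range(imputed.m):
        calls = imputed.marker_calls(i, target)
        g = GenotypeVector(target, ("A", "B"), calls)
        est = estimate_inbreeding(tabulate(g), n_var="observed")
        ests.append(est.f_hat)
        variances.append(est.var_f)
    q = np.asarray(ests)
    u = np.asarray(variances)
    if (u <= 0).any():
        m = q.size
        q_bar = float(q.mean())
        b = float(q.var(ddof=1))
        t_var = (1 + 1 / m) * b
        if t_var > 0:
            tdist = stats.t(df=m - 1)
            p = 2 * float(tdist.sf(abs(q_bar) / np.sqrt(t_var)))
            half = float(tdist.ppf(0.5 + level / 2)) * np.sqrt(t_var)
        else:
            p = float("nan")
            half = 0.0
        return PooledResult(
            q_bar=q_bar, w_bar=0.0, b=b, t_var=float(t_var),
            r=float("inf"), nu=float(m - 1), lmbda=1.0,
            ci=(q_bar - half, q_bar + half), p=p, m=m, level=level,
        )
    return pool_inbreeding(q, u, level=level, scale=scale)
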