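"""Diagnostics for the missing-completely-at-random (MCAR) assumption.

If genotype no-calls at a marker are MCAR, the individuals with a missing
call are a random subsample, so their allele-intensity distribution and
the genotype distribution of correlated neighbouring markers should match
those of the called individuals.  Three families of diagnostics compare
the two groups:

* per-channel two-sample Student t tests (pooled-variance or Welch),
* Hotelling's T^2 on the bivariate (A, B) intensity mean vectors, with a
  homoscedastic (pooled covariance) and a heteroscedastic variant
  (Yao's approximate-df F reference),
* a contingency-table test of the covariate-marker genotype distribution
  across missingness status (chi-square, or an exact/Monte-Carlo p-value
  when expected cells are sparse).

Rejection discredits MCAR; it cannot distinguish MAR from MNAR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genodata import MISSING, GenotypeVector, Panel

#: Smallest missing group for which diagnostics are considered reliable.
MIN_MISSING_GROUP = 15


@dataclass(frozen=True)
class MCARReport:
    """Per-marker MCAR diagnostics (statistic, p) for each test."""

    marker_id: str
    n_missing: int
    n_observed: int
    t_A: tuple[float, float]
    t_B: tuple[float, float]
    t_A_welch: tuple[float, float]
    t_B_welch: tuple[float, float]
    hotelling_pooled: tuple[float, float]
    hotelling_unpooled: tuple[float, float]
    contingency_p: float | None = None


def intensity_t_tests(
    intensities: np.ndarray, missing_mask: np.ndarray, equal_variance: bool = True
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Two-sample t tests per intensity channel, missing vs observed group.

    Returns ((t_A, p_A), (t_B, p_B)); Welch with Satterthwaite df when
    ``equal_variance`` is False.
    """
    intensities = np.asarray(intensities, float)
    mask = np.asarray(missing_mask, bool)
    g1, g2 = intensities[mask], intensities[~mask]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError(
            f"insufficient group size for t test ({len(g1)} missing, "
            f"{len(g2)} observed; need >= 2 each)"
        )
    out = []
    for ch in (0, 1):
        t, p = stats.ttest_ind(g1[:, ch], g2[:, ch], equal_var=equal_variance)
        out.append((float(t), float(p)))
    return out[0], out[1]


def hotelling_t2(
    intensities: np.ndarray, missing_mask: np.ndarray, pooled: bool = True
) -> tuple[float, float]:
    """Two-sample Hotelling T^2 on the bivariate intensity mean vectors.

    Pooled: T^2 = (n1 n2 / (n1+n2)) d' S^-1 d with the pooled covariance
    S, referred to F(p, n1+n2-p-1) after the usual scaling.  Unpooled:
    Yao's test, d' (S1/n1 + S2/n2)^-1 d with approximate denominator df.
    """
    x = np.asarray(intensities, float)
    mask = np.asarray(missing_mask, bool)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("Hotelling test expects a 2-channel intensity matrix")
    x1, x2 = x[mask], x[~mask]
    n1, n2 = len(x1), len(x2)
    if n1 < 3 or n2 < 3:
        raise ValueError(
            f"insufficient group size for Hotelling test ({n1} vs {n2}; need >= 3)"
        )
    p = 2
    d = x1.mean(axis=0) - x2.mean(axis=0)
    s1 = np.cov(x1, rowvar=False)
    s2 = np.cov(x2, rowvar=False)
    if pooled:
        s = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
        _check_nonsingular(s)
        t2 = (n1 * n2 / (n1 + n2)) * float(d @ np.linalg.solve(s, d))
        df2 = n1 + n2 - p - 1
        fstat = t2 * df2 / ((n1 + n2 - 2) * p)
        return t2, float(stats.f.sf(fstat, p, df2))
    # Yao (1965): T^2 with estimated covariance S1/n1 + S2/n2 and
    # data-dependent denominator degrees of freedom.
    se = s1 / n1 + s2 / n2
    _check_nonsingular(se)
    se_inv_d = np.linalg.solve(se, d)
    t2 = float(d @ se_inv_d)
    if t2 <= 1e-300:  # identical means: no evidence whatever the df
        return 0.0, 1.0
    inv_nu = 0.0
    for si, ni in ((s1 / n1, n1), (s2 / n2, n2)):
        frac = float(se_inv_d @ si @ se_inv_d) / t2
        inv_nu += frac**2 / (ni - 1)
    nu = 1.0 / inv_nu
    fstat = t2 * (nu - p + 1) / (nu * p)
    return t2, float(stats.f.sf(fstat, p, nu - p + 1))


def _check_nonsingular(s: np.ndarray) -> None:
    variances = np.diag(s)
    if (variances <= 0).any():
        ch = "A" if variances[0] <= 0 else "B"
        raise np.linalg.LinAlgError(f"degenerate (zero-variance) channel {ch}")
    if abs(np.linalg.det(s)) < 1e-300:
        raise np.linalg.LinAlgError("singular intensity covariance matrix")


def covariate_contingency(
    target_missing: np.ndarray,
    covariate: GenotypeVector,
    rng: np.random.Generator | None = None,
    n_mc: int = 20000,
) -> float:
    """Compare the covariate genotype distribution across missingness status.

    Builds the 2 x k table (target call missing / observed) x (covariate
    genotype) over individuals with an observed covariate.  Uses the
    chi-square test when every expected cell exceeds 5; otherwise
    Fisher's exact test (2 x 2) or a Monte-Carlo exact p (2 x 3).
    """
    mask = np.asarray(target_missing, bool)
    cov = covariate.calls
    known = cov != MISSING
    cats = np.unique(cov[known])
    if cats.size == 0:
        raise ValueError("covariate marker is entirely missing")
    if cats.size < 2:
        raise ValueError("covariate needs >= 2 observed genotype categories")
    table = np.array(
        [
            [int(((cov == c) & known & mask).sum()) for c in cats],
            [int(((cov == c) & known & ~mask).sum()) for c in cats],
        ]
    )
    expected = stats.contingency.expected_freq(table)
    if (expected > 5).all():
        return float(stats.chi2_contingency(table, correction=False)[1])
    if table.shape[1] == 2:
        return float(stats.fisher_exact(table)[1])
    rng = np.random.default_rng(0) if rng is None else rng
    res = stats.chi2_contingency(table, correction=False)
    obs = res[0]
    # Monte-Carlo permutation of the covariate labels, conditioning on margins
    flat = np.repeat(np.arange(table.shape[1]), table.sum(axis=0))
    n_row1 = table[0].sum()
    exceed = 0
    for _ in range(n_mc):
        rng.shuffle(flat)
        sim = np.array(
            [
                np.bincount(flat[:n_row1], minlength=table.shape[1]),
                np.bincount(flat[n_row1:], minlength=table.shape[1]),
            ]
        )
        with np.errstate(invalid="ignore"):
            sim_stat = stats.chi2_contingency(sim, correction=False)[0]
        if sim_stat >= obs - 1e-12:
            exceed += 1
    return (exceed + 1) / (n_mc + 1)


def mcar_report(
    panel: Panel,
    marker_id: str,
    covariate_id: str | None = None,
    min_missing: int = MIN_MISSING_GROUP,
) -> MCARReport:
    """Run all MCAR diagnostics for one marker of a panel."""
    g = panel.marker(marker_id)
    mask = g.missing_mask
    n_mis = int(mask.sum())
    if n_mis < min_missing:
        raise ValueError(
            f"marker {marker_id}: only {n_mis} missing calls "
            f"(minimum {min_missing} for reliable diagnostics)"
        )
    intens = panel.intensities.get(marker_id)
    if intens is None:
        raise ValueError(f"no intensities available for marker {marker_id}")
    tA, tB = intensity_t_tests(intens, mask, equal_variance=True)
    tAw, tBw = intensity_t_tests(intens, mask, equal_variance=False)
    contingency_p = None
    if covariate_id is not None:
        contingency_p = covariate_contingency(mask, panel.marker(covariate_id))
    return MCARReport(
        marker_id=marker_id,
        n_missing=n_mis,
        n_observed=int((~mask).sum()),
        t_A=tA, t_B=tB, t_A_welch=tAw, t_B_welch=tBw,
        hotelling_pooled=hotelling_t2(intens, mask, pooled=True),
        hotelling_unpooled=hotelling_t2(intens, mask, pooled=False),
        contingency_p=contingency_p,
    )
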