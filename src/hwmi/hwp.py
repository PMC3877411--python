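"""Complete-case Hardy-Weinberg statistics.

Deviation from Hardy-Weinberg proportions (HWP) at a diallelic locus is
parametrized by the inbreeding coefficient f: with minor allele frequency
p and q = 1 - p, the genotype frequencies are

    P(AA) = p^2 + p q f,   P(AB) = 2 p q (1 - f),   P(BB) = q^2 + p q f.

f = 0 reproduces HWP exactly; f > 0 means heterozygote dearth, f < 0
heterozygote excess.  The maximum-likelihood estimator from genotype
counts is f_hat = 1 - (n_AB / n) / (2 p_hat q_hat), whose square relates
to the classical 1-df chi-square goodness-of-fit statistic through
chi2 = n f_hat^2.  The large-sample variance (Weir) is

    Var(f_hat) = (1-f)^2 (1-2f) / n  +  f (1-f) (2-f) / (2 n p q).

The variance sample size is selectable: ``n_var="observed"`` (default)
uses the genotyped individuals only, the statistically standard choice
for complete-case inference; ``n_var="total"`` uses the full panel size
including no-calls, the convention required when the estimate feeds
multiple-imputation pooling, where every completed dataset has the full
sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .genodata import GenotypeCounts


class MonomorphicError(ValueError):
    """Raised when a statistic is undefined because only one allele is seen."""


@dataclass(frozen=True)
class HWModel:
    """Genotype law (p, f): minor allele frequency and inbreeding coefficient."""

    p: float
    f: float

    def __post_init__(self) -> None:
        if not 0 < self.p <= 1:
            raise ValueError("allele frequency p must be in (0, 1]")
        lo = f_lower_bound(self.p)
        if not lo <= self.f <= 1:
            raise ValueError(
                f"f={self.f} outside admissible range [{lo:.4f}, 1] for p={self.p}"
            )


def f_lower_bound(p: float) -> float:
    """Smallest f giving non-negative homozygote frequencies at MAF p."""
    q = 1.0 - p
    if p == 0 or q == 0:
        return 0.0
    return max(-p / q, -q / p)


def genotype_freqs(model: HWModel) -> tuple[float, float, float]:
    """Population genotype frequencies (AA, AB, BB) implied by (p, f)."""
    p, f = model.p, model.f
    q = 1.0 - p
    freqs = (p * p + p * q * f, 2 * p * q * (1 - f), q * q + p * q * f)
    if min(freqs) < -1e-12:
        raise ValueError(f"(p={p}, f={f}) implies a negative genotype frequency")
    return freqs


@dataclass(frozen=True)
class InbreedingEstimate:
    """ML estimate of the inbreeding coefficient with its sampling variance.

    ``n_obs`` is the number of genotyped individuals; ``n_var`` the sample
    size actually used in the variance denominator (see module docstring).
    """

    f_hat: float
    var_f: float
    n_obs: int
    n_var: int
    p_hat: float
    counts: GenotypeCounts

    @property
    def se(self) -> float:
        return float(np.sqrt(self.var_f))


def _check_counts(counts: GenotypeCounts) -> None:
    if counts.n < 2:
        raise ValueError(f"need at least 2 observed genotypes, got {counts.n}")
    a_count = 2 * counts.n_AA + counts.n_AB
    b_count = 2 * counts.n_BB + counts.n_AB
    if a_count == 0 or b_count == 0:
        raise MonomorphicError(
            "inbreeding coefficient undefined for a monomorphic marker (2*p*q = 0)"
        )


def inbreeding_variance(f: float, p: float, n: int) -> float:
    """Weir large-sample variance of f_hat; reduces to 1/n at f = 0."""
    q = 1.0 - p
    return (1 - f) ** 2 * (1 - 2 * f) / n + f * (1 - f) * (2 - f) / (2 * n * p * q)


def estimate_inbreeding(
    counts: GenotypeCounts, n_var: str | int = "observed"
) -> InbreedingEstimate:
    """ML estimate of f with its large-sample variance.

    Parameters
    ----------
    counts : GenotypeCounts
    n_var : {"observed", "total"} or int
        Sample size for the variance denominator: the observed genotypes
        (default), the full panel including missings, or an explicit value.
    """
    _check_counts(counts)
    n = counts.n
    p_hat = (2 * counts.n_AA + counts.n_AB) / (2 * n)
    q_hat = 1.0 - p_hat
    f_hat = 1.0 - (counts.n_AB / n) / (2 * p_hat * q_hat)
    if n_var == "observed":
        nv = n
    elif n_var == "total":
        nv = counts.n_total
    else:
        nv = int(n_var)
    var = inbreeding_variance(f_hat, p_hat, nv)
    return InbreedingEstimate(
        f_hat=float(f_hat), var_f=float(var), n_obs=n, n_var=nv,
        p_hat=float(p_hat), counts=counts,
    )


def wald_ci(est: InbreedingEstimate, level: float = 0.95) -> tuple[float, float]:
    """Normal-theory confidence interval f_hat +/- z * SE.

    Endpoints are not truncated to [-1, 1]; reported intervals for weak
    disequilibrium routinely have a negative lower bound.
    """
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * est.se
    return (est.f_hat - half, est.f_hat + half)


def chisq_hwp(counts: GenotypeCounts) -> tuple[float, float]:
    """Classical 1-df chi-square goodness-of-fit test for HWP.

    No continuity correction.  The statistic equals n * f_hat^2.
    """
    _check_counts(counts)
    n = counts.n
    p = (2 * counts.n_AA + counts.n_AB) / (2 * n)
    q = 1.0 - p
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array(counts.as_tuple(), float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


def exact_hwp(counts: GenotypeCounts) -> float:
    """Two-sided exact test for HWP (Levene-Haldane conditional law).

    Conditional on n and the allele counts, the number of heterozygotes
    follows the Levene-Haldane distribution; the two-sided p-value sums
    the probabilities of all outcomes no more probable than the observed
    table (the standard convention for this test).
    """
    _check_counts(counts)
    n = counts.n
    n_a = 2 * counts.n_AA + counts.n_AB  # minor-allele count, either allele works
    n_ab_obs = counts.n_AB
    probs = _levene_haldane_pmf(n, n_a)
    p_obs = probs[n_ab_obs]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def _levene_haldane_pmf(n: int, n_a: int) -> np.ndarray:
    """PMF of the heterozygote count given n genotypes and n_a copies of A.

    Index j of the returned array is P(n_AB = j); entries with j of the
    wrong parity or infeasible homozygote counts are zero.
    """
    n_b = 2 * n - n_a
    js = np.arange(0, min(n_a, n_b) + 1)
    js = js[(js % 2) == (n_a % 2)]
    # log P(j) = log n! - log nAA! - log j! - log nBB! + j log 2
    #            + log nA! + log nB! - log (2n)!
    n_aa = (n_a - js) // 2
    n_bb = (n_b - js) // 2
    logp = (
        gammaln(n + 1)
        - gammaln(n_aa + 1)
        - gammaln(js + 1)
        - gammaln(n_bb + 1)
        + js * np.log(2)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    pmf = np.zeros(min(n_a, n_b) + 1)
    pmf[js] = np.exp(logp)
    return pmf
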