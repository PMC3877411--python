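"""Desk-scale simulation harness: discarding vs imputing missing calls.

Degrades a complete panel under a missingness regime, re-estimates each
affected marker's inbreeding coefficient by (a) discarding missings and
(b) multiple imputation, and scores both against the complete-data
estimate by root-mean-squared error.  The complete-data estimate — not
the generative f — is the reference: the question is how much inference
is distorted by the missing-data handling, not by sampling noise.  RMSE
is aggregated over affected markers only, so the fraction of markers hit
by the regime does not in itself change the error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genodata import GenotypeVector, tabulate
from .hwp import MonomorphicError, chisq_hwp, estimate_inbreeding
from .impute import ImputationSpec, UnimputableError
from .pool import mi_hwp_test
from .synth import MissingnessRegime, apply_missingness


@dataclass(frozen=True)
class SimResult:
    """Scores for one regime: RMSE of f_hat for discarding vs imputation."""

    regime: MissingnessRegime
    overall_missing_rate: float
    rmse_discard: float
    rmse_mi: float
    n_markers_scored: int
    n_markers_skipped: int
    replicate_seeds: tuple[int, ...]


def _f_from_calls(calls: np.ndarray) -> float:
    g = GenotypeVector("tmp", ("A", "B"), calls)
    return estimate_inbreeding(tabulate(g)).f_hat


def run_regime(
    panel,
    regime: MissingnessRegime,
    spec: ImputationSpec,
    replicates: int = 20,
    method: str = "chained",
) -> SimResult:
    """Score discarding vs multiple imputation under one deletion regime.

    Per replicate: apply the regime, then for every affected marker
    compute f_hat three ways — from the pre-deletion truth, from the
    post-deletion observed calls, and pooled over the imputations — and
    accumulate squared errors of the latter two against the first.
    Markers rendered monomorphic-observed (or single-category) by the
    deletion are skipped and counted.
    """
    rng = np.random.default_rng(regime.seed)
    seeds = rng.integers(0, 2**31 - 1, size=replicates)
    ids = panel.marker_ids
    sq_discard: list[float] = []
    sq_mi: list[float] = []
    rates = []
    skipped = 0
    for rep_seed in seeds:
        deg = apply_missingness(panel, replace(regime, seed=int(rep_seed)))
        rates.append(deg.missing_rate)
        for mid in deg.affected:
            j = ids.index(mid)
            g = deg.panel.markers[j]
            if not g.missing_mask.any():
                continue
            try:
                f_true = _f_from_calls(deg.truth[:, j])
                f_disc = estimate_inbreeding(tabulate(g)).f_hat
                mspec = replace(spec, target=mid, seed=int(rep_seed) + j)
                pooled = mi_hwp_test(deg.panel, mspec, method=method)
            except (MonomorphicError, UnimputableError, ValueError):
                skipped += 1
                continue
            sq_discard.append((f_disc - f_true) ** 2)
            sq_mi.append((pooled.q_bar - f_true) ** 2)
    n_scored = len(sq_discard)
    # with nothing deleted (or every affected marker skipped) there is no
    # missing-data error to measure
    rmse_d = float(np.sqrt(np.mean(sq_discard))) if n_scored else 0.0
    rmse_m = float(np.sqrt(np.mean(sq_mi))) if n_scored else 0.0
    return SimResult(
        regime=regime,
        overall_missing_rate=float(np.mean(rates)),
        rmse_discard=rmse_d,
        rmse_mi=rmse_m,
        n_markers_scored=n_scored,
        n_markers_skipped=skipped,
        replicate_seeds=tuple(int(s) for s in seeds),
    )


@dataclass(frozen=True)
class ReversalReport:
    """Per-marker significance classification, discarding vs imputing."""

    classes: dict[str, str]     # marker -> one of the four classes below
    reversal_pct: float

    BOTH_NS = "both-nonsignificant"
    BOTH_SIG = "both-significant"
    ONLY_DISCARD = "significant-only-discarding"
    ONLY_IMPUTED = "significant-only-imputed"


def significance_reversal_report(
    panel,
    spec: ImputationSpec,
    alpha: float = 0.05,
    method: str = "chained",
) -> ReversalReport:
    """Classify each testable marker by the outcome of two HWP tests.

    Test 1 discards missings (chi-square); test 2 pools over multiple
    imputation.  Markers without missings are tested once and classified
    consistently (they can never reverse).  The reversal percentage is
    the share of classified markers whose significance status flips.
    """
    classes: dict[str, str] = {}
    for g in panel.markers:
        counts = tabulate(g)
        try:
            _, p_disc = chisq_hwp(counts)
        except (MonomorphicError, ValueError):
            continue
        if counts.n_missing == 0:
            sig = p_disc < alpha
            classes[g.marker_id] = (
                ReversalReport.BOTH_SIG if sig else ReversalReport.BOTH_NS
            )
            continue
        try:
            mspec = replace(spec, target=g.marker_id)
            pooled = mi_hwp_test(panel, mspec, method=method)
        except (UnimputableError, MonomorphicError, ValueError):
            continue
        sig_d, sig_i = p_disc < alpha, pooled.p < alpha
        if sig_d and sig_i:
            cls = ReversalReport.BOTH_SIG
        elif not sig_d and not sig_i:
            cls = ReversalReport.BOTH_NS
        elif sig_d:
            cls = ReversalReport.ONLY_DISCARD
        else:
            cls = ReversalReport.ONLY_IMPUTED
        classes[g.marker_id] = cls
    n = len(classes)
    n_rev = sum(
        c in (ReversalReport.ONLY_DISCARD, ReversalReport.ONLY_IMPUTED)
        for c in classes.values()
    )
    return ReversalReport(
        classes=classes, reversal_pct=100.0 * n_rev / n if n else 0.0
    )
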