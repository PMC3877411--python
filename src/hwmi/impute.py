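"""Multiple imputation of missing genotype calls.

Missing calls at a target SNP are imputed from its two allele-intensity
channels and/or from neighbouring SNPs in linkage disequilibrium with it,
using a multinomial logit model for the genotype categories:

    log( P(G = j | x) / P(G = ref | x) ) = alpha_j + beta_j' x

fitted on the individuals with an observed call.  The most frequent
genotype is the reference category.  A small always-on ridge penalty on
the slope coefficients keeps the fit finite under perfect separation,
which is common when intensities or a tightly linked SNP predict the
genotype without error; separation is a numerical problem, not a sign
that the predictors are useless.

Because missingness is non-monotone (covariate SNPs have no-calls too),
imputation runs as chained equations: all missing entries are initialised
by marginal draws, then each incomplete variable is revisited for a fixed
number of sweeps, refitting its model on the current completions of the
others.  Imputation is *proper*: before drawing categories, the model
coefficients are drawn from their asymptotic normal distribution, so that
parameter uncertainty propagates into the between-imputation variance of
Rubin's rules.

A model can only assign categories it has seen: a marker whose observed
calls lack heterozygotes will never receive an imputed heterozygote, and
its pooled inbreeding coefficient is driven towards 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .genodata import MISSING, GenotypeVector, Panel, tabulate
from .hwp import estimate_inbreeding

logger = logging.getLogger("hwmi")


class UnimputableError(ValueError):
    """Marker cannot be imputed (all-missing or a single observed category)."""


@dataclass
class ImputationSpec:
    """Configuration of one imputation run.

    Parameters
    ----------
    target : str
        Marker whose missing calls are the inferential focus.
    use_intensities : bool
        Include each marker's two allele-intensity channels as predictors
        (linear, untransformed) when available.
    covariates : list of str, optional
        Explicit covariate markers; ``None`` selects them automatically by
        the LD rule (dosage r^2 >= ``ld_threshold``, strongest first,
        capped at ``max_covariates``).
    ld_threshold : float
        Minimum LD r^2 for automatic covariate selection (default 0.5).
    max_covariates : int
        Cap on the number of covariate SNPs (default 10).
    m : int
        Number of imputed datasets (default 50).
    iterations : int
        Chained-equation sweeps per dataset (default 10).
    ridge : float
        L2 penalty scale on slope coefficients (default 1e-4).
    param_draw : {"bootstrap", "normal"}
        How parameter uncertainty enters each imputation (the *proper*
        imputation step feeding Rubin's between-imputation variance).
        "bootstrap" refits the model on a resample of the observed rows;
        "normal" draws coefficients from the asymptotic normal posterior
        of the penalized fit.  Bootstrap is the default because under
        perfect separation — the rule rather than the exception when
        intensities or a tightly linked SNP predict the genotype — the
        normal approximation's covariance is penalty-dominated and
        produces absurdly diffuse draws, while bootstrap refits stay
        confidently separated.
    seed : int
        RNG seed; identical spec + seed reproduces the imputations.
    """

    target: str
    use_intensities: bool = True
    covariates: list[str] | None = None
    ld_threshold: float = 0.5
    max_covariates: int = 10
    m: int = 50
    iterations: int = 10
    ridge: float = 1e-4
    param_draw: str = "bootstrap"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need m >= 2 imputations")
        if self.iterations < 1:
            raise ValueError("need >= 1 chained-equation iteration")
        if not 0 <= self.ld_threshold <= 1:
            raise ValueError("ld_threshold must be in [0, 1]")
        if self.ridge < 0:
            raise ValueError("ridge penalty must be >= 0")
        if self.param_draw not in ("bootstrap", "normal"):
            raise ValueError("param_draw must be 'bootstrap' or 'normal'")


# ---------------------------------------------------------------------------
# LD and covariate selection
# ---------------------------------------------------------------------------

def ld_r2(g1: GenotypeVector, g2: GenotypeVector) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete pairs.

    A composite-LD proxy that needs no phase information.  Returns 0 with
    a warning when either marker has no variation on the complete pairs.
    """
    both = ~g1.missing_mask & ~g2.missing_mask
    if both.sum() < 2:
        raise ValueError("need >= 2 pairwise-complete individuals")
    x = g1.calls[both].astype(float)
    y = g2.calls[both].astype(float)
    if x.std() == 0 or y.std() == 0:
        warnings.warn(
            f"no variation between {g1.marker_id} and {g2.marker_id} on "
            "complete pairs; r^2 treated as 0"
        )
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def select_covariates(
    target: str, panel: Panel, spec: ImputationSpec
) -> tuple[list[str], bool]:
    """LD-based covariate selection for a target marker.

    Returns (covariate ids sorted by descending r^2, intensity-fallback
    flag).  The target itself and its perfect duplicates (r^2 = 1) are
    excluded — a perfectly related predictor yields a diagonal contingency
    structure the imputation model cannot use.
    """
    tvec = panel.marker(target)
    scored = []
    for g in panel.markers:
        if g.marker_id == target:
            continue
        try:
            r2 = ld_r2(tvec, g)
        except ValueError:
            continue
        if r2 > 1 - 1e-9:
            continue
        if r2 >= spec.ld_threshold:
            scored.append((r2, g.marker_id))
    scored.sort(key=lambda t: (-t[0], t[1]))
    selected = [mid for _, mid in scored[: spec.max_covariates]]
    fallback = not selected and target in panel.intensities
    return selected, fallback


# ---------------------------------------------------------------------------
# Penalized multinomial logit
# ---------------------------------------------------------------------------

@dataclass
class LogitFit:
    """A fitted (ridge-penalized) multinomial logit model.

    ``coef`` has one row per non-reference category: [intercept, slopes].
    ``cov`` is the asymptotic covariance of the flattened coefficients
    (inverse penalized observed information), used for proper-imputation
    posterior draws.
    """

    categories: np.ndarray          # observed genotype codes, ascending
    reference: int                  # most frequent category
    coef: np.ndarray                # (J-1, k+1)
    cov: np.ndarray                 # ((J-1)(k+1), (J-1)(k+1))
    ridge: float

    def _eta(self, X: np.ndarray, coef: np.ndarray) -> np.ndarray:
        Xd = np.column_stack([np.ones(len(X)), X])
        return Xd @ coef.T

    def predict_proba(
        self, X: np.ndarray, coef: np.ndarray | None = None
    ) -> np.ndarray:
        """Category probabilities, columns ordered as ``categories``."""
        coef = self.coef if coef is None else coef
        X = np.atleast_2d(np.asarray(X, float))
        eta = np.zeros((len(X), len(self.categories)))
        nonref = [i for i, c in enumerate(self.categories) if c != self.reference]
        eta[:, nonref] = self._eta(X, coef)
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        return p / p.sum(axis=1, keepdims=True)

    def sample_coef(self, rng: np.random.Generator) -> np.ndarray:
        """Draw coefficients from their asymptotic normal distribution."""
        flat = self.coef.ravel()
        draw = rng.multivariate_normal(flat, self.cov, method="eigh")
        return draw.reshape(self.coef.shape)


def fit_multinomial_logit(
    y: np.ndarray, X: np.ndarray, ridge: float = 1e-4
) -> LogitFit:
    """Fit a multinomial logit by penalized maximum likelihood.

    Maximizes the multinomial log-likelihood minus ridge * ||slopes||^2 / 2
    (intercepts unpenalized, so the intercept-only model reproduces the
    observed category frequencies exactly).  With two observed categories
    the model reduces to binary logistic regression.  The positive ridge
    keeps the optimum finite under perfect separation.
    """
    y = np.asarray(y)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    if X.size == 0:
        X = np.empty((len(y), 0))
    cats, counts = np.unique(y, return_counts=True)
    if cats.size < 2:
        raise UnimputableError("multinomial logit needs >= 2 observed categories")
    reference = int(cats[np.argmax(counts)])
    nonref = cats[cats != reference]
    n, k = X.shape
    Xd = np.column_stack([np.ones(n), X])          # (n, k+1)
    J1 = len(nonref)
    Y = np.zeros((n, J1))                           # indicators per non-ref cat
    for j, c in enumerate(nonref):
        Y[:, j] = y == c
    pen_mask = np.tile(np.r_[0.0, np.ones(k)], J1)  # penalize slopes only

    def unpack(theta: np.ndarray) -> np.ndarray:
        return theta.reshape(J1, k + 1)

    def probs(theta: np.ndarray) -> np.ndarray:
        eta = Xd @ unpack(theta).T                  # (n, J1)
        # softmax over {ref (eta=0)} U nonref
        mx = np.maximum(eta.max(axis=1), 0.0)
        e = np.exp(eta - mx[:, None])
        denom = np.exp(-mx) + e.sum(axis=1)
        return e / denom[:, None]                   # P(nonref j | x)

    def negloglik(theta: np.ndarray) -> float:
        eta = Xd @ unpack(theta).T
        mx = np.maximum(eta.max(axis=1), 0.0)
        lse = mx + np.log(np.exp(-mx) + np.exp(eta - mx[:, None]).sum(axis=1))
        ll = (Y * eta).sum() - lse.sum()
        return -ll + 0.5 * ridge * float(((theta * pen_mask) ** 2).sum())

    def grad(theta: np.ndarray) -> np.ndarray:
        P = probs(theta)
        g = -((Y - P).T @ Xd).ravel() + ridge * theta * pen_mask
        return g

    theta0 = np.zeros(J1 * (k + 1))
    res = optimize.minimize(
        negloglik, theta0, jac=grad, method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success and np.linalg.norm(grad(res.x)) > 1e-3 * max(1, n):
        raise RuntimeError(
            f"multinomial logit did not converge: {res.message} "
            f"(|grad| = {np.linalg.norm(grad(res.x)):.3g})"
        )
    theta = res.x
    # observed penalized information: blocks H[jl] = Xd' diag(w_jl) Xd
    P = probs(theta)
    dim = J1 * (k + 1)
    H = np.zeros((dim, dim))
    for j in range(J1):
        for l in range(J1):
            w = P[:, j] * ((j == l) - P[:, l])
            blk = Xd.T @ (w[:, None] * Xd)
            H[j * (k + 1):(j + 1) * (k + 1), l * (k + 1):(l + 1) * (k + 1)] = blk
    H += np.diag(ridge * pen_mask)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return LogitFit(
        categories=cats, reference=reference,
        coef=unpack(theta), cov=cov, ridge=ridge,
    )


# ---------------------------------------------------------------------------
# Imputed dataset container
# ---------------------------------------------------------------------------

@dataclass
class ImputedPanelSet:
    """m completed copies of a panel, with provenance.

    ``calls`` holds m (n_individuals x n_markers) dosage matrices whose
    observed entries are identical to the source panel; ``traces`` maps a
    marker id to an (m, iterations) array of the per-sweep inbreeding
    coefficient of that marker, for convergence inspection.
    """

    source: Panel
    calls: list[np.ndarray]
    seed: int
    method: str
    traces: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.calls)

    def panel(self, i: int) -> Panel:
        """Materialize the i-th completed panel."""
        out = self.source.copy()
        for j, g in enumerate(out.markers):
            g.calls = self.calls[i][:, j].copy()
        return out

    def marker_calls(self, i: int, marker_id: str) -> np.ndarray:
        j = self.source.marker_ids.index(marker_id)
        return self.calls[i][:, j]


def convergence_trace(imputed: ImputedPanelSet, marker_id: str) -> np.ndarray:
    """Per-iteration f_hat series for one marker, shape (m, iterations)."""
    if marker_id not in imputed.traces:
        raise KeyError(f"no convergence trace recorded for {marker_id}")
    return imputed.traces[marker_id]


def _trace_f(calls: np.ndarray) -> float:
    g = GenotypeVector("trace", ("A", "B"), calls)
    try:
        return estimate_inbreeding(tabulate(g)).f_hat
    except ValueError:
        return np.nan


# ---------------------------------------------------------------------------
# Random (marginal-draw) imputation — the MCAR baseline
# ---------------------------------------------------------------------------

def impute_random(
    g_or_panel: GenotypeVector | Panel, m: int = 50, seed: int = 0
) -> ImputedPanelSet:
    """Impute every missing call by a draw from the observed marginal.

    Each missing call is drawn independently from the empirical genotype
    distribution of the observed calls at that marker.  This corresponds
    to assuming MCAR and serves as the no-covariate baseline.
    """
    if isinstance(g_or_panel, GenotypeVector):
        panel = Panel(
            individuals=[f"i{k}" for k in range(len(g_or_panel))],
            markers=[g_or_panel.copy()],
        )
    else:
        panel = g_or_panel
    rng = np.random.default_rng(seed)
    base = panel.call_matrix()
    completed = []
    traces = {g.marker_id: np.zeros((m, 1)) for g in panel.markers}
    for i in range(m):
        mat = base.copy()
        for j, g in enumerate(panel.markers):
            col = mat[:, j]
            mis = col == MISSING
            if not mis.any():
                traces[g.marker_id][i, 0] = _trace_f(col)
                continue
            obs = col[~mis]
            if obs.size == 0:
                raise UnimputableError(
                    f"marker {g.marker_id} is entirely missing"
                )
            col[mis] = rng.choice(obs, size=int(mis.sum()))
            traces[g.marker_id][i, 0] = _trace_f(col)
        completed.append(mat)
    return ImputedPanelSet(
        source=panel, calls=completed, seed=seed, method="random", traces=traces
    )


# ---------------------------------------------------------------------------
# Chained-equations imputation with multinomial logit models
# ---------------------------------------------------------------------------

def _design(
    panel: Panel,
    mat: np.ndarray,
    var: str,
    others: list[str],
    use_intensities: bool,
) -> np.ndarray:
    """Design matrix for imputing ``var``: dummy-coded other markers in the
    chain plus this marker's intensity channels.  Exact duplicate columns
    (collinear predictors) are dropped with a warning."""
    cols: list[np.ndarray] = []
    ids = panel.marker_ids
    for mid in others:
        dos = mat[:, ids.index(mid)].astype(float)
        cats = np.unique(dos)
        for c in cats[1:]:  # drop-first dummy coding
            cols.append((dos == c).astype(float))
    if use_intensities and var in panel.intensities:
        cols.append(panel.intensities[var][:, 0])
        cols.append(panel.intensities[var][:, 1])
    if not cols:
        return np.empty((mat.shape[0], 0))
    X = np.column_stack(cols)
    keep = []
    seen: list[np.ndarray] = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if col.std() == 0:
            continue
        if any(np.array_equal(col, s) for s in seen):
            logger.warning("dropping exactly collinear predictor column for %s", var)
            continue
        seen.append(col)
        keep.append(j)
    return X[:, keep]


def impute_chained(panel: Panel, spec: ImputationSpec) -> ImputedPanelSet:
    """Multiple imputation by chained equations for one target marker.

    Builds the variable set {target} + covariates (explicit, or selected
    by LD), initialises all missing entries by marginal draws, then for
    ``spec.iterations`` sweeps revisits each incomplete variable in order
    of increasing missingness, refits its multinomial logit on the current
    completions of the others, draws coefficients from their asymptotic
    normal distribution, and draws its missing genotypes from the
    resulting category probabilities.  Repeating this ``spec.m`` times
    with independent streams yields the imputed panel set; the per-sweep
    inbreeding coefficient of the target is recorded for convergence
    checks.
    """
    target = panel.marker(spec.target)
    t_counts = tabulate(target)
    if t_counts.n_missing < 1:
        base = panel.call_matrix()
        return ImputedPanelSet(
            source=panel, calls=[base.copy() for _ in range(spec.m)],
            seed=spec.seed, method="chained",
            traces={spec.target: np.full(
                (spec.m, spec.iterations), _trace_f(base[:, panel.marker_ids.index(spec.target)])
            )},
        )
    obs_cats = np.unique(target.calls[~target.missing_mask])
    if obs_cats.size < 2:
        raise UnimputableError(
            f"target {spec.target}: fewer than 2 observed genotype categories"
        )
    if spec.covariates is None:
        covariates, _ = select_covariates(spec.target, panel, spec)
    else:
        covariates = [c for c in spec.covariates if c != spec.target]
    chain_vars = [spec.target] + covariates
    ids = panel.marker_ids
    base = panel.call_matrix()
    # incomplete chain variables, visited in order of increasing missingness
    miss_count = {
        v: int((base[:, ids.index(v)] == MISSING).sum()) for v in chain_vars
    }
    incomplete = sorted(
        [v for v in chain_vars if miss_count[v] > 0], key=lambda v: miss_count[v]
    )
    rng = np.random.default_rng(spec.seed)
    t_col = ids.index(spec.target)
    completed: list[np.ndarray] = []
    trace = np.zeros((spec.m, spec.iterations))
    for i in range(spec.m):
        mat = base.copy()
        # initialization: marginal draws for every missing chain entry
        for v in incomplete:
            j = ids.index(v)
            col = mat[:, j]
            mis = col == MISSING
            obs = col[~mis]
            if obs.size == 0:
                raise UnimputableError(f"chain variable {v} is entirely missing")
            col[mis] = rng.choice(obs, size=int(mis.sum()))
        for it in range(spec.iterations):
            for v in incomplete:
                j = ids.index(v)
                vmask = base[:, j] == MISSING
                others = [w for w in chain_vars if w != v]
                X = _design(panel, mat, v, others, spec.use_intensities)
                yobs = base[~vmask, j]
                if np.unique(yobs).size < 2:
                    continue  # marginal-draw initialization stands
                Xobs = X[~vmask]
                if spec.param_draw == "bootstrap":
                    # parameter uncertainty via resampled refits
                    n_obs = len(yobs)
                    for _ in range(20):
                        bidx = rng.integers(0, n_obs, size=n_obs)
                        if np.unique(yobs[bidx]).size >= 2:
                            break
                    else:
                        bidx = np.arange(n_obs)
                    fit = fit_multinomial_logit(
                        yobs[bidx], Xobs[bidx], ridge=spec.ridge
                    )
                    probs = fit.predict_proba(X[vmask])
                else:
                    fit = fit_multinomial_logit(yobs, Xobs, ridge=spec.ridge)
                    probs = fit.predict_proba(X[vmask],
                                              coef=fit.sample_coef(rng))
                cum = probs.cumsum(axis=1)
                u = rng.random(int(vmask.sum()))
                picks = (u[:, None] > cum).sum(axis=1)
                mat[vmask, j] = fit.categories[picks]
            trace[i, it] = _trace_f(mat[:, t_col])
        completed.append(mat)
    return ImputedPanelSet(
        source=panel, calls=completed, seed=spec.seed, method="chained",
        traces={spec.target: trace},
    )
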