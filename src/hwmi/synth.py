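"""Synthetic genotype panels with known inbreeding, LD, and missingness.

The generator stands in for array genotyping data: each marker's
genotypes follow the inbreeding-parametrized law (p^2 + pqf,
2pq(1-f), q^2 + pqf); optional LD blocks are drawn from a two-locus
haplotype chain so that neighbouring markers have a controllable dosage
r^2 (with per-locus HWP inside blocks); allele intensities are isotropic
Gaussian clouds per genotype, mimicking the three clusters a genotype
caller sees; and no-calls are introduced by one of three mechanisms:

* MCAR — every call deleted with the same probability,
* MNAR — deletion probability depends on the (unobserved) genotype,
* MAR-intensity — deletion probability grows with the distance from the
  nearest intensity-cluster centroid, concentrating no-calls on the
  boundaries between the genotype clouds, the typical failure mode of
  calling algorithms.

Within an LD block all loci share the block's allele frequency: a
two-point haplotype chain can reach high r^2 only when the allele
frequencies at the linked loci are close, and equal frequencies make any
r^2 in [0, 1] feasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genodata import MISSING, GenotypeVector, Panel
from .hwp import HWModel, genotype_freqs

DEFAULT_INTENSITY_MEANS = {
    0: (2.0, 0.2),   # AA
    1: (1.1, 1.1),   # AB
    2: (0.2, 2.0),   # BB
}


@dataclass
class PanelConfig:
    """Configuration of a synthetic panel.

    ``maf`` may be a scalar, a (low, high) range sampled uniformly, or a
    per-marker list; ``f`` a scalar or per-marker list.  ``ld_blocks`` is
    a list of (block_size, target_r2) pairs; block markers are appended
    after the ``n_markers`` independent markers and have f = 0.
    """

    n_individuals: int = 150
    n_markers: int = 10
    maf: float | tuple[float, float] | list[float] = (0.2, 0.5)
    f: float | list[float] = 0.0
    ld_blocks: list[tuple[int, float]] = field(default_factory=list)
    intensity_means: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_MEANS)
    )
    intensity_sd: float = 0.25
    seed: int = 0


@dataclass
class MissingnessRegime:
    """How calls are deleted.

    ``probs`` is a scalar deletion probability for MCAR, a per-genotype
    (pi_AA, pi_AB, pi_BB) triple for MNAR, and a no-call-width scale (in
    intensity units) for MAR-intensity.  Under MAR-intensity a call is
    deleted with probability ``mar_max * exp(-(z/width)^2)`` where the
    no-call score z mimics what defeats a genotype caller: z = gap +
    max(0, total - median total), with gap the difference between the
    distances to the two nearest genotype centroids (zero on the
    decision boundary between two clouds) and total = A + B the overall
    signal strength.  Deletions therefore concentrate on ambiguous,
    dim samples — crosses between and below the clouds — which both
    reproduces the boundary phenotype and makes the missing group's mean
    intensity vector measurably different from the observed group's.
    ``snp_fraction`` is the fraction of markers subjected to deletion.
    """

    mechanism: str  # "MCAR" | "MNAR" | "MAR-intensity"
    probs: float | tuple[float, float, float]
    snp_fraction: float = 1.0
    mar_max: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in {"MCAR", "MNAR", "MAR-intensity"}:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        p = self.probs
        vals = (p,) if np.isscalar(p) else tuple(p)
        if self.mechanism != "MAR-intensity" and not all(0 <= v <= 1 for v in vals):
            raise ValueError("deletion probabilities must be in [0, 1]")
        if not 0 <= self.snp_fraction <= 1:
            raise ValueError("snp_fraction must be in [0, 1]")

    def genotype_probs(self) -> tuple[float, float, float]:
        if np.isscalar(self.probs):
            return (float(self.probs),) * 3
        return tuple(float(v) for v in self.probs)  # type: ignore[return-value]


def _per_marker(value, n: int, name: str) -> list[float]:
    if np.isscalar(value):
        return [float(value)] * n
    value = list(value)
    if len(value) != n:
        raise ValueError(f"{name}: expected {n} values, got {len(value)}")
    return [float(v) for v in value]


def gen_genotypes(cfg: PanelConfig, rng: np.random.Generator | None = None) -> Panel:
    """Draw a complete panel from the configured genotype law.

    Independent markers are trinomial draws from the (p, f) law; raises
    if any (maf, f) pair implies a negative genotype frequency.  LD-block
    markers come from a haplotype chain with per-locus HWP.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_individuals
    if isinstance(cfg.maf, tuple) and len(cfg.maf) == 2 and np.isscalar(cfg.maf[0]):
        mafs = rng.uniform(cfg.maf[0], cfg.maf[1], size=cfg.n_markers).tolist()
    else:
        mafs = _per_marker(cfg.maf, cfg.n_markers, "maf")
    fs = _per_marker(cfg.f, cfg.n_markers, "f")
    markers: list[GenotypeVector] = []
    pos = 0
    for j, (p, f) in enumerate(zip(mafs, fs)):
        freqs = genotype_freqs(HWModel(p=p, f=f))  # validates admissibility
        calls = rng.choice(3, size=n, p=freqs).astype(np.int8)
        pos += 1
        markers.append(
            GenotypeVector(f"snp{j:04d}", ("A", "B"), calls, chrom="1", pos=pos)
        )
    for b, (size, r2) in enumerate(cfg.ld_blocks):
        p = float(rng.uniform(0.2, 0.5))
        r = float(np.sqrt(r2))
        hap = np.empty((2 * n, size), dtype=np.int8)
        hap[:, 0] = rng.random(2 * n) < p
        for locus in range(1, size):
            prev = hap[:, locus - 1]
            # conditional allele probabilities giving corr r at equal freqs
            prob = np.where(prev == 1, p + r * (1 - p), p * (1 - r))
            hap[:, locus] = rng.random(2 * n) < prob
        dosage = hap[:n] + hap[n:]
        for locus in range(size):
            pos += 1
            markers.append(
                GenotypeVector(
                    f"blk{b}_{locus}", ("A", "B"), dosage[:, locus],
                    chrom="1", pos=pos,
                )
            )
    return Panel(individuals=[f"ind{k:04d}" for k in range(n)], markers=markers)


def gen_intensities(
    panel: Panel, cfg: PanelConfig, rng: np.random.Generator | None = None
) -> Panel:
    """Attach two-channel Gaussian intensity clouds to every marker.

    Each individual's intensity is the centroid of its true genotype plus
    isotropic N(0, sd^2) noise; requires a complete panel.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    means = np.array([cfg.intensity_means[g] for g in (0, 1, 2)])
    for g in panel.markers:
        if g.missing_mask.any():
            raise ValueError("gen_intensities requires a complete panel")
        mu = means[g.calls]
        panel.intensities[g.marker_id] = mu + rng.normal(
            0, cfg.intensity_sd, size=mu.shape
        )
    return panel


@dataclass
class DegradedPanel:
    """A panel with deletions applied, plus the pre-deletion truth."""

    panel: Panel
    truth: np.ndarray          # complete (n_individuals, n_markers) dosages
    affected: list[str]        # markers subjected to the deletion regime

    @property
    def missing_rate(self) -> float:
        mat = self.panel.call_matrix()
        return float((mat == MISSING).mean())


def apply_missingness(
    panel: Panel, regime: MissingnessRegime, rng: np.random.Generator | None = None
) -> DegradedPanel:
    """Delete calls from a complete panel under the configured mechanism.

    Affected markers are chosen uniformly at random (``snp_fraction``).
    The returned truth matrix records the pre-deletion calls for scoring.
    """
    rng = np.random.default_rng(regime.seed) if rng is None else rng
    truth = panel.call_matrix()
    if (truth == MISSING).any():
        raise ValueError("apply_missingness requires a complete panel")
    out = panel.copy()
    n_markers = len(out.markers)
    n_affected = int(round(regime.snp_fraction * n_markers))
    idx = rng.choice(n_markers, size=n_affected, replace=False)
    affected = []
    for j in sorted(idx):
        g = out.markers[j]
        affected.append(g.marker_id)
        if regime.mechanism in ("MCAR", "MNAR"):
            pi = np.array(regime.genotype_probs())[g.calls]
        else:  # MAR-intensity: boundary-concentrated deletion
            intens = out.intensities.get(g.marker_id)
            if intens is None:
                raise ValueError(
                    f"MAR-intensity regime needs intensities for {g.marker_id}"
                )
            cents = np.array(
                [intens[g.calls == c].mean(axis=0) for c in np.unique(g.calls)]
            )
            d = np.sort(
                np.linalg.norm(intens[:, None, :] - cents[None], axis=2), axis=1
            )
            # ambiguity gap: 0 on the boundary between two clouds
            gap = d[:, 1] - d[:, 0] if d.shape[1] > 1 else d[:, 0]
            total = intens.sum(axis=1)
            z = gap + np.maximum(0.0, total - np.median(total))
            width = float(regime.probs)
            pi = regime.mar_max * np.exp(-((z / width) ** 2))
        delete = rng.random(len(g)) < pi
        g.calls = np.where(delete, MISSING, g.calls).astype(np.int8)
    return DegradedPanel(panel=out, truth=truth, affected=affected)
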