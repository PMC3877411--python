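"""Data model for diallelic genotype panels and allele intensities.

Genotype calls are stored as alternate-allele dosages: 0 (AA), 1 (AB),
2 (BB) and ``MISSING`` (-1) for no-calls.  All downstream statistics
depend only on the genotype counts, which are symmetric under allele
relabelling, so the choice of which allele is counted is cosmetic.
Positions are 1-based (VCF convention); SNPs are treated as unordered
genotype categories, so there is no strand handling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("hwmi")

#: Sentinel for a missing genotype call.
MISSING: int = -1

_SYMBOLIC = {"AA": 0, "AB": 1, "BA": 1, "BB": 2}


class DataError(ValueError):
    """Malformed or degenerate input data."""


@dataclass
class GenotypeVector:
    """Calls for one diallelic SNP across all individuals of a panel.

    Parameters
    ----------
    marker_id : str
        Marker identifier (e.g. an rs number).
    alleles : tuple of str
        Ordered allele pair; ``calls`` counts copies of the second allele.
    calls : ndarray of int8
        Per-individual dosage in {0, 1, 2} or ``MISSING``.
    chrom : str
        Chromosome name.
    pos : int
        1-based chromosomal position.
    """

    marker_id: str
    alleles: tuple[str, str]
    calls: np.ndarray
    chrom: str = "1"
    pos: int = 0

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise DataError(
                f"marker {self.marker_id}: invalid call values "
                f"{sorted(set(self.calls[bad].tolist()))}"
            )

    def __len__(self) -> int:
        return self.calls.size

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask of individuals with a missing call."""
        return self.calls == MISSING

    def copy(self) -> "GenotypeVector":
        return replace(self, calls=self.calls.copy())


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts (n_AA, n_AB, n_BB) plus the number of no-calls."""

    n_AA: int
    n_AB: int
    n_BB: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        if min(self.n_AA, self.n_AB, self.n_BB, self.n_missing) < 0:
            raise DataError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        """Observed sample size (missings excluded)."""
        return self.n_AA + self.n_AB + self.n_BB

    @property
    def n_total(self) -> int:
        """Panel size including missing calls."""
        return self.n + self.n_missing

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_AA, self.n_AB, self.n_BB)


@dataclass
class Panel:
    """A genotype panel: individuals x markers, with optional intensities.

    ``intensities`` maps marker id to an (n_individuals, 2) float array of
    A- and B-channel signals, row-aligned with ``individuals``.  Intensity
    tables are complete by assumption: the genotyping platform always
    records the raw two-channel signal even when the caller produces a
    no-call, and the MCAR diagnostics rely on that completeness.
    """

    individuals: list[str]
    markers: list[GenotypeVector]
    intensities: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.individuals)
        for g in self.markers:
            if len(g) != n:
                raise DataError(
                    f"marker {g.marker_id} has {len(g)} calls for {n} individuals"
                )
        by_chrom: dict[str, int] = {}
        for g in self.markers:
            prev = by_chrom.get(g.chrom)
            if prev is not None and g.pos <= prev:
                raise DataError(
                    f"marker positions must be strictly increasing within a "
                    f"chromosome (marker {g.marker_id} at {g.chrom}:{g.pos})"
                )
            by_chrom[g.chrom] = g.pos
        for mid, arr in self.intensities.items():
            arr = np.asarray(arr, float)
            if arr.shape != (n, 2):
                raise DataError(
                    f"intensities for {mid}: expected shape ({n}, 2), got {arr.shape}"
                )
            if not np.isfinite(arr).all():
                raise DataError(f"intensities for {mid} contain missing values")
            self.intensities[mid] = arr

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def marker_ids(self) -> list[str]:
        return [g.marker_id for g in self.markers]

    def marker(self, marker_id: str) -> GenotypeVector:
        for g in self.markers:
            if g.marker_id == marker_id:
                return g
        raise KeyError(marker_id)

    def call_matrix(self) -> np.ndarray:
        """(n_individuals, n_markers) int8 dosage matrix with MISSING = -1."""
        return np.column_stack([g.calls for g in self.markers])

    def copy(self) -> "Panel":
        return Panel(
            individuals=list(self.individuals),
            markers=[g.copy() for g in self.markers],
            intensities={k: v.copy() for k, v in self.intensities.items()},
        )


def tabulate(g: GenotypeVector) -> GenotypeCounts:
    """Count genotypes of one marker; counts partition the panel size."""
    c = g.calls
    return GenotypeCounts(
        n_AA=int((c == 0).sum()),
        n_AB=int((c == 1).sum()),
        n_BB=int((c == 2).sum()),
        n_missing=int((c == MISSING).sum()),
    )


# ---------------------------------------------------------------------------
# VCF input/output (GT field only; diallelic SNPs)
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> Panel:
    """Read a VCF 4.x file into a :class:`Panel`.

    Only diallelic SNP records are accepted; multi-allelic records are
    skipped with a warning.  Phasing is ignored and the dosage counts the
    ALT allele; ``./.`` and ``.|.`` map to :data:`MISSING`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    if not individuals:
        raise DataError(f"{path}: no individuals")
    markers: list[GenotypeVector] = []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            logger.warning(
                "skipping non-diallelic-SNP record %s:%s", rec.CHROM, rec.POS
            )
            continue
        gt = rec.genotype.array()[:, :2]
        calls = np.where((gt < 0).any(axis=1), MISSING, gt.clip(min=0).sum(axis=1))
        mid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        markers.append(
            GenotypeVector(
                marker_id=mid,
                alleles=(rec.REF, rec.ALT[0]),
                calls=calls.astype(np.int8),
                chrom=rec.CHROM,
                pos=rec.POS,
            )
        )
    return Panel(individuals=individuals, markers=markers)


def write_vcf(panel: Panel, path: str) -> None:
    """Write a panel as a minimal VCF 4.2 file (GT field only)."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = dict.fromkeys(g.chrom for g in panel.markers)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.individuals)
            + "\n"
        )
        for g in panel.markers:
            row = [
                g.chrom,
                str(g.pos),
                g.marker_id,
                g.alleles[0],
                g.alleles[1],
                ".",
                ".",
                ".",
                "GT",
            ] + [gt_str[int(c)] for c in g.calls]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Delimited genotype matrix (rows = individuals, columns = markers)
# ---------------------------------------------------------------------------

def read_matrix(path: str, missing_code: str = "NA", sep: str | None = None) -> Panel:
    """Read a delimited genotype matrix into a :class:`Panel`.

    Rows are individuals, columns are markers.  Entries are dosages
    {0, 1, 2}, symbolic genotypes {AA, AB, BB}, or ``missing_code``.
    Symbolic entries are mapped so that the alphabetically-second allele
    is counted.  Markers are placed on a single pseudo-chromosome at
    consecutive positions.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0:
        raise DataError(f"{path}: no individuals")
    individuals = [str(i) for i in df.index]
    markers = []
    for j, col in enumerate(df.columns):
        calls = np.empty(len(individuals), dtype=np.int8)
        for i, raw in enumerate(df[col]):
            token = str(raw).strip()
            if token == missing_code:
                calls[i] = MISSING
            elif token in {"0", "1", "2"}:
                calls[i] = int(token)
            elif token.upper() in _SYMBOLIC:
                calls[i] = _SYMBOLIC[token.upper()]
            else:
                raise DataError(
                    f"{path}: invalid entry {token!r} at row "
                    f"{individuals[i]!r}, column {col!r}"
                )
        markers.append(
            GenotypeVector(
                marker_id=str(col), alleles=("A", "B"), calls=calls,
                chrom="1", pos=j + 1,
            )
        )
    return Panel(individuals=individuals, markers=markers)


def write_matrix(panel: Panel, path: str, missing_code: str = "NA",
                 sep: str = "\t") -> None:
    """Write the dosage matrix of a panel as a delimited table."""
    mat = panel.call_matrix().astype(object)
    mat[mat == MISSING] = missing_code
    pd.DataFrame(mat, index=panel.individuals, columns=panel.marker_ids).to_csv(
        path, sep=sep
    )


def read_intensities(path: str, sep: str = "\t") -> dict[str, pd.DataFrame]:
    """Read a long-format intensity table (individual, marker, A, B).

    Returns a mapping marker -> DataFrame indexed by individual with
    columns A and B.  Attach to a panel with :func:`attach_intensities`,
    which joins on individual identifier rather than row order.
    """
    df = pd.read_csv(path, sep=sep, dtype={"individual": str, "marker": str})
    expected = {"individual", "marker", "A", "B"}
    if not expected.issubset(df.columns):
        raise DataError(f"{path}: expected columns {sorted(expected)}")
    return {
        mid: sub.set_index("individual")[["A", "B"]]
        for mid, sub in df.groupby("marker")
    }


def attach_intensities(panel: Panel, tables: dict[str, pd.DataFrame]) -> None:
    """Join per-marker intensity tables onto a panel by individual id."""
    for mid, tab in tables.items():
        missing_ids = set(panel.individuals) - set(tab.index)
        if missing_ids:
            raise DataError(
                f"intensities for {mid} lack individuals {sorted(missing_ids)[:5]}"
            )
        arr = tab.loc[panel.individuals, ["A", "B"]].to_numpy(float)
        if not np.isfinite(arr).all():
            raise DataError(f"intensities for {mid} contain missing values")
        panel.intensities[mid] = arr


def write_intensities(panel: Panel, path: str, sep: str = "\t") -> None:
    rows = []
    for mid, arr in panel.intensities.items():
        for ind, (a, b) in zip(panel.individuals, arr):
            rows.append((ind, mid, a, b))
    pd.DataFrame(rows, columns=["individual", "marker", "A", "B"]).to_csv(
        path, sep=sep, index=False
    )
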