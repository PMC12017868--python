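"""Core genomic containers: intervals, annotations, binned tracks, contact maps.

Coordinate convention
---------------------
All coordinates are 0-based, half-open ``[start, end)`` — BED-native.  GFF3
input is converted at the I/O boundary.  A genomic position ``p`` belongs to
bin ``p // bin_size``; intervals are quantified over every bin they overlap.
Centromeres are stored as the midpoint of the annotated CEN interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GenomeAnnotation:
    """Chromosome lengths, centromere midpoints, genes and named site sets.

    Invariants enforced on construction: exactly one centromere per
    chromosome, lying inside it; every gene and site interval lies within its
    chromosome.  Out-of-bounds intervals are an error, never clipped.
    """

    chromosomes: dict[str, int]
    centromeres: dict[str, int]
    genes: list[GenomicInterval] = field(default_factory=list)
    sites: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"non-positive length for {chrom}")
            if chrom not in self.centromeres:
                raise ValueError(f"missing centromere for chromosome {chrom}")
        for chrom, pos in self.centromeres.items():
            if chrom not in self.chromosomes:
                raise ValueError(f"centromere on unknown chromosome {chrom}")
            if not 0 <= pos < self.chromosomes[chrom]:
                raise ValueError(f"centromere of {chrom} outside [0, length)")
        for iv in self.genes:
            self._check_interval(iv, "gene")
        for name, ivs in self.sites.items():
            for iv in ivs:
                self._check_interval(iv, f"site[{name}]")

    def _check_interval(self, iv: GenomicInterval, what: str) -> None:
        if iv.chrom not in self.chromosomes:
            raise ValueError(f"{what} {iv.name or iv} on unknown chromosome {iv.chrom}")
        if iv.end > self.chromosomes[iv.chrom]:
            raise ValueError(
                f"{what} {iv.name or iv} extends beyond end of {iv.chrom} "
                f"({iv.end} > {self.chromosomes[iv.chrom]})"
            )

    @property
    def genome_size(self) -> int:
        return sum(self.chromosomes.values())

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return math.ceil(self.chromosomes[chrom] / bin_size)

    def genes_by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {c: [] for c in self.chromosomes}
        for g in self.genes:
            out[g.chrom].append(g)
        for c in out:
            out[c].sort(key=lambda g: (g.start, g.end))
        return out


@dataclass
class BinnedTrack:
    """Fixed-bin-size per-chromosome signal vectors with a validity mask.

    ``mask[chrom][i]`` is True where the bin is unquantifiable; masked bins
    are excluded from every statistic.  ``semantics`` records what the values
    mean: ``"raw"`` counts, ``"scaled"`` counts, or ``"nFE"`` (normalized
    fold-enrichment).
    """

    bin_size: int
    values: dict[str, np.ndarray]
    mask: dict[str, np.ndarray] | None = None
    semantics: str = "raw"

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.mask is None:
            self.mask = {c: np.zeros(v.shape, dtype=bool) for c, v in self.values.items()}
        for c, v in self.values.items():
            if self.mask[c].shape != v.shape:
                raise ValueError(f"mask/value shape mismatch on {c}")

    @classmethod
    def zeros(cls, annotation: GenomeAnnotation, bin_size: int, semantics: str = "raw"):
        values = {
            c: np.zeros(annotation.n_bins(c, bin_size))
            for c in annotation.chromosomes
        }
        return cls(bin_size=bin_size, values=values, semantics=semantics)

    @property
    def chroms(self) -> list[str]:
        return list(self.values)

    def total(self) -> float:
        """Genome-wide sum of values over all bins (masked included: raw
        counts in masked bins still contribute to sequencing totals)."""
        return float(sum(v.sum() for v in self.values.values()))

    def same_grid(self, other: "BinnedTrack") -> bool:
        return self.bin_size == other.bin_size and all(
            c in other.values and other.values[c].shape == v.shape
            for c, v in self.values.items()
        ) and set(self.values) == set(other.values)

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(
            bin_size=self.bin_size,
            values={c: v.copy() for c, v in self.values.items()},
            mask={c: m.copy() for c, m in self.mask.items()},
            semantics=self.semantics,
        )


@dataclass
class ContactMap:
    """A cis, symmetric, binned contact matrix for one chromosome.

    ``counts`` stores the full symmetric matrix; the convention for ``total``
    is therefore simply the matrix sum (off-diagonal pairs counted twice,
    diagonal once).  ``weights`` are optional multiplicative balancing weights
    (NaN on masked bins).
    """

    chrom: str
    bin_size: int
    counts: sp.csr_matrix
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n, m = self.counts.shape
        if n != m:
            raise ValueError("contact matrix must be square")
        asym = abs(self.counts - self.counts.T)
        if asym.nnz and asym.max() > 1e-8 * max(1.0, abs(self.counts).max()):
            raise ValueError("contact matrix is not symmetric")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (n,):
                raise ValueError("weights length mismatch")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense(), dtype=float)

    def balanced_dense(self) -> np.ndarray:
        """Dense w_i * c_ij * w_j matrix; NaN rows/cols on masked bins."""
        if self.weights is None:
            raise ValueError("map has no balancing weights; run balance_iterative")
        w = self.weights
        return self.dense() * np.outer(w, w)

    @classmethod
    def from_upper_triplets(
        cls,
        chrom: str,
        bin_size: int,
        n_bins: int,
        rows: np.ndarray,
        cols: np.ndarray,
        vals: np.ndarray,
    ) -> "ContactMap":
        rows = np.asarray(rows, dtype=int)
        cols = np.asarray(cols, dtype=int)
        vals = np.asarray(vals, dtype=float)
        if len(rows) and (rows.min() < 0 or cols.min() < 0 or max(rows.max(), cols.max()) >= n_bins):
            raise ValueError("bin index beyond grid")
        if len(vals) and vals.min() < 0:
            raise ValueError("negative counts")
        i = np.minimum(rows, cols)
        j = np.maximum(rows, cols)
        upper = sp.coo_matrix((vals, (i, j)), shape=(n_bins, n_bins)).tocsr()
        upper.sum_duplicates()
        diag = sp.diags(upper.diagonal())
        full = upper + upper.T - diag
        return cls(chrom=chrom, bin_size=bin_size, counts=full.tocsr())


@dataclass
class Loop:
    """A called chromatin loop: two anchors on one chromosome.

    ``anchor1`` is the upstream anchor.  ``length`` is the midpoint distance
    in bp.  ``category`` is one of ``centromere-originated``,
    ``cohesin-anchored``, ``other`` or None before classification.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    obs_exp: float
    q_value: float
    category: str | None = None

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("trans loops are not supported")
        if self.anchor1.start >= self.anchor2.start:
            raise ValueError("anchor1 must be upstream of anchor2")

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom

    @property
    def length(self) -> int:
        return self.anchor2.midpoint - self.anchor1.midpoint
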