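"""Domain types shared by every pipeline stage.

Coordinate convention
---------------------
All intervals are stored **0-based half-open** internally (``start`` inclusive,
``end`` exclusive), which makes overlap and length arithmetic safe.  Every file
reader/writer converts at the boundary: GFF3, cluster tables, mQTL tables and
reports all use the field-standard 1-based inclusive convention on disk, BED
uses 0-based half-open.  :meth:`GenomicInterval.from_1based` and
:meth:`GenomicInterval.to_1based` are the only two places the conversion lives.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome-anchored span, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"interval end {self.end} precedes start {self.start} on {self.chrom}"
            )

    @classmethod
    def from_1based(cls, chrom: str, start: int, end: int) -> "GenomicInterval":
        """Build from 1-based inclusive coordinates as found in GFF3/TSV files."""
        if start < 1:
            raise ValidationError(f"1-based start must be >= 1, got {start}")
        return cls(chrom, start - 1, end)

    def to_1based(self) -> tuple[str, int, int]:
        """Return (chrom, start, end) in 1-based inclusive convention."""
        return self.chrom, self.start + 1, self.end

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos0: int) -> bool:
        """True if the 0-based position lies inside the interval."""
        return self.start <= pos0 < self.end

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Intersection length in bp; 0 for disjoint or cross-chromosome pairs."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def intersects(self, other: "GenomicInterval") -> bool:
        return self.overlap_bp(other) > 0

    def expand(self, flank: int) -> "GenomicInterval":
        """Widen by ``flank`` bp on each side, clipped at the chromosome origin."""
        return GenomicInterval(self.chrom, max(0, self.start - flank), self.end + flank)


@dataclass(frozen=True)
class Gene:
    gene_id: str
    interval: GenomicInterval
    strand: str = "unknown"  # "+", "-", or "unknown"; ignored by overlap logic
    enzyme_classes: frozenset[str] = frozenset()
    protein_id: Optional[str] = None

    def with_classes(self, classes: Iterable[str]) -> "Gene":
        return replace(self, enzyme_classes=frozenset(classes))

    @property
    def is_enzyme(self) -> bool:
        return bool(self.enzyme_classes)


@dataclass(frozen=True)
class Bgc:
    """A biosynthetic gene cluster: an interval plus its member genes.

    The interval always spans exactly min(start)..max(end) of the members, all
    of which sit on one chromosome; ``class_inventory`` is the multiset of
    enzyme classes carried by the members.
    """

    bgc_id: str
    interval: GenomicInterval
    genes: tuple[Gene, ...]
    class_inventory: tuple[tuple[str, int], ...] = ()
    product_label: Optional[str] = None

    @classmethod
    def from_genes(
        cls, bgc_id: str, genes: Sequence[Gene], product_label: Optional[str] = None
    ) -> "Bgc":
        if not genes:
            raise ValidationError(f"BGC {bgc_id} has no member genes")
        chroms = {g.interval.chrom for g in genes}
        if len(chroms) != 1:
            raise ValidationError(f"BGC {bgc_id} spans chromosomes {sorted(chroms)}")
        genes = tuple(sorted(genes, key=lambda g: (g.interval.start, g.gene_id)))
        interval = GenomicInterval(
            chroms.pop(),
            min(g.interval.start for g in genes),
            max(g.interval.end for g in genes),
        )
        inventory = Counter(c for g in genes for c in sorted(g.enzyme_classes))
        return cls(bgc_id, interval, genes, tuple(sorted(inventory.items())), product_label)

    @property
    def classes(self) -> frozenset[str]:
        return frozenset(c for c, _ in self.class_inventory)

    @property
    def enzyme_genes(self) -> tuple[Gene, ...]:
        return tuple(g for g in self.genes if g.is_enzyme)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.genes)


@dataclass(frozen=True)
class Marker:
    marker_id: str
    chrom: str
    pos: int  # 1-based bp


@dataclass(frozen=True)
class Mqtl:
    """A trait-linked support interval with its peak statistic."""

    trait_id: str
    interval: GenomicInterval
    peak_pos: int  # 1-based bp
    peak_stat: float
    stat_type: str  # "LOD" or "pvalue"
    member_markers: tuple[Marker, ...] = ()

    def __post_init__(self) -> None:
        if self.stat_type not in ("LOD", "pvalue"):
            raise ValidationError(f"unknown stat_type {self.stat_type!r}")
        if self.stat_type == "LOD" and self.peak_stat < 0:
            raise ValidationError("LOD peak statistic must be >= 0")
        if self.stat_type == "pvalue" and not (0 < self.peak_stat <= 1):
            raise ValidationError("p-value peak statistic must be in (0, 1]")
        if not self.interval.contains(self.peak_pos - 1):
            raise ValidationError(
                f"peak position {self.peak_pos} outside interval "
                f"{self.interval.to_1based()} for trait {self.trait_id}"
            )


@dataclass(frozen=True)
class MetaboliteFeature:
    trait_id: str
    mz: float  # m/z in Da; treated as a neutral-mass proxy for delta matching
    rt: float
    annotation: str = ""  # empty string <=> unknown feature
    compound_class: str = ""

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValidationError(f"feature {self.trait_id}: m/z must be > 0")

    @property
    def is_unknown(self) -> bool:
        return self.annotation == ""


MAX_MISSING_FRACTION = 0.10


@dataclass
class GenotypeMatrix:
    """Individuals x markers genotype calls.

    Calls are floats with NaN for missing; RIL populations use {0, 1}
    (homozygous parental genotypes), GWAS panels additive dosage {0, 1, 2}.
    """

    individuals: list[str]
    markers: list[Marker]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        n, m = self.calls.shape
        if n != len(self.individuals) or m != len(self.markers):
            raise ValidationError(
                f"genotype matrix shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )
        by_chrom: dict[str, int] = {}
        for mk in self.markers:
            prev = by_chrom.get(mk.chrom)
            if prev is not None and mk.pos <= prev:
                raise ValidationError(
                    f"marker positions not strictly increasing on {mk.chrom} "
                    f"(marker {mk.marker_id} at {mk.pos})"
                )
            by_chrom[mk.chrom] = mk.pos
        if m:
            missing = np.isnan(self.calls).mean(axis=0)
            worst = int(np.argmax(missing))
            if missing[worst] > MAX_MISSING_FRACTION:
                raise ValidationError(
                    f"marker {self.markers[worst].marker_id} has "
                    f"{missing[worst]:.1%} missing calls (cap {MAX_MISSING_FRACTION:.0%})"
                )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for mk in self.markers:
            seen.setdefault(mk.chrom, None)
        return list(seen)

    def marker_index(self, chrom: Optional[str] = None) -> np.ndarray:
        idx = np.arange(self.n_markers)
        if chrom is None:
            return idx
        keep = np.array([mk.chrom == chrom for mk in self.markers])
        return idx[keep]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            dupes = [g for g, c in Counter(self.genes).items() if c > 1]
            raise ValidationError(f"duplicate gene ids in expression matrix: {dupes[:5]}")
        self._row: dict[str, int] = {g: i for i, g in enumerate(self.genes)}

    def profile(self, gene_id: str) -> np.ndarray:
        return self.values[self._row[gene_id]]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._row
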