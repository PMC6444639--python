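"""Superimposing mQTL intervals on BGCs, plus the supporting evidence layers.

The core operation of the pipeline is interval superposition: any positive
intersection between an mQTL support interval and a predicted cluster is a
candidate link (no minimum-fraction rule; a configurable ``min_overlap_bp``
exists and defaults to 1).  Around each link three independent evidence layers
are computed:

* marker-to-gene assignment (GWAS only): which cluster genes carry a
  significant marker within a small flank, sharpening a window-based mQTL to
  gene resolution;
* coexpression among the cluster's enzyme genes (pairwise Pearson r, flagged
  at a threshold, default 0.79);
* mass-difference linkage: metabolite features whose m/z values differ by a
  known biotransformation delta (glycosylation, methylation, ...) are likely
  biosynthetically connected, so several mQTLs hitting one cluster with
  delta-linked traits are strong evidence for a real pathway locus.

m/z values are treated as neutral-mass proxies; adduct and isotope handling
is out of scope, so delta matching operates directly on m/z differences.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from .masses import BiotransformationTable
from .model import Bgc, ExpressionMatrix, Gene, MetaboliteFeature, Mqtl, ValidationError


@dataclass(frozen=True)
class OverlapLink:
    """One BGC x mQTL superposition."""

    bgc_id: str
    trait_id: str
    mqtl: Mqtl
    overlap_bp: int
    genes_hit: tuple[str, ...] = ()  # GWAS marker-level assignment; empty for RIL

    def __post_init__(self) -> None:
        if self.overlap_bp < 1:
            raise ValidationError("overlap_bp must be >= 1")


def find_overlaps(
    mqtls: Sequence[Mqtl],
    bgcs: Sequence[Bgc],
    min_overlap_bp: int = 1,
) -> list[OverlapLink]:
    """All (mQTL, BGC) pairs on a shared chromosome with intersecting intervals.

    Candidate clusters are indexed per chromosome by sorted interval start, so
    each mQTL only examines clusters whose start precedes its end; the final
    intersection test keeps exact semantics identical to an all-pairs scan.
    Links are returned in deterministic order: cluster genomic order, then
    trait id, then mQTL start.
    """
    by_chrom: dict[str, list[Bgc]] = {}
    for b in bgcs:
        by_chrom.setdefault(b.interval.chrom, []).append(b)
    for blist in by_chrom.values():
        blist.sort(key=lambda b: (b.interval.start, b.bgc_id))

    links: list[OverlapLink] = []
    for q in mqtls:
        blist = by_chrom.get(q.interval.chrom, [])
        starts = [b.interval.start for b in blist]
        hi = bisect_right(starts, q.interval.end - 1)
        for b in blist[:hi]:
            ov = b.interval.overlap_bp(q.interval)
            if ov >= min_overlap_bp and ov > 0:
                links.append(OverlapLink(b.bgc_id, q.trait_id, q, ov))
    order = {
        b.bgc_id: (b.interval.chrom, b.interval.start, b.bgc_id)
        for blist in by_chrom.values()
        for b in blist
    }
    links.sort(key=lambda l: (order[l.bgc_id], l.trait_id, l.mqtl.interval.start))
    return links


def assign_markers_to_genes(
    mqtl: Mqtl, genes: Sequence[Gene], flank: int = 2_000
) -> list[str]:
    """Gene ids whose flank-expanded interval contains a member marker.

    Used on GWAS mQTLs to resolve which genes the significant markers actually
    sit in or next to.  Overlapping genes both claim a shared marker (no
    arbitration); the result is deduplicated, in genomic order.
    """
    hit: list[Gene] = []
    for g in genes:
        if g.interval.chrom != mqtl.interval.chrom:
            continue
        span = g.interval.expand(flank)
        if any(span.contains(m.pos - 1) for m in mqtl.member_markers):
            hit.append(g)
    hit.sort(key=lambda g: (g.interval.start, g.gene_id))
    seen: dict[str, None] = {}
    for g in hit:
        seen.setdefault(g.gene_id, None)
    return list(seen)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN for degenerate (zero-variance) input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("pearson_r needs two equal-length vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("pearson_r requires finite values")
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class CoexpressionSupport:
    """Pairwise expression correlations among a cluster's enzyme genes."""

    bgc_id: str
    pairs: list[tuple[str, str, float]]
    max_r: float  # NaN when no usable pair
    mean_r: float
    n_pairs: int
    n_missing_genes: int
    flagged: bool


def coexpression_support(
    bgc: Bgc, expr: ExpressionMatrix, r_min: float = 0.79
) -> CoexpressionSupport:
    """All pairwise Pearson r among the cluster's class-bearing member genes.

    Genes absent from the expression matrix are skipped and counted.  The
    cluster is flagged when the maximum pairwise r reaches ``r_min`` —
    coexpressed enzyme genes are what distinguishes a co-regulated pathway
    locus from a coincidental gene neighbourhood.  Fewer than two usable genes
    yields an unflagged support with ``n_pairs`` 0.
    """
    usable = [g.gene_id for g in bgc.enzyme_genes if g.gene_id in expr]
    n_missing = len(bgc.enzyme_genes) - len(usable)
    pairs: list[tuple[str, str, float]] = []
    for i, ga in enumerate(usable):
        for gb in usable[i + 1 :]:
            r = pearson_r(expr.profile(ga), expr.profile(gb))
            pairs.append((ga, gb, r))
    rs = np.array([r for _, _, r in pairs if not math.isnan(r)])
    max_r = float(rs.max()) if rs.size else float("nan")
    mean_r = float(rs.mean()) if rs.size else float("nan")
    flagged = bool(rs.size) and max_r >= r_min
    return CoexpressionSupport(
        bgc.bgc_id, pairs, max_r, mean_r, len(pairs), n_missing, flagged
    )


def massdiff_edges(
    features: Sequence[MetaboliteFeature], table: BiotransformationTable
) -> list[tuple[str, str, str]]:
    """Biotransformation edges among features, matched by m/z difference.

    For each unordered feature pair an edge is emitted when the absolute m/z
    difference matches a table delta within
    ``max(tolerance_abs, tolerance_ppm * mean_mz * 1e-6)``; ties across table
    entries resolve to the smallest absolute deviation.  Edges are returned
    with trait ids in sorted order per pair, so the result is independent of
    input ordering.
    """
    feats = sorted(features, key=lambda f: f.trait_id)
    edges: list[tuple[str, str, str]] = []
    for i, fa in enumerate(feats):
        for fb in feats[i + 1 :]:
            dmz = abs(fa.mz - fb.mz)
            tol = table.tolerance_at((fa.mz + fb.mz) / 2.0)
            best: Optional[tuple[float, str]] = None
            for name, delta in table.entries:
                dev = abs(dmz - delta)
                if dev <= tol and (best is None or dev < best[0]):
                    best = (dev, name)
            if best is not None:
                edges.append((fa.trait_id, fb.trait_id, best[1]))
    return edges


def linked_components(
    edges: Iterable[tuple[str, str, str]], traits: Iterable[str]
) -> list[frozenset[str]]:
    """Connected components of the mass-difference graph restricted to ``traits``.

    Typically called with the traits whose mQTLs hit one cluster: a multi-trait
    component means the cluster is linked to a family of biosynthetically
    connected molecules.  Singletons are included.  Components are returned
    sorted by size (descending) then lexicographically.
    """
    keep = set(traits)
    g = nx.Graph()
    g.add_nodes_from(keep)
    for a, b, _ in edges:
        if a in keep and b in keep:
            g.add_edge(a, b)
    comps = [frozenset(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), sorted(c)))
    return comps
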