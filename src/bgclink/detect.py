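"""Enzyme-class assignment and candidate BGC detection.

Plant BGC predictors cluster physically adjacent genes that carry biosynthetic
protein domains.  This module implements a deliberately simple proxy for that
logic: genes are labelled with enzyme classes from externally supplied
profile-domain hits, and runs of class-bearing genes separated by at most
``max_gap`` bp are emitted as candidate clusters when they contain enough
enzyme genes (default 3) of enough distinct classes (default 2).  Full
predictor output can be supplied instead via :func:`bgclink.io.read_cluster_table`;
the pipeline treats cluster prediction as an upstream given either way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .io import PathLike
from .model import Bgc, Gene, GenomicInterval, ValidationError

log = logging.getLogger(__name__)

#: classes regarded as scaffold-generating by default: enzymes that build the
#: core skeleton of a specialized metabolite, as opposed to decorating it
DEFAULT_SCAFFOLD_CLASSES = frozenset(
    {"synthase", "chalcone_stilbene_synthase", "terpene_synthase",
     "oxidosqualene_cyclase", "dirigent"}
)


@dataclass(frozen=True)
class EnzymeClassMap:
    """Mapping from protein domain/profile ids to enzyme class labels."""

    domain_to_class: dict[str, str]
    scaffold_classes: frozenset[str] = DEFAULT_SCAFFOLD_CLASSES

    def __post_init__(self) -> None:
        known = set(self.domain_to_class.values())
        stray = self.scaffold_classes - known
        if stray:
            raise ValidationError(
                f"scaffold classes not present in the domain map: {sorted(stray)}"
            )

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "EnzymeClassMap":
        """Build from a table with columns domain_id, class, scaffold_flag."""
        mapping = dict(zip(df["domain_id"].astype(str), df["class"].astype(str)))
        scaffold = frozenset(
            df.loc[df["scaffold_flag"].astype(bool), "class"].astype(str)
        )
        return cls(mapping, scaffold)

    @classmethod
    def read(cls, path: PathLike) -> "EnzymeClassMap":
        return cls.from_table(pd.read_csv(path, sep="\t"))

    def write(self, path: PathLike) -> None:
        rows = [
            {"domain_id": d, "class": c, "scaffold_flag": c in self.scaffold_classes}
            for d, c in sorted(self.domain_to_class.items())
        ]
        pd.DataFrame(rows, columns=["domain_id", "class", "scaffold_flag"]).to_csv(
            path, sep="\t", index=False
        )


def default_class_map() -> EnzymeClassMap:
    """A small default domain->class map covering common plant pathway enzymes."""
    domain_to_class = {
        "chal_sti_synt": "chalcone_stilbene_synthase",
        "terpene_synth": "terpene_synthase",
        "squalene_cyclase": "oxidosqualene_cyclase",
        "dirigent_domain": "dirigent",
        "pks_ks": "synthase",
        "dioxygenase_domain": "dioxygenase",
        "p450_domain": "cytochrome_p450",
        "udp_gt": "glycosyltransferase",
        "transferase_domain": "acyltransferase",
        "methyltransf": "methyltransferase",
        "oxidase_domain": "oxidase",
        "epimerase_domain": "epimerase",
    }
    return EnzymeClassMap(dict(sorted(domain_to_class.items())))


def assign_enzyme_classes(
    genes: Sequence[Gene],
    domain_hits: pd.DataFrame,
    class_map: EnzymeClassMap,
    min_score: float = 20.0,
) -> list[Gene]:
    """Fill ``enzyme_classes`` from domain hits scoring at least ``min_score``.

    ``domain_hits`` has columns gene_id, domain_id, score (e.g. profile-HMM
    bit scores from an external scan).  Hits on unknown genes are errors; hits
    to domains absent from the class map are ignored.  Returns a new gene list
    in the input order; genes without qualifying hits keep empty class sets.
    """
    known = {g.gene_id for g in genes}
    unknown = set(domain_hits["gene_id"].astype(str)) - known
    if unknown:
        raise ValidationError(
            f"domain hits reference unknown genes: {sorted(unknown)[:5]}"
        )
    passing = domain_hits[domain_hits["score"] >= min_score]
    classes_by_gene: dict[str, set[str]] = {}
    for row in passing.itertuples(index=False):
        cls = class_map.domain_to_class.get(str(row.domain_id))
        if cls is not None:
            classes_by_gene.setdefault(str(row.gene_id), set()).add(cls)
    return [g.with_classes(classes_by_gene.get(g.gene_id, set())) for g in genes]


def _sorted_by_position(genes: Sequence[Gene]) -> dict[str, list[Gene]]:
    per_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        per_chrom.setdefault(g.interval.chrom, []).append(g)
    for chrom, glist in per_chrom.items():
        starts = [g.interval.start for g in glist]
        if starts != sorted(starts):
            raise ValidationError(f"annotation not sorted by position on {chrom}")
    return dict(sorted(per_chrom.items()))


def detect_bgcs(
    genes: Sequence[Gene],
    min_biosynthetic_genes: int = 3,
    min_distinct_classes: int = 2,
    max_gap: int = 10_000,
) -> list[Bgc]:
    """Detect candidate clusters by greedy chaining of enzyme genes.

    Consecutive class-bearing genes whose intervals lie at most ``max_gap`` bp
    apart (measured end -> next start) join one chain; class-free genes in
    between become members but neither extend nor break the chain.  A chain is
    emitted iff it holds at least ``min_biosynthetic_genes`` enzyme genes of at
    least ``min_distinct_classes`` distinct classes.  The annotation must be
    position-sorted within each chromosome; cluster ids are assigned in
    genomic order.
    """
    per_chrom = _sorted_by_position(genes)
    raw: list[list[Gene]] = []
    for chrom, glist in per_chrom.items():
        chain: list[Gene] = []        # members incl. interleaved class-free genes
        last_enzyme: Optional[Gene] = None
        pending: list[Gene] = []      # class-free genes since the last enzyme gene
        for g in glist:
            if not g.is_enzyme:
                if last_enzyme is not None:
                    pending.append(g)
                continue
            gap = g.interval.start - last_enzyme.interval.end if last_enzyme else 0
            if last_enzyme is not None and gap <= max_gap:
                chain.extend(pending)
                chain.append(g)
            else:
                if chain:
                    raw.append(chain)
                chain = [g]
            pending = []
            last_enzyme = g
        if chain:
            raw.append(chain)

    kept = []
    for chain in raw:
        enzymes = [g for g in chain if g.is_enzyme]
        distinct = set().union(*(g.enzyme_classes for g in enzymes))
        if len(enzymes) >= min_biosynthetic_genes and len(distinct) >= min_distinct_classes:
            kept.append(chain)
    kept.sort(key=lambda c: (c[0].interval.chrom, c[0].interval.start))
    width = max(3, len(str(len(kept))))
    return [
        Bgc.from_genes(f"bgc_{i + 1:0{width}d}", chain) for i, chain in enumerate(kept)
    ]


def annotate_region(
    genes: Sequence[Gene], region: GenomicInterval
) -> pd.DataFrame:
    """Tabulate genes intersecting ``region`` together with their enzyme classes.

    Supports scanning arbitrary loci (e.g. mQTL intervals) for enzyme-coding
    genes without requiring a predicted cluster.  An unknown chromosome yields
    an empty table (logged), not an error.  Rows are in genomic order with
    1-based coordinates.
    """
    hits = [
        g for g in genes
        if g.interval.chrom == region.chrom and g.interval.intersects(region)
    ]
    if not any(g.interval.chrom == region.chrom for g in genes):
        log.warning("annotate_region: chromosome %r absent from annotation", region.chrom)
    hits.sort(key=lambda g: (g.interval.start, g.gene_id))
    rows = []
    for g in hits:
        chrom, start, end = g.interval.to_1based()
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": g.strand,
                "enzyme_classes": ",".join(sorted(g.enzyme_classes)),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "enzyme_classes"]
    )
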