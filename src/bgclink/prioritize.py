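"""Classify and rank candidate BGC–metabolite links.

The qualitative logic: a cluster overlapped only by mQTLs of unannotated
metabolites is a **discovery candidate** (novel chemistry); a cluster whose
overlapping annotated metabolite is pathway-compatible with its enzyme
inventory is **known-compatible**; annotated metabolites with no compatible
enzyme class mark the cluster as a **putative false positive**; a mixture of
compatible and unknown traits is **mixed**.  On top of the labels, a
configurable weighted sum over five boolean evidence flags gives a ranking
score:

* ``multi_mqtl`` — at least two mQTLs hit the cluster;
* ``multi_gene`` — significant markers map to at least two distinct member
  genes (GWAS only);
* ``massdiff`` — at least two of the cluster's traits form one
  mass-difference component (biosynthetically connected molecules);
* ``coexpression`` — enzyme genes in the cluster are coexpressed above the
  threshold;
* ``compatibility`` — an annotated trait matches the enzyme inventory.

The flag taxonomy and unit default weights are this package's explicit
operationalisation of evidence that is usually argued case by case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .model import Bgc, MetaboliteFeature, Mqtl, ValidationError
from .overlap import CoexpressionSupport, OverlapLink

LABEL_DISCOVERY = "discovery_candidate"
LABEL_COMPATIBLE = "known_compatible"
LABEL_FALSE_POSITIVE = "known_incompatible_or_false_positive"
LABEL_MIXED = "mixed"


@dataclass(frozen=True)
class CompatibilityMap:
    """compound_class -> enzyme classes considered pathway-compatible."""

    mapping: dict[str, frozenset[str]]

    def compatible(self, compound_class: str, enzyme_classes: Iterable[str]) -> bool:
        allowed = self.mapping.get(compound_class)
        if allowed is None:
            return False
        return bool(allowed & set(enzyme_classes))


def default_compatibility_map() -> CompatibilityMap:
    """Small default pairing of compound classes with plausible enzyme classes."""
    return CompatibilityMap(
        {
            "lignan": frozenset({"dirigent", "dioxygenase"}),
            "flavonoid": frozenset(
                {"chalcone_stilbene_synthase", "glycosyltransferase", "acyltransferase"}
            ),
            "terpene": frozenset({"terpene_synthase", "oxidosqualene_cyclase"}),
        }
    )


@dataclass
class EvidenceWeights:
    w_multi_mqtl: float = 1.0
    w_multi_gene: float = 1.0
    w_massdiff: float = 1.0
    w_coexpr: float = 1.0
    w_compat: float = 1.0

    def __post_init__(self) -> None:
        for name, w in vars(self).items():
            if w < 0:
                raise ValidationError(f"evidence weight {name} must be non-negative")


@dataclass
class CandidateLink:
    """One cluster with all its mQTL evidence, classified and scored."""

    bgc: Bgc
    trait_ids: tuple[str, ...]
    class_label: str
    n_mqtls: int
    n_distinct_genes_hit: int
    massdiff_component_size: int
    coexpression_flagged: bool
    compatibility_match: bool
    score: float = 0.0
    rank: int = 0

    @property
    def flags(self) -> dict[str, bool]:
        return {
            "multi_mqtl": self.n_mqtls >= 2,
            "multi_gene": self.n_distinct_genes_hit >= 2,
            "massdiff": self.massdiff_component_size >= 2,
            "coexpression": self.coexpression_flagged,
            "compatibility": self.compatibility_match,
        }

    def evidence_note(self) -> str:
        """Human-readable sentence describing which evidence fired."""
        bits = []
        if self.flags["multi_mqtl"]:
            bits.append(f"{self.n_mqtls} mQTLs overlap this cluster")
        if self.flags["multi_gene"]:
            bits.append(
                f"significant markers map to {self.n_distinct_genes_hit} distinct member genes"
            )
        if self.flags["massdiff"]:
            bits.append(
                f"{self.massdiff_component_size} overlapping traits are linked by "
                "known mass differences"
            )
        if self.flags["coexpression"]:
            bits.append("enzyme genes in the cluster are coexpressed")
        if self.flags["compatibility"]:
            bits.append("an annotated trait matches the enzyme inventory")
        return "; ".join(bits) if bits else "single-mQTL overlap only"

    def to_record(self) -> dict:
        chrom, start, end = self.bgc.interval.to_1based()
        f = self.flags
        return {
            "rank": self.rank,
            "bgc_id": self.bgc.bgc_id,
            "trait_ids": ",".join(self.trait_ids),
            "class_label": self.class_label,
            "score": self.score,
            "multi_mqtl": int(f["multi_mqtl"]),
            "multi_gene": int(f["multi_gene"]),
            "massdiff": int(f["massdiff"]),
            "coexpression": int(f["coexpression"]),
            "compatibility": int(f["compatibility"]),
            "chrom": chrom,
            "start": start,
            "end": end,
            "n_mqtls": self.n_mqtls,
            "evidence_note": self.evidence_note(),
        }


def classify_bgc(
    bgc: Bgc,
    links: Sequence[OverlapLink],
    features_by_id: dict[str, MetaboliteFeature],
    compatibility: Optional[CompatibilityMap] = None,
) -> str:
    """Assign one of the four class labels from the overlapping traits.

    Precedence: all traits unannotated -> discovery candidate; no annotated
    trait compatible -> putative false positive; otherwise known-compatible,
    downgraded to mixed when unknown traits ride along with the compatible
    ones.  Raises when the cluster has no links (such clusters are excluded
    from the report upstream).
    """
    if not links:
        raise ValidationError(f"cluster {bgc.bgc_id} has no overlap links to classify")
    compatibility = compatibility or default_compatibility_map()
    traits = [features_by_id.get(l.trait_id) for l in links]
    annotated = [f for f in traits if f is not None and not f.is_unknown]
    n_unknown = len(links) - len(annotated)
    if not annotated:
        return LABEL_DISCOVERY
    any_compat = any(
        compatibility.compatible(f.compound_class, bgc.classes) for f in annotated
    )
    if not any_compat:
        return LABEL_FALSE_POSITIVE
    return LABEL_MIXED if n_unknown > 0 else LABEL_COMPATIBLE


def score_bgc(flags: dict[str, bool], weights: Optional[EvidenceWeights] = None) -> float:
    """Weighted sum over satisfied evidence flags."""
    w = weights or EvidenceWeights()
    return (
        w.w_multi_mqtl * flags["multi_mqtl"]
        + w.w_multi_gene * flags["multi_gene"]
        + w.w_massdiff * flags["massdiff"]
        + w.w_coexpr * flags["coexpression"]
        + w.w_compat * flags["compatibility"]
    )


def rank_candidates(candidates: Sequence[CandidateLink]) -> list[CandidateLink]:
    """Strict total order: score desc, supporting mQTLs desc, position, id."""
    ordered = sorted(
        candidates,
        key=lambda c: (
            -c.score,
            -c.n_mqtls,
            c.bgc.interval.chrom,
            c.bgc.interval.start,
            c.bgc.bgc_id,
        ),
    )
    for i, c in enumerate(ordered, start=1):
        c.rank = i
    return ordered


def build_candidates(
    bgcs: Sequence[Bgc],
    links: Sequence[OverlapLink],
    features: Sequence[MetaboliteFeature],
    massdiff_components: dict[str, list[frozenset[str]]],
    coexpression: dict[str, CoexpressionSupport],
    genes_hit: Optional[dict[tuple[str, str], Sequence[str]]] = None,
    compatibility: Optional[CompatibilityMap] = None,
    weights: Optional[EvidenceWeights] = None,
) -> list[CandidateLink]:
    """Aggregate per-cluster evidence into ranked :class:`CandidateLink` records.

    ``massdiff_components`` maps bgc_id to the mass-difference components of
    its overlapping traits; ``coexpression`` maps bgc_id to its support;
    ``genes_hit`` optionally maps (bgc_id, trait_id) to marker-assigned gene
    ids (GWAS).  Clusters without links are skipped.
    """
    compatibility = compatibility or default_compatibility_map()
    features_by_id = {f.trait_id: f for f in features}
    links_by_bgc: dict[str, list[OverlapLink]] = {}
    for l in links:
        links_by_bgc.setdefault(l.bgc_id, []).append(l)
    candidates = []
    for bgc in bgcs:
        blinks = links_by_bgc.get(bgc.bgc_id)
        if not blinks:
            continue
        trait_ids = tuple(sorted({l.trait_id for l in blinks}))
        label = classify_bgc(bgc, blinks, features_by_id, compatibility)
        hit_genes: set[str] = set()
        if genes_hit:
            for l in blinks:
                hit_genes.update(genes_hit.get((bgc.bgc_id, l.trait_id), ()))
        comps = massdiff_components.get(bgc.bgc_id, [])
        comp_size = max((len(c) for c in comps), default=1 if trait_ids else 0)
        coex = coexpression.get(bgc.bgc_id)
        annotated = [
            features_by_id[t]
            for t in trait_ids
            if t in features_by_id and not features_by_id[t].is_unknown
        ]
        compat = any(
            compatibility.compatible(f.compound_class, bgc.classes) for f in annotated
        )
        cand = CandidateLink(
            bgc=bgc,
            trait_ids=trait_ids,
            class_label=label,
            n_mqtls=len(blinks),
            n_distinct_genes_hit=len(hit_genes),
            massdiff_component_size=comp_size,
            coexpression_flagged=bool(coex and coex.flagged),
            compatibility_match=compat,
        )
        cand.score = score_bgc(cand.flags, weights)
        candidates.append(cand)
    return rank_candidates(candidates)
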