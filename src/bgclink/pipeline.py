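"""End-to-end orchestration: detect clusters, map mQTLs, overlay, prioritize.

This is the in-memory backbone behind the ``run-all`` CLI subcommand and the
recovery tests: it takes a :class:`~bgclink.simulate.StudyData` (or the
equivalent objects loaded from files) and produces the ranked candidate
report plus all intermediate artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import io as bio
from .detect import detect_bgcs
from .mapping import MappingConfig, call_mqtls_gwas, call_mqtls_ril, gwas_scan
from .masses import BiotransformationTable, default_biotransformations
from .model import Bgc, ExpressionMatrix, Gene, GenotypeMatrix, MetaboliteFeature, Mqtl
from .overlap import (
    CoexpressionSupport,
    OverlapLink,
    assign_markers_to_genes,
    coexpression_support,
    find_overlaps,
    linked_components,
    massdiff_edges,
)
from .prioritize import (
    CandidateLink,
    CompatibilityMap,
    EvidenceWeights,
    build_candidates,
)


@dataclass
class PipelineResult:
    bgcs: list[Bgc]
    mqtls: list[Mqtl]
    links: list[OverlapLink]
    massdiff: list[tuple[str, str, str]]
    coexpression: dict[str, CoexpressionSupport]
    candidates: list[CandidateLink]

    def top(self) -> Optional[CandidateLink]:
        return self.candidates[0] if self.candidates else None

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bio.write_cluster_table(self.bgcs, out / "clusters.tsv")
        bio.write_mqtl_table(self.mqtls, out / "mqtls.tsv")
        bio.write_mqtl_bed(self.mqtls, out / "mqtls.bed")
        pd.DataFrame(
            self.massdiff, columns=["trait_a", "trait_b", "transformation"]
        ).to_csv(out / "massdiff_edges.tsv", sep="\t", index=False)
        bio.write_candidate_report(self.candidates, out / "report.tsv", "tsv")
        bio.write_candidate_report(self.candidates, out / "report.json", "json")


def run_pipeline(
    genes: Sequence[Gene],
    genotypes: GenotypeMatrix,
    traits: pd.DataFrame,
    features: Sequence[MetaboliteFeature],
    expression: Optional[ExpressionMatrix] = None,
    population: str = "ril",
    bgcs: Optional[Sequence[Bgc]] = None,
    mapping_config: Optional[MappingConfig] = None,
    delta_table: Optional[BiotransformationTable] = None,
    compatibility: Optional[CompatibilityMap] = None,
    weights: Optional[EvidenceWeights] = None,
    coexpr_r_min: float = 0.79,
    marker_gene_flank: int = 2_000,
    seed: int = 0,
    min_biosynthetic_genes: int = 3,
    min_distinct_classes: int = 2,
    max_gap: int = 10_000,
) -> PipelineResult:
    """Run the full strategy on in-memory inputs.

    ``bgcs`` may be supplied (externally predicted clusters); otherwise the
    built-in detector runs on the annotation.  ``population`` selects the
    mapping regime ("ril" LOD scans, "gwas" PC-covariate regression).
    """
    config = mapping_config or MappingConfig()
    table = delta_table or default_biotransformations()
    if bgcs is None:
        bgcs = detect_bgcs(
            genes,
            min_biosynthetic_genes=min_biosynthetic_genes,
            min_distinct_classes=min_distinct_classes,
            max_gap=max_gap,
        )
    bgcs = list(bgcs)

    if population == "ril":
        mqtls = call_mqtls_ril(genotypes, traits, config, seed=seed)
    elif population == "gwas":
        scans = [
            gwas_scan(
                genotypes,
                traits[t].to_numpy(float),
                n_pcs=config.n_pcs,
                trait_id=str(t),
            )
            for t in traits.columns
        ]
        chrom_len = {}
        for m in genotypes.markers:
            chrom_len[m.chrom] = max(chrom_len.get(m.chrom, 0), m.pos)
        mqtls = call_mqtls_gwas(scans, config, chrom_lengths=chrom_len)
    else:
        raise ValueError(f"unknown population kind {population!r}")

    links = find_overlaps(mqtls, bgcs)

    edges = massdiff_edges(features, table)
    traits_by_bgc: dict[str, set[str]] = {}
    for l in links:
        traits_by_bgc.setdefault(l.bgc_id, set()).add(l.trait_id)
    components = {
        bgc_id: linked_components(edges, sorted(ts))
        for bgc_id, ts in traits_by_bgc.items()
    }

    coex: dict[str, CoexpressionSupport] = {}
    if expression is not None:
        for b in bgcs:
            if b.bgc_id in traits_by_bgc:
                coex[b.bgc_id] = coexpression_support(b, expression, r_min=coexpr_r_min)

    genes_hit: dict[tuple[str, str], list[str]] = {}
    if population == "gwas":
        for l in links:
            member_ids = set(next(b for b in bgcs if b.bgc_id == l.bgc_id).gene_ids)
            assigned = assign_markers_to_genes(l.mqtl, genes, flank=marker_gene_flank)
            genes_hit[(l.bgc_id, l.trait_id)] = [g for g in assigned if g in member_ids]

    candidates = build_candidates(
        bgcs,
        links,
        features,
        components,
        coex,
        genes_hit=genes_hit or None,
        compatibility=compatibility,
        weights=weights,
    )
    return PipelineResult(bgcs, mqtls, links, edges, coex, candidates)
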