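"""Readers and writers for every on-disk format the pipeline touches.

Standard formats: GFF3 for gene annotations (parsed with :mod:`gffutils`),
BED for mQTL interval export.  The remaining tables are explicit TSV dialects
(documented per function) chosen over tool-native output formats, which vary
by tool version.  All files carry 1-based inclusive coordinates except BED;
conversion to the internal 0-based half-open convention happens here and only
here.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line

from .model import (
    Bgc,
    ExpressionMatrix,
    Gene,
    GenomicInterval,
    GenotypeMatrix,
    Marker,
    MetaboliteFeature,
    Mqtl,
    ValidationError,
)

PathLike = Union[str, Path]

_FLOAT_FMT = "%.10g"


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line."""


# ---------------------------------------------------------------------------
# GFF3 gene annotations
# ---------------------------------------------------------------------------

def read_gff3(path: PathLike, feature_kind: str = "gene") -> list[Gene]:
    """Read genes from a GFF3 file.

    One :class:`Gene` is returned per feature of type ``feature_kind``, with
    1-based inclusive GFF3 coordinates converted internally and strand
    preserved.  Enzyme class sets start empty; they are filled later from
    domain hits.  Malformed lines (fewer than 9 tab-separated columns) raise
    :class:`ParseError` naming the line number.
    """
    genes: list[Gene] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.split("\t")) < 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns"
                )
            feat = feature_from_line(line)
            if feat.featuretype != feature_kind:
                continue
            if feat.start > feat.end:
                raise ValidationError(
                    f"{path}: line {lineno}: start {feat.start} > end {feat.end}"
                )
            attrs = feat.attributes
            gene_id = (attrs.get("ID") or attrs.get("Name") or [f"feature_{lineno}"])[0]
            protein = attrs.get("protein_id")
            strand = feat.strand if feat.strand in ("+", "-") else "unknown"
            genes.append(
                Gene(
                    gene_id=gene_id,
                    interval=GenomicInterval.from_1based(feat.seqid, feat.start, feat.end),
                    strand=strand,
                    protein_id=protein[0] if protein else None,
                )
            )
    return genes


def write_gff3(genes: Sequence[Gene], path: PathLike, source: str = "bgclink") -> None:
    """Write genes as GFF3 ``gene`` features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start)):
            chrom, start, end = g.interval.to_1based()
            strand = g.strand if g.strand in ("+", "-") else "."
            attrs = f"ID={g.gene_id}"
            if g.protein_id:
                attrs += f";protein_id={g.protein_id}"
            fh.write(
                f"{chrom}\t{source}\tgene\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Cluster tables (predicted BGCs)
# ---------------------------------------------------------------------------

CLUSTER_COLUMNS = ["bgc_id", "chrom", "start", "end", "product_label", "gene_ids"]


def read_cluster_table(path: PathLike, genes: Sequence[Gene]) -> list[Bgc]:
    """Read externally predicted clusters from the TSV dialect.

    Columns: bgc_id, chrom, start, end (1-based inclusive), product_label,
    gene_ids (comma-separated).  Member genes are resolved against the
    annotation and the class inventory recomputed from it; a gene id absent
    from the annotation, or a member gene outside the stated span, is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in CLUSTER_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing columns {missing_cols}")
    by_id = {g.gene_id: g for g in genes}
    bgcs: list[Bgc] = []
    for row in df.itertuples(index=False):
        span = GenomicInterval.from_1based(row.chrom, int(row.start), int(row.end))
        members: list[Gene] = []
        for gid in filter(None, (s.strip() for s in row.gene_ids.split(","))):
            if gid not in by_id:
                raise ValidationError(
                    f"{path}: cluster {row.bgc_id} references unknown gene {gid!r}"
                )
            gene = by_id[gid]
            if gene.interval.chrom != span.chrom or not (
                span.start <= gene.interval.start and gene.interval.end <= span.end
            ):
                raise ValidationError(
                    f"{path}: gene {gid} lies outside cluster {row.bgc_id} span"
                )
            members.append(gene)
        bgc = Bgc.from_genes(row.bgc_id, members, product_label=row.product_label or None)
        bgcs.append(bgc)
    return bgcs


def write_cluster_table(bgcs: Sequence[Bgc], path: PathLike) -> None:
    rows = []
    for b in bgcs:
        chrom, start, end = b.interval.to_1based()
        rows.append(
            {
                "bgc_id": b.bgc_id,
                "chrom": chrom,
                "start": start,
                "end": end,
                "product_label": b.product_label or "",
                "gene_ids": ",".join(b.gene_ids),
            }
        )
    pd.DataFrame(rows, columns=CLUSTER_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Metabolite feature metadata
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = ["trait_id", "mz", "rt", "annotation", "compound_class"]


def read_feature_table(path: PathLike) -> list[MetaboliteFeature]:
    """Read feature metadata (trait_id, mz, rt, annotation, compound_class).

    Empty annotation marks the feature as unknown.  Duplicate trait ids and
    non-numeric m/z values are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing columns {missing_cols}")
    dupes = df["trait_id"][df["trait_id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicate trait ids {sorted(set(dupes))[:5]}")
    features = []
    for row in df.itertuples(index=False):
        try:
            mz = float(row.mz)
            rt = float(row.rt)
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric mz/rt for trait {row.trait_id}") from exc
        features.append(
            MetaboliteFeature(row.trait_id, mz, rt, row.annotation, row.compound_class)
        )
    return features


def write_feature_table(features: Sequence[MetaboliteFeature], path: PathLike) -> None:
    rows = [
        {
            "trait_id": f.trait_id,
            "mz": f.mz,
            "rt": f.rt,
            "annotation": f.annotation,
            "compound_class": f.compound_class,
        }
        for f in features
    ]
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


# ---------------------------------------------------------------------------
# Genotypes, marker maps, trait and expression matrices
# ---------------------------------------------------------------------------

def read_marker_map(path: PathLike) -> list[Marker]:
    """Marker map TSV: marker_id, chrom, pos (1-based bp)."""
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str, "pos": int})
    return [Marker(r.marker_id, r.chrom, int(r.pos)) for r in df.itertuples(index=False)]


def write_marker_map(markers: Sequence[Marker], path: PathLike) -> None:
    pd.DataFrame(
        [{"marker_id": m.marker_id, "chrom": m.chrom, "pos": m.pos} for m in markers]
    ).to_csv(path, sep="\t", index=False)


def read_genotype_matrix(path: PathLike, marker_map_path: PathLike) -> GenotypeMatrix:
    """Genotype TSV: first column ``individual``, remaining columns marker ids.

    Missing calls are empty cells or ``NA``.  Marker order follows the
    companion marker map; every marker in the map must appear as a column.
    """
    markers = read_marker_map(marker_map_path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    missing = [m.marker_id for m in markers if m.marker_id not in df.columns]
    if missing:
        raise ParseError(f"{path}: markers missing from genotype matrix: {missing[:5]}")
    calls = df[[m.marker_id for m in markers]].to_numpy(dtype=float)
    return GenotypeMatrix(list(df.index.astype(str)), markers, calls)


def write_genotype_matrix(gm: GenotypeMatrix, path: PathLike) -> None:
    df = pd.DataFrame(
        gm.calls, index=pd.Index(gm.individuals, name="individual"),
        columns=[m.marker_id for m in gm.markers],
    )
    df.to_csv(path, sep="\t", float_format="%g", na_rep="NA")


def read_trait_matrix(path: PathLike) -> pd.DataFrame:
    """Trait matrix TSV: individuals (rows) x trait ids (columns)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_trait_matrix(traits: pd.DataFrame, path: PathLike) -> None:
    traits.to_csv(path, sep="\t", index_label="individual", float_format=_FLOAT_FMT)


def read_expression_matrix(path: PathLike) -> ExpressionMatrix:
    """Expression TSV: gene ids (rows) x sample ids (columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(float)
    )


def write_expression_matrix(em: ExpressionMatrix, path: PathLike) -> None:
    pd.DataFrame(
        em.values, index=pd.Index(em.genes, name="gene_id"), columns=em.samples
    ).to_csv(path, sep="\t", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Domain hits and enzyme-class maps
# ---------------------------------------------------------------------------

def read_domain_hits(path: PathLike) -> pd.DataFrame:
    """Domain hit TSV: gene_id, domain_id, score."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "domain_id": str})
    needed = {"gene_id", "domain_id", "score"}
    if not needed.issubset(df.columns):
        raise ParseError(f"{path}: domain hits need columns {sorted(needed)}")
    return df


def write_domain_hits(hits: pd.DataFrame, path: PathLike) -> None:
    hits[["gene_id", "domain_id", "score"]].to_csv(
        path, sep="\t", index=False, float_format="%g"
    )


# ---------------------------------------------------------------------------
# mQTL tables
# ---------------------------------------------------------------------------

MQTL_COLUMNS = [
    "trait_id", "chrom", "start", "end", "peak_pos", "peak_stat", "stat_type",
    "marker_ids",
]


def write_mqtl_table(mqtls: Sequence[Mqtl], path: PathLike) -> None:
    rows = []
    for q in mqtls:
        chrom, start, end = q.interval.to_1based()
        rows.append(
            {
                "trait_id": q.trait_id,
                "chrom": chrom,
                "start": start,
                "end": end,
                "peak_pos": q.peak_pos,
                "peak_stat": q.peak_stat,
                "stat_type": q.stat_type,
                "marker_ids": ",".join(m.marker_id for m in q.member_markers),
            }
        )
    pd.DataFrame(rows, columns=MQTL_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_mqtl_table(
    path: PathLike, marker_map: Optional[Sequence[Marker]] = None
) -> list[Mqtl]:
    df = pd.read_csv(path, sep="\t", dtype={"trait_id": str, "chrom": str}, keep_default_na=False)
    by_id = {m.marker_id: m for m in marker_map} if marker_map else {}
    out = []
    for row in df.itertuples(index=False):
        members = tuple(
            by_id[mid]
            for mid in filter(None, str(row.marker_ids).split(","))
            if mid in by_id
        )
        out.append(
            Mqtl(
                trait_id=row.trait_id,
                interval=GenomicInterval.from_1based(row.chrom, int(row.start), int(row.end)),
                peak_pos=int(row.peak_pos),
                peak_stat=float(row.peak_stat),
                stat_type=row.stat_type,
                member_markers=members,
            )
        )
    return out


def write_mqtl_bed(mqtls: Sequence[Mqtl], path: PathLike) -> None:
    """BED export (0-based half-open), one line per mQTL."""
    with open(path, "w") as fh:
        for q in mqtls:
            iv = q.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{q.trait_id}\n")


# ---------------------------------------------------------------------------
# Candidate report
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "rank", "bgc_id", "trait_ids", "class_label", "score",
    "multi_mqtl", "multi_gene", "massdiff", "coexpression", "compatibility",
    "chrom", "start", "end", "n_mqtls", "evidence_note",
]


def write_candidate_report(candidates, path: PathLike, format: str = "tsv") -> None:
    """Write the ranked candidate report as TSV or a JSON mirror.

    Candidates must already be ranked; rows are emitted in rank order with a
    fixed column layout and 1-based coordinates, so repeated writes of the
    same input are byte-identical.
    """
    rows = [c.to_record() for c in candidates]
    if format == "tsv":
        pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(
            path, sep="\t", index=False, float_format=_FLOAT_FMT
        )
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_candidate_report(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)
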