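"""Synthetic genetical-metabolomics studies with known ground truth.

Every downstream stage is exercised against data generated here: a genome
with planted gene clusters, a mapping population (RIL by selfing, or a
structured GWAS panel), metabolite traits with a controlled genetic signal,
feature metadata decorated by known biotransformation deltas, and an
expression matrix in which planted-cluster genes are coexpressed.  The
:class:`SimulationTruth` object records exactly what was planted so tests can
measure recovery.

All generators are deterministic given a seed; each pipeline stage draws from
a child generator seeded by ``(global seed, fixed stage offset)`` so stages
can be re-run independently with identical results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as bio
from .detect import default_class_map
from .masses import BiotransformationTable, default_biotransformations
from .model import (
    Bgc,
    ExpressionMatrix,
    Gene,
    GenomicInterval,
    GenotypeMatrix,
    Marker,
    MetaboliteFeature,
    ValidationError,
)

# fixed child-seed offsets per stage
_SEED_GENOME, _SEED_RIL, _SEED_GWAS, _SEED_TRAITS, _SEED_FEATURES, _SEED_EXPR = range(6)

#: pathway template cycled over planted-cluster genes
DEFAULT_TEMPLATE = ("synthase", "oxidase", "glycosyltransferase")


@dataclass
class CausalSpec:
    """One trait's genetic ground truth."""

    bgc_id: str
    h2: float
    effect_size: Optional[float] = None  # filled in by simulate_traits
    causal_marker: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2 <= 1.0):
            raise ValidationError(f"heritability must be in [0, 1], got {self.h2}")


@dataclass
class SimulationTruth:
    """What was planted: clusters, causal traits, decoration edges."""

    planted_bgcs: list[Bgc] = field(default_factory=list)
    causal_bgc_ids: set[str] = field(default_factory=set)
    causal_map: dict[str, CausalSpec] = field(default_factory=dict)
    decoration_graph: list[tuple[str, str, str]] = field(default_factory=list)

    def bgc_by_id(self, bgc_id: str) -> Bgc:
        for b in self.planted_bgcs:
            if b.bgc_id == bgc_id:
                return b
        raise KeyError(bgc_id)

    def to_json(self) -> str:
        payload = {
            "planted_bgcs": [
                {
                    "bgc_id": b.bgc_id,
                    "chrom": b.interval.to_1based()[0],
                    "start": b.interval.to_1based()[1],
                    "end": b.interval.to_1based()[2],
                    "gene_ids": list(b.gene_ids),
                    "causal": b.bgc_id in self.causal_bgc_ids,
                }
                for b in self.planted_bgcs
            ],
            "causal_map": {t: asdict(s) for t, s in sorted(self.causal_map.items())},
            "decoration_graph": [list(e) for e in self.decoration_graph],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Genome with planted clusters
# ---------------------------------------------------------------------------

def simulate_genome(
    n_chrom: int = 5,
    genes_per_chrom: int = 60,
    n_planted_bgcs: int = 6,
    cluster_size: int = 4,
    seed: int = 0,
    template: Sequence[str] = DEFAULT_TEMPLATE,
    lone_enzyme_fraction: float = 0.05,
    gene_length: tuple[int, int] = (1_000, 4_000),
    intergenic_gap: tuple[int, int] = (12_000, 20_000),
    cluster_gap: tuple[int, int] = (500, 3_000),
) -> tuple[list[Gene], SimulationTruth]:
    """Place non-overlapping genes on ``n_chrom`` chromosomes and plant clusters.

    Planted clusters are runs of ``cluster_size`` consecutive genes carrying
    enzyme classes cycled from the pathway ``template`` (at least two distinct
    classes), spaced tightly (``cluster_gap``); the background uses wide
    intergenic gaps so clusters are physically distinct, with a configurable
    fraction of lone enzyme genes scattered among otherwise class-free genes.
    """
    if cluster_size < 3:
        raise ValidationError("cluster_size must be >= 3")
    if len(set(template)) < 2:
        raise ValidationError("pathway template needs >= 2 distinct classes")
    if genes_per_chrom < cluster_size + 2:
        raise ValidationError("genome too small to place the requested clusters")
    rng = np.random.default_rng([seed, _SEED_GENOME])

    # distribute clusters over chromosomes, then pick non-touching index blocks
    chrom_of_cluster = [c % n_chrom for c in range(n_planted_bgcs)]
    per_chrom_count: dict[int, int] = {}
    for c in chrom_of_cluster:
        per_chrom_count[c] = per_chrom_count.get(c, 0) + 1
    max_on_one = max(per_chrom_count.values(), default=0)
    if max_on_one * (cluster_size + 1) > genes_per_chrom:
        raise ValidationError("genome too small to place the requested clusters")

    cluster_blocks: dict[int, list[int]] = {}  # chrom idx -> starting gene indices
    for ci in range(n_chrom):
        k = per_chrom_count.get(ci, 0)
        starts: list[int] = []
        attempts = 0
        while len(starts) < k:
            cand = int(rng.integers(1, genes_per_chrom - cluster_size))
            if all(abs(cand - s) >= cluster_size + 2 for s in starts):
                starts.append(cand)
            attempts += 1
            if attempts > 10_000:
                raise ValidationError("genome too small to place the requested clusters")
        cluster_blocks[ci] = sorted(starts)

    genes: list[Gene] = []
    planted: list[Bgc] = []
    planted_counter = 0
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        in_cluster = np.zeros(genes_per_chrom, dtype=bool)
        for s in cluster_blocks[ci]:
            in_cluster[s : s + cluster_size] = True
        pos = int(rng.integers(5_000, 15_000))
        members: list[Gene] = []
        cluster_pos_in_template = 0
        for gi in range(genes_per_chrom):
            length = int(rng.integers(*gene_length))
            interval_start0 = pos
            g = Gene(
                gene_id=f"g{ci + 1}_{gi + 1:03d}",
                interval=GenomicInterval(chrom, interval_start0, interval_start0 + length),
                strand="+" if rng.random() < 0.5 else "-",
            )
            if in_cluster[gi]:
                g = g.with_classes({template[cluster_pos_in_template % len(template)]})
                cluster_pos_in_template += 1
                members.append(g)
                if len(members) == cluster_size:
                    planted_counter += 1
                    planted.append(
                        Bgc.from_genes(
                            f"planted_{planted_counter}", members, product_label="planted"
                        )
                    )
                    members = []
                    cluster_pos_in_template = 0
            elif rng.random() < lone_enzyme_fraction:
                g = g.with_classes({template[int(rng.integers(len(template)))]})
            genes.append(g)
            next_in_cluster = gi + 1 < genes_per_chrom and in_cluster[gi] and in_cluster[gi + 1]
            gap = int(rng.integers(*cluster_gap)) if next_in_cluster else int(
                rng.integers(*intergenic_gap)
            )
            pos = interval_start0 + length + gap
    truth = SimulationTruth(planted_bgcs=planted)
    return genes, truth


# ---------------------------------------------------------------------------
# Marker maps and populations
# ---------------------------------------------------------------------------

def marker_map_for_genome(
    genes: Sequence[Gene], n_markers_per_chrom: int = 50, cm_per_interval: float = 2.0
) -> tuple[list[Marker], np.ndarray]:
    """Evenly spaced physical markers over each chromosome's gene span,
    with a uniform genetic map (``cm_per_interval`` between neighbours)."""
    span: dict[str, int] = {}
    for g in genes:
        span[g.interval.chrom] = max(span.get(g.interval.chrom, 0), g.interval.end)
    markers: list[Marker] = []
    cms: list[float] = []
    for chrom in sorted(span, key=lambda c: (len(c), c)):
        positions = np.linspace(1, span[chrom], n_markers_per_chrom).astype(int)
        positions = np.unique(positions)
        for i, p in enumerate(positions):
            markers.append(Marker(f"{chrom}_m{i + 1:03d}", chrom, int(p)))
            cms.append(i * cm_per_interval)
    return markers, np.array(cms)


def haldane_recombination(cm: float) -> float:
    """Meiotic recombination fraction from a map distance (Haldane, no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * cm / 100.0))


def ril_switch_probability(r: float) -> float:
    """Genotype switch probability between adjacent markers in selfed RILs.

    Repeated selfing expands a single-meiosis recombination fraction ``r`` to
    ``R = 2r / (1 + 2r)`` between the fixed homozygous genotypes.
    """
    return 2.0 * r / (1.0 + 2.0 * r)


def simulate_ril_population(
    marker_map: Sequence[Marker],
    genetic_map_cm: Sequence[float],
    n_lines: int = 200,
    seed: int = 0,
) -> GenotypeMatrix:
    """Fully homozygous RIL genotypes ({0,1}) as a Markov chain along each chromosome."""
    cms = np.asarray(genetic_map_cm, dtype=float)
    if len(marker_map) != cms.shape[0]:
        raise ValidationError("genetic map length does not match marker map")
    rng = np.random.default_rng([seed, _SEED_RIL])
    calls = np.empty((n_lines, len(marker_map)))
    start = 0
    while start < len(marker_map):
        chrom = marker_map[start].chrom
        end = start
        while end < len(marker_map) and marker_map[end].chrom == chrom:
            end += 1
        seg = cms[start:end]
        if np.any(np.diff(seg) < 0):
            raise ValidationError(f"genetic map not monotone on {chrom}")
        geno = rng.integers(0, 2, size=n_lines)
        calls[:, start] = geno
        for j in range(1, end - start):
            r = haldane_recombination(seg[j] - seg[j - 1])
            switch = rng.random(n_lines) < ril_switch_probability(r)
            geno = np.where(switch, 1 - geno, geno)
            calls[:, start + j] = geno
        start = end
    lines = [f"RIL{i + 1:04d}" for i in range(n_lines)]
    return GenotypeMatrix(lines, list(marker_map), calls)


def simulate_gwas_population(
    marker_map: Sequence[Marker],
    n_accessions: int = 349,
    n_subpops: int = 3,
    fst_like_divergence: float = 0.1,
    seed: int = 0,
) -> GenotypeMatrix:
    """Structured diploid panel with Balding–Nichols subpopulation divergence.

    Ancestral allele frequencies are uniform in [0.05, 0.95]; each
    subpopulation perturbs them with a Beta draw parameterised by the
    divergence ``F`` (variance ``F p (1-p)``), and accession dosages {0,1,2}
    are binomial in the subpopulation frequency.
    """
    if n_subpops < 1:
        raise ValidationError("n_subpops must be >= 1")
    if not (0.0 <= fst_like_divergence < 1.0):
        raise ValidationError("fst_like_divergence must lie in [0, 1)")
    rng = np.random.default_rng([seed, _SEED_GWAS])
    m = len(marker_map)
    p_anc = rng.uniform(0.05, 0.95, size=m)
    F = fst_like_divergence
    if F > 0:
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        p_sub = rng.beta(a, b, size=(n_subpops, m))
        p_sub = np.clip(p_sub, 1e-6, 1.0 - 1e-6)
    else:
        p_sub = np.tile(p_anc, (n_subpops, 1))
    membership = np.arange(n_accessions) % n_subpops
    calls = rng.binomial(2, p_sub[membership, :]).astype(float)
    ids = [f"acc{i + 1:04d}" for i in range(n_accessions)]
    return GenotypeMatrix(ids, list(marker_map), calls)


# ---------------------------------------------------------------------------
# Traits, features, expression
# ---------------------------------------------------------------------------

def nearest_marker(markers: Sequence[Marker], chrom: str, pos: int) -> int:
    """Index of the marker nearest a 1-based position on ``chrom``."""
    best = -1
    best_d = None
    for i, m in enumerate(markers):
        if m.chrom != chrom:
            continue
        d = abs(m.pos - pos)
        if best_d is None or d < best_d:
            best, best_d = i, d
    if best < 0:
        raise ValidationError(f"no marker on chromosome {chrom!r}")
    return best


def simulate_traits(
    genotypes: GenotypeMatrix,
    truth: SimulationTruth,
    seed: int = 0,
    null_trait_ids: Sequence[str] = (),
) -> pd.DataFrame:
    """Metabolite abundances: causal traits = effect x genotype + Gaussian noise.

    For each trait in ``truth.causal_map`` the causal marker is the one
    nearest the midpoint of its planted cluster, and the additive effect size
    is scaled so the genetic variance fraction equals the requested h²
    (``a = sqrt(h² / ((1 - h²) var(g)))`` with unit noise variance; h² = 1
    yields the standardised genotype itself).  Traits in ``null_trait_ids``
    are pure noise.  Realised effect sizes and causal markers are written back
    into the truth's causal map.
    """
    rng = np.random.default_rng([seed, _SEED_TRAITS])
    n = genotypes.n_individuals
    cols: dict[str, np.ndarray] = {}
    for trait_id in sorted(truth.causal_map):
        spec = truth.causal_map[trait_id]
        bgc = truth.bgc_by_id(spec.bgc_id)
        chrom, start, end = bgc.interval.to_1based()
        mid = (start + end) // 2
        mi = nearest_marker(genotypes.markers, chrom, mid)
        g = genotypes.calls[:, mi]
        if np.isnan(g).any():
            raise ValidationError("causal marker has missing calls")
        sd_g = g.std()
        if sd_g == 0:
            raise ValidationError(
                f"causal marker {genotypes.markers[mi].marker_id} is monomorphic"
            )
        spec.causal_marker = genotypes.markers[mi].marker_id
        if spec.h2 >= 1.0:
            spec.effect_size = float("inf")
            cols[trait_id] = (g - g.mean()) / sd_g
            continue
        a = float(np.sqrt(spec.h2 / ((1.0 - spec.h2) * sd_g**2)))
        spec.effect_size = a
        cols[trait_id] = a * g + rng.standard_normal(n)
    for trait_id in null_trait_ids:
        cols[trait_id] = rng.standard_normal(n)
    return pd.DataFrame(cols, index=genotypes.individuals)


def plan_decoration_family(
    trait_ids: Sequence[str], transformations: Sequence[str]
) -> list[tuple[str, str, str]]:
    """Chain ``trait_ids`` with one biotransformation per consecutive pair."""
    if len(transformations) < len(trait_ids) - 1:
        raise ValidationError("need one transformation per consecutive trait pair")
    return [
        (trait_ids[i], trait_ids[i + 1], transformations[i])
        for i in range(len(trait_ids) - 1)
    ]


def simulate_feature_metadata(
    trait_ids: Sequence[str],
    truth: SimulationTruth,
    delta_table: Optional[BiotransformationTable] = None,
    seed: int = 0,
    annotation_fraction: float = 0.0,
    base_mass_range: tuple[float, float] = (200.0, 600.0),
    rt_range: tuple[float, float] = (1.0, 15.0),
) -> list[MetaboliteFeature]:
    """Feature metadata (m/z, rt, annotation) consistent with the truth.

    Traits connected in ``truth.decoration_graph`` receive m/z values equal to
    a family base mass plus the cumulative biotransformation deltas along the
    chain, so mass-difference networking can reconnect the family exactly.
    Unrelated traits draw independent m/z values.  A fraction of features is
    annotated (synthetic compound names); the rest stay unknown.
    """
    if delta_table is None:
        delta_table = default_biotransformations()
    if not delta_table.entries:
        raise ValidationError("delta table must be non-empty")
    rng = np.random.default_rng([seed, _SEED_FEATURES])
    mz: dict[str, float] = {}
    children: dict[str, list[tuple[str, str]]] = {}
    roots: dict[str, None] = {}
    has_parent = {b for _, b, _ in truth.decoration_graph}
    for a, b, name in truth.decoration_graph:
        children.setdefault(a, []).append((b, name))
        if a not in has_parent:
            roots.setdefault(a, None)
    for root in roots:
        base = float(rng.uniform(*base_mass_range))
        stack = [(root, base)]
        while stack:
            node, mass = stack.pop()
            mz[node] = mass
            for child, name in children.get(node, []):
                stack.append((child, mass + delta_table.delta(name)))
    features = []
    for trait_id in trait_ids:
        m = mz.get(trait_id, float(rng.uniform(*base_mass_range)))
        rt = float(rng.uniform(*rt_range))
        annotated = rng.random() < annotation_fraction
        features.append(
            MetaboliteFeature(
                trait_id=trait_id,
                mz=m,
                rt=rt,
                annotation=f"cmpd_{trait_id}" if annotated else "",
                compound_class="",
            )
        )
    return features


def simulate_expression(
    genes: Sequence[Gene],
    planted_bgcs: Sequence[Bgc],
    n_samples: int = 50,
    within_cluster_r: float = 0.8,
    seed: int = 0,
) -> ExpressionMatrix:
    """Expression with a shared latent profile inside each planted cluster.

    Cluster genes follow ``sqrt(r) * latent + sqrt(1 - r) * noise`` so the
    expected pairwise Pearson correlation equals ``within_cluster_r``;
    background genes are independent standard normal.
    """
    if not (0.0 <= within_cluster_r < 1.0):
        raise ValidationError("within_cluster_r must lie in [0, 1)")
    rng = np.random.default_rng([seed, _SEED_EXPR])
    member_of: dict[str, int] = {}
    for k, b in enumerate(planted_bgcs):
        for gid in b.gene_ids:
            member_of[gid] = k
    latents = rng.standard_normal((len(planted_bgcs), n_samples))
    values = np.empty((len(genes), n_samples))
    for i, g in enumerate(genes):
        noise = rng.standard_normal(n_samples)
        k = member_of.get(g.gene_id)
        if k is None:
            values[i] = noise
        else:
            values[i] = np.sqrt(within_cluster_r) * latents[k] + np.sqrt(
                1.0 - within_cluster_r
            ) * noise
    samples = [f"s{j + 1:03d}" for j in range(n_samples)]
    return ExpressionMatrix([g.gene_id for g in genes], samples, values)


# ---------------------------------------------------------------------------
# Whole-study orchestration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Conditions of the bundled synthetic study.

    Defaults emulate a desk-scale RIL experiment: a 5-chromosome genome with
    six planted 4-gene clusters, one of which drives a 3-trait decoration
    family (glycosylation then methylation) at h² = 0.5 in 200 lines genotyped
    at 50 markers per chromosome, plus 12 pure-noise traits and a coexpressed
    (r = 0.8) expression matrix over 50 samples.
    """

    n_chrom: int = 5
    genes_per_chrom: int = 60
    n_clusters: int = 6
    cluster_size: int = 4
    n_causal_clusters: int = 1
    family_size: int = 3
    family_transformations: tuple[str, ...] = ("glycosylation", "methylation")
    h2: float = 0.5
    n_null_traits: int = 12
    population: str = "ril"  # "ril" or "gwas"
    n_lines: int = 200
    n_accessions: int = 349
    n_subpops: int = 3
    fst_like_divergence: float = 0.1
    markers_per_chrom: int = 50
    cm_per_interval: float = 2.0
    expression_samples: int = 50
    within_cluster_r: float = 0.8
    annotation_fraction: float = 0.0
    lone_enzyme_fraction: float = 0.05


@dataclass
class StudyData:
    """Everything a synthetic study produces, plus its ground truth."""

    config: StudyConfig
    genes: list[Gene]
    truth: SimulationTruth
    markers: list[Marker]
    genetic_map_cm: np.ndarray
    genotypes: GenotypeMatrix
    traits: pd.DataFrame
    features: list[MetaboliteFeature]
    expression: ExpressionMatrix
    domain_hits: pd.DataFrame

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bio.write_gff3(self.genes, out / "genes.gff3")
        self_map = default_class_map()
        self_map.write(out / "class_map.tsv")
        bio.write_domain_hits(self.domain_hits, out / "domain_hits.tsv")
        bio.write_marker_map(self.markers, out / "marker_map.tsv")
        bio.write_genotype_matrix(self.genotypes, out / "genotypes.tsv")
        bio.write_trait_matrix(self.traits, out / "traits.tsv")
        bio.write_feature_table(self.features, out / "features.tsv")
        bio.write_expression_matrix(self.expression, out / "expression.tsv")
        bio.write_cluster_table(self.truth.planted_bgcs, out / "planted_clusters.tsv")
        (out / "truth.json").write_text(self.truth.to_json() + "\n")


def _domain_hits_from_classes(genes: Sequence[Gene]) -> pd.DataFrame:
    """Synthesize a domain-hit table consistent with the genes' classes."""
    class_to_domain = {
        cls: dom for dom, cls in sorted(default_class_map().domain_to_class.items())
    }
    rows = [
        {"gene_id": g.gene_id, "domain_id": class_to_domain[c], "score": 100.0}
        for g in genes
        for c in sorted(g.enzyme_classes)
        if c in class_to_domain
    ]
    return pd.DataFrame(rows, columns=["gene_id", "domain_id", "score"])


def simulate_study(config: Optional[StudyConfig] = None, seed: int = 0) -> StudyData:
    """Generate a complete study under ``config`` (see :class:`StudyConfig`)."""
    config = config or StudyConfig()
    genes, truth = simulate_genome(
        n_chrom=config.n_chrom,
        genes_per_chrom=config.genes_per_chrom,
        n_planted_bgcs=config.n_clusters,
        cluster_size=config.cluster_size,
        seed=seed,
        lone_enzyme_fraction=config.lone_enzyme_fraction,
    )
    markers, cms = marker_map_for_genome(
        genes, config.markers_per_chrom, config.cm_per_interval
    )
    if config.population == "ril":
        genotypes = simulate_ril_population(markers, cms, config.n_lines, seed=seed)
    elif config.population == "gwas":
        genotypes = simulate_gwas_population(
            markers, config.n_accessions, config.n_subpops,
            config.fst_like_divergence, seed=seed,
        )
    else:
        raise ValidationError(f"unknown population kind {config.population!r}")

    causal = truth.planted_bgcs[: config.n_causal_clusters]
    trait_counter = 0
    for b in causal:
        truth.causal_bgc_ids.add(b.bgc_id)
        family = [f"mt{trait_counter + k + 1:03d}" for k in range(config.family_size)]
        trait_counter += config.family_size
        for t in family:
            truth.causal_map[t] = CausalSpec(bgc_id=b.bgc_id, h2=config.h2)
        truth.decoration_graph.extend(
            plan_decoration_family(family, config.family_transformations)
        )
    null_ids = [f"nt{k + 1:03d}" for k in range(config.n_null_traits)]
    traits = simulate_traits(genotypes, truth, seed=seed, null_trait_ids=null_ids)
    features = simulate_feature_metadata(
        list(traits.columns), truth, seed=seed,
        annotation_fraction=config.annotation_fraction,
    )
    expression = simulate_expression(
        genes, truth.planted_bgcs, config.expression_samples,
        config.within_cluster_r, seed=seed,
    )
    return StudyData(
        config=config,
        genes=genes,
        truth=truth,
        markers=markers,
        genetic_map_cm=cms,
        genotypes=genotypes,
        traits=traits,
        features=features,
        expression=expression,
        domain_hits=_domain_hits_from_classes(genes),
    )
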