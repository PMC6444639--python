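import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bgclink.model import Gene, GenomicInterval, GenotypeMatrix, Marker, Mqtl

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_gene(gene_id, chrom, start1, end1, classes=(), strand="+"):
    return Gene(
        gene_id,
        GenomicInterval.from_1based(chrom, start1, end1),
        strand=strand,
        enzyme_classes=frozenset(classes),
    )


def make_mqtl(trait_id, chrom, start1, end1, peak_pos=None, stat=5.0, stat_type="LOD"):
    peak = peak_pos if peak_pos is not None else (start1 + end1) // 2
    return Mqtl(
        trait_id,
        GenomicInterval.from_1based(chrom, start1, end1),
        peak_pos=peak,
        peak_stat=stat,
        stat_type=stat_type,
    )


def single_marker_genotypes(calls):
    calls = np.asarray(calls, dtype=float).reshape(-1, 1)
    ids = [f"i{k}" for k in range(calls.shape[0])]
    return GenotypeMatrix(ids, [Marker("m1", "chr1", 100)], calls)


def random_genotypes(rng, n_ind, markers_per_chrom, n_chrom=1, spacing=10_000):
    markers = [
        Marker(f"c{c}_m{j}", f"chr{c + 1}", (j + 1) * spacing)
        for c in range(n_chrom)
        for j in range(markers_per_chrom)
    ]
    calls = rng.integers(0, 2, size=(n_ind, len(markers))).astype(float)
    ids = [f"i{k}" for k in range(n_ind)]
    return GenotypeMatrix(ids, markers, calls)


@pytest.fixture
def three_gene_cluster():
    """Three enzyme genes with pairwise 2 kb gaps and three distinct classes."""
    return [
        make_gene("gA", "chr1", 1_000, 3_000, {"synthase"}),
        make_gene("gB", "chr1", 5_000, 7_000, {"oxidase"}),
        make_gene("gC", "chr1", 9_000, 11_000, {"glycosyltransferase"}),
    ]
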