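import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from bgclink.mapping import (
    MappingConfig,
    ScanResult,
    call_mqtls_gwas,
    call_mqtls_ril,
    gwas_scan,
    lod_scan,
    lod_support_interval,
    permutation_threshold,
)
from bgclink.model import GenotypeMatrix, Marker, ValidationError
from bgclink.simulate import marker_map_for_genome, simulate_genome, simulate_gwas_population, simulate_ril_population
from conftest import random_genotypes, single_marker_genotypes


def lod_oracle(g, y):
    """Independent normal-equations LOD: intercept-only vs intercept+genotype."""
    g = np.asarray(g, float)
    y = np.asarray(y, float)
    n = len(y)
    rss0 = float(((y - y.mean()) ** 2).sum())
    X = np.column_stack([np.ones(n), g])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = float(((y - X @ beta) ** 2).sum())
    return (n / 2.0) * np.log10(max(rss0, 1e-12) / max(rss1, 1e-12))


class TestLodScan:
    def test_hand_worked_example(self):
        gm = single_marker_genotypes([0, 0, 1, 1])
        scan = lod_scan(gm, np.array([1.0, 1.2, 2.0, 2.1]))
        # RSS0 = 0.9275, RSS1 = 0.025 -> LOD = 2*log10(37.1)
        assert scan.stats[0] == pytest.approx(2 * np.log10(0.9275 / 0.025), abs=1e-9)
        assert scan.stats[0] == pytest.approx(3.139, abs=1e-3)

    def test_identical_group_means_give_zero(self):
        gm = single_marker_genotypes([0, 0, 1, 1])
        scan = lod_scan(gm, np.array([1.0, 2.0, 1.0, 2.0]))
        assert scan.stats[0] == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_marker_scores_zero(self):
        gm = single_marker_genotypes([1, 1, 1, 1])
        assert lod_scan(gm, np.array([1.0, 2.0, 3.0, 4.0])).stats[0] == 0.0

    def test_constant_trait_rejected(self):
        gm = single_marker_genotypes([0, 1, 0, 1])
        with pytest.raises(ValidationError, match="constant"):
            lod_scan(gm, np.ones(4))

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        gm = random_genotypes(rng, n_ind=30, markers_per_chrom=20)
        y = rng.standard_normal(30)
        scan = lod_scan(gm, y)
        for j in range(gm.n_markers):
            g = gm.calls[:, j]
            if g.std() == 0:
                continue
            assert scan.stats[j] == pytest.approx(lod_oracle(g, y), abs=1e-9)

    def test_pairwise_deletion_of_missing_calls(self):
        markers = [Marker("m1", "chr1", 100)]
        calls = np.array([[0.0], [0.0], [1.0], [1.0], [np.nan]] + [[0.0]] * 45)
        gm = GenotypeMatrix([f"i{k}" for k in range(50)], markers, calls)
        y = np.concatenate([[1.0, 1.2, 2.0, 2.1, 99.0], np.full(45, 1.1)])
        full = lod_scan(gm, y).stats[0]
        # oracle on the 49 individuals with a genotype call
        mask = ~np.isnan(calls[:, 0])
        assert full == pytest.approx(lod_oracle(calls[mask, 0], y[mask]), abs=1e-9)

    @given(
        a=st.floats(0.1, 10.0), b=st.floats(-5.0, 5.0),
        seed=st.integers(0, 100),
    )
    def test_lod_invariant_to_affine_trait_rescaling(self, a, b, seed):
        rng = np.random.default_rng(seed)
        gm = random_genotypes(rng, n_ind=20, markers_per_chrom=5)
        y = rng.standard_normal(20)
        base = lod_scan(gm, y).stats
        scaled = lod_scan(gm, a * y + b).stats
        np.testing.assert_allclose(scaled, base, atol=1e-8)


class TestPermutationThreshold:
    def test_constant_genotypes_give_zero_threshold(self):
        markers = [Marker(f"m{j}", "chr1", 100 * (j + 1)) for j in range(5)]
        gm = GenotypeMatrix(["a", "b", "c", "d"], markers, np.zeros((4, 5)))
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert permutation_threshold(gm, y, 100, 0.05, seed=0) == 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        gm = random_genotypes(rng, n_ind=50, markers_per_chrom=30)
        y = rng.standard_normal(50)
        t1 = permutation_threshold(gm, y, 200, 0.05, seed=7)
        t2 = permutation_threshold(gm, y, 200, 0.05, seed=7)
        assert t1 == t2

    def test_invalid_alpha_rejected(self):
        rng = np.random.default_rng(0)
        gm = random_genotypes(rng, n_ind=10, markers_per_chrom=5)
        with pytest.raises(ValidationError):
            permutation_threshold(gm, rng.standard_normal(10), 100, alpha=1.5)


def track(lods, positions, chrom="chr1", trait="t"):
    markers = [Marker(f"m{j}", chrom, p) for j, p in enumerate(positions)]
    return ScanResult(trait, markers, np.array(lods, float), "LOD")


class TestSupportInterval:
    def test_rule_walkthrough(self):
        scan = track([1, 2, 4, 2, 1], [10, 20, 30, 40, 50])
        iv = lod_support_interval(scan, "chr1", lod_drop=1.5)
        # boundary = first marker with LOD < 2.5 on each side, included
        assert iv.to_1based() == ("chr1", 20, 40)

    def test_peak_at_first_marker_uses_chromosome_start(self):
        scan = track([4, 2, 1], [10, 20, 30])
        assert lod_support_interval(scan, "chr1", 1.5).to_1based() == ("chr1", 10, 20)

    def test_flat_track_spans_whole_chromosome(self):
        scan = track([3, 3, 3, 3], [10, 20, 30, 40])
        assert lod_support_interval(scan, "chr1", 1.5).to_1based() == ("chr1", 10, 40)

    def test_contains_peak_and_widening_drop_never_shrinks(self):
        rng = np.random.default_rng(4)
        lods = rng.uniform(0, 5, size=40)
        scan = track(lods, (np.arange(40) + 1) * 1_000)
        prev_len = 0
        peak_pos = scan.markers[int(np.argmax(lods))].pos
        for drop in (0.5, 1.0, 1.5, 2.0, 3.0):
            iv = lod_support_interval(scan, "chr1", drop)
            assert iv.contains(peak_pos - 1)
            assert len(iv) >= prev_len
            prev_len = len(iv)

    def test_peak_below_threshold_is_an_error(self):
        scan = track([1, 2, 1], [10, 20, 30])
        scan.threshold = 3.0
        with pytest.raises(ValidationError, match="below threshold"):
            lod_support_interval(scan, "chr1", 1.5)


class TestCallMqtlsRil:
    def _population(self, seed, h2, n_lines=200):
        from bgclink.simulate import CausalSpec, simulate_traits

        genes, truth = simulate_genome(n_planted_bgcs=1, seed=seed)
        markers, cms = marker_map_for_genome(genes)
        gm = simulate_ril_population(markers, cms, n_lines=n_lines, seed=seed)
        truth.causal_map["t1"] = CausalSpec(truth.planted_bgcs[0].bgc_id, h2)
        traits = simulate_traits(gm, truth, seed=seed)
        return gm, traits, truth

    def test_planted_qtl_found_on_causal_chromosome(self):
        found = 0
        for seed in range(10):
            gm, traits, truth = self._population(seed, h2=0.5)
            causal_chrom = truth.planted_bgcs[0].interval.chrom
            mqtls = call_mqtls_ril(
                gm, traits, MappingConfig(n_permutations=300), seed=seed
            )
            on_causal = [q for q in mqtls if q.interval.chrom == causal_chrom]
            if len(on_causal) == 1:
                found += 1
        assert found >= 9

    def test_same_seed_reproduces_calls(self):
        gm, traits, _ = self._population(3, h2=0.5)
        cfg = MappingConfig(n_permutations=200)
        assert call_mqtls_ril(gm, traits, cfg, seed=1) == call_mqtls_ril(
            gm, traits, cfg, seed=1
        )

    def test_member_markers_lie_inside_interval(self):
        gm, traits, _ = self._population(5, h2=0.8)
        for q in call_mqtls_ril(gm, traits, MappingConfig(n_permutations=200), seed=0):
            assert q.member_markers
            for m in q.member_markers:
                assert q.interval.contains(m.pos - 1)


class TestGwasScan:
    def test_hand_worked_example_without_covariates(self):
        gm = single_marker_genotypes([0, 0, 1, 1])
        y = np.array([1.0, 1.2, 2.0, 2.1])
        scan = gwas_scan(gm, y, n_pcs=0)
        # slope 0.95, t = 8.497 on 2 df
        t_expected = 0.95 / np.sqrt((0.025 / 2) / 1.0)
        p_expected = 2 * stats.t.sf(t_expected, 2)
        assert scan.stats[0] == pytest.approx(p_expected, abs=1e-12)
        assert scan.stats[0] == pytest.approx(0.0136, abs=2e-4)

    def test_monomorphic_marker_p_is_one(self):
        gm = single_marker_genotypes([1, 1, 1, 1])
        assert gwas_scan(gm, np.array([1.0, 2.0, 3.0, 4.0]), n_pcs=0).stats[0] == 1.0

    def test_agrees_with_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        markers, _ = zip(*[(Marker(f"m{j}", "chr1", (j + 1) * 1000), None) for j in range(15)])
        calls = rng.integers(0, 3, size=(40, 15)).astype(float)
        gm = GenotypeMatrix([f"i{k}" for k in range(40)], list(markers), calls)
        y = rng.standard_normal(40)
        n_pcs = 2
        scan = gwas_scan(gm, y, n_pcs=n_pcs)
        from bgclink.mapping import genotype_pcs

        pcs = genotype_pcs(calls, n_pcs)
        for j in range(15):
            X = sm.add_constant(np.column_stack([pcs, calls[:, j]]))
            fit = sm.OLS(y, X).fit()
            assert scan.stats[j] == pytest.approx(fit.pvalues[-1], abs=1e-9)

    def test_null_pvalues_uniform(self):
        markers = [Marker(f"m{j}", "chr1", (j + 1) * 1000) for j in range(400)]
        pooled = []
        for seed in (0, 1, 2):
            gm = simulate_gwas_population(
                markers, n_accessions=100, n_subpops=1, fst_like_divergence=0.0, seed=seed
            )
            y = np.random.default_rng(seed + 100).standard_normal(100)
            scan = gwas_scan(gm, y, n_pcs=0)
            keep = gm.calls.std(axis=0) > 0
            assert stats.kstest(scan.stats[keep], "uniform").pvalue > 0.01
            pooled.append(scan.stats[keep])

    def test_pcs_reduce_structure_inflation(self):
        markers = [Marker(f"m{j}", "chr1", (j + 1) * 1000) for j in range(300)]
        lam_with, lam_without = [], []
        for seed in range(3):
            gm = simulate_gwas_population(
                markers, n_accessions=150, n_subpops=2, fst_like_divergence=0.3, seed=seed
            )
            labels = (np.arange(150) % 2).astype(float)
            y = labels + 0.5 * np.random.default_rng(seed).standard_normal(150)

            def lam(p):
                chi2 = stats.chi2.isf(np.clip(p, 1e-300, 1), df=1)
                return np.median(chi2) / stats.chi2.ppf(0.5, 1)

            keep = gm.calls.std(axis=0) > 0
            lam_without.append(lam(gwas_scan(gm, y, n_pcs=0).stats[keep]))
            lam_with.append(lam(gwas_scan(gm, y, n_pcs=3).stats[keep]))
        assert abs(np.median(lam_with) - 1) < abs(np.median(lam_without) - 1)
        assert np.median(lam_without) > 1.5  # the confounding really inflates

    def test_too_many_pcs_rejected(self):
        gm = single_marker_genotypes([0, 1, 2, 1])
        with pytest.raises(ValidationError, match="n_pcs"):
            gwas_scan(gm, np.array([1.0, 2.0, 3.0, 4.0]), n_pcs=3)


class TestCallMqtlsGwas:
    def _scan(self, pvals, positions=None, chrom="chr1", trait="t"):
        positions = positions or [(j + 1) * 1_000 for j in range(len(pvals))]
        markers = [Marker(f"m{j}", chrom, p) for j, p in enumerate(positions)]
        return ScanResult(trait, markers, np.array(pvals), "pvalue")

    def test_bh_step_up_hand_example(self):
        scan = self._scan([0.001, 0.01, 0.02, 0.9], [1_000, 50_000, 100_000, 150_000])
        mqtls = call_mqtls_gwas([scan], MappingConfig(fdr_q=0.05))
        sig = {m.marker_id for q in mqtls for m in q.member_markers}
        assert sig == {"m0", "m1", "m2"}  # 3 of 4 pass BH at q=0.05

    def test_nearby_significant_markers_merge(self):
        scan = self._scan([1e-4, 1e-5, 0.9], [10_000, 15_000, 500_000])
        (q,) = call_mqtls_gwas([scan], MappingConfig(fdr_q=0.05, gwas_window=10_000))
        assert len(q.member_markers) == 2
        assert q.peak_pos == 15_000  # the more significant of the pair
        assert q.interval.to_1based() == ("chr1", 5_000, 20_000)

    def test_distant_markers_stay_separate(self):
        scan = self._scan([1e-4, 1e-5], [10_000, 200_000])
        mqtls = call_mqtls_gwas([scan], MappingConfig(gwas_window=10_000))
        assert len(mqtls) == 2

    def test_no_significant_markers_gives_empty_list(self):
        scan = self._scan([0.4, 0.5, 0.6])
        assert call_mqtls_gwas([scan]) == []

    def test_interval_clipped_to_chromosome(self):
        scan = self._scan([1e-6], [2_000])
        (q,) = call_mqtls_gwas(
            [scan], MappingConfig(gwas_window=10_000), chrom_lengths={"chr1": 4_000}
        )
        assert q.interval.to_1based() == ("chr1", 1, 4_000)

    def test_global_bh_pools_traits(self):
        # per-trait BH rejects m0 of the weak trait (0.004 <= 0.05*1/10);
        # pooling with 90 extra null markers tightens the rank-1 cutoff to 0.0005
        null = self._scan([0.9] * 90, trait="null")
        weak = self._scan([0.004] + [0.9] * 9, trait="weak")
        per_trait = call_mqtls_gwas([null, weak], MappingConfig(fdr_q=0.05))
        pooled = call_mqtls_gwas(
            [null, weak], MappingConfig(fdr_q=0.05, global_bh=True)
        )
        assert any(q.trait_id == "weak" for q in per_trait)
        assert not any(q.trait_id == "weak" for q in pooled)
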