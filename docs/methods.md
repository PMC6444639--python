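# Methods

This note documents the statistical models, the synthetic-data generator and
the numerical/design choices behind `bgclink`, in the spirit of a methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and data model

Intervals are stored 0-based half-open internally; every file format
converts at the I/O boundary (GFF3, cluster/mQTL/report TSVs are 1-based
inclusive, BED is 0-based half-open). Strand is recorded but ignored by all
overlap logic: QTL intervals and cluster spans are strand-agnostic. Missing
genotype calls are allowed up to 10 % per marker and handled by pairwise
deletion at the tested marker.

## RIL mQTL mapping

Genotypes are homozygous biparental codes {0, 1}. The per-marker statistic is
the least-squares LOD, `(n/2)·log10(RSS₀/RSS₁)`, intercept-only versus
intercept-plus-genotype; `RSS₁` is floored at 1e-12 so a perfectly fitting
marker yields a large finite LOD, monomorphic markers score 0, and the LOD is
clipped at 0 against floating-point cancellation. The scan is vectorised via
sufficient statistics (validity-masked `V'y` and `G'y` matmuls), which is
what makes 1000-permutation thresholds per trait cheap.

Genome-wide significance is a per-trait permutation test: the trait is
permuted across lines (default 1000 times), the genome-wide maximum LOD
recorded, and the threshold is the next-higher empirical 1−α order statistic
(α = 0.05). The exceedance probability of this estimator is
(P+1−⌈(1−α)P⌉)/(P+1) ≈ α, and the measured false-positive rate over
independent null scans sits inside the binomial confidence band around α
(checked in the acceptance suite).

Support intervals use the classical LOD-drop rule (default 1.5): from the
chromosome peak (ties broken toward the lowest coordinate) extend left and
right to the first marker falling below peak − drop, including that boundary
marker, or to the chromosome's terminal marker. The interval therefore always
contains the peak, and widening the drop can only widen the interval. One
mQTL is emitted per chromosome whose local peak exceeds the trait's
genome-wide threshold. Permutation seeds derive from (global seed, trait
index) so traits are independently reproducible.

## GWAS mQTL mapping

Accession genotypes are additive dosages {0, 1, 2}. Population structure is
absorbed by the leading principal components (default 3) of the mean-imputed,
centred genotype matrix, used as fixed covariates in a per-marker regression
`y ~ 1 + PCs + g`; the reported statistic is the two-sided p-value of the
genotype coefficient (via Frisch–Waugh residualisation, vectorised for
complete data). This is a deliberate simplification of kinship mixed models:
it corrects the dominant confounding axes but not fine-grained relatedness,
and the report metadata should be read with that caveat. The test suite
verifies per-marker agreement with an independent OLS fit, null-uniform
p-values, and that PCs shrink the genomic inflation factor on
structure-confounded traits.

Multiple testing is Benjamini–Hochberg per trait at q = 0.05 (per-trait
matches how mQTL counts are usually reported; a pooled global-BH switch
exists). Significant markers on one chromosome within 10 kb merge into one
mQTL; the interval is the marker span padded by half a window each side,
clipped to the chromosome; the peak is the most significant member, ties
toward the lowest coordinate.

## Cluster detection

Gene enzyme classes come from an external domain-hit table (gene, domain,
score; e.g. profile-HMM bit scores) thresholded at a minimum score and
mapped through a domain→class table; the shipped default covers common
plant pathway enzyme families, with synthases/cyclases/dirigents flagged as
scaffold-generating. Detection is a greedy chain rule — ≥ 3 enzyme genes of
≥ 2 distinct classes with ≤ 10 kb between consecutive enzyme-gene intervals
(end → next start); intervening class-free genes become members without
breaking the chain. This is an explicit proxy for full plant cluster
predictors (no redundancy filtering, no per-class rules); externally
predicted clusters can be supplied via the cluster TSV instead, and
`annotate_region` supports the complementary non-cluster-centric scan of any
interval for enzyme-coding genes.

## Evidence layers and ranking

Any positive intersection between an mQTL interval and a cluster is a link
(minimum-overlap option defaults to 1 bp). Mass-difference edges connect
feature pairs whose |Δm/z| matches a biotransformation delta within
max(0.005 Da, 10 ppm of the mean m/z); deltas are computed from monoisotopic
atomic masses (glycosylation C6H10O5 = 162.05282 Da, rhamnosylation C6H10O4,
methylation CH2, hydroxylation O, acetylation C2H2O, malonylation C3H2O3,
sinapoylation C11H10O4). m/z is treated as a neutral-mass proxy — adduct and
isotope handling is out of scope, so identical adduct forms are implicitly
assumed. Coexpression support is the pairwise Pearson matrix over a
cluster's enzyme genes, flagged at max r ≥ 0.79 — the level at which
co-regulated cluster genes clearly separate from the null correlation at
typical sample counts. Marker-to-gene assignment (GWAS) claims every gene
whose 2 kb-flanked interval contains a significant member marker, without
arbitration between overlapping genes.

Classification precedence: all overlapping traits unannotated →
`discovery_candidate`; no annotated trait compatible with the enzyme
inventory → `known_incompatible_or_false_positive`; at least one compatible
annotated trait → `known_compatible`, downgraded to `mixed` when unknown
traits ride along. (The four labels overlap as prose; this precedence makes
them a partition.) The compatibility table ships small and user-overridable:
lignan ↔ dirigent/dioxygenase, flavonoid ↔ chalcone-stilbene-synthase/
glycosyltransferase/acyltransferase, terpene ↔ terpene-synthase/
oxidosqualene-cyclase. The score is a weighted sum (unit defaults — there is
no principled exchange rate between genetic and expression evidence, so the
weights are deliberately neutral and configurable) over five flags:
≥ 2 mQTLs, ≥ 2 distinct genes hit, mass-difference component of ≥ 2 traits,
coexpression flag, compatibility match. Ranking breaks score ties by mQTL
count, then genomic position, then id, giving a strict total order.

## Synthetic studies

The generator plants ground truth and hands it to the tests:

* **Genome** — genes of 1–4 kb; background intergenic gaps 12–20 kb (wider
  than the 10 kb chaining gap, so planted clusters are physically unambiguous
  and lone background enzymes — 5 % of background genes — cannot chain);
  planted clusters are runs of 4 consecutive genes 0.5–3 kb apart with
  classes cycled from a synthase/oxidase/glycosyltransferase template.
* **RIL population** — selfed-RIL Markov chain: switch probability between
  adjacent markers R = 2r/(1+2r), r from Haldane's map function over a
  uniform 2 cM marker spacing (50 markers per chromosome).
* **GWAS panel** — Balding–Nichols: ancestral frequencies uniform in
  [0.05, 0.95], subpopulation frequencies Beta-perturbed by the divergence
  parameter, diploid dosages binomial.
* **Traits** — `y = a·g + ε`, ε standard normal, with
  `a = sqrt(h²/((1−h²)·var(g)))` so the genetic variance fraction equals the
  requested h²; the causal marker is the one nearest the planted cluster's
  midpoint (which keeps the true locus recoverable by the support interval).
  h² = 1 returns the standardised genotype itself. Non-causal traits are pure
  noise.
* **Features** — causal families take m/z = family base mass plus cumulative
  biotransformation deltas along a decoration chain, so mass-difference
  networking reconnects them exactly; other features draw independent m/z.
* **Expression** — cluster genes follow `sqrt(r)·latent + sqrt(1−r)·noise`,
  giving expected pairwise correlation r (default 0.8); background genes are
  independent.

The bundled study defaults (5 chromosomes × 60 genes, six planted clusters,
one causal with a 3-trait family at h² = 0.5, 12 null traits, 200 lines,
expression over 50 samples) are sized so a full end-to-end run takes well
under a second, which lets calibration and recovery be measured over
hundreds of seeded replicates. No heritability was available to copy for
real mQTLs, so h² = 0.3 (mapping calibration) and 0.5 (end-to-end study) are
calibration choices representative of moderately heritable metabolite
features.

**What passing these tests does not show:** the generator has no linkage
disequilibrium beyond subpopulation structure, one causal locus per trait, no
epistasis, exact single-delta mass relationships, and no adducts, isotopes or
retention-time drift. Real LC–MS/genetics data will be noisier on every one
of those axes, so recovery rates measured here are upper bounds on real-data
behaviour; the exact-arithmetic oracles (LOD, BH, interval overlap, mass
deltas) transfer as-is.

## Numerical choices and edge cases

* RSS floors at 1e-12; LODs clipped at 0; monomorphic markers give LOD 0 /
  p = 1; markers collinear with the structure covariates give p = 1 and are
  logged.
* Constant or all-missing traits are rejected rather than silently scored.
* Peak ties always resolve toward the lowest genomic coordinate; candidate
  ordering is a strict total order, so outputs are byte-reproducible for a
  given seed (verified across every CLI stage).
* Zero-variance expression profiles yield NaN correlations, which are
  excluded from max/mean and never set the coexpression flag.
* Empty inputs (header-only tables, traitless scans) produce empty outputs,
  not errors; unknown chromosomes in region queries return empty tables and
  a log line.

## Known limitations

Fixed-effect PC regression is not a kinship mixed model; the BGC chain rule
is far simpler than dedicated plant predictors; mass-difference matching on
raw m/z conflates adducts; and MS/MS-based structure evidence is explicitly
out of scope. The package's claim is the integration logic — mapping,
superposition, evidence aggregation, ranking — not state-of-the-art
components at each stage, each of which can be swapped in through the
external-interface formats (cluster TSV, domain-hit TSV, precomputed scans).
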