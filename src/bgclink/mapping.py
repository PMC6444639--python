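"""Metabolite QTL mapping.

Two mapping regimes are supported, matching the two population designs in
which genetical metabolomics is usually run:

* **RIL populations** (biparental, homozygous lines, genotypes coded {0, 1}):
  single-marker LOD scans.  For least squares the LOD at a marker is
  ``(n/2) * log10(RSS0 / RSS1)`` with ``RSS0`` the residual sum of squares of
  the intercept-only fit and ``RSS1`` that of the one-marker fit.  Genome-wide
  significance comes from a per-trait permutation test (empirical 1-alpha
  quantile of the genome-wide maximum LOD under trait permutation), and each
  significant chromosome contributes one mQTL delimited by a classical
  LOD-drop support interval (default 1.5 LOD units).

* **GWAS panels** (natural accessions, additive dosage {0, 1, 2}): per-marker
  fixed-effect regression with the leading principal components of the
  genotype matrix as covariates to absorb population structure — a
  deliberately light-weight stand-in for kinship mixed models that keeps the
  scan dependency-free while correcting the main confounding axis.
  Benjamini–Hochberg FDR control per trait, then significant markers within a
  merge window collapse into window-based mQTL intervals.

Scans are vectorised across markers (and across permutations) with sufficient
statistics, so the permutation-heavy calibration stays desk-scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import GenomicInterval, GenotypeMatrix, Marker, Mqtl, ValidationError

log = logging.getLogger(__name__)

_RSS_FLOOR = 1e-12


@dataclass
class MappingConfig:
    """Tuning knobs for both mapping regimes."""

    lod_drop: float = 1.5
    n_permutations: int = 1000
    alpha: float = 0.05
    fdr_q: float = 0.05
    gwas_window: int = 10_000
    n_pcs: int = 3
    global_bh: bool = False  # pool p-values across traits instead of per trait

    def __post_init__(self) -> None:
        if self.lod_drop <= 0 or self.n_permutations <= 0 or self.gwas_window <= 0:
            raise ValidationError("lod_drop, n_permutations and gwas_window must be positive")
        if not (0 < self.alpha < 1) or not (0 < self.fdr_q < 1):
            raise ValidationError("alpha and fdr_q must lie in (0, 1)")
        if self.n_pcs < 0:
            raise ValidationError("n_pcs must be >= 0")


@dataclass
class ScanResult:
    """Per-marker statistic track for one trait."""

    trait_id: str
    markers: list[Marker]
    stats: np.ndarray  # LOD scores or p-values, aligned with markers
    stat_type: str  # "LOD" or "pvalue"
    threshold: Optional[float] = None
    threshold_kind: Optional[str] = None  # permutation_LOD | BH_FDR | bonferroni

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=float)
        if len(self.markers) != self.stats.shape[0]:
            raise ValidationError("scan track length does not match marker count")

    def chrom_slice(self, chrom: str) -> tuple[list[Marker], np.ndarray]:
        idx = [i for i, m in enumerate(self.markers) if m.chrom == chrom]
        return [self.markers[i] for i in idx], self.stats[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trait_id": self.trait_id,
                "marker_id": [m.marker_id for m in self.markers],
                "chrom": [m.chrom for m in self.markers],
                "pos": [m.pos for m in self.markers],
                "stat": self.stats,
                "stat_type": self.stat_type,
            }
        )


# ---------------------------------------------------------------------------
# RIL LOD scans
# ---------------------------------------------------------------------------

def _check_trait(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    finite = np.isfinite(y)
    if not finite.any():
        raise ValidationError("trait has no finite values")
    if np.nanstd(y) == 0:
        raise ValidationError("trait is constant; nothing to map")
    return y


def _binary_lod_batch(calls: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """LOD scores for binary-coded markers against each column of ``Y``.

    ``calls`` is individuals x markers with values in {0, 1} or NaN; ``Y`` is
    individuals x traits with no NaN (missing-trait individuals are dropped
    before this point).  Missing calls are handled by pairwise deletion via
    the validity mask.  Returns markers x traits LOD scores; monomorphic
    markers (within the valid subset) score 0.
    """
    V = (~np.isnan(calls)).astype(float)
    G = np.nan_to_num(calls)
    nv = V.sum(axis=0)                       # valid n per marker
    n1 = G.sum(axis=0)                       # genotype-1 count per marker
    n0 = nv - n1
    Sy = V.T @ Y                             # markers x traits
    Syy = V.T @ (Y * Y)
    S1 = G.T @ Y
    S0 = Sy - S1
    with np.errstate(divide="ignore", invalid="ignore"):
        rss0 = Syy - Sy**2 / nv[:, None]
        denom0 = np.where(n0 > 0, n0, 1.0)[:, None]
        denom1 = np.where(n1 > 0, n1, 1.0)[:, None]
        rss1 = (
            Syy
            - (S0**2 / denom0) * (n0 > 0)[:, None]
            - (S1**2 / denom1) * (n1 > 0)[:, None]
        )
        lod = (nv[:, None] / 2.0) * np.log10(
            np.maximum(rss0, _RSS_FLOOR) / np.maximum(rss1, _RSS_FLOOR)
        )
    lod = np.clip(lod, 0.0, None)
    mono = (n0 < 0.5) | (n1 < 0.5)
    lod[mono, :] = 0.0
    return lod


def lod_scan(genotypes: GenotypeMatrix, trait: np.ndarray, trait_id: str = "trait") -> ScanResult:
    """Single-marker LOD scan of one trait across all markers.

    Individuals with a missing trait value are dropped; individuals missing
    the tested genotype call are dropped pairwise per marker.  Monomorphic
    markers score LOD 0, and ``RSS1`` is floored at 1e-12 so a perfectly
    fitting marker yields a large finite LOD.
    """
    y = _check_trait(trait)
    if y.shape[0] != genotypes.n_individuals:
        raise ValidationError("trait length does not match number of lines")
    keep = np.isfinite(y)
    calls = genotypes.calls[keep]
    vals = calls[~np.isnan(calls)]
    if vals.size and not np.isin(vals, (0.0, 1.0)).all():
        raise ValidationError("RIL LOD scan expects genotype calls coded {0, 1}")
    lod = _binary_lod_batch(calls, y[keep, None])[:, 0]
    return ScanResult(trait_id, list(genotypes.markers), lod, "LOD")


def permutation_threshold(
    genotypes: GenotypeMatrix,
    trait: np.ndarray,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int | Sequence[int] = 0,
) -> float:
    """Genome-wide LOD threshold from a trait-permutation null.

    The trait is permuted across lines ``n_permutations`` times, the
    genome-wide maximum LOD recorded each time, and the empirical
    ``1 - alpha`` quantile (next-higher order statistic) returned.
    """
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    y = _check_trait(trait)
    keep = np.isfinite(y)
    calls = genotypes.calls[keep]
    y = y[keep]
    rng = np.random.default_rng(seed)
    perms = np.empty((y.shape[0], n_permutations))
    for j in range(n_permutations):
        perms[:, j] = y[rng.permutation(y.shape[0])]
    maxima = _binary_lod_batch(calls, perms).max(axis=0)
    return float(np.quantile(maxima, 1.0 - alpha, method="higher"))


def lod_support_interval(
    scan: ScanResult, chrom: str, lod_drop: float = 1.5
) -> GenomicInterval:
    """LOD-drop support interval around the chromosome's peak marker.

    From the peak (ties broken toward the lowest coordinate) the interval
    extends left and right to the first marker whose LOD falls below
    ``peak - lod_drop``; that boundary marker is included.  If no marker
    falls below the drop the interval runs to the chromosome's terminal
    marker.  Raises if the scan carries a threshold and the peak sits below it.
    """
    markers, lods = scan.chrom_slice(chrom)
    if not markers:
        raise ValidationError(f"no markers on chromosome {chrom!r}")
    peak_idx = int(np.argmax(lods))  # argmax takes the first = lowest coordinate
    peak = lods[peak_idx]
    if scan.threshold is not None and peak < scan.threshold:
        raise ValidationError(
            f"peak LOD {peak:.3g} on {chrom} below threshold {scan.threshold:.3g}; "
            "no mQTL to delimit"
        )
    cut = peak - lod_drop
    left = 0
    for i in range(peak_idx - 1, -1, -1):
        if lods[i] < cut:
            left = i
            break
    right = len(markers) - 1
    for i in range(peak_idx + 1, len(markers)):
        if lods[i] < cut:
            right = i
            break
    return GenomicInterval.from_1based(chrom, markers[left].pos, markers[right].pos)


def call_mqtls_ril(
    genotypes: GenotypeMatrix,
    traits: pd.DataFrame,
    config: Optional[MappingConfig] = None,
    seed: int = 0,
) -> list[Mqtl]:
    """Scan every trait, apply per-trait permutation thresholds, emit mQTLs.

    For each chromosome whose local peak LOD exceeds the trait's genome-wide
    permutation threshold, one mQTL is emitted with the LOD-drop support
    interval, the peak marker position and the peak LOD.  Permutation seeds
    derive deterministically from ``(seed, trait index)`` so traits can be
    re-run independently.
    """
    config = config or MappingConfig()
    mqtls: list[Mqtl] = []
    for ti, trait_id in enumerate(traits.columns):
        y = traits[trait_id].to_numpy(dtype=float)
        scan = lod_scan(genotypes, y, trait_id=trait_id)
        thr = permutation_threshold(
            genotypes, y, config.n_permutations, config.alpha, seed=[seed, ti]
        )
        scan.threshold = thr
        scan.threshold_kind = "permutation_LOD"
        for chrom in genotypes.chromosomes():
            markers, lods = scan.chrom_slice(chrom)
            peak_idx = int(np.argmax(lods))
            if lods[peak_idx] <= thr:
                continue
            interval = lod_support_interval(scan, chrom, config.lod_drop)
            members = tuple(
                m for m in markers if interval.contains(m.pos - 1)
            )
            mqtls.append(
                Mqtl(
                    trait_id=trait_id,
                    interval=interval,
                    peak_pos=markers[peak_idx].pos,
                    peak_stat=float(lods[peak_idx]),
                    stat_type="LOD",
                    member_markers=members,
                )
            )
    return mqtls


# ---------------------------------------------------------------------------
# GWAS marker regression
# ---------------------------------------------------------------------------

def genotype_pcs(calls: np.ndarray, n_pcs: int) -> np.ndarray:
    """Leading principal-component scores of the centred genotype matrix.

    Missing calls are mean-imputed per marker before the SVD (imputation is
    used for the structure covariates only, never for the tested marker).
    """
    X = np.array(calls, dtype=float)
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    X = X[:, sd > 0]
    if n_pcs == 0 or X.shape[1] == 0:
        return np.empty((calls.shape[0], 0))
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    k = min(n_pcs, S.shape[0])
    return U[:, :k] * S[:k]


def _residualize(Q: np.ndarray, A: np.ndarray) -> np.ndarray:
    return A - Q @ (Q.T @ A)


def gwas_scan(
    genotypes: GenotypeMatrix,
    trait: np.ndarray,
    n_pcs: int = 3,
    trait_id: str = "trait",
) -> ScanResult:
    """Per-marker additive regression with PC structure covariates.

    For each marker the model ``trait ~ intercept + PCs + genotype`` is fitted
    by least squares and the two-sided p-value of the genotype coefficient
    reported.  Monomorphic markers, and markers collinear with the covariates
    after residualisation, get p = 1 (the latter logged).  Individuals with a
    missing call at the tested marker are dropped pairwise.
    """
    y = _check_trait(trait)
    if y.shape[0] != genotypes.n_individuals:
        raise ValidationError("trait length does not match number of accessions")
    keep = np.isfinite(y)
    calls = genotypes.calls[keep]
    y = y[keep]
    n = y.shape[0]
    if n_pcs >= n - 2:
        raise ValidationError(f"n_pcs={n_pcs} must be below n-2={n - 2}")
    pcs = genotype_pcs(calls, n_pcs)
    C = np.column_stack([np.ones(n), pcs])
    Q, _ = np.linalg.qr(C)
    df = n - C.shape[1] - 1
    pvals = np.ones(genotypes.n_markers)
    has_nan = np.isnan(calls).any(axis=0)

    complete = ~has_nan
    if complete.any():
        G = calls[:, complete]
        Gr = _residualize(Q, G)
        yr = _residualize(Q, y[:, None])[:, 0]
        sxx = (Gr**2).sum(axis=0)
        syy = float(yr @ yr)
        sxy = Gr.T @ yr
        tol = 1e-10 * np.maximum((G**2).sum(axis=0), 1.0)
        ok = sxx > tol
        mono = G.std(axis=0) == 0
        n_collinear = int((~ok & ~mono).sum())
        if n_collinear:
            log.warning("%d markers collinear with structure covariates; p set to 1", n_collinear)
        slope = np.zeros_like(sxx)
        slope[ok] = sxy[ok] / sxx[ok]
        rss1 = np.maximum(syy - slope**2 * sxx, _RSS_FLOOR)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = slope * np.sqrt(sxx * df / rss1)
        p = 2.0 * stats.t.sf(np.abs(tstat), df)
        p[~ok] = 1.0
        pvals[np.nonzero(complete)[0]] = p

    for j in np.nonzero(has_nan)[0]:
        g = calls[:, j]
        mask = ~np.isnan(g)
        gj, yj, Cj = g[mask], y[mask], C[mask]
        if gj.std() == 0 or mask.sum() <= Cj.shape[1] + 1:
            continue  # pvals[j] stays 1
        Qj, _ = np.linalg.qr(Cj)
        gr = gj - Qj @ (Qj.T @ gj)
        yrj = yj - Qj @ (Qj.T @ yj)
        sxx = float(gr @ gr)
        if sxx <= 1e-10 * max(float(gj @ gj), 1.0):
            log.warning("marker %s collinear with covariates; p set to 1",
                        genotypes.markers[j].marker_id)
            continue
        slope = float(gr @ yrj) / sxx
        dfj = mask.sum() - Cj.shape[1] - 1
        rss1 = max(float(yrj @ yrj) - slope**2 * sxx, _RSS_FLOOR)
        tstat = slope * np.sqrt(sxx * dfj / rss1)
        pvals[j] = 2.0 * stats.t.sf(abs(tstat), dfj)

    return ScanResult(trait_id, list(genotypes.markers), pvals, "pvalue")


def call_mqtls_gwas(
    scans: Sequence[ScanResult],
    config: Optional[MappingConfig] = None,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> list[Mqtl]:
    """Benjamini–Hochberg FDR control plus window merging of significant markers.

    By default BH runs per trait across that trait's markers (set
    ``config.global_bh`` to pool all traits).  Significant markers on one
    chromosome within ``gwas_window`` bp of each other merge into one mQTL
    whose interval is the marker span padded by half a window on each side,
    clipped to the chromosome; the peak is the most significant member (ties
    broken toward the lowest coordinate).
    """
    config = config or MappingConfig()
    rejections: list[np.ndarray] = []
    if config.global_bh:
        all_p = np.concatenate([s.stats for s in scans]) if scans else np.empty(0)
        if all_p.size:
            rej = multipletests(all_p, alpha=config.fdr_q, method="fdr_bh")[0]
            off = 0
            for s in scans:
                rejections.append(rej[off : off + s.stats.size])
                off += s.stats.size
    else:
        for s in scans:
            rejections.append(
                multipletests(s.stats, alpha=config.fdr_q, method="fdr_bh")[0]
            )

    half = config.gwas_window // 2
    mqtls: list[Mqtl] = []
    for scan, rej in zip(scans, rejections):
        if scan.stat_type != "pvalue":
            raise ValidationError("call_mqtls_gwas expects p-value scans")
        sig = [(m, p) for m, p, r in zip(scan.markers, scan.stats, rej) if r]
        by_chrom: dict[str, list[tuple[Marker, float]]] = {}
        for m, p in sig:
            by_chrom.setdefault(m.chrom, []).append((m, p))
        for chrom in sorted(by_chrom):
            group: list[tuple[Marker, float]] = []
            entries = sorted(by_chrom[chrom], key=lambda t: t[0].pos)
            for entry in entries:
                if group and entry[0].pos - group[-1][0].pos > config.gwas_window:
                    mqtls.append(_emit_gwas_mqtl(scan.trait_id, group, half, chrom_lengths))
                    group = []
                group.append(entry)
            if group:
                mqtls.append(_emit_gwas_mqtl(scan.trait_id, group, half, chrom_lengths))
    return mqtls


def _emit_gwas_mqtl(
    trait_id: str,
    group: list[tuple[Marker, float]],
    half_window: int,
    chrom_lengths: Optional[dict[str, int]],
) -> Mqtl:
    markers = [m for m, _ in group]
    chrom = markers[0].chrom
    start = max(1, markers[0].pos - half_window)
    end = markers[-1].pos + half_window
    if chrom_lengths and chrom in chrom_lengths:
        end = min(end, chrom_lengths[chrom])
    peak_marker, peak_p = min(group, key=lambda t: (t[1], t[0].pos))
    return Mqtl(
        trait_id=trait_id,
        interval=GenomicInterval.from_1based(chrom, start, end),
        peak_pos=peak_marker.pos,
        peak_stat=float(max(peak_p, np.nextafter(0, 1))),
        stat_type="pvalue",
        member_markers=tuple(markers),
    )
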