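"""Haplotype-based linkage disequilibrium: signed r and r2, decay curves,
adjacent-SNP summaries, cross-population phase persistence, and the marker
density helper.

Signed r between two SNPs is the Pearson correlation of their alt-allele
indicator columns across haplotypes, equivalently D / sqrt(pq at both loci).
Pairs involving a monomorphic column are undefined and excluded (never set to
zero). Phase persistence at a distance bin is the Pearson correlation, across
SNP pairs in the bin, of signed r between the two subpopulations: high values
mean marker-QTL phases transfer between them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .model import HaplotypePanel

logger = logging.getLogger("subpopscan.ld")

#: decay bins: 10 kb steps from 10 to 100 kb, then 100-200, 200-500, 500-1000 kb
DEFAULT_DECAY_EDGES_BP: tuple[int, ...] = tuple(
    list(range(10_000, 100_001, 10_000)) + [200_000, 500_000, 1_000_000]
)

#: Table-style adjacent-SNP distance classes, disjoint (lo, hi] bands in bp
DEFAULT_DISTANCE_CLASSES_BP: tuple[tuple[int, int], ...] = (
    (0, 100_000),
    (100_000, 300_000),
    (300_000, 500_000),
)


@dataclass
class LdPair:
    i: int
    j: int
    distance_bp: int
    r_signed: float

    @property
    def r2(self) -> float:
        return self.r_signed ** 2


def _standardize(hap_matrix: np.ndarray) -> np.ndarray:
    """Column-standardize a binary haplotype matrix; monomorphic columns NaN."""
    x = hap_matrix.astype(float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        xs = (x - mu) / sd
    xs[:, sd == 0] = np.nan
    return xs


def pair_r(hap: HaplotypePanel, i: int, j: int) -> LdPair:
    """Signed r between SNPs i and j (same chromosome) across haplotypes."""
    if hap.markers.chrom[i] != hap.markers.chrom[j]:
        raise ValueError("pair_r requires syntenic SNPs")
    if i == j:
        raise ValueError("pair_r requires two distinct SNPs")
    a = hap.haplotypes[:, i].astype(float)
    b = hap.haplotypes[:, j].astype(float)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError(
            f"r undefined: monomorphic column at SNP "
            f"{hap.markers.snp_id[i] if sa == 0 else hap.markers.snp_id[j]}"
        )
    r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    return LdPair(i=i, j=j,
                  distance_bp=int(abs(hap.markers.pos_bp[j] - hap.markers.pos_bp[i])),
                  r_signed=r)


def _iter_offset_r(xs: np.ndarray, pos: np.ndarray,
                   max_dist_bp: int) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield (distances, signed r) for all syntenic pairs at increasing map
    offsets until every pair exceeds max_dist_bp."""
    n_hap, m = xs.shape
    for d in range(1, m):
        dist = pos[d:] - pos[:-d]
        if dist.min() > max_dist_bp:
            break
        with np.errstate(invalid="ignore"):
            r = np.mean(xs[:, d:] * xs[:, :-d], axis=0)
        yield dist, r


def signed_r_pairs(hap: HaplotypePanel, max_dist_bp: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Distances and signed r of all syntenic pairs within max_dist_bp
    (pairs with a monomorphic SNP carry NaN)."""
    dists, rs = [], []
    for _, lo, hi in hap.markers.chrom_blocks():
        xs = _standardize(hap.haplotypes[:, lo:hi])
        for dist, r in _iter_offset_r(xs, hap.markers.pos_bp[lo:hi], max_dist_bp):
            dists.append(dist)
            rs.append(r)
    if not dists:
        return np.array([], dtype=np.int64), np.array([])
    return np.concatenate(dists), np.concatenate(rs)


def ld_decay(hap: HaplotypePanel,
             bin_edges_bp: Sequence[int] = DEFAULT_DECAY_EDGES_BP) -> pd.DataFrame:
    """Mean r2 per physical-distance bin (half-open [lo, hi) bins)."""
    edges = np.asarray(sorted(bin_edges_bp), dtype=np.int64)
    dist, r = signed_r_pairs(hap, int(edges[-1]))
    ok = np.isfinite(r) & (dist < edges[-1])
    dist, r2 = dist[ok], r[ok] ** 2
    k = np.searchsorted(edges, dist, side="right")
    inside = (k >= 1) & (k <= len(edges) - 1)
    k, r2 = k[inside] - 1, r2[inside]
    n_bins = len(edges) - 1
    counts = np.bincount(k, minlength=n_bins)
    sums = np.bincount(k, weights=r2, minlength=n_bins)
    sq = np.bincount(k, weights=r2 ** 2, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / counts, np.nan)
        var = np.where(counts > 1, (sq - counts * mean ** 2) / (counts - 1), np.nan)
        se = np.sqrt(np.where(var > 0, var, 0) / np.maximum(counts, 1))
        se = np.where(counts > 1, se, np.nan)
    return pd.DataFrame({
        "bin_lo_bp": edges[:-1],
        "bin_hi_bp": edges[1:],
        "n_pairs": counts,
        "mean_r2": mean,
        "se_r2": se,
    })


def adjacent_r2_summary(
    hap: HaplotypePanel,
    maf_thresholds: Sequence[float] = (0.0, 0.01, 0.05),
    distance_classes_bp: Sequence[tuple[int, int]] = DEFAULT_DISTANCE_CLASSES_BP,
    maf: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Mean +/- SE r2 of adjacent SNPs, overall and per distance class, at each
    MAF threshold (SNPs kept when MAF strictly exceeds the threshold).

    `maf` overrides the per-SNP MAF used for filtering (e.g. the minimum of the
    two subpopulations' MAFs when the thresholds must hold in both panels);
    by default the panel's own MAF is used. Adjacency means consecutive SNPs
    in the filtered map. Distance classes are disjoint (lo, hi] bands.
    """
    if maf is None:
        p = hap.haplotypes.mean(axis=0)
        maf = np.minimum(p, 1 - p)
    maf = np.asarray(maf, dtype=float)
    rows = []
    for t in maf_thresholds:
        keep = np.flatnonzero(maf > t)
        sub = hap.take_snps(keep)
        dists, rs = [], []
        for _, lo, hi in sub.markers.chrom_blocks():
            xs = _standardize(sub.haplotypes[:, lo:hi])
            pos = sub.markers.pos_bp[lo:hi]
            if hi - lo < 2:
                continue
            with np.errstate(invalid="ignore"):
                r = np.mean(xs[:, 1:] * xs[:, :-1], axis=0)
            dists.append(np.diff(pos))
            rs.append(r)
        dist = np.concatenate(dists) if dists else np.array([], dtype=np.int64)
        r = np.concatenate(rs) if rs else np.array([])
        ok = np.isfinite(r)
        dist, r2 = dist[ok], r[ok] ** 2

        def add_row(label: str, sel: np.ndarray) -> None:
            vals = r2[sel]
            rows.append({
                "maf_threshold": t,
                "distance_class": label,
                "n_pairs": int(sel.sum()),
                "mean_r2": float(vals.mean()) if len(vals) else np.nan,
                "se_r2": (float(vals.std(ddof=1) / math.sqrt(len(vals)))
                          if len(vals) > 1 else np.nan),
            })

        add_row("all", np.ones(len(r2), dtype=bool))
        for lo_bp, hi_bp in distance_classes_bp:
            add_row(f"({lo_bp // 1000}-{hi_bp // 1000}]kb",
                    (dist > lo_bp) & (dist <= hi_bp))
    return pd.DataFrame(rows)


def phase_persistence(
    hapA: HaplotypePanel,
    hapB: HaplotypePanel,
    max_pair_dist_bp: int = 10_000_000,
    bin_start_bp: int = 100_000,
    bin_stop_bp: int = 5_000_000,
    bin_width_bp: int = 100_000,
) -> pd.DataFrame:
    """Per-distance-bin Pearson correlation of signed r between two
    subpopulations sharing one map and allele coding.

    Bins are [lo, lo + width) from bin_start to bin_stop. Pairs undefined
    (monomorphic) in either population are excluded; bins with fewer than two
    pairs report NaN.
    """
    if not np.array_equal(hapA.markers.pos_bp, hapB.markers.pos_bp) or \
            not np.array_equal(hapA.markers.chrom, hapB.markers.chrom):
        raise ValueError("phase persistence requires panels on one shared map")
    max_dist = min(max_pair_dist_bp, bin_stop_bp)
    distA, rA = signed_r_pairs(hapA, max_dist)
    distB, rB = signed_r_pairs(hapB, max_dist)
    assert np.array_equal(distA, distB)
    ok = np.isfinite(rA) & np.isfinite(rB) \
        & (distA >= bin_start_bp) & (distA < bin_stop_bp)
    dist, rA, rB = distA[ok], rA[ok], rB[ok]
    k = ((dist - bin_start_bp) // bin_width_bp).astype(np.int64)
    n_bins = (bin_stop_bp - bin_start_bp) // bin_width_bp
    n = np.bincount(k, minlength=n_bins).astype(float)
    sA = np.bincount(k, weights=rA, minlength=n_bins)
    sB = np.bincount(k, weights=rB, minlength=n_bins)
    sAA = np.bincount(k, weights=rA * rA, minlength=n_bins)
    sBB = np.bincount(k, weights=rB * rB, minlength=n_bins)
    sAB = np.bincount(k, weights=rA * rB, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        meanA, meanB = sA / n, sB / n
        cov = sAB - sA * sB / n
        ssA = sAA - sA ** 2 / n
        ssB = sBB - sB ** 2 / n
        corr = cov / np.sqrt(ssA * ssB)
        sdA = np.sqrt(np.where(n > 1, ssA / (n - 1), np.nan))
        sdB = np.sqrt(np.where(n > 1, ssB / (n - 1), np.nan))
    corr = np.where(n >= 2, corr, np.nan)
    lows = bin_start_bp + bin_width_bp * np.arange(n_bins)
    return pd.DataFrame({
        "bin_lo_bp": lows,
        "bin_hi_bp": lows + bin_width_bp,
        "n_pairs": n.astype(int),
        "r_mean_a": np.where(n > 0, meanA, np.nan),
        "r_mean_b": np.where(n > 0, meanB, np.nan),
        "r_sd_a": sdA,
        "r_sd_b": sdB,
        "phase_corr": corr,
    })


def required_marker_density(genome_length_mb: float, max_spacing_kb: float) -> int:
    """Minimum SNP count so mean spacing matches max_spacing_kb:
    floor(genome length / spacing)."""
    if genome_length_mb <= 0 or max_spacing_kb <= 0:
        raise ValueError("genome length and spacing must be positive")
    return int(math.floor(genome_length_mb * 1000.0 / max_spacing_kb))
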