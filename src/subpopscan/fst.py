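"""Weir & Cockerham F_ST and the F_ST-heterozygosity outlier scan.

Per SNP the two-population Weir-Cockerham (1984) estimator is computed from
diploid sample sizes, alt-allele frequencies and observed heterozygote
proportions: variance components a (among populations), b (among individuals
within populations) and c (within individuals) give theta = a / (a + b + c).
Windowed theta uses the standard low-bias ratio-of-averages
(sum a / sum(a + b + c) over the window's SNPs); window heterozygosity is the
mean of 2 p_bar (1 - p_bar). Because the null range of theta depends on allele
frequency, outliers are called against the 99.9th percentile of theta within
each of 20 equal-count heterozygosity bins, and regions require at least two
consecutive flagged windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MISSING, CandidateRegion, GenotypePanel, WindowTrack
from .varld import consecutive_window_regions

logger = logging.getLogger("subpopscan.fst")


@dataclass
class FstComponents:
    n1: int
    n2: int
    p1: float
    p2: float
    h1: float
    h2: float
    a: float
    b: float
    c: float

    @property
    def theta(self) -> float:
        denom = self.a + self.b + self.c
        return self.a / denom if denom != 0 else np.nan


def _wc_components_arrays(n1, n2, p1, p2, h1, h2):
    """Vectorized Weir-Cockerham (1984) components for r=2 populations."""
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    h1 = np.asarray(h1, float)
    h2 = np.asarray(h2, float)
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - (r - 1.0) / r * s2
        - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c, pbar


def _per_snp_stats(panel: GenotypePanel):
    """(n, p, h) per subpopulation per SNP, ignoring missing genotypes."""
    pops = panel.subpop_labels()
    if len(pops) != 2:
        raise ValueError(f"F_ST needs exactly two subpopulations, got {pops}")
    out = []
    for pop in pops:
        d = panel.dosage[panel.sample_indices(pop)]
        obs = d != MISSING
        n = obs.sum(axis=0)
        alt = np.where(obs, d, 0).sum(axis=0)
        het = ((d == 1) & obs).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / (2.0 * n), np.nan)
            h = np.where(n > 0, het / n, np.nan)
        out.append((n, p, h))
    return pops, out


def wc_fst_components(panel: GenotypePanel) -> pd.DataFrame:
    """Per-SNP Weir-Cockerham components and theta for a two-subpopulation
    panel. SNPs monomorphic in the pooled sample, or with fewer than two
    genotyped samples in either subpopulation, are undefined (NaN theta)."""
    _, ((n1, p1, h1), (n2, p2, h2)) = _per_snp_stats(panel)
    with np.errstate(invalid="ignore", divide="ignore"):
        a, b, c, pbar = _wc_components_arrays(n1, n2, p1, p2, h1, h2)
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)
    defined = (n1 >= 2) & (n2 >= 2) & (pbar > 0) & (pbar < 1) & np.isfinite(theta)
    df = pd.DataFrame({
        "n1": n1, "n2": n2, "p1": p1, "p2": p2, "h1": h1, "h2": h2,
        "a": a, "b": b, "c": c, "pbar": pbar, "theta": theta,
        "defined": defined,
    })
    df.loc[~defined, ["a", "b", "c", "theta"]] = np.nan
    return df


def wc_fst_snp(panel: GenotypePanel, snp: int) -> FstComponents:
    """Weir-Cockerham components at a single SNP."""
    _, ((n1, p1, h1), (n2, p2, h2)) = _per_snp_stats(panel)
    if n1[snp] < 2 or n2[snp] < 2:
        raise ValueError("both subpopulations need >= 2 genotyped samples")
    a, b, c, pbar = _wc_components_arrays(
        n1[snp], n2[snp], p1[snp], p2[snp], h1[snp], h2[snp])
    if pbar in (0.0, 1.0):
        raise ValueError("theta undefined at a pooled-monomorphic SNP")
    return FstComponents(n1=int(n1[snp]), n2=int(n2[snp]), p1=float(p1[snp]),
                         p2=float(p2[snp]), h1=float(h1[snp]), h2=float(h2[snp]),
                         a=float(a), b=float(b), c=float(c))


def fst_window_track(panel: GenotypePanel, window_snps: int = 15) -> WindowTrack:
    """Sliding-window theta (ratio of averages) and window heterozygosity.

    Undefined SNPs are excluded from the window sums; windows with no defined
    SNP are dropped (logged). Window heterozygosity (`aux`) is the mean of
    2 p_bar (1 - p_bar) over the window's defined SNPs.
    """
    comp = wc_fst_components(panel)
    a = comp["a"].to_numpy()
    abc = (comp["a"] + comp["b"] + comp["c"]).to_numpy()
    het = (2.0 * comp["pbar"] * (1.0 - comp["pbar"])).to_numpy()
    defined = comp["defined"].to_numpy()
    mmap = panel.markers
    w = window_snps
    chroms, starts, ends, first_idx, score, aux = [], [], [], [], [], []
    n_dropped = 0
    for chrom, lo, hi in mmap.chrom_blocks():
        m = hi - lo
        if m < w:
            logger.warning("chromosome %s has %d SNPs < window %d; skipped",
                           chrom, m, w)
            continue
        pos = mmap.pos_bp[lo:hi]
        for s in range(m - w + 1):
            sel = slice(lo + s, lo + s + w)
            ok = defined[sel]
            if not ok.any():
                n_dropped += 1
                continue
            chroms.append(chrom)
            starts.append(int(pos[s]))
            ends.append(int(pos[s + w - 1]))
            first_idx.append(lo + s)
            score.append(float(np.nansum(a[sel]) / np.nansum(abc[sel])))
            aux.append(float(np.nanmean(het[sel][ok])))
    if n_dropped:
        logger.info("%d windows dropped: no defined SNPs", n_dropped)
    return WindowTrack(chrom=np.asarray(chroms, object), start_bp=starts,
                       end_bp=ends, first_snp_index=first_idx, n_snps=w,
                       score=np.asarray(score), aux=np.asarray(aux))


def assign_het_bins(het: np.ndarray, n_bins: int = 20,
                    min_bin_size: int = 50) -> np.ndarray:
    """Equal-count (quantile) heterozygosity bins; bins smaller than
    min_bin_size are merged with a neighbor."""
    het = np.asarray(het, float)
    order = np.argsort(het, kind="stable")
    n = len(het)
    n_bins = max(1, min(n_bins, n // max(min_bin_size, 1)) or 1)
    bins = np.zeros(n, dtype=np.int64)
    # equal-count split of the sorted order
    edges = np.linspace(0, n, n_bins + 1).astype(int)
    for b in range(n_bins):
        bins[order[edges[b]:edges[b + 1]]] = b
    # merge undersized bins into their lower neighbor
    for b in range(n_bins):
        size = int((bins == b).sum())
        if 0 < size < min_bin_size:
            target = b - 1 if b > 0 else b + 1
            if 0 <= target < n_bins:
                logger.info("heterozygosity bin %d (%d windows) merged into %d",
                            b, size, target)
                bins[bins == b] = target
    return bins


def fst_outlier_regions(
    track: WindowTrack,
    n_bins: int = 20,
    percentile: float = 99.9,
    min_consecutive: int = 2,
    min_bin_size: int = 50,
) -> list[CandidateRegion]:
    """F_ST-heterozygosity outlier calling: windows are grouped into
    equal-count heterozygosity bins, flagged when theta strictly exceeds the
    percentile threshold of their own bin, and runs of >= min_consecutive
    consecutive flagged windows become candidate regions."""
    if track.aux is None:
        raise ValueError("track must carry window heterozygosity in aux")
    bins = assign_het_bins(track.aux, n_bins=n_bins, min_bin_size=min_bin_size)
    flags = np.zeros(len(track), dtype=bool)
    for b in np.unique(bins):
        sel = bins == b
        threshold = float(np.percentile(track.score[sel], percentile))
        flags[sel] = track.score[sel] > threshold
    return consecutive_window_regions(track, min_consecutive=min_consecutive,
                                      source="FST", flags=flags)


def global_fst(panel: GenotypePanel) -> tuple[float, float]:
    """Mean and sd of per-SNP theta over defined SNPs (sd 0 for a single SNP)."""
    comp = wc_fst_components(panel)
    theta = comp.loc[comp["defined"], "theta"].to_numpy()
    if len(theta) == 0:
        raise ValueError("no defined SNPs for F_ST")
    if len(theta) == 1:
        logger.info("single defined SNP; sd reported as 0 by convention")
        return float(theta[0]), 0.0
    return float(theta.mean()), float(theta.std(ddof=1))
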