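"""varLD: regional LD contrast between two subpopulations.

For every sliding window of a fixed SNP count, an r2 matrix (unit diagonal) is
built per subpopulation from phased haplotypes; the raw varLD score of the
window is the sum of absolute differences between the two matrices' descending
eigenvalues. Because both matrices have unit diagonal, each eigenvalue list
sums to the window SNP count, which makes the score a pure contrast of LD
structure. Raw scores are standardized genome-wide (mean 0, sd 1; a monotone
map that leaves percentile calls unchanged) and regions with at least
`min_consecutive` consecutive windows strictly above the percentile threshold
are reported as candidate signals of divergent selection.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .ld import _standardize
from .model import CandidateRegion, HaplotypePanel, WindowTrack

logger = logging.getLogger("subpopscan.varld")


def window_ld_matrix(hap: HaplotypePanel, snp_indices: Sequence[int]) -> np.ndarray:
    """Symmetric r2 matrix over the window's SNPs within one subpopulation.

    Off-diagonal entries involving a within-population monomorphic SNP are set
    to 0 (no information) and the diagonal stays 1, so homologous windows keep
    identical dimensions across subpopulations.
    """
    idx = np.asarray(snp_indices)
    if len(set(hap.markers.chrom[idx])) > 1:
        raise ValueError("window spans more than one chromosome")
    xs = _standardize(hap.haplotypes[:, idx])
    xs = np.nan_to_num(xs)  # monomorphic columns -> zero vectors
    r = (xs.T @ xs) / xs.shape[0]
    mat = r ** 2
    np.fill_diagonal(mat, 1.0)
    return mat


def raw_varld(matA: np.ndarray, matB: np.ndarray) -> float:
    """Sum of absolute differences between the descending eigenvalues of two
    homologous symmetric LD matrices."""
    matA, matB = np.asarray(matA, float), np.asarray(matB, float)
    if matA.shape != matB.shape:
        raise ValueError("homologous matrices must share a dimension")
    for m in (matA, matB):
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("LD matrices must be symmetric")
    ev_a = np.sort(np.linalg.eigvalsh(matA))[::-1]
    ev_b = np.sort(np.linalg.eigvalsh(matB))[::-1]
    return float(np.abs(ev_a - ev_b).sum())


def varld_scan(
    hapA: HaplotypePanel,
    hapB: HaplotypePanel,
    window_snps: int = 15,
    percentile: float = 99.9,
    min_consecutive: int = 2,
) -> tuple[WindowTrack, list[CandidateRegion]]:
    """Sliding-window varLD scan; returns the standardized score track and the
    candidate regions (spanning the first SNP of the first window to the last
    SNP of the last window of each qualifying run)."""
    if not np.array_equal(hapA.markers.pos_bp, hapB.markers.pos_bp) or \
            not np.array_equal(hapA.markers.chrom, hapB.markers.chrom):
        raise ValueError("varLD requires panels on one shared map")
    mmap = hapA.markers
    w = window_snps
    chroms, starts, ends, first_idx, raw = [], [], [], [], []
    for chrom, lo, hi in mmap.chrom_blocks():
        m = hi - lo
        if m < w:
            logger.warning("chromosome %s has %d SNPs < window %d; skipped",
                           chrom, m, w)
            continue
        xa = np.nan_to_num(_standardize(hapA.haplotypes[:, lo:hi]))
        xb = np.nan_to_num(_standardize(hapB.haplotypes[:, lo:hi]))
        ra = ((xa.T @ xa) / xa.shape[0]) ** 2
        rb = ((xb.T @ xb) / xb.shape[0]) ** 2
        np.fill_diagonal(ra, 1.0)
        np.fill_diagonal(rb, 1.0)
        pos = mmap.pos_bp[lo:hi]
        for s in range(m - w + 1):
            ev_a = np.linalg.eigvalsh(ra[s:s + w, s:s + w])
            ev_b = np.linalg.eigvalsh(rb[s:s + w, s:s + w])
            raw.append(float(np.abs(ev_a - ev_b).sum()))  # both ascending
            chroms.append(chrom)
            starts.append(int(pos[s]))
            ends.append(int(pos[s + w - 1]))
            first_idx.append(lo + s)
    raw_arr = np.asarray(raw)
    if len(raw_arr):
        sd = raw_arr.std(ddof=0)
        std = (raw_arr - raw_arr.mean()) / sd if sd > 0 else raw_arr - raw_arr.mean()
    else:
        std = raw_arr
    track = WindowTrack(chrom=np.asarray(chroms, object), start_bp=starts,
                        end_bp=ends, first_snp_index=first_idx,
                        n_snps=w, score=std, aux=raw_arr)
    regions = consecutive_window_regions(track, percentile=percentile,
                                         min_consecutive=min_consecutive,
                                         source="VARLD")
    return track, regions


def consecutive_window_regions(
    track: WindowTrack,
    percentile: float = 99.9,
    min_consecutive: int = 2,
    source: str = "VARLD",
    flags: np.ndarray = None,
) -> list[CandidateRegion]:
    """Maximal runs of >= min_consecutive consecutive windows (same chromosome,
    window start advancing by one SNP) strictly above the percentile of the
    track's score distribution. Precomputed boolean `flags` override the
    percentile thresholding (used by the F_ST heterozygosity-bin variant)."""
    if len(track) == 0:
        return []
    if flags is None:
        threshold = float(np.percentile(track.score, percentile))
        flags = track.score > threshold
    flags = np.asarray(flags, bool)
    regions: list[CandidateRegion] = []
    idx = np.flatnonzero(flags)
    if len(idx) == 0:
        return regions
    new_run = np.ones(len(idx), dtype=bool)
    same = (track.first_snp_index[idx[1:]] == track.first_snp_index[idx[:-1]] + 1) \
        & (track.chrom[idx[1:]] == track.chrom[idx[:-1]])
    new_run[1:] = ~same
    for run in np.split(idx, np.flatnonzero(new_run)[1:]):
        if len(run) >= min_consecutive:
            regions.append(CandidateRegion(
                chrom=str(track.chrom[run[0]]),
                start_bp=int(track.start_bp[run[0]]),
                end_bp=int(track.end_bp[run[-1]]),
                source=source,
                n_units=int(len(run)),
            ))
    return regions
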