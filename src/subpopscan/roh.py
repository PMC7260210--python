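"""Runs of homozygosity: detection, inbreeding, autozygosity tracks, islands.

Two detectors are provided. The sliding detector mirrors the PLINK two-stage
algorithm: fixed-size SNP windows vote on each SNP (a window passes when it
contains at most one heterozygote and no more missing calls than allowed), a
SNP joins a run when the fraction of passing windows spanning it reaches the
hit-rate threshold, and maximal in-run stretches are split at long gaps and
filtered on length and mean marker density. The consecutive detector extends
runs SNP by SNP under the same per-run heterozygote allowance and gap rule,
then applies the same length/density filters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    MISSING,
    CandidateRegion,
    GenotypePanel,
    MarkerMap,
)

logger = logging.getLogger("subpopscan.roh")


@dataclass(frozen=True)
class RohParams:
    window_snps: int = 30
    het_allowed_per_window: int = 1
    missing_allowed_per_window: int = 0
    hit_rate_threshold: float = 0.05
    min_len_bp: int = 1_000_000
    min_density_bp_per_snp: int = 120_000
    max_gap_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if not 0 < self.hit_rate_threshold <= 1:
            raise ValueError("hit_rate_threshold must lie in (0, 1]")
        for v in (self.window_snps, self.min_len_bp,
                  self.min_density_bp_per_snp, self.max_gap_bp):
            if v <= 0:
                raise ValueError("RohParams sizes must be positive")


@dataclass
class RohSegment:
    sample: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def segments_to_dataframe(segments: Sequence[RohSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": s.sample,
                "chrom": s.chrom,
                "start_bp": s.start_bp,
                "end_bp": s.end_bp,
                "n_snps": s.n_snps,
                "length_bp": s.length_bp,
            }
            for s in segments
        ],
        columns=["sample", "chrom", "start_bp", "end_bp", "n_snps", "length_bp"],
    )


def _close_candidates(mask: np.ndarray, pos: np.ndarray, chrom: str,
                      sample: str, params: RohParams) -> list[RohSegment]:
    """Maximal True stretches of `mask`, split at long gaps, filtered on
    minimum length and mean inter-SNP density."""
    out: list[RohSegment] = []
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return out
    # maximal stretches of consecutive map indices
    breaks = np.flatnonzero(np.diff(idx) > 1)
    stretch_bounds = np.split(idx, breaks + 1)
    for stretch in stretch_bounds:
        # split at physical gaps exceeding max_gap_bp
        gaps = np.diff(pos[stretch])
        gap_breaks = np.flatnonzero(gaps > params.max_gap_bp)
        for part in np.split(stretch, gap_breaks + 1):
            out.extend(_finalize_run(part, pos, chrom, sample, params))
    return out


def _finalize_run(run_idx: np.ndarray, pos: np.ndarray, chrom: str,
                  sample: str, params: RohParams) -> list[RohSegment]:
    if len(run_idx) == 0:
        return []
    start, end = int(pos[run_idx[0]]), int(pos[run_idx[-1]])
    length = end - start + 1
    if length < params.min_len_bp:
        return []
    if length / len(run_idx) > params.min_density_bp_per_snp:
        return []
    return [RohSegment(sample=sample, chrom=chrom, start_bp=start,
                       end_bp=end, n_snps=int(len(run_idx)))]


def detect_roh_sliding(panel: GenotypePanel,
                       params: RohParams = RohParams()) -> list[RohSegment]:
    """PLINK-style two-stage window-vote ROH detection, per sample."""
    segments: list[RohSegment] = []
    mmap = panel.markers
    for chrom, lo, hi in mmap.chrom_blocks():
        pos = mmap.pos_bp[lo:hi]
        m = hi - lo
        w = min(params.window_snps, m)
        if w < params.window_snps:
            logger.info("chromosome %s has %d SNPs < window %d; window shrunk",
                        chrom, m, params.window_snps)
        n_windows = m - w + 1
        dos = panel.dosage[:, lo:hi]
        het = (dos == 1).astype(np.int32)
        miss = (dos == MISSING).astype(np.int32)
        # per-window counts via cumulative sums: window j covers [j, j+w)
        chet = np.concatenate([np.zeros((panel.n_samples, 1), np.int32),
                               np.cumsum(het, axis=1)], axis=1)
        cmiss = np.concatenate([np.zeros((panel.n_samples, 1), np.int32),
                                np.cumsum(miss, axis=1)], axis=1)
        win_het = chet[:, w:] - chet[:, :-w]
        win_miss = cmiss[:, w:] - cmiss[:, :-w]
        passing = ((win_het <= params.het_allowed_per_window)
                   & (win_miss <= params.missing_allowed_per_window))
        cpass = np.concatenate([np.zeros((panel.n_samples, 1), np.int32),
                                np.cumsum(passing, axis=1)], axis=1)
        snp_i = np.arange(m)
        w_lo = np.maximum(0, snp_i - w + 1)
        w_hi = np.minimum(snp_i, n_windows - 1)
        spans = (w_hi - w_lo + 1).astype(float)
        for si in range(panel.n_samples):
            hits = cpass[si, w_hi + 1] - cpass[si, w_lo]
            in_run = hits / spans >= params.hit_rate_threshold
            segments.extend(_close_candidates(in_run, pos, chrom,
                                              str(panel.samples[si]), params))
    return segments


def detect_roh_consecutive(panel: GenotypePanel,
                           params: RohParams = RohParams()) -> list[RohSegment]:
    """Single-pass run extension: extend while the run holds at most one
    heterozygote and adjacent gaps stay within max_gap_bp; missing calls break
    the run. Candidate runs face the same length/density filters as the
    sliding detector."""
    segments: list[RohSegment] = []
    mmap = panel.markers
    for chrom, lo, hi in mmap.chrom_blocks():
        pos = mmap.pos_bp[lo:hi]
        m = hi - lo
        dos = panel.dosage[:, lo:hi]
        for si in range(panel.n_samples):
            sample = str(panel.samples[si])
            d = dos[si]
            start: Optional[int] = None
            first_het = -1
            n_het = 0

            def close(end_idx: int) -> None:
                nonlocal start, first_het, n_het
                if start is not None and end_idx >= start:
                    run = np.arange(start, end_idx + 1)
                    segments.extend(_finalize_run(run, pos, chrom, sample, params))
                start, first_het, n_het = None, -1, 0

            for i in range(m):
                if d[i] == MISSING:
                    close(i - 1)
                    continue
                if start is not None and pos[i] - pos[i - 1] > params.max_gap_bp:
                    close(i - 1)
                if d[i] == 1:
                    if start is None:
                        start, first_het, n_het = i, i, 1
                    elif n_het < params.het_allowed_per_window:
                        n_het += 1
                        if first_het < 0:
                            first_het = i
                    else:
                        # too many heterozygotes: close at the previous SNP;
                        # the offending heterozygote opens the next run (runs
                        # never overlap)
                        close(i - 1)
                        start, first_het, n_het = i, i, 1
                else:
                    if start is None:
                        start = i
            close(m - 1)
    return segments


def f_roh(segments: Sequence[RohSegment], mmap: MarkerMap,
          samples: Sequence[str]) -> pd.Series:
    """Per-sample inbreeding: summed ROH length over SNP-covered genome length."""
    denom = mmap.covered_length_bp()
    if denom <= 0:
        raise ValueError("zero genome length covered by the SNP map")
    totals = {str(s): 0 for s in samples}
    for seg in segments:
        if seg.sample in totals:
            totals[seg.sample] += seg.length_bp
    return pd.Series({s: totals[s] / denom for s in totals}, name="f_roh")


def roh_length_summary(segments: Sequence[RohSegment], panel: GenotypePanel,
                       thresholds_mb: Sequence[float] = (4, 8, 16)) -> pd.DataFrame:
    """Per-subpopulation ROH length summary with %-longer-than columns."""
    df = segments_to_dataframe(segments)
    pop_of = {}
    if panel.subpop is not None:
        pop_of = dict(zip(panel.samples, panel.subpop))
    df["pop"] = [pop_of.get(s, "all") for s in df["sample"]] if len(df) else []
    pops = panel.subpop_labels() or ["all"]
    rows = []
    for pop in pops:
        sub = df[df["pop"] == pop] if len(df) else df
        pop_samples = [s for s in panel.samples if pop_of.get(s, "all") == pop]
        row = {"pop": pop, "n_segments": int(len(sub))}
        if len(sub):
            lens_mb = sub["length_bp"].to_numpy() / 1e6
            row.update(
                mean_mb=float(lens_mb.mean()),
                sd_mb=float(lens_mb.std(ddof=1)) if len(lens_mb) > 1 else 0.0,
                min_mb=float(lens_mb.min()),
                max_mb=float(lens_mb.max()),
            )
            for t in thresholds_mb:
                row[f"pct_segments_gt_{t:g}mb"] = float(100.0 * np.mean(lens_mb > t))
                carriers = sub.loc[lens_mb > t, "sample"].nunique()
                row[f"pct_samples_gt_{t:g}mb"] = (
                    float(100.0 * carriers / len(pop_samples)) if pop_samples else 0.0
                )
        else:
            row.update(mean_mb=np.nan, sd_mb=np.nan, min_mb=np.nan, max_mb=np.nan)
            for t in thresholds_mb:
                row[f"pct_segments_gt_{t:g}mb"] = 0.0
                row[f"pct_samples_gt_{t:g}mb"] = 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def autozygosity_track(segments: Sequence[RohSegment], mmap: MarkerMap,
                       samples: Sequence[str]) -> np.ndarray:
    """Per-SNP proportion of `samples` whose ROH set covers the SNP
    (segment boundaries inclusive)."""
    sample_set = {str(s) for s in samples}
    if not sample_set:
        raise ValueError("autozygosity track needs at least one sample")
    blocks = {c: (lo, hi) for c, lo, hi in mmap.chrom_blocks()}
    spans: dict[str, list[tuple[int, int]]] = {}
    for seg in segments:
        if seg.sample not in sample_set or seg.chrom not in blocks:
            continue
        lo, hi = blocks[seg.chrom]
        pos = mmap.pos_bp[lo:hi]
        i0 = int(np.searchsorted(pos, seg.start_bp, side="left")) + lo
        i1 = int(np.searchsorted(pos, seg.end_bp, side="right")) + lo
        spans.setdefault(seg.sample, []).append((i0, i1))
    counts = np.zeros(mmap.n_snps, dtype=np.int64)
    covered = np.zeros(mmap.n_snps, dtype=bool)
    for sample_spans in spans.values():
        covered[:] = False
        for i0, i1 in sample_spans:  # union: each animal counted once per SNP
            covered[i0:i1] = True
        counts += covered
    return counts / float(len(sample_set))


def roh_islands(scores: np.ndarray, mmap: MarkerMap, percentile: float = 99.9,
                min_adjacent: int = 2, source: str = "ROH") -> list[CandidateRegion]:
    """Regions of >= min_adjacent adjacent SNPs whose autozygosity score
    reaches the genome-wide percentile threshold (linear-interpolation
    percentile, inclusive comparison).

    Inclusive thresholding matters here because track scores are quantized
    (multiples of 1 / subpopulation size) and adjacent SNPs covered by the
    same animals tie exactly, so an island's crest is a plateau that a strict
    comparison would miss whenever the percentile lands on it. A track whose
    threshold does not exceed the genome-wide minimum (e.g. a constant track)
    yields no islands: nothing is exceptional."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("autozygosity scores must be finite")
    threshold = float(np.percentile(scores, percentile))
    if threshold <= scores.min():
        logger.info("degenerate track: %.4g percentile threshold at the "
                    "genome-wide minimum; no islands", percentile)
        return []
    above = scores >= threshold
    if not above.any():
        return []
    regions: list[CandidateRegion] = []
    for chrom, lo, hi in mmap.chrom_blocks():
        idx = np.flatnonzero(above[lo:hi]) + lo
        if len(idx) == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        for run in np.split(idx, breaks + 1):
            if len(run) >= min_adjacent:
                regions.append(CandidateRegion(
                    chrom=chrom,
                    start_bp=int(mmap.pos_bp[run[0]]),
                    end_bp=int(mmap.pos_bp[run[-1]]),
                    source=source,
                    n_units=int(len(run)),
                ))
    return regions


def generations_to_ancestor(length_mb: float) -> int:
    """Expected generations to the common ancestor of an autozygous segment,
    g = floor(100 / (2 L_cM)), under the 1 Mb = 1 cM convention."""
    if length_mb <= 0:
        raise ValueError("segment length must be positive")
    return int(math.floor(100.0 / (2.0 * length_mb)))
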