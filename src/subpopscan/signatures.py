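"""Consensus selection signatures from ROH islands, F_ST and varLD regions.

Candidate regions from different tests that overlap by at least one base pair
are merged (union of spans). A merged cluster qualifies as a selection
signature when it is supported by two or more distinct sources; the two
subpopulations' ROH islands count as distinct sources, so an island shared by
both subpopulations qualifies on its own. Signatures whose support includes a
between-population differentiation test (F_ST or varLD) are classified as
divergent selection; support from both subpopulations' ROH islands alone is
classified as shared selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import CandidateRegion, WindowTrack

DIFFERENTIATION_SOURCES = {"FST", "VARLD"}


@dataclass
class SelectionSignature:
    chrom: str
    start_bp: int
    end_bp: int
    supporting_tests: frozenset
    classification: str
    members: list = field(default_factory=list)

    @property
    def region_label(self) -> str:
        return f"BTA{self.chrom}:{self.start_bp / 1e6:.2f}–{self.end_bp / 1e6:.2f}"


def consensus(regions_by_source: Mapping[str, Sequence[CandidateRegion]]
              ) -> list[SelectionSignature]:
    """Merge overlapping regions across sources; emit clusters with >= 2
    distinct supporting tests, sorted and pairwise non-overlapping."""
    tagged: list[tuple[CandidateRegion, str]] = []
    for source, regions in regions_by_source.items():
        for r in regions:
            tagged.append((r, source))
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start_bp, t[0].end_bp, t[1]))

    signatures: list[SelectionSignature] = []
    cluster: list[tuple[CandidateRegion, str]] = []

    def flush() -> None:
        if not cluster:
            return
        sources = frozenset(s for _, s in cluster)
        if len(sources) >= 2:
            classification = ("divergent_selection"
                              if sources & DIFFERENTIATION_SOURCES
                              else "shared_selection")
            signatures.append(SelectionSignature(
                chrom=cluster[0][0].chrom,
                start_bp=min(r.start_bp for r, _ in cluster),
                end_bp=max(r.end_bp for r, _ in cluster),
                supporting_tests=sources,
                classification=classification,
                members=list(cluster),
            ))
        cluster.clear()

    cur_chrom, cur_end = None, -1
    for r, s in tagged:
        if r.chrom != cur_chrom or r.start_bp > cur_end:
            flush()
            cur_chrom, cur_end = r.chrom, r.end_bp
        else:
            cur_end = max(cur_end, r.end_bp)
        cluster.append((r, s))
    flush()
    return signatures


def signatures_to_regions(signatures: Sequence[SelectionSignature]
                          ) -> list[CandidateRegion]:
    return [
        CandidateRegion(chrom=s.chrom, start_bp=s.start_bp, end_bp=s.end_bp,
                        source="+".join(sorted(s.supporting_tests)),
                        n_units=len(s.members))
        for s in signatures
    ]


def report(signatures: Sequence[SelectionSignature],
           tracks: Optional[Mapping[str, object]] = None) -> pd.DataFrame:
    """Human-readable signature table with per-source peak scores.

    `tracks` maps source name to either a WindowTrack or a tuple
    (scores, marker_map) for per-SNP tracks such as autozygosity.
    """
    rows = []
    for sig in signatures:
        row = {
            "region": sig.region_label,
            "chrom": sig.chrom,
            "start_bp": sig.start_bp,
            "end_bp": sig.end_bp,
            "sources": "+".join(sorted(sig.supporting_tests)),
            "classification": sig.classification,
        }
        if tracks:
            for name, track in tracks.items():
                row[f"peak_{name}"] = _peak_score(track, sig)
        rows.append(row)
    columns = ["region", "chrom", "start_bp", "end_bp", "sources", "classification"]
    if tracks:
        columns += [f"peak_{name}" for name in tracks]
    return pd.DataFrame(rows, columns=columns)


def _peak_score(track, sig: SelectionSignature) -> float:
    if isinstance(track, WindowTrack):
        sel = ((track.chrom == sig.chrom)
               & (track.start_bp <= sig.end_bp)
               & (track.end_bp >= sig.start_bp))
        return float(np.max(track.score[sel])) if sel.any() else np.nan
    scores, mmap = track
    sel = ((mmap.chrom == sig.chrom)
           & (mmap.pos_bp >= sig.start_bp)
           & (mmap.pos_bp <= sig.end_bp))
    return float(np.max(np.asarray(scores)[sel])) if sel.any() else np.nan
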