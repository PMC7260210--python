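"""Shared data model: marker maps, genotype/haplotype panels, window tracks, regions.

Coordinates are 1-based inclusive base pairs throughout the library; only BED
output converts to 0-based half-open. Missing genotypes are encoded with the
single sentinel :data:`MISSING`; phased haplotypes never carry missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing diploid dosage (distinct from {0, 1, 2}).
MISSING: int = -1


def _as_str_array(values) -> np.ndarray:
    return np.asarray(values, dtype=object)


@dataclass
class MarkerMap:
    """Positions and alleles of biallelic SNPs, grouped by chromosome.

    Chromosomes must form contiguous blocks and positions must be strictly
    increasing within each chromosome, so (chrom, pos) pairs are unique and
    window/distance logic can rely on map order.
    """

    chrom: np.ndarray
    pos_bp: np.ndarray
    snp_id: np.ndarray
    allele_ref: np.ndarray
    allele_alt: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = _as_str_array([str(c) for c in self.chrom])
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.snp_id = _as_str_array([str(s) for s in self.snp_id])
        self.allele_ref = _as_str_array([str(a) for a in self.allele_ref])
        self.allele_alt = _as_str_array([str(a) for a in self.allele_alt])
        n = len(self.pos_bp)
        for arr, name in [
            (self.chrom, "chrom"),
            (self.snp_id, "snp_id"),
            (self.allele_ref, "allele_ref"),
            (self.allele_alt, "allele_alt"),
        ]:
            if len(arr) != n:
                raise ValueError(f"MarkerMap field {name} has length {len(arr)} != {n}")
        seen = {}
        for c, start, stop in self.chrom_blocks():
            if c in seen:
                raise ValueError(f"chromosome {c} appears in non-contiguous blocks")
            seen[c] = True
            p = self.pos_bp[start:stop]
            if np.any(np.diff(p) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {c}"
                )

    @property
    def n_snps(self) -> int:
        return len(self.pos_bp)

    def __len__(self) -> int:
        return self.n_snps

    def chrom_blocks(self) -> list[tuple[str, int, int]]:
        """Return [(chrom, start_index, stop_index)] in map order."""
        blocks = []
        n = len(self.chrom)
        i = 0
        while i < n:
            j = i
            while j < n and self.chrom[j] == self.chrom[i]:
                j += 1
            blocks.append((self.chrom[i], i, j))
            i = j
        return blocks

    def chromosomes(self) -> list[str]:
        return [c for c, _, _ in self.chrom_blocks()]

    def take(self, idx) -> "MarkerMap":
        idx = np.asarray(idx)
        return MarkerMap(
            chrom=self.chrom[idx],
            pos_bp=self.pos_bp[idx],
            snp_id=self.snp_id[idx],
            allele_ref=self.allele_ref[idx],
            allele_alt=self.allele_alt[idx],
        )

    def covered_length_bp(self) -> int:
        """Sum over chromosomes of (last SNP bp - first SNP bp)."""
        return int(
            sum(self.pos_bp[stop - 1] - self.pos_bp[start]
                for _, start, stop in self.chrom_blocks())
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos_bp": self.pos_bp,
                "snp_id": self.snp_id,
                "allele_ref": self.allele_ref,
                "allele_alt": self.allele_alt,
            }
        )


@dataclass
class GenotypePanel:
    """Samples x SNPs alt-allele dosage matrix with map and sample metadata."""

    markers: MarkerMap
    samples: np.ndarray
    dosage: np.ndarray
    subpop: Optional[np.ndarray] = None
    coat_color: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.samples = _as_str_array([str(s) for s in self.samples])
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), self.markers.n_snps):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.samples)}, {self.markers.n_snps})"
            )
        ok = np.isin(self.dosage, (MISSING, 0, 1, 2))
        if not ok.all():
            bad = np.unique(self.dosage[~ok])
            raise ValueError(f"invalid dosage values {bad}")
        if self.subpop is not None:
            self.subpop = _as_str_array([str(s) for s in self.subpop])
            if len(self.subpop) != len(self.samples):
                raise ValueError("subpop length mismatch")
        if self.coat_color is not None:
            self.coat_color = _as_str_array(self.coat_color)
            if len(self.coat_color) != len(self.samples):
                raise ValueError("coat_color length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return self.markers.n_snps

    def subpop_labels(self) -> list[str]:
        """Distinct subpopulation labels in order of first appearance."""
        if self.subpop is None:
            return []
        seen: dict[str, None] = {}
        for s in self.subpop:
            seen.setdefault(s, None)
        return list(seen)

    def sample_indices(self, pop: Optional[str] = None) -> np.ndarray:
        if pop is None:
            return np.arange(self.n_samples)
        if self.subpop is None:
            raise ValueError("panel has no subpopulation labels")
        return np.flatnonzero(self.subpop == pop)

    def call_rate_samples(self) -> np.ndarray:
        return 1.0 - np.mean(self.dosage == MISSING, axis=1)

    def call_rate_snps(self) -> np.ndarray:
        return 1.0 - np.mean(self.dosage == MISSING, axis=0)

    def alt_freq(self, pop: Optional[str] = None) -> np.ndarray:
        """Alt-allele frequency per SNP over non-missing genotypes (NaN if none)."""
        d = self.dosage[self.sample_indices(pop)]
        obs = d != MISSING
        n = obs.sum(axis=0)
        alt = np.where(obs, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    def maf(self, pop: Optional[str] = None) -> np.ndarray:
        p = self.alt_freq(pop)
        return np.minimum(p, 1.0 - p)

    def het_per_sample(self) -> np.ndarray:
        """Observed heterozygosity: fraction of heterozygous non-missing calls."""
        obs = self.dosage != MISSING
        n = obs.sum(axis=1)
        h = (self.dosage == 1).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, h / n, np.nan)

    def take_samples(self, idx) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            markers=self.markers,
            samples=self.samples[idx],
            dosage=self.dosage[idx],
            subpop=None if self.subpop is None else self.subpop[idx],
            coat_color=None if self.coat_color is None else self.coat_color[idx],
        )

    def take_snps(self, idx) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            markers=self.markers.take(idx),
            samples=self.samples,
            dosage=self.dosage[:, idx],
            subpop=self.subpop,
            coat_color=self.coat_color,
        )


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes; rows 2k and 2k+1 belong to sample k."""

    markers: MarkerMap
    samples: np.ndarray
    haplotypes: np.ndarray
    subpop: Optional[np.ndarray] = None
    coat_color: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.samples = _as_str_array([str(s) for s in self.samples])
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.shape != (2 * len(self.samples), self.markers.n_snps):
            raise ValueError(
                f"haplotypes shape {self.haplotypes.shape} != "
                f"({2 * len(self.samples)}, {self.markers.n_snps})"
            )
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype values must be strictly binary")
        if self.subpop is not None:
            self.subpop = _as_str_array([str(s) for s in self.subpop])
            if len(self.subpop) != len(self.samples):
                raise ValueError("subpop length mismatch")
        if self.coat_color is not None:
            self.coat_color = _as_str_array(self.coat_color)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return self.markers.n_snps

    def dosage(self) -> np.ndarray:
        return (
            self.haplotypes[0::2].astype(np.int8)
            + self.haplotypes[1::2].astype(np.int8)
        )

    def to_genotype_panel(self) -> GenotypePanel:
        return GenotypePanel(
            markers=self.markers,
            samples=self.samples,
            dosage=self.dosage(),
            subpop=self.subpop,
            coat_color=self.coat_color,
        )

    def hap_indices(self, pop: Optional[str] = None) -> np.ndarray:
        """Row indices of haplotypes belonging to samples of `pop`."""
        if pop is None:
            return np.arange(2 * self.n_samples)
        if self.subpop is None:
            raise ValueError("panel has no subpopulation labels")
        s = np.flatnonzero(self.subpop == pop)
        return np.stack([2 * s, 2 * s + 1], axis=1).ravel()

    def take_samples(self, idx) -> "HaplotypePanel":
        idx = np.asarray(idx)
        rows = np.stack([2 * idx, 2 * idx + 1], axis=1).ravel()
        return HaplotypePanel(
            markers=self.markers,
            samples=self.samples[idx],
            haplotypes=self.haplotypes[rows],
            subpop=None if self.subpop is None else self.subpop[idx],
            coat_color=None if self.coat_color is None else self.coat_color[idx],
        )

    def take_snps(self, idx) -> "HaplotypePanel":
        idx = np.asarray(idx)
        return HaplotypePanel(
            markers=self.markers.take(idx),
            samples=self.samples,
            haplotypes=self.haplotypes[:, idx],
            subpop=self.subpop,
            coat_color=self.coat_color,
        )

    def subset(self, pop: str) -> "HaplotypePanel":
        if self.subpop is None:
            raise ValueError("panel has no subpopulation labels")
        return self.take_samples(np.flatnonzero(self.subpop == pop))


@dataclass
class WindowTrack:
    """Per-window statistic over sliding fixed-SNP-count windows.

    Windows never span two chromosomes and consecutive windows of one
    chromosome advance by one SNP (``first_snp_index`` increments by one).
    """

    chrom: np.ndarray
    start_bp: np.ndarray
    end_bp: np.ndarray
    first_snp_index: np.ndarray
    n_snps: int
    score: np.ndarray
    aux: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.chrom = _as_str_array(self.chrom)
        self.start_bp = np.asarray(self.start_bp, dtype=np.int64)
        self.end_bp = np.asarray(self.end_bp, dtype=np.int64)
        self.first_snp_index = np.asarray(self.first_snp_index, dtype=np.int64)
        self.score = np.asarray(self.score, dtype=float)
        if self.aux is not None:
            self.aux = np.asarray(self.aux, dtype=float)

    def __len__(self) -> int:
        return len(self.score)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": self.chrom,
                "start_bp": self.start_bp,
                "end_bp": self.end_bp,
                "first_snp_index": self.first_snp_index,
                "n_snps": self.n_snps,
                "score": self.score,
            }
        )
        if self.aux is not None:
            df["aux"] = self.aux
        return df


@dataclass
class CandidateRegion:
    """Genomic interval flagged by one test (1-based inclusive coordinates)."""

    chrom: str
    start_bp: int
    end_bp: int
    source: str
    n_units: int = 0

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("region start_bp > end_bp")

    def overlaps(self, other: "CandidateRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start_bp <= other.end_bp
            and other.start_bp <= self.end_bp
        )


def regions_to_dataframe(regions: Sequence[CandidateRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "source": r.source,
                "n_units": r.n_units,
            }
            for r in regions
        ],
        columns=["chrom", "start_bp", "end_bp", "source", "n_units"],
    )
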