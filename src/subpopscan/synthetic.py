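"""Two-subpopulation phased genotype simulator.

A forward Wright-Fisher simulator on haplotypes, built for testability rather
than demographic realism: baseline LD is created by mosaic-copying founder
haplotypes from a small pool of template haplotypes (a Li-Stephens-style
copying process over templates that are themselves autocorrelated along the
chromosome), an ancestral population is evolved briefly and split into two
populations of configurable effective size, each evolved ``split_generations``
generations with recombination (exponential crossover spacing at
``recomb_rate`` Morgans/bp, 1 cM/Mb by default). Divergent selection is
injected by shifting the allele frequency of selected loci deterministically
by ``shift_per_gen`` per generation in the target population (gametes are
redrawn until the scheduled carrier count is met, so linked flanking variation
hitchhikes). Long autozygous runs come from a configurable fraction of final
samples bred by full-sib mating, or from :func:`plant_roh_cohort`.

Output panels are phased and complete (no missing genotypes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .model import GenotypePanel, HaplotypePanel, MarkerMap

logger = logging.getLogger("subpopscan.synthetic")


@dataclass(frozen=True)
class SelectedLocus:
    """A locus whose alt-allele frequency is pushed by `shift_per_gen` each
    generation in `target_pop` (clamped to the configured bounds)."""

    chrom: str
    pos_bp: int
    shift_per_gen: float
    target_pop: str


@dataclass(frozen=True)
class InbreedingSpec:
    """Fraction of a population's final samples produced by `depth` rounds of
    full-sib mating (depth 1 = offspring of two full sibs, E[F] = 0.25)."""

    pop: str
    fraction: float
    depth: int = 1


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_chrom: int = 3
    snps_per_chrom: int = 1000
    chrom_length_bp: int = 50_000_000
    n_founder_haplotypes: int = 30          # template pool size
    n_samples_per_pop: int = 200
    split_generations: int = 20
    recomb_rate: float = 1e-8               # Morgans per bp (1 cM/Mb)
    maf_beta_params: tuple[float, float] = (1.0, 1.0)
    freq_bounds: tuple[float, float] = (0.05, 0.95)
    selected_loci: tuple[SelectedLocus, ...] = ()
    selection_clamp: tuple[float, float] = (0.02, 0.98)
    inbreeding: tuple[InbreedingSpec, ...] = (
        InbreedingSpec("A", 0.3, 1),
        InbreedingSpec("B", 0.3, 1),
    )
    effective_size: int = 250
    ancestral_generations: int = 5
    template_ld_scale_bp: float = 300_000.0  # latent AR(1) scale of templates
    copy_segment_bp: float = 200_000.0       # mean copied-segment length
    pop_labels: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if self.split_generations < 0:
            raise ValueError("split_generations must be >= 0")
        for v in (self.n_chrom, self.snps_per_chrom, self.chrom_length_bp,
                  self.n_founder_haplotypes, self.n_samples_per_pop,
                  self.effective_size):
            if v <= 0:
                raise ValueError("all counts in SimConfig must be positive")


@dataclass
class PlantedSegment:
    sample: str
    chrom: str
    start_bp: int
    end_bp: int


@dataclass
class LocusTruth:
    chrom: str
    pos_bp: int
    snp_index: int                      # index into the emitted map
    target_pop: str
    shift_per_gen: float
    trajectory: dict = field(default_factory=dict)   # pop -> list of freqs
    achieved: bool = True


@dataclass
class SimTruth:
    loci: list = field(default_factory=list)
    ibd_segments: list = field(default_factory=list)
    n_templates: int = 0


# ---------------------------------------------------------------------------
# helpers


def _meiosis(h0: np.ndarray, h1: np.ndarray, pos: np.ndarray,
             length_bp: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete from a parent's two haplotypes."""
    n_x = rng.poisson(length_bp * rate)
    start = rng.integers(0, 2)
    if n_x == 0:
        return (h0 if start == 0 else h1).copy()
    breaks = np.sort(rng.integers(1, length_bp, size=n_x))
    phase = (np.searchsorted(breaks, pos) + start) % 2
    return np.where(phase == 0, h0, h1)


def _truncated_beta(rng, a, b, lo, hi, size):
    p = rng.beta(a, b, size=size)
    bad = (p < lo) | (p > hi)
    while bad.any():
        p[bad] = rng.beta(a, b, size=int(bad.sum()))
        bad = (p < lo) | (p > hi)
    return p


def _templates(rng, p: np.ndarray, pos: np.ndarray, k: int, scale: float) -> np.ndarray:
    """K autocorrelated binary templates: thresholded latent Gaussian AR(1)."""
    m = len(p)
    z = np.empty((k, m))
    z[:, 0] = rng.standard_normal(k)
    d = np.diff(pos)
    rho = np.exp(-d / scale)
    noise = rng.standard_normal((k, m - 1))
    for j in range(1, m):
        r = rho[j - 1]
        z[:, j] = r * z[:, j - 1] + np.sqrt(1.0 - r * r) * noise[:, j - 1]
    return (z < norm.ppf(p)[None, :]).astype(np.uint8)


def _mosaic_founders(rng, templates: np.ndarray, pos: np.ndarray,
                     n_hap: int, seg_bp: float) -> np.ndarray:
    """Copy founder haplotypes as template mosaics with ~seg_bp segments."""
    k, m = templates.shape
    switch_p = 1.0 - np.exp(-np.diff(pos) / seg_bp)
    out = np.empty((n_hap, m), dtype=np.uint8)
    cols = np.arange(m)
    for h in range(n_hap):
        switches = rng.random(m - 1) < switch_p
        seg_id = np.concatenate([[0], np.cumsum(switches)])
        choice = rng.integers(0, k, size=seg_id[-1] + 1)
        out[h] = templates[choice[seg_id], cols]
    return out


class _Population:
    """Diploid Wright-Fisher population: per-chromosome haplotype arrays,
    rows 2i and 2i+1 belong to individual i."""

    def __init__(self, haps: list[np.ndarray]):
        self.haps = haps  # list over chromosomes of (2N, m_c)

    @property
    def n(self) -> int:
        return self.haps[0].shape[0] // 2

    def copy(self) -> "_Population":
        return _Population([h.copy() for h in self.haps])

    def freq(self, c: int, j: int) -> float:
        return float(self.haps[c][:, j].mean())

    def child_gametes(self, father: int, mother: int, positions, length_bp,
                      rate, rng) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for c, pos in enumerate(positions):
            h = self.haps[c]
            g0 = _meiosis(h[2 * father], h[2 * father + 1], pos, length_bp, rate, rng)
            g1 = _meiosis(h[2 * mother], h[2 * mother + 1], pos, length_bp, rate, rng)
            out.append((g0, g1))
        return out


def _parent_pairs(rng, n_parents: int, n_offspring: int):
    f = rng.integers(0, n_parents, size=n_offspring)
    m = (f + 1 + rng.integers(0, n_parents - 1, size=n_offspring)) % n_parents
    return f, m


def _next_generation(pop: _Population, n_offspring: int, positions, length_bp,
                     rate, rng) -> tuple["_Population", np.ndarray]:
    """One Wright-Fisher generation; also returns the parent of every gamete
    (slot 2i = father of offspring i, slot 2i+1 = mother)."""
    fathers, mothers = _parent_pairs(rng, pop.n, n_offspring)
    new = [np.empty((2 * n_offspring, h.shape[1]), dtype=np.uint8) for h in pop.haps]
    for i in range(n_offspring):
        for c, pos in enumerate(positions):
            h = pop.haps[c]
            new[c][2 * i] = _meiosis(h[2 * fathers[i]], h[2 * fathers[i] + 1],
                                     pos, length_bp, rate, rng)
            new[c][2 * i + 1] = _meiosis(h[2 * mothers[i]], h[2 * mothers[i] + 1],
                                         pos, length_bp, rate, rng)
    gamete_parent = np.empty(2 * n_offspring, dtype=np.int64)
    gamete_parent[0::2] = fathers
    gamete_parent[1::2] = mothers
    return _Population(new), gamete_parent


def _condition_locus(pop_prev: _Population, pop_new: _Population,
                     gamete_parent: np.ndarray, c: int, j: int,
                     target_freq: float, positions, length_bp, rate, rng) -> bool:
    """Redraw gametes at chromosome c until the carrier count at SNP j matches
    round(2N * target_freq).

    Shortfall slots are re-drawn from random parents able to supply the
    required allele, which differentially amplifies carrier lineages the way
    truncation selection does, so flanking variation hitchhikes and the sweep
    leaves a local haplotype footprint. Returns False if the allele is extinct
    while an upward shift is scheduled (a fixed allele scheduled to decrease
    is left fixed: overshoot is harmless)."""
    h_new = pop_new.haps[c]
    n_gam = h_new.shape[0]
    target = int(round(n_gam * target_freq))
    pos = positions[c]
    prev = pop_prev.haps[c]
    parent_dos = prev[0::2, j] + prev[1::2, j]

    def redraw_from(slot: int, par: int, want: int) -> bool:
        for _ in range(200):
            g = _meiosis(prev[2 * par], prev[2 * par + 1], pos, length_bp, rate, rng)
            if g[j] == want:
                h_new[slot] = g
                return True
        return False

    for _ in range(4 * n_gam):
        count = int(h_new[:, j].sum())
        if count == target:
            return True
        want = 1 if count < target else 0
        pool = np.flatnonzero(parent_dos >= 1 if want == 1 else parent_dos <= 1)
        if len(pool) == 0:
            return want == 0
        wrong = np.flatnonzero(h_new[:, j] != want)
        if not redraw_from(int(rng.choice(wrong)), int(rng.choice(pool)), want):
            return False
    return int(h_new[:, j].sum()) == target


def _resolve_selected_snp(pop: _Population, ci: int, pos: np.ndarray,
                          sl: SelectedLocus) -> int:
    """Map a selected locus to the nearest SNP whose current frequency makes a
    near-hard sweep possible: a rare allele for an upward shift (a nearly
    fixed one for a downward shift), so few carrier lineages exist at onset
    and the sweep leaves a haplotype footprint. Falls back to the physically
    nearest SNP."""
    freqs = pop.haps[ci].mean(axis=0)
    lo, hi = (0.02, 0.10) if sl.shift_per_gen > 0 else (0.90, 0.98)
    order = np.argsort(np.abs(pos - sl.pos_bp))
    for j in order:
        if lo <= freqs[j] <= hi:
            return int(j)
    logger.warning("no SNP near %s:%d with frequency in [%.2f, %.2f]; "
                   "using nearest SNP", sl.chrom, sl.pos_bp, lo, hi)
    return int(order[0])


# ---------------------------------------------------------------------------
# public API


def simulate_two_pops(config: SimConfig) -> tuple[GenotypePanel, HaplotypePanel, SimTruth]:
    """Simulate two diverged subpopulations; returns (genotypes, haplotypes, truth)."""
    rng = np.random.default_rng(config.seed)
    n_chrom, m_c, L = config.n_chrom, config.snps_per_chrom, config.chrom_length_bp
    chroms = [str(c + 1) for c in range(n_chrom)]

    positions = []
    for _ in range(n_chrom):
        cand = np.unique(rng.integers(1, L, size=int(m_c * 1.2)))
        while len(cand) < m_c:
            cand = np.unique(np.concatenate([cand, rng.integers(1, L, size=m_c)]))
        keep = np.sort(rng.choice(len(cand), size=m_c, replace=False))
        positions.append(cand[keep])

    mmap = MarkerMap(
        chrom=np.repeat(chroms, m_c),
        pos_bp=np.concatenate(positions),
        snp_id=[f"snp_{c + 1}_{i + 1}" for c in range(n_chrom) for i in range(m_c)],
        allele_ref=["A"] * (n_chrom * m_c),
        allele_alt=["B"] * (n_chrom * m_c),
    )

    lo, hi = config.freq_bounds
    a, b = config.maf_beta_params
    ne2 = 2 * config.effective_size
    founder = []
    for c in range(n_chrom):
        p = _truncated_beta(rng, a, b, lo, hi, m_c)
        tpl = _templates(rng, p, positions[c], config.n_founder_haplotypes,
                         config.template_ld_scale_bp)
        founder.append(_mosaic_founders(rng, tpl, positions[c], ne2,
                                        config.copy_segment_bp))
    ancestral = _Population(founder)
    for _ in range(config.ancestral_generations):
        ancestral, _ = _next_generation(ancestral, config.effective_size, positions,
                                        L, config.recomb_rate, rng)

    # resolve selected loci to map indices
    chrom_offset = {c: i * m_c for i, c in enumerate(chroms)}
    truth = SimTruth(n_templates=config.n_founder_haplotypes)
    loci: list[tuple[int, int, LocusTruth]] = []   # (chrom index, snp col, truth)
    for sl in config.selected_loci:
        if str(sl.chrom) not in chrom_offset:
            raise ValueError(f"selected locus on unknown chromosome {sl.chrom}")
        ci = chroms.index(str(sl.chrom))
        j = _resolve_selected_snp(ancestral, ci, positions[ci], sl)
        lt = LocusTruth(chrom=str(sl.chrom), pos_bp=int(positions[ci][j]),
                        snp_index=chrom_offset[str(sl.chrom)] + j,
                        target_pop=sl.target_pop, shift_per_gen=sl.shift_per_gen,
                        trajectory={p: [] for p in config.pop_labels})
        truth.loci.append(lt)
        loci.append((ci, j, lt))

    pops = {label: ancestral.copy() for label in config.pop_labels}
    for ci, j, lt in loci:
        for label in config.pop_labels:
            lt.trajectory[label].append(pops[label].freq(ci, j))

    clamp_lo, clamp_hi = config.selection_clamp
    for _ in range(config.split_generations):
        for label in config.pop_labels:
            prev = pops[label]
            new, gamete_parent = _next_generation(prev, config.effective_size,
                                                  positions, L, config.recomb_rate, rng)
            for ci, j, lt in loci:
                if lt.target_pop != label or not lt.achieved:
                    continue
                p_cur = lt.trajectory[label][-1]
                p_next = float(np.clip(p_cur + lt.shift_per_gen, clamp_lo, clamp_hi))
                if not _condition_locus(prev, new, gamete_parent, ci, j, p_next,
                                        positions, L, config.recomb_rate, rng):
                    lt.achieved = False
                    logger.warning("selected locus %s:%s unreachable (extinct allele); "
                                   "conditioning stopped", lt.chrom, lt.pos_bp)
            pops[label] = new
            for ci, j, lt in loci:
                lt.trajectory[label].append(pops[label].freq(ci, j))

    # final diploid samples, with a configured fraction from full-sib matings
    inbreeding = {spec.pop: spec for spec in config.inbreeding}
    sample_ids, subpop, hap_rows = [], [], [[] for _ in range(n_chrom)]
    for label in config.pop_labels:
        pop = pops[label]
        spec = inbreeding.get(label)
        n_inbred = int(round((spec.fraction if spec else 0.0) * config.n_samples_per_pop))
        for i in range(config.n_samples_per_pop):
            sample_ids.append(f"{label}_{i + 1:04d}")
            subpop.append(label)
            if i < n_inbred:
                gam = _sib_mated_child(pop, spec.depth, positions, L,
                                       config.recomb_rate, rng)
            else:
                f, m = _parent_pairs(rng, pop.n, 1)
                gam = pop.child_gametes(int(f[0]), int(m[0]), positions, L,
                                        config.recomb_rate, rng)
            for c in range(n_chrom):
                hap_rows[c].append(gam[c][0])
                hap_rows[c].append(gam[c][1])

    hap = np.hstack([np.asarray(rows, dtype=np.uint8) for rows in hap_rows])
    hap_panel = HaplotypePanel(markers=mmap, samples=sample_ids, haplotypes=hap,
                               subpop=np.asarray(subpop, dtype=object))
    return hap_panel.to_genotype_panel(), hap_panel, truth


def _sib_mated_child(pop: _Population, depth: int, positions, length_bp, rate, rng):
    """Child of `depth` successive full-sib matings starting from a random couple."""
    f, m = _parent_pairs(rng, pop.n, 1)
    couple = _Population([
        np.stack([
            _meiosis(h[2 * f[0]], h[2 * f[0] + 1], positions[c], length_bp, rate, rng),
            _meiosis(h[2 * m[0]], h[2 * m[0] + 1], positions[c], length_bp, rate, rng),
            _meiosis(h[2 * f[0]], h[2 * f[0] + 1], positions[c], length_bp, rate, rng),
            _meiosis(h[2 * m[0]], h[2 * m[0] + 1], positions[c], length_bp, rate, rng),
        ])
        for c, h in enumerate(pop.haps)
    ])
    for _ in range(depth - 1):
        couple = _Population([
            np.stack([
                _meiosis(h[0], h[1], positions[c], length_bp, rate, rng),
                _meiosis(h[2], h[3], positions[c], length_bp, rate, rng),
                _meiosis(h[0], h[1], positions[c], length_bp, rate, rng),
                _meiosis(h[2], h[3], positions[c], length_bp, rate, rng),
            ])
            for c, h in enumerate(couple.haps)
        ])
    return couple.child_gametes(0, 1, positions, length_bp, rate, rng)


def plant_roh_cohort(hap_panel: HaplotypePanel, pop: str, fraction: float,
                     min_len_bp: int, seed: int = 0,
                     region: Optional[tuple[str, int, int]] = None,
                     ) -> tuple[HaplotypePanel, SimTruth]:
    """Copy one haplotype interval >= min_len_bp onto the homologous chromosome
    for a random `fraction` of `pop`'s samples, creating true autozygous
    segments recorded in the returned truth.

    If `region` (chrom, start_bp, end_bp) is given, each selected sample's
    interval is drawn inside that region (length uniform in
    [min_len_bp, 2*min_len_bp) clamped to the region, position uniform), so
    the cohort's coverage peaks inside the region the way selection-driven
    autozygosity does; otherwise intervals are drawn genome-wide per sample.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mmap = hap_panel.markers
    blocks = mmap.chrom_blocks()
    hap = hap_panel.haplotypes.copy()
    truth = SimTruth()
    if fraction == 0:
        return hap_panel, truth
    pop_idx = np.flatnonzero(hap_panel.subpop == pop) if hap_panel.subpop is not None \
        else np.arange(hap_panel.n_samples)
    n_sel = max(1, int(round(fraction * len(pop_idx))))
    chosen = rng.choice(pop_idx, size=n_sel, replace=False)
    for k in np.sort(chosen):
        if region is not None:
            chrom = str(region[0])
            r_lo, r_hi = int(region[1]), int(region[2])
            blk = next((b for b in blocks if b[0] == chrom), None)
            if blk is None:
                raise ValueError(f"region chromosome {chrom} not in map")
            length = min(int(min_len_bp * (1.0 + rng.random())), r_hi - r_lo)
            start = int(rng.integers(r_lo, max(r_lo + 1, r_hi - length)))
            end = start + length
        else:
            blk = blocks[rng.integers(0, len(blocks))]
            chrom = blk[0]
            span_lo = int(mmap.pos_bp[blk[1]])
            span_hi = int(mmap.pos_bp[blk[2] - 1])
            length = int(min_len_bp * (1.0 + rng.random()))
            if length > span_hi - span_lo:
                logger.warning("planted interval exceeds chromosome %s; shrunk", chrom)
                length = span_hi - span_lo
            start = int(rng.integers(span_lo, max(span_lo + 1, span_hi - length)))
            end = start + length
        lo = int(np.searchsorted(mmap.pos_bp[blk[1]:blk[2]], start, side="left")) + blk[1]
        hi = int(np.searchsorted(mmap.pos_bp[blk[1]:blk[2]], end, side="right")) + blk[1]
        if hi - lo < 2:
            continue
        hap[2 * k + 1, lo:hi] = hap[2 * k, lo:hi]
        truth.ibd_segments.append(PlantedSegment(
            sample=str(hap_panel.samples[k]), chrom=chrom,
            start_bp=int(mmap.pos_bp[lo]), end_bp=int(mmap.pos_bp[hi - 1]),
        ))
    out = HaplotypePanel(markers=mmap, samples=hap_panel.samples, haplotypes=hap,
                         subpop=hap_panel.subpop, coat_color=hap_panel.coat_color)
    return out, truth
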