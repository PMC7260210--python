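import numpy as np
import pytest

from subpopscan.model import GenotypePanel, HaplotypePanel, MarkerMap
from subpopscan.synthetic import (
    SelectedLocus,
    SimConfig,
    plant_roh_cohort,
    simulate_two_pops,
)

#: hitchhiking footprint half-width used to score sweep recovery: at 1 cM/Mb
#: over 20 generations the dragged haplotype block extends ~1 Mb around the
#: selected site, and LD-contrast statistics peak on its shoulders.
SWEEP_FOOTPRINT_BP = 1_000_000


def region_hits_locus(regions, chrom, pos_bp, slack_bp=SWEEP_FOOTPRINT_BP):
    return any(r.chrom == chrom and r.start_bp <= pos_bp + slack_bp
               and r.end_bp >= pos_bp - slack_bp for r in regions)


def make_map(n_snps, chrom="1", spacing=50_000, start=1_000_000):
    pos = start + spacing * np.arange(n_snps)
    return MarkerMap(
        chrom=[chrom] * n_snps,
        pos_bp=pos,
        snp_id=[f"{chrom}_{i}" for i in range(n_snps)],
        allele_ref=["A"] * n_snps,
        allele_alt=["B"] * n_snps,
    )


def concat_maps(*maps):
    return MarkerMap(
        chrom=np.concatenate([m.chrom for m in maps]),
        pos_bp=np.concatenate([m.pos_bp for m in maps]),
        snp_id=np.concatenate([m.snp_id for m in maps]),
        allele_ref=np.concatenate([m.allele_ref for m in maps]),
        allele_alt=np.concatenate([m.allele_alt for m in maps]),
    )


def make_panel(dosage, subpop=None, spacing=50_000, chrom="1", start=1_000_000):
    dosage = np.asarray(dosage)
    mmap = make_map(dosage.shape[1], chrom=chrom, spacing=spacing, start=start)
    return GenotypePanel(
        markers=mmap,
        samples=[f"s{i}" for i in range(dosage.shape[0])],
        dosage=dosage,
        subpop=None if subpop is None else np.asarray(subpop, dtype=object),
    )


def make_hap_panel(haplotypes, subpop=None, spacing=50_000, chrom="1",
                   start=1_000_000):
    hap = np.asarray(haplotypes, dtype=np.uint8)
    mmap = make_map(hap.shape[1], chrom=chrom, spacing=spacing, start=start)
    n = hap.shape[0] // 2
    return HaplotypePanel(
        markers=mmap,
        samples=[f"s{i}" for i in range(n)],
        haplotypes=hap,
        subpop=None if subpop is None else np.asarray(subpop, dtype=object),
    )


def random_panel(rng, n_samples=12, n_snps=40, subpops=None, missing_rate=0.0):
    dosage = rng.integers(0, 3, size=(n_samples, n_snps)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random((n_samples, n_snps)) < missing_rate
        dosage[mask] = -1
    return make_panel(dosage, subpop=subpops)


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded two-population simulation shared across tests."""
    cfg = SimConfig(seed=42, n_chrom=2, snps_per_chrom=400,
                    chrom_length_bp=20_000_000, n_samples_per_pop=60,
                    split_generations=5)
    return simulate_two_pops(cfg)


@pytest.fixture(scope="session")
def selected_replicates():
    """Twenty replicate simulations at the study scale (two populations of
    200 samples, 3,000 SNPs) with one locus under divergent selection
    (shift 0.05/generation for 20 generations in population B), analysed by
    the F_ST outlier scan and varLD, plus a variant of each panel with an ROH
    cohort planted at the locus for end-to-end consensus checks."""
    from subpopscan.fst import fst_outlier_regions, fst_window_track
    from subpopscan.roh import (RohParams, autozygosity_track,
                                detect_roh_sliding, roh_islands)
    from subpopscan.signatures import consensus
    from subpopscan.varld import varld_scan

    results = []
    for i in range(20):
        cfg = SimConfig(seed=1234 + i, selected_loci=(
            SelectedLocus("2", 25_000_000, 0.05, "B"),))
        panel, hap, truth = simulate_two_pops(cfg)
        lt = truth.loci[0]
        hA, hB = hap.subset("A"), hap.subset("B")
        fst_regions = fst_outlier_regions(fst_window_track(panel))
        _, varld_regions = varld_scan(hA, hB)

        # same panel with a cohort of planted autozygosity at the locus
        hap_p, _ = plant_roh_cohort(
            hap, "B", fraction=0.4, min_len_bp=3_000_000, seed=i,
            region=("2", lt.pos_bp - 1_500_000, lt.pos_bp + 1_500_000))
        panel_p = hap_p.to_genotype_panel()
        segs = detect_roh_sliding(panel_p, RohParams())
        sources = {}
        for pop in ("A", "B"):
            members = panel_p.samples[panel_p.sample_indices(pop)]
            scores = autozygosity_track(segs, panel_p.markers, members)
            sources[f"ROH_{pop}"] = roh_islands(scores, panel_p.markers,
                                                source=f"ROH_{pop}")
        sources["FST"] = fst_outlier_regions(fst_window_track(panel_p))
        _, sources["VARLD"] = varld_scan(hap_p.subset("A"), hap_p.subset("B"))
        signatures = consensus(sources)
        results.append({
            "locus_chrom": lt.chrom,
            "locus_pos": lt.pos_bp,
            "achieved": lt.achieved,
            "fst_regions": fst_regions,
            "varld_regions": varld_regions,
            "signatures": signatures,
        })
    return results
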