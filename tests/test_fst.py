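import numpy as np
import pytest

from subpopscan.fst import (
    fst_outlier_regions,
    fst_window_track,
    global_fst,
    wc_fst_components,
    wc_fst_snp,
)
from subpopscan.model import WindowTrack

from conftest import make_panel


def wc_oracle(n1, n2, p1, p2, h1, h2):
    """Independent two-population Weir-Cockerham (1984) implementation,
    written as the literal published formulas."""
    r = 2
    n_bar = (n1 + n2) / r
    nc = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / nc) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2
                              - h_bar / 4) / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - (r - 1) / r * s2
                                 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2
    return a, b, c


def panel_from_genotype_counts(counts1, counts2):
    """Build a two-subpopulation single-SNP panel from genotype counts
    (n_hom_ref, n_het, n_hom_alt) per subpopulation."""
    dosage, subpop = [], []
    for pop, (n0, n1, n2) in (("A", counts1), ("B", counts2)):
        dosage += [0] * n0 + [1] * n1 + [2] * n2
        subpop += [pop] * (n0 + n1 + n2)
    return make_panel(np.asarray(dosage)[:, None], subpop=subpop)


class TestSnpTheta:
    def test_fixed_difference_gives_one(self):
        panel = panel_from_genotype_counts((10, 0, 0), (0, 0, 10))
        assert wc_fst_snp(panel, 0).theta == pytest.approx(1.0)

    def test_hand_evaluated_components(self):
        # pop1 (n=10: AA=4, Aa=2, aa=4 -> p=0.5, h=0.2)
        # pop2 (n=10: AA=9, aa=1 -> p=0.1 alt... coded: hom_alt=1 -> p=0.1)
        panel = panel_from_genotype_counts((4, 2, 4), (9, 0, 1))
        comp = wc_fst_snp(panel, 0)
        assert comp.a == pytest.approx(0.063889, abs=1e-6)
        assert comp.b == pytest.approx(0.136111, abs=1e-6)
        assert comp.c == pytest.approx(0.05, abs=1e-12)
        assert comp.theta == pytest.approx(0.2556, abs=1e-4)

    def test_identical_populations_slightly_negative(self):
        panel = panel_from_genotype_counts((2, 5, 3), (2, 5, 3))
        # both pops p=0.55, h=0.5 at n=10: theta below zero
        assert wc_fst_snp(panel, 0).theta < 0

    def test_identical_pops_match_oracle_value(self):
        # identical pops, p=0.55, h=0.5, n=10 each: theta matches the
        # published-formula oracle exactly (and is negative)
        panel = panel_from_genotype_counts((2, 5, 3), (2, 5, 3))
        comp = wc_fst_snp(panel, 0)
        a, b, c = wc_oracle(10, 10, 0.55, 0.55, 0.5, 0.5)
        assert comp.theta == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_pooled_monomorphic_rejected(self):
        panel = panel_from_genotype_counts((5, 0, 0), (5, 0, 0))
        with pytest.raises(ValueError, match="monomorphic"):
            wc_fst_snp(panel, 0)

    def test_allele_swap_invariance(self):
        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 3, size=(40, 15))
        subpop = ["A"] * 20 + ["B"] * 20
        t1 = wc_fst_components(make_panel(dosage, subpop=subpop))["theta"]
        t2 = wc_fst_components(make_panel(2 - dosage, subpop=subpop))["theta"]
        assert np.allclose(t1, t2, equal_nan=True, atol=1e-12)


class TestWindows:
    def test_uniform_fixation_gives_window_theta_one(self):
        rng = np.random.default_rng(1)
        dosage = np.vstack([np.zeros((10, 20), int), np.full((10, 20), 2)])
        panel = make_panel(dosage, subpop=["A"] * 10 + ["B"] * 10)
        track = fst_window_track(panel, window_snps=15)
        assert np.allclose(track.score, 1.0)

    def test_ratio_of_averages_matches_oracle(self):
        rng = np.random.default_rng(2)
        dosage = rng.integers(0, 3, size=(30, 20))
        panel = make_panel(dosage, subpop=["A"] * 15 + ["B"] * 15)
        comp = wc_fst_components(panel)
        track = fst_window_track(panel, window_snps=15)
        w = 0
        sel = comp.iloc[track.first_snp_index[w]:track.first_snp_index[w] + 15]
        sel = sel[sel.defined]
        expected = sel.a.sum() / (sel.a + sel.b + sel.c).sum()
        assert track.score[w] == pytest.approx(expected, abs=1e-12)

    def test_window_heterozygosity_at_half_frequency(self):
        dosage = np.vstack([np.tile([0, 2], (10, 10)),
                            np.tile([2, 0], (10, 10))])
        panel = make_panel(dosage, subpop=["A"] * 10 + ["B"] * 10)
        track = fst_window_track(panel, window_snps=15)
        assert np.allclose(track.aux, 0.5)  # p_bar = 0.5 everywhere


class TestOutlierRegions:
    @staticmethod
    def flat_track(n, score=0.05, het=0.4, chrom=None):
        chrom = chrom if chrom is not None else np.asarray(["1"] * n, object)
        start = 1_000_000 + 50_000 * np.arange(n)
        return WindowTrack(chrom=chrom, start_bp=start, end_bp=start + 700_000,
                           first_snp_index=np.arange(n), n_snps=15,
                           score=np.full(n, float(score)),
                           aux=np.full(n, float(het)))

    def test_constant_scores_no_flags(self):
        track = self.flat_track(2000)
        assert fst_outlier_regions(track) == []

    def test_three_extreme_consecutive_windows_one_region(self):
        track = self.flat_track(3000)
        rng = np.random.default_rng(3)
        track.score += rng.normal(0, 0.01, size=3000)
        track.aux += rng.normal(0, 0.05, size=3000)
        track.score[1500:1503] = 0.6  # ~10 sd above everything
        regions = fst_outlier_regions(track)
        assert len(regions) == 1
        assert regions[0].n_units == 3
        assert regions[0].start_bp == track.start_bp[1500]
        assert regions[0].end_bp == track.end_bp[1502]

    def test_flagged_windows_on_different_chromosomes_not_joined(self):
        chrom = np.asarray(["1"] * 1500 + ["2"] * 1500, object)
        track = self.flat_track(3000, chrom=chrom)
        rng = np.random.default_rng(4)
        track.score += rng.normal(0, 0.01, size=3000)
        track.score[1499] = 0.6
        track.score[1500] = 0.6
        assert fst_outlier_regions(track) == []


class TestGlobal:
    def test_null_panel_near_zero(self, small_sim):
        panel, _, _ = small_sim
        mean, sd = global_fst(panel)
        assert abs(mean) < 0.1
        assert sd > 0

    def test_all_fixed_differences_mean_one(self):
        dosage = np.vstack([np.zeros((10, 5), int), np.full((10, 5), 2)])
        panel = make_panel(dosage, subpop=["A"] * 10 + ["B"] * 10)
        mean, sd = global_fst(panel)
        assert mean == pytest.approx(1.0)

    def test_single_snp_sd_zero(self):
        panel = panel_from_genotype_counts((4, 2, 4), (9, 0, 1))
        mean, sd = global_fst(panel)
        assert sd == 0.0
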