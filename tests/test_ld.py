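import numpy as np
import pandas as pd
import pytest

from subpopscan import ld as ld_mod
from subpopscan.ld import (
    adjacent_r2_summary,
    ld_decay,
    pair_r,
    phase_persistence,
    required_marker_density,
    signed_r_pairs,
)

from conftest import make_hap_panel


def haps_from_counts(n_ab, n_aB, n_Ab, n_AB):
    """Haplotype rows for two SNPs from the four gamete counts
    (a/A = ref/alt at SNP 1, b/B at SNP 2)."""
    rows = ([(0, 0)] * n_ab + [(0, 1)] * n_aB + [(1, 0)] * n_Ab
            + [(1, 1)] * n_AB)
    return make_hap_panel(np.asarray(rows))


class TestPairR:
    def test_perfect_coupling(self):
        hap = haps_from_counts(5, 0, 0, 5)
        assert pair_r(hap, 0, 1).r_signed == pytest.approx(1.0)
        assert pair_r(hap, 0, 1).r2 == pytest.approx(1.0)

    def test_hand_counted_gamete_frequencies(self):
        # counts AB=4, Ab=1, aB=1, ab=4 over 10 haplotypes:
        # D = 0.4 - 0.25 = 0.15, r = 0.15 / 0.25 = 0.6
        hap = haps_from_counts(4, 1, 1, 4)
        p = pair_r(hap, 0, 1)
        assert p.r_signed == pytest.approx(0.6)
        assert p.r2 == pytest.approx(0.36)

    def test_balanced_independent_columns(self):
        hap = haps_from_counts(1, 1, 1, 1)
        assert pair_r(hap, 0, 1).r_signed == pytest.approx(0.0)

    def test_monomorphic_column_undefined(self):
        hap = make_hap_panel([[0, 0], [0, 1], [0, 0], [0, 1]])
        with pytest.raises(ValueError, match="monomorphic"):
            pair_r(hap, 0, 1)

    def test_matches_pearson_oracle(self):
        rng = np.random.default_rng(2)
        hap = make_hap_panel(rng.integers(0, 2, size=(40, 12)))
        for _ in range(30):
            i, j = sorted(rng.choice(12, size=2, replace=False))
            expected = np.corrcoef(hap.haplotypes[:, i],
                                   hap.haplotypes[:, j])[0, 1]
            assert pair_r(hap, i, j).r_signed == pytest.approx(expected,
                                                               abs=1e-12)

    def test_allele_swap_flips_sign_only(self):
        rng = np.random.default_rng(3)
        hap = make_hap_panel(rng.integers(0, 2, size=(30, 2)))
        r = pair_r(hap, 0, 1).r_signed
        swapped = make_hap_panel(
            np.column_stack([1 - hap.haplotypes[:, 0], hap.haplotypes[:, 1]]))
        assert pair_r(swapped, 0, 1).r_signed == pytest.approx(-r, abs=1e-12)
        assert pair_r(swapped, 0, 1).r2 == pytest.approx(r ** 2, abs=1e-12)


class TestLdDecay:
    def test_no_close_pairs_all_bins_empty(self):
        hap = make_hap_panel(np.tile([[0, 1], [1, 0]], (4, 1)),
                             spacing=2_000_000)
        df = ld_decay(hap)
        assert (df.n_pairs == 0).all()

    def test_known_pair_lands_in_its_bin(self):
        # two SNPs 55 kb apart with hand-built r^2 = 0.36
        hap = haps_from_counts(4, 1, 1, 4)
        hap = make_hap_panel(hap.haplotypes, spacing=55_000)
        df = ld_decay(hap)
        row = df[(df.bin_lo_bp == 50_000) & (df.bin_hi_bp == 60_000)].iloc[0]
        assert row.n_pairs == 1
        assert row.mean_r2 == pytest.approx(0.36)
        assert df[df.bin_lo_bp != 50_000].n_pairs.sum() == 0

    def test_monotone_decay_on_synthetic_panel(self, small_sim):
        _, hap, _ = small_sim
        df = ld_decay(hap.subset("A"))
        near = df[df.bin_lo_bp.between(10_000, 40_000)].mean_r2.mean()
        far = df[df.bin_lo_bp == 500_000].mean_r2.iloc[0]
        assert near > far


class TestAdjacentSummary:
    def test_pair_count_is_n_minus_one(self):
        rng = np.random.default_rng(4)
        hap = make_hap_panel(rng.integers(0, 2, size=(20, 3)))
        df = adjacent_r2_summary(hap, maf_thresholds=[0.0])
        assert df[df.distance_class == "all"].iloc[0].n_pairs == 2

    def test_raising_maf_threshold_never_adds_pairs(self, small_sim):
        _, hap, _ = small_sim
        df = adjacent_r2_summary(hap.subset("A"))
        counts = df[df.distance_class == "all"].set_index("maf_threshold").n_pairs
        assert counts.loc[0.0] >= counts.loc[0.01] >= counts.loc[0.05]

    def test_identical_columns_give_unit_r2(self):
        col = np.tile([0, 1], 10)
        hap = make_hap_panel(np.column_stack([col, col]), spacing=40_000)
        df = adjacent_r2_summary(hap, maf_thresholds=[0.0])
        row = df[df.distance_class == "(0-100]kb"].iloc[0]
        assert row.mean_r2 == pytest.approx(1.0)


class TestPhasePersistence:
    def test_identical_panels_unit_correlation(self, small_sim):
        _, hap, _ = small_sim
        a = hap.subset("A")
        df = phase_persistence(a, a)
        filled = df.dropna(subset=["phase_corr"])
        assert len(filled) > 10
        assert np.allclose(filled.phase_corr, 1.0)

    def test_negated_r_gives_minus_one(self, monkeypatch):
        hap = make_hap_panel(np.tile([[0, 1], [1, 0]], (4, 1)))
        calls = []

        def fake_pairs(h, max_dist):
            calls.append(h)
            dist = np.array([150_000, 150_000, 150_000])
            r = np.array([0.8, 0.1, -0.4])
            return dist, (r if len(calls) == 1 else -r)

        monkeypatch.setattr(ld_mod, "signed_r_pairs", fake_pairs)
        df = phase_persistence(hap, hap)
        row = df[df.bin_lo_bp == 100_000].iloc[0]
        assert row.phase_corr == pytest.approx(-1.0)

    def test_hand_computed_bin_correlation(self, monkeypatch):
        """r_m = (0.9, 0.1, 0.5) vs r_n = (0.7, 0.3, 0.2) correlate ~0.756."""
        hap = make_hap_panel(np.tile([[0, 1], [1, 0]], (4, 1)))
        calls = []

        def fake_pairs(h, max_dist):
            calls.append(h)
            dist = np.array([150_000, 160_000, 170_000])
            r = (np.array([0.9, 0.1, 0.5]) if len(calls) == 1
                 else np.array([0.7, 0.3, 0.2]))
            return dist, r

        monkeypatch.setattr(ld_mod, "signed_r_pairs", fake_pairs)
        df = phase_persistence(hap, hap)
        row = df[df.bin_lo_bp == 100_000].iloc[0]
        expected = np.corrcoef([0.9, 0.1, 0.5], [0.7, 0.3, 0.2])[0, 1]
        assert row.phase_corr == pytest.approx(expected, abs=1e-12)
        assert row.phase_corr == pytest.approx(0.7559, abs=1e-4)

    def test_full_allele_swap_in_both_populations_is_invariant(self, small_sim):
        """Relabelling ref/alt at every SNP of both panels leaves every pair's
        signed r, and hence the per-bin phase correlation, unchanged."""
        from subpopscan.model import HaplotypePanel

        _, hap, _ = small_sim
        a, b = hap.subset("A"), hap.subset("B")
        df1 = phase_persistence(a, b)

        def swap(h):
            return HaplotypePanel(markers=h.markers, samples=h.samples,
                                  haplotypes=1 - h.haplotypes, subpop=h.subpop)

        df2 = phase_persistence(swap(a), swap(b))
        pd.testing.assert_series_equal(df1.phase_corr, df2.phase_corr,
                                       atol=1e-10)

    def test_underfilled_bin_reported_empty(self, monkeypatch):
        hap = make_hap_panel(np.tile([[0, 1], [1, 0]], (4, 1)))

        def fake_pairs(h, max_dist):
            return np.array([250_000]), np.array([0.5])

        monkeypatch.setattr(ld_mod, "signed_r_pairs", fake_pairs)
        df = phase_persistence(hap, hap)
        row = df[df.bin_lo_bp == 200_000].iloc[0]
        assert row.n_pairs == 1
        assert np.isnan(row.phase_corr)


@pytest.mark.parametrize("genome_mb,spacing_kb,expected", [
    (2875, 100, 28_750),
    (1000, 100, 10_000),
    (2875, 50, 57_500),
])
def test_required_marker_density(genome_mb, spacing_kb, expected):
    assert required_marker_density(genome_mb, spacing_kb) == expected
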