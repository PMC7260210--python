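import numpy as np
import pytest

from subpopscan.model import MarkerMap
from subpopscan.roh import (
    RohParams,
    RohSegment,
    autozygosity_track,
    detect_roh_consecutive,
    detect_roh_sliding,
    f_roh,
    generations_to_ancestor,
    roh_islands,
    roh_length_summary,
)

from conftest import make_map, make_panel

DETECTORS = [detect_roh_sliding, detect_roh_consecutive]


@pytest.mark.parametrize("detect", DETECTORS)
def test_long_homozygous_run_single_segment(detect):
    """60 homozygous SNPs spaced 50 kb (span 2.95 Mb) yield one segment
    covering all 60 SNPs."""
    panel = make_panel(np.zeros((1, 60), dtype=int))
    segs = detect(panel, RohParams())
    assert len(segs) == 1
    seg = segs[0]
    assert seg.n_snps == 60
    assert seg.start_bp == panel.markers.pos_bp[0]
    assert seg.end_bp == panel.markers.pos_bp[-1]


@pytest.mark.parametrize("detect", DETECTORS)
def test_fully_heterozygous_sample_no_segments(detect):
    panel = make_panel(np.ones((1, 60), dtype=int))
    assert detect(panel, RohParams()) == []


@pytest.mark.parametrize("detect", DETECTORS)
def test_long_gap_splits_run(detect):
    """A 1.2 Mb gap splits a homozygous run; both halves here stay >= 1 Mb."""
    pos = np.concatenate([
        1_000_000 + 50_000 * np.arange(30),
        1_000_000 + 50_000 * 29 + 1_200_000 + 50_000 * np.arange(30),
    ])
    mmap = MarkerMap(chrom=["1"] * 60, pos_bp=pos,
                     snp_id=[f"s{i}" for i in range(60)],
                     allele_ref=["A"] * 60, allele_alt=["B"] * 60)
    from subpopscan.model import GenotypePanel
    panel = GenotypePanel(markers=mmap, samples=["x"],
                          dosage=np.zeros((1, 60), dtype=np.int8))
    segs = detect(panel, RohParams())
    assert len(segs) == 2
    assert all(s.length_bp >= 1_000_000 for s in segs)
    assert all(s.n_snps == 30 for s in segs)


def test_consecutive_two_heterozygotes_split_into_subruns():
    """A run holding two heterozygotes splits into non-overlapping sub-runs
    with at most one heterozygote each."""
    dosage = np.zeros((1, 90), dtype=int)
    dosage[0, 30] = 1
    dosage[0, 60] = 1
    panel = make_panel(dosage)
    segs = detect_roh_consecutive(panel, RohParams())
    assert len(segs) >= 2
    # non-overlapping and each sub-run holds <= 1 heterozygote
    ordered = sorted(segs, key=lambda s: s.start_bp)
    for a, b in zip(ordered, ordered[1:]):
        assert a.end_bp < b.start_bp
    pos = panel.markers.pos_bp
    for s in ordered:
        inside = (pos >= s.start_bp) & (pos <= s.end_bp)
        assert (dosage[0, inside] == 1).sum() <= 1


def test_sliding_short_chromosome_shrinks_window():
    panel = make_panel(np.zeros((1, 25), dtype=int))  # < 30-SNP window
    segs = detect_roh_sliding(panel, RohParams())
    assert len(segs) == 1
    assert segs[0].n_snps == 25


def test_density_filter_rejects_sparse_runs():
    panel = make_panel(np.zeros((1, 10), dtype=int), spacing=150_000)
    assert detect_roh_sliding(panel, RohParams()) == []


class TestFRoh:
    def test_fraction_of_covered_genome(self):
        mmap = make_map(101, spacing=100_000)  # covers 10 Mb
        segs = [RohSegment("s0", "1", 1_000_000, 1_999_999, 10)]
        f = f_roh(segs, mmap, ["s0"])
        assert f["s0"] == pytest.approx(1_000_000 / 10_000_000)

    def test_no_segments_zero(self):
        mmap = make_map(11, spacing=100_000)
        assert f_roh([], mmap, ["s0"])["s0"] == 0.0

    def test_whole_chromosome_segment_is_one(self):
        mmap = make_map(11, spacing=100_000)
        span = int(mmap.pos_bp[-1] - mmap.pos_bp[0])
        segs = [RohSegment("s0", "1", int(mmap.pos_bp[0]),
                           int(mmap.pos_bp[-1]), 11)]
        assert f_roh(segs, mmap, ["s0"])["s0"] == pytest.approx(
            (span + 1) / span, rel=1e-6)


def test_length_summary_threshold_percentages():
    mmap = make_map(10)
    panel = make_panel(np.zeros((4, 10), dtype=int), subpop=["P"] * 4)
    segs = [RohSegment(f"s{i}", "1", 1, L * 10 ** 6, 10)
            for i, L in enumerate([2, 5, 9, 20])]
    df = roh_length_summary(segs, panel)
    row = df.iloc[0]
    assert row["pct_segments_gt_4mb"] == pytest.approx(75.0)
    assert row["pct_segments_gt_8mb"] == pytest.approx(50.0)
    assert row["pct_segments_gt_16mb"] == pytest.approx(25.0)
    assert row["n_segments"] == 4


def test_length_summary_empty_population():
    panel = make_panel(np.zeros((2, 10), dtype=int), subpop=["P", "P"])
    df = roh_length_summary([], panel)
    assert df.iloc[0]["n_segments"] == 0


class TestAutozygosityTrack:
    def test_proportion_of_covering_samples(self):
        mmap = make_map(10, spacing=100_000)
        segs = [RohSegment(f"s{i}", "1", 1_000_000, 1_400_000, 5)
                for i in range(3)]
        track = autozygosity_track(segs, mmap, [f"s{i}" for i in range(10)])
        assert track[0] == pytest.approx(0.3)
        assert track[-1] == 0.0

    def test_inclusive_boundaries_match_stabbing_oracle(self):
        rng = np.random.default_rng(5)
        mmap = make_map(50, spacing=100_000)
        samples = [f"s{i}" for i in range(8)]
        segs = []
        for s in samples:
            for _ in range(rng.integers(1, 4)):
                i0, i1 = sorted(rng.integers(0, 50, size=2))
                segs.append(RohSegment(s, "1", int(mmap.pos_bp[i0]),
                                       int(mmap.pos_bp[i1]), i1 - i0 + 1))
        track = autozygosity_track(segs, mmap, samples)
        # oracle: direct interval stabbing with inclusive ends
        expected = np.zeros(50)
        for s in samples:
            covered = np.zeros(50, dtype=bool)
            for seg in segs:
                if seg.sample == s:
                    covered |= ((mmap.pos_bp >= seg.start_bp)
                                & (mmap.pos_bp <= seg.end_bp))
            expected += covered
        assert np.allclose(track, expected / len(samples))

    def test_segment_end_position_counted(self):
        mmap = make_map(10, spacing=100_000)
        segs = [RohSegment("s0", "1", int(mmap.pos_bp[2]),
                           int(mmap.pos_bp[4]), 3)]
        track = autozygosity_track(segs, mmap, ["s0"])
        assert track[4] == 1.0 and track[5] == 0.0


class TestIslands:
    def test_two_adjacent_extreme_snps_form_island(self):
        mmap = make_map(1000, spacing=50_000)
        scores = np.full(1000, 0.1)
        scores[500:502] = 0.9
        islands = roh_islands(scores, mmap)
        assert len(islands) == 1
        assert islands[0].start_bp == mmap.pos_bp[500]
        assert islands[0].end_bp == mmap.pos_bp[501]
        assert islands[0].n_units == 2

    def test_single_isolated_extreme_snp_ignored(self):
        mmap = make_map(1000, spacing=50_000)
        scores = np.full(1000, 0.1)
        scores[500] = 0.9
        assert roh_islands(scores, mmap) == []

    def test_plateau_crest_is_called(self):
        """Quantized scores tie across an island's crest; the inclusive
        threshold still calls the island."""
        mmap = make_map(3000, spacing=50_000)
        scores = np.full(3000, 0.1)
        scores[1000:1008] = 0.54  # 8-way tie at the maximum
        islands = roh_islands(scores, mmap)
        assert len(islands) == 1
        assert islands[0].n_units == 8

    def test_constant_track_yields_no_islands(self):
        mmap = make_map(100, spacing=50_000)
        assert roh_islands(np.full(100, 0.4), mmap) == []

    def test_island_invariant_to_sample_order(self, small_sim):
        panel, _, _ = small_sim
        segs = detect_roh_sliding(panel, RohParams())
        pop = panel.samples[panel.sample_indices("A")]
        t1 = autozygosity_track(segs, panel.markers, pop)
        t2 = autozygosity_track(segs, panel.markers, pop[::-1])
        assert np.array_equal(t1, t2)


@pytest.mark.parametrize("length_mb,expected", [(8, 6), (16, 3), (50, 1)])
def test_generations_to_ancestor(length_mb, expected):
    """g = floor(100 / (2 L_cM)) at 1 cM/Mb: an 8 Mb autozygous segment
    points ~6 generations back, 16 Mb ~3 generations."""
    assert generations_to_ancestor(length_mb) == expected


def test_generations_decreasing_in_length():
    lengths = [1, 2, 4, 8, 16, 32]
    gens = [generations_to_ancestor(L) for L in lengths]
    assert gens == sorted(gens, reverse=True)
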