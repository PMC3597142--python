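import numpy as np
import pytest
from scipy import stats

from nucleofinder import (
    NucleosomeCall,
    ReadCenters,
    average_profile,
    bin_counts,
    compute_specificity,
    dinucleotide_profile,
    estimate_spacing,
    permute_reads,
    read_tss,
)
from nucleofinder.synthetic import simulate_spacing_genes


def _centers(positions, length=10_000):
    return ReadCenters("c", np.sort(np.asarray(positions, dtype=np.int64)), length)


class TestPermuteReads:
    def test_per_block_counts_conserved(self):
        rng = np.random.default_rng(0)
        centers = _centers(rng.integers(0, 10_000, 700))
        out = permute_reads(centers, window=1000, seed=1)
        before = np.bincount(centers.positions // 1000, minlength=10)
        after = np.bincount(out.positions // 1000, minlength=10)
        assert (before == after).all() and len(out) == 700

    def test_same_seed_is_deterministic(self):
        centers = _centers(np.arange(0, 5_000, 7))
        a = permute_reads(centers, seed=5).positions
        b = permute_reads(centers, seed=5).positions
        assert (a == b).all()

    def test_phased_input_becomes_uniform_within_blocks(self):
        # strongly phased: all reads at two coordinates per 1 kb block
        positions = np.concatenate([[b * 1000 + 500] * 60 for b in range(10)])
        rejected = 0
        n_seeds = 100
        for seed in range(n_seeds):
            out = permute_reads(_centers(positions), window=1000, seed=seed)
            counts = np.bincount(out.positions // 100, minlength=100)  # 100 bp bins
            _, p = stats.chisquare(counts)
            rejected += p < 0.01
        assert rejected <= 5  # ~1% expected at alpha = 0.01

    def test_last_partial_block_stays_in_range(self):
        centers = _centers([9_990] * 20, length=10_000)
        out = permute_reads(centers, window=1000, seed=3)
        assert out.positions.min() >= 9_000 and out.positions.max() < 10_000


class TestComputeSpecificity:
    def test_formula(self):
        rep = compute_specificity(1, 100)
        assert rep.specificity == pytest.approx(0.99)
        assert rep.true_negatives == 99

    def test_extremes(self):
        assert compute_specificity(0, 50).specificity == 1.0
        assert compute_specificity(50, 50).specificity == 0.0

    def test_scale_consistency(self):
        assert compute_specificity(3, 300).specificity == pytest.approx(
            compute_specificity(6, 600).specificity
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            compute_specificity(1, 0)
        with pytest.raises(ValueError):
            compute_specificity(10, 5)


def _call_at(center, chrom="c"):
    return NucleosomeCall(chrom, center - 75, center + 75, center - 15, center + 15, 1.0, 1.0)


class TestAverageProfile:
    def test_single_call_returns_its_own_window(self):
        centers = _centers([1_005] * 9 + [800, 1_200])
        track10 = bin_counts(centers, bin_size=10)
        call = NucleosomeCall("c", 930, 1080, 990, 1020, 1.0, 1.0)
        prof = average_profile([call], track10, flank=100)
        assert prof.size == 35
        start_bin = (1_005 - 75 - 100 - 0) // 10 - 0
        assert prof.tolist() == track10.counts[83:118].tolist()

    def test_two_identical_windows_average_to_either(self):
        centers = _centers([1_005] * 5 + [3_015] * 5)
        track10 = bin_counts(centers, bin_size=10)
        calls = [
            NucleosomeCall("c", 930, 1080, 990, 1020, 1.0, 1.0),
            NucleosomeCall("c", 2940, 3090, 3000, 3030, 1.0, 1.0),
        ]
        prof = average_profile(calls, track10, flank=50)
        single = average_profile(calls[:1], track10, flank=50)
        assert prof.tolist() == single.tolist()

    def test_phased_calls_give_central_maximum(self):
        rng = np.random.default_rng(8)
        true_centers = np.arange(1_005, 9_000, 480)
        reads = np.concatenate([
            np.rint(c + rng.normal(0, 15, size=40)).astype(np.int64) for c in true_centers
        ])
        track10 = bin_counts(_centers(reads), bin_size=10)
        calls = [NucleosomeCall("c", c - 75, c + 75, c - 15, c + 15, 1.0, 1.0) for c in true_centers]
        prof = average_profile(calls, track10, flank=100)
        # maximum lies in the central 30 bp (bins 10..24 cover the 150 bp window)
        central = range(16, 19)
        assert int(np.argmax(prof)) in central

    def test_edge_truncated_calls_dropped(self):
        track10 = bin_counts(_centers([50] * 5), bin_size=10)
        inner = NucleosomeCall("c", 930, 1080, 990, 1020, 1.0, 1.0)
        edge = NucleosomeCall("c", 0, 150, 45, 75, 1.0, 1.0)
        prof = average_profile([inner, edge], track10, flank=100)
        assert prof.sum() == 0  # only the inner (empty) window contributed


class TestEstimateSpacing:
    def _calls_from_offsets(self, tss, offsets, strand="+", chrom="c"):
        calls = []
        for off in offsets:
            center = tss + off if strand == "+" else tss - off
            b = int(center) // 30
            calls.append(NucleosomeCall(chrom, b * 30 - 60, b * 30 + 90, b * 30, b * 30 + 30, 1.0, 1.0))
        return calls

    def test_exact_arithmetic_progression(self):
        calls = self._calls_from_offsets(6_000, [90, 270, 450, 630, 810])
        est = estimate_spacing(calls, [("c", 6_000, "+", 50.0)])
        assert est.mean_spacing == pytest.approx(180.0, abs=1.0)
        assert est.n_genes == 1

    def test_missing_call_recovered_by_nonconsecutive_numbering(self):
        calls = self._calls_from_offsets(6_000, [90, 450, 630, 810])
        est = estimate_spacing(calls, [("c", 6_000, "+", 50.0)])
        assert est.mean_spacing == pytest.approx(180.0, abs=1.0)

    def test_strand_invariance(self):
        offsets = [92, 268, 455, 627, 812]
        plus = estimate_spacing(
            self._calls_from_offsets(6_000, offsets, "+"), [("c", 6_000, "+", 50.0)]
        )
        minus = estimate_spacing(
            self._calls_from_offsets(6_000, offsets, "-"), [("c", 6_000, "-", 50.0)]
        )
        assert plus.mean_spacing == pytest.approx(minus.mean_spacing, abs=2.0)

    def test_low_expression_genes_excluded(self):
        calls, tss = simulate_spacing_genes(n_genes=60, rpkm_low_fraction=0.5, seed=2)
        est = estimate_spacing(calls, tss)
        n_high = sum(1 for t in tss if t[3] > 10.0)
        assert est.n_genes <= n_high
        assert est.mean_spacing == pytest.approx(180.0, abs=5.0)

    def test_gene_with_single_call_skipped(self):
        calls = self._calls_from_offsets(6_000, [90])
        with pytest.raises(ValueError):
            estimate_spacing(calls, [("c", 6_000, "+", 50.0)])


class TestDinucleotideProfile:
    def test_all_g_sequence_has_no_dinucleotide_signal(self):
        genome = {"c": "G" * 2_000}
        prof = dinucleotide_profile([_call_at(1_000)], genome)
        assert np.nanmax(prof.f_gc) == 0 and np.nanmax(prof.f_aatt) == 0
        assert prof.D == 0

    def test_gc_repeat_alternates_by_phase(self):
        # even-length windows: the reverse complement of a GC repeat keeps
        # phase, so each position is GC on both strands or on neither
        genome = {"c": "GC" * 1_000}
        prof = dinucleotide_profile([_call_at(1_000)], genome)
        assert set(np.round(prof.f_gc, 12)) == {0.0, 1.0}
        # two calls offset by 1 bp pool opposite phases to 0.5 everywhere
        prof2 = dinucleotide_profile([_call_at(1_000), _call_at(1_001)], genome)
        assert np.allclose(prof2.f_gc, 0.5)
        assert np.nanmax(prof2.f_aatt) == 0

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=3_000))
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        calls = [_call_at(c) for c in (800, 1_500, 2_200)]
        mirrored = [_call_at(len(seq) - c) for c in (800, 1_500, 2_200)]
        a = dinucleotide_profile(calls, {"c": seq})
        b = dinucleotide_profile(mirrored, {"c": rc})
        assert a.D == pytest.approx(b.D, abs=1e-12)

    def test_non_acgt_positions_excluded(self):
        genome = {"c": "A" * 990 + "N" * 20 + "A" * 990}
        prof = dinucleotide_profile([_call_at(1_000)], genome)
        assert np.isfinite(prof.D)

    def test_include_ta_option_raises_at_frequency(self):
        genome = {"c": "TA" * 1_000}
        base = dinucleotide_profile([_call_at(1_000)], genome)
        with_ta = dinucleotide_profile([_call_at(1_000)], genome, include_ta=True)
        assert np.nanmax(base.f_aatt) == 0
        assert np.nanmean(with_ta.f_aatt) > 0.4

    def test_edge_calls_dropped_and_counted(self):
        genome = {"c": "ACGT" * 500}
        prof = dinucleotide_profile([_call_at(40), _call_at(1_000)], genome)
        assert prof.dropped == 1 and prof.n == 1

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), size=20_000))
        calls = [_call_at(c) for c in range(500, 19_500, 400)]
        prof = dinucleotide_profile(calls, {"c": seq})
        assert prof.ci_low <= prof.D <= prof.ci_high
        assert prof.m == 29


def test_read_tss_parses_bed6_with_rpkm_score(tmp_path):
    p = tmp_path / "tss.bed"
    p.write_text("chr1\t1000\t1001\tgeneA\t42.5\t+\nchr1\t9000\t9001\tgeneB\t3.1\t-\n")
    entries = read_tss(p)
    assert entries == [("chr1", 1000, "+", 42.5), ("chr1", 9000, "-", 3.1)]
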