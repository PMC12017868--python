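"""Occupancy ratio, normalization factor, nFE tracks and peak calling."""

import itertools

import numpy as np
import pytest
from scipy import stats

from cenloop.calibration import (
    CHIP_SCALE, Peak, ReadCounts, call_peaks, nfe_track, normalization_factor,
    occupancy_ratio, peak_overlap_fraction, track_correlation,
)
from cenloop.core import GenomeAnnotation, GenomicInterval
from cenloop.simulate import ChipSimConfig, simulate_chip_counts

from conftest import make_track


class TestOccupancyRatio:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (ReadCounts(1000, 400, 500, 200), 1.0),
            (ReadCounts(2000, 400, 500, 200), 2.0),   # linear in ChIP_target
        ],
    )
    def test_formula_on_integer_tables(self, counts, expected):
        assert occupancy_ratio(counts) == pytest.approx(expected)

    def test_zero_denominator_raises_instead_of_infinity(self):
        with pytest.raises(ValueError):
            occupancy_ratio(ReadCounts(1000, 0, 500, 200))
        with pytest.raises(ValueError):
            occupancy_ratio(ReadCounts(1000, 400, 0, 200))

    def test_depth_invariance_under_fraction_scaling(self, rng):
        """Multiplying both counts of one fraction by any constant leaves
        OR unchanged."""
        for _ in range(20):
            c = rng.integers(1, 10_000, 4).astype(float)
            base = occupancy_ratio(ReadCounts(*c))
            k_chip, k_input = rng.uniform(0.1, 10, 2)
            scaled = ReadCounts(c[0] * k_chip, c[1] * k_chip,
                                c[2] * k_input, c[3] * k_input)
            assert occupancy_ratio(scaled) == pytest.approx(base)

    def test_recovers_bound_fraction_ratio_from_simulation(self, rng):
        """OR ratio between conditions equals the true bound-fraction ratio
        of the multinomial generator (mean over replicates)."""
        ann = GenomeAnnotation({"chrA": 200_000}, {"chrA": 100_000})
        ors = {f: [] for f in (1.0, 3.0)}
        for _ in range(50):
            for f in ors:
                cfg = ChipSimConfig(
                    annotation=ann, depth=1_000_000, spike_genome_size=200_000,
                    bound_fraction=f,
                )
                ors[f].append(occupancy_ratio(simulate_chip_counts(cfg, rng=rng).counts))
        ratio = np.mean(ors[3.0]) / np.mean(ors[1.0])
        assert ratio == pytest.approx(3.0, rel=0.05)


class TestNormalizationFactor:
    def test_examples_and_identity(self):
        assert normalization_factor(2.0, 1.0) == 2.0
        for x in (0.1, 1.7, 42.0):
            assert normalization_factor(x, x) == 1.0

    def test_chain_property(self, rng):
        for _ in range(50):
            a, b, c = rng.uniform(0.01, 100, 3)
            assert normalization_factor(a, c) == pytest.approx(
                normalization_factor(a, b) * normalization_factor(b, c)
            )

    def test_non_positive_input_rejected(self):
        with pytest.raises(ValueError):
            normalization_factor(0.0, 1.0)


class TestNfeTrack:
    def test_identical_chip_and_input_give_unity(self):
        vals = {"chrI": np.full(50, 10.0)}
        t = nfe_track(make_track(vals, semantics="raw"),
                      make_track(vals, semantics="raw"), nf=1.0)
        assert np.allclose(t.values["chrI"], 1.0)
        assert t.semantics == "nFE"

    def test_single_elevated_bin_matches_closed_form(self):
        """100-bin toy: one bin holds 10x the per-bin ChIP average."""
        chip = np.full(100, 5.0)
        chip[40] = 50.0
        inp = np.full(100, 8.0)
        t = nfe_track(make_track({"c": chip}), make_track({"c": inp}), nf=1.0)
        # closed form: scaled_chip/scaled_input evaluated by hand
        expect_peak = (50.0 * CHIP_SCALE / chip.sum()) / (8.0 * CHIP_SCALE / inp.sum())
        expect_bg = (5.0 * CHIP_SCALE / chip.sum()) / (8.0 * CHIP_SCALE / inp.sum())
        assert t.values["c"][40] == pytest.approx(expect_peak)
        assert t.values["c"][0] == pytest.approx(expect_bg)

    def test_nf_scales_linearly(self):
        chip = {"c": np.arange(1.0, 21.0)}
        inp = {"c": np.full(20, 3.0)}
        t1 = nfe_track(make_track(chip), make_track(inp), nf=1.0)
        t2 = nfe_track(make_track(chip), make_track(inp), nf=2.0)
        assert np.allclose(t2.values["c"], 2 * t1.values["c"])

    def test_depth_invariance(self):
        chip = np.arange(1.0, 51.0)
        inp = np.full(50, 2.0)
        t1 = nfe_track(make_track({"c": chip}), make_track({"c": inp}), nf=1.0)
        t2 = nfe_track(make_track({"c": chip * 7}), make_track({"c": inp * 3}), nf=1.0)
        assert np.allclose(t1.values["c"], t2.values["c"])

    def test_low_input_bins_are_masked_not_smoothed(self):
        chip = {"c": np.full(10, 4.0)}
        inp = np.full(10, 3.0)
        inp[5] = 0.0
        t = nfe_track(make_track(chip), make_track({"c": inp}), nf=1.0,
                      min_input_reads=1.0)
        assert t.mask["c"][5]
        assert not t.mask["c"][4]

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            nfe_track(make_track({"c": np.ones(10)}),
                      make_track({"c": np.ones(11)}), nf=1.0)


def _oracle_runs(above: list[bool], gap: int, min_width: int) -> list[tuple[int, int]]:
    """Brute-force run/merge/width rule for peak calling."""
    runs = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j < len(above) and above[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    merged = []
    for r in runs:
        if merged and r[0] - merged[-1][1] <= gap:
            merged[-1][1] = r[1]
        else:
            merged.append(r)
    return [(s, e) for s, e in merged if e - s >= min_width]


class TestCallPeaks:
    def test_single_run_with_summit(self):
        t = make_track({"c": [1, 1, 3, 4, 1]})
        peaks = call_peaks(t, threshold=2.0)
        assert len(peaks) == 1
        p = peaks[0]
        assert (p.interval.start, p.interval.end) == (200, 400)
        assert 300 <= p.summit < 400
        assert p.max_nfe == 4

    def test_all_below_threshold_gives_empty_list(self):
        assert call_peaks(make_track({"c": [1.0, 1.5, 0.2]}), threshold=2.0) == []

    def test_merge_gap_rule(self):
        t = make_track({"c": [3, 1, 3]})
        assert len(call_peaks(t, threshold=2.0, merge_gap_bins=1)) == 1
        assert len(call_peaks(t, threshold=2.0, merge_gap_bins=0)) == 2

    @pytest.mark.parametrize("gap", [0, 1])
    @pytest.mark.parametrize("min_width", [1, 2])
    def test_exhaustive_small_patterns_match_oracle(self, gap, min_width):
        """All 5-bin above/below patterns against the brute-force rule."""
        for bits in itertools.product([0, 1], repeat=5):
            vals = [3.0 if b else 1.0 for b in bits]
            got = call_peaks(make_track({"c": vals}), threshold=2.0,
                             merge_gap_bins=gap, min_width_bins=min_width)
            want = _oracle_runs([bool(b) for b in bits], gap, min_width)
            assert [(p.interval.start // 100, p.interval.end // 100)
                    for p in got] == want

    def test_summit_ties_break_leftmost(self):
        t = make_track({"c": [1, 4, 4, 1]})
        p = call_peaks(t, threshold=2.0)[0]
        assert p.summit == 150  # center of the first max bin

    def test_threshold_monotonicity(self, rng):
        """Peaks at a higher threshold are contained in peaks at a lower
        threshold."""
        vals = rng.random(500) * 5
        t = make_track({"c": vals})
        low = call_peaks(t, threshold=2.0)
        high = call_peaks(t, threshold=3.0)
        cover = np.zeros(500, dtype=bool)
        for p in low:
            cover[p.interval.start // 100: p.interval.end // 100] = True
        for p in high:
            assert cover[p.interval.start // 100: p.interval.end // 100].all()


def _peak(chrom, s, e):
    return Peak(interval=GenomicInterval(chrom, s, e), summit=(s + e) // 2,
                max_nfe=3.0, mean_nfe=2.5)


class TestPeakOverlap:
    def test_identical_and_disjoint(self):
        a = [_peak("c", 0, 100), _peak("c", 500, 700)]
        assert peak_overlap_fraction(a, a) == 1.0
        b = [_peak("c", 1000, 1100)]
        assert peak_overlap_fraction(a, b) == 0.0

    def test_random_sets_match_brute_force(self, rng):
        def random_peaks(n):
            out = []
            for _ in range(n):
                s = int(rng.integers(0, 990_000))
                out.append(_peak("c", s, s + int(rng.integers(100, 5000))))
            return out

        a, b = random_peaks(50), random_peaks(50)
        got = peak_overlap_fraction(a, b)
        brute = sum(
            any(p.interval.start < q.interval.end and q.interval.start < p.interval.end
                for q in b)
            for p in a
        ) / len(a)
        assert got == pytest.approx(brute)


class TestTrackCorrelation:
    def test_self_correlation_is_one(self, rng):
        t = make_track({"c": rng.random(100)})
        assert track_correlation(t, t) == pytest.approx(1.0)

    def test_reversed_monotone_gives_minus_one(self):
        a = make_track({"c": np.arange(1.0, 21.0)})
        b = make_track({"c": np.arange(1.0, 21.0)[::-1]})
        assert track_correlation(a, b) == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2, 2, 3, 5, 5, 5, 8, 9, 9])
        y = np.array([2.0, 1, 4, 4, 4, 6, 7, 7, 10, 9])
        got = track_correlation(make_track({"c": x}), make_track({"c": y}))
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert got == pytest.approx(oracle)

    def test_too_few_values_rejected(self):
        a = make_track({"c": np.array([1.0, 2.0])})
        with pytest.raises(ValueError):
            track_correlation(a, a)
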