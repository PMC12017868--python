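"""Contact-map analytics: balancing, expected, decay, insulation, loops,
pile-ups and classification."""

import numpy as np
import pytest
import scipy.sparse as sp

from cenloop.contacts import (
    anchor_site_classification, balance_iterative, call_loops, classify_loops,
    cluster_pixels, decay_curve, decay_slope, distance_binned_cen_contact,
    expected_cis, insulation_score, normalize_depth,
    oe_matrix, pileup, pileup_at_loci,
)
from cenloop.core import ContactMap, GenomeAnnotation, GenomicInterval, Loop
from cenloop.simulate import (
    ContactSimConfig, DomainSpec, LoopSpec, simulate_contact_map,
)


def dense_map(A, chrom="c", bin_size=1000, weights=None):
    m = ContactMap(chrom, bin_size, sp.csr_matrix(np.asarray(A, dtype=float)))
    if weights is not None:
        m.weights = np.asarray(weights, dtype=float)
    return m


class TestNormalizeDepth:
    def test_scaling_to_own_total_is_identity(self, rng):
        cfg = ContactSimConfig(chrom="c", length=100_000, depth=50_000)
        m = simulate_contact_map(cfg, rng=rng)
        out = normalize_depth(m, m.total, mode="scale")
        assert (abs(out.counts - m.counts)).max() < 1e-9

    def test_thinning_halves_expected_counts(self, rng):
        A = np.full((20, 20), 40.0)
        m = dense_map(A)
        vals = []
        for seed in range(100):
            out = normalize_depth(m, m.total / 2, mode="thin", rng=seed)
            vals.append(out.dense()[3, 7])
        assert np.mean(vals) == pytest.approx(20.0, rel=0.02)

    def test_scaling_gives_exact_common_totals(self, rng):
        cfgs = [ContactSimConfig(chrom="c", length=100_000, depth=d)
                for d in (60_000, 90_000)]
        maps = [simulate_contact_map(c, rng=rng) for c in cfgs]
        scaled = [normalize_depth(m, 50_000, mode="scale") for m in maps]
        assert scaled[0].total == pytest.approx(scaled[1].total)

    def test_thinning_above_total_rejected(self):
        m = dense_map(np.ones((5, 5)))
        with pytest.raises(ValueError):
            normalize_depth(m, 1000, mode="thin", rng=0)


class TestBalancing:
    def test_doubly_stochastic_matrix_gives_equal_weights(self):
        A = np.array([
            [0.1, 0.4, 0.3, 0.2],
            [0.4, 0.2, 0.1, 0.3],
            [0.3, 0.1, 0.2, 0.4],
            [0.2, 0.3, 0.4, 0.1],
        ])
        w = balance_iterative(dense_map(A), tol=1e-12)
        assert np.allclose(w, w[0])

    def test_recovers_inverse_of_diagonal_scaling(self):
        base = np.array([[0.5, 0.5], [0.5, 0.5]])
        D = np.diag([2.0, 1.0])
        w = balance_iterative(dense_map(D @ base @ D), tol=1e-14,
                              min_marginal_frac=0.0)
        # weights proportional to the inverse scaling, up to a global factor
        assert w[0] / w[1] == pytest.approx(0.5, rel=1e-6)

    def test_simulated_map_row_sums_equalize(self, rng):
        cfg = ContactSimConfig(chrom="c", length=300_000, depth=2_000_000)
        m = simulate_contact_map(cfg, rng=rng)
        w = balance_iterative(m, tol=1e-9)
        b = m.dense() * np.outer(w, w)
        rows = b.sum(axis=1)
        assert rows.std() / rows.mean() < 1e-6

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            balance_iterative(dense_map(np.zeros((4, 4))))


class TestExpected:
    def test_expectation_mode_map_recovers_generator_curve(self):
        cfg = ContactSimConfig(chrom="c", length=200_000, depth=500_000,
                               decay_exponent=1.2)
        m = simulate_contact_map(cfg, expectation=True)
        m.weights = np.ones(m.n_bins)
        prof = expected_cis(m)
        lam = m.dense()
        for s in (3, 10, 50):
            assert prof.whole[s] == pytest.approx(np.diagonal(lam, s).mean())

    def test_observed_over_expected_of_own_map_is_unity(self):
        cfg = ContactSimConfig(chrom="c", length=200_000, depth=500_000)
        m = simulate_contact_map(cfg, expectation=True)
        m.weights = np.ones(m.n_bins)
        oe = oe_matrix(m, expected_cis(m))
        off = ~np.eye(m.n_bins, dtype=bool)
        assert np.nanmax(np.abs(oe[off] - 1.0)) < 1e-9

    def test_per_arm_expected_separates_mixed_decay(self, rng):
        """Two arms with different decay exponents: per-arm curves recover
        each exponent, the pooled curve recovers neither."""
        n = 300
        idx = np.arange(n)
        d = np.maximum(np.abs(np.subtract.outer(idx, idx)), 1).astype(float)
        lam = np.where(
            (idx[:, None] < 150) & (idx[None, :] < 150), 3000 * d ** -1.0,
            np.where((idx[:, None] >= 150) & (idx[None, :] >= 150),
                     3000 * d ** -1.8, 0.05),
        )
        m = dense_map((lam + lam.T) / 2)
        m.weights = np.ones(n)
        prof = expected_cis(m, cen=150_000)
        s = np.arange(5, 60)

        def fitted_slope(curve):
            return np.polyfit(np.log(s), np.log(curve[s]), 1)[0]

        assert fitted_slope(prof.by_arm["L"]) == pytest.approx(-1.0, abs=0.05)
        assert fitted_slope(prof.by_arm["R"]) == pytest.approx(-1.8, abs=0.05)
        pooled = fitted_slope(prof.whole)
        assert abs(pooled + 1.0) > 0.1 and abs(pooled + 1.8) > 0.1


class TestDecay:
    def test_flat_intensity_gives_zero_slope(self):
        m = dense_map(np.full((200, 200), 7.0))
        curve = decay_curve(m)
        assert decay_slope(curve, 5000, 100_000) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("alpha", [1.0, 1.5])
    def test_power_law_slope_recovered(self, alpha):
        cfg = ContactSimConfig(chrom="c", length=1_000_000, bin_size=1000,
                               depth=5_000_000, decay_exponent=alpha)
        m = simulate_contact_map(cfg, rng=np.random.default_rng(7))
        slope = decay_slope(decay_curve(m), 5000, 100_000)
        assert slope == pytest.approx(-alpha, abs=0.05)

    def test_too_small_map_rejected(self):
        with pytest.raises(ValueError):
            decay_curve(dense_map(np.ones((5, 5))))


class TestInsulation:
    def test_uniform_matrix_scores_zero_no_boundaries(self):
        m = dense_map(np.full((80, 80), 3.0), weights=np.ones(80))
        tr = insulation_score(m, window=10_000)
        defined = np.isfinite(tr.scores)
        assert defined.sum() > 0
        assert np.allclose(tr.scores[defined], 0.0)
        assert len(tr.boundaries) == 0

    def test_planted_boundary_is_found_within_one_bin(self):
        cfg = ContactSimConfig(
            chrom="c", length=600_000, bin_size=1000, depth=6_000_000,
            domains=[DomainSpec(0, 300_000, 4.0), DomainSpec(300_000, 600_000, 4.0)],
        )
        m = simulate_contact_map(cfg, rng=np.random.default_rng(5))
        m.weights = balance_iterative(m)
        tr = insulation_score(m, window=10_000)
        assert abs(int(np.nanargmin(tr.scores)) - 300) <= 1
        assert len(tr.boundaries) >= 1
        assert (abs(tr.boundaries["bin"] - 300) <= 1).any()

    def test_score_invariant_to_global_scaling(self):
        A = np.abs(np.random.default_rng(0).normal(5, 1, (60, 60)))
        A = (A + A.T) / 2
        m1 = dense_map(A, weights=np.ones(60))
        m2 = dense_map(A * 37.5, weights=np.ones(60))
        t1 = insulation_score(m1, window=5000)
        t2 = insulation_score(m2, window=5000)
        ok = np.isfinite(t1.scores)
        assert np.allclose(t1.scores[ok], t2.scores[ok])

    def test_window_larger_than_chromosome_rejected(self):
        m = dense_map(np.ones((10, 10)), weights=np.ones(10))
        with pytest.raises(ValueError):
            insulation_score(m, window=20_000)


class TestLoopCaller:
    def test_merge_rule_on_constructed_pixels(self):
        # 2,000 bp apart -> one cluster; 3,000 bp apart -> two clusters
        assert len(cluster_pixels([(10, 50), (10, 52)], 2500, 1000)) == 1
        assert len(cluster_pixels([(10, 50), (10, 53)], 2500, 1000)) == 2

    def test_single_injected_dot_yields_one_accurate_loop(self):
        cfg = ContactSimConfig(chrom="c", length=400_000, bin_size=1000,
                               depth=2_500_000,
                               loops=[LoopSpec(120_000, 250_000, 5.0, 2000.0)])
        m = simulate_contact_map(cfg, rng=np.random.default_rng(11))
        m.weights = balance_iterative(m)
        loops = call_loops(m)
        assert len(loops) == 1
        assert abs(loops[0].anchor1.midpoint - 120_000) <= 2500
        assert abs(loops[0].anchor2.midpoint - 250_000) <= 2500

    def test_null_map_rarely_produces_loops(self):
        fps = []
        for seed in range(5):
            cfg = ContactSimConfig(chrom="c", length=400_000, bin_size=1000,
                                   depth=2_000_000)
            m = simulate_contact_map(cfg, rng=np.random.default_rng(100 + seed))
            m.weights = balance_iterative(m)
            fps.append(len(call_loops(m)))
        assert np.mean(fps) <= 1.0

    def test_unbalanced_map_rejected(self):
        m = dense_map(np.ones((50, 50)))
        with pytest.raises(ValueError, match="balanced"):
            call_loops(m)


class TestPileup:
    def _exp_map(self, n=600, depth=4_000_000):
        cfg = ContactSimConfig(chrom="c", length=n * 1000, bin_size=1000,
                               depth=depth)
        m = simulate_contact_map(cfg, expectation=True)
        m.weights = np.ones(m.n_bins)
        return m

    def test_observed_equals_expected_gives_unity(self):
        m = self._exp_map()
        pairs = [
            (GenomicInterval("c", p - 500, p + 500),
             GenomicInterval("c", p + 49_500, p + 50_500))
            for p in range(100_000, 500_000, 40_000)
        ]
        res = pileup({"c": m}, pairs)
        assert res.central_score == pytest.approx(1.0, abs=1e-9)
        assert np.nanmax(np.abs(res.matrix - 1.0)) < 1e-9

    def test_pairs_under_min_distance_are_excluded(self):
        m = self._exp_map()
        close = [(GenomicInterval("c", 99_500, 100_500),
                  GenomicInterval("c", 103_500, 104_500))]
        with pytest.raises(ValueError, match="zero usable pairs"):
            pileup({"c": m}, close)

    def test_injected_dots_recovered_in_central_score(self):
        pairs = [(40_000 + 23_000 * k, 40_000 + 23_000 * k + 30_000 + 4_000 * k)
                 for k in range(10)]
        cfg = ContactSimConfig(
            chrom="c", length=800_000, bin_size=1000, depth=8_000_000,
            loops=[LoopSpec(a, b, 3.0, 4000.0) for a, b in pairs],
        )
        m = simulate_contact_map(cfg, rng=np.random.default_rng(2))
        m.weights = balance_iterative(m)
        ivs = [(GenomicInterval("c", a - 500, a + 500),
                GenomicInterval("c", b - 500, b + 500)) for a, b in pairs]
        res = pileup({"c": m}, ivs)
        assert res.n_used == 10
        assert res.central_score == pytest.approx(3.0, rel=0.15)

    def test_on_diagonal_mode_accepts_loci(self):
        m = self._exp_map()
        loci = [GenomicInterval("c", p - 500, p + 500)
                for p in range(100_000, 400_000, 50_000)]
        res = pileup_at_loci({"c": m}, loci, flank=10_000)
        assert res.n_used == len(loci)


def _loop(chrom, a, b, cat=None):
    return Loop(GenomicInterval(chrom, a - 500, a + 500),
                GenomicInterval(chrom, b - 500, b + 500),
                obs_exp=3.0, q_value=0.01, category=cat)


class TestClassification:
    @pytest.fixture
    def ann(self):
        return GenomeAnnotation({"chrI": 500_000}, {"chrI": 200_000})

    def test_anchor_at_cen_midpoint_is_centromere_originated(self, ann):
        loops = [_loop("chrI", 200_000, 300_000)]
        classify_loops(loops, ann, [])
        assert loops[0].category == "centromere-originated"

    def test_both_anchors_on_cohesin_far_from_cen(self, ann):
        sites = [GenomicInterval("chrI", 49_000, 51_000),
                 GenomicInterval("chrI", 99_000, 101_000)]
        loops = [_loop("chrI", 50_000, 100_000)]
        classify_loops(loops, ann, sites)
        assert loops[0].category == "cohesin-anchored"

    def test_no_loops_all_sites_non_anchor(self, ann):
        sites = [GenomicInterval("chrI", k, k + 200) for k in
                 range(10_000, 100_000, 10_000)]
        flags, n_anchor, n_non = anchor_site_classification(sites, [], ann)
        assert n_anchor == 0 and n_non == len(sites)

    def test_constructed_distal_anchors_flag_exactly_k_sites(self, ann):
        sites = [GenomicInterval("chrI", p - 100, p + 100)
                 for p in (50_000, 100_000, 300_000, 400_000)]
        loops = [_loop("chrI", 200_000, 300_000, cat="centromere-originated"),
                 _loop("chrI", 100_000, 200_000, cat="centromere-originated")]
        flags, n_anchor, _ = anchor_site_classification(sites, loops, ann)
        assert n_anchor == 2
        assert flags[1] and flags[2]

    def test_random_placement_matches_brute_force(self, ann, rng):
        sites = [GenomicInterval("chrI", int(p), int(p) + 300)
                 for p in rng.integers(1000, 490_000, 60)]
        loops = []
        for _ in range(15):
            far = int(rng.integers(10_000, 480_000))
            if abs(far - 200_000) < 10_000:
                continue
            loops.append(_loop("chrI", *(sorted((200_000, far))),
                               cat="centromere-originated"))
        flags, _, _ = anchor_site_classification(sites, loops, ann)
        distal = []
        for lp in loops:
            for a in (lp.anchor1, lp.anchor2):
                if abs(a.midpoint - 200_000) > 5000:
                    distal.append(a)
        brute = np.array([
            any(s.start < a.end and a.start < s.end for a in distal)
            for s in sites
        ])
        assert np.array_equal(flags, brute)

    def test_distance_bin_assignment_left_closed(self, ann):
        m = dense_map(np.full((500, 500), 2.0), chrom="chrI",
                      weights=np.ones(500))
        # site exactly at 25 kb from CEN goes to the second bin
        sites = [GenomicInterval("chrI", 224_900, 225_100)]
        df = distance_binned_cen_contact(
            {"chrI": m}, sites, ann, edges=[0, 25_000, 50_000, 100_000],
        )
        assert df.loc[1, "n"] == 1
        assert df.loc[0, "n"] == 0

    def test_no_loops_gives_flat_distance_bins(self, ann):
        cfg = ContactSimConfig(chrom="chrI", length=500_000, bin_size=1000,
                               depth=5_000_000)
        m = simulate_contact_map(cfg, rng=np.random.default_rng(8))
        m.weights = balance_iterative(m)
        sites = [GenomicInterval("chrI", p - 100, p + 100)
                 for p in (230_000, 260_000, 280_000, 330_000, 180_000, 120_000)]
        df = distance_binned_cen_contact(
            {"chrI": m}, sites, ann, edges=[0, 50_000, 100_000, 150_000],
        )
        got = df["central_score"].dropna()
        assert np.all(np.abs(got - 1.0) < 0.35)
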