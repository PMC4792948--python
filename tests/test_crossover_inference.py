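"""Boundary inference, stringency skew and power analyses."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import xovermap as xm
from xovermap.crossover_inference import (
    composite_retained_profile,
    loglik_curve,
)
from xovermap.seq_pipeline import JunctionProfilePair, PositionProfile, profile_positions


def brute_force_boundary(left, right, q, e, pseudocount=0.5):
    """Independent re-enumeration of the changepoint likelihood: a plain
    Python loop over every boundary and position, sharing no code with the
    vectorized search."""
    P = left.P
    kl, nl = left.nonwt_counts(), left.n
    kr, nr = right.nonwt_counts(), right.n

    def ll(k, n, p):
        k = k + 3 * pseudocount
        n = n + 4 * pseudocount
        return k * math.log(p) + (n - k) * math.log(1 - p)

    best_b, best = None, -math.inf
    curve = []
    for b in range(P + 1):
        total = 0.0
        for j in range(P):
            total += ll(kl[j], nl[j], q if j < b else e)
            total += ll(kr[j], nr[j], q if j >= b else e)
        curve.append(total)
        if total > best:
            best, best_b = total, b
    return best_b, curve


def make_pair(boundary, depth=10_000, error=0.001, seed=0):
    return xm.simulate_junction_counts(boundary, depth, error, seed=seed)


class TestInferBoundary:
    def test_noiseless_pool_recovers_truth_and_matches_brute_force(self):
        pair = make_pair(8, error=0.0, seed=1)
        call = xm.infer_boundary(pair, error_floor=1e-4)
        assert call.boundary_hat == 8
        q = float(np.mean(pair.library.nonwt_rates()))
        bb, curve = brute_force_boundary(pair.left, pair.right, q, 1e-4)
        assert bb == 8
        np.testing.assert_allclose(call.loglik_curve, curve, rtol=1e-10)

    def test_degenerate_split_is_boundary_p(self, site):
        """Left junction retaining non-WT everywhere, right nowhere, places
        the boundary at P."""
        P = 10
        hot = np.zeros((P, 4), dtype=int)
        cold = np.zeros((P, 4), dtype=int)
        wt = site.window_wt
        for j in range(P):
            wt_idx = "ACGT".index(wt[j])
            alt = [i for i in range(4) if i != wt_idx][0]
            hot[j, wt_idx] = 925
            hot[j, alt] = 75
            cold[j, wt_idx] = 1000
        pair = JunctionProfilePair(
            library=PositionProfile(hot.copy(), wt=wt),
            left=PositionProfile(hot, wt=wt),
            right=PositionProfile(cold, wt=wt),
        )
        assert xm.infer_boundary(pair).boundary_hat == P

    def test_paper_design_boundary_between_border_adenines(self, site, spec):
        """Simulating the published design (P=10, crossover between the two
        adenines of the L-box-border AAC triplet) puts the call at that
        inter-adenine boundary."""
        b_true = xm.ts_boundary_ordinal(site)
        pool = xm.simulate_cointegrate_pool(spec, b_true, 4000, seed=17)
        lib = [site.window_bases(m) for m in xm.draw_library(spec, 4000, 18)]
        pair = JunctionProfilePair(
            library=profile_positions(lib, wt=site.window_wt),
            left=profile_positions(
                [site.window_bases(e.left_site) for e in pool.events],
                wt=site.window_wt,
            ),
            right=profile_positions(
                [site.window_bases(e.right_site) for e in pool.events],
                wt=site.window_wt,
            ),
        )
        call = xm.infer_boundary(pair, error_floor=1e-4)
        assert call.boundary_hat == b_true == 6

    def test_all_zero_counts_raise(self):
        empty = PositionProfile(np.zeros((10, 4), int), wt="CCCTAAACGG")
        pair = JunctionProfilePair(library=empty, left=empty, right=empty)
        with pytest.raises(xm.DataError):
            xm.infer_boundary(pair, expected_nonwt=0.075)

    @given(b=st.integers(0, 10), seed=st.integers(0, 50))
    @settings(max_examples=40)
    def test_matches_brute_force_on_noisy_data(self, b, seed):
        pair = make_pair(b, depth=2000, seed=seed)
        call = xm.infer_boundary(pair, error_floor=1e-3)
        q = float(np.mean(pair.library.nonwt_rates()))
        bb, _ = brute_force_boundary(pair.left, pair.right, q, 1e-3)
        assert call.boundary_hat == bb

    @given(b=st.integers(0, 10), seed=st.integers(0, 50))
    @settings(max_examples=40)
    def test_mirror_symmetry(self, b, seed):
        """Swapping left/right and reversing position order maps the call
        b_hat -> P - b_hat (when the maximum is unique)."""
        pair = make_pair(b, depth=2000, seed=seed)
        call = xm.infer_boundary(pair, expected_nonwt=0.075)
        mirrored = JunctionProfilePair(
            library=PositionProfile(pair.library.counts[::-1].copy(),
                                    wt=pair.library.wt[::-1]),
            left=PositionProfile(pair.right.counts[::-1].copy(),
                                 wt=pair.right.wt[::-1]),
            right=PositionProfile(pair.left.counts[::-1].copy(),
                                  wt=pair.left.wt[::-1]),
        )
        mirror_call = xm.infer_boundary(mirrored, expected_nonwt=0.075)
        if len(call.ties) == 1:
            assert mirror_call.boundary_hat == 10 - call.boundary_hat

    def test_recovery_spot_checks(self):
        """At the default design scale (depth 10,000, error 0.001) the
        boundary is recovered across replicate simulations."""
        rng = np.random.default_rng(3)
        for b in (0, 5, 10):
            for _ in range(20):
                pair = make_pair(b, seed=int(rng.integers(2**31)))
                assert xm.infer_boundary(pair).boundary_hat == b


class TestStringency:
    def test_exact_expectation_gives_zero_skew_p_one(self):
        counts = np.zeros((1, 4), int)
        counts[0] = [925, 25, 25, 25]  # WT C at 925 of 1000... see wt below
        prof = PositionProfile(np.array([[25, 925, 25, 25]]), wt="C")
        rep = xm.stringency_skew(prof, expected_nonwt=0.075)
        assert rep.table.loc[0, "skew"] == pytest.approx(0.0)
        assert rep.table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_zero_retention_is_strong_depletion(self):
        """No non-WT reads at n=200: skew -1 and a p-value equal to the
        exact two-sided binomial tail, computed here by pmf enumeration."""
        n = 200
        prof = PositionProfile(np.array([[0, n, 0, 0]]), wt="C")
        rep = xm.stringency_skew(prof, expected_nonwt=0.075)
        pmf = stats.binom.pmf(np.arange(n + 1), n, 0.075)
        expected_p = pmf[pmf <= pmf[0] * (1 + 1e-7)].sum()
        assert rep.table.loc[0, "skew"] == pytest.approx(-1.0)
        assert rep.table.loc[0, "p_value"] == pytest.approx(expected_p, rel=1e-6)
        assert rep.table.loc[0, "p_value"] < 1e-4

    def test_selective_purging_is_detected_per_position(self, site, spec):
        """With neutral central L-box positions and purging elsewhere, only
        the neutral positions escape significant depletion."""
        neutral = {3, 4}  # the central CT of CCCTAAA (window ordinals)
        acceptance = [1.0 if j + 1 in neutral else 1 / 15 for j in range(10)]
        pool = xm.simulate_cointegrate_pool(spec, 6, 20_000, seed=23,
                                            acceptance=acceptance)
        pair = JunctionProfilePair(
            library=None,
            left=profile_positions(
                [site.window_bases(e.left_site) for e in pool.events],
                wt=site.window_wt,
            ),
            right=profile_positions(
                [site.window_bases(e.right_site) for e in pool.events],
                wt=site.window_wt,
            ),
        )
        post = composite_retained_profile(pair, 6)
        rep = xm.stringency_skew(post, expected_nonwt=0.075)
        # a position is called "under selection" when its non-WT retention
        # is significantly *depleted*; purging enriches the neutral
        # positions' share of the surviving pool, so they must never be
        # flagged as depleted
        flagged = (rep.table["q_value"] < 0.01) & (rep.table["skew"] < 0)
        for j in range(10):
            if j + 1 in neutral:
                assert not flagged[j]
                assert rep.table.loc[j, "skew"] > -0.3
            else:
                assert flagged[j]
                assert rep.table.loc[j, "skew"] < -0.5

    def test_null_pvalues_are_uniform(self):
        """Under neutral retention the exact-test p-values are uniform on
        [0,1] (Kolmogorov-Smirnov at 1,000 replicates)."""
        rng = np.random.default_rng(7)
        n = 10_000
        ks = rng.binomial(n, 0.075, size=1000)
        pvals = np.array(
            [stats.binomtest(int(k), n, 0.075).pvalue for k in ks]
        )
        d = stats.kstest(pvals, "uniform").statistic
        assert d < 0.06


class TestPowerCurve:
    def test_saturation_and_monotonicity(self):
        """Recovery is 1.0 at high depth / zero error and non-decreasing in
        depth at fixed error."""
        df = xm.power_curve(
            depth_grid=[10, 300, 100_000],
            error_grid=[0.0, 0.05],
            true_b=6,
            replicates=30,
            seed=9,
        )
        sat = df[(df.depth == 100_000) & (df.error_rate == 0.0)]
        assert sat.recovery.item() == 1.0
        for e in (0.0, 0.05):
            col = df[df.error_rate == e].sort_values("depth").recovery.tolist()
            assert col == sorted(col)
        noisy = df[(df.depth == 10) & (df.error_rate == 0.05)]
        assert noisy.recovery.item() < 1.0
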