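"""Ensemble analytics: (α,β) maps, state split, fraction curves, propensities."""

import math

import numpy as np
import pytest

from cutabi import ensemble_maps as em
from cutabi.ensemble_maps import (ConformationSummary, DensityMap,
                                  cumulative_fraction_curve, density_map,
                                  filter_monomers, per_residue_propensity,
                                  rg_by_state, summaries_frame, summarize)
from cutabi.synthetic import (Segment, SegmentPlan, build_coil, build_ensemble,
                              build_hairpin, build_helix)
from cutabi.trace import CaTrace


def summaries_at(points):
    """Build summaries at given (alpha, beta) integer points, rg=10."""
    return [ConformationSummary(frame=i, alpha=a, beta=b, rg=10.0,
                                state="B" if a == 0 else "HB")
            for i, (a, b) in enumerate(points)]


class TestSummarize:
    def test_identical_helices_summarised_identically(self):
        trace, _ = build_helix(10)
        summaries = summarize([trace] * 10, region=(1, 10))
        assert all((s.alpha, s.beta, s.state) == (8, 0, "HB") for s in summaries)
        assert all(s.rg == summaries[0].rg for s in summaries)

    def test_pure_hairpins_are_b_state(self):
        trace, _ = build_hairpin(6)
        summaries = summarize([trace] * 5, region=(1, 14))
        assert all(s.state == "B" and s.alpha == 0 for s in summaries)

    def test_empty_ensemble(self):
        assert summarize([]) == []

    def test_heterogeneous_lengths_rejected(self):
        a, _ = build_helix(10)
        b, _ = build_helix(12)
        with pytest.raises(ValueError, match="lengths"):
            summarize([a, b])

    def test_frame_dataframe_columns(self):
        trace, _ = build_helix(10)
        df = summaries_frame(summarize([trace] * 3, region=(1, 10)))
        assert list(df.columns) == ["frame", "alpha", "beta", "rg", "state"]
        assert len(df) == 3


class TestDensityMap:
    def test_single_cell(self):
        dm = density_map(summaries_at([(0, 50)] * 7))
        assert dm.P[0, 50] == 1.0 and dm.P_max_B == 1.0
        assert dm.b_fraction == 1.0

    def test_small_arithmetic_case(self):
        dm = density_map(summaries_at([(0, 10)] * 3 + [(2, 5)]))
        assert dm.P[0, 10] == pytest.approx(0.75)
        assert dm.P[2, 5] == pytest.approx(0.25)
        assert dm.b_fraction == pytest.approx(0.75)
        assert dm.P_max_B == pytest.approx(0.75)

    def test_normalisation_is_tight(self, rng):
        pts = [(int(a), int(b)) for a, b in
               zip(rng.integers(0, 5, 500), rng.integers(0, 40, 500))]
        dm = density_map(summaries_at(pts))
        assert abs(dm.P.sum() - 1.0) < 1e-12
        assert dm.b_fraction + dm.hb_block.sum() == pytest.approx(1.0, abs=1e-12)

    def test_multinomial_recovery_within_sampling_error(self, rng):
        # simulate frames from a known P over 3 cells and recover it
        cells = [(0, 10), (0, 20), (3, 15)]
        probs = np.array([0.5, 0.3, 0.2])
        draws = rng.choice(3, size=10_000, p=probs)
        dm = density_map(summaries_at([cells[d] for d in draws]))
        for (a, b), p in zip(cells, probs):
            se = math.sqrt(p * (1 - p) / 10_000)
            assert abs(dm.P[a, b] - p) < 4 * se


class TestFractionCurve:
    def test_single_cell_curve_is_one_everywhere(self):
        dm = density_map(summaries_at([(0, 5)] * 3))
        curve = cumulative_fraction_curve(dm, cutoffs=np.linspace(0, 5, 11))
        assert np.all(curve.fraction == 1.0)

    def test_two_cell_jump_at_ln2(self):
        dm = DensityMap(P=np.array([[2 / 3, 1 / 3]]), P_max_B=2 / 3)
        eps = 1e-9
        curve = cumulative_fraction_curve(
            dm, cutoffs=np.array([0.0, math.log(2) - eps, math.log(2), 3.0]))
        assert curve.fraction[0] == pytest.approx(2 / 3)
        assert curve.fraction[1] == pytest.approx(2 / 3)
        assert curve.fraction[2] == pytest.approx(1.0)
        assert curve.fraction[3] == pytest.approx(1.0)

    def test_matches_hand_summed_two_level_map(self):
        p = np.array([[0.4, 0.1], [0.3, 0.2]])
        dm = DensityMap(P=p, P_max_B=0.4)
        grid = np.linspace(-0.5, 2.0, 26)
        curve = cumulative_fraction_curve(dm, cutoffs=grid)
        flat = p.ravel()
        df = np.log(0.4 / flat)
        hand = np.array([flat[df <= c].sum() for c in grid])
        assert np.allclose(curve.fraction, hand)

    def test_nondecreasing_and_reaches_one(self, rng):
        pts = [(int(a), int(b)) for a, b in
               zip(rng.integers(0, 4, 300), rng.integers(0, 30, 300))]
        curve = cumulative_fraction_curve(density_map(summaries_at(pts)))
        assert np.all(np.diff(curve.fraction) >= -1e-15)
        assert curve.fraction[-1] == pytest.approx(1.0)

    def test_value_at_zero_is_probability_of_maximal_cells(self, rng):
        pts = [(0, 1)] * 5 + [(0, 2)] * 5 + [(1, 3)] * 2
        dm = density_map(summaries_at(pts))
        curve = cumulative_fraction_curve(dm, cutoffs=np.array([0.0]))
        expected = dm.P[dm.P >= dm.P_max_B - 1e-15].sum()
        assert curve.fraction[0] == pytest.approx(expected)

    def test_hb_cell_above_b_maximum_extends_grid_below_zero(self):
        p = np.array([[0.2, 0.1], [0.7, 0.0]])
        dm = DensityMap(P=p, P_max_B=0.2)
        curve = cumulative_fraction_curve(dm)
        assert curve.cutoffs[0] < 0
        assert curve.fraction[-1] == pytest.approx(1.0)

    def test_dos_integrates_back_to_curve_increment(self):
        dm = DensityMap(P=np.array([[0.5, 0.25, 0.25]]), P_max_B=0.5)
        curve = cumulative_fraction_curve(dm, cutoffs=np.linspace(0, 2, 101))
        mid, dos = curve.dos()
        recovered = np.cumsum(dos * np.diff(curve.cutoffs)) + curve.fraction[0]
        assert recovered[-1] == pytest.approx(curve.fraction[-1])


class TestPropensity:
    def test_identical_helices_have_unit_interior_propensity(self):
        trace, _ = build_helix(10)
        prop = per_residue_propensity([trace] * 6, region=(1, 10))
        assert np.allclose(prop.helix[1:9], 1.0)
        assert prop.helix[0] == 0.0 and prop.helix[9] == 0.0
        assert np.all(prop.sheet == 0.0)

    def test_mixed_ensemble_gives_half(self):
        helix, _ = build_helix(10)
        coil, _ = build_coil(10, seed=5)
        prop = per_residue_propensity([helix, coil], region=(1, 10))
        assert prop.helix[4] == pytest.approx(0.5)

    def test_b_subset_of_all_helix_ensemble_fails(self):
        trace, _ = build_helix(10)
        with pytest.raises(ValueError, match="B"):
            per_residue_propensity([trace] * 3, subset="B", region=(1, 10))

    def test_invariant_under_frame_permutation(self, rng):
        plan = SegmentPlan((Segment("helix", 8), Segment("coil", 6)))
        result = build_ensemble([(plan, 1.0)], n_frames=12, seed=3)
        frames = list(result.traces)
        p1 = per_residue_propensity(frames, region=(1, 14))
        shuffled = [frames[i] for i in rng.permutation(len(frames))]
        p2 = per_residue_propensity(shuffled, region=(1, 14))
        assert np.allclose(p1.helix, p2.helix) and np.allclose(p1.sheet, p2.sheet)


class TestRgByState:
    def test_single_rg_occupies_one_bin(self):
        out = rg_by_state(summaries_at([(0, 3)] * 4), bins=5)
        dens, _ = out["all"]
        assert np.count_nonzero(dens) == 1

    def test_b_and_hb_counts_sum_to_all(self, rng):
        summaries = []
        for i in range(200):
            a = int(rng.integers(0, 3))
            summaries.append(ConformationSummary(
                frame=i, alpha=a, beta=int(rng.integers(0, 10)),
                rg=float(rng.uniform(8, 20)), state="B" if a == 0 else "HB"))
        out = rg_by_state(summaries, bins=12)
        rg = np.array([s.rg for s in summaries])
        states = np.array([s.state for s in summaries])
        _, edges = out["all"]
        c_all, _ = np.histogram(rg, bins=edges)
        c_b, _ = np.histogram(rg[states == "B"], bins=edges)
        c_hb, _ = np.histogram(rg[states == "HB"], bins=edges)
        assert np.array_equal(c_b + c_hb, c_all)

    def test_bimodal_mixture_recovers_weights(self, rng):
        compact = [ConformationSummary(i, 0, 1, rg=float(rng.normal(8, 0.3)), state="B")
                   for i in range(700)]
        extended = [ConformationSummary(i, 0, 1, rg=float(rng.normal(25, 0.5)), state="B")
                    for i in range(300)]
        out = rg_by_state(compact + extended, bins=40)
        dens, edges = out["all"]
        widths = np.diff(edges)
        low_mass = (dens * widths)[edges[:-1] < 15].sum()
        assert low_mass == pytest.approx(0.7, abs=0.05)


class TestFilterMonomers:
    def test_far_apart_chains_retained(self):
        a, _ = build_coil(10, seed=1)
        b, _ = build_coil(10, seed=2)
        far = CaTrace(b.coords + np.array([200.0, 0, 0]))
        kept, frac = filter_monomers([(a, far)])
        assert frac == 1.0 and len(kept) == 1

    def test_touching_chains_removed(self):
        a, _ = build_coil(10, seed=1)
        kept, frac = filter_monomers([(a, a)])
        assert frac == 0.0 and kept == []

    def test_known_touching_fraction_recovered(self, rng):
        frames = []
        n_touching = 30
        for i in range(100):
            a, _ = build_coil(8, seed=rng)
            b, _ = build_coil(8, seed=rng)
            offset = 5.0 if i < n_touching else 120.0
            frames.append((a, CaTrace(b.coords + np.array([offset, 0.0, 0.0]))))
        kept, frac = filter_monomers(frames, cutoff=20.0)
        assert frac == pytest.approx(0.70, abs=0.05)

    def test_wrong_chain_count_rejected(self):
        a, _ = build_coil(5, seed=0)
        with pytest.raises(ValueError, match="frame 0"):
            filter_monomers([(a,)])
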