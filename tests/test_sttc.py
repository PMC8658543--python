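"""STTC, adjacency matrices and pairwise network summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from arcnet.core import SpikeTrain
from arcnet.errors import InvalidParameterError, UndefinedValueError
from arcnet.sttc import (
    STTCParams,
    adjacency_matrix,
    arc_pair_fraction_vs_threshold,
    classify_correlation_changes,
    density_distribution,
    distance_by_pair_type,
    group_mean_ci,
    pair_distances,
    sttc,
    tiled_spike_proportion,
    tiled_time_fraction,
    total_flow,
)
from conftest import random_train


def train(*times, duration=60.0):
    return SpikeTrain(np.array(times, dtype=float), duration)


class TestTiledTimeFraction:
    @pytest.mark.parametrize(
        "times, expected",
        [
            ((1.0,), 0.1 / 60),  # one interior spike: full 2*dt tile
            ((0.02,), 0.07 / 60),  # clipped at the recording start
            ((1.00, 1.04), 0.14 / 60),  # overlapping tiles merge
            ((), 0.0),
        ],
    )
    def test_hand_evaluated(self, times, expected):
        tr = SpikeTrain(np.array(times), 60.0)
        assert tiled_time_fraction(tr, 0.05) == pytest.approx(expected, abs=1e-12)

    def test_fine_grid_oracle(self, rng):
        """Interval-union tiling equals a 1 ms grid measure on ms-aligned
        trains (grid bin centres make the measure exact there)."""
        dt = 0.05
        for _ in range(100):
            tr = random_train(rng, duration_s=10.0, ms_aligned=True)
            centers = np.arange(0.0005, 10.0, 0.001)
            covered = np.zeros_like(centers, dtype=bool)
            for t in tr.times_s:
                covered |= np.abs(centers - t) < dt
            grid_measure = covered.mean()
            assert tiled_time_fraction(tr, dt) == pytest.approx(
                grid_measure, abs=1e-6
            )


class TestTiledSpikeProportion:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((1.0,), (1.02,), 1.0),
            ((1.0,), (10.0,), 0.0),
            ((1.0, 5.0), (1.02,), 0.5),
        ],
    )
    def test_hand_evaluated(self, a, b, expected):
        assert tiled_spike_proportion(train(*a), train(*b), 0.05) == expected

    def test_empty_a_is_undefined(self):
        with pytest.raises(UndefinedValueError):
            tiled_spike_proportion(train(), train(1.0), 0.05)

    def test_brute_force_oracle(self, rng):
        """Searchsorted nearest-spike distances match an O(nA*nB) loop."""
        for _ in range(100):
            a, b = random_train(rng), random_train(rng)
            brute = np.mean(
                [min(abs(t - u) for u in b.times_s) <= 0.05 for t in a.times_s]
            )
            assert tiled_spike_proportion(a, b, 0.05) == pytest.approx(brute)


class TestSTTC:
    def test_self_correlation_is_exactly_one(self):
        tr = train(1.0, 2.5, 7.3)
        assert tiled_time_fraction(tr, 0.05) < 1
        assert sttc(tr, tr) == 1.0

    def test_far_pair_hand_evaluated(self):
        # P=0 both, T=1/600 both: 1/2 * 2 * (0 - 1/600) = -1/600
        assert sttc(train(1.0), train(10.0)) == pytest.approx(-1 / 600)

    def test_coincident_pair_collapses_to_one(self):
        assert sttc(train(1.0), train(1.02)) == pytest.approx(1.0)

    def test_empty_train_undefined(self):
        assert np.isnan(sttc(train(), train(1.0)))

    def test_duration_mismatch_raises(self):
        with pytest.raises(InvalidParameterError):
            sttc(train(1.0), train(1.0, duration=30.0))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        a=st.lists(st.floats(0.1, 59.9), min_size=1, max_size=20),
        b=st.lists(st.floats(0.1, 59.9), min_size=1, max_size=20),
    )
    def test_symmetry_and_bounds(self, a, b):
        ta = SpikeTrain(np.sort(a), 60.0)
        tb = SpikeTrain(np.sort(b), 60.0)
        v1, v2 = sttc(ta, tb), sttc(tb, ta)
        if np.isnan(v1):
            assert np.isnan(v2)
        else:
            assert v1 == v2
            assert -1.0 <= v1 <= 1.0

    def test_time_shift_invariance(self, rng):
        for _ in range(20):
            a = random_train(rng, duration_s=50.0)
            b = random_train(rng, duration_s=50.0)
            a = SpikeTrain(a.times_s * 0.8 + 1.0, 50.0)  # keep away from edges
            b = SpikeTrain(b.times_s * 0.8 + 1.0, 50.0)
            v0 = sttc(a, b)
            v1 = sttc(a.shifted(3.0), b.shifted(3.0))
            assert v1 == pytest.approx(v0, abs=1e-12)

    def test_firing_rate_independence(self):
        """Independent Poisson pairs at very different rates still give
        mean STTC near zero — the design rationale for the statistic."""
        vals = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            a = SpikeTrain(np.sort(r.uniform(0, 300, r.poisson(0.1 * 300))), 300.0)
            b = SpikeTrain(np.sort(r.uniform(0, 300, r.poisson(1.0 * 300))), 300.0)
            v = sttc(a, b)
            if not np.isnan(v):
                vals.append(v)
        assert abs(np.mean(vals)) <= 0.01


class TestAdjacencyMatrix:
    def test_identical_trains_all_one(self):
        tr = train(1.0, 2.0, 3.0)
        M = adjacency_matrix([tr, tr, tr])
        off = ~np.eye(3, dtype=bool)
        assert np.all(M[off] == 1.0)
        assert np.all(np.isnan(np.diag(M)))

    def test_empty_train_row_missing(self):
        M = adjacency_matrix([train(1.0), train(), train(2.0)])
        assert np.all(np.isnan(M[1]))
        assert np.all(np.isnan(M[:, 1]))
        assert not np.isnan(M[0, 2])

    def test_matches_pairwise_brute_force(self, rng):
        trains = [random_train(rng) for _ in range(20)]
        M = adjacency_matrix(trains)
        for i in range(20):
            for j in range(i + 1, 20):
                expected = sttc(trains[i], trains[j])
                if np.isnan(expected):
                    assert np.isnan(M[i, j])
                else:
                    assert M[i, j] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(M, M.T, equal_nan=True)


class TestTotalFlow:
    def test_hand_summed_strengths(self):
        M = np.full((3, 3), np.nan)
        M[0, 1] = M[1, 0] = 0.5
        M[0, 2] = M[2, 0] = 0.2
        M[1, 2] = M[2, 1] = 0.1
        strengths, _, _ = total_flow(M)
        assert strengths == pytest.approx([0.7, 0.6, 0.3])

    def test_strength_sum_identity(self, rng):
        M = rng.normal(size=(10, 10))
        M = (M + M.T) / 2
        strengths, _, _ = total_flow(M)
        np.fill_diagonal(M, 0.0)
        assert strengths.sum() == pytest.approx(
            2 * np.triu(M, k=1).sum(), rel=1e-12
        )

    def test_all_zero(self):
        strengths, hist, _ = total_flow(np.zeros((4, 4)))
        assert np.all(strengths == 0)
        assert hist.sum() == 4


class TestGroupMeanCI:
    def _labels(self, arc, neun=None, cfos=None):
        n = len(arc)
        return pd.DataFrame(
            {
                "neun_pos": neun if neun is not None else [True] * n,
                "arc_pos": arc,
                "cfos_pos": cfos if cfos is not None else [False] * n,
            }
        )

    def test_toy_hand_computed(self):
        # neurons 0,1 Arc+; 2,3 Arc-
        M = np.full((4, 4), np.nan)
        vals = {(0, 1): 0.8, (0, 2): 0.3, (0, 3): 0.1, (1, 2): 0.5, (1, 3): 0.3, (2, 3): 0.2}
        for (i, j), v in vals.items():
            M[i, j] = M[j, i] = v
        out = group_mean_ci(M, self._labels([True, True, False, False]))
        means = dict(zip(out["pair_set"], out["mean_ci"]))
        assert means["Arc-Arc"] == pytest.approx(0.8)
        assert means["Arc-NeuN"] == pytest.approx((0.3 + 0.1 + 0.5 + 0.3) / 4)
        assert means["NeuN-NeuN"] == pytest.approx(0.2)

    def test_single_group_only_intra_defined(self):
        M = np.full((3, 3), 0.4)
        np.fill_diagonal(M, np.nan)
        with pytest.warns(UserWarning):
            out = group_mean_ci(M, self._labels([True, True, True]))
        means = dict(zip(out["pair_set"], out["mean_ci"]))
        assert means["Arc-Arc"] == pytest.approx(0.4)
        assert np.isnan(means["Arc-NeuN"]) and np.isnan(means["NeuN-NeuN"])

    def test_arc_cfos_emits_ten_pair_sets(self):
        arc = [True, True, False, False, True, False, False, True]
        cfos = [True, False, True, False, True, True, False, False]
        M = np.random.default_rng(0).uniform(0, 1, (8, 8))
        M = (M + M.T) / 2
        out = group_mean_ci(M, self._labels(arc, cfos=cfos), grouping="arc_cfos")
        assert len(out) == 10
        assert out["n_pairs"].sum() == 8 * 7 // 2


class TestChangeClassification:
    def test_band_crossing_rules(self):
        Mb = np.array([[np.nan, 0.2, 0.7, 0.3], [0.2, np.nan, 0.1, 0.9],
                       [0.7, 0.1, np.nan, 0.6], [0.3, 0.9, 0.6, np.nan]])
        Ma = np.array([[np.nan, 0.7, 0.2, 0.4], [0.7, np.nan, 0.2, 0.95],
                       [0.2, 0.2, np.nan, 0.1], [0.4, 0.95, 0.1, np.nan]])
        rec = classify_correlation_changes(Mb, Ma)
        cls = {(r.i, r.j): r.change_class for r in rec.itertuples()}
        assert cls[(0, 1)] == "positive"  # 0.2 -> 0.7
        assert cls[(0, 2)] == "negative"  # 0.7 -> 0.2
        assert cls[(0, 3)] == "none"      # 0.3 -> 0.4
        assert cls[(1, 3)] == "none"      # stays high
        assert cls[(2, 3)] == "negative"  # 0.6 -> 0.1

    def test_arc_fraction_curve_hand_counted(self):
        rec = pd.DataFrame(
            {
                "i": [0, 0, 1, 2],
                "j": [1, 2, 2, 3],
                "ci_before": [0.1, 0.2, 0.3, 0.7],
                "ci_after": [0.9, 0.6, 0.55, 0.2],
                "change_class": ["positive", "positive", "positive", "negative"],
                "pair_type": ["Arc-Arc", "Arc-NeuN", "Arc-Arc", "NeuN-NeuN"],
            }
        )
        curve = arc_pair_fraction_vs_threshold(rec, thresholds=[0.0, 0.58, 0.95])
        pos = curve[curve["change_class"] == "positive"].set_index("threshold")
        assert pos.loc[0.0, "arc_arc_fraction"] == pytest.approx(2 / 3)
        assert pos.loc[0.58, "arc_arc_fraction"] == pytest.approx(1 / 2)
        assert np.isnan(pos.loc[0.95, "arc_arc_fraction"])
        neg = curve[curve["change_class"] == "negative"].set_index("threshold")
        assert neg.loc[0.0, "arc_arc_fraction"] == 0.0

    def test_all_arc_pairs_fraction_one(self):
        rec = pd.DataFrame(
            {
                "ci_before": [0.1, 0.2],
                "ci_after": [0.8, 0.9],
                "change_class": ["positive", "positive"],
                "pair_type": ["Arc-Arc", "Arc-Arc"],
            }
        )
        curve = arc_pair_fraction_vs_threshold(rec, thresholds=[0.0, 0.5])
        pos = curve[curve["change_class"] == "positive"]
        assert (pos["arc_arc_fraction"] == 1.0).all()


class TestDistances:
    def test_pixel_scaling(self):
        d = pair_distances(np.array([[0, 0], [3, 4]]), pixel_size_um=0.8)
        assert d[0, 1] == pytest.approx(4.0)
        assert d[0, 0] == 0.0

    def test_toy_matrix(self):
        pts = np.array([[0, 0], [6, 8], [0, 5]])
        d = pair_distances(pts, pixel_size_um=1.0)
        expected = np.array([[0, 10, 5], [10, 0, np.hypot(6, 3)], [5, np.hypot(6, 3), 0]])
        assert np.allclose(d, expected)

    def test_by_pair_type_grouping(self):
        labels = pd.DataFrame(
            {"neun_pos": [True] * 3, "arc_pos": [True, True, False], "cfos_pos": [False] * 3}
        )
        d = pair_distances(np.array([[0, 0], [3, 4], [0, 10]]), pixel_size_um=1.0)
        out = distance_by_pair_type(d, labels).set_index("pair_type")
        assert out.loc["Arc-Arc", "mean_distance_um"] == pytest.approx(5.0)
        assert out.loc["Arc-NeuN", "n_pairs"] == 2


class TestDensityDistribution:
    def test_integrates_to_one(self, rng):
        density, edges = density_distribution(rng.normal(size=500), bins=17)
        assert np.sum(density * np.diff(edges)) == pytest.approx(1.0)

    def test_constant_values_single_bin(self):
        density, edges = density_distribution(np.full(50, 3.0), bins=5)
        assert np.sum(density * np.diff(edges)) == pytest.approx(1.0)
        assert np.count_nonzero(density) == 1

    def test_uniform_samples_flat(self):
        r = np.random.default_rng(42)
        x = r.uniform(0, 1, 4000)
        density, edges = density_distribution(x, bins=np.linspace(0, 1, 11))
        counts = density * np.diff(edges) * len(x)
        chi2 = np.sum((counts - 400) ** 2 / 400)
        assert stats.chi2.sf(chi2, df=9) > 0.01
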