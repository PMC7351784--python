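"""nRMSE scoring, error maps, side correction and statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from gaitsynth import (
    ErrorMap,
    build_error_map,
    correct_sides,
    error_levels,
    match_events,
    nrmse,
    rank_sum_test,
    rmse_count,
    select_extreme_sensors,
    spearman_rho,
)
from gaitsynth.evaluation import MatchedStrides, aggregate_rmse, mirror_sx
from gaitsynth.layout import SensorLayout, SensorSpec


def _matched(m, c):
    return MatchedStrides(sensor_durations_ms=np.asarray(m, dtype=float),
                          reference_durations_ms=np.asarray(c, dtype=float),
                          event_pairs=np.empty((0, 2)))


class TestMatchEvents:
    def test_identical_lists_fully_matched(self):
        ev = np.array([0.5, 1.5, 2.5, 3.5])
        m = match_events(ev, ev)
        assert m.unmatched_sensor == 0 and m.unmatched_reference == 0
        assert np.allclose(m.sensor_durations_ms, 1000.0)
        assert np.allclose(m.reference_durations_ms, 1000.0)

    def test_extra_spurious_event_left_unmatched(self):
        ref = np.array([1.0, 2.0, 3.0])
        sens = np.array([1.0, 1.5, 2.0, 3.0])
        m = match_events(sens, ref)
        assert m.unmatched_sensor == 1
        assert np.allclose(m.sensor_durations_ms, [1000.0, 1000.0])

    def test_matches_brute_force_on_small_lists(self, rng):
        """Greedy nearest-neighbour matching equals exhaustive pairing by
        increasing |dt| on lists of <= 10 events."""
        for _ in range(20):
            ref = np.sort(rng.uniform(0, 10, size=rng.integers(2, 6)))
            sens = np.sort(rng.uniform(0, 10, size=rng.integers(2, 6)))
            window = 0.5 * float(np.median(np.diff(ref))) if len(ref) > 1 else 1.0
            pairs = sorted(
                ((abs(s - r), i, j) for i, s in enumerate(sens) for j, r in enumerate(ref)
                 if abs(s - r) <= window),
                key=lambda p: (p[0], p[2], p[1]))
            used_i, used_j, want = set(), set(), {}
            for _, i, j in pairs:
                if i in used_i or j in used_j:
                    continue
                used_i.add(i); used_j.add(j); want[j] = i
            if not want:
                with pytest.raises(ValueError):
                    match_events(sens, ref)
                continue
            got = match_events(sens, ref)
            got_pairs = {tuple(p) for p in got.event_pairs}
            want_pairs = {(sens[i], ref[j]) for j, i in want.items()}
            assert got_pairs == want_pairs

    def test_disjoint_ranges_error(self):
        with pytest.raises(ValueError):
            match_events(np.array([100.0, 101.0]), np.array([1.0, 2.0, 3.0]))


class TestNrmse:
    def test_perfect_match_zero(self):
        assert nrmse(_matched([800, 810], [800, 810])) == 0.0

    def test_single_pair_ten_percent(self):
        assert nrmse(_matched([1100.0], [1000.0])) == pytest.approx(10.0)

    def test_scale_invariance(self, rng):
        m = rng.uniform(700, 900, 6)
        c = rng.uniform(700, 900, 6)
        assert nrmse(_matched(3.7 * m, 3.7 * c)) == pytest.approx(nrmse(_matched(m, c)))

    def test_zero_reference_mean_rejected(self):
        with pytest.raises(ValueError):
            nrmse(_matched([1.0], [0.0]))


class TestCounts:
    def test_equal_counts(self):
        assert rmse_count(10, 10) == 0

    def test_aggregate_over_trials(self):
        assert aggregate_rmse([1, -1]) == pytest.approx(1.0)
        assert aggregate_rmse([0, 0, 0]) == 0.0


@pytest.fixture()
def tiny_layout():
    sensors = [
        SensorSpec(id=f"upper_leg_{side}_R{r}S{sx}", segment="upper_leg", side=side,
                   ring=r, sx=sx, axial_fraction=0.2 * r, angle_deg=(sx - 1) * 22.5,
                   radius_m=0.06)
        for side in ("R", "L") for r in (1, 2) for sx in (1, 2)
    ]
    return SensorLayout(name="tiny", sensors=sensors)


class TestErrorMap:
    def test_uniform_scores(self, tiny_layout):
        scores = {s.id: 5.0 for s in tiny_layout}
        maps = build_error_map(tiny_layout, scores)
        for emap in maps.values():
            assert np.allclose(emap.values(), 5.0)

    def test_missing_sensor_flagged_nan(self, tiny_layout):
        scores = {s.id: 2.0 for s in tiny_layout if s.id != "upper_leg_R_R1S1"}
        maps = build_error_map(tiny_layout, scores)
        tab = maps[("upper_leg", "R")].table
        missing = tab[(tab.ring == 1) & (tab.sx == 1)]["nrmse_pct"]
        assert np.isnan(missing).all()

    def test_csv_round_trip_lossless(self, tiny_layout, tmp_path, rng):
        scores = {s.id: float(rng.uniform(0, 30)) for s in tiny_layout}
        maps = build_error_map(tiny_layout, scores)
        emap = maps[("upper_leg", "L")]
        path = tmp_path / "map.csv"
        emap.to_csv(path)
        again = ErrorMap.from_csv(path)
        pd.testing.assert_frame_equal(emap.table, again.table)
        assert (again.segment, again.side) == (emap.segment, emap.side)


class TestErrorLevels:
    def test_one_value_per_level(self):
        assert error_levels([0.5, 3.0, 7.0]) == {
            "below_1pct": 1, "1_to_5pct": 1, "above_5pct": 1, "le_10pct": 3}

    def test_boundary_conventions(self):
        levels = error_levels([1.0, 5.0, 10.0, 10.001])
        assert levels["below_1pct"] == 0
        assert levels["1_to_5pct"] == 2  # both 1.0 and 5.0 inclusive
        assert levels["above_5pct"] == 2
        assert levels["le_10pct"] == 3

    def test_matches_oracle_loop(self, rng):
        vals = rng.uniform(0, 20, 500)
        got = error_levels(vals)
        want = {"below_1pct": 0, "1_to_5pct": 0, "above_5pct": 0, "le_10pct": 0}
        for v in vals:
            if v < 1:
                want["below_1pct"] += 1
            elif v <= 5:
                want["1_to_5pct"] += 1
            else:
                want["above_5pct"] += 1
            if v <= 10:
                want["le_10pct"] += 1
        assert got == want


class TestExtremeSensors:
    def test_single_sensor_both(self, tiny_layout):
        one = SensorLayout(name="one", sensors=[tiny_layout.sensors[0]])
        sid = one.sensors[0].id
        assert select_extreme_sensors({sid: 4.0}, one) == (sid, sid)

    def test_tie_broken_lexicographically(self, tiny_layout):
        scores = {s.id: 1.0 for s in tiny_layout}
        best, worst = select_extreme_sensors(scores, tiny_layout)
        assert best == "upper_leg_L_R1S1"  # side is the last tie-break key
        assert worst == best

    def test_matches_exhaustive_scan(self, tiny_layout, rng):
        scores = {s.id: float(rng.uniform(0, 50)) for s in tiny_layout}
        best, worst = select_extreme_sensors(scores, tiny_layout)
        assert scores[best] == min(scores.values())
        assert scores[worst] == max(scores.values())


class TestCorrectSides:
    def _maps(self, values_by_side):
        out = {}
        for side, vals in values_by_side.items():
            rows = [dict(ring=1, sx=sx, nrmse_pct=v, n_pairs=5)
                    for sx, v in enumerate(vals, start=1)]
            out[side] = ErrorMap(segment="upper_leg", side=side, table=pd.DataFrame(rows))
        return out

    def test_all_affected_right_equals_right_aggregate(self):
        subjects = {f"s{i}": self._maps({"right": [float(i + 1)] * 4,
                                         "left": [0.0] * 4}) for i in range(3)}
        labels = {f"s{i}": "right" for i in range(3)}
        out = correct_sides(subjects, labels)
        assert np.allclose(out["affected"].table["nrmse_pct"], 2.0)  # mean of 1, 2, 3
        assert np.allclose(out["less_affected"].table["nrmse_pct"], 0.0)

    def test_flipping_labels_swaps_groups(self):
        subjects = {f"s{i}": self._maps({"right": [float(i)] * 4,
                                         "left": [10.0 + i] * 4}) for i in range(3)}
        right = correct_sides(subjects, {f"s{i}": "right" for i in range(3)})
        left = correct_sides(subjects, {f"s{i}": "left" for i in range(3)})
        assert np.allclose(right["affected"].table["nrmse_pct"],
                           left["less_affected"].table["nrmse_pct"])
        assert np.allclose(right["less_affected"].table["nrmse_pct"],
                           left["affected"].table["nrmse_pct"])

    def test_mixed_labels_match_manual_regrouping(self, rng):
        vals = {f"s{i}": {"right": list(rng.uniform(0, 20, 16)),
                          "left": list(rng.uniform(0, 20, 16))} for i in range(3)}
        subjects = {k: self._maps(d) for k, d in vals.items()}
        labels = {"s0": "right", "s1": "left", "s2": "right"}
        out = correct_sides(subjects, labels)
        # affected group: s0 right (as-is), s1 left (mirrored), s2 right (as-is)
        s1_mirr = {mirror_sx(sx): v for sx, v in enumerate(vals["s1"]["left"], start=1)}
        for sx in range(1, 17):
            cell = out["affected"].table
            got = float(cell[cell.sx == sx]["nrmse_pct"].iloc[0])
            manual = np.mean([vals["s0"]["right"][sx - 1], s1_mirr[sx],
                              vals["s2"]["right"][sx - 1]])
            assert got == pytest.approx(manual)

    def test_mirror_sx_fixed_points(self):
        assert mirror_sx(1) == 1
        assert mirror_sx(2) == 16
        assert mirror_sx(9) == 9
        assert [mirror_sx(mirror_sx(i)) for i in range(1, 17)] == list(range(1, 17))

    def test_unlabelled_subjects_excluded(self):
        subjects = {"a": self._maps({"right": [1.0] * 4, "left": [2.0] * 4}),
                    "b": self._maps({"right": [9.0] * 4, "left": [8.0] * 4})}
        out = correct_sides(subjects, {"a": "right", "b": "left"})
        assert set(out) == {"affected", "less_affected"}
        with pytest.raises(ValueError):
            correct_sides(subjects, {})


class TestRankSum:
    def test_identical_samples_not_significant(self):
        r = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_value >= 0.99
        assert not r.significant

    def test_fully_separated_exact_p(self):
        # most extreme of C(6,3) = 20 orderings, two-sided: p = 2/20
        r = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert r.method == "exact"
        assert r.p_value == pytest.approx(0.1)

    def test_exact_matches_enumeration_all_small_splits(self):
        """Every two-group split of 1..6 with n1 <= 6 agrees with direct
        enumeration of rank-sum tail probabilities."""
        values = np.arange(1.0, 7.0)
        for n1 in range(1, 6):
            for comb in itertools.combinations(range(6), n1):
                a = values[list(comb)]
                b = np.delete(values, list(comb))
                r = rank_sum_test(a, b)
                ranks = sstats.rankdata(np.concatenate([a, b]))
                w = ranks[:n1].sum()
                mu = n1 * 7 / 2.0
                total = math.comb(6, n1)
                count = sum(
                    1 for c in itertools.combinations(range(6), n1)
                    if abs(ranks[list(c)].sum() - mu) >= abs(w - mu) - 1e-12)
                assert r.p_value == pytest.approx(count / total)

    def test_normal_approximation_close_to_exact_at_n8(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.8, 1, 8)
        exact = rank_sum_test(a, b)
        assert exact.method == "exact"
        big = rank_sum_test(np.concatenate([a, [a.mean()]]), b)  # forces normal path
        assert big.method == "normal"
        # same data through scipy's asymptotic Mann-Whitney agrees closely
        scipy_p = sstats.mannwhitneyu(a, b, alternative="two-sided",
                                      method="asymptotic", use_continuity=False).pvalue
        assert abs(exact.p_value - scipy_p) < 0.01

    def test_ties_handled(self):
        r = rank_sum_test([1, 1, 2, 2], [2, 2, 3, 3])
        assert 0.0 < r.p_value <= 1.0

    def test_degenerate_all_equal(self):
        assert rank_sum_test([5, 5], [5, 5, 5]).p_value == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        x = np.arange(10.0)
        assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)

    def test_monotone_decreasing_is_minus_one(self):
        x = np.arange(10.0)
        assert spearman_rho(x, -(x**3)) == pytest.approx(-1.0)

    def test_matches_midrank_oracle_with_ties(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 12))
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, n).astype(float)
            rx, ry = sstats.rankdata(x), sstats.rankdata(y)
            if np.std(rx) == 0 or np.std(ry) == 0:
                with pytest.raises(ValueError):
                    spearman_rho(x, y)
                continue
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert spearman_rho(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])
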