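import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chemoquant import (
    ComputationError,
    FilterCriteria,
    GradientAxis,
    InputError,
    Track,
    compare_groups,
    directionality,
    filter_tracks,
    induced_transmigration,
    net_displacement,
    normalize_to_reference,
    path_length,
    select_analysis_window,
    summarize_group,
    velocity,
)

from .conftest import make_track


class TestTrackType:
    def test_needs_two_points(self):
        with pytest.raises(InputError):
            Track(id="a", group="g", points=np.array([[0.0, 0.0, 0.0]]))

    def test_time_strictly_increasing(self):
        pts = np.array([[0.0, 0, 0], [0.0, 1, 1]])
        with pytest.raises(InputError, match="increasing"):
            Track(id="a", group="g", points=pts)

    def test_non_finite_rejected(self):
        pts = np.array([[0.0, 0, 0], [1.0, np.nan, 1]])
        with pytest.raises(InputError):
            Track(id="a", group="g", points=pts)


class TestPathLength:
    def test_3_4_5(self):
        assert path_length(make_track([(0, 0), (3, 4)])) == 5.0

    def test_collinear(self):
        assert path_length(make_track([(0, 0), (1, 0), (2, 0)])) == 2.0

    def test_matches_bruteforce(self, rng):
        xy = rng.normal(size=(10, 2)) * 20
        tr = make_track(xy)
        # independent segment-wise recomputation
        expected = sum(
            math.sqrt((xy[i + 1, 0] - xy[i, 0]) ** 2 + (xy[i + 1, 1] - xy[i, 1]) ** 2)
            for i in range(9)
        )
        assert path_length(tr) == pytest.approx(expected, abs=1e-12)


class TestVelocity:
    def test_simple(self):
        assert velocity(make_track([(0, 0), (3, 4)])) == 5.0

    def test_two_minutes(self):
        tr = make_track([(0, 0), (12, 0), (24, 0)])  # dt = 1 min
        assert velocity(tr) == 12.0

    def test_constant_speed_construction(self, rng):
        # step length s*dt at any heading -> velocity == s
        s, dt = 7.5, 0.5
        headings = rng.uniform(0, 2 * np.pi, 40)
        steps = s * dt * np.column_stack([np.cos(headings), np.sin(headings)])
        xy = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
        assert velocity(make_track(xy, dt=dt)) == pytest.approx(s, abs=1e-9)

    def test_zero_duration_unconstructible(self):
        # strictly-increasing time makes zero-duration tracks impossible
        with pytest.raises(InputError):
            Track(id="b", group="g", points=np.array([[0.0, 0, 0], [0.0, 1, 0]]))


class TestDirectionality:
    def test_parallel_is_one(self, x_axis):
        assert directionality(make_track([(0, 0), (60, 0)]), x_axis) == 1.0

    def test_antiparallel_is_minus_one(self, x_axis):
        assert directionality(make_track([(0, 0), (-60, 0)]), x_axis) == -1.0

    def test_3_4_displacement(self, x_axis):
        assert directionality(make_track([(0, 0), (3, 4)]), x_axis) == pytest.approx(0.6)

    def test_perpendicular_is_zero(self, x_axis):
        assert directionality(make_track([(0, 0), (0, 5)]), x_axis) == pytest.approx(
            0.0, abs=1e-15
        )

    def test_zero_displacement_is_nan(self, x_axis):
        tr = make_track([(1, 1), (5, 5), (1, 1)])
        assert math.isnan(directionality(tr, x_axis))

    def test_zero_axis_rejected(self):
        with pytest.raises(InputError):
            GradientAxis(np.array([0.0, 0.0]))

    def test_sine_bearing_coincides(self, x_axis, rng):
        tr = make_track(rng.normal(size=(5, 2)))
        assert directionality(tr, x_axis, "sine_bearing") == directionality(tr, x_axis)

    def test_endpoints_only(self, x_axis):
        # a meandering middle does not change the index
        straight = make_track([(0, 0), (10, 0)])
        wiggly = make_track([(0, 0), (3, 9), (-4, -2), (10, 0)])
        assert directionality(wiggly, x_axis) == directionality(straight, x_axis)

    @pytest.mark.parametrize("seed", range(5))
    def test_rotation_translation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        xy = rng.normal(size=(8, 2)) * 30
        axis_vec = rng.normal(size=2)
        base = directionality(make_track(xy), GradientAxis(axis_vec))
        for _ in range(50):
            th = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            shift = rng.normal(size=2) * 100
            got = directionality(
                make_track(xy @ rot.T + shift), GradientAxis(rot @ axis_vec)
            )
            assert got == pytest.approx(base, abs=1e-9)

    def test_path_ge_net_displacement(self, rng):
        for _ in range(200):
            tr = make_track(rng.normal(size=(rng.integers(2, 12), 2)) * 10)
            assert path_length(tr) >= net_displacement(tr) - 1e-12


class TestFilterTracks:
    def test_volume_rejection(self):
        tr = make_track([(0, 0), (100, 0)], volume=10.0)
        retained, rej = filter_tracks([tr])
        assert not retained
        assert rej.iloc[0].tolist() == ["t0", "volume"]

    def test_static_rejection(self):
        tr = make_track([(0, 0), (5, 5), (0.5, 0)], volume=20.0)
        _, rej = filter_tracks([tr])
        assert rej.iloc[0]["reason"] == "static"

    def test_short_rejected_long_retained(self):
        short = make_track([(0, 0), (40, 0)], id="s", volume=20.0)
        long = make_track([(0, 0), (60, 0)], id="l", volume=20.0)
        retained, rej = filter_tracks([short, long])
        assert [t.id for t in retained] == ["l"]
        assert rej.iloc[0].tolist() == ["s", "short"]

    def test_missing_volume_skips_rule(self, caplog):
        tr = make_track([(0, 0), (100, 0)], volume=None)
        retained, _ = filter_tracks([tr])
        assert len(retained) == 1

    def test_first_applicable_reason_wins(self):
        # violates volume AND static AND short; order gives "volume"
        tr = make_track([(0, 0), (0.1, 0)], volume=1.0)
        _, rej = filter_tracks([tr])
        assert rej.iloc[0]["reason"] == "volume"
        _, rej2 = filter_tracks([tr], order=("static", "short", "volume"))
        assert rej2.iloc[0]["reason"] == "static"

    def test_six_track_fixture_matches_hand_check(self):
        crit = FilterCriteria()
        tracks = [
            make_track([(0, 0), (100, 0)], id="ok1", volume=20.0),
            make_track([(0, 0), (100, 0)], id="smallvol", volume=15.0),
            make_track([(0, 0), (30, 0), (1, 0)], id="static", volume=20.0),
            make_track([(0, 0), (45, 0)], id="short", volume=20.0),
            make_track([(0, 0), (60, 30)], id="ok2", volume=16.0),  # vol == thresh kept
            make_track([(0, 0), (20, 0), (0, 10)], id="short2", volume=20.0),
        ]
        # independent per-rule hand check
        expect_keep = {
            t.id
            for t in tracks
            if (t.volume is None or t.volume >= 16)
            and net_displacement(t) >= 2
            and path_length(t) >= 50
        }
        retained, rej = filter_tracks(tracks, crit)
        assert {t.id for t in retained} == expect_keep == {"ok1", "ok2"}
        assert len(retained) + len(rej) == len(tracks)

    def test_idempotent(self, rng):
        tracks = [
            make_track(rng.normal(size=(6, 2)) * rng.uniform(1, 60), id=f"t{i}",
                       volume=float(rng.uniform(5, 30)))
            for i in range(30)
        ]
        retained, _ = filter_tracks(tracks)
        again, rej = filter_tracks(retained)
        assert [t.id for t in again] == [t.id for t in retained]
        assert rej.empty

    def test_empty_input(self):
        retained, rej = filter_tracks([])
        assert retained == [] and rej.empty


class TestSelectAnalysisWindow:
    crit = FilterCriteria()

    def test_centered_hour_track_retained(self):
        pts = np.column_stack([np.arange(30.0, 91.0), np.arange(61.0), np.zeros(61)])
        tr = Track(id="mid", group="g", points=pts)
        assert select_analysis_window([tr], self.crit, (0.0, 120.0)) == [tr]

    def test_short_track_excluded(self):
        pts = np.column_stack([np.arange(55.0, 66.0), np.arange(11.0), np.zeros(11)])
        tr = Track(id="short", group="g", points=pts)
        assert select_analysis_window([tr], self.crit, (0.0, 120.0)) == []

    def test_mixed_fixture_matches_manual(self):
        def span_track(t0, t1, id):
            t = np.linspace(t0, t1, 25)
            return Track(id=id, group="g",
                         points=np.column_stack([t, t - t0, np.zeros(25)]))

        fixture = [
            span_track(30, 90, "a"),    # 60 min, mid 60 -> keep
            span_track(0, 60, "b"),     # mid 30, edge of central half -> keep
            span_track(0, 50, "c"),     # 50 min ok, mid 25 < 30 -> drop
            span_track(60, 120, "d"),   # mid 90, boundary -> keep
            span_track(28, 100, "e"),   # 72 min ok (<=72), mid 64 -> keep
            span_track(20, 95, "f"),    # 75 min > 72 -> drop
            span_track(40, 87, "g"),    # 47 min < 48 -> drop
            span_track(35, 95, "h"),    # keep
        ]
        # manual application of both rules
        manual = []
        for tr in fixture:
            dur = tr.t[-1] - tr.t[0]
            mid = (tr.t[0] + tr.t[-1]) / 2
            if 48 <= dur <= 72 and 30 <= mid <= 90:
                manual.append(tr.id)
        got = select_analysis_window(fixture, self.crit, (0.0, 120.0))
        assert sorted(t.id for t in got) == sorted(manual)
        assert {t.id for t in got} == {"a", "b", "d", "e", "h"}
        # sorted by descending path length
        lengths = [path_length(t) for t in got]
        assert lengths == sorted(lengths, reverse=True)

    def test_bad_span(self):
        with pytest.raises(InputError):
            select_analysis_window([], self.crit, (10.0, 10.0))


class TestSummarizeGroup:
    def test_constant(self):
        s = summarize_group([1, 1, 1], "g")
        assert (s.mean, s.sem, s.n) == (1.0, 0.0, 3)

    def test_zero_two(self):
        s = summarize_group([0, 2])
        assert s.mean == 1.0
        assert s.sem == pytest.approx(1.0)  # sd = sqrt(2), sem = sqrt(2)/sqrt(2)

    def test_matches_scipy(self, rng):
        v = rng.normal(3.0, 2.0, 100)
        s = summarize_group(v)
        assert s.mean == pytest.approx(np.mean(v), abs=1e-12)
        assert s.sem == pytest.approx(stats.sem(v), abs=1e-12)

    def test_empty_error(self):
        with pytest.raises(InputError):
            summarize_group([])


def _exact_ranksum_oracle(a, b):
    """Independent exact enumeration using Fractions and direct counting."""
    pooled = list(a) + list(b)
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    mu = Fraction(n1 * len(b), 2)
    u_obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2
    dev = abs(Fraction(u_obs) - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = sum(ranks[i] for i in combo) - n1 * (n1 + 1) / 2
        total += 1
        if abs(Fraction(u) - mu) >= dev - Fraction(1, 10**9):
            hits += 1
    return u_obs, hits / total


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        stat, p = compare_groups([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_separated_groups_u_zero(self):
        stat, p = compare_groups([1, 2, 3], [10, 11, 12])
        assert stat == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 6, rng.integers(3, 9)).astype(float)  # ties likely
        b = rng.integers(0, 6, rng.integers(3, 9)).astype(float)
        stat, p = compare_groups(a, b)
        stat_o, p_o = _exact_ranksum_oracle(a, b)
        assert stat == pytest.approx(stat_o)
        assert p == pytest.approx(p_o, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_matches_scipy_when_no_ties(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = rng.normal(0, 1, 7)
        b = rng.normal(0.5, 1, 6)
        stat, p = compare_groups(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_asymptotic_matches_scipy(self):
        rng = np.random.default_rng(3)
        a = np.round(rng.normal(0, 1, 30), 1)  # rounding induces ties
        b = np.round(rng.normal(0.4, 1, 25), 1)
        stat, p = compare_groups(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_t_test(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 15)
        stat, p = compare_groups(a, b, method="t_test")
        ref = stats.ttest_ind(a, b)
        assert (stat, p) == (pytest.approx(ref.statistic), pytest.approx(ref.pvalue))

    def test_small_n_error(self):
        with pytest.raises(InputError):
            compare_groups([1.0], [1.0, 2.0])


class TestTransmigration:
    def test_subtraction(self):
        assert induced_transmigration(100, 30) == 70

    def test_equal_gives_zero(self):
        assert induced_transmigration(42, 42) == 0

    def test_negative_result_allowed(self):
        assert induced_transmigration(10, 30) == -20

    def test_negative_input_rejected(self):
        with pytest.raises(InputError):
            induced_transmigration(-1, 0)

    def test_four_well_table(self):
        total = [120.0, 90.0, 60.0, 80.0]
        rand = [20.0, 25.0, 15.0, 80.0]
        got = [induced_transmigration(t, r) for t, r in zip(total, rand)]
        assert got == [t - r for t, r in zip(total, rand)] == [100, 65, 45, 0]


class TestNormalizeToReference:
    def test_simple(self):
        df = pd.DataFrame({"group": ["wt", "wt", "ko", "ko"],
                           "value": [2.0, 2.0, 1.0, 3.0]})
        out = normalize_to_reference(df, "wt")
        assert out.loc[out.group == "ko", "normalized"].tolist() == [0.5, 1.5]

    def test_reference_mean_is_one(self, rng):
        df = pd.DataFrame({"group": ["wt"] * 10 + ["ko"] * 8,
                           "value": rng.uniform(1, 5, 18)})
        out = normalize_to_reference(df, "wt")
        assert out.loc[out.group == "wt", "normalized"].mean() == pytest.approx(1.0)

    def test_mixed_fixture_matches_hand_division(self):
        df = pd.DataFrame({"group": ["a", "a", "b"], "value": [4.0, 8.0, 3.0]})
        out = normalize_to_reference(df, "a")  # ref mean 6
        assert out["normalized"].tolist() == pytest.approx([4 / 6, 8 / 6, 0.5])

    def test_missing_reference(self):
        df = pd.DataFrame({"group": ["a"], "value": [1.0]})
        with pytest.raises(InputError):
            normalize_to_reference(df, "zz")

    def test_zero_reference_mean(self):
        df = pd.DataFrame({"group": ["a", "b"], "value": [0.0, 1.0]})
        with pytest.raises(ComputationError):
            normalize_to_reference(df, "a")
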