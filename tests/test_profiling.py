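"""Blank correction and the four functional diversity indices."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecoplate import (
    awcd,
    blank_correct,
    diversity_trajectory,
    guild_profile,
    mcintosh_index,
    shannon_index,
    simpson_index,
    substrate_heatmap_matrix,
)
from ecoplate.errors import ValidationError
from ecoplate.plate_io import GUILDS, PlateTimeSeries, all_well_ids


def _plate_from_diffs(layout, diff_by_substrate, blank=0.05, times=(24.0,)):
    """Construct a plate whose blank-corrected value per substrate is known."""
    od = pd.DataFrame(index=all_well_ids(), columns=list(times), dtype=float)
    for t in times:
        od[t] = blank
        for s, d in diff_by_substrate.items():
            for b, w in layout.substrate_wells(s).items():
                dv = d[b - 1] if isinstance(d, (tuple, list)) else d
                od.at[w, t] = blank + dv
    return PlateTimeSeries(sample_id="x", treatment="t", od=od)


class TestBlankCorrect:
    def test_simple_difference(self, layout):
        s = layout.substrates[0]
        ts = _plate_from_diffs(layout, {s: 0.5})
        prof = blank_correct(ts, layout)[0]
        i = prof.substrates.index(s)
        assert prof.ni[i] == pytest.approx(0.5, abs=1e-12)

    def test_equal_control_gives_zeros(self, layout):
        ts = _plate_from_diffs(layout, {})
        prof = blank_correct(ts, layout)[0]
        assert np.allclose(prof.ni, 0.0)

    def test_block_replicates_averaged(self, layout):
        s = layout.substrates[5]
        ts = _plate_from_diffs(layout, {s: (0.4, 0.5, 0.6)})
        prof = blank_correct(ts, layout)[0]
        assert prof.ni[prof.substrates.index(s)] == pytest.approx(0.5, abs=1e-12)

    def test_floor_preserves_raw(self, layout):
        s = layout.substrates[3]
        od = _plate_from_diffs(layout, {}).od
        # drive the three replicate wells below the control reading
        for b, w in layout.substrate_wells(s).items():
            od.loc[w] = 0.02
        ts = PlateTimeSeries(sample_id="x", treatment="t", od=od)
        prof = blank_correct(ts, layout)[0]
        i = prof.substrates.index(s)
        assert prof.ni[i] == 0.0
        assert prof.raw_diff[i] == pytest.approx(-0.03, abs=1e-12)
        unfloored = blank_correct(ts, layout, floor_at_zero=False)[0]
        assert unfloored.ni[i] == pytest.approx(-0.03, abs=1e-12)

    def test_missing_control_skips_time_point(self, layout):
        ts = _plate_from_diffs(layout, {layout.substrates[0]: 0.4}, times=(24.0, 48.0))
        ts.od.at[layout.control_well(2), 48.0] = np.nan
        with pytest.warns(UserWarning, match="48"):
            profs = blank_correct(ts, layout)
        assert [p.time for p in profs] == [24.0]


class TestIndices:
    def test_uniform_profile_closed_forms(self, make_profile):
        p = make_profile(np.ones(31))
        assert awcd(p) == pytest.approx(1.0, abs=1e-12)
        assert shannon_index(p) == pytest.approx(math.log(31), abs=1e-12)
        assert simpson_index(p) == pytest.approx(30 / 31, abs=1e-12)
        assert mcintosh_index(p, "paper") == pytest.approx(31.0, abs=1e-12)
        assert mcintosh_index(p, "sqrt") == pytest.approx(math.sqrt(31), abs=1e-12)

    def test_single_substrate(self, make_profile):
        ni = np.zeros(31)
        ni[4] = 0.7
        p = make_profile(ni)
        assert shannon_index(p) == pytest.approx(0.0, abs=1e-12)
        assert simpson_index(p) == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_substrates(self, make_profile):
        ni = np.zeros(31)
        ni[[2, 9]] = 0.4
        p = make_profile(ni)
        assert shannon_index(p) == pytest.approx(math.log(2), abs=1e-12)
        assert simpson_index(p) == pytest.approx(0.5, abs=1e-12)

    def test_three_four_five(self, make_profile):
        ni = np.zeros(31)
        ni[0], ni[1] = 3.0, 4.0
        p = make_profile(ni)
        assert mcintosh_index(p, "paper") == pytest.approx(25.0, abs=1e-12)
        assert mcintosh_index(p, "sqrt") == pytest.approx(5.0, abs=1e-12)

    def test_awcd_floored_vs_raw(self, make_profile):
        ni = np.full(31, 0.5)
        ni[-1] = 0.0
        raw = np.full(31, 0.5)
        raw[-1] = -0.1
        p = make_profile(ni, raw=raw)
        assert awcd(p) == pytest.approx(15.0 / 31, abs=1e-12)
        assert awcd(p, use_floored=False) == pytest.approx(14.9 / 31, abs=1e-12)

    def test_all_zero_profile_is_missing_not_zero(self, make_profile):
        p = make_profile(np.zeros(31))
        with pytest.warns(UserWarning):
            assert math.isnan(shannon_index(p))
        with pytest.warns(UserWarning):
            assert math.isnan(simpson_index(p))
        assert awcd(p) == 0.0
        assert mcintosh_index(p) == 0.0

    def test_oracle_equivalence_loop_vs_vectorized(self, make_profile):
        """1,000 random profiles: per-element loop arithmetic agrees to 1e-12."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            ni = rng.uniform(0, 2, size=31) * rng.integers(0, 2, size=31)
            if ni.sum() == 0:
                ni[0] = 0.5
            p = make_profile(ni)
            total = sum(ni)
            h = d2 = u = 0.0
            for v in ni:
                pi = v / total
                if pi > 0:
                    h -= pi * math.log(pi)
                d2 += pi * pi
                u += v * v
            assert abs(awcd(p) - total / 31) < 1e-12
            assert abs(shannon_index(p) - h) < 1e-12
            assert abs(simpson_index(p) - (1 - d2)) < 1e-12
            assert abs(mcintosh_index(p) - u) < 1e-12

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        c=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_invariance(self, make_profile, seed, c):
        """H and D ignore scaling; AWCD scales as c, U (paper form) as c^2."""
        rng = np.random.default_rng(seed)
        ni = rng.uniform(0.01, 2, size=31)
        p, pc = make_profile(ni), make_profile(c * ni)
        assert shannon_index(pc) == pytest.approx(shannon_index(p), rel=1e-9)
        assert simpson_index(pc) == pytest.approx(simpson_index(p), rel=1e-9)
        assert awcd(pc) == pytest.approx(c * awcd(p), rel=1e-9)
        assert mcintosh_index(pc) == pytest.approx(c**2 * mcintosh_index(p), rel=1e-9)

    def test_bounds_and_uniform_attainment(self, make_profile):
        rng = np.random.default_rng(7)
        for _ in range(200):
            ni = rng.uniform(0, 1, 31)
            p = make_profile(ni)
            assert shannon_index(p) <= math.log(31) + 1e-12
            assert simpson_index(p) <= 30 / 31 + 1e-12
            assert mcintosh_index(p) >= 0

    def test_merging_mass_never_increases_shannon(self, make_profile):
        """Moving one well's mass onto another (majorization) lowers H."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            ni = rng.uniform(0.01, 1, 31)
            i, j = rng.choice(31, size=2, replace=False)
            merged = ni.copy()
            merged[i] += merged[j]
            merged[j] = 0.0
            h0 = shannon_index(make_profile(ni))
            h1 = shannon_index(make_profile(merged))
            assert h1 <= h0 + 1e-12


class TestTrajectory:
    def test_stable_archetype_plateau_shape(self, layout):
        from ecoplate.simulate import preset_study, simulate_plate

        cfg = preset_study()
        cfg.noise_sd = 0.0
        cfg.capacity_sd = 0.0
        s75 = [a for a in cfg.archetypes if a.name == "s75"][0]
        ts = simulate_plate(s75, cfg, "p", seed=0)
        traj = diversity_trajectory(ts, layout)
        a = traj["awcd"].to_numpy()
        assert np.all(np.diff(a) >= -1e-12)  # non-decreasing
        # plateau: last step much smaller than the largest step
        assert (a[-1] - a[-2]) < 0.1 * np.max(np.diff(a))

    def test_all_blank_plate(self, layout):
        od = pd.DataFrame(0.05, index=all_well_ids(), columns=[24.0, 48.0])
        ts = PlateTimeSeries(sample_id="b", treatment="t", od=od)
        with pytest.warns(UserWarning):
            traj = diversity_trajectory(ts, layout)
        assert np.allclose(traj["awcd"], 0.0)
        assert traj["shannon"].isna().all() and traj["simpson"].isna().all()

    def test_single_time_point(self, layout):
        od = pd.DataFrame(0.05, index=all_well_ids(), columns=[24.0])
        ts = PlateTimeSeries(sample_id="b", treatment="t", od=od)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj = diversity_trajectory(ts, layout)
        assert len(traj) == 1

    def test_mcintosh_form_recorded(self, layout, preset_exp):
        traj = diversity_trajectory(preset_exp.plates[0], layout, mcintosh_form="sqrt")
        assert (traj["mcintosh_form"] == "sqrt").all()


class TestGuilds:
    def test_uniform_means(self, make_profile, layout):
        gp = guild_profile(make_profile(np.ones(31)), layout)
        assert np.allclose(gp["mean_ni"], 1.0)
        assert gp["n_substrates"].sum() == 31

    def test_single_guild_active(self, make_profile, layout):
        prof = make_profile(np.ones(31))
        ni = np.where(prof.guilds == "carbohydrate", 1.0, 0.0)
        gp = guild_profile(make_profile(ni), layout)
        by = gp.set_index("guild")["mean_ni"]
        assert by["carbohydrate"] == pytest.approx(1.0)
        assert np.allclose(by.drop("carbohydrate"), 0.0)

    def test_partition_conservation(self, make_profile, layout):
        rng = np.random.default_rng(5)
        ni = rng.uniform(0, 1, 31)
        gp = guild_profile(make_profile(ni), layout)
        assert gp["sum_ni"].sum() == pytest.approx(ni.sum(), abs=1e-12)
        assert set(gp["guild"]) == set(GUILDS)


class TestHeatmapMatrix:
    def test_single_sample_single_time(self, layout, make_profile):
        rng = np.random.default_rng(9)
        diffs = dict(zip(layout.substrates, rng.uniform(0.1, 1, 31)))
        ts = _plate_from_diffs(layout, diffs)
        m = substrate_heatmap_matrix([ts], layout)
        assert len(m) == 31
        for s, v in diffs.items():
            assert m[m["substrate"] == s]["value"].iloc[0] == pytest.approx(v, abs=1e-9)

    def test_replicate_mean(self, layout):
        d0 = {s: 0.0 for s in layout.substrates}
        d1 = {s: 1.0 for s in layout.substrates}
        ts0 = _plate_from_diffs(layout, d0)
        ts1 = _plate_from_diffs(layout, d1)
        ts1.sample_id = "y"
        m = substrate_heatmap_matrix([ts0, ts1], layout)
        assert np.allclose(m["value"], 0.5)

    def test_rate_statistic(self, layout):
        s = layout.substrates[0]
        ts = _plate_from_diffs(layout, {s: 0.24}, times=(0.0, 24.0))
        ts.od.loc[:, 0.0] = 0.05  # flat at t=0 -> rate = 0.24/24 = 0.01
        m = substrate_heatmap_matrix([ts], layout, statistic="rate")
        v = m[m["substrate"] == s]["value"].iloc[0]
        assert v == pytest.approx(0.01, abs=1e-12)

    def test_guild_then_name_ordering(self, layout, preset_exp):
        m = substrate_heatmap_matrix(preset_exp.plates[:3], layout)
        one_t = m[m["time_h"] == 168.0]
        guild_seq = one_t["guild"].tolist()
        order = {g: i for i, g in enumerate(GUILDS)}
        assert guild_seq == sorted(guild_seq, key=order.get)


def test_unknown_mcintosh_form_rejected(make_profile):
    with pytest.raises(ValidationError):
        mcintosh_index(make_profile(np.ones(31)), form="cubic")
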