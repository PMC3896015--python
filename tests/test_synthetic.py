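from datetime import date

import numpy as np
import pytest

from bycatchrisk.geogrid import bin_position, field_sum, quarter_of
from bycatchrisk.synthetic_data import (
    EffortSimConfig,
    PopulationGeography,
    TrackSimConfig,
    make_scenario,
    simulate_effort,
    simulate_tracks,
)


def small_cfg(**kw):
    defaults = dict(n_turtles={"EP": 3}, duration_mean_days=60.0)
    defaults.update(kw)
    return TrackSimConfig(**defaults)


class TestSimulateTracks:
    def test_one_position_per_day_within_window(self):
        tracks = simulate_tracks(small_cfg(), seed=1)
        for tr in tracks:
            dates = [p.date for p in tr.points]
            assert len(dates) == len(set(dates)) == tr.duration_days
            assert (dates[-1] - dates[0]).days + 1 == len(dates)  # daily, no holes
            assert dates[0] >= date(1992, 1, 1) and dates[-1] <= date(2008, 12, 31)
            assert tr.population == "EP"

    def test_forced_short_duration_no_gaps(self):
        cfg = small_cfg(
            n_turtles={"EP": 1},
            duration_mean_days=10.0,
            duration_sigma=1e-6,  # degenerate sampler: duration pinned to 10
            gap_prob=0.0,
        )
        (tr,) = simulate_tracks(cfg, seed=5)
        assert len(tr) == 10
        assert tr.observation_dates == frozenset(p.date for p in tr.points)

    def test_durations_respect_truncation(self):
        tracks = simulate_tracks(TrackSimConfig(n_turtles={"EP": 60}), seed=2)
        for tr in tracks:
            assert 4 <= tr.duration_days <= 948

    def test_mean_duration_near_configured_target(self):
        """Monte-Carlo check of the duration sampler at the study sample size."""
        tracks = simulate_tracks(TrackSimConfig(), seed=11)  # 135 turtles
        mean = np.mean([tr.duration_days for tr in tracks])
        assert 209 * 0.75 <= mean <= 209 * 1.25

    def test_determinism(self):
        cfg = small_cfg()
        a = simulate_tracks(cfg, seed=9)
        b = simulate_tracks(cfg, seed=9)
        assert [(t.turtle_id, [(p.date, p.lat, p.lon) for p in t.points]) for t in a] == [
            (t.turtle_id, [(p.date, p.lat, p.lon) for p in t.points]) for t in b
        ]

    def test_seeds_differ(self):
        cfg = small_cfg()
        a = simulate_tracks(cfg, seed=1)
        b = simulate_tracks(cfg, seed=2)
        assert [p.lat for p in a[0].points] != [p.lat for p in b[0].points]

    def test_gaps_marked_unobserved(self):
        cfg = small_cfg(n_turtles={"EP": 30}, gap_prob=1.0, duration_mean_days=200.0)
        tracks = simulate_tracks(cfg, seed=3)
        n_gap_days = sum(len(tr) - len(tr.observation_dates) for tr in tracks)
        assert n_gap_days > 0
        # positions exist on gap days too (filter-style interpolation)
        assert all(len(tr) == tr.duration_days for tr in tracks)

    def test_positions_stay_in_envelope(self):
        tracks = simulate_tracks(small_cfg(n_turtles={"EP": 5, "WP": 5}), seed=4)
        from bycatchrisk.synthetic_data import EP_GEOGRAPHY, WP_GEOGRAPHY

        for tr in tracks:
            geo = EP_GEOGRAPHY if tr.population == "EP" else WP_GEOGRAPHY
            for p in tr.points:
                assert geo.lat_min <= p.lat <= geo.lat_max
                assert geo.lon_min <= p.lon <= geo.lon_max

    def test_infeasible_geography_rejected(self):
        with pytest.raises(ValueError, match="envelope"):
            PopulationGeography(
                "bad", 10.0, 275.0, ((0.0, 100.0),), -40.0, 25.0, 230.0, 300.0
            )


class TestSimulateEffort:
    def cfg(self, **kw):
        defaults = dict(
            lat_min=0.0, lat_max=10.0, lon_min=200.0, lon_max=210.0,
            hook_noise_sigma=0.0,
        )
        defaults.update(kw)
        return EffortSimConfig(**defaults)

    def test_zero_billfish_fraction_gives_only_tuna_rows(self):
        _, catch = simulate_effort(self.cfg(billfish_baseline=0.0), seed=1)
        assert set(catch["species_group"]) == {"tuna"}

    def test_uniform_hooks_total(self):
        hooks, _ = simulate_effort(self.cfg(baseline_hooks=100.0), seed=1)
        # 2x2 cells x 4 quarters x 100 hooks
        assert field_sum(hooks) == pytest.approx(4 * 4 * 100.0)

    def test_planted_hotspot_has_max_hooks(self):
        cfg = self.cfg(planted_hotspot=(2.5, 202.5, 3, 10.0))
        hooks, _ = simulate_effort(cfg, seed=1)
        best = max(hooks.items(), key=lambda kv: kv[1])[0]
        assert best == (bin_position(2.5, 202.5), 3)

    def test_catch_split_matches_configured_fraction(self):
        cfg = self.cfg(billfish_baseline=0.3)
        _, catch = simulate_effort(cfg, seed=1)
        pooled = catch.groupby("species_group")["tonnes"].sum()
        frac = pooled["billfish"] / pooled.sum()
        assert frac == pytest.approx(0.3)

    def test_coverage_mask_consistent(self):
        cfg = self.cfg(coverage_prob=0.5)
        hooks, catch = simulate_effort(cfg, seed=8)
        catch_keys = {
            (bin_position(r.lat_lo + 0.1, r.lon_lo + 0.1), r.quarter)
            for r in catch.itertuples(index=False)
        }
        assert catch_keys <= set(hooks.keys())
        assert len(hooks) < 16  # some cell-quarters masked

    def test_negative_baseline_rejected(self):
        with pytest.raises(ValueError):
            EffortSimConfig(baseline_hooks=-1.0)

    def test_determinism(self):
        cfg = self.cfg(hook_noise_sigma=0.4)
        a, ca = simulate_effort(cfg, seed=6)
        b, cb = simulate_effort(cfg, seed=6)
        assert a.values == b.values
        assert ca.equals(cb)


class TestScenarios:
    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            make_scenario("nope", 1)

    def test_planted_truth_recorded(self, planted_scenario_data):
        assert planted_scenario_data.planted_hotspot is not None
        cell, q = planted_scenario_data.planted_hotspot
        assert q in (1, 2, 3, 4)
        # the planted cell-quarter carries the maximum hooks by construction
        best = max(planted_scenario_data.hooks.items(), key=lambda kv: kv[1])[0]
        assert best == (cell, q)

    def test_null_overlap_seeds_differ(self):
        a = make_scenario("null_overlap", 1).generate()
        b = make_scenario("null_overlap", 2).generate()
        assert [p.lat for p in a.tracks[0].points] != [p.lat for p in b.tracks[0].points]

    def test_paper_like_populations_disjoint_at_cell_level(self):
        data = make_scenario("paper_like", 3).generate()
        cells = {"EP": set(), "WP": set()}
        for tr in data.tracks:
            for p in tr.points:
                cells[tr.population].add(bin_position(p.lat, p.lon))
        assert cells["EP"] and cells["WP"]
        assert not (cells["EP"] & cells["WP"])
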