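import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bycatchrisk.geogrid import CellIndex, QuarterlyField, field_sum
from bycatchrisk.interaction import interaction_index, relative_probability, top_hotspots

C0 = CellIndex(0.0, 200.0)
C1 = CellIndex(5.0, 200.0)


def brute_force_interaction(pt: QuarterlyField, pe: QuarterlyField) -> dict:
    """Independent oracle: explicit double loop over every cell-quarter."""
    keys = []
    for key in pt.keys():
        for other in pe.keys():
            if key == other:
                keys.append(key)
    denom = 0.0
    for key in keys:
        denom += pt[key] * pe[key]
    return {key: pt[key] * pe[key] / denom for key in keys}


def random_fields(rng, n_lat=4, n_lon=4):
    """A pair of random fields on <= 4x4 cells with random masks."""
    pt, pe = QuarterlyField(), QuarterlyField()
    for i in range(n_lat):
        for j in range(n_lon):
            cell = CellIndex(float(5 * i), float(200 + 5 * j))
            for q in (1, 2, 3, 4):
                if rng.random() > 0.3:
                    pt.set(cell, q, float(rng.random()))
                if rng.random() > 0.3:
                    pe.set(cell, q, float(rng.random()))
    return relative_probability(pt), relative_probability(pe)


class TestRelativeProbability:
    def test_two_cell_normalization(self):
        f = QuarterlyField({(C0, 1): 3.0, (C1, 1): 1.0})
        p = relative_probability(f)
        assert p[(C0, 1)] == pytest.approx(0.75)
        assert p[(C1, 1)] == pytest.approx(0.25)

    def test_uniform_field(self):
        f = QuarterlyField({(C0, q): 2.0 for q in (1, 2, 3, 4)})
        p = relative_probability(f)
        assert all(v == pytest.approx(0.25) for v in p.values.values())

    def test_output_sums_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            f = QuarterlyField(
                {(CellIndex(float(5 * i), 200.0), q): float(rng.random())
                 for i in range(6) for q in (1, 2, 3, 4)}
            )
            assert field_sum(relative_probability(f)) == pytest.approx(1.0, abs=1e-9)

    def test_mask_preserved(self):
        f = QuarterlyField({(C0, 1): 3.0})
        p = relative_probability(f)
        assert (C1, 1) not in p

    def test_rejects_degenerate_fields(self):
        with pytest.raises(ValueError, match="empty"):
            relative_probability(QuarterlyField())
        with pytest.raises(ValueError, match="zero"):
            relative_probability(QuarterlyField({(C0, 1): 0.0}))
        with pytest.raises(ValueError, match="negative"):
            relative_probability(QuarterlyField({(C0, 1): -1.0}))


class TestInteractionIndex:
    def test_two_cell_hand_example(self):
        pt = QuarterlyField({(C0, 1): 0.75, (C1, 1): 0.25})
        pe = QuarterlyField({(C0, 1): 0.25, (C1, 1): 0.75})
        surf = interaction_index(pt, pe)
        # products are {0.1875, 0.1875}; renormalized -> {0.5, 0.5}
        assert surf[(C0, 1)] == pytest.approx(0.5)
        assert surf[(C1, 1)] == pytest.approx(0.5)

    def test_uniform_effort_returns_renormalized_occupancy(self):
        pt = relative_probability(QuarterlyField({(C0, 1): 3.0, (C1, 1): 1.0}))
        pe = QuarterlyField({(C0, 1): 0.5, (C1, 1): 0.5})
        surf = interaction_index(pt, pe)
        assert surf[(C0, 1)] == pytest.approx(pt[(C0, 1)])

    def test_single_cell_support(self):
        surf = interaction_index(
            QuarterlyField({(C0, 1): 1.0}), QuarterlyField({(C0, 1): 1.0})
        )
        assert surf[(C0, 1)] == pytest.approx(1.0)

    def test_matches_brute_force_oracle_on_random_fields(self):
        """>= 100 random small masked fields agree with the double-loop oracle."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            pt, pe = random_fields(rng)
            surf = interaction_index(pt, pe)
            oracle = brute_force_interaction(pt, pe)
            assert surf.keys() == oracle.keys()
            for key, v in oracle.items():
                assert abs(surf[key] - v) < 1e-12

    def test_sums_to_one(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            pt, pe = random_fields(rng)
            assert field_sum(interaction_index(pt, pe)) == pytest.approx(1.0, abs=1e-9)

    @given(st.floats(min_value=1e-3, max_value=1e3), st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, a, b):
        rng = np.random.default_rng(3)
        pt, pe = random_fields(rng, 2, 2)
        base = interaction_index(pt, pe)
        scaled = interaction_index(
            relative_probability(pt.scaled(a)), relative_probability(pe.scaled(b))
        )
        for key, v in base.items():
            assert scaled[key] == pytest.approx(v, rel=1e-9)

    def test_monotone_response_to_joint_intensity(self):
        raw_t = QuarterlyField({(C0, 1): 1.0, (C1, 1): 1.0})
        raw_e = QuarterlyField({(C0, 1): 1.0, (C1, 1): 1.0})
        base = interaction_index(relative_probability(raw_t), relative_probability(raw_e))
        raw_t.set(C0, 1, 2.0)
        raw_e.set(C0, 1, 2.0)
        bumped = interaction_index(relative_probability(raw_t), relative_probability(raw_e))
        assert bumped[(C0, 1)] > base[(C0, 1)]
        assert bumped[(C1, 1)] < base[(C1, 1)]

    def test_mask_intersection(self):
        pt = QuarterlyField({(C0, 1): 0.6, (C1, 1): 0.4})
        pe = QuarterlyField({(C0, 1): 1.0})
        surf = interaction_index(pt, pe)
        assert set(surf.keys()) == {(C0, 1)}

    def test_empty_joint_support_rejected(self):
        pt = QuarterlyField({(C0, 1): 1.0})
        pe = QuarterlyField({(C1, 1): 1.0})
        with pytest.raises(ValueError, match="joint support"):
            interaction_index(pt, pe)


class TestTopHotspots:
    def surface(self):
        return QuarterlyField(
            {(C0, 1): 0.5, (C1, 1): 0.3, (C0, 2): 0.15, (C1, 2): 0.05}
        )

    def test_descending_order_and_rank(self):
        table = top_hotspots(self.surface(), k=2)
        assert list(table["value"]) == [0.5, 0.3]
        assert list(table["rank"]) == [1, 2]

    def test_k_larger_than_support_returns_all(self):
        table = top_hotspots(self.surface(), k=100)
        assert len(table) == 4
        assert math.fsum(table["value"]) == pytest.approx(1.0)

    def test_deterministic_tie_break(self):
        surf = QuarterlyField({(C1, 2): 0.25, (C0, 2): 0.25, (C1, 1): 0.25, (C0, 1): 0.25})
        table = top_hotspots(surf, k=4)
        # ties broken by (quarter, lat_lo, lon_lo) ascending
        assert list(zip(table["quarter"], table["lat_lo"])) == [
            (1, 0.0), (1, 5.0), (2, 0.0), (2, 5.0),
        ]

    def test_quantile_selection(self):
        table = top_hotspots(self.surface(), q=0.75)
        assert list(table["value"]) == [0.5]

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            top_hotspots(self.surface())
        with pytest.raises(ValueError):
            top_hotspots(self.surface(), k=2, q=0.5)
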