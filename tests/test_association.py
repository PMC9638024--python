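"""Same-channel discounting, neighbor graph and group extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palmcensus import (
    AnalysisParams,
    Field,
    GroupingOrder,
    build_neighbor_graph,
    extract_groups,
    merge_same_channel,
    order_robustness,
)

from conftest import random_field
from _oracles import brute_force_edges, union_find_components, violating_same_channel_pairs


def make_field(points, channels):
    return Field(
        ids=np.arange(len(points)),
        channels=np.asarray(channels, dtype=np.uint8),
        xy=np.asarray(points, dtype=float),
        width=7000.0,
        height=7000.0,
    )


class TestParams:
    def test_radius_ordering_enforced(self):
        with pytest.raises(ValueError):
            AnalysisParams(merge_radius=60.0, search_radius=50.0)

    def test_class_boundary_consistency(self):
        with pytest.raises(ValueError):
            AnalysisParams(low_order_max=5, higher_order_min=7)


class TestMergeSameChannel:
    def test_close_same_channel_pair_keeps_lower_id(self):
        f = make_field([[100, 100], [103, 104]], [0, 0])
        m = merge_same_channel(f)
        assert list(m.ids) == [0]

    def test_cross_channel_pair_retained(self):
        f = make_field([[100, 100], [103, 104]], [0, 1])
        assert len(merge_same_channel(f)) == 2

    def test_pair_exactly_at_radius_survives(self):
        """The discounting rule is 'within 10 nm', read strictly."""
        f = make_field([[100, 100], [110, 100]], [0, 0])
        assert len(merge_same_channel(f)) == 2

    def test_random_fields_audit_and_idempotence(self, rng):
        params = AnalysisParams()
        for _ in range(10):
            f = random_field(rng, 200, width=1500.0)
            m = merge_same_channel(f, params)
            assert not violating_same_channel_pairs(
                m.xy, m.channels, params.merge_radius
            )
            again = merge_same_channel(m, params)
            assert again.equals(m)
            # survivors keep their original coordinates and ids
            assert set(m.ids) <= set(f.ids)


class TestNeighborGraph:
    @pytest.mark.parametrize("gap,expect", [(49.0, 1), (50.0, 1), (51.0, 0)])
    def test_search_radius_is_closed_at_50nm(self, gap, expect):
        f = make_field([[100, 100], [100 + gap, 100]], [0, 1])
        assert build_neighbor_graph(f).n_edges == expect

    def test_single_point_has_empty_graph(self):
        g = build_neighbor_graph(make_field([[5, 5]], [0]))
        assert g.n_edges == 0 and g.degree(0) == 0

    def test_matches_brute_force_on_random_fields(self, rng):
        params = AnalysisParams()
        for _ in range(20):
            f = random_field(rng, int(rng.integers(2, 120)), width=1000.0)
            g = build_neighbor_graph(f, params)
            got = {
                frozenset((i, j)) for i, nb in g.adjacency.items() for j in nb
            }
            assert got == brute_force_edges(f.xy, f.ids, params.search_radius)


class TestExtractGroups:
    def test_isolated_point_is_singleton(self):
        f = make_field([[100, 100]], [0])
        groups = extract_groups(build_neighbor_graph(f), f)
        assert len(groups) == 1 and groups[0].size == 1

    def test_chain_closes_transitively(self):
        """A-B 40 nm, B-C 40 nm, A-C 80 nm: one group under full closure."""
        f = make_field([[0, 0], [40, 0], [80, 0]], [0, 1, 0])
        groups = extract_groups(build_neighbor_graph(f), f)
        assert len(groups) == 1
        assert groups[0].member_ids == frozenset({0, 1, 2})
        assert (groups[0].n_a, groups[0].n_b) == (2, 1)

    def test_full_closure_equals_union_find(self, rng):
        params = AnalysisParams()
        for _ in range(15):
            f = random_field(rng, int(rng.integers(1, 150)), width=1200.0)
            g = build_neighbor_graph(f, params)
            got = {gr.member_ids for gr in extract_groups(g, f, params)}
            edges = brute_force_edges(f.xy, f.ids, params.search_radius)
            assert got == union_find_components(f.ids, edges)

    def test_partition_property(self, rng):
        for _ in range(10):
            f = random_field(rng, int(rng.integers(0, 200)), width=1500.0)
            groups = extract_groups(build_neighbor_graph(f), f)
            seen = [i for g in groups for i in g.member_ids]
            assert sorted(seen) == sorted(int(i) for i in f.ids)

    def test_second_order_stops_at_two_breadth_levels(self):
        """A 5-point chain at 40 nm: seed 0 reaches ids {0,1,2} only."""
        f = make_field([[40 * k, 0] for k in range(5)], [0] * 5)
        params = AnalysisParams(grouping_order=GroupingOrder.second_order)
        groups = extract_groups(build_neighbor_graph(f, params), f, params)
        assert [sorted(g.member_ids) for g in groups] == [[0, 1, 2], [3, 4]]

    def test_search_radius_monotonicity(self, rng):
        """Enlarging the search radius never splits a group."""
        f = random_field(rng, 150, width=1200.0)
        small = AnalysisParams(search_radius=40.0)
        large = AnalysisParams(search_radius=60.0)
        gs = extract_groups(build_neighbor_graph(f, small), f, small)
        gl = extract_groups(build_neighbor_graph(f, large), f, large)
        member_of_large = {i: g.member_ids for g in gl for i in g.member_ids}
        for g in gs:
            targets = {member_of_large[i] for i in g.member_ids}
            assert len(targets) == 1  # each small group inside one large group


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.floats(0.0, 1000.0, allow_nan=False),
            st.floats(0.0, 1000.0, allow_nan=False),
            st.integers(0, 1),
        ),
        max_size=60,
    )
)
def test_pipeline_invariants_hold_on_arbitrary_fields(pts):
    """Merge leaves no violating pair and grouping partitions the field,
    for arbitrary point configurations (including exact duplicates)."""
    f = make_field(
        [[x, y] for x, y, _ in pts] or np.empty((0, 2)),
        [c for _, _, c in pts],
    )
    params = AnalysisParams()
    m = merge_same_channel(f, params)
    assert not violating_same_channel_pairs(m.xy, m.channels, params.merge_radius)
    assert merge_same_channel(m, params).equals(m)
    groups = extract_groups(build_neighbor_graph(m, params), m, params)
    assert sorted(i for g in groups for i in g.member_ids) == sorted(
        int(i) for i in m.ids
    )


class TestOrderRobustness:
    def test_zero_for_well_separated_clusters(self):
        pts, chans = [], []
        for cx in range(5):
            for k in range(3):
                pts.append([500 * (cx + 1) + 20 * k, 500])
                chans.append(k % 2)
        f = make_field(pts, chans)
        assert order_robustness(f) == 0.0
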