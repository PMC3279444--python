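"""Walkability variables: density, network buffers, land-use entropy,
tertile classification."""
import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from walkrisk.built_env import (
    NetworkBuffer,
    RoadIndex,
    buffer_footprint,
    classify_walkability,
    intersection_density,
    land_use_areas,
    land_use_mix,
    network_buffer,
    population_density,
    tertile_indices,
)
from walkrisk.synthetic_city import Parcel, Tract


def grid_graph(n: int, spacing: float, freeway_row: int | None = None) -> nx.Graph:
    g = nx.Graph()
    for i in range(n):
        for j in range(n):
            g.add_node((i, j), x=i * spacing, y=j * spacing)
    for i in range(n):
        for j in range(n):
            for di, dj in ((1, 0), (0, 1)):
                if i + di < n and j + dj < n:
                    g.add_edge((i, j), (i + di, j + dj), length=spacing,
                               freeway=(dj == 0 and j == freeway_row))
    return g


class TestPopulationDensity:
    def test_division(self):
        tracts = [Tract("A", box(0, 0, 2000, 1000), 1000.0)]  # 2 km2
        homes = pd.DataFrame({"participant_id": ["P1", "P2"], "home_x": [100.0, 1500.0], "home_y": [500.0, 700.0]})
        dens = population_density(homes, tracts)
        assert np.allclose(dens, 500.0)  # same tract -> equal densities

    def test_outside_all_tracts_names_participant(self):
        tracts = [Tract("A", box(0, 0, 1000, 1000), 10.0)]
        homes = pd.DataFrame({"participant_id": ["LOST"], "home_x": [5000.0], "home_y": [5000.0]})
        with pytest.raises(ValueError, match="LOST"):
            population_density(homes, tracts)

    def test_synthetic_city_density_matches_config(self, small_city, small_cohort):
        participants, _ = small_cohort
        dens = population_density(participants, small_city.tracts)
        lookup = {t.tract_id: t.population / (t.polygon.area / 1e6) for t in small_city.tracts}
        assert set(np.round(dens, 6)) <= set(np.round(list(lookup.values()), 6))


class TestNetworkBuffer:
    def test_matches_brute_force_dijkstra(self):
        g = grid_graph(7, 500.0)
        home = (1500.0, 1500.0)  # exactly node (3, 3)
        buf = network_buffer(home, g, radius=1000.0)
        oracle = nx.single_source_dijkstra_path_length(g, (3, 3), cutoff=1000.0, weight="length")
        assert buf.node_distances == pytest.approx(oracle)
        assert len(buf.nodes) == 13  # diamond of network radius 2 grid steps

    def test_radius_zero_contains_only_snapped_point(self):
        g = grid_graph(5, 500.0)
        buf = network_buffer((1000.0, 1000.0), g, radius=0.0)
        assert buf.snapped_point == (1000.0, 1000.0)
        assert buf.node_distances == {(2, 2): 0.0}

    def test_removing_freeway_flags_never_shrinks_buffer(self):
        g = grid_graph(7, 500.0, freeway_row=3)
        no_fw = grid_graph(7, 500.0)
        home = (1500.0, 1240.0)
        with_exclusion = network_buffer(home, g, radius=1000.0, exclude_freeways=True)
        without = network_buffer(home, no_fw, radius=1000.0)
        assert set(with_exclusion.nodes) <= set(without.nodes)

    def test_unsnappable_home_gives_empty_buffer_and_warning(self):
        g = grid_graph(3, 500.0)
        with pytest.warns(UserWarning, match="empty buffer"):
            buf = network_buffer((90000.0, 90000.0), g, radius=1000.0)
        assert buf.empty
        assert intersection_density(buf, g) == 0

    def test_monotone_in_radius(self):
        g = grid_graph(9, 400.0)
        home = (1650.0, 1250.0)
        counts = [
            intersection_density(network_buffer(home, g, radius=r), g)
            for r in (200, 500, 1000, 1500)
        ]
        assert counts == sorted(counts)


class TestIntersectionDensity:
    def test_3x3_grid_has_5_intersections(self):
        # center node degree 4; the 4 mid-side nodes degree 3; corners degree 2
        g = grid_graph(3, 400.0)
        buf = network_buffer((400.0, 400.0), g, radius=1600.0)
        assert len(buf.nodes) == 9
        assert intersection_density(buf, g) == 5

    def test_counts_only_non_freeway_degree(self):
        g = grid_graph(3, 400.0, freeway_row=1)
        index = RoadIndex(g, exclude_freeways=True)
        buf = network_buffer((400.0, 0.0), index, radius=2000.0)
        # with the middle horizontal row removed, the center node drops to
        # degree 2 and the mid-side nodes on that row to degree 1
        assert intersection_density(buf, index) == 2


class TestLandUseMix:
    def test_boundary_values(self):
        assert land_use_mix([1, 1, 1, 1]) == pytest.approx(1.0)
        assert land_use_mix({"residential": 7.0}) == 0.0
        assert land_use_mix([0.5, 0.5, 0, 0]) == pytest.approx(0.5)

    def test_zero_area_scores_zero(self):
        assert land_use_mix([0, 0, 0, 0]) == 0.0

    def test_negative_area_errors(self):
        with pytest.raises(ValueError):
            land_use_mix([1, -1, 0, 0])

    @given(st.lists(st.floats(0.01, 100), min_size=4, max_size=4), st.floats(0.1, 50))
    @settings(max_examples=50, deadline=None)
    def test_permutation_and_scale_invariance(self, areas, scale):
        base = land_use_mix(areas)
        assert land_use_mix(areas[::-1]) == pytest.approx(base)
        assert land_use_mix([a * scale for a in areas]) == pytest.approx(base)
        assert base <= 1.0 + 1e-12

    @given(st.lists(st.floats(0.01, 100), min_size=4, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_maximized_at_equal_shares(self, areas):
        assert land_use_mix(areas) <= land_use_mix([1, 1, 1, 1]) + 1e-12

    def test_areas_from_footprint(self):
        parcels = [
            Parcel("a", box(0, 0, 100, 100), "residential"),
            Parcel("b", box(100, 0, 200, 100), "commercial"),
            Parcel("c", box(0, 100, 100, 200), "retail"),
            Parcel("d", box(100, 100, 200, 200), "institutional"),
            Parcel("e", box(200, 0, 300, 200), "other"),  # not a primary use
        ]
        areas = land_use_areas(box(0, 0, 300, 200), parcels)
        assert areas == {"residential": pytest.approx(1e4), "commercial": pytest.approx(1e4),
                         "retail": pytest.approx(1e4), "institutional": pytest.approx(1e4)}
        assert land_use_mix(areas) == pytest.approx(1.0)


class TestClassification:
    def make_table(self, pd_vals, id_vals, lm_vals):
        return pd.DataFrame(
            {"participant_id": [f"P{i}" for i in range(len(pd_vals))],
             "population_density": pd_vals, "intersection_density": id_vals,
             "land_use_mix": lm_vals}
        )

    def test_three_ranked_participants(self):
        t = self.make_table([1, 2, 3], [10, 20, 30], [0.1, 0.2, 0.3])
        out = classify_walkability(t)
        assert list(out.walkability_class) == ["low", "middle", "high"]

    def test_classes_disjoint_and_partition(self, demo_run):
        _, result = demo_run
        walk = pd.read_csv(result["outdir"] / "built_env.csv")
        counts = walk.walkability_class.value_counts()
        assert counts.sum() == len(walk)
        assert set(counts.index) <= {"high", "low", "middle"}

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        t = self.make_table(rng.uniform(1, 9, 200), rng.uniform(0, 50, 200), rng.uniform(0, 1, 200))
        base = classify_walkability(t)
        transformed = t.copy()
        transformed.population_density = np.exp(t.population_density)
        transformed.intersection_density = t.intersection_density**3
        assert (classify_walkability(transformed).walkability_class == base.walkability_class).all()

    def test_comonotone_variables_give_one_third_high(self):
        v = np.random.default_rng(9).uniform(0, 1, 3000)
        out = classify_walkability(self.make_table(v, v * 2, v**2))
        assert out.walkability_class.value_counts(normalize=True)["high"] == pytest.approx(1 / 3, abs=0.02)

    def test_independent_variables_give_cube_of_one_third(self):
        rng = np.random.default_rng(10)
        out = classify_walkability(
            self.make_table(rng.uniform(size=30000), rng.uniform(size=30000), rng.uniform(size=30000))
        )
        share = out.walkability_class.value_counts(normalize=True)["high"]
        assert share == pytest.approx((1 / 3) ** 3, abs=0.01)

    def test_constant_variable_errors(self):
        with pytest.raises(ValueError, match="constant"):
            classify_walkability(self.make_table([1, 1, 1], [1, 2, 3], [0.1, 0.2, 0.3]))

    def test_tie_goes_to_lower_bin(self):
        values = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], name="v")
        idx, cuts = tertile_indices(values)
        assert (values[idx == 0] <= cuts[0]).all()

    def test_deciles_mode(self):
        rng = np.random.default_rng(12)
        t = self.make_table(rng.uniform(size=500), rng.uniform(size=500), rng.uniform(size=500))
        out = classify_walkability(t, bins="deciles")
        assert out.population_density_bin.max() == 9


def test_footprint_modes_cover_buffer(small_city):
    index = RoadIndex(small_city.roads)
    home = (small_city.center[0] + 130.0, small_city.center[1] - 260.0)
    buf = network_buffer(home, index, radius=1000.0)
    hull = buffer_footprint(buf, index, "convex_hull")
    corridor = buffer_footprint(buf, index, "corridor", 50.0)
    assert hull.area > 0 and corridor.area > 0
    with pytest.raises(ValueError):
        buffer_footprint(buf, index, "bowtie")
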