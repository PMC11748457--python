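import itertools

import numpy as np
import pandas as pd
import pytest

from scenariosdm.geo import haversine_km
from scenariosdm.preprocess import (
    ModelTable,
    ScenarioConfig,
    build_model_table,
    pearson_filter,
    sample_pseudo_absences,
    split_rows,
    thin_occurrences,
)
from scenariosdm.stack import OccurrenceSet
from scenariosdm.synthetic import generate_env_stack

from .conftest import make_stack


def _points_at_km_separation(sep_km):
    dlat = sep_km / 111.1950
    return OccurrenceSet(np.array([100.0, 100.0]), np.array([30.0, 30.0 + dlat]))


class TestThinning:
    def test_pair_inside_radius_keeps_one(self):
        occ = _points_at_km_separation(10.0)
        assert len(thin_occurrences(occ, 30.0, seed=0)) == 1

    def test_pair_outside_radius_keeps_both(self):
        occ = _points_at_km_separation(40.0)
        assert len(thin_occurrences(occ, 30.0, seed=0)) == 2

    def test_empty_input_empty_output(self):
        occ = OccurrenceSet(np.array([]), np.array([]), [])
        assert len(thin_occurrences(occ, 30.0, seed=0)) == 0

    def test_minimum_separation_holds(self, landscape, niche):
        from scenariosdm.synthetic import generate_occurrences

        occ = generate_occurrences(landscape, niche, 80, seed=1)
        thinned = thin_occurrences(occ, 30.0, seed=1)
        d = haversine_km(
            thinned.lons[:, None], thinned.lats[:, None],
            thinned.lons[None, :], thinned.lats[None, :],
        )
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 30.0

    def test_idempotent(self, landscape, niche):
        from scenariosdm.synthetic import generate_occurrences

        occ = generate_occurrences(landscape, niche, 80, seed=2)
        once = thin_occurrences(occ, 30.0, seed=3)
        twice = thin_occurrences(once, 30.0, seed=99)
        np.testing.assert_array_equal(once.lons, twice.lons)

    def test_seed_determinism(self, landscape, niche):
        from scenariosdm.synthetic import generate_occurrences

        occ = generate_occurrences(landscape, niche, 80, seed=2)
        a = thin_occurrences(occ, 30.0, seed=5)
        b = thin_occurrences(occ, 30.0, seed=5)
        np.testing.assert_array_equal(a.lons, b.lons)


class TestPearsonFilter:
    def test_identical_layers_keep_first_priority(self):
        g = np.random.default_rng(0).normal(size=(20, 20))
        stack = make_stack({"a": g, "b": g.copy()})
        kept = pearson_filter(stack, 0.8, priority_order=["a", "b"])
        assert kept == ["a"]

    def test_independent_layers_all_kept(self):
        rng = np.random.default_rng(1)
        stack = make_stack({f"v{i}": rng.normal(size=(40, 40)) for i in range(5)})
        kept = pearson_filter(stack, 0.8)
        assert set(kept) == {f"v{i}" for i in range(5)}

    def test_matches_exhaustive_priority_respecting_search(self):
        """Greedy selection equals the priority-lexicographic best subset
        among all subsets satisfying the pairwise bound."""
        stack = generate_env_stack(
            60, 60, 1.0, 6,
            [(0, 1, 0.95), (0, 2, 0.85), (3, 4, 0.9)], seed=11,
        )
        names = list(stack.layers)
        threshold = 0.8
        flat = {v: stack.layers[v].ravel() for v in names}
        corr = {
            (a, b): abs(np.corrcoef(flat[a], flat[b])[0, 1])
            for a, b in itertools.combinations(names, 2)
        }

        def valid(subset):
            return all(corr[(a, b)] <= threshold for a, b in itertools.combinations(subset, 2))

        best = max(
            (s for r in range(len(names) + 1) for s in itertools.combinations(names, r) if valid(s)),
            key=lambda s: [v in s for v in names],  # lexicographic on priority order
        )
        kept = pearson_filter(stack, threshold, priority_order=names)
        assert tuple(kept) == best

    def test_output_satisfies_pairwise_bound(self, landscape):
        kept = pearson_filter(landscape, 0.8)
        cont = [v for v in kept if v in landscape.layers]
        for a, b in itertools.combinations(cont, 2):
            r = np.corrcoef(landscape.layers[a].ravel(), landscape.layers[b].ravel())[0, 1]
            assert abs(r) <= 0.8

    def test_categorical_passes_through(self, landscape):
        kept = pearson_filter(landscape, 0.8)
        assert "lucc" in kept

    def test_nonpositive_threshold_rejected(self, landscape):
        with pytest.raises(ValueError):
            pearson_filter(landscape, 0.0)


class TestPseudoAbsences:
    def test_draw_avoids_presence_cells(self, landscape, niche):
        from scenariosdm.synthetic import generate_occurrences

        occ = generate_occurrences(landscape, niche, 40, seed=1)
        pa = sample_pseudo_absences(landscape, occ, 500, seed=2)
        assert len(pa) == 500
        pres_cells = {landscape.geometry.cell_of(lo, la) for lo, la in zip(occ.lons, occ.lats)}
        pa_cells = {landscape.geometry.cell_of(lo, la) for lo, la in zip(pa.lons, pa.lats)}
        assert len(pa_cells) == 500
        assert not pres_cells & pa_cells

    def test_exclusion_distance_respected(self, landscape, niche):
        from scenariosdm.synthetic import generate_occurrences

        occ = generate_occurrences(landscape, niche, 10, seed=1)
        pa = sample_pseudo_absences(landscape, occ, 100, exclusion_km=30.0, seed=2)
        d = haversine_km(
            pa.lons[:, None], pa.lats[:, None], occ.lons[None, :], occ.lats[None, :]
        )
        assert d.min() >= 30.0

    def test_shortfall_raises_with_count(self):
        rng = np.random.default_rng(0)
        stack = make_stack({"a": rng.normal(size=(10, 10)), "b": rng.normal(size=(10, 10))})
        occ = OccurrenceSet(np.array([100.0]), np.array([30.0]))
        with pytest.raises(ValueError, match="eligible"):
            sample_pseudo_absences(stack, occ, 500, seed=0)

    def test_seed_determinism(self, landscape, niche):
        from scenariosdm.synthetic import generate_occurrences

        occ = generate_occurrences(landscape, niche, 20, seed=1)
        a = sample_pseudo_absences(landscape, occ, 200, seed=9)
        b = sample_pseudo_absences(landscape, occ, 200, seed=9)
        np.testing.assert_array_equal(a.lons, b.lons)


def _toy_table(n_pres, n_abs):
    rng = np.random.default_rng(0)
    n = n_pres + n_abs
    data = pd.DataFrame(
        {
            "lon": rng.uniform(100, 101, n),
            "lat": rng.uniform(29, 30, n),
            "response": [1] * n_pres + [0] * n_abs,
            "split": "train",
            "x": rng.normal(size=n),
        }
    )
    return ModelTable(data=data, variables=["x"])


class TestSplitRows:
    def test_forced_counts_reproduce_45_17(self):
        table = _toy_table(62, 100)
        out = split_rows(table, (0.75, 0.25), seed=1, forced_counts={1: (45, 17)})
        pres = out.rows()[out.rows().response == 1]
        assert (pres.split == "train").sum() == 45
        assert (pres.split == "valid").sum() == 17

    def test_rounded_fractions(self):
        out = split_rows(_toy_table(10, 0), (0.8, 0.2), seed=1)
        assert (out.rows().split == "train").sum() == 8
        assert (out.rows().split == "valid").sum() == 2

    def test_seed_determinism(self):
        t = _toy_table(30, 50)
        a = split_rows(t, (0.8, 0.2), seed=4)
        b = split_rows(t, (0.8, 0.2), seed=4)
        assert (a.rows().split == b.rows().split).all()

    def test_zero_presence_split_raises(self):
        with pytest.raises(ValueError):
            split_rows(_toy_table(1, 20), (1.0, 0.0), seed=0)


class TestScenarioConfig:
    def test_rejects_unknown_scenario(self):
        with pytest.raises(ValueError):
            ScenarioConfig(scenario="scenario3")

    def test_scenario2_includes_human_layer(self):
        assert ScenarioConfig(scenario="scenario2_disturbance").includes_human_layer
        assert not ScenarioConfig().includes_human_layer


def test_build_model_table_has_no_missing_values(landscape, niche):
    from scenariosdm.synthetic import generate_occurrences

    occ = generate_occurrences(landscape, niche, 30, seed=1)
    pa = sample_pseudo_absences(landscape, occ, 200, seed=2)
    variables = ["bio12", "slope", "lucc"]
    table = build_model_table(landscape, occ, pa, variables)
    assert table.categorical == ["lucc"]
    assert not table.X().isna().any().any()
    assert set(table.y()) == {0, 1}
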