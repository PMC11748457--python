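"""Data preparation: occurrence thinning, collinearity filtering,
pseudo-absence sampling and train/validation splitting.

Distances are great-circle (haversine) on cell-center coordinates. All
sampling is seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import haversine_km, pairwise_distances_km
from .stack import EnvStack, OccurrenceSet

#: default keep-priority for the collinearity filter: the canonical surviving
#: variable order of a bioclim + terrain analysis (topographic shade first),
#: used whenever all its members exist in the stack
CANONICAL_PRIORITY = (
    "hillshade", "bio15", "alt", "bio08", "bio12",
    "bio17", "aspect", "bio07", "slope", "bio02",
)


@dataclass
class ScenarioConfig:
    """Configuration of one modelling scenario.

    ``scenario1_natural`` uses climate + terrain predictors only;
    ``scenario2_disturbance`` additionally includes the categorical land-use
    layer.
    """

    scenario: str = "scenario1_natural"
    correlation_threshold: float = 0.8
    selected_variables: list[str] | None = None
    thinning_radius_km: float = 30.0
    n_pseudo_absence: int = 500
    split: tuple[float, float] = (0.8, 0.2)
    n_repetitions: int = 10
    seed: int = 0
    redraw_pseudo_absences_per_repetition: bool = True
    pa_exclusion_km: float = 0.0

    def __post_init__(self):
        if self.scenario not in {"scenario1_natural", "scenario2_disturbance"}:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0 < self.correlation_threshold <= 1:
            raise ValueError("correlation_threshold must be in (0, 1]")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")

    @property
    def includes_human_layer(self) -> bool:
        return self.scenario == "scenario2_disturbance"


@dataclass
class ModelTable:
    """Presence/pseudo-absence rows with predictors and split tags.

    ``data`` columns: lon, lat, response (1 presence / 0 absence), split
    ('train'/'valid'), then one column per predictor variable.
    """

    data: pd.DataFrame
    variables: list[str]
    categorical: list[str] = field(default_factory=list)

    def __post_init__(self):
        missing = [v for v in self.variables if v not in self.data.columns]
        if missing:
            raise ValueError(f"predictor columns missing from table: {missing}")
        if self.data[self.variables].isna().any().any():
            raise ValueError("model table contains missing predictor values")

    @property
    def continuous(self) -> list[str]:
        return [v for v in self.variables if v not in self.categorical]

    def rows(self, split: str | None = None) -> pd.DataFrame:
        if split is None:
            return self.data
        return self.data[self.data["split"] == split]

    def X(self, split: str | None = None) -> pd.DataFrame:
        return self.rows(split)[self.variables]

    def y(self, split: str | None = None) -> np.ndarray:
        return self.rows(split)["response"].to_numpy(dtype=int)

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def thin_occurrences(occ: OccurrenceSet, radius_km: float, seed: int = 0) -> OccurrenceSet:
    """Greedy spatial thinning: keep points so no two are within ``radius_km``.

    Points are visited in a seeded random order; a point is kept iff it is at
    least ``radius_km`` (great-circle) from every already-kept point.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    n = len(occ)
    if n == 0:
        return OccurrenceSet(np.array([]), np.array([]), [])
    order = np.random.default_rng(seed).permutation(n)
    dist = pairwise_distances_km(occ.lons, occ.lats)
    kept: list[int] = []
    for i in order:
        if all(dist[i, j] >= radius_km for j in kept):
            kept.append(int(i))
    kept.sort()
    return OccurrenceSet(occ.lons[kept], occ.lats[kept], [occ.sources[k] for k in kept])


def pearson_filter(
    stack: EnvStack,
    threshold: float = 0.8,
    priority_order: list[str] | None = None,
) -> list[str]:
    """Greedy collinearity filter over the stack's continuous layers.

    Variables are visited in ``priority_order``; a variable is kept iff its
    absolute Pearson correlation with every already-kept variable is at most
    ``threshold``. Categorical layers pass through untested and are appended
    at the end. Default priority: the canonical order when all of its
    members are present, else descending variance.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    names = list(stack.layers)
    if len(names) < 2:
        raise ValueError("need at least 2 continuous variables")
    if priority_order is None:
        if all(v in names for v in CANONICAL_PRIORITY):
            rest = [v for v in names if v not in CANONICAL_PRIORITY]
            rest.sort(key=lambda v: -np.nanvar(stack.layers[v]))
            priority_order = list(CANONICAL_PRIORITY) + rest
        else:
            priority_order = sorted(names, key=lambda v: -np.nanvar(stack.layers[v]))
    valid = stack.valid_mask()
    flat = {v: stack.layers[v][valid] for v in names}
    kept: list[str] = []
    for v in priority_order:
        if v not in flat:
            continue
        ok = True
        for u in kept:
            r = np.corrcoef(flat[v], flat[u])[0, 1]
            if abs(r) > threshold:
                ok = False
                break
        if ok:
            kept.append(v)
    return kept + list(stack.categorical_layers)


def sample_pseudo_absences(
    stack: EnvStack,
    presences: OccurrenceSet,
    n: int = 500,
    exclusion_km: float = 0.0,
    seed: int = 0,
) -> OccurrenceSet:
    """Uniform pseudo-absence draw over eligible cells.

    Eligible cells are valid (no missing predictors), do not contain a
    presence, and — when ``exclusion_km`` > 0 — lie at least that far from
    every presence point.
    """
    geom = stack.geometry
    eligible = stack.valid_mask().copy()
    for lon, lat in zip(presences.lons, presences.lats):
        cell = geom.cell_of(lon, lat)
        if cell is not None:
            eligible[cell] = False
    if exclusion_km > 0 and len(presences) > 0:
        lons, lats = geom.lonlat_grids()
        dmin = np.full(eligible.shape, np.inf)
        for lon, lat in zip(presences.lons, presences.lats):
            dmin = np.minimum(dmin, haversine_km(lons, lats, lon, lat))
        eligible &= dmin >= exclusion_km
    idx = np.flatnonzero(eligible.ravel())
    if len(idx) < n:
        raise ValueError(
            f"only {len(idx)} eligible cells for {n} pseudo-absences "
            f"(short by {n - len(idx)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(idx, size=n, replace=False)
    rows, cols = np.unravel_index(chosen, eligible.shape)
    return OccurrenceSet.from_cells(geom, rows, cols, source="pseudo-absence")


def build_model_table(
    stack: EnvStack,
    presences: OccurrenceSet,
    absences: OccurrenceSet,
    variables: list[str],
) -> ModelTable:
    """Assemble the modelling table from presences, absences and a stack."""
    frames = []
    for occ, resp in ((presences, 1), (absences, 0)):
        vals = stack.values_at(occ.lons, occ.lats, variables)
        vals.insert(0, "lon", occ.lons)
        vals.insert(1, "lat", occ.lats)
        vals.insert(2, "response", resp)
        frames.append(vals)
    data = pd.concat(frames, ignore_index=True)
    data = data.dropna().reset_index(drop=True)
    data["split"] = "train"
    categorical = [v for v in variables if v in stack.categorical_layers]
    return ModelTable(data=data, variables=list(variables), categorical=categorical)


def split_rows(
    table: ModelTable,
    fractions: tuple[float, float] = (0.8, 0.2),
    seed: int = 0,
    forced_counts: dict[int, tuple[int, int]] | None = None,
) -> ModelTable:
    """Stratified train/validation split with seeded shuffling.

    Per response class, ``round(train_fraction * class_size)`` rows go to
    train unless ``forced_counts[class] = (n_train, n_valid)`` pins exact
    counts (to reproduce externally fixed splits such as 45/17 from 62).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    tags = pd.Series(index=table.data.index, dtype=object)
    for cls, group in table.data.groupby("response"):
        idx = group.index.to_numpy()
        if forced_counts and int(cls) in forced_counts:
            n_train, n_valid = forced_counts[int(cls)]
            if n_train + n_valid != len(idx):
                raise ValueError(
                    f"forced counts {n_train}+{n_valid} != {len(idx)} rows of class {cls}"
                )
        else:
            n_train = int(round(fractions[0] * len(idx)))
            n_valid = len(idx) - n_train
        perm = rng.permutation(idx)
        tags[perm[:n_train]] = "train"
        tags[perm[n_train:]] = "valid"
        if cls == 1 and (n_train == 0 or n_valid == 0):
            raise ValueError("a split received zero presences")
    data = table.data.copy()
    data["split"] = tags
    return ModelTable(data=data, variables=table.variables, categorical=table.categorical)
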