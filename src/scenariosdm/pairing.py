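"""Randomized pairing validation of disturbance-aware vs natural-only maps.

Each validation point is scored against a control map (natural scenario) and
a test map (disturbance scenario) with a five-rule rubric, applied in order:

1. suitable in control only               -> control scores 1;
2. suitable in test only                  -> test scores 1;
3. suitable in both, different grade      -> the higher-grade side scores 1;
4. equal grade, but the test map shows evident habitat fragmentation within
   a radius (default 50 km) around the point -> test scores 1 (flagged);
5. equal grade, no fragmentation          -> no score.

"Evident fragmentation" is operationalized as: inside the buffer, the test
map splits suitable habitat into more 8-connected patches than the control
AND its suitable-cell fraction drops by at least a declared margin (default
0.10). Repetition tallies feed a likelihood-ratio G-test of independence on
the repetition-by-(control, test) count table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import chi2

from .geo import haversine_km
from .habitat import ClassifiedMap


@dataclass(frozen=True)
class RubricConfig:
    """Parameters of the pairing rubric."""

    fragmentation_radius_km: float = 50.0
    fragmentation_margin: float = 0.10
    suitable_classes: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self):
        if self.fragmentation_radius_km <= 0:
            raise ValueError("fragmentation radius must be positive")
        if not 0 <= self.fragmentation_margin < 1:
            raise ValueError("fragmentation margin must be in [0, 1)")


@dataclass(frozen=True)
class PointOutcome:
    """Rubric outcome for one validation point."""

    group: str  # 'control' | 'test' | 'equal'
    rule: int  # 1..5
    fragmentation: bool = False


@dataclass(frozen=True)
class GTestResult:
    G: float
    df: int
    p_value: float


_EIGHT = np.ones((3, 3), dtype=int)  # 8-neighbor connectivity structure


def _buffer_mask(cmap: ClassifiedMap, lon: float, lat: float, radius_km: float) -> np.ndarray:
    lons, lats = cmap.geometry.lonlat_grids()
    return haversine_km(lons, lats, lon, lat) <= radius_km


def _patch_stats(cmap: ClassifiedMap, buffer: np.ndarray, cfg: RubricConfig):
    suitable = cmap.suitable_mask(cfg.suitable_classes) & buffer
    n_patches = int(ndimage.label(suitable, structure=_EIGHT)[1])
    n_cells = int(buffer.sum())
    fraction = suitable.sum() / n_cells if n_cells else 0.0
    return n_patches, float(fraction)


def fragmentation_evident(
    control: ClassifiedMap, test: ClassifiedMap, lon: float, lat: float, cfg: RubricConfig
) -> bool:
    """True iff, within the buffer, the test map has more suitable patches
    than the control and its suitable fraction dropped by >= the margin."""
    buffer = _buffer_mask(control, lon, lat, cfg.fragmentation_radius_km)
    if not buffer.any():
        warnings.warn("fragmentation buffer contains no cells", stacklevel=2)
        return False
    ctrl_patches, ctrl_frac = _patch_stats(control, buffer, cfg)
    test_patches, test_frac = _patch_stats(test, buffer, cfg)
    return test_patches > ctrl_patches and test_frac <= ctrl_frac - cfg.fragmentation_margin


def score_point(
    lon: float,
    lat: float,
    control: ClassifiedMap,
    test: ClassifiedMap,
    cfg: RubricConfig = RubricConfig(),
) -> PointOutcome:
    """Apply the five-rule rubric to one validation point (see module doc)."""
    cell_c = control.geometry.cell_of(lon, lat)
    cell_t = test.geometry.cell_of(lon, lat)
    if cell_c is None or cell_t is None:
        raise ValueError(f"point ({lon:.4f}, {lat:.4f}) outside map extent")
    grade_c = int(control.classes[cell_c])
    grade_t = int(test.classes[cell_t])
    in_c = grade_c in cfg.suitable_classes
    in_t = grade_t in cfg.suitable_classes
    if in_c and not in_t:
        return PointOutcome("control", 1)
    if in_t and not in_c:
        return PointOutcome("test", 2)
    if not in_c and not in_t:
        return PointOutcome("equal", 5)
    if grade_c != grade_t:
        return PointOutcome("control" if grade_c > grade_t else "test", 3)
    if fragmentation_evident(control, test, lon, lat, cfg):
        return PointOutcome("test", 4, fragmentation=True)
    return PointOutcome("equal", 5)


@dataclass
class PairingScore:
    """Tallies of one pairing repetition."""

    repetition: int
    control: int
    test: int
    equality: int
    # recorded alongside the tallies; reported studies have tabulated
    # fragmentation scores exceeding the per-repetition test tally, so this
    # column is bookkeeping, not bounded by it
    fragmentation: int = 0

    @property
    def total(self) -> int:
        return self.control + self.test + self.equality


def score_repetition(
    points, control: ClassifiedMap, test: ClassifiedMap, cfg: RubricConfig = RubricConfig(),
    repetition: int = 1,
):
    """Score every (lon, lat) validation point; returns (PairingScore, trace).

    The trace is a DataFrame with one row per point (rule fired, group
    credited, fragmentation flag).
    """
    rows = []
    tally = {"control": 0, "test": 0, "equal": 0}
    n_frag = 0
    for i, (lon, lat) in enumerate(points):
        out = score_point(lon, lat, control, test, cfg)
        tally[out.group] += 1
        n_frag += out.fragmentation
        rows.append(
            {"point": i, "lon": lon, "lat": lat, "rule": out.rule, "group": out.group,
             "fragmentation": out.fragmentation}
        )
    score = PairingScore(
        repetition=repetition,
        control=tally["control"],
        test=tally["test"],
        equality=tally["equal"],
        fragmentation=n_frag,
    )
    return score, pd.DataFrame(rows)


def tally_repetitions(scores) -> pd.DataFrame:
    """Tally table: one row per repetition, a summation row, and each
    group's share of the grand total of scored points."""
    rows = [
        {
            "rand_group": s.repetition,
            "control": s.control,
            "test": s.test,
            "equality": s.equality,
            "fragmentation_score": s.fragmentation,
        }
        for s in scores
    ]
    df = pd.DataFrame(rows)
    sums = df[["control", "test", "equality", "fragmentation_score"]].sum()
    grand = int(sums["control"] + sums["test"] + sums["equality"])
    total_row = {"rand_group": "summation", **{k: int(v) for k, v in sums.items()}}
    share_row = {
        "rand_group": "share_pct",
        "control": 100.0 * sums["control"] / grand,
        "test": 100.0 * sums["test"] / grand,
        "equality": 100.0 * sums["equality"] / grand,
        "fragmentation_score": np.nan,
    }
    return pd.concat([df, pd.DataFrame([total_row, share_row])], ignore_index=True)


def g_test(table) -> GTestResult:
    """Likelihood-ratio G-test of independence on a count table.

    G = 2 * sum O * ln(O / E) with expectations from the independence model,
    0 * ln(0) taken as 0, no continuity or Williams correction;
    df = (rows - 1) * (cols - 1); p from the chi-square upper tail.
    """
    O = np.asarray(table, dtype=float)
    if O.ndim != 2 or min(O.shape) < 2:
        raise ValueError("need a table with at least 2 rows and 2 columns")
    if (O < 0).any():
        raise ValueError("counts must be non-negative")
    row_sums = O.sum(axis=1, keepdims=True)
    col_sums = O.sum(axis=0, keepdims=True)
    if (row_sums == 0).any() or (col_sums == 0).any():
        raise ValueError("zero row or column sum")
    E = row_sums * col_sums / O.sum()
    nz = O > 0
    G = 2.0 * float(np.sum(O[nz] * np.log(O[nz] / E[nz])))
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    return GTestResult(G=G, df=df, p_value=float(chi2.sf(G, df)))


def g_test_from_tallies(scores) -> GTestResult:
    """G-test on the repetitions-by-(control, test) table of pairing tallies."""
    table = np.array([[s.control, s.test] for s in scores], dtype=float)
    return g_test(table)


def random_pair_selection(ranked_labels, n_top: int = 20, seed: int = 0) -> str:
    """Uniform draw among the top ``n_top`` entries of a gamma-ranked list.

    ``ranked_labels`` must already be sorted best-first. Warns and draws from
    all available entries if fewer than ``n_top`` exist.
    """
    labels = list(ranked_labels)
    if not labels:
        raise ValueError("empty model list")
    if len(labels) < n_top:
        warnings.warn(
            f"only {len(labels)} models available for a top-{n_top} draw", stacklevel=2
        )
        n_top = len(labels)
    rng = np.random.default_rng(seed)
    return labels[int(rng.integers(n_top))]
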