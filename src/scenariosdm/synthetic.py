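"""Seeded synthetic study areas and virtual species.

The generators emulate the statistical structure a two-scenario habitat
analysis assumes: a stack of spatially autocorrelated continuous predictors
(climate analogs), terrain derivatives computed from a synthetic DEM, a
spatially clustered categorical land-use grid, and presence points drawn
from a known logistic niche. Everything is a pure function of its arguments
including the seed, so any run is reproducible bit-for-bit.

Spatial autocorrelation comes from Gaussian-smoothed white noise with a
declared smoothing radius in cells. Pairwise correlation targets between
layers are hit *exactly* (up to float rounding) by empirically
orthogonalizing the second field against the first before mixing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .stack import EnvStack, GridGeometry, OccurrenceSet

#: hillshade sun position (cartographic default)
SUN_AZIMUTH_DEG = 315.0
SUN_ALTITUDE_DEG = 45.0

#: sentinel for the aspect of flat cells
FLAT_ASPECT = -1.0


def _standardize(grid: np.ndarray) -> np.ndarray:
    sd = grid.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant field")
    return (grid - grid.mean()) / sd


def smooth_field(n_rows: int, n_cols: int, smoothing_cells: float, rng: np.random.Generator) -> np.ndarray:
    """Standardized spatially autocorrelated Gaussian random field."""
    noise = rng.standard_normal((n_rows, n_cols))
    if smoothing_cells > 0:
        noise = ndimage.gaussian_filter(noise, sigma=smoothing_cells, mode="reflect")
    return _standardize(noise)


def generate_env_stack(
    n_rows: int,
    n_cols: int,
    cell_size_km: float,
    n_continuous: int,
    correlated_pairs: Sequence[tuple[int, int, float]] = (),
    seed: int = 0,
    smoothing_cells: float = 5.0,
    origin: tuple[float, float] = (104.0, 28.0),
    names: Sequence[str] | None = None,
    meta: str = "climate",
) -> EnvStack:
    """Generate a stack of autocorrelated continuous predictor layers.

    ``correlated_pairs`` lists (i, j, target_r): layer ``j`` is rebuilt as a
    mix of layer ``i`` and an orthogonalized residual so its empirical
    Pearson correlation with layer ``i`` equals ``target_r`` exactly.
    """
    if n_continuous < 2:
        raise ValueError("need at least 2 continuous layers")
    for i, j, r in correlated_pairs:
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"target correlation {r} outside [-1, 1]")
        if not (0 <= i < n_continuous and 0 <= j < n_continuous) or i == j:
            raise ValueError(f"bad pair indices ({i}, {j})")
    geom = GridGeometry(n_rows, n_cols, cell_size_km, origin)
    rng = np.random.default_rng(seed)
    fields = [smooth_field(n_rows, n_cols, smoothing_cells, rng) for _ in range(n_continuous)]
    for i, j, r in correlated_pairs:
        zi, zj = fields[i], fields[j]
        resid = zj - (zi * zj).mean() / (zi * zi).mean() * zi
        if resid.std() == 0:  # zj was an exact multiple of zi
            resid = smooth_field(n_rows, n_cols, smoothing_cells, rng)
            resid = _standardize(resid - (zi * resid).mean() / (zi * zi).mean() * zi)
        else:
            resid = _standardize(resid)
        fields[j] = _standardize(r * zi + np.sqrt(max(0.0, 1.0 - r * r)) * resid)
    if names is None:
        names = [f"var{i:02d}" for i in range(n_continuous)]
    stack = EnvStack(geometry=geom)
    for name, grid in zip(names, fields):
        stack.add_layer(name, grid, meta=meta)
    return stack


def compute_terrain(dem_km: np.ndarray, cell_size_km: float):
    """Slope (degrees), aspect (degrees) and hillshade from a DEM in km.

    Slope uses Horn's 8-neighbor finite-difference gradient; border cells use
    one-sided differences via linear edge extrapolation. Aspect is the
    downslope direction in [0, 360) clockwise from north, with flat cells
    flagged ``FLAT_ASPECT`` (-1). Hillshade is in [0, 1] for a sun at azimuth
    315 deg, altitude 45 deg.
    """
    dem_km = np.asarray(dem_km, dtype=float)
    if dem_km.ndim != 2 or min(dem_km.shape) < 3:
        raise ValueError("DEM must be at least 3x3")
    # odd reflection == linear extrapolation, so Horn at the border reduces
    # to a one-sided difference
    z = np.pad(dem_km, 1, mode="reflect", reflect_type="odd")
    a, b, c = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    d, f = z[1:-1, :-2], z[1:-1, 2:]
    g, h, i = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dz_dx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * cell_size_km)  # eastward
    dz_dy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8.0 * cell_size_km)  # northward
    grad = np.hypot(dz_dx, dz_dy)
    slope_deg = np.degrees(np.arctan(grad))
    flat = grad < 1e-12
    aspect_deg = np.where(flat, FLAT_ASPECT, np.degrees(np.arctan2(-dz_dx, -dz_dy)) % 360.0)
    zen = np.radians(90.0 - SUN_ALTITUDE_DEG)
    slope_rad = np.arctan(grad)
    az = np.radians(SUN_AZIMUTH_DEG)
    aspect_rad = np.radians(np.where(flat, 0.0, aspect_deg))
    shade = np.cos(zen) * np.cos(slope_rad) + np.sin(zen) * np.sin(slope_rad) * np.cos(az - aspect_rad)
    shade = np.where(flat, np.cos(zen), shade)
    return slope_deg, aspect_deg, np.clip(shade, 0.0, 1.0)


def generate_lucc(
    stack: EnvStack,
    class_shares: Mapping[str, float],
    clustering: float = 5.0,
    seed: int = 0,
    anchor: str | None = None,
    anchor_blend: float = 0.0,
    name: str = "lucc",
) -> np.ndarray:
    """Generate a spatially clustered categorical land-use layer.

    Classes are assigned contiguous quantile bands of a smooth ordering
    field, in the declared order from the top of the field, so the first
    class occupies the highest-field cells. With ``anchor`` set to a
    continuous layer name and ``anchor_blend`` > 0 the ordering field is
    blended with that layer, co-locating the first classes with its high
    values. Empirical shares match the targets to cell-rounding precision.

    Codes are assigned 1, 2, ... in declaration order and registered in the
    stack's class table; the layer is added to the stack and returned.
    """
    if not class_shares:
        raise ValueError("class table must be non-empty")
    geom = stack.geometry
    rng = np.random.default_rng(seed)
    if len(class_shares) == 1:
        grid = np.ones((geom.n_rows, geom.n_cols), dtype=int)
    else:
        order_field = smooth_field(geom.n_rows, geom.n_cols, clustering, rng)
        if anchor is not None and anchor_blend > 0:
            order_field = _standardize(
                anchor_blend * _standardize(stack.layer(anchor)) + (1 - anchor_blend) * order_field
            )
        shares = np.array([max(0.0, s) for s in class_shares.values()], dtype=float)
        if shares.sum() == 0:
            raise ValueError("all class shares are zero")
        shares = shares / shares.sum()
        n = order_field.size
        bounds = np.round(np.cumsum(shares) * n).astype(int)
        counts = np.diff(np.concatenate([[0], bounds]))
        # guarantee presence of every positive-share class
        for k in range(len(counts)):
            if counts[k] == 0 and shares[k] > 0:
                counts[np.argmax(counts)] -= 1
                counts[k] = 1
        order = np.argsort(-order_field, axis=None, kind="stable")
        flat = np.empty(n, dtype=int)
        start = 0
        for code, cnt in enumerate(counts, start=1):
            flat[order[start : start + cnt]] = code
            start += cnt
        grid = flat.reshape(geom.n_rows, geom.n_cols)
    stack.add_layer(name, grid, meta="human", categorical=True)
    stack.class_table = {code: cname for code, cname in enumerate(class_shares, start=1)}
    return grid


@dataclass(frozen=True)
class NicheParams:
    """Ground-truth logistic niche of a virtual species.

    Suitability is the inverse logit of a linear + quadratic form over
    per-layer z-scores, forced to zero on cells whose land-use code is in
    ``disturbance_mask_classes``.
    """

    intercept: float
    linear: Mapping[str, float] = field(default_factory=dict)
    quadratic: Mapping[str, float] = field(default_factory=dict)
    disturbance_mask_classes: frozenset[int] = frozenset()
    lucc_var: str = "lucc"

    def __post_init__(self):
        coeffs = list(self.linear.values()) + list(self.quadratic.values())
        if not any(c != 0 for c in coeffs):
            raise ValueError("niche needs at least one nonzero coefficient")

    @property
    def driver_variables(self) -> list[str]:
        return sorted(set(self.linear) | set(self.quadratic))

    def true_suitability(self, stack: EnvStack, apply_mask: bool = True) -> np.ndarray:
        """Ground-truth suitability surface in [0, 1] (NaN outside valid cells)."""
        for v in self.driver_variables:
            if v not in stack.layers:
                raise KeyError(f"niche driver {v!r} not in stack")
        valid = stack.valid_mask()
        logit = np.full(valid.shape, float(self.intercept))
        # z-scores over valid cells only
        for v in self.driver_variables:
            vals = stack.layers[v]
            mu = vals[valid].mean()
            sd = vals[valid].std()
            zs = (vals - mu) / (sd if sd > 0 else 1.0)
            logit = logit + self.linear.get(v, 0.0) * zs + self.quadratic.get(v, 0.0) * zs**2
        suit = expit(logit)
        if apply_mask and self.disturbance_mask_classes and self.lucc_var in stack.categorical_layers:
            masked = np.isin(stack.categorical_layers[self.lucc_var], list(self.disturbance_mask_classes))
            suit = np.where(masked, 0.0, suit)
        suit = np.where(valid, suit, np.nan)
        return suit


def generate_occurrences(
    stack: EnvStack, niche: NicheParams, n_presences: int, seed: int = 0
) -> OccurrenceSet:
    """Sample presence cells proportional to true suitability, without replacement."""
    if n_presences < 1:
        raise ValueError("n_presences must be >= 1")
    suit = niche.true_suitability(stack)
    flat = np.nan_to_num(suit, nan=0.0).ravel()
    total = flat.sum()
    if total <= 0:
        raise ValueError("degenerate niche: suitability is zero everywhere")
    if (flat > 0).sum() < n_presences:
        raise ValueError("fewer positive-suitability cells than requested presences")
    rng = np.random.default_rng(seed)
    idx = rng.choice(flat.size, size=n_presences, replace=False, p=flat / total)
    rows, cols = np.unravel_index(idx, suit.shape)
    return OccurrenceSet.from_cells(stack.geometry, rows, cols, source="virtual")


# -------------------------------------------------- default study conditions

#: land-use class shares of the default landscape (woodland-dominated)
DEFAULT_CLASS_SHARES = {
    "woodland": 0.45,
    "shrub": 0.10,
    "grassland": 0.10,
    "cropland": 0.20,
    "urban": 0.10,
    "water": 0.05,
}

#: climate-analog correlation structure: several pairs above |r| = 0.8, as a
#: bioclim-like set exhibits (temperature family, precipitation family)
DEFAULT_CORRELATED_PAIRS = (
    (4, 0, 0.95),   # warmest-month max temp ~ annual mean temp
    (5, 0, 0.92),   # coldest-month min temp ~ annual mean temp
    (9, 0, 0.97),
    (10, 0, 0.94),
    (12, 11, 0.96),  # wettest-month precip ~ annual precip
    (15, 11, 0.93),
    (3, 6, 0.86),
    (18, 16, 0.88),
)


def composite_lucc(
    stack: EnvStack,
    class_shares: Mapping[str, float] = None,
    human_classes: tuple[str, ...] = ("cropland", "urban"),
    human_clustering: float = 2.5,
    natural_clustering: float = 5.0,
    anchor: str = "bio12",
    anchor_blend: float = 0.6,
    seed: int = 0,
    name: str = "lucc",
) -> np.ndarray:
    """Land-use grid with a human footprint independent of climate.

    Two-stage assignment: a fine-scale footprint field places the human
    classes (cropland, urban) anywhere in the study area — including
    climatically suitable cells, which is what lets a disturbance mask
    fragment otherwise contiguous habitat — while the remaining natural
    cells are banded along an anchored ordering field so woodland occupies
    the wetter cells. Shares are exact to cell rounding; codes follow
    declaration order as in :func:`generate_lucc`.
    """
    if class_shares is None:
        class_shares = DEFAULT_CLASS_SHARES
    geom = stack.geometry
    rng = np.random.default_rng(np.random.SeedSequence([seed, 29]))
    n = geom.n_rows * geom.n_cols
    shares = {k: max(0.0, v) for k, v in class_shares.items()}
    tot = sum(shares.values())
    shares = {k: v / tot for k, v in shares.items()}
    codes = {cname: code for code, cname in enumerate(class_shares, start=1)}

    footprint = smooth_field(geom.n_rows, geom.n_cols, human_clustering, rng).ravel()
    nat_order = smooth_field(geom.n_rows, geom.n_cols, natural_clustering, rng)
    if anchor is not None and anchor_blend > 0:
        nat_order = anchor_blend * _standardize(stack.layer(anchor)) + (1 - anchor_blend) * nat_order
    nat_order = nat_order.ravel()

    grid = np.zeros(n, dtype=int)
    human_order = np.argsort(-footprint, kind="stable")
    start = 0
    for cname in human_classes:
        cnt = int(round(shares[cname] * n))
        grid[human_order[start : start + cnt]] = codes[cname]
        start += cnt
    natural = np.flatnonzero(grid == 0)
    nat_classes = [c for c in class_shares if c not in human_classes]
    nat_tot = sum(shares[c] for c in nat_classes)
    order = natural[np.argsort(-nat_order[natural], kind="stable")]
    bounds = np.round(np.cumsum([shares[c] / nat_tot for c in nat_classes]) * len(order)).astype(int)
    start = 0
    for cname, stop in zip(nat_classes, bounds):
        grid[order[start:stop]] = codes[cname]
        start = stop
    grid = grid.reshape(geom.n_rows, geom.n_cols)
    stack.add_layer(name, grid, meta="human", categorical=True)
    stack.class_table = dict(enumerate(class_shares, start=1))
    return grid


def default_landscape(
    seed: int,
    n_rows: int = 100,
    n_cols: int = 100,
    cell_size_km: float = 10.0,
) -> EnvStack:
    """The package's reference synthetic study area.

    19 climate analogs (``bio01``..``bio19``, several pairs correlated above
    0.8), a DEM (``alt``, km) with slope/aspect/hillshade derivatives, and a
    6-class land-use grid anchored on the precipitation analog so woodland
    co-locates with wet cells.
    """
    names = [f"bio{i:02d}" for i in range(1, 20)]
    stack = generate_env_stack(
        n_rows,
        n_cols,
        cell_size_km,
        n_continuous=19,
        correlated_pairs=DEFAULT_CORRELATED_PAIRS,
        seed=seed,
        smoothing_cells=6.0,
        names=names,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    dem = 1.0 + 0.8 * smooth_field(n_rows, n_cols, 10.0, rng) + 0.1 * smooth_field(n_rows, n_cols, 2.0, rng)
    slope, aspect, hillshade = compute_terrain(dem, cell_size_km)
    stack.add_layer("alt", dem, meta="terrain")
    stack.add_layer("slope", slope, meta="terrain")
    stack.add_layer("aspect", aspect, meta="terrain")
    stack.add_layer("hillshade", hillshade, meta="terrain")
    composite_lucc(stack, DEFAULT_CLASS_SHARES, seed=seed + 13)
    return stack


def default_niche(stack: EnvStack) -> NicheParams:
    """Reference niche: precipitation- and slope-driven, urban/cropland masked.

    The steep logistic response emulates a habitat specialist whose suitable
    range covers under a tenth of the study area, giving the strong
    environmental determinism (single-model discrimination around 0.9+)
    that a two-scenario comparison presumes.
    """
    codes = {name: code for code, name in stack.class_table.items()}
    return NicheParams(
        intercept=-12.0,
        linear={"bio12": 9.0, "slope": 4.5},
        quadratic={"bio12": -1.5},
        disturbance_mask_classes=frozenset({codes["urban"], codes["cropland"]}),
    )
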