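"""Min--max decision-surface pattern recognition in the SAT--IMAT plane.

For each criterion, the training records at every grid node give a minimum
and a maximum value; the two piecewise-linear envelope surfaces over the
5x5 SAT-IMAT grid form a decision volume.  Akima splines insert three new
nodes into every grid interval (5 -> 17 nodes per axis).  A measured
criterion value selects the feasible region where it lies between the two
envelopes; intersecting the regions of all six criteria and taking the
area centroid of the result yields the (SAT, IMAT) estimate.

Region extraction is marching-squares contour polygonisation of the two
level sets {value >= min_surface} and {value <= max_surface} on a raster
refined from the densified node grid, intersected exactly with shapely.
When the six-way intersection is empty the estimator falls back to the
maximum-cardinality subset of criteria with a non-empty intersection
(ties broken by smallest area).
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import Akima1DInterpolator, RegularGridInterpolator
from shapely.geometry import MultiPolygon, Polygon, box
from shapely.ops import unary_union
from skimage import measure

from .features import CRITERION_COLUMNS

__all__ = [
    "DecisionSurface",
    "FeasibleRegion",
    "RecognitionResult",
    "UnrecognizableObjectError",
    "DENSIFY_POINTS_PER_INTERVAL",
    "fit_surfaces",
    "slice_region",
    "intersect_regions",
    "centroid_estimate",
    "estimate",
    "estimate_object",
    "surfaces_to_json",
    "surfaces_from_json",
]

#: new interpolated nodes inserted between each pair of original nodes
DENSIFY_POINTS_PER_INTERVAL = 3

#: domain of the SAT-IMAT plane, percent
DOMAIN = (0.0, 50.0)

#: regions smaller than this area (%^2) are treated as empty
_AREA_EPS = 1e-9

#: relative envelope padding; keeps degenerate (zero-noise) envelopes
#: sliceable as vanishingly thin bands instead of measure-zero sets
_PAD_REL = 1e-6


class UnrecognizableObjectError(ValueError):
    """Every single-criterion feasible region is empty."""


def densify_axis(levels: np.ndarray,
                 points_per_interval: int = DENSIFY_POINTS_PER_INTERVAL
                 ) -> np.ndarray:
    """Insert ``points_per_interval`` nodes in each interval (5 -> 17)."""
    levels = np.asarray(levels, dtype=float)
    parts = []
    for a, b in zip(levels[:-1], levels[1:]):
        parts.append(np.linspace(a, b, points_per_interval + 2)[:-1])
    parts.append(levels[-1:])
    return np.concatenate(parts)


def _akima_densify(levels: np.ndarray, values: np.ndarray,
                   dense: np.ndarray) -> np.ndarray:
    """Tensor-product Akima interpolation of a node grid onto dense axes.

    Akima splines run along each SAT row first, then along the densified
    IMAT columns; nodes stay strictly inside the original span so no
    extrapolation occurs.
    """
    n = levels.size
    tmp = np.empty((n, dense.size))
    for r in range(n):
        tmp[r] = Akima1DInterpolator(levels, values[r])(dense)
    out = np.empty((dense.size, dense.size))
    for c in range(dense.size):
        out[:, c] = Akima1DInterpolator(levels, tmp[:, c])(dense)
    return out


@dataclass
class DecisionSurface:
    """Per-criterion min/max envelopes over the SAT-IMAT grid."""

    criterion: str
    levels: np.ndarray                  # original node axis (both axes equal)
    min_nodes: np.ndarray               # (n, n), SAT rows x IMAT cols
    max_nodes: np.ndarray
    dense_axis: np.ndarray = field(init=False)
    min_dense: np.ndarray = field(init=False)
    max_dense: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.min_nodes = np.asarray(self.min_nodes, dtype=float)
        self.max_nodes = np.asarray(self.max_nodes, dtype=float)
        if np.any(self.min_nodes > self.max_nodes):
            raise ValueError("min envelope exceeds max envelope at a node")
        if self.levels.size < 2:
            warnings.warn(f"degenerate decision surface for {self.criterion}: "
                          f"a single grid level cannot localise an estimate")
            self.dense_axis = self.levels
            self.min_dense = self.min_nodes.astype(float)
            self.max_dense = self.max_nodes.astype(float)
            return
        self.dense_axis = densify_axis(self.levels)
        self.min_dense = _akima_densify(self.levels, self.min_nodes,
                                        self.dense_axis)
        self.max_dense = _akima_densify(self.levels, self.max_nodes,
                                        self.dense_axis)

    @property
    def scale(self) -> float:
        return float(np.max(np.abs(self.max_nodes)) or 1.0)


@dataclass
class FeasibleRegion:
    """Disjoint polygons of (SAT, IMAT) values consistent with criteria."""

    polygons: list[Polygon]
    criteria: tuple[str, ...] = ()

    @property
    def area(self) -> float:
        return float(sum(p.area for p in self.polygons))

    @property
    def is_empty(self) -> bool:
        return self.area <= _AREA_EPS

    def as_multipolygon(self) -> MultiPolygon:
        return MultiPolygon(self.polygons)

    @classmethod
    def from_geometry(cls, geom, criteria: tuple[str, ...] = ()
                      ) -> "FeasibleRegion":
        polys: list[Polygon] = []
        if geom is not None and not geom.is_empty:
            geoms = geom.geoms if hasattr(geom, "geoms") else [geom]
            for g in geoms:
                if isinstance(g, Polygon) and g.area > _AREA_EPS:
                    polys.append(g)
        return cls(polygons=polys, criteria=criteria)


@dataclass
class RecognitionResult:
    """Estimate plus diagnostics of one decision-rule evaluation."""

    sat_pct: float
    imat_pct: float
    region: FeasibleRegion
    criteria_used: int
    per_criterion: dict[str, FeasibleRegion]
    fallback_used: bool = False
    multiple_components: bool = False


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_surfaces(records: pd.DataFrame,
                 levels=None,
                 criteria: list[str] | None = None) -> dict[str, DecisionSurface]:
    """Envelope surfaces from training records tagged with grid truth.

    ``records`` must contain ``sat``, ``imat`` and the criterion columns;
    every grid node needs at least one record.
    """
    criteria = criteria or CRITERION_COLUMNS
    if levels is None:
        levels = np.unique(records["sat"].to_numpy())
    levels = np.asarray(levels, dtype=float)
    n = levels.size
    surfaces: dict[str, DecisionSurface] = {}
    grouped = records.groupby(["sat", "imat"])
    for crit in criteria:
        mn = np.full((n, n), np.nan)
        mx = np.full((n, n), np.nan)
        for (s, i), grp in grouped:
            r = int(np.argmin(np.abs(levels - s)))
            c = int(np.argmin(np.abs(levels - i)))
            vals = grp[crit].to_numpy()
            mn[r, c] = vals.min()
            mx[r, c] = vals.max()
        if np.any(np.isnan(mn)):
            missing = np.argwhere(np.isnan(mn))
            raise ValueError(f"grid nodes without training records: "
                             f"{[(levels[r], levels[c]) for r, c in missing]}")
        surfaces[crit] = DecisionSurface(crit, levels, mn, mx)
    return surfaces


# ---------------------------------------------------------------------------
# region geometry
# ---------------------------------------------------------------------------

def _upsample(surface: np.ndarray, axis: np.ndarray,
              refine: int) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear refinement of the densified node grid for contouring."""
    if refine <= 1:
        return surface, axis
    fine = densify_axis(axis, refine - 1)
    interp = RegularGridInterpolator((axis, axis), surface, method="linear")
    ss, ii = np.meshgrid(fine, fine, indexing="ij")
    return interp(np.stack([ss.ravel(), ii.ravel()], axis=1)).reshape(
        fine.size, fine.size), fine


def _level_region(g: np.ndarray, axis: np.ndarray):
    """Polygonise {g >= 0} for a scalar field sampled on axis x axis.

    The field is padded with a large negative border so contours close at
    the domain boundary; rings are combined even-odd (symmetric difference)
    so nested contours become holes.
    """
    if np.all(g >= 0):
        return box(axis[0], axis[0], axis[-1], axis[-1])
    if np.all(g < 0):
        return Polygon()
    pad_val = -1e30
    gp = np.pad(g, 1, constant_values=pad_val)
    step = axis[1] - axis[0]
    ax_p = np.concatenate([[axis[0] - step], axis, [axis[-1] + step]])
    region = Polygon()
    for ring in measure.find_contours(gp, 0.0):
        xs = np.interp(ring[:, 0], np.arange(ax_p.size), ax_p)
        ys = np.interp(ring[:, 1], np.arange(ax_p.size), ax_p)
        if xs.size < 4:
            continue
        poly = Polygon(np.column_stack([xs, ys]))
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty:
            continue
        region = region.symmetric_difference(poly)
    return region.intersection(box(axis[0], axis[0], axis[-1], axis[-1]))


def slice_region(value: float, surface: DecisionSurface,
                 refine: int = 8) -> FeasibleRegion:
    """Feasible region where min_surface <= value <= max_surface.

    ``refine`` bilinearly subdivides each densified cell before marching
    squares; edge crossings of the bilinear envelopes are then located by
    linear interpolation, so thin bands are resolved far below the node
    spacing.
    """
    pad = _PAD_REL * surface.scale
    if surface.dense_axis.size < 2:
        inside = (surface.min_dense[0, 0] - pad <= value
                  <= surface.max_dense[0, 0] + pad)
        geom = (box(DOMAIN[0], DOMAIN[0], DOMAIN[1], DOMAIN[1])
                if inside else Polygon())
        return FeasibleRegion.from_geometry(geom,
                                            criteria=(surface.criterion,))
    lo, axis = _upsample(surface.min_dense, surface.dense_axis, refine)
    hi, _ = _upsample(surface.max_dense, surface.dense_axis, refine)
    above = _level_region(value - lo + pad, axis)       # {value >= min}
    below = _level_region(hi - value + pad, axis)       # {value <= max}
    geom = above.intersection(below)
    return FeasibleRegion.from_geometry(geom, criteria=(surface.criterion,))


def intersect_regions(regions: list[FeasibleRegion]) -> FeasibleRegion:
    """Geometric intersection of feasible regions (possibly empty)."""
    if not regions:
        raise ValueError("need at least one region")
    geom = unary_union(regions[0].as_multipolygon())
    for reg in regions[1:]:
        geom = geom.intersection(unary_union(reg.as_multipolygon()))
        if geom.is_empty:
            break
    crit = tuple(c for r in regions for c in r.criteria)
    return FeasibleRegion.from_geometry(geom, criteria=crit)


def centroid_estimate(region: FeasibleRegion) -> tuple[float, float]:
    """Area-weighted center of mass of all region components."""
    if region.is_empty:
        raise ValueError("cannot take the centroid of an empty region")
    c = region.as_multipolygon().centroid
    return float(c.x), float(c.y)


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def estimate(values, surfaces: dict[str, DecisionSurface],
             refine: int = 8) -> RecognitionResult:
    """Decision-rule estimate of (SAT, IMAT) from one criterion vector.

    ``values`` is a mapping criterion -> measured value (a CriterionVector,
    a pandas row or a plain dict).  Slices every criterion, intersects all
    regions, and falls back to the largest criterion subset with a
    non-empty intersection when the full intersection is empty.
    """
    if hasattr(values, "as_array"):
        values = dict(zip(CRITERION_COLUMNS, values.as_array()))
    elif isinstance(values, pd.Series):
        values = {c: float(values[c]) for c in surfaces}

    per_criterion = {c: slice_region(float(values[c]), surfaces[c], refine)
                     for c in surfaces}
    names = list(per_criterion)
    nonempty = [c for c in names if not per_criterion[c].is_empty]
    if not nonempty:
        raise UnrecognizableObjectError(
            "no criterion produced a feasible region")

    full = intersect_regions([per_criterion[c] for c in nonempty])
    fallback = len(nonempty) < len(names)
    region = full
    if full.is_empty:
        fallback = True
        region = None
        for k in range(len(nonempty) - 1, 0, -1):
            candidates = []
            for combo in itertools.combinations(nonempty, k):
                inter = intersect_regions([per_criterion[c] for c in combo])
                if not inter.is_empty:
                    candidates.append(inter)
            if candidates:
                region = min(candidates, key=lambda r: r.area)
                break
        if region is None:
            raise UnrecognizableObjectError(
                "no subset of criteria has a common feasible region")

    sat, imat = centroid_estimate(region)
    return RecognitionResult(
        sat_pct=sat, imat_pct=imat, region=region,
        criteria_used=len(region.criteria),
        per_criterion=per_criterion,
        fallback_used=fallback,
        multiple_components=len(region.polygons) > 1,
    )


def estimate_object(records: pd.DataFrame,
                    surfaces: dict[str, DecisionSurface],
                    refine: int = 8) -> tuple[float, float]:
    """Object-level estimate: mean of the per-signal estimates."""
    ests = [estimate(row, surfaces, refine)
            for _, row in records.iterrows()]
    return (float(np.mean([e.sat_pct for e in ests])),
            float(np.mean([e.imat_pct for e in ests])))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def surfaces_to_json(surfaces: dict[str, DecisionSurface]) -> str:
    d = {c: {"levels": s.levels.tolist(),
             "min_nodes": s.min_nodes.tolist(),
             "max_nodes": s.max_nodes.tolist()}
         for c, s in surfaces.items()}
    return json.dumps(d, indent=2)


def surfaces_from_json(text: str) -> dict[str, DecisionSurface]:
    d = json.loads(text)
    return {c: DecisionSurface(c, np.array(v["levels"]),
                               np.array(v["min_nodes"]),
                               np.array(v["max_nodes"]))
            for c, v in d.items()}
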