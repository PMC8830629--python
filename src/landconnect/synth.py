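"""Synthetic landscape generator.

Builds raster landscapes with the statistical structure the analysis
assumes — spatially autocorrelated continuous predictors, distance-to-
feature layers (roads, settlements, dumpsites, croplands), occurrences
drawn from a known logistic suitability function, prey suitability/density
zones, and conservation-area polygons in three categories — so that every
downstream stage can be exercised and validated without external data.

All randomness flows from the single integer seed of the spec through named
``numpy.random.Generator`` instances; identical specs give bit-identical
output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit
from shapely.geometry import box, mapping, shape
from skimage.draw import line as draw_line

from .grid import Grid, OccurrenceSet, Stack, euclidean_distance

__all__ = [
    "LandscapeSpec",
    "TrueModel",
    "ConservationAreas",
    "generate_predictor_stack",
    "simulate_occurrences",
    "generate_conservation_areas",
    "generate_prey_zones",
]

CA_CATEGORIES = ("wildlife_refuge", "protected_area", "non_hunting_area")


@dataclass
class LandscapeSpec:
    """Parameters of a synthetic landscape.

    Defaults emulate the study conditions of the analysis: 100 m cells,
    distance layers for four anthropogenic feature classes, a nine-area
    conservation network mixed 2 wildlife refuges / 2 protected areas /
    5 non-hunting areas, and three prey species.
    """

    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 100.0
    n_continuous_vars: int = 3
    autocorr_range: float = 500.0
    n_roads: int = 4
    n_settlements: int = 5
    n_dumpsites: int = 3
    n_croplands: int = 4
    n_cas: int = 9
    ca_category_mix: tuple[int, int, int] = (2, 2, 5)
    n_prey_species: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 16 or self.n_cols < 16:
            raise ValueError("grid must be at least 16 x 16 cells")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")
        if self.autocorr_range < 0:
            raise ValueError("autocorr_range must be >= 0")

    @property
    def extent_x(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def extent_y(self) -> float:
        return self.n_rows * self.cell_size


@dataclass
class TrueModel:
    """Ground-truth logistic suitability function over stack variables."""

    coefficients: dict[str, float]
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if not any(v != 0 for v in self.coefficients.values()):
            warnings.warn(
                "all true-model coefficients are zero; occurrences will be "
                "uniform and coefficient signs unrecoverable"
            )


def _named_rng(spec_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec_seed, stream]))


# stream ids keep sub-generators independent and reproducible
_STREAM_FIELDS = 1
_STREAM_FEATURES = 2
_STREAM_CAS = 3
_STREAM_PREY = 4


def generate_predictor_stack(spec: LandscapeSpec) -> Stack:
    """Autocorrelated continuous predictors plus distance-to-feature layers.

    Continuous fields are white noise smoothed by a Gaussian kernel of
    scale ``autocorr_range`` meters (``autocorr_range = 0`` leaves iid
    noise) and standardized to mean 0, sd 1.  Each feature class with a
    positive count contributes one Euclidean-distance layer in meters.
    """
    rng = _named_rng(spec.seed, _STREAM_FIELDS)
    shape2d = (spec.n_rows, spec.n_cols)
    base = Grid(np.zeros(shape2d), spec.cell_size, origin=(0.0, spec.extent_y))
    grids: dict[str, Grid] = {}
    sigma = spec.autocorr_range / spec.cell_size
    for i in range(spec.n_continuous_vars):
        noise = rng.standard_normal(shape2d)
        fieldv = gaussian_filter(noise, sigma=sigma) if sigma > 0 else noise
        fieldv = (fieldv - fieldv.mean()) / fieldv.std()
        grids[f"env{i + 1}"] = base.copy(values=fieldv)

    frng = _named_rng(spec.seed, _STREAM_FEATURES)
    for name, count, kind in (
        ("roads", spec.n_roads, "line"),
        ("settlements", spec.n_settlements, "point"),
        ("dumpsites", spec.n_dumpsites, "point"),
        ("croplands", spec.n_croplands, "patch"),
    ):
        if count <= 0:
            continue
        feat = _rasterize_features(frng, shape2d, count, kind)
        grids[f"dist_{name}"] = euclidean_distance(base.copy(values=feat.astype(float)))
    return Stack(grids)


def _rasterize_features(
    rng: np.random.Generator, shape2d: tuple[int, int], count: int, kind: str
) -> np.ndarray:
    nr, nc = shape2d
    feat = np.zeros(shape2d, dtype=bool)
    for _ in range(count):
        if kind == "line":
            r0, r1 = rng.integers(0, nr, 2)
            c0, c1 = rng.integers(0, nc, 2)
            rr, cc = draw_line(int(r0), int(c0), int(r1), int(c1))
            feat[rr, cc] = True
        elif kind == "point":
            feat[rng.integers(0, nr), rng.integers(0, nc)] = True
        elif kind == "patch":
            h = int(rng.integers(2, max(3, nr // 10)))
            w = int(rng.integers(2, max(3, nc // 10)))
            r0 = int(rng.integers(0, nr - h))
            c0 = int(rng.integers(0, nc - w))
            feat[r0 : r0 + h, c0 : c0 + w] = True
        else:  # pragma: no cover
            raise ValueError(kind)
    return feat


def standardize_stack(stack: Stack) -> Stack:
    """Z-score every layer over its valid cells (distance layers included)."""
    out = {}
    for name, g in stack.items():
        v = g.values
        m = np.nanmean(v)
        s = np.nanstd(v)
        out[name] = g.copy(values=(v - m) / s if s > 0 else v - m)
    return Stack(out)


def true_suitability(truth: TrueModel, stack: Stack) -> Grid:
    """Logistic suitability of the ground-truth model on the standardized
    stack."""
    zstack = standardize_stack(stack)
    eta = np.full(stack.geometry.shape, truth.intercept, dtype=float)
    for name, coef in truth.coefficients.items():
        if name not in zstack.names:
            raise KeyError(f"true-model variable '{name}' not in stack")
        eta = eta + coef * zstack[name].values
    return stack.geometry.copy(values=expit(eta))


def simulate_occurrences(
    truth: TrueModel,
    stack: Stack,
    n_points: int,
    seed: int,
    class_mix: Sequence[int] = (55, 88, 45),
    class_names: Sequence[str] = ("den", "scat", "sighting"),
) -> OccurrenceSet:
    """Sample occurrence points from the true suitability surface.

    Cells are drawn *without replacement* with probability proportional to
    the logistic suitability; each point sits at its cell centre, which
    keeps coordinates distinct (duplicate coordinates would distort the
    Moran's I screen).  Source classes are assigned in proportion to
    ``class_mix`` (default mirrors a 55 den / 88 scat / 45 sighting
    composition, n = 188).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    suit = true_suitability(truth, stack)
    valid = np.isfinite(suit.values)
    flat_idx = np.flatnonzero(valid.ravel())
    if n_points > len(flat_idx):
        raise ValueError(
            f"n_points = {n_points} exceeds the {len(flat_idx)} available cells"
        )
    p = suit.values.ravel()[flat_idx]
    chosen = rng.choice(flat_idx, size=n_points, replace=False, p=p / p.sum())
    rows, cols = np.unravel_index(chosen, suit.shape)
    xy = np.array([suit.xy_of(r, c) for r, c in zip(rows, cols)])
    mix = np.asarray(class_mix, dtype=float)
    counts = np.floor(mix / mix.sum() * n_points).astype(int)
    counts[0] += n_points - counts.sum()
    classes = np.repeat(list(class_names), counts)
    return OccurrenceSet(xy=xy, source_class=classes)


@dataclass
class ConservationAreas:
    """Conservation-area polygons with a category label per polygon."""

    polygons: list
    categories: list[str]

    def __post_init__(self) -> None:
        if len(self.polygons) != len(self.categories):
            raise ValueError("polygons and categories length mismatch")

    @property
    def n(self) -> int:
        return len(self.polygons)

    def by_category(self, category: str) -> list:
        return [p for p, c in zip(self.polygons, self.categories) if c == category]

    def to_geojson(self, path: str | Path) -> None:
        features = [
            {
                "type": "Feature",
                "properties": {"category": cat, "id": i},
                "geometry": mapping(poly),
            }
            for i, (poly, cat) in enumerate(zip(self.polygons, self.categories))
        ]
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": features})
        )

    @classmethod
    def from_geojson(cls, path: str | Path) -> "ConservationAreas":
        data = json.loads(Path(path).read_text())
        polys = [shape(f["geometry"]) for f in data["features"]]
        cats = [f["properties"]["category"] for f in data["features"]]
        return cls(polys, cats)


def _category_counts(n_cas: int, mix: Sequence[int]) -> list[int]:
    """Largest-remainder apportionment of n_cas over the category mix."""
    mix = np.asarray(mix, dtype=float)
    quota = mix / mix.sum() * n_cas
    counts = np.floor(quota).astype(int)
    rem = quota - counts
    for i in np.argsort(-rem)[: n_cas - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def generate_conservation_areas(
    spec: LandscapeSpec, max_tries_per_area: int = 200
) -> ConservationAreas:
    """Non-overlapping rectangular conservation areas within the landscape.

    The default category mix 2/2/5 mirrors a network of two wildlife
    refuges, two protected areas, and five non-hunting areas.  Placement is
    rejection sampling; exhausting the retry budget raises.
    """
    if spec.n_cas < 1:
        return ConservationAreas([], [])
    rng = _named_rng(spec.seed, _STREAM_CAS)
    counts = _category_counts(spec.n_cas, spec.ca_category_mix)
    categories = [c for c, k in zip(CA_CATEGORIES, counts) for _ in range(k)]
    ex, ey = spec.extent_x, spec.extent_y
    polys: list = []
    for cat in categories:
        for attempt in range(max_tries_per_area):
            w = rng.uniform(0.08, 0.22) * ex
            h = rng.uniform(0.08, 0.22) * ey
            x0 = rng.uniform(0, ex - w)
            y0 = rng.uniform(0, ey - h)
            cand = box(x0, y0, x0 + w, y0 + h)
            if not any(cand.intersects(p) for p in polys):
                polys.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place conservation area ({cat}) without overlap "
                f"after {max_tries_per_area} tries"
            )
    return ConservationAreas(polys, categories)


def generate_prey_zones(
    spec: LandscapeSpec, n_zones: int = 6, max_density: float = 5.0
) -> list[tuple[Grid, Grid]]:
    """Per-prey-species (suitability, zone density) grid pairs.

    Suitability is a smoothed random field squashed to [0, 1]; density is
    piecewise constant over rectangular abundance zones (emulating
    per-conservation-area abundance divided by area) with a low background
    density elsewhere.  Default of three species mirrors a wild goat /
    mouflon / goitered gazelle prey base.
    """
    rng = _named_rng(spec.seed, _STREAM_PREY)
    shape2d = (spec.n_rows, spec.n_cols)
    base = Grid(np.zeros(shape2d), spec.cell_size, origin=(0.0, spec.extent_y))
    sigma = max(spec.autocorr_range / spec.cell_size, 1.0)
    out = []
    for _ in range(spec.n_prey_species):
        fieldv = gaussian_filter(rng.standard_normal(shape2d), sigma=sigma)
        fieldv = (fieldv - fieldv.min()) / (fieldv.max() - fieldv.min())
        dens = np.full(shape2d, rng.uniform(0, 0.2 * max_density))
        for _z in range(n_zones):
            h = int(rng.integers(spec.n_rows // 8, spec.n_rows // 3))
            w = int(rng.integers(spec.n_cols // 8, spec.n_cols // 3))
            r0 = int(rng.integers(0, spec.n_rows - h))
            c0 = int(rng.integers(0, spec.n_cols - w))
            dens[r0 : r0 + h, c0 : c0 + w] = rng.uniform(0, max_density)
        out.append((base.copy(values=fieldv), base.copy(values=dens)))
    return out
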