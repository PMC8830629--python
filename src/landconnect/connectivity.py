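"""Resistance surfaces, cost distance, resistant kernels, and factorial
least-cost-path corridors.

Habitat suitability HS in [0, 1] maps to movement resistance through the
exponential decay R_raw = 1000^(-HS), linearly rescaled over the
transform's analytic codomain [0.001, 1] onto [1, 10], so the endpoints
are exact: R = 1 at HS = 1 and R = 10 at HS = 0.

Movement is modelled on the 8-neighbour cell lattice.  The cost of an edge
between neighbouring cells i, j is ((R_i + R_j) / 2) * d_ij with d_ij one
cell size orthogonally and sqrt(2) cell sizes diagonally, so one cost unit
is one resistance-weighted meter: a dispersal threshold of 50000 cost
units corresponds to 50 km of movement through optimal habitat (R = 1).

The resistant kernel around a source decays linearly from 1 at the source
to 0 at the dispersal threshold in accumulated cost, and the per-source
kernels are summed into a movement-rate surface.  Factorial least-cost
paths connect every pair of source points; buffered paths are summed into
a corridor-strength count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .grid import Grid, OccurrenceSet

__all__ = [
    "ResistanceSurface",
    "KernelSurface",
    "DISPERSAL_THRESHOLDS",
    "suitability_to_resistance",
    "cost_distance",
    "resistant_kernel",
    "max_reach",
    "least_cost_path",
    "factorial_lcp",
]

#: Cost-unit dispersal thresholds of the sensitivity analysis
#: (50 .. 250 km of movement through optimal habitat).
DISPERSAL_THRESHOLDS = (50_000.0, 100_000.0, 150_000.0, 200_000.0, 250_000.0)

_R_RAW_MIN = 1000.0 ** -1  # R_raw at HS = 1
_R_RAW_MAX = 1000.0 ** 0  # R_raw at HS = 0


@dataclass
class ResistanceSurface:
    """Per-cell movement resistance in [1, 10] with provenance."""

    grid: Grid
    provenance: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


@dataclass
class KernelSurface:
    """Summed per-source dispersal kernels; zero beyond the threshold."""

    grid: Grid
    sources: np.ndarray  # (n, 2) source cells (row, col)
    threshold: float

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


def suitability_to_resistance(hs: Grid) -> ResistanceSurface:
    """Exponential-decay resistance transform rescaled to [1, 10].

    The rescale domain is the analytic codomain of 1000^(-HS) on HS in
    [0, 1] — (0.001, 1) — not the empirical range of the particular map,
    which makes R(HS) map-independent and pins the endpoints exactly.
    """
    v = hs.values
    finite = hs.mask
    if np.any((v[finite] < 0) | (v[finite] > 1)):
        raise ValueError("habitat suitability must lie in [0, 1]")
    r_raw = np.power(1000.0, -v)
    r = 1.0 + 9.0 * (r_raw - _R_RAW_MIN) / (_R_RAW_MAX - _R_RAW_MIN)
    r[~finite] = np.nan
    return ResistanceSurface(
        grid=hs.copy(values=r),
        provenance={"transform": "1000^(-HS), rescaled [0.001,1]->[1,10]"},
    )


# ---------------------------------------------------------------------------
# Lattice graph
# ---------------------------------------------------------------------------

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _lattice_graph(resistance: ResistanceSurface):
    """CSR cost graph over valid cells; nodes are flat cell indices."""
    g = resistance.grid
    nr, nc = g.shape
    r = g.values
    valid = np.isfinite(r)
    rows_i, cols_i, data = [], [], []
    # half the directions; the graph is used undirected
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        length = g.cell_size * (np.sqrt(2.0) if dr and dc else 1.0)
        r0 = slice(max(0, -dr), nr - max(0, dr))
        r1 = slice(max(0, dr), nr - max(0, -dr))
        c0 = slice(max(0, -dc), nc - max(0, dc))
        c1 = slice(max(0, dc), nc - max(0, -dc))
        ok = valid[r0, c0] & valid[r1, c1]
        w = 0.5 * (r[r0, c0] + r[r1, c1]) * length
        idx0 = (
            np.arange(nr)[r0][:, None] * nc + np.arange(nc)[c0][None, :]
        )
        idx1 = (
            np.arange(nr)[r1][:, None] * nc + np.arange(nc)[c1][None, :]
        )
        rows_i.append(idx0[ok])
        cols_i.append(idx1[ok])
        data.append(w[ok])
    n = nr * nc
    return coo_matrix(
        (np.concatenate(data), (np.concatenate(rows_i), np.concatenate(cols_i))),
        shape=(n, n),
    ).tocsr()


def _as_cells(resistance: ResistanceSurface, sources) -> np.ndarray:
    """Sources given as an OccurrenceSet or a sequence of (row, col)."""
    if isinstance(sources, OccurrenceSet):
        return sources.cells(resistance.grid)
    return np.asarray(sources, dtype=int).reshape(-1, 2)


def _check_source(resistance: ResistanceSurface, cell: tuple[int, int]) -> int:
    r, c = int(cell[0]), int(cell[1])
    g = resistance.grid
    if not (0 <= r < g.n_rows and 0 <= c < g.n_cols):
        raise ValueError(f"source cell {cell} outside the grid")
    if not np.isfinite(g.values[r, c]):
        raise ValueError(f"source cell {cell} lies on nodata")
    return r * g.n_cols + c


def cost_distance(
    resistance: ResistanceSurface,
    source: tuple[int, int],
    max_cost: float = np.inf,
) -> Grid:
    """Minimal accumulated cost (Dijkstra) from a source cell to every
    cell; cells beyond ``max_cost`` (and nodata) are +inf."""
    g = resistance.grid
    src = _check_source(resistance, source)
    graph = _lattice_graph(resistance)
    dist = _csgraph_dijkstra(
        graph, directed=False, indices=[src], limit=max_cost
    )[0]
    return g.copy(values=dist.reshape(g.shape))


def resistant_kernel(
    resistance: ResistanceSurface,
    sources,
    threshold: float,
) -> KernelSurface:
    """Summed linear-decay dispersal kernels around all source points.

    Per source s: K_s(x) = max(0, 1 - c_s(x) / D) where c_s is the cost
    distance and D the dispersal threshold in cost units; K = sum_s K_s.
    """
    if not threshold > 0:
        raise ValueError("dispersal threshold must be > 0")
    g = resistance.grid
    cells = _as_cells(resistance, sources)
    if len(cells) == 0:
        raise ValueError("need at least one source")
    src_ids = [_check_source(resistance, c) for c in cells]
    graph = _lattice_graph(resistance)
    dist = _csgraph_dijkstra(
        graph, directed=False, indices=src_ids, limit=threshold
    )
    k = np.maximum(0.0, 1.0 - dist / threshold).sum(axis=0)
    k[~np.isfinite(g.values.ravel())] = np.nan
    return KernelSurface(
        grid=g.copy(values=k.reshape(g.shape)), sources=cells, threshold=threshold
    )


def max_reach(resistance_value: float, threshold: float) -> float:
    """Geodesic path length (meters) at which accumulated cost through
    uniform resistance reaches the threshold; D meters at R = 1."""
    if resistance_value <= 0:
        raise ValueError("resistance must be > 0")
    return threshold / resistance_value


# ---------------------------------------------------------------------------
# Least-cost paths
# ---------------------------------------------------------------------------

def _neighbors(resistance: ResistanceSurface, cell: tuple[int, int]):
    g = resistance.grid
    r, c = cell
    for dr, dc in _OFFSETS:
        rr, cc = r + dr, c + dc
        if 0 <= rr < g.n_rows and 0 <= cc < g.n_cols and np.isfinite(g.values[rr, cc]):
            length = g.cell_size * (np.sqrt(2.0) if dr and dc else 1.0)
            yield (rr, cc), 0.5 * (g.values[r, c] + g.values[rr, cc]) * length


def _walk_back(
    resistance: ResistanceSurface,
    dist: np.ndarray,
    source: tuple[int, int],
    target: tuple[int, int],
) -> list[tuple[int, int]]:
    """Deterministic backward reconstruction of a least-cost path.

    From the target, repeatedly steps to the neighbour minimizing
    dist[n] + edge(n, cur); cost ties break toward the lower flat index.
    """
    nc = resistance.grid.n_cols
    path = [target]
    cur = target
    while cur != source:
        best = None
        for nb, w in _neighbors(resistance, cur):
            cand = (dist[nb[0] * nc + nb[1]] + w, nb[0] * nc + nb[1])
            if best is None or cand < best:
                best = cand
                best_nb = nb
        cur = best_nb
        path.append(cur)
    path.reverse()
    return path


def least_cost_path(
    resistance: ResistanceSurface,
    a: tuple[int, int],
    b: tuple[int, int],
) -> tuple[list[tuple[int, int]], float]:
    """A minimal-cost 8-connected path between two cells and its cost.

    Cost is symmetric in (a, b); at equal cost the path preferring lower
    flat cell indices is returned.  Unreachable targets raise.
    """
    if tuple(a) == tuple(b):
        raise ValueError("path endpoints must differ")
    _check_source(resistance, b)
    dist_grid = cost_distance(resistance, a)
    dist = dist_grid.values.ravel()
    nc = resistance.grid.n_cols
    total = dist[b[0] * nc + b[1]]
    if not np.isfinite(total):
        raise ValueError(f"target {tuple(b)} unreachable from {tuple(a)}")
    return _walk_back(resistance, dist, tuple(a), tuple(b)), float(total)


def _buffer_offsets(buffer_width: float, cell_size: float) -> np.ndarray:
    k = int(np.floor(buffer_width / cell_size))
    off = np.arange(-k, k + 1)
    dr, dc = np.meshgrid(off, off, indexing="ij")
    keep = (dr ** 2 + dc ** 2) * cell_size ** 2 <= buffer_width ** 2 + 1e-9
    return np.stack([dr[keep], dc[keep]], axis=1)


def factorial_lcp(
    resistance: ResistanceSurface,
    sources,
    buffer_width: float = 200.0,
) -> Grid:
    """Corridor strength from buffered least-cost paths of all pairs.

    For every unordered pair of source points the least-cost path is
    computed (one Dijkstra tree per source is reused across its pairs),
    cells within ``buffer_width`` meters of the path are marked, and each
    pair adds 1 to the marked cells.  No dispersal threshold is applied.
    """
    g = resistance.grid
    cells = [tuple(c) for c in _as_cells(resistance, sources)]
    # coincident sources contribute no path; deduplicate
    uniq = sorted(set(cells))
    if len(uniq) < 2:
        raise ValueError("need at least two distinct source cells")
    for c in uniq:
        _check_source(resistance, c)
    graph = _lattice_graph(resistance)
    offsets = _buffer_offsets(buffer_width, g.cell_size)
    strength = np.zeros(g.shape)
    nc = g.n_cols
    for i, a in enumerate(uniq[:-1]):
        dist = _csgraph_dijkstra(
            graph, directed=False, indices=[a[0] * nc + a[1]]
        )[0]
        for b in uniq[i + 1 :]:
            if not np.isfinite(dist[b[0] * nc + b[1]]):
                continue
            path = np.array(_walk_back(resistance, dist, a, b))
            marked = np.zeros(g.shape, dtype=bool)
            pts = (path[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
            ok = (
                (pts[:, 0] >= 0)
                & (pts[:, 0] < g.n_rows)
                & (pts[:, 1] >= 0)
                & (pts[:, 1] < nc)
            )
            marked[pts[ok, 0], pts[ok, 1]] = True
            strength[marked] += 1
    strength[~g.mask] = np.nan
    return g.copy(values=strength)
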