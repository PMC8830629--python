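"""Graph-theoretic patch prioritization (PC / dPC) and conservation-area
gap analysis.

The probability of connectivity index of a patch network is

    PC = (sum_i sum_j a_i * a_j * p*_ij) / A_L^2

over ordered node pairs (including i = j with p*_ii = 1), where a_i is a
patch attribute (area or kernel strength), A_L the landscape area in the
same units, and p*_ij the maximum-probability dispersal path between i and
j: direct step probabilities p_ij = exp(-k d_ij) are calibrated so that
p(d_med) = p_med, and p*_ij maximizes the product of step probabilities
(equivalently, minimizes the sum of -ln p_ij edge weights).

A node's importance dPC_k = 100 (PC - PC_without_k) / PC decomposes
exactly into dPCintra (the patch's own area term), dPCflux (dispersal
flux between the patch and the rest), and dPCconnector (its stepping-
stone role in other pairs' best paths), computed here as the residual.

Gap analysis overlays core habitat against conservation-area polygons by
the cell-centre point-in-polygon rule and reports percent coverage per
category; conservation areas can themselves be prioritized by treating
each as a patch whose attribute is the suitable-habitat area inside it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely import contains_xy
from shapely.geometry.base import BaseGeometry

from .grid import Grid
from .patches import PatchSet
from .synth import CA_CATEGORIES, ConservationAreas

__all__ = [
    "PatchGraph",
    "DpcDecomposition",
    "build_patch_graph",
    "pc_index",
    "dpc",
    "dpc_fractions",
    "rank_patches",
    "gap_coverage",
    "ca_prioritization",
]


@dataclass
class PatchGraph:
    """Nodes with attributes and pairwise distances; substrate for PC."""

    ids: list
    attributes: np.ndarray  # a_i > 0
    distances: np.ndarray  # (n, n) Euclidean meters, symmetric
    total_area: float  # A_L, same units as attributes
    p_med: float = 0.5
    d_med: float = 10_000.0

    def __post_init__(self) -> None:
        self.attributes = np.asarray(self.attributes, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(self.attributes <= 0):
            raise ValueError("node attributes must be > 0")
        if not 0 < self.p_med < 1:
            raise ValueError("p_med must lie in (0, 1)")
        if self.total_area <= 0:
            raise ValueError("landscape total area must be > 0")
        if not np.allclose(self.distances, self.distances.T):
            raise ValueError("distance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def decay(self) -> float:
        """k in p(d) = exp(-k d), calibrated by p(d_med) = p_med."""
        return -np.log(self.p_med) / self.d_med

    def direct_p(self) -> np.ndarray:
        p = np.exp(-self.decay * self.distances)
        p[~np.isfinite(self.distances)] = 0.0
        np.fill_diagonal(p, 1.0)
        return p

    def without(self, node_id) -> "PatchGraph":
        keep = [i for i, nid in enumerate(self.ids) if nid != node_id]
        if len(keep) == self.n:
            raise KeyError(f"node {node_id} not in graph")
        return PatchGraph(
            ids=[self.ids[i] for i in keep],
            attributes=self.attributes[keep],
            distances=self.distances[np.ix_(keep, keep)],
            total_area=self.total_area,
            p_med=self.p_med,
            d_med=self.d_med,
        )


def _patch_distances(patchset: PatchSet, cell_size: float) -> np.ndarray:
    """Minimal cell-centre-to-cell-centre (edge-to-edge) distances."""
    n = patchset.n
    pts = []
    for p in patchset.patches:
        cells = p.cells.astype(float)
        pts.append(np.stack([(cells[:, 1] + 0.5), (cells[:, 0] + 0.5)], axis=1) * cell_size)
    d = np.zeros((n, n))
    trees = [cKDTree(p) for p in pts]
    for i in range(n):
        for j in range(i + 1, n):
            dd, _ = trees[i].query(pts[j])
            d[i, j] = d[j, i] = dd.min()
    return d


def build_patch_graph(
    patchset: PatchSet,
    attribute: str = "area",
    dispersal: tuple[float, float] = (0.5, 10_000.0),
    total_area: float | None = None,
) -> PatchGraph:
    """Patch graph from delineated cores.

    ``attribute`` selects patch area (km^2) or kernel strength as a_i;
    ``dispersal = (p_med, d_med)`` calibrates p(d_med) = p_med.
    ``total_area`` (A_L) defaults to the full non-nodata landscape area in
    the attribute's units (km^2 for area; total kernel mass for strength).
    """
    if patchset.n < 1:
        raise ValueError("need at least one patch")
    if attribute == "area":
        attrs = np.array([p.area_km2 for p in patchset.patches])
        if total_area is None:
            cell_km2 = (patchset.labels.cell_size / 1000.0) ** 2
            total_area = float(patchset.labels.mask.sum() * cell_km2)
    elif attribute == "strength":
        attrs = np.array([p.strength for p in patchset.patches])
        if total_area is None:
            total_area = float(max(attrs.sum(), 1e-12))
    else:
        raise ValueError("attribute must be 'area' or 'strength'")
    d = _patch_distances(patchset, patchset.labels.cell_size)
    return PatchGraph(
        ids=[p.id for p in patchset.patches],
        attributes=attrs,
        distances=d,
        total_area=float(total_area),
        p_med=dispersal[0],
        d_med=dispersal[1],
    )


# ---------------------------------------------------------------------------
# PC / dPC
# ---------------------------------------------------------------------------

def _pstar(graph: PatchGraph) -> np.ndarray:
    """Maximum-probability path matrix via shortest paths on -ln p."""
    p = graph.direct_p()
    n = graph.n
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if p[i, j] > 0:
                G.add_edge(i, j, weight=-np.log(p[i, j]))
    pstar = np.zeros((n, n))
    for i, lengths in nx.all_pairs_dijkstra_path_length(G, weight="weight"):
        for j, L in lengths.items():
            pstar[i, j] = np.exp(-L)
    np.fill_diagonal(pstar, 1.0)
    return pstar


def pc_index(graph: PatchGraph) -> float:
    """Probability of connectivity of the full network."""
    a = graph.attributes
    pstar = _pstar(graph)
    return float(a @ pstar @ a / graph.total_area ** 2)


def dpc(graph: PatchGraph, node_id) -> float:
    """Percent drop in PC when the node is removed (100 for the only
    node)."""
    pc_full = pc_index(graph)
    sub = graph.without(node_id)
    pc_minus = pc_index(sub) if sub.n else 0.0
    return 100.0 * (pc_full - pc_minus) / pc_full


@dataclass
class DpcDecomposition:
    node_id: object
    dpc: float
    intra: float
    flux: float
    connector: float


def dpc_fractions(graph: PatchGraph, node_id) -> DpcDecomposition:
    """dPC split into intra, flux, and connector fractions (percent).

    intra = 100 a_k^2 / (PC A_L^2); flux = 100 * 2 sum_{j != k} a_k a_j
    p*_kj / (PC A_L^2); connector is the residual (the loss in other
    pairs' best-path probabilities when k is removed), which equals the
    direct definition by the decomposition identity.
    """
    k = graph.ids.index(node_id)
    pc_full = pc_index(graph)
    a = graph.attributes
    pstar = _pstar(graph)
    denom = pc_full * graph.total_area ** 2
    intra = 100.0 * a[k] ** 2 / denom
    flux = 100.0 * 2.0 * np.sum(np.delete(a * pstar[k], k)) * a[k] / denom
    total = dpc(graph, node_id)
    return DpcDecomposition(
        node_id=node_id,
        dpc=total,
        intra=intra,
        flux=flux,
        connector=total - intra - flux,
    )


def rank_patches(graph: PatchGraph) -> pd.DataFrame:
    """Nodes ranked by descending dPC; ties break toward the larger
    attribute, then the lower node id."""
    rows = []
    for nid, attr in zip(graph.ids, graph.attributes):
        rows.append({"id": nid, "attribute": attr, "dpc": dpc(graph, nid)})
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["dpc", "attribute", "id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


# ---------------------------------------------------------------------------
# Gap analysis
# ---------------------------------------------------------------------------

def _target_centers(targets: PatchSet | Grid) -> np.ndarray:
    """(n, 2) x/y centres of target cells (core patches or habitat==1)."""
    if isinstance(targets, PatchSet):
        grid = targets.labels
        rows, cols = np.nonzero(np.nan_to_num(grid.values) > 0)
    else:
        grid = targets
        rows, cols = np.nonzero(
            np.where(np.isfinite(grid.values), grid.values, 0) == 1
        )
    if len(rows) == 0:
        return np.empty((0, 2))
    return np.array([grid.xy_of(r, c) for r, c in zip(rows, cols)])


def gap_coverage(
    targets: PatchSet | Grid, cas: ConservationAreas
) -> pd.DataFrame:
    """Percent of target cells whose centres fall inside conservation
    areas, per category, per individual area, and in total.

    Returns a table with rows per CA (``kind == "ca"``), per category
    (``kind == "category"``), and one ``kind == "total"`` row; empty
    targets give 0% with status noted in the total row.
    """
    centers = _target_centers(targets)
    n_t = len(centers)
    rows = []
    in_any = np.zeros(n_t, dtype=bool)
    cat_cover = {c: np.zeros(n_t, dtype=bool) for c in CA_CATEGORIES}
    for i, (poly, cat) in enumerate(zip(cas.polygons, cas.categories)):
        inside = (
            contains_xy(poly, centers[:, 0], centers[:, 1])
            if n_t
            else np.zeros(0, dtype=bool)
        )
        in_any |= inside
        if cat in cat_cover:
            cat_cover[cat] |= inside
        rows.append(
            {
                "kind": "ca",
                "name": f"ca_{i}",
                "category": cat,
                "covered_pct": 100.0 * inside.sum() / n_t if n_t else 0.0,
            }
        )
    for cat in CA_CATEGORIES:
        rows.append(
            {
                "kind": "category",
                "name": cat,
                "category": cat,
                "covered_pct": 100.0 * cat_cover[cat].sum() / n_t if n_t else 0.0,
            }
        )
    rows.append(
        {
            "kind": "total",
            "name": "all_categories",
            "category": "",
            "covered_pct": 100.0 * in_any.sum() / n_t if n_t else 0.0,
        }
    )
    df = pd.DataFrame(rows)
    if n_t == 0:
        df.attrs["status"] = "empty_targets"
    return df


def ca_prioritization(
    cas: ConservationAreas,
    suitable: Grid,
    dispersal: tuple[float, float] = (0.5, 10_000.0),
) -> pd.DataFrame:
    """dPC fractions per conservation area, treating each CA as a patch
    whose attribute is the suitable-habitat area (km^2) inside it.

    CAs containing no suitable habitat violate the positive-attribute
    graph invariant and are excluded with a warning.
    """
    if cas.n < 1:
        raise ValueError("need at least one conservation area")
    centers = _target_centers(suitable)
    cell_km2 = (suitable.cell_size / 1000.0) ** 2
    ids, attrs, polys = [], [], []
    for i, (poly, cat) in enumerate(zip(cas.polygons, cas.categories)):
        n_in = (
            int(contains_xy(poly, centers[:, 0], centers[:, 1]).sum())
            if len(centers)
            else 0
        )
        if n_in == 0:
            warnings.warn(
                f"conservation area ca_{i} ({cat}) holds no suitable habitat; excluded"
            )
            continue
        ids.append(f"ca_{i}")
        attrs.append(n_in * cell_km2)
        polys.append(poly)
    if not ids:
        return pd.DataFrame(
            columns=["id", "category", "attribute", "dpc", "intra", "flux", "connector"]
        )
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = polys[i].distance(polys[j])
    total_area = float(suitable.mask.sum() * cell_km2)
    graph = PatchGraph(
        ids=ids,
        attributes=np.array(attrs),
        distances=d,
        total_area=total_area,
        p_med=dispersal[0],
        d_med=dispersal[1],
    )
    cat_of = {f"ca_{i}": c for i, c in enumerate(cas.categories)}
    rows = []
    for nid, attr in zip(ids, attrs):
        dec = dpc_fractions(graph, nid)
        rows.append(
            {
                "id": nid,
                "category": cat_of[nid],
                "attribute": attr,
                "dpc": dec.dpc,
                "intra": dec.intra,
                "flux": dec.flux,
                "connector": dec.connector,
            }
        )
    return pd.DataFrame(rows).sort_values("dpc", ascending=False).reset_index(drop=True)
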