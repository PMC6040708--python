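"""Circuit-theory effective resistance over resistance rasters.

Each finite-resistance cell is a node of an electrical network; neighbouring
cells are joined by resistors.  The effective resistance between two plots is
the voltage drop per unit current injected between their nodes, obtained by
solving the reduced graph-Laplacian system.  Resistance distance decreases
with every additional connecting path (Rayleigh monotonicity), which makes it
an isolation measure that accounts for the full corridor network rather than
a single least-cost route.

Conventions (matching the circuit tools commonly used for landscape rasters):
cell conductance is the reciprocal of cell resistance; an edge between
orthogonal neighbours carries the mean of the two cell conductances; diagonal
edges (8-neighbourhood) carry that mean divided by sqrt(2) to account for the
longer centre-to-centre distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .rasterize import ResistanceRaster

#: maximum snap distance (m) from a plot coordinate to a finite cell
SNAP_RADIUS_M = 5.0

_DENSE_LIMIT = 1500  # solve reduced systems densely below this node count


@dataclass
class ConductanceGraph:
    """Sparse conductance network built from a resistance raster."""

    n_nodes: int
    edges_i: np.ndarray
    edges_j: np.ndarray
    conductance: np.ndarray
    component: np.ndarray  # component id per node
    node_index: np.ndarray | None = None  # (nrows, ncols) int, -1 = infinite cell
    raster: ResistanceRaster | None = None
    _laplacian_cache: sparse.csr_matrix | None = None

    def laplacian(self) -> sparse.csr_matrix:
        if self._laplacian_cache is None:
            i, j, g = self.edges_i, self.edges_j, self.conductance
            adj = sparse.coo_matrix(
                (g, (i, j)), shape=(self.n_nodes, self.n_nodes)
            ).tocsr()
            adj = adj + adj.T
            deg = np.asarray(adj.sum(axis=1)).ravel()
            self._laplacian_cache = sparse.diags(deg, format="csr") - adj
        return self._laplacian_cache


def raster_to_graph(raster: ResistanceRaster, neighborhood: int = 8) -> ConductanceGraph:
    """Build the conductance network of all finite-resistance cells.

    ``neighborhood`` is 4 (orthogonal) or 8 (orthogonal + diagonal).
    """
    if neighborhood not in (4, 8):
        raise ValueError("neighborhood must be 4 or 8")
    finite = raster.finite_mask
    n_nodes = int(finite.sum())
    if n_nodes == 0:
        raise ValueError("raster has no finite-resistance cells")
    node_index = np.full(raster.values.shape, -1, dtype=np.int64)
    node_index[finite] = np.arange(n_nodes)
    cond = np.zeros_like(raster.values)
    cond[finite] = 1.0 / raster.values[finite]

    offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    if neighborhood == 8:
        s = 1.0 / np.sqrt(2.0)
        offsets += [(1, 1, s), (1, -1, s)]

    ei, ej, eg = [], [], []
    for dr, dc, scale in offsets:
        r0 = slice(max(0, -dr), raster.n_rows - max(0, dr))
        c0 = slice(max(0, -dc), raster.n_cols - max(0, dc))
        r1 = slice(max(0, dr), raster.n_rows - max(0, -dr))
        c1 = slice(max(0, dc), raster.n_cols - max(0, -dc))
        a = node_index[r0, c0]
        b = node_index[r1, c1]
        ok = (a >= 0) & (b >= 0)
        if not ok.any():
            continue
        g = 0.5 * (cond[r0, c0][ok] + cond[r1, c1][ok]) * scale
        ei.append(a[ok])
        ej.append(b[ok])
        eg.append(g)
    if ei:
        edges_i = np.concatenate(ei)
        edges_j = np.concatenate(ej)
        conduct = np.concatenate(eg)
    else:
        edges_i = np.empty(0, dtype=np.int64)
        edges_j = np.empty(0, dtype=np.int64)
        conduct = np.empty(0)

    adj = sparse.coo_matrix(
        (np.ones(edges_i.size), (edges_i, edges_j)), shape=(n_nodes, n_nodes)
    )
    _, labels = connected_components(adj, directed=False)
    return ConductanceGraph(
        n_nodes=n_nodes,
        edges_i=edges_i,
        edges_j=edges_j,
        conductance=conduct,
        component=labels,
        node_index=node_index,
        raster=raster,
    )


def graph_from_edges(n_nodes: int, edges: list[tuple[int, int, float]]) -> ConductanceGraph:
    """Construct a graph directly from (i, j, conductance) triples (for tests
    and small networks)."""
    if any(g <= 0 or not np.isfinite(g) for _, _, g in edges):
        raise ValueError("conductances must be positive and finite")
    ei = np.array([e[0] for e in edges], dtype=np.int64)
    ej = np.array([e[1] for e in edges], dtype=np.int64)
    eg = np.array([e[2] for e in edges], dtype=float)
    adj = sparse.coo_matrix((np.ones(ei.size), (ei, ej)), shape=(n_nodes, n_nodes))
    _, labels = connected_components(adj, directed=False)
    return ConductanceGraph(n_nodes, ei, ej, eg, labels)


class _ComponentSolver:
    """Factorised reduced Laplacian of one connected component.

    One node of the component is grounded (removed); the factorisation is
    reused for every source node, so all pairwise resistances within the
    component cost one factorisation plus one solve per non-ground terminal.
    """

    def __init__(self, graph: ConductanceGraph, comp_id: int, ground: int):
        members = np.flatnonzero(graph.component == comp_id)
        self.local = -np.ones(graph.n_nodes, dtype=np.int64)
        keep = members[members != ground]
        self.local[keep] = np.arange(keep.size)
        self.ground = ground
        lap = graph.laplacian()
        k = lap[keep][:, keep].tocsc()
        self.n = keep.size
        if self.n == 0:
            self._solve = None
        elif self.n <= _DENSE_LIMIT:
            dense = k.toarray()
            try:
                self._chol = np.linalg.cholesky(dense)
            except np.linalg.LinAlgError:
                # isolated-node corner cases; tiny ridge restores SPD
                dense.flat[:: self.n + 1] += 1e-10 * max(1.0, dense.diagonal().max())
                self._chol = np.linalg.cholesky(dense)
            self._solve = self._dense_solve
        else:
            self._lu = splu(k.tocsc(), permc_spec="COLAMD",
                            options={"SymmetricMode": True})
            self._solve = self._lu.solve
        self._cache: dict[int, np.ndarray] = {}

    def _dense_solve(self, b: np.ndarray) -> np.ndarray:
        y = np.linalg.solve(self._chol, b)
        return np.linalg.solve(self._chol.T, y)

    def potential(self, node: int) -> np.ndarray:
        """Solve K v = e_node (unit current at node, ground at potential 0)."""
        if node not in self._cache:
            b = np.zeros(self.n)
            b[self.local[node]] = 1.0
            self._cache[node] = self._solve(b)
        return self._cache[node]

    def resistance(self, a: int, b: int) -> float:
        if a == b:
            return 0.0
        if a == self.ground:
            a, b = b, a
        va = self.potential(a)
        if b == self.ground:
            return float(va[self.local[a]])
        vb = self.potential(b)
        la, lb = self.local[a], self.local[b]
        return float(va[la] - va[lb] - vb[la] + vb[lb])


def effective_resistance(graph: ConductanceGraph, node_a: int, node_b: int) -> float:
    """Effective resistance between two nodes; ``inf`` if disconnected."""
    if not (0 <= node_a < graph.n_nodes and 0 <= node_b < graph.n_nodes):
        raise IndexError("node index out of range")
    if node_a == node_b:
        return 0.0
    if graph.component[node_a] != graph.component[node_b]:
        return np.inf
    solver = _ComponentSolver(graph, graph.component[node_a], ground=node_b)
    return solver.resistance(node_a, node_b)


def snap_to_finite(raster: ResistanceRaster, x: float, y: float,
                   radius_m: float = SNAP_RADIUS_M) -> tuple[int, int]:
    """Nearest finite cell within ``radius_m`` of (x, y); ties broken by
    (row, col) order.  Raises ``ValueError`` if none exists."""
    row, col = raster.world_to_cell(x, y)
    r = int(np.ceil(radius_m / raster.cell_m)) + 1
    r0, r1 = max(0, row - r), min(raster.n_rows, row + r + 1)
    c0, c1 = max(0, col - r), min(raster.n_cols, col + r + 1)
    window = raster.finite_mask[r0:r1, c0:c1]
    if not window.any():
        raise ValueError(f"no finite cell within {radius_m} m of ({x}, {y})")
    rows, cols = np.nonzero(window)
    cx, cy = raster.cell_center(rows + r0, cols + c0)
    dist = np.hypot(cx - x, cy - y)
    order = np.lexsort((cols, rows, dist))
    best = order[0]
    if dist[best] > radius_m:
        raise ValueError(f"no finite cell within {radius_m} m of ({x}, {y})")
    return int(rows[best] + r0), int(cols[best] + c0)


def pairwise_resistance(
    raster: ResistanceRaster,
    plots: pd.DataFrame,
    neighborhood: int = 8,
) -> pd.DataFrame:
    """Effective resistance between all pairs of plots on one raster.

    ``plots`` needs columns ``plot_id, x, y`` (one study area at a time).
    Returns one row per unordered pair with columns ``plot_a, plot_b,
    resistance_ohm, connected``; pairs in different raster components get
    ``resistance_ohm = inf`` and ``connected = False``.
    """
    graph = raster_to_graph(raster, neighborhood=neighborhood)
    nodes = {}
    for rec in plots.itertuples(index=False):
        try:
            row, col = snap_to_finite(raster, rec.x, rec.y)
        except ValueError as err:
            raise ValueError(f"plot {rec.plot_id}: {err}") from err
        nodes[rec.plot_id] = int(graph.node_index[row, col])

    solvers: dict[int, _ComponentSolver] = {}
    out = []
    ids = list(plots["plot_id"])
    for ia in range(len(ids)):
        for ib in range(ia + 1, len(ids)):
            pa, pb = ids[ia], ids[ib]
            na, nb = nodes[pa], nodes[pb]
            ca, cb = graph.component[na], graph.component[nb]
            if ca != cb:
                out.append((pa, pb, np.inf, False))
                continue
            if ca not in solvers:
                solvers[ca] = _ComponentSolver(graph, ca, ground=na)
            out.append((pa, pb, solvers[ca].resistance(na, nb), True))
    return pd.DataFrame(out, columns=["plot_a", "plot_b", "resistance_ohm", "connected"])
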