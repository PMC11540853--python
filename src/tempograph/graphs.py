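"""Stimulus-transition graphs and their distance templates.

The experiment orders image presentations by a random walk on a small
labelled graph.  Whether neural population geometry tracks that graph is
assessed by comparing empirical representational distance matrices against
*templates* derived from the graph:

``geodesic``
    Shortest-path edge counts.
``euclidean``
    Geodesic distances except for node pairs that form the hypotenuse of a
    unit right triangle on the pyramid layout, which get sqrt(2).
``successor``
    The negative matrix exponential of the adjacency matrix, ``-e^A``.
    ``e^A = sum_n A^n / n!`` counts paths of every length with factorial
    discounting, so entries grow with the expected future co-occurrence of
    two nodes under a random walk; negation orients the matrix as a
    distance (larger = farther).
``discounted_successor``
    ``(I - gamma*A)^{-1} = sum_n gamma^n A^n``, the resolvent form of the
    successor representation with geometric discount ``gamma``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import pdist, squareform

INNER = "inner"
OUTER = "outer"

__all__ = [
    "GraphSpec",
    "DistanceTemplate",
    "build_pyramid",
    "build_diamond",
    "geodesic_template",
    "euclidean_template",
    "successor_template",
    "discounted_successor_template",
    "mds_embed",
    "embedded_distances",
    "shift_positive",
]


@dataclass(frozen=True)
class GraphSpec:
    """An undirected, connected, unweighted experiment graph.

    Parameters
    ----------
    node_ids : tuple of int
        Ordered node labels; row/column order of ``adjacency``.
    roles : tuple of str
        Per-node tag, ``"inner"`` or ``"outer"``.
    adjacency : ndarray
        Square binary adjacency matrix, symmetric, zero diagonal.
    coords : ndarray or None
        Optional 2-D display layout (n_nodes x 2).
    """

    node_ids: tuple
    roles: tuple
    adjacency: np.ndarray
    coords: np.ndarray | None = None

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have zero diagonal (no self-loops)")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        n = a.shape[0]
        if len(self.node_ids) != n or len(self.roles) != n:
            raise ValueError("node_ids/roles length must match adjacency")
        # connectivity
        d = shortest_path(a, method="D", unweighted=True)
        if np.isinf(d).any():
            i, j = np.argwhere(np.isinf(d))[0]
            raise ValueError(
                f"graph is disconnected: no path between nodes "
                f"{self.node_ids[i]} and {self.node_ids[j]}"
            )
        object.__setattr__(self, "adjacency", a.astype(float))

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index(self, node) -> int:
        return self.node_ids.index(node)

    def degree(self, node) -> int:
        return int(self.adjacency[self.index(node)].sum())

    def neighbors(self, node) -> list:
        i = self.index(node)
        return [self.node_ids[j] for j in np.flatnonzero(self.adjacency[i])]

    def non_neighbors(self, node) -> list:
        i = self.index(node)
        return [
            self.node_ids[j]
            for j in range(self.n_nodes)
            if j != i and self.adjacency[i, j] == 0
        ]

    def is_edge(self, u, v) -> bool:
        return bool(self.adjacency[self.index(u), self.index(v)])

    def role_of(self, node) -> str:
        return self.roles[self.index(node)]

    def to_json(self) -> str:
        obj = {
            "nodes": [
                {"id": int(i), "role": r} for i, r in zip(self.node_ids, self.roles)
            ],
            "edges": [
                [int(self.node_ids[i]), int(self.node_ids[j])]
                for i, j in zip(*np.triu_indices(self.n_nodes, 1))
                if self.adjacency[i, j]
            ],
        }
        if self.coords is not None:
            obj["coords"] = np.asarray(self.coords).tolist()
        return json.dumps(obj, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GraphSpec":
        obj = json.loads(text)
        ids = tuple(n["id"] for n in obj["nodes"])
        roles = tuple(n["role"] for n in obj["nodes"])
        a = np.zeros((len(ids), len(ids)))
        for u, v in obj["edges"]:
            i, j = ids.index(u), ids.index(v)
            a[i, j] = a[j, i] = 1
        coords = np.asarray(obj["coords"]) if "coords" in obj else None
        return cls(ids, roles, a, coords)


@dataclass(frozen=True)
class DistanceTemplate:
    """A node-pair distance matrix on the common 'larger = farther' scale."""

    kind: str
    matrix: np.ndarray
    node_ids: tuple
    gamma: float | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T):
            raise ValueError("template matrix must be symmetric")
        if not np.isfinite(m).all():
            raise ValueError("template matrix must be finite")
        # note: the diagonal is constant for path-length templates but not
        # for successor templates (closed-walk counts depend on degree);
        # all statistics use off-diagonal entries only
        object.__setattr__(self, "matrix", m)

    def offdiag(self) -> np.ndarray:
        """Upper-triangle off-diagonal entries (the statistic carrier)."""
        iu = np.triu_indices(self.matrix.shape[0], 1)
        return self.matrix[iu]

    def to_csv(self) -> str:
        header = "," + ",".join(str(i) for i in self.node_ids)
        rows = [
            f"{self.node_ids[i]}," + ",".join(f"{v:.10g}" for v in row)
            for i, row in enumerate(self.matrix)
        ]
        return "\n".join([header, *rows]) + "\n"


# three unit right triangles on the pyramid; the first pair of each is the
# hypotenuse used by the euclidean template
_PYRAMID_HYPOTENUSES = ((1, 5), (4, 3), (6, 2))


def build_pyramid() -> GraphSpec:
    """Canonical 6-node pyramid: complete inner triangle {1, 3, 6}, with
    each outer node (2, 4, 5) attached to a distinct pair of inner nodes.

    9 edges; inner nodes have degree 4, outer nodes degree 2; every
    non-adjacent pair is exactly two edges apart.
    """
    node_ids = (1, 2, 3, 4, 5, 6)
    roles = (INNER, OUTER, INNER, OUTER, OUTER, INNER)
    edges = [(1, 3), (1, 6), (3, 6), (2, 1), (2, 3), (4, 1), (4, 6), (5, 3), (5, 6)]
    a = np.zeros((6, 6))
    for u, v in edges:
        a[u - 1, v - 1] = a[v - 1, u - 1] = 1
    # display layout: inner equilateral triangle, outer nodes reflected
    # outward across their adjacent inner edge (display only)
    s3 = np.sqrt(3) / 2
    coords = np.array(
        [
            [0.0, 0.0],  # 1
            [0.5, -s3],  # 2 (outside edge 1-3)
            [1.0, 0.0],  # 3
            [-0.5, s3],  # 4 (outside edge 1-6)
            [1.5, s3],  # 5 (outside edge 3-6)
            [0.5, 2 * s3],  # 6
        ]
    )
    return GraphSpec(node_ids, roles, a, coords)


def build_diamond() -> GraphSpec:
    """Diamond-shaped control graph whose non-adjacent node pairs sit at
    geodesic distance two *or* three (a 6-cycle with one chord).

    Nodes on the chord are tagged inner, the rest outer.
    """
    node_ids = (1, 2, 3, 4, 5, 6)
    a = np.zeros((6, 6))
    cycle = [(1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 1)]
    for u, v in cycle + [(2, 6)]:  # chord
        a[u - 1, v - 1] = a[v - 1, u - 1] = 1
    roles = (OUTER, INNER, OUTER, OUTER, OUTER, INNER)
    theta = np.pi / 2 + np.arange(6) * np.pi / 3
    coords = np.column_stack([np.cos(theta), np.sin(theta)])
    return GraphSpec(node_ids, roles, a, coords)


def geodesic_template(g: GraphSpec) -> DistanceTemplate:
    """All-pairs shortest-path edge counts."""
    d = shortest_path(g.adjacency, method="D", unweighted=True)
    return DistanceTemplate("geodesic", d, g.node_ids)


def euclidean_template(g: GraphSpec) -> DistanceTemplate:
    """Geodesic distances except that non-adjacent inner–outer pairs at
    distance two form the hypotenuse of a unit right triangle and get
    sqrt(2) (Pythagoras); edges stay at 1, remaining pairs at geodesic.
    """
    d = shortest_path(g.adjacency, method="D", unweighted=True).astype(float)
    found = False
    for i in range(g.n_nodes):
        for j in range(i + 1, g.n_nodes):
            if d[i, j] == 2 and {g.roles[i], g.roles[j]} == {INNER, OUTER}:
                d[i, j] = d[j, i] = np.sqrt(2.0)
                found = True
    if not found:
        raise ValueError(
            "graph has no non-adjacent inner-outer pair at distance 2; "
            "euclidean template is undefined"
        )
    return DistanceTemplate("euclidean", d, g.node_ids)


def successor_template(g: GraphSpec) -> DistanceTemplate:
    """Successor template ``-e^A``: path counts of all lengths with
    factorial discounting, negated so larger means farther."""
    return DistanceTemplate("successor", -expm(g.adjacency), g.node_ids)


def discounted_successor_template(g: GraphSpec, gamma: float) -> DistanceTemplate:
    """Discounted successor template, distance-oriented ``-(I - gamma*A)^{-1}``.

    The resolvent series ``sum_n gamma^n A^n`` converges only for
    ``gamma < 1/rho(A)`` (spectral radius); larger values raise ``ValueError``.
    """
    if not 0 < gamma < 1:
        raise ValueError("gamma must be in (0, 1)")
    rho = float(np.max(np.abs(np.linalg.eigvals(g.adjacency))))
    if rho > 0 and gamma >= 1.0 / rho:
        raise ValueError(
            f"gamma={gamma} >= 1/spectral radius = {1.0 / rho:.6g}; "
            "the discounted successor series diverges"
        )
    m = np.linalg.inv(np.eye(g.n_nodes) - gamma * g.adjacency)
    return DistanceTemplate("discounted_successor", -m, g.node_ids, gamma=gamma)


def shift_positive(matrix: np.ndarray, constant: float = 0.1) -> np.ndarray:
    """Shift a matrix entirely positive by adding |min| + constant."""
    m = np.asarray(matrix, dtype=float)
    return m + abs(m.min()) + constant


def _sammon_stress_grad(x_flat, d_target, n):
    x = x_flat.reshape(n, 2)
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(n, 1)
    dt = d_target[iu]
    de = d[iu]
    scale = dt.sum()
    stress = (((de - dt) ** 2) / dt).sum() / scale
    # gradient
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(d > 0, (d - d_target) / (d_target * np.maximum(d, 1e-12)), 0.0)
    np.fill_diagonal(w, 0.0)
    grad = 2.0 / scale * (w[:, :, None] * diff).sum(axis=1)
    return stress, grad.ravel()


def mds_embed(
    template,
    n_restarts: int = 100,
    seed: int = 0,
    shift_constant: float = 0.1,
) -> np.ndarray:
    """Embed a distance matrix in 2-D by minimising Sammon stress.

    The matrix is first shifted positive (|min| + ``shift_constant`` added
    to every entry), then ``n_restarts`` random initialisations are refined
    with L-BFGS and the lowest-stress solution is returned.  Deterministic
    given ``seed``.
    """
    m = template.matrix if isinstance(template, DistanceTemplate) else np.asarray(template, float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or not np.allclose(m, m.T):
        raise ValueError("mds_embed requires a square symmetric matrix")
    n = m.shape[0]
    d = shift_positive(m, shift_constant)
    np.fill_diagonal(d, 0.0)
    rng = np.random.default_rng(seed)
    best, best_stress = None, np.inf
    for _ in range(n_restarts):
        x0 = rng.normal(scale=d.max() / 2, size=(n, 2)).ravel()
        res = minimize(
            _sammon_stress_grad,
            x0,
            args=(d, n),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500},
        )
        if res.fun < best_stress:
            best_stress, best = res.fun, res.x.reshape(n, 2)
    return best


def embedded_distances(coords: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances of an embedding (square form)."""
    return squareform(pdist(np.asarray(coords, float)))
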