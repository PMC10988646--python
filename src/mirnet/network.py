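"""Signed phenotype-hub networks built from association records.

Each phenotype gets up to two hub nodes — ``<phenotype>_pos`` for
positive and ``<phenotype>_neg`` for negative correlations — and each
significant miRNA links to the relevant hub with edge weight
100 * |rho|.  The graph is bipartite by construction (miRNA nodes on one
side, hubs on the other); node degree records the number of connections,
which drives node size in plots.

Layout is a two-phase force-directed loop: phase A applies weighted
edge attraction plus pairwise repulsion, phase B pulls nodes toward the
origin with a gravity force scaled by degree.  Iteration stops at a
steady state (max displacement below tolerance), a detected limit cycle
(repeated position digest), or the iteration cap.  Coordinates are
presentation-only and never feed any statistic.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import ValidationError

__all__ = [
    "PhenotypeNetwork",
    "LayoutState",
    "build_network",
    "two_step_gravity_layout",
    "degree_table",
    "plot_network",
]


class PhenotypeNetwork:
    """Bipartite signed network of miRNA nodes and phenotype hub nodes."""

    def __init__(self, graph: nx.Graph, coordinates: dict[str, tuple[float, float]] | None = None):
        self.graph = graph
        self.coordinates = coordinates

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_of_kind(self, kind: str) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == kind]

    @property
    def hubs(self) -> list[str]:
        return self.nodes_of_kind("phenotype_hub")

    @property
    def mirnas(self) -> list[str]:
        return self.nodes_of_kind("mirna")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PhenotypeNetwork({len(self.hubs)} hubs, {len(self.mirnas)} miRNAs, "
            f"{self.n_edges} edges)"
        )


def build_network(records: pd.DataFrame) -> PhenotypeNetwork:
    """Build the signed hub network from (pre-filtered) association records.

    One hub per (phenotype, sign) with at least one record; one node per
    distinct miRNA; edge weight = 100 * |rho|.
    """
    g = nx.Graph()
    if len(records) == 0:
        return PhenotypeNetwork(g)
    for row in records.sort_values(["phenotype", "mirna"], kind="mergesort").itertuples():
        suffix = "pos" if row.sign == "positive" else "neg"
        hub = f"{row.phenotype}_{suffix}"
        if hub not in g:
            g.add_node(hub, kind="phenotype_hub", sign=suffix)
        if row.mirna not in g:
            g.add_node(row.mirna, kind="mirna", sign=None)
        g.add_edge(
            row.mirna,
            hub,
            weight=100.0 * abs(float(row.rho)),
            rho=float(row.rho),
            p=float(row.p),
        )
    return PhenotypeNetwork(g)


@dataclass
class LayoutState:
    """Coordinates plus convergence bookkeeping of the gravity loop."""

    coordinates: dict[str, tuple[float, float]]
    iterations: int
    displacement: float
    converged: bool
    limit_cycle: bool
    digest_history: list[str] = field(default_factory=list)


def _digest(pos: np.ndarray) -> str:
    return hashlib.sha1(np.round(pos, 4).tobytes()).hexdigest()


def two_step_gravity_layout(
    net: PhenotypeNetwork,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-3,
    attraction: float = 0.01,
    repulsion: float = 1.0,
    gravity: float = 0.05,
    step: float = 0.1,
) -> LayoutState:
    """Two-phase force-directed layout, deterministic given ``seed``.

    Per iteration, phase A moves nodes under weighted linear attraction
    along edges and inverse-distance pairwise repulsion; phase B applies
    a radial pull toward the origin proportional to (1 + degree).
    Terminates on steady state (max displacement < tol), on a repeated
    rounded-position digest (limit cycle), or at ``max_iter``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    g = net.graph
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n == 0:
        raise ValidationError("cannot lay out an empty network")
    rng = np.random.default_rng(seed)
    pos = rng.standard_normal((n, 2))
    if n == 1:
        # a lone node has no pairwise forces; gravity parks it at the origin
        return LayoutState({nodes[0]: (0.0, 0.0)}, 1, 0.0, True, False)
    idx = {v: i for i, v in enumerate(nodes)}
    edges = np.array([(idx[u], idx[v]) for u, v in g.edges], dtype=int)
    weights = np.array([d["weight"] for _, _, d in g.edges(data=True)], dtype=float)
    degree = np.array([g.degree(v) for v in nodes], dtype=float)

    digests: list[str] = []
    it, disp, converged, cycle = 0, np.inf, False, False
    for it in range(1, max_iter + 1):
        prev = pos.copy()
        # phase A: attraction along edges + global repulsion
        force = np.zeros_like(pos)
        if len(edges):
            delta = pos[edges[:, 1]] - pos[edges[:, 0]]
            pull = attraction * weights[:, None] * delta
            np.add.at(force, edges[:, 0], pull)
            np.add.at(force, edges[:, 1], -pull)
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(dist, np.inf)
        dist = np.maximum(dist, 1e-6)
        force += repulsion * (diff / dist[..., None] ** 2).sum(axis=1)
        move = step * force
        norm = np.linalg.norm(move, axis=1, keepdims=True)
        move = np.where(norm > 1.0, move / norm, move)  # displacement cap
        pos = pos + move
        # phase B: degree-scaled gravity toward the origin
        pos = pos - step * gravity * (1.0 + degree[:, None]) * pos
        disp = float(np.abs(pos - prev).max())
        if disp < tol:
            converged = True
            break
        d = _digest(pos)
        if d in digests:
            cycle = True
            break
        digests.append(d)
        if len(digests) > 50:
            digests.pop(0)
    coords = {v: (float(pos[i, 0]), float(pos[i, 1])) for i, v in enumerate(nodes)}
    state = LayoutState(coords, it, disp, converged, cycle, digests)
    net.coordinates = coords
    return state


def degree_table(net: PhenotypeNetwork) -> pd.DataFrame:
    """Node/kind/sign/degree table sorted by descending degree, then name."""
    rows = [
        {
            "node": v,
            "kind": d["kind"],
            "sign": d.get("sign") or "",
            "degree": net.graph.degree(v),
        }
        for v, d in net.graph.nodes(data=True)
    ]
    df = pd.DataFrame(rows, columns=["node", "kind", "sign", "degree"])
    if len(df):
        df = df.sort_values(["degree", "node"], ascending=[False, True], kind="mergesort")
    return df.reset_index(drop=True)


def plot_network(net: PhenotypeNetwork, path=None, ax=None):
    """Static scatter of the layout; node size proportional to degree."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if net.coordinates is None:
        two_step_gravity_layout(net)
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 7))
    for u, v, d in net.graph.edges(data=True):
        xs = [net.coordinates[u][0], net.coordinates[v][0]]
        ys = [net.coordinates[u][1], net.coordinates[v][1]]
        rho = d["rho"]
        ax.plot(xs, ys, color=("purple" if rho > 0 else "teal"), lw=0.3, alpha=0.5, zorder=1)
    for kind, color in [("mirna", "steelblue"), ("phenotype_hub", "darkorange")]:
        ns = net.nodes_of_kind(kind)
        if not ns:
            continue
        xy = np.array([net.coordinates[v] for v in ns])
        sizes = np.array([10 + 12 * net.graph.degree(v) for v in ns])
        ax.scatter(xy[:, 0], xy[:, 1], s=sizes, c=color, zorder=2, label=kind)
    for v in net.hubs:
        ax.annotate(v, net.coordinates[v], fontsize=7)
    ax.set_axis_off()
    ax.legend(loc="lower right", fontsize=7)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
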