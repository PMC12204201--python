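"""Interaction-network I/O, set algebra, and degree-distribution analysis.

A protein interaction network (PIN) is modelled as an undirected simple
graph over string identifiers.  Directionality and edge annotations in the
source files are discarded: the entropy-rate model only uses symmetric
neighbourhoods.  Edge-reliability scores live in a separate structure
(:mod:`sigentropy.correction`), never on the graph itself.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.special import zeta

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "DegreeHistogram",
    "PowerLawFit",
    "NetworkParseError",
    "read_network",
    "read_mapping_table",
    "write_edgelist",
    "network_union",
    "network_intersection",
    "largest_connected_component",
    "degree_distribution",
    "fit_power_law",
    "sample_power_law_degrees",
]


class NetworkParseError(ValueError):
    """Raised when a network file does not parse in its declared dialect."""


def _canonical(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass
class InteractionNetwork:
    """Undirected simple graph of gene/protein identifiers.

    Invariants: no self-loops, no duplicate edges, every edge endpoint is a
    node, identifiers are non-empty strings.
    """

    graph: nx.Graph
    name: str = ""

    def __post_init__(self) -> None:
        for node in self.graph.nodes:
            if not isinstance(node, str) or not node:
                raise ValueError(f"node identifiers must be non-empty strings, got {node!r}")
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops not allowed: {loops[:3]}")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        name: str = "",
        nodes: Iterable[str] = (),
    ) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        n_loops = 0
        for u, v in edges:
            if u == v:
                n_loops += 1
                g.add_node(u)
                continue
            g.add_edge(u, v)
        if n_loops:
            logger.warning("dropped %d self-loop(s) while building %r", n_loops, name)
        return cls(g, name)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {_canonical(u, v) for u, v in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return int(self.graph.degree[node])

    def neighbors(self, node: str) -> set[str]:
        return set(self.graph.neighbors(node))

    def copy(self, name: str | None = None) -> "InteractionNetwork":
        return InteractionNetwork(self.graph.copy(), self.name if name is None else name)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges


@dataclass(frozen=True)
class DegreeHistogram:
    """Histogram of node degrees >= 1 (isolated nodes are not counted)."""

    counts: Mapping[int, int]

    def __post_init__(self) -> None:
        for k, c in self.counts.items():
            if k < 1 or c < 0:
                raise ValueError("degrees must be >= 1 and counts nonnegative")

    @property
    def n_nodes(self) -> int:
        return sum(self.counts.values())

    def expand(self) -> np.ndarray:
        """All degree observations as a flat array."""
        return np.repeat(
            np.fromiter(self.counts.keys(), dtype=np.int64),
            np.fromiter(self.counts.values(), dtype=np.int64),
        )


@dataclass(frozen=True)
class PowerLawFit:
    """Maximum-likelihood power-law fit p(k) ~ k^-gamma for k >= xmin."""

    gamma: float
    xmin: int
    loglik: float
    n_tail: int = 0
    ks_distance: float = math.nan

    def __post_init__(self) -> None:
        if not self.gamma > 1:
            raise ValueError(f"gamma must be > 1, got {self.gamma}")
        if self.xmin < 1:
            raise ValueError(f"xmin must be >= 1, got {self.xmin}")


# ---------------------------------------------------------------------------
# Readers / writers


def read_mapping_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping source identifier -> target identifier."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise NetworkParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            mapping[parts[0]] = parts[1]
    return mapping


def read_network(
    path: str | Path,
    format: str = "edgelist",
    name: str | None = None,
    mapping: Mapping[str, str] | None = None,
) -> InteractionNetwork:
    """Read an interaction network from a text file.

    Supported dialects:

    ``edgelist``
        Two whitespace/tab-separated identifier columns; ``#`` comments
        ignored.
    ``sif``
        ``node1 relation node2 [node3 ...]``; the relation label is ignored.
    ``string_links``
        STRING protein-links table with header
        ``protein1 protein2 combined_score`` (score 0-1000, ignored here;
        use :func:`sigentropy.correction.load_string_scores` for scores).

    Duplicate lines and reversed duplicates collapse to one undirected
    edge; self-loops are dropped with a warning.  An optional two-column
    ``mapping`` renames identifiers at read time (entries absent from the
    mapping keep their original name).
    """
    path = Path(path)
    if format not in {"edgelist", "sif", "string_links"}:
        raise ValueError(f"unknown network format {format!r}")

    def remap(x: str) -> str:
        return mapping.get(x, x) if mapping else x

    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        lines = fh.readlines()
    if format == "string_links":
        if not lines:
            raise NetworkParseError(f"{path}: empty file")
        header = lines[0].split()
        if header[:3] != ["protein1", "protein2", "combined_score"]:
            raise NetworkParseError(f"{path}:1: missing string_links header")
        body = list(enumerate(lines[1:], 2))
    else:
        body = list(enumerate(lines, 1))

    n_parsed = 0
    for lineno, line in body:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if format == "edgelist":
            if len(parts) != 2:
                raise NetworkParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            pairs = [(parts[0], parts[1])]
        elif format == "sif":
            if len(parts) < 3:
                raise NetworkParseError(f"{path}:{lineno}: SIF line needs >= 3 columns")
            pairs = [(parts[0], t) for t in parts[2:]]
        else:  # string_links
            if len(parts) != 3:
                raise NetworkParseError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                score = int(parts[2])
            except ValueError as exc:
                raise NetworkParseError(f"{path}:{lineno}: bad combined_score {parts[2]!r}") from exc
            if not 0 <= score <= 1000:
                raise NetworkParseError(f"{path}:{lineno}: combined_score {score} outside 0-1000")
            pairs = [(parts[0], parts[1])]
        for u, v in pairs:
            edges.append((remap(u), remap(v)))
            n_parsed += 1
    if n_parsed == 0:
        raise NetworkParseError(f"{path}: no edges found")
    return InteractionNetwork.from_edges(edges, name=name if name is not None else path.stem)


def write_edgelist(net: InteractionNetwork, path: str | Path) -> None:
    """Write a network as a two-column tab-separated edge list (sorted)."""
    with open(path, "w") as fh:
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")


# ---------------------------------------------------------------------------
# Set algebra


def network_union(networks: Sequence[InteractionNetwork]) -> InteractionNetwork:
    """Union of node sets and edge sets."""
    if not networks:
        raise ValueError("network_union of an empty list")
    g = nx.Graph()
    for net in networks:
        g.add_nodes_from(net.graph.nodes)
        g.add_edges_from(net.graph.edges)
    return InteractionNetwork(g, name="union")


def network_intersection(networks: Sequence[InteractionNetwork]) -> InteractionNetwork:
    """Intersection of edge sets; isolated nodes are dropped."""
    if not networks:
        raise ValueError("network_intersection of an empty list")
    common = set(networks[0].edges)
    for net in networks[1:]:
        common &= net.edges
    g = nx.Graph()
    g.add_edges_from(common)
    return InteractionNetwork(g, name="intersection")


def largest_connected_component(net: InteractionNetwork) -> InteractionNetwork:
    """Induced subgraph on the largest connected component.

    Ties are broken by the lexicographically smallest sorted node list, so
    the result is deterministic.
    """
    if net.n_nodes == 0:
        raise ValueError("largest_connected_component of an empty network")
    comps = [sorted(c) for c in nx.connected_components(net.graph)]
    comps.sort(key=lambda c: (-len(c), c))
    best = comps[0]
    return InteractionNetwork(net.graph.subgraph(best).copy(), name=net.name)


def degree_distribution(net: InteractionNetwork) -> DegreeHistogram:
    """Histogram over node degrees >= 1."""
    if net.n_nodes == 0:
        raise ValueError("degree_distribution of an empty network")
    counts: dict[int, int] = {}
    for _, k in net.graph.degree:
        if k >= 1:
            counts[k] = counts.get(k, 0) + 1
    return DegreeHistogram(counts)


# ---------------------------------------------------------------------------
# Power-law fitting (discrete MLE with KS-selected xmin)


def _zeta(gamma: float, xmin: int) -> float:
    return float(zeta(gamma, xmin))


def _discrete_loglik(gamma: float, degrees: np.ndarray, xmin: int) -> float:
    n = degrees.size
    return -n * math.log(_zeta(gamma, xmin)) - gamma * float(np.log(degrees).sum())


def _fit_discrete_gamma(degrees: np.ndarray, xmin: int) -> tuple[float, float]:
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda g: -_discrete_loglik(g, degrees, xmin),
        bounds=(1.0 + 1e-6, 12.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x), float(-res.fun)


def _fit_continuous_gamma(degrees: np.ndarray, xmin: int) -> tuple[float, float]:
    n = degrees.size
    s = float(np.log(degrees / xmin).sum())
    if s <= 0:
        raise ValueError("cannot fit: degenerate degree sample")
    gamma = 1.0 + n / s
    loglik = n * math.log(gamma - 1.0) - n * math.log(xmin) - gamma * s
    return gamma, loglik


def _ks_distance(degrees: np.ndarray, gamma: float, xmin: int) -> float:
    """KS distance between the empirical tail CDF and the zeta model."""
    ks = np.sort(np.unique(degrees))
    z0 = _zeta(gamma, xmin)
    # model CDF at k: 1 - zeta(gamma, k+1)/zeta(gamma, xmin)
    model = 1.0 - np.array([_zeta(gamma, int(k) + 1) for k in ks]) / z0
    counts = np.searchsorted(np.sort(degrees), ks, side="right")
    empirical = counts / degrees.size
    return float(np.max(np.abs(empirical - model)))


def fit_power_law(
    hist: DegreeHistogram,
    xmin: int | None = None,
    method: str = "discrete",
) -> PowerLawFit:
    """Fit the scale exponent gamma of a power-law degree distribution.

    With ``method="discrete"`` (default) the exponent maximises the zeta
    likelihood p(k) = k^-gamma / zeta(gamma, xmin).  With
    ``method="continuous"`` the closed-form Hill-type estimator
    ``1 + n / sum(log(k / xmin))`` is used instead.  When ``xmin`` is not
    given it is selected by minimising the Kolmogorov-Smirnov distance
    between the fitted model and the empirical tail.
    """
    if method not in {"discrete", "continuous"}:
        raise ValueError(f"unknown method {method!r}")
    all_deg = hist.expand()
    if all_deg.size == 0:
        raise ValueError("cannot fit: empty histogram")

    def fit_at(xm: int) -> PowerLawFit:
        tail = all_deg[all_deg >= xm].astype(float)
        if np.unique(tail).size < 3:
            raise ValueError("cannot fit: fewer than 3 distinct degrees above xmin")
        if method == "discrete":
            gamma, loglik = _fit_discrete_gamma(tail, xm)
        else:
            gamma, loglik = _fit_continuous_gamma(tail, xm)
        ks = _ks_distance(tail.astype(np.int64), gamma, xm)
        return PowerLawFit(gamma=gamma, xmin=xm, loglik=loglik, n_tail=tail.size, ks_distance=ks)

    if xmin is not None:
        return fit_at(int(xmin))

    candidates = sorted(set(int(k) for k in np.unique(all_deg)))
    best: PowerLawFit | None = None
    for xm in candidates:
        try:
            fit = fit_at(xm)
        except ValueError:
            continue
        if best is None or fit.ks_distance < best.ks_distance:
            best = fit
    if best is None:
        raise ValueError("cannot fit: no admissible xmin (degenerate degrees)")
    return best


def sample_power_law_degrees(
    n: int,
    gamma: float,
    xmin: int = 1,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` degrees from the discrete (zeta) power law, exactly.

    Inverse-CDF sampling against the Hurwitz-zeta survival function; used
    as the reference generator when validating :func:`fit_power_law`.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u = rng.random(n)
    z0 = _zeta(gamma, xmin)
    # cumulative pmf table, extended until it covers the largest u
    kmax = xmin + 1024
    while True:
        ks = np.arange(xmin, kmax + 1, dtype=np.float64)
        pmf = ks ** (-gamma) / z0
        cdf = np.cumsum(pmf)
        if cdf[-1] >= u.max() or kmax > 10**8:
            break
        kmax *= 4
    idx = np.searchsorted(cdf, u, side="left")
    idx = np.minimum(idx, len(ks) - 1)
    return (idx + xmin).astype(np.int64)
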