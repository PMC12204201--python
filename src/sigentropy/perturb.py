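"""Random edge perturbations of an interaction network and sweep experiments.

Four operators model distinct kinds of interactome corruption, each applied
to a stated fraction (the *level*) of the original edge set:

``add``
    insert new edges between non-adjacent pairs (false positives);
``remove``
    delete existing edges (false negatives);
``flip``
    relocate existing edges to random non-adjacent pairs (edge count
    preserved, degrees not);
``rewire``
    degree-preserving double-edge swaps until the requested fraction of
    original edges has been displaced.

Levels are measured against the ORIGINAL edge set: level 0.9 means 90% of
the initial interactions affected.  All operators are deterministic given
their seed.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .entropy import ExpressionMatrix, entropy_table, integrate
from .network import (
    InteractionNetwork,
    degree_distribution,
    fit_power_law,
    largest_connected_component,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PerturbationSpec",
    "add_edges",
    "remove_edges",
    "flip_edges",
    "rewire_edges",
    "perturb",
    "perturbation_sweep",
    "derive_seed",
]

KINDS = ("add", "remove", "flip", "rewire")


@dataclass(frozen=True)
class PerturbationSpec:
    """One perturbation: kind, fraction of |E| affected, RNG seed."""

    kind: str
    level: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if not 0 < self.level <= 0.9:
            raise ValueError(f"level must be in (0, 0.9], got {self.level}")

def _count(level: float, n_edges: int) -> int:
    """round-half-up of level * |E|."""
    return int(math.floor(level * n_edges + 0.5))


def derive_seed(seed: int, kind: str, level: float, replicate: int) -> int:
    """Stable per-cell seed so each sweep row is independently reproducible."""
    key = f"{seed}|{kind}|{level:.6f}|{replicate}".encode()
    return zlib.crc32(key) & 0x7FFFFFFF


def _sample_nonadjacent_pairs(
    graph,
    nodes: list[str],
    n_pairs: int,
    rng: np.random.Generator,
    forbidden: set[tuple[str, str]] | None = None,
) -> list[tuple[str, str]]:
    """Uniformly sample distinct non-adjacent node pairs by rejection.

    ``forbidden`` pairs (canonical order) are excluded even if currently
    non-adjacent.
    """
    n = len(nodes)
    forbidden = forbidden or set()
    extra = sum(1 for e in forbidden if not graph.has_edge(*e))
    capacity = n * (n - 1) // 2 - graph.number_of_edges() - extra
    if n_pairs > capacity:
        raise ValueError(
            f"cannot place {n_pairs} new edges: only {capacity} non-adjacent pairs available"
        )
    chosen: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    max_trials = 100 * max(n_pairs, 1) + 1000
    trials = 0
    while len(chosen) < n_pairs:
        trials += 1
        if trials > max_trials:
            # dense graph: fall back to explicit enumeration of free pairs
            free = [
                (nodes[i], nodes[j])
                for i in range(n)
                for j in range(i + 1, n)
                if not graph.has_edge(nodes[i], nodes[j])
                and (nodes[i], nodes[j]) not in seen
                and (nodes[i], nodes[j]) not in forbidden
            ]
            idx = rng.choice(len(free), size=n_pairs - len(chosen), replace=False)
            chosen.extend(free[i] for i in idx)
            break
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        u, v = (nodes[i], nodes[j]) if nodes[i] <= nodes[j] else (nodes[j], nodes[i])
        if graph.has_edge(u, v) or (u, v) in seen or (u, v) in forbidden:
            continue
        seen.add((u, v))
        chosen.append((u, v))
    return chosen


def add_edges(net: InteractionNetwork, spec: PerturbationSpec) -> InteractionNetwork:
    """Add round(level * |E|) edges between uniformly sampled non-adjacent
    pairs; original edges untouched."""
    rng = np.random.default_rng(spec.seed)
    g = net.graph.copy()
    nodes = sorted(g.nodes)
    n_new = _count(spec.level, g.number_of_edges())
    if n_new == 0:
        return InteractionNetwork(g, net.name)
    for u, v in _sample_nonadjacent_pairs(g, nodes, n_new, rng):
        g.add_edge(u, v)
    return InteractionNetwork(g, net.name)


def remove_edges(net: InteractionNetwork, spec: PerturbationSpec) -> InteractionNetwork:
    """Delete round(level * |E|) uniformly sampled edges.  Nodes are never
    removed; newly isolated nodes are counted in a warning."""
    rng = np.random.default_rng(spec.seed)
    g = net.graph.copy()
    edges = sorted((u, v) if u <= v else (v, u) for u, v in g.edges)
    n_del = _count(spec.level, len(edges))
    if n_del == 0:
        return InteractionNetwork(g, net.name)
    idx = rng.choice(len(edges), size=n_del, replace=False)
    g.remove_edges_from([edges[i] for i in idx])
    n_isolated = sum(1 for _, k in g.degree if k == 0)
    if n_isolated:
        logger.warning("remove_edges left %d isolated node(s)", n_isolated)
    return InteractionNetwork(g, net.name)


def flip_edges(net: InteractionNetwork, spec: PerturbationSpec) -> InteractionNetwork:
    """Relocate round(level * |E|) distinct original edges: each sampled
    edge is deleted and a new edge placed between a uniformly sampled
    currently non-adjacent pair.  Relocations never land on an original
    edge position, so the requested fraction of the original edge set is
    genuinely displaced.  |E| is preserved; degrees are not."""
    rng = np.random.default_rng(spec.seed)
    g = net.graph.copy()
    nodes = sorted(g.nodes)
    edges = sorted((u, v) if u <= v else (v, u) for u, v in g.edges)
    original = set(edges)
    n_flip = _count(spec.level, len(edges))
    if n_flip == 0:
        return InteractionNetwork(g, net.name)
    idx = rng.choice(len(edges), size=n_flip, replace=False)
    for i in idx:
        u, v = edges[i]
        g.remove_edge(u, v)
        a, b = _sample_nonadjacent_pairs(g, nodes, 1, rng, forbidden=original)[0]
        g.add_edge(a, b)
    assert g.number_of_edges() == len(edges)
    return InteractionNetwork(g, net.name)


def rewire_edges(net: InteractionNetwork, spec: PerturbationSpec) -> InteractionNetwork:
    """Degree-preserving double-edge swaps until round(level * |E|)
    distinct ORIGINAL edges have been displaced.

    Swaps draw two current edges (a, b), (c, d) with four distinct
    endpoints and exchange them for (a, d), (c, b) when neither exists.
    After 10 * |E| failed-or-successful trials without reaching the target
    the operation errors, reporting the fraction achieved.
    """
    rng = np.random.default_rng(spec.seed)
    g = net.graph.copy()
    original = {(u, v) if u <= v else (v, u) for u, v in g.edges}
    m = len(original)
    target = _count(spec.level, m)
    if target == 0:
        return InteractionNetwork(g, net.name)

    def displaced() -> int:
        current = {(u, v) if u <= v else (v, u) for u, v in g.edges}
        return len(original - current)

    max_trials = 10 * m
    trials = 0
    n_disp = 0
    while n_disp < target:
        if trials >= max_trials:
            raise ValueError(
                f"rewire: displaced only {n_disp}/{target} original edges "
                f"({n_disp / m:.2%} of |E|) after {max_trials} trials"
            )
        trials += 1
        edges = list(g.edges)
        i, j = rng.integers(0, len(edges), size=2)
        a, b = edges[i]
        c, d = edges[j]
        if len({a, b, c, d}) != 4:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d)
        g.add_edge(c, b)
        n_disp = displaced()
    assert g.number_of_edges() == m
    return InteractionNetwork(g, net.name)


_OPERATORS = {
    "add": add_edges,
    "remove": remove_edges,
    "flip": flip_edges,
    "rewire": rewire_edges,
}


def perturb(net: InteractionNetwork, spec: PerturbationSpec) -> InteractionNetwork:
    """Apply the operator named by ``spec.kind``."""
    return _OPERATORS[spec.kind](net, spec)


def perturbation_sweep(
    net: InteractionNetwork,
    expr: ExpressionMatrix,
    kinds: Sequence[str] = KINDS,
    levels: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    replicates: int = 5,
    seed: int = 0,
    measures: Sequence[str] = ("neq", "eq"),
    fit_gamma: bool = True,
    skip_cells: set[tuple[str, float, int]] | None = None,
) -> pd.DataFrame:
    """Entropy rates across a (kind x level x replicate) perturbation grid.

    For every cell the network is perturbed with a seed derived from
    ``(seed, kind, level, replicate)``, integrated with the expression
    matrix, and summarised: one output row per sample with the entropy
    rates, the size of the largest connected component, and (optionally)
    the fitted power-law exponent of the perturbed degree distribution.
    Cells listed in ``skip_cells`` are omitted (resume support).
    """
    rows = []
    for kind in kinds:
        for level in levels:
            for rep in range(replicates):
                if skip_cells and (kind, float(level), rep) in skip_cells:
                    continue
                cell_seed = derive_seed(seed, kind, level, rep)
                pert = perturb(net, PerturbationSpec(kind, level, cell_seed))
                lcc = largest_connected_component(pert)
                gamma = math.nan
                if fit_gamma:
                    try:
                        gamma = fit_power_law(degree_distribution(pert)).gamma
                    except ValueError:
                        logger.warning("gamma fit failed for %s level %.2f rep %d", kind, level, rep)
                system = integrate(pert, expr)
                table = entropy_table(system, measures=measures)
                for sample, row in table.iterrows():
                    rows.append(
                        {
                            "kind": kind,
                            "level": float(level),
                            "replicate": rep,
                            "sample": sample,
                            "sr_neq": row.get("sr_neq", math.nan),
                            "sr_eq": row.get("sr_eq", math.nan),
                            "lcc_nodes": lcc.n_nodes,
                            "lcc_edges": lcc.n_edges,
                            "gamma": gamma,
                        }
                    )
    return pd.DataFrame(rows)
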