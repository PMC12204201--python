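"""Signalling entropy rates of expression-weighted random walks on a PIN.

The model: expression values are integrated with an undirected interaction
network under the mass-action principle, so the probability that gene *i*
signals to a neighbour *j* in sample *s* is proportional to the product of
their expression values,

    p_ij = E_is * E_js / sum_{k in N_i} E_is * E_ks,

stored in a row-stochastic matrix P.  Each node's local entropy
S_i = -sum_j p_ij log p_ij (natural log) quantifies the promiscuity of its
signalling.  Two global summaries are derived per sample:

* the equilibrium entropy rate  SR_eq = sum_i pi_i S_i / M_R, where pi is
  the stationary distribution of P and M_R the maximum reachable entropy
  rate of the network (log of the adjacency spectral radius); and
* the non-equilibrium entropy rate  SR_neq = mean_i S_i / log k_i, the
  plain average of degree-normalized local entropies.

The chain is reversible (mass-action weights are symmetric), so pi has the
closed form pi_i ∝ E_is * sum_{k in N_i} E_ks; the fixed-point residual
||pi P - pi||_inf is asserted after every computation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import InteractionNetwork, largest_connected_component

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "IntegratedSystem",
    "TransitionMatrix",
    "EntropyProfile",
    "read_expression",
    "write_entropy_table",
    "integrate",
    "transition_matrix",
    "entropy_profile",
    "local_entropies",
    "normalized_local_entropies",
    "stationary_distribution",
    "max_entropy_rate",
    "equilibrium_rate",
    "nonequilibrium_rate",
    "entropy_table",
]


@dataclass
class ExpressionMatrix:
    """Nonnegative genes x samples expression values (unitless intensity)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers in expression matrix")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")
        if (arr < 0).any():
            raise ValueError("expression values must be nonnegative")

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    def sample_values(self, sample: str) -> pd.Series:
        return self.values[sample]


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV/CSV expression table: first column gene id, header row of
    sample ids."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df)


@dataclass
class IntegratedSystem:
    """A network and an expression matrix restricted to a common gene set.

    Every node has degree >= 1; zero expression values have been replaced,
    per sample, by epsilon = (smallest positive value in that sample) / 10
    so the mass-action transition probabilities stay defined.
    """

    network: InteractionNetwork
    expression: pd.DataFrame  # genes (node order) x samples, strictly positive
    epsilon: pd.Series  # per-sample replacement value
    node_order: list[str] = field(default_factory=list)
    _adjacency: sp.csr_matrix | None = field(default=None, repr=False)

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.expression.columns]

    @property
    def n_nodes(self) -> int:
        return len(self.node_order)

    def adjacency(self) -> sp.csr_matrix:
        if self._adjacency is None:
            import networkx as nx

            self._adjacency = nx.to_scipy_sparse_array(
                self.network.graph, nodelist=self.node_order, dtype=float, format="csr"
            )
        return self._adjacency

    def degrees(self) -> np.ndarray:
        A = self.adjacency()
        return np.asarray(A.sum(axis=1)).ravel()

    def sample_vector(self, sample: str) -> np.ndarray:
        if sample not in self.expression.columns:
            raise KeyError(f"unknown sample {sample!r}")
        return self.expression[sample].to_numpy(dtype=float)

    def restrict_to(self, nodes: Iterable[str]) -> "IntegratedSystem":
        """Induced subsystem on a node subset (no re-epsilon: values are
        already positive)."""
        keep = [n for n in self.node_order if n in set(nodes)]
        sub = InteractionNetwork(self.network.graph.subgraph(keep).copy(), self.network.name)
        return IntegratedSystem(
            network=sub,
            expression=self.expression.loc[keep],
            epsilon=self.epsilon,
            node_order=keep,
        )


@dataclass
class TransitionMatrix:
    """Per-sample row-stochastic transition matrix over an ordered node list."""

    nodes: list[str]
    matrix: sp.csr_matrix

    def __post_init__(self) -> None:
        rs = np.asarray(self.matrix.sum(axis=1)).ravel()
        if np.max(np.abs(rs - 1.0)) > 1e-9:
            raise ValueError("transition matrix rows must sum to 1 within 1e-9")

    def row(self, node: str) -> dict[str, float]:
        i = self.nodes.index(node)
        r = self.matrix.getrow(i).tocoo()
        return {self.nodes[j]: float(v) for j, v in zip(r.col, r.data)}


@dataclass
class EntropyProfile:
    """Per-node local entropies S_i (nats) and normalized S~_i in [0, 1]."""

    nodes: list[str]
    s: np.ndarray
    s_norm: np.ndarray
    degrees: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"s": self.s, "s_norm": self.s_norm, "degree": self.degrees},
            index=pd.Index(self.nodes, name="gene"),
        )


# ---------------------------------------------------------------------------
# Integration


def integrate(net: InteractionNetwork, expr: ExpressionMatrix) -> IntegratedSystem:
    """Restrict a network and an expression matrix to their common genes.

    Nodes left isolated by the restriction are removed.  Per sample, zero
    expression values are replaced by epsilon = min positive value / 10
    (logged); a sample that is all zero is rejected.
    """
    common = net.nodes & set(expr.genes)
    if not common:
        raise ValueError("network and expression matrix share no genes")
    sub = net.graph.subgraph(common).copy()
    sub.remove_nodes_from([n for n, k in list(sub.degree) if k == 0])
    if sub.number_of_nodes() == 0:
        raise ValueError("no connected genes remain after integration")
    order = sorted(sub.nodes)
    values = expr.values.loc[order].astype(float).copy()

    eps = {}
    for s in values.columns:
        col = values[s].to_numpy()
        positive = col[col > 0]
        if positive.size == 0:
            raise ValueError(f"sample {s!r} has no positive expression values")
        e = float(positive.min()) / 10.0
        n_zero = int((col == 0).sum())
        if n_zero:
            logger.info("sample %s: replacing %d zero value(s) with epsilon=%g", s, n_zero, e)
            col = np.where(col == 0, e, col)
            values[s] = col
        eps[s] = e
    return IntegratedSystem(
        network=InteractionNetwork(sub, net.name),
        expression=values,
        epsilon=pd.Series(eps),
        node_order=order,
    )


# ---------------------------------------------------------------------------
# Per-sample computations


def transition_matrix(system: IntegratedSystem, sample: str) -> TransitionMatrix:
    """Mass-action transition matrix P for one sample.

    p_ij = E_js / sum_{k in N_i} E_ks for neighbours j of i (the factor
    E_is cancels row-wise), zero elsewhere; rows sum to 1 exactly by
    construction.
    """
    w = system.sample_vector(sample)
    assert (w > 0).all(), "expression must be strictly positive after integration"
    A = system.adjacency()
    num = A.multiply(w[np.newaxis, :]).tocsr()
    denom = np.asarray(num.sum(axis=1)).ravel()
    assert (denom > 0).all(), "every node must have a neighbour"
    P = sp.diags(1.0 / denom) @ num
    return TransitionMatrix(nodes=list(system.node_order), matrix=P.tocsr())


def local_entropies(P: TransitionMatrix) -> np.ndarray:
    """Local entropies S_i = -sum_j p_ij log p_ij in nats (0 log 0 := 0)."""
    M = P.matrix.tocoo()
    contrib = np.zeros(len(P.nodes))
    mask = M.data > 0
    np.add.at(contrib, M.row[mask], -M.data[mask] * np.log(M.data[mask]))
    # clip tiny negative round-off
    return np.maximum(contrib, 0.0)


def normalized_local_entropies(P: TransitionMatrix, degrees: np.ndarray) -> np.ndarray:
    """S~_i = S_i / log k_i for k_i >= 2; degree-1 nodes get 0 (their S_i is
    0 and log 1 = 0, an indeterminate 0/0 resolved by convention)."""
    s = local_entropies(P)
    out = np.zeros_like(s)
    multi = degrees >= 2
    out[multi] = s[multi] / np.log(degrees[multi])
    return np.clip(out, 0.0, 1.0)


def entropy_profile(system: IntegratedSystem, sample: str) -> EntropyProfile:
    """Local and normalized local entropies for one sample."""
    P = transition_matrix(system, sample)
    deg = system.degrees()
    s = local_entropies(P)
    return EntropyProfile(nodes=list(system.node_order), s=s, s_norm=normalized_local_entropies(P, deg), degrees=deg)


def stationary_distribution(
    system: IntegratedSystem,
    sample: str,
    transition: TransitionMatrix | None = None,
    residual_tol: float = 1e-10,
) -> np.ndarray:
    """Stationary distribution pi of the per-sample transition matrix.

    Computed in closed form via detailed balance, pi_i ∝ E_is * sum_{k in
    N_i} E_ks, then verified against pi P = pi.  Requires a connected
    network; apply :func:`largest_connected_component` first otherwise.
    """
    import networkx as nx

    if not nx.is_connected(system.network.graph):
        raise ValueError(
            "stationary distribution requires a connected network; "
            "restrict to the largest connected component first"
        )
    w = system.sample_vector(sample)
    A = system.adjacency()
    pi = w * (A @ w)
    pi = pi / pi.sum()
    P = transition if transition is not None else transition_matrix(system, sample)
    residual = np.max(np.abs(pi @ P.matrix - pi))
    assert residual < residual_tol, f"pi P = pi residual {residual:.2e} exceeds {residual_tol}"
    return pi


def max_entropy_rate(net: InteractionNetwork) -> float:
    """Maximum reachable entropy rate M_R = log(lambda_max) of the adjacency
    matrix — the topological entropy of walks on the graph."""
    import networkx as nx

    if net.n_nodes == 0:
        raise ValueError("empty network")
    if not nx.is_connected(net.graph):
        raise ValueError("max_entropy_rate requires a connected network")
    n = net.n_nodes
    if n <= 64:
        A = nx.to_numpy_array(net.graph, nodelist=sorted(net.nodes))
        lam = float(np.max(np.linalg.eigvalsh(A)))
    else:
        A = nx.to_scipy_sparse_array(net.graph, nodelist=sorted(net.nodes), dtype=float, format="csr")
        lam = float(spla.eigsh(A, k=1, which="LA", return_eigenvectors=False)[0])
    if lam <= 1.0:
        raise ValueError("M_R nonpositive: adjacency spectral radius <= 1")
    return math.log(lam)


def equilibrium_rate(profile: EntropyProfile, pi: np.ndarray, m_r: float) -> float:
    """SR_eq = sum_i pi_i S_i / M_R."""
    if m_r <= 0:
        raise ValueError("M_R must be positive")
    if len(profile.s) != len(pi):
        raise ValueError("profile and stationary distribution sizes differ")
    return float(np.dot(pi, profile.s) / m_r)


def nonequilibrium_rate(profile: EntropyProfile) -> float:
    """SR_neq = mean of the normalized local entropies over all nodes."""
    if len(profile.s_norm) == 0:
        raise ValueError("empty entropy profile")
    return float(np.mean(profile.s_norm))


# ---------------------------------------------------------------------------
# Per-sample summary table


def entropy_table(
    system: IntegratedSystem,
    measures: Sequence[str] = ("neq", "eq"),
) -> pd.DataFrame:
    """One row per sample with the requested global entropy rates.

    The non-equilibrium rate is computed on the full integrated network;
    the equilibrium rate (which needs a stationary distribution) on its
    largest connected component.  Columns: ``sr_neq``, ``sr_eq``, ``m_r``,
    ``n_nodes``, ``n_edges_used``.
    """
    measures = set(measures)
    unknown = measures - {"eq", "neq"}
    if unknown:
        raise ValueError(f"unknown measures: {sorted(unknown)}")

    rows: dict[str, dict[str, float]] = {s: {} for s in system.samples}
    if "neq" in measures:
        for s in system.samples:
            rows[s]["sr_neq"] = nonequilibrium_rate(entropy_profile(system, s))
    if "eq" in measures:
        lcc = largest_connected_component(system.network)
        sub = system.restrict_to(lcc.nodes) if lcc.n_nodes < system.n_nodes else system
        m_r = max_entropy_rate(sub.network)
        for s in system.samples:
            P = transition_matrix(sub, s)
            prof = EntropyProfile(
                nodes=list(sub.node_order),
                s=local_entropies(P),
                s_norm=np.zeros(sub.n_nodes),
                degrees=sub.degrees(),
            )
            pi = stationary_distribution(sub, s, transition=P)
            rows[s]["sr_eq"] = equilibrium_rate(prof, pi, m_r)
            rows[s]["m_r"] = m_r
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample"
    out["n_nodes"] = system.n_nodes
    out["n_edges_used"] = system.network.n_edges
    return out


def write_entropy_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the per-sample entropy summary as TSV."""
    cols = [c for c in ("sr_neq", "sr_eq", "m_r", "n_nodes", "n_edges_used") if c in table.columns]
    table.to_csv(path, sep="\t", columns=cols, float_format="%.10g")
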