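"""Edge-reliability scoring and threshold filtering of interaction networks.

False-positive interactions inflate signalling-entropy estimates; this
module assigns each edge a reliability score in [0, 1] and filters the
network at a threshold.  Three families of scores are provided:

* **topological** — Jaccard, Czekanowski-Dice, and inverse-log-weighted
  shared-neighbour scores, computed from the network itself;
* **semantic** — Resnik, Lin, Jiang-Conrath, Schlicker, and Wang
  similarities over a Gene Ontology-style DAG with gene annotations,
  combined gene-to-gene by best-match averaging;
* **STRING** — combined confidence scores consumed from a protein-links
  table (0-1000, rescaled to [0, 1]).

Edges without a score are treated as score 0 when filtering: an
interaction with no supporting evidence is exactly the suspected false
positive the procedure targets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from .network import InteractionNetwork, NetworkParseError

logger = logging.getLogger(__name__)

__all__ = [
    "ReliabilityScores",
    "Ontology",
    "AnnotationMap",
    "ICTable",
    "FilterStats",
    "topological_scores",
    "read_obo",
    "read_annotations",
    "write_annotations",
    "information_content",
    "term_similarity",
    "gene_similarity",
    "semantic_edge_scores",
    "load_string_scores",
    "write_scores",
    "read_scores",
    "filter_network",
]

TOPOLOGICAL_METHODS = ("jaccard", "dice", "invlog")
SEMANTIC_METHODS = ("resnik", "lin", "jiang", "schlicker", "wang")
ALL_METHODS = TOPOLOGICAL_METHODS + SEMANTIC_METHODS + ("string",)

Edge = tuple[str, str]


def _key(u: str, v: str) -> Edge:
    return (u, v) if u <= v else (v, u)


@dataclass
class ReliabilityScores:
    """Map from unordered node pair to a confidence score in [0, 1]."""

    scores: dict[Edge, float]
    method: str = ""

    def __post_init__(self) -> None:
        for e, s in self.scores.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"score {s} for edge {e} outside [0, 1]")

    def get(self, u: str, v: str, default: float = 0.0) -> float:
        return self.scores.get(_key(u, v), default)

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class Ontology:
    """Rooted DAG of terms with is_a / part_of parent relations.

    ``dag`` stores child -> parent edges with a ``relation`` attribute.
    """

    dag: nx.DiGraph
    root: str = ""

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.dag):
            raise ValueError("ontology relations contain a cycle")
        roots = [t for t in self.dag.nodes if self.dag.out_degree(t) == 0]
        if len(roots) != 1:
            raise ValueError(f"ontology must have exactly one root, found {len(roots)}")
        if not self.root:
            self.root = roots[0]
        elif self.root != roots[0]:
            raise ValueError("declared root does not match the DAG root")
        for t in self.dag.nodes:
            if t != self.root and not nx.has_path(self.dag, t, self.root):
                raise ValueError(f"term {t} cannot reach the root")

    @property
    def terms(self) -> set[str]:
        return set(self.dag.nodes)

    def parents(self, term: str) -> set[str]:
        return set(self.dag.successors(term))

    def children(self, term: str) -> set[str]:
        return set(self.dag.predecessors(term))

    def ancestors(self, term: str) -> set[str]:
        """The term itself plus everything reachable towards the root."""
        return {term} | nx.descendants(self.dag, term)

    def descendants(self, term: str) -> set[str]:
        return {term} | nx.ancestors(self.dag, term)


AnnotationMap = dict[str, set[str]]
"""Gene identifier -> set of directly annotated ontology terms."""


@dataclass
class ICTable:
    """Per-term information content (nats) and annotation probability."""

    ic: dict[str, float]
    p: dict[str, float]

    @property
    def max_ic(self) -> float:
        return max(self.ic.values()) if self.ic else 0.0


@dataclass(frozen=True)
class FilterStats:
    """Bookkeeping from a threshold-filtering pass."""

    threshold: float
    n_edges_before: int
    n_edges_after: int
    n_removed_scored: int
    n_removed_unscored: int
    n_nodes_dropped: int


# ---------------------------------------------------------------------------
# Topological scoring


def topological_scores(net: InteractionNetwork, method: str) -> ReliabilityScores:
    """Shared-neighbour reliability for every existing edge.

    ``jaccard``: |N_i ∩ N_j| / |N_i ∪ N_j| with the endpoints themselves
    excluded from the neighbour sets.  ``dice``: the Czekanowski-Dice
    similarity 1 - |Int_i Δ Int_j| / (|Int_i ∪ Int_j| + |Int_i ∩ Int_j|)
    with Int_x = N_x ∪ {x}.  ``invlog``: sum over common neighbours z of
    1/ln k_z, min-max rescaled over the scored edges into [0, 1] (a common
    neighbour always has degree >= 2, so ln k_z > 0).
    """
    if method not in TOPOLOGICAL_METHODS:
        raise ValueError(f"unknown topological method {method!r}")
    g = net.graph
    raw: dict[Edge, float] = {}
    for u, v in g.edges:
        nu, nv = set(g.neighbors(u)), set(g.neighbors(v))
        if method == "jaccard":
            a = nu - {v}
            b = nv - {u}
            union = a | b
            raw[_key(u, v)] = len(a & b) / len(union) if union else 0.0
        elif method == "dice":
            a = nu | {u}
            b = nv | {v}
            inter, union = a & b, a | b
            raw[_key(u, v)] = 1.0 - len(union - inter) / (len(union) + len(inter))
        else:  # invlog
            raw[_key(u, v)] = sum(1.0 / math.log(g.degree[z]) for z in nu & nv)
    if method == "invlog" and raw:
        lo, hi = min(raw.values()), max(raw.values())
        if hi > lo:
            raw = {e: (s - lo) / (hi - lo) for e, s in raw.items()}
        else:
            # no discrimination possible: all edges equally (un)supported
            flat = 1.0 if hi > 0 else 0.0
            raw = {e: flat for e in raw}
    return ReliabilityScores(raw, method=method)


# ---------------------------------------------------------------------------
# Ontology / annotation I/O


def read_obo(path: str | Path) -> Ontology:
    """Read an OBO ontology keeping is_a and part_of relations.

    Other relationship types are dropped with a warning.  Obsolete terms
    are excluded.
    """
    import obonet

    multi = obonet.read_obo(str(path))
    dag = nx.DiGraph()
    dropped: set[str] = set()
    dag.add_nodes_from(multi.nodes)
    for child, parent, rel in multi.edges(keys=True):
        if rel in {"is_a", "part_of"}:
            dag.add_edge(child, parent, relation=rel)
        else:
            dropped.add(rel)
    if dropped:
        logger.warning("ignored ontology relation types: %s", sorted(dropped))
    isolated = [t for t in dag.nodes if dag.degree(t) == 0]
    if isolated:
        logger.warning("dropping %d isolated ontology term(s)", len(isolated))
        dag.remove_nodes_from(isolated)
    return Ontology(dag)


def read_annotations(path: str | Path, ont: Ontology | None = None) -> AnnotationMap:
    """Read gene -> term annotations from GAF 2.x or a two-column TSV.

    GAF is detected from the ``!gaf-version`` header or a ``.gaf`` suffix;
    columns 2 (DB object symbol) and 5 (GO id) are used.  Annotations to
    terms absent from ``ont`` (when given) are dropped with a warning.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    is_gaf = path.suffix == ".gaf" or (lines and lines[0].startswith("!gaf"))
    ann: AnnotationMap = {}
    n_unknown = 0
    for lineno, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line or line.startswith(("!", "#")):
            continue
        parts = line.split("\t")
        if is_gaf:
            if len(parts) < 5:
                raise NetworkParseError(f"{path}:{lineno}: GAF line needs >= 5 columns")
            gene, term = parts[1], parts[4]
        else:
            if len(parts) < 2:
                parts = line.split()
            if len(parts) != 2:
                raise NetworkParseError(f"{path}:{lineno}: expected 2 columns")
            gene, term = parts[0], parts[1]
        if ont is not None and term not in ont.terms:
            n_unknown += 1
            continue
        ann.setdefault(gene, set()).add(term)
    if n_unknown:
        logger.warning("dropped %d annotation(s) to unknown terms", n_unknown)
    return ann


def write_annotations(ann: AnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(ann):
            for term in sorted(ann[gene]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# Information content and semantic similarity


def information_content(ont: Ontology, ann: AnnotationMap) -> ICTable:
    """Corpus information content under true-path propagation.

    p(t) = (number of genes annotated to t or any descendant) / (number of
    annotated genes); IC(t) = -ln p(t).  Terms with zero propagated
    annotations are excluded with a warning.
    """
    if not ann:
        raise ValueError("no annotated genes")
    genes_at: dict[str, set[str]] = {t: set() for t in ont.terms}
    for gene, terms in ann.items():
        for t in terms:
            if t not in genes_at:
                raise ValueError(f"annotation to unknown term {t!r}")
            for anc in ont.ancestors(t):
                genes_at[anc].add(gene)
    total = len(genes_at[ont.root])
    if total == 0:
        raise ValueError("no annotations propagate to the root")
    ic: dict[str, float] = {}
    p: dict[str, float] = {}
    n_empty = 0
    for t, genes in genes_at.items():
        if not genes:
            n_empty += 1
            continue
        pt = len(genes) / total
        p[t] = pt
        ic[t] = -math.log(pt)
    if n_empty:
        logger.warning("%d term(s) with no propagated annotations excluded from IC table", n_empty)
    return ICTable(ic=ic, p=p)


_WANG_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


def _wang_svalues(ont: Ontology, term: str, weights: Mapping[str, float]) -> dict[str, float]:
    """Wang semantic-contribution S-values of every ancestor of ``term``."""
    s: dict[str, float] = {term: 1.0}
    # process ancestors in topological order away from the term
    order = [t for t in nx.topological_sort(ont.dag) if t in ont.ancestors(term)]
    for t in order:
        if t == term:
            continue
        best = 0.0
        for child in ont.children(t):
            if child in s:
                w = weights.get(ont.dag.edges[child, t].get("relation", "is_a"), 0.8)
                best = max(best, w * s[child])
        if best > 0:
            s[t] = best
    return s


def term_similarity(
    ic: ICTable,
    ont: Ontology,
    t1: str,
    t2: str,
    method: str,
    wang_weights: Mapping[str, float] = _WANG_WEIGHTS,
) -> float:
    """Similarity of two ontology terms in [0, 1].

    IC-based methods use the most informative common ancestor (MICA):
    ``resnik`` = IC(MICA) / max IC, ``lin`` = 2 IC(MICA) / (IC1 + IC2)
    (0 when both ICs are 0), ``jiang`` = 1 - min(1, IC1 + IC2 - 2 IC(MICA)),
    ``schlicker`` = lin * (1 - p(MICA)).  ``wang`` is the S-value overlap
    ratio with contribution factors 0.8 (is_a) / 0.6 (part_of).
    """
    if method not in SEMANTIC_METHODS:
        raise ValueError(f"unknown semantic method {method!r}")
    if t1 not in ont.terms or t2 not in ont.terms:
        raise KeyError(f"term missing from ontology: {t1!r} or {t2!r}")

    if method == "wang":
        s1 = _wang_svalues(ont, t1, wang_weights)
        s2 = _wang_svalues(ont, t2, wang_weights)
        common = set(s1) & set(s2)
        denom = sum(s1.values()) + sum(s2.values())
        return sum(s1[t] + s2[t] for t in common) / denom if denom else 0.0

    if t1 not in ic.ic or t2 not in ic.ic:
        raise KeyError(f"term missing from IC table: {t1!r} or {t2!r}")
    common = ont.ancestors(t1) & ont.ancestors(t2)
    common = {t for t in common if t in ic.ic}
    if not common:
        return 0.0
    mica = max(common, key=lambda t: ic.ic[t])
    ic_mica = ic.ic[mica]
    ic1, ic2 = ic.ic[t1], ic.ic[t2]
    if method == "resnik":
        return ic_mica / ic.max_ic if ic.max_ic > 0 else 0.0
    if method == "lin":
        return 2.0 * ic_mica / (ic1 + ic2) if ic1 + ic2 > 0 else 0.0
    if method == "jiang":
        return 1.0 - min(1.0, ic1 + ic2 - 2.0 * ic_mica)
    # schlicker relevance similarity
    lin = 2.0 * ic_mica / (ic1 + ic2) if ic1 + ic2 > 0 else 0.0
    return lin * (1.0 - ic.p[mica])


def gene_similarity(
    ann: AnnotationMap,
    ic: ICTable,
    ont: Ontology,
    g1: str,
    g2: str,
    method: str,
) -> float:
    """Best-match-average similarity of two annotated genes.

    For each term of one gene take its best match in the other gene's term
    set; average those best matches, then average the two directions.
    """
    if g1 not in ann or g2 not in ann or not ann[g1] or not ann[g2]:
        raise KeyError(f"gene without annotations: {g1!r} or {g2!r}")
    t1s, t2s = sorted(ann[g1]), sorted(ann[g2])
    sim = {
        (a, b): term_similarity(ic, ont, a, b, method) for a in t1s for b in t2s
    }
    fwd = np.mean([max(sim[(a, b)] for b in t2s) for a in t1s])
    rev = np.mean([max(sim[(a, b)] for a in t1s) for b in t2s])
    return float((fwd + rev) / 2.0)


def semantic_edge_scores(
    net: InteractionNetwork,
    ann: AnnotationMap,
    ic: ICTable,
    ont: Ontology,
    method: str,
) -> ReliabilityScores:
    """Gene-level semantic similarity for every edge with both endpoints
    annotated; edges touching an unannotated gene are absent from the
    result (the filter treats them as score 0)."""
    scores: dict[Edge, float] = {}
    n_missing = 0
    for u, v in net.graph.edges:
        if u in ann and v in ann and ann[u] and ann[v]:
            s = gene_similarity(ann, ic, ont, u, v, method)
            scores[_key(u, v)] = min(1.0, max(0.0, s))
        else:
            n_missing += 1
    if n_missing:
        logger.warning("%d edge(s) with unannotated endpoint(s) left unscored", n_missing)
    return ReliabilityScores(scores, method=method)


# ---------------------------------------------------------------------------
# STRING scores and generic score tables


def load_string_scores(path: str | Path, scale: int = 1000) -> ReliabilityScores:
    """Read a STRING protein-links table into [0, 1] reliability scores.

    Expects the header ``protein1 protein2 combined_score`` and integer
    scores in 0-1000.  Duplicate pairs keep the maximum score (warned).
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise NetworkParseError(f"{path}: empty file")
    if lines[0].split()[:3] != ["protein1", "protein2", "combined_score"]:
        raise NetworkParseError(f"{path}:1: missing string_links header")
    scores: dict[Edge, float] = {}
    n_dup = 0
    for lineno, line in enumerate(lines[1:], 2):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise NetworkParseError(f"{path}:{lineno}: expected 3 columns")
        try:
            raw = int(parts[2])
        except ValueError as exc:
            raise NetworkParseError(f"{path}:{lineno}: bad combined_score {parts[2]!r}") from exc
        if not 0 <= raw <= scale:
            raise NetworkParseError(f"{path}:{lineno}: combined_score {raw} outside 0-{scale}")
        e = _key(parts[0], parts[1])
        val = raw / scale
        if e in scores and scores[e] != val:
            n_dup += 1
            val = max(val, scores[e])
        scores[e] = val
    if n_dup:
        logger.warning("%d duplicate pair(s) in %s; kept the maximum score", n_dup, path)
    return ReliabilityScores(scores, method="string")


def write_scores(scores: ReliabilityScores, path: str | Path) -> None:
    """Three-column TSV: node1, node2, score."""
    with open(path, "w") as fh:
        for (u, v), s in sorted(scores.scores.items()):
            fh.write(f"{u}\t{v}\t{s:.6g}\n")


def read_scores(path: str | Path, method: str = "") -> ReliabilityScores:
    """Read a three-column TSV score table."""
    scores: dict[Edge, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise NetworkParseError(f"{path}:{lineno}: expected 3 columns")
            scores[_key(parts[0], parts[1])] = float(parts[2])
    return ReliabilityScores(scores, method=method)


# ---------------------------------------------------------------------------
# Filtering


def filter_network(
    net: InteractionNetwork,
    scores: ReliabilityScores,
    threshold: float,
) -> tuple[InteractionNetwork, FilterStats]:
    """Keep edges whose reliability score is >= threshold.

    Edges absent from the score table count as score 0 and are removed at
    any positive threshold; nodes left isolated are dropped.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    keep, rm_scored, rm_unscored = [], 0, 0
    for u, v in net.graph.edges:
        e = _key(u, v)
        if e in scores.scores:
            if scores.scores[e] >= threshold:
                keep.append(e)
            else:
                rm_scored += 1
        elif threshold <= 0.0:
            keep.append(e)
        else:
            rm_unscored += 1
    g = nx.Graph()
    g.add_edges_from(keep)
    n_dropped = net.n_nodes - g.number_of_nodes()
    if g.number_of_edges() == 0:
        logger.warning("filtering at threshold %.2f removed every edge", threshold)
    stats = FilterStats(
        threshold=threshold,
        n_edges_before=net.n_edges,
        n_edges_after=g.number_of_edges(),
        n_removed_scored=rm_scored,
        n_removed_unscored=rm_unscored,
        n_nodes_dropped=n_dropped,
    )
    return InteractionNetwork(g, name=f"{net.name}|{scores.method}>={threshold:g}"), stats
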