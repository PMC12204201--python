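"""Synthetic study systems: interactomes, two-class expression, toy
ontologies, and edge-reliability score tables.

The generator emulates the ingredients of an entropy-stability study
without any external downloads:

* a scale-free interactome (preferential attachment, so the degree
  exponent sits near the 2-3 range typical of PINs);
* two-class expression data — either a wildtype vs *dual-knockout* design,
  where each knockout sample silences a pair of well-connected genes, or a
  generic two-condition design with a fold-change on a subset of genes;
* a small rooted DAG ontology with leaf-level gene annotations, for
  exercising semantic similarity scoring;
* reliability-score tables in which true edges draw from Beta(8, 2) and
  spurious edges from Beta(2, 8), mimicking an informative confidence
  channel such as STRING's combined score.

Expression model: gene baselines b_g ~ LogNormal(mu, sigma); sample s has
a measurement-dispersion level sigma_s taken from a fixed gradient
(linspace over [noise_sigma_min, noise_sigma_max], identical in both
classes, emulating array-to-array technical variability in a balanced
design), and its value for gene g is b_g * exp(N(0, sigma_s)).
Knocked-out genes are set to the integration epsilon (smallest positive
value in the sample / 10) rather than literal zero so the mass-action
transition probabilities stay defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .correction import AnnotationMap, Ontology, ReliabilityScores
from .entropy import ExpressionMatrix
from .network import InteractionNetwork, largest_connected_component

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticSpec",
    "generate_network",
    "generate_expression",
    "generate_ontology",
    "generate_score_table",
    "write_ontology_obo",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study system.

    Defaults give a 500-node scale-free interactome and 20 samples per
    class.  Gene baselines are log-normal (mu=2, sigma=0.15); samples span
    a deterministic dispersion gradient from noise_sigma_min to
    noise_sigma_max.  The narrow baseline spread and the balanced
    dispersion gradient keep the between-sample variability of the global
    entropy rates comparable to the dual-knockout effect, so the two-class
    comparison is clearly detectable on the clean interactome yet
    degradable by heavy edge corruption — the regime the perturbation and
    correction analyses probe.
    """

    n_nodes: int = 500
    m: int = 2  # preferential-attachment edges per new node
    n_samples: int = 20  # per class
    baseline_mu: float = 2.0
    baseline_sigma: float = 0.15
    noise_sigma_min: float = 0.2
    noise_sigma_max: float = 0.5
    n_knockout: int = 2  # genes silenced per dual-KO sample
    knockout_pool_fraction: float = 0.1  # top-degree share of the LCC
    fraction_changed: float = 0.1  # condition_b design: genes affected
    fold_change: float = 3.0  # condition_b design: multiplicative shift
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 10:
            raise ValueError("n_nodes must be >= 10")
        if self.baseline_sigma <= 0 or self.noise_sigma_min <= 0:
            raise ValueError("all sigma parameters must be positive")
        if self.noise_sigma_max < self.noise_sigma_min:
            raise ValueError("noise_sigma_max must be >= noise_sigma_min")
        if self.n_knockout < 0:
            raise ValueError("knockout count must be >= 0")


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_network(spec: SyntheticSpec) -> InteractionNetwork:
    """Connected preferential-attachment (scale-free) interactome with
    m * (n - m) edges."""
    if spec.m >= spec.n_nodes:
        raise ValueError("attachment count m must be < n_nodes")
    if spec.m < 1:
        raise ValueError("attachment count m must be >= 1")
    g = nx.barabasi_albert_graph(spec.n_nodes, spec.m, seed=spec.seed)
    names = _gene_names(spec.n_nodes)
    g = nx.relabel_nodes(g, dict(enumerate(names)))
    net = InteractionNetwork(g, name="synthetic")
    assert nx.is_connected(net.graph)
    return net


def _knockout_pool(net: InteractionNetwork, top_fraction: float = 0.1) -> list[str]:
    """Well-connected candidate genes: the top-degree decile of the LCC.

    Silencing hubs propagates to many neighbouring transition rows, which
    is what makes the knockout class distinguishable at moderate sample
    sizes.
    """
    lcc = largest_connected_component(net)
    nodes = sorted(lcc.nodes, key=lambda n: (-lcc.degree(n), n))
    k = max(2, int(len(nodes) * top_fraction))
    return nodes[:k]


def generate_expression(
    net: InteractionNetwork,
    spec: SyntheticSpec,
    classes: Sequence[str] = ("wildtype", "dual_ko"),
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Two-class expression matrix over the network's genes.

    Supported designs: ``("wildtype", "dual_ko")`` — each dual-KO sample
    silences ``n_knockout`` genes redrawn per sample from the top-degree
    pool of the largest connected component; or
    ``("condition_a", "condition_b")`` — condition_b scales a fixed
    ``fraction_changed`` of genes by ``fold_change``.  Sample *s* of
    either class is generated at dispersion level sigma_s from the fixed
    gradient, so the two classes are balanced in technical variability.

    Returns the matrix and a sample -> class-label map.
    """
    classes = tuple(classes)
    if classes not in {("wildtype", "dual_ko"), ("condition_a", "condition_b")}:
        raise ValueError(f"unsupported class design {classes!r}")
    rng = np.random.default_rng(spec.seed)
    genes = sorted(net.nodes)
    n_genes = len(genes)
    baselines = rng.lognormal(mean=spec.baseline_mu, sigma=spec.baseline_sigma, size=n_genes)
    if spec.n_samples > 1:
        sigma_grid = np.linspace(spec.noise_sigma_min, spec.noise_sigma_max, spec.n_samples)
    else:
        sigma_grid = np.array([spec.noise_sigma_min])

    if classes == ("wildtype", "dual_ko") and spec.n_knockout > 0:
        pool = _knockout_pool(net, spec.knockout_pool_fraction)
        if len(pool) < spec.n_knockout:
            raise ValueError(
                f"largest component offers only {len(pool)} knockout candidates, "
                f"need {spec.n_knockout}"
            )
        pool_idx = [genes.index(g) for g in pool]

    changed_idx = None
    if classes == ("condition_a", "condition_b"):
        n_changed = max(1, int(round(spec.fraction_changed * n_genes)))
        changed_idx = rng.choice(n_genes, size=n_changed, replace=False)

    columns: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    for ci, label in enumerate(classes):
        for s in range(spec.n_samples):
            name = f"{label}_{s:02d}"
            values = baselines * np.exp(rng.normal(0.0, float(sigma_grid[s]), size=n_genes))
            if label == "dual_ko" and spec.n_knockout > 0:
                ko = rng.choice(pool_idx, size=spec.n_knockout, replace=False)
                eps = float(np.delete(values, ko).min()) / 10.0
                values[ko] = eps
            elif label == "condition_b" and changed_idx is not None:
                values = values.copy()
                values[changed_idx] *= spec.fold_change
            columns[name] = values
            labels[name] = label
    df = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    return ExpressionMatrix(df), labels


def generate_ontology(
    n_terms: int = 30,
    max_children: int = 4,
    depth: int = 4,
    seed: int = 0,
    genes: Iterable[str] | None = None,
    terms_per_gene: tuple[int, int] = (1, 3),
) -> tuple[Ontology, AnnotationMap]:
    """Random single-root DAG with is_a / part_of labels plus leaf-level
    gene annotations (every gene gets at least one term)."""
    if n_terms < 3:
        raise ValueError("need at least 3 terms")
    rng = np.random.default_rng(seed)
    names = [f"T{i:04d}" for i in range(n_terms)]
    dag = nx.DiGraph()
    dag.add_node(names[0])
    levels: list[list[str]] = [[names[0]]]
    i = 1
    while i < n_terms:
        level: list[str] = []
        parents_pool = levels[-1] if len(levels) < depth else [t for lv in levels[1:] for t in lv]
        for parent in parents_pool:
            n_children = int(rng.integers(1, max_children + 1))
            for _ in range(n_children):
                if i >= n_terms:
                    break
                t = names[i]
                rel = "is_a" if rng.random() < 0.75 else "part_of"
                dag.add_edge(t, parent, relation=rel)
                # occasionally give a second parent to make a proper DAG
                existing = [x for lv in levels for x in lv if x != parent]
                if existing and rng.random() < 0.25:
                    extra = existing[int(rng.integers(0, len(existing)))]
                    rel2 = "is_a" if rng.random() < 0.75 else "part_of"
                    dag.add_edge(t, extra, relation=rel2)
                level.append(t)
                i += 1
            if i >= n_terms:
                break
        if not level:
            break
        levels.append(level)
    ont = Ontology(dag)

    leaves = sorted(t for t in ont.terms if not ont.children(t))
    gene_list = sorted(genes) if genes is not None else _gene_names(50)
    lo, hi = terms_per_gene
    ann: AnnotationMap = {}
    for g in gene_list:
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(leaves), size=min(k, len(leaves)), replace=False)
        ann[g] = {leaves[j] for j in chosen}
    return ont, ann


def generate_score_table(
    net: InteractionNetwork,
    true_edges: Iterable[tuple[str, str]],
    spurious_edges: Iterable[tuple[str, str]],
    seed: int = 0,
    true_beta: tuple[float, float] = (8.0, 2.0),
    spurious_beta: tuple[float, float] = (2.0, 8.0),
) -> ReliabilityScores:
    """Score table separating true from spurious edges.

    True edges draw from Beta(8, 2) (mean 0.8), spurious edges from
    Beta(2, 8) (mean 0.2).  The two edge sets must partition the
    network's edges.
    """
    canon = lambda e: (e[0], e[1]) if e[0] <= e[1] else (e[1], e[0])
    true_set = {canon(e) for e in true_edges}
    spur_set = {canon(e) for e in spurious_edges}
    overlap = true_set & spur_set
    if overlap:
        raise ValueError(f"edge partitions overlap: {sorted(overlap)[:3]}")
    missing = net.edges - (true_set | spur_set)
    if missing:
        raise ValueError(f"edge partition does not cover the network: {sorted(missing)[:3]}")
    rng = np.random.default_rng(seed)
    scores: dict[tuple[str, str], float] = {}
    for e in sorted(true_set):
        scores[e] = float(rng.beta(*true_beta))
    for e in sorted(spur_set):
        scores[e] = float(rng.beta(*spurious_beta))
    return ReliabilityScores(scores, method="synthetic")


def write_ontology_obo(ont: Ontology, path) -> None:
    """Write the ontology as a minimal OBO document (is_a and
    relationship: part_of stanzas), round-trippable through the reader."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for term in sorted(ont.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {term}\n")
            for parent in sorted(ont.parents(term)):
                rel = ont.dag.edges[term, parent].get("relation", "is_a")
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")
            fh.write("\n")
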