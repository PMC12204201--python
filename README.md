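# sigentropy

Signalling-entropy rates on protein interaction networks, with tools for
quantifying — and correcting — the distortions that network quality
imposes on them.

## The problem

Signalling entropy measures the uncertainty of information flow through a
cell's protein interaction network (PIN) and is widely used to compare
biological conditions: stem versus differentiated cells, healthy versus
tumour tissue, drug-sensitive versus resistant lines. The measure is
computed by integrating per-sample expression data with a PIN — which
means it inherits every defect of that PIN. Interaction databases carry
substantial false-positive rates, and different databases disagree
wildly, so the *same* expression data can yield significant or
non-significant entropy differences depending on which interactome was
chosen. `sigentropy` is for systems biologists who want entropy-based
comparisons that survive that choice: it computes the standard entropy
rates, quantifies how sensitive they are to network corruption, and
stabilises them with edge-reliability scoring and threshold filtering.

## The model

Under the mass-action principle, the probability that gene *i* signals to
a neighbouring gene *j* in sample *s* is proportional to the product of
their expression values:

    p_ij = E_is E_js / Σ_{k∈N_i} E_is E_ks        (row-stochastic matrix P)

Each node's local entropy S_i = −Σ_j p_ij log p_ij (natural log)
quantifies its signalling promiscuity. Two global per-sample summaries
are derived:

- **equilibrium entropy rate** — SR_eq = Σ_i π_i S_i / M_R, where π is the
  stationary distribution of P (computed in closed form via detailed
  balance, π_i ∝ E_is Σ_{k∈N_i} E_ks) and M_R = log λ_max(A) is the
  maximum entropy rate the network topology admits;
- **non-equilibrium entropy rate** — SR_neq = (1/n) Σ_i S_i / log k_i, the
  plain mean of degree-normalized local entropies, far less sensitive to
  global topology.

Around this core the package provides: the four edge-perturbation null
models (add / remove / flip / rewire at 10–90% of the edge set) with
sweep experiments tracking entropy rates, component breakdown, and the
degree-distribution scale exponent γ; edge-reliability scoring
(topological: Jaccard, Czekanowski-Dice, inverse-log; semantic over a GO
DAG: Resnik, Lin, Jiang-Conrath, Schlicker, Wang with best-match-average
gene combination; STRING combined scores) with threshold filtering; rank-
sum significance analysis between and within sample classes; and a
synthetic-data module generating complete study systems so everything is
testable offline.

## Worked example

Generate a synthetic two-class study (a 200-node scale-free interactome;
10 wildtype and 10 dual-knockout samples), compute entropy rates, and
test the class difference:

```sh
sigentropy --seed 7 simulate --n-nodes 200 --n-samples 10 --out demo
sigentropy compute --network demo/network_edgelist.tsv \
                   --expression demo/expression.tsv --out demo/entropy
sigentropy compare --entropy-table demo/entropy/entropy.tsv \
                   --labels demo/labels.tsv
```

which prints:

```
wrote synthetic system to demo (200 nodes, 396 edges)
wrote demo/entropy/entropy.tsv (20 samples)
dual_ko (n=10, median=0.916883) vs wildtype (n=10, median=0.963789): p=0.0003248 [wilcoxon-exact]
```

The entropy table has one row per sample:

```
sample        sr_neq        sr_eq         m_r          n_nodes  n_edges_used
wildtype_00   0.9846500078  0.826204248   1.996857445  200      396
wildtype_01   0.9790012857  0.8293324603  1.996857445  200      396
...
```

`sr_neq` is the non-equilibrium rate in [0, 1]; knocking out two
well-connected genes per sample lowers it (dual-KO median 0.917 vs
wildtype 0.964), and the exact rank-sum test calls the two classes apart
at p ≈ 3·10⁻⁴. The same pipeline exposes the fragility of that call:
`sigentropy perturb` sweeps the four corruption operators over levels
0.1–0.9 (adding 60% spurious edges typically erases the distinction), and
`sigentropy score` + `sigentropy filter` (or the full `sigentropy
stabilise` grid) recover it by discarding low-reliability edges — the
recommended preset filters STRING combined scores at threshold 0.6.

Real data drop into the same commands: networks as edge lists, SIF, or
STRING `protein_links` tables (optionally with a two-column identifier
mapping), expression as TSV/CSV with genes in rows, ontologies as OBO
with GAF or two-column annotations.

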