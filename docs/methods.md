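# Methods

This note documents the model implemented by `sigentropy`, the design
choices that were genuinely open, the synthetic-data generator that
defines the package's study conditions, and the numerical conventions.
It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Entropy model

A sample's signalling state is modelled as a random walk on the
integrated system: an undirected interaction network restricted to the
genes present in the expression matrix (nodes left isolated by the
restriction are dropped), with mass-action transition probabilities

    p_ij = E_is E_js / Σ_{k∈N_i} E_is E_ks,   j ∈ N_i.

The factor E_is cancels within each row, so row *i* of the transition
matrix is simply its neighbours' expression renormalized; rows sum to 1
by construction. All entropies use the natural logarithm. The local
entropy is S_i = −Σ_j p_ij log p_ij, its normalized form S̃_i = S_i /
log k_i.

Two global rates summarise a sample:

- **SR_neq**, the mean of S̃_i over all integrated nodes of degree ≥ 1.
  Degree-1 nodes have S_i = 0 and log k_i = 0; the 0/0 is resolved as
  S̃_i := 0, so pruning a network towards a tree drives SR_neq down.
- **SR_eq** = Σ_i π_i S_i / M_R. The mass-action chain is reversible
  (edge weights E_i E_j are symmetric), so the stationary distribution
  has the closed form π_i ∝ E_is Σ_{k∈N_i} E_ks; the implementation
  normalises this vector and asserts ‖πP − π‖∞ < 1e-10 on every call.
  Power iteration exists only as an independent test oracle (on the lazy
  chain (I+P)/2, which shares the fixed point but cannot oscillate on
  bipartite graphs).

**M_R.** The maximum reachable entropy rate of a walk on a graph is
log λ_max of its adjacency matrix (the topological entropy; attained by
the maximal-entropy walk). SR_eq therefore equals exactly 1 on complete
graphs with uniform expression — one of the closed-form limits the suite
checks. SR_eq needs a connected network, so it is computed on the
largest connected component; SR_neq uses the full integrated network.

**Zeros and scaling.** Zero expression values are replaced per sample by
ε = (smallest positive value in that sample)/10, so transition rows stay
defined; the replacement is logged. No internal normalisation (quantile,
log2) is applied: p_ij is a ratio, so per-sample rescaling cancels
exactly — the suite asserts bit-level invariance of P, π, and both rates
under positive scaling. Preprocessing beyond that is the caller's
responsibility.

## Perturbation operators

Four operators corrupt a network by a *level* ∈ (0, 0.9], always counted
against the original edge set with round-half-up:

- **add** — round(level·|E|) new edges between uniformly sampled
  non-adjacent pairs (false positives);
- **remove** — that many uniformly sampled deletions (false negatives);
  nodes are kept, so isolated nodes can appear;
- **flip** — that many original edges relocated to uniformly sampled
  non-adjacent pairs. "Flip" admits several readings (direction reversal
  is meaningless in an undirected graph; pair-state toggling changes
  |E|); relocation is the committed one: it preserves the edge count,
  changes degrees, and behaves like simultaneous false positive + false
  negative noise. Relocations never land on an original edge position,
  so the displaced fraction is exact.
- **rewire** — degree-preserving double-edge swaps until the requested
  number of distinct original edges is displaced; after 10·|E| trials
  without reaching the target the operator errors, reporting the
  achieved fraction (a triangle, which admits no valid swap, errors
  immediately).

Every operator is deterministic given its seed; sweep cells derive their
seed from (global seed, kind, level, replicate) via CRC-32, so any cell
is reproducible in isolation — this is also what makes the sweep's
resume mode sound. Perturbations are drawn independently per cell, not
nested along a level trajectory.

## Scale-exponent fitting

The degree-distribution exponent γ is estimated by discrete maximum
likelihood under the zeta model p(k) ∝ k^−γ, k ≥ xmin, with xmin chosen
by Kolmogorov–Smirnov minimisation over the observed degree values when
not supplied. A closed-form continuous approximation
(γ̂ = 1 + n / Σ log(k/xmin)) is available as `method="continuous"`; it is
cheap but biased low for discrete data at small xmin, which is why the
discrete MLE is the default. The reference sampler
(`sample_power_law_degrees`) inverts the Hurwitz-zeta CDF exactly and is
used to validate recovery (±0.15 at 10⁵ draws).

## Reliability scoring

Scores live in [0, 1] on unordered node pairs, never on the graph.

- **Jaccard** uses open neighbourhoods (endpoints excluded);
  **Czekanowski-Dice** uses closed ones (Int_x = N_x ∪ {x}), following
  the original definitions: 1 − |Int_i Δ Int_j| / (|Int_i ∪ Int_j| +
  |Int_i ∩ Int_j|). The **inverse-log** score Σ_{z∈N_i∩N_j} 1/log k_z
  has no natural upper bound and is min–max rescaled over the scored
  edge set (a common neighbour always has k ≥ 2, so log k_z > 0; if all
  raw scores are equal the rescaling is undefined and the score is 1
  when the shared support is positive, else 0).
- **Semantic** scores need an ontology (rooted DAG, is_a/part_of) and
  annotations. Information content is corpus-based with true-path
  propagation: p(t) = annotated genes at-or-below t / all annotated
  genes, IC = −log p. With MICA the most informative common ancestor:
  Resnik IC(MICA)/max-IC, Lin 2·IC(MICA)/(IC₁+IC₂) (0 when both ICs are
  0), Jiang-Conrath 1 − min(1, IC₁+IC₂−2·IC(MICA)) on nats, Schlicker
  Lin·(1 − p(MICA)). Wang similarity uses semantic-contribution factors
  0.8 (is_a) / 0.6 (part_of), configurable. Gene-level combination is
  best-match average in both directions.
- **STRING** combined scores are consumed from protein-links tables
  (integer 0–1000, divided by 1000; duplicate pairs keep the maximum,
  with a warning). The package never re-derives STRING's channel
  integration.

**Filtering** keeps edges with score ≥ threshold and drops isolated
nodes. Edges missing from the score table count as score 0: an
interaction with no supporting evidence is exactly the suspected false
positive the procedure targets. This is aggressive for partially
annotated inputs — the per-pass statistics report scored and unscored
removals separately so the effect is visible.

## Significance analysis

Between-class comparisons use the two-sided Wilcoxon rank-sum test:
exact null for combined n ≤ 20, normal approximation with continuity
correction beyond (Welch's t-test is selectable but non-default; rank
tests are the safer default at the small group sizes typical here).
Within-class stability splits one class into two disjoint random halves
of size ⌊n/2⌋, repeatedly (default 50), and reports all p-values plus
their median. The evaluation grid runs (dataset × PIN × correction ×
threshold ∪ {uncorrected baseline}), recomputes SR_neq per cell, and
tallies at α = 0.05: between-class errors (true difference lost) and
within-class errors (spurious difference induced). Raw p-values are
used — no multiple-testing correction — because the grid is a stability
diagnostic, not a discovery screen. Cells whose filtered network cannot
be integrated are NA and counted separately.

## Synthetic study systems

The generator defines the conditions under which the package's
qualitative claims are tested; it emulates an in-silico yeast-like
study, not any particular dataset.

- **Interactome**: Barabási–Albert preferential attachment, n = 500,
  m = 2 (996 edges), connected, γ near 3.
- **Expression**: gene baselines b_g ~ LogNormal(μ=2, σ=0.15); sample
  *s* has a dispersion level σ_s from the deterministic gradient
  linspace(0.2, 0.5) — identical in both classes — and values
  b_g·exp(N(0, σ_s)). The gradient models array-to-array technical
  variability in a balanced design. These two choices are deliberate:
  with a wide baseline spread and a single shared noise level, the
  between-sample variance of SR_neq collapses with network densification
  at the same rate as any class signal, making rank tests essentially
  immune to edge corruption. Dispersion-driven variance instead decays
  only like 1/log k̄ while a knockout's footprint decays like 1/k̄, so
  heavy edge addition genuinely buries the class difference — the regime
  the perturbation and correction analyses are about.
- **Dual-knockout class**: each sample silences 2 genes, redrawn per
  sample from the top-degree decile of the largest connected component
  ("well-connected" genes; silencing hubs touches many transition rows).
  Knockout values are set to the sample's integration epsilon, not 0.
- **Score tables**: true edges ~ Beta(8, 2) (mean 0.8), spurious ~
  Beta(2, 8) (mean 0.2) — an informative but overlapping confidence
  channel.
- **Ontology**: random single-root DAG with is_a/part_of labels and
  leaf-level annotations, for exercising the semantic scorers.

What passing tests do and do not show: the generator has independent
log-normal noise, no co-expression structure, no batch effects, and a
degree-homogeneous knockout mechanism, so results on it demonstrate the
*mechanics* (normalisation, invariances, direction of perturbation
effects, benefit of informative filtering), not effect sizes on real
expression data.

## Problem sizes and tolerances

The test suite runs the study reproductions at n = 500 nodes, 20
samples per class, 10 replicates (seeds 0–9) — comfortably desk-scale —
and asserts the qualitative patterns at the ≥ 8/10 or ≥ 9/10 replicate
level. Oracle equivalences use 1000 random systems (stationary
distribution, 1e-8), 100 random 50-term DAGs (semantic similarity,
1e-12), and full rank-assignment enumeration (exact Wilcoxon, n ≤ 8,
1e-12). Analytic identities are asserted at 1e-12, hand-worked examples
at 1e-9. Transition rows must sum to 1 within 1e-9 at construction;
stationary residuals within 1e-10.

## Known limitations

- M_R is a modelling commitment (adjacency spectral radius); other
  normalisations of SR_eq would change its absolute scale, though not
  per-sample rankings.
- The missing-score → 0 filtering policy can shrink sparsely annotated
  networks aggressively; inspect the unscored-removal counts before
  interpreting a filtered grid.
- The evaluation grid recomputes only SR_neq (the stabler measure);
  SR_eq users should expect additional variance from largest-component
  breakdown under filtering.
- Identifier harmonisation is a flat two-column mapping applied at read
  time; no online lookups.
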