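# Methods

## Problem and model

`hetppi` predicts protein–protein interactions (PPIs) by treating each
protein as a node of a heterogeneous molecular network — proteins, lncRNAs,
miRNAs, diseases and drugs joined by nine undirected association types —
and classifying protein pairs from a representation that fuses two views:

- **Inter-view (sequence).** The 20 amino acids are collapsed into four
  side-chain-polarity groups, `{A,V,L,I,M,F,W,P}`, `{G,S,T,C,N,Q,Y}`,
  `{R,K,H}`, `{D,E}` (the conjoint-triad grouping of Shen et al.). A
  width-3 window slides over the reduced sequence at step 1 and each window
  increments one of the 4³ = 64 triplet bins; counts are normalised by the
  number of counted windows, so the vector is a frequency profile that sums
  to 1. The bin of triplet (g₁,g₂,g₃) is 16·g₁ + 4·g₂ + g₃ (base-4,
  leftmost significant) — any bijection would do; this one is fixed and
  documented. Windows containing a non-standard residue (X, U, B, Z, …)
  are skipped rather than discarding the whole sequence, and the
  normaliser is the count of *valid* windows so the frequency reading
  survives skips. A protein with no sequence (or none ≥ 3 residues) gets
  the all-zero vector with a logged warning.

- **Intra-view (network).** A from-scratch LINE embedder. First-order
  proximity models a connected pair (vᵢ, vⱼ) by the joint probability
  σ(v⃗ᵢ·v⃗ⱼ); second-order proximity models the conditional neighbourhood
  distribution P(vᵢ|vⱼ) with a softmax over *context* vectors — each node
  plays two roles, itself and a neighbour of others — so nodes with shared
  neighbours embed nearby even without a mutual edge. Both objectives are
  optimised by SGD with negative sampling: draw an edge uniformly (alias
  method), apply the positive-pair gradient and K noise-node gradients,
  noise drawn with probability ∝ degree^0.75. The two orders are trained
  separately and their vertex vectors concatenated. The network is
  embedded as an unweighted, undirected, untyped graph.

The per-protein representation is e = σ(W·(e_inter ; e_intra) + b); the
default is the identity pass-through (no W, identity σ), i.e. the plain
192-dimensional concatenation, because no training objective for W, b is
prescribed for the aggregation step. A `sum` aggregator (zero-padding the
shorter vector) and an optional trainable projection
(`pipeline.fit_projection`, a one-layer logistic link-prediction head) are
provided for comparison. A protein *pair* becomes one classifier input via
`ordered_concat` (stacking in canonical node-id order; deterministic) —
`hadamard`, `average` and `abs_diff` symmetric modes are available since
order-dependence is an artifact of concatenation. The default classifier is
a random forest with library defaults; SVM, logistic regression, Gaussian
naive Bayes, AdaBoost and XGBoost plug in behind the same interface.

## Evaluation protocol

Five-fold cross-validation over the positive PPI edges, leakage-controlled:

1. the positives are shuffled and split into five near-equal test sets
   (sizes differ by ≤ 1);
2. per fold, the test positives are **removed from the network before the
   embedder is retrained** — LINE runs five times per evaluation, on the
   reduced network, with the full node set retained so isolated proteins
   keep a (finite) initial embedding;
3. negatives are sampled per fold from the complement of the known-PPI set
   over protein pairs, sized 1:1 with the positives, train and test
   negatives disjoint within a fold;
4. a classifier is fit on train pairs and scored on held-out pairs.

Both guards (no test edge in the training network; no test pair among
training samples) are asserted at run time. Metrics per fold and averaged:
Acc = (TP+TN)/N, Pre = TP/(TP+FP), Sen = TP/(TP+FN) (standard recall — a
published variant of this formula divides by TN+TP, which is not a
sensitivity; `as_printed=True` / `--metrics-as-printed` evaluates that
literal variant for audit), AUC via the rank (Mann–Whitney) formulation and
AUPR via the precision–recall step integral (scikit-learn's
`roc_auc_score` / `average_precision_score`; the test suite checks both
against explicit pair-counting and step-sum oracles).

## Synthetic data generator

The generator emulates the two-view structure the predictor assumes:

- proteins split into equal communities; PPIs drawn Bernoulli(p_within)
  inside and Bernoulli(p_between) across communities (planted partition);
- each non-protein node adopts one random community and attaches to each
  of its proteins with probability p_cross_type, producing the four
  protein-touching cross-type relations, so the heterogeneous context
  reinforces — rather than merely adds noise to — the PPI structure;
- each community carries a distinct random motif injected (once, at a
  random offset, with probability `motif_injection_rate`) into members'
  otherwise uniform-random sequences, so the sequence view carries the
  same community signal at an independently tunable strength.

Fixed study configuration (`default_acceptance_config`): 300 proteins in 6
communities, p_within = 0.15, p_between = 0.005, 100 nodes each of
lncRNA/miRNA/disease/drug at p_cross_type = 0.05, motif length 6 injected
at rate 0.8 into sequences of 80–300 residues, seed 1213 (≈ 2 300 edges,
≈ 1 300 of them PPIs). This is deliberately a *scaled-down* network: it
keeps a five-fold evaluation (five LINE retrainings) under a minute.

What it does **not** emulate: heavy-tailed degree distributions, homology
between interacting partners beyond a shared motif, overlapping
communities, noisy/false-positive edges, or biased negative annotation.
Passing here shows the pipeline recovers planted two-view signal under the
leakage-controlled protocol — not that it attains any particular accuracy
on curated interactome data.

An instructive property of this generator: because edges are Bernoulli-
independent, once a fold's test edges are removed, a within-community
removed edge and a within-community non-edge are *statistically
identical* to every observer (common neighbours, cross-type context,
motifs). The best possible ranker therefore reduces to same-community
detection; `scripts/acceptance.py` computes this oracle's AUC
(`community_oracle_auc`, ≈ 0.85 under the default configuration) alongside
the pipeline's, and the pipeline's AUC should be read against that
ceiling, not against 1.0.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `dim_per_order` | 64 | per-order embedding length; intra-view = 128 |
| `negative_samples` | 5 | noise nodes per positive draw |
| `initial_learning_rate` | 0.025 | linear decay to 1e-4 of initial |
| `total_samples` | 100·\|E\| | SGD edge draws per order |
| `noise_exponent` | 0.75 | degree power of the noise distribution |
| aggregation | concat, identity | no invented projection objective |
| pair mode | ordered_concat | deterministic via canonical id order |
| classifier | RF, library defaults | reference configuration |
| folds | 5 | evaluation protocol |

The embedding defaults are the original LINE publication's standard
settings; nothing here was fit to data.

## Numerical choices

- **Initialisation:** vertex vectors uniform in [−0.5/d, 0.5/d] per
  coordinate; second-order context vectors start at zero. Seeded
  `numpy.random.Generator` throughout; identical seeds give bitwise
  identical embeddings, folds and reports.
- **Batched SGD:** draws are processed in synchronous mini-batches
  (gradients at pre-update parameters, accumulated with scatter-add). The
  effective batch is capped at |V|: sequential negative-sampling SGD is
  self-stabilising (a vector pushed too far immediately sees corrective
  gradients), and large stale batches break that on small graphs — norms
  diverge. The cap keeps per-node accumulation of order its degree share.
- **Sigmoid arguments clipped to ±30** to avoid overflow; softmax computed
  with the max-subtraction trick.
- **Negative sampling of pairs:** exact enumeration of the complement when
  the pair universe is small, seeded rejection sampling otherwise.
- **Ties/degenerates:** classification threshold 0.5; precision is NaN if
  nothing is predicted positive; AUC/AUPR raise on one-class labels while
  threshold metrics remain defined; `make_folds` uses `array_split` so
  fold sizes differ by at most one.
- **Edge canonicalisation:** endpoints stored lexicographically smaller id
  first, so undirected equality and set de-duplication hold structurally;
  node identity is the pair (id, type).

## Known limitations

- Self-loop PPIs (self-interacting proteins) are dropped on load.
- The embedder ignores relation types; semantics of the nine association
  types enter only through topology.
- The aggregation projection (W, b) has no principled training objective
  in this design; the provided logistic head is one reasonable choice,
  not a canonical one.
- `cmd_ablate` runs two panels (feature×aggregator on the full network;
  the six named sub-networks at defaults), not the full 36-run cross
  product.
- Reproducing the published counts of the originally collected network
  requires its deposited edge table, which is not redistributed here; the
  corresponding test fails until the file is supplied at
  `data/deposited/edges.tsv`.
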