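# Methods

## Patient modelling

The unit of classification is one patient represented as an attributed
graph: the shared PPI topology *G = (V, E)* (undirected, no self-loops, gene
symbols as node identities, lexicographic node order) with that patient's
expression vector as single-channel node features. All patients in a cohort
share one topology object, which both documents and enforces the assumption
that the knowledge graph is population-level while only the molecular
measurements are patient-specific. Genes present in only one of the two
inputs (expression table, PPI) are dropped, never imputed; the intersection
must hold at least two genes. Expression values are used as provided; an
optional per-gene z-scoring (`zscore_expression`) exists but is off by
default, since the synthetic generator already emits standardized values and
real pipelines usually arrive normalized.

## Graph classifier

The classifier is deliberately the smallest standard architecture adequate
for recovering a planted additive signal:

* `message_passing_layers = 2` rounds of sum aggregation over *A + I*
  followed by a learned linear map and ReLU (weights shared across nodes);
* global mean pooling over nodes;
* one linear layer to 2 logits, softmax cross-entropy loss.

Defaults: `hidden_dim = 32`, `epochs = 50`, `learning_rate = 1e-2` (Adam),
`batch_size = 16`. Two message-passing rounds let information propagate
across a signal subnetwork's 2-hop neighbourhood; mean pooling makes the
model size independent of cohort size and the prediction invariant under a
consistent relabelling of the node order (tested). Training is plain numpy
with explicit reverse-mode gradients: single-threaded, every random draw
(initialisation, shuffles) taken from the config seed, so repeated fits are
bitwise identical — determinism is a contract here, not an aspiration,
because federated ensembles are audited by re-running them.
`training_log[0]` records the pre-training loss so convergence claims can be
made against a measured baseline. Exact probability ties predict class 0.

## Explanation and subgraph extraction

Edge importance is the averaged absolute sensitivity of the predicted-class
logit to a multiplicative gate on the edge's two adjacency entries,
evaluated at gate = 1 and averaged over correctly classified training
graphs (falling back, with a warning, to all graphs when nothing is
classified correctly). This gradient-based attribution was chosen over a
learned-mask explainer because it is deterministic, needs no extra
optimisation, and is exactly reusable from the classifier's own backward
pass; the module boundary allows swapping in a mask-learning explainer
without touching the ensemble code. Node importance is the maximum over
incident edges, keeping node and edge tables consistent when displayed
together; both tables are rescaled so their maximum is 1 (skipped when all
scores are 0, e.g. an all-zero model).

Subgraph extraction seeds one subgraph at each of the `n_members` (default
10, capped at the node count) top-importance genes, ties broken
lexicographically, and greedily adds the highest-importance neighbouring
gene until `member_size` (default 5) nodes are reached or the component is
exhausted. Subgraphs may overlap — overlapping neighbourhoods keep every
member connected and centred on a relevant gene, at the cost that members
are not independent; the weighted vote does not require independence.
Extraction is fully deterministic given the scores.

## Ensemble and weighting

One classifier per subgraph, trained on that subgraph's gene features only,
with the member index added to the seed so members are decorrelated. Members
vote with hard labels; the ensemble prediction is the class with the larger
weighted vote sum, ties to class 0. Weights are non-negative with no upper
bound and no normalisation — rescaling all weights by a positive constant
provably never changes a prediction, so normalisation would be cosmetic.
Member performance is reported on the validation split (accuracy, balanced
accuracy, sensitivity, specificity); balanced accuracy is the headline
metric since cohorts need not be balanced. Every interactive weight change
is re-scored on the validation split only, keeping the test split untouched
until final reporting.

Detachment serialises a member as (subgraph topology, gene names, model
hyper-parameters + flat parameter vector, rate summary) — no sample ids,
labels or expression values, verified by a transcript audit. Numbers are
serialized in fixed-width form (`+.17e` for parameters, `+.6f` for rates,
exact float64 round-trip) so the payload's byte size carries no information
about cohort size; rate summaries rather than raw confusion counts are
shared for the same reason.

## Federation protocol

The workflow is a state machine with an `INITIAL` and `TERMINAL` state, the
client states `LOCAL_TRAINING`, `WAITING_FOR_GLOBAL_MODEL`,
`WEB_CONTROLLED`, `DISTRIBUTE_WEIGHTS`, `WAITING_FOR_GLOBAL_WEIGHTS`, and
the coordinator states `GLOBAL_MODEL_AGGREGATION`,
`WAITING_FOR_CLIENTS_TO_FINISH`, `GLOBAL_WEIGHT_AGGREGATION` — ten named
values in all (descriptions of such coordinator/client designs sometimes
quote "9 states" by counting the two waiting states together; the
implementation enumerates every distinct value). The coordinator holds no
patient data. Global aggregation is pure concatenation: members appended in
client registration order, preserving each client's internal order, so a
weight index means the same member on every participant. Weight aggregation
pads each submitted list with the neutral weight 1 up to the global member
count, rejects longer lists and negative entries, and takes the elementwise
arithmetic mean; each round averages only the freshly submitted lists.
A client may not submit twice within one round (the transition is illegal,
mirroring a blocked UI), a terminating client decrements the coordinator's
active count, and the coordinator terminates when no client remains active.
The simulation is synchronous and in-process but drives every participant
through `step()` and records a full transcript (transitions, messages,
evaluations); messages must be JSON-serializable, which structurally
prevents live objects — and hence hidden patient data — from crossing
participants. Scripted runs that leave an active client without a next
action raise a deadlock error carrying the transcript.

## Synthetic data generator

The generator emulates the two standard inputs with a known ground truth:

* **Topology:** a preferential-attachment (Barabási–Albert) graph —
  connected and heavy-tailed in degree like curated PPI networks — over
  genes `G0001..Gn`; default 100 genes, 2 attachment edges.
* **Signal:** a connected subnetwork of `signal_size` genes (default 5)
  picked by seeded breadth-first growth from a random gene.
* **Expression:** i.i.d. Normal(0, `noise_sd`²) background (default sd 1);
  class-1 patients get `effect_size · noise_sd` (default 2) added to each
  signal gene. Classes balanced at `n_patients_per_class` (default 100).

The three draws use independent seeded streams, so changing the cohort size
never changes the network. What this emulates — and what it does not: real
expression has correlated genes, batch effects, heavier tails and
co-regulation along pathways; the generator's independence and additivity
make the recovery task clean. Passing tests therefore demonstrate that the
pipeline recovers a localized additive class signal through the full
train–explain–extract–vote–federate chain, not that it matches the accuracy
obtainable on any particular real cohort.

## Study conditions and problem sizes

The end-to-end recovery study runs ten seeds at the generator defaults
(100 genes, 200 patients, 5 signal genes at 2 sd): per seed, the single-site
pipeline on the full cohort plus a two-client federation with the cohort
split evenly (0.6/0.2/0.2 train/validation/test within each site,
stratified by label). Recovery per seed means pooled global test balanced
accuracy ≥ 0.80 together with signal genes outranking background genes in
importance (one-sided Wilcoxon rank-sum p < 0.05). The federated-vs-local
sanity comparison is made on means across the ten seeds, because a 20-patient
per-site test split gives any single seed's balanced accuracy a standard
error (~0.08) larger than the 0.05 slack the comparison allows.

## Numerical choices and degenerate inputs

* Splits: largest-remainder allocation within each label class; fractions
  must be positive and sum to 1 (tolerance 1e-9); n < 3 is an error.
* Non-numeric binary labels map lexicographically smaller → 0 (logged).
* Training requires ≥ 2 graphs and both classes; empty topologies and
  mismatched node sets are errors, not warnings.
* A member whose restricted training fails is dropped with a warning; an
  ensemble must retain at least one member.
* An extraction seed whose component has a single node is skipped (a
  one-gene subgraph cannot carry an interaction).
* Softmax is computed with max-shift; cross-entropy clamps probabilities at
  1e-12.

## Known limitations

Single expression channel per node (no multi-omics feature stacking);
hard-label voting only (no probability averaging or calibration); binary
outcomes only; the in-process simulation models protocol logic and data
flow, not network failures, stragglers or adversarial participants; no
privacy mechanism beyond detachment (no secure aggregation or differential
privacy).
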