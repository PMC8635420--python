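# Methods

## Model and pipeline

The package predicts drug–target interactions (DTIs) by combining two
information channels per candidate pair: a *heterogeneous* channel — vectors
for the drug and protein entities learned from a biomedical knowledge graph
(KG) — and a *structural* channel — a hashed circular fingerprint for the
drug and a CTD sequence descriptor for the protein.

**DistMult.** Entities and relations live in R^d; triple (h, r, t) scores
Σ_i r_i h_i t_i, i.e. the bilinear form hᵀ M_r t with M_r restricted to
diag(r). The score is symmetric in head and tail, which is acceptable here
because the DTI relation (and most supporting relations in the synthetic
benchmarks) is effectively undirected. Training: binary logistic loss on
observed triples against η uniformly drawn head-or-tail corruptions,
filtered so a corruption never equals a known triple; L2 on all embeddings;
Adam over without-replacement mini-batches; Xavier-uniform initialization
from the run seed. There is no entity-norm projection step — the L2 term
plays that role. The loss and its gradients are hand-derived numpy
(∂f/∂h = r⊙t etc.); the training loop is deterministic given the config.

**PCA.** Drug and protein entity embeddings are reduced *separately*, each
with its own output width: the two entity populations have different
embedding geometries (drugs gather DTI and drug–disease evidence; proteins
gather interaction, pathway, and disease evidence), and a joint fit would
let the larger population dominate the components. Relations are never
PCA-ed; they are not features. Per-component sign is fixed by making the
largest-magnitude loading positive, so fits are bit-reproducible.

**NFM.** Each scalar dimension i of the concatenated instance owns an
embedding v_i scaled by its value x_i. Bi-Interaction pooling sums ⊙
products over all pairs via the O(nk) identity; a small ReLU stack and a
prediction vector p produce the non-linear term, added to a global bias and
a linear term; a logistic link plus binary cross-entropy make it a
classifier. Inverted dropout (default 0.2) after the pooling layer is the
only regularizer beyond weight decay, drawn from the run seed; batch
normalization was considered for the pooling output and deliberately left
out — at desk-scale batch sizes it adds cross-instance coupling and state
without measurable benefit. Backprop is hand-written
and guarded by a finite-difference check (relative error ≤ 1e-4) in the
suite.

**Leakage discipline.** Per fold, the KGE trains on the supporting graph ∪
that fold's positive training DTIs as triples; negatives never enter the
KG, and `pipeline.leakage_audit` verifies the training triple set is
disjoint from test DTIs. Structural blocks are min-max scaled with
training-fold statistics only.

## Evaluation protocols

Warm start shuffles positives into k folds. Cold start for drugs
(proteins) partitions the drug (protein) set; every positive of a test
entity goes to that fold's test side, and entities with no positives at all
are spread across the test groups — they are unseen in every training set
and widen the cold-side negative pool. Negatives are unlabeled pairs
sampled uniformly per fold at ratio 10:1 (1:1 in the balanced setting),
excluding *all* known positives (train ∪ test) so no known interaction is
ever labeled negative anywhere, and excluding the fold's test negatives
when drawing train negatives. If a pool cannot supply the requested count
the draw is capped with a logged warning. AUROC uses the rank statistic
with ties counted ½; AUPR is the step-wise precision–recall area with tied
scores processed as one threshold block (no interpolation). Box-plot
summaries report median, quartiles (linear interpolation), min and max.

## Synthetic benchmarks

The generator emulates the *shape* of protein-heavy DTI benchmarks, not
their biology:

* Latent factors u ∈ R^r per drug/protein/disease/pathway, per-coordinate
  std r^(−1/4) so ⟨u_d, u_p⟩ has unit variance — `effect_size` is then the
  interaction signal strength in logit units.
* Interaction probability logistic(effect·⟨u_d,u_p⟩ + intercept + noise·ε).
  The intercept (default −3) keeps the off-signal interaction prevalence
  low; without it roughly half of all pairs would be latent interactions
  and uniformly sampled "unlabeled" negatives would mostly be true
  positives, capping every measurable AUROC regardless of method. Exactly
  `n_positives` pairs are drawn without replacement, weighted by that
  probability.
* Annotation edges (protein–pathway, protein–disease, drug–disease,
  protein–protein, drug–drug) are drawn weighted by exp(affinity·⟨u,u′⟩).
  The log-linear weight is deliberate: a logistic weight saturates, making
  high- and low-affinity pairs nearly equally likely to share an
  annotation, and the KG then carries almost no transferable signal
  (measured as the correlation between neighbor-Jaccard similarity and
  latent dot product: 0.34 logistic vs 0.77 log-linear).
* Every drug and protein is guaranteed at least one heterogeneous edge
  (its highest-affinity annotation, charged against the relation budget):
  cold-start entities must own supporting information, matching the
  method's scope rule. Per-relation budgets are allocated by largest
  remainder within the protein-related/drug-related split (default 0.83
  protein-related), so the realized composition matches the knob exactly
  up to pool exhaustion.
* Protein sequences draw hydrophobicity-class frequencies from the first
  latent coordinate (so CTD composition carries recoverable signal); drug
  "fingerprints" are deterministic bit vectors whose first bits threshold
  random projections of u_d. Tests therefore run without a chemistry
  backend; real SMILES go through RDKit.

What passing tests on these benchmarks shows: the pipeline recovers a
planted low-rank signal through the KG channel, respects the protocol
invariants, and reproduces the qualitative ordering (KGE fusion helps most
on cold-start proteins). What it does not show: performance on real
benchmarks with realistic degree distributions, annotation noise, and
chemistry — the generator makes no attempt at those.

## Numerical and design choices

* **Desk-scale defaults** (`experiments.desk_config`): KGE d=16, 150
  epochs, lr 0.05, η=5, batch 512; PCA 16+16 (a lossless rotation at
  d=16); NFM k=16, one hidden layer of 32, 30 epochs. The small embedding
  dimension is load-bearing: at d≥32 DistMult memorizes the training
  triples without sharing structure across entities and generalization to
  unseen pairs collapses toward chance.
* **KGE L2 default 1e-6.** The penalty is applied to the full embedding
  tables every step through Adam, which rescales the decay gradient by the
  adaptive denominator; at 1e-4 this decay dominates the sparse structural
  gradients and drives all embeddings to the class-prior solution. The tiny
  default keeps norms finite without erasing signal.
* **Corruption filtering** resamples only offending rows (vectorized), so
  η corruptions per positive are exact and the filter terminates on any
  vocabulary where an admissible corruption exists; a triple whose entire
  corruption neighborhood is known raises a sampling error rather than
  looping.
* **Tie conventions**: AUROC ties ½; AUPR tie blocks; link-prediction
  ranks use the mean rank of the tie block.
* **Determinism**: one top-level seed; per-stage and per-fold seeds are
  derived through `numpy.random.SeedSequence` and kept below 2³¹. Model
  archives are zip files with pinned timestamps, so identical fits are
  byte-identical; metric TSV/JSON writers use fixed float formatting.
* **Degenerate inputs**: empty KGs refuse to train; single-class label
  sets refuse NFM training; metrics refuse single-class inputs; PCA
  refuses k beyond min(rows−1, dim); constant feature columns min-max
  scale to 0 and out-of-range transform values clip to [0, 1].
* Inverse/reciprocal triples are not added before KGE training.

## Problem sizes

The direction-of-effect study runs five seeds of the 200-drug × 150-protein
benchmark (1000 positives, effect 2.0) with a single 80/20 holdout per
scenario rather than full 10-fold cross-validation; with deterministic
seeding the holdout is exactly one fold of the corresponding 5-fold plan,
and the multi-seed mean is the quantity compared. Protocol invariants are
exercised at 40×30 scale over 100 seeds, where every fold can draw its full
10:1 negatives.

## Known limitations

DistMult's symmetric score cannot model anti-symmetric relations; the NFM
treats every scalar input dimension as a feature with its own embedding,
which is faithful to the dense-input formulation but costly for very wide
fingerprints; negative "unlabeled" pairs may contain true interactions (by
construction in the generator, and in reality), so AUPR values are lower
bounds on performance against a clean negative set; and the acceptance-
scale benchmarks are small enough that reported metrics carry seed-level
variance of a few points.
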