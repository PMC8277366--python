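# Methods

## Model

`richddi` embeds a drug knowledge graph and multi-label DDI relations into
one low-dimensional space and predicts the label set of an unseen drug
pair by translation-based link prediction.

**Basic triple encoder.** Entities live in R^k, relations in R^d, and each
relation `r` owns a projection `M_r ∈ R^{k×d}` (TransR).  The score of a
triple is `z_bte = b₁ − ‖hM_r + r − tM_r‖` under an L1 or L2 dissimilarity;
it is bounded above by the bias `b₁`, attained exactly when the projected
translation residual vanishes.

**Rich DDI encoder.** DDI relations are label sets over a fixed vocabulary
`L`.  A label set is binarized to `s ∈ {0,1}^|L|` and passed through the
encoder half of a symmetric deep autoencoder
(`|L| → m → d → m → |L|`, `m = max(d, |L|/2)`, tanh activations); the code
layer is the relation embedding `l`.  Both drug slots share a single
projection `M_l`, giving `z_dte = b₂ − ‖uM_l + l − vM_l‖`.  The decoder
(tanh hidden, logistic output so `ŝ ∈ (0,1)^|L|`) reconstructs the label
vector; the reconstruction score `z_rcl = b₃ − ‖(s − ŝ) ⊙ x‖` weights the
sparse nonzero components by `x_i = β > 1` so the decoder is penalized more
for missing a present label than for hallucinating an absent one.

**Objective.** Softmax conditional likelihoods are impractical to
normalize, so every term uses the sigmoid negative-sampling surrogate
`log σ(z⁺) + Σ_{c} log σ(−z⁻)`; each triple contributes one surrogate per
slot (head, relation, tail).  Corruptions are drawn uniformly from the
appropriate candidate pool; for DDI triples the drug slots draw from drug
entities and the relation slot substitutes the label vector of a different
training DDI.  Reconstruction negatives flip `max(1, min(5, |L|/10))`
random components of `s`.  Corruptions that reproduce a training triple
are rejected and resampled (best-effort: a slot with no valid corruption
keeps an unfiltered draw rather than aborting the step).  Soft constraints
`C(X) = Σ [‖·‖² − 1]₊` over entity vectors, relation vectors, and the
observed projections enter with weight γ; the joint objective
`L_bte + L_dte + L_rcl − γC(X)` is maximized by Adam over random
mini-batches of 128 positives, split between basic and DDI triples in
proportion to their counts.

**Gradients.** There is no autodiff dependency: gradients of every
parameter group (entities, relation vectors, projections, autoencoder
weights) are derived analytically and verified against central finite
differences (step 1e-6, relative error < 1e-5) in the test suite.  The L1
dissimilarity uses the sign subgradient; random initialization keeps
evaluation away from the non-differentiable set.

**Prediction.** For a pair `(u, v)` the candidate relation embedding is
the translation `l = vM_l − uM_l`; decoding it scores every vocabulary
label, and labels are returned top-n or thresholded.

## Defaults and why

| parameter | default | note |
|---|---|---|
| lr (Adam) | 0.001 | best grid-searched configuration |
| γ (soft constraints) | 0.01 | idem |
| k | 100 | idem; desk-scale runs use 20 |
| b₁, b₂, b₃ | 5, 5, 1 | idem |
| c (negatives/positive) | 10 | idem |
| norm | L1 | idem |
| d | = k | unstated; simplest consistent choice |
| β | 5 | tuned value unreported; exposed in config |
| dropout | 0.2 | autoencoder hidden layers only (not the code layer) |
| batch size | 128 | unstated; standard mini-batch size |
| iterations | 1000 | reported training length; the desk-scale acceptance run uses 8000, where the objective trace plateaus |

The autoencoder depth is a documented interpretation: the architecture is
symmetric with 2 encoder and 2 decoder layers and the code at the midpoint.
Initialization is seeded: embeddings uniform(−6/√k, 6/√k), projections
identity-plus-noise, Glorot autoencoder weights.  Every random behavior
(init, batching, negative sampling, dropout, splits) flows from explicit
seeds, and two runs with the same seeds are bitwise identical.

## Synthetic data

The generator emulates, at desk scale, a Bio2RDF-style KG plus a DDI
sentence corpus.  Group anchors sit on a 2-D integer lattice embedded in
latent space and relation translations are lattice shifts, so the set of
*exactly* translation-consistent triples can be enumerated; the requested
number of basic triples is a uniform subsample of it, and the lattice
basis is quantized to multiples of 2⁻²⁰ so that with `noise_sd = 0` every
emitted triple satisfies `latent(t) = latent(h) + latent(r)` bit-exactly.
Drugs are partitioned into interaction classes, each split into a
perpetrator and a victim role (mirroring inhibitor/substrate mechanisms);
DDI pairs are drawn perpetrator × victim within a class, and each class
owns a coherent label pool (within-class sampling weight 0.8,
cross-class 0.05).  The corpus writer emits one sentence per pair whose
content words are the pair's labels plus stop-word filler, so the TF-IDF
pipeline recovers the planted labels (recovery is ~100% at the default
configuration).

Features of real data deliberately *not* emulated: long-tailed label
frequencies (labels here are balanced across classes), degree
heterogeneity (every drug has similar interaction propensity), relation
semantics (the three drug→protein relation types share one lattice
translation, as in coarse KGs where target/enzyme/transporter links are
near-synonymous), and natural sentence grammar.  Passing tests therefore
demonstrate the mechanics and numerics of the method, not clinical
performance.

## What the method does and does not recover (desk-scale findings)

Two structural properties of the evaluation protocol bound what the
planted-structure benchmark can show, and both are reported by
`scripts/acceptance.py` rather than hidden:

1. **Bidirectional DDI storage cancels the translation–code alignment.**
   Every DDI pair is stored as two directed triples `(u, l, v)` and
   `(v, l, u)` with one shared code `l = encode(s)`.  The translation term
   therefore pulls `l` toward both `+a` and `−a` (`a = vM_l − uM_l`) with
   exactly cancelling gradients, and the symmetric optimum places the pair
   difference near zero with the code orthogonal to it.  Empirically,
   after convergence at the default conditions the cosine between `a` and
   `l` averages 0.00 (|cos| ≈ 0.08, below the random-direction
   expectation), and filtered Hits@5 on held-out pairs stays near the
   random baseline.  A control run with DDIs stored in one direction only
   — not the model's convention — reaches cos ≈ 0.92 and triples the
   forward-direction Hits@5, confirming the mechanism.  What the model
   *does* learn robustly: basic-triple plausibility (true triples outscore
   corruptions by large margins) and label-set reconstruction (nonzero
   recall ≈ 0.87 on training label sets).

2. **Linear pair classification cannot represent class co-membership.**
   The binary protocol trains logistic regression on concatenated entity
   embeddings.  With balanced interaction classes, "u and v are in the
   same class" is an XOR-type pair predicate outside the hypothesis class
   of any additive scorer, so the binary AUROC on this benchmark hovers
   near chance regardless of embedding quality.  On real pharmacovigilance
   data the binary signal largely rides on per-drug interaction
   propensity, which this balanced design deliberately lacks.

## Numerical choices and edge cases

* L2 norm gradient is guarded at zero residual; L1 uses `sign`.
* Ranking ties are pessimistic: a correct label receives the worst rank of
  its tie group, so a constant decoder cannot inflate Hits@k.
* Hits@k is computed as `100 · count / n` in exact integer-count
  arithmetic so it matches enumeration oracles bit-for-bit.
* The filtered rank removes the triple's other correct labels from the
  candidate list before ranking; by construction filtered ≤ raw.
* `split_ddi` operates on undirected pairs: both directions of a held-out
  DDI leave the training KG together; negative test pairs are sampled
  uniformly from non-DDI, non-self pairs of the full KG.
* Binary-task training negatives are resampled non-DDI pairs disjoint from
  both test negatives and test positives, equal in count to the training
  positives; pairs are canonicalized (sorted order) before concatenation.
* Training raises a divergence error naming the iteration if the
  objective goes non-finite; checkpoints round-trip bit-exactly.
* MeanRank averages over all (triple, correct-label) pairs (per-label,
  not per-triple macro).

## Known limitations

* No GPU path and no autodiff; training beyond ~10⁵ triples would need a
  faster backend.
* The entity-linking stage is an alias-table lookup, not a learned linker.
* TF-IDF is the natural unsmoothed variant computed per sentence; other
  textual features can be substituted upstream of `select_top_labels`.
* Alternative graph encoders (e.g. holographic embeddings) are out of
  scope; only the TransR-style translational encoder is implemented.
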