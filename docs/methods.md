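# Methods

## Model

The encoder is a pre-LayerNorm transformer over character tokens
({A, C, G, T, N, PAD}), with fixed sinusoidal positional encodings and masked
mean pooling of the final hidden states as the sequence embedding.  The
forward pass factors exactly as f(x) = f_m(g_m(x)) at every layer index m
(m = 0 denotes the embedding output), which is the contract manifold mixing
needs; the split identity is enforced by construction and verified to 1e-5 in
the tests.  There is no final LayerNorm, so the suffix at m = n_layers is the
identity.

Two numerical choices matter and are easy to miss:

- **Positional scale.**  Unit-scale sinusoids give every pooled embedding a
  large shared offset (the mean positional vector), driving all cosine
  similarities to ≈ 1.0; every contrastive loss then sits frozen at its
  uniform value log(2B−1) and training goes nowhere.  Positions are therefore
  scaled to the token-embedding magnitude (`pos_scale = 0.02`, matching the
  0.02 init of the embeddings).
- **Stabilized weighted softmax.**  All losses subtract the row maximum
  before exponentiation.  The hard-negative weights α_ij = e^{s_ij/τ} /
  mean_k e^{s_ik/τ} are a ratio and hence invariant to that shift; they are
  treated as constants under differentiation (a `differentiable_weights` flag
  reverses this).

## Objectives

Weighted SimCLR uses all 2B−2 other views as negatives, with the positive
entering the denominator at weight 1; both views anchor (batch loss averages
over 2B anchors).  MI-Mix draws one mixing layer m per step uniformly from
the eligible set, one λ_i ~ Beta(α, α) per anchor, mixes hidden grids with a
shuffled copy of the batch (pad masks are OR-combined: both parents' tokens
are real in the mixture) and scores the re-encoded mixture only against the B
positive-view embeddings, with negatives normalized over the B−1 non-self
positives.  With all embeddings identical the losses reduce to log(2B−1) and
log B; with λ = 1 MI-Mix reduces to the unmixed one-sided weighted loss —
both reductions are oracle-checked.  i-Mix is MI-Mix with the eligible set
pinned to {0}.  SupCon (standard form, singleton-class anchors skipped with a
logged count) completes the ablation grid.

## Training

Two-phase curriculum: phase I Weighted SimCLR (1 epoch), phase II MI-Mix
(2 epochs), Adam, constant learning rate.  Defaults are desk-scale:
learning rate 1e-4 (reference-scale settings use 3e-6 with much larger
corpora and batch 48; at a few hundred steps that rate cannot move the
model), batch 16, τ = 0.05, α = 1.0, dropout 0.1.  Validation loss is
computed in evaluation mode with fixed mix seeds every `checkpoint_every`
steps and at each phase end; the returned checkpoint is the validation-loss
argmin *within the final phase* — losses of different objectives are not
comparable, so cross-phase selection would be meaningless.  Single-objective
ablations run all epochs as one phase under the same contract.

Batches are genome-stratified by default (`stratify_by_genome`): each batch
takes pairs from distinct genomes whenever enough genomes remain.  With
thousands of training genomes a uniformly shuffled batch almost never
contains two pairs from the same genome; with tens of genomes it nearly
always does, and those same-genome pairs are false negatives that the
exp(s/τ) hard-negative weighting amplifies dramatically at τ = 0.05.
Stratified sampling restores the large-corpus batch statistics without any
label entering the loss.

## Synthetic data

Each species is an order-k Markov chain (default k = 2) whose 4^k transition
rows are independent symmetric Dirichlet(c) draws; c = 0.2 (the default study
condition) gives strongly divergent compositions, c → ∞ collapses all species
to uniform i.i.d. sequence.  Genomes are sampled from the chain (uniform
start context); training pairs are two non-overlapping fragments of one
genome, placed uniformly over all disjoint ordered placements via a
sorted-offsets construction — exact even in the boundary case where the
genome is exactly twice the fragment length (rejection sampling fails there).
Evaluation mixtures draw per-species fragment counts log-uniformly to mimic
the heavy size skew of real communities (or balanced counts on request), with
an optional substitution/indel read-noise channel.  Positive-pair baselines:
`mutate` (adjacent transpositions at 5% of positions plus deletion of an
independent 5%; counts are rounded, so output length is deterministic),
`double` (true reverse complement), and duplicate pairs relying on encoder
dropout.

What the generator does *not* emulate: repeats, horizontal transfer, shared
k-mer vocabularies between related species, coverage/abundance signal,
instrument-specific error profiles, plasmids and circular elements.  Passing
tests on this generator therefore show the machinery is correct and that the
method extracts compositional signal — not that it matches its reference-scale
behaviour on real communities, where species are far less divergent and
training corpora are orders of magnitude larger.

## Evaluation

- ARI is computed from the contingency-table closed form (cross-checked
  exactly against an independent pair-counting oracle and scikit-learn).
  When both partitions are degenerate in the same way (all singletons or one
  cluster) they are identical and ARI is 1.
- K-means uses k-means++ with 10 restarts per seeded run; the reported value
  averages seeded runs.  Raw embeddings by default; L2-normalization is a
  flag.
- The binning threshold is learned as the Otsu split (256 bins) of pairwise
  cosine distances on a seeded subsample of ≤ 2000 points — a concrete
  realization of "learned threshold" chosen for determinism and
  swappability; it sits in the valley between the intra- and inter-cluster
  distance modes whenever the distance histogram is bimodal.  Binning then
  repeatedly takes the maximum-density point (ties to the lowest index) and
  carves out its closed τ-neighbourhood until no neighbourhood holds
  `min_bin_size` points.  The length filter is strict ("longer than
  2500 bp").  Species recovery takes each species' best F1 over bins;
  unbinned sequences count against recall only.
- Few-shot splits are nested across shot counts within a run (the k-shot
  training set is a prefix of the 20-shot one), which makes the
  macro-F1-vs-shots curve monotone in expectation.

## Desk-scale study and its honest limits

The end-to-end study (20 species, concentration 0.2, 100 pairs/species of
1000 bp, 2-layer/64-dim encoder, 128-token context, batch 16, 1+2 epochs)
runs in ~3 minutes per seed on one CPU.  Under these conditions curriculum
training reliably improves held-out K-means ARI over the random
initialization (≈ +0.07–0.09 across seeds and settings) and phase-II loss
falls — but the improvement is bounded by two facts worth stating plainly.
First, a randomly initialized mean-pooled encoder is *not* an uninformative
baseline: pooled random token embeddings are a random projection of base
composition, and concentration-0.2 species are separable at the 1-mer level
(1-mer K-means ARI ≈ 0.59 on the same fragments, random-init encoder
≈ 0.57).  Second, the information ceiling of a 128-bp view is TNF's
ARI ≈ 0.87 here, and a 2-layer character-level transformer given ~375
gradient steps learns low-order compositional features, not 4-mer counting.
Longer contexts raise the floor faster than the ceiling (256 tokens: floor
0.75, TNF ceiling 0.93).  Large gains over *random initialization* of the
kind seen at reference scale require training corpora and step counts that a
desk-scale run cannot supply; the ablation grid, loss oracles and protocol
tests are exact regardless of scale.
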