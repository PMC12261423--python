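# dnaclr

Species-aware DNA sequence embeddings via curriculum contrastive learning,
with the evaluation protocols used in metagenomics: species clustering,
reference-free binning, and few-shot classification.

## The problem

Grouping DNA fragments by species without reference genomes — the core of
metagenomic binning — requires an embedding in which fragments of the same
species cluster and fragments of different species separate.  Classical
practice uses tetranucleotide frequencies (TNF); this package implements a
*trainable* alternative: a small transformer encoder trained contrastively on
positive pairs, where a positive pair is two non-overlapping fragments of the
same genome.

## The method

Training proceeds in two phases (curriculum contrastive learning):

**Phase I — Weighted SimCLR.**  For a batch of B pairs (x_i, x_i⁺), every
other sample among the 2B views is a negative.  With s(·,·) cosine similarity
and temperature τ = 0.05, the per-anchor loss is

    ℓ(f(x_i), v_i) = −log  exp(s(f(x_i), f(x_i⁺))/τ)
                           ─────────────────────────────────
                           Σ_j α_ij · exp(s(f(x_i), f(x_j))/τ)

where the hard-negative weights α_ij = exp(s_ij/τ) / mean_k exp(s_ik/τ)
(mean over the 2B−2 negatives, α for the positive fixed at 1) emphasize
negatives close to the anchor.  Both views of each pair act as anchors.

**Phase II — Manifold Instance Mixup (MI-Mix).**  Harder anchors are built by
mixing *hidden states*: pick a random eligible layer m, run the anchors to
layer m, mix each state with a shuffled partner, h_i^m = λ_i·g_m(x_i) +
(1−λ_i)·g_m(x̂_i) with λ_i ~ Beta(α, α), mix the one-hot virtual labels the
same way, finish the forward pass, and score the mixed anchor against the B
positive-view embeddings with the same hard-negative weighting (normalized
over the B−1 non-self positives).  i-Mix is the special case m = 0 (mixing at
the token-embedding output); SupCon is included as an ablation baseline.

The encoder is a character-tokenized transformer exposing the split forward
contract f(x) = f_m(g_m(x)) that manifold mixing requires, with masked mean
pooling of the final hidden states as the embedding.  Checkpoints are ranked
by validation loss.

Evaluation mirrors the standard species-differentiation protocols:

- **Clustering** — K-means with K = true species count, scored by Adjusted
  Rand Index (ARI), averaged over seeded runs.
- **Binning** — modified K-medoid: iteratively take the densest remaining
  point and bin everything within a learned cosine-distance threshold;
  sequences ≤ 2500 bp and species with < 10 sequences are filtered first.  A
  species is identified if its best per-bin F1 exceeds 0.5.
- **Few-shot classification** — logistic regression on k labelled embeddings
  per species (k = 1…20), scored by macro-F1 on 80 held-out per species.

Because real training corpora (thousands of genomes) are out of desk reach,
the package ships a first-class synthetic-data module: each species is an
order-2 Markov chain with Dirichlet-sampled transition rows; smaller
concentration means more divergent composition.  All generators, training and
evaluation are deterministic given a seed.

## Worked example

```bash
python examples/03_train_and_cluster.py
```

trains a 2-layer, 64-dim encoder on fragment pairs from 8 synthetic species
and prints (numbers from this exact script, seed 0):

```
training (phase I: weighted SimCLR, phase II: MI-Mix) ...
phase II loss: 3.413 -> 2.711
K-means ARI, random init: 0.831
K-means ARI, trained:     0.907
K-means ARI, TNF:         1.000
```

The phase-II loss falling means the model separates mixed anchors better
over time; the trained encoder clusters held-out fragments by species better
than its random initialization (ARI up ~0.08), while TNF remains the
stronger embedding on clean compositional data at this training scale — the
expected desk-scale picture.  Other examples cover the synthetic generator
(`01_synthetic_species.py`), the loss closed forms (`02_losses.py`), binning
(`04_binning.py`) and few-shot evaluation (`05_fewshot.py`).

The same workflow is scriptable from a shell:

```bash
dnaclr generate --n-species 8 --outdir data/
dnaclr train --data data/ --outdir run/
dnaclr embed --fasta data/eval.fasta --method model \
       --checkpoint run/checkpoint.npz --out emb.tsv
dnaclr eval-cluster --embeddings emb.tsv --labels data/eval_labels.tsv \
       --outdir cluster/
```

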