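"""The contrastive objectives on a toy batch, including their closed forms.

With every embedding identical, Weighted SimCLR gives log(2B-1) and the
manifold-mix loss gives log(B): the softmax over the comparison set is uniform
and the weights collapse to 1.  With structured embeddings the losses drop as
positives align with their anchors.
"""

import numpy as np

from dnaclr import (
    Encoder,
    EncoderConfig,
    MixConfig,
    SequenceRecord,
    mi_mix_loss,
    tokenize,
    weighted_simclr_loss,
)

B = 4
flat = np.ones((B, 8))
print(f"all-identical embeddings, B={B}:")
print(f"  weighted SimCLR loss = {float(weighted_simclr_loss(flat, flat.copy())):.4f}"
      f"  (log(2B-1) = {np.log(2 * B - 1):.4f})")

rng = np.random.default_rng(0)
Z = rng.normal(size=(B, 8))
aligned = Z + 0.05 * rng.normal(size=(B, 8))   # positives close to anchors
print(f"aligned positives:   loss = {float(weighted_simclr_loss(Z, aligned)):.4f}")
print(f"random positives:    loss = "
      f"{float(weighted_simclr_loss(Z, rng.normal(size=(B, 8)))):.4f}")

enc = Encoder(EncoderConfig(max_tokens=16, n_layers=2, hidden_dim=16, n_heads=2),
              seed=0)
recs = [SequenceRecord(f"s{i}", "ACGTACGTACGT") for i in range(B)]
tok = tokenize(recs, 16)
loss = mi_mix_loss(enc, tok, tok, MixConfig(1.0, frozenset({1}), seed=2), tau=0.05)
print(f"MI-Mix on identical sequences = {float(loss):.4f}  "
      f"(log B = {np.log(B):.4f})")
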