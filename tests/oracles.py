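"""Independent, loop-based reference implementations used only by tests.

Everything here is written with explicit Python loops and scalar math, sharing
no vectorized code paths with the package, so it can serve as an oracle for
the production implementations.
"""

import math

import numpy as np


def cos(u, v):
    u, v = np.asarray(u, float), np.asarray(v, float)
    return float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))


def wsimclr_oracle(Z, Zp, tau):
    """Direct summation of the weighted contrastive loss over all 2B anchors."""
    B = len(Z)
    S = [np.asarray(z, float) for z in list(Z) + list(Zp)]
    n = 2 * B
    total = 0.0
    for i in range(n):
        pos = (i + B) % n
        negs = [k for k in range(n) if k not in (i, pos)]
        e = {k: math.exp(cos(S[i], S[k]) / tau) for k in negs}
        e_pos = math.exp(cos(S[i], S[pos]) / tau)
        if negs:
            mean_e = sum(e.values()) / len(negs)
            denom = e_pos + sum((e[k] / mean_e) * e[k] for k in negs)
        else:
            denom = e_pos
        total += -math.log(e_pos / denom)
    return total / n


def onesided_weighted_oracle(A, Zp, v, tau):
    """Per-anchor weighted loss of anchors A against the positive-view set Zp.

    ``v`` is the (B, B) matrix of (possibly soft) virtual labels.  Negatives
    for anchor i are the positives with index k != i; weights are normalized
    by their mean over those B - 1 samples, the self column has weight 1.
    """
    B = len(A)
    total = 0.0
    for i in range(B):
        e = [math.exp(cos(A[i], Zp[j]) / tau) for j in range(B)]
        others = [e[k] for k in range(B) if k != i]
        denom = 0.0
        for j in range(B):
            if j == i:
                alpha = 1.0
            else:
                alpha = e[j] / (sum(others) / len(others)) if others else 1.0
            denom += alpha * e[j]
        li = 0.0
        for nn in range(B):
            li += -v[i][nn] * math.log(e[nn] / denom)
        total += li
    return total / B


def mimix_oracle(encoder, anchors_tok, positives_tok, perm, lam, m, tau):
    """Step-by-step manifold-mix loss: explicit loops over i, n, j and
    one-at-a-time suffix/pooling through the encoder's forward contract."""
    from dnaclr.encoder import HiddenState

    hid = encoder.forward_prefix(anchors_tok, m)
    states = np.asarray(hid.states)
    mask = hid.pad_mask
    B = states.shape[0]

    A = []
    for i in range(B):
        mixed = lam[i] * states[i] + (1.0 - lam[i]) * states[perm[i]]
        mmask = mask[i] | mask[perm[i]]
        one = HiddenState(m, mixed[None], mmask[None])
        fin = encoder.forward_suffix(one)
        A.append(np.asarray(encoder.pool(fin))[0])

    Zp = []
    for i in range(B):
        one_tok = type(anchors_tok)(
            token_ids=positives_tok.token_ids[i : i + 1],
            pad_mask=positives_tok.pad_mask[i : i + 1],
            lengths=positives_tok.lengths[i : i + 1],
        )
        fin = encoder.forward_suffix(encoder.forward_prefix(one_tok, 0))
        Zp.append(np.asarray(encoder.pool(fin))[0])

    v = np.zeros((B, B))
    for i in range(B):
        v[i, i] += lam[i]
        v[i, perm[i]] += 1.0 - lam[i]
    return onesided_weighted_oracle(A, Zp, v, tau), np.array(A), np.array(Zp)


def supcon_oracle(X, labels, tau):
    n = len(X)
    labels = list(labels)
    per_anchor = []
    for i in range(n):
        pos = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not pos:
            continue
        e = {k: math.exp(cos(X[i], X[k]) / tau) for k in range(n) if k != i}
        denom = sum(e.values())
        per_anchor.append(
            sum(-math.log(e[p] / denom) for p in pos) / len(pos)
        )
    return sum(per_anchor) / len(per_anchor)


def ari_oracle(a, b):
    """Adjusted Rand index by explicit pair counting (O(n^2) loops)."""
    n = len(a)
    n11 = n10 = n01 = 0
    for i in range(n):
        for j in range(i + 1, n):
            sa, sb = a[i] == a[j], b[i] == b[j]
            if sa and sb:
                n11 += 1
            elif sa:
                n10 += 1
            elif sb:
                n01 += 1
    pairs = n * (n - 1) / 2
    sum_a, sum_b = n11 + n10, n11 + n01
    expected = sum_a * sum_b / pairs
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        # both all-singletons or both all-in-one: identical partitions
        return 1.0
    return (n11 - expected) / (max_index - expected)


def stationary_composition(P, order):
    """Stationary single-base composition of a context Markov chain by
    enumeration + power iteration over the 4^order context states."""
    K = P.shape[0]
    T = np.zeros((K, K))
    mod = max(K // 4, 1)
    for c in range(K):
        for b in range(4):
            nxt = (c % mod) * 4 + b if K > 1 else 0
            T[c, nxt] += P[c, b]
    pi = np.full(K, 1.0 / K)
    for _ in range(2000):
        pi = pi @ T
    base = np.zeros(4)
    if K == 1:
        return P[0]
    for c in range(K):
        base[c % 4] += pi[c]
    return base
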