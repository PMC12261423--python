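import numpy as np
import pytest

from dnaclr import (
    MixConfig,
    cosine_similarity_matrix,
    i_mix_loss,
    mi_mix_loss,
    mix_hidden,
    negative_weights_full,
    sample_mix,
    supcon_loss,
    tokenize,
    weighted_simclr_loss,
)
from dnaclr.encoder import HiddenState
from dnaclr.records import SequenceRecord

from oracles import (
    mimix_oracle,
    onesided_weighted_oracle,
    supcon_oracle,
    wsimclr_oracle,
)


def _rand_views(B, d, seed):
    rng = np.random.default_rng(seed)
    return rng.normal(size=(B, d)), rng.normal(size=(B, d))


class TestCosineSimilarity:
    def test_identical_unit_vectors(self):
        v = np.array([[3.0, 4.0]]) / 5
        assert cosine_similarity_matrix(v, v)[0, 0] == pytest.approx(1.0)

    def test_orthogonal(self):
        a, b = np.array([[1.0, 0.0]]), np.array([[0.0, 2.0]])
        assert cosine_similarity_matrix(a, b)[0, 0] == pytest.approx(0.0)

    def test_hand_value(self):
        a, b = np.array([[1.0, 2.0]]), np.array([[2.0, 1.0]])
        assert cosine_similarity_matrix(a, b)[0, 0] == pytest.approx(0.8)

    def test_zero_row_raises(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cosine_similarity_matrix(np.zeros((1, 3)), np.ones((1, 3)))


class TestNegativeWeights:
    def test_identical_embeddings_give_unit_weights(self):
        Z = np.ones((3, 4))
        w = negative_weights_full(Z, Z.copy(), i=0, tau=0.05)
        assert w.shape == (4,)
        np.testing.assert_allclose(w, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_mean_is_exactly_one(self, seed):
        Z, Zp = _rand_views(5, 7, seed)
        for i in range(5):
            w = negative_weights_full(Z, Zp, i, tau=0.05)
            assert np.mean(w) == pytest.approx(1.0, abs=1e-12)

    def test_hand_enumeration_b2(self):
        Z = np.array([[1.0, 0.0], [0.0, 1.0]])
        Zp = np.array([[1.0, 1.0], [-1.0, 0.5]])
        tau = 0.5
        S = np.vstack([Z, Zp])
        # anchor 0: positive is index 2; negatives are indices 1 and 3
        sims = [np.dot(S[0], S[k]) / np.linalg.norm(S[0]) / np.linalg.norm(S[k])
                for k in (1, 3)]
        e = np.exp(np.array(sims) / tau)
        expected = e / e.mean()
        got = negative_weights_full(Z, Zp, 0, tau)
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_single_pair_has_no_negatives(self):
        assert negative_weights_full(np.ones((1, 3)), np.ones((1, 3)), 0).size == 0


class TestWeightedSimCLR:
    def test_single_pair_loss_is_zero(self):
        Z, Zp = _rand_views(1, 5, 0)
        assert float(weighted_simclr_loss(Z, Zp)) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("B", [2, 4, 8])
    def test_identical_embeddings_closed_form(self, B):
        Z = np.ones((B, 6))
        loss = float(weighted_simclr_loss(Z, Z.copy()))
        assert loss == pytest.approx(np.log(2 * B - 1), abs=1e-6)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(50):
            B = int(rng.integers(2, 9))
            d = int(rng.integers(2, 17))
            Z, Zp = _rand_views(B, d, 1000 + trial)
            got = float(weighted_simclr_loss(Z, Zp, tau=0.05))
            want = wsimclr_oracle(Z, Zp, tau=0.05)
            assert got == pytest.approx(want, abs=1e-6)

    def test_pair_permutation_invariance(self):
        Z, Zp = _rand_views(6, 8, 7)
        perm = np.random.default_rng(1).permutation(6)
        a = float(weighted_simclr_loss(Z, Zp))
        b = float(weighted_simclr_loss(Z[perm], Zp[perm]))
        assert a == pytest.approx(b, abs=1e-6)

    def test_scale_invariance(self):
        Z, Zp = _rand_views(4, 5, 8)
        a = float(weighted_simclr_loss(Z, Zp))
        b = float(weighted_simclr_loss(3.7 * Z, 3.7 * Zp))
        assert a == pytest.approx(b, abs=1e-9)

    def test_closer_positive_never_increases_anchor_loss(self):
        # anchor 0 fixed; its positive rotates toward it; per-anchor loss from
        # the loop oracle must be non-increasing in the cosine similarity
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(3, 2))
        Zp = rng.normal(size=(3, 2))
        losses = []
        for theta in np.linspace(np.pi * 0.9, 0.05, 12):
            direction = Z[0] / np.linalg.norm(Z[0])
            rot = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            Zp2 = Zp.copy()
            Zp2[0] = rot @ direction
            # per-anchor loss for anchor x_0 only, computed independently
            S = np.vstack([Z, Zp2])
            import math

            from oracles import cos

            e = {k: math.exp(cos(S[0], S[k]) / 0.05) for k in range(6)
                 if k not in (0, 3)}
            e_pos = math.exp(cos(S[0], S[3]) / 0.05)
            mean_e = sum(e.values()) / len(e)
            denom = e_pos + sum(v * v / mean_e for v in e.values())
            losses.append(-math.log(e_pos / denom))
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))


class TestSampleMix:
    def test_singleton_layer_set(self):
        perm, lam, m = sample_mix(4, MixConfig(eligible_layers=frozenset({3}), seed=0))
        assert m == 3

    def test_beta_one_is_uniform(self):
        cfg = MixConfig(beta_alpha=1.0, eligible_layers=frozenset({0}), seed=123)
        rng_draws = [sample_mix(1000, MixConfig(1.0, frozenset({0}), seed=s))[1]
                     for s in range(10)]
        lam = np.concatenate(rng_draws)
        assert abs(lam.mean() - 0.5) < 0.01

    def test_seed_determinism(self):
        cfg = MixConfig(eligible_layers=frozenset({0, 1, 2}), seed=9)
        a, b = sample_mix(8, cfg), sample_mix(8, cfg)
        assert np.array_equal(a[0], b[0])
        assert np.array_equal(a[1], b[1])
        assert a[2] == b[2]

    def test_empty_layer_set_rejected(self):
        with pytest.raises(ValueError):
            MixConfig(eligible_layers=frozenset())


class TestMixHidden:
    def _hidden(self, B=4, L=3, d=5, seed=0):
        rng = np.random.default_rng(seed)
        mask = np.ones((B, L), dtype=bool)
        mask[0, -1] = False
        return HiddenState(1, rng.normal(size=(B, L, d)), mask)

    def test_lambda_one_identity(self):
        hid = self._hidden()
        perm = np.array([1, 2, 3, 0])
        mixed = mix_hidden(hid, perm, np.ones(4))
        np.testing.assert_allclose(mixed.hidden.states, hid.states)
        np.testing.assert_allclose(mixed.v_mix, np.eye(4))

    def test_self_mix_is_identity(self):
        hid = self._hidden()
        mixed = mix_hidden(hid, np.arange(4), np.full(4, 0.5))
        np.testing.assert_allclose(mixed.hidden.states, hid.states)
        np.testing.assert_allclose(mixed.v_mix, np.eye(4))

    def test_matches_loop_oracle(self):
        hid = self._hidden(seed=2)
        rng = np.random.default_rng(3)
        perm = rng.permutation(4)
        lam = rng.random(4)
        mixed = mix_hidden(hid, perm, lam)
        states = np.asarray(hid.states)
        for i in range(4):
            expect = lam[i] * states[i] + (1 - lam[i]) * states[perm[i]]
            np.testing.assert_allclose(
                np.asarray(mixed.hidden.states)[i], expect, atol=1e-7
            )
            assert mixed.v_mix[i].sum() == pytest.approx(1.0)
            assert (mixed.v_mix[i] > 0).sum() <= 2
        np.testing.assert_array_equal(
            mixed.hidden.pad_mask, hid.pad_mask | hid.pad_mask[perm]
        )

    def test_or_mask_combines_padding(self):
        hid = self._hidden()
        perm = np.array([3, 0, 1, 2])
        mixed = mix_hidden(hid, perm, np.full(4, 0.3))
        assert mixed.hidden.pad_mask[1].all()  # row 1 mixed with full row 0? no:
        # row 0 has a padded tail; OR with a full row is full
        assert mixed.hidden.pad_mask[0].all()


def _tok_records(encoder, seqs):
    recs = [SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)]
    return tokenize(recs, encoder.config.max_tokens)


class TestMiMix:
    def test_identical_inputs_closed_form(self, tiny_encoder):
        B = 4
        tok = _tok_records(tiny_encoder, ["ACGTACGT"] * B)
        cfg = MixConfig(1.0, frozenset({1}), seed=5)
        loss = float(mi_mix_loss(tiny_encoder, tok, tok, cfg, tau=0.05))
        assert loss == pytest.approx(np.log(B), abs=1e-6)

    def test_lambda_one_reduction(self, tiny_encoder):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), size=10)) for _ in range(5)]
        seqs_p = ["".join(rng.choice(list("ACGT"), size=10)) for _ in range(5)]
        ank = _tok_records(tiny_encoder, seqs)
        pos = _tok_records(tiny_encoder, seqs_p)
        n_layers = tiny_encoder.config.n_layers
        override = (np.random.default_rng(1).permutation(5), np.ones(5), n_layers)
        cfg = MixConfig(1.0, frozenset({n_layers}), seed=0)
        got = float(mi_mix_loss(tiny_encoder, ank, pos, cfg, tau=0.05,
                                mix_override=override))
        A = np.asarray(tiny_encoder.encode_batch(ank))
        Zp = np.asarray(tiny_encoder.encode_batch(pos))
        want = onesided_weighted_oracle(A, Zp, np.eye(5), tau=0.05)
        assert got == pytest.approx(want, abs=1e-6)

    @pytest.mark.parametrize("B", [2, 3, 4, 5, 6])
    def test_matches_step_by_step_oracle(self, tiny_encoder, B):
        rng = np.random.default_rng(100 + B)
        seqs = ["".join(rng.choice(list("ACGT"), size=int(rng.integers(6, 14))))
                for _ in range(2 * B)]
        ank = _tok_records(tiny_encoder, seqs[:B])
        pos = _tok_records(tiny_encoder, seqs[B:])
        perm = rng.permutation(B)
        lam = rng.random(B)
        for m in (0, 1, tiny_encoder.config.n_layers):
            got = float(
                mi_mix_loss(tiny_encoder, ank, pos,
                            MixConfig(1.0, frozenset({m}), 0), tau=0.05,
                            mix_override=(perm, lam, m))
            )
            want, _, _ = mimix_oracle(tiny_encoder, ank, pos, perm, lam, m, 0.05)
            assert got == pytest.approx(want, abs=1e-5)

    def test_imix_equals_mimix_at_layer_zero(self, tiny_encoder):
        rng = np.random.default_rng(17)
        seqs = ["".join(rng.choice(list("ACGT"), size=9)) for _ in range(8)]
        ank = _tok_records(tiny_encoder, seqs[:4])
        pos = _tok_records(tiny_encoder, seqs[4:])
        cfg = MixConfig(1.0, frozenset({0, 1, 2}), seed=21)
        cfg0 = MixConfig(1.0, frozenset({0}), seed=21)
        a = float(i_mix_loss(tiny_encoder, ank, pos, cfg, tau=0.05))
        b = float(mi_mix_loss(tiny_encoder, ank, pos, cfg0, tau=0.05))
        assert a == b

    def test_permutation_equivariance(self, tiny_encoder):
        rng = np.random.default_rng(31)
        seqs = ["".join(rng.choice(list("ACGT"), size=10)) for _ in range(8)]
        ank_s, pos_s = seqs[:4], seqs[4:]
        perm_mix = rng.permutation(4)
        lam = rng.random(4)
        sigma = np.array([2, 0, 3, 1])  # batch reordering
        ank = _tok_records(tiny_encoder, ank_s)
        pos = _tok_records(tiny_encoder, pos_s)
        base = float(mi_mix_loss(tiny_encoder, ank, pos,
                                 MixConfig(1.0, frozenset({1}), 0), 0.05,
                                 mix_override=(perm_mix, lam, 1)))
        # reorder the batch and conjugate the mixing permutation accordingly
        inv = np.argsort(sigma)
        perm2 = inv[perm_mix[sigma]]
        ank2 = _tok_records(tiny_encoder, [ank_s[i] for i in sigma])
        pos2 = _tok_records(tiny_encoder, [pos_s[i] for i in sigma])
        other = float(mi_mix_loss(tiny_encoder, ank2, pos2,
                                  MixConfig(1.0, frozenset({1}), 0), 0.05,
                                  mix_override=(perm2, lam[sigma], 1)))
        assert base == pytest.approx(other, abs=1e-6)


class TestSupCon:
    def test_swapping_positive_class_increases_loss(self):
        close = np.array([[1.0, 0.0], [1.0, 0.01]])
        far = np.array([[-1.0, 0.0], [-1.0, -0.01]])
        X = np.vstack([close, far])
        good = float(supcon_loss(X, ["a", "a", "b", "b"]))
        bad = float(supcon_loss(X, ["a", "b", "a", "b"]))
        assert good < bad

    @pytest.mark.parametrize("n,k", [(4, 2), (6, 3)])
    def test_identical_embeddings_closed_form(self, n, k):
        X = np.ones((n, 5))
        labels = [f"c{i % k}" for i in range(n)]
        assert float(supcon_loss(X, labels)) == pytest.approx(
            np.log(n - 1), abs=1e-9
        )

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(77)
        for trial in range(20):
            X = rng.normal(size=(6, 4))
            labels = ["a", "a", "b", "b", "c", "c"]
            got = float(supcon_loss(X, labels, tau=0.1))
            want = supcon_oracle(X, labels, tau=0.1)
            assert got == pytest.approx(want, abs=1e-6)
            X = X * 2.5  # scale invariance on the same draw
            assert float(supcon_loss(X, labels, tau=0.1)) == pytest.approx(
                want, abs=1e-6
            )

    def test_all_singletons_rejected(self):
        with pytest.raises(ValueError):
            supcon_loss(np.eye(3), ["a", "b", "c"])
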