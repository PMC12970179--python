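import numpy as np
import pytest

from mvmol.fusion import (
    ALPHA_PRETRAIN_REFERENCE,
    AltFusionConfig,
    AltFusionParams,
    GatingParams,
    ZeroNormEmbeddingError,
    alt_fuse,
    gated_fusion,
    pretrain_aggregator,
)


def _hand_alpha(params, arrays):
    """Independent arithmetic evaluation of the gating equations."""
    q, W, b = params.q.data, params.W.data, params.b.data
    w = np.array(
        [
            np.mean([q @ np.tanh(W @ (v / np.linalg.norm(v)) + b) for v in arr])
            for arr in arrays
        ]
    )
    e = np.exp(w - w.max())
    return w, e / e.sum()


class TestGatedFusion:
    def test_matches_hand_evaluation(self, rng):
        params = GatingParams(2, seed=1)
        arrays = [rng.normal(size=(2, 2)) for _ in range(3)]
        out = gated_fusion(arrays, params)
        w_hand, a_hand = _hand_alpha(params, arrays)
        assert np.allclose(out.w, w_hand, atol=1e-12)
        assert np.allclose(out.alpha, a_hand, atol=1e-10)

    def test_single_view_alpha_one(self, rng):
        out = gated_fusion([rng.normal(size=(3, 4))], GatingParams(4))
        assert out.alpha.shape == (1,) and abs(out.alpha[0] - 1.0) < 1e-12

    def test_identical_views_split_evenly(self, rng):
        z = rng.normal(size=(5, 4))
        out = gated_fusion([z, z.copy()], GatingParams(4, seed=2))
        assert np.allclose(out.alpha, [0.5, 0.5], atol=1e-12)

    def test_alpha_simplex_invariants(self, rng):
        for _ in range(100):
            params = GatingParams(3, seed=int(rng.integers(2**31)))
            arrays = [rng.normal(size=(4, 3)) for _ in range(3)]
            out = gated_fusion(arrays, params)
            assert abs(out.alpha.sum() - 1.0) < 1e-12
            assert np.all(out.alpha > 0)

    def test_batch_order_invariance(self, rng):
        params = GatingParams(3, seed=4)
        arrays = [rng.normal(size=(6, 3)) for _ in range(3)]
        perm = rng.permutation(6)
        out1 = gated_fusion(arrays, params)
        out2 = gated_fusion([a[perm] for a in arrays], params)
        assert np.allclose(out1.alpha, out2.alpha, atol=1e-12)

    def test_per_sample_scale_invariance(self, rng):
        """W z/||z|| is unchanged under z -> c z (c > 0), so alpha is too."""
        params = GatingParams(3, seed=5)
        arrays = [rng.normal(size=(4, 3)) for _ in range(3)]
        scales = [rng.uniform(0.1, 10.0, size=(4, 1)) for _ in range(3)]
        out1 = gated_fusion(arrays, params)
        out2 = gated_fusion([a * s for a, s in zip(arrays, scales)], params)
        assert np.allclose(out1.alpha, out2.alpha, atol=1e-10)

    def test_softmax_shift_invariance(self, rng):
        params = GatingParams(3, seed=6)
        out = gated_fusion([rng.normal(size=(4, 3)) for _ in range(3)], params)
        e = np.exp(out.w + 7.3 - (out.w + 7.3).max())
        assert np.allclose(out.alpha, e / e.sum(), atol=1e-12)

    def test_zero_norm_embedding_rejected(self, rng):
        arrays = [np.zeros((2, 3)), rng.normal(size=(2, 3))]
        with pytest.raises(ZeroNormEmbeddingError):
            gated_fusion(arrays, GatingParams(3))

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            gated_fusion([np.zeros((0, 3))], GatingParams(3))

    def test_reference_constants_recorded(self):
        assert ALPHA_PRETRAIN_REFERENCE == {"image": 0.6, "graph": 0.3, "text": 0.1}


class TestAltFusion:
    def test_unprojected_gate_dim(self):
        cfg = AltFusionConfig("unprojected_gating", (256, 256, 256))
        assert cfg.gate_input_dim == 768

    def test_projected_gate_dim(self):
        cfg = AltFusionConfig("projected_gating", (256, 512, 768))
        assert cfg.gate_input_dim == 768

    def test_weighted_concatenation_width(self, rng):
        dims = (4, 6, 8)
        cfg = AltFusionConfig("unprojected_gating", dims, seed=0)
        out = alt_fuse([rng.normal(size=(3, d)) for d in dims], cfg)
        assert out.z_mv.shape == (3, sum(dims))

    def test_feature_addition_convexity(self, rng):
        """Equal inputs with convex weights return the same vector."""
        dims = (5, 5, 5)
        cfg = AltFusionConfig("projected_gating_feature_addition", dims, seed=1)
        params = AltFusionParams(cfg)
        # make all three projections identical so projected views coincide
        for p in params.projections[1:]:
            p.weight.data = params.projections[0].weight.data.copy()
            p.bias.data = params.projections[0].bias.data.copy()
        z = rng.normal(size=(3, 5))
        out = alt_fuse([z, z.copy(), z.copy()], cfg, params)
        proj = np.tanh(z @ params.projections[0].weight.data + params.projections[0].bias.data)
        assert np.allclose(out.z_mv, proj, atol=1e-10)
        assert abs(out.alpha.sum() - 1.0) < 1e-10

    def test_dim_mismatch_rejected(self, rng):
        cfg = AltFusionConfig("unprojected_gating", (4, 4, 4))
        with pytest.raises(ValueError, match="dims"):
            alt_fuse([rng.normal(size=(2, 5))] * 3, cfg)


class TestAggregatorPretraining:
    def test_reconstruction_loss_decreases_toward_zero(self, rng):
        z = rng.normal(size=(64, 6))
        triples = {"image": z, "graph": z.copy(), "text": z.copy()}
        res = pretrain_aggregator(triples, epochs=300, lr=1e-2, seed=0)
        for v in triples:
            assert res.final_losses[v] <= res.initial_losses[v]
        assert sum(res.final_losses.values()) < 0.1 * sum(res.initial_losses.values())

    def test_alpha_history_and_frozen_scores(self, rng):
        triples = [rng.normal(size=(32, 4)) for _ in range(3)]
        res = pretrain_aggregator(triples, epochs=5, seed=1)
        assert len(res.alpha_history) == 5
        assert res.params.frozen_w is not None
        assert abs(res.alpha.sum() - 1.0) < 1e-9

    def test_noise_view_downweighted(self, rng):
        """When one view is pure noise, reconstruction gating learns the
        smallest weight for it (checked over 3 seeds)."""
        wins = 0
        for seed in range(3):
            r = np.random.default_rng(seed)
            latent = r.normal(size=(96, 6))
            triples = {
                "a": latent + 0.05 * r.normal(size=latent.shape),
                "b": latent + 0.05 * r.normal(size=latent.shape),
                "noise": 1.0 * r.normal(size=latent.shape),
            }
            res = pretrain_aggregator(triples, epochs=150, lr=1e-2, seed=seed)
            alpha = dict(zip(res.views, res.alpha))
            if alpha["noise"] == min(alpha.values()):
                wins += 1
        assert wins >= 2
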