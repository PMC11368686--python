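"""Spatial kNN batches, infoNCE correctness (vs an explicit oracle),
backprop gradients, and training behavior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import contrastmap as cm
from contrastmap import _mlp
from contrastmap.contrastive import _nce_loss_grad
from contrastmap.data_io import ValidationError


# ---------------------------------------------------------------------------
# spatial kNN graph
# ---------------------------------------------------------------------------

class TestBuildSpatialKnn:
    def test_collinear_points(self):
        coords = np.array([[0.0, 0], [1, 0], [3, 0]])
        graph = cm.build_spatial_knn(coords, k=1)
        assert graph.neighbor_idx[:, 0].tolist() == [1, 0, 1]

    def test_full_graph_is_permutation(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 1, (15, 2))
        graph = cm.build_spatial_knn(coords, k=14)
        for i, row in enumerate(graph.neighbor_idx):
            assert sorted(row) == [j for j in range(15) if j != i]

    def test_coincident_points_pair_up(self):
        coords = np.array([[0.5, 0.5], [0.5, 0.5], [3.0, 3.0]])
        graph = cm.build_spatial_knn(coords, k=2)
        assert graph.neighbor_idx[0, 0] == 1
        assert graph.neighbor_idx[1, 0] == 0

    def test_k_too_large(self):
        with pytest.raises(ValidationError):
            cm.build_spatial_knn(np.zeros((3, 2)), k=3)

    def test_rows_sorted_by_distance(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 1, (40, 2))
        graph = cm.build_spatial_knn(coords, k=10)
        for i, row in enumerate(graph.neighbor_idx):
            d = np.linalg.norm(coords[row] - coords[i], axis=1)
            assert (np.diff(d) >= 0).all()


class TestSampleBatch:
    def test_forced_positive_at_k1(self):
        coords = np.array([[0.0, 0], [1, 0], [3, 0]])
        graph = cm.build_spatial_knn(coords, k=1)
        batch = cm.sample_batch(graph, [0, 2], np.random.default_rng(0))
        assert batch.positive_idx.tolist() == [1, 1]

    def test_same_seed_same_batch(self):
        graph = cm.build_spatial_knn(np.random.default_rng(1).uniform(0, 1, (30, 2)), 5)
        b1 = cm.sample_batch(graph, [0, 5, 9], np.random.default_rng(42))
        b2 = cm.sample_batch(graph, [0, 5, 9], np.random.default_rng(42))
        assert (b1.positive_idx == b2.positive_idx).all()

    def test_uniform_positive_choice(self):
        # binomial check: each of 3 neighbors chosen 1/3 of the time
        coords = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]])
        graph = cm.build_spatial_knn(coords, k=3)
        rng = np.random.default_rng(7)
        n_draw = 10_000
        counts = np.zeros(4)
        for _ in range(n_draw):
            batch = cm.sample_batch(graph, [0], rng)
            counts[batch.positive_idx[0]] += 1
        se = np.sqrt((1 / 3) * (2 / 3) / n_draw)
        for j in (1, 2, 3):
            assert abs(counts[j] / n_draw - 1 / 3) < 3 * se

    def test_duplicate_anchors_rejected(self):
        graph = cm.build_spatial_knn(np.random.default_rng(1).uniform(0, 1, (10, 2)), 3)
        with pytest.raises(ValidationError):
            cm.sample_batch(graph, [1, 1], np.random.default_rng(0))


# ---------------------------------------------------------------------------
# infoNCE loss
# ---------------------------------------------------------------------------

def _pair_batch(n_pairs):
    return cm.ContrastiveBatch(anchor_idx=np.arange(n_pairs),
                               positive_idx=np.arange(n_pairs, 2 * n_pairs))


def oracle_loss(projections, tau, mode):
    """Naive double-loop infoNCE built on the single-sample form."""
    Z = np.asarray(projections, float)
    N = Z.shape[0]
    half = N // 2
    losses = []
    for q in range(N):
        partner = q + half if q < half else q - half
        negatives = [Z[i] for i in range(N) if i not in (q, partner)]
        losses.append(cm.info_nce_loss_single(Z[q], Z[partner], negatives,
                                              tau, denominator_mode=mode))
    return float(np.mean(losses))


class TestInfoNceLoss:
    def test_degenerate_identical_projections(self):
        proj = np.tile([1.0, 0.0], (4, 1))
        loss = cm.info_nce_loss(proj, _pair_batch(2), tau=0.05)
        assert loss == pytest.approx(np.log(3), abs=1e-12)

    def test_single_negative_closed_form(self):
        # textbook one-negative case via the single-sample form
        loss = cm.info_nce_loss_single([1, 0], [1, 0], [[0, 1]], tau=1.0)
        assert loss == pytest.approx(-np.log(np.e / (np.e + 1)), abs=1e-4)

    def test_separable_limit(self):
        # positive similarity 1, negatives -1: loss -> 0 as tau -> 0+
        q = np.array([[1.0, 0], [-1, 0], [1, 0], [-1, 0]])
        loss = cm.info_nce_loss(q, _pair_batch(2), tau=0.01)
        assert loss < 1e-6

    @pytest.mark.parametrize("mode", ["with_positive", "negatives_only"])
    def test_matches_double_loop_oracle(self, mode):
        rng = np.random.default_rng(0)
        for _ in range(50):
            proj = rng.normal(size=(64, 128))
            ours = cm.info_nce_loss(proj, _pair_batch(32), tau=0.05,
                                    denominator_mode=mode)
            assert ours == pytest.approx(oracle_loss(proj, 0.05, mode), abs=1e-6)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.1, 10.0))
    def test_scale_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        proj = rng.normal(size=(8, 5))
        base = cm.info_nce_loss(proj, _pair_batch(4), tau=0.2)
        scaled = proj.copy()
        scaled[3] *= scale
        assert cm.info_nce_loss(scaled, _pair_batch(4), tau=0.2) == pytest.approx(base, rel=1e-9)

    def test_sign_properties(self):
        # with_positive is bounded below by 0; negatives_only can go
        # negative once the positive dominates the denominator
        rng = np.random.default_rng(1)
        for _ in range(100):
            proj = rng.normal(size=(8, 4))
            assert cm.info_nce_loss(proj, _pair_batch(4), tau=0.3) >= 0
        proj = np.array([[1.0, 0], [-1, 0], [1, 0], [-1, 0]])
        assert cm.info_nce_loss(proj, _pair_batch(2), tau=0.3,
                                denominator_mode="negatives_only") < 0

    def test_invalid_inputs(self):
        proj = np.ones((4, 2))
        with pytest.raises(ValidationError):
            cm.info_nce_loss(proj, _pair_batch(2), tau=0.0)
        bad = proj.copy()
        bad[0, 0] = np.inf
        with pytest.raises(ValidationError):
            cm.info_nce_loss(bad, _pair_batch(2), tau=0.1)
        with pytest.raises(ValidationError):
            cm.info_nce_loss(np.zeros((4, 2)), _pair_batch(2), tau=0.1)


class TestGradients:
    """Analytic backprop vs central finite differences."""

    def _build(self, rng):
        enc = _mlp.Sequential([
            _mlp.Linear(5, 8, rng), _mlp.BatchNorm(8), _mlp.LeakyReLU(),
            _mlp.Linear(8, 6, rng),
        ])
        proj = _mlp.Sequential([
            _mlp.Linear(6, 4, rng), _mlp.ReLU(), _mlp.Linear(4, 3, rng),
        ])
        return enc, proj

    @pytest.mark.parametrize("mode", ["with_positive", "negatives_only"])
    def test_end_to_end_gradient(self, mode):
        rng = np.random.default_rng(1)
        enc, proj = self._build(rng)
        X = rng.normal(size=(8, 5))

        def forward():
            h = enc.forward(X, train=True)
            p = proj.forward(h, train=True)
            norms = np.linalg.norm(p, axis=1, keepdims=True)
            Z = p / norms
            loss, dZ = _nce_loss_grad(Z, 0.5, mode)
            return loss, dZ, Z, norms

        loss, dZ, Z, norms = forward()
        dp = (dZ - Z * (dZ * Z).sum(axis=1, keepdims=True)) / norms
        enc.backward(proj.backward(dp))
        h = 1e-6
        for layer in [enc.layers[0], enc.layers[1], proj.layers[0]]:
            for _, pname, gname in layer.params_grads():
                param = getattr(layer, pname)
                grad = getattr(layer, gname)
                flat_idx = np.random.default_rng(0).integers(0, param.size, 4)
                for fi in flat_idx:
                    idx = np.unravel_index(fi, param.shape)
                    orig = param[idx]
                    param[idx] = orig + h
                    lp = forward()[0]
                    param[idx] = orig - h
                    lm = forward()[0]
                    param[idx] = orig
                    assert grad[idx] == pytest.approx((lp - lm) / (2 * h), abs=1e-5)


# ---------------------------------------------------------------------------
# training and encoding
# ---------------------------------------------------------------------------

class TestTrain:
    def test_zero_epochs_returns_initialized_state(self, small_lognorm_reference):
        losses = []
        state = cm.train(small_lognorm_reference,
                         cm.ModelConfig(epochs=0, seed=0), progress_log=losses)
        assert losses == []
        assert state.loss_history == []
        reps = cm.encode(state, small_lognorm_reference.profile)
        assert np.isfinite(reps).all()

    def test_seed_reproduces_loss_trajectory(self, small_lognorm_reference):
        runs = []
        for _ in range(2):
            log = []
            cm.train(small_lognorm_reference,
                     cm.ModelConfig(epochs=3, batch_size=16, positive_knn=10,
                                    seed=5), progress_log=log)
            runs.append(log)
        assert runs[0] == runs[1]  # bit-identical

    def test_requires_lognorm(self, small_reference):
        with pytest.raises(ValidationError):
            cm.train(small_reference, cm.ModelConfig(epochs=1))

    def test_loss_decreases(self, small_lognorm_reference):
        log = []
        cm.train(small_lognorm_reference,
                 cm.ModelConfig(epochs=40, batch_size=16, positive_knn=10,
                                seed=2), progress_log=log)
        assert log[-1] < log[0]

    def test_platform_default_knn(self):
        assert cm.ModelConfig.for_platform("single_cell").positive_knn == 80
        assert cm.ModelConfig.for_platform("spot").positive_knn == 20

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            cm.ModelConfig(batch_size=7)
        with pytest.raises(ValidationError):
            cm.ModelConfig(temperature=-1.0)


class TestEncode:
    def test_deterministic(self, tiny_trained_state, small_lognorm_reference):
        r1 = cm.encode(tiny_trained_state, small_lognorm_reference.profile)
        r2 = cm.encode(tiny_trained_state, small_lognorm_reference.profile)
        np.testing.assert_array_equal(r1, r2)

    def test_output_dim_follows_encoder(self, tiny_trained_state,
                                        small_lognorm_reference):
        reps = cm.encode(tiny_trained_state, small_lognorm_reference.profile)
        # 40 input genes -> first layer auto-shrunk, last stays 512
        assert reps.shape == (small_lognorm_reference.n_cells, 512)

    def test_gene_mismatch_rejected(self, tiny_trained_state,
                                    small_lognorm_reference):
        profile = small_lognorm_reference.profile
        permuted = cm.ExpressionProfile(
            values=profile.values[:, ::-1],
            gene_ids=profile.gene_ids[::-1],
            cell_ids=profile.cell_ids,
            is_lognorm=True,
        )
        with pytest.raises(ValidationError):
            cm.encode(tiny_trained_state, permuted)

    def test_checkpoint_roundtrip(self, tiny_trained_state,
                                  small_lognorm_reference, tmp_path):
        path = tmp_path / "ckpt.npz"
        tiny_trained_state.save(path)
        loaded = cm.EncoderState.load(path)
        r1 = cm.encode(tiny_trained_state, small_lognorm_reference.profile)
        r2 = cm.encode(loaded, small_lognorm_reference.profile)
        np.testing.assert_array_equal(r1, r2)
        assert loaded.config == tiny_trained_state.config
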