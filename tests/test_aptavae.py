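"""AptaVAE loss primitives, training behavior, and generation contracts."""

import math

import numpy as np
import pytest

from dlselex.aptavae import (
    AptamerTargetPair,
    LatentDistribution,
    LossBreakdown,
    LossWeights,
    ModelConfig,
    bce_loss,
    composite_loss,
    encode_pair_latent,
    kl_gaussian,
    load_model,
    make_pair,
    matrix_loss,
    mse_loss,
    read_pairs_tsv,
    save_model,
    train_aptavae,
    write_pairs_tsv,
)
from dlselex.seqstruct import fold_structure
from dlselex.synthesim import _CLASS_SMILES


class TestLossPrimitives:
    def test_bce_perfect_prediction_near_zero(self):
        assert bce_loss([0.0, 1.0], [0.0, 1.0]) < 1e-6

    def test_bce_half_is_ln2(self):
        assert math.isclose(bce_loss([0.5], [1.0]), math.log(2), rel_tol=1e-9)

    def test_bce_linear_in_weights(self):
        x, y = [0.3, 0.8], [1.0, 0.0]
        assert math.isclose(bce_loss(x, y, w=[2, 2]), 2 * bce_loss(x, y), rel_tol=1e-12)

    def test_mse_examples_and_scaling(self):
        assert mse_loss([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert mse_loss([0.0, 1.0], [1.0, 1.0]) == 0.5
        x, y = np.array([0.2, 0.7]), np.array([1.0, -0.5])
        assert math.isclose(mse_loss(3 * x, 3 * y), 9 * mse_loss(x, y), rel_tol=1e-12)

    def test_mse_shape_mismatch(self):
        with pytest.raises(ValueError):
            mse_loss([1.0], [1.0, 2.0])

    def test_kl_standard_normal_is_zero(self):
        assert kl_gaussian(np.zeros(4), np.zeros(4)) == 0.0

    def test_kl_unit_mean_closed_form(self):
        assert math.isclose(kl_gaussian([1.0], [0.0]), 0.5, rel_tol=1e-12)

    def test_kl_matches_monte_carlo(self, rng):
        """Closed form vs a 1e5-sample estimate of E[log q - log p]."""
        mu = np.array([0.5, -1.2, 0.3])
        logvar = np.array([0.2, -0.5, 0.0])
        sd = np.exp(0.5 * logvar)
        n = 100_000
        z = mu + sd * rng.standard_normal((n, 3))
        log_q = (-0.5 * (((z - mu) / sd) ** 2 + np.log(2 * np.pi) + logvar)).sum(axis=1)
        log_p = (-0.5 * (z**2 + np.log(2 * np.pi))).sum(axis=1)
        samples = log_q - log_p
        est, se = samples.mean(), samples.std(ddof=1) / np.sqrt(n)
        assert abs(kl_gaussian(mu, logvar) - est) < 3 * se

    def test_kl_nonnegative_random(self, rng):
        for _ in range(50):
            assert kl_gaussian(rng.standard_normal(6), rng.standard_normal(6)) >= 0

    def test_matrix_loss_defaults(self):
        assert math.isclose(
            matrix_loss({"distance": 1.0, "structure": 0.0, "adjacency": 0.0}), 0.3
        )
        assert math.isclose(
            matrix_loss({"distance": 5.0, "structure": 5.0, "adjacency": 5.0}), 5.0
        )

    def test_matrix_loss_matches_scalar_recomputation(self, rng):
        for _ in range(20):
            d, s, a = rng.uniform(0, 3, 3)
            w = LossWeights(alpha=0.25, beta=0.5)
            got = matrix_loss({"distance": d, "structure": s, "adjacency": a}, w)
            assert math.isclose(got, 0.25 * d + 0.5 * s + 0.25 * a, rel_tol=1e-12)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=0.7, beta=0.5)

    def test_composite_arithmetic(self):
        b = LossBreakdown(sequence=1, target=1, class_=1, score=1, attention=1,
                          distance=1, structure=1, adjacency=1, kl=0)
        # matrix collapses to 1 under convexity, so total = 1+1+1+2+1+1+0
        assert composite_loss(b) == 7.0
        zero = LossBreakdown(*([0.0] * 9))
        assert composite_loss(zero) == 0.0

    def test_composite_rejects_negative(self):
        b = LossBreakdown(sequence=-1, target=0, class_=0, score=0, attention=0,
                          distance=0, structure=0, adjacency=0, kl=0)
        with pytest.raises(ValueError):
            composite_loss(b)

    def test_score_gradient_doubles_sequence_gradient(self):
        """Finite-difference sensitivity of the total: d/d(score) = 2 x d/d(sequence)."""
        base = dict(sequence=1.0, target=1.0, class_=1.0, score=1.0, attention=1.0,
                    distance=1.0, structure=1.0, adjacency=1.0, kl=1.0)
        eps = 1e-6

        def total(**over):
            return composite_loss(LossBreakdown(**{**base, **over}))

        g_score = (total(score=1 + eps) - total(score=1 - eps)) / (2 * eps)
        g_seq = (total(sequence=1 + eps) - total(sequence=1 - eps)) / (2 * eps)
        assert math.isclose(g_score, 2 * g_seq, rel_tol=1e-6)


class TestLatentDistribution:
    def test_seeded_sampling_reproducible(self):
        ld = LatentDistribution(mu=np.zeros(8), logvar=np.zeros(8))
        a = ld.sample(np.random.default_rng(3))
        b = ld.sample(np.random.default_rng(3))
        assert np.array_equal(a, b)


def _near_duplicate_pairs(n=50, n_classes=4, seed=0):
    """Low-entropy family: per-class prototype with two point substitutions,
    the regime where autoencoding should approach perfect identity."""
    rng = np.random.default_rng(seed)
    protos = ["".join("ACGT"[i] for i in rng.integers(0, 4, 24)) for _ in range(n_classes)]
    pairs = []
    for k in range(n):
        c = k % n_classes + 1
        s = list(protos[c - 1])
        for pos in rng.choice(len(s), size=2, replace=False):
            s[pos] = "ACGT"[int(rng.integers(0, 4))]
        seq = "".join(s)
        pairs.append(make_pair(seq, str(fold_structure(seq)), _CLASS_SMILES[c - 1],
                               c, float(rng.uniform(0.1, 1.0))))
    return pairs


@pytest.fixture(scope="module")
def small_model():
    pairs = _near_duplicate_pairs()
    cfg = ModelConfig(latent_dim=32, hidden=96, hidden_3d=32, epochs=150,
                      patience=150, n_classes=4, seed=4, kl_warmup_epochs=15)
    return pairs, train_aptavae(pairs, cfg)


class TestTraining:
    def test_preconditions(self):
        pairs = _near_duplicate_pairs(n=10)
        with pytest.raises(ValueError):
            train_aptavae(pairs, ModelConfig())
        one_class = [p for p in _near_duplicate_pairs(n=60) if p.class_label == 1]
        with pytest.raises(ValueError):
            train_aptavae(one_class[:25], ModelConfig())

    def test_loss_decreases_early(self, small_model):
        _, model = small_model
        h = model.history
        assert h[9]["train_total"] < h[0]["train_total"]

    def test_history_satisfies_loss_identities(self, small_model):
        """Every logged epoch obeys the composite and matrix identities."""
        _, model = small_model
        w = model.cfg.weights
        for rec in model.history:
            matrix = (w.alpha * rec["val_distance"] + w.beta * rec["val_structure"]
                      + (1 - w.alpha - w.beta) * rec["val_adjacency"])
            total = (rec["val_sequence"] + rec["val_target"] + rec["val_class"]
                     + w.score_multiplier * rec["val_score"] + rec["val_attention"]
                     + matrix + rec["val_kl"])
            assert math.isclose(total, rec["val_total"], rel_tol=1e-9)

    def test_best_checkpoint_not_worse_than_final(self, small_model):
        _, model = small_model
        assert model.best_val <= model.history[-1]["val_total"] + 1e-9

    def test_autoencode_identity_on_training_items(self, small_model):
        """decode(encode(x).mu) reproduces training sequences at >=90% identity."""
        pairs, model = small_model
        ds = model.dataset
        lat = model.encode_features(ds.x1d, ds.x3d, ds.ctx)
        bundles = model.decode_latent(lat.mu)
        idents = [
            np.mean([a == b for a, b in zip(str(p.seq), str(bun.sequence))])
            for p, bun in zip(pairs, bundles)
        ]
        assert np.mean(idents) >= 0.90

    def test_decode_is_deterministic_and_score_bounded(self, small_model, rng):
        _, model = small_model
        z = rng.standard_normal((5, model.cfg.latent_dim))
        a = model.decode_latent(z)
        b = model.decode_latent(z)
        for x, y in zip(a, b):
            assert str(x.sequence) == str(y.sequence)
            assert x.score == y.score
            assert 0.0 <= x.score <= 1.0

    def test_encode_pair_latent_matches_dataset_encoding(self, small_model):
        pairs, model = small_model
        ld = encode_pair_latent(model, pairs[0])
        assert ld.mu.shape[-1] == model.cfg.latent_dim
        assert np.isfinite(ld.mu).all() and np.isfinite(ld.logvar).all()

    @pytest.mark.parametrize(
        "toggles",
        [dict(use_3d=False, skip_connections=False, attention=False),
         dict(use_3d=True, skip_connections=False, attention=False),
         dict(use_3d=True, skip_connections=True, attention=False),
         dict(use_3d=True, skip_connections=True, attention=True)],
        ids=["1d_only", "plus_3d", "plus_skip", "plus_attention"],
    )
    def test_ablation_configurations_train(self, toggles):
        """The four architecture ablations are plain config toggles."""
        pairs = _near_duplicate_pairs(n=24, n_classes=2)
        cfg = ModelConfig(latent_dim=16, hidden=48, hidden_3d=16, epochs=8,
                          patience=8, n_classes=2, seed=1, kl_warmup_epochs=2,
                          **toggles)
        model = train_aptavae(pairs, cfg)
        assert np.isfinite(model.best_val)


class TestPersistence:
    def test_tsv_roundtrip(self, tmp_path):
        pairs = _near_duplicate_pairs(n=6)
        path = tmp_path / "pairs.tsv"
        write_pairs_tsv(path, pairs)
        back = read_pairs_tsv(path)
        assert len(back) == 6
        for a, b in zip(pairs, back):
            assert str(a.seq) == str(b.seq) and a.class_label == b.class_label
            assert math.isclose(a.score, b.score, abs_tol=1e-6)

    def test_model_save_load_identical_decodes(self, small_model, tmp_path, rng):
        _, model = small_model
        path = tmp_path / "model.npz"
        save_model(model, path)
        clone = load_model(path)
        z = rng.standard_normal((3, model.cfg.latent_dim))
        for a, b in zip(model.decode_latent(z), clone.decode_latent(z)):
            assert str(a.sequence) == str(b.sequence)
            assert a.score == b.score


class TestPairValidation:
    def test_score_clamped_and_lengths_checked(self):
        p = make_pair("ACGTACGT", "........", _CLASS_SMILES[0], 1, 1.7)
        assert p.score == 1.0
        with pytest.raises(ValueError):
            make_pair("ACGT", "...", _CLASS_SMILES[0], 1, 0.5)
        with pytest.raises(ValueError):
            make_pair("ACGT", "....", _CLASS_SMILES[0], 0, 0.5)
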