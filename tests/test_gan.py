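"""Three-player model: contracts, gradient penalty, training mechanics."""

import copy
import dataclasses

import numpy as np
import pytest

from phasegan import gan, nn
from phasegan.simulate import ClassModel, SimConfig, simulate_dataset
from phasegan.spectra import normalize_minmax

CLASSES = ["solution", "gel"]


def small_config(**overrides):
    base = dict(epochs=2, pretrain_epochs=2, critic_warmup_epochs=1,
                latent_dim=8, batch_size=8,
                disc_kernels=(4, 8, 8, 8), gen_kernels=(8, 8, 4),
                gen_initial_channels=8, clf_kernels=(4, 4, 8, 8), seed=0)
    base.update(overrides)
    return gan.ThreePlayerConfig(**base)


def tiny_dataset(similarity=0.0, noise_sd=0.5, n=(24, 8), length=64, seed=5,
                 jitter_sd=0.02):
    cfg = SimConfig(length=length, similarity=similarity, noise_sd=noise_sd,
                    jitter_sd=jitter_sd,
                    n_per_class={"solution": n[0], "gel": n[1]}, seed=seed)
    ds, _ = normalize_minmax(simulate_dataset(cfg))
    return ds


@pytest.fixture(scope="module")
def trained_players():
    """One short three-player run on easy synthetic data, reused across tests."""
    data = tiny_dataset(n=(40, 12))
    config = small_config(epochs=10, pretrain_epochs=15, critic_warmup_epochs=4,
                          seed=7)
    players, log = gan.train(data, config)
    return players, log, data


class TestBuild:
    def test_classifier_simplex_contract(self):
        players = gan.build_players(small_config(), 2, 200, classes=CLASSES)
        x = np.random.default_rng(0).uniform(-1, 1, (5, 200))
        probs = gan.predict_proba(players, x)
        assert probs.shape == (5, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_generator_shape_and_range(self):
        players = gan.build_players(small_config(), 2, 200, classes=CLASSES)
        z = np.random.default_rng(1).standard_normal((6, 8))
        out = players.generator.forward(z, np.zeros(6, dtype=int), train=True)
        assert out.shape == (6, 1, 10, 20)
        assert out.min() >= -1.0 and out.max() <= 1.0

    def test_same_seed_identical_parameters(self):
        a = gan.build_players(small_config(seed=3), 2, 64, classes=CLASSES)
        b = gan.build_players(small_config(seed=3), 2, 64, classes=CLASSES)
        for pa, pb in zip(a.generator.params() + a.discriminator.params()
                          + a.classifier.params(),
                          b.generator.params() + b.discriminator.params()
                          + b.classifier.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_incompatible_reshape_rejected(self):
        with pytest.raises(ValueError, match="reshape"):
            gan.build_players(small_config(reshape=(3, 5)), 2, 64)


class TestGradientPenalty:
    def setup_method(self):
        rng = np.random.default_rng(2)
        self.x = rng.uniform(-1, 1, (8, 1, 8, 8))
        self.y = rng.integers(0, 2, 8)

    def test_unit_gradient_linear_probe_zero(self):
        class LinD:
            def __init__(self, shape):
                w = np.ones(shape)
                self.w = w / np.sqrt(w.size)
            def params(self):
                return []
            def forward(self, x, labels, train=True):
                return np.tensordot(x, self.w, axes=3).reshape(-1, 1)
            def backward(self, g):
                return g[:, :, None, None] * self.w[None]
        pen = gan.gradient_penalty(LinD((1, 8, 8)), self.x, 0.5 * self.x, self.y,
                                   lam=10.0, seed=1)
        assert pen == pytest.approx(0.0, abs=1e-6)

    def test_constant_critic_gives_lambda(self):
        class ConstD:
            def params(self):
                return []
            def forward(self, x, labels, train=True):
                self._shape = x.shape
                return np.zeros((x.shape[0], 1))
            def backward(self, g):
                return np.zeros(self._shape)
        assert gan.gradient_penalty(ConstD(), self.x, 0.3 * self.x, self.y,
                                    lam=10.0, seed=1) == pytest.approx(10.0)

    def test_input_gradients_match_finite_differences(self):
        players = gan.build_players(small_config(seed=4), 2, 64, classes=CLASSES)
        disc = players.discriminator
        x = np.random.default_rng(3).uniform(-1, 1, (3, 1, 8, 8))
        y = np.array([0, 1, 0])
        gx = gan._input_gradients(disc, x, y)
        eps = 1e-6
        rng = np.random.default_rng(4)
        for _ in range(10):
            i = rng.integers(0, x.size)
            xp, xm = x.copy(), x.copy()
            xp.ravel()[i] += eps
            xm.ravel()[i] -= eps
            fd = (disc.forward(xp, y).sum() - disc.forward(xm, y).sum()) / (2 * eps)
            assert gx.ravel()[i] == pytest.approx(fd, rel=1e-3, abs=1e-9)

    def test_penalty_parameter_gradient_matches_finite_differences(self):
        players = gan.build_players(small_config(seed=5), 2, 64, classes=CLASSES)
        disc = players.discriminator
        rng = np.random.default_rng(6)
        xhat = rng.uniform(-1, 1, (4, 1, 8, 8))
        y = rng.integers(0, 2, 4)
        pen, grads = gan._gp_value_and_param_grads(disc, xhat, y, 10.0)

        def penalty():
            g = gan._input_gradients(disc, xhat, y)
            norms = np.sqrt((g ** 2).sum(axis=(1, 2, 3)))
            return 10.0 * np.mean((norms - 1.0) ** 2)

        assert pen == pytest.approx(penalty())
        eps = 1e-6
        for p, g in zip(disc.params(), grads):
            for k in rng.integers(0, p.value.size, size=3):
                old = p.value.ravel()[k]
                p.value.ravel()[k] = old + eps
                fp = penalty()
                p.value.ravel()[k] = old - eps
                fm = penalty()
                p.value.ravel()[k] = old
                fd = (fp - fm) / (2 * eps)
                assert g.ravel()[k] == pytest.approx(fd, rel=1e-3, abs=1e-7)

    def test_shape_mismatch_rejected(self):
        players = gan.build_players(small_config(), 2, 64, classes=CLASSES)
        with pytest.raises(ValueError, match="identical shapes"):
            gan.gradient_penalty(players.discriminator, self.x, self.x[:4],
                                 self.y, 10.0)


class TestBalancedBatch:
    def _generator(self):
        players = gan.build_players(small_config(), 2, 64, classes=CLASSES)
        return players.generator

    def test_deficit_fill_arithmetic(self):
        g = self._generator()
        rng = np.random.default_rng(0)
        real = rng.uniform(-1, 1, (8, 1, 8, 8))
        labels = np.array([0] * 7 + [1])
        grids, lab, mask = gan.assemble_balanced_batch(real, labels, g, 7, 2, rng)
        assert np.bincount(lab).tolist() == [7, 7]
        assert mask.sum() == 6 and not mask[:8].any()

    def test_already_balanced_no_generation(self):
        g = self._generator()
        rng = np.random.default_rng(1)
        real = rng.uniform(-1, 1, (6, 1, 8, 8))
        labels = np.array([0, 1] * 3)
        grids, lab, mask = gan.assemble_balanced_batch(real, labels, g, 3, 2, rng)
        assert mask.sum() == 0 and grids is real

    @pytest.mark.parametrize("seed", range(20))
    def test_counts_equal_over_random_batches(self, seed):
        g = self._generator()
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 20))
        labels = rng.integers(0, 2, n)
        real = rng.uniform(-1, 1, (n, 1, 8, 8))
        target = int(np.bincount(labels, minlength=2).max())
        _, lab, _ = gan.assemble_balanced_batch(real, labels, g, target, 2, rng)
        counts = np.bincount(lab, minlength=2)
        assert counts[0] == counts[1] == target


class TestTrainStep:
    def _setup(self, **cfg_over):
        config = small_config(**cfg_over)
        players = gan.build_players(config, 2, 64, classes=CLASSES)
        rng = np.random.default_rng(9)
        grids = rng.uniform(-1, 1, (12, 1, 8, 8))
        labels = np.array([0] * 9 + [1] * 3)
        return players, grids, labels, config

    def test_losses_finite_and_batch_balanced(self):
        players, grids, labels, config = self._setup()
        rec = gan.train_step(players, grids, labels, config,
                             np.random.default_rng(0))
        for key in ("d_loss", "gp", "g_adv", "g_coop", "c_loss"):
            assert np.isfinite(rec[key])
        assert len(set(rec["batch_class_counts"])) == 1

    def test_identical_state_identical_update(self):
        players_a, grids, labels, config = self._setup()
        players_b = copy.deepcopy(players_a)
        rec_a = gan.train_step(players_a, grids, labels, config,
                               np.random.default_rng(5))
        rec_b = gan.train_step(players_b, grids, labels, config,
                               np.random.default_rng(5))
        assert rec_a == rec_b
        for pa, pb in zip(players_a.generator.params(), players_b.generator.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_zero_cooperative_weight_ignores_classifier(self):
        """With the cooperative term off, the generator update must not depend
        on the classifier's parameters; with it on, it must."""
        players_a, grids, labels, _ = self._setup(cooperative_weight=0.0)
        players_b = copy.deepcopy(players_a)
        # scramble the classifier in one copy only
        rng = np.random.default_rng(11)
        for p in players_b.classifier.params():
            p.value += rng.normal(0, 0.1, p.value.shape)
        cfg0 = players_a.config
        gan.train_step(players_a, grids, labels, cfg0, np.random.default_rng(3))
        gan.train_step(players_b, grids, labels, cfg0, np.random.default_rng(3))
        for pa, pb in zip(players_a.generator.params(), players_b.generator.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

        players_c, grids, labels, _ = self._setup(cooperative_weight=1.0)
        players_d = copy.deepcopy(players_c)
        for p in players_d.classifier.params():
            p.value += rng.normal(0, 0.1, p.value.shape)
        cfg1 = players_c.config
        gan.train_step(players_c, grids, labels, cfg1, np.random.default_rng(3))
        gan.train_step(players_d, grids, labels, cfg1, np.random.default_rng(3))
        diffs = [np.abs(pc.value - pd.value).max()
                 for pc, pd in zip(players_c.generator.params(),
                                   players_d.generator.params())]
        assert max(diffs) > 0


class TestPretrain:
    def test_zero_epochs_identity(self):
        data = tiny_dataset()
        players = gan.build_players(small_config(pretrain_epochs=0), 2,
                                    data.length, classes=data.classes)
        before = [p.value.copy() for p in players.generator.params()]
        gan.pretrain(players, data)
        for b, p in zip(before, players.generator.params()):
            np.testing.assert_array_equal(b, p.value)

    def test_reconstruction_improves(self):
        data = tiny_dataset(n=(20, 10))
        config = small_config(pretrain_epochs=12, seed=2)
        players = gan.build_players(config, 2, data.length, classes=data.classes)
        grids = players.to_grid(data.values)
        labels = players.label_index(data.labels)
        rng = np.random.default_rng(0)
        enc = gan._Encoder(players.discriminator, config.latent_dim, rng)
        before = gan.reconstruction_loss(players, enc, grids, labels)
        gan.pretrain(players, data, config)
        after_enc = gan._Encoder(players.discriminator, config.latent_dim, rng)
        after = gan.reconstruction_loss(players, after_enc, grids, labels)
        assert after < before

    def test_single_class_noiseless_reconstruction(self):
        """Median reconstruction error below 0.05 on a clean one-class set."""
        errors = []
        for seed in range(3):
            cfg = SimConfig(length=64, noise_sd=0.0, jitter_sd=0.0,
                            n_per_class={"solution": 256, "gel": 2},
                            class_models={
                                "solution": ClassModel(0.45, 0.1, -25.0, -2.0, -18.0),
                                "gel": ClassModel(0.6, 0.15, -15.0, -2.0, -20.0)},
                            seed=seed)
            data, _ = normalize_minmax(simulate_dataset(cfg))
            config = gan.ThreePlayerConfig.scaled_down(pretrain_epochs=100,
                                                       seed=seed)
            players = gan.build_players(config, 2, 64, classes=data.classes)
            gan.pretrain(players, data, config)
            sol = players.to_grid(data.by_class("solution").values)
            gen = gan.generate_minority(players, "solution", 32, seed)
            err = np.abs(gen.values.mean(axis=0)
                         - players.to_flat(sol).mean(axis=0)).mean()
            errors.append(err)
        assert np.median(errors) < 0.05


class TestTrainAndGenerate:
    def test_log_one_record_per_epoch(self):
        data = tiny_dataset(n=(14, 6))
        players, log = gan.train(data, small_config(epochs=1))
        assert len(log.records) == 1
        assert set(log.records[0]) >= {"epoch", "d_loss", "g_adv", "g_coop",
                                       "c_loss", "gp", "batch_class_counts"}

    def test_balanced_batch_invariant_whole_log(self, trained_players):
        _, log, _ = trained_players
        for rec in log.records:
            for counts in rec["batch_class_counts"]:
                assert len(set(counts)) == 1

    def test_generated_range_and_determinism(self, trained_players):
        players, _, _ = trained_players
        a = gan.generate_minority(players, "gel", 20, seed=3)
        b = gan.generate_minority(players, "gel", 20, seed=3)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.values.min() >= -1.0 and a.values.max() <= 1.0
        assert all(s.meta["generated"] for s in a.spectra)
        assert gan.generate_minority(players, "gel", 0, seed=1) == []
        with pytest.raises(ValueError, match="unknown class"):
            gan.generate_minority(players, "plasma", 3, seed=1)

    def test_generated_peak_position_recovery(self, trained_players):
        players, _, data = trained_players
        for cls in data.classes:
            gen_mean = gan.generate_minority(players, cls, 40, seed=9).values.mean(axis=0)
            real_mean = data.by_class(cls).values.mean(axis=0)
            drift = abs(int(gen_mean.argmin()) - int(real_mean.argmin()))
            assert drift <= 0.05 * data.length + 1

    def test_extract_features_contract(self, trained_players):
        players, _, data = trained_players
        feats = gan.extract_features(players, data)
        assert feats.shape[0] == len(data)
        # identical spectra give identical rows
        twin = data.subset([0, 0])
        f2 = gan.extract_features(players, twin)
        np.testing.assert_array_equal(f2[0], f2[1])

    def test_feature_space_class_separation(self, trained_players):
        players, _, data = trained_players
        feats = gan.extract_features(players, data)
        labels = np.array(data.labels)
        a, b = feats[labels == "solution"], feats[labels == "gel"]
        within = (np.linalg.norm(a - a.mean(0), axis=1).mean()
                  + np.linalg.norm(b - b.mean(0), axis=1).mean()) / 2
        between = np.linalg.norm(a.mean(0) - b.mean(0))
        assert between > within

    def test_checkpoint_round_trip(self, trained_players, tmp_path):
        players, _, data = trained_players
        path = tmp_path / "ckpt.npz"
        gan.save_players(players, path)
        loaded = gan.load_players(path)
        np.testing.assert_array_equal(gan.predict_proba(loaded, data.values),
                                      gan.predict_proba(players, data.values))
        np.testing.assert_array_equal(
            gan.generate_minority(loaded, "gel", 5, 1).values,
            gan.generate_minority(players, "gel", 5, 1).values)
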