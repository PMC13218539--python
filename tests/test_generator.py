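"""Conditional VAE: FiLM, schedules, losses, gradients, gate, sampling."""

import numpy as np
import pandas as pd
import pytest

from mealforge.generator import (
    CVAEConfig,
    MealCVAE,
    beta_schedule,
    film,
    fit_pair_stats,
    load_model,
    micro_f1,
    save_model,
)


class TestFilm:
    def test_identity(self):
        h = np.array([1.0, -2.0, 3.0])
        np.testing.assert_allclose(film(h, np.ones(3), np.zeros(3)), h)

    def test_zero_gamma_gives_beta(self):
        beta = np.array([0.5, -1.0])
        np.testing.assert_allclose(film(np.array([9.0, 9.0]), np.zeros(2), beta), beta)

    def test_hand_arithmetic(self):
        out = film(np.array([1.0, 2.0]), np.array([2.0, 0.5]), np.array([1.0, -1.0]))
        np.testing.assert_allclose(out, [3.0, 0.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            film(np.zeros(3), np.zeros(2), np.zeros(3))


class TestBetaSchedule:
    CFG = CVAEConfig(beta_max=1.0, beta_min_frac=0.1, warmup_epochs=10, cycle_epochs=10)

    def test_zero_at_step_zero(self):
        assert beta_schedule(0, self.CFG) == 0.0

    def test_beta_max_at_end_of_warmup(self):
        assert beta_schedule(10, self.CFG) == pytest.approx(1.0)

    def test_midpoint_mid_cycle(self):
        # halfway through a post-warmup cycle: (beta_min + beta_max) / 2
        assert beta_schedule(15, self.CFG) == pytest.approx((0.1 + 1.0) / 2)

    def test_cycle_restarts_at_beta_max(self):
        assert beta_schedule(20, self.CFG) == pytest.approx(1.0)

    def test_fractional_steps_within_epoch(self):
        assert beta_schedule(5, self.CFG, steps_per_epoch=1) == pytest.approx(0.5)
        assert beta_schedule(50, self.CFG, steps_per_epoch=10) == pytest.approx(0.5)


def _tiny_model(n_foods=8, n_clusters=2, **kw):
    defaults = dict(latent_dim=4, hidden_dim=10, n_blocks=2, embed_dim=3, seed=0,
                    warmup_epochs=2, cycle_epochs=4, batch_size=8)
    defaults.update(kw)
    cfg = CVAEConfig(**defaults)
    return MealCVAE([f"F{i}" for i in range(n_foods)], list(range(n_clusters)), cfg), cfg


def _tiny_batch(n=6, n_foods=8, seed=0):
    rng = np.random.default_rng(seed)
    X = (rng.random((n, n_foods)) < 0.3).astype(float)
    X[X.sum(axis=1) == 0, 0] = 1
    cl = rng.integers(0, 2, n)
    mt = rng.integers(0, 3, n)
    return X, cl, mt


class TestLosses:
    def test_components_match_independent_formulas(self):
        model, cfg = _tiny_model()
        X, cl, mt = _tiny_batch()
        model.pair_stats = fit_pair_stats(X, cl, mt)
        (bce, kl, count, total), caches = model.loss_components(X, cl, mt, beta=0.7)
        p = caches["probs"]
        w = caches["pos_weight"]
        n_pos, n_neg = X.sum(), X.size - X.sum()
        assert w == pytest.approx(np.clip(n_neg / n_pos, 1, 50))
        exp_bce = np.sum(-w * X * np.log(p + 1e-12) - (1 - X) * np.log(1 - p + 1e-12)) / len(X)
        assert bce == pytest.approx(exp_bce)
        kl_dim = 0.5 * (caches["mu"] ** 2 + np.exp(caches["logvar"]) - 1 - caches["logvar"]).mean(0)
        assert kl == pytest.approx(0.7 * np.maximum(cfg.free_bits, kl_dim).sum())
        exp_count = np.mean((p.sum(axis=1) - X.sum(axis=1)) ** 2)
        assert count == pytest.approx(exp_count)
        assert total == pytest.approx(bce + kl + cfg.count_loss_weight * count)

    def test_free_bits_floor_when_posterior_equals_prior(self):
        """With mu=0 and logvar=0 the raw KL is 0, so the floored KL is
        free_bits * latent_dim (scaled by beta)."""
        model, cfg = _tiny_model()
        # force posterior = prior by zeroing the encoder output heads
        model.params["W_mu"][:] = 0
        model.params["b_mu"][:] = 0
        model.params["W_logvar"][:] = 0
        model.params["b_logvar"][:] = 0
        X, cl, mt = _tiny_batch()
        model.pair_stats = fit_pair_stats(X, cl, mt)
        (_, kl, _, _), _ = model.loss_components(X, cl, mt, beta=1.0)
        assert kl == pytest.approx(cfg.free_bits * cfg.latent_dim)

    def test_count_loss_squared_error(self):
        """Predicted probability mass 3 vs true count 5 contributes (5-3)^2."""
        model, _ = _tiny_model()
        X, cl, mt = _tiny_batch(n=1)
        X[:] = 0
        X[0, :5] = 1  # count 5
        model.pair_stats = fit_pair_stats(X, cl[:1], mt[:1])
        (_, _, count, _), caches = model.loss_components(X, cl[:1], mt[:1], beta=0.0)
        s = caches["probs"].sum()
        assert count == pytest.approx((s - 5.0) ** 2)

    def test_all_zero_targets_no_division_error(self):
        model, _ = _tiny_model()
        X = np.zeros((4, 8))
        cl = np.zeros(4, dtype=int)
        mt = np.zeros(4, dtype=int)
        (bce, _, _, total), caches = model.loss_components(X, cl, mt, beta=0.0)
        assert np.isfinite(total)
        # zero positives: the guarded denominator keeps the weight finite
        assert caches["pos_weight"] == np.clip(X.size, 1.0, 50.0)


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        model, cfg = _tiny_model()
        rng = np.random.default_rng(7)
        X, cl, mt = _tiny_batch(seed=7)
        model.pair_stats = fit_pair_stats(X, cl, mt)
        eps = rng.standard_normal((len(X), cfg.latent_dim))
        (_, _, _, _), caches = model.loss_components(X, cl, mt, beta=0.6, eps=eps)
        grads = model._backward(X, cl, mt, caches)
        for name in ("W_enc0", "W_film_dec1", "W_mu", "W_logvar", "W_out", "E_cluster", "E_meal"):
            P = model.params[name]
            for _ in range(3):
                ix = tuple(rng.integers(s) for s in P.shape)
                h = 1e-6
                old = P[ix]
                P[ix] = old + h
                fp = model.loss_components(X, cl, mt, beta=0.6, eps=eps)[0][3]
                P[ix] = old - h
                fm = model.loss_components(X, cl, mt, beta=0.6, eps=eps)[0][3]
                P[ix] = old
                num = (fp - fm) / (2 * h)
                assert grads[name][ix] == pytest.approx(num, abs=1e-5, rel=1e-4)


class TestTraining:
    def test_memorization_capacity(self):
        """A tiny corpus is reconstructed almost perfectly after training."""
        rng = np.random.default_rng(0)
        F = 30
        X = (rng.random((20, F)) < 0.15).astype(float)
        X[X.sum(axis=1) == 0, 0] = 1
        cl = np.repeat([0, 1], 10)
        mt = np.tile([0, 1], 10)
        cfg = CVAEConfig(latent_dim=16, hidden_dim=64, n_blocks=3, epochs=500,
                         batch_size=20, seed=0, warmup_epochs=50, cycle_epochs=100)
        model = MealCVAE([f"F{i}" for i in range(F)], [0, 1], cfg)
        model.fit(X, cl, mt)
        assert micro_f1(X, model.reconstruct(X, cl, mt)) >= 0.95

    def test_seeded_determinism(self):
        X, cl, mt = _tiny_batch(n=16)
        hists = []
        for _ in range(2):
            model, _ = _tiny_model(epochs=5)
            hists.append(model.fit(X, cl, mt))
        pd.testing.assert_frame_equal(hists[0], hists[1])

    def test_history_records_all_components(self):
        X, cl, mt = _tiny_batch(n=16)
        model, _ = _tiny_model(epochs=3)
        hist = model.fit(X, cl, mt)
        assert list(hist.columns) == ["epoch", "bce", "kl", "count", "total"]
        assert len(hist) == 3


class TestGateAndSampling:
    def _trained_degenerate(self):
        """All meals of each pair are exactly the same 2-food set."""
        F = 10
        X = np.zeros((40, F))
        X[:20, [0, 1]] = 1  # pair (0, lunch) -> {F0, F1}
        X[20:, [4, 7]] = 1  # pair (1, dinner) -> {F4, F7}
        cl = np.repeat([0, 1], 20)
        mt = np.repeat([1, 2], 20)
        cfg = CVAEConfig(latent_dim=4, hidden_dim=16, n_blocks=2, embed_dim=3,
                         epochs=60, batch_size=20, seed=0, warmup_epochs=5, cycle_epochs=10)
        model = MealCVAE([f"F{i}" for i in range(F)], [0, 1], cfg)
        model.fit(X, cl, mt)
        return model

    def test_gate_is_top_k_by_prevalence(self):
        X, cl, mt = _tiny_batch(n=30, seed=2)
        stats = fit_pair_stats(X, cl, mt)
        for s in stats.values():
            k = max(1, s.median_items)
            assert len(s.allowed) == k
            cutoff = np.sort(s.prevalence)[::-1][k - 1]
            assert (s.prevalence[s.allowed] >= cutoff).all()

    def test_prior_logits_finite(self):
        X, cl, mt = _tiny_batch(n=30, seed=3)
        for s in fit_pair_stats(X, cl, mt).values():
            assert np.isfinite(s.prior_logits).all()

    def test_sampled_foods_within_allowed_set(self):
        model = self._trained_degenerate()
        for cluster, meal_type in ((0, "lunch"), (1, "dinner")):
            key = model._pair_key(cluster, ["breakfast", "lunch", "dinner"].index(meal_type))
            allowed = {model.food_codes[i] for i in model.pair_stats[key].allowed}
            for meal in model.sample_meals(cluster, meal_type, 50, seed=1):
                assert set(meal) <= allowed

    def test_degenerate_pair_reproduced(self):
        model = self._trained_degenerate()
        meals = model.sample_meals(0, "lunch", 50, seed=2)
        frac = np.mean([set(m) == {"F0", "F1"} for m in meals])
        assert frac >= 0.9

    def test_sample_zero_returns_empty(self):
        model = self._trained_degenerate()
        assert model.sample_meals(0, "lunch", 0, seed=0) == []

    def test_unknown_pair_lists_known(self):
        model = self._trained_degenerate()
        with pytest.raises(KeyError, match="known pairs"):
            model.sample_meals(5, "breakfast", 1, seed=0)

    def test_save_load_round_trip(self, tmp_path):
        model = self._trained_degenerate()
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        a = model.sample_meals(0, "lunch", 10, seed=3)
        b = back.sample_meals(0, "lunch", 10, seed=3)
        assert a == b


class TestMicroF1:
    def test_perfect_and_disjoint(self):
        y = np.array([[1, 0, 1], [0, 1, 0]])
        assert micro_f1(y, y) == 1.0
        assert micro_f1(y, 1 - y) == 0.0
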