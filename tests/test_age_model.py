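"""Age-regression loss, healthy split, training mechanics and evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from organ_age import synthetic
from organ_age.age_model import (
    AgeModel,
    HeteroscedasticPrediction,
    evaluate_predictions,
    nll_loss,
    split_healthy,
)
from organ_age.config import DataError, PhantomConfig, TrainConfig
from organ_age.preprocess import normalize_intensity


def _pred(mu, log_sigma=0.0):
    return HeteroscedasticPrediction(mu, log_sigma)


class TestNLL:
    def test_zero_residual_unit_sigma_gives_zero(self):
        assert nll_loss([_pred(5.0)], [5.0]) == pytest.approx(0.0)

    def test_single_case_closed_form(self):
        # (1/2)*(2-0)^2 + log 1 = 2
        assert nll_loss([_pred(0.0, 0.0)], [2.0]) == pytest.approx(2.0)

    def test_matches_gaussian_log_density(self, rng):
        for _ in range(100):
            m = int(rng.integers(1, 6))
            mu = rng.normal(60, 10, m)
            y = rng.normal(60, 10, m)
            ls = rng.uniform(-1.5, 2.5, m)
            ours = nll_loss([_pred(a, b) for a, b in zip(mu, ls)], y)
            oracle = np.mean(-stats.norm.logpdf(y, mu, np.exp(ls))
                             - 0.5 * np.log(2 * np.pi))
            assert ours == pytest.approx(oracle, abs=1e-10)

    def test_sigma_minimizer_is_absolute_residual(self):
        for r in (0.5, 1.7, 4.0):
            res = optimize.minimize_scalar(
                lambda s: r**2 / (2 * s**2) + np.log(s),
                bounds=(1e-3, 50), method="bounded",
                options={"xatol": 1e-10})
            assert res.x == pytest.approx(r, abs=1e-5)
            assert res.fun == pytest.approx(0.5 + np.log(r), abs=1e-9)

    def test_empty_batch_rejected(self):
        with pytest.raises(DataError):
            nll_loss([], [])

    def test_frozen_sigma_reduces_to_least_squares(self, rng):
        """With log sigma shared, the NLL-optimal linear mu is the OLS fit."""
        x = np.column_stack([np.ones(40), rng.normal(size=40)])
        y = x @ np.array([2.0, -1.3]) + rng.normal(0, 0.5, 40)

        def total_nll(beta):
            mu = x @ beta
            return nll_loss([_pred(m, 0.7) for m in mu], y)

        res = optimize.minimize(total_nll, x0=np.zeros(2), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        ols = np.linalg.lstsq(x, y, rcond=None)[0]
        np.testing.assert_allclose(res.x, ols, atol=1e-4)


class TestSplitHealthy:
    def test_80_20_split_when_nobody_diseased(self):
        cohort = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(100)],
            "ca_at_imaging": np.full(100, 60.0),
        })
        train, test = split_healthy(cohort, (), 0.8, seed=0)
        assert len(train) == 80 and len(test) == 20
        assert not set(train) & set(test)

    def test_pre_imaging_diagnoses_excluded(self):
        cohort = pd.DataFrame({
            "subject_id": ["A", "B", "C", "D"],
            "ca_at_imaging": [60.0, 60.0, 60.0, 60.0],
            "age_ckd": [55.0, np.nan, 65.0, 50.0],
        })
        train, test = split_healthy(cohort, ("ckd",), 0.5, seed=1)
        kept = set(train) | set(test)
        assert kept == {"B", "C"}  # post-imaging diagnosis stays healthy at imaging

    def test_everyone_diseased_is_an_error(self):
        cohort = pd.DataFrame({
            "subject_id": ["A", "B"],
            "ca_at_imaging": [60.0, 62.0],
            "age_ckd": [50.0, 51.0],
        })
        with pytest.raises(DataError):
            split_healthy(cohort, ("ckd",), 0.8, seed=0)

    def test_same_seed_same_split(self, small_cohort):
        a = split_healthy(small_cohort, ("ckd",), 0.8, seed=3)
        b = split_healthy(small_cohort, ("ckd",), 0.8, seed=3)
        assert a == b


class TestTraining:
    def test_single_epoch_history_and_determinism(self, tiny_train_config, rng):
        x = rng.random((8, 1, 8, 8, 8))
        y = rng.uniform(50, 70, 8)
        cfg = TrainConfig(epochs=1, batch_size=4, channels=(4, 8), seed=5)
        res_a = AgeModel(dims=3, config=cfg).fit(x, y)
        res_b = AgeModel(dims=3, config=cfg).fit(x, y)
        assert len(res_a.loss_history) == 1
        assert res_a.loss_history == res_b.loss_history

    def test_shape_mismatch_rejected(self, tiny_train_config, rng):
        model = AgeModel(dims=3, config=tiny_train_config)
        with pytest.raises(DataError):
            model.fit(rng.random((4, 3, 8, 8)), np.ones(4))  # 2D batch, 3D arch

    def test_training_reduces_nll_on_learnable_signal(self):
        """A short run on clean radius-encoded phantoms lowers the NLL."""
        cohort = synthetic.generate_cohort(64, seed=21)
        phantom = PhantomConfig(texture_blur_levels=(0.5,), radius_noise_sd=0.05)
        images = [normalize_intensity(im) for im in
                  synthetic.render_cohort(cohort, "liver", phantom, base_seed=21)]
        cfg = TrainConfig(epochs=6, batch_size=16, channels=(4, 8), seed=2)
        res = AgeModel(dims=3, config=cfg).fit(images, cohort["ca_at_imaging"])
        assert res.loss_history[-1] <= res.loss_history[0]

    def test_shuffled_labels_leave_no_signal(self):
        cohort = synthetic.generate_cohort(64, seed=22)
        images = [normalize_intensity(im) for im in
                  synthetic.render_cohort(cohort, "liver", base_seed=22)]
        y = cohort["ca_at_imaging"].to_numpy().copy()
        np.random.default_rng(0).shuffle(y)
        cfg = TrainConfig(epochs=4, batch_size=16, channels=(4, 8), seed=2)
        res = AgeModel(dims=3, config=cfg).fit(images[:48], y[:48])
        ev = res.evaluate(images[48:], y[48:])
        baseline = np.abs(y[48:] - y[:48].mean()).mean()
        assert ev["mae"] > 0.6 * baseline  # indistinguishable from the mean predictor


class TestPrediction:
    def test_duplicate_images_get_identical_predictions(self, e2e):
        res = e2e["artifacts"]["results"]
        img = e2e["artifacts"]["images"][0]
        a, b = res.predict([img, img])
        assert (a.mu, a.log_sigma) == (b.mu, b.log_sigma)

    def test_batch_predictions_are_order_preserving(self, e2e):
        res = e2e["artifacts"]["results"]
        imgs = e2e["artifacts"]["images"][:7]
        all_at_once = res.predict(imgs)
        one_by_one = [res.predict([im])[0] for im in imgs]
        for a, b in zip(all_at_once, one_by_one):
            assert a.mu == pytest.approx(b.mu, abs=1e-4)

    def test_log_sigma_respects_clamp(self, e2e):
        res = e2e["artifacts"]["results"]
        lo, hi = res.config.sigma_clamp
        for p in res.predict(e2e["artifacts"]["images"][:32]):
            assert lo <= p.log_sigma <= hi

    def test_predicted_uncertainty_tracks_texture_blur(self, e2e):
        """Blurrier phantoms carry noisier age labels; sigma should notice."""
        res = e2e["artifacts"]["results"]
        cohort = e2e["artifacts"]["cohort"].iloc[:60]
        organ = e2e["organ"]
        subsets = {}
        for blur in (0.5, 1.5):
            phantom = PhantomConfig(texture_blur_levels=(blur,))
            imgs = [normalize_intensity(synthetic.render_organ_image(
                row, organ, phantom, seed=synthetic.render_seed(33, i, organ)))
                for i, (_, row) in enumerate(cohort.iterrows())]
            subsets[blur] = np.mean([p.log_sigma for p in res.predict(imgs)])
        assert subsets[1.5] > subsets[0.5]


class TestEvaluation:
    def test_perfect_predictions(self):
        y = [50.0, 60.0, 70.0]
        out = evaluate_predictions([_pred(v) for v in y], y)
        assert out["mae"] == 0.0
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_constant_offset(self):
        y = np.array([50.0, 60.0, 70.0, 80.0])
        out = evaluate_predictions([_pred(v + 1.0) for v in y], y)
        assert out["mae"] == pytest.approx(1.0)
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_matches_textbook_pearson_formula(self, rng):
        mu = rng.normal(60, 8, 10)
        y = rng.normal(60, 8, 10)
        out = evaluate_predictions([_pred(m) for m in mu], y)
        mx, my = mu.mean(), y.mean()
        r_hand = (np.sum((mu - mx) * (y - my))
                  / np.sqrt(np.sum((mu - mx) ** 2) * np.sum((y - my) ** 2)))
        assert out["pearson_r"] == pytest.approx(r_hand, abs=1e-12)

    def test_zero_variance_labels_rejected(self):
        with pytest.raises(DataError):
            evaluate_predictions([_pred(1.0)] * 3, [5.0, 5.0, 5.0])


class TestPersistence:
    def test_save_load_round_trip(self, e2e, tmp_path):
        res = e2e["artifacts"]["results"]
        res.save(tmp_path / "m.npz", tmp_path / "m.json")
        from organ_age.age_model import AgeFitResults

        back = AgeFitResults.load(tmp_path / "m.npz", tmp_path / "m.json")
        imgs = e2e["artifacts"]["images"][:4]
        for a, b in zip(res.predict(imgs), back.predict(imgs)):
            assert a.mu == pytest.approx(b.mu, abs=1e-6)
            assert a.log_sigma == pytest.approx(b.log_sigma, abs=1e-6)
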