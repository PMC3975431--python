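"""Pair vectors, standardization, SVM training/prediction, grid search and
the model/results layer."""

import numpy as np
import pytest

from dtipred import (
    InteractionModel,
    ValidationError,
    apply_standardizer,
    combine,
    fit_standardizer,
    predict,
    train,
)
from dtipred.io import DrugFingerprint
from dtipred.model import N_PAIR, grid_search, predict_many


class TestCombine:
    def test_layout_identity(self, rng):
        d = DrugFingerprint("D1", rng.random(256))
        psi = rng.random(500)
        raw = combine(d, psi)
        assert raw.shape == (N_PAIR,)
        assert raw[0] == d.values[0]
        assert raw[256] == psi[0]
        np.testing.assert_array_equal(raw[:256], d.values)
        np.testing.assert_array_equal(raw[256:], psi)

    def test_zero_inputs_give_zero_vector(self):
        raw = combine(DrugFingerprint("D0", np.zeros(256)), np.zeros(500))
        assert not raw.any()

    def test_wrong_protein_length_rejected(self):
        with pytest.raises(ValidationError):
            combine(DrugFingerprint("D0", np.zeros(256)), np.zeros(499))


class TestStandardizer:
    def test_two_point_symmetry(self):
        std = fit_standardizer(np.vstack([np.zeros(756), np.full(756, 2.0)]))
        np.testing.assert_allclose(std.mean, 1.0)
        np.testing.assert_allclose(std.sd, 1.0)  # population SD

    def test_single_vector_sd_zero(self, rng):
        x = rng.random(756)
        std = fit_standardizer(x[None, :])
        np.testing.assert_allclose(std.sd, 0.0)
        np.testing.assert_allclose(apply_standardizer(std, x), 0.0)

    def test_matches_two_pass_oracle(self, rng):
        x = rng.normal(size=(50, 10))
        std = fit_standardizer(x)
        for j in range(10):
            mean_j = sum(x[:, j]) / 50
            var_j = sum((v - mean_j) ** 2 for v in x[:, j]) / 50
            assert std.mean[j] == pytest.approx(mean_j)
            assert std.sd[j] == pytest.approx(np.sqrt(var_j))

    def test_training_set_standardizes_to_zero_mean_unit_sd(self, rng):
        x = rng.normal(2.0, 3.0, size=(40, 8))
        x[:, 5] = 7.0  # constant feature
        std = fit_standardizer(x)
        y = apply_standardizer(std, x)
        np.testing.assert_allclose(y.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(y[:, 5], 0.0)
        varying = [j for j in range(8) if j != 5]
        np.testing.assert_allclose(y[:, varying].std(axis=0), 1.0, atol=1e-12)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValidationError):
            fit_standardizer(np.empty((0, 756)))


def _separable_clouds(rng, n_per_class=20, dim=20, separation=10.0):
    centers = np.zeros((2, dim))
    centers[1, :5] = separation
    x = np.vstack(
        [rng.normal(centers[0], 1.0, size=(n_per_class, dim)),
         rng.normal(centers[1], 1.0, size=(n_per_class, dim))]
    )
    y = np.array([-1] * n_per_class + [1] * n_per_class)
    return x, y


class TestTrainPredict:
    def test_separable_clouds_reproduce_training_labels(self, rng):
        x, y = _separable_clouds(rng)
        std = fit_standardizer(x)
        z = apply_standardizer(std, x)
        clf = train(z, y, C=8.0, gamma=2.0**-9)
        labels, dvs = predict_many(clf, z)
        np.testing.assert_array_equal(labels, y)
        assert np.all((dvs > 0) == (labels == 1))

    def test_paper_operating_point_accepted(self, rng):
        x, y = _separable_clouds(rng, n_per_class=5)
        clf = train(x, y, C=2.0**3, gamma=2.0**-9)
        assert clf.C == 8.0 and clf.gamma == pytest.approx(0.001953125)

    @pytest.mark.parametrize("C,gamma", [(0.0, 0.1), (-1.0, 0.1), (1.0, 0.0)])
    def test_nonpositive_parameters_rejected(self, rng, C, gamma):
        x, y = _separable_clouds(rng, n_per_class=3)
        with pytest.raises(ValidationError):
            train(x, y, C=C, gamma=gamma)

    def test_single_class_rejected(self, rng):
        x = rng.normal(size=(6, 4))
        with pytest.raises(ValidationError):
            train(x, [1] * 6)

    def test_dimension_mismatch_rejected(self, rng):
        x, y = _separable_clouds(rng, n_per_class=5)
        clf = train(x, y)
        with pytest.raises(ValidationError):
            predict(clf, np.zeros(x.shape[1] + 1))

    def test_predict_deterministic(self, rng):
        x, y = _separable_clouds(rng, n_per_class=8)
        clf = train(x, y)
        probe = rng.normal(size=x.shape[1])
        assert predict(clf, probe) == predict(clf, probe)

    def test_affine_rescaling_absorbed_by_standardizer(self, rng):
        """Scaling and shifting a raw feature leaves decision values
        unchanged within 1e-9 once standardization is applied."""
        x, y = _separable_clouds(rng)
        x2 = x.copy()
        x2[:, 3] = 7.5 * x2[:, 3] - 2.0
        dvs = []
        for data in (x, x2):
            std = fit_standardizer(data)
            z = apply_standardizer(std, data)
            clf = train(z, y, C=8.0, gamma=2.0**-7)
            dvs.append(predict_many(clf, z)[1])
        np.testing.assert_allclose(dvs[0], dvs[1], atol=1e-9)


class TestModelResults:
    def test_fit_and_summary(self, benchmark30):
        model = InteractionModel(benchmark30)
        res = model.fit(seed=0)
        text = res.summary()
        assert "756" in text and "RBF" in text
        preds = res.predict_pairs(benchmark30.pairs)
        assert set(preds.columns) == {"drug_id", "protein_id", "decision_value", "label"}
        assert len(preds) == 30

    def test_training_predictions_recover_planted_labels(self, benchmark30):
        res = InteractionModel(benchmark30).fit(seed=0)
        preds = res.predict_pairs(benchmark30.pairs)
        truth = np.array([p.label for p in benchmark30.pairs])
        assert (preds["label"].to_numpy() == truth).mean() >= 0.95

    def test_jackknife_beats_permutation_baseline_by_20_points(self, benchmark60):
        """The planted-signal benchmark is learnable: leave-one-out accuracy
        at the (C=2^3, gamma=2^-9) operating point exceeds the mean accuracy
        under label permutation by at least 20 percentage points."""
        from dtipred.evaluation import jackknife, permutation_null_mcc
        from dtipred.io import Dataset, LabeledPair

        metrics, _ = jackknife(benchmark60, C=8.0, gamma=2.0**-9)
        rng = np.random.default_rng(11)
        labels = np.array([p.label for p in benchmark60.pairs])
        null_accs = []
        for _ in range(5):
            perm = rng.permutation(len(labels))
            shuffled = [
                LabeledPair(p.drug_id, p.protein_id, int(labels[perm[i]]))
                for i, p in enumerate(benchmark60.pairs)
            ]
            ds = Dataset(shuffled, benchmark60.proteins, benchmark60.pssms,
                         benchmark60.fingerprints, benchmark60.metadata)
            m, _ = jackknife(ds, C=8.0, gamma=2.0**-9)
            null_accs.append(m.acc)
        assert metrics.acc - np.mean(null_accs) >= 0.20


class TestGridSearch:
    def test_argmax_found_on_planted_signal(self, benchmark30):
        """Separability is planted at smooth kernels; a degenerate
        memorization-scale gamma loses it. The search must return the cell
        an exhaustive surface inspection identifies."""
        from dtipred.evaluation import jackknife

        c_grid = [8.0]
        gamma_grid = [2.0**-9, 2.0**5]
        result = grid_search(benchmark30, c_grid, gamma_grid, seed=0)
        surface = {
            (row["C"], row["gamma"]): row["accuracy"]
            for _, row in result.surface.iterrows()
        }
        for (c, g), acc in surface.items():
            manual, _ = jackknife(benchmark30, C=c, gamma=g)
            assert acc == pytest.approx(manual.acc)
        best_manual = max(surface, key=lambda k: surface[k])
        assert (result.best_C, result.best_gamma) == best_manual
        assert result.best_gamma == 2.0**-9  # the planted-signal cell

    def test_single_cell_grid_returns_it(self, benchmark30):
        result = grid_search(benchmark30, [4.0], [0.01], seed=0)
        assert (result.best_C, result.best_gamma) == (4.0, 0.01)

    def test_surface_within_unit_interval(self, benchmark30):
        result = grid_search(benchmark30, [8.0], [2.0**-9, 2.0**-3], seed=0)
        assert ((result.surface["accuracy"] >= 0) & (result.surface["accuracy"] <= 1)).all()

    def test_empty_grid_rejected(self, benchmark30):
        with pytest.raises(ValidationError):
            grid_search(benchmark30, [], [0.1])
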