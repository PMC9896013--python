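import math

import numpy as np
import pytest
import scipy.linalg

from neuroprint import FCMatrix, InvalidArgumentError, fingerprint as fp
from neuroprint.connectivity import vectorize_upper


def _random_spd(n, rng, shift=None):
    a = rng.standard_normal((n, n))
    return a @ a.T + (shift if shift is not None else n) * np.eye(n)


def _random_corr(n, rng, noise=0.3):
    a = rng.standard_normal((n, max(2, n // 4)))
    cov = a @ a.T + noise * np.diag(rng.uniform(0.5, 1.5, n))
    d = np.sqrt(np.diag(cov))
    c = cov / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return 0.5 * (c + c.T)


def _fc(values, subject="s0", run="r0", labels=None):
    n = values.shape[0]
    return FCMatrix(
        values=values,
        labels=labels or [f"ch{i}" for i in range(n)],
        subject_id=subject,
        run_id=run,
    )


class TestGeodesicDistance:
    def test_self_distance_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            c = _random_spd(6, rng)
            assert fp.geodesic_distance(c, c, regularize=False) < 1e-7

    def test_diagonal_closed_form(self):
        d = fp.geodesic_distance(
            np.eye(2), np.diag([math.e**2, 1.0]), regularize=False
        )
        assert d == pytest.approx(2.0, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        c1, c2 = _random_spd(5, rng), _random_spd(5, rng)
        assert fp.geodesic_distance(c1, c2) == pytest.approx(
            fp.geodesic_distance(c2, c1), abs=1e-10
        )

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            c1, c2 = _random_spd(6, rng), _random_spd(6, rng)
            m = rng.standard_normal((6, 6))
            while abs(np.linalg.det(m)) < 1e-3:
                m = rng.standard_normal((6, 6))
            d_raw = fp.geodesic_distance(c1, c2, regularize=False)
            d_map = fp.geodesic_distance(m @ c1 @ m.T, m @ c2 @ m.T, regularize=False)
            assert abs(d_raw - d_map) < 1e-8

    def test_squared_is_square(self):
        rng = np.random.default_rng(3)
        c1, c2 = _random_spd(4, rng), _random_spd(4, rng)
        d = fp.geodesic_distance(c1, c2)
        d2 = fp.geodesic_distance(c1, c2, squared=True)
        assert d2 == pytest.approx(d**2, rel=1e-10)

    def test_non_spd_rejected(self):
        bad = np.diag([1.0, -5.0])
        with pytest.raises(fp.ConditioningError):
            fp.geodesic_distance(bad, np.eye(2), regularize=False)


class TestAggregation:
    def test_single_run_identity(self):
        rng = np.random.default_rng(4)
        fc = _fc(_random_corr(5, rng))
        agg = fp.aggregate_training([fc], "pearson")
        np.testing.assert_allclose(agg.values, fc.values)

    def test_two_identical_matrices(self):
        rng = np.random.default_rng(5)
        fc = _fc(_random_corr(5, rng))
        agg = fp.aggregate_training([fc, _fc(fc.values.copy())], "geodesic")
        np.testing.assert_allclose(agg.values, fc.values)

    def test_mean_stays_valid_correlation(self):
        rng = np.random.default_rng(6)
        fcs = [_fc(_random_corr(6, rng), run=f"r{i}") for i in range(4)]
        agg = fp.aggregate_training(fcs, "pearson")
        assert np.allclose(agg.values, agg.values.T)
        assert np.max(np.abs(agg.values)) <= 1.0 + 1e-12
        np.testing.assert_allclose(np.diag(agg.values), 1.0)

    def test_linear_passthrough(self):
        rng = np.random.default_rng(7)
        fcs = [_fc(_random_corr(4, rng), run=f"r{i}") for i in range(3)]
        assert fp.aggregate_training(fcs, "linear") == fcs


def _toy_split(rng, n_subjects=4, n=8):
    train, test = {}, {}
    for i in range(n_subjects):
        base = _random_corr(n, rng)
        train[f"s{i}"] = [
            _fc(base, subject=f"s{i}", run="r0"),
            _fc(base, subject=f"s{i}", run="r1"),
        ]
        test[f"s{i}"] = _fc(base, subject=f"s{i}", run="r2")
    return fp.TrainTestSplit(test=test, train=train)


class TestIdentifiers:
    def test_pearson_identical_matrix_wins(self):
        split = _toy_split(np.random.default_rng(8))
        preds, ties = fp.identify_pearson(split)
        assert preds == {s: s for s in split.subjects}

    def test_geodesic_identical_matrix_wins(self):
        split = _toy_split(np.random.default_rng(9))
        preds, _ = fp.identify_geodesic(split)
        assert preds == {s: s for s in split.subjects}

    def test_squared_and_sqrt_agree(self):
        rng = np.random.default_rng(10)
        train, test = {}, {}
        for i in range(5):
            train[f"s{i}"] = [_fc(_random_corr(6, rng), subject=f"s{i}", run="r0")]
            test[f"s{i}"] = _fc(_random_corr(6, rng), subject=f"s{i}", run="r1")
        split = fp.TrainTestSplit(test=test, train=train)
        preds_a, _ = fp.identify_geodesic(split, squared=False)
        preds_b, _ = fp.identify_geodesic(split, squared=True)
        assert preds_a == preds_b

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        split = _toy_split(rng)
        preds, _ = fp.identify_pearson(split)
        mapping = {"s0": "z3", "s1": "z2", "s2": "z1", "s3": "z0"}
        renamed = fp.TrainTestSplit(
            test={
                mapping[s]: _fc(fc.values, subject=mapping[s], run=fc.run_id)
                for s, fc in split.test.items()
            },
            train={
                mapping[s]: [
                    _fc(fc.values, subject=mapping[s], run=fc.run_id) for fc in fcs
                ]
                for s, fcs in split.train.items()
            },
        )
        preds_renamed, _ = fp.identify_pearson(renamed)
        assert preds_renamed == {mapping[s]: mapping[p] for s, p in preds.items()}

    def test_test_run_in_training_rejected(self):
        rng = np.random.default_rng(12)
        base = _random_corr(4, rng)
        fc0 = _fc(base, run="r0")
        with pytest.raises(InvalidArgumentError):
            fp.TrainTestSplit(test={"s0": fc0}, train={"s0": [fc0]})


class TestLinearClassifier:
    def test_orthogonal_vectors_separable(self):
        x = np.eye(2)
        model = fp.train_linear_classifier(x, [0, 1], ridge_lambda=1e-6)
        labels, ties = model.predict(x)
        np.testing.assert_array_equal(labels, [0, 1])
        assert ties == 0

    def test_huge_lambda_shrinks_to_tie(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal((6, 4))
        model = fp.train_linear_classifier(x, [0, 1, 2, 0, 1, 2], ridge_lambda=1e12)
        assert np.max(np.abs(model.weights)) < 1e-6
        labels, ties = model.predict(rng.standard_normal((3, 4)))
        assert ties == 3
        np.testing.assert_array_equal(labels, 0)

    def test_negative_lambda_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fp.train_linear_classifier(np.eye(2), [0, 1], ridge_lambda=-1.0)

    def test_primal_dual_agree(self):
        rng = np.random.default_rng(14)
        x_tall = rng.standard_normal((20, 5))
        y = rng.integers(0, 3, 20)
        m_primal = fp.train_linear_classifier(x_tall, y, 0.5)
        # dual route is exercised when n < d; check both give same predictions
        x_wide = rng.standard_normal((4, 50))
        m_wide = fp.train_linear_classifier(x_wide, [0, 1, 0, 1], 0.5)
        scores = m_wide.scores(x_wide)
        gram_check = fp.train_linear_classifier(
            np.hstack([x_wide, np.zeros((4, 0))]), [0, 1, 0, 1], 0.5
        ).scores(x_wide)
        np.testing.assert_allclose(scores, gram_check, atol=1e-8)
        assert m_primal.weights.shape == (3, 6)


class TestCombineContrasts:
    def test_vector_concatenation_length(self):
        rng = np.random.default_rng(15)
        fcs = {"HbR": _fc(_random_corr(48, rng)), "HbT": _fc(_random_corr(48, rng))}
        vec = fp.combine_contrasts(fcs, "pearson")
        assert vec.shape == (2 * 1128,)

    def test_block_diagonal_shape_and_spd(self):
        rng = np.random.default_rng(16)
        fcs = {"HbR": _fc(_random_corr(48, rng)), "HbT": _fc(_random_corr(48, rng))}
        block = fp.combine_contrasts(fcs, "geodesic")
        assert block.values.shape == (96, 96)
        assert np.linalg.eigvalsh(block.values + np.eye(96))[0] > 0

    def test_block_diagonal_distance_decomposes(self):
        rng = np.random.default_rng(17)
        a1, a2 = _random_spd(5, rng), _random_spd(5, rng)
        b1, b2 = _random_spd(5, rng), _random_spd(5, rng)
        d1 = fp.geodesic_distance(a1, b1, regularize=False)
        d2 = fp.geodesic_distance(a2, b2, regularize=False)
        d_block = fp.geodesic_distance(
            scipy.linalg.block_diag(a1, a2),
            scipy.linalg.block_diag(b1, b2),
            regularize=False,
        )
        assert d_block == pytest.approx(np.sqrt(d1**2 + d2**2), rel=1e-10)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(18)
        fcs = {"HbR": _fc(_random_corr(4, rng)), "HbT": _fc(_random_corr(5, rng))}
        with pytest.raises(InvalidArgumentError):
            fp.combine_contrasts(fcs, "pearson")


def _separable_fcset(rng, n_subjects=6, n=10, n_runs=3, jitter=0.0):
    fcs = []
    for i in range(n_subjects):
        base = _random_corr(n, rng)
        for r in range(n_runs):
            values = base.copy()
            if jitter:
                noise = jitter * rng.standard_normal((n, n))
                values = np.clip(values + 0.5 * (noise + noise.T), -0.99, 0.99)
                np.fill_diagonal(values, 1.0)
            fcs.append(_fc(values, subject=f"s{i}", run=f"r{r}"))
    return fp.build_fc_set(fcs)


class TestExperiment:
    def test_perfectly_separable_is_100(self):
        fcset = _separable_fcset(np.random.default_rng(19))
        for method in ("pearson", "geodesic", "linear"):
            res = fp.run_identification_experiment(fcset, method, 1, n_reps=20, seed=0)
            assert res.mean_accuracy == 100.0

    def test_accuracy_formula(self):
        fcset = _separable_fcset(np.random.default_rng(20), jitter=0.35)
        res = fp.run_identification_experiment(fcset, "pearson", 1, n_reps=30, seed=1)
        for rep in range(res.n_repetitions):
            correct = np.sum(res.predictions[rep] == np.arange(len(res.subjects)))
            assert res.accuracies[rep] == pytest.approx(100.0 * correct / len(res.subjects))

    def test_fixed_seed_reproducible(self):
        fcset = _separable_fcset(np.random.default_rng(21), jitter=0.3)
        a = fp.run_identification_experiment(fcset, "linear", 1, n_reps=15, seed=5)
        b = fp.run_identification_experiment(fcset, "linear", 1, n_reps=15, seed=5)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)
        np.testing.assert_array_equal(a.predictions, b.predictions)

    def test_insufficient_runs_names_subjects(self):
        fcset = _separable_fcset(np.random.default_rng(22), n_runs=2)
        with pytest.raises(InvalidArgumentError, match="s0"):
            fp.run_identification_experiment(fcset, "pearson", 2, n_reps=5)


class TestROISubsample:
    def test_full_size_single_draw_matches_plain_experiment(self):
        fcset = _separable_fcset(np.random.default_rng(23), jitter=0.12)
        summary, detail = fp.roi_subsample_experiment(
            fcset, sizes=[10], n_roi_draws=4, n_reps=10, seed=2
        )
        assert len(detail) == 1  # size == n_labels -> no resampling
        plain = fp.run_identification_experiment(fcset, "geodesic", 1, n_reps=10, seed=2)
        assert summary.loc[0, "mean_accuracy"] == pytest.approx(plain.mean_accuracy)

    def test_subset_commutes_with_vectorize(self):
        rng = np.random.default_rng(24)
        fc = _fc(_random_corr(8, rng))
        idx = np.array([1, 3, 4, 6])
        sub_then_vec = vectorize_upper(fc.select(idx))
        full = fc.values[np.ix_(idx, idx)]
        np.testing.assert_array_equal(sub_then_vec, full[np.triu_indices(4, 1)])

    def test_oversize_rejected(self):
        fcset = _separable_fcset(np.random.default_rng(25))
        with pytest.raises(InvalidArgumentError):
            fp.roi_subsample_experiment(fcset, sizes=[99], n_reps=2)


class TestCombineFCSets:
    def test_combined_vectors_used(self):
        rng = np.random.default_rng(26)
        set_a = _separable_fcset(rng, n_subjects=4, jitter=0.2)
        set_b = _separable_fcset(rng, n_subjects=4, jitter=0.2)
        combined = fp.combine_fc_sets({"HbR": set_a, "HbT": set_b}, "pearson")
        vec = combined.run_vectors("s0")[0]
        assert vec.shape == (2 * 45,)
        res = fp.run_identification_experiment(combined, "pearson", 1, n_reps=5, seed=0)
        assert 0 <= res.mean_accuracy <= 100

    def test_combined_geodesic_block(self):
        rng = np.random.default_rng(27)
        set_a = _separable_fcset(rng, n_subjects=3)
        set_b = _separable_fcset(rng, n_subjects=3)
        combined = fp.combine_fc_sets({"HbR": set_a, "HbT": set_b}, "geodesic")
        assert combined.matrices["s0"][0].n == 20


class TestQualitativeOrdering:
    """Method orderings on the harder synthetic cohort."""

    def test_geodesic_beats_pearson_single_run(self, graded_fcset):
        geo = fp.run_identification_experiment(graded_fcset, "geodesic", 1, n_reps=300, seed=4)
        pea = fp.run_identification_experiment(graded_fcset, "pearson", 1, n_reps=300, seed=4)
        assert geo.mean_accuracy >= pea.mean_accuracy

    def test_linear_gains_from_extra_runs(self, graded_fcset):
        one = fp.run_identification_experiment(graded_fcset, "linear", 1, n_reps=300, seed=4)
        many = fp.run_identification_experiment(graded_fcset, "linear", "all", n_reps=300, seed=4)
        assert many.mean_accuracy > one.mean_accuracy

    def test_linear_never_degrades_with_more_runs(self, graded_fcset):
        means = [
            fp.run_identification_experiment(
                graded_fcset, "linear", k, n_reps=300, seed=5
            ).mean_accuracy
            for k in (1, 2, 3, 4)
        ]
        for lo, hi in zip(means, means[1:]):
            assert hi >= lo - 1.0
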