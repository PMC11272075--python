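import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voxnmf.clinical import (
    ClinicalTable,
    OutcomeSpec,
    accuracy,
    assemble_design,
    compare_paired_errors,
    confusion_counts,
    fdr_adjust,
    fit_elastic_net,
    loads_to_frame,
    mcc,
    mean_abs_error,
    median_abs_error,
    predict_outcome,
    r_squared,
)
from voxnmf.errors import (
    ArgumentError,
    DegenerateOutcomeError,
    DimensionError,
    InsufficientDataError,
)


def _clinical(n=20, seed=0, missing_at=()):
    rng = np.random.default_rng(seed)
    ids = [f"s{i:03d}" for i in range(n)]
    df = pd.DataFrame(
        {
            "age": rng.uniform(55, 85, n),
            "flag": rng.integers(0, 2, n).astype(float),
            "score": rng.normal(20, 5, n),
        },
        index=pd.Index(ids, name="subject_id"),
    )
    for name, idx in missing_at:
        df.iloc[idx, df.columns.get_loc(name)] = np.nan
    return ClinicalTable(df, ["flag"], ["score"])


class TestMcc:
    def test_mri_worked_example(self):
        assert mcc(tp=12, fn=4, fp=3, tn=1) == pytest.approx(0.0, abs=1e-12)

    def test_fdg_worked_example(self):
        assert round(mcc(tp=8, fn=8, fp=0, tn=4), 3) == 0.408

    def test_perfect_classifier(self):
        assert mcc(tp=7, fp=0, tn=5, fn=0) == pytest.approx(1.0)

    def test_zero_marginal_convention(self):
        assert mcc(tp=5, fp=0, tn=0, fn=0) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ArgumentError):
            mcc(-1, 0, 1, 0)

    def test_swap_symmetry_and_label_flip_antisymmetry(self):
        for tp, fp, tn, fn in [(3, 1, 4, 2), (5, 0, 2, 1), (2, 2, 2, 2)]:
            assert mcc(tp, fp, tn, fn) == pytest.approx(mcc(tn, fn, tp, fp))
            assert mcc(tp, fp, tn, fn) == pytest.approx(-mcc(fn, tn, fp, tp))

    def test_equals_pearson_over_all_small_tables(self):
        """Brute force over every 2x2 table with total <= 6."""
        checked = 0
        for tp, fp, tn, fn in itertools.product(range(7), repeat=4):
            total = tp + fp + tn + fn
            if total == 0 or total > 6:
                continue
            truth = np.array([1] * tp + [0] * fp + [0] * tn + [1] * fn)
            pred = np.array([1] * tp + [1] * fp + [0] * tn + [0] * fn)
            if truth.std() == 0 or pred.std() == 0:
                continue  # Pearson undefined; mcc returns 0 by convention
            expected = np.corrcoef(truth, pred)[0, 1]
            assert mcc(tp, fp, tn, fn) == pytest.approx(expected, abs=1e-12)
            checked += 1
        assert checked > 100


class TestAccuracy:
    def test_worked_examples(self):
        assert accuracy(tp=12, fn=4, fp=3, tn=1) == pytest.approx(0.65)
        assert accuracy(tp=8, fn=8, fp=0, tn=4) == pytest.approx(0.6)

    def test_all_wrong(self):
        assert accuracy(tp=0, fp=3, tn=0, fn=2) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ArgumentError):
            accuracy(0, 0, 0, 0)


class TestContinuousMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == 1.0
        assert mean_abs_error(y, y) == 0.0
        assert median_abs_error(y, y) == 0.0

    def test_constant_mean_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        y = np.array([1.0, 2.0, 3.0])
        y_hat = np.array([1.0, 1.0, 5.0])
        assert median_abs_error(y, y_hat) == 1.0
        assert mean_abs_error(y, y_hat) == 1.0
        assert r_squared(y, y_hat) == pytest.approx(-1.5)

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            r_squared([1.0, 2.0], [1.0])


class TestAssembleDesign:
    def test_missing_outcome_drops_row(self):
        clin = _clinical(n=14, missing_at=[("score", [3])])
        loads = loads_to_frame(np.random.default_rng(1).random((14, 2)),
                               clin.subject_ids, "mri")
        design, y, subjects = assemble_design(
            {"MRI": loads}, clin, OutcomeSpec("score", "continuous")
        )
        assert len(design) == 13 and len(y) == 13
        assert "s003" not in subjects

    def test_combined_column_count(self):
        clin = _clinical(n=30)
        rng = np.random.default_rng(2)
        mri = loads_to_frame(rng.random((30, 9)), clin.subject_ids, "mri")
        fdg = loads_to_frame(rng.random((30, 14)), clin.subject_ids, "fdg")
        design, _, _ = assemble_design(
            {"MRI": mri, "FDG": fdg}, clin, OutcomeSpec("score", "continuous")
        )
        assert design.shape[1] == 1 + 9 + 14
        assert design.columns[0] == "age"

    def test_id_rematching_tolerates_row_permutation(self):
        clin = _clinical(n=12)
        rng = np.random.default_rng(3)
        loads = loads_to_frame(rng.random((12, 3)), clin.subject_ids, "mri")
        shuffled = loads.sample(frac=1.0, random_state=0)
        a, ya, _ = assemble_design({"MRI": loads}, clin, OutcomeSpec("score", "continuous"))
        b, yb, _ = assemble_design({"MRI": shuffled}, clin, OutcomeSpec("score", "continuous"))
        pd.testing.assert_frame_equal(a, b)

    def test_bare_array_block_rejected(self):
        clin = _clinical(n=12)
        with pytest.raises(ArgumentError):
            assemble_design({"MRI": np.random.random((12, 3))}, clin,
                            OutcomeSpec("score", "continuous"))

    def test_too_few_complete_cases(self):
        clin = _clinical(n=12, missing_at=[("score", list(range(6)))])
        loads = loads_to_frame(np.random.default_rng(4).random((12, 2)),
                               clin.subject_ids, "mri")
        with pytest.raises(InsufficientDataError):
            assemble_design({"MRI": loads}, clin, OutcomeSpec("score", "continuous"))

    def test_zero_variance_response(self):
        clin = _clinical(n=12)
        clin.data["score"] = 5.0
        loads = loads_to_frame(np.random.default_rng(5).random((12, 2)),
                               clin.subject_ids, "mri")
        with pytest.raises(DegenerateOutcomeError):
            assemble_design({"MRI": loads}, clin, OutcomeSpec("score", "continuous"))


class TestFitElasticNet:
    def _design(self, n=60, p=4, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{j}" for j in range(p)])
        return X, rng

    def test_full_penalty_gives_intercept_only(self):
        X, rng = self._design()
        y = rng.normal(10.0, 2.0, size=len(X))
        model = fit_elastic_net(X, y, "continuous", alpha=0.2, fixed_lambda=1e6, seed=0)
        assert np.allclose(model.slopes, 0.0, atol=1e-10)
        assert model.intercept == pytest.approx(y.mean())

    def test_ridge_duplicate_symmetry(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=80)
        X = pd.DataFrame({"a": z, "b": z.copy(), "c": rng.normal(size=80)})
        y = 3.0 * z + rng.normal(0, 0.1, 80)
        model = fit_elastic_net(X, y, "continuous", alpha=0.0, fixed_lambda=0.5, seed=0)
        assert model.slopes["a"] == pytest.approx(model.slopes["b"], abs=1e-6)
        # closed-form ridge on standardized predictors as an oracle
        Z = (X - X.mean()) / X.std(ddof=0)
        n = len(y)
        lam_ridge = 0.5 * n  # sklearn scales the loss by 1/(2n)
        beta = np.linalg.solve(Z.T @ Z + lam_ridge * np.eye(3), Z.T @ (y - y.mean()))
        assert np.allclose(model.slopes.to_numpy(), beta, atol=1e-5)

    def test_strong_signal_heldout_r2(self):
        rng = np.random.default_rng(2)
        loads = rng.dirichlet(np.ones(4), size=400) * 0.9
        age = rng.uniform(55, 85, 400)
        y = 2.0 * loads[:, 0] + rng.normal(0, 0.05, 400)
        X = pd.DataFrame(np.column_stack([age, loads]),
                         columns=["age"] + [f"l{j}" for j in range(4)])
        model = fit_elastic_net(X.iloc[:200], y[:200], "continuous", alpha=0.2, seed=0)
        y_hat = predict_outcome(model, X.iloc[200:])
        assert r_squared(y[200:], y_hat) >= 0.8

    def test_lambda_path_monotone_l1_norm(self):
        X, rng = self._design(n=50, p=5, seed=3)
        y = X.to_numpy() @ np.array([2.0, -1.0, 0.5, 0.0, 0.0]) + rng.normal(0, 0.2, 50)
        norms = []
        for lam in np.logspace(-3, 1, 12):
            model = fit_elastic_net(X, y, "continuous", alpha=0.5, fixed_lambda=lam, seed=0)
            norms.append(np.abs(model.slopes).sum())
        assert all(b <= a + 1e-8 for a, b in zip(norms, norms[1:]))

    def test_binary_class_imbalance_error(self):
        X, rng = self._design(n=30, seed=4)
        y = np.zeros(30)
        y[:2] = 1.0
        with pytest.raises(DegenerateOutcomeError, match="outcome"):
            fit_elastic_net(X, y, "binary", alpha=0.2, seed=0)

    def test_binary_parameter_recovery_bootstrap_mcc(self):
        rng = np.random.default_rng(5)
        loads = rng.dirichlet(np.ones(4), size=400) * 0.9
        age = rng.uniform(55, 85, 400)
        eta = -1.5 + 4.0 * loads[:, 0] + 3.0 * loads[:, 1]
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        X = pd.DataFrame(np.column_stack([age, loads]),
                         columns=["age"] + [f"l{j}" for j in range(4)])
        model = fit_elastic_net(X.iloc[:200], y[:200], "binary", alpha=0.2,
                                seed=0, n_lambda=25)
        _, labels = predict_outcome(model, X.iloc[200:])
        y_test = y[200:]
        boots = []
        for b in range(200):
            idx = rng.integers(0, 200, 200)
            boots.append(mcc(*confusion_counts(y_test[idx], labels[idx])))
        lo = np.percentile(boots, 2.5)
        assert lo > 0

    def test_serialization_roundtrip(self, tmp_path):
        X, rng = self._design(n=40, seed=6)
        y = rng.normal(size=40)
        model = fit_elastic_net(X, y, "continuous", alpha=0.2, fixed_lambda=0.1, seed=0)
        model.to_json(tmp_path / "m.json")
        from voxnmf.clinical import PredictionModel

        back = PredictionModel.from_json(tmp_path / "m.json")
        assert np.allclose(predict_outcome(back, X), predict_outcome(model, X))


class TestPredictOutcome:
    def test_constant_model(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        from voxnmf.clinical import PredictionModel

        model = PredictionModel(
            outcome=OutcomeSpec("o", "binary"), modalities=("MRI",), alpha=0.2,
            lambda_en=1.0, intercept=0.4,
            slopes=pd.Series([0.0], index=["x"]),
            center=pd.Series([0.0], index=["x"]),
            scale=pd.Series([1.0], index=["x"]),
        )
        prob, label = predict_outcome(model, X)
        assert np.allclose(prob, 1 / (1 + np.exp(-0.4)))
        assert np.all(label == 1)  # p ~ 0.6 >= threshold 0.5

    def test_training_predictions_reproduced_bitwise(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        y = rng.normal(size=30)
        model = fit_elastic_net(X, y, "continuous", alpha=0.2, fixed_lambda=0.05, seed=0)
        assert np.array_equal(predict_outcome(model, X), model.training_predictions)

    def test_hand_computed_row(self):
        from voxnmf.clinical import PredictionModel

        model = PredictionModel(
            outcome=OutcomeSpec("o", "continuous"), modalities=("MRI",), alpha=0.2,
            lambda_en=1.0, intercept=2.0,
            slopes=pd.Series([1.5, -0.5], index=["u", "v"]),
            center=pd.Series([1.0, 2.0], index=["u", "v"]),
            scale=pd.Series([2.0, 4.0], index=["u", "v"]),
        )
        row = pd.DataFrame({"u": [3.0], "v": [6.0]})
        expected = 2.0 + 1.5 * (3.0 - 1.0) / 2.0 + (-0.5) * (6.0 - 2.0) / 4.0
        assert predict_outcome(model, row)[0] == pytest.approx(expected, abs=1e-12)

    def test_column_mismatch(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        model = fit_elastic_net(X, rng.normal(size=20), "continuous", alpha=0.2,
                                fixed_lambda=0.1, seed=0)
        with pytest.raises(DimensionError):
            predict_outcome(model, X[["b", "a"]])


class TestComparePairedErrors:
    def test_identical_errors(self):
        e = np.arange(8.0)
        assert compare_paired_errors(e, e) == 1.0

    def test_all_positive_differences_exact(self):
        a = np.array([1.0, 1.1, 1.25, 1.4, 1.3, 1.2, 1.5, 1.05])
        b = np.zeros(8)
        # all 8 differences positive with distinct magnitudes: only the
        # all-plus and all-minus assignments reach |mean|, p = 2/256
        assert compare_paired_errors(a, b) == pytest.approx(2 / 256)

    def test_monte_carlo_close_to_exact(self):
        rng = np.random.default_rng(9)
        d = rng.normal(0.3, 1.0, 12)
        exact = compare_paired_errors(d, np.zeros(12))
        mc = _mc_signflip_p(d, n_perm=10000, seed=1)
        assert abs(mc - exact) <= 0.02

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(10)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            d = rng.normal(0.0, 1.0, 12)
            p = compare_paired_errors(d, np.zeros(12))
            rejections += p <= 0.05
        rate = rejections / n_sim
        assert 0.03 <= rate <= 0.07

    def test_too_short(self):
        with pytest.raises(ArgumentError):
            compare_paired_errors([1.0, 2.0], [0.0, 0.0])


def _mc_signflip_p(d, n_perm, seed):
    rng = np.random.default_rng(seed)
    obs = abs(d.mean())
    signs = rng.choice([-1.0, 1.0], size=(n_perm, len(d)))
    stats = np.abs(signs @ d) / len(d)
    return (1 + np.sum(stats >= obs - 1e-12)) / (n_perm + 1)


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_textbook_example(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_bh_formula_on_enumerated_cases(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 10))
            m = len(p)
            order = np.argsort(p)
            # textbook step-up: q_(i) = min_{j >= i} p_(j) * m / j
            q_expected = np.empty(m)
            for i_rank, idx in enumerate(order):
                tail = [p[order[j]] * m / (j + 1) for j in range(i_rank, m)]
                q_expected[idx] = min(1.0, min(tail))
            assert np.allclose(fdr_adjust(p), q_expected, atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_permutation_equivariance_and_bounds(self, p):
        p = np.asarray(p)
        q = fdr_adjust(p)
        assert np.all(q <= 1.0 + 1e-12) and np.all(q >= p - 1e-12)
        perm = np.random.default_rng(0).permutation(len(p))
        assert np.allclose(fdr_adjust(p[perm]), q[perm], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ArgumentError):
            fdr_adjust([0.5, 1.5])
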