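import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from pcclock.clock import (
    PCAgeClock,
    SexConsensusPCClock,
    apply_linear_cpg_clock,
    consensus_core,
    fit_core_clock,
    load_model,
    predict_age,
    save_model,
    train_degenerate_models,
)
from pcclock.enet import ClockModel, fit_elastic_net
from pcclock.io import BetaMatrix
from pcclock.pc import PCModel, fit_svd, project


class TestConsensusCore:
    def test_three_way_intersection(self):
        assert consensus_core([{1, 2, 3}, {2, 3, 4}, {2, 3, 5}]) == [2, 3]

    def test_idempotent_on_identical_sets(self):
        assert consensus_core([{4, 9, 1}, {1, 4, 9}]) == [1, 4, 9]

    def test_empty_intersection_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            assert consensus_core([{1}, {2}]) == []

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            consensus_core([{1}, set()])


class TestFitCoreClock:
    def test_all_pcs_equals_unrestricted_fit(self, small_cohort):
        matrix, sheet, _ = small_cohort
        _, scores = fit_svd(matrix)
        ages = sheet["age"].to_numpy()
        all_pcs = list(range(1, scores.scores.shape[1]))
        core = fit_core_clock(scores, ages, all_pcs, cv_seed=0)
        free = fit_elastic_net(scores.scores[:, :-1], ages, cv_seed=0)
        assert core.pc_indices == free.pc_indices
        np.testing.assert_allclose(core.coefficients, free.coefficients, atol=1e-12)

    def test_zeroed_columns_equivalent_to_restricted_design(self, small_cohort):
        matrix, sheet, _ = small_cohort
        _, scores = fit_svd(matrix)
        ages = sheet["age"].to_numpy()
        core_pcs = [2, 5, 9, 17]
        zeroed = fit_core_clock(scores, ages, core_pcs, cv_seed=3)
        # restricted formulation: keep only the core columns in the design
        S = scores.scores[:, :-1]
        restricted = fit_elastic_net(S[:, [k - 1 for k in core_pcs]], ages, cv_seed=3)
        remapped = [core_pcs[k - 1] for k in restricted.pc_indices]
        assert zeroed.pc_indices == remapped
        np.testing.assert_allclose(
            zeroed.coefficients, restricted.coefficients, atol=1e-10
        )
        assert set(zeroed.pc_indices) <= set(core_pcs)

    def test_ablating_signal_pcs_destroys_age_prediction(self, small_cohort):
        matrix, sheet, truth = small_cohort
        model, scores = fit_svd(matrix)
        ages = sheet["age"].to_numpy()
        # PCs most aligned with the age-linked factors
        z = truth.factor_scores[:, 1:4]
        corr = np.abs(np.corrcoef(scores.scores.T, z.T)[: scores.scores.shape[1], -3:])
        signal_pcs = {int(k) + 1 for k in np.argsort(corr.max(axis=1))[-6:]}
        noncore = [k for k in range(1, scores.scores.shape[1]) if k not in signal_pcs]
        ablated = fit_core_clock(scores, ages, noncore, cv_seed=1)
        pred = ablated.predict_from_scores(scores.scores)
        r = 0.0 if np.std(pred) == 0 else np.corrcoef(pred, ages)[0, 1]
        assert r < 0.5

    def test_invalid_core_rejected(self, small_cohort):
        matrix, sheet, _ = small_cohort
        _, scores = fit_svd(matrix)
        with pytest.raises(ValueError, match="core_pcs"):
            fit_core_clock(scores, sheet["age"].to_numpy(), [0, 5], cv_seed=0)


class TestTrainDegenerateModels:
    def test_shared_age_pc_reaches_core(self, small_cohort):
        matrix, sheet, truth = small_cohort
        pc_model, c_both, c_male, c_female, core = train_degenerate_models(
            matrix, sheet, n_folds=5, cv_seed=0
        )
        _, scores = fit_svd(matrix)
        # the PC best aligned with the strongest sex-independent age factor
        z1 = truth.factor_scores[:, 1]
        corr = np.abs([np.corrcoef(scores.scores[:, k], z1)[0, 1]
                       for k in range(scores.scores.shape[1] - 1)])
        age_pc = int(np.argmax(corr)) + 1
        for clk in (c_both, c_male, c_female):
            assert age_pc in clk.pc_indices
        assert age_pc in core

    def test_single_sex_rejected(self, small_cohort):
        matrix, sheet, _ = small_cohort
        males = sheet[sheet["sex"] == "male"]
        sub = matrix.select_samples(list(males["sample_id"]))
        with pytest.raises(ValueError, match="stratum"):
            train_degenerate_models(sub, males, n_folds=5)

    def test_deterministic_under_cv_seed(self, small_cohort):
        matrix, sheet, _ = small_cohort
        out1 = train_degenerate_models(matrix, sheet, n_folds=5, cv_seed=11)
        out2 = train_degenerate_models(matrix, sheet, n_folds=5, cv_seed=11)
        assert out1[1].pc_indices == out2[1].pc_indices
        assert out1[4] == out2[4]


class TestPredictAge:
    def test_hand_computed_toy(self):
        # 3 samples x 5 probes with hand-set centers, rotation and clock
        V = np.zeros((5, 2))
        V[0, 0] = 1.0
        V[1, 1] = 1.0
        model = PCModel(probe_ids=[f"p{j}" for j in range(5)],
                        center=np.full(5, 0.5), rotation=V,
                        singular_values=np.array([2.0, 1.0]), n_train=3)
        clock = ClockModel(pc_indices=[1, 2], coefficients=np.array([10.0, -5.0]),
                           intercept=50.0, alpha=0.5, lambda_=1.0, cv_seed=0, n_pcs=2)
        cohort = BetaMatrix(
            ["a", "b", "c"], model.probe_ids,
            np.array([[0.6, 0.5, 0.5, 0.5, 0.5],
                      [0.5, 0.7, 0.5, 0.5, 0.5],
                      [0.4, 0.3, 0.5, 0.5, 0.5]]),
        )
        # scores: (beta - 0.5) on probes p0 (PC1) and p1 (PC2)
        expected = np.array([50 + 10 * 0.1, 50 - 5 * 0.2, 50 + 10 * -0.1 - 5 * -0.2])
        np.testing.assert_allclose(predict_age(clock, model, cohort), expected,
                                   atol=1e-12)

    def test_zero_coefficients_predict_intercept(self, small_cohort):
        matrix, _, _ = small_cohort
        model, _ = fit_svd(matrix)
        clock = ClockModel(pc_indices=[], coefficients=np.empty(0), intercept=63.0,
                           alpha=0.5, lambda_=1.0, cv_seed=0, n_pcs=3)
        np.testing.assert_array_equal(predict_age(clock, model, matrix),
                                      np.full(matrix.n_samples, 63.0))

    def test_in_sample_predictions_consistent_with_fit(self, small_cohort):
        matrix, sheet, _ = small_cohort
        ages = sheet["age"].to_numpy()
        est = PCAgeClock(n_folds=5, cv_seed=2).fit(matrix, ages)
        pred_via_projection = est.predict(matrix)
        scores = project(est.pc_model_, matrix)
        pred_direct = est.clock_model_.predict_from_scores(scores)
        np.testing.assert_allclose(pred_via_projection, pred_direct, atol=1e-8)
        assert np.corrcoef(pred_via_projection, ages)[0, 1] > 0.9


class TestApplyLinearCpgClock:
    def test_single_probe_identity(self, small_beta):
        out = apply_linear_cpg_clock(small_beta, {"cg003": 1.0}, intercept=0.0)
        np.testing.assert_allclose(out, small_beta.values[:, 3], atol=1e-12)

    def test_zero_weights_give_intercept(self, small_beta):
        out = apply_linear_cpg_clock(small_beta, {"cg000": 0.0, "cg001": 0.0}, 12.5)
        np.testing.assert_array_equal(out, np.full(small_beta.n_samples, 12.5))

    def test_matches_brute_force_dot_product(self, small_beta, rng):
        probes = list(rng.choice(small_beta.probe_ids, size=20, replace=False))
        weights = dict(zip(probes, rng.normal(size=20)))
        out = apply_linear_cpg_clock(small_beta, weights, intercept=3.0)
        frame = small_beta.to_frame()
        expected = 3.0 + sum(w * frame[p].to_numpy() for p, w in weights.items())
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_absent_probes_warn_and_contribute_zero(self, small_beta):
        with pytest.warns(UserWarning, match="absent"):
            out = apply_linear_cpg_clock(
                small_beta, {"cg000": 2.0, "missing_probe": 100.0}, intercept=1.0
            )
        np.testing.assert_allclose(out, 1.0 + 2.0 * small_beta.values[:, 0])

    def test_empty_overlap_rejected(self, small_beta):
        with pytest.raises(ValueError, match="overlap"):
            apply_linear_cpg_clock(small_beta, {"nope": 1.0})

    def test_named_output_transform(self, small_beta):
        raw = apply_linear_cpg_clock(small_beta, {"cg000": 1.0})
        transformed = apply_linear_cpg_clock(small_beta, {"cg000": 1.0},
                                             output_transform="exp")
        np.testing.assert_allclose(transformed, np.exp(raw), atol=1e-12)


class TestSaveLoad:
    @pytest.fixture
    def fitted(self, small_cohort):
        matrix, sheet, _ = small_cohort
        est = PCAgeClock(n_folds=5, cv_seed=0).fit(matrix, sheet["age"].to_numpy())
        return est.pc_model_, est.clock_model_, matrix

    def test_round_trip_reproduces_predictions(self, fitted, tmp_path):
        model, clock, matrix = fitted
        path = tmp_path / "clock.npz"
        save_model(model, clock, path)
        model2, clock2 = load_model(path)
        np.testing.assert_allclose(
            predict_age(clock2, model2, matrix),
            predict_age(clock, model, matrix), atol=1e-10,
        )

    def test_clock_only_rotation_columns_suffice(self, fitted, tmp_path):
        model, clock, matrix = fitted
        path = tmp_path / "lean.npz"
        save_model(model, clock, path, store_full_rotation=False)
        model2, clock2 = load_model(path)
        assert model2.n_components == len(clock.pc_indices)
        np.testing.assert_allclose(
            predict_age(clock2, model2, matrix),
            predict_age(clock, model, matrix), atol=1e-10,
        )

    def test_corrupted_container_rejected(self, fitted, tmp_path):
        model, clock, _ = fitted
        path = tmp_path / "clock.npz"
        save_model(model, clock, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(ValueError, match="corrupt"):
            load_model(path)

    def test_wrong_format_rejected(self, tmp_path):
        path = tmp_path / "other.npz"
        np.savez(path, foo=np.arange(3))
        with pytest.raises(ValueError, match="version|corrupt"):
            load_model(path)


class TestSexConsensusEstimator:
    def test_fit_predict_and_attributes(self, small_cohort):
        matrix, sheet, _ = small_cohort
        est = SexConsensusPCClock(n_folds=5, cv_seed=0)
        est.fit(matrix, sheet["age"].to_numpy(), sex=sheet["sex"])
        assert est.core_pcs_ == sorted(est.core_pcs_)
        assert set(est.core_clock_.pc_indices) <= set(est.core_pcs_)
        pred = est.predict(matrix)
        assert np.corrcoef(pred, sheet["age"])[0, 1] > 0.9

    def test_sklearn_param_interface(self):
        est = SexConsensusPCClock(alpha=0.7, cv_seed=5)
        cloned = clone(est)
        assert cloned.get_params()["alpha"] == 0.7
        assert cloned.get_params()["cv_seed"] == 5

    def test_requires_sex_labels(self, small_cohort):
        matrix, sheet, _ = small_cohort
        with pytest.raises(ValueError, match="sex"):
            SexConsensusPCClock().fit(matrix, sheet["age"].to_numpy())
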