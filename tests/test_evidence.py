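import logging

import numpy as np
import pytest

from socketgen.evidence import (
    DesignEvidenceModel,
    PriorSpec,
    build_design_matrix,
    fit_evidence_model,
    predict_from_row,
    predict_rectifications,
)
from socketgen.rectify import FEATURES
from socketgen.synthetic_limb import (
    REASONS,
    ExpertRule,
    PatientRecord,
    expert_design,
    generate_cohort,
    rule_predictor_vector,
)


def make_patients(n, seed=0):
    cohort = generate_cohort(n, seed=seed, generate_scans=False)
    return [c[0] for c in cohort], [c[2] for c in cohort]


def rule_design_matrix(patients, params_list):
    rows = [rule_predictor_vector(p, prm) for p, prm in zip(patients, params_list)]
    return np.hstack([np.ones((len(rows), 1)), np.stack(rows)])


class TestDesignMatrix:
    def test_column_accounting(self):
        patients, _ = make_patients(10)
        scores = [np.zeros(4)] * 10
        X, spec = build_design_matrix(patients, scores, "fit")
        # 1 intercept + 2 continuous + 1 gender + 6 reason dummies + 4 modes
        assert X.shape == (10, 1 + 2 + 1 + (len(REASONS) - 1) + 4)
        assert len(spec.col_names) == X.shape[1]

    def test_training_mean_patient_standardizes_to_zero(self):
        patients, _ = make_patients(50)
        scores = [np.random.default_rng(i).normal(size=3) for i in range(50)]
        X, spec = build_design_matrix(patients, scores, "fit")
        mean_age = float(np.mean([p.age for p in patients]))
        mean_tsa = float(np.mean([p.time_since_amputation for p in patients]))
        probe = PatientRecord(mean_age, "man", mean_tsa, REASONS[0])
        Xp, _ = build_design_matrix([probe], [spec.means[2:]], spec)
        assert Xp[0, 1] == pytest.approx(0.0, abs=1e-10)
        assert Xp[0, 2] == pytest.approx(0.0, abs=1e-10)

    def test_refitting_with_stored_spec_reproduces_matrix(self):
        patients, _ = make_patients(20)
        scores = [np.full(2, float(i)) for i in range(20)]
        X1, spec = build_design_matrix(patients, scores, "fit")
        X2, _ = build_design_matrix(patients, scores, spec)
        assert np.array_equal(X1, X2)

    def test_unseen_reason_maps_to_reference_with_warning(self, caplog):
        patients, _ = make_patients(5)
        scores = [np.zeros(2)] * 5
        _, spec = build_design_matrix(patients, scores, "fit")
        probe = PatientRecord(60.0, "man", 3.0, REASONS[1])
        probe.reason = "space_wolves"  # bypass constructor validation
        with caplog.at_level(logging.WARNING):
            Xp, _ = build_design_matrix([probe], [np.zeros(2)], spec)
        assert "unseen reason" in caplog.text
        # all one-hot reason columns zero = reference level
        assert np.all(Xp[0, 4 : 4 + len(REASONS) - 1] == 0.0)


class TestFit:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        n, p = 2000, 5
        X = np.hstack([np.ones((n, 1)), rng.standard_normal((n, p - 1))])
        beta = rng.uniform(-3, 3, size=(p, len(FEATURES)))
        Y = X @ beta
        model = fit_evidence_model(X, Y, prior=PriorSpec(precision=1e-6))
        for j, f in enumerate(FEATURES):
            assert np.allclose(model.posteriors[f].mean, beta[:, j], atol=1e-4)
            assert model.posteriors[f].r2 > 0.999999

    def test_infinite_prior_precision_shrinks_slopes_to_zero(self):
        rng = np.random.default_rng(1)
        n = 200
        X = np.hstack([np.ones((n, 1)), rng.standard_normal((n, 3))])
        Y = rng.standard_normal((n, len(FEATURES)))
        model = fit_evidence_model(X, Y, prior=PriorSpec(precision=1e12))
        for f in FEATURES:
            assert np.allclose(model.posteriors[f].mean[1:], 0.0, atol=1e-8)

    def test_row_count_validation(self):
        with pytest.raises(ValueError):
            fit_evidence_model(np.ones((3, 2)), np.ones((4, len(FEATURES))))

    def test_posterior_covariance_is_positive_semidefinite(self):
        rng = np.random.default_rng(2)
        X = np.hstack([np.ones((30, 1)), rng.standard_normal((30, 4))])
        Y = rng.standard_normal((30, len(FEATURES)))
        model = fit_evidence_model(X, Y)
        for f in FEATURES:
            eig = np.linalg.eigvalsh(model.posteriors[f].covariance)
            assert np.all(eig > -1e-12)

    def test_bias_shrinks_with_sample_size(self):
        rule = ExpertRule.default()
        true_b = rule.coeff_matrix()[0]  # patella_tendon_bar row
        biases = []
        for n in (50, 200, 800):
            errs = []
            for rep in range(30):
                cohort = generate_cohort(n, seed=1000 * n + rep,
                                         generate_scans=False, coupling={})
                patients = [c[0] for c in cohort]
                params = [c[2] for c in cohort]
                X = rule_design_matrix(patients, params)
                Y = np.stack([
                    expert_design(p, prm, rule, seed=rep * n + i, clip=False)
                    for i, (p, prm) in enumerate(zip(patients, params))
                ])
                model = fit_evidence_model(X, Y, prior=PriorSpec(precision=0.01))
                errs.append(model.posteriors["patella_tendon_bar"].mean[1:] - true_b)
            biases.append(np.abs(np.mean(errs, axis=0)).max())
        assert biases[2] < biases[0]
        assert biases[2] < 0.05


class TestPredict:
    def test_prediction_at_training_mean_is_intercept(self):
        rng = np.random.default_rng(3)
        n = 300
        X = np.hstack([np.ones((n, 1)), rng.standard_normal((n, 4))])
        intercepts = np.array([-3.0, -2.0, 2.0, 4.0, 2.0, 1.5, -2.0, -0.05])
        Y = intercepts + 0.01 * rng.standard_normal((n, len(FEATURES)))
        model = fit_evidence_model(X, Y)
        x0 = np.zeros(5)
        x0[0] = 1.0
        rects, _ = predict_from_row(model, x0)
        assert np.allclose(rects.as_array(), intercepts, atol=0.05)

    def test_predictive_interval_widens_away_from_training_mean(self):
        rng = np.random.default_rng(4)
        n = 100
        X = np.hstack([np.ones((n, 1)), rng.standard_normal((n, 3))])
        Y = rng.standard_normal((n, len(FEATURES)))
        model = fit_evidence_model(X, Y)
        x_center = np.array([1.0, 0.0, 0.0, 0.0])
        x_far = np.array([1.0, 3.0, 0.0, 0.0])
        _, ci_center = predict_from_row(model, x_center)
        _, ci_far = predict_from_row(model, x_far)
        for f in FEATURES:
            w0 = ci_center[f][1] - ci_center[f][0]
            w3 = ci_far[f][1] - ci_far[f][0]
            assert w3 > w0

    def test_point_prediction_is_sign_clipped_but_interval_is_not(self):
        rng = np.random.default_rng(5)
        n = 200
        X = np.hstack([np.ones((n, 1)), rng.standard_normal((n, 2))])
        # force a positive mean for a carve feature
        Y = np.full((n, len(FEATURES)), 2.0) + 0.1 * rng.standard_normal((n, len(FEATURES)))
        model = fit_evidence_model(X, Y)
        rects, intervals = predict_from_row(model, np.array([1.0, 0.0, 0.0]))
        assert rects.patella_tendon_bar == 0.0
        assert intervals["patella_tendon_bar"][0] > 0.0  # honest, unclipped

    def test_end_to_end_patient_prediction(self):
        cohort = generate_cohort(80, seed=7, generate_scans=False)
        patients = [c[0] for c in cohort]
        rng = np.random.default_rng(8)
        scores = [rng.normal(size=3) for _ in patients]
        X, spec = build_design_matrix(patients, scores, "fit")
        Y = rng.standard_normal((80, len(FEATURES)))
        model = fit_evidence_model(X, Y, spec=spec)
        rects, intervals = predict_rectifications(model, patients[0], scores[0])
        assert set(intervals) == set(FEATURES)
        assert np.all(np.isfinite(rects.as_array()))

    def test_model_file_roundtrip(self, tmp_path):
        rng = np.random.default_rng(9)
        X = np.hstack([np.ones((40, 1)), rng.standard_normal((40, 3))])
        Y = rng.standard_normal((40, len(FEATURES)))
        model = fit_evidence_model(X, Y)
        path = tmp_path / "evidence.npz"
        model.save(path)
        back = DesignEvidenceModel.load(path)
        for f in FEATURES:
            assert np.allclose(back.posteriors[f].mean, model.posteriors[f].mean)
            assert back.posteriors[f].a_n == model.posteriors[f].a_n
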