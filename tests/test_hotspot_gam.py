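"""Hotspot GAM: frame assembly, penalized fitting, prediction, evidence."""

import math

import numpy as np
import pytest

from cbkit.core_data import CASE, CONTROL
from cbkit.hotspot_gam import (
    SeparationError,
    SmallSampleError,
    assemble_gam_frame,
    empirical_or_haldane,
    fit_hotspot,
    load_model,
    predict_log_or,
    predict_position_or,
    probability_odds_map,
    save_model,
    stratify_evidence,
)
from conftest import make_carrier_frame, make_dataset


@pytest.fixture()
def clustered_frame():
    rng = np.random.default_rng(3)
    frame, _, _ = make_carrier_frame(
        rng, n_car=200, or_fn=lambda p: 20.0 if 100 <= p <= 130 else 1.0
    )
    return frame


class TestFrameAssembly:
    def test_row_bookkeeping_without_coverage(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.integers(1, 101, 10), rng.integers(1, 101, 20),
                          L=100, n_cases=100, n_controls=1000)
        frame = assemble_gam_frame(ds)
        assert len(frame.is_case) == 32 and frame.n_carrier_rows == 30
        # aggregate rows carry the non-carrier counts when coverage == 1
        assert frame.weight[-2] == pytest.approx(90.0)
        assert frame.weight[-1] == pytest.approx(980.0)
        assert frame.position[-2:].tolist() == [0.0, 0.0]

    def test_half_coverage_doubles_every_weight(self):
        rng = np.random.default_rng(1)
        case_pos = rng.integers(1, 101, 12)
        ctrl_pos = rng.integers(1, 101, 15)
        full = assemble_gam_frame(
            make_dataset(case_pos, ctrl_pos, coverage_case=np.ones(100),
                         coverage_control=np.ones(100))
        )
        half = assemble_gam_frame(
            make_dataset(case_pos, ctrl_pos, coverage_case=np.full(100, 0.5),
                         coverage_control=np.full(100, 0.5))
        )
        np.testing.assert_allclose(half.weight, 2.0 * full.weight)

    def test_total_weight_matches_cohort_sizes_at_full_coverage(self):
        rng = np.random.default_rng(2)
        frame = assemble_gam_frame(
            make_dataset(rng.integers(1, 101, 11), rng.integers(1, 101, 13),
                         n_cases=250, n_controls=800)
        )
        case_rows = frame.is_case == 1.0
        assert frame.weight[case_rows].sum() == pytest.approx(250.0)
        assert frame.weight[~case_rows].sum() == pytest.approx(800.0)

    def test_small_gene_refused_and_overridable(self):
        ds = make_dataset([1, 2], [3, 4], L=100)
        with pytest.raises(SmallSampleError):
            assemble_gam_frame(ds)
        frame = assemble_gam_frame(ds, allow_small=True)
        assert frame.n_carrier_rows == 4


class TestFitting:
    def test_separation_error(self):
        ds = make_dataset(range(1, 25), [], L=100)
        frame = assemble_gam_frame(ds)
        with pytest.raises(SeparationError):
            fit_hotspot(frame)

    def test_infinite_smoothing_matches_linear_logistic(self, clustered_frame):
        """lambda -> inf leaves only the penalty null space: a linear trend.

        Oracle: statsmodels GLM on [1, carrier, carrier * centred position].
        """
        import statsmodels.api as sm

        frame = clustered_frame
        model = fit_hotspot(frame, lam=1e9)
        carr = frame.carrier_mask()
        xbar = frame.position[carr].mean()
        Xg = np.column_stack([
            np.ones(len(frame.is_case)), frame.carrier,
            frame.carrier * (frame.position - xbar),
        ])
        glm = sm.GLM(
            frame.is_case, Xg, family=sm.families.Binomial(),
            freq_weights=frame.weight,
        ).fit()
        eta_glm = Xg @ glm.params
        eta_gam = model.beta0 + model.contrast_rows(frame.position[carr]) @ model.beta
        np.testing.assert_allclose(eta_gam, eta_glm[carr], atol=1e-6)

    def test_unpenalized_fit_matches_glm_refit_oracle(self, clustered_frame):
        """Small basis, no penalty: our PIRLS equals an independent GLM fit
        on the explicitly constructed design matrix."""
        import statsmodels.api as sm

        frame = clustered_frame
        model = fit_hotspot(frame, basis_dim=5, lam=0.0)
        carr = frame.carrier_mask()
        Bz = np.zeros((len(frame.is_case), model.n_spline))
        Bz[carr] = model.smooth_basis(frame.position[carr])
        Xg = np.column_stack([np.ones(len(frame.is_case)), frame.carrier, Bz])
        glm = sm.GLM(
            frame.is_case, Xg, family=sm.families.Binomial(),
            freq_weights=frame.weight,
        ).fit()
        pos = np.arange(1, frame.L + 1)
        log_or_ours, _ = predict_log_or(model, pos)
        V = model.contrast_rows(pos.astype(float))
        log_or_glm = V @ glm.params
        np.testing.assert_allclose(log_or_ours, log_or_glm, atol=1e-6)

    def test_prediction_consistency_at_training_positions(self, clustered_frame):
        frame = clustered_frame
        model = fit_hotspot(frame)
        carr = frame.carrier_mask()
        pos = frame.position[carr]
        # recomputed linear predictor == direct design-matrix product
        from cbkit.hotspot_gam import _design

        X, _, _, _, _ = _design(frame, 10, None)
        eta_direct = (X @ model.beta)[carr]
        eta_pred = model.beta0 + model.contrast_rows(pos) @ model.beta
        np.testing.assert_allclose(eta_pred, eta_direct, atol=1e-10)

    def test_weight_scale_invariance_at_matched_lambda(self, clustered_frame):
        frame = clustered_frame
        m1 = fit_hotspot(frame, lam=1.0)
        scaled = type(frame)(
            is_case=frame.is_case, carrier=frame.carrier,
            position=frame.position, weight=3.0 * frame.weight,
            gene=frame.gene, L=frame.L,
        )
        m3 = fit_hotspot(scaled, lam=3.0)
        np.testing.assert_allclose(m1.beta, m3.beta, atol=1e-8)
        # information triples, so the covariance shrinks threefold
        np.testing.assert_allclose(m3.cov, m1.cov / 3.0, atol=1e-8)

    def test_null_recovery(self):
        """No true burden or positional effect: the carrier coefficient is
        consistent with zero and the smooth shrinks towards linearity."""
        ok, edfs = 0, []
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            frame, _, _ = make_carrier_frame(rng)
            model = fit_hotspot(frame)
            se1 = math.sqrt(model.cov[1, 1])
            edfs.append(model.edf_smooth)
            if abs(model.beta1) < 2 * se1:
                ok += 1
        assert ok >= 0.85 * n_seeds
        assert np.median(edfs) <= 1.5

    def test_step_function_truth_recovered_away_from_jump(self):
        """A sharp OR-20 step is tracked well except near the discontinuity,
        where smoothing bias is intrinsic to any penalized spline."""
        step = lambda p: 20.0 if p <= 250 else 1.0
        truth = np.log([step(p) for p in np.arange(1, 501)])
        away = np.abs(np.arange(1, 501) - 250.5) > 60
        glob, aw = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            frame, _, _ = make_carrier_frame(rng, or_fn=step)
            model = fit_hotspot(frame)
            log_or, se = predict_log_or(model, np.arange(1, 501))
            covered = (truth >= log_or - 1.96 * se) & (truth <= log_or + 1.96 * se)
            glob.append(covered.mean())
            aw.append(covered[away].mean())
        assert np.mean(aw) >= 0.82
        assert np.mean(glob) >= 0.70

    def test_gcv_smoothing_also_fits(self, clustered_frame):
        model = fit_hotspot(clustered_frame, smoothing="GCV")
        assert model.lam > 0 and np.isfinite(model.edf)


class TestPrediction:
    def test_null_model_predicts_or_one(self, clustered_frame):
        model = fit_hotspot(clustered_frame)
        model.beta[:] = 0.0
        preds = predict_position_or(model, [1, 250, 500])
        for p in preds:
            assert p.or_ == pytest.approx(1.0)
            assert p.ci_low < 1.0 < p.ci_high

    def test_ci_brackets_point_estimate(self, clustered_frame):
        model = fit_hotspot(clustered_frame)
        for p in predict_position_or(model, np.arange(1, 501, 37)):
            assert p.ci_low < p.or_ < p.ci_high

    def test_out_of_range_position_raises(self, clustered_frame):
        model = fit_hotspot(clustered_frame)
        with pytest.raises(ValueError):
            predict_log_or(model, [0])
        with pytest.raises(ValueError):
            predict_log_or(model, [501])

    def test_json_roundtrip_preserves_predictions(self, clustered_frame, tmp_path):
        model = fit_hotspot(clustered_frame)
        path = tmp_path / "model.json"
        save_model(model, path)
        clone = load_model(path)
        lo1, se1 = predict_log_or(model, np.arange(1, 501, 11))
        lo2, se2 = predict_log_or(clone, np.arange(1, 501, 11))
        np.testing.assert_allclose(lo1, lo2)
        np.testing.assert_allclose(se1, se2)

    def test_null_calibration_ci_covers_unity(self, gam_null_coverage):
        assert gam_null_coverage.mean() >= 0.90


class TestEvidence:
    @pytest.mark.parametrize(
        "or_,stratum",
        [
            (150.0, "strong"), (100.0, "strong"), (25.0, "moderate"),
            (20.0, "moderate"), (10.0, "supporting"), (9.999, "weak"),
            (5.0, "weak"), (1.0, "none"), (0.2, "none"),
        ],
    )
    def test_strata(self, or_, stratum):
        assert stratify_evidence(or_) == stratum

    def test_monotone_in_or(self):
        order = ["none", "weak", "supporting", "moderate", "strong"]
        values = np.exp(np.linspace(-2, 6, 60))
        ranks = [order.index(stratify_evidence(v)) for v in values]
        assert ranks == sorted(ranks)

    @pytest.mark.parametrize("p,odds", [(0.5, 1.0), (0.9, 9.0), (0.95, 19.0),
                                        (0.99, 99.0)])
    def test_probability_odds_map(self, p, odds):
        assert probability_odds_map(p) == pytest.approx(odds)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_probability_endpoints_rejected(self, p):
        with pytest.raises(ValueError):
            probability_odds_map(p)


class TestHaldaneOr:
    def test_balanced_table(self):
        or_, lo, hi = empirical_or_haldane(5, 5, 5, 5)
        assert or_ == pytest.approx(1.0)
        assert lo * hi == pytest.approx(1.0)  # symmetric on the log scale

    def test_zero_cell_correction(self):
        # corrected cells (1.5, 9.5, 0.5, 100.5)
        or_, lo, hi = empirical_or_haldane(1, 9, 0, 100)
        assert or_ == pytest.approx(150.75 / 4.75, rel=1e-6)
        assert lo == pytest.approx(1.207, rel=1e-3)
        assert hi == pytest.approx(834.4, rel=1e-3)

    def test_no_correction_without_zero(self):
        or_, _, _ = empirical_or_haldane(2, 8, 1, 99)
        assert or_ == pytest.approx(198 / 8)

    def test_requires_some_carrier(self):
        with pytest.raises(ValueError, match="carrier"):
            empirical_or_haldane(0, 10, 0, 100)
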