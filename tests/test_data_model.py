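"""Tests for the data containers and the joint observation model."""

import numpy as np
import pytest

from habfuse.data import CensusLayer, DataConsistencyError, QATable, SurveyTable
from habfuse.model import (
    DegeneratePriorWarning,
    InsufficientQAError,
    ModelParams,
    PriorSpec,
    bias_surface,
    elicit_sigma_prior,
    log_joint,
)
from habfuse.truncnorm import truncnorm_sample, TruncNormSpec

from oracle_utils import tn0_logpdf


def small_census():
    return CensusLayer(
        cell_id=np.array([0, 1, 2, 3, 4]),
        easting=np.array([0.0, 1.0, 2.0, 0.0, 1.0]),
        northing=np.array([0.0, 0.0, 0.0, 1.0, 1.0]),
        q=np.array([0.10, 0.35, 0.20, 0.55, 0.40]),
    )


def small_survey():
    return SurveyTable(cell_id=np.array([1, 3]), y=np.array([0.30, 0.60]))


class TestContainers:
    def test_duplicate_cell_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SurveyTable(cell_id=np.array([1, 1]), y=np.array([0.1, 0.2]))

    def test_large_proportion_violations_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SurveyTable(cell_id=np.array([1]), y=np.array([1.2]))

    def test_roundtrip_noise_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            table = SurveyTable(cell_id=np.array([1]), y=np.array([1.0 + 1e-12]))
        assert table.y[0] == 1.0

    def test_csv_roundtrip(self, tmp_path):
        census = small_census()
        path = tmp_path / "census.csv"
        census.to_csv(path)
        back = CensusLayer.from_csv(path)
        np.testing.assert_array_equal(back.cell_id, census.cell_id)
        np.testing.assert_allclose(back.q, census.q)

    def test_index_of_missing_cell_raises(self):
        with pytest.raises(DataConsistencyError):
            small_census().index_of(np.array([99]))

    def test_index_of_resolves_positions(self):
        idx = small_census().index_of(np.array([3, 0]))
        np.testing.assert_array_equal(idx, [3, 0])


class TestBiasSurface:
    def test_zero_thetas_give_constant_bias(self):
        params = ModelParams(-0.1, 1.2, 0, 0, 0, 0, sigma=0.1, tau=0.1)
        for e, n in [(0.0, 0.0), (5e5, 1e6), (-3.0, 7.0)]:
            alpha, beta = bias_surface(e, n, params)
            assert (alpha, beta) == (-0.1, 1.2)

    def test_constant_bias_posterior_median_case(self):
        # broadleaved-woodland style constant bias: alpha=-0.340, beta=0.475
        params = ModelParams(-0.340, 0.475, 0, 0, 0, 0, sigma=0.1, tau=0.1)
        alpha, beta = bias_surface(123456.0, 654321.0, params)
        assert (alpha, beta) == (-0.340, 0.475)

    def test_hand_computed_linear_surface(self):
        params = ModelParams(1.0, 0.0, 2e-6, 1e-6, 0, 0, sigma=0.1, tau=0.1)
        alpha, _ = bias_surface(300_000.0, 500_000.0, params)
        assert alpha == pytest.approx(2.3)


class TestLogJoint:
    def priors(self, **kw):
        kw.setdefault("sigma_lower", 0.01)
        kw.setdefault("sigma_upper", 0.3)
        kw.setdefault("z_prior", "uniform")
        return PriorSpec(**kw)

    def params(self, census, **kw):
        base = dict(
            delta1=0.05, delta2=0.9, theta1=0.01, theta2=-0.02,
            theta3=0.005, theta4=0.0, sigma=0.1, tau=0.15,
            z=np.array([0.12, 0.3, 0.25, 0.5, 0.41]),
        )
        base.update(kw)
        return ModelParams(**base)

    def test_matches_per_term_scalar_oracle(self):
        census, survey = small_census(), small_survey()
        priors = self.priors()
        params = self.params(census)
        got = log_joint(census, survey, params, priors)

        # likelihood: one scipy truncnorm term at a time
        expected = 0.0
        zmap = dict(zip(census.cell_id.tolist(), params.z))
        for cid, y in zip(survey.cell_id.tolist(), survey.y):
            expected += tn0_logpdf(y, zmap[cid], params.sigma)
        for cid, e, n, q in zip(
            census.cell_id.tolist(), census.easting, census.northing, census.q
        ):
            alpha = params.delta1 + params.theta1 * n + params.theta2 * e
            beta = params.delta2 + params.theta3 * n + params.theta4 * e
            expected += tn0_logpdf(q, alpha + beta * zmap[cid], params.tau)
        # priors, standardizing coordinates independently of the package
        e_m, e_s = census.easting.mean(), census.easting.std()
        n_m, n_s = census.northing.mean(), census.northing.std()
        coefs_s = np.array(
            [
                params.delta1 + params.theta1 * n_m + params.theta2 * e_m,
                params.delta2 + params.theta3 * n_m + params.theta4 * e_m,
                params.theta1 * n_s,
                params.theta2 * e_s,
                params.theta3 * n_s,
                params.theta4 * e_s,
            ]
        )
        from scipy.stats import norm

        expected += norm.logpdf(coefs_s, 0, priors.coef_sd).sum()
        expected += -np.log(priors.sigma_upper - priors.sigma_lower)
        expected += -np.log(priors.tau_upper)
        assert got == pytest.approx(float(expected), rel=1e-10)

    def test_invariant_to_row_ordering(self):
        census, survey = small_census(), small_survey()
        priors, params = self.priors(), self.params(census)
        base = log_joint(census, survey, params, priors)

        perm = np.array([4, 2, 0, 3, 1])
        census_p = CensusLayer(
            census.cell_id[perm], census.easting[perm],
            census.northing[perm], census.q[perm],
        )
        params_p = self.params(census_p, z=params.z[perm])
        survey_p = SurveyTable(survey.cell_id[::-1], survey.y[::-1])
        assert log_joint(census_p, survey_p, params_p, priors) == pytest.approx(
            base, rel=1e-12
        )

    def test_sigma_outside_prior_support_is_minus_inf(self):
        census, survey = small_census(), small_survey()
        params = self.params(census, sigma=0.5)
        assert log_joint(census, survey, params, self.priors()) == -np.inf

    def test_latent_field_outside_unit_interval_is_minus_inf(self):
        census, survey = small_census(), small_survey()
        params = self.params(census, z=np.array([0.1, 0.2, 1.3, 0.4, 0.5]))
        assert log_joint(census, survey, params, self.priors()) == -np.inf

    def test_empty_survey_contributes_nothing(self):
        census = small_census()
        empty = SurveyTable(cell_id=np.array([], dtype=int), y=np.array([]))
        priors, params = self.priors(), self.params(census)
        with_survey = log_joint(census, small_survey(), params, priors)
        without = log_joint(census, empty, params, priors)
        survey_terms = sum(
            tn0_logpdf(y, params.z[cid], params.sigma)
            for cid, y in zip(small_survey().cell_id.tolist(), small_survey().y)
        )
        assert with_survey - without == pytest.approx(float(survey_terms), rel=1e-9)

    def test_unresolvable_survey_cell_raises(self):
        census = small_census()
        bad = SurveyTable(cell_id=np.array([42]), y=np.array([0.2]))
        with pytest.raises(DataConsistencyError):
            log_joint(census, bad, self.params(census), self.priors())

    def test_observation_models_exchangeable_in_symmetric_case(self):
        # theta=0, delta2=1, delta1=0, sigma=tau: swapping a cell's Y and Q
        # leaves the joint density unchanged
        census = small_census()
        survey = SurveyTable(cell_id=np.array([1, 3]), y=np.array([0.3, 0.6]))
        priors = self.priors(sigma_lower=0.0, sigma_upper=1.0, tau_upper=1.0)
        params = self.params(
            census, delta1=0.0, delta2=1.0, theta1=0, theta2=0, theta3=0,
            theta4=0, sigma=0.2, tau=0.2,
        )
        base = log_joint(census, survey, params, priors)

        q2 = census.q.copy()
        q2[1], q2[3] = survey.y
        census_sw = CensusLayer(census.cell_id, census.easting, census.northing, q2)
        survey_sw = SurveyTable(survey.cell_id, np.array([census.q[1], census.q[3]]))
        assert log_joint(census_sw, survey_sw, params, priors) == pytest.approx(
            base, rel=1e-12
        )


class TestSigmaPriorElicitation:
    def test_hand_computed_point_estimate(self):
        qa = QATable(
            cell_id=np.arange(4),
            y_first=np.array([0.10, 0.20, 0.30, 0.05]),
            y_second=np.array([0.14, 0.16, 0.34, 0.01]),
        )
        lower, upper = elicit_sigma_prior(qa, inflation=2.0)
        sigma_hat = np.std([-0.04, 0.04, -0.04, 0.04], ddof=1) / np.sqrt(2)
        assert lower == 0.0
        assert upper == pytest.approx(2 * sigma_hat)
        assert upper == pytest.approx(2 * 0.032659863237, rel=1e-9)

    def test_identical_revisits_warn_degenerate(self):
        qa = QATable(
            cell_id=np.arange(3),
            y_first=np.array([0.1, 0.2, 0.3]),
            y_second=np.array([0.1, 0.2, 0.3]),
        )
        with pytest.warns(DegeneratePriorWarning):
            lower, upper = elicit_sigma_prior(qa)
        assert (lower, upper) == (0.0, 0.0)

    def test_too_few_rows_raise(self):
        qa = QATable(np.array([0]), np.array([0.1]), np.array([0.2]))
        with pytest.raises(InsufficientQAError):
            elicit_sigma_prior(qa)

    def test_recovers_generating_error_sd(self, rng):
        sigma = 0.01
        z = rng.uniform(0.2, 0.8, size=500)
        y1 = np.array([truncnorm_sample(TruncNormSpec(m, sigma), 1, rng)[0] for m in z])
        y2 = np.array([truncnorm_sample(TruncNormSpec(m, sigma), 1, rng)[0] for m in z])
        qa = QATable(np.arange(500), np.clip(y1, 0, 1), np.clip(y2, 0, 1))
        _, upper = elicit_sigma_prior(qa, inflation=1.0)
        assert upper == pytest.approx(sigma, rel=0.15)
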