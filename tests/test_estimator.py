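"""Moment summaries and the a-priori error-propagation pipeline."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pmcerr import (
    Perturbation,
    back_transform_variance,
    compute_moments,
    estimate_error,
    estimate_full_variance,
    estimator_discrepancy,
    from_ratio,
    moments_for_detector,
    propagate_log_variance,
)
from pmcerr.estimator import TransformDerivatives, propagate_variance
from pmcerr.photon_db import records_from_arrays
from pmcerr.pmc import perturbed_log_weights


def _records(lnw, j, L):
    lnw = np.asarray(lnw, float)
    n = len(lnw)
    return records_from_arrays(
        photon_id=np.arange(n, dtype=np.int64),
        detector_id=np.array(["proximal"] * n, dtype=object),
        weight=np.exp(lnw),
        n_collisions=np.asarray(j, dtype=np.int64),
        path_length_mm=np.asarray(L, dtype=float),
        n_rr=np.zeros(n, dtype=np.int64),
    )


MEDIUM_KEY = (0.1, 4.0, 0.8, 1.4)


class TestComputeMoments:
    def test_closed_form_small_sample(self):
        # x = [1, 2, 3]: population variance 2/3, zero skew
        m = compute_moments(_records([1.0, 2.0, 3.0], [1, 2, 3], [1.0, 2.0, 3.0]), n_launched=10)
        assert m.var["lnw"] == pytest.approx(2 / 3, rel=1e-12)
        assert m.skew["lnw"] == pytest.approx(0.0, abs=1e-12)
        assert m.mean["lnw"] == pytest.approx(2.0)
        assert m.n_tallied == 3 and m.n_untallied == 7
        assert m.w_bar_r == pytest.approx(0.3 * m.w_bar_rt)

    def test_cov_diagonal_is_variance(self):
        rng = np.random.default_rng(0)
        lnw = rng.normal(size=200)
        m = compute_moments(_records(lnw, rng.integers(1, 50, 200), rng.uniform(0.1, 9, 200)), 500)
        for x in ("lnw", "j", "L"):
            assert m.cov[(x, x)] == m.var[x]

    @given(st.integers(0, 1000))
    def test_cauchy_schwarz_on_random_samples(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        lnw = rng.normal(-2, 1, n)
        m = compute_moments(
            _records(lnw, rng.integers(1, 100, n), rng.uniform(0.1, 20, n)), n + 10
        )
        for x in ("lnw", "j", "L"):
            for y in ("lnw", "j", "L"):
                assert abs(m.cov[(x, y)]) <= m.sd(x) * m.sd(y) * (1 + 1e-9)

    def test_requires_two_records(self):
        with pytest.raises(ValueError, match="at least 2"):
            compute_moments(_records([1.0], [1], [1.0]), 5)

    def test_caw_log_weight_path_identities(self, db_r5_norr_small):
        # continuous absorption weighting forces ln W = -mua * L, hence a
        # perfect anticorrelation, equal normalized variances and mirrored skew
        for det in ("proximal", "distal"):
            m = moments_for_detector(db_r5_norr_small, det)
            assert round(m.corr("lnw", "L"), 3) == -1.000
            assert m.normalized_var("lnw") == pytest.approx(m.normalized_var("L"), rel=1e-9)
            assert m.skew["lnw"] == pytest.approx(-m.skew["L"], rel=1e-9)


class TestPropagation:
    def test_identity_transform_returns_log_variance(self, db_r5_norr_small):
        m = moments_for_detector(db_r5_norr_small, "proximal")
        assert propagate_log_variance(m, Perturbation()) == pytest.approx(
            m.var["lnw"], rel=1e-12
        )

    def test_absorption_only_closed_form(self, db_r5_norr_small):
        # on a no-RR CAW database lnW = -mua*L, so a pure absorption change
        # propagates to (mua + d_mua)^2 * var(L)
        med = db_r5_norr_small.meta.medium
        m = moments_for_detector(db_r5_norr_small, "distal")
        eps_a = 0.3
        b = med.mua * eps_a
        got = propagate_log_variance(m, Perturbation(eps_a=eps_a))
        assert got == pytest.approx((med.mua + b) ** 2 * m.var["L"], rel=1e-9)

    @given(st.integers(0, 500), st.floats(-0.5, 2.0), st.floats(-0.5, 2.0))
    def test_matches_brute_force_log_variance(self, seed, eps_s, eps_a):
        # the transform is linear, so propagation through the moment template
        # must equal the directly computed variance of ln W_P
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 60))
        recs = _records(
            rng.normal(-1, 0.8, n), rng.integers(1, 200, n), rng.uniform(0.1, 40, n)
        )
        m = compute_moments(recs, n + 5, medium_key=MEDIUM_KEY)
        pert = Perturbation(eps_s=eps_s, eps_a=eps_a)
        from pmcerr.optics import OpticalProperties

        med = OpticalProperties(*MEDIUM_KEY)
        lnwp = perturbed_log_weights(recs, med, pert)
        assert propagate_log_variance(m, pert) == pytest.approx(
            float(lnwp.var()), rel=1e-10, abs=1e-12
        )

    def test_brute_force_on_simulated_database(self, db_r5_norr_small):
        med = db_r5_norr_small.meta.medium
        for det in ("proximal", "distal"):
            m = moments_for_detector(db_r5_norr_small, det)
            recs = db_r5_norr_small.records.query("detector_id == @det")
            for eps in (-0.2, -0.05, 0.1, 0.2):
                pert = Perturbation(eps_s=eps)
                lnwp = perturbed_log_weights(recs, med, pert)
                assert propagate_log_variance(m, pert) == pytest.approx(
                    float(lnwp.var()), rel=1e-10
                )

    def test_nonlinear_transform_engages_skew_terms(self):
        # the nine-term template must honour supplied second derivatives:
        # for f with nonzero curvature the skewness terms contribute
        recs = _records([-1.0, -2.0, -4.0, -0.5], [1, 2, 3, 4], [1.0, 2.0, 3.0, 4.0])
        m = compute_moments(recs, 10)
        linear = TransformDerivatives(
            grad={"lnw": 1.0, "j": 0.0, "L": 0.0}, hess_diag={"lnw": 0.0, "j": 0.0, "L": 0.0}
        )
        curved = TransformDerivatives(
            grad={"lnw": 1.0, "j": 0.0, "L": 0.0}, hess_diag={"lnw": 1.0, "j": 0.0, "L": 0.0}
        )
        diff = propagate_variance(m, curved) - propagate_variance(m, linear)
        assert diff == pytest.approx(m.third_moment("lnw"), rel=1e-12)


class TestBackTransformAndAssembly:
    def test_zero_variance_maps_to_zero(self, db_r5_norr_small):
        m = moments_for_detector(db_r5_norr_small, "proximal")
        assert back_transform_variance(0.0, m) == 0.0

    def test_unit_mean_is_identity(self):
        recs = _records([0.0, 0.0, 0.0], [1, 2, 3], [1.0, 2.0, 3.0])
        m = compute_moments(recs, 3)
        assert m.w_bar_rt == 1.0
        assert back_transform_variance(0.37, m) == pytest.approx(0.37)

    def test_delta_method_accurate_for_narrow_weights(self):
        # weights within +-1% of their mean: the first-order back-transform
        # matches the true tallied variance within 5%
        rng = np.random.default_rng(1)
        w = 0.5 * (1 + 0.01 * (2 * rng.random(5000) - 1))
        recs = _records(np.log(w), rng.integers(1, 50, 5000), rng.uniform(0.1, 9, 5000))
        m = compute_moments(recs, 10_000)
        est = back_transform_variance(m.var["lnw"], m)
        assert est == pytest.approx(float(w.var()), rel=0.05)

    def test_all_tallied_reduces_to_tallied_sigma(self):
        recs = _records([-1.0, -1.5, -0.7], [1, 2, 3], [1.0, 2.0, 3.0])
        m = compute_moments(recs, 3)  # N_T = N, phi_bar = 0
        assert estimate_full_variance(m, 0.04) == pytest.approx(0.2, rel=1e-12)

    def test_four_photon_fixture_recovers_direct_variance(self):
        # supplying the true tallied variance reproduces sqrt(0.375) = 0.6124
        # for tallied weights {0.5, 1.5} of N = 4
        recs = _records(np.log([0.5, 1.5]), [1, 2], [1.0, 2.0])
        m = compute_moments(recs, 4)
        true_var_t = float(np.array([0.5, 1.5]).var())
        assert estimate_full_variance(m, true_var_t) == pytest.approx(
            math.sqrt(0.375), rel=1e-12
        )

    def test_monotone_in_tallied_variance(self, db_r5_norr_small):
        m = moments_for_detector(db_r5_norr_small, "distal")
        vals = [estimate_full_variance(m, v) for v in (0.0, 0.01, 0.1, 1.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestDiscrepancy:
    @pytest.mark.parametrize(
        "est,true,expected", [(1.0, 1.0, 0.0), (1.2, 1.0, 0.2), (0.8, 1.0, -0.2)]
    )
    def test_definition(self, est, true, expected):
        assert estimator_discrepancy(est, true) == pytest.approx(expected, abs=1e-15)

    def test_zero_true_sigma_rejected(self):
        with pytest.raises(ValueError):
            estimator_discrepancy(1.0, 0.0)

    def test_full_pipeline_attaches_delta(self, db_r5_norr_small):
        m = moments_for_detector(db_r5_norr_small, "proximal")
        est = estimate_error(m, Perturbation(eps_s=0.05), sigma_wp_true=1.0)
        assert est.delta == pytest.approx(est.sigma_wp_est - 1.0, rel=1e-12)
        assert est.var_ln_wpt > 0 and est.sigma_wp_est > 0
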