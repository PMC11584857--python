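"""Tests for the closed-form error/uncertainty machinery."""

import numpy as np
import pytest
from scipy.integrate import quad

from qsfilter.error_analysis import (
    EigenPerturbation,
    MeasurementModel,
    NoiseBudget,
    bit_success_probability,
    closed_form_I1,
    closed_form_I2,
    eigen_error_budget,
    expected_inverse_moments,
    measurement_pmf,
    measurement_pmf_printed,
    measurement_variance,
    mse_bound,
    perturbed_filter_apply,
)
from qsfilter.smoothing import SmoothingConfig, apply_smoothing_filter, build_filter_matrix


def _quad_I1(K, sw, u):
    return quad(lambda x: (1 - x**2 / (2 * sw**2)) / (K + x), 0, u, epsabs=1e-12)[0]


def _quad_I2(K, sw, u):
    return quad(lambda x: (1 - x**2 / (2 * sw**2)) / (K + x) ** 2, 0, u, epsabs=1e-12)[0]


def test_mse_bound_degenerate_cases():
    assert mse_bound([1.0], NoiseBudget(sigma_x2=1.0, sigma_w2=0.0)) == pytest.approx(0.0)
    # very large eigenvalues: bound approaches the signal power
    big = mse_bound([1e12] * 4, NoiseBudget(sigma_x2=2.5, sigma_w2=0.1))
    assert big == pytest.approx(2.5, abs=1e-10)
    with pytest.raises(ZeroDivisionError):
        mse_bound([0.0, 1.0], NoiseBudget())


def test_mse_bound_direct_substitution_warns_when_negative():
    with pytest.warns(RuntimeWarning):
        val = mse_bound([1.0, 2.0], NoiseBudget(sigma_x2=1.0, sigma_w2=0.1))
    # 1*(1 - 2*1.5 + 1.25) + 0.1*1.25
    assert val == pytest.approx(-0.625)


def test_eigen_error_budget_sum_and_monotonicity():
    assert eigen_error_budget(0.0, 0.0, 0.0) == 0.0
    assert eigen_error_budget(0.01, 0.02, 0.03) == pytest.approx(0.0501)
    base = eigen_error_budget(0.01, 0.02, 0.03)
    assert eigen_error_budget(0.02, 0.02, 0.03) > base
    assert eigen_error_budget(0.01, 0.05, 0.03) > base
    assert eigen_error_budget(0.01, 0.02, 0.07) > base


def test_bit_success_probability_limits():
    model = MeasurementModel(N_q=3, tau=((0.0,),), beta=((0.0,),), m=((0,),), B=(1.0,))
    assert bit_success_probability(model, [1.23]) == pytest.approx(1.0)
    model_pi = MeasurementModel(N_q=3, tau=((1.0,),), beta=((0.0,),), m=((0,),), B=(1.0,))
    assert bit_success_probability(model_pi, [np.pi]) == pytest.approx(0.0, abs=1e-30)
    with pytest.raises(ValueError):
        bit_success_probability(model, [])


def test_bit_success_probability_stays_in_unit_interval(rng):
    for _ in range(1000):
        n_groups = rng.integers(1, 4)
        r = rng.integers(1, 4)
        model = MeasurementModel(
            N_q=4,
            tau=tuple(tuple(rng.uniform(0, 5, r)) for _ in range(n_groups)),
            beta=tuple(tuple(rng.uniform(-np.pi, np.pi, r)) for _ in range(n_groups)),
            m=tuple(tuple(rng.integers(0, 2, r)) for _ in range(n_groups)),
        )
        p = bit_success_probability(model, rng.uniform(0.1, 5.0, 3))
        assert 0.0 <= p <= 1.0


@pytest.mark.parametrize("N_q", [1, 3, 5, 8])
@pytest.mark.parametrize("p_b", [0.0, 0.25, 0.5, 0.83, 1.0])
def test_measurement_pmf_normalizes(N_q, p_b):
    pmf = measurement_pmf(N_q, p_b)
    assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(pmf >= 0)


def test_measurement_pmf_point_cases():
    np.testing.assert_allclose(measurement_pmf(3, 1.0), [1, 0, 0, 0])
    np.testing.assert_allclose(measurement_pmf(1, 0.75), [0.75, 0.25])


def test_printed_pmf_does_not_normalize():
    # the literal printed form under-counts; kept only for comparison
    assert measurement_pmf_printed(2, 0.8).sum() != pytest.approx(1.0, abs=1e-3)


def test_measurement_variance_no_flips_at_perfect_readout():
    model = MeasurementModel(N_q=4)
    assert measurement_variance(model, ["1010"], 1.0) == 0.0


def test_measurement_variance_matches_enumeration_oracle():
    # N_q=1, d='1', p_b=0.5: single flip pattern, distance 1, weight 0.5,
    # normalization 1/(1 strings * 1 pattern * 1 bit)
    model = MeasurementModel(N_q=1)
    assert measurement_variance(model, ["1"], 0.5) == pytest.approx(0.5)
    # independent brute force for N_q=2
    model2 = MeasurementModel(N_q=2)
    p_b = 0.8
    total = 0.0
    for d in (0b10,):
        for mask in (0b01, 0b10, 0b11):
            j = bin(mask).count("1")
            total += p_b ** (2 - j) * (1 - p_b) ** j * (d - (d ^ mask)) ** 2
    expected = total / (1 * 3 * 2)
    assert measurement_variance(model2, ["10"], p_b) == pytest.approx(expected)


def test_measurement_variance_decreasing_in_pb():
    model = MeasurementModel(N_q=4)
    vals = [measurement_variance(model, ["1011"], p) for p in np.linspace(0.5, 1.0, 11)]
    assert all(a >= b for a, b in zip(vals, vals[1:]))


def test_closed_form_integrals_vanish_with_empty_range():
    for u in (1e-12, 1e-9):
        pert = EigenPerturbation(lambda_tr=1.0, u_max=u)
        assert closed_form_I1(pert, 1.0) == pytest.approx(0.0, abs=1e-8)
        assert closed_form_I2(pert, 1.0) == pytest.approx(0.0, abs=1e-8)


def test_closed_form_I1_matches_quadrature_reference():
    pert = EigenPerturbation(lambda_tr=1.0, u_max=1.0)
    assert closed_form_I1(pert, 1.0) == pytest.approx(_quad_I1(1.0, 1.0, 1.0), abs=1e-8)


def test_closed_form_I2_matches_quadrature_reference():
    pert = EigenPerturbation(lambda_tr=1.0, u_max=1.0)
    assert closed_form_I2(pert, 1.0) == pytest.approx(_quad_I2(1.0, 1.0, 1.0), abs=1e-8)


def test_closed_forms_on_parameter_grid():
    """Both closed forms agree with adaptive quadrature across a >=100-point grid."""
    grid = [
        (K, sw, u)
        for K in (0.5, 1.0, 1.7, 2.5, 4.0)
        for sw in (0.5, 1.0, 2.0, 3.5)
        for u in (0.1, 0.5, 1.0, 2.0, 5.0)
    ]
    assert len(grid) >= 100
    for K, sw, u in grid:
        pert = EigenPerturbation(lambda_tr=K, u_max=u)
        assert closed_form_I1(pert, sw) == pytest.approx(_quad_I1(K, sw, u), abs=1e-8)
        assert closed_form_I2(pert, sw) == pytest.approx(_quad_I2(K, sw, u), abs=1e-8)


def test_I2_below_I1_for_K_at_least_one():
    for K in (1.0, 1.5, 3.0):
        for u in (0.5, 1.0, 2.0):
            pert = EigenPerturbation(lambda_tr=K, u_max=u)
            assert closed_form_I2(pert, 1.0) < closed_form_I1(pert, 1.0)


def test_truncated_taylor_underapproximates_gaussian_tail():
    # 1 - y <= exp(-y) pointwise, so the two-term expansion under-approximates
    # the Gaussian integrand; the gap stays within the O(u^5) truncation error
    pert = EigenPerturbation(lambda_tr=1.0, u_max=0.5)
    gauss = quad(lambda x: np.exp(-(x**2) / 2.0) / (1 + x), 0, 0.5)[0]
    val = closed_form_I1(pert, 1.0)
    assert val <= gauss
    assert gauss - val <= 0.5**5 / 8  # |e^-y - (1-y)| <= y^2/2 with y = x^2/2


def test_expected_inverse_moments_against_monte_carlo(rng):
    """Deterministic-measurement limit vs direct truncated-Gaussian sampling."""
    lam_tr, sw, u_max = 1.5, 1.0, 0.5
    pert = EigenPerturbation(lambda_tr=lam_tr, u_max=u_max)
    model = MeasurementModel(N_q=5, tau=((0.0,),), beta=((0.0,),), m=((0,),), B=(1.0,))
    e1, e2 = expected_inverse_moments(pert, model, sw)  # p_b = 1: no lambda_m spread
    draws = rng.normal(0.0, sw, size=2_000_000)
    draws = np.abs(draws)[np.abs(draws) <= u_max][:1_000_000]
    mc1 = np.mean(1.0 / (lam_tr + draws))
    # the closed form integrates an un-normalized truncated density; rescale the
    # Monte-Carlo estimate by the same mass for comparison
    mass = quad(lambda x: np.exp(-(x**2) / (2 * sw**2)) / (sw * np.sqrt(2 * np.pi)), 0, u_max)[0]
    # agreement within the two-term Taylor truncation error of the integrand
    assert e1 == pytest.approx(mc1 * mass, rel=0.02)
    assert 0 < e2 <= e1 * (1.0 / lam_tr)


def test_expected_inverse_moments_finite_positive_on_grid():
    model = MeasurementModel(N_q=4)
    for lam_tr in (1.0, 2.0, 5.0):
        for u in (0.2, 1.0):
            e1, e2 = expected_inverse_moments(
                EigenPerturbation(lambda_tr=lam_tr, u_max=u), model, 1.0, p_b=0.9
            )
            assert np.isfinite(e1) and np.isfinite(e2)
            assert e1 > 0 and e2 > 0


def test_perturbed_filter_identity_limit(rng):
    P = build_filter_matrix(SmoothingConfig(eta=0.5), 16)
    y = rng.normal(size=16)
    np.testing.assert_allclose(
        perturbed_filter_apply(P, 0.0, y),
        apply_smoothing_filter(y, P).samples,
        atol=1e-10,
    )


def test_perturbed_filter_matches_shifted_dense_inverse(rng):
    P = build_filter_matrix(SmoothingConfig(eta=0.5), 12)
    y = rng.normal(size=12)
    for eps in (1e-4, 0.01, 0.1):
        x = perturbed_filter_apply(P, eps, y)
        ref = np.linalg.solve(P.toarray() + eps * np.eye(12), y)
        np.testing.assert_allclose(x, ref, atol=1e-10)


def test_perturbed_filter_error_grows_continuously(rng):
    P = build_filter_matrix(SmoothingConfig(eta=0.5), 12)
    y = rng.normal(size=12)
    x0 = perturbed_filter_apply(P, 0.0, y)
    errs = [
        np.linalg.norm(perturbed_filter_apply(P, eps, y) - x0)
        for eps in np.linspace(0.0, 0.1, 11)
    ]
    assert errs[0] == 0.0
    assert all(b >= a for a, b in zip(errs, errs[1:]))
    assert max(np.diff(errs)) < 0.2 * np.linalg.norm(x0)  # no jumps


def test_perturbed_filter_rejects_indefinite_shift(rng):
    P = build_filter_matrix(SmoothingConfig(eta=0.5), 8)
    with pytest.raises(np.linalg.LinAlgError):
        perturbed_filter_apply(P, -10.0, rng.normal(size=8))


def test_noise_budget_total_variance():
    b = NoiseBudget(eps_P=0.1, sigma_m2=0.02, sigma_h2=0.005)
    assert b.sigma_e2 == pytest.approx(0.01 + 0.02 + 0.005)
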