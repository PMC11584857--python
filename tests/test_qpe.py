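"""Tests for amplitude encoding, QPE, conditional rotation and the pipeline."""

import numpy as np
import pytest

from qsfilter.qpe import (
    QPEConfig,
    QPEJointState,
    QuantumRegisterState,
    amplitude_encode,
    conditional_rotation,
    postselect_and_uncompute,
    quantum_filter,
    run_qpe,
    sample_histogram,
)
from qsfilter.smoothing import SmoothingConfig, apply_smoothing_filter, build_filter_matrix


def test_amplitude_encode_normalizes_and_pads():
    st = amplitude_encode(np.array([3.0, 4.0]))
    np.testing.assert_allclose(st.amplitudes, [0.6, 0.8])
    assert st.norm_factor == pytest.approx(5.0)
    st3 = amplitude_encode(np.array([1.0, 0.0, 0.0]))  # padded to 4
    assert st3.amplitudes.size == 4
    np.testing.assert_allclose(st3.amplitudes, [1, 0, 0, 0])
    assert np.linalg.norm(st3.amplitudes) == pytest.approx(1.0)


def test_amplitude_encode_rejects_zero_signal():
    with pytest.raises(ValueError):
        amplitude_encode(np.zeros(4))


def test_register_state_norm_invariant():
    with pytest.raises(ValueError):
        QuantumRegisterState(amplitudes=np.array([1.0, 1.0]))


def test_qpe_identity_unitary_reports_phase_zero():
    est = run_qpe(np.eye(2), np.array([0.0, 1.0]), QPEConfig(n_a=4))
    assert est.k == 0 and est.theta == 0.0
    assert est.probabilities[0] == pytest.approx(1.0)


def test_qpe_exact_phase_concentrates_fully():
    # eigenphase 0.25 on 5 bits -> bin 8 with probability 1
    U = np.diag([1.0, np.exp(2j * np.pi * 0.25)])
    est = run_qpe(U, np.array([0.0, 1.0]), QPEConfig(n_a=5))
    assert est.k == 8
    assert est.probabilities[8] == pytest.approx(1.0, abs=1e-12)


def test_qpe_inexact_phase_within_resolution():
    U = np.diag([1.0, np.exp(2j * np.pi * 0.3)])
    est = run_qpe(U, np.array([0.0, 1.0]), QPEConfig(n_a=5))
    assert est.k in (9, 10)
    assert abs(est.theta - 0.3) <= 2**-5


def test_qpe_idealized_path_bins_each_eigencomponent():
    U = np.diag([np.exp(2j * np.pi * 0.30), np.exp(2j * np.pi * 0.65)])
    psi = np.array([1.0, 1.0]) / np.sqrt(2)
    est = run_qpe(U, psi, QPEConfig(n_a=5, idealized=True))
    probs = est.probabilities
    # nearest bins to 0.3*32=9.6 and 0.65*32=20.8 get all the weight
    assert probs[10] == pytest.approx(0.5, abs=1e-12)
    assert probs[21] == pytest.approx(0.5, abs=1e-12)
    assert probs.sum() == pytest.approx(1.0, abs=1e-12)


def test_conditional_rotation_weights_and_norm():
    # two occupied branches with decoded eigenvalues 1 and 2, C_m = 1:
    # flag-|1> relative squared weights must be {1, 0.25}
    T, d = 8, 2
    arr = np.zeros((T, d), dtype=complex)
    t0 = 2 * np.pi  # lambda(k) = k with these units
    arr[1, 0] = arr[2, 1] = 1 / np.sqrt(2)
    joint = QPEJointState(array=arr, t0=t0)
    rotated, C_m = conditional_rotation(joint, QPEConfig(n_a=3, C_m=1.0))
    assert C_m == 1.0
    w1 = np.abs(rotated.array[1, 0, 1]) ** 2
    w2 = np.abs(rotated.array[2, 1, 1]) ** 2
    assert w2 / w1 == pytest.approx(0.25)
    assert np.sum(np.abs(rotated.array) ** 2) == pytest.approx(1.0)


def test_conditional_rotation_all_lambda_equal_cm_always_succeeds():
    T = 8
    arr = np.zeros((T, 1), dtype=complex)
    arr[4, 0] = 1.0
    joint = QPEJointState(array=arr, t0=2 * np.pi)
    rotated, _ = conditional_rotation(joint, QPEConfig(n_a=3, C_m=4.0))
    assert np.abs(rotated.array[4, 0, 1]) ** 2 == pytest.approx(1.0)


def test_postselection_inverts_diagonal_operator():
    # P = diag(1, 2) scaled; with exactly representable phases the pipeline
    # output must be proportional to [1, 0.5] for input [1, 1]/sqrt(2)
    n_a = 5
    T = 2**n_a
    k_top = int(np.floor(0.95 * T))  # 30, even: both phases exact
    t_step = 2 * np.pi * k_top / T
    lam = np.array([0.5, 1.0])
    U = np.diag(np.exp(1j * lam * t_step))
    psi = np.array([1.0, 1.0]) / np.sqrt(2)
    config = QPEConfig(n_a=n_a)
    est = run_qpe(U, psi, config, t0=T * t_step, scale=2.0)  # original lam = (1, 2)
    rotated, C_m = conditional_rotation(est.joint, config)
    state, p, unnorm = postselect_and_uncompute(rotated, U, config)
    out = np.real(unnorm) / C_m  # = P^{-1} psi, proportional to [1, 0.5]
    np.testing.assert_allclose(out, np.array([1.0, 0.5]) / np.sqrt(2), atol=1e-9)
    assert out[0] / out[1] == pytest.approx(2.0, abs=1e-9)
    assert p > 0


def test_postselection_probability_lower_bound():
    """Success probability >= (C_m / lambda_max)^2 analytically."""
    N = 8
    cfg = SmoothingConfig(eta=N / 25)
    P = build_filter_matrix(cfg, N)
    lam_max = np.linalg.eigvalsh(P.toarray())[-1]
    y = np.sin(np.arange(N))
    from qsfilter.hamiltonian import HamiltonianSpec, scale_hamiltonian, truncated_exponential

    P_s, scale = scale_hamiltonian(P)
    config = QPEConfig(n_a=8)
    T = config.T
    k_top = int(np.floor(0.95 * T))
    t_step = 2 * np.pi * k_top / T
    U = truncated_exponential(
        HamiltonianSpec(P=P_s, t=t_step, eps_P=1e-8 / T)
    ).U_tilde.conj().T
    est = run_qpe(U, amplitude_encode(y), config, t0=T * t_step, scale=scale)
    rotated, C_m = conditional_rotation(est.joint, config)
    _, p, _ = postselect_and_uncompute(rotated, U, config)
    assert p >= (C_m / lam_max) ** 2 * (1 - 1e-6)


def test_quantum_filter_identity_limit():
    y = np.array([0.3, -1.2, 0.7, 0.1, 0.9, -0.4, 0.2, 0.8])
    out = quantum_filter(y, SmoothingConfig(eta=1e-12), QPEConfig(n_a=6)).samples
    np.testing.assert_allclose(out, y, atol=1e-6)


def test_quantum_filter_matches_classical_solver(rng):
    N = 8
    cfg = SmoothingConfig(eta=N / 25)
    P = build_filter_matrix(cfg, N)
    y = rng.normal(size=N)
    x_c = apply_smoothing_filter(y, P).samples
    x_q = quantum_filter(y, cfg, QPEConfig(n_a=8)).samples
    assert np.linalg.norm(x_q - x_c) / np.linalg.norm(x_c) <= 0.05


def test_quantum_filter_statevector_deterministic(rng):
    y = rng.normal(size=8)
    cfg = SmoothingConfig(eta=0.16)
    a = quantum_filter(y, cfg, QPEConfig(n_a=6)).samples
    b = quantum_filter(y, cfg, QPEConfig(n_a=6)).samples
    np.testing.assert_array_equal(a, b)


def test_norm_bookkeeping():
    """Decoded output norm ~ ||y|| * ||P^{-1} y_unit||."""
    N = 8
    cfg = SmoothingConfig(eta=0.16)
    P = build_filter_matrix(cfg, N).toarray()
    y = np.linspace(1.0, 2.0, N)
    out = quantum_filter(y, cfg, QPEConfig(n_a=9)).samples
    expected = np.linalg.norm(y) * np.linalg.norm(np.linalg.solve(P, y / np.linalg.norm(y)))
    assert np.linalg.norm(out) == pytest.approx(expected, rel=5e-3)


def test_sample_histogram_reproducible_and_conserving():
    state = QuantumRegisterState(amplitudes=np.array([1.0, 1.0]) / np.sqrt(2))
    c1 = sample_histogram(state, 10_000, seed=7)
    c2 = sample_histogram(state, 10_000, seed=7)
    np.testing.assert_array_equal(c1, c2)
    assert c1.sum() == 10_000
    # each bin within 5 sigma of the 50/50 expectation
    sigma = np.sqrt(10_000 * 0.25)
    assert all(abs(c - 5000) <= 5 * sigma for c in c1)


def test_sample_histogram_basis_state():
    state = QuantumRegisterState(amplitudes=np.array([0.0, 0.0, 1.0, 0.0], dtype=complex))
    counts = sample_histogram(state, 123, seed=0)
    assert counts[2] == 123 and counts.sum() == 123
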