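"""Closed-form uncertainty machinery for the quantum smoothing filter.

The estimated eigenvalue of the filter operator decomposes as

    lambda_hat = lambda_tr + lambda_m + lambda_eps + lambda_w

where the perturbations come from quantum measurement uncertainty, from the
Hamiltonian-simulation truncation, and from observation noise. Writing
K = lambda_tr + lambda_m + lambda_eps and modeling lambda_w as a truncated
zero-mean Gaussian on [0, u_max], the inverse-eigenvalue moments reduce to
the definite integrals

    I1 = int_0^{u_max} (1 - x^2/(2 sigma_w^2)) / (K + x)     dx
    I2 = int_0^{u_max} (1 - x^2/(2 sigma_w^2)) / (K + x)^2   dx

(the Gaussian is replaced by its two-term Taylor expansion, which makes the
otherwise divergent integrals tractable). Their closed forms feed the
filter's mean-square-error bound, which is a function of the eigenvalue
spectrum, the signal power sigma_x^2 and the noise power sigma_w^2.

The measurement model assigns each bit of the N_q-bit eigenvalue register an
independent success probability p_b; the flip-count distribution is the
normalized binomial, and the measurement variance sigma_m^2 averages squared
decimal distances over all bit-flip patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb, log, pi, sqrt

import numpy as np
from scipy.linalg import eigh

from .smoothing import FilterMatrix, SignalVector

__all__ = [
    "NoiseBudget",
    "EigenPerturbation",
    "MeasurementModel",
    "mse_bound",
    "eigen_error_budget",
    "bit_success_probability",
    "measurement_pmf",
    "measurement_pmf_printed",
    "measurement_variance",
    "closed_form_I1",
    "closed_form_I2",
    "expected_inverse_moments",
    "perturbed_filter_apply",
]


@dataclass(frozen=True)
class NoiseBudget:
    """Variance budget: sigma_e^2 = |eps_P|^2 + sigma_m^2 + sigma_h^2."""

    sigma_x2: float = 1.0
    sigma_w2: float = 0.0
    sigma_m2: float = 0.0
    sigma_h2: float = 0.0
    eps_P: float = 0.0

    def __post_init__(self):
        for name in ("sigma_x2", "sigma_w2", "sigma_m2", "sigma_h2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def sigma_e2(self) -> float:
        return abs(self.eps_P) ** 2 + self.sigma_m2 + self.sigma_h2


@dataclass(frozen=True)
class EigenPerturbation:
    """Eigenvalue perturbation symbols; K = lambda_tr + lambda_m + lambda_eps."""

    lambda_tr: float
    lambda_m: float = 0.0
    lambda_eps: float = 0.0
    u_max: float = 1.0

    def __post_init__(self):
        if not self.K > 0:
            raise ValueError("K = lambda_tr + lambda_m + lambda_eps must be > 0")
        if not self.u_max > 0:
            raise ValueError("u_max must be > 0")

    @property
    def K(self) -> float:
        return self.lambda_tr + self.lambda_m + self.lambda_eps


@dataclass(frozen=True)
class MeasurementModel:
    """Per-bit measurement model for an N_q-bit eigenvalue register.

    Each rotation-parameter group j contributes a product of R_n squared
    cosines weighted by its normalizing coefficient B_j; tau_r counts unitary
    rotations, beta_r are Z-rotation phases (rad), m_r in {0, 1}.
    """

    N_q: int = 5
    tau: tuple[tuple[float, ...], ...] = ((1.0,),)
    beta: tuple[tuple[float, ...], ...] = ((0.0,),)
    m: tuple[tuple[int, ...], ...] = ((0,),)
    B: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.N_q < 1:
            raise ValueError("N_q must be >= 1")
        if not (len(self.tau) == len(self.beta) == len(self.m)):
            raise ValueError("tau, beta, m must list the same number of groups")
        if self.B is not None and len(self.B) != len(self.tau):
            raise ValueError("B must match the number of groups")

    @property
    def coefficients(self) -> tuple[float, ...]:
        if self.B is not None:
            return self.B
        return tuple([1.0 / len(self.tau)] * len(self.tau))


def mse_bound(eigenvalues, budget: NoiseBudget, moments=None) -> float:
    """Filter MSE bound from the eigenvalue spectrum.

    err <= sigma_x^2 (1 - 2 sum E[1/l_i] + sum E[1/l_i^2])
           + sigma_w^2 sum E[1/l_i^2].

    ``moments``: optional (E_inv, E_inv2) arrays; default is the point-mass
    evaluation E[1/l] = 1/l. Because upper bounds on cross terms are
    subtracted, the expression can be negative; a warning is issued then.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam == 0):
        raise ZeroDivisionError("zero eigenvalue: filter is singular")
    if moments is None:
        e1, e2 = 1.0 / lam, 1.0 / lam**2
    else:
        e1, e2 = (np.asarray(m, dtype=float) for m in moments)
    bound = budget.sigma_x2 * (1.0 - 2.0 * e1.sum() + e2.sum()) + budget.sigma_w2 * e2.sum()
    if bound < 0:
        warnings.warn(
            "MSE bound is negative: subtracted cross-term upper bounds exceed "
            "the retained terms; the bound is vacuous for this spectrum",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(bound)


def eigen_error_budget(eps_P: float, sigma_m2: float, sigma_w2: float) -> float:
    """Upper bound |eps_P|^2 + sigma_m^2 + sigma_w^2 on ||lambda_hat - lambda_tr||^2."""
    if sigma_m2 < 0 or sigma_w2 < 0:
        raise ValueError("variances must be non-negative")
    return abs(eps_P) ** 2 + sigma_m2 + sigma_w2


def bit_success_probability(model: MeasurementModel, eigenvalue_estimates) -> float:
    """Per-bit correct-measurement probability p_b.

    p_b = (1/N) sum_i sum_j B_j prod_r cos^2(tau_r lambda_i / 2
                                             + (beta_r - m_r pi) / 2).
    Clipped to [0, 1] only for sub-1e-12 numerical excursions.
    """
    lam = np.atleast_1d(np.asarray(eigenvalue_estimates, dtype=float))
    if lam.size == 0:
        raise ValueError("eigenvalue_estimates must be nonempty")
    total = 0.0
    for lam_i in lam:
        acc = 0.0
        for B_j, tau_j, beta_j, m_j in zip(model.coefficients, model.tau, model.beta, model.m):
            prod = 1.0
            for tau_r, beta_r, m_r in zip(tau_j, beta_j, m_j):
                prod *= np.cos(tau_r * lam_i / 2.0 + (beta_r - m_r * pi) / 2.0) ** 2
            acc += B_j * prod
        total += acc
    p_b = total / lam.size
    if -1e-12 <= p_b < 0:
        p_b = 0.0
    if 1 < p_b <= 1 + 1e-12:
        p_b = 1.0
    return float(p_b)


def measurement_pmf(N_q: int, p_b: float) -> np.ndarray:
    """Normalized flip-count pmf: p(k) = C(N_q, k) p_b^(N_q-k) (1-p_b)^k over
    k = 0..N_q flipped bits (p_b the per-bit success probability)."""
    if not 0 <= p_b <= 1:
        raise ValueError("p_b must lie in [0, 1]")
    k = np.arange(N_q + 1)
    with np.errstate(invalid="ignore"):
        pmf = np.array(
            [comb(N_q, int(j)) * p_b ** (N_q - j) * (1 - p_b) ** j for j in k], dtype=float
        )
    return pmf


def measurement_pmf_printed(N_q: int, p_b: float) -> np.ndarray:
    """The literal printed form: (1/2^N_q) C(l, k) p_b^(l-k) (1-p_b)^k with
    l = 2^N_q, over k = 1..2^N_q - 1. Kept for comparison only — it does not
    normalize, which is why the binomial flip-count pmf is used downstream."""
    l = 2**N_q
    k = np.arange(1, l)
    return np.array(
        [comb(l, int(j)) * p_b ** (l - j) * (1 - p_b) ** j / l for j in k], dtype=float
    )


def measurement_variance(model: MeasurementModel, true_eigen_bitstrings, p_b: float) -> float:
    """Average squared decimal distance over bit-flip patterns.

    For each true eigenvalue bitstring d_i, every pattern of j flipped bits
    (j = 1..N_q) is weighted p_b^(N_q-j) (1-p_b)^j; distances are normalized
    by the string count, the pattern count 2^N_q - 1 and the register width.
    """
    if not 0 <= p_b <= 1:
        raise ValueError("p_b must lie in [0, 1]")
    strings = list(true_eigen_bitstrings)
    if not strings:
        raise ValueError("need at least one eigenvalue bitstring")
    N_q = model.N_q
    total = 0.0
    for s in strings:
        if len(s) != N_q:
            raise ValueError(f"bitstring {s!r} does not have length N_q={N_q}")
        d_i = int(s, 2)
        for j in range(1, N_q + 1):
            weight = p_b ** (N_q - j) * (1 - p_b) ** j
            for flips in combinations(range(N_q), j):
                mask = sum(1 << (N_q - 1 - pos) for pos in flips)
                d_flip = d_i ^ mask
                total += weight * (d_i - d_flip) ** 2
    return total / (len(strings) * (2**N_q - 1) * N_q)


def closed_form_I1(pert: EigenPerturbation, sigma_w: float) -> float:
    """Closed form of I1 = int_0^{u_max} (1 - x^2/(2 s^2)) / (K + x) dx."""
    if not sigma_w > 0:
        raise ValueError("sigma_w must be > 0")
    K, u = pert.K, pert.u_max
    s2 = sigma_w**2
    return (
        ((4 * s2 - 2 * K**2) * log(u + K) - u**2 + 2 * K * u) / (4 * s2)
        + K**2 * log(K) / (2 * s2)
        - log(K)
    )


def closed_form_I2(pert: EigenPerturbation, sigma_w: float) -> float:
    """Closed form of I2 = int_0^{u_max} (1 - x^2/(2 s^2)) / (K + x)^2 dx."""
    if not sigma_w > 0:
        raise ValueError("sigma_w must be > 0")
    K, u = pert.K, pert.u_max
    s2 = sigma_w**2
    first = ((2 * K * u + 2 * K**2) * log(u + K) - u**2 - K * u - 2 * s2 + K**2) / (
        2 * s2 * u + 2 * K * s2
    )
    second = (2 * s2 - 2 * K**2 * log(K) - K**2) / (2 * K * s2)
    return first + second


def expected_inverse_moments(
    pert: EigenPerturbation,
    model: MeasurementModel,
    sigma_w: float,
    M: int | None = None,
    p_b: float | None = None,
    lambda_m_scale: float | None = None,
) -> tuple[float, float]:
    """Approximate (E[1/lambda_hat], E[1/lambda_hat^2]).

    The measurement perturbation lambda_m ranges over flip-count realizations
    i = 0..min(M, N_q+1)-1 with lambda_m(i) = i * lambda_m_scale (default one
    register LSB, 2^-N_q), weighted by the flip-count pmf; each realization
    evaluates the closed-form truncated integrals with the 1/(sigma_w
    sqrt(2 pi)) Gaussian prefactor.
    """
    if not sigma_w > 0:
        raise ValueError("sigma_w must be > 0")
    if p_b is None:
        p_b = bit_success_probability(model, [pert.lambda_tr])
    pmf = measurement_pmf(model.N_q, p_b)
    if M is not None:
        if M < 1:
            raise ValueError("M must be >= 1")
        pmf = pmf[:M]
    scale = lambda_m_scale if lambda_m_scale is not None else 2.0 ** (-model.N_q)
    pref = 1.0 / (sigma_w * sqrt(2.0 * pi))
    e1 = e2 = 0.0
    for i, p_i in enumerate(pmf):
        if p_i == 0.0:
            continue
        pert_i = EigenPerturbation(
            lambda_tr=pert.lambda_tr,
            lambda_m=pert.lambda_m + i * scale,
            lambda_eps=pert.lambda_eps,
            u_max=pert.u_max,
        )
        e1 += p_i * closed_form_I1(pert_i, sigma_w)
        e2 += p_i * closed_form_I2(pert_i, sigma_w)
    return pref * e1, pref * e2


def perturbed_filter_apply(P: FilterMatrix, Sigma_e, y) -> np.ndarray:
    """Apply the perturbed inverse filter (P + U Sigma_e U^T)^{-1} y.

    Sigma_e is the diagonal eigenbasis error matrix (scalar, vector or
    diagonal matrix accepted). Uses P's eigendecomposition P = U S U^T, so
    the perturbed solve is U (S + Sigma_e)^{-1} U^T y.
    """
    samples = y.samples if isinstance(y, SignalVector) else np.asarray(y, dtype=float)
    if samples.size != P.N:
        raise ValueError("signal length does not match filter order")
    Se = np.asarray(Sigma_e, dtype=float)
    if Se.ndim == 2:
        if not np.allclose(Se, np.diag(np.diag(Se))):
            raise ValueError("Sigma_e must be diagonal")
        Se = np.diag(Se)
    elif Se.ndim == 0:
        Se = np.full(P.N, float(Se))
    if Se.size != P.N:
        raise ValueError("Sigma_e dimension mismatch")
    w, U = eigh(P.toarray())
    shifted = w + Se
    if np.any(shifted <= 0):
        raise np.linalg.LinAlgError("perturbed operator is not positive definite")
    return U @ ((U.T @ samples) / shifted)
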