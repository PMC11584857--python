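"""Truncated-Taylor Hamiltonian simulation: U_tilde ~ exp(-i P t).

The unitary is approximated by the first L terms of the Taylor series of the
matrix exponential. The truncation order is chosen from the standard tail
bound: with x = ||P t||_2, the remainder after L terms satisfies

    || sum_{l>=L} (-iPt)^l / l! ||  <=  x^L * e^x / L!

so the smallest L with x^L e^x / L! <= eps_P certifies spectral-norm error
eps_P. The operator is first rescaled to unit spectral norm (the filter
spectrum is mapped into (0, 1]); the scale factor is kept so eigenvalue
estimates downstream can be expressed in the original units.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, factorial

import numpy as np
from scipy.linalg import eigh

from .smoothing import FilterMatrix

__all__ = [
    "HamiltonianSpec",
    "UnitaryApprox",
    "scale_hamiltonian",
    "taylor_order_for",
    "truncated_exponential",
]

_MAX_TAYLOR_ORDER = 500


@dataclass(frozen=True)
class HamiltonianSpec:
    """A scaled Hermitian operator with evolution time and target precision."""

    P: np.ndarray
    t: float = 0.2
    eps_P: float = 0.01
    scale: float = 1.0
    L: int | None = None  # explicit truncation order; None = auto from eps_P

    def __post_init__(self):
        P = np.asarray(self.P, dtype=complex)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("P must be square")
        if not self.t > 0:
            raise ValueError("t must be > 0")
        if not (0 < self.eps_P < 1):
            raise ValueError("eps_P must be in (0, 1)")
        if self.L is not None and self.L < 1:
            raise ValueError("L must be >= 1")
        object.__setattr__(self, "P", P)


@dataclass(frozen=True)
class UnitaryApprox:
    """Dense approximate unitary with its certified spectral-norm error bound."""

    U_tilde: np.ndarray
    error_bound: float
    L_used: int
    t: float
    scale: float = 1.0


def scale_hamiltonian(P: FilterMatrix | np.ndarray) -> tuple[np.ndarray, float]:
    """Rescale a positive-definite operator to unit spectral norm.

    Returns (P / ||P||_2, ||P||_2). Eigenvalues of the scaled matrix are the
    originals divided by the scale factor.
    """
    A = P.toarray() if isinstance(P, FilterMatrix) else np.asarray(P, dtype=float)
    w = eigh(A, eigvals_only=True)
    norm = float(np.max(np.abs(w)))
    if norm == 0:
        raise ValueError("cannot scale the zero matrix")
    return A / norm, norm


def taylor_order_for(eps_P: float, x: float) -> int:
    """Smallest truncation order L with tail bound x^L * e^x / L! <= eps_P."""
    if not eps_P > 0:
        raise ValueError("eps_P must be > 0")
    if x < 0:
        raise ValueError("x must be >= 0")
    if x == 0:
        return 1
    ex = exp(x)
    term = 1.0  # x^L / L! at L = 0
    for L in range(1, _MAX_TAYLOR_ORDER + 1):
        term *= x / L
        if term * ex <= eps_P:
            return L
    raise ValueError("||Pt|| too large for a tractable Taylor order; rescale t")


def truncated_exponential(spec: HamiltonianSpec) -> UnitaryApprox:
    """Evaluate U_tilde = sum_{l=0}^{L-1} (-i P t)^l / l!.

    With auto-selected L the recorded error bound dominates the true
    spectral-norm distance to expm(-iPt).
    """
    P, t = spec.P, spec.t
    x = float(np.linalg.norm(P * t, ord=2))
    if x > 50:
        raise ValueError(f"||Pt||={x:.1f} is too large; rescale t before simulating")
    if spec.L is not None:
        L = spec.L
    else:
        L = taylor_order_for(spec.eps_P, x)
    A = -1j * P * t
    U = np.eye(P.shape[0], dtype=complex)
    term = np.eye(P.shape[0], dtype=complex)
    for l in range(1, L):
        term = term @ A / l
        U = U + term
    bound = x**L * exp(x) / factorial(L) if x > 0 else 0.0
    return UnitaryApprox(U_tilde=U, error_bound=float(bound), L_used=L, t=t, scale=spec.scale)
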