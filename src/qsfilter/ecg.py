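"""Synthetic ECG generation and the three canonical ECG noise classes.

The generator implements the standard three-ODE dynamical ECG model: a
trajectory circles the unit limit cycle in the (x, y) plane at the heart
rate's angular velocity, and the z coordinate is pushed by five Gaussian
events placed at fixed angles around the cycle — the P, Q, R, S and T waves:

    x' = alpha x - omega y,   y' = alpha y + omega x,  alpha = 1 - sqrt(x^2+y^2)
    z' = -sum_i a_i dtheta_i exp(-dtheta_i^2 / (2 b_i^2)) - (z - z0)

with dtheta_i = (theta - theta_i) wrapped to (-pi, pi]. Integration is
fixed-step RK4 at the sampling rate. Beat-to-beat variability modulates
omega per revolution from a seeded normal RR distribution. A cheaper
template-repetition mode tiles one analytically evaluated beat.

Noise generators return (noisy, noise) pairs so clean + noise == noisy holds
exactly: additive white Gaussian noise at a target SNR, powerline (AC)
interference at 50/60 Hz, and sub-0.5 Hz baseline wander with an optional
random-walk drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .smoothing import SignalVector

__all__ = [
    "ECGModelParams",
    "ECGRecord",
    "generate_ecg",
    "add_awgn",
    "add_powerline",
    "add_baseline_wander",
]

# (angle rad, amplitude, width rad) for P, Q, R, S, T on the unit cycle.
_PQRST = (
    (-np.pi / 3.0, 1.2, 0.25),
    (-np.pi / 12.0, -5.0, 0.1),
    (0.0, 30.0, 0.1),
    (np.pi / 12.0, -7.5, 0.1),
    (np.pi / 2.0, 0.75, 0.4),
)


@dataclass(frozen=True)
class ECGModelParams:
    """Dynamical-model parameters for one synthetic record."""

    hr_bpm: float = 60.0
    fs: float = 360.0
    duration_s: float = 10.0
    events: tuple = _PQRST
    hr_std: float = 1.0  # beat-to-beat heart-rate standard deviation (bpm)
    amplitude_mv: float = 1.1  # rescaled R-peak amplitude
    seed: int | None = None
    mode: str = "dynamical"  # or "template"

    def __post_init__(self):
        if self.fs <= 0 or self.duration_s <= 0 or self.hr_bpm <= 0:
            raise ValueError("fs, duration_s and hr_bpm must be positive")
        if self.fs * self.duration_s < 2:
            raise ValueError("degenerate record: fewer than 2 samples")
        angles = [e[0] for e in self.events]
        if any(b <= 0 for _, _, b in self.events):
            raise ValueError("event widths must be positive")
        if any(a2 <= a1 for a1, a2 in zip(angles, angles[1:])):
            raise ValueError("event angles must be strictly increasing")
        if self.mode not in ("dynamical", "template"):
            raise ValueError("mode must be 'dynamical' or 'template'")


@dataclass(frozen=True)
class ECGRecord:
    """Samples (mV), sampling rate, and ground-truth R-peak sample indices."""

    signal: SignalVector
    rpeaks: np.ndarray
    params: ECGModelParams | None = None

    @property
    def samples(self) -> np.ndarray:
        return self.signal.samples

    @property
    def fs(self) -> float:
        return self.signal.fs


def _wrap(angle: np.ndarray | float) -> np.ndarray | float:
    return np.mod(angle + np.pi, 2.0 * np.pi) - np.pi


def _z_template(theta: np.ndarray, events) -> np.ndarray:
    """Closed-form beat morphology: z(theta) = sum_i a_i exp(-dtheta^2/(2 b^2))
    scaled by the event amplitude — used by the template mode."""
    z = np.zeros_like(theta)
    for th_i, a_i, b_i in events:
        d = _wrap(theta - th_i)
        z += a_i * np.exp(-(d**2) / (2.0 * b_i**2))
    return z


def generate_ecg(params: ECGModelParams) -> ECGRecord:
    """Generate a quasi-periodic P-QRS-T trace with ground-truth R peaks."""
    n = int(round(params.fs * params.duration_s))
    dt = 1.0 / params.fs
    rng = np.random.default_rng(params.seed)

    # Per-beat angular velocity from the seeded RR distribution.
    mean_omega = 2.0 * np.pi * params.hr_bpm / 60.0
    n_beats = int(np.ceil(params.duration_s * params.hr_bpm / 60.0)) + 3
    hr_draws = np.clip(
        rng.normal(params.hr_bpm, params.hr_std, size=n_beats), params.hr_bpm * 0.5, None
    )
    omegas = 2.0 * np.pi * hr_draws / 60.0

    if params.mode == "template":
        # Analytic evaluation along the phase trajectory; no ODE solve.
        theta = np.empty(n)
        th = -np.pi
        beat = 0
        for i in range(n):
            theta[i] = _wrap(th)
            th += omegas[min(beat, n_beats - 1)] * dt
            if th >= np.pi:
                th -= 2.0 * np.pi
                beat += 1
        z = _z_template(theta, params.events)
    else:
        theta = np.empty(n)
        z = np.empty(n)
        state = np.array([-1.0, 0.0, 0.0])  # on the limit cycle at theta = -pi
        beat = 0
        crossed = False

        def deriv(s, omega):
            x, y, zz = s
            alpha = 1.0 - np.hypot(x, y)
            th = np.arctan2(y, x)
            dz = 0.0
            for th_i, a_i, b_i in params.events:
                d = _wrap(th - th_i)
                dz -= a_i * d * np.exp(-(d**2) / (2.0 * b_i**2))
            dz -= zz
            return np.array([alpha * x - omega * y, alpha * y + omega * x, dz])

        for i in range(n):
            theta[i] = np.arctan2(state[1], state[0])
            z[i] = state[2]
            omega = omegas[min(beat, n_beats - 1)]
            k1 = deriv(state, omega)
            k2 = deriv(state + 0.5 * dt * k1, omega)
            k3 = deriv(state + 0.5 * dt * k2, omega)
            k4 = deriv(state + dt * k3, omega)
            state = state + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            new_theta = np.arctan2(state[1], state[0])
            # count a beat when the phase wraps past +pi
            if theta[i] > np.pi / 2 and new_theta < -np.pi / 2:
                beat += 1

    # R peaks: local maxima of z nearest each upward crossing of theta = 0.
    rpeaks = []
    for i in range(1, n):
        if theta[i - 1] < 0.0 <= theta[i] and theta[i] - theta[i - 1] < np.pi:
            lo, hi = max(0, i - 3), min(n, i + 4)
            rpeaks.append(lo + int(np.argmax(z[lo:hi])))
    rpeaks = np.array(sorted(set(rpeaks)), dtype=int)

    span = np.max(np.abs(z)) if np.any(z) else 1.0
    samples = z / span * params.amplitude_mv if np.any(z) else z
    return ECGRecord(
        signal=SignalVector(samples=samples, fs=params.fs), rpeaks=rpeaks, params=params
    )


def add_awgn(x: np.ndarray, snr_db: float, seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Add white Gaussian noise at a target SNR (dB). Returns (noisy, noise)."""
    x = np.asarray(x, dtype=float)
    p_x = float(np.mean(x**2))
    if p_x == 0:
        raise ValueError("cannot set an SNR against a zero-power signal")
    sigma = np.sqrt(p_x / 10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, sigma, size=x.shape)
    return x + w, w


def add_powerline(
    x: np.ndarray,
    amp_mv: float,
    freq_hz: float = 50.0,
    phase: float = 0.0,
    fs: float = 360.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Add sinusoidal AC interference (50/60 Hz). Returns (noisy, noise)."""
    x = np.asarray(x, dtype=float)
    if not 0 < freq_hz < fs / 2.0:
        raise ValueError(f"powerline frequency {freq_hz} Hz aliases at fs={fs} Hz")
    t = np.arange(x.size) / fs
    w = amp_mv * np.sin(2.0 * np.pi * freq_hz * t + phase)
    return x + w, w


def add_baseline_wander(
    x: np.ndarray,
    amp_mv: float,
    freq_hz: float = 0.2,
    fs: float = 360.0,
    seed: int | None = None,
    drift_mv: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Add slow baseline wander: a sub-0.5 Hz sinusoid plus an optional seeded
    random-walk drift (low-pass filtered to stay in the wander band).
    Returns (noisy, noise)."""
    x = np.asarray(x, dtype=float)
    if not 0 < freq_hz < 0.5:
        raise ValueError("baseline wander frequency must lie in (0, 0.5) Hz")
    t = np.arange(x.size) / fs
    w = amp_mv * np.sin(2.0 * np.pi * freq_hz * t)
    if drift_mv > 0:
        rng = np.random.default_rng(seed)
        walk = np.cumsum(rng.normal(0.0, 1.0, size=x.size))
        # single-pole smoothing keeps the drift below the wander band
        alpha = min(1.0, 2.0 * np.pi * 0.1 / fs)
        smooth = np.empty_like(walk)
        acc = 0.0
        for i, v in enumerate(walk):
            acc += alpha * (v - acc)
            smooth[i] = acc
        smooth -= smooth.mean()
        peak = np.max(np.abs(smooth))
        if peak > 0:
            w = w + drift_mv * smooth / peak
    return x + w, w
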