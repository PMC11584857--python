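"""Classical denoising baselines (DWT, EMD) and the MSE/PSNR metrics.

MSE is the mean squared error (1/M) sum (x_hat - x)^2 and PSNR is
20 log10(MAX_x) - 10 log10(MSE). The wavelet baseline is a conventional
multilevel soft-threshold denoiser on PyWavelets; the EMD baseline sifts the
signal into intrinsic mode functions with cubic-spline envelopes and
reconstructs without the noisiest leading mode(s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.interpolate import CubicSpline

from .smoothing import SignalVector

__all__ = ["DenoiseResult", "mse", "psnr", "dwt_denoise", "emd_denoise", "emd_sift"]


@dataclass(frozen=True)
class DenoiseResult:
    """A denoised signal with the method tag and parameters that produced it."""

    x_hat: np.ndarray
    method: str
    params: dict
    mse: float | None = None
    psnr_db: float | None = None


def mse(x_hat, x) -> float:
    """Mean squared error between a reconstruction and its reference."""
    x_hat = np.asarray(x_hat, dtype=float)
    x = np.asarray(x, dtype=float)
    if x_hat.shape != x.shape:
        raise ValueError("length mismatch between reconstruction and reference")
    return float(np.mean((x_hat - x) ** 2))


def psnr(x_hat, x, max_x: float | None = None) -> float:
    """Peak signal-to-noise ratio 20 log10(MAX_x) - 10 log10(MSE), in dB.

    A perfect reconstruction (zero MSE) reports +inf.
    """
    err = mse(x_hat, x)
    if max_x is None:
        max_x = float(np.max(np.abs(np.asarray(x, dtype=float))))
    if err == 0:
        return float("inf")
    return 20.0 * np.log10(max_x) - 10.0 * np.log10(err)


def dwt_denoise(
    y,
    wavelet_name: str = "db4",
    levels: int = 4,
    threshold_rule: str = "universal",
    threshold: float | None = None,
) -> DenoiseResult:
    """Multilevel wavelet soft-threshold denoising.

    Detail coefficients at every level are soft-thresholded; the default
    universal threshold is sigma_hat * sqrt(2 ln N) with sigma_hat the median
    absolute deviation of the finest detail band divided by 0.6745.
    """
    y = np.asarray(y.samples if isinstance(y, SignalVector) else y, dtype=float)
    if y.size < 2**levels:
        raise ValueError(f"signal of length {y.size} too short for {levels} levels")
    try:
        wavelet = pywt.Wavelet(wavelet_name)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet {wavelet_name!r}") from exc
    coeffs = pywt.wavedec(y, wavelet, level=levels)
    if threshold is not None:
        thr = float(threshold)
    elif threshold_rule == "universal":
        sigma_hat = np.median(np.abs(coeffs[-1])) / 0.6745
        thr = sigma_hat * np.sqrt(2.0 * np.log(y.size))
    else:
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    if thr > 0:
        den = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]]
    else:
        den = coeffs
    x_hat = pywt.waverec(den, wavelet)[: y.size]
    return DenoiseResult(
        x_hat=x_hat,
        method="dwt",
        params={"wavelet": wavelet_name, "levels": levels, "threshold": thr},
    )


def _envelope(x: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through extrema, mirrored about the signal ends."""
    t = np.arange(n)
    ti = idx.astype(float)
    vi = x[idx]
    # reflect up to two extrema about each signal endpoint so the spline is
    # anchored beyond the data and end swings stay bounded
    m = min(2, ti.size)
    pre_t, pre_v = -ti[:m][::-1], vi[:m][::-1]
    post_t, post_v = 2 * (n - 1) - ti[-m:][::-1], vi[-m:][::-1]
    tt = np.concatenate([pre_t, ti, post_t])
    vv = np.concatenate([pre_v, vi, post_v])
    order = np.argsort(tt)
    tt, vv = tt[order], vv[order]
    keep = np.concatenate([[True], np.diff(tt) > 0])
    return CubicSpline(tt[keep], vv[keep])(t)


def _extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strict interior extrema (endpoints are never extrema: they are anchored
    by the mirrored envelope instead)."""
    d = np.diff(x)
    maxima = np.where((d[:-1] > 0) & (d[1:] < 0))[0] + 1
    minima = np.where((d[:-1] < 0) & (d[1:] > 0))[0] + 1
    return maxima, minima


def emd_sift(
    y,
    max_imfs: int = 8,
    sift_sd_stop: float = 0.3,
    max_sift_iters: int = 200,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Empirical mode decomposition: returns (IMF list, residual).

    Each IMF is extracted by iterative sifting — subtracting the mean of the
    upper/lower cubic-spline envelopes — until the Cauchy-type standard
    deviation criterion falls below ``sift_sd_stop``. IMFs plus the residual
    reconstruct the input exactly.
    """
    y = np.asarray(y.samples if isinstance(y, SignalVector) else y, dtype=float)
    if y.size < 16:
        raise ValueError("EMD needs at least 16 samples")
    residual = y.copy()
    imfs: list[np.ndarray] = []
    n = y.size
    for _ in range(max_imfs):
        maxima, minima = _extrema(residual)
        if maxima.size < 2 or minima.size < 2:
            break
        h = residual.copy()
        for _ in range(max_sift_iters):
            maxima, minima = _extrema(h)
            if maxima.size < 2 or minima.size < 2:
                break
            mean_env = 0.5 * (_envelope(h, maxima, n) + _envelope(h, minima, n))
            h_new = h - mean_env
            denom = np.sum(h**2)
            sd = np.sum((h - h_new) ** 2) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sift_sd_stop:
                break
        else:
            raise RuntimeError("sifting did not converge within the iteration budget")
        imfs.append(h)
        residual = residual - h
    return imfs, residual


def emd_denoise(
    y,
    max_imfs: int = 8,
    sift_sd_stop: float = 0.3,
    drop_imfs: int = 1,
) -> DenoiseResult:
    """EMD-based denoising: partial reconstruction without the leading (highest
    frequency, noisiest) IMF(s)."""
    y_arr = np.asarray(y.samples if isinstance(y, SignalVector) else y, dtype=float)
    imfs, residual = emd_sift(y_arr, max_imfs=max_imfs, sift_sd_stop=sift_sd_stop)
    kept = imfs[drop_imfs:] if drop_imfs < len(imfs) else []
    x_hat = np.sum(kept, axis=0) + residual if kept else residual.copy()
    return DenoiseResult(
        x_hat=x_hat,
        method="emd",
        params={
            "max_imfs": max_imfs,
            "sift_sd_stop": sift_sd_stop,
            "drop_imfs": drop_imfs,
            "n_imfs": len(imfs),
        },
    )
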