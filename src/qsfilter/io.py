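"""Signal and configuration I/O.

Supported signal formats: two-column CSV (time_s, amplitude_mV), single-column
plain text, and — when the optional ``wfdb`` package is installed — WFDB
records (MIT-BIH style). Flat key=value configs cover eta, order, mode, fs.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .smoothing import SignalVector

__all__ = ["read_signal", "write_signal", "read_config", "read_wfdb", "write_provenance"]


def read_signal(path: str | Path, fs: float | None = None) -> SignalVector:
    """Read a signal from two-column CSV (time, amplitude) or one-column text.

    For two-column input the sampling rate is inferred from the time column
    unless ``fs`` overrides it.
    """
    path = Path(path)
    rows = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in line.replace(",", " ").split() if p]
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                continue  # header line
    if not rows:
        raise ValueError(f"no numeric data found in {path}")
    arr = np.asarray(rows, dtype=float)
    if arr.shape[1] == 1:
        return SignalVector(samples=arr[:, 0], fs=fs or 1.0)
    t, amp = arr[:, 0], arr[:, 1]
    if fs is None:
        dt = np.diff(t)
        fs = 1.0 / float(np.median(dt)) if dt.size and np.all(dt > 0) else 1.0
    return SignalVector(samples=amp, fs=fs)


def write_signal(path: str | Path, signal: SignalVector, header: bool = True) -> None:
    """Write a signal as two-column CSV (time_s, amplitude_mV)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        if header:
            writer.writerow(["time_s", "amplitude_mV"])
        for i, v in enumerate(signal.samples):
            writer.writerow([f"{i / signal.fs:.9g}", f"{v:.12g}"])


def read_config(path: str | Path) -> dict:
    """Read a flat key = value (or key: value) config file.

    Recognized keys: eta, order, mode, fs (extra keys pass through verbatim).
    """
    out: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        for sep in ("=", ":"):
            if sep in line:
                key, val = (s.strip() for s in line.split(sep, 1))
                break
        else:
            continue
        val = val.strip("\"'")
        if key in ("eta", "fs"):
            out[key] = float(val)
        elif key == "order":
            out[key] = int(val)
        else:
            out[key] = val
    return out


def read_wfdb(record_name: str, channel: int = 0) -> SignalVector:
    """Read one channel of a WFDB record (requires the optional wfdb package)."""
    try:
        import wfdb  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package "
            "(pip install qsfilter[wfdb])"
        ) from exc
    rec = wfdb.rdrecord(record_name)
    return SignalVector(samples=np.asarray(rec.p_signal)[:, channel], fs=float(rec.fs))


def write_provenance(path: str | Path, config: dict) -> None:
    """Write a JSON provenance sidecar (full config, seed, package version)."""
    from . import __version__

    payload = {"package": "qsfilter", "version": __version__, **config}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
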