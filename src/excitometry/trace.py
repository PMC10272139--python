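"""Core signal container, filters and file I/O.

A :class:`Trace` is a uniformly sampled scalar signal (extracellular voltage
in µV, membrane potential in mV, or holding current in pA).  The two filters
used throughout the pipeline live here: a unit-area Gaussian smoother that
suppresses high-frequency noise before spike detection, and a zero-phase
4th-order type-I Chebyshev low-pass that isolates the local-field-potential
band.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
from scipy import ndimage, signal

__all__ = [
    "Unit",
    "Trace",
    "FilterSpec",
    "gaussian_smooth",
    "chebyshev_lowpass",
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
]


class Unit(str, Enum):
    """Physical unit of a trace."""

    uV = "uV"
    mV = "mV"
    pA = "pA"


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled scalar signal.

    Sample ``i`` sits at time ``t0 + i / fs`` (sample-centred convention,
    0-based indices, times in seconds).
    """

    samples: np.ndarray
    fs: float
    unit: Unit = Unit.uV
    t0: float = 0.0
    channel_id: Optional[str] = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "unit", Unit(self.unit))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Time of every sample in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def index_at(self, t_s: float) -> int:
        """Nearest sample index for a time in seconds (clipped to range)."""
        i = int(round((t_s - self.t0) * self.fs))
        return min(max(i, 0), self.samples.size - 1)

    def with_samples(self, samples: np.ndarray) -> "Trace":
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


class FilterKind(str, Enum):
    gaussian_smooth = "gaussian_smooth"
    chebyshev_lowpass = "chebyshev_lowpass"


@dataclass(frozen=True)
class FilterSpec:
    """Declarative description of one of the two supported filters.

    Exactly the fields of the chosen kind must be set: ``sigma_ms`` for
    ``gaussian_smooth``; ``cutoff_hz``, ``order`` and ``ripple_db`` for
    ``chebyshev_lowpass``.
    """

    kind: FilterKind
    sigma_ms: Optional[float] = None
    cutoff_hz: Optional[float] = None
    order: Optional[int] = None
    ripple_db: Optional[float] = None

    def __post_init__(self) -> None:
        kind = FilterKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is FilterKind.gaussian_smooth:
            if self.sigma_ms is None or not self.sigma_ms > 0:
                raise ValueError("gaussian_smooth requires sigma_ms > 0")
            if any(v is not None for v in (self.cutoff_hz, self.order, self.ripple_db)):
                raise ValueError("gaussian_smooth takes only sigma_ms")
        else:
            if self.cutoff_hz is None or not self.cutoff_hz > 0:
                raise ValueError("chebyshev_lowpass requires cutoff_hz > 0")
            if self.order is None or self.order < 1:
                raise ValueError("chebyshev_lowpass requires order >= 1")
            if self.ripple_db is None or not self.ripple_db > 0:
                raise ValueError("chebyshev_lowpass requires ripple_db > 0")
            if self.sigma_ms is not None:
                raise ValueError("chebyshev_lowpass does not take sigma_ms")

    def apply(self, trace: Trace) -> Trace:
        if self.kind is FilterKind.gaussian_smooth:
            return gaussian_smooth(trace, self.sigma_ms)
        return chebyshev_lowpass(trace, self.cutoff_hz, self.order, self.ripple_db)


def gaussian_smooth(trace: Trace, sigma_ms: float = 1.5) -> Trace:
    """Smooth a trace with a unit-area Gaussian kernel.

    The kernel is truncated at ±4σ and the trace is reflect-padded at the
    edges, so a constant trace passes through unchanged (DC gain exactly 1).

    Parameters
    ----------
    trace
        Input signal.
    sigma_ms
        Kernel standard deviation in milliseconds (default 1.5 ms, the value
        used to suppress high-frequency noise before spike detection).
    """
    if not sigma_ms > 0:
        raise ValueError(f"sigma_ms must be positive, got {sigma_ms}")
    if trace.duration_s * 1000.0 < 6.0 * sigma_ms:
        raise ValueError(
            f"trace of {trace.duration_s * 1000:.3f} ms is shorter than "
            f"6 x sigma ({6 * sigma_ms:.3f} ms); kernel would dominate"
        )
    sigma_samples = sigma_ms / 1000.0 * trace.fs
    out = ndimage.gaussian_filter1d(
        trace.samples, sigma_samples, mode="reflect", truncate=4.0
    )
    return trace.with_samples(out)


def chebyshev_lowpass(
    trace: Trace,
    cutoff_hz: float = 150.0,
    order: int = 4,
    ripple_db: float = 0.5,
) -> Trace:
    """Zero-phase type-I Chebyshev low-pass filter.

    Applied forward–backward (:func:`scipy.signal.filtfilt`) so event timing
    is preserved; defaults (150 Hz, 4th order) isolate the LFP band.  The
    passband ripple defaults to 0.5 dB.
    """
    if not 0 < cutoff_hz < trace.fs / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={trace.fs / 2} Hz)"
        )
    b, a = signal.cheby1(order, ripple_db, cutoff_hz, btype="low", fs=trace.fs)
    out = signal.filtfilt(b, a, trace.samples)
    return trace.with_samples(out)


# ---------------------------------------------------------------------------
# I/O
#
# HDF5 layout: dataset /trace (float64) with attributes fs_hz, unit, t0_s and
# (optionally) channel_id.  Text dialect: "# key=value" metadata lines then
# one sample per line.

_TEXT_META = re.compile(r"^#\s*(\w+)\s*=\s*(.+?)\s*$")


def write_trace(path: str | Path, trace: Trace, format: str | None = None) -> None:
    """Write a trace as HDF5 (``.h5``/``.hdf5``) or delimited text."""
    path = Path(path)
    fmt = format or ("hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "text")
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("trace", data=trace.samples, dtype="float64")
            ds.attrs["fs_hz"] = float(trace.fs)
            ds.attrs["unit"] = trace.unit.value
            ds.attrs["t0_s"] = float(trace.t0)
            if trace.channel_id is not None:
                ds.attrs["channel_id"] = str(trace.channel_id)
    elif fmt == "text":
        with open(path, "w") as f:
            f.write(f"# fs_hz={trace.fs!r}\n")
            f.write(f"# unit={trace.unit.value}\n")
            f.write(f"# t0_s={trace.t0!r}\n")
            if trace.channel_id is not None:
                f.write(f"# channel_id={trace.channel_id}\n")
            for v in trace.samples:
                f.write(f"{v:.17g}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_trace(path: str | Path, format: str | None = None) -> Trace:
    """Read a trace written by :func:`write_trace`.

    Raises if the sampling-rate metadata is missing or a text row is ragged.
    """
    path = Path(path)
    fmt = format or ("hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "text")
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "trace" not in f:
                raise ValueError(f"{path}: no /trace dataset")
            ds = f["trace"]
            if "fs_hz" not in ds.attrs:
                raise ValueError(f"{path}: missing fs_hz attribute")
            return Trace(
                samples=ds[()],
                fs=float(ds.attrs["fs_hz"]),
                unit=Unit(ds.attrs.get("unit", "uV")),
                t0=float(ds.attrs.get("t0_s", 0.0)),
                channel_id=(
                    str(ds.attrs["channel_id"]) if "channel_id" in ds.attrs else None
                ),
            )
    if fmt != "text":
        raise ValueError(f"unknown format {fmt!r}")
    meta: dict[str, str] = {}
    values: list[float] = []
    with open(path) as f:
        for lineno, line in enumerate(f, 1):
            line = line.strip()
            if not line:
                continue
            m = _TEXT_META.match(line)
            if m:
                meta[m.group(1)] = m.group(2)
                continue
            parts = line.split()
            if len(parts) != 1:
                raise ValueError(f"{path}:{lineno}: ragged row {line!r}")
            values.append(float(parts[0]))
    if "fs_hz" not in meta:
        raise ValueError(f"{path}: missing '# fs_hz=' metadata line")
    return Trace(
        samples=np.array(values),
        fs=float(meta["fs_hz"]),
        unit=Unit(meta.get("unit", "uV")),
        t0=float(meta.get("t0_s", 0.0)),
        channel_id=meta.get("channel_id"),
    )


def write_events(path: str | Path, table: pd.DataFrame) -> None:
    """Write an event table (spikes, bursts, LFP events, APs) as CSV."""
    table.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
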