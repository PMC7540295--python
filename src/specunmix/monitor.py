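"""Conversion time series: assembly, isosbestic QC and equilibrium detection.

Unmixing each quenched sample of a reaction yields one degree of
conversion; ordered by sampling time these form the reaction progress
curve.  Because the total analyte absorbance at the isosbestic point is
constant throughout a reaction, the raw (un-normalized) isosbestic trace
doubles as a QC channel: drift there means sampling-volume or
instrument trouble, not chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .spectra import SpecUnmixError, Spectrum
from .unmix import UnmixingResult

__all__ = [
    "ConversionSeries",
    "IsosbesticCheck",
    "build_conversion_series",
    "check_isosbestic_constancy",
    "detect_equilibrium",
    "plot_conversion_series",
]

#: Trailing-window size (points) for plateau detection.
EQUILIBRIUM_WINDOW = 5
#: Absolute slope (mole fraction per second) below which a window is flat.
EQUILIBRIUM_SLOPE_TOL = 1e-4
#: Relative isosbestic drift above which the series is warned.
ISOSBESTIC_DRIFT_TOL = 0.10


@dataclass(frozen=True)
class ConversionSeries:
    """Time-ordered conversions with per-point QC flags.

    ``equilibrium_conversion`` and ``time_to_equilibrium_s`` are present
    only together, after :func:`detect_equilibrium` found a plateau.
    """

    times_s: np.ndarray
    conversions: np.ndarray
    flags: tuple[frozenset[str], ...]
    equilibrium_conversion: Optional[float] = None
    time_to_equilibrium_s: Optional[float] = None

    def __post_init__(self):
        t = np.asarray(self.times_s, dtype=float)
        x = np.asarray(self.conversions, dtype=float)
        if t.size != x.size:
            raise SpecUnmixError("times and conversions must have equal length")
        if not np.all(np.diff(t) > 0):
            raise SpecUnmixError("series times must be strictly increasing")
        if np.any((x < -1e-12) | (x > 1 + 1e-12)):
            raise SpecUnmixError("conversions must lie in [0, 1]")
        if (self.equilibrium_conversion is None) != (
            self.time_to_equilibrium_s is None
        ):
            raise SpecUnmixError(
                "equilibrium_conversion and time_to_equilibrium_s must be "
                "present together"
            )
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "conversions", x)
        object.__setattr__(
            self, "flags", tuple(frozenset(f) for f in self.flags)
        )
        if len(self.flags) != t.size:
            raise SpecUnmixError("one flag set per point required")

    def __len__(self) -> int:
        return self.times_s.size

    def unflagged_mask(self) -> np.ndarray:
        return np.array([not f for f in self.flags], dtype=bool)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "conversion": self.conversions,
                "flags": [";".join(sorted(f)) for f in self.flags],
            }
        )


def build_conversion_series(results: Sequence[UnmixingResult]) -> ConversionSeries:
    """Assemble unmixing results (each carrying a time) into a series.

    Results are sorted by time; duplicate times are an error; per-sample
    flags are kept on their points (flagged points are retained but
    marked — exclusion decisions happen downstream).
    """
    results = list(results)
    if len(results) < 2:
        raise SpecUnmixError("a conversion series needs at least 2 points")
    if any(r.time_s is None for r in results):
        missing = [r.label for r in results if r.time_s is None]
        raise SpecUnmixError(f"results without sampling time: {missing}")
    ordered = sorted(results, key=lambda r: r.time_s)
    times = np.array([r.time_s for r in ordered], dtype=float)
    if np.any(np.diff(times) == 0):
        raise SpecUnmixError("duplicate sampling times in series")
    return ConversionSeries(
        times_s=times,
        conversions=np.array([r.conversion for r in ordered]),
        flags=tuple(frozenset(r.flags) for r in ordered),
    )


@dataclass(frozen=True)
class IsosbesticCheck:
    max_relative_deviation: float
    warn: bool
    tolerance: float = ISOSBESTIC_DRIFT_TOL


def check_isosbestic_constancy(
    raw_samples: Iterable[Spectrum],
    iso_nm: float,
    tolerance: float = ISOSBESTIC_DRIFT_TOL,
) -> IsosbesticCheck:
    """Relative spread of the raw isosbestic absorbance across a series.

    deviation = (max - min) / median of A(iso).  At constant sampling
    volume this is pure noise; a pipetting error sticks out as a step.
    Order-invariant by construction.  Raises when the median signal is
    not positive (nothing to normalize against).
    """
    values = np.array([s.at(iso_nm) for s in raw_samples], dtype=float)
    if values.size < 2:
        raise SpecUnmixError("isosbestic constancy needs >= 2 spectra")
    med = float(np.median(values))
    if med <= 0:
        raise SpecUnmixError(
            f"median isosbestic absorbance is {med:.4f} AU (<= 0)"
        )
    dev = float((values.max() - values.min()) / med)
    return IsosbesticCheck(
        max_relative_deviation=dev, warn=dev > tolerance, tolerance=tolerance
    )


def _window_slope(t: np.ndarray, x: np.ndarray) -> float:
    """Ordinary least-squares slope of x against t."""
    t = t - t.mean()
    denom = float(t @ t)
    if denom == 0:
        return 0.0
    return float(t @ (x - x.mean()) / denom)


def detect_equilibrium(
    series: ConversionSeries,
    window: int = EQUILIBRIUM_WINDOW,
    slope_tol: float = EQUILIBRIUM_SLOPE_TOL,
) -> tuple[Optional[float], Optional[float]]:
    """Find the plateau of a progress curve, if any.

    The plateau starts at the earliest time from which every trailing
    window of ``window`` consecutive (unflagged) points has an absolute
    fitted slope below ``slope_tol`` (mole fraction per second).  The
    equilibrium conversion is the mean over the plateau.  Returns
    ``(None, None)`` when the curve never flattens.  Flagged points are
    excluded from slope fits and the plateau mean but remain in the
    series.
    """
    if window < 3:
        raise SpecUnmixError("plateau window must span at least 3 points")
    mask = series.unflagged_mask()
    t = series.times_s[mask]
    x = series.conversions[mask]
    n = t.size
    if n < window:
        return None, None
    slopes = np.array(
        [_window_slope(t[i : i + window], x[i : i + window]) for i in range(n - window + 1)]
    )
    flat = np.abs(slopes) < slope_tol
    # earliest window index from which all later windows are flat
    start_idx = None
    for i in range(flat.size):
        if flat[i:].all():
            start_idx = i
            break
    if start_idx is None:
        return None, None
    t_eq = float(t[start_idx])
    x_eq = float(np.mean(x[start_idx:]))
    return t_eq, x_eq


def with_equilibrium(
    series: ConversionSeries,
    window: int = EQUILIBRIUM_WINDOW,
    slope_tol: float = EQUILIBRIUM_SLOPE_TOL,
) -> ConversionSeries:
    """Series copy with the equilibrium summary filled in (when found)."""
    t_eq, x_eq = detect_equilibrium(series, window=window, slope_tol=slope_tol)
    return replace(
        series, time_to_equilibrium_s=t_eq, equilibrium_conversion=x_eq
    )


def plot_conversion_series(
    series: ConversionSeries,
    iso_trace: Optional[tuple[np.ndarray, np.ndarray]] = None,
    path=None,
):
    """Two-panel progress plot: conversion vs time, plus the raw isosbestic trace.

    Flagged points are drawn as open markers.  ``iso_trace`` is an
    optional ``(times_s, A_iso)`` pair from the un-normalized spectra.
    Returns the matplotlib Figure; saves to ``path`` when given.
    """
    from matplotlib.figure import Figure

    n_panels = 2 if iso_trace is not None else 1
    fig = Figure(figsize=(8, 3.2), dpi=110)
    axes = fig.subplots(1, n_panels, squeeze=False)[0]

    ax = axes[0]
    good = series.unflagged_mask()
    ax.plot(series.times_s[good], series.conversions[good], "o-", ms=4, label="conversion")
    if (~good).any():
        ax.plot(
            series.times_s[~good],
            series.conversions[~good],
            "o",
            mfc="none",
            ms=6,
            label="flagged",
        )
    if series.equilibrium_conversion is not None:
        ax.axhline(series.equilibrium_conversion, ls="--", lw=0.8, color="grey")
        ax.axvline(series.time_to_equilibrium_s, ls=":", lw=0.8, color="grey")
    ax.set_xlabel("time [s]")
    ax.set_ylabel("conversion")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="best", fontsize=8)

    if iso_trace is not None:
        ax2 = axes[1]
        ax2.plot(iso_trace[0], iso_trace[1], "s-", ms=4, color="tab:orange")
        ax2.set_xlabel("time [s]")
        ax2.set_ylabel("A(isosbestic) [AU]")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
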