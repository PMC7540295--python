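"""Preprocessing of experimental spectra ahead of unmixing.

The fixed order of operations is: subtract blanks, estimate and flag the
baseline, restrict to the fit range, normalize to the isosbestic point.
Normalization must see background-free absorbance at the isosbestic
point, which is why it comes last.  Samples whose baseline is shifted by
more than the threshold (default 0.10 AU) are flagged for exclusion —
the remedy in the underlying assay is remeasurement in a different well,
not numerical correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .spectra import GridError, ReferencePair, SpecUnmixError, Spectrum

__all__ = [
    "PreprocessConfig",
    "PreprocessReport",
    "SignalToBackground",
    "subtract_background",
    "estimate_baseline_offset",
    "flag_baseline_shift",
    "normalize_to_isosbestic",
    "restrict_to_fit_range",
    "signal_to_background",
    "preprocess_sample",
]

#: Baseline shifts above this flat offset (AU) flag a sample for exclusion.
BASELINE_THRESHOLD_AU = 0.10
#: Isosbestic absorbance below this floor (AU) is too close to the noise
#: to normalize against (at sigma ~ 0.002 AU this caps the induced
#: relative error at ~4 %).
NOISE_FLOOR_AU = 0.05
#: Minimum signal-to-background ratio for a trustworthy fit (the 20 % rule).
SNR_THRESHOLD = 5.0
#: The analyte-free baseline window starts this far past the spectral extension.
BASELINE_WINDOW_GAP_NM = 5.0
#: ... and ends here (upper end of the standard acquisition range).
BASELINE_WINDOW_END_NM = 350.0


@dataclass(frozen=True)
class PreprocessConfig:
    """Thresholds and switches for the preprocessing pipeline."""

    baseline_threshold_au: float = BASELINE_THRESHOLD_AU
    noise_floor_au: float = NOISE_FLOOR_AU
    snr_threshold: float = SNR_THRESHOLD
    fit_range_nm: Optional[tuple[float, float]] = None
    normalize: bool = True

    def __post_init__(self):
        for name in ("baseline_threshold_au", "noise_floor_au", "snr_threshold"):
            if not getattr(self, name) > 0:
                raise SpecUnmixError(f"{name} must be > 0")


@dataclass
class PreprocessReport:
    """What preprocessing did to one sample."""

    baseline_offset_au: Optional[float] = None
    baseline_flag: bool = False
    signal_to_background: Optional[float] = None
    applied_blanks: list[str] = field(default_factory=list)
    normalization_scale: Optional[float] = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.normalization_scale is not None and not self.normalization_scale > 0:
            raise SpecUnmixError("normalization_scale must be > 0 when present")


def subtract_background(sample: Spectrum, blank: Spectrum, kind: str = "blank") -> Spectrum:
    """Pointwise subtraction of a blank spectrum from a sample.

    The blank is interpolated onto the sample grid; it must cover the
    sample range (extrapolation is an error).  The applied blank kind is
    recorded in the result's metadata.  Reference spectra are never
    re-corrected here — they are already background-corrected.
    """
    blank_on_grid = blank.interp_to(sample.wavelengths_nm)
    applied = list(sample.meta.get("applied_blanks", [])) + [kind]
    return sample.with_absorbance(
        sample.absorbance_au - blank_on_grid.absorbance_au,
        applied_blanks=applied,
    )


def estimate_baseline_offset(sample: Spectrum, pair: ReferencePair) -> float:
    """Mean absorbance over the analyte-free window past the spectral extension.

    Beyond the pair's spectral extension neither analyte absorbs, so any
    signal in (extension + 5 nm .. 350 nm) is background.  Requires the
    sample grid to reach at least 5 points into that window.
    """
    lo = pair.min_extension_nm + BASELINE_WINDOW_GAP_NM
    hi = min(BASELINE_WINDOW_END_NM, sample.range_nm[1])
    wl = sample.wavelengths_nm
    mask = (wl >= lo) & (wl <= hi)
    if int(mask.sum()) < 5:
        raise SpecUnmixError(
            "cannot estimate baseline: analyte-free window "
            f"[{lo}, {hi}] nm has fewer than 5 points on the sample grid"
        )
    return float(np.mean(sample.absorbance_au[mask]))


def flag_baseline_shift(offset_au: float, threshold_au: float = BASELINE_THRESHOLD_AU) -> bool:
    """True iff the flat baseline offset strictly exceeds the threshold."""
    return offset_au > threshold_au


def normalize_to_isosbestic(
    sample: Spectrum, iso_nm: float, floor_au: float = NOISE_FLOOR_AU
) -> tuple[Spectrum, float]:
    """Scale a spectrum so its absorbance at the isosbestic point is 1.

    Returns the normalized spectrum and the applied scale ``1 / A(iso)``.
    Normalization makes the fit insensitive to sampling-volume and
    pipetting variation, because the total analyte signal at the
    isosbestic point is constant throughout the reaction.

    Raises when ``A(iso) <= floor_au``: an isosbestic signal that close
    to the noise floor cannot anchor a normalization — re-sample with a
    smaller dilution instead.
    """
    a_iso = sample.at(iso_nm)
    if a_iso <= floor_au:
        raise SpecUnmixError(
            f"isosbestic signal below noise floor (A({iso_nm} nm) = {a_iso:.4f} "
            f"<= {floor_au} AU); re-sample with less dilution"
        )
    scale = 1.0 / a_iso
    normalized = sample.with_absorbance(
        sample.absorbance_au * scale, normalization_scale=scale
    )
    return normalized, scale


def restrict_to_fit_range(sample: Spectrum, range_nm: Sequence[float]) -> Spectrum:
    """Subset a spectrum to the closed fitting window ``[lo, hi]`` nm.

    Restricting to an information-rich window (e.g. 265-295 nm for
    uridine) rescues fits when solvent background swamps the short-
    wavelength region.
    """
    lo, hi = float(range_nm[0]), float(range_nm[1])
    if not lo < hi:
        raise SpecUnmixError(f"empty fit window [{lo}, {hi}]")
    return sample.restrict(lo, hi)


@dataclass(frozen=True)
class SignalToBackground:
    ratio: float
    passed: bool
    threshold: float = SNR_THRESHOLD


def signal_to_background(
    sample: Spectrum,
    background: Spectrum,
    range_nm: Optional[Sequence[float]] = None,
    threshold: float = SNR_THRESHOLD,
) -> SignalToBackground:
    """Peak analyte signal over peak background within a window.

    The method is recommended only while background stays below 20 % of
    the analyte signal, i.e. this ratio should remain above 5.  An
    identically zero background reports an infinite ratio (pass).
    """
    bg = background.interp_to(sample.wavelengths_nm)
    s, b = sample, bg
    if range_nm is not None:
        s = restrict_to_fit_range(s, range_nm)
        b = restrict_to_fit_range(b, range_nm)
    peak_signal = float(np.max(np.abs(s.absorbance_au)))
    peak_bg = float(np.max(np.abs(b.absorbance_au)))
    if peak_bg == 0.0:
        return SignalToBackground(ratio=float("inf"), passed=True, threshold=threshold)
    ratio = peak_signal / peak_bg
    return SignalToBackground(ratio=ratio, passed=ratio > threshold, threshold=threshold)


def preprocess_sample(
    sample: Spectrum,
    pair: ReferencePair,
    blanks: Optional[Mapping[str, Spectrum]] = None,
    config: PreprocessConfig = PreprocessConfig(),
) -> tuple[Spectrum, PreprocessReport]:
    """Run the full preprocessing pipeline on one sample.

    Order: subtract blanks -> estimate/flag baseline -> restrict to the
    fit range -> normalize to the isosbestic point.  The returned report
    records the estimated offset, the applied blanks, the S/N ratio
    against the summed blanks and the normalization scale.  A flagged
    baseline does not abort; the flag marks the sample for exclusion.
    """
    report = PreprocessReport()
    work = sample
    total_blank = None
    for kind, blank in (blanks or {}).items():
        work = subtract_background(work, blank, kind=kind)
        report.applied_blanks.append(kind)
        if total_blank is None:
            total_blank = blank.interp_to(sample.wavelengths_nm).absorbance_au.copy()
        else:
            total_blank = total_blank + blank.interp_to(sample.wavelengths_nm).absorbance_au

    try:
        report.baseline_offset_au = estimate_baseline_offset(work, pair)
    except SpecUnmixError:
        report.baseline_offset_au = None  # grid too short; leave unflagged
    if report.baseline_offset_au is not None:
        report.baseline_flag = flag_baseline_shift(
            report.baseline_offset_au, config.baseline_threshold_au
        )
        if report.baseline_flag:
            report.flags.add("baseline")

    fit_range = config.fit_range_nm or pair.fit_range_nm
    if total_blank is not None:
        snb = signal_to_background(
            work,
            Spectrum(sample.wavelengths_nm, total_blank),
            range_nm=fit_range,
            threshold=config.snr_threshold,
        )
        report.signal_to_background = snb.ratio
        if not snb.passed:
            report.flags.add("low_snr")

    work = restrict_to_fit_range(work, fit_range)
    if config.normalize and pair.active_isosbestic_nm is not None:
        work, scale = normalize_to_isosbestic(
            work, pair.active_isosbestic_nm, config.noise_floor_au
        )
        report.normalization_scale = scale
    return work, report
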