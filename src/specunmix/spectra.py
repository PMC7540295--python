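"""Core domain objects: absorbance spectra, reference spectra and reference pairs.

A :class:`Spectrum` is a UV absorbance trace on a strictly increasing
wavelength grid (plate readers in this workflow scan 250-350 nm in 1 nm
steps).  A :class:`ReferenceSpectrum` is the alkaline spectrum of a pure
nucleoside or nucleobase together with its spectral metadata (lambda_max,
isosbestic point(s) of base cleavage, spectral extension, quench medium).
A :class:`ReferencePair` couples a nucleoside with its nucleobase on a
common grid, normalized to the active isosbestic point, and carries the
wavelength window used for fitting.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "SpecUnmixError",
    "GridError",
    "MetadataError",
    "Spectrum",
    "ReferenceSpectrum",
    "ReferencePair",
    "PlateSpectraSet",
    "BLANK_KINDS",
    "build_reference_pair",
    "find_crossings",
]

#: Fixed vocabulary of blank spectra the pipeline knows how to subtract.
BLANK_KINDS = ("plate", "protein", "solvent", "buffer")


class SpecUnmixError(ValueError):
    """Base class for all domain errors raised by this package."""


class GridError(SpecUnmixError):
    """Wavelength-grid problem: non-increasing, mismatched or out of range."""


class MetadataError(SpecUnmixError):
    """Reference metadata missing or violating an invariant."""


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise SpecUnmixError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class Spectrum:
    """An absorbance spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths_nm : array-like
        Strictly increasing wavelengths in nm (>= 2 points).
    absorbance_au : array-like
        Absorbance in AU at each wavelength.  Negative values are allowed
        (they arise legitimately after background subtraction) but every
        value must be finite.
    label : str
        Free-text sample identifier.
    well : str, optional
        Plate well id, e.g. ``"B7"``.
    time_s : float, optional
        Sampling time in seconds since reaction start.
    dilution_factor : float, optional
        Dilution applied during quenching (> 0).
    meta : mapping
        Free-form provenance (applied blanks, normalization scale, ...).
    """

    wavelengths_nm: np.ndarray
    absorbance_au: np.ndarray
    label: str = ""
    well: Optional[str] = None
    time_s: Optional[float] = None
    dilution_factor: Optional[float] = None
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self):
        wl = _as_float_array(self.wavelengths_nm, "wavelengths_nm")
        ab = _as_float_array(self.absorbance_au, "absorbance_au")
        if wl.size < 2:
            raise GridError("a spectrum needs at least 2 points")
        if wl.size != ab.size:
            raise GridError(
                f"wavelength/absorbance length mismatch ({wl.size} vs {ab.size})"
            )
        if not np.all(np.diff(wl) > 0):
            raise GridError("wavelengths not strictly increasing")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(ab)):
            raise SpecUnmixError("spectrum contains non-finite values")
        if self.dilution_factor is not None and not self.dilution_factor > 0:
            raise SpecUnmixError("dilution_factor must be positive")
        wl.flags.writeable = False
        ab.flags.writeable = False
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "absorbance_au", ab)
        object.__setattr__(self, "meta", dict(self.meta))

    # -- basic queries -------------------------------------------------

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    @property
    def range_nm(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def at(self, nm: float) -> float:
        """Absorbance at ``nm``, linearly interpolated on the grid.

        Raises :class:`GridError` outside the grid: interpolation between
        1 nm samples of a smooth band is safe, extrapolation invents data.
        """
        lo, hi = self.range_nm
        if not (lo <= nm <= hi):
            raise GridError(
                f"{nm} nm outside spectrum range [{lo}, {hi}] (no extrapolation)"
            )
        return float(np.interp(nm, self.wavelengths_nm, self.absorbance_au))

    def same_grid(self, other: "Spectrum") -> bool:
        return (
            self.wavelengths_nm.size == other.wavelengths_nm.size
            and np.array_equal(self.wavelengths_nm, other.wavelengths_nm)
        )

    # -- derived spectra -----------------------------------------------

    def replace(self, **updates) -> "Spectrum":
        """Copy with replaced fields (dataclasses.replace that unlocks arrays)."""
        return dataclasses.replace(self, **updates)

    def with_absorbance(self, absorbance, **meta_updates) -> "Spectrum":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return self.replace(absorbance_au=np.asarray(absorbance, float), meta=meta)

    def interp_to(self, grid_nm) -> "Spectrum":
        """Resample onto ``grid_nm`` by linear interpolation (no extrapolation)."""
        grid = _as_float_array(grid_nm, "grid_nm")
        lo, hi = self.range_nm
        if grid[0] < lo or grid[-1] > hi:
            raise GridError(
                f"target grid [{grid[0]}, {grid[-1]}] exceeds spectrum range "
                f"[{lo}, {hi}]; extrapolation is not permitted"
            )
        ab = np.interp(grid, self.wavelengths_nm, self.absorbance_au)
        return self.replace(wavelengths_nm=grid, absorbance_au=ab)

    def restrict(self, lo_nm: float, hi_nm: float) -> "Spectrum":
        """Subset to wavelengths in the closed interval [lo_nm, hi_nm]."""
        mask = (self.wavelengths_nm >= lo_nm) & (self.wavelengths_nm <= hi_nm)
        if int(mask.sum()) < 2:
            raise GridError(
                f"restriction to [{lo_nm}, {hi_nm}] nm leaves fewer than 2 points"
            )
        return self.replace(
            wavelengths_nm=self.wavelengths_nm[mask],
            absorbance_au=self.absorbance_au[mask],
        )

    def scaled(self, factor: float) -> "Spectrum":
        return self.with_absorbance(self.absorbance_au * float(factor))


@dataclass(frozen=True)
class ReferenceSpectrum:
    """Alkaline spectrum of a pure compound plus its spectral metadata.

    ``role`` is ``"nucleoside"`` or ``"nucleobase"``.  ``ph_condition``
    records the quench/analysis medium (e.g. ``"100 mM NaOH, pH 13"``),
    ``isosbestic_points_nm`` lists 0, 1 or 2 isosbestic points of base
    cleavage, and ``spectral_extension_nm`` is the wavelength beyond which
    the compound pair no longer absorbs appreciably.  ``normalization_scale``
    is set once the spectrum has been normalized to an isosbestic point
    (stored value = normalized; raw = normalized / scale).
    """

    spectrum: Spectrum
    compound_id: str
    role: str
    lambda_max_nm: float
    isosbestic_points_nm: tuple[float, ...]
    spectral_extension_nm: float
    ph_condition: str = ""
    quench_medium: str = ""
    stability_window_s: Optional[float] = None
    normalization_scale: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(
            self, "isosbestic_points_nm", tuple(float(p) for p in self.isosbestic_points_nm)
        )
        self.validate()

    def validate(self) -> None:
        if self.role not in ("nucleoside", "nucleobase"):
            raise MetadataError(
                f"{self.compound_id}: role must be 'nucleoside' or 'nucleobase', "
                f"got {self.role!r}"
            )
        lo, hi = self.spectrum.range_nm
        if not (lo <= self.lambda_max_nm <= hi):
            raise MetadataError(
                f"{self.compound_id}: lambda_max {self.lambda_max_nm} nm outside "
                f"spectrum range [{lo}, {hi}]"
            )
        for p in self.isosbestic_points_nm:
            if not (lo <= p <= hi):
                raise MetadataError(
                    f"{self.compound_id}: isosbestic point {p} nm outside "
                    f"spectrum range [{lo}, {hi}]"
                )
        if len(self.isosbestic_points_nm) > 2:
            raise MetadataError(
                f"{self.compound_id}: at most 2 isosbestic points supported"
            )
        if self.spectral_extension_nm < self.lambda_max_nm:
            raise MetadataError(
                f"{self.compound_id}: spectral extension "
                f"({self.spectral_extension_nm} nm) below lambda_max "
                f"({self.lambda_max_nm} nm)"
            )
        if self.normalization_scale is not None and not self.normalization_scale > 0:
            raise MetadataError(f"{self.compound_id}: normalization_scale must be > 0")

    @property
    def is_normalized(self) -> bool:
        return self.normalization_scale is not None

    def raw_spectrum(self) -> Spectrum:
        """The pre-normalization spectrum (identity if never normalized)."""
        if self.normalization_scale is None:
            return self.spectrum
        return self.spectrum.scaled(1.0 / self.normalization_scale)


@dataclass(frozen=True)
class ReferencePair:
    """A nucleoside/nucleobase pair prepared for unmixing.

    Members share one wavelength grid.  When the pair has an isosbestic
    point of base cleavage, both members are stored normalized to 1 AU at
    ``active_isosbestic_nm`` and ``wavelength_mode_only`` is False; pairs
    without one (e.g. ribavirin) can only be monitored by single- or
    multi-wavelength detection.
    """

    nucleoside: ReferenceSpectrum
    nucleobase: ReferenceSpectrum
    fit_range_nm: tuple[float, float]
    active_isosbestic_nm: Optional[float] = None
    wavelength_mode_only: bool = False

    def __post_init__(self):
        ns, nb = self.nucleoside.spectrum, self.nucleobase.spectrum
        if not ns.same_grid(nb):
            raise GridError("pair members must share one wavelength grid")
        lo, hi = self.fit_range_nm
        if not lo < hi:
            raise SpecUnmixError("fit range must be a non-empty interval")
        glo, ghi = ns.range_nm
        if lo < glo or hi > ghi:
            raise GridError(
                f"fit range [{lo}, {hi}] outside the pair grid [{glo}, {ghi}]"
            )
        ext = self.min_extension_nm
        if hi > ext:
            raise SpecUnmixError(
                f"fit range upper bound {hi} nm exceeds the pair's spectral "
                f"extension {ext} nm"
            )
        if self.active_isosbestic_nm is not None:
            for member in (self.nucleoside, self.nucleobase):
                a = member.spectrum.at(self.active_isosbestic_nm)
                if abs(a - 1.0) > 0.02:
                    raise SpecUnmixError(
                        f"{member.compound_id}: absorbance at the active "
                        f"isosbestic point is {a:.4f}, not 1.00 +/- 0.02 "
                        "(pair not normalized?)"
                    )
        elif not self.wavelength_mode_only:
            raise SpecUnmixError(
                "a pair without an active isosbestic point must be flagged "
                "wavelength_mode_only"
            )

    @property
    def grid_nm(self) -> np.ndarray:
        return self.nucleoside.spectrum.wavelengths_nm

    @property
    def min_extension_nm(self) -> float:
        return min(
            self.nucleoside.spectral_extension_nm,
            self.nucleobase.spectral_extension_nm,
        )

    def swapped(self) -> "ReferencePair":
        """Pair with the roles of the two members exchanged (diagnostics)."""
        return ReferencePair(
            nucleoside=self.nucleobase,
            nucleobase=self.nucleoside,
            fit_range_nm=self.fit_range_nm,
            active_isosbestic_nm=self.active_isosbestic_nm,
            wavelength_mode_only=self.wavelength_mode_only,
        )

    def design_columns(self, grid_nm) -> tuple[np.ndarray, np.ndarray]:
        """Reference shapes interpolated onto ``grid_nm`` (R_N, R_B)."""
        rn = self.nucleoside.spectrum.interp_to(grid_nm).absorbance_au
        rb = self.nucleobase.spectrum.interp_to(grid_nm).absorbance_au
        return rn, rb


_WELL_RE = re.compile(r"^[A-Ha-h](?:[1-9]|1[0-2])$")


@dataclass
class PlateSpectraSet:
    """All spectra read from one plate export: samples plus optional blanks.

    ``samples`` maps column label -> Spectrum; ``blanks`` maps blank kind
    (one of :data:`BLANK_KINDS`) -> Spectrum.  All members share one grid.
    """

    samples: dict[str, Spectrum]
    blanks: dict[str, Spectrum] = field(default_factory=dict)

    def __post_init__(self):
        for kind in self.blanks:
            if kind not in BLANK_KINDS:
                raise SpecUnmixError(
                    f"unknown blank kind {kind!r}; expected one of {BLANK_KINDS}"
                )
        members = list(self.samples.values()) + list(self.blanks.values())
        if members:
            first = members[0]
            for m in members[1:]:
                if not first.same_grid(m):
                    raise GridError("all spectra in a plate set must share one grid")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def grid_nm(self) -> np.ndarray:
        member = next(iter(self.samples.values()), None) or next(
            iter(self.blanks.values())
        )
        return member.wavelengths_nm

    def ordered_samples(self) -> list[Spectrum]:
        """Samples sorted by time when every sample has one, else by label."""
        values = list(self.samples.values())
        if values and all(s.time_s is not None for s in values):
            return sorted(values, key=lambda s: s.time_s)
        return [self.samples[k] for k in sorted(self.samples)]


def find_crossings(a: Spectrum, b: Spectrum, lo_nm=None, hi_nm=None) -> list[float]:
    """Wavelengths where the difference a - b changes sign (linear roots).

    Used both to verify that a declared isosbestic point corresponds to an
    actual crossing of the pair and as the numeric oracle for synthetic
    pairs.
    """
    if not a.same_grid(b):
        raise GridError("crossing scan requires a shared grid")
    wl = a.wavelengths_nm
    diff = a.absorbance_au - b.absorbance_au
    mask = np.ones_like(wl, dtype=bool)
    if lo_nm is not None:
        mask &= wl >= lo_nm
    if hi_nm is not None:
        mask &= wl <= hi_nm
    wl, diff = wl[mask], diff[mask]
    out: list[float] = []
    for i in range(diff.size - 1):
        d0, d1 = diff[i], diff[i + 1]
        if d0 == 0.0:
            out.append(float(wl[i]))
        elif d0 * d1 < 0:
            # linear interpolation of the root between grid points
            t = d0 / (d0 - d1)
            out.append(float(wl[i] + t * (wl[i + 1] - wl[i])))
    if diff.size and diff[-1] == 0.0:
        out.append(float(wl[-1]))
    return out


def _select_isosbestic(
    nucleoside: ReferenceSpectrum,
    nucleobase: ReferenceSpectrum,
    override_nm: Optional[float],
) -> Optional[float]:
    candidates = tuple(
        p for p in nucleoside.isosbestic_points_nm
        if p in nucleobase.isosbestic_points_nm
    ) or nucleoside.isosbestic_points_nm or nucleobase.isosbestic_points_nm
    if override_nm is not None:
        listed = set(nucleoside.isosbestic_points_nm) | set(
            nucleobase.isosbestic_points_nm
        )
        if float(override_nm) not in listed:
            raise MetadataError(
                f"requested isosbestic point {override_nm} nm is not listed in "
                f"the metadata of {nucleoside.compound_id}/{nucleobase.compound_id} "
                f"(listed: {sorted(listed)})"
            )
        return float(override_nm)
    if not candidates:
        return None
    if len(candidates) == 1:
        return float(candidates[0])
    # Two listed isosbestic points (e.g. 5-ethynyluridine: 262 and 288 nm):
    # default to the one where the pair's common absorbance is larger, which
    # gives the better signal-to-noise for normalization.
    def common_absorbance(p: float) -> float:
        return 0.5 * (
            nucleoside.raw_spectrum().at(p) + nucleobase.raw_spectrum().at(p)
        )

    return float(max(candidates, key=common_absorbance))


def build_reference_pair(
    nucleoside: ReferenceSpectrum,
    nucleobase: ReferenceSpectrum,
    *,
    isosbestic_override_nm: Optional[float] = None,
    fit_range_nm: Optional[Sequence[float]] = None,
) -> ReferencePair:
    """Couple a nucleoside and its nucleobase into a fit-ready pair.

    The members are interpolated onto their common grid, the active
    isosbestic point of base cleavage is selected (metadata default or
    explicit override) and both spectra are normalized to absorbance 1
    there, recording the pre-normalization scale.  The default fit range
    spans the common grid from its lower edge up to the smaller spectral
    extension of the two members.

    Pairs whose metadata lists no isosbestic point are returned raw and
    flagged ``wavelength_mode_only``.
    """
    if nucleoside.role != "nucleoside" or nucleobase.role != "nucleobase":
        raise MetadataError(
            f"pair roles must be nucleoside+nucleobase, got "
            f"{nucleoside.role!r}+{nucleobase.role!r}"
        )
    if nucleoside.ph_condition != nucleobase.ph_condition:
        raise MetadataError(
            f"pH condition mismatch: {nucleoside.compound_id} "
            f"({nucleoside.ph_condition!r}) vs {nucleobase.compound_id} "
            f"({nucleobase.ph_condition!r})"
        )
    lo = max(nucleoside.spectrum.range_nm[0], nucleobase.spectrum.range_nm[0])
    hi = min(nucleoside.spectrum.range_nm[1], nucleobase.spectrum.range_nm[1])
    if not lo < hi:
        raise GridError(
            f"spectra of {nucleoside.compound_id} and {nucleobase.compound_id} "
            "do not overlap"
        )
    # common grid = the nucleoside grid clipped to the overlap; the base is
    # interpolated onto it (1 nm spacing makes this loss-free in practice)
    grid = nucleoside.spectrum.wavelengths_nm
    grid = grid[(grid >= lo) & (grid <= hi)]
    ns = dataclasses.replace(nucleoside, spectrum=nucleoside.spectrum.interp_to(grid))
    nb = dataclasses.replace(nucleobase, spectrum=nucleobase.spectrum.interp_to(grid))

    iso = _select_isosbestic(ns, nb, isosbestic_override_nm)

    ext = min(ns.spectral_extension_nm, nb.spectral_extension_nm)
    if fit_range_nm is None:
        fit_range = (float(grid[0]), float(min(ext, grid[-1])))
    else:
        fit_range = (float(fit_range_nm[0]), float(fit_range_nm[1]))

    if iso is None:
        return ReferencePair(
            nucleoside=ns,
            nucleobase=nb,
            fit_range_nm=fit_range,
            active_isosbestic_nm=None,
            wavelength_mode_only=True,
        )

    if not (fit_range[0] <= iso <= fit_range[1]):
        raise SpecUnmixError(
            f"active isosbestic point {iso} nm lies outside the fit range "
            f"{fit_range}"
        )

    def normalized(ref: ReferenceSpectrum) -> ReferenceSpectrum:
        a_iso = ref.spectrum.at(iso)
        if a_iso <= 0:
            raise SpecUnmixError(
                f"{ref.compound_id}: non-positive absorbance at the isosbestic "
                f"point ({a_iso:.4f} AU)"
            )
        scale = 1.0 / a_iso
        prior = ref.normalization_scale or 1.0
        return dataclasses.replace(
            ref,
            spectrum=ref.spectrum.scaled(scale),
            normalization_scale=prior * scale,
        )

    return ReferencePair(
        nucleoside=normalized(ns),
        nucleobase=normalized(nb),
        fit_range_nm=fit_range,
        active_isosbestic_nm=iso,
        wavelength_mode_only=False,
    )
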