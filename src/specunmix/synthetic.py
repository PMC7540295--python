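"""Synthetic spectra generator: reference pairs, mixtures, backgrounds, series.

Real alkaline reference spectra live in an external repository; this
module builds statistically faithful stand-ins so every pipeline stage
is testable offline.  Each component is a sum of one or two Gaussian
bands — the smooth single/two-band shapes nucleoside and nucleobase
spectra show under alkaline conditions — with the nucleobase rescaled so
both components cross exactly at the designed isosbestic point.  The
default scenario mimics the thymidine/thymine pair (lambda_max 266/290 nm,
isosbestic point 278 nm, spectral extension 320 nm, pH 13 quench).

Everything is seeded; the same scenario + seed reproduces a fixture
bit-for-bit, and every simulated dataset is returned together with its
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .spectra import (
    ReferencePair,
    ReferenceSpectrum,
    SpecUnmixError,
    Spectrum,
    build_reference_pair,
    find_crossings,
)

__all__ = [
    "GaussianBand",
    "Kinetics",
    "SyntheticScenario",
    "thymidine_like_scenario",
    "uridine_like_scenario",
    "no_isosbestic_scenario",
    "generate_reference_pair",
    "generate_background",
    "simulate_mixture",
    "simulate_reaction_series",
    "BACKGROUND_KINDS",
]

BACKGROUND_KINDS = ("none", "plate", "shift", "protein", "solvent")

#: Default measurement noise, AU.  Typical peak signals in this assay are
#: ~0.5-0.8 AU (2 mM substrate, ~15-fold dilution), so 0.002 AU gives the
#: realistic S/N of a decent plate reader.
DEFAULT_NOISE_SIGMA_AU = 0.002
#: Pipetting scatter: multiplicative lognormal with this log-sd.
DEFAULT_SCALE_JITTER_SD = 0.05


@dataclass(frozen=True)
class GaussianBand:
    center_nm: float
    width_nm: float
    amplitude_au: float

    def __post_init__(self):
        if not self.width_nm > 0:
            raise SpecUnmixError("band width must be > 0")
        if not self.amplitude_au > 0:
            raise SpecUnmixError("band amplitude must be > 0")

    def __call__(self, wl: np.ndarray) -> np.ndarray:
        z = (wl - self.center_nm) / self.width_nm
        return self.amplitude_au * np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class Kinetics:
    """First-order approach to equilibrium: x(t) = x_eq * (1 - exp(-k t))."""

    x_eq: float = 0.8
    k_per_s: float = 0.01
    times_s: tuple[float, ...] = tuple(float(t) for t in range(0, 3001, 30))

    def __post_init__(self):
        if not 0 <= self.x_eq <= 1:
            raise SpecUnmixError("x_eq must lie in [0, 1]")
        if not self.k_per_s > 0:
            raise SpecUnmixError("rate constant must be > 0")
        if len(self.times_s) == 0:
            raise SpecUnmixError("kinetics needs at least one sample time")
        object.__setattr__(self, "times_s", tuple(float(t) for t in self.times_s))

    def conversion_at(self, t) -> np.ndarray:
        return self.x_eq * (1.0 - np.exp(-self.k_per_s * np.asarray(t, dtype=float)))


@dataclass(frozen=True)
class SyntheticScenario:
    """Full parameter set behind one synthetic dataset.

    The defaults are the thymidine-like stated world: one band per
    component, designed isosbestic crossing at 278 nm, the standard
    250-350 nm / 1 nm acquisition grid, noise sigma 0.002 AU and
    first-order kinetics to x_eq = 0.8.
    """

    nucleoside_bands: tuple[GaussianBand, ...] = (GaussianBand(266.0, 11.0, 0.95),)
    nucleobase_bands: tuple[GaussianBand, ...] = (GaussianBand(290.0, 9.0, 0.80),)
    target_isosbestic_nm: Optional[float] = 278.0
    grid_nm: tuple[float, float, float] = (250.0, 350.0, 1.0)
    spectral_extension_nm: float = 320.0
    noise_sigma_au: float = DEFAULT_NOISE_SIGMA_AU
    background_kind: str = "none"
    background_params: dict = field(default_factory=dict)
    kinetics: Kinetics = Kinetics()
    scale_jitter_sd: float = DEFAULT_SCALE_JITTER_SD
    nucleoside_id: str = "syn-nucleoside"
    nucleobase_id: str = "syn-nucleobase"
    ph_condition: str = "100 mM NaOH, pH 13"
    quench_medium: str = "NaOH"
    stability_window_s: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if self.background_kind not in BACKGROUND_KINDS:
            raise SpecUnmixError(
                f"unknown background kind {self.background_kind!r}; "
                f"expected one of {BACKGROUND_KINDS}"
            )
        if self.noise_sigma_au < 0:
            raise SpecUnmixError("noise sigma must be >= 0")
        object.__setattr__(
            self, "nucleoside_bands", tuple(self.nucleoside_bands)
        )
        object.__setattr__(
            self, "nucleobase_bands", tuple(self.nucleobase_bands)
        )
        for bands in (self.nucleoside_bands, self.nucleobase_bands):
            if not 1 <= len(bands) <= 2:
                raise SpecUnmixError("each component takes 1 or 2 Gaussian bands")

    def wavelength_grid(self) -> np.ndarray:
        lo, hi, step = self.grid_nm
        return np.arange(lo, hi + step / 2, step)

    def provenance(self) -> dict:
        return {
            "seed": self.seed,
            "noise_sigma_au": self.noise_sigma_au,
            "background_kind": self.background_kind,
            "target_isosbestic_nm": self.target_isosbestic_nm,
        }


def thymidine_like_scenario(**overrides) -> SyntheticScenario:
    """The default stated world: thymidine/thymine-like pair."""
    return SyntheticScenario(**overrides)


def uridine_like_scenario(**overrides) -> SyntheticScenario:
    """Uridine/uracil-like pair: lambda_max 262/281 nm, isosbestic 271 nm,
    spectral extension 310 nm.  The restricted fitting window for this
    pair is the information-rich tail region 265-295 nm."""
    defaults = dict(
        nucleoside_bands=(GaussianBand(262.0, 10.0, 0.90),),
        nucleobase_bands=(GaussianBand(281.0, 9.0, 0.75),),
        target_isosbestic_nm=271.0,
        spectral_extension_nm=310.0,
        nucleoside_id="syn-uridine",
        nucleobase_id="syn-uracil",
    )
    defaults.update(overrides)
    return SyntheticScenario(**defaults)


def no_isosbestic_scenario(**overrides) -> SyntheticScenario:
    """Ribavirin-like pair whose metadata lists no isosbestic point of
    base cleavage, so only single-/multi-wavelength monitoring is
    possible."""
    defaults = dict(
        nucleoside_bands=(GaussianBand(256.0, 9.0, 0.50),),
        nucleobase_bands=(GaussianBand(252.0, 7.0, 0.95),),
        target_isosbestic_nm=None,
        spectral_extension_nm=300.0,
        nucleoside_id="syn-ribavirin",
        nucleobase_id="syn-triazole-carboxamide",
    )
    defaults.update(overrides)
    return SyntheticScenario(**defaults)


def _band_sum(bands: Sequence[GaussianBand], wl: np.ndarray) -> np.ndarray:
    out = np.zeros_like(wl, dtype=float)
    for b in bands:
        out += b(wl)
    return out


def generate_reference_pair(scenario: SyntheticScenario) -> ReferencePair:
    """Build a validated reference pair from a scenario.

    The nucleobase spectrum is rescaled so both components are exactly
    equal at the target isosbestic wavelength (the crossing is thereby
    guaranteed, verified by a sign-change scan), metadata (lambda_max,
    isosbestic list, spectral extension) is derived from the generated
    shapes, and both members are normalized at the isosbestic point via
    :func:`specunmix.spectra.build_reference_pair`.

    Raises ``"degenerate pair"`` when the two shapes correlate > 0.999
    over the fit range — such references cannot be told apart.
    """
    wl = scenario.wavelength_grid()
    a_n = _band_sum(scenario.nucleoside_bands, wl)
    a_b = _band_sum(scenario.nucleobase_bands, wl)

    iso = scenario.target_isosbestic_nm
    if iso is not None:
        v_n = float(np.interp(iso, wl, a_n))
        v_b = float(np.interp(iso, wl, a_b))
        if v_b <= 0 or v_n <= 0:
            raise SpecUnmixError(
                "components have no absorbance at the target isosbestic point"
            )
        a_b = a_b * (v_n / v_b)

    ext = scenario.spectral_extension_nm
    lam_n = float(wl[int(np.argmax(a_n))])
    lam_b = float(wl[int(np.argmax(a_b))])
    fit_hi = min(ext, float(wl[-1]))
    corr = float(np.corrcoef(
        a_n[(wl >= wl[0]) & (wl <= fit_hi)], a_b[(wl >= wl[0]) & (wl <= fit_hi)]
    )[0, 1])
    if corr > 0.999:
        raise SpecUnmixError(
            f"degenerate pair: shape correlation {corr:.5f} > 0.999 over the fit range"
        )

    iso_list = (iso,) if iso is not None else ()
    common = dict(
        ph_condition=scenario.ph_condition,
        quench_medium=scenario.quench_medium,
        spectral_extension_nm=ext,
        stability_window_s=scenario.stability_window_s,
    )
    ns = ReferenceSpectrum(
        spectrum=Spectrum(wl, a_n, label=scenario.nucleoside_id),
        compound_id=scenario.nucleoside_id,
        role="nucleoside",
        lambda_max_nm=lam_n,
        isosbestic_points_nm=iso_list,
        **common,
    )
    nb = ReferenceSpectrum(
        spectrum=Spectrum(wl, a_b, label=scenario.nucleobase_id),
        compound_id=scenario.nucleobase_id,
        role="nucleobase",
        lambda_max_nm=lam_b,
        isosbestic_points_nm=iso_list,
        **common,
    )
    pair = build_reference_pair(ns, nb)

    if iso is not None:
        crossings = find_crossings(
            pair.nucleoside.spectrum, pair.nucleobase.spectrum,
            lo_nm=pair.fit_range_nm[0], hi_nm=pair.fit_range_nm[1],
        )
        if not any(abs(c - iso) <= 1.0 for c in crossings):
            raise SpecUnmixError(
                f"generated pair does not cross within 1 nm of the target "
                f"isosbestic point {iso} nm (crossings: {crossings})"
            )
    return pair


def generate_background(
    kind: str, params: Optional[dict] = None, grid_nm=None
) -> Spectrum:
    """One of the four background archetypes seen on real plates.

    * ``plate`` — well/plate absorption: ~``level`` AU at 300 nm
      (default 0.03) curving up toward slightly higher values at 250 nm.
    * ``shift`` — flat baseline elevation of ``level`` AU (default 0.12),
      the particle/well artifact seen in 1-2 % of measurements.
    * ``protein`` — tail of an aromatic band centered near 280 nm
      (``amplitude`` AU at the center, default 0.04; ``width_nm`` 15).
    * ``solvent`` — steep monotone rise below ``cutoff_nm`` (default 280,
      DMSO/DMF-like), exactly zero at and above the cutoff;
      ``amplitude`` is the value at the short-wavelength grid edge.
    """
    params = dict(params or {})
    if grid_nm is None:
        grid_nm = np.arange(250.0, 350.5, 1.0)
    wl = np.asarray(grid_nm, dtype=float)

    if kind == "none":
        ab = np.zeros_like(wl)
    elif kind == "plate":
        level = float(params.pop("level", 0.03))
        shape = 0.7 + 0.6 * np.exp(-(wl - wl[0]) / 35.0)
        anchor = 0.7 + 0.6 * np.exp(-(300.0 - wl[0]) / 35.0)
        ab = level * shape / anchor
    elif kind == "shift":
        level = float(params.pop("level", 0.12))
        ab = np.full_like(wl, level)
    elif kind == "protein":
        amp = float(params.pop("amplitude", 0.04))
        width = float(params.pop("width_nm", 15.0))
        center = float(params.pop("center_nm", 280.0))
        ab = amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    elif kind == "solvent":
        amp = float(params.pop("amplitude", 0.20))
        cutoff = float(params.pop("cutoff_nm", 280.0))
        power = float(params.pop("power", 3.0))
        frac = np.clip((cutoff - wl) / (cutoff - wl[0]), 0.0, None)
        ab = amp * frac**power
    else:
        raise SpecUnmixError(
            f"unknown background kind {kind!r}; expected one of {BACKGROUND_KINDS}"
        )
    if params:
        raise SpecUnmixError(f"unused background parameters: {sorted(params)}")
    return Spectrum(wl, ab, label=f"blank:{kind}", meta={"kind": kind})


def simulate_mixture(
    pair: ReferencePair,
    x: float,
    noise_sigma_au: float = DEFAULT_NOISE_SIGMA_AU,
    background: Optional[Spectrum] = None,
    scale: float = 1.0,
    seed: Optional[int] = 0,
    label: str = "",
    time_s: Optional[float] = None,
) -> Spectrum:
    """One noisy mixture spectrum at known conversion ``x``.

    S = scale * [(1-x) R_N + x R_B] + background + eps,
    eps ~ iid Normal(0, noise_sigma^2).  ``seed`` (or an
    ``np.random.Generator``) makes the draw reproducible bit-for-bit.
    The true conversion is recorded in the result's metadata.
    """
    if not 0 <= x <= 1:
        raise SpecUnmixError(f"mole fraction x={x} outside [0, 1]")
    if not scale > 0:
        raise SpecUnmixError("scale must be positive")
    wl = pair.grid_nm
    rn = pair.nucleoside.spectrum.absorbance_au
    rb = pair.nucleobase.spectrum.absorbance_au
    ab = scale * ((1.0 - x) * rn + x * rb)
    if background is not None:
        ab = ab + background.interp_to(wl).absorbance_au
    if noise_sigma_au > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        ab = ab + rng.normal(0.0, noise_sigma_au, size=wl.size)
    return Spectrum(
        wl,
        ab,
        label=label or f"x={x:.4f}",
        time_s=time_s,
        meta={"true_conversion": float(x), "scale": float(scale)},
    )


def simulate_reaction_series(
    pair: ReferencePair, scenario: SyntheticScenario
) -> tuple[list[Spectrum], np.ndarray]:
    """Simulate a sampled reaction: one mixture per time point, plus truth.

    Conversions follow the scenario's first-order kinetics; each sample
    gets an independent multiplicative pipetting jitter
    (lognormal, log-sd ``scenario.scale_jitter_sd``) and iid measurement
    noise; the scenario background (if any) is added to every sample.
    Returns ``(spectra, true_conversions)`` — no fixture without its
    ground truth.
    """
    rng = np.random.default_rng(scenario.seed)
    times = np.asarray(scenario.kinetics.times_s, dtype=float)
    if times.size == 0:
        raise SpecUnmixError("empty sample-time list")
    truths = scenario.kinetics.conversion_at(times)
    background = (
        generate_background(
            scenario.background_kind,
            scenario.background_params,
            pair.grid_nm,
        )
        if scenario.background_kind != "none"
        else None
    )
    spectra = []
    for i, (t, x) in enumerate(zip(times, truths)):
        scale = (
            float(np.exp(rng.normal(0.0, scenario.scale_jitter_sd)))
            if scenario.scale_jitter_sd > 0
            else 1.0
        )
        spectra.append(
            simulate_mixture(
                pair,
                float(x),
                noise_sigma_au=scenario.noise_sigma_au,
                background=background,
                scale=scale,
                seed=rng,
                label=f"t{int(t)}@{t:g}s",
                time_s=float(t),
            )
        )
    return spectra, truths
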