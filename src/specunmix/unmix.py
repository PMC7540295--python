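"""Two-component spectral unmixing by non-negative least squares.

The measured absorbance of a quenched reaction sample is, by the
additivity of absorbance (Beer-Lambert), a linear combination of the
nucleoside and nucleobase reference spectra:

    A(lambda) = c_N * R_N(lambda) + c_B * R_B(lambda) + eps(lambda)

After normalization to the isosbestic point of base cleavage, both
references have absorbance 1 there, so the coefficients are directly the
mole fractions of the two species (their sum is ~1) and the degree of
conversion is ``c_B / (c_N + c_B)``.

The central object is :class:`UnmixingModel`, a small statsmodels-style
model whose :meth:`~UnmixingModel.fit` returns an
:class:`UnmixingResult` carrying the coefficient estimates, their
standard errors, the conversion with a delta-method standard error, the
RMS residual and QC flags, plus a ``summary()`` table.  The convenience
functions :func:`unmix_spectrum`, :func:`unmix_series`,
:func:`brute_force_unmix` and :func:`unmix_wavelength_mode` wrap it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import lsq_linear, nnls

from .spectra import ReferencePair, SpecUnmixError, Spectrum

__all__ = [
    "UnmixingModel",
    "UnmixingResult",
    "UnmixResult",
    "WavelengthModeCalibration",
    "unmix_spectrum",
    "unmix_series",
    "brute_force_unmix",
    "unmix_wavelength_mode",
    "DegenerateReferencesError",
]

#: Fits whose RMS residual (normalized units) exceeds this are flagged.
RESIDUAL_THRESHOLD = 0.01
#: After isosbestic normalization c_N + c_B should be ~1; flag beyond this.
COEF_SUM_TOLERANCE = 0.10
#: Reference shapes whose Pearson correlation over the fit range exceeds
#: this are indistinguishable to the solver.
COLLINEARITY_LIMIT = 0.999


class DegenerateReferencesError(SpecUnmixError):
    """The two reference shapes are (numerically) indistinguishable."""


@dataclass(frozen=True)
class UnmixingResult:
    """Outcome of unmixing one spectrum.

    ``params`` holds ``(c_N, c_B)``; ``conversion`` is the derived mole
    fraction ``c_B / (c_N + c_B)``.  ``bse`` / ``conversion_se`` are
    ordinary-least-squares standard errors (delta method for the
    conversion); they are NaN when a coefficient sits on the
    non-negativity boundary, where the linear approximation fails.
    """

    params: np.ndarray
    conversion: float
    residual_rms: float
    fit_range_nm: tuple[float, float]
    nobs: int
    bse: np.ndarray = field(default_factory=lambda: np.full(2, np.nan))
    conversion_se: float = float("nan")
    offset: Optional[float] = None
    flags: frozenset[str] = frozenset()
    label: str = ""
    time_s: Optional[float] = None
    method: str = "nnls"

    def __post_init__(self):
        p = np.asarray(self.params, dtype=float)
        object.__setattr__(self, "params", p)
        object.__setattr__(self, "bse", np.asarray(self.bse, dtype=float))
        if self.residual_rms < 0:
            raise SpecUnmixError("residual_rms must be >= 0")
        if not (-1e-12 <= self.conversion <= 1 + 1e-12):
            raise SpecUnmixError(f"conversion {self.conversion} outside [0, 1]")

    @property
    def coeff_nucleoside(self) -> float:
        return float(self.params[0])

    @property
    def coeff_nucleobase(self) -> float:
        return float(self.params[1])

    @property
    def coef_sum(self) -> float:
        return float(self.params.sum())

    def with_flags(self, *extra: str) -> "UnmixingResult":
        import dataclasses

        return dataclasses.replace(self, flags=self.flags | frozenset(extra))

    def summary(self) -> str:
        """Plain-text summary table, statsmodels style."""
        lines = [
            "Spectral unmixing result",
            "=" * 58,
            f"{'sample':<24}{self.label or '-':>34}",
            f"{'method':<24}{self.method:>34}",
            f"{'fit range [nm]':<24}{str(self.fit_range_nm):>34}",
            f"{'n wavelengths':<24}{self.nobs:>34d}",
            "-" * 58,
            f"{'':<14}{'coef':>12}{'std err':>12}",
            f"{'nucleoside':<14}{self.coeff_nucleoside:>12.5f}{self.bse[0]:>12.5f}",
            f"{'nucleobase':<14}{self.coeff_nucleobase:>12.5f}{self.bse[1]:>12.5f}",
        ]
        if self.offset is not None:
            lines.append(f"{'offset':<14}{self.offset:>12.5f}")
        lines += [
            "-" * 58,
            f"{'conversion':<24}{self.conversion:>28.5f} "
            f"(se {self.conversion_se:.2g})",
            f"{'residual rms':<24}{self.residual_rms:>34.3e}",
            f"{'coef sum':<24}{self.coef_sum:>34.4f}",
            f"{'flags':<24}{', '.join(sorted(self.flags)) or 'none':>34}",
            "=" * 58,
        ]
        return "\n".join(lines)


#: Back-compat alias; the domain name for the result record.
UnmixResult = UnmixingResult


def _conversion_from_coeffs(c_n: float, c_b: float) -> float:
    total = c_n + c_b
    if total <= 0:
        raise SpecUnmixError(
            "both component coefficients are zero; conversion undefined"
        )
    return min(1.0, max(0.0, c_b / total))


class UnmixingModel:
    """Least-squares unmixing of one processed spectrum against a pair.

    Parameters
    ----------
    spectrum : Spectrum
        The preprocessed (background-corrected, range-restricted and,
        in isosbestic mode, normalized) sample spectrum.
    pair : ReferencePair
        Validated nucleoside/nucleobase pair.
    nonnegative : bool
        Constrain both coefficients to be >= 0 (default; physical
        concentrations cannot be negative).  The unconstrained variant is
        available for diagnostics.
    fit_offset : bool
        Add a free flat-offset column.  Off by default: baseline shifts
        are handled by exclusion upstream, not absorbed into the fit.
    """

    def __init__(
        self,
        spectrum: Spectrum,
        pair: ReferencePair,
        *,
        nonnegative: bool = True,
        fit_offset: bool = False,
        residual_threshold: float = RESIDUAL_THRESHOLD,
        coef_sum_tolerance: float = COEF_SUM_TOLERANCE,
        collinearity_limit: float = COLLINEARITY_LIMIT,
    ):
        lo, hi = pair.fit_range_nm
        wl = spectrum.wavelengths_nm
        mask = (wl >= lo) & (wl <= hi)
        if int(mask.sum()) < 3:
            raise SpecUnmixError(
                f"fewer than 3 sample points inside the fit range [{lo}, {hi}] nm"
            )
        self.spectrum = spectrum
        self.pair = pair
        self.nonnegative = nonnegative
        self.fit_offset = fit_offset
        self.residual_threshold = residual_threshold
        self.coef_sum_tolerance = coef_sum_tolerance
        self.wavelengths_nm = wl[mask]
        self.endog = spectrum.absorbance_au[mask]
        rn, rb = pair.design_columns(self.wavelengths_nm)
        self.exog = np.column_stack([rn, rb])
        self.fit_range_nm = (float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1]))

        if np.allclose(self.endog, 0.0):
            raise SpecUnmixError("sample spectrum is identically zero over the fit range")
        corr = float(np.corrcoef(rn, rb)[0, 1])
        if corr > collinearity_limit:
            raise DegenerateReferencesError(
                f"references indistinguishable over the fit range "
                f"(shape correlation {corr:.5f} > {collinearity_limit})"
            )

    # -- solvers -------------------------------------------------------

    def _solve(self) -> tuple[np.ndarray, Optional[float]]:
        X, y = self.exog, self.endog
        if self.fit_offset:
            Xo = np.column_stack([X, np.ones_like(y)])
            if self.nonnegative:
                lb = np.array([0.0, 0.0, -np.inf])
                ub = np.full(3, np.inf)
                sol = lsq_linear(Xo, y, bounds=(lb, ub), method="bvls")
                coefs = sol.x
            else:
                coefs, *_ = np.linalg.lstsq(Xo, y, rcond=None)
            return coefs[:2], float(coefs[2])
        if self.nonnegative:
            coefs, _ = nnls(X, y)
        else:
            coefs, *_ = np.linalg.lstsq(X, y, rcond=None)
        return coefs, None

    def _standard_errors(
        self, coefs: np.ndarray, offset: Optional[float], rss: float
    ) -> tuple[np.ndarray, float]:
        """OLS covariance; NaN when the active set touches the boundary."""
        n = self.endog.size
        p = 2 + (offset is not None)
        if n <= p:
            return np.full(2, np.nan), float("nan")
        if self.nonnegative and np.any(coefs <= 0):
            return np.full(2, np.nan), float("nan")
        X = self.exog
        if offset is not None:
            X = np.column_stack([X, np.ones(n)])
        sigma2 = rss / (n - p)
        try:
            cov = sigma2 * np.linalg.inv(X.T @ X)
        except np.linalg.LinAlgError:
            return np.full(2, np.nan), float("nan")
        bse = np.sqrt(np.diag(cov)[:2])
        c_n, c_b = coefs
        s = c_n + c_b
        grad = np.array([-c_b, c_n]) / s**2
        var_conv = float(grad @ cov[:2, :2] @ grad)
        return bse, math.sqrt(max(var_conv, 0.0))

    def fit(self) -> UnmixingResult:
        coefs, offset = self._solve()
        if self.nonnegative:
            coefs = np.maximum(coefs, 0.0)
        pred = self.exog @ coefs
        if offset is not None:
            pred = pred + offset
        resid = self.endog - pred
        rss = float(resid @ resid)
        residual_rms = math.sqrt(rss / self.endog.size)
        conversion = _conversion_from_coeffs(*coefs)
        bse, conv_se = self._standard_errors(coefs, offset, rss)

        flags: set[str] = set()
        if residual_rms > self.residual_threshold:
            flags.add("poor_fit")
        # coefficient sum ~ 1 only holds in isosbestic-normalized mode
        if self.pair.active_isosbestic_nm is not None:
            if abs(float(coefs.sum()) - 1.0) > self.coef_sum_tolerance:
                flags.add("coef_sum_anomaly")

        return UnmixingResult(
            params=coefs,
            conversion=conversion,
            residual_rms=residual_rms,
            fit_range_nm=self.fit_range_nm,
            nobs=self.endog.size,
            bse=bse,
            conversion_se=conv_se,
            offset=offset,
            flags=frozenset(flags),
            label=self.spectrum.label,
            time_s=self.spectrum.time_s,
            method="nnls" if self.nonnegative else "ols",
        )


def unmix_spectrum(sample: Spectrum, pair: ReferencePair, **options) -> UnmixingResult:
    """Fit the pair's reference spectra to one processed sample.

    Thin functional wrapper over ``UnmixingModel(sample, pair, **options).fit()``.
    """
    return UnmixingModel(sample, pair, **options).fit()


def unmix_series(
    samples: Sequence[Spectrum], pair: ReferencePair, **options
) -> list[UnmixingResult]:
    """Unmix an ordered list of identically preprocessed spectra.

    Order is preserved; per-sample QC flags are carried on each result.
    Samples whose metadata record an age since quench exceeding the
    references' stability window get a ``"stability"`` flag (the analytes
    may have degraded in the alkaline medium; e.g. fluorinated purine
    nucleosides are only stable for ~10 min at pH 13).
    """
    samples = list(samples)
    if not samples:
        raise SpecUnmixError("unmix_series: empty sample list")
    stability = [
        w
        for w in (
            pair.nucleoside.stability_window_s,
            pair.nucleobase.stability_window_s,
        )
        if w is not None
    ]
    window = min(stability) if stability else None
    out = []
    for s in samples:
        res = unmix_spectrum(s, pair, **options)
        extra = set(s.meta.get("flags", ()))
        age = s.meta.get("age_since_quench_s")
        if window is not None and age is not None and age > window:
            extra.add("stability")
        if extra:
            res = res.with_flags(*extra)
        out.append(res)
    return out


def brute_force_unmix(
    sample: Spectrum, pair: ReferencePair, grid_step: float = 1e-4
) -> UnmixingResult:
    """Exhaustive grid search over conversion: the independent test oracle.

    For every conversion ``x`` on a uniform grid the mixture shape
    ``S_x = (1-x) R_N + x R_B`` is fixed and the best total amount is the
    scalar least-squares projection ``t = max(0, <A, S_x> / <S_x, S_x>)``;
    the SSE-minimizing grid point wins.  This spans exactly the
    non-negative coefficient quadrant, so it must agree with the
    constrained solver to within the grid resolution — but it shares no
    code path with it.
    """
    if not 0 < grid_step <= 0.5:
        raise SpecUnmixError("grid_step must be in (0, 0.5]")
    model = UnmixingModel(sample, pair)  # validation + design matrix
    y = model.endog
    rn, rb = model.exog[:, 0], model.exog[:, 1]
    xs = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    xs = np.minimum(xs, 1.0)
    # dot products of the mixture shape with y and itself, vectorized in x
    d_n, d_b = float(y @ rn), float(y @ rb)
    n_nn, n_bb, n_nb = float(rn @ rn), float(rb @ rb), float(rn @ rb)
    dots = (1 - xs) * d_n + xs * d_b
    norms = (1 - xs) ** 2 * n_nn + 2 * xs * (1 - xs) * n_nb + xs**2 * n_bb
    totals = np.where(norms > 0, np.maximum(dots / np.where(norms > 0, norms, 1.0), 0.0), 0.0)
    sse = float(y @ y) - 2 * totals * dots + totals**2 * norms
    best = int(np.argmin(sse))
    x_best, t_best = float(xs[best]), float(totals[best])
    coefs = np.array([t_best * (1 - x_best), t_best * x_best])
    if t_best <= 0:
        raise SpecUnmixError("brute_force_unmix: sample projects to zero amount")
    return UnmixingResult(
        params=coefs,
        conversion=x_best,
        residual_rms=math.sqrt(max(sse[best], 0.0) / y.size),
        fit_range_nm=model.fit_range_nm,
        nobs=y.size,
        label=sample.label,
        time_s=sample.time_s,
        method=f"grid({grid_step:g})",
    )


@dataclass(frozen=True)
class WavelengthModeCalibration:
    """Fallback calibration for pairs without an isosbestic point.

    ``response_matrix`` holds the relative absorptivity of
    (nucleoside, nucleobase) at each calibration wavelength, row per
    wavelength — i.e. the reference absorbances there, in whatever
    common units the references were recorded in.
    """

    wavelengths_nm: tuple[float, ...]
    response_matrix: np.ndarray
    condition_limit: float = 1e8

    def __post_init__(self):
        object.__setattr__(
            self, "wavelengths_nm", tuple(float(w) for w in self.wavelengths_nm)
        )
        M = np.atleast_2d(np.asarray(self.response_matrix, dtype=float))
        if M.shape != (len(self.wavelengths_nm), 2):
            raise SpecUnmixError(
                f"response matrix shape {M.shape} does not match "
                f"{len(self.wavelengths_nm)} wavelength(s) x 2 components"
            )
        object.__setattr__(self, "response_matrix", M)
        if M.shape[0] == 2:
            cond = float(np.linalg.cond(M))
            if not np.isfinite(cond) or cond > self.condition_limit:
                raise SpecUnmixError(
                    f"singular response matrix (condition number {cond:.3g}); "
                    "choose wavelengths where the components differ"
                )

    @classmethod
    def from_pair(
        cls, pair: ReferencePair, wavelengths_nm: Sequence[float], **kw
    ) -> "WavelengthModeCalibration":
        rows = [
            [pair.nucleoside.spectrum.at(w), pair.nucleobase.spectrum.at(w)]
            for w in wavelengths_nm
        ]
        return cls(tuple(wavelengths_nm), np.array(rows), **kw)


def unmix_wavelength_mode(
    sample: Spectrum,
    calib: WavelengthModeCalibration,
    total_amount: Optional[float] = None,
) -> UnmixingResult:
    """Single- or two-wavelength fallback for pairs without an isosbestic point.

    Two-wavelength mode solves the 2x2 linear system
    ``A(w_i) = M_i1 c_N + M_i2 c_B`` exactly.  Single-wavelength mode
    additionally needs the known total amount ``c_N + c_B``
    (``total_amount``).  Negative solved amounts are clipped to zero and
    flagged ``"clipped"``.
    """
    M = calib.response_matrix
    a = np.array([sample.at(w) for w in calib.wavelengths_nm])
    if M.shape[0] == 2:
        coefs = np.linalg.solve(M, a)
    elif M.shape[0] == 1:
        if total_amount is None:
            raise SpecUnmixError(
                "single-wavelength mode requires the known total amount "
                "(total_amount) of nucleoside + nucleobase"
            )
        r_n, r_b = M[0]
        if r_n == r_b:
            raise SpecUnmixError(
                "components respond identically at the calibration wavelength"
            )
        c_b = (a[0] - total_amount * r_n) / (r_b - r_n)
        coefs = np.array([total_amount - c_b, c_b])
    else:  # pragma: no cover - shape enforced in the calibration
        raise SpecUnmixError("wavelength mode supports 1 or 2 wavelengths")

    flags: set[str] = set()
    if np.any(coefs < 0):
        coefs = np.maximum(coefs, 0.0)
        flags.add("clipped")
    conversion = _conversion_from_coeffs(*coefs)
    lo, hi = min(calib.wavelengths_nm), max(calib.wavelengths_nm)
    return UnmixingResult(
        params=coefs,
        conversion=conversion,
        residual_rms=0.0,
        fit_range_nm=(lo, hi if hi > lo else lo + 1.0),
        nobs=len(calib.wavelengths_nm),
        flags=frozenset(flags),
        label=sample.label,
        time_s=sample.time_s,
        method=f"{len(calib.wavelengths_nm)}-wavelength",
    )


def results_to_frame(results: Iterable[UnmixingResult]):
    """Tabulate results (one row per sample) for CSV export."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {
                "label": r.label,
                "time_s": r.time_s,
                "conversion": r.conversion,
                "conversion_se": r.conversion_se,
                "coeff_nucleoside": r.coeff_nucleoside,
                "coeff_nucleobase": r.coeff_nucleobase,
                "residual_rms": r.residual_rms,
                "flags": ";".join(sorted(r.flags)),
            }
        )
    return pd.DataFrame(rows)
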