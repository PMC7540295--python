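"""Reading and writing spectra tables and the reference-spectrum library.

Table dialect
-------------
Spectra travel as UTF-8 CSV with a header row and "." as decimal mark.
The first column is the wavelength grid and is named ``wavelength_nm``;
every further column is one spectrum (one well/timepoint).  Plate-reader
exports are converted to this dialect up front, never sniffed.

Column-label conventions:

* ``blank:<kind>`` marks a blank spectrum; ``<kind>`` is one of
  ``plate``, ``protein``, ``solvent``, ``buffer``.
* a trailing ``@<seconds>s`` encodes the sampling time, e.g.
  ``A3@120s`` is well A3 sampled 120 s after reaction start.

Reference library layout
------------------------
One directory; per compound a two-column CSV (``wavelength_nm``,
``absorbance_au``) plus a YAML sidecar of the same stem carrying the
metadata schema: ``compound_id``, ``role``, ``ph_condition``,
``quench_medium``, ``lambda_max_nm``, ``isosbestic_points_nm``,
``spectral_extension_nm`` and optional ``stability_window_s``.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .spectra import (
    BLANK_KINDS,
    GridError,
    MetadataError,
    PlateSpectraSet,
    ReferenceSpectrum,
    SpecUnmixError,
    Spectrum,
)

__all__ = [
    "read_spectra_table",
    "write_spectra_table",
    "load_reference_library",
    "write_reference_library",
]

WAVELENGTH_COLUMN = "wavelength_nm"

_TIME_SUFFIX = re.compile(r"^(?P<label>.*)@(?P<secs>[0-9]+(?:\.[0-9]+)?)s$")
_WELL = re.compile(r"^[A-Ha-h](?:[1-9]|1[0-2])$")

_REQUIRED_META = (
    "compound_id",
    "role",
    "lambda_max_nm",
    "isosbestic_points_nm",
    "spectral_extension_nm",
)


def _parse_label(label: str) -> dict:
    """Split a column label into label / optional well / optional time."""
    out = {"label": label, "well": None, "time_s": None}
    m = _TIME_SUFFIX.match(label)
    stem = label
    if m:
        stem = m.group("label")
        out["time_s"] = float(m.group("secs"))
        out["label"] = label
    if _WELL.match(stem):
        out["well"] = stem.upper()
    return out


def read_spectra_table(path: Union[str, Path]) -> PlateSpectraSet:
    """Read a spectra CSV into a :class:`PlateSpectraSet`.

    The first column is the wavelength grid (strictly increasing); every
    other column becomes one :class:`Spectrum`.  Columns labelled
    ``blank:<kind>`` are routed to the blank slots.

    Raises
    ------
    SpecUnmixError
        On duplicate column labels, non-numeric cells (named by row and
        column), fewer than 2 data rows, or a non-increasing grid.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline().strip("\n\r")
    if not header_line:
        raise SpecUnmixError(f"{path}: empty file")
    header = header_line.split(",")
    if len(header) < 2:
        raise SpecUnmixError(f"{path}: need a wavelength column plus >=1 spectrum")
    dupes = {h for h in header if header.count(h) > 1}
    if dupes:
        raise SpecUnmixError(f"{path}: duplicate column labels {sorted(dupes)}")

    frame = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")  # exact float round-trip
    if len(frame) < 2:
        raise SpecUnmixError(f"{path}: fewer than 2 data rows")
    for col in frame.columns:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna() & frame[col].notna()
        if bad.any() or frame[col].isna().any():
            row = int(np.argmax((bad | frame[col].isna()).to_numpy()))
            raise SpecUnmixError(
                f"{path}: non-numeric or missing value in column {col!r}, "
                f"data row {row + 1}"
            )
        frame[col] = numeric

    wl_col = frame.columns[0]
    wl = frame[wl_col].to_numpy(dtype=float)
    if not np.all(np.diff(wl) > 0):
        raise GridError(f"{path}: wavelengths not strictly increasing")

    samples: dict[str, Spectrum] = {}
    blanks: dict[str, Spectrum] = {}
    for col in frame.columns[1:]:
        ab = frame[col].to_numpy(dtype=float)
        if col.startswith("blank:"):
            kind = col.split(":", 1)[1]
            if kind not in BLANK_KINDS:
                raise SpecUnmixError(
                    f"{path}: unknown blank kind {kind!r} in column {col!r}"
                )
            blanks[kind] = Spectrum(wl, ab, label=col)
        else:
            info = _parse_label(str(col))
            samples[str(col)] = Spectrum(
                wl, ab, label=info["label"], well=info["well"], time_s=info["time_s"]
            )
    return PlateSpectraSet(samples=samples, blanks=blanks)


def write_spectra_table(spectra: PlateSpectraSet, path: Union[str, Path]) -> None:
    """Write a plate set as CSV in the package dialect (see module docs).

    Float values are written at full ``repr`` precision so a
    write -> read round trip is value-preserving.
    """
    if len(spectra.samples) + len(spectra.blanks) == 0:
        raise SpecUnmixError("cannot write an empty spectra set")
    grid = spectra.grid_nm
    data = {WAVELENGTH_COLUMN: grid}
    for label, s in spectra.samples.items():
        if not np.array_equal(s.wavelengths_nm, grid):
            raise GridError(f"sample {label!r} is not on the shared grid")
        data[label] = s.absorbance_au
    for kind, s in spectra.blanks.items():
        data[f"blank:{kind}"] = s.absorbance_au
    frame = pd.DataFrame(data)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def _load_reference_entry(csv_path: Path, meta_path: Path) -> ReferenceSpectrum:
    with open(meta_path, "r", encoding="utf-8") as fh:
        meta = yaml.safe_load(fh) or {}
    compound = meta.get("compound_id", csv_path.stem)
    for key in _REQUIRED_META:
        if key not in meta:
            raise MetadataError(f"{compound}: metadata missing required field {key!r}")
    frame = pd.read_csv(csv_path, encoding="utf-8")
    if frame.shape[1] < 2:
        raise SpecUnmixError(f"{csv_path}: expected wavelength + absorbance columns")
    spectrum = Spectrum(
        frame.iloc[:, 0].to_numpy(float),
        frame.iloc[:, 1].to_numpy(float),
        label=compound,
    )
    iso = meta["isosbestic_points_nm"]
    if iso is None:
        iso = []
    elif np.isscalar(iso):
        iso = [iso]
    return ReferenceSpectrum(
        spectrum=spectrum,
        compound_id=str(meta["compound_id"]),
        role=str(meta["role"]),
        ph_condition=str(meta.get("ph_condition", "")),
        quench_medium=str(meta.get("quench_medium", "")),
        lambda_max_nm=float(meta["lambda_max_nm"]),
        isosbestic_points_nm=tuple(float(p) for p in iso),
        spectral_extension_nm=float(meta["spectral_extension_nm"]),
        stability_window_s=(
            float(meta["stability_window_s"])
            if meta.get("stability_window_s") is not None
            else None
        ),
        normalization_scale=(
            float(meta["normalization_scale"])
            if meta.get("normalization_scale") is not None
            else None
        ),
    )


def load_reference_library(directory: Union[str, Path]) -> list[ReferenceSpectrum]:
    """Load every reference spectrum in ``directory``.

    Each compound is one CSV + one YAML sidecar sharing a file stem.
    Every entry is validated against the reference-spectrum invariants;
    a violation raises :class:`MetadataError` naming compound and field.
    Entries are returned sorted by compound id.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise SpecUnmixError(f"reference library {directory} is not a directory")
    entries: list[ReferenceSpectrum] = []
    sidecars = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".yaml", ".yml", ".json")
    )
    if not sidecars:
        raise SpecUnmixError(f"no metadata sidecars (*.yaml) found in {directory}")
    for meta_path in sidecars:
        csv_path = meta_path.with_suffix(".csv")
        if not csv_path.exists():
            raise SpecUnmixError(
                f"{meta_path.stem}: metadata sidecar without spectrum file "
                f"{csv_path.name}"
            )
        entries.append(_load_reference_entry(csv_path, meta_path))
    ids = [e.compound_id for e in entries]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise MetadataError(f"duplicate compound ids in library: {sorted(dupes)}")
    return sorted(entries, key=lambda e: e.compound_id)


def write_reference_library(
    entries: Iterable[ReferenceSpectrum], directory: Union[str, Path]
) -> None:
    """Write reference spectra (raw, pre-normalization) plus sidecars."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for ref in entries:
        raw = ref.raw_spectrum()
        stem = re.sub(r"[^A-Za-z0-9._-]+", "_", ref.compound_id)
        pd.DataFrame(
            {
                WAVELENGTH_COLUMN: raw.wavelengths_nm,
                "absorbance_au": raw.absorbance_au,
            }
        ).to_csv(directory / f"{stem}.csv", index=False, lineterminator="\n")
        meta = {
            "compound_id": ref.compound_id,
            "role": ref.role,
            "ph_condition": ref.ph_condition,
            "quench_medium": ref.quench_medium,
            "lambda_max_nm": float(ref.lambda_max_nm),
            "isosbestic_points_nm": [float(p) for p in ref.isosbestic_points_nm],
            "spectral_extension_nm": float(ref.spectral_extension_nm),
            "stability_window_s": ref.stability_window_s,
        }
        with open(directory / f"{stem}.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)
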