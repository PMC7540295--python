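"""Spectrum/reference containers, table IO and reference-pair assembly."""

import tempfile
from pathlib import Path

import numpy as np
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

import specunmix as su
from specunmix.io import write_reference_library

GRID = np.arange(250.0, 351.0)


def make_ref(absorbance, compound="cmp", role="nucleoside", lam=266.0,
             isos=(278.0,), ext=320.0, ph="pH 13", grid=GRID, **kw):
    return su.ReferenceSpectrum(
        spectrum=su.Spectrum(grid, absorbance, label=compound),
        compound_id=compound, role=role, lambda_max_nm=lam,
        isosbestic_points_nm=isos, spectral_extension_nm=ext,
        ph_condition=ph, **kw,
    )


class TestSpectrum:
    def test_invariants(self):
        with pytest.raises(su.GridError, match="strictly increasing"):
            su.Spectrum([250, 250, 252], [1, 2, 3])
        with pytest.raises(su.GridError):
            su.Spectrum([250], [1.0])
        with pytest.raises(su.GridError, match="mismatch"):
            su.Spectrum([250, 251], [1.0, 2.0, 3.0])
        with pytest.raises(su.SpecUnmixError):
            su.Spectrum([250, 251], [np.nan, 1.0])
        # negative absorbance is legal (post background subtraction)
        su.Spectrum([250, 251], [-0.01, 0.02])

    def test_interpolation_and_restriction(self):
        s = su.Spectrum([250, 251, 252, 253], [0.0, 1.0, 2.0, 3.0])
        assert s.at(251.5) == pytest.approx(1.5)
        with pytest.raises(su.GridError, match="extrapolation|outside"):
            s.at(249.0)
        with pytest.raises(su.GridError):
            s.interp_to([249.5, 251.0])
        r = s.restrict(251, 253)
        assert r.wavelengths_nm.tolist() == [251, 252, 253]


class TestSpectraTable:
    def test_read_standard_grid(self, tmp_path, thymidine_pair):
        plate = su.PlateSpectraSet(
            samples={
                f"s{i}": su.simulate_mixture(thymidine_pair, x, seed=i)
                for i, x in enumerate([0.0, 0.4, 0.9])
            }
        )
        path = tmp_path / "plate.csv"
        su.write_spectra_table(plate, path)
        back = su.read_spectra_table(path)
        assert len(back.samples) == 3
        assert all(len(s) == 101 for s in back.samples.values())

    def test_decreasing_wavelengths_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("wavelength_nm,a\n260,0.1\n250,0.2\n")
        with pytest.raises(su.GridError, match="strictly increasing"):
            su.read_spectra_table(path)

    def test_non_numeric_cell_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("wavelength_nm,a\n250,0.1\n251,oops\n")
        with pytest.raises(su.SpecUnmixError, match="column 'a'.*row 2"):
            su.read_spectra_table(path)

    def test_duplicate_labels_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("wavelength_nm,a,a\n250,0.1,0.2\n251,0.1,0.2\n")
        with pytest.raises(su.SpecUnmixError, match="duplicate"):
            su.read_spectra_table(path)

    def test_too_few_rows_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("wavelength_nm,a\n250,0.1\n")
        with pytest.raises(su.SpecUnmixError, match="fewer than 2"):
            su.read_spectra_table(path)

    def test_empty_set_rejected(self, tmp_path):
        with pytest.raises(su.SpecUnmixError, match="empty"):
            su.write_spectra_table(su.PlateSpectraSet(samples={}), tmp_path / "x.csv")

    def test_time_and_blank_parsing(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "wavelength_nm,A3@120s,blank:plate\n250,0.5,0.03\n251,0.6,0.03\n"
        )
        plate = su.read_spectra_table(path)
        (sample,) = plate.samples.values()
        assert sample.time_s == 120.0 and sample.well == "A3"
        assert set(plate.blanks) == {"plate"}

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(
        data=st.lists(
            st.lists(
                st.floats(min_value=-1.0, max_value=3.0,
                          allow_nan=False, allow_infinity=False, width=64),
                min_size=5, max_size=5,
            ),
            min_size=1, max_size=4,
        )
    )
    def test_roundtrip_value_preserving(self, data):
        """write -> read preserves every absorbance value exactly."""
        grid = np.arange(250.0, 255.0)
        plate = su.PlateSpectraSet(
            samples={f"s{i}": su.Spectrum(grid, col) for i, col in enumerate(data)}
        )
        with tempfile.TemporaryDirectory() as d:
            path = Path(d) / "rt.csv"
            su.write_spectra_table(plate, path)
            back = su.read_spectra_table(path)
        for label, original in plate.samples.items():
            np.testing.assert_array_equal(
                back.samples[label].absorbance_au, original.absorbance_au
            )


class TestReferenceLibrary:
    def test_synthetic_library_roundtrip(self, tmp_path, thymidine_pair):
        """A thymidine-like entry (lambda_max 266, iso 278, ext 320) validates."""
        write_reference_library(
            [thymidine_pair.nucleoside, thymidine_pair.nucleobase], tmp_path
        )
        entries = su.load_reference_library(tmp_path)
        assert [e.compound_id for e in entries] == ["syn-nucleobase", "syn-nucleoside"]
        ns = next(e for e in entries if e.role == "nucleoside")
        assert ns.lambda_max_nm == 266.0
        assert ns.isosbestic_points_nm == (278.0,)
        assert ns.spectral_extension_nm == 320.0

    def test_missing_field_names_compound(self, tmp_path):
        (tmp_path / "c.csv").write_text("wavelength_nm,absorbance_au\n250,0.1\n251,0.2\n")
        meta = {"compound_id": "cmp-x", "role": "nucleoside",
                "lambda_max_nm": 250.5, "isosbestic_points_nm": [250.5]}
        (tmp_path / "c.yaml").write_text(yaml.safe_dump(meta))
        with pytest.raises(su.MetadataError, match="cmp-x.*spectral_extension_nm"):
            su.load_reference_library(tmp_path)

    def test_isosbestic_outside_grid_rejected(self):
        grid = np.arange(280.0, 351.0)
        with pytest.raises(su.MetadataError, match="outside"):
            make_ref(np.ones(grid.size), grid=grid, lam=290.0, isos=(278.0,), ext=330.0)

    def test_two_isosbestic_points_retained(self, tmp_path):
        """5-ethynyluridine-like metadata (isosbestics 262 and 288 nm)."""
        ref = make_ref(np.exp(-0.5 * ((GRID - 285) / 12) ** 2), compound="ethynyl",
                       lam=285.0, isos=(262.0, 288.0), ext=340.0)
        write_reference_library([ref], tmp_path)
        (entry,) = su.load_reference_library(tmp_path)
        assert entry.isosbestic_points_nm == (262.0, 288.0)

    def test_extension_below_lambda_max_rejected(self):
        with pytest.raises(su.MetadataError, match="extension"):
            make_ref(np.ones(GRID.size), lam=300.0, isos=(), ext=290.0)


class TestBuildReferencePair:
    def test_thymidine_defaults(self, thymidine_pair):
        assert thymidine_pair.active_isosbestic_nm == 278.0
        assert thymidine_pair.fit_range_nm == (250.0, 320.0)
        assert not thymidine_pair.wavelength_mode_only
        # both members normalized to 1 at the isosbestic point
        for m in (thymidine_pair.nucleoside, thymidine_pair.nucleobase):
            assert m.spectrum.at(278.0) == pytest.approx(1.0, abs=1e-12)
            assert m.normalization_scale is not None

    def test_no_isosbestic_flags_wavelength_mode(self):
        pair = su.generate_reference_pair(su.no_isosbestic_scenario())
        assert pair.active_isosbestic_nm is None
        assert pair.wavelength_mode_only

    def _two_crossing_members(self):
        a = np.exp(-0.5 * ((GRID - 275) / 20) ** 2)
        b = 0.9 * np.exp(-0.5 * ((GRID - 280) / 30) ** 2)
        sa = su.Spectrum(GRID, a)
        sb = su.Spectrum(GRID, b)
        crossings = su.find_crossings(sa, sb)
        assert len(crossings) == 2
        isos = tuple(round(c) for c in crossings)
        ns = make_ref(a, compound="N", lam=275.0, isos=isos, ext=340.0)
        nb = make_ref(b, compound="B", role="nucleobase", lam=280.0, isos=isos, ext=340.0)
        return ns, nb, isos

    def test_two_point_default_picks_larger_common_absorbance(self):
        ns, nb, isos = self._two_crossing_members()
        # independent choice: compare the mean raw absorbance at each candidate
        expected = max(isos, key=lambda p: ns.spectrum.at(p) + nb.spectrum.at(p))
        pair = su.build_reference_pair(ns, nb)
        assert pair.active_isosbestic_nm == float(expected)

    def test_explicit_override_wins(self):
        ns, nb, isos = self._two_crossing_members()
        other = min(isos)
        pair = su.build_reference_pair(ns, nb, isosbestic_override_nm=other)
        assert pair.active_isosbestic_nm == float(other)

    def test_override_not_in_metadata_rejected(self, thymidine_pair):
        with pytest.raises(su.MetadataError, match="not listed"):
            su.build_reference_pair(
                thymidine_pair.nucleoside, thymidine_pair.nucleobase,
                isosbestic_override_nm=300.0,
            )

    def test_non_overlapping_grids_rejected(self):
        lo = np.arange(250.0, 280.0)
        hi = np.arange(300.0, 351.0)
        ns = make_ref(np.ones(lo.size), grid=lo, lam=260.0, isos=(), ext=279.0)
        nb = make_ref(np.ones(hi.size), grid=hi, role="nucleobase",
                      lam=310.0, isos=(), ext=340.0)
        with pytest.raises(su.GridError, match="overlap"):
            su.build_reference_pair(ns, nb)

    def test_ph_mismatch_rejected(self, thymidine_pair):
        import dataclasses
        other = dataclasses.replace(thymidine_pair.nucleobase, ph_condition="pH 9")
        with pytest.raises(su.MetadataError, match="pH"):
            su.build_reference_pair(thymidine_pair.nucleoside, other)
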