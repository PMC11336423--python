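"""Cube/mask I/O and lamp correction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hsinuclei import (BinaryMask, SpectralCube, lamp_correction,
                       read_envi_cube, read_mask, write_envi_cube, write_mask)
from hsinuclei.synthetic_data import default_wavelength_grid

from conftest import make_cube


class TestSpectralCubeInvariants:
    def test_wavelengths_must_ascend(self):
        with pytest.raises(ValueError, match="ascending"):
            SpectralCube(np.ones((2, 2, 3)), [500.0, 450.0, 400.0])

    def test_negative_intensities_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            make_cube(-np.ones((2, 2, 3)))

    def test_band_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="band count"):
            SpectralCube(np.ones((2, 2, 3)), [400.0, 410.0])

    def test_nonuniform_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            SpectralCube(np.ones((1, 1, 4)), [400.0, 410.0, 420.0, 500.0])

    def test_nearest_band_lookup_ties_resolve_low(self):
        cube = make_cube(np.ones((1, 1, 3)), [400.0, 410.0, 420.0])
        assert cube.band_index(404.9) == 0
        assert cube.band_index(405.0) == 0  # exact tie -> lower band
        assert cube.band_index(405.1) == 1


class TestEnviRoundTrip:
    @pytest.mark.parametrize("interleave", ["bsq", "bil", "bip"])
    @pytest.mark.parametrize("dtype", [np.float32, np.uint16])
    def test_roundtrip_identity(self, tmp_path, rng, interleave, dtype):
        arr = (rng.uniform(0, 1000, size=(8, 8, 10))).astype(dtype)
        cube = make_cube(arr.astype(float))
        cube.intensities = cube.intensities.astype(dtype)
        hdr = write_envi_cube(cube, tmp_path / "c", interleave=interleave)
        back = read_envi_cube(hdr)
        np.testing.assert_array_equal(back.intensities, arr)
        np.testing.assert_allclose(back.wavelengths, cube.wavelengths)

    def test_bsq_matches_hand_constructed_byte_layout(self, tmp_path):
        # Independent oracle: lay the bytes out by hand per the BSQ
        # definition (band-major planes, each row-major) and read them back.
        values = np.arange(48, dtype=np.float32)  # 3 bands x 4 lines x 4 cols
        (tmp_path / "hand.raw").write_bytes(values.tobytes())
        wl = "{400.0, 410.0, 420.0}"
        (tmp_path / "hand.hdr").write_text(
            "ENVI\nsamples = 4\nlines = 4\nbands = 3\nheader offset = 0\n"
            f"data type = 4\ninterleave = bsq\nbyte order = 0\n"
            f"wavelength = {wl}\n")
        cube = read_envi_cube(tmp_path / "hand.hdr")
        for b in range(3):
            for r in range(4):
                for c in range(4):
                    assert cube.intensities[r, c, b] == b * 16 + r * 4 + c

    def test_full_468_band_grid(self, tmp_path, rng):
        wl = default_wavelength_grid()
        cube = SpectralCube(rng.uniform(0, 1, (2, 2, wl.size)), wl)
        hdr = write_envi_cube(cube, tmp_path / "g")
        assert read_envi_cube(hdr).n_bands == 468

    def test_header_always_complete(self, tmp_path):
        hdr = write_envi_cube(make_cube(np.ones((2, 3, 2))), tmp_path / "m")
        text = hdr.read_text()
        for key in ("samples = 3", "lines = 2", "bands = 2", "wavelength ="):
            assert key in text

    def test_file_size_matches_sample_count(self, tmp_path):
        cube = make_cube(np.array([[[3.0, 5.0]]]))
        write_envi_cube(cube, tmp_path / "tiny")
        raw = np.fromfile(tmp_path / "tiny.raw", dtype="<f4")
        assert raw.size == 2
        np.testing.assert_array_equal(np.sort(raw), [3.0, 5.0])

    def test_missing_wavelength_block_names_header(self, tmp_path):
        (tmp_path / "bad.raw").write_bytes(np.zeros(4, "<f4").tobytes())
        (tmp_path / "bad.hdr").write_text(
            "ENVI\nsamples = 2\nlines = 2\nbands = 1\ndata type = 4\n"
            "interleave = bsq\n")
        with pytest.raises(ValueError, match="bad.hdr"):
            read_envi_cube(tmp_path / "bad.hdr")

    def test_unsupported_interleave_rejected(self, tmp_path):
        (tmp_path / "x.raw").write_bytes(np.zeros(4, "<f4").tobytes())
        (tmp_path / "x.hdr").write_text(
            "ENVI\nsamples = 2\nlines = 2\nbands = 1\ndata type = 4\n"
            "interleave = weird\nwavelength = {500.0}\n")
        with pytest.raises(ValueError, match="interleave"):
            read_envi_cube(tmp_path / "x.hdr")

    @given(rows=st.integers(1, 5), cols=st.integers(1, 5),
           bands=st.integers(1, 6),
           interleave=st.sampled_from(["bsq", "bil", "bip"]),
           seed=st.integers(0, 1000))
    def test_roundtrip_property(self, tmp_path_factory, rows, cols, bands,
                                interleave, seed):
        rng = np.random.default_rng(seed)
        cube = make_cube(rng.uniform(0, 100, (rows, cols, bands)))
        path = tmp_path_factory.mktemp("envi") / "p"
        back = read_envi_cube(write_envi_cube(cube, path,
                                              interleave=interleave))
        np.testing.assert_allclose(back.intensities, cube.intensities,
                                   rtol=1e-6)


class TestMaskIO:
    def test_png_roundtrip(self, tmp_path):
        values = np.zeros((5, 7), dtype=np.uint8)
        values[1:4, 2:5] = 1
        mask = BinaryMask(values, nucleus_id="n1", class_label="CI")
        write_mask(mask, tmp_path / "m.png")
        back = read_mask(tmp_path / "m.png", "n1", "CI")
        np.testing.assert_array_equal(back.values, values)
        assert back.area_px == 9

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="no pixels"):
            BinaryMask(np.zeros((3, 3)), nucleus_id="e", class_label="REF")

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="class_label"):
            BinaryMask(np.ones((2, 2)), nucleus_id="e", class_label="UV")


class TestLampCorrection:
    def test_flat_lamp_is_identity(self, rng):
        cube = make_cube(rng.uniform(0, 5, (3, 3, 4)))
        out = lamp_correction(cube, np.full(4, 7.0))
        np.testing.assert_allclose(out.intensities, cube.intensities)

    def test_hand_arithmetic_on_2x2x2(self):
        # lamp (2, 1): unit-mean normalization -> (4/3, 2/3); each band is
        # divided by its normalized entry.
        arr = np.array([[[4.0, 6.0], [2.0, 3.0]],
                        [[8.0, 1.0], [0.0, 9.0]]])
        out = lamp_correction(make_cube(arr), [2.0, 1.0])
        np.testing.assert_allclose(out.intensities[..., 0], arr[..., 0] / (4 / 3))
        np.testing.assert_allclose(out.intensities[..., 1], arr[..., 1] / (2 / 3))

    def test_wavelengths_unchanged(self, rng):
        cube = make_cube(rng.uniform(0, 5, (2, 2, 3)))
        out = lamp_correction(cube, [1.0, 2.0, 3.0])
        np.testing.assert_array_equal(out.wavelengths, cube.wavelengths)

    def test_nonpositive_lamp_entry_names_band(self):
        cube = make_cube(np.ones((2, 2, 3)))
        with pytest.raises(ValueError, match="band index 1"):
            lamp_correction(cube, [1.0, 0.0, 2.0])

    def test_double_application_equals_squared_normalized_lamp(self, rng):
        cube = make_cube(rng.uniform(0.1, 5, (2, 2, 2)))
        lamp = np.array([2.0, 1.0])
        norm = lamp / lamp.mean()
        twice = lamp_correction(lamp_correction(cube, lamp), lamp)
        np.testing.assert_allclose(twice.intensities,
                                   cube.intensities / norm ** 2)
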