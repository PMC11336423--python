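"""Hyperspectral cube and nucleus-mask I/O.

A darkfield hyperspectral record is a 3D data cube I(x, y, lambda): at every
spatial pixel the camera stores a full scattering spectrum.  Cubes are
exchanged as ENVI header/binary pairs (a plain-text ``.hdr`` describing
dimensions, interleave and the wavelength grid, next to a raw binary file).
Nucleus masks are single-channel PNG/TIFF images, 0 = background and any
positive value = nucleus.

The reader/writer here covers the dialect produced by visible/near-infrared
microscope exports: interleaves BSQ, BIL and BIP, little-endian storage,
float32 (ENVI data type 4) or uint16 (type 12) samples, and a mandatory
wavelength block.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "SpectralCube",
    "BinaryMask",
    "read_envi_cube",
    "write_envi_cube",
    "read_mask",
    "write_mask",
    "lamp_correction",
]

CLASS_LABELS = ("REF", "CI", "XR")

# ENVI numeric data-type codes supported by this dialect.
_ENVI_DTYPES = {4: np.dtype("<f4"), 12: np.dtype("<u2")}
_DTYPE_CODES = {np.dtype("float32"): 4, np.dtype("uint16"): 12}


@dataclass
class SpectralCube:
    """A hyperspectral data cube indexed ``(row, col, band)``.

    Parameters
    ----------
    intensities
        Nonnegative array of shape ``(rows, cols, bands)``.
    wavelengths
        Band-center wavelengths in nm, strictly ascending, one per band.
    pixel_size_nm
        Spatial sampling in nm/pixel (default 107.5, the microscope's
        60x configuration).
    meta
        Free-form acquisition metadata carried through I/O.
    """

    intensities: np.ndarray
    wavelengths: np.ndarray
    pixel_size_nm: float = 107.5
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"intensities must be 3D (row, col, band); got shape "
                f"{self.intensities.shape}"
            )
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.n_bands:
            raise ValueError(
                f"wavelength list length {len(self.wavelengths)} does not match "
                f"band count {self.n_bands}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly ascending")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")
        if self.n_bands >= 3:
            spacing = np.diff(self.wavelengths)
            med = np.median(spacing)
            if np.max(np.abs(spacing - med)) >= 0.1 * med:
                raise ValueError(
                    "band spacing deviates more than 10% from the median; "
                    "the grid must be approximately uniform"
                )

    @property
    def n_rows(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_cols(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_bands(self) -> int:
        return self.intensities.shape[2]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band whose center is nearest ``wavelength_nm``.

        Exact ties resolve to the lower band.
        """
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))


@dataclass
class BinaryMask:
    """A per-nucleus binary mask sharing its cube's spatial shape."""

    values: np.ndarray
    nucleus_id: str
    class_label: str

    def __post_init__(self) -> None:
        self.values = (np.asarray(self.values) > 0).astype(np.uint8)
        if self.values.ndim != 2:
            raise ValueError(f"mask must be 2D; got shape {self.values.shape}")
        if self.values.sum() == 0:
            raise ValueError(f"mask {self.nucleus_id!r} has no pixels set")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"class_label must be one of {CLASS_LABELS}; got "
                f"{self.class_label!r}"
            )

    @property
    def area_px(self) -> int:
        return int(self.values.sum())


def _data_path_for(header_path: Path) -> Path:
    stem = header_path.with_suffix("")
    for cand in (stem.with_suffix(".raw"), stem.with_suffix(".img"),
                 stem.with_suffix(".dat"), stem):
        if cand.exists() and cand != header_path:
            return cand
    raise FileNotFoundError(
        f"no data file (.raw/.img/.dat) found next to header {header_path}"
    )


def _parse_header(text: str, header_path: Path) -> dict:
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValueError(f"{header_path} is not an ENVI header (missing magic)")
    fields: dict[str, str] = {}
    # Join brace-delimited blocks (wavelength lists span many lines).
    body = text.split("\n", 1)[1] if "\n" in text else ""
    pattern = re.compile(r"^\s*([^=\n]+?)\s*=\s*(\{[^}]*\}|[^\n]*)",
                         re.MULTILINE | re.DOTALL)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        fields[key] = m.group(2).strip()
    return fields


def read_envi_cube(header_path) -> SpectralCube:
    """Read an ENVI header/binary pair into a :class:`SpectralCube`.

    Raises
    ------
    ValueError
        If the header lacks a wavelength block, declares an unsupported
        interleave, or an unsupported data type / byte order.
    """
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text(), header_path)

    for key in ("samples", "lines", "bands", "data type", "interleave"):
        if key not in fields:
            raise ValueError(f"header {header_path} is missing '{key}'")
    if "wavelength" not in fields:
        raise ValueError(
            f"header {header_path} has no wavelength block; band centers are "
            "required"
        )

    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    dtype_code = int(fields["data type"])
    interleave = fields["interleave"].lower()
    byte_order = int(fields.get("byte order", "0"))

    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(
            f"unsupported interleave {interleave!r} in {header_path}; "
            "expected one of bsq, bil, bip"
        )
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(
            f"unsupported ENVI data type {dtype_code} in {header_path}; "
            f"supported: {sorted(_ENVI_DTYPES)}"
        )
    if byte_order != 0:
        raise ValueError(
            f"unsupported byte order {byte_order} in {header_path}; only "
            "little-endian (0) is handled"
        )

    wl_text = fields["wavelength"].strip().strip("{}")
    wavelengths = np.array(
        [float(tok) for tok in wl_text.replace("\n", " ").split(",") if tok.strip()]
    )
    if len(wavelengths) != bands:
        raise ValueError(
            f"header {header_path} declares {bands} bands but lists "
            f"{len(wavelengths)} wavelengths"
        )

    offset = int(fields.get("header offset", "0"))
    raw = np.fromfile(_data_path_for(header_path),
                      dtype=_ENVI_DTYPES[dtype_code], offset=offset)
    expected = samples * lines * bands
    if raw.size != expected:
        raise ValueError(
            f"data file for {header_path} holds {raw.size} samples; expected "
            f"{expected}"
        )
    if interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        cube = raw.reshape(lines, samples, bands)

    pixel_size = float(fields.get("pixel size", "107.5"))
    meta = {"source": str(header_path), "interleave": interleave}
    if "description" in fields:
        meta["description"] = fields["description"].strip("{} \n")
    return SpectralCube(cube.copy(), wavelengths, pixel_size_nm=pixel_size,
                        meta=meta)


def write_envi_cube(cube: SpectralCube, path, interleave: str = "bsq") -> Path:
    """Write ``cube`` as an ENVI pair ``<path>.hdr`` + ``<path>.raw``.

    ``path`` may carry the ``.hdr`` suffix or none.  Returns the header path.
    """
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    path = Path(path)
    if path.suffix == ".hdr":
        path = path.with_suffix("")
    header_path = path.with_suffix(".hdr")
    data_path = path.with_suffix(".raw")

    data = np.ascontiguousarray(cube.intensities)
    if data.dtype not in _DTYPE_CODES:
        data = data.astype(np.float32)
    dtype_code = _DTYPE_CODES[data.dtype]

    if interleave == "bsq":
        out = data.transpose(2, 0, 1)
    elif interleave == "bil":
        out = data.transpose(0, 2, 1)
    else:
        out = data

    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    lines = [
        "ENVI",
        f"description = {{{cube.meta.get('description', 'hsinuclei export')}}}",
        f"samples = {cube.n_cols}",
        f"lines = {cube.n_rows}",
        f"bands = {cube.n_bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {dtype_code}",
        f"interleave = {interleave}",
        "byte order = 0",
        "wavelength units = Nanometers",
        f"pixel size = {cube.pixel_size_nm}",
        f"wavelength = {{{wl}}}",
    ]
    header_path.write_text("\n".join(lines) + "\n")
    np.ascontiguousarray(out).tofile(data_path)
    return header_path


def read_mask(path, nucleus_id: str, class_label: str) -> BinaryMask:
    """Load a single-channel mask image (PNG/TIFF); any positive pixel is 1."""
    img = Image.open(Path(path))
    arr = np.asarray(img.convert("L") if img.mode not in ("1", "L", "I;16") else img)
    return BinaryMask(arr > 0, nucleus_id=nucleus_id, class_label=class_label)


def write_mask(mask: BinaryMask, path) -> Path:
    """Save a mask as an 8-bit PNG (nucleus = 255, background = 0)."""
    path = Path(path)
    Image.fromarray((mask.values * 255).astype(np.uint8), mode="L").save(path)
    return path


def lamp_correction(cube: SpectralCube, lamp_spectrum) -> SpectralCube:
    """Divide every pixel spectrum by the unit-mean-normalized lamp spectrum.

    Darkfield illumination imposes the lamp's own spectral shape on every
    recorded spectrum; dividing it out leaves the sample's relative
    scattering response.  Normalizing the lamp spectrum to unit mean keeps
    the overall intensity scale of the cube.
    """
    lamp = np.asarray(lamp_spectrum, dtype=float)
    if lamp.shape != (cube.n_bands,):
        raise ValueError(
            f"lamp spectrum length {lamp.size} does not match band count "
            f"{cube.n_bands}"
        )
    bad = np.nonzero(lamp <= 0)[0]
    if bad.size:
        raise ValueError(
            f"lamp spectrum must be positive; first offending band index "
            f"{bad[0]} ({cube.wavelengths[bad[0]]:.2f} nm)"
        )
    norm = lamp / lamp.mean()
    return SpectralCube(cube.intensities / norm, cube.wavelengths.copy(),
                        pixel_size_nm=cube.pixel_size_nm, meta=dict(cube.meta))
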