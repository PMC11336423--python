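"""Spectral sub-images.

A sub-image collapses a nucleus ROI cube onto one band set: for an interval
(or the full range) each pixel carries the unweighted mean intensity over
the bands whose centers lie in the closed interval; for a pointwise spec it
carries the intensity at the band nearest that wavelength.  Intervals are
closed at both endpoints, so a band sitting on a shared boundary (e.g.,
430 nm in 415-430 and 430-440) contributes to both sub-images; each band
set is treated independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hsi_io import BinaryMask

__all__ = ["BandSpec", "SubImage", "extract_subimage", "build_subimage_set"]

_EPS = 1e-9


@dataclass(frozen=True)
class BandSpec:
    """A pointwise wavelength or closed wavelength interval."""

    kind: str  # "full" | "pointwise" | "interval"
    low_nm: float
    high_nm: float
    label: str

    def __post_init__(self) -> None:
        if self.kind not in ("full", "pointwise", "interval"):
            raise ValueError(f"unknown BandSpec kind {self.kind!r}")
        if self.low_nm > self.high_nm:
            raise ValueError(
                f"BandSpec bounds out of order: {self.low_nm} > {self.high_nm}"
            )

    @staticmethod
    def full(low_nm: float, high_nm: float) -> "BandSpec":
        return BandSpec("full", low_nm, high_nm,
                        f"{low_nm:.0f}-{high_nm:.0f}nm")

    @staticmethod
    def pointwise(wavelength_nm: float) -> "BandSpec":
        return BandSpec("pointwise", wavelength_nm, wavelength_nm,
                        f"{wavelength_nm:.0f}nm")

    @staticmethod
    def interval(low_nm: float, high_nm: float) -> "BandSpec":
        return BandSpec("interval", low_nm, high_nm,
                        f"{low_nm:.0f}-{high_nm:.0f}nm")


@dataclass
class SubImage:
    """One nucleus collapsed onto one band set; out-of-mask pixels carry no
    information and must be excluded via ``mask``."""

    values: np.ndarray
    mask: BinaryMask
    band_spec: BandSpec
    nucleus_id: str
    class_label: str

    def in_mask(self) -> np.ndarray:
        return self.values[self.mask.values.astype(bool)]


def extract_subimage(roi, spec: BandSpec, endpoint_mode: str = "closed"
                     ) -> SubImage:
    """Collapse one ROI onto one band set.

    ``endpoint_mode`` controls interval endpoint inclusion ("closed" keeps
    both boundary bands, "open" drops them) so the sensitivity of results
    to the boundary convention can be probed.
    """
    wl = roi.cube.wavelengths
    if spec.kind == "pointwise":
        band = roi.cube.band_index(spec.low_nm)
        values = roi.cube.intensities[:, :, band].astype(float)
    else:
        if endpoint_mode == "closed":
            sel = (wl >= spec.low_nm - _EPS) & (wl <= spec.high_nm + _EPS)
        elif endpoint_mode == "open":
            sel = (wl > spec.low_nm + _EPS) & (wl < spec.high_nm - _EPS)
        else:
            raise ValueError(f"unknown endpoint_mode {endpoint_mode!r}")
        if not sel.any():
            raise ValueError(
                f"band spec {spec.label!r} selects no bands on the grid "
                f"[{wl[0]:.2f}, {wl[-1]:.2f}] nm"
            )
        values = roi.cube.intensities[:, :, sel].mean(axis=2)
    return SubImage(values=values, mask=roi.mask, band_spec=spec,
                    nucleus_id=roi.nucleus_id, class_label=roi.class_label)


def build_subimage_set(cohort, specs, endpoint_mode: str = "closed"
                       ) -> dict[tuple[str, str], SubImage]:
    """All |cohort| x |specs| sub-images, keyed by ``(nucleus_id, label)``."""
    out: dict[tuple[str, str], SubImage] = {}
    for roi in cohort:
        for spec in specs:
            out[(roi.nucleus_id, spec.label)] = extract_subimage(
                roi, spec, endpoint_mode=endpoint_mode)
    return out
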