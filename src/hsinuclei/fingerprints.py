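"""Spectral fingerprints and characteristic wavelengths.

A nucleus's spectral fingerprint is its per-band mean intensity over the
in-mask pixels; a class fingerprint averages nucleus fingerprints with one
vote per nucleus regardless of size.  The non-irradiated (REF) class
fingerprint drives the spectral partition: its local extrema and inflection
points inside a search window are the characteristic wavelengths, and the
band-set families derived from them define the spectral sub-images.

Standard deviations use the population convention (divide by n) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import NucleusROI
from .subimages import BandSpec

__all__ = [
    "SpectralFingerprint",
    "CharacteristicWavelengths",
    "nucleus_fingerprint",
    "class_fingerprint",
    "find_characteristic_wavelengths",
    "make_band_specs",
]


@dataclass
class SpectralFingerprint:
    wavelengths: np.ndarray
    mean_intensity: np.ndarray
    sd_intensity: np.ndarray
    n: int
    level: str  # "nucleus" or "class"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=float)
        self.sd_intensity = np.asarray(self.sd_intensity, dtype=float)
        if not (len(self.wavelengths) == len(self.mean_intensity)
                == len(self.sd_intensity)):
            raise ValueError("fingerprint arrays must share one length")
        if np.any(self.mean_intensity < 0) or np.any(self.sd_intensity < 0):
            raise ValueError("fingerprint mean and sd must be nonnegative")


@dataclass
class CharacteristicWavelengths:
    maxima_nm: list[float]
    minima_nm: list[float]
    inflections_nm: list[float]
    search_window_nm: tuple[float, float]

    @property
    def extrema_nm(self) -> list[float]:
        return sorted(self.maxima_nm + self.minima_nm)


def nucleus_fingerprint(roi: NucleusROI) -> SpectralFingerprint:
    """Per-band mean and population sd over the nucleus's in-mask pixels."""
    pixels = roi.in_mask()  # (area_px, n_bands)
    return SpectralFingerprint(
        wavelengths=roi.cube.wavelengths.copy(),
        mean_intensity=pixels.mean(axis=0),
        sd_intensity=pixels.std(axis=0),
        n=roi.area_px,
        level="nucleus",
    )


def class_fingerprint(fps: list[SpectralFingerprint]) -> SpectralFingerprint:
    """Unweighted per-band mean over nuclei (each nucleus counts once).

    The sd is the population spread of nucleus means across the class,
    matching the per-band error bars on class spectra.
    """
    if not fps:
        raise ValueError("need at least one nucleus fingerprint")
    wl = fps[0].wavelengths
    for fp in fps[1:]:
        if fp.wavelengths.shape != wl.shape or not np.allclose(
                fp.wavelengths, wl):
            raise ValueError("nucleus fingerprints use different "
                             "wavelength grids")
    stack = np.vstack([fp.mean_intensity for fp in fps])
    return SpectralFingerprint(
        wavelengths=wl.copy(),
        mean_intensity=stack.mean(axis=0),
        sd_intensity=stack.std(axis=0),
        n=len(fps),
        level="class",
    )


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float)
    pad = window // 2
    padded = np.pad(y, pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def _sign_changes(values: np.ndarray):
    """Yield ``(left_index, right_index, from_sign, to_sign)`` for each
    transition between consecutive *nonzero* signs, skipping flat runs."""
    signs = np.sign(values)
    nz = np.nonzero(signs)[0]
    for a, b in zip(nz[:-1], nz[1:]):
        if signs[a] != signs[b]:
            yield a, b, signs[a], signs[b]


def find_characteristic_wavelengths(
        fp: SpectralFingerprint,
        search_window_nm: tuple[float, float] = (405.0, 470.0),
        smooth_window: int = 3,
        curvature_tol: float = 0.05) -> CharacteristicWavelengths:
    """Detect extrema and inflection points of a fingerprint.

    The spectrum is smoothed by a centered moving average of
    ``smooth_window`` bands (odd, >= 1), then maxima/minima are read off
    sign changes of the first difference and inflections off sign changes
    of the second difference.  Flat plateaus resolve to their center band.
    Results are the band centers inside the search window, ascending.

    ``curvature_tol`` suppresses spurious inflections from measurement
    noise: second differences smaller than this fraction of the window's
    peak curvature count as zero, so only transitions between significant
    concavity and convexity register (0 disables the dead zone).
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be an odd count >= 1")
    wl = fp.wavelengths
    lo, hi = search_window_nm
    if lo < wl[0] or hi > wl[-1]:
        raise ValueError(
            f"search window {search_window_nm} outside the wavelength range "
            f"[{wl[0]}, {wl[-1]}]"
        )
    in_window = np.nonzero((wl >= lo) & (wl <= hi))[0]
    if in_window.size < 3:
        raise ValueError(
            f"search window {search_window_nm} covers {in_window.size} bands; "
            "need at least 3"
        )

    y = _smooth(fp.mean_intensity, smooth_window)

    maxima: list[float] = []
    minima: list[float] = []
    d1 = np.diff(y)
    # d1[i] is the slope between bands i and i+1; a +/- transition between
    # nonzero slopes d1[a] and d1[b] brackets an extremum on bands a+1..b,
    # whose center is taken (the midpoint of a flat plateau).
    for a, b, s_from, s_to in _sign_changes(d1):
        band = (a + 1 + b) // 2
        if s_from > 0:
            maxima.append(wl[band])
        else:
            minima.append(wl[band])

    inflections: list[float] = []
    d2_raw = np.diff(y, 2)
    d2 = d2_raw
    if curvature_tol > 0:
        # Curvature indices i correspond to bands i+1; judge significance
        # against the peak curvature inside the search window.
        win_curv = np.abs(d2_raw[np.clip(in_window - 1, 0, len(d2_raw) - 1)])
        dead = curvature_tol * win_curv.max()
        d2 = np.where(np.abs(d2_raw) < dead, 0.0, d2_raw)
    # d2[i] is the curvature at band i+1; a transition between significant
    # curvatures of opposite sign at indices a < b (any dead-zone run in
    # between) marks an inflection at the band where the raw curvature is
    # closest to zero, i.e. nearest the true crossing.
    for a, b, _s_from, _s_to in _sign_changes(d2):
        i_star = a + int(np.argmin(np.abs(d2_raw[a:b + 1])))
        inflections.append(wl[i_star + 1])

    keep = lambda vals: sorted(v for v in vals if lo <= v <= hi)
    return CharacteristicWavelengths(
        maxima_nm=keep(maxima),
        minima_nm=keep(minima),
        inflections_nm=keep(inflections),
        search_window_nm=(lo, hi),
    )


def make_band_specs(cw: CharacteristicWavelengths,
                    full_range_nm: tuple[float, float] = (400.0, 1000.0)
                    ) -> list[BandSpec]:
    """Enumerate the band-set families defined by characteristic wavelengths.

    In order: (i) the full spectral range; (ii) one pointwise spec per
    extremum, ascending; (iii) one interval per consecutive inflection pair,
    then one per consecutive extremum pair, plus the outer first-to-last
    maximum interval when it is not already present.
    """
    specs = [BandSpec.full(*full_range_nm)]
    extrema = cw.extrema_nm
    for w in extrema:
        specs.append(BandSpec.pointwise(w))
    for a, b in zip(cw.inflections_nm[:-1], cw.inflections_nm[1:]):
        specs.append(BandSpec.interval(a, b))
    pairs = list(zip(extrema[:-1], extrema[1:]))
    if len(cw.maxima_nm) >= 2:
        outer = (cw.maxima_nm[0], cw.maxima_nm[-1])
        if outer not in pairs:
            pairs.append(outer)
    for a, b in pairs:
        specs.append(BandSpec.interval(a, b))
    return specs
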