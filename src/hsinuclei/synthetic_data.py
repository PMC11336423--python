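"""Seeded synthetic phantoms of darkfield hyperspectral nucleus images.

Real acquisitions of chondrosarcoma nuclei are large microscope exports;
this module generates stand-ins with the statistical structure the analysis
relies on, so every downstream stage is testable offline:

* a wavelength grid of 468 bands spanning 400-1000 nm (~1.28 nm spacing);
* elliptical nucleus regions of thousands of pixels at 107.5 nm/pixel;
* class-conditional spectral fingerprints -- the non-irradiated (REF) class
  shows two scattering maxima near 424 and 445 nm separated by a minimum
  near 436 nm, with inflection points near 415, 430, 440 and 460 nm; the
  carbon-ion class (CI) lacks the second maximum; the X-ray class (XR) has
  both maxima with their intensities exchanged;
* a band-localized, spatially correlated texture alteration applied to
  irradiated nuclei only, emulating clustered damage at the ~1.5 um scale.

The fingerprint model is a smooth scattering baseline plus two Gaussian
peaks and a Gaussian notch.  Component centers are calibrated so that the
*summed* REF spectrum places its local extrema and inflection points on the
grid bands nearest the nominal wavelengths above (overlapping components
shift extrema away from their individual centers, so component centers and
spectrum extrema differ deliberately).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .hsi_io import BinaryMask, SpectralCube

__all__ = [
    "FingerprintParams",
    "PhantomConfig",
    "default_wavelength_grid",
    "class_fingerprint_model",
    "generate_phantom",
    "generate_phantom_cohort",
    "generate_feature_table",
]


def default_wavelength_grid(start_nm: float = 400.0, stop_nm: float = 1000.0,
                            n_bands: int = 468) -> np.ndarray:
    """The acquisition band grid: 468 centers from 400 to 1000 nm (~1.28 nm)."""
    return np.linspace(start_nm, stop_nm, n_bands)


@dataclass(frozen=True)
class FingerprintParams:
    """Parameters of the class fingerprint model.

    ``peak_centers_nm``/``dip_center_nm`` are Gaussian *component* centers;
    the ``expected_*`` fields record where the summed REF spectrum's features
    land with the defaults (the nominal characteristic wavelengths).  The dip
    is a notch carved between the two maxima, so it is dropped whenever
    either peak amplitude is zero.
    """

    peak_centers_nm: tuple[float, float] = (421.358, 444.803)
    peak_amps: tuple[float, float] = (0.984, 1.508)
    peak_sigmas_nm: tuple[float, float] = (7.119, 13.804)
    dip_center_nm: float = 437.431
    dip_amp: float = 0.166
    dip_sigma_nm: float = 3.022
    baseline_amp: float = 0.25
    baseline_center_nm: float = 520.0
    baseline_width_nm: float = 180.0
    expected_maxima_nm: tuple[float, float] = (424.0, 445.0)
    expected_minimum_nm: float = 436.0
    expected_inflections_nm: tuple[float, ...] = (415.0, 430.0, 440.0, 460.0)


def class_fingerprint_model(class_label: str, wavelengths,
                            params: FingerprintParams | None = None
                            ) -> np.ndarray:
    """Mean spectrum of one nucleus class on ``wavelengths``.

    REF uses the parameters as given; CI zeroes the second peak (and hence
    the inter-peak dip); XR exchanges the two peak amplitudes.
    """
    params = params or FingerprintParams()
    wl = np.asarray(wavelengths, dtype=float)
    for c in params.peak_centers_nm:
        if not (wl[0] <= c <= wl[-1]):
            raise ValueError(
                f"peak center {c} nm outside wavelength range "
                f"[{wl[0]}, {wl[-1]}] nm"
            )

    a1, a2 = params.peak_amps
    if class_label == "REF":
        amps = (a1, a2)
    elif class_label == "CI":
        amps = (a1, 0.0)
    elif class_label == "XR":
        amps = (a2, a1)
    else:
        raise ValueError(f"unknown class label {class_label!r}")

    spectrum = params.baseline_amp * np.exp(
        -((wl - params.baseline_center_nm) / params.baseline_width_nm) ** 2
    )
    for amp, center, sigma in zip(amps, params.peak_centers_nm,
                                  params.peak_sigmas_nm):
        spectrum = spectrum + amp * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
    if amps[0] > 0 and amps[1] > 0:
        spectrum = spectrum - params.dip_amp * np.exp(
            -0.5 * ((wl - params.dip_center_nm) / params.dip_sigma_nm) ** 2
        )
    return spectrum


@dataclass
class PhantomConfig:
    """Geometry, optics and noise of one synthetic field of view.

    Defaults mimic one cropped microscope field holding a few nuclei:
    107.5 nm/pixel sampling, semi-axes 16-26 px (nucleus areas of one to a
    few thousand pixels), alteration injected between 424 and 436 nm with a
    Gaussian random field of ~14 px correlation length (~1.5 um), 5%
    multiplicative noise, and a small positive darkfield background (1% of
    the fingerprint peak).
    """

    image_shape: tuple[int, int] = (256, 256)
    n_nuclei_per_class: tuple[int, int, int] = (2, 1, 1)  # REF, CI, XR
    ellipse_axes_px: tuple[float, float] = (16.0, 26.0)
    wavelengths: np.ndarray = field(default_factory=default_wavelength_grid)
    fingerprint_params: FingerprintParams = field(
        default_factory=FingerprintParams)
    alteration_band_nm: tuple[float, float] = (424.0, 436.0)
    alteration_amp: float = 0.25
    texture_corr_len_px: float = 14.0
    noise_cv: float = 0.05
    background_frac: float = 0.01
    pixel_size_nm: float = 107.5
    max_placement_tries: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        lo, hi = self.alteration_band_nm
        if not (wl[0] <= lo <= hi <= wl[-1]):
            raise ValueError(
                f"alteration band {self.alteration_band_nm} outside the "
                f"wavelength range [{wl[0]}, {wl[-1]}]"
            )
        if self.texture_corr_len_px < 1:
            raise ValueError("texture_corr_len_px must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def _ellipse_mask(shape, center, axes, angle, inflate=0.0):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    a, b = axes[0] + inflate, axes[1] + inflate
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _correlated_field(shape, corr_len_px, rng):
    """Zero-mean, unit-variance Gaussian random field (smoothed white noise).

    The smoothing kernel's standard deviation is half the nominal
    correlation length, giving blobs of roughly ``corr_len_px`` extent.
    """
    white = rng.standard_normal(shape)
    smooth = gaussian_filter(white, sigma=corr_len_px / 2.0, mode="reflect")
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return (smooth - smooth.mean()) / sd


def generate_phantom(config: PhantomConfig
                     ) -> tuple[SpectralCube, list[BinaryMask], list[str]]:
    """Render one synthetic field: cube, per-nucleus masks, class labels.

    Nuclei are placed by rejection sampling with a 2 px gap; failure to
    place every requested nucleus within ``max_placement_tries`` attempts
    each raises an error reporting how many were placed.  Each nucleus pixel
    spectrum is ``fingerprint x (1 + amp * g(x, y))`` on the alteration
    band (irradiated classes only, ``g`` the correlated field) times
    ``(1 + noise_cv * eps)`` i.i.d. multiplicative noise, clipped to stay
    nonnegative.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    wl = np.asarray(config.wavelengths, dtype=float)
    rows, cols = config.image_shape
    n_bands = wl.size

    spectra = {lab: class_fingerprint_model(lab, wl, config.fingerprint_params)
               for lab in ("REF", "CI", "XR")}
    peak = max(s.max() for s in spectra.values())
    background = config.background_frac * peak

    lo, hi = config.alteration_band_nm
    alt_sel = (wl >= lo - 1e-9) & (wl <= hi + 1e-9)

    cube = np.full((rows, cols, n_bands), background, dtype=np.float32)
    occupancy = np.zeros((rows, cols), dtype=bool)
    masks: list[BinaryMask] = []
    labels: list[str] = []

    requested = [("REF", config.n_nuclei_per_class[0]),
                 ("CI", config.n_nuclei_per_class[1]),
                 ("XR", config.n_nuclei_per_class[2])]
    amin, amax = config.ellipse_axes_px
    idx = 0
    for label, count in requested:
        for _ in range(count):
            placed = False
            for _try in range(config.max_placement_tries):
                axes = rng.uniform(amin, amax, size=2)
                margin = axes.max() + 2
                if 2 * margin >= min(rows, cols):
                    continue
                center = (rng.uniform(margin, rows - margin),
                          rng.uniform(margin, cols - margin))
                angle = rng.uniform(0, np.pi)
                # 2 px inflation keeps a gap between neighboring nuclei.
                inflated = _ellipse_mask((rows, cols), center, axes, angle,
                                         inflate=2.0)
                if not (inflated & occupancy).any():
                    mask = _ellipse_mask((rows, cols), center, axes, angle)
                    occupancy |= inflated
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"could not place nucleus {idx} without overlap after "
                    f"{config.max_placement_tries} tries; placed {len(masks)} "
                    f"of {sum(c for _, c in requested)}"
                )
            nucleus_id = f"N{idx:03d}_{label}"
            masks.append(BinaryMask(mask.astype(np.uint8),
                                    nucleus_id=nucleus_id, class_label=label))
            labels.append(label)

            # Paint the nucleus into its bounding box only.
            rr, cc = np.nonzero(mask)
            r0, r1 = rr.min(), rr.max() + 1
            c0, c1 = cc.min(), cc.max() + 1
            sub_mask = mask[r0:r1, c0:c1]
            box = np.broadcast_to(spectra[label],
                                  (r1 - r0, c1 - c0, n_bands)).copy()
            if label in ("CI", "XR") and config.alteration_amp > 0:
                g = _correlated_field(sub_mask.shape,
                                      config.texture_corr_len_px, rng)
                gain = np.clip(1.0 + config.alteration_amp * g, 0.05, None)
                box[:, :, alt_sel] *= gain[:, :, None]
            if config.noise_cv > 0:
                eps = rng.standard_normal(box.shape)
                box *= np.clip(1.0 + config.noise_cv * eps, 0.0, None)
            region = cube[r0:r1, c0:c1]
            region[sub_mask.astype(bool)] = box[sub_mask.astype(bool)]
            idx += 1

    out = SpectralCube(cube, wl, pixel_size_nm=config.pixel_size_nm,
                       meta={"description": "synthetic phantom",
                             "seed": config.seed})
    return out, masks, labels


def generate_phantom_cohort(n_per_class: tuple[int, int, int],
                            config: PhantomConfig | None = None,
                            nuclei_per_field: int = 4,
                            seed: int = 0):
    """Generate a cohort of nucleus ROIs across as many fields as needed.

    A microscope session yields a few nuclei per field of view; this helper
    renders fields (seeded ``seed``, ``seed + 1``, ...) until the requested
    per-class counts are met and returns the masked ROIs.  Keeping fields
    small bounds peak memory regardless of cohort size.
    """
    from .segmentation import apply_mask

    base = config or PhantomConfig()
    remaining = list(n_per_class)
    rois = []
    field_seed = seed
    while any(r > 0 for r in remaining):
        take = [0, 0, 0]
        budget = nuclei_per_field
        for i in range(3):
            take[i] = min(remaining[i], budget)
            budget -= take[i]
        cfg = replace(base, n_nuclei_per_class=tuple(take), seed=field_seed)
        cube, masks, _ = generate_phantom(cfg)
        for mask in masks:
            roi = apply_mask(cube, mask)
            roi.nucleus_id = f"F{field_seed}_{mask.nucleus_id}"
            roi.mask.nucleus_id = roi.nucleus_id
            rois.append(roi)
        remaining = [r - t for r, t in zip(remaining, take)]
        field_seed += 1
    return rois


def generate_feature_table(n_per_class: tuple[int, int] = (60, 60),
                           effect_size: float = 1.0,
                           n_features: int = 6,
                           n_informative: int = 3,
                           seed: int = 0,
                           labels: tuple[str, str] = ("REF", "CI"),
                           band_label: str = "synthetic",
                           group: str = "texture") -> pd.DataFrame:
    """Two-class Gaussian feature table for testing the classifier stage.

    The first ``n_informative`` features of the second class are shifted by
    ``effect_size`` standard deviations; the rest are pure noise.  Columns
    match the long feature-table layout (``nucleus_id``, ``class_label``,
    ``band_label``, ``group``, then feature columns); when ``n_features``
    matches the chosen group's size the canonical feature names are used so
    the table plugs straight into the classification stage.
    """
    from .spatial_features import ROUGHNESS_NAMES, TEXTURE_NAMES

    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if not 0 < n_informative <= n_features:
        raise ValueError("need 0 < n_informative <= n_features")
    rng = np.random.default_rng(seed)
    n0, n1 = n_per_class
    X0 = rng.standard_normal((n0, n_features))
    X1 = rng.standard_normal((n1, n_features))
    X1[:, :n_informative] += effect_size
    X = np.vstack([X0, X1])
    y = [labels[0]] * n0 + [labels[1]] * n1
    if group == "texture" and n_features == len(TEXTURE_NAMES):
        names = list(TEXTURE_NAMES)
    elif group == "roughness" and n_features == len(ROUGHNESS_NAMES):
        names = list(ROUGHNESS_NAMES)
    else:
        names = [f"f{i}" for i in range(n_features)]
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "group", group)
    df.insert(0, "band_label", band_label)
    df.insert(0, "class_label", y)
    df.insert(0, "nucleus_id", [f"S{i:04d}" for i in range(n0 + n1)])
    return df
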