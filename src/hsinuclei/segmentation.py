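"""Masked nucleus ROIs.

Nucleus outlines are drawn by hand on the darkfield images and supplied as
binary mask files; this module only *applies* them.  Masking follows the
multiply-and-crop convention: out-of-mask intensities are zeroed and the
cube is cropped to the mask's bounding box, while the mask itself is kept
so downstream statistics can exclude background pixels rather than treat
them as true zero intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .hsi_io import BinaryMask, SpectralCube, read_envi_cube, read_mask

__all__ = ["NucleusROI", "apply_mask", "load_cohort"]

logger = logging.getLogger(__name__)


@dataclass
class NucleusROI:
    """One nucleus: a cube and mask cropped to the mask's bounding box."""

    cube: SpectralCube
    mask: BinaryMask
    nucleus_id: str
    class_label: str
    area_px: int

    def in_mask(self) -> np.ndarray:
        """In-mask pixel spectra as an ``(area_px, n_bands)`` array."""
        return self.cube.intensities[self.mask.values.astype(bool)]


def apply_mask(cube: SpectralCube, mask: BinaryMask) -> NucleusROI:
    """Restrict ``cube`` to one nucleus.

    The mask must share the cube's spatial shape and be nonempty.  In-mask
    spectra are copied verbatim; out-of-mask intensities are zeroed
    (multiplication by the binary mask) and the result is cropped to the
    mask's bounding box.  Idempotent: re-masking an ROI with its own mask
    changes nothing.
    """
    spatial = cube.intensities.shape[:2]
    if mask.values.shape != spatial:
        raise ValueError(
            f"mask shape {mask.values.shape} does not match cube spatial "
            f"shape {spatial}"
        )
    rr, cc = np.nonzero(mask.values)
    if rr.size == 0:
        raise ValueError(f"mask {mask.nucleus_id!r} is empty")
    r0, r1 = rr.min(), rr.max() + 1
    c0, c1 = cc.min(), cc.max() + 1

    sub_mask = mask.values[r0:r1, c0:c1]
    sub = cube.intensities[r0:r1, c0:c1] * sub_mask[:, :, None]
    cropped_cube = SpectralCube(sub, cube.wavelengths.copy(),
                                pixel_size_nm=cube.pixel_size_nm,
                                meta=dict(cube.meta))
    cropped_mask = BinaryMask(sub_mask, nucleus_id=mask.nucleus_id,
                              class_label=mask.class_label)
    return NucleusROI(cube=cropped_cube, mask=cropped_mask,
                      nucleus_id=mask.nucleus_id,
                      class_label=mask.class_label,
                      area_px=cropped_mask.area_px)


def load_cohort(manifest_path, min_area_px: int = 50) -> list[NucleusROI]:
    """Load every nucleus listed in a manifest CSV.

    The manifest has columns ``cube_path, mask_path, nucleus_id,
    class_label``; paths are resolved relative to the manifest's directory.
    Cubes referenced by several masks are read once.  Nuclei smaller than
    ``min_area_px`` are rejected as segmentation artifacts.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    if df.empty:
        logger.warning("manifest %s is empty; returning empty cohort",
                       manifest_path)
        return []
    required = {"cube_path", "mask_path", "nucleus_id", "class_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {manifest_path} lacks columns {missing}")
    dupes = df["nucleus_id"][df["nucleus_id"].duplicated()]
    if not dupes.empty:
        raise ValueError(
            f"duplicate nucleus_id values in manifest: {sorted(set(dupes))}"
        )

    root = manifest_path.parent
    cube_cache: dict[str, SpectralCube] = {}
    rois: list[NucleusROI] = []
    for i, row in df.iterrows():
        cube_path = root / row["cube_path"]
        mask_path = root / row["mask_path"]
        for p in (cube_path, mask_path):
            if not p.exists():
                raise FileNotFoundError(
                    f"manifest row {i} (nucleus {row['nucleus_id']!r}) "
                    f"references missing file {p}"
                )
        key = str(cube_path)
        if key not in cube_cache:
            cube_cache[key] = read_envi_cube(cube_path)
        mask = read_mask(mask_path, nucleus_id=str(row["nucleus_id"]),
                         class_label=str(row["class_label"]))
        roi = apply_mask(cube_cache[key], mask)
        if roi.area_px < min_area_px:
            raise ValueError(
                f"nucleus {roi.nucleus_id!r} has area {roi.area_px} px, below "
                f"the minimum {min_area_px}"
            )
        rois.append(roi)

    counts = pd.Series([r.class_label for r in rois]).value_counts().to_dict()
    logger.info("loaded cohort of %d nuclei: %s", len(rois), counts)
    return rois
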