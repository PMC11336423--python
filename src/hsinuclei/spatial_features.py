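"""Texture and roughness features of masked sub-images.

Radiation damage clusters at the micrometer scale, so it shows up as local
intensity structure inside the nucleus rather than as a global brightness
change.  Two feature groups capture this on each spectral sub-image:

* six gray-level co-occurrence (GLCM) texture parameters -- contrast,
  correlation, energy, homogeneity, entropy, dissimilarity -- at pixel
  distance 1 along directions 0, 45, 180 and 315 degrees, averaged over
  the four directions;
* seven roughness parameters of the in-mask intensity distribution --
  mean, RMS, skewness, kurtosis, minimum, maximum, and the sum of the
  averages of the five highest local maxima and five lowest local minima.

The co-occurrence computation is mask-aware: a pixel pair counts only when
both pixels lie inside the nucleus, so background never contaminates the
statistics.  Intensities are min-max quantized over the in-mask range
(default 32 levels), which makes all six texture features invariant to
positive affine rescaling of the sub-image.

Conventions (they differ across libraries, so they are fixed here): energy
is the angular second moment sum(P^2); entropy is base 2 with 0*log0 = 0;
correlation of a zero-variance matrix is 1; moments are population moments;
kurtosis is excess (Gaussian -> 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .subimages import SubImage

__all__ = [
    "TextureConfig",
    "FeatureVector",
    "TEXTURE_NAMES",
    "ROUGHNESS_NAMES",
    "quantize_masked",
    "cooccurrence",
    "texture_features",
    "roughness_features",
    "build_feature_table",
]

TEXTURE_NAMES = ("contrast", "correlation", "energy", "homogeneity",
                 "entropy", "dissimilarity")
ROUGHNESS_NAMES = ("mean", "rms", "skewness", "kurtosis", "min", "max",
                   "extrema5")

# Ordered (row, col) pixel offsets per direction, distance 1.
OFFSETS = {0: (0, 1), 45: (-1, 1), 180: (0, -1), 315: (1, 1)}


@dataclass(frozen=True)
class TextureConfig:
    levels: int = 32
    distance: int = 1
    angles_deg: tuple[int, ...] = (0, 45, 180, 315)
    symmetric: bool = False

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("need at least 2 quantization levels")
        bad = set(self.angles_deg) - set(OFFSETS)
        if bad:
            raise ValueError(f"unsupported angles {sorted(bad)}; "
                             f"supported: {sorted(OFFSETS)}")


@dataclass
class FeatureVector:
    nucleus_id: str
    class_label: str
    band_label: str
    group: str  # "texture" | "roughness"
    names: tuple[str, ...]
    values: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def quantize_masked(sub: SubImage, levels: int = 32) -> np.ndarray:
    """Min-max quantize the in-mask values into ``{0 .. levels-1}``.

    A constant sub-image maps to level 0 everywhere.  Out-of-mask entries
    are set to 0 but carry no meaning; consumers must re-apply the mask.
    """
    inside = sub.mask.values.astype(bool)
    vals = sub.values[inside]
    q = np.zeros(sub.values.shape, dtype=np.intp)
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        scaled = (sub.values - lo) / (hi - lo) * levels
        q_all = np.clip(np.floor(scaled), 0, levels - 1).astype(np.intp)
        q[inside] = q_all[inside]
    return q


def cooccurrence(q: np.ndarray, mask: np.ndarray, angle_deg: int,
                 distance: int = 1, levels: int | None = None,
                 symmetric: bool = False) -> np.ndarray:
    """Normalized co-occurrence matrix of ordered in-mask pixel pairs.

    A pair ``(p, p + offset)`` counts only when both pixels are in-mask.
    The matrix is normalized to sum 1 and left non-symmetric by default
    (the 180-degree matrix is then the transpose of the 0-degree one).
    """
    if angle_deg not in OFFSETS:
        raise ValueError(f"unsupported angle {angle_deg}")
    mask = mask.astype(bool)
    if levels is None:
        levels = int(q[mask].max()) + 1 if mask.any() else 1
    dr, dc = OFFSETS[angle_deg]
    dr *= distance
    dc *= distance
    rows, cols = q.shape

    r0s, r0e = max(0, -dr), min(rows, rows - dr)
    c0s, c0e = max(0, -dc), min(cols, cols - dc)
    if r0s >= r0e or c0s >= c0e:
        raise ValueError(f"no pixel pairs fit offset for angle {angle_deg}")
    src = np.s_[r0s:r0e, c0s:c0e]
    dst = np.s_[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
    valid = mask[src] & mask[dst]
    if not valid.any():
        raise ValueError(
            f"no in-mask pixel pair for angle {angle_deg} at distance "
            f"{distance}"
        )
    i = q[src][valid]
    j = q[dst][valid]
    P = np.zeros((levels, levels))
    np.add.at(P, (i, j), 1.0)
    if symmetric:
        P = P + P.T
    return P / P.sum()


def _texture_from_matrix(P: np.ndarray) -> dict[str, float]:
    levels = P.shape[0]
    i, j = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    diff = i - j
    contrast = float((diff ** 2 * P).sum())
    dissimilarity = float((np.abs(diff) * P).sum())
    homogeneity = float((P / (1.0 + diff ** 2)).sum())
    energy = float((P ** 2).sum())
    nz = P[P > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = float((np.arange(levels) * pi).sum())
    mu_j = float((np.arange(levels) * pj).sum())
    var_i = float(((np.arange(levels) - mu_i) ** 2 * pi).sum())
    var_j = float(((np.arange(levels) - mu_j) ** 2 * pj).sum())
    if var_i <= 0 or var_j <= 0:
        correlation = 1.0
    else:
        correlation = float(
            (((i - mu_i) * (j - mu_j) * P).sum()) / np.sqrt(var_i * var_j))
    return {
        "contrast": contrast,
        "correlation": correlation,
        "energy": energy,
        "homogeneity": homogeneity,
        "entropy": entropy,
        "dissimilarity": dissimilarity,
    }


def texture_features(sub: SubImage, cfg: TextureConfig | None = None
                     ) -> FeatureVector:
    """Six GLCM texture parameters, averaged over the configured directions."""
    cfg = cfg or TextureConfig()
    if sub.mask.area_px < 2:
        raise ValueError("texture features need a mask of at least 2 pixels")
    q = quantize_masked(sub, cfg.levels)
    mask = sub.mask.values.astype(bool)
    per_dir = []
    for angle in cfg.angles_deg:
        P = cooccurrence(q, mask, angle, distance=cfg.distance,
                         levels=cfg.levels, symmetric=cfg.symmetric)
        per_dir.append(_texture_from_matrix(P))
    values = np.array([np.mean([d[name] for d in per_dir])
                       for name in TEXTURE_NAMES])
    return FeatureVector(sub.nucleus_id, sub.class_label,
                         sub.band_spec.label, "texture", TEXTURE_NAMES,
                         values)


def _local_extrema(values: np.ndarray, mask: np.ndarray,
                   min_neighbors: int = 3):
    """In-mask 8-neighborhood local maxima and minima.

    A pixel qualifies when it has at least ``min_neighbors`` in-mask
    neighbors and is strictly greater (maxima) / smaller (minima) than all
    of them.
    """
    rows, cols = values.shape
    vpad = np.pad(values.astype(float), 1, mode="constant")
    mpad = np.pad(mask, 1, mode="constant", constant_values=False)
    n_valid = np.zeros((rows, cols), dtype=int)
    is_max = np.ones((rows, cols), dtype=bool)
    is_min = np.ones((rows, cols), dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nb_vals = vpad[1 + dr:1 + dr + rows, 1 + dc:1 + dc + cols]
            nb_mask = mpad[1 + dr:1 + dr + rows, 1 + dc:1 + dc + cols]
            n_valid += nb_mask
            is_max &= ~nb_mask | (values > nb_vals)
            is_min &= ~nb_mask | (values < nb_vals)
    ok = mask & (n_valid >= min_neighbors)
    return values[ok & is_max], values[ok & is_min]


def roughness_features(sub: SubImage) -> FeatureVector:
    """Seven roughness parameters of the in-mask intensity distribution.

    ``extrema5`` sums the mean of the five highest local maxima and the
    mean of the five lowest local minima; with fewer than five of either,
    those found are averaged, and with none the global max (resp. min)
    stands in.  Skewness and kurtosis of a zero-variance field are 0.
    """
    h = sub.in_mask().astype(float)
    mean = float(h.mean())
    rms = float(np.sqrt(np.mean(h ** 2)))
    centered = h - mean
    m2 = float(np.mean(centered ** 2))
    if m2 > 0:
        skewness = float(np.mean(centered ** 3) / m2 ** 1.5)
        kurtosis = float(np.mean(centered ** 4) / m2 ** 2 - 3.0)
    else:
        skewness = 0.0
        kurtosis = 0.0
    hmin = float(h.min())
    hmax = float(h.max())

    mask = sub.mask.values.astype(bool)
    loc_max, loc_min = _local_extrema(sub.values, mask)
    top = np.sort(loc_max)[-5:] if loc_max.size else np.array([hmax])
    bottom = np.sort(loc_min)[:5] if loc_min.size else np.array([hmin])
    extrema5 = float(top.mean() + bottom.mean())

    values = np.array([mean, rms, skewness, kurtosis, hmin, hmax, extrema5])
    return FeatureVector(sub.nucleus_id, sub.class_label,
                         sub.band_spec.label, "roughness", ROUGHNESS_NAMES,
                         values)


def build_feature_table(subs: dict, cfg: TextureConfig | None = None,
                        groups: tuple[str, ...] = ("texture", "roughness")
                        ) -> pd.DataFrame:
    """Long feature table: one row per (nucleus, band set, feature group).

    Columns are ``nucleus_id, class_label, band_label, group`` followed by
    the six texture then seven roughness feature columns; the columns of
    the other group are left NaN in each row.  Rows are sorted by
    ``(nucleus_id, band_label, group)`` so the table is order-invariant.
    """
    if not subs:
        raise ValueError("no sub-images supplied")
    cfg = cfg or TextureConfig()
    records = []
    for sub in subs.values():
        if "texture" in groups:
            records.append(texture_features(sub, cfg))
        if "roughness" in groups:
            records.append(roughness_features(sub))
    all_names = list(TEXTURE_NAMES) + list(ROUGHNESS_NAMES)
    rows = []
    for fv in records:
        row = {"nucleus_id": fv.nucleus_id, "class_label": fv.class_label,
               "band_label": fv.band_label, "group": fv.group}
        row.update({name: np.nan for name in all_names})
        row.update(fv.as_dict())
        rows.append(row)
    df = pd.DataFrame(rows, columns=["nucleus_id", "class_label",
                                     "band_label", "group"] + all_names)
    return df.sort_values(["nucleus_id", "band_label", "group"],
                          kind="stable").reset_index(drop=True)
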