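"""Reference point-metric tables from the original irradiation experiment.

The darkfield hyperspectral study of carbon-ion (CI) and X-ray (XR)
irradiated chondrosarcoma nuclei reported its classifier point metrics
(SEN, ACC, PREC, two decimals) per spectral band set and feature group.
Those printed values are bundled here as worked-example inputs: they
exercise the F1 arithmetic and the enabling/priority selection rules on
known data, independent of any synthetic cohort.  They are *inputs* to the
rule machinery, not outputs of this package.
"""

from __future__ import annotations

from .classification import MetricsRecord, f1_score

__all__ = [
    "WHOLE_SPECTRUM_METRICS",
    "POINTWISE_METRICS",
    "SUBINTERVAL_METRICS",
    "SUBINTERVAL_F1_TEXTURE",
    "subinterval_records",
    "whole_spectrum_records",
]

# (radiation, band_label, group) -> (SEN, ACC, PREC), on the 400-1000 nm
# whole-spectrum sub-image.
WHOLE_SPECTRUM_METRICS = {
    ("CI", "400-1000nm", "texture"): (1.00, 1.00, 1.00),
    ("CI", "400-1000nm", "roughness"): (0.96, 0.82, 0.81),
    ("XR", "400-1000nm", "texture"): (1.00, 0.95, 0.93),
    ("XR", "400-1000nm", "roughness"): (0.96, 0.76, 0.76),
}

# Pointwise band sets at the characteristic extrema.
POINTWISE_METRICS = {
    ("CI", "424nm", "texture"): (0.93, 0.69, 0.71),
    ("CI", "424nm", "roughness"): (0.81, 0.67, 0.73),
    ("CI", "436nm", "texture"): (1.00, 0.69, 0.69),
    ("CI", "436nm", "roughness"): (0.95, 0.80, 0.81),
    ("CI", "445nm", "texture"): (0.96, 0.67, 0.68),
    ("CI", "445nm", "roughness"): (0.96, 0.77, 0.76),
    ("XR", "424nm", "texture"): (0.89, 0.70, 0.75),
    ("XR", "424nm", "roughness"): (1.00, 0.81, 0.79),
    ("XR", "436nm", "texture"): (0.81, 0.70, 0.79),
    ("XR", "436nm", "roughness"): (1.00, 0.84, 0.82),
    ("XR", "445nm", "texture"): (0.89, 0.76, 0.80),
    ("XR", "445nm", "roughness"): (0.93, 0.70, 0.74),
}

# Spectral subintervals delimited by the characteristic wavelengths.
SUBINTERVAL_METRICS = {
    ("CI", "415-430nm", "texture"): (0.88, 0.87, 0.92),
    ("CI", "430-440nm", "texture"): (0.96, 0.92, 0.93),
    ("CI", "440-460nm", "texture"): (0.96, 0.92, 0.93),
    ("CI", "424-436nm", "texture"): (1.00, 0.97, 0.96),
    ("CI", "436-445nm", "texture"): (0.92, 0.89, 0.92),
    ("CI", "424-445nm", "texture"): (0.96, 0.95, 0.96),
    ("CI", "415-430nm", "roughness"): (0.96, 0.76, 0.76),
    ("CI", "430-440nm", "roughness"): (1.00, 0.82, 0.80),
    ("CI", "440-460nm", "roughness"): (0.96, 0.82, 0.81),
    ("CI", "424-436nm", "roughness"): (0.92, 0.76, 0.77),
    ("CI", "436-445nm", "roughness"): (0.96, 0.80, 0.78),
    ("CI", "424-445nm", "roughness"): (1.00, 0.82, 0.79),
    ("XR", "415-430nm", "texture"): (1.00, 0.92, 0.89),
    ("XR", "430-440nm", "texture"): (0.96, 0.89, 0.89),
    ("XR", "440-460nm", "texture"): (1.00, 0.92, 0.89),
    ("XR", "424-436nm", "texture"): (1.00, 0.89, 0.87),
    ("XR", "436-445nm", "texture"): (1.00, 0.94, 0.93),
    ("XR", "424-445nm", "texture"): (0.96, 0.89, 0.89),
    ("XR", "415-430nm", "roughness"): (0.92, 0.72, 0.75),
    ("XR", "430-440nm", "roughness"): (0.96, 0.75, 0.76),
    ("XR", "440-460nm", "roughness"): (0.89, 0.67, 0.72),
    ("XR", "424-436nm", "roughness"): (0.92, 0.72, 0.75),
    ("XR", "436-445nm", "roughness"): (0.84, 0.72, 0.79),
    ("XR", "424-445nm", "roughness"): (0.93, 0.76, 0.78),
}

# Reported F1 scores for the texture group on the subintervals (two
# decimals, derived from the SEN/PREC values above).
SUBINTERVAL_F1_TEXTURE = {
    ("CI", "415-430nm"): 0.90,
    ("CI", "430-440nm"): 0.94,
    ("CI", "440-460nm"): 0.94,
    ("CI", "424-436nm"): 0.98,
    ("CI", "436-445nm"): 0.92,
    ("CI", "424-445nm"): 0.96,
    ("XR", "415-430nm"): 0.94,
    ("XR", "430-440nm"): 0.92,
    ("XR", "440-460nm"): 0.94,
    ("XR", "424-436nm"): 0.93,
    ("XR", "436-445nm"): 0.96,
    ("XR", "424-445nm"): 0.92,
}


def _to_records(table: dict) -> list[MetricsRecord]:
    records = []
    for (radiation, band, group), (sen, acc, prec) in table.items():
        records.append(MetricsRecord(
            sen=sen, acc=acc, prec=prec, f1=f1_score(sen, prec),
            counts=None, context=(radiation, band, group)))
    return records


def subinterval_records(radiation: str | None = None,
                        group: str | None = None) -> list[MetricsRecord]:
    """Subinterval worked-example metrics as records, optionally filtered."""
    records = _to_records(SUBINTERVAL_METRICS)
    if radiation is not None:
        records = [m for m in records if m.context[0] == radiation]
    if group is not None:
        records = [m for m in records if m.context[2] == group]
    return records


def whole_spectrum_records() -> list[MetricsRecord]:
    return _to_records(WHOLE_SPECTRUM_METRICS)
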