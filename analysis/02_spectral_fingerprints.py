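"""Compute nucleus and class spectral fingerprints for the phantom cohort,
detect the characteristic wavelengths on the REF class profile, and derive
the spectral band partition.

Writes per-class fingerprint CSVs, the characteristic wavelengths JSON and
the band-spec list to results/.  Run 01_build_phantom_cohort.py first.
"""

import json
import sys
from collections import defaultdict
from pathlib import Path

import pandas as pd

from hsinuclei import (class_fingerprint, find_characteristic_wavelengths,
                       load_cohort, make_band_specs, nucleus_fingerprint)

ROOT = Path(__file__).resolve().parents[1]
PHANTOM = ROOT / "scratch" / "phantom"
RESULTS = ROOT / "results"


def main() -> None:
    manifest = PHANTOM / "manifest.csv"
    if not manifest.exists():
        sys.exit("no phantom cohort found; run 01_build_phantom_cohort.py")
    cohort = load_cohort(manifest)

    by_class = defaultdict(list)
    for roi in cohort:
        by_class[roi.class_label].append(nucleus_fingerprint(roi))

    frames = []
    class_fps = {}
    for label, fps in sorted(by_class.items()):
        cf = class_fingerprint(fps)
        class_fps[label] = cf
        frames.append(pd.DataFrame({
            "class_label": label, "wavelength_nm": cf.wavelengths,
            "mean_intensity": cf.mean_intensity,
            "sd_intensity": cf.sd_intensity}))
    pd.concat(frames).to_csv(RESULTS / "class_fingerprints.csv", index=False)

    # The partition is driven by the REF (non-irradiated) profile only.
    cw = find_characteristic_wavelengths(class_fps["REF"])
    specs = make_band_specs(cw, full_range_nm=(
        class_fps["REF"].wavelengths[0], class_fps["REF"].wavelengths[-1]))
    (RESULTS / "characteristic_wavelengths.json").write_text(json.dumps({
        "maxima_nm": cw.maxima_nm, "minima_nm": cw.minima_nm,
        "inflections_nm": cw.inflections_nm,
        "search_window_nm": list(cw.search_window_nm),
        "band_specs": [{"kind": s.kind, "low_nm": s.low_nm,
                        "high_nm": s.high_nm, "label": s.label}
                       for s in specs],
    }, indent=2) + "\n")

    print(f"cohort: { {k: len(v) for k, v in sorted(by_class.items())} }")
    print(f"REF maxima at {[round(w, 2) for w in cw.maxima_nm]} nm, "
          f"minimum at {[round(w, 2) for w in cw.minima_nm]} nm")
    print(f"inflections at {[round(w, 2) for w in cw.inflections_nm]} nm")
    print(f"{len(specs)} spectral band sets: "
          f"{[s.label for s in specs]}")


if __name__ == "__main__":
    main()
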