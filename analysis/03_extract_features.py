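"""Collapse every nucleus onto every spectral band set and compute the six
texture and seven roughness parameters on each masked sub-image.

Writes the long feature table (one row per nucleus x band set x feature
group) to results/feature_table.csv.  Run 01 and 02 first.
"""

import json
import sys
from pathlib import Path

from hsinuclei import (BandSpec, build_feature_table, build_subimage_set,
                       load_cohort)

ROOT = Path(__file__).resolve().parents[1]
PHANTOM = ROOT / "scratch" / "phantom"
RESULTS = ROOT / "results"


def main() -> None:
    manifest = PHANTOM / "manifest.csv"
    cw_path = RESULTS / "characteristic_wavelengths.json"
    if not manifest.exists() or not cw_path.exists():
        sys.exit("run 01_build_phantom_cohort.py and "
                 "02_spectral_fingerprints.py first")
    cohort = load_cohort(manifest)
    specs = [BandSpec(s["kind"], s["low_nm"], s["high_nm"], s["label"])
             for s in json.loads(cw_path.read_text())["band_specs"]]

    subs = build_subimage_set(cohort, specs)
    table = build_feature_table(subs)
    table.to_csv(RESULTS / "feature_table.csv", index=False)
    print(f"{len(cohort)} nuclei x {len(specs)} band sets -> "
          f"{len(subs)} sub-images, {len(table)} feature rows")


if __name__ == "__main__":
    main()
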