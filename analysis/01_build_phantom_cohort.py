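"""Build a synthetic phantom cohort and write it to disk as a microscope
session would be stored: ENVI cube per field of view, one PNG mask per
nucleus, and a manifest CSV tying them together.

The cohort mirrors the real study's class imbalance at reduced size
(20 REF, 10 CI, 8 XR nuclei) so the whole analysis chain runs in seconds.
Cubes land under scratch/phantom/ (bulky binaries); the cohort summary
lands under results/.
"""

import sys
from dataclasses import replace
from pathlib import Path

import pandas as pd

from hsinuclei import PhantomConfig, generate_phantom, write_envi_cube, write_mask

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "phantom"
RESULTS = ROOT / "results"

N_PER_CLASS = (20, 10, 8)  # REF, CI, XR
NUCLEI_PER_FIELD = 3
BASE = PhantomConfig(image_shape=(160, 160), ellipse_axes_px=(12.0, 20.0))


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    remaining = list(N_PER_CLASS)
    rows = []
    field_seed = seed
    while any(remaining):
        take = [0, 0, 0]
        budget = NUCLEI_PER_FIELD
        for i in range(3):
            take[i] = min(remaining[i], budget)
            budget -= take[i]
        cfg = replace(BASE, n_nuclei_per_class=tuple(take), seed=field_seed)
        cube, masks, _ = generate_phantom(cfg)
        cube_name = f"field_{field_seed:03d}"
        write_envi_cube(cube, OUT / cube_name)
        for mask in masks:
            nucleus_id = f"F{field_seed:03d}_{mask.nucleus_id}"
            mask_name = f"{nucleus_id}.png"
            mask.nucleus_id = nucleus_id
            write_mask(mask, OUT / mask_name)
            rows.append({"cube_path": f"{cube_name}.hdr",
                         "mask_path": mask_name,
                         "nucleus_id": nucleus_id,
                         "class_label": mask.class_label,
                         "area_px": mask.area_px})
        remaining = [r - t for r, t in zip(remaining, take)]
        field_seed += 1

    manifest = pd.DataFrame(rows)
    manifest[["cube_path", "mask_path", "nucleus_id", "class_label"]].to_csv(
        OUT / "manifest.csv", index=False)
    summary = (manifest.groupby("class_label")["area_px"]
               .agg(["count", "mean", "min", "max"]).round(1))
    summary.to_csv(RESULTS / "cohort_summary.csv")
    print(f"wrote {len(manifest)} nuclei across {field_seed - seed} fields "
          f"to {OUT}")
    print(summary)


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
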