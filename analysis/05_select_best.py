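"""Apply the enabling and priority rules, both to the phantom metrics
computed in step 04 and to the bundled reference metric tables from the
original irradiation experiment (the worked example).

Writes rule reports under results/selection_phantom/ and
results/selection_reference/ and prints the qualifying counts.
"""

import sys
from pathlib import Path

import pandas as pd

from hsinuclei import (MetricsRecord, RuleConfig, count_enabled,
                       count_metric_at_least, emit_reports, f1_score,
                       rank_classifiers)
from hsinuclei.example_metrics import subinterval_records

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def records_from_csv(path: Path) -> list[MetricsRecord]:
    df = pd.read_csv(path)
    return [MetricsRecord(sen=r.sen, acc=r.acc, prec=r.prec,
                          f1=f1_score(r.sen, r.prec),
                          context=(r.radiation, r.band_label, r.group))
            for r in df.itertuples()]


def report(tag: str, records: list[MetricsRecord]) -> None:
    cfg = RuleConfig()
    emit_reports(records, cfg, RESULTS / f"selection_{tag}")
    print(f"--- {tag} ---")
    for radiation in ("CI", "XR"):
        subset = [m for m in records if m.context[0] == radiation]
        texture = [m for m in subset if m.context[2] == "texture"]
        n_en = count_enabled(texture, cfg)
        n_sen = count_metric_at_least(subset, "sen", 0.96)
        ranked = rank_classifiers(subset, cfg)
        top = ranked[0].context[1] if ranked else "none"
        print(f"{radiation}: {n_en} texture band sets pass the enabling "
              f"rule; SEN>=0.96 in {n_sen} cases; best classifier: {top}")


def main() -> None:
    report("reference", subinterval_records())
    phantom_path = RESULTS / "phantom_point_metrics.csv"
    if phantom_path.exists():
        report("phantom", records_from_csv(phantom_path))
    else:
        sys.exit("run 04_train_classifiers.py to also rank the "
                 "phantom classifiers")


if __name__ == "__main__":
    main()
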