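"""Classifier selection rules and report tables.

Classifiers are screened by two cumulative rules applied to their point
metrics, rounded to two decimals as they appear in report tables:

* an *enabling* rule -- SEN >= 0.95, ACC >= 0.91 and PREC >= 0.91 must all
  hold (inclusive thresholds);
* a *priority* rule -- enabled classifiers are ranked lexicographically by
  the greatest SEN, then the greatest ACC, then the greatest PREC; records
  tied on all three keep their input order and are all reported.

Rounding is half-up (0.975 -> 0.98), matching how table values are printed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .classification import MetricsRecord, f1_score

__all__ = [
    "RuleConfig",
    "round2",
    "enabling_rule",
    "rank_classifiers",
    "count_enabled",
    "count_metric_at_least",
    "emit_reports",
]

_METRIC_NAMES = ("sen", "acc", "prec")


@dataclass(frozen=True)
class RuleConfig:
    sen_min: float = 0.95
    acc_min: float = 0.91
    prec_min: float = 0.91
    priority: tuple[str, str, str] = ("sen", "acc", "prec")

    def __post_init__(self) -> None:
        for t in (self.sen_min, self.acc_min, self.prec_min):
            if not 0 <= t <= 1.01 + 1e-9:
                raise ValueError("thresholds must lie in [0, 1] "
                                 "(or just above, to disable)")
        if sorted(self.priority) != sorted(_METRIC_NAMES):
            raise ValueError(
                f"priority must permute {_METRIC_NAMES}; got {self.priority}")


def round2(x: float) -> float:
    """Two-decimal half-up rounding, as printed in report tables."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


def enabling_rule(m: MetricsRecord, cfg: RuleConfig | None = None) -> bool:
    """All three rounded point metrics at or above their thresholds."""
    cfg = cfg or RuleConfig()
    return (round2(m.sen) >= cfg.sen_min
            and round2(m.acc) >= cfg.acc_min
            and round2(m.prec) >= cfg.prec_min)


def rank_classifiers(records: list[MetricsRecord],
                     cfg: RuleConfig | None = None) -> list[MetricsRecord]:
    """Enabled records, best first by the priority rule (stable on ties)."""
    cfg = cfg or RuleConfig()
    enabled = [m for m in records if enabling_rule(m, cfg)]
    key = lambda m: tuple(-round2(getattr(m, name)) for name in cfg.priority)
    return sorted(enabled, key=key)  # sorted() is stable


def count_enabled(records: list[MetricsRecord],
                  cfg: RuleConfig | None = None) -> int:
    cfg = cfg or RuleConfig()
    return sum(enabling_rule(m, cfg) for m in records)


def count_metric_at_least(records: list[MetricsRecord], metric_name: str,
                          threshold: float, group: str | None = None) -> int:
    """Count records whose rounded metric meets ``threshold``; optionally
    restricted to one feature group (the third context element)."""
    if metric_name not in _METRIC_NAMES + ("f1",):
        raise ValueError(f"unknown metric {metric_name!r}")
    out = 0
    for m in records:
        if group is not None and (m.context is None or m.context[2] != group):
            continue
        if round2(getattr(m, metric_name)) >= threshold:
            out += 1
    return out


def _records_frame(records: list[MetricsRecord]) -> pd.DataFrame:
    rows = []
    for m in records:
        radiation, band, grp = m.context if m.context else ("", "", "")
        rows.append({
            "radiation": radiation, "band_label": band, "group": grp,
            "sen": round2(m.sen), "acc": round2(m.acc),
            "prec": round2(m.prec), "f1": round2(m.f1),
        })
    return pd.DataFrame(rows)


def emit_reports(records: list[MetricsRecord], cfg: RuleConfig | None,
                 out_dir) -> dict[str, Path]:
    """Write the report files for a set of classifier records.

    Per radiation type: a point-metric CSV (band x group), an F1 CSV for
    the texture group, a best-classifier JSON holding the full priority
    ranking, and a run-log JSON with the rule configuration.  Output is
    deterministic: rerunning on the same records reproduces the bytes.
    """
    if not records:
        raise ValueError("no records to report")
    cfg = cfg or RuleConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = _records_frame(records)
    paths: dict[str, Path] = {}

    metrics_path = out_dir / "point_metrics.csv"
    frame.sort_values(["radiation", "group", "band_label"],
                      kind="stable").to_csv(metrics_path, index=False)
    paths["point_metrics"] = metrics_path

    f1_frame = frame[frame["group"] == "texture"][
        ["radiation", "band_label", "f1"]]
    if not f1_frame.empty:
        f1_path = out_dir / "f1_texture.csv"
        f1_frame.to_csv(f1_path, index=False)
        paths["f1_texture"] = f1_path

    best: dict[str, list] = {}
    for radiation in sorted({m.context[0] for m in records if m.context}):
        subset = [m for m in records if m.context
                  and m.context[0] == radiation]
        ranking = rank_classifiers(subset, cfg)
        best[radiation] = [
            {"band_label": m.context[1], "group": m.context[2],
             "sen": round2(m.sen), "acc": round2(m.acc),
             "prec": round2(m.prec), "f1": round2(m.f1)}
            for m in ranking
        ]
    best_path = out_dir / "best_classifiers.json"
    best_path.write_text(json.dumps(best, indent=2) + "\n")
    paths["best_classifiers"] = best_path

    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps({
        "rules": {"sen_min": cfg.sen_min, "acc_min": cfg.acc_min,
                  "prec_min": cfg.prec_min,
                  "priority": list(cfg.priority)},
        "n_records": len(records),
        "n_enabled": count_enabled(records, cfg),
    }, indent=2) + "\n")
    paths["run_log"] = log_path
    return paths
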