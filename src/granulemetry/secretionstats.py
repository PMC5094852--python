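"""Secretion-ratio arithmetic, shared summary statistics and reporting.

The proinsulin/insulin ratio is the fraction of unprocessed prohormone in
serum relative to mature hormone — elevated when granule maturation is
impaired.  Summaries follow the mean ± SEM convention (sample sd, n-1
denominator, over sqrt(n)) with round-half-up presentation to one decimal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._util import require, round_half_up

__all__ = [
    "SecretionSample",
    "MeanSem",
    "proinsulin_ratio",
    "mean_sem",
    "build_report",
    "render_report_text",
]


@dataclass(frozen=True)
class SecretionSample:
    """Serum proinsulin and insulin concentrations (pM) for one group."""

    proinsulin_pm: float
    insulin_pm: float
    group: str = ""

    def __post_init__(self) -> None:
        require(
            self.proinsulin_pm >= 0 and self.insulin_pm >= 0,
            "concentrations must be non-negative",
        )

    def ratio_percent(self) -> float:
        return proinsulin_ratio(self.proinsulin_pm, self.insulin_pm)


def proinsulin_ratio(proinsulin_pm: float, insulin_pm: float) -> float:
    """100 x proinsulin / insulin, round-half-up to one decimal.

    Scale-invariant: multiplying both concentrations by the same positive
    factor leaves the percentage unchanged.
    """
    require(proinsulin_pm >= 0, "proinsulin concentration must be non-negative")
    if insulin_pm <= 0:
        raise ValueError("insulin concentration must be positive")
    return round_half_up(100.0 * proinsulin_pm / insulin_pm, 1)


@dataclass(frozen=True)
class MeanSem:
    mean: float
    sem: float
    n: int
    degenerate: bool = False  # n = 1: SEM undefined, reported as 0 with a flag


def mean_sem(values: Sequence[float]) -> MeanSem:
    """Mean and standard error of the mean of a sample."""
    require(len(values) > 0, "mean_sem needs at least one value")
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    if len(arr) == 1:
        return MeanSem(mean=mean, sem=0.0, n=1, degenerate=True)
    sem = float(arr.std(ddof=1) / math.sqrt(len(arr)))
    return MeanSem(mean=mean, sem=sem, n=len(arr))


def build_report(
    granule_summary: Optional[dict] = None,
    fusion: Optional[dict] = None,
    assay: Optional[dict] = None,
    secretion: Optional[dict] = None,
    parameters: Optional[dict] = None,
) -> dict:
    """Consolidated analysis report with deterministic field ordering.

    Sections are included only when provided and echoed unchanged (no silent
    filtering); ``parameters`` records every knob and seed for provenance.
    At least one data section must be present.
    """
    sections = {
        "granules": granule_summary,
        "fusion_3d": fusion,
        "fusion_assay": assay,
        "secretion": secretion,
    }
    present = {k: v for k, v in sections.items() if v is not None}
    require(len(present) > 0, "build_report needs at least one input section")
    report: dict = {"sections": sorted(present)}
    report.update(present)
    if parameters is not None:
        report["parameters"] = parameters
    return report


def _fmt(value, indent: str = "  ") -> list[str]:
    lines = []
    if isinstance(value, dict):
        for key in value:
            sub = value[key]
            if isinstance(sub, (dict, list)):
                lines.append(f"{indent}{key}:")
                lines.extend(_fmt(sub, indent + "  "))
            else:
                lines.append(f"{indent}{key}: {sub}")
    elif isinstance(value, list):
        for item in value:
            lines.append(f"{indent}- {item}")
    else:
        lines.append(f"{indent}{value}")
    return lines


def render_report_text(report: dict) -> str:
    """Human-readable rendering of :func:`build_report` output (byte-stable)."""
    lines = ["granulemetry report", "===================", ""]
    for section in report:
        if section == "sections":
            continue
        lines.append(section)
        lines.extend(_fmt(report[section]))
        lines.append("")
    return "\n".join(lines)


def write_report(report: dict, json_path, text_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=False)
        fh.write("\n")
    if text_path is not None:
        with open(text_path, "w") as fh:
            fh.write(render_report_text(report))
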