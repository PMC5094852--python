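"""Homotypic fusion events in 3D and the per-cell fusion frequency.

A fusion event is a granule with two (or more) dense cores inside one
limiting membrane.  The frequency statistic is the per-cell mean ± SEM of
``1000 x events / granules`` — events per 1,000 secretory granules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._util import require, round_half_up
from .morphometry import GranuleRecord

__all__ = [
    "FusionEvent3D",
    "CellFusionCount",
    "FusionFrequency",
    "detect_fusion_events",
    "fusion_frequency",
]


@dataclass(frozen=True)
class FusionEvent3D:
    granule_id: str
    core_ids: tuple[int, ...]
    n_cores: int
    cell_id: Optional[str] = None

    def __post_init__(self) -> None:
        require(self.n_cores >= 2, "a fusion event has at least two cores")


@dataclass(frozen=True)
class CellFusionCount:
    """Events over granules for one cell, e.g. 19/2632."""

    cell_id: str
    n_events: int
    n_granules: int

    def __post_init__(self) -> None:
        require(self.n_granules > 0, "a cell must contain granules")
        require(
            0 <= self.n_events <= self.n_granules,
            "event count must lie in [0, n_granules]",
        )


@dataclass
class FusionFrequency:
    """Fusion events per 1,000 granules, aggregated across cells.

    ``mean`` and ``sem`` are round-half-up to one decimal; ``sem`` is 0.0
    with ``degenerate`` set when only one cell is available.
    """

    per_cell_rates: list[float]
    mean: float
    sem: float
    n_cells: int
    degenerate: bool = False


def detect_fusion_events(granules: Sequence[GranuleRecord]) -> list[FusionEvent3D]:
    """One event per multi-core granule (a triplet still counts once)."""
    return [
        FusionEvent3D(
            granule_id=g.id, core_ids=g.core_ids, n_cores=g.n_cores, cell_id=g.cell_id
        )
        for g in granules
        if g.n_cores >= 2
    ]


def fusion_frequency(counts: Sequence[CellFusionCount]) -> FusionFrequency:
    """Per-cell fusion rates and their mean ± SEM.

    Aggregation is across cells (each cell one independent unit), not pooled
    events over pooled granules: cells with few granules would otherwise be
    swamped by large ones.
    """
    require(len(counts) > 0, "at least one cell is required")
    rates = [1000.0 * c.n_events / c.n_granules for c in counts]
    mean = float(np.mean(rates))
    if len(rates) == 1:
        return FusionFrequency(rates, round_half_up(mean, 1), 0.0, 1, degenerate=True)
    sem = float(np.std(rates, ddof=1) / math.sqrt(len(rates)))
    return FusionFrequency(
        per_cell_rates=rates,
        mean=round_half_up(mean, 1),
        sem=round_half_up(sem, 1),
        n_cells=len(rates),
    )
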