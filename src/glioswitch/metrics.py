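"""Derived quantities: domain totals, phase classification, cycle counts.

The growth/invasion phase of the population at a given time is defined by
the tumor-weighted mean miR-451 level: growth when it exceeds the switch
threshold M_th, invasion otherwise.  A completed cycle is one full
invasion -> growth -> invasion alternation; brief crossings shorter than a
debounce dwell time are ignored, matching how the alternations are counted
by eye on total-population time courses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from glioswitch.spatial_model import FieldSet, Grid1D

__all__ = [
    "Snapshot",
    "ScenarioResult",
    "PhaseInterval",
    "CycleReport",
    "totals",
    "tumor_weighted_mean",
    "classify_phases",
    "sweep_summary",
]

_WEIGHT_FLOOR = 1e-6  # avoids division by an empty tumor support


@dataclass
class Snapshot:
    t: float
    fields: FieldSet


@dataclass
class ScenarioResult:
    """Time series produced by a scenario run.

    ``totals`` maps field name -> per-time domain integrals; ``mean_M`` is
    the tumor-weighted mean miR-451 used for phase classification.
    """

    times: np.ndarray
    totals: dict[str, np.ndarray]
    mean_M: np.ndarray
    M_th: float
    snapshots: list[Snapshot] = field(default_factory=list)
    config: object | None = None
    partial: bool = False

    @property
    def phase(self) -> np.ndarray:
        """Per-time phase label: 'growth' where mean_M > M_th else 'invasion'."""
        return np.where(self.mean_M > self.M_th, "growth", "invasion")

    def final_tumor_total(self) -> float:
        return float(self.totals["n"][-1])


@dataclass(frozen=True)
class PhaseInterval:
    phase: str  # "growth" | "invasion"
    t_start: float
    t_end: float


@dataclass(frozen=True)
class CycleReport:
    intervals: tuple[PhaseInterval, ...]
    n_cycles: int


def totals(fields: FieldSet, grid: Grid1D) -> dict[str, float]:
    """Midpoint-rule domain integrals (cell sum times dx) of all six fields."""
    return {name: float(arr.sum() * grid.dx) for name, arr in fields.as_dict().items()}


def tumor_weighted_mean(values: np.ndarray, n: np.ndarray, grid: Grid1D | None = None) -> float:
    """Mean of ``values`` weighted by tumor density n (floored weight)."""
    w = np.maximum(n, 0.0)
    return float(np.sum(w * values) / max(np.sum(w), _WEIGHT_FLOOR))


def classify_phases(
    times: np.ndarray,
    mean_M: np.ndarray,
    M_th: float,
    debounce: float = 0.5,
) -> CycleReport:
    """Threshold the mean-miR-451 series and count completed cycles.

    The series is labeled growth/invasion by comparison with ``M_th``;
    runs shorter than ``debounce`` (same time units as ``times``) are merged
    into their predecessor.  ``n_cycles`` counts completed
    invasion -> growth -> invasion alternation pairs, i.e. the number of
    debounced phase transitions divided by two.
    """
    times = np.asarray(times, dtype=float)
    mean_M = np.asarray(mean_M, dtype=float)
    if times.size == 0:
        raise ValueError("empty time series")
    labels = np.where(mean_M > M_th, "growth", "invasion")

    # contiguous runs as [label, t_start, t_end]; t_end of a run is the
    # t_start of the next, so the intervals partition [t0, t_last]
    runs: list[list] = []
    start = 0
    for i in range(1, times.size + 1):
        if i == times.size or labels[i] != labels[start]:
            t_end = times[-1] if i == times.size else times[i]
            runs.append([str(labels[start]), float(times[start]), float(t_end)])
            start = i

    def coalesce(rs):
        out = [rs[0]]
        for r in rs[1:]:
            if out[-1][0] == r[0]:
                out[-1][2] = r[2]
            else:
                out.append(r)
        return out

    # debounce: repeatedly relabel the shortest run below the dwell time to
    # match its longer neighbor, coalescing as we go
    while len(runs) > 1:
        durations = [r[2] - r[1] for r in runs]
        idx = int(np.argmin(durations))
        if durations[idx] >= debounce:
            break
        if idx == 0:
            runs[0][0] = runs[1][0]
        elif idx == len(runs) - 1:
            runs[-1][0] = runs[-2][0]
        else:
            left, right = runs[idx - 1], runs[idx + 1]
            donor = left if (left[2] - left[1]) >= (right[2] - right[1]) else right
            runs[idx][0] = donor[0]
        runs = coalesce(runs)

    intervals = tuple(PhaseInterval(r[0], r[1], r[2]) for r in runs)
    n_transitions = len(runs) - 1
    return CycleReport(intervals=intervals, n_cycles=n_transitions // 2)


def sweep_summary(
    points: list[tuple[float, "ScenarioResult"]],
    control_value: float,
    parameter: str = "value",
    debounce: float = 0.5,
) -> pd.DataFrame:
    """Summary table of a one-parameter sweep.

    One row per sweep point with the final tumor total, completed cycle
    count and time-mean total AMPK; the control row is flagged.  Raises if
    the control value is absent from the sweep.
    """
    if len(points) < 2:
        raise ValueError("a sweep needs at least 2 points (including the control)")
    values = [v for v, _ in points]
    if not any(np.isclose(v, control_value) for v in values):
        raise ValueError(f"sweep is missing the control point {parameter}={control_value}")
    rows = []
    for v, res in points:
        report = classify_phases(res.times, res.mean_M, res.M_th, debounce=debounce)
        rows.append({
            parameter: v,
            "final_tumor_total": res.final_tumor_total(),
            "n_cycles": report.n_cycles,
            "mean_total_A": float(np.mean(res.totals["A"])),
            "is_control": bool(np.isclose(v, control_value)),
        })
    return pd.DataFrame(rows, columns=[parameter, "final_tumor_total", "n_cycles",
                                       "mean_total_A", "is_control"])
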