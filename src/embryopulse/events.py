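"""Cleavage-event timelines: wave assignment, stage durations, cell counts.

Divisions of different cells belong to the same cleavage wave when they
occur within 30 min of another division of the same embryo; the rule is
applied by transitive (single-linkage) chaining, so a wave is a maximal run
of divisions with consecutive gaps of at most 30 min. Failed cytokineses
count as part of waves but do not increment the cell count. All event times
are normalised to the end of the third cleavage (the last division of the
third wave).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WAVE_GAP_H = 0.5  # 30 min
_EPS = 1e-9

#: event types that participate in cleavage waves
DIVISION_TYPES = ("division", "failed_division")


@dataclass(frozen=True)
class Event:
    time_h: float
    type: str  # division | failed_division | fusion_reversion | lumen_open | max_compaction
    cell_id: int = -1


@dataclass
class EmbryoTimeline:
    """Time-stamped events of one embryo on the 30-min sampling grid."""

    embryo_id: str
    events: list[Event] = field(default_factory=list)
    initial_cells: int = 1
    first_wave: int = 1  # wave number of the first observed division group

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.time_h)

    def division_times(self) -> np.ndarray:
        """Times of successful and failed cleavage attempts, sorted."""
        return np.array(
            [e.time_h for e in self.events if e.type in DIVISION_TYPES]
        )

    def wave_labels(self) -> np.ndarray:
        """Wave number of every cleavage attempt (``first_wave``-based)."""
        labels = assign_waves(self.division_times())
        return labels + (self.first_wave - 1)

    @property
    def t0(self) -> float:
        """End of the third cleavage: last attempt of wave 3."""
        times = self.division_times()
        labels = self.wave_labels()
        in_third = times[labels == 3]
        if in_third.size == 0:
            return np.nan
        return float(in_third.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "embryo_id": self.embryo_id,
                "time_h": [e.time_h for e in self.events],
                "type": [e.type for e in self.events],
                "cell_id": [e.cell_id for e in self.events],
            }
        )


def assign_waves(division_times: np.ndarray) -> np.ndarray:
    """Label sorted division times with contiguous wave numbers from 1.

    Consecutive divisions no more than 30 min apart share a wave (inclusive
    at exactly 30 min); a larger gap starts the next wave. Empty input
    yields an empty label array.
    """
    times = np.asarray(division_times, dtype=float)
    if times.size == 0:
        return np.array([], dtype=int)
    if np.any(np.diff(times) < 0):
        raise ValueError("division times must be sorted")
    gaps = np.diff(times)
    new_wave = gaps > WAVE_GAP_H + _EPS
    return 1 + np.concatenate([[0], np.cumsum(new_wave)]).astype(int)


def stage_duration(timeline: EmbryoTimeline, from_wave: int = 3,
                   to_wave: int = 4) -> float:
    """Interval between the last division of one wave and the first of another.

    With the defaults this is the 8-cell-stage duration: last third-wave
    cleavage to first fourth-wave cleavage. Returns NaN when either wave is
    absent (e.g. all subsequent divisions failed to be observed).
    """
    times = timeline.division_times()
    labels = timeline.wave_labels()
    start = times[labels == from_wave]
    end = times[labels == to_wave]
    if start.size == 0 or end.size == 0:
        return np.nan
    return float(end.min() - start.max())


def lumen_time(timeline: EmbryoTimeline) -> float:
    """Time of lumen opening, normalised to the end of the third cleavage.

    Returns NaN when the embryo never opens a lumen.
    """
    opens = [e.time_h for e in timeline.events if e.type == "lumen_open"]
    if not opens:
        return np.nan
    return float(min(opens) - timeline.t0)


def lumen_time_from_diameters(times_h: np.ndarray, diameters_um: np.ndarray,
                              min_diameter_um: float = 20.0) -> float:
    """First time an annotated fluid-compartment diameter reaches 20 µm."""
    times_h = np.asarray(times_h, dtype=float)
    diameters_um = np.asarray(diameters_um, dtype=float)
    if times_h.shape != diameters_um.shape:
        raise ValueError("times and diameters must align")
    hit = np.nonzero(diameters_um >= min_diameter_um)[0]
    if hit.size == 0:
        return np.nan
    return float(times_h[hit[0]])


def final_cell_count(timeline: EmbryoTimeline) -> int:
    """Cell count after all events: +1 per successful division, -1 per
    reverting cleavage, failed cytokineses contribute nothing."""
    count = timeline.initial_cells
    for e in timeline.events:
        if e.type == "division":
            count += 1
        elif e.type == "fusion_reversion":
            count -= 1
    if count < 1:
        raise ValueError("timeline bookkeeping produced fewer than one cell")
    return count


def max_compaction_time(times_h: np.ndarray, angles_deg: np.ndarray,
                        smooth: int = 3) -> float:
    """Time at which the embryo stops increasing its contact angle.

    The angle series is smoothed with a short moving average and the time of
    its (earliest) maximum is returned.
    """
    times_h = np.asarray(times_h, dtype=float)
    angles = np.asarray(angles_deg, dtype=float)
    if times_h.size != angles.size or times_h.size == 0:
        raise ValueError("need matching, non-empty series")
    if smooth > 1 and angles.size >= smooth:
        kernel = np.ones(smooth) / smooth
        angles = np.convolve(angles, kernel, mode="same")
    return float(times_h[int(np.argmax(angles))])


def summarize_timelines(timelines: list[EmbryoTimeline]) -> pd.DataFrame:
    """Per-embryo summary: 8-cell-stage duration, lumen time, final count."""
    rows = []
    for tl in timelines:
        rows.append(
            {
                "embryo_id": tl.embryo_id,
                "t0_h": tl.t0,
                "stage8_duration_h": stage_duration(tl, 3, 4),
                "lumen_time_h": lumen_time(tl),
                "final_cell_count": final_cell_count(tl),
            }
        )
    return pd.DataFrame(rows)
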