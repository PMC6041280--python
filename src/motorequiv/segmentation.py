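"""Movement-cycle detection and the cycle-selection rule.

A cycle is one forth stroke (e.g. raised hammer position down to the nail)
plus the back stroke returning to the start.  Boundaries are placed at
extrema of the primary-axis coordinate on the stroke-start side (hammer:
z maxima; brush: y maxima, the right end of the sweep; roller: x minima,
nearest the body); the forth/back switch point is the opposite extremum
inside the cycle.  Extrema are found with a prominence threshold and a
minimum separation, which makes the boundaries robust to measurement
noise after 10 Hz low-pass filtering.

Recordings contain 20-25 cycles; analysis retains cycles 6-19 (14 cycles),
discarding the first five as familiarization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .conventions import AXIS_INDEX, BOUNDARY_SIGN, FORTH_SIGN, PRIMARY_AXIS, validate_tool
from .exceptions import SegmentationError, SelectionError
from .kinematics import KinematicSeries

__all__ = ["Cycle", "CycleSet", "detect_cycles", "select_cycles"]

DEFAULT_PROMINENCE_FRAC = 0.20
DEFAULT_MIN_SEPARATION_FRAC = 0.25
FIRST_KEPT = 6
LAST_KEPT = 19


@dataclass(frozen=True)
class Cycle:
    start: int
    switch: int
    end: int
    ordinal: int

    def __post_init__(self) -> None:
        if not self.start < self.switch < self.end:
            raise SegmentationError(
                f"cycle {self.ordinal}: indices must satisfy start < switch < end "
                f"(got {self.start}, {self.switch}, {self.end})"
            )


@dataclass
class CycleSet:
    cycles: list[Cycle]
    primary_axis: str
    forth_sign: int

    def __len__(self) -> int:
        return len(self.cycles)

    def __iter__(self):
        return iter(self.cycles)

    def ordinals(self) -> list[int]:
        return [c.ordinal for c in self.cycles]


def _boundary_peaks(coord: np.ndarray, prominence_frac: float,
                    min_separation_frac: float) -> np.ndarray:
    """Indices of boundary extrema of a sign-adjusted coordinate (maxima)."""
    n = len(coord)
    rng = float(np.ptp(coord))
    if rng <= 0:
        raise SegmentationError("primary-axis coordinate has zero range")
    prominence = prominence_frac * rng

    # reflect-pad so extrema at the very first/last sample are detectable;
    # peaks found inside the mirrored margins fold back onto their source
    pad = min(n - 1, max(2, n // 4))
    padded = np.concatenate([coord[pad:0:-1], coord, coord[-2:-pad - 2:-1]])

    def _fold(idx: np.ndarray) -> np.ndarray:
        idx = idx - pad
        idx = np.where(idx < 0, -idx, idx)
        idx = np.where(idx >= n, 2 * n - 2 - idx, idx)
        return np.unique(idx)

    peaks = _fold(find_peaks(padded, prominence=prominence)[0])
    if len(peaks) >= 3:
        median_interval = float(np.median(np.diff(peaks)))
        distance = max(1, int(round(min_separation_frac * median_interval)))
        peaks = _fold(find_peaks(padded, prominence=prominence,
                                 distance=distance)[0])
    return peaks


def detect_cycles(
    series: KinematicSeries,
    tool: str,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
    min_separation_frac: float = DEFAULT_MIN_SEPARATION_FRAC,
) -> CycleSet:
    """Detect movement cycles on the tool's primary axis.

    Parameters
    ----------
    series : KinematicSeries
        Filtered kinematics of the tool end-point.
    tool : str
        Determines the primary axis and boundary side (see module docs).
    prominence_frac : float
        Peak prominence threshold, as a fraction of the primary-axis range.
    min_separation_frac : float
        Minimum boundary separation, as a fraction of the median
        inter-extremum interval found in a first prominence-only pass.

    Raises
    ------
    SegmentationError
        If fewer than two boundary extrema are found.
    """
    validate_tool(tool)
    axis = PRIMARY_AXIS[tool]
    coord = series.position[:, AXIS_INDEX[axis]] * BOUNDARY_SIGN[tool]
    boundaries = _boundary_peaks(coord, prominence_frac, min_separation_frac)
    if len(boundaries) < 2:
        raise SegmentationError(
            f"found {len(boundaries)} boundary extrema on axis {axis}; "
            "need at least 2 to delimit one cycle (is the movement cyclic?)"
        )
    cycles = []
    ordinal = 1
    for start, end in zip(boundaries[:-1], boundaries[1:]):
        inner = coord[start + 1: end]
        if len(inner) == 0:
            continue
        switch = start + 1 + int(np.argmin(inner))
        cycles.append(Cycle(int(start), int(switch), int(end), ordinal))
        ordinal += 1
    if not cycles:
        raise SegmentationError("no valid cycles between detected boundaries")
    return CycleSet(cycles=cycles, primary_axis=axis, forth_sign=FORTH_SIGN[tool])


def select_cycles(
    cycleset: CycleSet,
    first_kept: int = FIRST_KEPT,
    last_kept: int = LAST_KEPT,
) -> CycleSet:
    """Retain cycles with ordinal in [first_kept, last_kept].

    With the defaults this keeps cycles 6-19 — exactly 14 cycles — and
    discards the first five.  Idempotent: re-selecting an already selected
    set is a no-op because ordinals are preserved.
    """
    if first_kept < 1 or last_kept < first_kept:
        raise SelectionError(f"invalid retention range [{first_kept}, {last_kept}]")
    max_ordinal = max(cycleset.ordinals(), default=0)
    if max_ordinal < last_kept:
        raise SelectionError(
            f"only {len(cycleset)} cycles detected (max ordinal {max_ordinal}); "
            f"need at least {last_kept} to retain cycles "
            f"{first_kept}-{last_kept}"
        )
    kept = [c for c in cycleset.cycles if first_kept <= c.ordinal <= last_kept]
    return CycleSet(cycles=kept, primary_axis=cycleset.primary_axis,
                    forth_sign=cycleset.forth_sign)
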