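"""Published reference values bundled as fixtures.

The study whose analysis this package re-implements did not deposit raw
motion-capture data, so its participant-level statistics cannot be
recomputed.  What it did print — the 90-entry cross-effector correlation
table with significance flags, the per-effector hammering-depth means,
and the protocol constants — is transcribed here and used as input to the
summary operations.  The printed significance flags are treated as data
(the rounded two-decimal r values do not determine them exactly), never
as a recomputation target.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "PROTOCOL",
    "DEPTH_MEANS_CM",
    "table1_frame",
    "TABLE1",
]

#: protocol constants of the study design
PROTOCOL = {
    "n_participants": 10,
    "n_cycles_recorded": (20, 25),
    "first_kept_cycle": 6,
    "last_kept_cycle": 19,
    "n_retained_cycles": 14,
    "sample_rate_hz": 200.0,
    "filter_cutoff_hz": 10.0,
    "n_markers_per_tool": 6,
}

#: hammering performance: nail depth per end-effector, (mean cm, SE cm)
DEPTH_MEANS_CM = {
    "right_foot": (1.6, 0.5),
    "right_elbow": (2.2, 0.8),
    "left_hand": (3.0, 1.5),
    "right_hand": (2.5, 1.1),
}

# (tool, parameter, effector_a, effector_b, r, holm_significant)
# Pair order within each matrix: (foot,elbow), (foot,l-hand), (elbow,l-hand),
# (foot,r-hand), (elbow,r-hand), (l-hand,r-hand).
_RF, _RE, _LH, _RH = "right_foot", "right_elbow", "left_hand", "right_hand"
_PAIRS = ((_RF, _RE), (_RF, _LH), (_RE, _LH), (_RF, _RH), (_RE, _RH), (_LH, _RH))

_CELLS = {
    ("hammer", "vertical_amplitude"):
        [(0.68, False), (0.63, False), (0.88, True),
         (0.64, False), (0.85, True), (0.98, True)],
    ("brush", "vertical_amplitude"):
        [(0.49, False), (0.43, False), (0.93, True),
         (0.46, False), (0.93, True), (0.89, True)],
    ("roller", "vertical_amplitude"):
        [(0.86, True), (0.76, True), (0.98, True),
         (0.77, True), (0.94, True), (0.92, True)],
    ("hammer", "cycle_duration"):
        [(0.94, True), (0.91, True), (0.99, True),
         (0.93, True), (0.99, True), (0.99, True)],
    ("brush", "cycle_duration"):
        [(0.89, True), (0.94, True), (0.98, True),
         (0.86, True), (0.93, True), (0.94, True)],
    ("roller", "cycle_duration"):
        [(0.98, True), (0.99, True), (0.98, True),
         (0.99, True), (0.98, True), (0.99, True)],
    ("hammer", "max_velocity_forth"):
        [(0.85, True), (0.93, True), (0.83, True),
         (0.96, True), (0.83, True), (0.98, True)],
    ("brush", "max_velocity_forth"):
        [(0.70, True), (0.82, True), (0.92, True),
         (0.74, True), (0.81, True), (0.83, True)],
    ("roller", "max_velocity_forth"):
        [(0.92, True), (0.84, True), (0.94, True),
         (0.87, True), (0.95, True), (0.93, True)],
    ("hammer", "peak_acceleration_forth"):
        [(0.84, True), (0.82, True), (0.96, True),
         (0.87, True), (0.96, True), (0.98, True)],
    ("brush", "peak_acceleration_forth"):
        [(0.64, False), (0.57, False), (0.75, True),
         (0.63, False), (0.93, True), (0.70, True)],
    ("roller", "peak_acceleration_forth"):
        [(0.75, True), (0.65, True), (0.94, True),
         (0.77, True), (0.94, True), (0.90, True)],
    ("hammer", "peak_deceleration_forth"):
        [(0.68, True), (0.86, True), (0.78, True),
         (0.89, True), (0.72, True), (0.95, True)],
    ("brush", "peak_deceleration_forth"):
        [(0.62, True), (0.96, True), (0.75, True),
         (0.74, True), (0.92, True), (0.78, True)],
    ("roller", "peak_deceleration_forth"):
        [(0.70, True), (0.84, True), (0.82, True),
         (0.61, False), (0.86, True), (0.80, True)],
}

#: flat tuple of the 90 published correlation entries
TABLE1 = tuple(
    (tool, parameter, a, b, r, sig)
    for (tool, parameter), cells in _CELLS.items()
    for (a, b), (r, sig) in zip(_PAIRS, cells)
)


def table1_frame() -> pd.DataFrame:
    """The published correlation table as a tidy DataFrame."""
    return pd.DataFrame(
        TABLE1,
        columns=["tool", "parameter", "effector_a", "effector_b",
                 "r", "holm_significant"],
    )
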