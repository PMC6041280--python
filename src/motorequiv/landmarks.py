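"""Per-cycle kinematic landmarks and their aggregation.

Five landmarks summarize each movement cycle:

* ``cycle_duration`` (s) — boundary-to-boundary time, whole cycle;
* ``vertical_amplitude`` (mm) — z range over the whole cycle;
* ``max_velocity_forth`` (mm/s) — peak 3D speed on the forth stroke;
* ``peak_acceleration_forth`` (mm/s^2) — max tangential acceleration on
  the forth stroke;
* ``peak_deceleration_forth`` (mm/s^2) — magnitude of the most negative
  tangential acceleration on the forth stroke.

Velocity/acceleration landmarks are restricted to the forth stroke because
it characterizes the tool-use action better than the return; duration and
amplitude are whole-cycle quantities.  Cells of the aggregated table are
arithmetic means over the retained cycles, with SD/SE kept for error bars.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .conventions import LANDMARKS
from .exceptions import CompletenessError, ExtractionError
from .kinematics import KinematicSeries
from .segmentation import CycleSet

__all__ = ["LandmarkRecord", "LandmarkTable", "extract_landmarks", "aggregate"]

_MIN_FORTH_SAMPLES = 3


@dataclass(frozen=True)
class LandmarkRecord:
    participant_id: str
    tool: str
    effector: str
    cycle_ordinal: int
    cycle_duration: float
    vertical_amplitude: float
    max_velocity_forth: float
    peak_acceleration_forth: float
    peak_deceleration_forth: float

    def __post_init__(self) -> None:
        if self.cycle_duration <= 0:
            raise ExtractionError("cycle_duration must be positive")
        if self.vertical_amplitude < 0 or self.peak_deceleration_forth < 0:
            raise ExtractionError("amplitude and deceleration must be >= 0")
        if self.max_velocity_forth <= 0:
            raise ExtractionError("max_velocity_forth must be positive")
        vals = (self.cycle_duration, self.vertical_amplitude,
                self.max_velocity_forth, self.peak_acceleration_forth,
                self.peak_deceleration_forth)
        if not all(np.isfinite(vals)):
            raise ExtractionError("non-finite landmark value")


def extract_landmarks(
    series: KinematicSeries,
    cycleset: CycleSet,
    participant_id: str = "unknown",
    tool: str = "hammer",
    effector: str = "right_hand",
) -> list[LandmarkRecord]:
    """Compute the five landmarks for every cycle in ``cycleset``."""
    z = series.position[:, 2]
    records = []
    for cyc in cycleset:
        if cyc.switch - cyc.start + 1 < _MIN_FORTH_SAMPLES:
            raise ExtractionError(
                f"cycle {cyc.ordinal}: forth stroke has "
                f"{cyc.switch - cyc.start + 1} samples (< {_MIN_FORTH_SAMPLES})"
            )
        forth = slice(cyc.start, cyc.switch + 1)
        whole = slice(cyc.start, cyc.end + 1)
        tang = series.tangential_acceleration[forth]
        records.append(
            LandmarkRecord(
                participant_id=participant_id,
                tool=tool,
                effector=effector,
                cycle_ordinal=cyc.ordinal,
                cycle_duration=(cyc.end - cyc.start) / series.sample_rate,
                vertical_amplitude=float(np.ptp(z[whole])),
                max_velocity_forth=float(series.speed[forth].max()),
                peak_acceleration_forth=float(tang.max()),
                peak_deceleration_forth=float(abs(tang.min())),
            )
        )
    return records


@dataclass
class LandmarkTable:
    """Participant x tool x effector means of the five landmarks.

    ``data`` is tidy: columns participant, tool, effector, parameter,
    value, sd, se, n_cycles — one row per design cell per parameter.
    """

    data: pd.DataFrame = field(repr=False)

    REQUIRED = ("participant", "tool", "effector", "parameter", "value")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise CompletenessError(f"landmark table missing columns {sorted(missing)}")

    @property
    def participants(self) -> list[str]:
        return sorted(self.data["participant"].unique())

    @property
    def tools(self) -> list[str]:
        return sorted(self.data["tool"].unique())

    @property
    def effectors(self) -> list[str]:
        return sorted(self.data["effector"].unique())

    def values_matrix(self, tool: str, parameter: str) -> pd.DataFrame:
        """Participants x effectors wide matrix of cell means."""
        sub = self.data[(self.data["tool"] == tool)
                        & (self.data["parameter"] == parameter)]
        wide = sub.pivot(index="participant", columns="effector", values="value")
        if wide.isna().any().any():
            gaps = [
                (p, e) for p in wide.index for e in wide.columns
                if pd.isna(wide.loc[p, e])
            ]
            raise CompletenessError(
                f"missing cells for tool={tool}, parameter={parameter}: {gaps}"
            )
        return wide

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.data.to_csv(path, index=False)
        return path

    @classmethod
    def read_csv(cls, path: str | Path) -> "LandmarkTable":
        return cls(pd.read_csv(path))


def aggregate(records: list[LandmarkRecord]) -> LandmarkTable:
    """Mean each landmark over cycles, per participant x tool x effector.

    Raises :class:`CompletenessError` when the records do not cover the
    full cross of observed participants, tools and effectors.
    """
    if not records:
        raise CompletenessError("no landmark records to aggregate")
    df = pd.DataFrame([r.__dict__ for r in records]).rename(
        columns={"participant_id": "participant"}
    )
    long = df.melt(
        id_vars=["participant", "tool", "effector", "cycle_ordinal"],
        value_vars=list(LANDMARKS),
        var_name="parameter",
        value_name="value",
    )
    grouped = long.groupby(
        ["participant", "tool", "effector", "parameter"], as_index=False
    ).agg(
        mean_value=("value", "mean"),
        sd=("value", "std"),
        n_cycles=("value", "size"),
    )
    grouped = grouped.rename(columns={"mean_value": "value"})
    grouped["se"] = grouped["sd"] / np.sqrt(grouped["n_cycles"])

    observed = df[["participant", "tool", "effector"]].drop_duplicates()
    expected = pd.MultiIndex.from_product(
        [sorted(df["participant"].unique()), sorted(df["tool"].unique()),
         sorted(df["effector"].unique())],
        names=["participant", "tool", "effector"],
    )
    have = set(map(tuple, observed.to_numpy()))
    gaps = [cell for cell in expected if cell not in have]
    if gaps:
        raise CompletenessError(f"missing participant x tool x effector cells: {gaps}")
    return LandmarkTable(grouped)
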