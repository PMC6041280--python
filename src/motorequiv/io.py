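"""Trajectory and manifest I/O.

Recordings are stored as plain tab-separated text with ``#key=value``
metadata header lines, a canonical dialect that round-trips exactly at six
decimal places.  Cohorts are described by a manifest CSV mapping
participant / tool / effector labels to trajectory files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .conventions import validate_effector, validate_tool
from .exceptions import DataError, FormatError, SamplingError

__all__ = [
    "Recording",
    "read_trajectory_tsv",
    "write_trajectory_tsv",
    "read_manifest",
    "write_manifest",
]

_TIME_TOL = 1e-6  # s; allowed deviation from uniform spacing


@dataclass
class Recording:
    """One trial's raw marker trajectories.

    Parameters
    ----------
    participant_id : str
        Participant label.
    tool : str or None
        One of ``hammer``, ``brush``, ``roller`` (validated when given).
    effector : str or None
        One of ``right_foot``, ``right_elbow``, ``left_hand``, ``right_hand``.
    sample_rate : float
        Sampling frequency in Hz.
    markers : dict of str -> (n, 3) ndarray
        Marker positions in mm, insertion-ordered; all equal length >= 2.
    endpoint_marker : str, optional
        The marker treated as the tool end-point.  When absent the
        end-point is the centroid of all markers.
    """

    participant_id: str
    tool: str | None
    effector: str | None
    sample_rate: float
    markers: dict[str, np.ndarray] = field(default_factory=dict)
    endpoint_marker: str | None = None

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise FormatError("sample_rate must be positive")
        if self.tool is not None:
            validate_tool(self.tool)
        if self.effector is not None:
            validate_effector(self.effector)
        lengths = set()
        for name, xyz in self.markers.items():
            xyz = np.asarray(xyz, dtype=float)
            if xyz.ndim != 2 or xyz.shape[1] != 3:
                raise FormatError(f"marker {name!r} is not an (n, 3) array")
            if not np.isfinite(xyz).all():
                raise DataError(f"marker {name!r} contains non-finite samples")
            self.markers[name] = xyz
            lengths.add(len(xyz))
        if self.markers:
            if len(lengths) != 1:
                raise FormatError("marker trajectories have unequal lengths")
            if lengths.pop() < 2:
                raise FormatError("marker trajectories must have length >= 2")
        if self.endpoint_marker is not None and self.endpoint_marker not in self.markers:
            raise FormatError(
                f"endpoint_marker {self.endpoint_marker!r} not among markers"
            )

    @property
    def n_samples(self) -> int:
        if not self.markers:
            return 0
        return len(next(iter(self.markers.values())))

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def endpoint(self) -> np.ndarray:
        """(n, 3) end-point path: designated marker, else marker centroid."""
        if not self.markers:
            raise FormatError("recording has no markers")
        if self.endpoint_marker is not None:
            return self.markers[self.endpoint_marker]
        return np.mean(np.stack(list(self.markers.values())), axis=0)


def write_trajectory_tsv(recording: Recording, path: str | Path) -> Path:
    """Write a recording in the canonical TSV dialect.

    Tab separated, ``.`` decimal, positions fixed to six decimals, metadata
    as ``#key=value`` header lines, columns ``time, <marker>_x, _y, _z``.
    """
    if not recording.markers:
        raise FormatError("refusing to write a recording with no markers")
    path = Path(path)
    names = list(recording.markers)
    header = [
        f"#participant_id={recording.participant_id}",
        f"#tool={recording.tool or ''}",
        f"#effector={recording.effector or ''}",
        f"#sample_rate={recording.sample_rate!r}",
        f"#endpoint_marker={recording.endpoint_marker or ''}",
    ]
    cols = ["time"] + [f"{m}_{ax}" for m in names for ax in "xyz"]
    data = np.column_stack(
        [recording.time] + [recording.markers[m] for m in names]
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(header) + "\n")
        fh.write("\t".join(cols) + "\n")
        np.savetxt(fh, data, fmt="%.6f", delimiter="\t")
    return path


def read_trajectory_tsv(path: str | Path) -> Recording:
    """Read a recording written in the canonical TSV dialect."""
    path = Path(path)
    meta: dict[str, str] = {}
    n_header = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, value = line[1:].strip().partition("=")
            meta[key] = value
    if "sample_rate" not in meta:
        raise FormatError(f"{path}: missing #sample_rate header")
    try:
        sample_rate = float(meta["sample_rate"])
    except ValueError as exc:
        raise FormatError(f"{path}: unparsable sample_rate") from exc

    df = pd.read_csv(path, sep="\t", skiprows=n_header)
    if "time" not in df.columns:
        raise FormatError(f"{path}: missing 'time' column")
    marker_names: list[str] = []
    for col in df.columns:
        if col.endswith("_x"):
            marker_names.append(col[:-2])
    if not marker_names:
        raise FormatError(f"{path}: no marker columns found")
    for m in marker_names:
        for ax in "xyz":
            if f"{m}_{ax}" not in df.columns:
                raise FormatError(f"{path}: missing column {m}_{ax}")

    if df.isna().any().any():
        raise DataError(f"{path}: NaN coordinates present (no gap-filling)")

    t = df["time"].to_numpy(dtype=float)
    if len(t) >= 2:
        dt = np.diff(t)
        if np.any(np.abs(dt - 1.0 / sample_rate) > _TIME_TOL):
            raise SamplingError(
                f"{path}: time column not uniform at declared "
                f"{sample_rate} Hz (max deviation "
                f"{np.max(np.abs(dt - 1.0 / sample_rate)):.3g} s)"
            )

    markers = {
        m: df[[f"{m}_x", f"{m}_y", f"{m}_z"]].to_numpy(dtype=float)
        for m in marker_names
    }
    return Recording(
        participant_id=meta.get("participant_id", "unknown"),
        tool=meta.get("tool") or None,
        effector=meta.get("effector") or None,
        sample_rate=sample_rate,
        markers=markers,
        endpoint_marker=meta.get("endpoint_marker") or None,
    )


def write_manifest(entries: pd.DataFrame, path: str | Path) -> Path:
    """Write a cohort manifest CSV (participant, tool, effector, path)."""
    required = {"participant", "tool", "effector", "path"}
    missing = required - set(entries.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    path = Path(path)
    entries.to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"participant", "tool", "effector", "path"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: manifest missing columns {sorted(missing)}")
    return df
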