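"""Synthetic motion-capture cohorts with controllable cross-effector structure.

The generator emulates the study protocol the analysis pipeline expects:
each participant performs each tool-use action (hammer, brush, roller) with
four end-effectors, producing 20-25 movement cycles sampled at 200 Hz by a
six-marker optical capture system.

A participant's *motor signature* — stroke amplitude, cycle duration and
forth-stroke fraction per tool — is drawn once from per-tool population
distributions.  In ``preserved`` mode the same signature underlies all four
effectors, modulated only by fixed effector-specific biomechanical scales;
this is the regime in which cross-effector correlations of the landmarks
are high.  In ``null`` mode an independent signature is redrawn for every
effector, so the expected cross-effector correlation is zero.

Strokes follow the minimum-jerk quintic s(tau) = 10 tau^3 - 15 tau^4 +
6 tau^5, which has closed-form peak speed 1.875 A/d and peak acceleration
(10/sqrt(3)) A/d^2 for amplitude A and duration d — these analytic values
are stored alongside each recording as ground truth.  Small single-cycle
sinusoids on the two secondary axes make the 3D path non-degenerate, and
i.i.d. Gaussian noise models optical measurement error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conventions import (
    AXIS_INDEX,
    EFFECTORS,
    FORTH_SIGN,
    PEAK_ACC_FACTOR,
    PEAK_SPEED_FACTOR,
    PRIMARY_AXIS,
    TOOLS,
    validate_effector,
    validate_tool,
)
from .exceptions import ConfigurationError, SamplingError
from .io import Recording
from .landmarks import LandmarkTable
from .segmentation import FIRST_KEPT, LAST_KEPT

__all__ = [
    "ToolPopulation",
    "MotorSignature",
    "EffectorModulation",
    "SimulationConfig",
    "SimulatedRecording",
    "Cohort",
    "draw_signatures",
    "synthesize_recording",
    "iter_recordings",
    "generate_cohort",
]

_MIN_SAMPLES_PER_CYCLE = 20

#: six markers at fixed rigid offsets (mm) within a 100 mm cube of the
#: end-point; marker_1 coincides with the end-point and is the designated
#: endpoint marker.
MARKER_OFFSETS = {
    "marker_1": (0.0, 0.0, 0.0),
    "marker_2": (50.0, 0.0, 0.0),
    "marker_3": (0.0, 50.0, 0.0),
    "marker_4": (0.0, 0.0, 50.0),
    "marker_5": (-40.0, 30.0, 20.0),
    "marker_6": (25.0, -45.0, -35.0),
}

#: which secondary axis carries the full-amplitude single-cycle sinusoid
#: (first) and which the half-amplitude double-frequency one (second); the
#: vertical axis is ordered so that brush > roller in vertical amplitude,
#: matching the tools' qualitative ordering.
_SECONDARY_AXES = {
    "hammer": ("x", "y"),
    "brush": ("z", "x"),
    "roller": ("y", "z"),
}


@dataclass(frozen=True)
class ToolPopulation:
    """Population distribution of signature parameters for one tool."""

    amplitude_mean: float  # mm
    amplitude_sd: float
    duration_mean: float  # s
    duration_sd: float
    forth_fraction_mean: float
    forth_fraction_sd: float
    rest_offset: tuple[float, float, float]  # mm

    def __post_init__(self) -> None:
        if self.amplitude_mean <= 0 or self.duration_mean <= 0:
            raise ConfigurationError(
                "population means of positive-valued parameters must be > 0"
            )
        if not 0 < self.forth_fraction_mean < 1:
            raise ConfigurationError("forth_fraction_mean must lie in (0, 1)")
        if min(self.amplitude_sd, self.duration_sd, self.forth_fraction_sd) < 0:
            raise ConfigurationError("population SDs must be >= 0")


# Defaults chosen so tool orderings are qualitatively realistic: the hammer
# swings widest and fastest with the sharpest acceleration transients; the
# roller is slowest with the smallest vertical excursion; the brush sits in
# between.  Exact values are configuration, not contract.
DEFAULT_TOOL_POPULATIONS = {
    "hammer": ToolPopulation(300.0, 60.0, 0.80, 0.15, 0.45, 0.05, (0.0, 0.0, 400.0)),
    "brush": ToolPopulation(400.0, 70.0, 1.20, 0.20, 0.50, 0.05, (0.0, 200.0, 100.0)),
    "roller": ToolPopulation(350.0, 60.0, 1.40, 0.25, 0.50, 0.05, (-175.0, 0.0, 100.0)),
}

DEFAULT_MODULATIONS = {
    "right_foot": (0.80, 1.15),
    "right_elbow": (0.85, 1.10),
    "left_hand": (0.95, 1.05),
    "right_hand": (1.00, 1.00),
}


@dataclass(frozen=True)
class MotorSignature:
    """One participant's spatiotemporal signature for one tool."""

    participant_id: str
    tool: str
    stroke_amplitude: float  # mm
    cycle_duration: float  # s
    forth_fraction: float
    rest_offset: tuple[float, float, float]  # mm

    def __post_init__(self) -> None:
        validate_tool(self.tool)
        if self.stroke_amplitude <= 0 or self.cycle_duration <= 0:
            raise ConfigurationError("amplitude and duration must be positive")
        if not 0 < self.forth_fraction < 1:
            raise ConfigurationError("forth_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class EffectorModulation:
    """Fixed biomechanical scaling an effector applies to any signature."""

    effector: str
    amplitude_scale: float = 1.0
    duration_scale: float = 1.0

    def __post_init__(self) -> None:
        validate_effector(self.effector)
        if self.amplitude_scale <= 0 or self.duration_scale <= 0:
            raise ConfigurationError("modulation scales must be strictly positive")


@dataclass(frozen=True)
class SimulationConfig:
    n_participants: int = 10
    tools: tuple[str, ...] = TOOLS
    effectors: tuple[str, ...] = EFFECTORS
    n_cycles: int = 22
    sample_rate: float = 200.0
    noise_sd: float = 1.0  # mm, optical measurement error
    preservation_mode: str = "preserved"  # or "null"
    cycle_jitter: float = 0.03  # multiplicative SD of per-cycle A and D
    secondary_amplitude_frac: float = 0.05
    tool_populations: dict[str, ToolPopulation] = field(
        default_factory=lambda: dict(DEFAULT_TOOL_POPULATIONS)
    )
    modulations: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MODULATIONS)
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if not self.tools or not self.effectors:
            raise ConfigurationError("tools and effectors must be non-empty")
        for t in self.tools:
            validate_tool(t)
            if t not in self.tool_populations:
                raise ConfigurationError(f"no population parameters for tool {t!r}")
        for e in self.effectors:
            validate_effector(e)
        if self.preservation_mode not in ("preserved", "null"):
            raise ConfigurationError(
                f"preservation_mode must be 'preserved' or 'null', "
                f"got {self.preservation_mode!r}"
            )
        if self.n_cycles < 1 or self.sample_rate <= 0:
            raise ConfigurationError("n_cycles and sample_rate must be positive")
        if self.noise_sd < 0 or self.cycle_jitter < 0:
            raise ConfigurationError("noise_sd and cycle_jitter must be >= 0")

    def modulation(self, effector: str) -> EffectorModulation:
        a, d = self.modulations.get(effector, (1.0, 1.0))
        return EffectorModulation(effector, a, d)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "tool_populations" in d:
            d["tool_populations"] = {
                t: ToolPopulation(**(p if isinstance(p, dict) else p.__dict__))
                if not isinstance(p, ToolPopulation) else p
                for t, p in d["tool_populations"].items()
            }
        if "tools" in d:
            d["tools"] = tuple(d["tools"])
        if "effectors" in d:
            d["effectors"] = tuple(d["effectors"])
        if "modulations" in d:
            d["modulations"] = {e: tuple(v) for e, v in d["modulations"].items()}
        return cls(**d)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated at zero (redraw; mean assumed well above 0)."""
    if sd == 0:
        return mean
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)
    raise ConfigurationError(
        f"could not draw a positive value from N({mean}, {sd}^2)"
    )


def _draw_signature(rng: np.random.Generator, participant_id: str, tool: str,
                    pop: ToolPopulation) -> MotorSignature:
    frac = rng.normal(pop.forth_fraction_mean, pop.forth_fraction_sd) \
        if pop.forth_fraction_sd > 0 else pop.forth_fraction_mean
    frac = float(np.clip(frac, 0.05, 0.95))
    return MotorSignature(
        participant_id=participant_id,
        tool=tool,
        stroke_amplitude=_truncated_normal(rng, pop.amplitude_mean, pop.amplitude_sd),
        cycle_duration=_truncated_normal(rng, pop.duration_mean, pop.duration_sd),
        forth_fraction=frac,
        rest_offset=pop.rest_offset,
    )


def participant_ids(config: SimulationConfig) -> list[str]:
    width = max(2, len(str(config.n_participants)))
    return [f"P{i + 1:0{width}d}" for i in range(config.n_participants)]


def draw_signatures(config: SimulationConfig) -> list[MotorSignature]:
    """Draw one signature per participant per tool (preserved-mode draws).

    Deterministic given ``config.rng_seed``; with all population SDs zero
    every participant receives the population-mean signature.
    """
    rng = np.random.default_rng(config.rng_seed)
    return [
        _draw_signature(rng, pid, tool, config.tool_populations[tool])
        for pid in participant_ids(config)
        for tool in config.tools
    ]


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on tau in [0, 1]."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


@dataclass
class SimulatedRecording:
    """A synthetic recording with its construction ground truth."""

    recording: Recording
    #: (start, switch, end) sample indices of every generated cycle
    cycle_boundaries: list[tuple[int, int, int]]
    #: per-cycle analytic landmark values (columns = landmark names)
    cycle_truth: pd.DataFrame


def synthesize_recording(
    signature: MotorSignature,
    tool: str,
    effector: str,
    modulation: EffectorModulation,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedRecording:
    """Generate one recording from a signature under an effector modulation.

    The end-point path starts and ends at the signature's rest offset and
    concatenates ``config.n_cycles`` cycles, each a minimum-jerk forth
    stroke followed by a minimum-jerk back stroke along the tool's primary
    axis, with small sinusoidal secondary-axis components and additive
    Gaussian noise.  Six marker trajectories are rigid offsets of the
    end-point path, each with independent measurement noise.
    """
    if tool != signature.tool:
        raise ConfigurationError(
            f"signature is for tool {signature.tool!r}, not {tool!r}"
        )
    if modulation.effector != effector:
        raise ConfigurationError(
            f"modulation is for effector {modulation.effector!r}, not {effector!r}"
        )
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    fs = config.sample_rate
    amp = modulation.amplitude_scale * signature.stroke_amplitude
    dur = modulation.duration_scale * signature.cycle_duration
    frac = signature.forth_fraction

    axis_p = AXIS_INDEX[PRIMARY_AXIS[tool]]
    sign = FORTH_SIGN[tool]
    sec_full, sec_half = (AXIS_INDEX[a] for a in _SECONDARY_AXES[tool])
    q = config.secondary_amplitude_frac

    primary_parts: list[np.ndarray] = []
    phase_parts: list[np.ndarray] = []
    amp_per_sample: list[np.ndarray] = []
    boundaries: list[tuple[int, int, int]] = []
    truth_rows: list[dict[str, float]] = []
    pos = 0
    for c in range(config.n_cycles):
        if config.cycle_jitter > 0:
            a_c = amp * max(0.1, 1.0 + config.cycle_jitter * rng.standard_normal())
            d_c = dur * max(0.1, 1.0 + config.cycle_jitter * rng.standard_normal())
        else:
            a_c, d_c = amp, dur
        n_f = int(round(frac * d_c * fs))
        n_b = int(round((1 - frac) * d_c * fs))
        if n_f + n_b < _MIN_SAMPLES_PER_CYCLE:
            raise SamplingError(
                f"cycle {c + 1}: {n_f + n_b} samples at {fs} Hz "
                f"(< {_MIN_SAMPLES_PER_CYCLE}); raise sample_rate or duration"
            )
        if n_f < 2 or n_b < 2:
            raise SamplingError(f"cycle {c + 1}: degenerate stroke lengths")
        tau_f = np.arange(n_f) / n_f
        tau_b = np.arange(n_b) / n_b
        forth = sign * a_c * minimum_jerk(tau_f)
        back = sign * a_c * (1.0 - minimum_jerk(tau_b))
        primary_parts.append(forth)
        primary_parts.append(back)
        n_c = n_f + n_b
        phase_parts.append(np.arange(n_c) / n_c)
        amp_per_sample.append(np.full(n_c, a_c))
        boundaries.append((pos, pos + n_f, pos + n_c))
        d_f = n_f / fs
        vert_amp = a_c if axis_p == 2 else (
            2 * q * a_c if sec_full == 2 else q * a_c
        )
        truth_rows.append({
            "cycle_ordinal": c + 1,
            "cycle_duration": n_c / fs,
            "vertical_amplitude": vert_amp,
            "max_velocity_forth": PEAK_SPEED_FACTOR * a_c / d_f,
            "peak_acceleration_forth": PEAK_ACC_FACTOR * a_c / d_f**2,
            "peak_deceleration_forth": PEAK_ACC_FACTOR * a_c / d_f**2,
        })
        pos += n_c

    primary = np.concatenate(primary_parts + [np.array([0.0])])
    phase = np.concatenate(phase_parts + [np.array([0.0])])
    a_samp = np.concatenate(amp_per_sample + [np.array([amp])])
    n = len(primary)

    endpoint = np.tile(np.asarray(signature.rest_offset, dtype=float), (n, 1))
    endpoint[:, axis_p] += primary
    endpoint[:, sec_full] += q * a_samp * np.sin(2 * np.pi * phase)
    endpoint[:, sec_half] += 0.5 * q * a_samp * np.sin(4 * np.pi * phase)

    markers = {}
    for name, offset in MARKER_OFFSETS.items():
        traj = endpoint + np.asarray(offset)
        if config.noise_sd > 0:
            traj = traj + rng.normal(0.0, config.noise_sd, size=traj.shape)
        markers[name] = traj

    recording = Recording(
        participant_id=signature.participant_id,
        tool=tool,
        effector=effector,
        sample_rate=fs,
        markers=markers,
        endpoint_marker="marker_1",
    )
    return SimulatedRecording(
        recording=recording,
        cycle_boundaries=boundaries,
        cycle_truth=pd.DataFrame(truth_rows),
    )


@dataclass
class Cohort:
    """A generated cohort: recordings plus analytic ground truth."""

    recordings: list[SimulatedRecording]
    ground_truth: LandmarkTable
    config: SimulationConfig


def _truth_table(recordings: list[SimulatedRecording],
                 first_kept: int, last_kept: int) -> LandmarkTable:
    rows = []
    for sim in recordings:
        truth = sim.cycle_truth
        if truth["cycle_ordinal"].max() >= last_kept:
            truth = truth[truth["cycle_ordinal"].between(first_kept, last_kept)]
        long = truth.drop(columns="cycle_ordinal").agg(["mean", "std", "size"]).T
        rec = sim.recording
        for param, row in long.iterrows():
            rows.append({
                "participant": rec.participant_id,
                "tool": rec.tool,
                "effector": rec.effector,
                "parameter": param,
                "value": row["mean"],
                "sd": row["std"],
                "n_cycles": int(row["size"]),
                "se": row["std"] / math.sqrt(row["size"]),
            })
    return LandmarkTable(pd.DataFrame(rows))


def iter_recordings(config: SimulationConfig):
    """Yield the cohort's recordings one at a time (constant memory).

    Same draw order — hence bit-identical output — as
    :func:`generate_cohort` with the same config.
    """
    rng = np.random.default_rng(config.rng_seed)
    sig_rng = np.random.default_rng(rng.integers(2**31))
    noise_rng = np.random.default_rng(rng.integers(2**31))

    pids = participant_ids(config)
    preserved = {
        (pid, tool): _draw_signature(sig_rng, pid, tool, config.tool_populations[tool])
        for pid in pids
        for tool in config.tools
    }
    for pid in pids:
        for tool in config.tools:
            for effector in config.effectors:
                if config.preservation_mode == "preserved":
                    sig = preserved[(pid, tool)]
                else:
                    sig = _draw_signature(
                        sig_rng, pid, tool, config.tool_populations[tool]
                    )
                yield synthesize_recording(
                    sig, tool, effector, config.modulation(effector),
                    config, rng=noise_rng,
                )


def generate_cohort(
    config: SimulationConfig,
    first_kept: int = FIRST_KEPT,
    last_kept: int = LAST_KEPT,
) -> Cohort:
    """Generate one recording per participant x tool x effector.

    In ``preserved`` mode a participant's per-tool signature is shared
    (after effector modulation) by all effectors; in ``null`` mode an
    independent signature is redrawn for each effector.  The ground-truth
    table holds the analytic landmark means over the retained cycle range
    (falling back to all cycles when fewer than ``last_kept`` were
    generated).
    """
    recordings = list(iter_recordings(config))
    truth = _truth_table(recordings, first_kept, last_kept)
    return Cohort(recordings=recordings, ground_truth=truth, config=config)
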