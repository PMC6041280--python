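"""Filtering and differentiation of end-point trajectories.

Raw marker positions are low-pass filtered with a zero-phase (forward-
backward) Butterworth filter — 10 Hz cut-off, 4th order per pass — then
differentiated with central differences to obtain 3D velocity, speed
(Euclidean norm) and signed tangential acceleration (the time derivative
of speed).  Deceleration is the negative part of tangential acceleration.

The dual-pass application squares the magnitude response, so the -3 dB
point of the effective filter is slightly below the nominal cut-off; this
is the standard movement-science convention and is left uncompensated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import LengthError, ParameterError
from .io import Recording

__all__ = [
    "FilterDescriptor",
    "KinematicSeries",
    "lowpass_filter",
    "differentiate",
    "compute_kinematics",
]

DEFAULT_CUTOFF_HZ = 10.0
DEFAULT_ORDER = 4


@dataclass(frozen=True)
class FilterDescriptor:
    type: str = "butterworth"
    cutoff_hz: float = DEFAULT_CUTOFF_HZ
    order: int = DEFAULT_ORDER
    zero_phase: bool = True


@dataclass
class KinematicSeries:
    """Filtered end-point position with derived velocity and acceleration.

    All arrays share the same length; positions in mm, velocity in mm/s,
    tangential acceleration in mm/s^2 (signed).
    """

    time: np.ndarray
    position: np.ndarray  # (n, 3)
    velocity: np.ndarray  # (n, 3)
    speed: np.ndarray  # (n,)
    tangential_acceleration: np.ndarray  # (n,)
    sample_rate: float
    filter_descriptor: FilterDescriptor | None = None

    def __post_init__(self) -> None:
        n = len(self.time)
        for arr in (self.position, self.velocity, self.speed,
                    self.tangential_acceleration):
            if len(arr) != n:
                raise LengthError("kinematic series arrays have unequal lengths")
        if not np.allclose(
            self.speed, np.linalg.norm(self.velocity, axis=1), rtol=1e-9, atol=1e-9
        ):
            raise ValueError("speed is not the norm of velocity")

    def __len__(self) -> int:
        return len(self.time)


def lowpass_filter(
    positions: np.ndarray,
    sample_rate: float,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass, applied per coordinate.

    ``order`` is the order of each pass; the forward-backward application
    doubles the effective roll-off and cancels phase delay.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    nyquist = sample_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ParameterError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={nyquist} Hz)"
        )
    # filtfilt's default edge padding needs 3 * (order + 1) samples
    min_len = 3 * (order + 1) + 1
    if positions.shape[0] < min_len:
        raise LengthError(
            f"series of length {positions.shape[0]} too short for order-{order} "
            f"zero-phase filtering (need >= {min_len})"
        )
    sos = signal.butter(order, cutoff, btype="low", fs=sample_rate, output="sos")
    return signal.sosfiltfilt(sos, positions, axis=0)


def dual_pass_gain(freq_hz: float, sample_rate: float,
                   cutoff: float = DEFAULT_CUTOFF_HZ,
                   order: int = DEFAULT_ORDER) -> float:
    """Magnitude gain of the forward-backward filter at ``freq_hz``."""
    sos = signal.butter(order, cutoff, btype="low", fs=sample_rate, output="sos")
    _, h = signal.sosfreqz(sos, worN=[freq_hz], fs=sample_rate)
    return float(np.abs(h[0]) ** 2)


def differentiate(
    position: np.ndarray, sample_rate: float,
    filter_descriptor: FilterDescriptor | None = None,
) -> KinematicSeries:
    """Central-difference velocity, speed and tangential acceleration.

    Central differences (one-sided at the ends) are exact for quadratics,
    so the scheme's error is testable against polynomial oracles.
    """
    position = np.asarray(position, dtype=float)
    if position.ndim != 2 or position.shape[1] != 3:
        raise ValueError("position must be an (n, 3) array")
    if len(position) < 3:
        raise LengthError("need at least 3 samples to differentiate")
    dt = 1.0 / sample_rate
    velocity = np.gradient(position, dt, axis=0)
    speed = np.linalg.norm(velocity, axis=1)
    tangential = np.gradient(speed, dt)
    time = np.arange(len(position)) * dt
    return KinematicSeries(
        time=time,
        position=position,
        velocity=velocity,
        speed=speed,
        tangential_acceleration=tangential,
        sample_rate=sample_rate,
        filter_descriptor=filter_descriptor,
    )


def compute_kinematics(
    recording: Recording,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
) -> KinematicSeries:
    """Filter a recording's end-point path and differentiate it."""
    filtered = lowpass_filter(recording.endpoint(), recording.sample_rate,
                              cutoff=cutoff, order=order)
    desc = FilterDescriptor(cutoff_hz=cutoff, order=order)
    return differentiate(filtered, recording.sample_rate, filter_descriptor=desc)
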