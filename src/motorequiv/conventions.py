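"""Shared naming and axis conventions.

The laboratory frame is fixed: x anteroposterior (positive away from the
body), y lateral (positive toward the participant's right), z vertical
(positive up).  Each tool-use action is performed preferentially along one
axis: hammering vertically, brushing laterally, painting (roller)
anteroposteriorly.

Cycle boundaries sit at the stroke-start extremum of the primary coordinate:
the hammer starts each cycle at the raised (maximum z) position, the brush at
the right end of the sweep (maximum y), the roller at the position nearest
the body (minimum x).  The forth stroke therefore moves in the direction of
``FORTH_SIGN`` along the primary axis.
"""

TOOLS = ("hammer", "brush", "roller")

EFFECTORS = ("right_foot", "right_elbow", "left_hand", "right_hand")

AXES = ("x", "y", "z")
AXIS_INDEX = {"x": 0, "y": 1, "z": 2}

#: primary movement axis per tool
PRIMARY_AXIS = {"hammer": "z", "brush": "y", "roller": "x"}

#: +1 -> cycle boundaries at maxima of the primary coordinate, -1 -> minima
BOUNDARY_SIGN = {"hammer": +1, "brush": +1, "roller": -1}

#: sign of the primary-coordinate displacement during the forth stroke
FORTH_SIGN = {"hammer": -1, "brush": -1, "roller": +1}

#: the five kinematic landmarks, in reporting order
LANDMARKS = (
    "vertical_amplitude",
    "cycle_duration",
    "max_velocity_forth",
    "peak_acceleration_forth",
    "peak_deceleration_forth",
)

#: the six unordered effector pairs, in reporting order
EFFECTOR_PAIRS = (
    ("right_foot", "right_elbow"),
    ("right_foot", "left_hand"),
    ("right_elbow", "left_hand"),
    ("right_foot", "right_hand"),
    ("right_elbow", "right_hand"),
    ("left_hand", "right_hand"),
)

# minimum-jerk closed-form peak factors: peak speed = PEAK_SPEED_FACTOR * A/d,
# peak (tangential) acceleration = PEAK_ACC_FACTOR * A/d**2 for a stroke of
# amplitude A and duration d following s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5
PEAK_SPEED_FACTOR = 1.875
PEAK_ACC_FACTOR = 5.7735026919  # 10 / sqrt(3)


def validate_tool(tool: str) -> str:
    if tool not in TOOLS:
        raise ValueError(f"unknown tool {tool!r}; expected one of {TOOLS}")
    return tool


def validate_effector(effector: str) -> str:
    if effector not in EFFECTORS:
        raise ValueError(
            f"unknown effector {effector!r}; expected one of {EFFECTORS}"
        )
    return effector
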