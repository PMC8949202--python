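"""Sensor registry for the simulated 10-sensor bend-sensor glove.

The glove carries one flexion sensor over each MCP and PIP joint of the
four fingers, plus one over the thumb MCP and one over the thumb IP —
ten joint sensors in all (the four abduction/adduction sensors between
fingers are not part of the angle-table method and are not modeled).
"""

from __future__ import annotations

#: Joint classes. MCP knuckle joints flex to ~95 deg, PIP (and the thumb
#: IP, which behaves like a PIP hinge) to ~105 deg.
MCP = "MCP"
PIP = "PIP"

#: Sensor identifiers in glove order.
SENSOR_IDS: tuple[str, ...] = (
    "thumb_mcp",
    "thumb_ip",
    "index_mcp",
    "index_pip",
    "middle_mcp",
    "middle_pip",
    "ring_mcp",
    "ring_pip",
    "little_mcp",
    "little_pip",
)

#: Joint class per sensor; the thumb IP is grouped with the PIP sensors.
JOINT_CLASS: dict[str, str] = {
    s: (MCP if s.endswith("_mcp") else PIP) for s in SENSOR_IDS
}

#: Physical flexion limit (degrees) per joint class — the maxima of the
#: calibration grids below.
THETA_MAX: dict[str, float] = {MCP: 95.0, PIP: 105.0}

#: Calibration pose grids (degrees).  MCP sensors are sampled at 13
#: angles up to 95 deg; PIP-class sensors additionally at 105 deg
#: (14 points) to cover their larger flexion range.
MCP_GRID: tuple[float, ...] = (0, 5, 15, 25, 30, 35, 40, 50, 55, 65, 75, 85, 95)
PIP_GRID: tuple[float, ...] = MCP_GRID + (105,)

#: Wooden-block accuracy-test angles (degrees).
TEST_GRID: tuple[float, ...] = (0, 20, 45, 60, 70, 90)

#: Glove hand sizes (inches) a table bank is built for.
HAND_SIZES: tuple[float, ...] = (7.0, 7.5, 7.75, 8.0)

#: 12-bit sensor output ceiling.
RAW_MAX = 4095

#: Glove frame rate (Hz).
FRAME_RATE = 50.0


def theta_max_for(sensor_id: str) -> float:
    """Physical joint limit in degrees for a sensor."""
    return THETA_MAX[JOINT_CLASS[sensor_id]]


def grid_for(sensor_id: str) -> tuple[float, ...]:
    """Default calibration angle grid for a sensor."""
    return MCP_GRID if JOINT_CLASS[sensor_id] == MCP else PIP_GRID
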