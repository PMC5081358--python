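"""Circular sensor-array geometry and acoustic propagation delays.

The array is a ring of omnidirectional sensors ("legs" in the scorpion
analogy) lying in a single horizontal plane.  Bearings and sensor angles are
expressed in degrees, counterclockwise, with 0 deg at sensor 1, and wrapped
to [0, 360).  The set-up is strictly two-dimensional: no elevation, no
directivity, no reflections.

Two propagation models are available:

* spherical (default): the exact source-to-sensor distance is used, which
  matters when the source sits only ~10 array radii away;
* far field: a plane wave, where only the delay *differences* across the
  array survive.

The quantity ``max_interleg_delay`` -- the travel time of a wavefront across
the array diameter -- is the network's characteristic timescale: it is the
default command-neuron refractory period and, scaled by 0.7, the inhibitory
synaptic delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ArrayGeometry",
    "GeometryError",
    "make_geometry",
    "propagation_delay",
    "max_interleg_delay",
    "wrap_degrees",
]


class GeometryError(ValueError):
    """Raised for physically invalid array geometries or source positions."""


def wrap_degrees(angle_deg):
    """Wrap an angle (scalar or array) into [0, 360)."""
    return np.asarray(angle_deg) % 360.0


def _default_angles(n: int) -> tuple[float, ...]:
    return tuple((360.0 * j) / n for j in range(n))


@dataclass(frozen=True)
class ArrayGeometry:
    """A circular array of ``n_sensors`` omnidirectional sensors.

    Parameters
    ----------
    n_sensors:
        Number of sensors, at least 2 (the scorpion layout uses 8).
    radius:
        Ring radius in metres (default 0.045, i.e. a 90 mm diameter board).
    sensor_angles_deg:
        One angle per sensor, degrees in [0, 360).  Defaults to equal
        spacing starting at 0 deg: angle_j = (j - 1) * 360 / n_sensors.
    sound_speed:
        Propagation speed in m/s (default 343, air at ~20 C).
    """

    n_sensors: int = 8
    radius: float = 0.045
    sensor_angles_deg: tuple[float, ...] = field(default=None)  # type: ignore[assignment]
    sound_speed: float = 343.0

    def __post_init__(self) -> None:
        if self.n_sensors < 2:
            raise GeometryError(f"need at least 2 sensors, got {self.n_sensors}")
        if not self.radius > 0:
            raise GeometryError(f"radius must be positive, got {self.radius}")
        if not self.sound_speed > 0:
            raise GeometryError(f"sound speed must be positive, got {self.sound_speed}")
        if self.sensor_angles_deg is None:
            object.__setattr__(
                self, "sensor_angles_deg", _default_angles(self.n_sensors)
            )
        angles = tuple(float(a) for a in self.sensor_angles_deg)
        if len(angles) != self.n_sensors:
            raise GeometryError(
                f"expected {self.n_sensors} sensor angles, got {len(angles)}"
            )
        if any(a < 0.0 or a >= 360.0 for a in angles):
            raise GeometryError("sensor angles must lie in [0, 360)")
        object.__setattr__(self, "sensor_angles_deg", angles)

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    @property
    def angles_rad(self) -> np.ndarray:
        return np.deg2rad(np.asarray(self.sensor_angles_deg))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_sensors": self.n_sensors,
            "diameter_m": self.diameter,
            "sound_speed_mps": self.sound_speed,
            "angles_deg": list(self.sensor_angles_deg),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArrayGeometry":
        return cls(
            n_sensors=int(d["n_sensors"]),
            radius=float(d["diameter_m"]) / 2.0,
            sensor_angles_deg=tuple(d["angles_deg"]) if "angles_deg" in d else None,
            sound_speed=float(d.get("sound_speed_mps", 343.0)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ArrayGeometry":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def make_geometry(
    n_sensors: int = 8,
    diameter: float = 0.09,
    sound_speed: float = 343.0,
) -> ArrayGeometry:
    """Build an equally spaced circular array from its diameter.

    Angles start at 0 deg for sensor 1 and increase counterclockwise in
    steps of 360/n_sensors.
    """
    if not diameter > 0:
        raise GeometryError(f"diameter must be positive, got {diameter}")
    return ArrayGeometry(
        n_sensors=n_sensors, radius=diameter / 2.0, sound_speed=sound_speed
    )


def propagation_delay(
    g: ArrayGeometry,
    source_bearing_deg,
    source_distance: float,
    sensor=None,
    far_field: bool = False,
):
    """Propagation delay from a source to one sensor (or all sensors).

    Spherical model (default)::

        d_j = sqrt(R^2 + r^2 - 2 R r cos(bearing - theta_j)),  delay = d_j / c

    with R the source distance from the array centre and r the ring radius.
    In far-field mode the plane-wave expression
    ``(R - r cos(bearing - theta_j)) / c`` is used instead.

    Parameters
    ----------
    source_bearing_deg:
        Source bearing in degrees (scalar or array; 360-periodic).
    source_distance:
        Distance from the array centre in metres; must exceed the radius.
    sensor:
        0-based sensor index, or None to return delays for all sensors
        (last axis indexes the sensor).

    Returns
    -------
    Delay in seconds; scalar if both inputs are scalars, otherwise an array
    broadcast over bearing with a trailing sensor axis when ``sensor`` is
    None.
    """
    if not source_distance > g.radius:
        raise GeometryError(
            f"source distance {source_distance} m must exceed the array "
            f"radius {g.radius} m"
        )
    bearing = np.asarray(source_bearing_deg, dtype=float)
    if sensor is None:
        theta = np.asarray(g.sensor_angles_deg)
        diff_deg = bearing[..., None] - theta
    else:
        theta = g.sensor_angles_deg[int(sensor)]
        diff_deg = bearing - theta
    cos_diff = np.cos(np.deg2rad(diff_deg))
    R, r = float(source_distance), g.radius
    if far_field:
        dist = R - r * cos_diff
    else:
        dist = np.sqrt(R * R + r * r - 2.0 * R * r * cos_diff)
    delay = dist / g.sound_speed
    if np.ndim(source_bearing_deg) == 0 and sensor is not None:
        return float(delay)
    return delay


def max_interleg_delay(g: ArrayGeometry) -> float:
    """Far-field wavefront travel time across the array diameter, 2r/c."""
    return g.diameter / g.sound_speed
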