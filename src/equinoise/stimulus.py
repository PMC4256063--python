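"""Random-dot kinematogram stimulus generation.

Direction convention: angles are measured in degrees from vertical-upward,
positive clockwise (rightward), and stored wrapped to (-180, 180].  Two
stimulus dialects are supported:

* wrapped-normal fields (equivalent-noise task): every dot direction is an
  independent draw from a wrapped normal with a given mean and SD (the
  external noise, ``sigma_ext``);
* coherence mixtures (motion-coherence task): a fixed fraction of dots move
  in a single signal direction while the remainder move in uniformly random
  directions.

Dot kinematics use degrees of visual angle in a Cartesian frame centred on
the circular aperture; there is no screen/pixel model.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "StimulusSpec",
    "DirectionField",
    "wrap_degrees",
    "sample_wrapped_normal_directions",
    "make_coherence_directions",
    "displacement_per_update",
    "generate_dot_trajectory",
    "write_trajectory_csv",
]

#: above this nominal SD (degrees) a wrapped normal is numerically
#: indistinguishable from the circular uniform, which we substitute.
UNIFORM_FALLBACK_SD = 180.0


def wrap_degrees(angle):
    """Wrap angles (degrees) to the interval (-180, 180]."""
    return 180.0 - np.mod(180.0 - np.asarray(angle, dtype=float), 360.0)


@dataclass(frozen=True)
class StimulusSpec:
    """Geometry and timing of the dot kinematogram.

    Defaults follow the study design: 100 overlapping white dots of 0.44 deg
    diameter drifting for 400 ms in a 15 deg aperture at 60 Hz, positions
    updated every 3 frames.
    """

    n_dots: int = 100
    dot_diameter: float = 0.44
    aperture_diameter: float = 15.0
    duration: float = 400.0  # ms
    frame_rate: float = 60.0  # Hz
    update_interval: int = 3  # frames between position updates
    speed: float = 1.5  # deg/s

    def __post_init__(self):
        if self.n_dots <= 0:
            raise ValueError("n_dots must be positive")
        if self.speed < 0:
            raise ValueError("speed must be non-negative")
        if self.frame_rate <= 0 or self.update_interval <= 0:
            raise ValueError("frame_rate and update_interval must be positive")
        if self.duration <= 0 or self.aperture_diameter <= 0:
            raise ValueError("duration and aperture_diameter must be positive")
        n_frames = self.duration / 1000.0 * self.frame_rate
        if abs(n_frames - round(n_frames)) > 1e-9:
            raise ValueError("duration must correspond to an integer frame count")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / 1000.0 * self.frame_rate))

    @property
    def n_updates(self) -> int:
        """Number of position updates after the initial frame."""
        return self.n_frames // self.update_interval

    @property
    def displacement(self) -> float:
        return displacement_per_update(self.speed, self.frame_rate, self.update_interval)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "StimulusSpec":
        return cls(**json.loads(s))


@dataclass(frozen=True)
class DirectionField:
    """Per-dot directions for one stimulus interval.

    Exactly one of ``direction_sd`` (wrapped-normal dialect) and
    ``coherence`` (coherence dialect) is set.
    """

    directions: np.ndarray = field(repr=False)
    mean_direction: float = 0.0
    direction_sd: Optional[float] = None
    coherence: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "directions", np.asarray(self.directions, dtype=float))
        if self.directions.ndim != 1 or self.directions.size == 0:
            raise ValueError("directions must be a non-empty 1-D array")
        if (self.direction_sd is None) == (self.coherence is None):
            raise ValueError("exactly one of direction_sd and coherence must be set")

    @property
    def n_dots(self) -> int:
        return self.directions.size


def sample_wrapped_normal_directions(mean: float, sd: float, n: int, rng: np.random.Generator) -> DirectionField:
    """Draw ``n`` dot directions from a wrapped normal (degrees).

    Sampling draws from the ordinary normal and wraps to (-180, 180].  For
    ``sd`` above 180 deg the wrapped normal is indistinguishable from the
    circular uniform, which is substituted.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if n < 1:
        raise ValueError("n must be at least 1")
    if sd > UNIFORM_FALLBACK_SD:
        raw = rng.uniform(-180.0, 180.0, size=n)
    else:
        raw = rng.normal(mean, sd, size=n)
    return DirectionField(wrap_degrees(raw), mean_direction=float(wrap_degrees(mean)), direction_sd=float(sd))


def make_coherence_directions(coherence: float, signal_direction: float, n: int, rng: np.random.Generator) -> DirectionField:
    """Coherence-mixture field: round(coherence*n) signal dots, rest uniform.

    Signal-dot identities are chosen at random each call; the signal count is
    deterministic (not Bernoulli per dot), which reduces threshold-estimate
    variance.
    """
    if not 0.0 <= coherence <= 1.0:
        raise ValueError("coherence must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be at least 1")
    n_signal = int(round(coherence * n))
    dirs = rng.uniform(-180.0, 180.0, size=n)
    idx = rng.choice(n, size=n_signal, replace=False)
    dirs[idx] = signal_direction
    return DirectionField(
        wrap_degrees(dirs),
        mean_direction=float(wrap_degrees(signal_direction)),
        coherence=float(coherence),
    )


def displacement_per_update(speed: float, frame_rate: float, update_interval: int) -> float:
    """Dot displacement (deg) per position update: speed * interval / rate.

    At 60 Hz with updates every 3 frames this gives 0.075 deg at 1.5 deg/s
    and 0.3 deg at 6 deg/s.
    """
    if speed < 0:
        raise ValueError("speed must be non-negative")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if update_interval <= 0:
        raise ValueError("update_interval must be positive")
    return speed * update_interval / frame_rate


def _uniform_disc(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([r * np.sin(theta), r * np.cos(theta)])


def generate_dot_trajectory(spec: StimulusSpec, fld: DirectionField, rng: np.random.Generator) -> np.ndarray:
    """Per-update dot positions, shape (n_updates + 1, n_dots, 2).

    Dots start uniformly inside the aperture and step by
    ``spec.displacement`` along their (fixed) direction at every update;
    lifetimes are unlimited.  A dot whose step would leave the aperture is
    re-entered at a uniformly random position inside it (the source design
    does not state a boundary rule; see the methods note).
    """
    if fld.n_dots != spec.n_dots:
        raise ValueError("field must contain spec.n_dots directions")
    radius = spec.aperture_diameter / 2.0
    step = spec.displacement
    theta = np.deg2rad(fld.directions)
    # 0 deg = up, positive clockwise => x grows with sin, y with cos
    velocity = step * np.column_stack([np.sin(theta), np.cos(theta)])
    pos = np.empty((spec.n_updates + 1, spec.n_dots, 2))
    pos[0] = _uniform_disc(spec.n_dots, radius, rng)
    for k in range(1, spec.n_updates + 1):
        nxt = pos[k - 1] + velocity
        outside = np.hypot(nxt[:, 0], nxt[:, 1]) > radius
        if outside.any():
            nxt[outside] = _uniform_disc(int(outside.sum()), radius, rng)
        pos[k] = nxt
    return pos


def write_trajectory_csv(path, positions: np.ndarray, directions: Sequence[float]) -> None:
    """Write per-update dot positions as plain CSV."""
    directions = np.asarray(directions, dtype=float)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["update_index", "dot_id", "x_deg", "y_deg", "direction_deg"])
        for k in range(positions.shape[0]):
            for d in range(positions.shape[1]):
                w.writerow([k, d, f"{positions[k, d, 0]:.6f}", f"{positions[k, d, 1]:.6f}", f"{directions[d]:.6f}"])
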