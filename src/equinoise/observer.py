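"""Generative observer models for direction-integration tasks.

An observer is the triple ``ObserverParams(sigma_int, n_samp, lapse)``:

* ``sigma_int`` -- additive internal noise (deg): the precision limit on
  estimating each local motion direction;
* ``n_samp`` -- effective number of local samples averaged.  Values below 1
  have no literal dot-count reading; pooling is therefore implemented as
  variance scaling of a single decision variable (equivalently, global
  multiplicative noise), so fractional ``n_samp`` is well defined;
* ``lapse`` -- probability of a stimulus-independent uniformly random
  response.

For the equivalent-noise task the internal direction estimate is drawn from
a wrapped normal with SD ``sqrt((sigma_int**2 + sigma_ext**2) / n_samp)``
and the response is its sign, which makes the 84%-correct threshold equal
the equivalent-noise prediction by construction.  The motion-coherence
observer (per-dot noise, circular pooling, global noise) is a plausible
construction validated only by qualitative properties; there is no ideal
observer for coherence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .stimulus import DirectionField, wrap_degrees

__all__ = [
    "ObserverParams",
    "Response",
    "en_decision",
    "en_decision_batch",
    "en_pcorrect",
    "coherence_decision",
    "coherence_pcorrect",
]

# wrapped normal with this nominal SD (deg) is numerically uniform; used to
# cap degenerate global-noise draws (e.g. zero resultant length)
_HUGE_SD = 1e4


@dataclass(frozen=True)
class ObserverParams:
    sigma_int: float
    n_samp: float
    lapse: float = 0.0

    def __post_init__(self):
        if self.sigma_int < 0:
            raise ValueError("sigma_int must be non-negative")
        if self.n_samp <= 0:
            raise ValueError("n_samp must be positive")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must lie in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ObserverParams":
        return cls(**json.loads(s))


@dataclass(frozen=True)
class Response:
    choice: str  # "left" | "right"
    lapsed: bool = False  # simulation truth, not observable

    def __post_init__(self):
        if self.choice not in ("left", "right"):
            raise ValueError("choice must be 'left' or 'right'")


def _decision_sd(params: ObserverParams, external_sd) -> np.ndarray:
    return np.sqrt((params.sigma_int**2 + np.asarray(external_sd, dtype=float) ** 2) / params.n_samp)


def en_decision(params: ObserverParams, mean_direction: float, external_sd: float, rng: np.random.Generator) -> Response:
    """One equivalent-noise trial: report left/right of vertical.

    With probability ``lapse`` the response is uniformly random; otherwise
    the internal estimate is a wrapped-normal draw around ``mean_direction``
    with the pooled decision SD, and the choice is its sign.
    """
    if external_sd < 0:
        raise ValueError("external_sd must be non-negative")
    if rng.uniform() < params.lapse:
        return Response("right" if rng.uniform() < 0.5 else "left", lapsed=True)
    d = wrap_degrees(rng.normal(mean_direction, _decision_sd(params, external_sd)))
    return Response("right" if d > 0 else "left")


def en_decision_batch(
    params: ObserverParams,
    mean_directions,
    external_sds,
    rng: np.random.Generator,
):
    """Vectorised equivalent-noise decisions.

    Returns ``(right, lapsed)`` boolean arrays broadcast over the inputs.
    """
    means = np.asarray(mean_directions, dtype=float)
    sds = _decision_sd(params, external_sds)
    means, sds = np.broadcast_arrays(means, sds)
    d = wrap_degrees(rng.normal(means, sds))
    right = d > 0
    lapsed = rng.uniform(size=means.shape) < params.lapse
    if lapsed.any():
        right = np.where(lapsed, rng.uniform(size=means.shape) < 0.5, right)
    return right, lapsed


def en_pcorrect(params: ObserverParams, mean_direction: float, external_sd: float, n_trials: int, rng: np.random.Generator) -> float:
    """Monte-Carlo proportion correct at a fixed signed mean direction."""
    right, _ = en_decision_batch(params, np.full(n_trials, mean_direction), external_sd, rng)
    return float(np.mean(right == (mean_direction > 0)))


def _circ_mean_sd(directions_deg: np.ndarray, axis=-1):
    """Circular mean direction and SD (deg) via the resultant vector."""
    theta = np.deg2rad(directions_deg)
    c = np.mean(np.cos(theta), axis=axis)
    s = np.mean(np.sin(theta), axis=axis)
    r = np.hypot(c, s)
    # note: 0 deg = up => direction angle from (cos, sin) via atan2(sin, cos)
    mean = np.rad2deg(np.arctan2(s, c))
    with np.errstate(divide="ignore"):
        sd = np.rad2deg(np.sqrt(np.maximum(-2.0 * np.log(r), 0.0)))
    return mean, sd


def coherence_decision(params: ObserverParams, fld: DirectionField, rng: np.random.Generator) -> Response:
    """One motion-coherence trial.

    Each dot direction is perturbed by independent Gaussian noise of SD
    ``sigma_int``; the circular mean of the perturbed dots is computed; a
    global pooling perturbation of SD ``circSD(perturbed)/sqrt(n_samp)`` is
    added; the choice is the sign of the horizontal component.
    """
    if fld.coherence is None:
        raise ValueError("coherence_decision requires a coherence-dialect field")
    if rng.uniform() < params.lapse:
        return Response("right" if rng.uniform() < 0.5 else "left", lapsed=True)
    # dot-direction angles are measured from vertical-up; _circ_mean_sd is
    # convention-agnostic because perturbation and pooling are rotationally
    # invariant
    noisy = fld.directions + rng.normal(0.0, params.sigma_int, size=fld.n_dots)
    mu, sd = _circ_mean_sd(noisy)
    g = sd / np.sqrt(params.n_samp)
    if not np.isfinite(g) or g > _HUGE_SD:
        g = _HUGE_SD
    final = wrap_degrees(mu + rng.normal(0.0, g))
    return Response("right" if final > 0 else "left")


def coherence_pcorrect(
    params: ObserverParams,
    coherence: float,
    signal_direction: float,
    n_dots: int,
    n_trials: int,
    rng: np.random.Generator,
) -> float:
    """Monte-Carlo proportion correct for the coherence observer.

    Trials are generated and judged in a vectorised batch; signal-dot
    identity is immaterial to the pooled statistic, so signal dots occupy
    the leading columns.
    """
    if not 0.0 <= coherence <= 1.0:
        raise ValueError("coherence must lie in [0, 1]")
    n_signal = int(round(coherence * n_dots))
    dirs = rng.uniform(-180.0, 180.0, size=(n_trials, n_dots))
    dirs[:, :n_signal] = signal_direction
    noisy = dirs + rng.normal(0.0, params.sigma_int, size=dirs.shape)
    mu, sd = _circ_mean_sd(noisy, axis=1)
    g = sd / np.sqrt(params.n_samp)
    g = np.where(np.isfinite(g) & (g <= _HUGE_SD), g, _HUGE_SD)
    final = wrap_degrees(mu + rng.normal(0.0, 1.0, size=n_trials) * g)
    right = final > 0
    lapsed = rng.uniform(size=n_trials) < params.lapse
    if lapsed.any():
        right = np.where(lapsed, rng.uniform(size=n_trials) < 0.5, right)
    correct = right == (wrap_degrees(signal_direction) > 0)
    return float(np.mean(correct))
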