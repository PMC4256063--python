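"""Equivalent-noise decomposition and lapse correction.

The equivalent-noise model writes the squared direction-discrimination
threshold as

    sigma_obs**2 = (sigma_int**2 + sigma_ext**2) / n_samp

so that two measured thresholds -- the no-noise threshold (sigma_obs at
sigma_ext = 0) and the maximum tolerable noise (MTN, the largest direction
SD still supporting 84%-correct judgements of a +/-45 deg signal) --
suffice to recover the additive internal noise sigma_int and the effective
sample number n_samp:

    n_samp    = exp(0.000121*MTN**2 + 0.0357*MTN - 1.8093)
    sigma_int = no_noise_threshold * sqrt(n_samp)

The exponential-quadratic MTN -> n_samp mapping is taken as authoritative
for analysis; :func:`rederive_mtn_mapping` re-derives it by Monte-Carlo
simulation of the high-noise task so the printed coefficients can be
validated (and their domain of validity mapped) rather than trusted
blindly.

Lapse correction: inattentive (stimulus-independent) responses inflate
staircase thresholds.  :func:`lapse_correction_build` simulates staircases
at a grid of lapse rates and tabulates multiplicative threshold-inflation
factors per task; :func:`lapse_correct` divides a measured threshold by the
interpolated factor.  The table is indexed by the *observed* catch-trial
error rate (a lapsed guess is correct half the time, so an observer with
true lapse probability lambda shows a catch error rate of lambda/2).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats
from sklearn.isotonic import IsotonicRegression

from .observer import ObserverParams, en_decision_batch
from .staircase import (
    HIGH_NOISE_SIGNAL,
    STAIRCASE_DEFAULTS,
    QuestState,
    _staircase_trial,
    EN_PLAN,
    COHERENCE_PLAN,
)

__all__ = [
    "EQ2_COEFFS",
    "ENEstimates",
    "nsamp_from_mtn",
    "mtn_from_nsamp",
    "sigma_int_from",
    "en_curve",
    "estimates_from_thresholds",
    "fit_en_full",
    "MtnMapping",
    "rederive_mtn_mapping",
    "LapseCorrectionTable",
    "lapse_correction_build",
    "lapse_correct",
]

#: printed coefficients of the exponential-quadratic MTN -> n_samp mapping
EQ2_COEFFS = (0.000121, 0.0357, -1.8093)


def nsamp_from_mtn(mtn):
    """Effective sample number from the maximum tolerable noise (deg)."""
    mtn = np.asarray(mtn, dtype=float)
    if np.any(mtn < 0):
        raise ValueError("MTN must be non-negative")
    a, b, c = EQ2_COEFFS
    out = np.exp(a * mtn**2 + b * mtn + c)
    return float(out) if out.ndim == 0 else out


def mtn_from_nsamp(n_samp: float) -> float:
    """Inverse of :func:`nsamp_from_mtn` (positive root of the quadratic)."""
    if n_samp <= 0:
        raise ValueError("n_samp must be positive")
    a, b, c = EQ2_COEFFS
    c = c - math.log(n_samp)
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError("n_samp out of the mapping's range")
    return (-b + math.sqrt(disc)) / (2 * a)


def sigma_int_from(no_noise_threshold, n_samp):
    """Internal noise (deg) from the no-noise threshold and n_samp."""
    t = np.asarray(no_noise_threshold, dtype=float)
    n = np.asarray(n_samp, dtype=float)
    if np.any(t <= 0) or np.any(n <= 0):
        raise ValueError("inputs must be positive")
    out = t * np.sqrt(n)
    return float(out) if out.ndim == 0 else out


def en_curve(sigma_int, n_samp, external_sd):
    """Predicted 84% threshold (deg) at a given external noise level."""
    s = np.asarray(sigma_int, dtype=float)
    n = np.asarray(n_samp, dtype=float)
    x = np.asarray(external_sd, dtype=float)
    if np.any(s < 0) or np.any(n <= 0) or np.any(x < 0):
        raise ValueError("invalid equivalent-noise parameters")
    out = np.sqrt((s**2 + x**2) / n)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ENEstimates:
    """The four quantities recovered by the rapid two-point paradigm."""

    no_noise_threshold: float
    mtn: float
    n_samp: float
    sigma_int: float

    def __post_init__(self):
        for name in ("no_noise_threshold", "mtn", "n_samp", "sigma_int"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def estimates_from_thresholds(no_noise_threshold: float, mtn: float) -> ENEstimates:
    """Rapid two-point decomposition of the two staircase thresholds."""
    n = nsamp_from_mtn(mtn)
    return ENEstimates(
        no_noise_threshold=float(no_noise_threshold),
        mtn=float(mtn),
        n_samp=float(n),
        sigma_int=float(sigma_int_from(no_noise_threshold, n)),
    )


def fit_en_full(thresholds: Sequence[Tuple[float, float]]) -> Tuple[float, float]:
    """Full-curve equivalent-noise fit (the slow-paradigm oracle).

    Least-squares fit of the model in log-threshold space (equal weights)
    to (external_sd, threshold) pairs measured at >= 3 distinct noise
    levels.  Returns ``(sigma_int, n_samp)``.
    """
    pts = np.asarray(thresholds, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("thresholds must be (external_sd, threshold) pairs")
    xs, ys = pts[:, 0], pts[:, 1]
    if np.unique(xs).size < 3:
        raise ValueError("need >= 3 distinct external noise levels")
    if np.any(ys <= 0) or np.any(xs < 0):
        raise ValueError("thresholds must be positive, noise levels non-negative")
    n0 = max((xs.max() / ys[np.argmax(xs)]) ** 2, 1e-3)
    s0 = max(ys[np.argmin(xs)] * math.sqrt(n0), 1e-3)

    def resid(p):
        sig, n = np.exp(p)
        return np.log(ys) - np.log(en_curve(sig, n, xs))

    sol = optimize.least_squares(resid, x0=[math.log(s0), math.log(n0)])
    sig, n = np.exp(sol.x)
    return float(sig), float(n)


# ---------------------------------------------------------------------------
# Monte-Carlo re-derivation of the MTN -> n_samp mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MtnSimulationConfig:
    """Grid and sizes for the mapping re-derivation.

    The sampling grid spans the developmentally relevant range of effective
    sample numbers (roughly 0.5-1.9 in school-age children and adults) with
    a safety margin on both sides.  Internal noise is set to 1 deg rather
    than 0 (the mapping assumes it is negligible at high noise levels; a
    small positive value avoids degenerate simulations).
    """

    n_samp_grid: Tuple[float, ...] = tuple(np.geomspace(0.1, 2.5, 12).round(4))
    sigma_int: float = 1.0
    trials_per_level: int = 20000
    sd_levels: Tuple[float, ...] = tuple(np.geomspace(2.0, 170.0, 25).round(3))

    def __post_init__(self):
        if self.trials_per_level < 2000:
            warnings.warn("fewer than 2000 trials per level: MTN estimates will be noisy")


@dataclass
class MtnMapping:
    """Fitted mapping log n_samp = a*MTN**2 + b*MTN + c and its inputs."""

    coeffs: Tuple[float, float, float]
    r_squared: float
    mtn_grid: np.ndarray
    n_samp_grid: np.ndarray
    config: MtnSimulationConfig

    def predict(self, mtn):
        a, b, c = self.coeffs
        mtn = np.asarray(mtn, dtype=float)
        out = np.exp(a * mtn**2 + b * mtn + c)
        return float(out) if out.ndim == 0 else out


def _mc_mtn(params: ObserverParams, levels: np.ndarray, trials: int, rng: np.random.Generator, target: float = 0.84) -> float:
    """84% direction-SD threshold by constant-stimuli Monte Carlo.

    Proportion correct is estimated at each SD level for a +45 deg signal,
    converted to probit z, and the target crossing located by linear
    interpolation of z against log SD.
    """
    p = np.empty(levels.size)
    for i, sd in enumerate(levels):
        right, _ = en_decision_batch(params, np.full(trials, HIGH_NOISE_SIGNAL), sd, rng)
        p[i] = right.mean()
    eps = 0.5 / trials
    z = stats.norm.ppf(np.clip(p, eps, 1 - eps))
    z_target = stats.norm.ppf(target)
    # z decreases with SD; enforce monotonicity for a clean crossing
    z_mono = np.minimum.accumulate(z)
    if z_mono[0] < z_target:
        raise ValueError("performance below target at the lowest SD level")
    if z_mono[-1] > z_target:
        raise ValueError("performance above target at the highest SD level")
    logsd = np.log10(levels)
    return float(10 ** np.interp(-z_target, -z_mono, logsd))


def rederive_mtn_mapping(
    config: MtnSimulationConfig,
    rng: np.random.Generator,
) -> MtnMapping:
    """Re-derive the MTN -> n_samp mapping by simulating the high-noise task.

    For each n_samp on the grid, the 84% MTN of an observer with
    near-negligible internal noise is measured by Monte Carlo, and
    log n_samp is fit as a quadratic in MTN (the functional form of the
    printed mapping).  Returns the fitted coefficients, goodness of fit and
    the simulated grid, so agreement with the printed coefficients can be
    assessed per MTN region.
    """
    levels = np.asarray(config.sd_levels, dtype=float)
    mtns = np.empty(len(config.n_samp_grid))
    for i, n in enumerate(config.n_samp_grid):
        params = ObserverParams(sigma_int=config.sigma_int, n_samp=float(n), lapse=0.0)
        mtns[i] = _mc_mtn(params, levels, config.trials_per_level, rng)
    ln_n = np.log(np.asarray(config.n_samp_grid, dtype=float))
    coeffs = np.polyfit(mtns, ln_n, 2)  # highest power first
    fit = np.polyval(coeffs, mtns)
    ss_res = float(np.sum((ln_n - fit) ** 2))
    ss_tot = float(np.sum((ln_n - ln_n.mean()) ** 2))
    return MtnMapping(
        coeffs=(float(coeffs[0]), float(coeffs[1]), float(coeffs[2])),
        r_squared=1.0 - ss_res / ss_tot,
        mtn_grid=mtns,
        n_samp_grid=np.asarray(config.n_samp_grid, dtype=float),
        config=config,
    )


# ---------------------------------------------------------------------------
# Lapse correction
# ---------------------------------------------------------------------------

TASK_TYPES = ("no_noise", "high_noise", "coherence")

#: default observed-lapse grid (catch-trial error rates)
DEFAULT_LAPSE_GRID = (0.0, 0.005, 0.01, 0.02, 0.03, 0.045, 0.06, 0.08, 0.10, 0.125, 0.15)


@dataclass
class LapseCorrectionTable:
    """Threshold-inflation factors per task over an observed-lapse grid.

    ``factors[task][i]`` is the median ratio of the staircase threshold of
    a lapsing observer (true lapse = 2 * observed rate) to that of the same
    observer without lapses.  Factors are isotonically smoothed: they rise
    with lapse for the no-noise and coherence staircases (lapses inflate
    those thresholds) and fall for the high-noise staircase (lapses shrink
    the tolerable noise).  At observed lapse 0 the factor is exactly 1.
    """

    observed_lapse_grid: np.ndarray
    factors: Dict[str, np.ndarray]
    base_params: ObserverParams
    n_replicates: int

    def factor(self, task: str, observed_lapse: float) -> float:
        if task not in self.factors:
            raise KeyError(f"unknown task type {task!r}")
        grid = self.observed_lapse_grid
        if observed_lapse < grid[0] or observed_lapse > grid[-1]:
            warnings.warn(
                f"observed lapse {observed_lapse:.3f} outside table range "
                f"[{grid[0]:.3f}, {grid[-1]:.3f}]; clamped",
                stacklevel=2,
            )
            observed_lapse = min(max(observed_lapse, grid[0]), grid[-1])
        return float(np.interp(observed_lapse, grid, self.factors[task]))

    def to_json(self) -> str:
        return json.dumps(
            dict(
                observed_lapse_grid=self.observed_lapse_grid.tolist(),
                factors={k: v.tolist() for k, v in self.factors.items()},
                base_params=dict(
                    sigma_int=self.base_params.sigma_int,
                    n_samp=self.base_params.n_samp,
                    lapse=self.base_params.lapse,
                ),
                n_replicates=self.n_replicates,
            ),
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, s: str) -> "LapseCorrectionTable":
        d = json.loads(s)
        return cls(
            observed_lapse_grid=np.asarray(d["observed_lapse_grid"], dtype=float),
            factors={k: np.asarray(v, dtype=float) for k, v in d["factors"].items()},
            base_params=ObserverParams(**d["base_params"]),
            n_replicates=int(d["n_replicates"]),
        )


def _single_staircase_threshold(sc_id: str, params: ObserverParams, rng: np.random.Generator, n_trials: int = 75) -> float:
    plan = EN_PLAN if sc_id in ("no_noise", "high_noise") else COHERENCE_PLAN
    q = QuestState(**STAIRCASE_DEFAULTS[sc_id])
    for _ in range(n_trials):
        x = q.next_intensity_log10()
        intensity = 10.0**x
        side = 1 if rng.uniform() < 0.5 else -1
        choice = _staircase_trial(sc_id, intensity, params, side, plan, rng)
        q.update(x, (choice == "right") == (side > 0))
    return q.threshold()


def lapse_correction_build(
    task_types: Sequence[str] = TASK_TYPES,
    lapse_grid: Sequence[float] = DEFAULT_LAPSE_GRID,
    base_params: Optional[ObserverParams] = None,
    rng: Optional[np.random.Generator] = None,
    *,
    n_replicates: int = 60,
) -> LapseCorrectionTable:
    """Build the lapse-correction table by paired staircase simulation.

    For each observed-lapse grid point g the observer is simulated with
    true lapse 2*g and, from the same random stream, with lapse 0
    (``n_replicates`` staircase pairs); the factor is the median of the
    paired threshold ratios, so common staircase noise cancels.  Factors
    are isotonically smoothed in the task-appropriate direction and pinned
    to 1 at g = 0.
    """
    grid = np.asarray(sorted(set(float(g) for g in lapse_grid)), dtype=float)
    if grid[0] != 0.0:
        grid = np.concatenate([[0.0], grid])
    if grid[-1] < 0.15:
        warnings.warn("lapse grid does not cover [0, 0.15]")
    if np.any(grid * 2 > 1.0):
        raise ValueError("observed lapse grid implies true lapse > 1")
    if base_params is None:
        base_params = ObserverParams(sigma_int=6.0, n_samp=1.0, lapse=0.0)
    rng = np.random.default_rng(0) if rng is None else rng
    pair_seeds = rng.integers(0, 2**31, size=n_replicates)

    factors: Dict[str, np.ndarray] = {}
    for task in task_types:
        if task not in TASK_TYPES:
            raise ValueError(f"unknown task type {task!r}")
        base = ObserverParams(base_params.sigma_int, base_params.n_samp, 0.0)
        thr0 = np.array(
            [
                _single_staircase_threshold(task, base, np.random.default_rng(s))
                for s in pair_seeds
            ]
        )
        raw = np.empty(grid.size)
        raw[0] = 1.0
        for i, g in enumerate(grid[1:], start=1):
            lap = ObserverParams(base_params.sigma_int, base_params.n_samp, min(2.0 * g, 1.0))
            thr = np.array(
                [
                    _single_staircase_threshold(task, lap, np.random.default_rng(s))
                    for s in pair_seeds
                ]
            )
            raw[i] = float(np.median(thr / thr0))
        increasing = task != "high_noise"
        iso = IsotonicRegression(increasing=increasing, out_of_bounds="clip")
        smooth = iso.fit_transform(grid, raw)
        # pin the identity at zero lapse exactly
        smooth = np.maximum(smooth, 1.0) if increasing else np.minimum(smooth, 1.0)
        smooth[0] = 1.0
        factors[task] = smooth
    return LapseCorrectionTable(
        observed_lapse_grid=grid,
        factors=factors,
        base_params=base_params,
        n_replicates=n_replicates,
    )


def lapse_correct(threshold: float, observed_lapse: float, table: LapseCorrectionTable, task: str) -> float:
    """Undo the lapse-induced threshold distortion (divide by the factor)."""
    return threshold / table.factor(task, observed_lapse)
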