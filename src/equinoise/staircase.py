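"""QUEST Bayesian adaptive staircase and task sequencing.

The staircase maintains a discretised posterior over log10 threshold.  The
psychometric likelihood is a Weibull in log10 intensity (slope ``beta``,
guess rate ``gamma`` = 0.5 for the two-alternative tasks, lapse allowance
``delta``), horizontally shifted so that the tracked threshold is exactly
the 84%-correct point of the assumed function.  Trials are placed at the
posterior mean (the QUEST+ convention), which is more stable than the mode
at 75 trials.

Task sequencing implements the study design: the equivalent-noise task
interleaves a 75-trial "no noise" staircase (varying the mean direction
offset at direction SD 0) with a 75-trial "high noise" staircase (varying
the direction SD at a +/-45 deg signal), plus 15 randomly positioned catch
trials (165 trials); the motion-coherence task runs one 75-trial staircase
on coherence plus 15 catch trials (90 trials).  Catch trials replicate the
criterion-phase stimuli (45 deg offset at SD 0, or 100% coherence).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .observer import ObserverParams, coherence_decision, en_decision
from .stimulus import make_coherence_directions

__all__ = [
    "QuestState",
    "TaskPlan",
    "TaskResult",
    "quest_update",
    "quest_next",
    "run_task",
    "run_en_task",
    "run_coherence_task",
    "STAIRCASE_DEFAULTS",
    "EN_PLAN",
    "COHERENCE_PLAN",
]


class QuestState:
    """Posterior over log10 threshold with Weibull psychometric likelihood.

    Parameters
    ----------
    start : float
        Initial intensity guess (natural units); centre of the Gaussian
        prior on log10 intensity.
    lo, hi : float
        Intensity lattice range (natural units).
    beta : float
        Weibull slope on log10 intensity.
    gamma : float
        Guess rate (0.5 for two-alternative tasks).
    delta : float
        Lapse allowance built into the assumed psychometric function.
    grain : float
        Lattice spacing in log10 units.
    prior_sd : float
        SD of the Gaussian prior in log10 units.
    target : float
        Proportion correct tracked by the staircase (threshold criterion).
    increasing : bool
        True when performance improves with intensity (offset, coherence);
        False when it falls (direction SD in the high-noise staircase), in
        which case the psychometric function is mirrored.
    """

    def __init__(
        self,
        start: float,
        lo: float,
        hi: float,
        *,
        beta: float = 3.5,
        gamma: float = 0.5,
        delta: float = 0.01,
        grain: float = 0.01,
        prior_sd: float = 1.5,
        target: float = 0.84,
        increasing: bool = True,
    ):
        if not (0 < lo < hi):
            raise ValueError("need 0 < lo < hi")
        if not (lo <= start <= hi):
            raise ValueError("start must lie within [lo, hi]")
        self.beta = float(beta)
        self.gamma = float(gamma)
        self.delta = float(delta)
        self.target = float(target)
        self.increasing = bool(increasing)
        self.lattice = np.arange(math.log10(lo), math.log10(hi) + grain / 2, grain)
        prior = np.exp(-0.5 * ((self.lattice - math.log10(start)) / prior_sd) ** 2)
        self.posterior = prior / prior.sum()
        # shift constant k: assumed psychometric passes through `target`
        # exactly at zero threshold offset
        inner = (1.0 - (self.target - self.delta * self.gamma) / (1.0 - self.delta)) / (1.0 - self.gamma)
        if not 0.0 < inner < 1.0:
            raise ValueError("target incompatible with gamma/delta")
        self._k = -math.log(inner)
        self.history: List[Tuple[float, bool]] = []

    def copy(self) -> "QuestState":
        new = object.__new__(QuestState)
        new.__dict__.update(self.__dict__)
        new.posterior = self.posterior.copy()
        new.history = list(self.history)
        return new

    # -- likelihood ----------------------------------------------------
    def p_correct(self, intensity_log10: float, threshold_log10=None) -> np.ndarray:
        """Assumed P(correct) at an intensity for each candidate threshold."""
        t = self.lattice if threshold_log10 is None else np.asarray(threshold_log10, dtype=float)
        u = intensity_log10 - t
        if not self.increasing:
            u = -u
        return self.delta * self.gamma + (1.0 - self.delta) * (
            1.0 - (1.0 - self.gamma) * np.exp(-self._k * 10.0 ** (self.beta * u))
        )

    # -- updating ------------------------------------------------------
    def update(self, intensity_log10: float, correct: bool) -> None:
        lo, hi = self.lattice[0], self.lattice[-1]
        if intensity_log10 < lo or intensity_log10 > hi:
            warnings.warn(
                f"intensity {intensity_log10:.3f} outside lattice [{lo:.3f}, {hi:.3f}]; clamped",
                stacklevel=2,
            )
            intensity_log10 = min(max(intensity_log10, lo), hi)
        p = self.p_correct(intensity_log10)
        like = p if correct else 1.0 - p
        self.posterior = self.posterior * like
        self.posterior /= self.posterior.sum()
        self.history.append((intensity_log10, bool(correct)))

    # -- summaries -----------------------------------------------------
    def mean_log10(self) -> float:
        return float(np.dot(self.posterior, self.lattice))

    def next_intensity_log10(self) -> float:
        """Placement rule: posterior mean of log10 threshold."""
        return self.mean_log10()

    def threshold(self) -> float:
        """Current 84%-criterion threshold estimate in natural units."""
        return 10.0 ** self.mean_log10()

    def interval(self, level: float = 0.95) -> Tuple[float, float]:
        """Central posterior credible interval on log10 threshold."""
        cdf = np.cumsum(self.posterior)
        lo = float(np.interp((1 - level) / 2, cdf, self.lattice))
        hi = float(np.interp((1 + level) / 2, cdf, self.lattice))
        return lo, hi


def quest_update(state: QuestState, intensity_log10: float, correct: bool) -> QuestState:
    """Functional update: returns a new state, leaving the input untouched."""
    new = state.copy()
    new.update(intensity_log10, correct)
    return new


def quest_next(state: QuestState) -> float:
    """Next trial placement (log10 units): the posterior mean."""
    return state.next_intensity_log10()


# staircase lattice ranges, start values (natural units) and assumed
# psychometric slopes; the source design does not state these, so they are
# package defaults recorded in the per-run config.  The betas are matched
# to the generative observer family's true psychometric slopes in log10
# intensity (probit-in-linear-offset gives ~0.53 per decade at the 84%
# point for the direction staircases, steeper for coherence): a grossly
# steeper assumed slope makes the posterior overconfident and its credible
# intervals badly undercover.
STAIRCASE_DEFAULTS = {
    "no_noise": dict(start=20.0, lo=0.1, hi=90.0, increasing=True, beta=1.3),
    "high_noise": dict(start=20.0, lo=1.0, hi=150.0, increasing=False, beta=1.3),
    "coherence": dict(start=0.5, lo=0.01, hi=1.0, increasing=True, beta=1.9),
}

#: fixed signal offset (deg) of the high-noise staircase and of EN catch trials
HIGH_NOISE_SIGNAL = 45.0
#: coherence-task signal direction (deg from vertical): +/-90
COHERENCE_SIGNAL = 90.0


@dataclass(frozen=True)
class TaskPlan:
    task: str  # "equivalent_noise" | "coherence"
    staircase_trials: int = 75
    catch_trials: int = 15
    interleaving: Tuple[str, ...] = ()
    target_performance: float = 0.84
    n_dots: int = 100

    def __post_init__(self):
        if self.task not in ("equivalent_noise", "coherence"):
            raise ValueError("task must be 'equivalent_noise' or 'coherence'")
        want = ("no_noise", "high_noise") if self.task == "equivalent_noise" else ("coherence",)
        inter = self.interleaving or want
        object.__setattr__(self, "interleaving", tuple(inter))
        if set(self.interleaving) != set(want):
            raise ValueError(f"interleaving for {self.task} must be {want}")
        if self.staircase_trials < 1 or self.catch_trials < 0:
            raise ValueError("invalid trial counts")

    @property
    def total_trials(self) -> int:
        return self.staircase_trials * len(self.interleaving) + self.catch_trials


EN_PLAN = TaskPlan(task="equivalent_noise")
COHERENCE_PLAN = TaskPlan(task="coherence")


@dataclass
class TaskResult:
    plan: TaskPlan
    trials: List[dict]
    thresholds: Dict[str, float]
    quests: Dict[str, QuestState]
    catch_incorrect: int
    catch_total: int

    @property
    def catch_error_rate(self) -> float:
        return self.catch_incorrect / self.catch_total if self.catch_total else 0.0


def _catch_trial(plan: TaskPlan, params: ObserverParams, side: int, rng) -> Tuple[float, str]:
    if plan.task == "equivalent_noise":
        resp = en_decision(params, side * HIGH_NOISE_SIGNAL, 0.0, rng)
        return HIGH_NOISE_SIGNAL, resp.choice
    fld = make_coherence_directions(1.0, side * COHERENCE_SIGNAL, plan.n_dots, rng)
    return 1.0, coherence_decision(params, fld, rng).choice


def _staircase_trial(sc_id: str, intensity: float, params: ObserverParams, side: int, plan: TaskPlan, rng) -> str:
    if sc_id == "no_noise":
        return en_decision(params, side * intensity, 0.0, rng).choice
    if sc_id == "high_noise":
        return en_decision(params, side * HIGH_NOISE_SIGNAL, intensity, rng).choice
    fld = make_coherence_directions(intensity, side * COHERENCE_SIGNAL, plan.n_dots, rng)
    return coherence_decision(params, fld, rng).choice


def run_task(
    plan: TaskPlan,
    params: ObserverParams,
    speed: float,
    rng: np.random.Generator,
    *,
    participant_id: str = "obs",
    quest_kwargs: Optional[dict] = None,
) -> TaskResult:
    """Run one task (EN pair or coherence) for one simulated observer.

    Staircase order is a random interleaving of the component staircases;
    catch-trial positions are drawn uniformly without replacement; the
    signal side is randomised on every trial.  Returns the trial log,
    the 84% threshold per staircase and the catch-trial tally.
    """
    quest_kwargs = quest_kwargs or {}
    quests = {
        sc: QuestState(target=plan.target_performance, **{**STAIRCASE_DEFAULTS[sc], **quest_kwargs})
        for sc in plan.interleaving
    }
    total = plan.total_trials
    catch_idx = set(rng.choice(total, size=plan.catch_trials, replace=False).tolist())
    order = np.repeat(list(plan.interleaving), plan.staircase_trials)
    rng.shuffle(order)
    order_iter = iter(order)

    trials: List[dict] = []
    catch_incorrect = 0
    for t in range(total):
        side = 1 if rng.uniform() < 0.5 else -1
        is_catch = t in catch_idx
        if is_catch:
            sc_id = "catch"
            intensity, choice = _catch_trial(plan, params, side, rng)
        else:
            sc_id = next(order_iter)
            q = quests[sc_id]
            x = quest_next(q)
            intensity = 10.0**x
            choice = _staircase_trial(sc_id, intensity, params, side, plan, rng)
        correct = (choice == "right") == (side > 0)
        if is_catch and not correct:
            catch_incorrect += 1
        if not is_catch:
            quests[sc_id].update(math.log10(intensity), correct)
        trials.append(
            dict(
                participant_id=participant_id,
                task=plan.task,
                speed=speed,
                trial_index=t,
                staircase_id=sc_id,
                is_catch=is_catch,
                intensity=intensity,
                signal_side="right" if side > 0 else "left",
                choice=choice,
                correct=correct,
            )
        )
    thresholds = {sc: q.threshold() for sc, q in quests.items()}
    return TaskResult(plan, trials, thresholds, quests, catch_incorrect, plan.catch_trials)


def run_en_task(params: ObserverParams, speed: float, rng: np.random.Generator, **kw) -> TaskResult:
    """The 165-trial equivalent-noise task (no-noise + high-noise + catch)."""
    return run_task(EN_PLAN, params, speed, rng, **kw)


def run_coherence_task(params: ObserverParams, speed: float, rng: np.random.Generator, **kw) -> TaskResult:
    """The 90-trial motion-coherence task (single staircase + catch)."""
    return run_task(COHERENCE_PLAN, params, speed, rng, **kw)
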