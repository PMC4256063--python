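"""Synthetic developmental cohort generation and full-experiment simulation.

The generator emulates the structure of a developmental equivalent-noise /
motion-coherence study: five age groups (around 5, 7, 9 and 11 years plus
adults), two stimulus speeds (1.5 and 6 deg/s), and per participant one
165-trial equivalent-noise task and one 90-trial motion-coherence task per
speed.  Observer parameters follow log-log-linear developmental
trajectories between an age-5 anchor and an adult anchor:

* internal noise falls with age, with a steeper slope at the fast speed;
* effective sampling rises with age, with equal slopes across speed;
* lapse rate falls with age, slightly higher at the slow speed.

Default anchors are the study's group means (internal noise 9.62/9.69 deg
at age 5 falling to 6.72/4.80 deg in adults for slow/fast; sampling
0.51 -> 1.47 slow and 0.98 -> 1.85 fast; lapse ~.04 -> ~.005).  A
participant's between-subject deviation is drawn once per parameter and
shared across speed conditions (individual traits persist across
condition), on the log10 scale.

Optional 40 Hz fixation traces with per-eye validity codes are generated
with an age-dependent positional spread, emulating the poorer fixation
stability of younger children.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .observer import ObserverParams
from .staircase import TaskResult, run_coherence_task, run_en_task

__all__ = [
    "CohortConfig",
    "Participant",
    "CohortDataset",
    "generate_cohort",
    "run_experiment",
    "generate_fixation",
    "simulate",
    "ADULT_AGE",
]

ADULT_AGE = 26.75  # years; adult group mean age used on the log-age axis

_DEFAULT_GROUPS = (
    ("5y", 5.33, 21),
    ("7y", 7.25, 27),
    ("9y", 9.17, 25),
    ("11y", 11.25, 20),
    ("adult", ADULT_AGE, 30),
)

_DEFAULT_FIXATION_COUNTS = {"5y": 12, "7y": 17, "9y": 11, "11y": 9, "adult": 10}


@dataclass(frozen=True)
class CohortConfig:
    """Generative description of a synthetic cohort.

    Anchors are (age-5 value, adult value) pairs per speed; trajectories
    interpolate linearly in log10 parameter vs log10 age.
    """

    age_groups: Tuple[Tuple[str, float, int], ...] = _DEFAULT_GROUPS
    speeds: Tuple[float, ...] = (1.5, 6.0)
    sigma_int_anchors: Tuple[Tuple[float, float], ...] = ((9.62, 6.72), (9.69, 4.80))
    n_samp_anchors: Tuple[Tuple[float, float], ...] = ((0.51, 1.47), (0.98, 1.85))
    lapse_anchors: Tuple[Tuple[float, float], ...] = ((0.05, 0.006), (0.03, 0.004))
    between_sd_log10: Tuple[Tuple[str, float], ...] = (
        ("sigma_int", 0.12),
        ("n_samp", 0.12),
        ("lapse", 0.2),
    )
    anchor_ages: Tuple[float, float] = (5.0, ADULT_AGE)
    fixation_counts: Tuple[Tuple[str, int], ...] = tuple(_DEFAULT_FIXATION_COUNTS.items())
    fixation_sd_anchors: Tuple[float, float] = (0.120, 0.054)  # normalised screen units
    fixation_eye_jitter: float = 0.005
    validity_probs: Tuple[float, float, float] = (0.90, 0.05, 0.05)  # code 0 / 1 / 2-4
    include_fixation: bool = False
    seed: int = 0

    def __post_init__(self):
        if len(self.speeds) != len(self.sigma_int_anchors):
            raise ValueError("one sigma_int anchor pair per speed required")
        for anchors in (self.sigma_int_anchors, self.n_samp_anchors, self.lapse_anchors):
            if any(a <= 0 or b <= 0 for a, b in anchors):
                raise ValueError("anchors must be positive")
        if any(n < 1 for _, _, n in self.age_groups):
            raise ValueError("each age group needs n >= 1")

    @property
    def n_participants(self) -> int:
        return sum(n for _, _, n in self.age_groups)

    def between_sd(self, name: str) -> float:
        return dict(self.between_sd_log10)[name]

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return json.dumps(d, sort_keys=True, default=list)

    @classmethod
    def from_json(cls, s: str) -> "CohortConfig":
        d = json.loads(s)
        tup = lambda v: tuple(tuple(x) if isinstance(x, list) else x for x in v)
        for k in (
            "age_groups",
            "speeds",
            "sigma_int_anchors",
            "n_samp_anchors",
            "lapse_anchors",
            "between_sd_log10",
            "anchor_ages",
            "fixation_counts",
            "fixation_sd_anchors",
            "validity_probs",
        ):
            d[k] = tup(d[k])
        return cls(**d)


@dataclass
class Participant:
    participant_id: str
    age_group: str
    age_years: float
    params: Dict[float, ObserverParams]  # per speed


def _loglog_interp(age: float, anchor_ages: Tuple[float, float], anchor_vals: Tuple[float, float]) -> float:
    """Value at `age` on the log10-log10 line through the two anchors."""
    la0, la1 = (math.log10(a) for a in anchor_ages)
    lv0, lv1 = (math.log10(v) for v in anchor_vals)
    slope = (lv1 - lv0) / (la1 - la0)
    return 10.0 ** (lv0 + slope * (math.log10(age) - la0))


def generate_cohort(config: CohortConfig, rng: np.random.Generator) -> List[Participant]:
    """Draw a cohort of simulated participants from the generative model."""
    out: List[Participant] = []
    i = 0
    for label, age, n in config.age_groups:
        for _ in range(n):
            i += 1
            dev = {name: rng.normal(0.0, 1.0) for name, _ in config.between_sd_log10}
            params: Dict[float, ObserverParams] = {}
            for k, speed in enumerate(config.speeds):
                sig = _loglog_interp(age, config.anchor_ages, config.sigma_int_anchors[k])
                nsamp = _loglog_interp(age, config.anchor_ages, config.n_samp_anchors[k])
                lapse = _loglog_interp(age, config.anchor_ages, config.lapse_anchors[k])
                sig *= 10.0 ** (dev["sigma_int"] * config.between_sd("sigma_int"))
                nsamp *= 10.0 ** (dev["n_samp"] * config.between_sd("n_samp"))
                lapse = min(lapse * 10.0 ** (dev["lapse"] * config.between_sd("lapse")), 0.3)
                params[speed] = ObserverParams(sigma_int=sig, n_samp=nsamp, lapse=lapse)
            out.append(Participant(f"p{i:03d}", label, age, params))
    return out


@dataclass
class CohortDataset:
    """Trial-level records plus per-participant raw threshold estimates."""

    config: CohortConfig
    trials: pd.DataFrame
    estimates: pd.DataFrame
    fixation: Optional[pd.DataFrame] = None

    def write(self, outdir) -> None:
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        kw = dict(index=False, float_format="%.10g")
        self.trials.to_csv(outdir / "trials.csv", **kw)
        self.estimates.to_csv(outdir / "estimates.csv", **kw)
        if self.fixation is not None:
            self.fixation.to_csv(outdir / "fixation.csv", **kw)
        (outdir / "config.json").write_text(self.config.to_json() + "\n")


def _task_rows(res: TaskResult, participant: Participant) -> List[dict]:
    rows = []
    for tr in res.trials:
        row = dict(tr)
        row["participant_id"] = participant.participant_id
        row["age_group"] = participant.age_group
        row["age_years"] = participant.age_years
        rows.append(row)
    return rows


def run_experiment(
    cohort: List[Participant],
    rng: np.random.Generator,
    config: Optional[CohortConfig] = None,
) -> CohortDataset:
    """Run the full design (EN + coherence at each speed) for every participant."""
    if not cohort:
        raise ValueError("cohort must be non-empty")
    config = config or CohortConfig()
    fixation_counts = dict(config.fixation_counts)
    seen_per_group: Dict[str, int] = {}
    trial_rows: List[dict] = []
    est_rows: List[dict] = []
    fix_frames: List[pd.DataFrame] = []
    for part in cohort:
        idx = seen_per_group.get(part.age_group, 0)
        seen_per_group[part.age_group] = idx + 1
        track_fixation = config.include_fixation and idx < fixation_counts.get(part.age_group, 0)
        for speed in config.speeds:
            params = part.params[speed]
            en = run_en_task(params, speed, rng, participant_id=part.participant_id)
            mc = run_coherence_task(params, speed, rng, participant_id=part.participant_id)
            trial_rows.extend(_task_rows(en, part))
            trial_rows.extend(_task_rows(mc, part))
            est_rows.append(
                dict(
                    participant_id=part.participant_id,
                    age_group=part.age_group,
                    age_years=part.age_years,
                    speed=speed,
                    no_noise_threshold=en.thresholds["no_noise"],
                    mtn=en.thresholds["high_noise"],
                    coherence_threshold=mc.thresholds["coherence"],
                    catch_incorrect_en=en.catch_incorrect,
                    catch_incorrect_mc=mc.catch_incorrect,
                    lapse_en=en.catch_error_rate,
                    lapse_mc=mc.catch_error_rate,
                    true_sigma_int=params.sigma_int,
                    true_n_samp=params.n_samp,
                    true_lapse=params.lapse,
                )
            )
            if track_fixation:
                for task_name, n_trials in (("equivalent_noise", en.plan.total_trials), ("coherence", mc.plan.total_trials)):
                    fx = generate_fixation(part.age_years, n_trials, rng, config=config)
                    fx.insert(0, "participant_id", part.participant_id)
                    fx.insert(1, "task", task_name)
                    fx.insert(2, "speed", speed)
                    fix_frames.append(fx)
    trials = pd.DataFrame(trial_rows)
    estimates = pd.DataFrame(est_rows)
    fixation = pd.concat(fix_frames, ignore_index=True) if fix_frames else None
    return CohortDataset(config=config, trials=trials, estimates=estimates, fixation=fixation)


def generate_fixation(
    age: float,
    n_trials: int,
    rng: np.random.Generator,
    *,
    config: Optional[CohortConfig] = None,
    samples_per_trial: int = 16,  # 400 ms at 40 Hz
) -> pd.DataFrame:
    """Synthetic 40 Hz gaze traces during each stimulus interval.

    Gaze positions are Gaussian around screen-centre fixation with an
    age-dependent SD (normalised screen units); left/right eye coordinates
    share the gaze sample (hence are correlated) plus small independent
    per-eye jitter.  A small proportion of samples carry validity codes
    >= 2 and unrelated (uniform) coordinates, emulating tracker dropouts.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    config = config or CohortConfig()
    if min(config.fixation_sd_anchors) <= 0:
        sd = 0.0  # degenerate perfectly-stable fixation
    else:
        sd = _loglog_interp(age, config.anchor_ages, config.fixation_sd_anchors)
    n = n_trials * samples_per_trial
    gaze = rng.normal(0.5, sd, size=(n, 2))
    jit = config.fixation_eye_jitter
    eye_l = gaze + rng.normal(0.0, jit, size=(n, 2))
    eye_r = gaze + rng.normal(0.0, jit, size=(n, 2))
    p0, p1, p234 = config.validity_probs
    val = np.empty((n, 2), dtype=int)
    for j in range(2):
        u = rng.uniform(size=n)
        val[:, j] = np.where(u < p0, 0, np.where(u < p0 + p1, 1, rng.integers(2, 5, size=n)))
    # invalid samples report junk coordinates
    for eye, col in ((eye_l, 0), (eye_r, 1)):
        bad = val[:, col] >= 2
        eye[bad] = rng.uniform(0.0, 1.0, size=(int(bad.sum()), 2))
    trial = np.repeat(np.arange(n_trials), samples_per_trial)
    t_ms = np.tile(np.arange(samples_per_trial) * 25.0, n_trials)
    return pd.DataFrame(
        dict(
            trial=trial,
            t_ms=t_ms,
            x_l=eye_l[:, 0],
            y_l=eye_l[:, 1],
            x_r=eye_r[:, 0],
            y_r=eye_r[:, 1],
            val_l=val[:, 0],
            val_r=val[:, 1],
        )
    )


def simulate(config: Optional[CohortConfig] = None, outdir=None) -> CohortDataset:
    """Generate a cohort from ``config.seed`` and run the full experiment.

    Fully reproducible: the same config (including seed) yields
    byte-identical CSV output.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    cohort = generate_cohort(config, rng)
    ds = run_experiment(cohort, rng, config)
    if outdir is not None:
        ds.write(outdir)
    return ds
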