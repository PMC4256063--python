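"""Parameter-recovery and self-consistency suites.

These routines exercise the whole pipeline against known ground truth and
are what the package's claims rest on:

* :func:`eq1_threshold_equivalence` -- the generative observer's simulated
  84% thresholds equal the equivalent-noise prediction
  ``sqrt((sigma_int**2 + sigma_ext**2)/n_samp)``;
* :func:`mapping_agreement` -- the Monte-Carlo re-derivation of the
  MTN -> n_samp mapping compared, per MTN, against the printed
  coefficients;
* :func:`recovery_grid` -- end-to-end recovery of (sigma_int, n_samp) by
  the rapid two-point pipeline (QUEST staircases, lapse correction, the
  two-point decomposition) over a grid of ground-truth observers;
* :func:`cohort_structure_rates` -- how often, across seeded synthetic
  cohorts, the group analysis reproduces the structural findings that are
  true by construction (sampling, not internal noise, drives coherence
  thresholds; the internal-noise trajectory is steeper at the fast speed);
* :func:`determinism_check` -- byte-identical simulate + analyze reruns.

All randomness flows from an integer seed through ``numpy`` seed
sequences, so every summary is reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .analysis import analyze
from .cohort import CohortConfig, simulate
from .equivalent_noise import (
    LapseCorrectionTable,
    MtnMapping,
    MtnSimulationConfig,
    en_curve,
    estimates_from_thresholds,
    lapse_correct,
    lapse_correction_build,
    nsamp_from_mtn,
    rederive_mtn_mapping,
)
from .observer import ObserverParams, en_decision_batch
from .staircase import run_en_task

__all__ = [
    "eq1_threshold_equivalence",
    "mapping_agreement",
    "RecoverySummary",
    "recovery_grid",
    "cohort_structure_rates",
    "determinism_check",
]


def eq1_threshold_equivalence(
    seed: int,
    sigma_grid: Sequence[float] = (4.0, 6.0, 8.0),
    nsamp_grid: Sequence[float] = (0.5, 1.0, 2.0),
    ext_grid: Sequence[float] = (0.0, 8.0, 16.0),
    n_trials: int = 20000,
) -> pd.DataFrame:
    """Simulated 84% thresholds vs the closed-form prediction, per grid cell.

    The direction-offset threshold is measured by probing the observer at
    the predicted threshold and probit-inverting the observed proportion
    correct (threshold = offset / z(p)); ``rel_err`` is the relative
    deviation of the measured threshold from the closed form.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    z84 = stats.norm.ppf(0.84)
    rows = []
    for s in sigma_grid:
        for n in nsamp_grid:
            for x in ext_grid:
                pred = en_curve(s, n, x)
                probe = z84 * pred  # offset whose predicted P(correct) is 84%
                right, _ = en_decision_batch(
                    ObserverParams(s, n, 0.0), np.full(n_trials, probe), x, rng
                )
                p = float(np.mean(right))
                meas = probe / stats.norm.ppf(p) * z84
                rows.append(
                    dict(
                        sigma_int=s,
                        n_samp=n,
                        external_sd=x,
                        predicted=pred,
                        measured=meas,
                        p_at_predicted=p,
                        rel_err=meas / pred - 1.0,
                    )
                )
    return pd.DataFrame(rows)


def mapping_agreement(
    seed: int,
    config: Optional[MtnSimulationConfig] = None,
    eval_mtn: Sequence[float] = tuple(range(15, 61, 5)),
) -> Tuple[MtnMapping, pd.DataFrame]:
    """Re-derive the MTN -> n_samp mapping and compare with the printed one."""
    config = config or MtnSimulationConfig()
    mapping = rederive_mtn_mapping(config, np.random.default_rng(np.random.SeedSequence(seed)))
    mtns = np.asarray(eval_mtn, dtype=float)
    fitted = mapping.predict(mtns)
    printed = nsamp_from_mtn(mtns)
    table = pd.DataFrame(
        dict(mtn=mtns, fitted=fitted, printed=printed, ratio=fitted / printed)
    )
    return mapping, table


@dataclass
class RecoverySummary:
    runs: pd.DataFrame  # one row per simulated observer run
    cells: pd.DataFrame  # per-cell median recoveries
    median_bias_log10_sigma_int: float
    median_bias_log10_n_samp: float
    spearman_sigma_int: float
    spearman_n_samp: float


def recovery_grid(
    seed: int,
    sigma_grid: Sequence[float] = (4.0, 6.0, 8.0, 10.0),
    nsamp_grid: Sequence[float] = (0.5, 1.0, 2.0),
    lapse_grid: Sequence[float] = (0.0, 0.02, 0.04),
    n_replicates: int = 20,
    speed: float = 1.5,
    lapse_table: Optional[LapseCorrectionTable] = None,
) -> RecoverySummary:
    """End-to-end recovery of (sigma_int, n_samp) by the rapid pipeline.

    Each grid cell defines a ground-truth observer; each replicate runs the
    full 165-trial equivalent-noise task, estimates the lapse rate from the
    catch trials, lapse-corrects both thresholds and applies the two-point
    decomposition.  Biases are medians of (log10 estimate - log10 truth)
    over all runs; rank correlations compare per-cell median estimates with
    the truth across the grid.
    """
    if lapse_table is None:
        lapse_table = lapse_correction_build(rng=np.random.default_rng(np.random.SeedSequence((seed, 1))))
    cells = [(s, n, l) for s in sigma_grid for n in nsamp_grid for l in lapse_grid]
    children = np.random.SeedSequence((seed, 2)).spawn(len(cells) * n_replicates)
    rows = []
    k = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rare out-of-grid lapse clamps
        for s, n, l in cells:
            params = ObserverParams(s, n, l)
            for rep in range(n_replicates):
                rng = np.random.default_rng(children[k])
                k += 1
                res = run_en_task(params, speed, rng)
                lam = res.catch_error_rate
                nn = lapse_correct(res.thresholds["no_noise"], lam, lapse_table, "no_noise")
                mtn = lapse_correct(res.thresholds["high_noise"], lam, lapse_table, "high_noise")
                est = estimates_from_thresholds(nn, mtn)
                rows.append(
                    dict(
                        sigma_int=s,
                        n_samp=n,
                        lapse=l,
                        rep=rep,
                        est_sigma_int=est.sigma_int,
                        est_n_samp=est.n_samp,
                        bias_log10_sigma_int=np.log10(est.sigma_int / s),
                        bias_log10_n_samp=np.log10(est.n_samp / n),
                    )
                )
    runs = pd.DataFrame(rows)
    cells_df = (
        runs.groupby(["sigma_int", "n_samp", "lapse"], as_index=False)[["est_sigma_int", "est_n_samp"]]
        .median()
    )
    rho_s = stats.spearmanr(np.log10(cells_df["sigma_int"]), np.log10(cells_df["est_sigma_int"])).statistic
    rho_n = stats.spearmanr(np.log10(cells_df["n_samp"]), np.log10(cells_df["est_n_samp"])).statistic
    return RecoverySummary(
        runs=runs,
        cells=cells_df,
        median_bias_log10_sigma_int=float(runs["bias_log10_sigma_int"].median()),
        median_bias_log10_n_samp=float(runs["bias_log10_n_samp"].median()),
        spearman_sigma_int=float(rho_s),
        spearman_n_samp=float(rho_n),
    )


def cohort_structure_rates(
    seed: int,
    n_seeds: int = 20,
    base_config: Optional[CohortConfig] = None,
    lapse_table: Optional[LapseCorrectionTable] = None,
) -> Dict[str, object]:
    """Structural-finding recovery rates across seeded default cohorts.

    For each cohort seed the full simulate + analyze pipeline runs; a seed
    counts as a *structure* success when the hierarchical regression enters
    log sampling and excludes log internal noise in both speed conditions,
    and as an *interaction* success when the internal-noise trajectory
    shows a significantly negative speed x log-age interaction (steeper
    development at the fast speed, as generated).
    """
    base_config = base_config or CohortConfig()
    if lapse_table is None:
        lapse_table = lapse_correction_build(rng=np.random.default_rng(np.random.SeedSequence((seed, 1))))
    per_seed = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_seeds):
            cfg_kwargs = {f: getattr(base_config, f) for f in base_config.__dataclass_fields__}
            cfg_kwargs["seed"] = int(np.random.SeedSequence((seed, 3, i)).generate_state(1)[0] % (2**31))
            ds = simulate(CohortConfig(**cfg_kwargs))
            rep = analyze(ds, lapse_table=lapse_table)
            structure = all(
                ("log_sampling" in r.entered) and ("log_internal_noise" not in r.entered)
                for r in rep.regressions.values()
            )
            traj = rep.trajectories["sigma_int"]
            interaction = (traj.interaction_p < 0.05) and (traj.interaction_slope < 0)
            scr = rep.screened.data
            n_outliers = int((~scr["included"] & scr["reason"].str.contains("outlier")).sum())
            per_seed.append(
                dict(
                    cohort_seed=cfg_kwargs["seed"],
                    structure=structure,
                    interaction=interaction,
                    interaction_p=traj.interaction_p,
                    interaction_slope=traj.interaction_slope,
                    noise_excluded_conditions=sum(
                        "log_internal_noise" not in r.entered for r in rep.regressions.values()
                    ),
                    sampling_entered_conditions=sum(
                        "log_sampling" in r.entered for r in rep.regressions.values()
                    ),
                    n_outliers=n_outliers,
                )
            )
    df = pd.DataFrame(per_seed)
    return dict(
        per_seed=df,
        structure_rate=float(df["structure"].mean()),
        interaction_rate=float(df["interaction"].mean()),
        sampling_entered_rate=float(df["sampling_entered_conditions"].sum() / (2 * n_seeds)),
        noise_excluded_rate=float(df["noise_excluded_conditions"].sum() / (2 * n_seeds)),
        total_outliers=int(df["n_outliers"].sum()),
        n_seeds=n_seeds,
        n_participants=base_config.n_participants,
    )


def determinism_check(seed: int, workdir) -> bool:
    """Byte-identical simulate + analyze outputs on rerun with a fixed seed."""
    import pathlib

    workdir = pathlib.Path(workdir)
    small = CohortConfig(
        age_groups=(("5y", 5.33, 3), ("9y", 9.17, 3), ("adult", 26.75, 3)),
        include_fixation=True,
        seed=int(seed),
    )
    table = lapse_correction_build(
        lapse_grid=(0.0, 0.05, 0.10, 0.15),
        rng=np.random.default_rng(np.random.SeedSequence((seed, 4))),
        n_replicates=10,
    )
    outputs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for run in ("a", "b"):
            d = workdir / run
            ds = simulate(small, outdir=d)
            analyze(ds, lapse_table=table, outdir=d)
            outputs.append(sorted(p for p in d.iterdir() if p.suffix in (".csv", ".json")))
    if [p.name for p in outputs[0]] != [p.name for p in outputs[1]]:
        return False
    return all(a.read_bytes() == b.read_bytes() for a, b in zip(*outputs))
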