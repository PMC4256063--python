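"""Group-level statistical pipeline.

Mirrors the analysis a developmental equivalent-noise study applies to its
threshold estimates:

1. catch-trial screening (exact one-sided binomial test against chance);
2. lapse-rate estimation from catch trials, averaged across tasks per
   speed, and multiplicative lapse correction of all thresholds;
3. equivalent-noise decomposition of the corrected thresholds;
4. log10 transform, skew/kurtosis assessment, and removal of values more
   than three z-scores from their age-group x speed mean;
5. developmental trajectory fits (log measure vs log age per speed) with a
   speed x log-age interaction test;
6. Pearson correlations between the equivalent-noise measures and motion
   coherence thresholds;
7. hierarchical regression on log coherence thresholds: log age entered
   first, then sampling and internal noise compete stepwise
   (p-to-enter .05, p-to-remove .10);
8. fixation stability: validity filtering, eye averaging, pooled SD of
   gaze positions, log10.

The within-participant speed factor is handled by difference-score
contrasts (each participant contributes both speeds), which is the
regression formulation of the repeated-measures analysis of covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import CohortDataset
from .equivalent_noise import (
    LapseCorrectionTable,
    estimates_from_thresholds,
    lapse_correct,
    lapse_correction_build,
)

__all__ = [
    "catch_screen",
    "apply_catch_screen",
    "correct_and_decompose",
    "ScreenedEstimates",
    "screen_and_transform",
    "TrajectoryFit",
    "fit_trajectory",
    "RegressionReport",
    "hierarchical_regression",
    "correlations",
    "fixation_stability",
    "AnalysisReport",
    "analyze",
]

MEASURES = ("sigma_int", "n_samp", "coherence_threshold")


# ---------------------------------------------------------------------------
# catch screening
# ---------------------------------------------------------------------------


def catch_screen(n_catch: int, chance: float = 0.5, alpha: float = 0.05) -> int:
    """Smallest incorrect count at which performance is not above chance.

    Returns the smallest k such that an exact one-sided binomial test of
    (n_catch - k) correct responses against ``chance`` fails to reject at
    ``alpha``; participants with k or more incorrect catch responses are
    excluded.  If even all-incorrect still rejects (tiny alpha cannot
    happen; degenerate alpha >= 1 can), returns ``n_catch + 1`` meaning no
    exclusion is possible.
    """
    if n_catch < 1:
        raise ValueError("n_catch must be >= 1")
    if not 0.0 < alpha:
        raise ValueError("alpha must be positive")
    for k in range(n_catch + 1):
        p = stats.binomtest(n_catch - k, n_catch, chance, alternative="greater").pvalue
        if p > alpha:
            return k
    return n_catch + 1


def apply_catch_screen(estimates: pd.DataFrame, n_catch: int = 15, chance: float = 0.5, alpha: float = 0.05) -> pd.Series:
    """Exclusion flag per participant: any task x speed failing the screen."""
    k = catch_screen(n_catch, chance, alpha)
    bad = (estimates["catch_incorrect_en"] >= k) | (estimates["catch_incorrect_mc"] >= k)
    bad_participants = set(estimates.loc[bad, "participant_id"])
    return estimates["participant_id"].isin(bad_participants)


# ---------------------------------------------------------------------------
# lapse correction + decomposition
# ---------------------------------------------------------------------------


def correct_and_decompose(estimates: pd.DataFrame, table: LapseCorrectionTable) -> pd.DataFrame:
    """Lapse-correct raw thresholds and apply the two-point decomposition.

    The lapse rate is the catch-trial error rate averaged across the two
    tasks within each speed condition.  Returns a copy of the estimates
    with corrected thresholds and the derived (n_samp, sigma_int).
    """
    df = estimates.copy()
    df["lapse"] = (df["lapse_en"] + df["lapse_mc"]) / 2.0
    nn, mtn, coh = [], [], []
    for _, row in df.iterrows():
        lam = row["lapse"]
        nn.append(lapse_correct(row["no_noise_threshold"], lam, table, "no_noise"))
        mtn.append(lapse_correct(row["mtn"], lam, table, "high_noise"))
        coh.append(lapse_correct(row["coherence_threshold"], lam, table, "coherence"))
    df["no_noise_threshold"] = nn
    df["mtn"] = mtn
    df["coherence_threshold"] = coh
    dec = [estimates_from_thresholds(t, m) for t, m in zip(df["no_noise_threshold"], df["mtn"])]
    df["n_samp"] = [d.n_samp for d in dec]
    df["sigma_int"] = [d.sigma_int for d in dec]
    return df


# ---------------------------------------------------------------------------
# transforms + screening
# ---------------------------------------------------------------------------


@dataclass
class ScreenedEstimates:
    """Log-transformed estimates with inclusion flags and screening report."""

    data: pd.DataFrame  # all rows, with log10 columns, `included`, `reason`
    skew_kurtosis: pd.DataFrame  # per measure x speed: skew, kurtosis, z, p

    @property
    def included(self) -> pd.DataFrame:
        return self.data[self.data["included"]].copy()


def screen_and_transform(estimates: pd.DataFrame, z_cut: float = 3.0, measures: Sequence[str] = MEASURES) -> ScreenedEstimates:
    """Log-transform the measures, report skew/kurtosis, drop 3-z outliers.

    Skewness and kurtosis significance is assessed per measure and speed by
    the standard-error z-tests; outliers are values more than ``z_cut``
    z-scores from their age-group x speed mean on the log scale.  Rows with
    non-positive raw values are excluded with a reason.
    """
    df = estimates.copy()
    df["included"] = True
    df["reason"] = ""
    for m in measures:
        nonpos = df[m] <= 0
        df.loc[nonpos, ["included", "reason"]] = [False, f"non-positive {m}"]
        df[f"log10_{m}"] = np.where(nonpos, np.nan, np.log10(df[m].where(~nonpos)))

    sk_rows = []
    for m in measures:
        for speed, grp in df[df["included"]].groupby("speed"):
            vals = grp[f"log10_{m}"].to_numpy()
            raw = grp[m].to_numpy()
            if raw.size >= 8:
                zs, ps = stats.skewtest(raw)
                zk, pk = stats.kurtosistest(raw)
            else:  # too few rows for the asymptotic tests
                zs = ps = zk = pk = np.nan
            sk_rows.append(
                dict(
                    measure=m,
                    speed=speed,
                    skew_raw=stats.skew(raw),
                    skew_z=zs,
                    skew_p=ps,
                    kurtosis_raw=stats.kurtosis(raw),
                    kurtosis_z=zk,
                    kurtosis_p=pk,
                    skew_log=stats.skew(vals),
                )
            )
    skrep = pd.DataFrame(sk_rows)

    for m in measures:
        col = f"log10_{m}"
        for (_, _), grp in df[df["included"]].groupby(["age_group", "speed"]):
            v = grp[col]
            sd = v.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                continue
            z = (v - v.mean()) / sd
            out_idx = z.index[z.abs() > z_cut]
            df.loc[out_idx, ["included", "reason"]] = [False, f"outlier {m} (|z|>{z_cut:g})"]
    return ScreenedEstimates(data=df, skew_kurtosis=skrep)


# ---------------------------------------------------------------------------
# developmental trajectories
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryFit:
    """Per-speed log-log fits plus the speed x log-age interaction."""

    per_speed: pd.DataFrame  # speed, slope, intercept, slope_se, slope_p, r2
    interaction_slope: float
    interaction_p: float
    speed_main_effect_p: float


def fit_trajectory(log_values, log_age, speed_labels, participant_ids=None) -> TrajectoryFit:
    """Fit log measure vs log age per speed and test the speed interaction.

    With participant identifiers and two speeds, the interaction (and the
    speed main effect) is assessed on within-participant fast-minus-slow
    differences regressed on log age, the paired formulation of the
    repeated-measures analysis; otherwise a pooled model with a
    speed x log-age term is used.
    """
    y = np.asarray(log_values, dtype=float)
    x = np.asarray(log_age, dtype=float)
    lab = np.asarray(speed_labels)
    if np.unique(x).size < 2:
        raise ValueError("log_age is constant; need >= 2 age levels")
    speeds = np.unique(lab)
    rows = []
    for s in speeds:
        sel = lab == s
        res = sm.OLS(y[sel], sm.add_constant(x[sel])).fit()
        rows.append(
            dict(
                speed=s,
                intercept=res.params[0],
                slope=res.params[1],
                slope_se=res.bse[1],
                slope_p=res.pvalues[1],
                r2=res.rsquared,
            )
        )
    per_speed = pd.DataFrame(rows)

    if participant_ids is not None and speeds.size == 2:
        pid = np.asarray(participant_ids)
        tab = pd.DataFrame(dict(pid=pid, speed=lab, y=y, x=x))
        wide = tab.pivot_table(index="pid", columns="speed", values="y")
        ages = tab.groupby("pid")["x"].first()
        wide = wide.dropna()
        ages = ages.loc[wide.index]
        diff = wide[speeds[1]] - wide[speeds[0]]
        res = sm.OLS(diff.to_numpy(), sm.add_constant(ages.to_numpy())).fit()
        inter_slope, inter_p = res.params[1], res.pvalues[1]
        main_p = stats.ttest_rel(wide[speeds[1]], wide[speeds[0]]).pvalue
    else:
        d = (lab == speeds[-1]).astype(float)
        X = sm.add_constant(np.column_stack([x, d, x * d]))
        res = sm.OLS(y, X).fit()
        inter_slope, inter_p = res.params[3], res.pvalues[3]
        main_p = res.pvalues[2]
    return TrajectoryFit(
        per_speed=per_speed,
        interaction_slope=float(inter_slope),
        interaction_p=float(inter_p),
        speed_main_effect_p=float(main_p),
    )


# ---------------------------------------------------------------------------
# hierarchical stepwise regression
# ---------------------------------------------------------------------------


@dataclass
class RegressionStep:
    terms: Tuple[str, ...]
    table: pd.DataFrame  # term, B, SE_B, beta, p
    r2: float
    delta_r2: float


@dataclass
class RegressionReport:
    steps: List[RegressionStep]
    entered: Tuple[str, ...]
    excluded: Dict[str, float]  # term -> p at final consideration
    condition_number: float


def _ols_table(y: np.ndarray, X: pd.DataFrame):
    res = sm.OLS(y, sm.add_constant(X)).fit()
    sy = y.std(ddof=1)
    rows = [dict(term="const", B=res.params.iloc[0], SE_B=res.bse.iloc[0], beta=np.nan, p=res.pvalues.iloc[0])]
    for t in X.columns:
        rows.append(
            dict(
                term=t,
                B=res.params[t],
                SE_B=res.bse[t],
                beta=res.params[t] * X[t].std(ddof=1) / sy,
                p=res.pvalues[t],
            )
        )
    return res, pd.DataFrame(rows)


def hierarchical_regression(
    log_mc_thresholds,
    log_age,
    log_n_samp,
    log_sigma_int,
    *,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> RegressionReport:
    """Hierarchical model on log coherence thresholds.

    Step 1 enters log age alone.  Step 2 offers log sampling and log
    internal noise stepwise: at each round the candidate with the smallest
    p-value below ``p_enter`` (when added to the current model) enters, and
    entered covariates whose p rises above ``p_remove`` drop out.  Log age
    is never removed (it is the hierarchical block).
    """
    y = np.asarray(log_mc_thresholds, dtype=float)
    X_all = pd.DataFrame(
        dict(
            log_age=np.asarray(log_age, dtype=float),
            log_sampling=np.asarray(log_n_samp, dtype=float),
            log_internal_noise=np.asarray(log_sigma_int, dtype=float),
        )
    )
    if not (len(y) == len(X_all)):
        raise ValueError("inputs must be aligned")
    if len(y) < 5:
        raise ValueError("too few rows for the regression")
    cond = float(np.linalg.cond(sm.add_constant((X_all - X_all.mean()) / X_all.std(ddof=1))))

    res1, tab1 = _ols_table(y, X_all[["log_age"]])
    steps = [RegressionStep(("log_age",), tab1, float(res1.rsquared), float(res1.rsquared))]

    current: List[str] = []
    candidates = ["log_sampling", "log_internal_noise"]
    excluded: Dict[str, float] = {}
    while True:
        changed = False
        best, best_p = None, 1.0
        for c in candidates:
            if c in current:
                continue
            res_c, _ = _ols_table(y, X_all[["log_age"] + current + [c]])
            p = res_c.pvalues[c]
            excluded[c] = float(p)
            if p < p_enter and p < best_p:
                best, best_p = c, p
        if best is not None:
            current.append(best)
            excluded.pop(best, None)
            changed = True
        # removal pass (log_age is protected)
        res, _ = _ols_table(y, X_all[["log_age"] + current])
        for c in list(current):
            p = res.pvalues[c]
            if p > p_remove:
                current.remove(c)
                excluded[c] = float(p)
                changed = True
        if not changed:
            break
    res2, tab2 = _ols_table(y, X_all[["log_age"] + current])
    steps.append(
        RegressionStep(
            tuple(["log_age"] + current),
            tab2,
            float(res2.rsquared),
            float(res2.rsquared - res1.rsquared),
        )
    )
    return RegressionReport(steps=steps, entered=tuple(current), excluded=excluded, condition_number=cond)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def correlations(screened: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (log scale) of each EN measure against log MC threshold."""
    rows = []
    for speed, grp in screened.groupby("speed"):
        if len(grp) < 3:
            raise ValueError("need >= 3 rows per speed")
        for m in ("sigma_int", "n_samp"):
            x = grp[f"log10_{m}"].to_numpy()
            y = grp["log10_coherence_threshold"].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append(dict(speed=speed, measure=m, r=np.nan, df=len(grp) - 2, p=np.nan, note="zero variance"))
                continue
            r, p = stats.pearsonr(x, y)
            rows.append(dict(speed=speed, measure=m, r=r, df=len(grp) - 2, p=p, note=""))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixation stability
# ---------------------------------------------------------------------------


def fixation_stability(traces: pd.DataFrame, method: str = "rms") -> pd.DataFrame:
    """Log pooled SD of gaze position per participant x task x speed.

    Samples with a validity code >= 2 in either eye are discarded; the
    remaining samples are averaged across eyes; the pooled SD combines the
    x and y SDs by root-mean-square (default) or arithmetic mean.
    Conditions with fewer than two valid samples, or zero spread, are
    flagged missing.
    """
    if method not in ("rms", "mean"):
        raise ValueError("method must be 'rms' or 'mean'")
    rows = []
    for (pid, task, speed), grp in traces.groupby(["participant_id", "task", "speed"]):
        valid = grp[(grp["val_l"] < 2) & (grp["val_r"] < 2)]
        n = len(valid)
        if n < 2:
            rows.append(dict(participant_id=pid, task=task, speed=speed, n_valid=n, pooled_sd=np.nan, log10_pooled_sd=np.nan, flag="too few valid samples"))
            continue
        x = (valid["x_l"] + valid["x_r"]) / 2.0
        y = (valid["y_l"] + valid["y_r"]) / 2.0
        sx, sy = x.std(ddof=1), y.std(ddof=1)
        pooled = math.sqrt((sx**2 + sy**2) / 2.0) if method == "rms" else (sx + sy) / 2.0
        if pooled == 0:
            rows.append(dict(participant_id=pid, task=task, speed=speed, n_valid=n, pooled_sd=0.0, log10_pooled_sd=np.nan, flag="zero spread"))
            continue
        rows.append(dict(participant_id=pid, task=task, speed=speed, n_valid=n, pooled_sd=pooled, log10_pooled_sd=math.log10(pooled), flag=""))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


@dataclass
class AnalysisReport:
    screened: ScreenedEstimates
    excluded_participants: Tuple[str, ...]
    trajectories: Dict[str, TrajectoryFit]
    correlation_table: pd.DataFrame
    regressions: Dict[float, RegressionReport]
    fixation: Optional[pd.DataFrame] = None
    fixation_correlations: Optional[pd.DataFrame] = None

    def write(self, outdir) -> None:
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        kw = dict(index=False, float_format="%.10g")
        self.screened.data.to_csv(outdir / "screened_estimates.csv", **kw)
        self.screened.skew_kurtosis.to_csv(outdir / "skew_kurtosis.csv", **kw)
        traj_rows = []
        for m, t in self.trajectories.items():
            for _, r in t.per_speed.iterrows():
                traj_rows.append(dict(measure=m, **r.to_dict(), interaction_slope=t.interaction_slope, interaction_p=t.interaction_p))
        pd.DataFrame(traj_rows).to_csv(outdir / "trajectories.csv", **kw)
        self.correlation_table.to_csv(outdir / "correlations.csv", **kw)
        reg_rows = []
        for speed, rep in self.regressions.items():
            for i, step in enumerate(rep.steps, start=1):
                for _, r in step.table.iterrows():
                    reg_rows.append(dict(speed=speed, step=i, r2=step.r2, delta_r2=step.delta_r2, **r.to_dict()))
        pd.DataFrame(reg_rows).to_csv(outdir / "regression.csv", **kw)
        if self.fixation is not None:
            self.fixation.to_csv(outdir / "fixation_stability.csv", **kw)


def analyze(
    dataset: CohortDataset,
    lapse_table: Optional[LapseCorrectionTable] = None,
    outdir=None,
    *,
    catch_alpha: float = 0.05,
    table_seed: int = 7042,
) -> AnalysisReport:
    """Run the full statistical pipeline on a simulated cohort dataset.

    Pure function of (dataset, lapse table): identical reports on rerun.
    When no lapse table is supplied one is built from a fixed internal
    seed, preserving determinism.
    """
    est = dataset.estimates
    if lapse_table is None:
        lapse_table = lapse_correction_build(rng=np.random.default_rng(table_seed))
    excluded = apply_catch_screen(est, alpha=catch_alpha)
    kept = est[~excluded].copy()
    corrected = correct_and_decompose(kept, lapse_table)
    screened = screen_and_transform(corrected)
    inc = screened.included
    la = np.log10(inc["age_years"].to_numpy())
    trajectories = {
        m: fit_trajectory(
            inc[f"log10_{m}"].to_numpy(),
            la,
            inc["speed"].to_numpy(),
            participant_ids=inc["participant_id"].to_numpy(),
        )
        for m in MEASURES
    }
    corr = correlations(inc)
    regressions = {}
    for speed, grp in inc.groupby("speed"):
        regressions[float(speed)] = hierarchical_regression(
            grp["log10_coherence_threshold"].to_numpy(),
            np.log10(grp["age_years"].to_numpy()),
            grp["log10_n_samp"].to_numpy(),
            grp["log10_sigma_int"].to_numpy(),
        )
    fix = fixcorr = None
    if dataset.fixation is not None:
        fix = fixation_stability(dataset.fixation)
        ok = fix[fix["flag"] == ""]
        merged = ok.groupby(["participant_id", "speed"], as_index=False)["log10_pooled_sd"].mean().merge(
            inc[["participant_id", "speed", "log10_sigma_int", "log10_n_samp", "log10_coherence_threshold"]],
            on=["participant_id", "speed"],
        )
        fc_rows = []
        for speed, grp in merged.groupby("speed"):
            for m in ("log10_sigma_int", "log10_n_samp", "log10_coherence_threshold"):
                if len(grp) >= 3 and grp[m].std() > 0 and grp["log10_pooled_sd"].std() > 0:
                    r, p = stats.pearsonr(grp["log10_pooled_sd"], grp[m])
                    fc_rows.append(dict(speed=speed, measure=m, r=r, df=len(grp) - 2, p=p))
        fixcorr = pd.DataFrame(fc_rows)
    report = AnalysisReport(
        screened=screened,
        excluded_participants=tuple(sorted(set(est.loc[excluded, "participant_id"]))),
        trajectories=trajectories,
        correlation_table=corr,
        regressions=regressions,
        fixation=fix,
        fixation_correlations=fixcorr,
    )
    if outdir is not None:
        report.write(outdir)
    return report
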