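"""End-to-end orchestration: cohort -> unit metrics -> synchrony -> behavior
coupling -> group statistics, emitting flat CSV/JSON artifacts.

Artifacts written to the output directory:

* ``unit_metrics.csv`` — unit_id, group, structure, trial, rate_hz, cv2,
  n_bursts, spikes_per_burst, burst_dur_s
* ``pair_metrics.csv`` — pair_id, group, trial, Q, q_downsampled, median_tau
  (``q_downsampled`` is the 50%-NAc-downsampling control, recomputed for the
  saline group and equal to Q for the PCP group)
* ``coherence.csv`` — frequency_hz, group, mean_coherence, lower, upper
* ``xcorr_long.csv`` — lag_s, object_role, group, structure, trial, mean_r, sem
* ``stats_report.json`` — Wilcoxon, bootstrap CI, ANOVAs, normality screen
* ``run_log.txt``

The pipeline is deterministic given the input cohort (or its generator
config, which carries its own seed) and the run seed, which drives only the
analysis-stage randomness (downsampling, bootstraps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior_coupling as bc
from . import group_stats as gs
from . import synchrony as sy
from . import unit_metrics as um
from .session_model import (
    Session,
    SpikeTrain,
    UndefinedResultError,
    ValidationError,
    read_cohort_dir,
)
from .synthetic_cohort import CohortConfig, gen_cohort

logger = logging.getLogger("cortistri")

__all__ = ["RunConfig", "run_pipeline", "filter_units", "PipelineResult"]


@dataclass
class RunConfig:
    """Parameterization of a full pipeline run."""

    out_dir: str = "results"
    input_dir: str | None = None  # read sessions from here ...
    cohort: CohortConfig | None = None  # ... or generate them
    seed: int = 0
    rate_ceiling_hz: float = 6.0  # units at/above this baseline rate excluded
    surprise_threshold: float = 5.0
    min_burst_spikes: int = 3
    downsample_fraction: float = 0.5
    bin_s: float = 0.1
    max_lag_s: float = 5.0
    coherence_bin_s: float = 0.001
    coherence_segment_len: int = 1024
    coherence_max_hz: float = 100.0
    n_boot: int = 2000
    run_sync: bool = True
    run_coherence: bool = True
    run_behavior: bool = True
    run_stats: bool = True

    def validate(self) -> None:
        if self.input_dir is None and self.cohort is None:
            raise ValidationError("RunConfig needs input_dir or a cohort config")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise ValidationError(f"input_dir {self.input_dir!r} does not exist")
        if not (0.0 < self.downsample_fraction <= 1.0):
            raise ValidationError("downsample_fraction must be in (0, 1]")
        if self.rate_ceiling_hz <= 0:
            raise ValidationError("rate_ceiling_hz must be > 0")


@dataclass
class PipelineResult:
    out_dir: Path
    unit_metrics: pd.DataFrame
    pair_metrics: pd.DataFrame | None
    coherence: pd.DataFrame | None
    xcorr: pd.DataFrame | None
    stats_report: dict | None
    sessions: list[Session] = field(default_factory=list)


def filter_units(
    trains: list[SpikeTrain], ceiling_hz: float = 6.0
) -> list[SpikeTrain]:
    """Drop units whose baseline (pre-exposure) firing rate is >= ceiling.

    The analysis targets low-rate units (putative MSNs in NAc, regular
    spiking cells in mPFC); faster units are excluded and logged. A unit
    lacking a pre-exposure train is judged on its first available trial.
    """
    by_unit: dict[str, list[SpikeTrain]] = {}
    for t in trains:
        by_unit.setdefault(t.unit_id, []).append(t)
    kept: list[SpikeTrain] = []
    for unit_id, ts in by_unit.items():
        base = next((t for t in ts if t.trial == "pre_exposure"), ts[0])
        rate = um.firing_rate(base)
        if rate >= ceiling_hz:
            logger.info("filter_units: excluding %s (baseline %.2f Hz)", unit_id, rate)
        else:
            kept.extend(ts)
    return kept


# ---------------------------------------------------------------------------
# Stage computations


def _unit_metrics_table(sessions: list[Session], cfg: RunConfig) -> pd.DataFrame:
    rows = []
    for s in sessions:
        for t in s.trains:
            try:
                c = um.cv2(t)
            except UndefinedResultError:
                c = float("nan")
            bs = um.detect_bursts(
                t, surprise_threshold=cfg.surprise_threshold,
                min_spikes=cfg.min_burst_spikes,
            )
            rows.append(
                {
                    "unit_id": t.unit_id,
                    "animal_id": t.animal_id,
                    "group": t.group,
                    "structure": t.structure,
                    "trial": t.trial,
                    "rate_hz": um.firing_rate(t),
                    "cv2": c,
                    "n_bursts": bs.n_bursts,
                    "spikes_per_burst": bs.mean_spikes_per_burst,
                    "burst_dur_s": bs.mean_duration,
                }
            )
    return pd.DataFrame(rows)


def _pairs(session: Session, trial: str) -> list[tuple[SpikeTrain, SpikeTrain]]:
    return [
        (x, y)
        for x in session.units("mPFC", trial)
        for y in session.units("NAc", trial)
    ]


def _pair_metrics_table(
    sessions: list[Session], cfg: RunConfig, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    from .session_model import TRIALS

    for s in sessions:
        for trial in TRIALS:
            for x, y in _pairs(s, trial):
                try:
                    res = sy.event_synchronization(x, y)
                except UndefinedResultError as exc:
                    logger.warning("synchrony skipped: %s", exc)
                    continue
                q_ds = res.Q
                if s.group == "saline" and cfg.downsample_fraction < 1.0:
                    y_ds = sy.subsample_spikes(y, cfg.downsample_fraction, rng)
                    try:
                        q_ds = sy.event_synchronization(x, y_ds).Q
                    except UndefinedResultError:
                        q_ds = float("nan")
                rows.append(
                    {
                        "pair_id": f"{x.unit_id}|{y.unit_id}",
                        "animal_id": s.animal_id,
                        "group": s.group,
                        "trial": trial,
                        "Q": res.Q,
                        "q_downsampled": q_ds,
                        "median_tau": res.median_tau,
                    }
                )
    df = pd.DataFrame(rows)
    if len(df):
        logger.info(
            "pair_metrics: %d pair-trials; median tau across pairs = %.1f ms",
            len(df), 1000.0 * float(df["median_tau"].median()),
        )
    return df


def _coherence_table(
    sessions: list[Session], cfg: RunConfig, rng: np.random.Generator
) -> pd.DataFrame:
    from .session_model import TRIALS

    spectra: dict[str, list[sy.PairCoherence]] = {"saline": [], "pcp": []}
    for s in sessions:
        for trial in TRIALS:
            for x, y in _pairs(s, trial):
                try:
                    spectra[s.group].append(
                        sy.spike_coherence(
                            x, y, cfg.coherence_bin_s, cfg.coherence_segment_len
                        )
                    )
                except (UndefinedResultError, ValidationError) as exc:
                    logger.warning("coherence skipped: %s", exc)
    rows = []
    for group, pairs in spectra.items():
        if len(pairs) < 2:
            logger.warning("coherence: group %s has < 2 pairs; omitted", group)
            continue
        res = sy.group_coherence(pairs, n_boot=cfg.n_boot, seed=rng)
        keep = res.frequencies <= cfg.coherence_max_hz
        for f, m, lo, hi in zip(
            res.frequencies[keep], res.mean[keep], res.lower[keep], res.upper[keep]
        ):
            rows.append(
                {
                    "frequency_hz": f,
                    "group": group,
                    "mean_coherence": m,
                    "lower": lo,
                    "upper": hi,
                }
            )
    return pd.DataFrame(rows)


def _xcorr_table(sessions: list[Session], cfg: RunConfig) -> pd.DataFrame:
    curves: list[bc.UnitXCorr] = []
    for s in sessions:
        curves.extend(bc.unit_xcorr_curves(s, cfg.bin_s, cfg.max_lag_s))
    rows = []
    for res in bc.group_xcorr(curves):
        for lag, m, sem in zip(res.lags_s, res.mean, res.sem):
            rows.append(
                {
                    "lag_s": lag,
                    "object_role": res.object_role,
                    "group": res.group,
                    "structure": res.structure,
                    "trial": res.trial,
                    "mean_r": m,
                    "sem": sem,
                }
            )
    return pd.DataFrame(rows)


def _stats_report(
    sessions: list[Session],
    units_df: pd.DataFrame,
    pairs_df: pd.DataFrame | None,
    cfg: RunConfig,
    rng: np.random.Generator,
) -> dict:
    report: dict = {}

    # --- unit firing rates: per-unit mean across trials, one-way ANOVA per structure
    per_unit = (
        units_df.groupby(["unit_id", "animal_id", "group", "structure"], observed=True)
        .agg(rate_hz=("rate_hz", "mean"), n_bursts=("n_bursts", "mean"))
        .reset_index()
    )
    report["firing_rate"] = {}
    for structure, sub in per_unit.groupby("structure", observed=True):
        try:
            rep = gs.oneway_anova(sub["rate_hz"].to_numpy(), sub["group"].to_numpy())
            report["firing_rate"][structure] = {
                "group_means": sub.groupby("group", observed=True)["rate_hz"]
                .mean().to_dict(),
                "anova": rep.to_dict(),
            }
        except ValidationError as exc:
            report["firing_rate"][structure] = {"error": str(exc)}

    # --- burst counts per trial, per structure
    report["bursts"] = {}
    for structure, sub in per_unit.groupby("structure", observed=True):
        try:
            rep = gs.oneway_anova(sub["n_bursts"].to_numpy(), sub["group"].to_numpy())
            report["bursts"][structure] = {
                "group_means": sub.groupby("group", observed=True)["n_bursts"]
                .mean().to_dict(),
                "anova": rep.to_dict(),
            }
        except ValidationError as exc:
            report["bursts"][structure] = {"error": str(exc)}

    # --- per-animal mean rates: structure x group mixed ANOVA with LSD
    per_animal = (
        units_df.groupby(["animal_id", "group", "structure"], observed=True)["rate_hz"]
        .mean().reset_index().rename(columns={"rate_hz": "value"})
    )
    complete = per_animal.groupby("animal_id", observed=True)["structure"].nunique()
    keep = complete[complete == 2].index
    dropped = sorted(set(per_animal["animal_id"]) - set(keep))
    if dropped:
        logger.warning("mixed ANOVA: dropping animals without both structures: %s", dropped)
    per_animal = per_animal[per_animal["animal_id"].isin(keep)]
    try:
        rep = gs.mixed_anova(per_animal, dv="value", subject="animal_id")
        report["per_animal_rate_anova"] = rep.to_dict()
    except (ValidationError, UndefinedResultError) as exc:
        report["per_animal_rate_anova"] = {"error": str(exc)}

    # --- synchrony: group comparison over pair x trial observations
    if pairs_df is not None and len(pairs_df):
        rep = gs.oneway_anova(pairs_df["Q"].to_numpy(), pairs_df["group"].to_numpy())
        report["synchrony"] = {
            "group_means": pairs_df.groupby("group", observed=True)["Q"].mean().to_dict(),
            "anova": rep.to_dict(),
            "median_tau_s": float(pairs_df["median_tau"].median()),
        }
        ctrl = pairs_df.copy()
        ctrl["Q_ctrl"] = np.where(
            ctrl["group"] == "saline", ctrl["q_downsampled"], ctrl["Q"]
        )
        ctrl = ctrl.dropna(subset=["Q_ctrl"])
        rep2 = gs.oneway_anova(ctrl["Q_ctrl"].to_numpy(), ctrl["group"].to_numpy())
        report["synchrony"]["downsampling_control"] = {
            "group_means": ctrl.groupby("group", observed=True)["Q_ctrl"].mean().to_dict(),
            "anova": rep2.to_dict(),
        }

    # --- exploration: Wilcoxon per group + bootstrap CI of group difference
    expl_rows = []
    for s in sessions:
        for e in bc.exploration_summary(s.contacts, s.animal_id):
            expl_rows.append({**dataclasses.asdict(e), "group": s.group})
    expl = pd.DataFrame(expl_rows)
    report["exploration"] = {}
    if len(expl):
        ret = expl[expl["trial"] == "retention"].pivot_table(
            index=["animal_id", "group"], columns="object_role",
            values="total_seconds", observed=True,
        ).reset_index()
        if {"novel", "familiar"} <= set(ret.columns):
            times = ret[["novel", "familiar"]].to_numpy().ravel()
            try:
                report["exploration"]["normality"] = gs.normality_screen(times)
            except ValidationError as exc:
                report["exploration"]["normality"] = {"error": str(exc)}
            diffs = {}
            for group, sub in ret.groupby("group", observed=True):
                d = (sub["novel"] - sub["familiar"]).to_numpy()
                diffs[group] = d
                try:
                    report["exploration"][f"wilcoxon_{group}"] = (
                        gs.wilcoxon_signed_rank(d).to_dict()
                    )
                except (ValidationError, UndefinedResultError) as exc:
                    report["exploration"][f"wilcoxon_{group}"] = {"error": str(exc)}
                report["exploration"][f"median_{group}"] = {
                    "familiar": float(sub["familiar"].median()),
                    "novel": float(sub["novel"].median()),
                }
            if {"saline", "pcp"} <= diffs.keys():
                try:
                    ci = gs.bootstrap_median_diff(
                        diffs["saline"], diffs["pcp"], n_boot=cfg.n_boot, seed=rng
                    )
                    report["exploration"]["bootstrap_median_diff"] = ci.to_dict()
                except ValidationError as exc:
                    report["exploration"]["bootstrap_median_diff"] = {"error": str(exc)}
    return report


# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every enabled stage and write all artifacts to ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run_log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        if config.input_dir is not None:
            sessions = read_cohort_dir(config.input_dir)
            logger.info("loaded %d sessions from %s", len(sessions), config.input_dir)
        else:
            sessions, _ = gen_cohort(config.cohort)
            logger.info(
                "generated %d synthetic sessions (seed %d)",
                len(sessions), config.cohort.seed,
            )

        # analysis-stage randomness
        ss = np.random.SeedSequence(config.seed)
        rng_ds, rng_coh, rng_stats = (np.random.default_rng(s) for s in ss.spawn(3))

        # inclusion filter
        n_before = len({t.unit_id for s in sessions for t in s.trains})
        for s in sessions:
            s.trains = filter_units(s.trains, config.rate_ceiling_hz)
        n_after = len({t.unit_id for s in sessions for t in s.trains})
        logger.info("filter_units: kept %d/%d units (< %.1f Hz baseline)",
                    n_after, n_before, config.rate_ceiling_hz)

        units_df = _unit_metrics_table(sessions, config)
        units_df.to_csv(out / "unit_metrics.csv", index=False)
        logger.info("unit_metrics: %d unit-trials", len(units_df))

        pairs_df = coh_df = xc_df = None
        if config.run_sync:
            pairs_df = _pair_metrics_table(sessions, config, rng_ds)
            pairs_df.to_csv(out / "pair_metrics.csv", index=False)
        if config.run_coherence:
            coh_df = _coherence_table(sessions, config, rng_coh)
            coh_df.to_csv(out / "coherence.csv", index=False)
            logger.info("coherence: %d rows", 0 if coh_df is None else len(coh_df))
        if config.run_behavior:
            xc_df = _xcorr_table(sessions, config)
            xc_df.to_csv(out / "xcorr_long.csv", index=False)

        stats_report = None
        if config.run_stats:
            stats_report = _stats_report(sessions, units_df, pairs_df, config, rng_stats)
            with open(out / "stats_report.json", "w") as fh:
                json.dump(stats_report, fh, indent=1, default=float)
                fh.write("\n")
        logger.info("pipeline complete: artifacts in %s", out)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return PipelineResult(
        out_dir=out,
        unit_metrics=units_df,
        pair_metrics=pairs_df,
        coherence=coh_df,
        xcorr=xc_df,
        stats_report=stats_report,
        sessions=sessions,
    )
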