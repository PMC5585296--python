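"""Synthetic two-group cohort generator with known ground truth.

Emulates the statistical structure of a sub-chronic PCP study in which two
groups of six rats (saline vs PCP pre-treated) are recorded simultaneously in
mPFC and NAc shell during the three trials of a novel object recognition
task. The generator injects, with configurable magnitudes, every effect the
analysis pipeline is meant to recover:

* tonic NAc rate reduction in the PCP group (1.9 vs 0.93 Hz targets);
* elevated mPFC->NAc spike synchrony in the saline group, injected by copying
  a fraction of mPFC spikes into NAc trains with small Gaussian jitter
  (the event-synchronization index counts coincidences, not rhythm);
* a saline-only multiplicative rate gain during novel-object contact;
* Poisson-surprise-detectable burst episodes (9 vs 5 bursts/trial in NAc);
* group-specific object exploration totals (29.9/36.2 s saline,
  30.1/30.8 s PCP medians).

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning (one child stream per animal, one
grandchild per purpose), so identical configs give byte-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from .session_model import (
    TRIAL_DURATION_S,
    TRIALS,
    ContactTrace,
    Session,
    SpikeTrain,
    ValidationError,
)

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "UnitGroundTruth",
    "gen_poisson_train",
    "gen_contact_trace",
    "gen_modulated_train",
    "gen_synchronized_pair",
    "gen_common_modulated_pair",
    "gen_bursty_train",
    "gen_cohort",
]


def _rng(seed: int | np.random.Generator | np.random.SeedSequence) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class CohortConfig:
    """Full parameterization of the synthetic two-group study.

    Defaults reproduce the study conditions: group sizes, firing-rate
    targets, exploration totals, synchrony levels, and burst counts.
    Rates are in Hz, times in seconds.
    """

    n_animals_per_group: int = 6
    units_per_structure: tuple[int, int] = (2, 4)  # inclusive range
    rate_mpfc_hz: float = 1.1
    rate_nac_hz: dict[str, float] = field(
        default_factory=lambda: {"saline": 1.9, "pcp": 0.93}
    )
    #: group -> object_role -> mean total contact seconds per 180-s trial
    contact_seconds: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "saline": {"familiar": 29.9, "novel": 36.2},
            "pcp": {"familiar": 30.1, "novel": 30.8},
        }
    )
    #: SD of the animal-level exploration baseline shared by both objects.
    animal_contact_sd_s: float = 3.0
    #: SD of the object-specific exploration noise (cancels out of paired
    #: novel-familiar differences only via the shared baseline above).
    contact_sd_s: float = 1.5
    n_contact_epochs: int = 12
    #: multiplicative rate gain during novel-object contact
    novelty_gain: dict[str, float] = field(
        default_factory=lambda: {"saline": 1.5, "pcp": 1.0}
    )
    #: probability an NAc spike is a jittered copy of an mPFC spike
    sync_prob: dict[str, float] = field(
        default_factory=lambda: {"saline": 0.15, "pcp": 0.03}
    )
    sync_jitter_s: float = 0.005
    #: structure -> group -> bursts per 180-s trial
    bursts_per_trial: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "NAc": {"saline": 9.0, "pcp": 5.0},
            "mPFC": {"saline": 6.0, "pcp": 6.0},
        }
    )
    burst_rate_gain: float = 8.0
    burst_len_spikes: int = 14
    #: log-SD of the per-unit lognormal rate heterogeneity (mean at target)
    unit_rate_log_sd: float = 0.5
    trial_duration_s: float = TRIAL_DURATION_S
    seed: int = 0

    def validate(self) -> None:
        if self.n_animals_per_group < 1:
            raise ValidationError("n_animals_per_group must be >= 1")
        lo, hi = self.units_per_structure
        if not (1 <= lo <= hi):
            raise ValidationError("units_per_structure must be a valid range")
        if self.rate_mpfc_hz <= 0 or any(v <= 0 for v in self.rate_nac_hz.values()):
            raise ValidationError("all rates must be > 0")
        for g, roles in self.contact_seconds.items():
            for role, s in roles.items():
                if not (0 <= s < self.trial_duration_s):
                    raise ValidationError(
                        f"contact seconds for {g}/{role} must be < trial duration"
                    )
        for g, p in self.sync_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"sync_prob[{g}] must be in [0, 1]")
        if self.trial_duration_s <= 0:
            raise ValidationError("trial_duration_s must be > 0")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "CohortConfig":
        with open(path) as fh:
            doc = json.load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "CohortConfig":
        kw = dict(doc)
        if "units_per_structure" in kw:
            kw["units_per_structure"] = tuple(kw["units_per_structure"])
        return cls(**kw)


@dataclass
class UnitGroundTruth:
    """Injected parameters for one synthetic unit."""

    unit_id: str
    animal_id: str
    structure: str
    rate_hz: float  # target total rate (lognormal draw)
    parent_unit_id: str | None = None  # mPFC unit whose spikes are copied
    copy_prob: float = 0.0  # expected copied fraction of this unit's spikes
    #: trial -> (n_bursts, 2) array of injected burst [onset, offset) epochs
    burst_epochs: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Everything injected into a synthetic cohort, for recovery tests."""

    units: list[UnitGroundTruth] = field(default_factory=list)
    novelty_gain: dict[str, float] = field(default_factory=dict)
    sync_prob: dict[str, float] = field(default_factory=dict)
    config: CohortConfig | None = None

    def unit(self, unit_id: str) -> UnitGroundTruth:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)


# ---------------------------------------------------------------------------
# Elementary generators


def _poisson_times(rate: float, duration: float, rng: np.random.Generator) -> np.ndarray:
    if rate < 0:
        raise ValidationError("rate must be >= 0")
    n = rng.poisson(rate * duration)
    t = np.sort(rng.uniform(0.0, duration, size=n))
    return np.unique(t)  # exact duplicates are invalid within a unit


def gen_poisson_train(
    rate: float,
    duration: float = TRIAL_DURATION_S,
    seed: int | np.random.Generator = 0,
    **meta: Any,
) -> SpikeTrain:
    """Homogeneous Poisson spike train on ``[0, duration)``.

    ``meta`` may override the SpikeTrain tag fields (unit_id, group, ...).
    """
    rng = _rng(seed)
    times = _poisson_times(rate, duration, rng)
    tags = {
        "unit_id": "u0",
        "animal_id": "a0",
        "group": "saline",
        "structure": "mPFC",
        "trial": "pre_exposure",
    }
    tags.update(meta)
    return SpikeTrain(times=times, duration=duration, **tags)


def gen_contact_trace(
    total_seconds: float,
    n_epochs: int = 12,
    duration: float = TRIAL_DURATION_S,
    seed: int | np.random.Generator = 0,
    object_role: str = "novel",
    trial: str = "retention",
    animal_id: str = "",
) -> ContactTrace:
    """``n_epochs`` non-overlapping contact intervals summing to ``total_seconds``.

    Epoch lengths are a Dirichlet split of the total (concentration 5, so
    epochs are of comparable size); gaps are a Dirichlet split of the free
    time. Raises on infeasible packing (total >= duration).
    """
    if total_seconds < 0:
        raise ValidationError("total_seconds must be >= 0")
    if total_seconds >= duration:
        raise ValidationError("total contact seconds must be < trial duration")
    rng = _rng(seed)
    if total_seconds == 0 or n_epochs == 0:
        return ContactTrace(
            object_role=object_role, trial=trial, intervals=np.empty((0, 2)),
            duration=duration, animal_id=animal_id,
        )
    lens = rng.dirichlet(np.full(n_epochs, 5.0)) * total_seconds
    gaps = rng.dirichlet(np.ones(n_epochs + 1)) * (duration - total_seconds)
    starts = np.cumsum(gaps[:-1]) + np.concatenate(([0.0], np.cumsum(lens[:-1])))
    intervals = np.column_stack([starts, starts + lens])
    intervals[-1, 1] = min(intervals[-1, 1], np.nextafter(duration, 0.0))
    return ContactTrace(
        object_role=object_role, trial=trial, intervals=intervals,
        duration=duration, animal_id=animal_id,
    )


def _in_intervals(t: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Boolean mask: which times fall inside any half-open interval."""
    if intervals.shape[0] == 0:
        return np.zeros(t.shape, dtype=bool)
    idx = np.searchsorted(intervals[:, 0], t, side="right") - 1
    ok = idx >= 0
    hit = np.zeros(t.shape, dtype=bool)
    hit[ok] = t[ok] < intervals[idx[ok], 1]
    return hit


def _modulated_times(
    base_rate: float,
    intervals: np.ndarray,
    gain: float,
    duration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inhomogeneous Poisson by thinning: base_rate*gain inside intervals."""
    if base_rate < 0:
        raise ValidationError("rate must be >= 0")
    if gain < 0:
        raise ValidationError("gain must be >= 0")
    rate_max = base_rate * max(gain, 1.0)
    if rate_max == 0:
        return np.empty(0)
    t = _poisson_times(rate_max, duration, rng)
    inside = _in_intervals(t, intervals)
    p = np.where(inside, base_rate * gain / rate_max, base_rate / rate_max)
    keep = rng.uniform(size=t.size) < p
    return t[keep]


def gen_modulated_train(
    base_rate: float,
    contact: ContactTrace,
    gain: float = 1.5,
    duration: float | None = None,
    seed: int | np.random.Generator = 0,
    **meta: Any,
) -> SpikeTrain:
    """Poisson train at ``base_rate`` outside contact, ``base_rate*gain`` inside."""
    rng = _rng(seed)
    duration = contact.duration if duration is None else duration
    times = _modulated_times(base_rate, contact.intervals, gain, duration, rng)
    tags = {
        "unit_id": "u0",
        "animal_id": "a0",
        "group": "saline",
        "structure": "NAc",
        "trial": contact.trial,
    }
    tags.update(meta)
    return SpikeTrain(times=times, duration=duration, **tags)


def _copy_with_jitter(
    parent: np.ndarray,
    copy_prob: float,
    jitter_s: float,
    duration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    keep = rng.uniform(size=parent.size) < copy_prob
    t = parent[keep] + rng.normal(0.0, jitter_s, size=int(keep.sum()))
    return t[(t >= 0.0) & (t < duration)]


def gen_synchronized_pair(
    rate_x: float,
    rate_y: float,
    sync_prob: float,
    jitter_s: float = 0.005,
    duration: float = TRIAL_DURATION_S,
    seed: int | np.random.Generator = 0,
) -> tuple[SpikeTrain, SpikeTrain]:
    """A Poisson train ``x`` and a partner ``y`` with injected coincidences.

    A fraction ``sync_prob`` of y's spikes are copies of x spikes displaced
    by Gaussian jitter (SD ``jitter_s``); the remainder is independent
    Poisson at ``(1 - sync_prob) * rate_y``, so both marginal rates are
    approximately preserved.
    """
    if not (0.0 <= sync_prob <= 1.0):
        raise ValidationError("sync_prob must be in [0, 1]")
    rng = _rng(seed)
    x = _poisson_times(rate_x, duration, rng)
    copy_rate = sync_prob * rate_y
    p_copy = min(1.0, copy_rate / rate_x) if rate_x > 0 else 0.0
    copies = _copy_with_jitter(x, p_copy, jitter_s, duration, rng)
    bg = _poisson_times((1.0 - sync_prob) * rate_y, duration, rng)
    y = np.unique(np.concatenate([copies, bg]))
    tx = SpikeTrain("x", "a0", "saline", "mPFC", "pre_exposure", x, duration)
    ty = SpikeTrain("y", "a0", "saline", "NAc", "pre_exposure", y, duration)
    return tx, ty


def gen_common_modulated_pair(
    rate_x: float,
    rate_y: float,
    mod_hz: float = 4.0,
    depth: float = 0.5,
    duration: float = TRIAL_DURATION_S,
    seed: int | np.random.Generator = 0,
) -> tuple[SpikeTrain, SpikeTrain]:
    """Two Poisson trains sharing a sinusoidal rate modulation (for coherence
    tests): lambda(t) = rate * (1 + depth * sin(2 pi f t)), common phase."""
    rng = _rng(seed)

    def _sin_thinned(rate: float) -> np.ndarray:
        t = _poisson_times(rate * (1 + depth), duration, rng)
        lam = rate * (1.0 + depth * np.sin(2 * math.pi * mod_hz * t))
        keep = rng.uniform(size=t.size) < lam / (rate * (1 + depth))
        return t[keep]

    tx = SpikeTrain("x", "a0", "saline", "mPFC", "pre_exposure", _sin_thinned(rate_x), duration)
    ty = SpikeTrain("y", "a0", "saline", "NAc", "pre_exposure", _sin_thinned(rate_y), duration)
    return tx, ty


def _burst_epoch_times(
    n_bursts: int,
    burst_len_spikes: int,
    burst_rate: float,
    duration: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Spike times and (n, 2) epochs for non-overlapping burst episodes."""
    if n_bursts == 0:
        return np.empty(0), np.empty((0, 2))
    bursts = []
    for _ in range(n_bursts):
        isis = rng.exponential(1.0 / burst_rate, size=burst_len_spikes - 1)
        bursts.append(np.concatenate(([0.0], np.cumsum(isis))))
    lens = np.array([b[-1] for b in bursts])
    total = float(np.sum(lens))
    if total >= duration:
        raise ValidationError("burst episodes do not fit in the trial")
    gaps = rng.dirichlet(np.ones(n_bursts + 1)) * (duration - total)
    starts = np.cumsum(gaps[:-1]) + np.concatenate(([0.0], np.cumsum(lens[:-1])))
    spikes = np.concatenate([s + b for s, b in zip(starts, bursts)])
    epochs = np.column_stack([starts, starts + lens])
    return spikes, epochs


def gen_bursty_train(
    base_rate: float = 1.9,
    bursts_per_trial: float = 9.0,
    burst_len_spikes: int = 14,
    burst_rate_gain: float = 8.0,
    duration: float = TRIAL_DURATION_S,
    seed: int | np.random.Generator = 0,
    **meta: Any,
) -> tuple[SpikeTrain, UnitGroundTruth]:
    """Poisson background plus injected burst episodes, with ground truth.

    Each episode has ``burst_len_spikes`` spikes at ``base_rate *
    burst_rate_gain``; episode onsets are placed so episodes never overlap.
    The expected total count is ``base_rate*duration + bursts*len``.
    """
    if base_rate <= 0 or bursts_per_trial < 0 or burst_len_spikes < 2 or burst_rate_gain <= 0:
        raise ValidationError("burst generator parameters must be positive")
    rng = _rng(seed)
    n_bursts = int(round(bursts_per_trial))
    burst_spikes, epochs = _burst_epoch_times(
        n_bursts, burst_len_spikes, base_rate * burst_rate_gain, duration, rng
    )
    bg = _poisson_times(base_rate, duration, rng)
    times = np.unique(np.concatenate([bg, burst_spikes]))
    tags = {
        "unit_id": "u0",
        "animal_id": "a0",
        "group": "saline",
        "structure": "NAc",
        "trial": "pre_exposure",
    }
    tags.update(meta)
    train = SpikeTrain(times=times, duration=duration, **tags)
    gt = UnitGroundTruth(
        unit_id=tags["unit_id"],
        animal_id=tags["animal_id"],
        structure=tags["structure"],
        rate_hz=base_rate,
        burst_epochs={tags["trial"]: epochs},
    )
    return train, gt


# ---------------------------------------------------------------------------
# Cohort assembly


def _unit_rate_factor(rng: np.random.Generator, log_sd: float) -> float:
    """Lognormal heterogeneity factor with mean exactly 1 (group means hit
    the configured rate targets)."""
    return float(rng.lognormal(-0.5 * log_sd**2, log_sd))


def _animal_contacts(
    config: CohortConfig, group: str, animal_id: str, rng: np.random.Generator
) -> list[ContactTrace]:
    """Contact traces for acquisition (two objects, both physically novel)
    and retention (novel vs familiar). Pre-exposure has no objects."""
    targets = config.contact_seconds[group]
    baseline = rng.normal(0.0, config.animal_contact_sd_s)
    traces = []
    for trial in ("acquisition", "retention"):
        for role in ("familiar", "novel"):
            if trial == "acquisition":
                mean = targets["familiar"]  # both acquisition objects are new
            else:
                mean = targets[role]
            total = mean + baseline + rng.normal(0.0, config.contact_sd_s)
            total = float(np.clip(total, 5.0, config.trial_duration_s - 20.0))
            traces.append(
                gen_contact_trace(
                    total,
                    n_epochs=config.n_contact_epochs,
                    duration=config.trial_duration_s,
                    seed=rng,
                    object_role=role,
                    trial=trial,
                    animal_id=animal_id,
                )
            )
    return traces


def _gain_intervals(
    contacts: list[ContactTrace], trial: str, group_gain: float
) -> np.ndarray:
    """Intervals during which the novelty gain applies in ``trial``.

    Retention: novel-object contact only. Acquisition: both objects (both are
    novel). Pre-exposure: none.
    """
    if group_gain == 1.0 or trial == "pre_exposure":
        return np.empty((0, 2))
    ivs = [
        c.intervals
        for c in contacts
        if c.trial == trial and (trial == "acquisition" or c.object_role == "novel")
    ]
    if not ivs:
        return np.empty((0, 2))
    iv = np.concatenate(ivs)
    return iv[np.argsort(iv[:, 0])]


def gen_cohort(config: CohortConfig) -> tuple[list[Session], GroundTruth]:
    """Generate the full two-group cohort with ground truth.

    Deterministic given ``config.seed``. Within each animal, every NAc unit
    is assigned a parent mPFC unit from which a fraction of its spikes are
    copied (with jitter), producing elevated event synchronization and
    spike coherence in the saline group. Burst spikes and copied spikes are
    carved out of each unit's target rate so measured firing rates match the
    configured group targets.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    groups = ["saline"] * config.n_animals_per_group + ["pcp"] * config.n_animals_per_group
    animal_seeds = ss.spawn(len(groups))
    sessions: list[Session] = []
    gt = GroundTruth(
        novelty_gain=dict(config.novelty_gain),
        sync_prob=dict(config.sync_prob),
        config=config,
    )
    dur = config.trial_duration_s
    lo, hi = config.units_per_structure
    for k, (group, aseed) in enumerate(zip(groups, animal_seeds)):
        rng = np.random.default_rng(aseed)
        animal_id = f"{group}_{k % config.n_animals_per_group + 1:02d}"
        contacts = _animal_contacts(config, group, animal_id, rng)
        n_mpfc = int(rng.integers(lo, hi + 1))
        n_nac = int(rng.integers(lo, hi + 1))
        gain = config.novelty_gain[group]
        trains: list[SpikeTrain] = []

        # --- mPFC units
        mpfc_units: list[UnitGroundTruth] = []
        mpfc_trial_times: dict[tuple[str, str], np.ndarray] = {}
        for m in range(n_mpfc):
            unit_id = f"{animal_id}_mPFC_{m + 1}"
            rate = float(config.rate_mpfc_hz * _unit_rate_factor(rng, config.unit_rate_log_sd))
            n_bursts = int(round(config.bursts_per_trial["mPFC"][group]))
            burst_contrib = n_bursts * config.burst_len_spikes / dur
            bg_rate = max(0.05, rate - burst_contrib)
            ugt = UnitGroundTruth(unit_id, animal_id, "mPFC", rate)
            for trial in TRIALS:
                burst_spk, epochs = _burst_epoch_times(
                    n_bursts, config.burst_len_spikes,
                    rate * config.burst_rate_gain, dur, rng,
                )
                ivs = _gain_intervals(contacts, trial, gain)
                bg = _modulated_times(bg_rate, ivs, gain, dur, rng)
                times = np.unique(np.concatenate([bg, burst_spk]))
                mpfc_trial_times[(unit_id, trial)] = times
                ugt.burst_epochs[trial] = epochs
                trains.append(
                    SpikeTrain(unit_id, animal_id, group, "mPFC", trial, times, dur)
                )
            mpfc_units.append(ugt)

        # --- NAc units (each with a parent mPFC unit providing copied spikes)
        for m in range(n_nac):
            unit_id = f"{animal_id}_NAc_{m + 1}"
            rate = float(
                config.rate_nac_hz[group] * _unit_rate_factor(rng, config.unit_rate_log_sd)
            )
            parent = mpfc_units[int(rng.integers(0, n_mpfc))]
            copy_rate = config.sync_prob[group] * rate
            p_copy = min(1.0, copy_rate / parent.rate_hz)
            n_bursts = int(round(config.bursts_per_trial["NAc"][group]))
            burst_contrib = n_bursts * config.burst_len_spikes / dur
            bg_rate = max(0.05, rate - copy_rate - burst_contrib)
            ugt = UnitGroundTruth(
                unit_id, animal_id, "NAc", rate,
                parent_unit_id=parent.unit_id, copy_prob=config.sync_prob[group],
            )
            for trial in TRIALS:
                copies = _copy_with_jitter(
                    mpfc_trial_times[(parent.unit_id, trial)],
                    p_copy, config.sync_jitter_s, dur, rng,
                )
                burst_spk, epochs = _burst_epoch_times(
                    n_bursts, config.burst_len_spikes,
                    rate * config.burst_rate_gain, dur, rng,
                )
                ivs = _gain_intervals(contacts, trial, gain)
                bg = _modulated_times(bg_rate, ivs, gain, dur, rng)
                times = np.unique(np.concatenate([copies, bg, burst_spk]))
                ugt.burst_epochs[trial] = epochs
                trains.append(
                    SpikeTrain(unit_id, animal_id, group, "NAc", trial, times, dur)
                )
            gt.units.append(ugt)
        gt.units.extend(mpfc_units)

        sessions.append(
            Session(
                animal_id=animal_id,
                group=group,
                trains=trains,
                contacts=contacts,
                metadata={"seed": int(config.seed), "synthetic": True},
            )
        )
    return sessions, gt
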