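"""Session data model for cortico-striatal recordings during novel object recognition.

A *session* is one animal's recording across the three 3-minute trials of the
novel object recognition (NOR) task: pre-exposure (empty arena), acquisition
(two identical novel objects), and retention (one familiar copy, one novel
object). It holds per-trial single-unit spike trains from medial prefrontal
cortex (mPFC) and nucleus accumbens shell (NAc), plus manually scored
object-contact intervals.

Conventions
-----------
* Times are in seconds, trial-relative, zero at trial start, half-open
  ``[0, duration)``.
* Spike times within a unit are strictly increasing (duplicates are invalid);
  ties *across* units are allowed.
* On-disk format is one JSON file per animal-session (see
  ``docs/session_schema.md``); readers validate and never silently repair.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np

logger = logging.getLogger("cortistri")

GROUPS = ("saline", "pcp")
STRUCTURES = ("mPFC", "NAc")
TRIALS = ("pre_exposure", "acquisition", "retention")
OBJECT_ROLES = ("novel", "familiar")

#: Default trial duration of the NOR protocol, seconds.
TRIAL_DURATION_S = 180.0

#: Tolerance for round-trip equality of times, seconds.
TIME_ATOL_S = 1e-9


class ValidationError(ValueError):
    """An object violates a data-model invariant; message names the field."""


class UndefinedResultError(ValueError):
    """A metric is undefined for the given input (e.g. too few spikes)."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(eq=False)
class SpikeTrain:
    """One unit's spike times within one trial.

    Parameters
    ----------
    unit_id, animal_id : str
        Identifiers; ``unit_id`` is unique within the animal.
    group : {"saline", "pcp"}
        Drug pre-treatment group of the animal.
    structure : {"mPFC", "NAc"}
        Recorded structure.
    trial : {"pre_exposure", "acquisition", "retention"}
    times : array-like of float
        Strictly increasing spike times in seconds, all in ``[0, duration)``.
    duration : float
        Trial duration in seconds (default 180).
    """

    unit_id: str
    animal_id: str
    group: str
    structure: str
    trial: str
    times: np.ndarray
    duration: float = TRIAL_DURATION_S

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        _check(self.times.ndim == 1, f"times must be 1-D (unit {self.unit_id})")
        _check(self.group in GROUPS, f"group {self.group!r} not in {GROUPS}")
        _check(
            self.structure in STRUCTURES,
            f"structure {self.structure!r} not in {STRUCTURES}",
        )
        _check(self.trial in TRIALS, f"trial {self.trial!r} not in {TRIALS}")
        _check(self.duration > 0, f"duration must be > 0 (unit {self.unit_id})")
        if self.times.size:
            _check(
                bool(np.all(np.diff(self.times) > 0)),
                f"times must be strictly increasing (unit {self.unit_id})",
            )
            _check(
                self.times[0] >= 0.0 and self.times[-1] < self.duration,
                f"times must lie in [0, duration) (unit {self.unit_id})",
            )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def isis(self) -> np.ndarray:
        """Interspike intervals, seconds."""
        return np.diff(self.times)

    def replace(self, **kw: Any) -> "SpikeTrain":
        return dataclasses.replace(self, **kw)

    def equals(self, other: "SpikeTrain", atol: float = TIME_ATOL_S) -> bool:
        meta = all(
            getattr(self, f) == getattr(other, f)
            for f in ("unit_id", "animal_id", "group", "structure", "trial")
        )
        return (
            meta
            and abs(self.duration - other.duration) <= atol
            and self.times.size == other.times.size
            and bool(np.allclose(self.times, other.times, atol=atol, rtol=0.0))
        )


@dataclass(eq=False)
class ContactTrace:
    """Per-object exploration intervals within one trial.

    ``intervals`` is an (n, 2) array of half-open ``[start, end)`` second
    pairs, sorted and non-overlapping, all within ``[0, duration)``.
    """

    object_role: str
    trial: str
    intervals: np.ndarray
    duration: float = TRIAL_DURATION_S
    animal_id: str = ""

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float)
        if iv.size == 0:
            iv = iv.reshape(0, 2)
        self.intervals = iv
        _check(
            self.object_role in OBJECT_ROLES,
            f"object_role {self.object_role!r} not in {OBJECT_ROLES}",
        )
        _check(self.trial in TRIALS, f"trial {self.trial!r} not in {TRIALS}")
        _check(self.duration > 0, "duration must be > 0")
        _check(iv.ndim == 2 and iv.shape[1] == 2, "intervals must have shape (n, 2)")
        if iv.shape[0]:
            _check(bool(np.all(iv[:, 1] > iv[:, 0])), "interval end must exceed start")
            _check(
                iv[0, 0] >= 0.0 and iv[-1, 1] <= self.duration,
                "intervals must lie within [0, duration)",
            )
            if iv.shape[0] > 1:
                _check(
                    bool(np.all(iv[1:, 0] >= iv[:-1, 1])),
                    "intervals must be sorted and non-overlapping",
                )

    @property
    def total_seconds(self) -> float:
        """Summed exploration time, seconds."""
        if self.intervals.shape[0] == 0:
            return 0.0
        return float(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))

    def equals(self, other: "ContactTrace", atol: float = TIME_ATOL_S) -> bool:
        meta = (
            self.object_role == other.object_role
            and self.trial == other.trial
            and self.animal_id == other.animal_id
        )
        return (
            meta
            and abs(self.duration - other.duration) <= atol
            and self.intervals.shape == other.intervals.shape
            and bool(np.allclose(self.intervals, other.intervals, atol=atol, rtol=0.0))
        )


@dataclass(eq=False)
class WidebandSnippet:
    """A snippet of band-passed wideband voltage used for spike detection.

    samples : 1-D voltage array; rate : sampling rate (Hz, default 40 kHz);
    band : (low, high) cutoff of the applied band-pass, Hz.
    """

    samples: np.ndarray
    rate: float = 40_000.0
    band: tuple[float, float] = (300.0, 3000.0)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        _check(self.samples.ndim == 1, "samples must be 1-D")
        _check(self.samples.size >= 1, "snippet must contain at least one sample")
        _check(self.rate > 0, "rate must be > 0")


@dataclass(eq=False)
class Session:
    """One animal's recorded session: spike trains plus contact traces."""

    animal_id: str
    group: str
    trains: list[SpikeTrain] = field(default_factory=list)
    contacts: list[ContactTrace] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check(self.group in GROUPS, f"group {self.group!r} not in {GROUPS}")
        for tr in self.trains:
            _check(
                tr.animal_id == self.animal_id,
                f"train {tr.unit_id} animal_id {tr.animal_id!r} != session "
                f"{self.animal_id!r}",
            )
            _check(
                tr.group == self.group,
                f"train {tr.unit_id} group {tr.group!r} != session {self.group!r}",
            )
        # all trains/contacts in the same trial share a duration
        durs: dict[str, float] = {}
        for obj in (*self.trains, *self.contacts):
            d = durs.setdefault(obj.trial, obj.duration)
            _check(
                abs(d - obj.duration) <= TIME_ATOL_S,
                f"inconsistent durations in trial {obj.trial!r}",
            )

    def units(self, structure: str | None = None, trial: str | None = None) -> list[SpikeTrain]:
        out = self.trains
        if structure is not None:
            out = [t for t in out if t.structure == structure]
        if trial is not None:
            out = [t for t in out if t.trial == trial]
        return out

    def unit_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trains:
            seen.setdefault(t.unit_id)
        return list(seen)

    def has_pairable_units(self, trial: str) -> bool:
        """True if at least one unit per structure was recorded in ``trial``."""
        return bool(self.units("mPFC", trial)) and bool(self.units("NAc", trial))

    def equals(self, other: "Session", atol: float = TIME_ATOL_S) -> bool:
        if (
            self.animal_id != other.animal_id
            or self.group != other.group
            or len(self.trains) != len(other.trains)
            or len(self.contacts) != len(other.contacts)
            or self.metadata != other.metadata
        ):
            return False
        return all(a.equals(b, atol) for a, b in zip(self.trains, other.trains)) and all(
            a.equals(b, atol) for a, b in zip(self.contacts, other.contacts)
        )


# ---------------------------------------------------------------------------
# JSON session I/O


def session_to_dict(session: Session) -> dict[str, Any]:
    """Serialize a Session to the documented JSON schema."""
    durs: dict[str, float] = {}
    for obj in (*session.trains, *session.contacts):
        durs.setdefault(obj.trial, obj.duration)
    return {
        "animal_id": session.animal_id,
        "group": session.group,
        "trials": [
            {"name": t, "duration_s": durs.get(t, TRIAL_DURATION_S)} for t in TRIALS
        ],
        "units": [
            {
                "unit_id": t.unit_id,
                "structure": t.structure,
                "trial": t.trial,
                "times_s": t.times.tolist(),
            }
            for t in session.trains
        ],
        "contacts": [
            {
                "object_role": c.object_role,
                "trial": c.trial,
                "intervals_s": c.intervals.tolist(),
            }
            for c in session.contacts
        ],
        "metadata": session.metadata,
    }


def _require(d: Mapping[str, Any], key: str, ctx: str) -> Any:
    if key not in d:
        raise ValidationError(f"missing field {key!r} in {ctx}")
    return d[key]


def session_from_dict(doc: Mapping[str, Any]) -> Session:
    """Build and validate a Session from its JSON schema dict."""
    animal_id = _require(doc, "animal_id", "session")
    group = _require(doc, "group", "session")
    durs = {
        _require(t, "name", "trials"): float(_require(t, "duration_s", "trials"))
        for t in doc.get("trials", [])
    }
    trains = []
    for u in _require(doc, "units", "session"):
        trial = _require(u, "trial", "unit")
        trains.append(
            SpikeTrain(
                unit_id=str(_require(u, "unit_id", "unit")),
                animal_id=str(animal_id),
                group=str(group),
                structure=str(_require(u, "structure", "unit")),
                trial=str(trial),
                times=np.asarray(_require(u, "times_s", "unit"), dtype=float),
                duration=durs.get(trial, TRIAL_DURATION_S),
            )
        )
    contacts = []
    for c in doc.get("contacts", []):
        trial = _require(c, "trial", "contact")
        contacts.append(
            ContactTrace(
                object_role=str(_require(c, "object_role", "contact")),
                trial=str(trial),
                intervals=np.asarray(_require(c, "intervals_s", "contact"), dtype=float),
                duration=durs.get(trial, TRIAL_DURATION_S),
                animal_id=str(animal_id),
            )
        )
    return Session(
        animal_id=str(animal_id),
        group=str(group),
        trains=trains,
        contacts=contacts,
        metadata=dict(doc.get("metadata", {})),
    )


def read_session(path: str | Path) -> Session:
    """Read one animal-session JSON file; validates every invariant.

    Raises :class:`ValidationError` naming the offending field on schema
    violations; unsorted spike times are an error, never re-sorted.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"{path}: not valid JSON ({exc})") from exc
    return session_from_dict(doc)


def write_session(session: Session, path: str | Path) -> None:
    """Write a Session as JSON; ``read_session`` inverts it field-wise."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(session_to_dict(session), fh, indent=1)
        fh.write("\n")


def read_cohort_dir(directory: str | Path) -> list[Session]:
    """Read every ``*.json`` session in a directory, sorted by filename."""
    directory = Path(directory)
    sessions = [read_session(p) for p in sorted(directory.glob("*.json"))]
    if not sessions:
        raise ValidationError(f"no session files found in {directory}")
    return sessions


def write_cohort_dir(sessions: Iterable[Session], directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in sessions:
        p = directory / f"{s.animal_id}.json"
        write_session(s, p)
        paths.append(p)
    return paths
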