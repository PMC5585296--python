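"""Firing-rate / object-contact cross-correlation.

Aligns 100-ms firing-rate histograms to binary object-contact traces (1
during exploration, 0 otherwise) and computes lagged correlation-coefficient
curves per unit, then group mean +/- SEM curves per structure, drug group and
object role. A positive coefficient means firing is elevated during
exploration relative to no exploration; the zero lag is the center of the
cross-correlogram. In the acquisition trial both objects are novel, so each
unit's two object curves are averaged before group statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .session_model import (
    ContactTrace,
    Session,
    SpikeTrain,
    UndefinedResultError,
    ValidationError,
)

logger = logging.getLogger("cortistri")

__all__ = [
    "RateHistogram",
    "XCorrResult",
    "ExplorationSummary",
    "rate_histogram",
    "contact_vector",
    "xcorr_rate_contact",
    "group_xcorr",
    "exploration_summary",
]


@dataclass
class RateHistogram:
    """Binned firing rate of one unit in one trial, Hz per bin."""

    unit_id: str
    structure: str
    group: str
    trial: str
    bin_s: float
    rates: np.ndarray  # Hz; counts / bin_s in half-open bins


@dataclass
class XCorrResult:
    """Group mean +/- SEM cross-correlation curve for one cell of the design."""

    structure: str
    group: str
    trial: str
    object_role: str
    lags_s: np.ndarray  # symmetric around 0, 0 at the center
    mean: np.ndarray
    sem: np.ndarray
    n_units: int


@dataclass
class ExplorationSummary:
    animal_id: str
    trial: str
    object_role: str
    total_seconds: float


def rate_histogram(train: SpikeTrain, bin_s: float = 0.1) -> RateHistogram:
    """Spike counts in half-open ``[k*bin_s, (k+1)*bin_s)`` bins, scaled to Hz."""
    if bin_s <= 0:
        raise ValidationError("bin_s must be > 0")
    n_bins = int(np.ceil(train.duration / bin_s))
    edges = np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(train.times, bins=edges)
    return RateHistogram(
        unit_id=train.unit_id,
        structure=train.structure,
        group=train.group,
        trial=train.trial,
        bin_s=bin_s,
        rates=counts / bin_s,
    )


def contact_vector(trace: ContactTrace, bin_s: float = 0.1) -> np.ndarray:
    """Binary contact series on the rate-histogram grid.

    A bin is 1 if its midpoint lies inside any contact interval.
    """
    if bin_s <= 0:
        raise ValidationError("bin_s must be > 0")
    n_bins = int(np.ceil(trace.duration / bin_s))
    mids = (np.arange(n_bins) + 0.5) * bin_s
    iv = trace.intervals
    if iv.shape[0] == 0:
        return np.zeros(n_bins)
    idx = np.searchsorted(iv[:, 0], mids, side="right") - 1
    ok = idx >= 0
    out = np.zeros(n_bins)
    out[ok] = (mids[ok] < iv[idx[ok], 1]).astype(float)
    return out


def xcorr_rate_contact(
    hist: RateHistogram | np.ndarray,
    contact: np.ndarray,
    max_lag_s: float = 5.0,
    bin_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Lagged correlation coefficients between a rate series and a contact series.

    At lag ``l`` (seconds, positive = rate follows contact onset) the value
    is the Pearson correlation of the overlapping region of the two series
    with the contact series shifted by ``l`` bins. Returns ``(lags_s, r)``
    with the zero lag at the center. Raises
    :class:`UndefinedResultError` if either full series has zero variance;
    individual lags whose overlap is degenerate yield NaN.
    """
    if isinstance(hist, RateHistogram):
        rates = hist.rates
        bin_s = hist.bin_s
    else:
        rates = np.asarray(hist, dtype=float)
        if bin_s is None:
            raise ValidationError("bin_s required when passing a bare array")
    contact = np.asarray(contact, dtype=float)
    if rates.size != contact.size:
        raise ValidationError("rate and contact series must have equal length")
    if np.std(rates) == 0 or np.std(contact) == 0:
        raise UndefinedResultError("zero-variance series: correlation undefined")
    max_lag = int(round(max_lag_s / bin_s))
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.full(lags.size, np.nan)
    n = rates.size
    for k, lag in enumerate(lags):
        if lag >= 0:
            a, b = rates[lag:], contact[: n - lag]
        else:
            a, b = rates[: n + lag], contact[-lag:]
        if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
            continue
        r[k] = float(np.corrcoef(a, b)[0, 1])
    return lags * bin_s, r


@dataclass
class UnitXCorr:
    """Per-unit cross-correlation curve, input record for group_xcorr."""

    unit_id: str
    structure: str
    group: str
    trial: str
    object_role: str
    lags_s: np.ndarray
    r: np.ndarray


def group_xcorr(curves: list[UnitXCorr]) -> list[XCorrResult]:
    """Per-lag mean and SEM across units, per structure x group x object role.

    In the acquisition trial both objects are novel; each unit's two object
    curves are first averaged and reported under object_role ``"novel"``.
    Cells with fewer than 2 units are omitted with a warning.
    """
    if not curves:
        return []
    lags = curves[0].lags_s

    # acquisition: average the two object curves within each unit
    merged: list[UnitXCorr] = []
    acq: dict[str, list[UnitXCorr]] = {}
    for c in curves:
        if c.trial == "acquisition":
            acq.setdefault(c.unit_id, []).append(c)
        else:
            merged.append(c)
    for unit_id, cs in acq.items():
        r = np.nanmean(np.vstack([c.r for c in cs]), axis=0)
        c0 = cs[0]
        merged.append(
            UnitXCorr(unit_id, c0.structure, c0.group, "acquisition", "novel", c0.lags_s, r)
        )

    cells: dict[tuple[str, str, str, str], list[UnitXCorr]] = {}
    for c in merged:
        cells.setdefault((c.structure, c.group, c.trial, c.object_role), []).append(c)
    out: list[XCorrResult] = []
    for (structure, group, trial, role), cs in sorted(cells.items()):
        if len(cs) < 2:
            logger.warning(
                "group_xcorr: cell %s/%s/%s/%s has %d unit(s); omitted",
                structure, group, trial, role, len(cs),
            )
            continue
        mat = np.vstack([c.r for c in cs])
        mean = np.nanmean(mat, axis=0)
        n_eff = np.sum(~np.isnan(mat), axis=0)
        sem = np.nanstd(mat, axis=0, ddof=1) / np.sqrt(np.maximum(n_eff, 1))
        out.append(
            XCorrResult(structure, group, trial, role, lags, mean, sem, len(cs))
        )
    return out


def unit_xcorr_curves(
    session: Session, bin_s: float = 0.1, max_lag_s: float = 5.0
) -> list[UnitXCorr]:
    """All per-unit curves of one session (every unit x trial x object)."""
    out: list[UnitXCorr] = []
    for contact in session.contacts:
        cvec = contact_vector(contact, bin_s)
        if not cvec.any():
            continue
        for train in session.units(trial=contact.trial):
            hist = rate_histogram(train, bin_s)
            try:
                lags, r = xcorr_rate_contact(hist, cvec, max_lag_s)
            except UndefinedResultError:
                logger.warning(
                    "xcorr undefined for unit %s in %s; skipped",
                    train.unit_id, contact.trial,
                )
                continue
            out.append(
                UnitXCorr(
                    train.unit_id, train.structure, train.group,
                    contact.trial, contact.object_role, lags, r,
                )
            )
    return out


def exploration_summary(
    contacts: list[ContactTrace], animal_id: str | None = None
) -> list[ExplorationSummary]:
    """Total exploration seconds per trial and object role."""
    return [
        ExplorationSummary(
            animal_id=animal_id if animal_id is not None else c.animal_id,
            trial=c.trial,
            object_role=c.object_role,
            total_seconds=c.total_seconds,
        )
        for c in contacts
    ]
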