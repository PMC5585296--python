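"""Pairwise mPFC-NAc synchrony measures.

Two independent measures are provided, mirroring the dual approach of the
analysis this package implements:

1. **Event synchronization** — a model-free coincidence count with a locally
   adaptive coincidence window. For spikes ``t^x_i`` and ``t^y_j`` the window
   is half the minimum of the (up to four) adjacent interspike intervals,

       tau_ij = min{ t^x_{i+1}-t^x_i, t^x_i-t^x_{i-1},
                     t^y_{j+1}-t^y_j, t^y_j-t^y_{j-1} } / 2,

   so the window shrinks automatically where either train fires fast. With
   c(x|y) the number of times an x spike follows a y spike within tau
   (exact ties count 1/2), the index is

       Q = (c(x|y) + c(y|x)) / sqrt(m_x * m_y),

   ranging from 0 (no coincidences) to 1 (identical trains).
2. **Spike coherence** — magnitude-squared coherence of the 1-ms binned
   trains from segment-averaged periodograms, with a pair-level bootstrap
   band for group comparison.

A 50% random spike-downsampling control is included to verify that group
differences in Q are not rate artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .session_model import SpikeTrain, UndefinedResultError, ValidationError

logger = logging.getLogger("cortistri")

__all__ = [
    "SyncResult",
    "PairCoherence",
    "CoherenceResult",
    "local_tau",
    "event_synchronization",
    "subsample_spikes",
    "spike_coherence",
    "group_coherence",
]


# ---------------------------------------------------------------------------
# Event synchronization


def _adjacent_min_isi(t: np.ndarray) -> np.ndarray:
    """Per spike, the smaller adjacent ISI (one-sided at the boundaries)."""
    isis = np.diff(t)
    left = np.concatenate(([np.inf], isis))
    right = np.concatenate((isis, [np.inf]))
    return np.minimum(left, right)


def local_tau(x: SpikeTrain, y: SpikeTrain, i: int, j: int) -> float:
    """Locally adaptive coincidence half-window for spikes ``x[i]``, ``y[j]``.

    Half the minimum over the up-to-four adjacent ISIs; at the first/last
    spike of a train the missing ISI is simply omitted from the minimum.
    """
    if x.n_spikes < 2 or y.n_spikes < 2:
        raise ValidationError("local_tau requires >= 2 spikes in both trains")
    ax = _adjacent_min_isi(x.times)[i]
    ay = _adjacent_min_isi(y.times)[j]
    return float(min(ax, ay) / 2.0)


@dataclass
class SyncResult:
    """Event-synchronization result for one mPFC-NAc pair in one trial."""

    pair_id: tuple[str, str]
    trial: str
    Q: float
    #: event times of coincidences and the running normalized count
    #: (non-decreasing, ends at Q)
    curve_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    curve_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    #: median coincidence window over the coincident spike pairs, seconds
    median_tau: float = float("nan")


def event_synchronization(
    x: SpikeTrain, y: SpikeTrain, max_tau: float | None = None
) -> SyncResult:
    """Event-synchronization index Q with its cumulative coincidence curve.

    ``max_tau`` optionally caps the adaptive window (no cap by default).
    Raises :class:`UndefinedResultError` for trains with < 2 spikes.
    """
    tx, ty = x.times, y.times
    if tx.size < 2 or ty.size < 2:
        raise UndefinedResultError(
            f"event synchronization undefined for pair ({x.unit_id}, {y.unit_id}): "
            "both trains need >= 2 spikes"
        )
    tau = np.minimum.outer(_adjacent_min_isi(tx), _adjacent_min_isi(ty)) / 2.0
    if max_tau is not None:
        tau = np.minimum(tau, max_tau)
    d = tx[:, None] - ty[None, :]
    hits_xy = (d > 0) & (d <= tau)  # x spike follows y spike
    hits_yx = (d < 0) & (-d <= tau)  # y spike follows x spike
    ties = d == 0.0
    norm = float(np.sqrt(tx.size * ty.size))
    c_xy = hits_xy.sum() + 0.5 * ties.sum()
    c_yx = hits_yx.sum() + 0.5 * ties.sum()
    q = float((c_xy + c_yx) / norm)

    # cumulative curve: each coincidence lands at the later spike's time
    ev_t = np.concatenate(
        [
            np.broadcast_to(tx[:, None], d.shape)[hits_xy],
            np.broadcast_to(ty[None, :], d.shape)[hits_yx],
            np.broadcast_to(tx[:, None], d.shape)[ties],
        ]
    )
    ev_w = np.concatenate(
        [
            np.ones(int(hits_xy.sum())),
            np.ones(int(hits_yx.sum())),
            np.ones(int(ties.sum())),
        ]
    )
    order = np.argsort(ev_t, kind="stable")
    curve_t = ev_t[order]
    curve_v = np.cumsum(ev_w[order]) / norm
    coincident = hits_xy | hits_yx | ties
    med_tau = float(np.median(tau[coincident])) if coincident.any() else float("nan")
    return SyncResult(
        pair_id=(x.unit_id, y.unit_id),
        trial=x.trial,
        Q=q,
        curve_times=curve_t,
        curve_values=curve_v,
        median_tau=med_tau,
    )


def subsample_spikes(
    train: SpikeTrain, fraction: float = 0.5, seed: int | np.random.Generator = 0
) -> SpikeTrain:
    """Uniform random subset of ``round(fraction * m)`` spikes, order kept.

    The rate-matching control: recomputing Q on 50%-downsampled saline
    trains checks that synchrony differences are not driven by firing rate.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValidationError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return train
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = train.n_spikes
    k = int(round(fraction * m))
    idx = np.sort(rng.choice(m, size=k, replace=False))
    return train.replace(times=train.times[idx])


# ---------------------------------------------------------------------------
# Spike coherence


@dataclass
class PairCoherence:
    """Magnitude-squared coherence spectrum for one pair."""

    pair_id: tuple[str, str]
    trial: str
    frequencies: np.ndarray
    coherence: np.ndarray


@dataclass
class CoherenceResult:
    """Group-mean coherence with a 95% pair-bootstrap percentile band."""

    frequencies: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_pairs: int = 0


def _bin_train(train: SpikeTrain, bin_s: float) -> np.ndarray:
    n_bins = int(np.ceil(train.duration / bin_s))
    edges = np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(train.times, bins=edges)
    return counts.astype(float)


def spike_coherence(
    x: SpikeTrain,
    y: SpikeTrain,
    bin_s: float = 0.001,
    segment_len: int = 1024,
) -> PairCoherence:
    """Segment-averaged spike-spike coherence.

    Both trains are binned to counts at ``bin_s`` resolution; periodograms of
    non-overlapping rectangular-window segments of ``segment_len`` bins are
    averaged into auto- and cross-spectra, and coherence is
    |f_xy|^2 / (f_xx * f_yy) on the segment frequency grid. The trial must
    be long enough for at least 8 segments; for independent trains the
    expected coherence floor is ~1/L with L segments.
    """
    if x.n_spikes == 0 or y.n_spikes == 0:
        raise UndefinedResultError(
            f"coherence undefined for pair ({x.unit_id}, {y.unit_id}): empty train"
        )
    bx, by = _bin_train(x, bin_s), _bin_train(y, bin_s)
    n = min(bx.size, by.size)
    if n < 8 * segment_len:
        raise ValidationError(
            f"trial too short for >= 8 segments of {segment_len} bins"
        )
    f, coh = signal.coherence(
        bx[:n],
        by[:n],
        fs=1.0 / bin_s,
        window="boxcar",
        nperseg=segment_len,
        noverlap=0,
        detrend="constant",
    )
    # drop DC (mean-removed segments make it degenerate)
    return PairCoherence(
        pair_id=(x.unit_id, y.unit_id),
        trial=x.trial,
        frequencies=f[1:],
        coherence=np.clip(coh[1:], 0.0, 1.0),
    )


def group_coherence(
    pairs: list[PairCoherence],
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
) -> CoherenceResult:
    """Mean coherence across pairs with a 95% bootstrap percentile band.

    The resampling unit is the pair (with replacement). Fewer than 100
    bootstrap replicates is allowed but logged as a warning.
    """
    if len(pairs) < 2:
        raise ValidationError("group_coherence requires >= 2 pairs")
    if n_boot < 100:
        logger.warning("group_coherence: n_boot=%d < 100; band will be noisy", n_boot)
    freqs = pairs[0].frequencies
    for p in pairs[1:]:
        if p.frequencies.shape != freqs.shape or not np.allclose(p.frequencies, freqs):
            raise ValidationError("all pairs must share one frequency grid")
    mat = np.vstack([p.coherence for p in pairs])
    mean = mat.mean(axis=0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, len(pairs), size=(n_boot, len(pairs)))
    boots = mat[idx].mean(axis=1)  # (n_boot, n_freq)
    lower = np.percentile(boots, 2.5, axis=0)
    upper = np.percentile(boots, 97.5, axis=0)
    # the percentile band brackets the bootstrap distribution; clip so the
    # reported band always contains the point estimate
    lower = np.minimum(lower, mean)
    upper = np.maximum(upper, mean)
    return CoherenceResult(
        frequencies=freqs, mean=mean, lower=lower, upper=upper, n_pairs=len(pairs)
    )
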