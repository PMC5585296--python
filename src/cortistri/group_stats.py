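"""Group-level inferential statistics for the pipeline.

Implements the study's statistical toolkit:

* Wilcoxon signed-rank with the normal approximation (midranks, tie-corrected
  variance, **no** continuity correction) and the effect size r = Z/sqrt(2n)
  with n pairs (two observations per pair) — the convention that yields
  Z = 2.201, r = 0.64 for six same-sign differences.
* A bootstrap (BCa by default, percentile optional) confidence interval for
  the between-group difference of the within-group medians of paired
  novel-familiar differences, resampling animals with replacement.
* One-way ANOVA (delegated to scipy) for unit-level group comparisons.
* Mixed (split-plot) ANOVA with one between-subject factor and one or two
  within-subject factors, with Fisher-LSD follow-up comparisons; used for
  the per-animal structure x drug-group analysis and the behavior-category
  (sniff/touch/approach x object x drug) analysis. Sums of squares use the
  standard split-plot decomposition; for unequal group sizes this is the
  weighted-means analysis (within factors are complete per subject, so the
  strata stay orthogonal).
* A Shapiro-Wilk normality screen used as the gate before choosing
  nonparametric tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .session_model import UndefinedResultError, ValidationError

__all__ = [
    "WilcoxonReport",
    "BootstrapCI",
    "AnovaEffect",
    "PairwiseComparison",
    "AnovaReport",
    "wilcoxon_signed_rank",
    "bootstrap_median_diff",
    "oneway_anova",
    "mixed_anova",
    "behavior_category_anova",
    "normality_screen",
]


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


@dataclass
class WilcoxonReport:
    n_pairs: int  # pairs remaining after dropping zero differences
    W: float  # sum of positive ranks
    Z: float
    p: float  # two-sided, normal approximation
    r: float  # effect size Z / sqrt(2 n)

    def to_dict(self) -> dict[str, Any]:
        return {"n_pairs": self.n_pairs, "W": self.W, "Z": self.Z, "p": self.p, "r": self.r}


def wilcoxon_signed_rank(diffs: Sequence[float] | np.ndarray) -> WilcoxonReport:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (classic treatment); |differences| are
    midranked; W is the sum of ranks of positive differences;
    Z = (W - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24 - tie correction) with no
    continuity correction; p is the two-sided normal tail. The effect size
    is r = Z / sqrt(2n), counting two observations per pair.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise UndefinedResultError("all differences are zero: test degenerate")
    if n < 2:
        raise ValidationError("need >= 2 nonzero differences")
    ranks = stats.rankdata(np.abs(d))
    w = float(np.sum(ranks[d > 0]))
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var -= float(np.sum(counts**3 - counts)) / 48.0
    if var <= 0:
        raise UndefinedResultError("zero variance after tie correction")
    z = (w - mu) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    r = z / math.sqrt(2 * n)
    return WilcoxonReport(n_pairs=n, W=w, Z=float(z), p=float(min(p, 1.0)), r=float(r))


# ---------------------------------------------------------------------------
# Bootstrap of the difference of group medians


@dataclass
class BootstrapCI:
    estimate: float
    lower: float
    upper: float
    n_boot: int
    method: str

    def to_dict(self) -> dict[str, Any]:
        return {
            "estimate": self.estimate,
            "lower": self.lower,
            "upper": self.upper,
            "n_boot": self.n_boot,
            "method": self.method,
        }


def bootstrap_median_diff(
    saline_pairs: Sequence[float] | np.ndarray,
    pcp_pairs: Sequence[float] | np.ndarray,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    method: str = "bca",
) -> BootstrapCI:
    """95% CI for median(saline diffs) - median(pcp diffs), animal resampling.

    ``*_pairs`` are per-animal paired differences (novel - familiar
    exploration seconds). Each bootstrap replicate resamples animals with
    replacement within each group, recomputes the two medians, and takes
    saline minus PCP. ``method`` is ``"bca"`` (bias-corrected and
    accelerated; the default of the tool the analysis mirrors) or
    ``"percentile"``.
    """
    s = np.asarray(saline_pairs, dtype=float)
    p = np.asarray(pcp_pairs, dtype=float)
    if s.size < 2 or p.size < 2:
        raise ValidationError("need >= 2 animals per group for resampling")
    if method not in ("bca", "percentile"):
        raise ValidationError(f"unknown method {method!r}")
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    point = float(np.median(s) - np.median(p))
    reps = np.median(
        s[rng.integers(0, s.size, size=(n_boot, s.size))], axis=1
    ) - np.median(p[rng.integers(0, p.size, size=(n_boot, p.size))], axis=1)

    if np.ptp(reps) == 0.0:
        return BootstrapCI(point, float(reps[0]), float(reps[0]), n_boot, method)

    if method == "percentile":
        lo, hi = np.percentile(reps, [2.5, 97.5])
        return BootstrapCI(point, float(lo), float(hi), n_boot, method)

    # BCa: bias correction from the replicate distribution, acceleration
    # from a leave-one-animal-out jackknife over both groups.
    prop = (np.sum(reps < point) + 0.5 * np.sum(reps == point)) / n_boot
    prop = min(max(prop, 1.0 / (n_boot + 1)), n_boot / (n_boot + 1.0))
    z0 = stats.norm.ppf(prop)
    jack = [
        float(np.median(np.delete(s, i)) - np.median(p)) for i in range(s.size)
    ] + [float(np.median(s) - np.median(np.delete(p, i))) for i in range(p.size)]
    jack = np.asarray(jack)
    dev = jack.mean() - jack
    denom = 6.0 * float(np.sum(dev**2)) ** 1.5
    a = float(np.sum(dev**3)) / denom if denom > 0 else 0.0
    z = stats.norm.ppf([0.025, 0.975])
    adj = z0 + (z0 + z) / (1.0 - a * (z0 + z))
    alphas = stats.norm.cdf(adj)
    lo, hi = np.quantile(reps, alphas)
    return BootstrapCI(point, float(lo), float(hi), n_boot, "bca")


# ---------------------------------------------------------------------------
# ANOVA reports


@dataclass
class AnovaEffect:
    term: str
    df1: int
    df2: int
    F: float
    p: float

    def to_dict(self) -> dict[str, Any]:
        return {"term": self.term, "df1": self.df1, "df2": self.df2, "F": self.F, "p": self.p}


@dataclass
class PairwiseComparison:
    description: str
    estimate: float
    t: float
    df: float
    p: float

    def to_dict(self) -> dict[str, Any]:
        return {
            "description": self.description,
            "estimate": self.estimate,
            "t": self.t,
            "df": self.df,
            "p": self.p,
        }


@dataclass
class AnovaReport:
    effects: list[AnovaEffect] = field(default_factory=list)
    posthoc: list[PairwiseComparison] = field(default_factory=list)

    def effect(self, term: str) -> AnovaEffect:
        for e in self.effects:
            if e.term == term:
                return e
        raise KeyError(term)

    def to_dict(self) -> dict[str, Any]:
        return {
            "effects": [e.to_dict() for e in self.effects],
            "posthoc": [c.to_dict() for c in self.posthoc],
        }


def _safe_f(ss_eff: float, df1: int, ss_err: float, df2: int) -> tuple[float, float]:
    """F and p; a zero-SS effect is F = 0 even with zero error variance."""
    ss_eff = max(ss_eff, 0.0)
    ss_err = max(ss_err, 0.0)
    if df1 <= 0 or df2 <= 0:
        return float("nan"), float("nan")
    if ss_eff <= 1e-12 * max(1.0, ss_err):
        return 0.0, 1.0
    if ss_err <= 0.0:
        return float("inf"), 0.0
    f = (ss_eff / df1) / (ss_err / df2)
    return float(f), float(stats.f.sf(f, df1, df2))


def oneway_anova(
    values: Sequence[float] | np.ndarray, groups: Sequence[str]
) -> AnovaReport:
    """Standard between-groups one-way ANOVA, df (k-1, N-k)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = [str(g) for g in pd.unique(groups)]
    arrays = [values[groups == g] for g in levels]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValidationError("need >= 2 groups with >= 2 values each")
    k, n = len(arrays), values.size
    gm = values.mean()
    ss_b = sum(a.size * (a.mean() - gm) ** 2 for a in arrays)
    ss_w = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    f, p = _safe_f(ss_b, k - 1, ss_w, n - k)
    return AnovaReport(effects=[AnovaEffect("group", k - 1, n - k, f, p)])


# ---------------------------------------------------------------------------
# Split-plot (mixed) ANOVA, one between factor, one or two within factors


def _check_complete(df: pd.DataFrame, subject: str, within: list[str]) -> None:
    cells = df.groupby(subject, observed=True)[within].apply(
        lambda g: len(g.drop_duplicates())
    )
    expected = int(np.prod([df[w].nunique() for w in within]))
    sizes = df.groupby(subject, observed=True).size()
    for subj in sizes.index:
        if sizes[subj] != expected or cells[subj] != expected:
            raise ValidationError(
                f"subject {subj!r} is missing within-factor cells "
                f"(has {sizes[subj]} rows, design needs {expected})"
            )


def _ss_of_means(df: pd.DataFrame, dv: str, by: list[str], gm: float) -> float:
    """Sum over cells of n_cell * (cell mean - grand mean)^2."""
    g = df.groupby(by, observed=True)[dv]
    return float((g.count() * (g.mean() - gm) ** 2).sum())


def _splitplot(
    df: pd.DataFrame,
    dv: str,
    subject: str,
    between: str,
    within: list[str],
) -> AnovaReport:
    df = df.copy()
    _check_complete(df, subject, within)
    # one group per subject
    gmap = df.groupby(subject, observed=True)[between].nunique()
    if (gmap > 1).any():
        bad = gmap[gmap > 1].index[0]
        raise ValidationError(f"subject {bad!r} appears in more than one group")
    n_subj = df[subject].nunique()
    k = df[between].nunique()  # k == 1 degenerates to a fully-within design
    m = {w: df[w].nunique() for w in within}
    y = df[dv].to_numpy(dtype=float)
    gm = float(y.mean())
    ss_total = float(np.sum((y - gm) ** 2))

    ss = {}
    ss["__bs"] = _ss_of_means(df, dv, [subject], gm)
    ss[between] = _ss_of_means(df, dv, [between], gm)
    ss["__subj(group)"] = ss["__bs"] - ss[between]
    df_subj = n_subj - k

    effects: list[AnovaEffect] = []
    if k >= 2:
        f, p = _safe_f(ss[between], k - 1, ss["__subj(group)"], df_subj)
        effects.append(AnovaEffect(between, k - 1, df_subj, f, p))

    err_ss_used = 0.0
    for w in within:
        ss[w] = _ss_of_means(df, dv, [w], gm)
        ss_gw = _ss_of_means(df, dv, [between, w], gm) - ss[between] - ss[w]
        ss[f"{between}*{w}"] = ss_gw
        ss_sw = _ss_of_means(df, dv, [subject, w], gm) - ss["__bs"] - ss[w] - ss_gw
        df_err = (m[w] - 1) * df_subj
        err_ss_used += ss_sw
        f, p = _safe_f(ss[w], m[w] - 1, ss_sw, df_err)
        effects.append(AnovaEffect(w, m[w] - 1, df_err, f, p))
        if k >= 2:
            f, p = _safe_f(ss_gw, (k - 1) * (m[w] - 1), ss_sw, df_err)
            effects.append(
                AnovaEffect(f"{between}*{w}", (k - 1) * (m[w] - 1), df_err, f, p)
            )
        ss[f"__err({w})"] = ss_sw

    if len(within) == 2:
        w1, w2 = within
        ss_ww = _ss_of_means(df, dv, [w1, w2], gm) - ss[w1] - ss[w2]
        ss_gww = (
            _ss_of_means(df, dv, [between, w1, w2], gm)
            - ss[between] - ss[w1] - ss[w2]
            - ss[f"{between}*{w1}"] - ss[f"{between}*{w2}"] - ss_ww
        )
        used = (
            ss["__bs"]
            + ss[w1] + ss[w2] + ss[f"{between}*{w1}"] + ss[f"{between}*{w2}"]
            + ss["__err(" + w1 + ")"] + ss["__err(" + w2 + ")"]
            + ss_ww + ss_gww
        )
        ss_err_ww = ss_total - used
        df_err = (m[w1] - 1) * (m[w2] - 1) * df_subj
        f, p = _safe_f(ss_ww, (m[w1] - 1) * (m[w2] - 1), ss_err_ww, df_err)
        effects.append(AnovaEffect(f"{w1}*{w2}", (m[w1] - 1) * (m[w2] - 1), df_err, f, p))
        if k >= 2:
            df1 = (k - 1) * (m[w1] - 1) * (m[w2] - 1)
            f, p = _safe_f(ss_gww, df1, ss_err_ww, df_err)
            effects.append(AnovaEffect(f"{between}*{w1}*{w2}", df1, df_err, f, p))

    return AnovaReport(effects=effects)


def _lsd_posthoc(
    df: pd.DataFrame,
    dv: str,
    subject: str,
    between: str,
    within: str,
    report: AnovaReport,
) -> list[PairwiseComparison]:
    """Fisher-LSD group comparisons at each within level.

    Between-group contrasts at a fixed within level mix both error strata;
    the pooled error (Winer) is (MS_subj(group) + (m-1) MS_within_err) / m
    with Satterthwaite df.
    """
    n_subj = df[subject].nunique()
    k = df[between].nunique()
    m = df[within].nunique()
    df_subj = n_subj - k
    df_w = (m - 1) * df_subj
    # recover the stratum MSs from the report's F denominators is fragile;
    # recompute directly
    gm = float(df[dv].mean())
    ss_bs = _ss_of_means(df, dv, [subject], gm)
    ss_g = _ss_of_means(df, dv, [between], gm)
    ms_subj = (ss_bs - ss_g) / df_subj if df_subj > 0 else float("nan")
    ss_w = _ss_of_means(df, dv, [within], gm)
    ss_gw = _ss_of_means(df, dv, [between, within], gm) - ss_g - ss_w
    ss_sw = _ss_of_means(df, dv, [subject, within], gm) - ss_bs - ss_w - ss_gw
    ms_werr = ss_sw / df_w if df_w > 0 else float("nan")

    ms_pool = (ms_subj + (m - 1) * ms_werr) / m
    num = ms_pool**2
    den = (ms_subj / m) ** 2 / df_subj + ((m - 1) * ms_werr / m) ** 2 / df_w
    df_sat = num / den if den > 0 else df_subj

    out: list[PairwiseComparison] = []
    levels_b = list(pd.unique(df[between]))
    sizes = df.groupby(between, observed=True)[subject].nunique()
    for w in pd.unique(df[within]):
        sub = df[df[within] == w]
        means = sub.groupby(between, observed=True)[dv].mean()
        for i in range(len(levels_b)):
            for j in range(i + 1, len(levels_b)):
                g1, g2 = levels_b[i], levels_b[j]
                est = float(means[g1] - means[g2])
                se = math.sqrt(ms_pool * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
                t = est / se if se > 0 else (0.0 if est == 0 else math.inf)
                p = 2.0 * stats.t.sf(abs(t), df_sat) if math.isfinite(t) else 0.0
                out.append(
                    PairwiseComparison(
                        f"{g1} vs {g2} at {within}={w}", est, float(t), float(df_sat), float(p)
                    )
                )
    return out


def mixed_anova(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "animal",
    between: str = "group",
    within: str = "structure",
    posthoc: bool = True,
) -> AnovaReport:
    """Split-plot ANOVA: one between-subject and one within-subject factor.

    ``table`` is long-format with one row per subject x within level (e.g.
    per-animal mean firing rates in mPFC and NAc). Each subject must
    contribute every within level; a missing cell is an error naming the
    subject. With two-level within factors no sphericity correction is
    needed. Fisher-LSD group comparisons at each within level are appended
    when ``posthoc``.
    """
    report = _splitplot(table, dv, subject, between, [within])
    if posthoc:
        report.posthoc = _lsd_posthoc(table, dv, subject, between, within, report)
    return report


def behavior_category_anova(
    table: pd.DataFrame,
    dv: str = "seconds",
    subject: str = "animal",
    between: str = "group",
    within: tuple[str, str] = ("behavior", "object"),
) -> AnovaReport:
    """Three-way mixed ANOVA: behavior type x object role (within) x group.

    Used for the sniffing/touching/approaching x familiar/novel x drug
    analysis of how animals interact with the objects. The table must be
    complete: every subject x behavior x object cell present exactly once.
    """
    return _splitplot(table, dv, subject, between, list(within))


# ---------------------------------------------------------------------------
# Normality screen


def normality_screen(values: Sequence[float] | np.ndarray, alpha: float = 0.05) -> dict[str, Any]:
    """Shapiro-Wilk gate: decides parametric vs rank-based comparison."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValidationError("Shapiro-Wilk needs >= 3 values")
    w, p = stats.shapiro(values)
    return {"W": float(w), "p": float(p), "normal": bool(p >= alpha)}
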