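# Methods

This note documents the models, defaults, and numerical choices behind
`cortistri`: what each stage computes, what the synthetic cohort emulates
(and what it does not), and where the design was genuinely open.

## Data model

A session is one animal's recording across the three 3-minute NOR trials
(`pre_exposure`, `acquisition`, `retention`). Times are in seconds,
trial-relative, half-open `[0, duration)`. Spike times within a unit must
be strictly increasing (duplicate times within a unit are invalid; ties
across units are allowed). Sessions are stored one JSON file per animal
(schema in `session_schema.md`); readers validate every invariant and never
silently repair, so an unsorted train is an error rather than a re-sort.

## Single-unit metrics

* **Firing rate** — spike count / trial duration (Hz). The pipeline
  excludes units whose *pre-exposure* rate is ≥ 6 Hz (the analysis targets
  low-rate putative medium spiny neurons in NAc and regular-spiking mPFC
  cells); the baseline trial for this gate is a design choice, since
  "baseline" could also mean the session mean. A unit with no pre-exposure
  train is judged on its first available trial.
* **CV2** — mean of `2|ISI_{i+1} − ISI_i| / (ISI_{i+1} + ISI_i)`; 0 for a
  clock-regular train, expectation 1 for a Poisson process, < 2 always.
  Undefined (an explicit error, never silently 0) below 3 spikes.
* **Spike detection** (wideband stage) — zero-phase 4th-order Butterworth
  band-pass 300–3000 Hz; noise SD estimated as `median(|x|)/0.6745` (the
  MAD of a zero-mean Gaussian), which is insensitive to the spikes
  themselves; threshold at 5σ, negative-going (extracellular convention),
  events aligned to the trough with a 1-ms censoring window. Polarity,
  alignment and censoring are package conventions; only the 5× multiplier
  and the MAD estimator are fixed by the analysis being implemented.

### Poisson-surprise bursts

The null model is a homogeneous Poisson process at the unit's mean rate
over the trial (per-trial, since burst counts are reported per 3-min
trial). Candidate runs are seeded wherever ≥ 2 consecutive ISIs fall below
half the mean ISI, extended at the end and then trimmed at the start to
maximize the surprise

    S = −ln P(N ≥ n | Poisson(λ·T + c))

with a lookahead of 10 spikes to escape local maxima; runs with S ≥ 5 and
≥ 3 spikes are kept, overlaps resolved in favor of the larger S. All knobs
(threshold, minimum size, lookahead, log base) are parameters.

The term `c` is an **anchored-window correction**, default 2 mean ISIs.
Both edges of a run are spikes, so the tip-to-tip span `T` understates the
maximal window containing exactly that run, which extends up to one
flanking ISI beyond each edge (2/λ in expectation). Without the correction
(set `window_correction_isi=0` for the textbook scan) any chance triplet of
close spikes reaches S ≥ 5, giving ~15 false bursts per 180-s 1.9-Hz
Poisson trial; with it the measured false rate is ≈ 0.4 per trial while
injected 14-spike bursts (S ≈ 15–20) are recovered with recall and
precision ≈ 1. Threshold 5 corresponds to bursts e⁵ ≈ 150× less probable
than the Poisson expectation.

## Synchrony

**Event synchronization.** Implemented exactly as defined (see README for
the formula); the locally adaptive window uses one-sided adjacent ISIs at
the first/last spike of a train rather than discarding boundary spikes
(exposed choice), no maximum-τ cap by default (an optional cap parameter
exists), and exact cross-train ties contribute ½ to each directed count.
The cumulative curve assigns each coincidence to the later spike of the
pair and is normalized to end at Q. `median_tau` (the median coincidence
window over coincident pairs) is reported and logged per run — on default
synthetic cohorts it lands in the tens of milliseconds, the same order as
real cortico-accumbal pairs — but is rate-dependent and therefore never
asserted. The implementation is verified against a literal double-loop
evaluation to 1e-12.

**Downsampling control.** Q is recomputed with saline NAc trains thinned to
a random 50% subset (order preserved, `round(0.5·m)` spikes), checking that
group differences survive approximate rate matching.

**Spike coherence.** Both trains are binned to counts at 1 ms; rectangular
non-overlapping 1024-bin segments (175 segments per 180-s trial) give
segment-averaged auto-/cross-spectra and magnitude-squared coherence (the
DC bin is dropped; segments are mean-detrended). None of these constants is
dictated by the analysis being reproduced; all are parameters. For
independent trains the estimator's bias floor is ≈ 1/L with L segments —
group *differences*, not absolute levels, are the meaningful quantity. The
group band is a 95% percentile bootstrap resampling *pairs* with
replacement (2000 replicates).

## Behavior coupling

Firing-rate histograms (100-ms bins, counts scaled to Hz) are correlated
with binary contact vectors (bin = 1 if its midpoint falls inside a contact
interval). At each lag the value is the Pearson coefficient of the
overlapping region — a normalization choice; a raw series is recoverable by
the caller since per-lag covariance is Pearson × the two SDs. Positive lag
means rate follows contact onset; the maximum lag (±5 s) is a parameter.
In the acquisition trial both objects are physically novel, so each unit's
two object curves are averaged before group statistics and reported under
the novel role. Group curves are mean ± SEM across units per
structure × group × trial × object role; cells with < 2 units are omitted
with a warning.

## Group statistics

* **Wilcoxon signed-rank** — zero differences dropped, midranks of |d|,
  W = sum of positive ranks, Z from the tie-corrected normal approximation
  *without* continuity correction, r = Z/√(2n) with two observations per
  pair. These two conventions are forced by the worked example they must
  reproduce (six same-sign differences → Z = 2.201, r = 0.64); with a
  continuity correction Z would be 2.097. The normal p approximates the
  exact distribution's mid-p (verified by enumeration at n = 8); at n ≤ 10
  an exact test would normally be preferred — the approximation is kept
  because it is the convention of the analysis being implemented.
* **Bootstrap CI** — per replicate, animals are resampled with replacement
  within each group, each group's median of paired novel−familiar
  differences is recomputed, and the saline−PCP difference is collected;
  2000 replicates, BCa by default (bias correction from the replicate
  distribution, acceleration from a leave-one-animal-out jackknife across
  both groups), percentile optional. Degenerate replicate distributions
  (constant data) collapse to a zero-width interval.
* **One-way ANOVA** — textbook between-groups F, df (k−1, N−k); equal to
  squared pooled t for two groups (asserted as an identity test).
* **Mixed (split-plot) ANOVA** — one between-subject factor and one or two
  within-subject factors, one observation per subject × within-cell.
  Between effects are tested over MS subjects-within-groups; each within
  effect and its group interaction over the corresponding
  within × subject(group) stratum. With two-level within factors no
  sphericity correction is needed. For unequal group sizes this is the
  weighted-means analysis (strata remain orthogonal because within factors
  are complete per subject); results match pingouin for one within factor
  and statsmodels AnovaRM for the pure within part. Fisher-LSD follow-ups
  compare groups at each within level using Winer's pooled error
  (MS_subj + (m−1)·MS_within)/m with Satterthwaite df. Degrees of freedom
  always follow the realized design.
* **Normality screen** — Shapiro–Wilk (scipy), gate at α = 0.05, used to
  justify the rank-based exploration comparison.

## Synthetic cohort

The generator emulates a 2 × 6 animal study with 2–4 units per structure
per animal and injects every effect the pipeline must recover. Defaults are
the study conditions:

| parameter | default | meaning |
|---|---|---|
| rate_mpfc_hz | 1.1 | mPFC unit rate, both groups |
| rate_nac_hz | 1.9 / 0.93 | NAc rate, saline / PCP |
| unit_rate_log_sd | 0.5 | lognormal unit heterogeneity (mean-centered, so group means hit the targets; implies between-unit SD ≈ 0.53 × mean, matching reported SEMs) |
| contact_seconds (retention) | 29.9 / 36.2 (saline), 30.1 / 30.8 (PCP) | familiar / novel mean totals per trial |
| animal_contact_sd_s / contact_sd_s | 3.0 / 1.5 | animal-shared vs object-specific exploration noise |
| n_contact_epochs | 12 | contact epochs per object per trial |
| novelty_gain | 1.5 / 1.0 | rate gain during novel-object contact |
| sync_prob | 0.15 / 0.03 | fraction of NAc spikes copied from mPFC |
| sync_jitter_s | 0.005 | SD of the copy jitter |
| bursts_per_trial | NAc 9/5, mPFC 6/6 | injected burst episodes |
| burst_len_spikes / burst_rate_gain | 14 / 8 | burst size and intra-burst rate factor |

Notes on the less obvious choices:

* **Synchrony by spike copying.** Each NAc unit is assigned a parent mPFC
  unit; a thinned, jittered copy of the parent's spikes supplies the
  synchronous fraction, with the remainder independent Poisson. Copying
  matches what the event-synchronization index measures (coincidences, not
  rhythm); a shared 4-Hz sinusoidal rate modulation generator is provided
  separately for coherence tests. Because pairs are the Cartesian product
  of an animal's units, only pairs sharing a parent carry injected
  synchrony — the group contrast is diluted accordingly, as in real data
  where not every pair is coupled.
* **Rate budgeting.** Within `gen_cohort`, burst spikes and copied spikes
  are carved out of each unit's target rate (the Poisson background rate is
  reduced to compensate), so measured unit rates match the configured
  group means. The standalone `gen_bursty_train` keeps the simpler additive
  contract (total ≈ base·duration + bursts·length) for counting-oracle
  tests.
* **Exploration noise.** The paired design constrains the noise split: a
  same-sign Wilcoxon outcome at n = 6 with a ~6-s novel−familiar gap
  requires the paired-difference SD to be ≲ 2 s, while total exploration
  varies more across animals. Hence a shared per-animal baseline (SD 3 s)
  that cancels in the pairing, plus small object-specific noise (SD 1.5 s).
* **Acquisition trial.** Both objects are new, so both contact traces get
  the familiar-object duration target and (in the saline group) the novelty
  gain.
* **Seeding.** All randomness flows from one integer seed through
  `numpy.random.SeedSequence` spawning (one child per animal, drawn in a
  fixed order within each animal), so identical configs give byte-identical
  cohorts.

**What the generator does not emulate:** refractory periods and spike-sorting
artifacts, non-stationary drift across trials, oscillatory coupling (unless
the 4-Hz option is used), behavior-category structure (sniff/touch/approach
labels), and any correlation between a unit's rate and its synchrony or
burstiness. Passing recovery tests therefore shows the pipeline detects the
modeled effect structure at realistic sizes — not that real recordings
satisfy these independence assumptions.

## Problem sizes used in tests

Recovery and calibration tests use 10–20 independent cohorts (seed-swept),
50 seeds for burst recall/precision, 500 Poisson trials for the
false-burst rate, 1000 random pairs for the brute-force synchronization
oracle, and 2000 simulations for type-I calibration of the Wilcoxon
(n = 20 pairs, where the normal approximation is expected to be calibrated)
and the mixed ANOVA (12 subjects, the study's design). Coherence tests use
single 180-s trials (175 segments).

## Known limitations

* The event-synchronization implementation materializes an m×m window
  matrix; fine for 3-min low-rate trains, quadratic in memory for long
  high-rate recordings.
* Burst detection assumes rate stationarity within a trial (the null λ is
  the whole-trial mean), so slow modulation inflates surprise.
* The mixed ANOVA handles one observation per subject × within-cell and, for
  unbalanced groups, implements the weighted-means decomposition rather
  than Type-III sums of squares.
* The BCa acceleration uses a pooled jackknife across both groups; with
  very small groups (n = 2–3) the interval degrades toward percentile.
* No support for vendor acquisition formats, spike sorting, LFP analysis,
  or lagged directionality measures.
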