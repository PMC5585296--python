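# cortistri

Cortico-striatal spike-train analysis for novel object recognition (NOR)
experiments: single-unit firing metrics, mPFC–NAc synchrony, firing-rate /
behavior coupling, and the matching group statistics — together with a
synthetic cohort generator that provides a ground-truth test bed for the
whole pipeline.

## Who this is for

In the sub-chronic phencyclidine (PCP) rodent model of schizophrenia, rats
pre-treated with PCP show lasting recognition-memory deficits. A typical
electrophysiology study records single units simultaneously from medial
prefrontal cortex (mPFC) and nucleus accumbens shell (NAc) during the three
3-minute NOR trials (pre-exposure, acquisition, retention) and asks three
questions: is tonic striatal activity reduced, is cortico-accumbal
communication desynchronized, and is the novelty-related rate increase
during object exploration lost? `cortistri` implements that analysis as a
tested, reusable Python pipeline.

## The measures

**Event synchronization.** For spike trains x, y with spikes t^x_i, t^y_j,
the coincidence window is locally adaptive:

    tau_ij = min{ t^x_{i+1}−t^x_i, t^x_i−t^x_{i−1}, t^y_{j+1}−t^y_j, t^y_j−t^y_{j−1} } / 2

With c(x|y) the count of x spikes trailing a y spike by at most tau (exact
ties count 1/2), the index is

    Q = ( c(x|y) + c(y|x) ) / sqrt(m_x · m_y)  ∈  [0, 1]

Q = 0 means no quasi-coincidences; Q = 1 means identical trains. A 50%
random spike-downsampling control verifies that group differences in Q are
not firing-rate artifacts, and segment-averaged spike coherence
|f_xy|² / (f_xx · f_yy) with a pair-level bootstrap band provides an
independent spectral check.

**Single-unit metrics.** Firing rate (count/duration), the CV2 local
irregularity measure CV2_i = 2|ISI_{i+1} − ISI_i| / (ISI_{i+1} + ISI_i)
averaged over i, and Legéndy–Salcman Poisson-surprise burst detection with
S = −ln P(N ≥ n | Poisson), threshold S ≥ 5 (bursts ≈ e⁵ ≈ 150× rarer than
the rate-matched Poisson null). Threshold spike detection at 5× the
MAD-based noise SD (σ = median(|x|)/0.6745) is included for the wideband
detection stage.

**Behavior coupling.** 100-ms firing-rate histograms are cross-correlated
(Pearson, per lag) with binary object-contact traces; positive values mean
exploration-related rate increases.

**Group statistics.** Wilcoxon signed-rank (normal approximation, no
continuity correction, effect size r = Z/√(2n)), a BCa bootstrap CI for the
between-group difference of median novel−familiar exploration, one-way
ANOVA, and split-plot mixed ANOVAs (structure × drug group; behavior ×
object × drug group) with Fisher-LSD follow-ups.

## Worked example

```python
from cortistri import CohortConfig, RunConfig, run_pipeline

cfg = RunConfig(out_dir="results/demo", cohort=CohortConfig(seed=1), seed=1)
result = run_pipeline(cfg)

rep = result.stats_report
print(rep["firing_rate"]["NAc"]["group_means"])
print(rep["synchrony"]["group_means"])
print(rep["exploration"]["wilcoxon_saline"])
print(rep["exploration"]["bootstrap_median_diff"])
```

Output for this seed:

```
{'pcp': 1.0174291938997821, 'saline': 2.2164609053497943}
{'pcp': 0.13036370745894163, 'saline': 0.1949276019185157}
{'n_pairs': 6, 'W': 21.0, 'Z': 2.2013981571160284, 'p': 0.027707849358079864, 'r': 0.6354889093022426}
{'estimate': 7.632084973881513, 'lower': 4.023717066260171, 'upper': 11.150993170217426, 'n_boot': 2000, 'method': 'bca'}
```

Reading: NAc units fire at ~2.2 Hz in saline-pre-treated animals versus
~1.0 Hz after PCP; mean mPFC–NAc event synchronization is lower in the PCP
group; the saline group shows a significant novel-over-familiar exploration
preference (all six paired differences positive, Z = 2.201, r = 0.64)
whose group difference is confirmed by a bootstrap CI excluding zero. The
same run writes `unit_metrics.csv`, `pair_metrics.csv`, `coherence.csv`,
`xcorr_long.csv`, `stats_report.json` and `run_log.txt` under `out_dir`.

The same pipeline runs from the shell:

```bash
cortistri synth --out sessions/ --seed 1      # write session JSON files
cortistri run --out results/demo --seed 1     # full pipeline on a synthetic cohort
cortistri units --in sessions/ --out results/units
```

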