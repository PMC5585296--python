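# Session JSON schema

One file per animal-session. All times are seconds, trial-relative,
half-open `[0, duration_s)`.

```json
{
 "animal_id": "saline_01",
 "group": "saline",
 "trials": [
  {"name": "pre_exposure", "duration_s": 180.0},
  {"name": "acquisition", "duration_s": 180.0},
  {"name": "retention", "duration_s": 180.0}
 ],
 "units": [
  {
   "unit_id": "saline_01_mPFC_1",
   "structure": "mPFC",
   "trial": "retention",
   "times_s": [0.412, 1.275, 3.948]
  }
 ],
 "contacts": [
  {
   "object_role": "novel",
   "trial": "retention",
   "intervals_s": [[12.1, 14.75], [31.0, 33.4]]
  }
 ],
 "metadata": {}
}
```

Constraints (validated on read; violations raise an error naming the field):

* `group` ∈ {`saline`, `pcp`}; `structure` ∈ {`mPFC`, `NAc`};
  `trial` ∈ {`pre_exposure`, `acquisition`, `retention`};
  `object_role` ∈ {`novel`, `familiar`}.
* `times_s` strictly increasing, within `[0, duration_s)`; never re-sorted.
* `intervals_s` sorted, non-overlapping, `end > start`, within the trial.
* One `units` entry per unit per trial; every entry for the same trial
  shares that trial's `duration_s`.

Flat CSV exports written by the pipeline (`unit_metrics.csv`,
`pair_metrics.csv`, `coherence.csv`, `xcorr_long.csv`) are described in the
`cortistri.pipeline` module docstring.
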