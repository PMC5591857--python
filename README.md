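# songmem

Quantifying neuronal memory for conspecific songs from stimulus-specific
adaptation (SSA) of auditory responses, in the zebra finch higher auditory
region NCM (caudal medial nidopallidum).

## The scientific problem

Neurons in NCM adapt to a repeated song: the multiunit response magnitude
declines with each presentation, and the decline is specific to each song.
Because adaptation persists for many hours, the *rate* of adaptation on
re-exposure is a physiological readout of memory: a song heard the day
before adapts more slowly than a never-heard song. `songmem` implements the
full analysis chain used to turn raw trial-wise responses into group-level
memory statistics:

1. **Response magnitude** — per trial, the RMS of the voltage in the
   stimulus window minus the RMS in a silent baseline window (demeaned per
   window; clamped at zero).
2. **SSA rate** — for each recording site × stimulus, the OLS slope of
   magnitude *m* versus trial number *t* over the linear region of the
   adaptation profile (trials 6–25), normalized by the window mean and
   expressed in percent per trial:
   `rate = 100 · slope / mean(m₆…m₂₅)`. Negative = adaptation.
3. **Familiarity Index** — per site × test set × familiar song,
   `FI = mean(novel rates) / familiar rate`. FI > 1 means the familiar song
   adapts more slowly than novel songs, i.e. it is remembered; FI = 1 means
   it is processed as if novel. Records whose component rates are not both
   negative are excluded with an explicit reason code.
4. **Statistics** — pooled FI distributions per (group, hemisphere, region)
   are summarized by median and IQR and compared with a sign test against
   FI = 1 (exact binomial for n ≤ 100, continuity-corrected normal Z above),
   two-sample Kolmogorov–Smirnov tests between groups/hemispheres/regions,
   and Bonferroni correction (m = 2) for hemisphere pairs.
5. **Gene expression** — the companion ΔΔCT analysis for immediate early
   genes (*zenk*, *c-fos*) against a housekeeping gene (*18s*):
   `rel% = 100 · 2^(−ΔΔCT)` relative to the vehicle group, with pooled
   two-sample (or one-sample vs 100%) t contrasts.

Because the electrophysiology this design comes from is not publicly
deposited, the package ships a first-class synthetic-data generator
(`songmem.synthgen`) that emulates the paradigm — 4 test sets × (2 familiar
+ 2 novel) songs × 25 shuffled repetitions, recorded bilaterally from 4
electrodes per hemisphere in NCM and a non-NCM control region — with known
ground-truth adaptation slopes and FI, so every stage is testable by
parameter recovery.

## Worked example

```python
import songmem as sm

cfg = sm.paper_mirror_config(seed=1)      # drug / vehicle / extended-exposure scenario
report = sm.run_analysis(cfg, out_dir="songmem_out")

for row in report["pooled_fi"]:
    if row["region"] == "NCM":
        print(row["group"], row["hemisphere"], row["n"], round(row["median_fi"], 3))
```

prints

```
hdac3i left 246 1.225
hdac3i right 253 1.073
vehicle left 191 1.015
vehicle right 190 0.926
x200 left 192 1.093
x200 right 192 1.253
```

i.e. 246 usable FI records in left NCM of the drug group with median FI
1.225 — a left-lateralized memory effect — while vehicle medians sit near
1.0. The corresponding comparisons in `report["comparisons"]` include the
drug-vs-vehicle K-S test (d = 0.165, p ≈ 1.3e-5 at this seed), the drug
pooled sign test (Z = 4.39) and the drug left-vs-right K-S test
(d = 0.144, p ≈ 0.01); `report["exclusions"]` tallies the records dropped
by the sign checks (23 of 2560 at this seed).

The same stages are available from the shell:

```bash
songmem run-all --seed 1 --out-dir songmem_out     # report.json + all CSVs
songmem simulate --out-dir out && songmem rates --trials out/trials.csv --out-dir out
songmem fi --rates out/rates.csv --out-dir out
songmem stats --fi out/fi.csv --out-dir out
```

Each stage consumes its predecessor's CSV, so real trial tables with the
same columns (`bird,group,hemisphere,region,site,set,stimulus,stim_class,
trial,magnitude`) drop straight in at the `rates` stage, and raw float-WAV
epochs can enter at `songmem extract`.

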