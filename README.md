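# fusionpace

In-silico cardiac resynchronization therapy (CRT) fusion pacing on virtual
left-bundle-branch-block (LBBB) cohorts.

## The problem

In heart failure with LBBB, the left ventricle activates late via slow
transseptal spread, and pacing both ventricles (CRT) shortens the total
ventricular activation time (VAT). Simultaneous biventricular pacing at a
nominal fixed AV delay ignores the patient's own conduction; *fusion pacing*
instead times the stimuli so that the paced wavefronts merge with the
intrinsic right-sided wavefront. Commercial devices implement this as a
dynamic negative AV hysteresis: every 256 beats the device extends the AV
delay for three beats, measures the intrinsic atrioventricular interval
(AVI, atrial sense to RV-lead sense), and reprograms the paced AV delay to

```
AVD_paced = AVI − offset,    offset programmable 10–120 ms
```

The clinical question this package simulates is which offset minimizes VAT.
`fusionpace` is for device-programming researchers and modelers who want a
transparent, fully reproducible sandbox for that question: it generates
virtual LBBB patients, builds per-patient biventricular conduction graphs,
runs the beat-by-beat device state machine, computes activation maps as
multi-source fastest arrivals,

```
t(v) = min_s [ onset(s) + d(s, v) ]
```

over intrinsic breakout and lead stimulus sources `s` (shortest-path
traversal times `d`), and reproduces the full 14-mode study protocol
(intrinsic rhythm, RV-only pacing, simultaneous biventricular pacing, and
fusion pacing at offsets 10–110 ms) with paired t statistics.

## Worked example

Sweep all 14 protocol modes for an average patient (PR 189 ms, native VAT
181.6 ms) — `python examples/04_offset_sweep.py`:

```
mode  1  native       VAT  182.0 ms
mode  2  rv_only      VAT  185.3 ms
mode  3  biv          VAT  106.7 ms
mode  4  syncav_10    VAT  120.9 ms
mode  5  syncav_20    VAT  113.8 ms
mode  6  syncav_30    VAT  108.5 ms
mode  7  syncav_40    VAT  100.7 ms
mode  8  syncav_50    VAT  101.9 ms
mode  9  syncav_60    VAT  106.6 ms
...
mode 14  syncav_110   VAT  106.7 ms
```

Native conduction has the longest activation span (calibration matched it to
the patient's 181.6 ms QRS duration). Fixed-delay biventricular pacing
shortens it to 106.7 ms. The fusion offset sweep is U-shaped: small offsets
pace too late to help the LV much, large offsets fully pre-empt intrinsic
conduction and converge back to the plain biventricular map, and the minimum
(100.7 ms at offset 40) sits where the paced stimuli and the intrinsic
breakout fire together and three wavefronts fuse.

The cohort-level study — `python examples/05_full_study.py` — prints the
mode-summary table (mean ± SD VAT, paired difference to biventricular
pacing, 95% CI, paired-t p) for the default 14-patient cohort and reports

```
cohort-mean optimal offset: 50 ms
optimized fusion mean VAT: 102.6 ms vs BiV 107.6 ms vs native 185.5 ms
```

i.e. the optimum emerges in the 30–50 ms band and individually optimized
fusion pacing beats every fixed programming, which beats nominal
biventricular pacing.

A thin CLI wraps the same library calls:

```
fusionpace simulate --seed 1 --out-dir results/
fusionpace summarize results/vat_by_patient_mode.csv
fusionpace maps --patient-index 0 --mode 8 --out map.csv
```

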