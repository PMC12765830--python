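# paintrial

Endpoint and statistical machinery for randomized acute-pain trials that
deliver a loading dose followed by patient-controlled analgesia (PCA), in
the style of a 4-arm placebo- and active-controlled phase 3 study
(placebo, two doses of an investigational analgesic, morphine). It is
aimed at biostatisticians and trialists who need the full chain —
scoring, imputation, testing, design — as tested, reusable code, plus a
synthetic trial generator so every stage can be exercised without any
real data.

## What it computes

Pain intensity (PI) is a 0–10 numerical rating scale; pain relief (PR) a
0–4 Likert scale, assessed on a fixed grid over the 24 h from the start
of the loading infusion (Time 0). The composite endpoints are
time-weighted sums over the grid:

    SPID_t   = Σ (PI_t − PI_0) · (TIME_t − TIME_{t−1})
    TOTPAR_t = Σ PR_t · (TIME_t − TIME_{t−1})

computed in exact rational hours, so the interval weights sum to exactly
24 and the theoretical SPID_24 range of [−240, 240] is achieved exactly.
Around the scores the package implements:

- the protocol's imputation rules — night-sleep PI → NRS 3 with the
  previous PR carried, post-rescue carry-back windows (6 h parecoxib,
  2 h sufentanil), last observation carried forward elsewhere — with a
  sensitivity mode that leaves post-rescue scores as recorded;
- the fixed-sequence gatekeeping primary analysis (high dose vs placebo
  first, low dose confirmatory only if the first test rejects), pooled or
  Welch two-sample t tests, Wilcoxon rank-sum (exact by enumeration up to
  combined n = 20, midranks under ties), and Fisher's exact test;
- rescue-medication outcomes: no-rescue proportions with Clopper-Pearson
  intervals, Kaplan-Meier time to first rescue (censored at 24 h) with
  log-rank comparisons, and zero-filled cumulative consumption;
- design numbers: the z-approximation two-sample sample size, dropout
  inflation, and achieved power;
- a simulator of the whole trial, including the PCA pump's demand window,
  10-min lockout and hourly cap, rescue triggering, and night-sleep
  missingness.

## Worked example

```python
import paintrial as pt

cfg = pt.RunConfig(simulation=pt.default_config(n_per_arm=132), seed=7)
bundle = pt.run_full_analysis(cfg, "out")
print(bundle["summary_table"].set_index("endpoint").loc["spid_24"])
```

prints (seed 7):

```
placebo_mean_sd                                             -50.49 (13.52)
placebo_diff_se                                                         ND
tegileridine_0_75_mean_sd                                   -62.71 (12.47)
tegileridine_0_75_diff_se                                    -12.23 (1.60)
tegileridine_0_75_ci_p        (-15.38 to -9.07); p = <0.001 [confirmatory]
tegileridine_1_0_mean_sd                                    -68.06 (12.66)
tegileridine_1_0_diff_se                                     -17.58 (1.61)
tegileridine_1_0_ci_p        (-20.75 to -14.40); p = <0.001 [confirmatory]
morphine_mean_sd                                            -71.80 (14.05)
morphine_diff_se                                             -21.31 (1.70)
morphine_ci_p                     (-24.65 to -17.97); p = <0.001 [nominal]
```

Reading the row: each arm's mean (SD) SPID_24 — more negative means more
cumulative pain reduction — then the difference from placebo with its
standard error, the 95% CI and p. Both dose-vs-placebo contrasts passed
the gate in sequence, so both are confirmatory; the morphine contrast sits
outside the gate and is nominal. The same bundle carries the endpoint
panel, no-rescue proportions with exact CIs, survival curves and the
design summary; `run_full_analysis` also writes each of them as CSV/JSON
into the output directory together with a run log of the imputation
provenance tallies.

The same pipeline is available from a shell:

```
paintrial simulate --n-per-arm 132 --seed 7 --out data/
paintrial endpoints data/ --out endpoints.csv
paintrial analyze endpoints.csv --out comparisons.csv
paintrial design
```

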