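# Methods

## Scoring model

The trial observes pain intensity (PI, NRS 0–10) and pain relief (PR,
Likert 0–4) on a nominal grid anchored at Time 0, the start of the 10-min
loading infusion: 0, 10, 20, 30, 45 min, 1, 1.5, 2, 3, 4, 5, 6, 8, 10,
12, 18, 24 h. The stated post-dose offsets are treated as clock times
from Time 0 with the last assessment at exactly 24 h; this is the only
anchoring under which the interval weights telescope to 24 and the
theoretical SPID_24 range is exactly ±240. The end-of-loading-infusion
assessment is placed at 10/60 h and participates in the grid; whether it
should instead be excluded from scoring is genuinely ambiguous, and the
package keeps it in because excluding it would change no endpoint (the
weights re-telescope) while dropping information.

All times are `fractions.Fraction` hours and all interval arithmetic is
exact; floats appear only in rendered panels and reports. SPID over a
window (s, e] sums (PI_t − PI_0)·(t − t_prev) over grid points in the
window, with t_prev the preceding grid point; PID at baseline is
identically 0 and time 0 carries no weight. Windows are half-open (s, e]
throughout the package.

## Imputation

Rules are applied point by point in time order:

1. **Rescue carry-back** — grid points inside (r, r + w], with w = 6 h
   after parecoxib and 2 h after sufentanil, take the last score on
   record before the rescue at r. When windows overlap, the later
   rescue's own pre-rescue score governs from its event time. By default
   the rule fills *missing* points only; `strict_rescue=True` overwrites
   observed points in the window as well. Both readings of "imputed
   within the window" are defensible, so both are selectable; the
   non-strict form is the default because it never discards an observed
   measurement.
2. **Night sleep** — missing PI during flagged night sleep becomes NRS 3;
   missing PR carries the previous PR forward. If no PR exists before the
   first flagged point the series is an error rather than a guess (a
   pre-night PR always exists under the protocol grid, where night falls
   hours after the first post-dose assessments).
3. **LOCF** — any other missing score carries the last observation
   forward. A missing PR at the first post-baseline point, where nothing
   precedes it, is imputed as 0: PR is relief relative to entry, and no
   relief can have accrued before the first post-dose observation.

Rule precedence on overlap is rescue > night > LOCF, because the rescue
rule is the analysis-defining one: it prevents analgesia delivered by the
rescue drug from being credited to the study drug. In the sensitivity
mode (`sensitivity_no_rescue_imputation`) rule 1 is disabled and
post-rescue observations are used as recorded. Imputation is idempotent:
re-running it on its own output changes nothing (tested).

## Analysis

The primary analysis is a fixed-sequence gate at two-sided α = 0.05: the
high dose is compared with placebo first; the low dose is confirmatory
only if that test rejects, otherwise its result is labelled exploratory.
Individual p values are never adjusted — error control comes from the
ordering — and all comparisons outside the gate are labelled nominal.
"Group t test" is implemented as the pooled-variance two-sample t
(classical usage, and consistent with reporting a single SE per
contrast); Welch's form is available by flag since the original choice is
not stated. CIs for differences use the t quantile at the pooled df.

No-rescue proportions use the full analysis-set arm size as denominator
with Clopper-Pearson intervals from beta quantiles. (A published placebo
figure of 40.8% of 131 is not an integer count, implying an unstated
evaluable subset; the package deliberately uses the full arm.) Time to
first rescue censors non-users at 24 h; a rescue recorded slightly after
24 h remains an event at its recorded time. Kaplan-Meier estimation and
the log-rank test are delegated to lifelines; ties use the standard
hypergeometric variance without continuity correction. The Wilcoxon
rank-sum is exact by full enumeration for combined n ≤ 20 — with
midranks, so ties (including identical samples, which must give p = 1)
are handled exactly — and otherwise uses the normal approximation with
tie and continuity corrections. Fisher's two-sided p is the conventional
sum of hypergeometric probabilities no larger than the observed table's.

## Design calculations

Sample size uses the two-sided z approximation
n = ⌈(z_{1−α/2} + z_{1−β})²(σ₁² + σ₀²)/δ²⌉ with the planning assumptions
(means 88 vs 70, SDs 45 and 40, α = 0.05, power 0.90) giving 118
evaluable per group; the z form is the default because the planned
numbers round from it exactly (117.56 → 118) where a noncentral-t
iteration lands at 119. Dropout inflation divides by (1 − rate) and
ceilings (118/0.9 → 132; ×4 arms → 528). `power_at_n` inverts the same
approximation and is validated against a Monte-Carlo t-test simulation.

## Synthetic trial generator

The generator exists to give the analysis machinery data with the
structure it assumes, at the planned scale. Per participant, baseline
NRS is drawn on {4,…,10} (inclusion criterion ≥ 4) with mass concentrated
at 4–6, and the latent trajectory is

    PI(t) = clamp( round( baseline − effect·(1 − e^{−t/τ}) + ε_t ), 0, 10 )

with iid ε_t ~ N(0, 1 NRS) and τ = 0.8 h; PR is the monotone map
clamp(baseline − PI, 0, 4). Default arm effects (1.85, 2.45, 2.8, 2.95
NRS for placebo, low dose, high dose, morphine) were chosen once so the
long-run arm mean SPID_24 sits near the levels a trial of this design
reports (≈ −50/−61/−69/−71); they are ordered placebo < low < high ≈
comparator. A rescue is drawn with hazard 0.25 at any assessment with
PI ≥ 5 (parecoxib 40 mg first, sufentanil 5 µg after the 80 mg daily
cap), dropping PI by 2 inside the drug's window. Assessments in the
night window (10 h, 16 h] — the protocol never defines "night", so a
plausible post-afternoon-surgery window is used, configurable — go
missing with probability 0.4 (flagged night-sleep), others with 0.02;
dropout is 1.5%, matching a ~98.5% completion rate. PCA demand presses
arrive as a Poisson stream whose rate grows with residual pain and are
filtered by the pump rules (window 0.5–24 h, 10-min lockout, hourly cap
6 enforced on a sliding trailing 60-min window — the conservative
reading of a per-hour maximum). An optional coupling of accepted presses
to a small PI decrement exists and is off by default, since demand doses
this small should not visibly move NRS between assessments.

Randomness is counter-based: participant i of arm j draws from
`SeedSequence([master, j, i])`, so participants are independent and
per-arm output does not depend on simulation order.

What the generator does *not* emulate: between-participant heterogeneity
in drug response (noise is within-participant only, so simulated SPID_24
SDs, ~12–14, are narrower than the ~28–35 a real trial reports),
pharmacokinetic concentration–effect dynamics, site effects, and adverse
events. Passing tests therefore demonstrate correctness of the scoring,
imputation and testing machinery and the operating characteristics of
the procedures under a clean data-generating process — not agreement
with any real trial's per-arm variability.

## Numerical and testing choices

- Exact rational arithmetic for all interval weights; endpoint additivity
  (SPID_24 = SPID_12 + SPID_12–24) holds exactly, not to tolerance.
- Degenerate t test (both samples constant and equal) returns p = 1.
- A Fisher comparison whose 2×2 table has a zero margin (e.g. no rescue
  use anywhere) is reported as p = 1 in the proportions table; the raw
  `fisher_exact_2x2` keeps the positive-margin contract.
- Operating-characteristic tests run at the planned trial scale:
  gatekeeping familywise error under a global null with 10,000
  replicates of 132/arm; parameter recovery over 200 simulated trials at
  132/arm against long-run truth from a 2,500/arm reference run; CI
  coverage at 2,000 replicates; Clopper-Pearson coverage exhaustively for
  n ≤ 30 on a 499-point grid of true proportions.
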