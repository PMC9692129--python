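# Methods

## Scope and philosophy

`neutroflow` packages three linked in-silico assays of early neutrophil
adhesion under flow — tether events, calcium bursts, activation imaging —
each as a seeded generator plus the estimators a flow-chamber lab would run
on the corresponding real recordings. The generators encode the accepted
qualitative biology (catch–slip selectin bonds, fast force-triggered local
integrin activation, ligand reinforcement, two calcium sources, minute-scale
whole-cell activation) with the fewest parameters that reproduce the
published summary statistics; they are stand-ins for wet-lab cohorts, not
mechanistic simulations of signaling.

## Tether-event model

A stop is governed by three independent exponential clocks at constant
force f = 125·WSS pN (WSS in dyne/cm²):

* selectin bond lifetime `T_s ~ Exp(k_off(f))` with the two-pathway
  catch–slip rate `k_off(f) = k_c e^{−f/f_c} + k_s e^{f/f_s}`;
* local activation latency `T_a ~ Exp(λ)`, running only while the selectin
  bond persists;
* integrin–ligand bond lifetime `T_i ~ Exp(k_i(f))` with the Bell slip rate
  `k_i(f) = k_0 e^{f/f_i}`, drawn only when a ligand is coated, the clock
  won the race (`T_a < T_s`) and an engagement coin (probability `p`)
  landed heads.

The recorded stop is `max(T_s, T_a + T_i)` for engaged events and `T_s`
otherwise. The full tether force loads whichever bond holds; simultaneous
bonds do not share load, consistent with the low site densities that make a
single molecular bond dominate each stop. Lifetimes are rounded *up* to the
0.01 s frame of a 100 fps recording, and stops shorter than 3 frames
(0.03 s) are below the detection floor: the generator redraws them, so a
requested event count is a count of *detected* events, and all recorded
moments are conditioned on detectability, as in a real video analysis.

### Defaults and calibration

| parameter | value | units | role |
|---|---|---|---|
| k_c, f_c | 4.5121, 10 | 1/s, pN | catch pathway |
| k_s, f_s | 0.48290, 30 | 1/s, pN | slip pathway |
| λ (latency_rate) | 40 | 1/s | local activation clock |
| p (engage_prob) | 0.55 | – | ligand capture probability |
| k_0, f_i (integrin) | 0.52790, 100 | 1/s, pN | reinforcement bond |

`calibrate_defaults()` reproduces the frozen values: the catch–slip pair is
solved in closed form so that (i) the off-rate minimum sits at 25 pN — the
interior of the 0.1–0.45 dyne/cm² window, making the mean-lifetime-vs-WSS
curve biphasic with an interior apex — and (ii) the *measured*
(floored + quantized) selectin-only mean at 0.2 dyne/cm² is 0.70 s, using
the geometric-lifetime identity E = h·(2 + 1/(1 − e^{−k h})) for frame
quantum h. The integrin off-rate is then bisected against simulation until
the ligand-present measured mean is 1.25 s; λ and p were chosen on a coarse
grid so that the integrin-involved fraction (IIF, below) crosses 0.10
before 0.2 s and 0.50 before 1.4 s at every WSS in the window.

One calibration target is provably out of reach and deliberately left
unmet: complete integrin takeover (IIF = 0.95) by 3.5 s. Writing
q for the engaged fraction and using the memorylessness of `T_s`, the mean
constraint pins `q·k/((k+μ)μ) = 0.55 s` (μ the integrin off-rate at 25 pN),
while the takeover constraint needs an engaged tail mass
`q·e^{−3.4μ} ≳ 0.20`; the ratio of the two is bounded by
`max_μ e^{−3.4μ}·μ(k+μ)/k ≈ 0.13 < 0.20/0.55·0.55`. No (λ, p, μ) satisfies
both, and with the means pinned the best achievable 0.95-crossing is
≈ 4.0–4.3 s. `calibrate_defaults()` reports exactly this violated
constraint, and the defaults favor the mean lifetimes, which are the
better-determined targets. The corresponding recovery check is expected to
fail and is retained unmodified as an honest record of the tension.

### Inhibitor semantics

Pre-treatments are binary switches on the activation parameters: MβCD,
staurosporine, cytochalasin B and MNS (raft / moesin / actin / talin
interference) set λ = 0; TS1/22 and 2LPM19c zero the engagement
probability for ICAM-1 and GPIbα respectively; KPL-1 (anti-PSGL-1)
suppresses tethering entirely (zero rows); piceatannol (Syk) and DMSO are
identities for tether generation. Partial inhibition is out of scope.

## Tether statistics

* **Survival ratio** S(t) = #{lifetime ≥ t}/N_T on a fixed grid, 0–5 s in
  0.01 s steps (the frame quantum); no censoring machinery is needed since
  every stop is fully observed.
* **IIF** (P_E − P)/P_E from a paired pair of survival curves. Sampling
  noise can push the raw ratio negative or non-monotone, so the adjusted
  curve clips to [0, 1] and applies least-squares isotonic regression; the
  raw curve is retained. Points where the with-ligand survival P_E falls
  below a floor (default 0.02, configurable) are undefined rather than
  amplified; cohorts under 100 events are refused. Crossing times
  interpolate linearly within the first crossing interval and report NaN —
  never an extrapolation — when a threshold is not reached. Measuring the
  0.95 crossing at 10⁴ events/arm needs the floor at 0.01, since P_E sits
  near 0.02–0.03 exactly where that crossing occurs.
* **Mean lifetime vs WSS** with SEM, plus a degree-2 polynomial fit whose
  apex estimates the catch–slip optimum; levels with fewer than 2 events
  are excluded with a warning.
* **Lifetime mixture**: two-component Gaussian EM on raw lifetimes
  (10 restarts, seeded, input sorted so the fit is order-invariant).
* Bootstrap percentile CIs (default 1000 resamples, seeded) for means.

## Calcium model and detection

Each cell contributes a 7-min recording at 20 fps: cell fluorescence
`baseline·(1 + F(t)) + noise` and four background domains
`baseline + noise` (baseline 100 a.u., noise SD 5 a.u.). A burst happens
with probability logistic in log-WSS from a floor of 0.1 (static cells) to
a saturation of 0.8 (midpoint 0.15 dyne/cm², slope 0.6 in ln WSS) — the
steep-then-saturating shape of force-triggered bursting; the same curve is
used for every substrate since burst *frequency* is substrate-insensitive.
The pulse is a peak-normalized product of exponential rise (τ_r = 2 s) and
decay (τ_d = 40 s) with amplitude 3 in F_IN units. The onset delay is
Gamma-distributed (CV 0.3) with a mean that decays in WSS (scale
0.06 dyne/cm², doubling toward WSS → 0) to a plateau reached by
0.2 dyne/cm²: 84 s for cells on P-selectin alone, 60 s whenever integrin
ligands are engaged (ICAM-1/GPIbα with P-selectin, or Mg²⁺-primed cells on
either ligand alone). Channel blockade multiplies burst probability by 0.2
and delay by 1.5 — 2-APB for the P-selectin-alone geometry (store release),
LaCl3 for the integrin-engaged geometries (membrane influx); both factors
are exposed in the parameters.

Detection normalizes per frame against the mean of the four background
domains, then calls a burst when F_IN stays above 0.5 for 5 s. The delay is
read at the foot of the pulse: the last sample under a low onset floor
(0.1, ~2 noise SDs) before the sustained crossing. Reading the onset at the
0.5 threshold itself would inherit a rise-time bias of ≈ 0.4 s; the foot
rule recovers noiseless onsets to within one frame and keeps the bias under
0.1 s at the default noise. A peak-based delay is available as an option.
On default-noise cohorts the detector's sensitivity and specificity are
both ≈ 1 and the delay RMSE ≈ 0.05 s, so cohort delay summaries are
limited by biological spread, not detection error.

Pearson correlations with WSS are offered at two units of analysis:
per-cell burst indicators (the default) and per-(condition, WSS) burst
ratios. The ratio level is the right one for comparing against published
correlation coefficients computed on cohort means: with a saturating
probability curve the per-cell correlation is capped near 0.4 by binomial
within-level variance no matter how strong the trend, while the ratio-level
correlation on the default grid is ≈ 0.7.

## Imaging model and metrics

Per condition the generator carries two logistic curves in stimulus time:
the activated fraction (static 0.20 → plateau 0.42 on P-selectin alone;
0.60 with ligands) and the mean relative density of activated cells
(16 → 24; 30 with ligands), with threshold 1.5 min on P-selectin alone and
0.75 min with ligands (slope 0.25 min). Activated/inactive cells draw
mean-preserving lognormal densities (σ = 0.25) around their curve or around
a low residual level (3), and the background density carries a 5% lognormal
error. Blockade (2-APB for P-selectin alone, LaCl3 for ligand conditions)
keeps only 30% of the rise above baseline. The static activated fraction
is not pinned by any published number; 0.20 is this package's choice and
all normalized ratios are relative to it.

Metrics: relative density FI_C/FI_B − 1; activation call at density ≥ ρ = 5
(the curves put activated cells an order of magnitude above the residual
level, so calls are insensitive to ρ across [0.3·ρ, 4·ρ]); activation ratio
normalized by the static cohort (identically 1 there by construction); and
a 4-parameter logistic fit whose inflection estimates the stimulus-time
threshold. The firm-adhesion filter keeps tracks whose net displacement
stays under 10 μm in every 60 s window (strict inequality); shorter tracks
are excluded, not counted.

A power note: at 300 cells per cohort the normalized activation ratio
carries a sampling SE of ≈ 0.3 on a center of 2.1 — the binomial noise of
the static denominator dominates — so single-cohort estimates scatter by
±15%; the density plateau, an average over ~125 activated cells, is
estimated to ±2%. Recovery checks on the ratio at this cohort size are
accordingly loose in practice even though the estimator is centered.

## Infrastructure

All tables are plain CSV (schemas validated by exact header), summaries
JSON, configs YAML with a mandatory integer seed; one global seed fans out
to per-stage children through `numpy.random.SeedSequence`, and the
end-to-end pipeline writes a manifest of SHA-256 hashes that makes reruns
byte-for-byte reproducible. Hidden generator truth (engagement flags, true
burst delays, true activation flags) is written only behind an explicit
`--truth` flag so analyses cannot read it by accident. Group comparisons
delegate to standard routines (one/two-way ANOVA, Welch pairwise t-tests,
Bonferroni adjustment with both raw and adjusted p reported); correlation
to `scipy.stats.pearsonr`; mixtures to scikit-learn's EM; isotonic
adjustment to scikit-learn; the logistic fit to `scipy.optimize.curve_fit`.

## What the generators do and do not emulate

They emulate the *statistical* structure of the three assays: biphasic
force-dependent single-bond lifetimes with a ligand-dependent long-lived
subpopulation; IIF curves rising from a ~0.1 latency plateau toward 1
within a few seconds; WSS-dependent burst probability and delay with
source-specific blockade; and minute-scale sigmoidal activation with
ligand-halved thresholds. They do not simulate cell motion or
hydrodynamics, rolling velocities, multi-bond clusters, load sharing,
spatially resolved calcium, secondary calcium transients, photobleaching,
or any molecular signaling intermediates; inhibitors are ideal on/off
switches. Consequently, passing recovery tests shows that the estimators
are unbiased and correctly wired at realistic noise levels — not that the
models capture every feature of real recordings.

## Problem sizes

Default analysis cohorts: 5000 events per tether arm for mean lifetimes,
10⁴ events per arm for IIF curves, 200–500 calcium traces for delay and
detector studies, 30 cells per (condition, WSS) cell for the correlation
grid, 300 cells per imaging cohort. These sizes put every
well-powered estimate within a few percent of its target while keeping a
full end-to-end run on a single CPU in well under a minute.
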