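# Methods

This note documents the models, estimators and design choices behind
`pomcpop`, in the order of the pipeline.

## Neuron surrogate

The membrane simulator is a two-variable adaptive leaky
integrate-and-fire model: membrane potential *V* (mV) and adaptation
current *w* (pA) with

    C dV/dt = g_L (E_rest − V) + I(t) − w
    τ_w dw/dt = a (V − E_rest) − w

Euler-integrated at the trace sampling rate (default 25 kHz).  A
threshold crossing paints a stylized +30 mV peak sample, resets
*V* → *V*_reset and jumps *w* → *w* + *b*.  The two adaptation
pathways were chosen deliberately: the spike-triggered increment *b*
produces spike-frequency adaptation, while the subthreshold coupling
*a* drives *w* negative during hyperpolarization, which yields both the
sag (a slow depolarizing relaxation during a hyperpolarizing step) and
post-inhibitory rebound (excess drive *−w* after release).  A bias
current holds the cell at the protocol's holding potential (−70 mV)
between stimuli.

Preset parameters (C = 20 pF, E_rest = −70 mV, V_th = −58 mV,
V_reset = −65 mV for both):

| preset | g_L (nS) | a (nS) | b (pA) | τ_w (ms) |
|---|---|---|---|---|
| tonic | 1.0 | 0.1 | 0.3 | 120 |
| phasic_adaptive | 0.6 | 0.4 | 3.0 | 400 |

The phasic preset's lower leak (higher input resistance) mirrors the
recorded direction of the R_i difference between the two populations
and keeps its effective rheobase, (g_L + a)(V_th − E_rest) = 12 pA,
below the 15-pA ramp used in the input–output protocol; its larger
*a·τ_w* product produces the pronounced rebound and ramp asymmetry.
These values were fixed once from the subthreshold algebra of the model
(rheobase, steady-state firing self-consistency) and are the defaults
the tests and the acceptance script run against.

Known limitations of the surrogate: the simulated sag is larger in the
*phasic* preset (the recordings show the opposite ordering between the
two populations), and the strong adaptation of the phasic preset
flattens its 1-s frequency–current slope below the tonic preset's,
whereas the recorded phasic population had the steeper slope.  Neither
quantity enters the cross-preset contrasts the suite asserts
(SFA ratio, ramp spike ratio, rebound f_max), which all reproduce the
recorded direction.  Noise, when enabled, is an additive Gaussian
voltage increment of sd `noise_sd`·√dt per step (a diffusion scale in
mV/√ms).

## Electrophysiological feature extraction

Parameters the source analysis leaves open are explicit keywords with
these defaults:

* **Spike detection** — upward crossing of −20 mV with a 2-ms
  refractory period; spike time = first at-threshold sample.  The
  detector is property-tested against an exhaustive per-sample scan.
* **Passive properties** — R is the least-squares slope of steady-state
  ΔV (mean of the last 20 % of each pulse) against ΔI over the
  hyperpolarizing series; τ is a mono-exponential least-squares fit to
  the 10–90 % relaxation segment of the smallest pulse; C = τ/R holds
  by construction (enforced at 10⁻⁶ relative).  Any spike during the
  series raises an analysis error.
* **Sag** — minimum over the first 25 % of the pulse minus the mean of
  the last 10 %, so a depolarizing relaxation yields a negative value
  (matching the reported sign, e.g. −7.46 mV).
* **Rebound** — pre-pulse potential is the mean over the final 200 ms
  of the 2-s pre-pulse; the rebound frequency is the maximum 1/ISI in
  the 1-s test window; fewer than two spikes records 0 Hz with a flag.
  The test pulse is 15 pA (one increment of the simulated series),
  which reaches both presets' rheobase so the rebound enhancement is
  measurable for both.
* **SFA fit** — instantaneous frequencies (1/ISI at the ISI midpoint)
  are fitted by bounded nonlinear least squares to the mono-exponential
  decay with *Y*₀ fixed to the maximum initial frequency and plateau
  constrained to (0, *Y*₀]; time is measured from the first frequency
  midpoint, which makes the fit exactly self-consistent on data
  generated from the curve and scale-equivariant under ISI rescaling.
  A constant train returns plateau = *Y*₀, ratio 1 and an
  unidentifiable *K* reported as 0; fewer than 5 ISIs refuse the fit;
  an initial frequency outside 30–40 Hz warns (the recordings selected
  stimuli to land in that band).
* **AP waveform** — d*E*_M/d*t* by centered finite differences (no
  smoothing by default, a flag enables it); threshold = *E*_M at the
  first rising-phase sample with d*E*_M/d*t* ≥ 10 mV/ms; only spikes
  with instantaneous frequency ≤ 5 Hz enter, with the first spike of a
  train (no preceding interval) counted as eligible.  The liquid-
  junction-potential correction is assumed already applied to inputs.

## 3σ responsiveness and charge transfer

Baseline and end-of-application windows are binned (default 12 × 10 s);
for spike trains the windows are half-open, so a spike exactly on the
boundary belongs to the next window.  δ = mean(post) − mean(pre); σ is
the sample SD (n−1) of the **baseline** bins only — the source text
says "the standard deviation" without fixing the period, and the
baseline reading is the conservative, conventional one (a pooled
alternative would only inflate σ).  Because δ is a difference of
12-bin means (SD σ/√12) compared against 3σ, the criterion is strongly
conservative under the null: the nominal false-call probability is
2Φ(−3√6) ≈ 10⁻¹³, and the 10,000-replicate null simulation calls 0 %.
A zero-variance baseline with nonzero δ is labeled by sign and flagged
degenerate.

Charge transfer integrates the baseline-subtracted clamp current over
the application window by the trapezoid rule (including the right-edge
sample, which makes the integral exactly additive over a partition of
the window) and reports the magnitude in nC with the deflection sign
kept separately, matching the positive printed values.

## Spatial statistics

Coordinates are µm in a right-handed atlas frame (x medio-lateral,
y dorso-ventral, z antero-posterior).  The kernel density estimate is a
plain isotropic Gaussian kernel average with a user-set bandwidth in µm
(Scott's rule, n^(−1/7) × mean per-axis SD, when unset); it is computed
separably over the grid axes and agrees with the naive O(n·m) kernel
sum to 10⁻⁸ relative, integrating to 1 within 10⁻² when the grid
covers the mass.

The cube partition uses half-open [lo, lo+edge) intervals (a point on
an interior boundary goes to the higher cube; points exactly on the
upper box face land in the last cube so counts are conserved).  Default
cube edge is 100 µm in the library (the drivers use 200 µm for the
simulated cloud sizes); neither value is prescribed by the source.  The
density factor n_Glp1r/n_Lepr multiplies the Lepr group's per-cube
counts so both groups reach equal corrected totals — the source phrase
is ambiguous about the direction, so it is exposed as a parameter.  The
per-cube test is a two-sided two-sample Student t with the per-animal
corrected count as the unit of replication (the only reading that gives
a valid t at 7–8 animals per group); cubes with zero variance in both
groups and equal means are flagged untested.  Raw p-values are reported
(the source plots raw two-sided P spheres); a Benjamini–Hochberg column
is optional.  Under the null simulation the pooled fraction of
informative cubes at p < 0.05 is calibrated to 0.05 (acceptance band
0.035–0.065 over 200 replicates).

## TRAP enrichment

Per replicate, enrichment = (IP + pc)/(input + pc) with pseudocount
0.5 by default (zero-count handling is unstated in the source), on the
log2 scale.  The between-group contrast is a Welch t on per-replicate
log2 ratios with Benjamini–Hochberg adjustment across genes — a
deliberately simple stand-in for a negative-binomial
differential-expression model, labeled as such in the output metadata
so results are not misread as DESeq2 replicas.  The significance flag
defaults to nominal p ≤ 0.05 (the volcano-plot convention), with a
switch to adjusted p.  Cluster overlap counts a cluster's markers
significant toward each group by the sign of the log2 fold difference;
log ratio = log2(n_Glp1r/n_Lepr) with an infinity sentinel (and flag)
when one side is zero, and the call thresholds are boundary-inclusive
(log ratio ≥ 2 / ≤ −2).  Gene z-scoring standardizes each gene row to
mean 0, sample SD 1, zeroing and flagging constant rows.

## Summary-statistics inference

From (mean, s.e.m., n): sd = sem·√n; pooled t uses the pooled variance
with df = n₁+n₂−2, Welch t divides by √(sem₁²+sem₂²) with
Welch–Satterthwaite df.  Printed legend values are compared on |t| at
1 % relative tolerance, absorbing the rounding of printed summaries.
Holm–Šídák is the step-down 1−(1−p)^(m−i+1) procedure and
Benjamini–Hochberg the step-up p·m/rank procedure, both with
monotonicity enforcement and order preservation; both are cross-checked
against definitional brute-force oracles and against statsmodels.
2^−ΔΔCt copy number anchors the calibrator at two gene copies.

## Synthetic-data generators

All generators take one integer seed; per-animal/per-sample sub-streams
are spawned deterministically from it, so outputs are bit-reproducible.

* **Point clouds** are Gaussian mixtures rejection-sampled into the
  bounding box (the resulting edge truncation bias is accepted and
  documented).  The drivers emulate an arcuate-nucleus-like region of
  0.8 × 0.6 × 1.6 mm with ~300–400 neurons per animal and 5–8 animals
  per group, matching the study's group sizes (n = 7/8).
* **TRAP counts** are negative-binomial with a gene-shared shape
  parameter, paired input/IP per replicate, IP mean = input mean ×
  2^log2fc, library-size factors fixed to 1 (normalization is the
  downstream stage's job).  The default shape of 50 (overdispersion
  α = 0.02) reflects real bulk TRAP libraries of pooled hypothalami;
  `dispersion = inf` is the documented noiseless limit in which counts
  equal their means exactly.  The benchmark dataset (50 enriched genes
  at |log2fc| = 3 among 2,000 nulls, 4 replicates/group) follows the
  study's replicate design.
* **Rate series** default to the recording analysis design (12 × 10-s
  bins per window); Poisson noise draws per-bin counts, Gaussian noise
  adds N(0, sd) per bin.

What the generators do **not** emulate: conductance-based membrane
dynamics or channel pharmacology, imaging-level structure of the
cleared-brain volumes (registration error, segmentation artifacts),
library-size variation and composition bias in the count matrices, and
the wash-in/wash-out kinetics of peptide applications.  Passing tests
therefore demonstrate the correctness and calibration of the
estimators under the assumed statistical structure, not robustness of
the upstream acquisition pipeline.

## Problem sizes

The test suite and acceptance script run the null spatial calibration
at 200 replicates × 10 animals × 300 neurons, the 3σ null at 10,000
series, the SFA recovery at 100 replicates and the TRAP benchmark at
2,050 genes × 16 samples; the full suite completes in well under a
minute on one CPU, chosen so the calibration bands are tight relative
to their Monte-Carlo error.
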