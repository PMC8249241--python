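# pomcpop

Analysis toolkit for two intersectionally labeled subpopulations of
hypothalamic POMC neurons — the leptin-receptor-expressing
(POMC^Lepr+) and GLP-1-receptor-expressing (POMC^Glp1r+) cells of the
arcuate nucleus.  The package reimplements, as tested library code, the
quantitative procedures used to characterize these populations:

* **Intrinsic electrophysiology** (`pomcpop.ephys`): spike detection,
  input resistance R from the I–V slope of small hyperpolarizing
  pulses, membrane time constant τ and whole-cell capacitance C = τ/R,
  sag amplitude (minimum minus steady voltage during hyperpolarization),
  post-inhibitory rebound profiles (max 1/ISI vs pre-pulse potential),
  ascending/descending ramp spike ratios, linear excitability fits over
  spiking amplitudes only, the mono-exponential spike-frequency-
  adaptation fit *Y* = (*Y*₀ − plateau)·exp(−*K·T*) + plateau with
  *Y*₀ fixed to the maximum initial instantaneous frequency (SFA ratio
  = *Y*₀/plateau), and action-potential waveform metrics with the
  threshold defined at d*E*_M/d*t* = 10 mV/ms.
* **Peptide responsiveness** (`pomcpop.responsiveness`): the 3σ
  criterion — a neuron is responsive if the change in firing rate or
  membrane potential between a 120-s baseline and the end of the
  application (each 12 × 10-s bins) exceeds three baseline-bin standard
  deviations — plus baseline-subtracted charge transfer in nC for
  voltage-clamp peptide applications.
* **3D spatial statistics** (`pomcpop.spatial`): isotropic Gaussian
  kernel density fields over atlas-registered neuron coordinates, a
  cube partition of the common bounding box with per-animal counts, a
  density-factor correction (n_Glp1r/n_Lepr) equalizing unequal group
  totals, per-cube two-sided Student t-tests, coronal cross-sections
  and per-ROI projection densities normalized to neuron number.
* **TRAP enrichment** (`pomcpop.trap`): per-replicate IP/input count
  ratios, a clearly labeled differential-enrichment stand-in (Welch t
  on log2 ratios + Benjamini–Hochberg), single-cell cluster-marker
  overlap calls with log ratio = log2(n_Glp1r/n_Lepr) and the
  boundary-inclusive |log ratio| ≥ 2 rule, and per-gene z-scoring.
* **Summary-statistics inference** (`pomcpop.stats`): pooled and Welch
  two-sample t from printed (mean, s.e.m., n) triples, Holm–Šídák and
  Benjamini–Hochberg adjustments, and the 2^−ΔΔCt copy-number formula.
* **Synthetic data** (`pomcpop.synthetic`): seeded generators for every
  input — an adaptive integrate-and-fire neuron with *tonic* and
  *phasic-adaptive* presets, Gaussian-mixture 3D point clouds,
  negative-binomial TRAP count matrices with paired input/IP samples,
  and binned firing-rate series — so the entire pipeline runs with no
  external data.

## Worked example

`analysis/` contains numbered drivers that run each stage over the
synthetic study conditions and write their tables under `results/`.
For instance:

```bash
python analysis/01_ephys_features.py
```

prints the per-cell feature table for the two simulated presets:

```
        cell_id  input_resistance_gohm  ...  ramp_spike_ratio  rebound_fmax_hz  sfa_ratio
          tonic                  0.909  ...             1.333           62.500      1.293
phasic_adaptive                  1.016  ...             5.000          183.824      9.818

phasic vs tonic: SFA ratio 9.82 vs 1.29; ramp ratio 5.00 vs 1.33; rebound f_max 183.8 vs 62.5 Hz
```

i.e. the phasic-adaptive surrogate reproduces the recorded POMC^Glp1r+
phenotype — stronger spike-frequency adaptation, a higher
ascending/descending ramp spike ratio (voltage-dependent adaptation)
and a stronger post-inhibitory rebound — against the tonically firing
POMC^Lepr+-like preset.  Similarly, `analysis/05_summary_ttests.py`
recomputes the published figure-legend t statistics from their printed
summaries; for the NPY charge-transfer comparison
(6.54 ± 0.80 nC, n = 14 vs 3.53 ± 0.48 nC, n = 14) it prints
|t| = 3.226 with df = 26, within 0.2 % of the printed t = 3.23.

A `pomcpop` console script exposes the same stages as subcommands
(`simulate-ephys`, `extract-features`, `classify-response`,
`spatial-density`, `spatial-test`, `trap-normalize`, `trap-test`,
`overlap-score`, `summary-ttest`); every output TSV is accompanied by a
JSON run manifest with version, seed, parameters and input digests.

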