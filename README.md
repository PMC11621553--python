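# caspike

Quantification of symbiotic nuclear Ca²⁺ spiking from fluorescence
time series, ROI fluorescence quantification on confocal stacks, and the
gated group-comparison statistics used to analyse such data.

Legume root cells preparing for rhizobial or mycorrhizal infection show
repeated transient elevations of nuclear calcium ("Ca²⁺ spiking"), read out
as fluorescence peaks of a genetically encoded sensor such as NR-GECO1
sampled every 5 s for 10–15 min. This package is for researchers who need to
turn such per-nucleus traces into frequency/amplitude statistics and
defensible group comparisons — and to validate every step against synthetic
data with known ground truth.

## The method

For a trace F_t the local baseline is the mean of four flanking samples,

    B_t = (F_{t−15s} + F_{t−10s} + F_{t+10s} + F_{t+15s}) / 4

and the signal-to-noise ratio is SNR_t = (F_t − B_t)/B_t (an absolute
difference mode F_t − B_t is also available). Peaks are maximal runs of
consecutive samples with SNR ≥ θ (default θ = 0.3); per nucleus the package
reports

* **frequency** — peak count rescaled to a 10-minute window,
  n·600/((N−1)·dt);
* **amplitude** — the mean of peak (apex) SNR values, defined only when at
  least one peak exists;
* **spiking** — true iff frequency > 2 peaks per 10 min.

Image quantification follows the two-projection protocol: an automatic
threshold (isodata by default) on the *maximal* z-projection of a selected
sub-stack defines the ROI, and the mean grey value is measured on the
*average* z-projection of the same sub-stack. Time-lapse stacks are reduced
to traces by averaging each frame under an ROI mask.

Group comparisons run through a gated decision tree: Shapiro–Wilk normality
per group (with log₁₀ then Box–Cox transform attempts on failure), a
variance gate (F test for two groups, Bartlett for more), then Student t /
Welch t / one-way ANOVA + Tukey HSD, or Mann–Whitney / Kruskal–Wallis on the
nonparametric branch. The Mann–Whitney W follows the R convention (U of the
first group); its exact null distribution is computed by dynamic programming
for untied samples with n₁+n₂ ≤ 50. Every gate decision is kept in an audit
trail on the result.

A synthetic-data module generates NR-GECO1-like traces (exponential
photobleaching, refractory Poisson-like spike timing, linear-rise /
exponential-decay spike shape, additive Gaussian noise), labelled cohorts,
and toy image stacks with exact ground truth.

## Worked example

```python
from caspike import compute_snr, detect_peaks, summarize_nucleus
from caspike.simulate import SimulationParams, simulate_trace

params = SimulationParams(spike_rate=8.0, spike_amplitude=0.6,
                          noise_sigma=0.02, seed=7)
trace, truth = simulate_trace(params)    # 10 min at 5 s sampling
snr = compute_snr(trace)                 # relative mode, theta = 0.3
peaks = detect_peaks(snr)
summary = summarize_nucleus(trace, peaks)
print(f"simulated spikes : {len(truth.spike_times)}")
print(f"detected peaks   : {summary.n_peaks}")
print(f"frequency        : {summary.frequency:.1f} peaks / 10 min")
print(f"amplitude        : {summary.mean_peak_snr:.3f} (mean peak SNR)")
print(f"spiking nucleus  : {summary.spiking}")
```

prints

```
simulated spikes : 7
detected peaks   : 7
frequency        : 7.0 peaks / 10 min
amplitude        : 0.451 (mean peak SNR)
spiking nucleus  : True
```

Seven spikes were generated at a nominal rate of 8 per 600 s; all seven are
recovered. The mean apex SNR of 0.45 is what a relative amplitude of
A = 0.6 looks like through this baseline window: the two post-apex baseline
samples sit on the decaying spike, which pulls B_t up and the apex SNR below
A (see `docs/methods.md`).

The same analysis is available from the shell:

```sh
caspike simulate --config cohorts.yaml --out-dir sim/
caspike spikes --input sim/traces.csv --out-dir metrics/
caspike stats --input measurements.csv --tail two
caspike quantify-roi --stack stack.tif --first 2 --last 6
caspike run --config cohorts.yaml --out-dir run/    # full pipeline + report
```

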