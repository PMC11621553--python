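# Methods

## The SNR statistic and peak calling

The per-timepoint statistic contrasts fluorescence F_t with a local baseline
B_t averaged from the samples 10 s and 15 s before and after t. At the
native 5 s sampling this uses samples t±2 and t±3; other sampling intervals
are accepted only when 10/dt and 15/dt are whole numbers, otherwise the
baseline the statistic is defined on would not exist. The first and last
15 s of a trace (3 samples at dt = 5) have no complete window; SNR is
undefined there and excluded — no partial-window fallback is attempted,
because asymmetric windows reintroduce exactly the trend sensitivity the
symmetric window removes. A trace must therefore have at least 7 samples
(2·15/dt + 1) for any SNR value to exist.

Because the window is symmetric around t, any affine trace gives SNR ≡ 0
exactly, and slow exponential photobleaching (time constant ≥ 100·dt)
produces |SNR| orders of magnitude below the θ = 0.3 peak threshold, so
bleaching alone never calls peaks at default settings (asserted in the test
suite).

Two modes exist. The default, *relative* mode (F_t − B_t)/B_t is scale-free,
which is the only reading under which a fixed unitless threshold of 0.3 is
meaningful across nuclei of different brightness; the *absolute* difference
F_t − B_t is retained as an option. A peak is a maximal run of consecutive
samples with SNR ≥ θ (boundary inclusive); its apex is the run maximum,
earliest index on ties. No prominence or minimum-width criterion is applied:
the threshold alone defines peaks.

Per nucleus: frequency = n_peaks·600/duration with duration = (N−1)·dt
(acquisitions run 10–15 min; counts are normalised to a 10-minute window so
they are comparable); amplitude = mean apex SNR, defined only when
n_peaks ≥ 1; a nucleus is classified *spiking* iff frequency > 2 (strict).
Batch summaries emit two tables: a frequency table containing every nucleus
(zero-peak nuclei contribute frequency 0) and an amplitude table restricted
to nuclei with at least one peak — hence the amplitude n is never larger
than the frequency n for a group.

### What the apex SNR measures

The apex SNR systematically underestimates the generative relative
amplitude A: the two post-apex baseline samples (10 s and 15 s after the
apex) still carry the decaying spike, inflating B_t. With a 10 s decay
constant, apex SNR ≈ (A − 0.148·A)/(1 + 0.148·A); A = 0.6 reads as ≈ 0.47
and A = 0.4 as ≈ 0.32. The detection floor at θ = 0.3 is therefore near
A ≈ 0.37; group comparisons of amplitude are unaffected (the mapping is
monotone), but detected *frequency* develops a downward bias for cohorts
whose amplitudes approach the floor, because marginal spikes are missed.
This is an inherent property of a thresholded local-baseline detector, and
it is why the end-to-end two-cohort comparison can show a mild spurious
frequency deficit in the low-amplitude group on some seeds.

## Synthetic traces

The generator produces
F(t) = f0·exp(−t/bleach_tau)·(1 + Σ_k A_k·g(t−t_k)) + ε with
ε ~ N(0, noise_sigma·f0), negative values clipped to 0. The spike shape g
rises linearly over `rise_samples` samples (default 1 — a sharp transient at
5 s sampling) to 1 at the apex and decays as exp(−u/decay_tau). Defaults and
rationale:

| parameter | default | why |
|---|---|---|
| baseline_f0 | 100 a.u. | arbitrary scale; relative SNR is scale-free |
| bleach_tau | ∞ | bleaching is opt-in; ≥ 100·dt values are trend-safe |
| spike_amplitude A | 0.6 | mid-range spike, well above the detection floor |
| decay_tau | 10 s | returns to < 5% within 30 s, matching sharp nuclear transients at 5 s sampling, and keeps moderate spikes (A ≈ 0.4) above the θ = 0.3 floor |
| rise_samples | 1 | transients reach apex within one sample at dt = 5 |
| spike_rate | 8 / 600 s | a high-frequency (root-hair-like) regime; low-frequency regimes use 1–3 |
| refractory | 20 s | prevents unresolvable overlaps; 4 samples at dt = 5 |
| noise_sigma | 0.02 | SNR noise SD ≈ 0.022, ~13σ below θ: no false peaks |
| duration, dt | 600 s, 5 s | the acquisition regime the analysis assumes |

Spike apices are snapped to the sampling grid so the clean trace attains
f0·exp(−t_apex/bleach_tau)·(1+A) exactly at an isolated apex. Timing is a
renewal process with a hard dead time: each gap is
refractory + Exp(λ) with λ = r/(1 − r·refractory), r = spike_rate/600, so
the *mean* event rate equals the nominal rate exactly despite the refractory
gap (plain thinning of a Poisson stream would depress the realised rate by
~20% at the default settings and make rate-recovery checks meaningless).
Ground-truth gaps are guaranteed ≥ refractory after grid snapping.

Cohorts draw per-nucleus spike rate and amplitude from normal distributions
(clipped at small positive floors); a configurable fraction of nuclei is
non-spiking (rate 0). The generator emulates the statistical structure the
analysis assumes — stationary baseline, stereotyped spikes, additive
Gaussian noise. It does not emulate nuclear movement, focus drift,
multiplicative/photon noise, spike-shape variability or sensor saturation,
so passing tests demonstrate correctness of the analysis chain, not
robustness to those real-data artefacts.

Spike-count recovery is asserted against ground-truth spikes whose apex lies
in the SNR-evaluable window (samples 3 … N−4): a spike in the first or last
three samples is invisible to any detector built on this baseline, which
also gives the ~4–5% downward bias of mean detected frequency (≈ 7.7–8.0
observed for a nominal 8).

## Image quantification

Sub-stack selection is inclusive on both ends. Thresholding defaults to
isodata (the historical default family of the common ImageJ workflow), with
Otsu and `fixed:<value>` alternatives; the chosen grey level is always
recorded on the mask. Foreground is `image >= threshold` (bright fusion
signal on dark background). On noise-free two-level images both automatic
methods recover the ground-truth mask exactly; under noise with extreme
class imbalance (a few percent foreground) Otsu may bisect the background
mode — a known property of the criterion — while isodata remains exact at
moderate noise, which is one reason it is the default. No morphological
cleanup is applied. Quantification is deliberately asymmetric: the mask
comes from the max-projection (best contrast for contouring), the mean grey
value from the mean-projection of the same sub-stack.

## Statistics

Gates run at α = 0.05 (the ANOVA α extended to the gates for determinism).
Transform order is log₁₀ first, then Box–Cox with a single maximum-
likelihood λ fitted on the pooled sample (a per-group λ would test different
quantities across groups); both require strictly positive data and are
skipped otherwise. Nonparametric tests run on the original values — they are
rank-based and any monotone transform leaves them unchanged.

Dispatch: two normal homoscedastic groups → Student t; two normal
heteroscedastic (two-tailed variance-ratio F gate) → Welch t with
Welch–Satterthwaite fractional df; ≥3 normal homoscedastic (Bartlett) →
one-way ANOVA with Tukey HSD (studentized range) and a compact letter
display built from maximal cliques of the non-significance graph; non-normal
→ Mann–Whitney or Kruskal–Wallis (chi-square p with k−1 df, tie-corrected).
Two edge policies: any group with n < 3 forces the nonparametric branch
(Shapiro–Wilk needs n ≥ 3), and ≥3 normal groups failing Bartlett also fall
back to Kruskal–Wallis — a conservative choice, recorded in the audit trail,
since the engine deliberately offers no Welch-ANOVA.

Mann–Whitney: W is the U statistic of the first-listed group. The exact null
distribution is a 0/1-knapsack dynamic programme over rank sums in integer
arithmetic, used when n₁+n₂ ≤ 50 and the pooled sample is tie-free (the
two-tailed exact p is 2·min(P(U≤u), P(U≥u)) capped at 1); otherwise the
normal approximation with the usual tie correction and a continuity
correction (default on; both settings reproduce the reference two-tailed
values at 4 decimals). `p_from_W` exposes the statistic-only route for
verifying published (W, n₁, n₂) triples. One-tailed p is the upper tail of
the statistic as computed for the first-listed group.

Fisher's exact test (2×2, minimum-likelihood two-tailed rule), Shapiro–Wilk,
Bartlett, Kruskal–Wallis, the ANOVA F and the studentized-range
distribution delegate to scipy; the exact Mann–Whitney distribution is
cross-checked in the tests against brute-force enumeration of all
C(n₁+n₂, n₁) labelings, never against the library that could have produced
it.

## Pipeline

A run is a validated configuration (unknown keys rejected at any nesting
level) plus a global seed; per-cohort seeds derive from it through a seed
sequence, so reports are byte-identical across re-runs (no timestamps are
embedded; provenance carries the package version, seed and a SHA-256 config
hash). Box-plot summaries use Tukey's convention: whiskers at the most
extreme values within 1.5·IQR of the quartiles, values beyond flagged as
outliers. Reports render as JSON or markdown; plotting is intentionally out
of scope — the numeric box-plot statistics are the report.

## Problem sizes used in the checks

The shipped verification uses 100 seeded traces for frequency/recovery
checks, 1000 replicates for type-I calibration (both the plain decision-tree
route and the full cohort-simulation route at 15 nuclei per cohort), 100
replicates for the amplitude-difference power simulation at 30 nuclei per
cohort, and a 2×25-nucleus end-to-end pipeline run. These sizes give
Monte-Carlo standard errors comfortably inside the asserted bands (e.g.
±0.7% on a 5% rejection rate at 1000 replicates) while keeping the whole
suite fast.

## Known limitations

* The spike kinetics of the target sensor in this system are uncalibrated;
  decay_tau = 10 s is a modelling choice, and conclusions that depend on
  absolute amplitude calibration should not be drawn from apex SNR values.
* Detected frequency is biased low near the amplitude detection floor and by
  the undefined SNR edges (~5% at a 600 s acquisition).
* The exact Mann–Whitney route requires tie-free data; heavily tied discrete
  outcomes (e.g. small-count frequencies) make the rank tests conservative.
* Automatic thresholds are reliable on high-contrast two-level images;
  low-contrast or heavily imbalanced images should use a supplied mask or a
  fixed threshold.
* No tracking/registration: traces are assumed to come from a stable ROI.
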