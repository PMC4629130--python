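# Methods

This note documents the models, conventions and numerical choices behind
`cimexolf`, and what the synthetic-data tests do and do not demonstrate
about real recordings.

## Spike-train model

Simulated trains are inhomogeneous Poisson processes with a hard
non-paralyzable refractory period of 2 ms, sampled by thinning. The
instantaneous rate is

    r(t) = b + A(d) · k(t − t_on)

with spontaneous baseline `b`, dose-dependent evoked amplitude
`A(d) = A_max / (1 + 10^(h·(p50 − d)))` (a Hill law on the log10 dose
axis, midpoint `p50`, slope `h`), and temporal kernel `k`:

* **phasic** — `exp(−s/τ)` from onset, default τ = 0.3 s;
* **tonic** — 1 throughout the 0.5 s stimulus, then `exp(−s'/2 s)`, so
  firing stays elevated across the 2 s PSTH window, matching the
  sustained responses seen for the C5–C9 aldehydes.

Because a dead time `d_ref` deletes events, thinning at intensity λ
realizes the observed rate λ/(1 + λ·d_ref). The generator inverts this
exactly — it thins at `λ(t) = r(t)/(1 − r(t)·d_ref)` — so *configured
rates are realized rates*. This is what lets Monte-Carlo calibration
tests compare window statistics directly against configured values. The
inversion caps representable rates at 0.9/d_ref = 450 spikes/s, well
above the strongest archetype (≈294 spikes/s instantaneous).

Spontaneous baselines are not reported for the real preparations; the
package assumes Dα 20, Dβ 25, Dγ 20, C 15, E1 5, E2 8 spikes/s. Baseline
subtraction removes them from every response statistic, so their exact
values only affect replicate variance.

## Voltage traces and detection

Traces are a spike template (biphasic, dominant lobe at the center
sample, default width 1.2 ms, 100 µV) added at the sample nearest each
spike time plus white Gaussian noise. No 1/f or line-frequency components
are modeled. The detector thresholds at `k × 1.4826 × MAD` (default
k = 5), takes local extrema of supra-threshold excursions with the
polarity of the expected spikes, and enforces the refractory spacing.
All supra-threshold events are pooled — sensilla house several neurons
but whole-sensillum rates are the quantity of interest, so there is no
unit sorting. On noiseless renders detection is exact; at template-peak
to noise-SD ratio 8 recall and precision both exceed 0.95 (calibrated in
the test-suite and the acceptance script).

Simulated recordings run 3.5 s with stimulus onset at 1 s — long enough
for the full 0.5 s baseline window and the 2 s PSTH window. The real
acquisitions ran 10 s at 96 kHz; the trace generator reproduces that
geometry when asked (960 000 samples), but routine simulations use
shorter traces and 20 kHz rendering, which leaves every window statistic
unchanged.

## Counting conventions

Windows are half-open `[start, start+width)`, so adjacent windows
partition the recording. The response rate is
`(post − pre) × 2 spikes/s` over the 500 ms windows around onset;
negative (inhibitory) values are retained. The PSTH uses 100 ms bins over
2 s (20 bins); bin counts sum exactly to the window count. Stimulus
onset is always an explicit input — whether the response window starts at
valve opening or odor arrival is an acquisition-side decision the
analysis never infers.

## Response matrix and tuning statistics

Cell means are arithmetic means over replicates, SEM = sd/√n (0 for a
single replicate). Cells under 15 spikes/s are flagged non-responders;
the flag never alters stored values. Band edges follow the printed
inclusive bands, with ties at 50/100/150/200 assigned to the lower band
so the partition is exact. The excitatory criterion of 50 spikes/s is
20% of the strongest recorded response (248.5 spikes/s, nonanal on Dα).

Tuning curves place the sorted responses center-out — rank 1 at the
center, rank 2 immediately left, rank 3 immediately right, alternating —
with rate ties broken by odorant id, so the arrangement is deterministic
and always a permutation of the column. The K value is the corrected
sample excess kurtosis (the default of mainstream statistics packages);
it is computed on signed rates, inhibition included, and a raw
(non-excess) variant is exposed. K is location- and scale-invariant and
grows monotonically as a single dominant response sharpens.

## Odorant space

Distances are Euclidean in spikes/s on the mean-rate vectors at the
1:100 v/v reference dose, signed values kept. "Between-group linkage" is
implemented as unweighted pair-group average linkage (UPGMA):
`D(A,B) = mean over a∈A, b∈B of d(a,b)` — the meaning that the term
carries in the statistics packages that popularized it. PCA standardizes
sensillum columns (sample SD) and eigendecomposes the 6×6 correlation
matrix; the variance fraction of component *i* is λᵢ/6 with no
sample-size correction. Odorants are the observations and sensilla the
variables — the only orientation that yields a six-dimensional odorant
space. Loading signs are fixed (largest-magnitude loading positive) for
deterministic output.

The phasic/tonic index of a PSTH is mean rate in bins 11–20 divided by
peak rate in bins 1–5, clipped to [0,1], with 0.5 as the tonic label
threshold. The 0.5 threshold is this package's operationalization of a
qualitative distinction; the index itself is the robust quantity.

## Dose-response fitting

The Hill model `R(d) = b + (Emax − b)/(1 + (EC50/d)^n)` is fitted by
least squares in `(Emax, log10 EC50, n)` with the baseline fixed at 0 by
default (water-injected control oocytes show no response); a free
baseline is optional. Initialization is a grid over every observed dose
decade crossed with slopes {0.5, 1, 2}; the best bounded solution is
polished unconstrained (Levenberg–Marquardt), which recovers noiseless
parameters to ~1e-12 relative error. The EC50 CI is the linear
(Jacobian) approximation on the log10 scale. Exactly-flat series are
flagged unidentifiable without fitting; an EC50 outside
[min dose/10, max dose×10] is flagged extrapolated. Threshold doses
invert the fitted Hill analytically and can also be snapped to the
tested dose grid. SSR dose axes use log10 v/v dilution as a
pseudo-concentration; an EC50 fitted there is in dilution units, not
molar.

Oocyte traces use a raised-cosine rise to the peak (exact maximum on the
sample grid) followed by exponential desensitization and washout.
Amplitude extraction takes the extremum in the application window
relative to the pre-application median; when the baseline shows
measurable noise the window is first smoothed with a 25 ms moving
average so noise extremes do not inflate the peak, while noiseless
traces are read raw and the extraction stays exact. Channel kinetics
(activation/desensitization rate constants) are deliberately not
modeled — only peak-amplitude pharmacology.

## Synthetic archetypes: what they are and are not

The default preset encodes the qualitative response structure of the
antenna — aldehyde-dominated D types with nonanal strongest everywhere,
amine-specialist C, long-chain-tuned E2, silent E1, no excitatory acids —
using printed response rates where available and small sub-criterion
rates (uniform on [0,12) spikes/s from a fixed preset seed) elsewhere.
It is an *emulation*, not a fit: no generator parameter was estimated
from the measured response table, so matrix-level statistics computed on
synthetic data (band fractions, K values, PCA variance, extreme-pair
distances) approximate but do not reproduce the measured values. Tests
passing on synthetic data demonstrate that the estimators are correct
and calibrated, not that the preset is the real antenna. The replication
module (`cimexolf.replication`) computes the measured-matrix statistics
exactly once the supplementary table is transcribed.

Simulation sizes in the test-suite and acceptance script (hundreds of
seeded replicates per Monte-Carlo check, 200 fits per EC50 recovery
study, 50–100 detector traces) were chosen so that Monte-Carlo standard
errors are several times smaller than the tolerances being checked.

## Known limitations

* White Gaussian trace noise only; no drift, artifacts or line hum, so
  detector performance on real traces will be somewhat worse than the
  calibrated figures.
* The refractory period is a hard dead time shared by all pooled
  neurons, which slightly understates the peak rates a multi-neuron
  sensillum could sustain.
* Phasic/tonic labels from single replicates are noisy near the 0.5
  threshold (the early-peak estimate is biased upward by taking a max of
  five bins); averaging PSTHs over replicates before scoring is
  recommended.
* The elevated low-dose currents occasionally seen in real oocyte series
  are not modeled; simulated series are strictly Hill-monotone.
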