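# Methods

`nsdyn` analyses trial-to-trial variability of *network spikes* (NS) —
transient (~100 ms) synchronized bursts of population firing recorded
from cultured cortical networks on multi-electrode arrays under
periodic electrical stimulation.  The pipeline has four analysis
stages and a synthetic-recording generator that serves as its test
harness.  Time is seconds everywhere; firing rates are network-summed
spikes per millisecond; binning intervals are half-open `[start, end)`.

## Network-spike detection

The population firing rate (all electrodes pooled) is binned at 3 ms.
Each maximal run of bins above a threshold is one NS; runs separated by
less than a 200 ms merge window are merged (well below the 1–10 s
network refractory period, above within-burst rate dips).  Per event:
onset = left edge of the first supra-threshold bin; peak = center of
the earliest bin attaining the run maximum (ties to the earliest bin,
for determinism); peak rate = that maximum.  The peak time is the
fiducial used by all counting statistics.

The threshold is a free parameter.  The library default is
0.15 spikes/ms — the only rate anchor shared with the decay measure —
but note that at 3 ms bins a *single* background spike already reads
1/3 ≈ 0.33 spikes/ms, so on recordings with appreciable background the
threshold must sit above the quantization level.  For the synthetic
recordings produced by this package's generator the standard choice is
2.0 spikes/ms (6 spikes per 3 ms bin): with the default
0.02 spikes/ms background the per-bin false-positive probability is
~1e-10, while every envelope peak (5 spikes/ms) exceeds the threshold
2.5-fold.  An adaptive option (baseline mean + 3 SD outside stimulus
windows) is available but does not resolve the quantization floor.

Stimulus pairing: a stimulus is a success iff an NS *onset* falls
within 1 s after it; the earliest such NS is assigned and never
reassigned; unassigned NSs are spontaneous.

## Response features

For each success, a PSTH of the 1500 ms after the stimulus is built at
1 ms bins and smoothed twice: a 5 ms moving average (latency) and a
wider 30–100 ms moving average (decay; default 50 ms, one value per
run rather than per-network tuning).  Smoothing is centered with
shrinking windows at the edges (divisor = bins actually used);
zero-padding would bias latencies near the window edges.

* **Latency** = bin center of the first local maximum of the 5 ms
  trace whose height reaches `prominence_frac` (default 0.5) of the
  global maximum; if none qualifies, the earliest global-max bin.
  Reverberatory second peaks make a pure argmax ambiguous; early
  sub-half-height bumps are noise.  Plateaus resolve to their earliest
  bin.  A pure-argmax mode is config-exposed.
* **Decay duration** = time from the latency bin to the first drop of
  the wide-smoothed trace below 0.15 spikes/ms.  If the trace never
  drops inside the window, the decay is censored at `1500 − latency`
  and flagged; censored decays are excluded from autocorrelation and
  trajectory analyses by default (keeping them injects a ceiling
  artefact).  The latency bin is inherited from the 5 ms trace (not
  re-located on the wide trace); a config flag can re-locate it.
* **Local response probability** = fraction of successes among the 10
  preceding and 10 following stimuli, the index stimulus excluded
  (including it makes success-conditioned analyses partially
  tautological); at the series edges the denominator truncates to the
  actual neighbor count.

Latency is invariant under uniform rescaling of rates; decay is not
(it references an absolute floor) — both properties are tested.

## Fano-factor scaling

The NS train (absolute peak times, not referenced to stimuli;
spontaneous NSs between stimuli are included) is counted in disjoint
windows `[kT, (k+1)T)` anchored at t = 0, the partial final window
discarded, over a log-spaced grid (20 points/decade, 0.05 s up to the
largest T retaining at least `min_windows` complete windows).
`FF(T) = var(Z)/mean(Z)` with the n−1 variance.

**Why `min_windows = 50`.**  The n−1 correction removes the iid bias
only.  For long-memory counts the window sample mean absorbs the
low-frequency variance: for fractional-Brownian-type counts,
`E[var̂] ≈ var · (1 − n^(2H−2))` over n windows, so FF is
under-measured by more than 50% at n = 10 windows when H is near 1.
Retaining T only while ≥ 50 windows exist keeps that bias moderate;
beyond it the estimator is bias- (not variance-) limited.  The same
algebra implies a hard ceiling: on a single 24 h record no mechanism
can *measure* an exponent much above ~0.7 with this estimator, because
at H → 1 the low-frequency power is absorbed into each record's mean
(see Limitations).

**Power-law fit.**  Ordinary least squares of log10 FF on log10 T;
`beta` = slope, `alpha` = 10^intercept.  The default "post-minimum"
rule for the final rising section starts at twice the T of the FF
minimum and is capped at the final 1.25 decades: just above the
refractoriness dip the curve still bends away from its short-time
plateau (the Bernoulli occurrence floor decays only as a power of the
window count), and an uncapped range mixes that curvature into the
slope.  If the minimum falls inside the final section (flat or
declining curves — e.g. renewal surrogates), the final 1.25 decades
are fitted with a warning; a near-zero slope is then the honest
answer.  Explicit `(T_lo, T_hi)` overrides are supported.

**Surrogate.**  Inter-event intervals are permuted uniformly at random
(seeded Fisher–Yates via the generator's permutation); first event
time, span and interval multiset are preserved exactly.  The surrogate
is renewal by construction; its FF curve is fitted over
`[100 s, duration/10]` on a 10-window grid — the long-memory bias
constraint above does not apply to a renewal train.  Note that a
heavy-tailed interval distribution (long silent epochs are the flip
side of strongly clustered occurrence) produces a renewal FF transient
that can extend beyond 100 s, so small positive surrogate slopes
(~0.1–0.2) can occur without any residual long-range order.

## Serial structure

Feature series over successful responses are treated as equally
spaced: the autocorrelation is computed over serial-index lags with
the full-series mean and the full-length denominator,

    rho[l] = Σ_{i=1..n−l} (x_i − m)(x_{i+l} − m) / Σ_{i=1..n} (x_i − m)²,

implemented verbatim (no unbiased per-lag variant), guaranteeing
`rho[0] = 1` and `|rho| ≤ 1` and damping drift artefacts.  Failed
responses are dropped, not interpolated.  The warped time axis maps
lag l to `l × mean inter-response interval` of the retained responses.

Latency–decay trajectories pair the two features per success, smooth
each coordinate with a centered 11-response moving average (window
config-exposed; odd by construction), and segment the sequence into
consecutive 50-response ranges.  The plane's center of mass is the
coordinate-wise geometric mean (log-log plane; linear option exposed).

## Synthetic recordings

The generator is a statistical test harness, not a biophysical model.
Defaults are the study conditions; they are set once and are not
per-test dials.

| parameter | default | why |
|---|---|---|
| duration | 3600 s (86400 s for Fano runs) | standard session / 24 h protocol |
| stim_rate | 1/5 s⁻¹ | rate of the long stimulation runs |
| n_electrodes | 60 | standard MEA layout |
| baseline_rate | 0.02 spikes/ms (network) | sparse inter-burst background |
| refractory | 2 s | inside the stated 1–10 s range |
| response_threshold | z = 0.77 | response probability ≈ 0.22 in long evoked recordings |
| amplitude | 5 spikes/ms | envelope peak well above threshold and floor |
| rise_sigma | 10 ms | sharp synchronized recruitment |
| latency base/gain | 150 / 30 ms | latencies ~100–250 ms |
| decay base/gain | 90 / 25 ms | onset→floor event scale ≈ 100 ms |
| latent tau (OU) | 100 s | minutes-scale excitability drift |
| spont grid / gate | 2.5 s, z = −0.25 | spontaneous NS every ~4 s in active cultures |

Two latent processes stand for effective exciting/restoring forces:
`e(t)` gates responses (`e ≥ threshold`, plus refractoriness on the
would-be peak time) and lengthens decay; `i(t)` lengthens latency.
Modes: two independent OU processes (`ou`); a sinusoid of programmed
period in responses plus OU noise on `i` (`oscillatory`); exact
fractional Gaussian noise on `e` via Davies–Harte circulant embedding
(`fgn`).  `coupled_latents` sets `i = −e`, making one process drive
both failure probability and latency (the configuration that
reproduces the inverse probability–latency relation).

Each response is an inhomogeneous-Poisson burst under a rate envelope:
Gaussian rise peaking at amplitude A exactly L ms after the stimulus,
then exponential fall with time constant `D / ln(A/0.15)` so the
envelope crosses the 0.15 spikes/ms floor at exactly L + D — the two
measured fiducials are exact by construction.  Spikes scatter over
electrodes uniformly (no stage uses electrode identity).  A
deterministic sampling mode places spikes at quantile positions of the
cumulative envelope, giving noise-free traces for exact recovery
tests.  Spontaneous mode gates a denser candidate grid (2.5 s,
p ≈ 0.6) by the same latent; the higher event rate pushes the Poisson
floor of the Fano curve down so the rising section spans more
measurable decades.

**Hurst calibration.**  Asking for `target_ff_exponent = β₀` does not
set `H = (1+β₀)/2` naively: the threshold nonlinearity compresses the
latent autocovariance (only the Hermite-rank-1 term carries the full
memory) and the window estimator under-measures long-memory variance
(above), so the *measured* exponent falls 0.1–0.25 short of `2H − 1`.
The generator therefore inverts an empirically characterized transfer
table (latent exponent → measured exponent, frozen in `synth.py`,
characterized once on the standard 24 h protocol) so that the exponent
*recovered by the pipeline* is β₀.  Targets above the mechanism's
measurable ceiling (~0.70 evoked, ~0.68–0.73 spontaneous) trigger a
warning and use the ceiling configuration.

## What the generator does and does not emulate

It reproduces: the NS shape fiducials, response failures with
minutes-scale structure, refractoriness (exact, by construction),
latency/decay coupling to latent states, oscillatory serial structure,
and long-range-correlated occurrence with a controllable measured
exponent.  It does not emulate: spatial electrode structure,
per-electrode waveforms, stimulus artefacts, amplitude dynamics,
pharmacological dose–response behavior, or non-stationary drift in
mean responsiveness.  Passing recovery tests therefore validates the
*analysis chain*, not claims about real tissue.

## Problem sizes and runtime

The standard validation runs use: 24 h simulated recordings
(~17,280 stimuli, ~2–3 M spikes) for Fano-exponent recovery, cohorts
of 8 (evoked) and 7 (spontaneous) replicate networks matching the
cohort sizes behind the reference averages; 500 zero-noise responses for
feature recovery; 2000 stimuli for the oscillation and coupling
experiments.  The full test suite runs in ~1 minute, the acceptance
script in ~1 minute on one CPU.

## Known limitations

* **Spontaneous exponent ceiling.**  Pooled characterization over
  ~100 simulated networks puts the largest spontaneous exponent this
  chain can measure at ≈ 0.68–0.73 (finite-record variance absorption
  at H → 1, plus threshold-transfer compression).  The spontaneous
  recovery experiment therefore reports its ceiling rather than the
  nominal 0.89 target; depending on the seed the cohort mean lands a
  few hundredths either side of 0.68.
* **Surrogate transient.**  Heavy-tailed inter-NS intervals give the
  renewal surrogate a positive FF slope transient reaching into the
  100 s range (see above); the surrogate contrast is qualitative
  (rising vs near-flat), and its fitted slope is seed-dependent.
* The detection threshold, merge window, T-grid, fit-section rule and
  window anchoring are all config-exposed conventions; results at the
  margins (e.g. slopes near band edges) can shift by a few hundredths
  under defensible alternative conventions.
* Even-width wide smoothing (e.g. 50 ms) is centered with a half-bin
  asymmetry inherited from the convolution; at the 1 ms PSTH
  resolution this is negligible relative to the stated tolerances.
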