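# nsdyn

Trial-to-trial variability of evoked **network spikes** in cultured
cortical networks on multi-electrode arrays.

Cortical cultures respond to periodic electrical stimulation with
network spikes (NS): transient (~100 ms) synchronized bursts of
population firing with a threshold-like character and a network
refractory period of 1–10 s.  Across repeated, identical stimuli the
responses vary — failures cluster, latencies drift — and the structure
of that variability spans milliseconds to many minutes.  `nsdyn`
implements the complete analysis chain for such recordings, for
electrophysiologists and modelers working with MEA spike data:

* **Detection** — threshold crossing of the population firing rate
  (3 ms bins) with run merging; events carry onset, peak time and peak
  rate; NSs are paired to stimuli (success iff an NS onset falls
  within 1 s).
* **Response features** — per-stimulus PSTH (1 ms bins, 1500 ms
  window); *latency* = time to the first maximum of the 5 ms-smoothed
  rate; *decay duration* = time from that maximum to the first drop of
  a 30–100 ms-smoothed rate below 0.15 spikes/ms; *local response
  probability* over a ±10-stimulus window.
* **Fano-factor scaling** — count sequences Z(T) of the NS train over
  log-spaced windows; FF(T) = var(Z)/mean(Z); power-law fit
  FF ≈ αT^β of the final rising section (β ≈ 0 for a renewal process;
  0 < β < 1 indicates long-range correlation of NS occurrence);
  ISI-shuffled surrogates as the renewal control.
* **Serial structure** — autocorrelation of latency/decay series over
  serial-index lags, ρ(l) = Σ(xᵢ−μ̂)(xᵢ₊ₗ−μ̂)/Σ(xᵢ−μ̂)², with a warped
  seconds axis from the mean inter-response interval; latency–decay
  plane trajectories with moving-average smoothing and 50-response
  segments.
* **Synthetic recordings** — a seeded generator producing MEA-like
  spike tables with ground truth: latent excitability states (OU,
  oscillatory, or exact fractional Gaussian noise), probabilistic
  response failures, refractoriness, programmable latency/decay, and
  long-range-correlated NS occurrence with a calibrated measured
  Fano exponent.  Every pipeline stage is testable against truth
  without access to recordings.

See `docs/methods.md` for the full model description, parameter
tables, estimator caveats and limitations.

## Worked example

```python
import numpy as np
from nsdyn import (SynthConfig, generate_recording, population_rate,
                   detect_network_spikes, pair_stimuli, compute_features)

cfg = SynthConfig(duration=3600.0, seed=1)          # 1 h at 1/5 s^-1
spikes, stims, truth = generate_recording(cfg)
rate = population_rate(spikes)                      # 3 ms bins
ns = detect_network_spikes(rate, threshold=2.0)     # spikes/ms
table, assigned = pair_stimuli(ns, stims)
table = compute_features(spikes, table)

ok = table[table["success"] & table["latency_ms"].notna()]
print(f"{spikes.n_spikes} spikes, {len(stims)} stimuli, {len(ns)} network spikes")
print(f"response probability: {table['success'].mean():.2f}")
print(f"median latency: {ok['latency_ms'].median():.1f} ms, "
      f"median decay: {ok['decay_ms'].median():.1f} ms")
print(f"min inter-NS interval: {np.diff(ns.peak_times).min():.2f} s")
```

prints

```
96211 spikes, 719 stimuli, 100 network spikes
response probability: 0.14
median latency: 144.0 ms, median decay: 136.0 ms
min inter-NS interval: 4.94 s
```

All 100 detected NSs are stimulus-evoked here; the realized response
probability of a single hour fluctuates widely around its long-run
mean (0.22) precisely because NS occurrence is long-range correlated —
that is the phenomenon the Fano analysis quantifies.  The minimum
inter-NS interval respects the 2 s network refractory period (with a
5 s stimulus period, successive evoked peaks are ≈ 5 s apart).

The same stages are available from a shell via the `nsdyn` CLI:

```sh
nsdyn simulate --duration 3600 --seed 1 --out-prefix demo
nsdyn detect --spikes demo.spikes.tsv --stimuli demo.stimuli.tsv \
             --threshold 2.0 --out-prefix demo
nsdyn features --spikes demo.spikes.tsv --responses demo.responses.tsv
nsdyn fano --ns-train demo.ns_train.tsv --out demo.fano.tsv
nsdyn serial --responses demo.responses.tsv --out-prefix demo
nsdyn run --config run.toml --out-dir out/     # all stages + manifest
```

All interchange formats are tab-separated text (documented in
`nsdyn.io`); `nsdyn run` writes a `manifest.json` with the effective
configuration and SHA-256 digests of every output, so identical
config + seed reproduces identical files.

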