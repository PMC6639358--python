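# nirlymph

Quantification of collecting-lymphatic pump function from near-infrared
(NIR) fluorescence imaging.

## The problem

Collecting lymphatic vessels move lymph by intrinsic contraction of their
pumping segments (lymphangions). In NIR lymphatic imaging — an intradermal
injection of an NIR dye, imaged at ~10 frames/s — each contraction pushes
a bolus of dye past a fixed region of interest and appears as a transient
intensity spike, a **packet**, bounded by intensity troughs. Tracking how
packet dynamics change after lymphatic injury, during swelling and its
resolution, is how pump failure is measured in rodent lymphedema models.
This package implements that measurement chain for researchers running
such experiments: packet detection and packet metrics, cuff-ramp pumping
pressure, fluorescent tail area, swelling quantification, and the cohort
statistics relating swelling to function — plus a synthetic-data module
that generates every input with known ground truth, so each stage is
validated by parameter recovery.

## Core quantities

For packets *i = 1…n* detected in a steady-state window of duration
*T* (default 5–20 min post-injection), with trough bounds
*t*<sub>min *i*</sub>, *t*<sub>max *i*</sub> and baseline *b*ᵢ (the
packet-minimum intensity):

* **Lymphatic fluorescence transport** = Σᵢ ∫ f(t) dt / *T*
  (integral over each packet; by default f − *b*ᵢ is integrated, making
  the metric insensitive to residual background; the literal raw mode is
  available and stamped into outputs). A proxy for actively pumped flow.
* **Packet frequency** = 60·*n*/*T* per minute (contraction rate).
* **Packet amplitude** = mean(peak − *b*ᵢ), a proxy for contraction
  amplitude / ejection fraction; reported missing (not 0) when no packets
  exist.
* **Pumping pressure**: a tail cuff is inflated to 80 mmHg for 5 min,
  dropped to 55, then stepped to 0 in 2.5 mmHg/5 s decrements. The
  estimate is the cuff pressure at which distal intensity first rises
  halfway between its occluded minimum and restored maximum — the
  maximal pressure the vessel chain pumps against.
* **Fluorescence area**: fraction of the tail's projected area above a
  per-frame Otsu (two-cluster) threshold; proxy for capillary-network
  recruitment.
* **Swelling**: maximum transverse tail width from 2-D projected masks,
  π·width as a circumference proxy, normalized to the pre-surgery
  baseline; animals classify as `gt20`/`le20` by whether peak swelling
  exceeds 20 % at any timepoint.

See `docs/methods.md` for the detection algorithm, estimator design and
noise handling.

## Worked example

```python
from nirlymph.simulate import TraceSimParams, RampSimParams, \
    simulate_packet_trace, simulate_ramp
from nirlymph.io import crop_steady_state
from nirlymph.packets import compute_metrics
from nirlymph.pressure import estimate_pumping_pressure

# 20 min recording, healthy contraction rate, SNR 5
params = TraceSimParams(duration_s=1200, packet_frequency_per_min=6.7,
                        packet_amplitude=10.0, noise_sd=2.0, seed=42)
trace, truth = simulate_packet_trace(params)
m = compute_metrics(crop_steady_state(trace))
print(f"packets detected : {m.n_packets}")
print(f"frequency        : {m.frequency_per_min:.2f} / min")
print(f"transport        : {m.transport:.3f} a.u.")
print(f"mean amplitude   : {m.mean_amplitude:.2f} a.u.")

rec, _ = simulate_ramp(RampSimParams(true_pumping_pressure_mmHg=27.5,
                                     noise_sd=4.0, seed=42))
res = estimate_pumping_pressure(rec)
print(f"pumping pressure : {res.pressure_mmHg:.1f} mmHg")
```

prints

```
packets detected : 100
frequency        : 6.67 / min
transport        : 2.270 a.u.
mean amplitude   : 10.58 a.u.
pumping pressure : 27.5 mmHg
```

100 packets over the 15 min steady-state window is 6.67/min against the
simulated 6.7/min; transport 2.270 a.u. against a ground-truth
time-normalized pulse area of 2.222 a.u. (+2 %); amplitude and pressure
recover the simulated 10 a.u. and 27.5 mmHg.

The same flows are scriptable from the shell:

```sh
nirlymph simulate trace --seed 42 --out run/sim
nirlymph analyze --inputs run/sim --out run/metrics
nirlymph simulate cohort --seed 1 --out run/cohort
nirlymph report --table run/cohort/cohort.csv --out run/report
```

Each output directory carries a `manifest.json` (tool version, seed,
config hash), and identical config + seed reproduces outputs
byte-for-byte.

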