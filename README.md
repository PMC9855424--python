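# cardiopheno

Quantitative phenotyping for iPSC-derived cardiomyocyte (iPSC-CM) disease
models — the measurement side of a Danon-disease-style study in which LAMP2
loss degrades sarcomere organization, calcium handling and mitochondrial
health. The package turns raw microscopy-derived signals into the numbers
such studies report:

* **Sarcomere organization** (`cardiopheno.sarcomere`) — a striation
  intensity profile I(x) sampled along a myofibril is mean-subtracted,
  Hann-windowed and Fourier-transformed into a power distribution over
  spatial frequency. The main in-band peak gives the sarcomere period
  (1/f*, ~2 µm in healthy cells) and its height — calibrated so a
  unit-amplitude cosine scores 1.0 — is the regularity index: disarrayed
  sarcomeres have lower peak power and often a lengthened period.
* **Calcium transient kinetics** (`cardiopheno.calcium`) — from Fluo-4
  ΔF/F0 or background-corrected Fura-2 ratio R = (F340−bg)/(F380−bg)
  traces: per-beat time to peak (onset at 10% of amplitude), amplitude,
  local diastolic level, and the decay time constant τ from a
  three-parameter monoexponential fit y(t) = A·e^−(t−t_peak)/τ + C; per
  cell: beating rate, the beat-interval SD, and the irregular-event
  fraction (intervals deviating >25% from the median) as pro-arrhythmia
  metrics.
* **Mitochondrial morphometry and ROS** (`cardiopheno.mito`) — MiNA-style
  skeleton statistics (individuals, networks, branches per network,
  branch lengths with √2 diagonal steps, footprint) and intensity
  readouts: MitoSOX/MitoTracker mean ratio and CellROX RFU.
* **Quantification statistics** (`cardiopheno.stats`) — 2^−ΔΔCT fold
  changes, Western-blot band ratios with control normalization, and
  pairwise t comparisons with Holm–Šidák or Tukey adjustment.
* **Synthetic ground truth** (`cardiopheno.synthetic`) — deterministic
  generators for every input type (striation profiles/images, paced or
  spontaneous calcium traces, Fura-2 pairs, toy mitochondrial networks,
  ROS channel pairs), each returning a `SyntheticSpec` with the exact
  truth the analysis should recover. All validation is
  parameter-recovery against these generators.

## Worked example

Generate a 60 s Fura-2-like trace paced at 0.5 Hz and measure it:

```python
from cardiopheno.synthetic import make_calcium_trace, make_fura2_pair
from cardiopheno.calcium import compute_ratio, extract_beats, summarize_trace

ratio, spec = make_calcium_trace(duration_s=60, fs_hz=50, interval_s=2.0,
                                 ttp_s=0.2, tau_s=0.4, amplitude=0.6,
                                 diastolic=0.9, signal_kind="ratio")
f340, f380, _ = make_fura2_pair(ratio, f380_baseline=1000.0)
trace = compute_ratio(f340, f380)
s = summarize_trace(trace, extract_beats(trace))
print(f"{s.n_beats} beats at {s.beat_rate_hz:.3f} Hz, interval SD {s.interval_sd_s} s")
print(f"tau {s.mean_tau_s:.3f} s, amplitude {s.mean_amplitude:.3f}, "
      f"diastolic {s.mean_diastolic:.3f}")
```

prints

```
30 beats at 0.500 Hz, interval SD 0.0 s
tau 0.400 s, amplitude 0.594, diastolic 0.906
```

— the pacing rate and decay constant are recovered exactly; amplitude and
diastolic level differ from the generator values (0.6 / 0.9) by ~1%
because the per-beat baseline is measured locally on a trace whose decay
has not fully returned before the next stimulus.

The same pipelines are scriptable from the shell, e.g.

```sh
cardiopheno simulate striation_profile --period-um 1.99 --jitter 0.03 \
    --noise 0.1 --seed 1 --out profile.csv
cardiopheno sarcomere --profile-csv profile.csv --pixel-um 0.1 --out scores.csv
```

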