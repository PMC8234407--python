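# eogkit

Gaze decoding from forehead biosignals for hands-free device control.

A single soft sensor on the forehead picks up two superimposed signals: the
electrooculogram (EOG) — the cornea–retina dipole projects horizontal
saccades as signed spikes of roughly 500–600 μV (left gaze positive, right
gaze negative) — and a strain signal, the relative resistance change ΔR/R0
of the sensor as vertical gaze stretches or compresses the skin (down gaze
stretch, ΔR > 0; up gaze compression, ΔR < 0 — the convention is
configurable). Five gaze states (straight, up, down, left, right) map to
five wheelchair commands (stop, forward, backward, turn left, turn right).

`eogkit` implements the complete decoding chain as a tested library plus a
thin CLI, with a synthetic trial generator standing in for recorded data:

1. **Synthetic trials** — raised-cosine saccade spikes, plateau-shaped
   strain events, 50 Hz powerline pickup, white noise, baseline drift; a
   `rigid` electrode mode doubles the contact-dependent noise.
2. **Analog front end** — ideal instrumentation amplification, a zero-phase
   48–52 Hz notch, a zero-phase 10 Hz low-pass (EOG energy lies below
   10 Hz), 12-bit A/D conversion.
3. **Kalman smoothing** — scalar random-walk observation model,

       x̂ₖ⁻ = A·x̂ₖ₋₁ + B·uₖ₋₁         Pₖ⁻ = A·Pₖ₋₁·Aᵀ + Q
       Kₖ  = Pₖ⁻Cᵀ(C·Pₖ⁻Cᵀ + R)⁻¹     x̂ₖ = x̂ₖ⁻ + Kₖ(zₖ − C·x̂ₖ⁻)
       Pₖ  = Pₖ⁻ − Kₖ·C·Pₖ⁻

4. **Wavelet separation** — the filtered signal is a superposition of the
   slow strain component and the faster EOG component; a multilevel DWT
   (db4, 6 levels) with coefficient thresholding and an event-masking pass
   splits it into the two branches, which always sum back to the input.
5. **Features** — per channel: signed peak amplitude, duration, and
   inter-event interval of the dominant supra-threshold event, plus the
   event count, z-scored into the 8-vector ζ.
6. **Classification** — ten one-against-one SVMs with the Gaussian kernel
   k(x,x′) = exp(−‖x−x′‖²/2σ²); the votes aggregate to a scalar score
   V = Σ w_k·m_k over the plurality winner's contests, decoded by open
   intervals: up (0,1), down (−1,0), left (1,2), right (−2,−1), with
   boundary values (|V−b| ≤ ε) read as straight gaze.
7. **Metrics** — a 5×5 confusion matrix in a reversed-row convention
   (correct counts on the anti-diagonal), per-state recognition rate
   Sₙ = a₍₆₋ₙ₎ₙ / Σᵢ aᵢₙ and overall accuracy 0.2·ΣSₙ.

A `sensors` module collects the film-design calculators: cantilever
stiffness K = E·W·T³/6L³, plate load–deflection
P = π⁴·E·T³·c / 6(1−ν²)L⁴, tensile modulus E = F·L/(A·ΔL), and
voltammetric resistivity ρ = U·S/(I·L) with its reciprocal conductivity.

## Worked example

```python
import numpy as np
from eogkit import (PipelineConfig, TraceConfig, generate_dataset,
                    generate_trial, process_trace, run_pipeline, train)

trace_cfg, pipe_cfg = TraceConfig(), PipelineConfig()
traces, manifest = generate_dataset(100, trace_cfg, seed=0)
features = np.vstack([process_trace(t, pipe_cfg).features for t in traces])
model = train(features, manifest["state"].tolist())

trial = generate_trial("left", trace_cfg, seed=903)
state, event = run_pipeline(trial, model, pipe_cfg)
print(state, event.command)
```

prints

```
left turn_left
```

— the noisy left-gaze trial's positive EOG spike survives the front end and
Kalman smoothing, lands in the fast wavelet branch, is detected and scored
at V = +1.5 (the `left` interval midpoint), and maps to the turn-left
command. The `examples/` directory walks through each stage the same way
(`python examples/06_benchmark.py` prints the full confusion matrix; a
600-trial run scores 99.7 % overall accuracy at default noise).

The same flows are scriptable from the shell:

```bash
eogkit simulate --n 600 --out data --seed 1
eogkit train --data data/manifest.csv --out model.json
eogkit classify --trace data/trial_0000.csv --model model.json
eogkit benchmark --n 600 --seed 1 --mode rigid
eogkit sensor-calc cantilever --width 0.025 --thickness 3e-4 \
    --length 0.06 --modulus 286e3
```

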