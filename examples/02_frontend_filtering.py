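"""Emulate the analog acquisition chain and verify its spectral contract.

Probes the amplifier → 48–52 Hz notch → 10 Hz low-pass → 12-bit ADC chain
with sinusoids and a noisy saccade trial, printing the attenuation each
stage achieves.
"""

import numpy as np

from eogkit import FrontendConfig, TraceConfig, apply_frontend, generate_trial
from eogkit.frontend import lowpass_filter, notch_filter

fs = 250.0
t = np.arange(2000) / fs
mid = slice(500, 1500)


def db(x, y):
    return 20 * np.log10(np.sqrt(np.mean(y[mid] ** 2))
                         / np.sqrt(np.mean(x[mid] ** 2)))


for freq in (5.0, 10.0, 50.0):
    x = np.sin(2 * np.pi * freq * t)
    print(f"{freq:5.0f} Hz probe: notch {db(x, notch_filter(x, fs)):+7.2f} dB, "
          f"low-pass {db(x, lowpass_filter(x, fs, 10.0)):+7.2f} dB")

trial = generate_trial("left", TraceConfig(), seed=5)
clean = generate_trial("left", TraceConfig().noise_free(), seed=5)
out = apply_frontend(trial.eog, FrontendConfig())
print(f"\nnoisy left-gaze trial: raw peak {np.max(np.abs(trial.eog)):.0f} uV, "
      f"digitized peak {np.max(np.abs(out)):.0f} uV "
      f"(clean spike {clean.events[0][3]:.0f} uV)")
print("The 50 Hz interferer is notched out and the sub-10 Hz saccade energy "
      "passes; the ADC step at this scale is ~0.8 uV input-referred.")
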