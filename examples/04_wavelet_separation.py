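"""Separate a compound saccade + strain signal into its two components.

Builds a known mixture — a 0.25 s EOG pulse plus a 1.8 s strain plateau —
and splits it with the multilevel wavelet separator, printing how well each
recovered component correlates with its ground-truth ingredient.
"""

import numpy as np

from eogkit import WaveletConfig, separate_components
from eogkit.synth import _plateau, _raised_cosine_pulse

fs = 250.0
t = np.arange(1000) / fs
pulse = _raised_cosine_pulse(t, onset=2.8, duration=0.25, amplitude=550.0)
plateau = _plateau(t, onset=0.4, duration=1.8, amplitude=500.0, ramp=0.5)
compound = pulse + plateau

strain, eog = separate_components(compound, WaveletConfig(), sampling_rate=fs)

print(f"corr(strain component, true plateau) = {np.corrcoef(strain, plateau)[0,1]:.3f}")
print(f"corr(EOG component,   true pulse)    = {np.corrcoef(eog, pulse)[0,1]:.3f}")
print(f"additivity |strain + eog - compound| = {np.max(np.abs(strain + eog - compound)):.2e}")
print(f"pulse leakage into strain branch     = {np.max(np.abs(strain - plateau)):.1f} uV peak")
print("\nThe slow plateau lands in the coarse (approximation) branch, the "
      "saccade spike in the detail branches; an event-masking pass keeps the "
      "spike's low-frequency tail out of the strain estimate.")
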