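"""Synthetic two-channel (EOG + strain) gaze-trial generator.

The generator emulates forehead recordings during five gaze states:

* ``left`` / ``right`` — a single horizontal saccade producing a positive /
  negative EOG spike of 500–600 μV (cornea–retina dipole swinging toward or
  away from the inner canthus).
* ``up`` / ``down`` — vertical gaze compressing or stretching the forehead
  epidermis, seen as a plateau-shaped relative-resistance change (ΔR/R0) on
  the strain channel while the EOG channel stays near baseline.
* ``straight`` — both channels at baseline.

Noise sources follow typical surface-biopotential acquisition: 50 Hz
powerline pickup, white Gaussian sensor noise, and slow sinusoidal baseline
drift.  A ``rigid`` electrode mode multiplies the powerline and white-noise
amplitudes to emulate the poorer skin contact of conventional rigid
electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

#: Canonical gaze-state vocabulary, in the column (actual-state) order used
#: by the confusion-matrix convention downstream.
STATES: Tuple[str, ...] = ("straight", "up", "down", "left", "right")

POWERLINE_HZ = 50.0


class UnknownStateError(ValueError):
    """Raised when a gaze state is not one of the five known states."""


@dataclass
class TraceConfig:
    """Generator and acquisition parameters for one synthetic trial.

    Amplitudes are in μV for the EOG channel and dimensionless ΔR/R0 for the
    strain channel.  ``strain_noise_scale`` converts an EOG-channel noise
    amplitude (μV) into the equivalent strain-channel amplitude; the default
    ``1/25000`` makes both channels contribute equal-magnitude noise once the
    strain channel is conditioned to μV-equivalent units by the front end.
    """

    sampling_rate: float = 250.0
    trial_duration: float = 4.0
    eog_spike_amplitude_range: Tuple[float, float] = (500.0, 600.0)
    eog_spike_duration_range: Tuple[float, float] = (0.15, 0.35)
    strain_rel_magnitude: float = 0.02
    strain_event_duration_range: Tuple[float, float] = (1.5, 2.2)
    strain_ramp_time: float = 0.5
    powerline_amplitude: float = 20.0
    white_noise_sd: float = 15.0
    drift_amplitude: float = 30.0
    electrode_mode: str = "flexible"
    rigid_noise_factor: float = 2.0
    strain_noise_scale: float = 1.0 / 25000.0
    down_is_stretch: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.sampling_rate <= 2.0 * POWERLINE_HZ:
            raise ValueError(
                f"sampling_rate must exceed {2 * POWERLINE_HZ} Hz to represent "
                f"the {POWERLINE_HZ} Hz powerline component, got {self.sampling_rate}"
            )
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        for name in ("eog_spike_amplitude_range", "eog_spike_duration_range",
                     "strain_event_duration_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name} must satisfy 0 <= low <= high, got {(lo, hi)}")
        for name in ("powerline_amplitude", "white_noise_sd", "drift_amplitude",
                     "strain_rel_magnitude", "strain_noise_scale", "strain_ramp_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.electrode_mode not in ("flexible", "rigid"):
            raise ValueError(f"electrode_mode must be 'flexible' or 'rigid', "
                             f"got {self.electrode_mode!r}")
        if self.rigid_noise_factor <= 0:
            raise ValueError("rigid_noise_factor must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.trial_duration))

    def noise_free(self) -> "TraceConfig":
        """Copy of this config with every noise amplitude set to zero."""
        return replace(self, powerline_amplitude=0.0, white_noise_sd=0.0,
                       drift_amplitude=0.0)


@dataclass
class LabeledTrace:
    """A two-channel sampled trial with its ground-truth annotations.

    ``events`` holds tuples ``(channel, onset_s, duration_s, signed_amplitude)``
    describing each generated event; straight trials carry none.
    """

    t: np.ndarray
    eog: np.ndarray
    strain_rel: np.ndarray
    state_label: str | None = None
    events: List[Tuple[str, float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.eog = np.asarray(self.eog, dtype=float)
        self.strain_rel = np.asarray(self.strain_rel, dtype=float)
        if not (len(self.t) == len(self.eog) == len(self.strain_rel)):
            raise ValueError("t, eog and strain_rel must have equal length")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])


def _raised_cosine_pulse(t: np.ndarray, onset: float, duration: float,
                         amplitude: float) -> np.ndarray:
    """Smooth unimodal pulse: a(1 - cos(2π(t-onset)/d))/2 on [onset, onset+d]."""
    out = np.zeros_like(t)
    inside = (t >= onset) & (t <= onset + duration)
    phase = (t[inside] - onset) / duration
    out[inside] = amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    return out


def _plateau(t: np.ndarray, onset: float, duration: float, amplitude: float,
             ramp: float) -> np.ndarray:
    """Rise–hold–fall event with raised-cosine ramps of width ``ramp``."""
    ramp = min(ramp, duration / 2.0)
    out = np.zeros_like(t)
    rel = t - onset
    rising = (rel >= 0) & (rel < ramp)
    hold = (rel >= ramp) & (rel <= duration - ramp)
    falling = (rel > duration - ramp) & (rel <= duration)
    out[rising] = 0.5 * (1.0 - np.cos(np.pi * rel[rising] / ramp))
    out[hold] = 1.0
    out[falling] = 0.5 * (1.0 - np.cos(np.pi * (duration - rel[falling]) / ramp))
    return amplitude * out


def generate_trial(state: str, config: TraceConfig, seed: int) -> LabeledTrace:
    """Generate one labeled trial for ``state``, noise included per config.

    Deterministic for a fixed ``seed``.  With all noise amplitudes zero the
    trace contains only the clean event waveform: a positive (left) or
    negative (right) raised-cosine EOG spike whose peak lies inside
    ``eog_spike_amplitude_range``, or a signed strain plateau for vertical
    gaze; straight trials are identically zero.
    """
    if state not in STATES:
        raise UnknownStateError(f"unknown gaze state {state!r}; expected one of {STATES}")
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_samples
    t = np.arange(n) / config.sampling_rate
    eog = np.zeros(n)
    strain = np.zeros(n)
    events: List[Tuple[str, float, float, float]] = []

    if state in ("left", "right"):
        lo, hi = config.eog_spike_amplitude_range
        amp = rng.uniform(lo, hi) * (1.0 if state == "left" else -1.0)
        dlo, dhi = config.eog_spike_duration_range
        dur = rng.uniform(dlo, dhi)
        margin = min(0.5, 0.1 * config.trial_duration)
        onset = rng.uniform(margin, max(margin, config.trial_duration - dur - margin))
        eog = _raised_cosine_pulse(t, onset, dur, amp)
        events.append(("eog", onset, dur, amp))
    elif state in ("up", "down"):
        stretch = (state == "down") == config.down_is_stretch
        amp = config.strain_rel_magnitude * (1.0 if stretch else -1.0)
        dlo, dhi = config.strain_event_duration_range
        dur = rng.uniform(dlo, dhi)
        margin = min(0.3, 0.05 * config.trial_duration)
        onset = rng.uniform(margin, max(margin, config.trial_duration - dur - margin))
        strain = _plateau(t, onset, dur, amp, config.strain_ramp_time)
        events.append(("strain", onset, dur, amp))

    clean = LabeledTrace(t=t, eog=eog, strain_rel=strain, state_label=state,
                         events=events)
    # Independent noise stream so the clean waveform draw is unaffected by
    # toggling noise parameters.
    return add_noise(clean, config, seed=int(rng.integers(0, 2**31 - 1)))


def add_noise(trace: LabeledTrace, config: TraceConfig, seed: int) -> LabeledTrace:
    """Add powerline, white and drift noise to both channels of ``trace``.

    The EOG channel receives the configured μV amplitudes; the strain channel
    receives the same recipe scaled by ``config.strain_noise_scale``.  Rigid
    electrode mode multiplies the powerline amplitude and white-noise sd by
    ``config.rigid_noise_factor``; drift is a skin/electrode property common
    to both modes.  Output = input + noise; annotations are preserved.
    """
    config.validate()
    fs = trace.sampling_rate
    if abs(fs - config.sampling_rate) > 1e-6 * config.sampling_rate:
        raise ValueError(f"trace sampled at {fs:.3f} Hz but config expects "
                         f"{config.sampling_rate} Hz")
    rng = np.random.default_rng(seed)
    factor = config.rigid_noise_factor if config.electrode_mode == "rigid" else 1.0
    pw = config.powerline_amplitude * factor
    wn = config.white_noise_sd * factor
    dr = config.drift_amplitude
    t = trace.t
    n = len(t)
    duration = n / fs

    def channel_noise(scale: float) -> np.ndarray:
        noise = np.zeros(n)
        if pw > 0:
            noise += pw * scale * np.sin(2 * np.pi * POWERLINE_HZ * t
                                         + rng.uniform(0, 2 * np.pi))
        else:
            rng.uniform(0, 2 * np.pi)  # keep the stream layout stable
        if wn > 0:
            noise += wn * scale * rng.standard_normal(n)
        else:
            rng.standard_normal(n)
        # Drift period drawn in [1, 2] trial lengths: always >= trial length.
        period = duration * rng.uniform(1.0, 2.0)
        phase = rng.uniform(0, 2 * np.pi)
        if dr > 0:
            noise += dr * scale * np.sin(2 * np.pi * t / period + phase)
        return noise

    eog = trace.eog + channel_noise(1.0)
    strain = trace.strain_rel + channel_noise(config.strain_noise_scale)
    return LabeledTrace(t=t.copy(), eog=eog, strain_rel=strain,
                        state_label=trace.state_label,
                        events=list(trace.events))


def generate_dataset(n_trials: int, config: TraceConfig,
                     seed: int) -> Tuple[List[LabeledTrace], pd.DataFrame]:
    """Generate a balanced labeled dataset of ``n_trials`` trials.

    States are assigned round-robin so class counts differ by at most one
    (600 trials → 120 per state).  Per-trial seeds are drawn deterministically
    from the master ``seed`` and recorded in the returned manifest
    (columns ``trial_id, state, seed``).
    """
    if n_trials < len(STATES):
        raise ValueError(f"n_trials must be >= {len(STATES)} so every state "
                         f"appears at least once, got {n_trials}")
    rng = np.random.default_rng(seed)
    trial_seeds = rng.integers(0, 2**31 - 1, size=n_trials)
    states = [STATES[i % len(STATES)] for i in range(n_trials)]
    traces = [generate_trial(s, config, int(ts)) for s, ts in zip(states, trial_seeds)]
    manifest = pd.DataFrame({
        "trial_id": np.arange(n_trials),
        "state": states,
        "seed": trial_seeds,
    })
    return traces, manifest
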