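"""End-to-end processing: trace → conditioned components → features → command.

The forehead sensor's output is treated as a single compound signal — the
EOG potential plus the strain-induced resistance signal conditioned to an
equivalent voltage (``strain_to_uv`` μV per unit ΔR/R0).  The stages run in
a fixed order:

    front end (amplify, notch, low-pass, ADC)
    → Kalman smoothing
    → wavelet separation into strain / EOG components
    → event detection and ζ-feature extraction
    → one-against-one SVM with the interval decision rule
    → wheelchair command

Recognized states map to commands: up→forward, down→backward,
left→turn_left, right→turn_right, straight→stop.  A dwell filter is
available for streaming use: a command is only issued once the same state
has persisted for the configured dwell time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .features import EyeEvent, detect_events, raw_feature_vector
from .frontend import FrontendConfig, apply_frontend
from .kalman import KalmanModel, kalman_filter_trace
from .synth import LabeledTrace, STATES
from .wavelets import WaveletConfig, separate_components

#: Gaze state → wheelchair command.
COMMAND_MAP = {
    "up": "forward",
    "down": "backward",
    "left": "turn_left",
    "right": "turn_right",
    "straight": "stop",
}


@dataclass
class CommandEvent:
    """A decoded wheelchair command at a point in time."""

    timestamp: float
    state: str
    command: str


@dataclass
class PipelineConfig:
    """Stage parameters and wiring flags for the full pipeline."""

    frontend: FrontendConfig = field(default_factory=FrontendConfig)
    kalman: KalmanModel = field(default_factory=KalmanModel)
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    strain_to_uv: float = 25000.0
    eog_threshold_uv: float = 250.0
    strain_threshold_rel: float = 0.01
    min_event_duration_s: float = 0.05
    classifier_sigma: Optional[float] = None
    classifier_penalty: float = 1.0
    classifier_epsilon: float = 0.05
    skip_kalman: bool = False
    skip_wavelet: bool = False
    dwell_time_s: float = 0.5

    def validate(self) -> None:
        self.frontend.validate()
        self.wavelet.validate()
        if self.strain_to_uv <= 0:
            raise ValueError("strain_to_uv must be positive")
        if self.eog_threshold_uv <= 0 or self.strain_threshold_rel <= 0:
            raise ValueError("detection thresholds must be positive")


@dataclass
class ProcessedTrace:
    """Intermediate and final outputs of the conditioning stages."""

    t: np.ndarray
    compound_uv: np.ndarray
    filtered_uv: np.ndarray
    strain_component_rel: np.ndarray
    eog_component_uv: np.ndarray
    eog_events: List[EyeEvent]
    strain_events: List[EyeEvent]
    features: np.ndarray
    stages_run: Tuple[str, ...]


def process_trace(trace: LabeledTrace, config: PipelineConfig) -> ProcessedTrace:
    """Run front end, Kalman, wavelet separation and feature extraction."""
    config.validate()
    fs = trace.sampling_rate
    if abs(fs - config.frontend.sampling_rate) > 1e-6 * config.frontend.sampling_rate:
        raise ValueError(f"trace sampled at {fs:.3f} Hz but the front end is "
                         f"configured for {config.frontend.sampling_rate} Hz")
    stages = ["frontend"]
    compound = trace.eog + config.strain_to_uv * trace.strain_rel
    filtered = apply_frontend(compound, config.frontend)
    if not config.skip_kalman:
        filtered = kalman_filter_trace(filtered, config.kalman)
        stages.append("kalman")
    if not config.skip_wavelet:
        strain_uv, eog_uv = separate_components(filtered, config.wavelet,
                                                sampling_rate=fs)
        stages.append("wavelet")
    else:
        strain_uv, eog_uv = np.zeros_like(filtered), filtered
    strain_rel = strain_uv / config.strain_to_uv
    eog_events = detect_events(eog_uv, trace.t, config.eog_threshold_uv,
                               config.min_event_duration_s, channel="eog")
    strain_events = detect_events(strain_rel, trace.t, config.strain_threshold_rel,
                                  config.min_event_duration_s, channel="strain")
    features = raw_feature_vector(eog_events, strain_events)
    return ProcessedTrace(t=trace.t, compound_uv=compound, filtered_uv=filtered,
                          strain_component_rel=strain_rel, eog_component_uv=eog_uv,
                          eog_events=eog_events, strain_events=strain_events,
                          features=features, stages_run=tuple(stages))


def run_pipeline(trace: LabeledTrace, model, config: PipelineConfig
                 ) -> Tuple[str, CommandEvent]:
    """Process one trial and decode its gaze state and wheelchair command."""
    from .classifier import classify
    processed = process_trace(trace, config)
    state = classify(model, processed.features)
    timestamp = float(trace.t[-1])
    return state, CommandEvent(timestamp=timestamp, state=state,
                               command=COMMAND_MAP[state])


class DwellFilter:
    """Debounce streaming state decisions: emit a command only after the
    same state has persisted for ``dwell_time_s``."""

    def __init__(self, dwell_time_s: float = 0.5):
        if dwell_time_s < 0:
            raise ValueError("dwell time must be >= 0")
        self.dwell_time_s = dwell_time_s
        self._candidate: Optional[str] = None
        self._since: Optional[float] = None
        self.current: Optional[str] = None

    def update(self, timestamp: float, state: str) -> Optional[CommandEvent]:
        """Feed one decision; returns a CommandEvent when the command changes."""
        if state not in STATES:
            raise ValueError(f"unknown state {state!r}")
        if state != self._candidate:
            self._candidate, self._since = state, timestamp
        if (self._candidate != self.current
                and timestamp - self._since >= self.dwell_time_s):
            self.current = self._candidate
            return CommandEvent(timestamp=timestamp, state=state,
                                command=COMMAND_MAP[state])
        return None
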