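"""Event detection and (amplitude, duration, interval) feature extraction.

An event is a maximal run of samples whose absolute value exceeds a
threshold, lasting at least ``min_duration``.  Each trial is summarized by a
fixed 8-vector ζ — per channel (EOG first, strain second): signed peak
amplitude of the largest event, its duration, its interval to the previous
event, and the event count.  Event-free trials encode as zeros before
normalization.  Features are z-scored by training-set statistics so a single
Gaussian-kernel width treats μV-scale and ΔR/R0-scale coordinates equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

FEATURE_LENGTH = 8
FEATURE_NAMES = ("eog_amp", "eog_dur", "eog_interval", "eog_count",
                 "strain_amp", "strain_dur", "strain_interval", "strain_count")


@dataclass
class EyeEvent:
    """A detected supra-threshold excursion on one channel."""

    channel: str
    polarity: int
    amplitude: float
    onset: float
    duration: float
    interval: float


def detect_events(component: np.ndarray, t: np.ndarray, threshold: float,
                  min_duration: float = 0.05,
                  channel: str = "eog") -> List[EyeEvent]:
    """Find maximal runs where ``|component| > threshold``.

    Runs shorter than ``min_duration`` are discarded; the interval of each
    surviving event is the gap from the previous surviving event's end
    (0 for the first).  Amplitude is the signed extremum within the run.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    x = np.asarray(component, dtype=float)
    t = np.asarray(t, dtype=float)
    if x.shape != t.shape:
        raise ValueError("component and t must have the same shape")
    above = np.abs(x) > threshold
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:]) - 1
    dt = t[1] - t[0] if t.size > 1 else 0.0
    events: List[EyeEvent] = []
    prev_end_time: float | None = None
    for s, e in zip(starts, ends):
        duration = (e - s + 1) * dt
        if duration < min_duration:
            continue
        run = x[s:e + 1]
        peak_idx = int(np.argmax(np.abs(run)))
        amplitude = float(run[peak_idx])
        onset = float(t[s])
        interval = 0.0 if prev_end_time is None else onset - prev_end_time
        events.append(EyeEvent(channel=channel, polarity=1 if amplitude >= 0 else -1,
                               amplitude=amplitude, onset=onset,
                               duration=duration, interval=interval))
        prev_end_time = float(t[e])
    return events


@dataclass
class FeatureNormalizer:
    """Per-coordinate z-scoring statistics fitted on a training matrix.

    ``identity()`` builds a pass-through normalizer.  Coordinates with zero
    variance are left unscaled to keep the transform finite.
    """

    mean_: np.ndarray = field(default_factory=lambda: np.zeros(FEATURE_LENGTH))
    scale_: np.ndarray = field(default_factory=lambda: np.ones(FEATURE_LENGTH))
    fitted: bool = False

    @classmethod
    def identity(cls) -> "FeatureNormalizer":
        return cls(fitted=True)

    @classmethod
    def fit(cls, matrix: np.ndarray) -> "FeatureNormalizer":
        m = np.asarray(matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != FEATURE_LENGTH:
            raise ValueError(f"expected (n, {FEATURE_LENGTH}) matrix, got {m.shape}")
        mean = m.mean(axis=0)
        scale = m.std(axis=0, ddof=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(mean_=mean, scale_=scale, fitted=True)

    def transform(self, vec: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise ValueError("normalizer has not been fitted")
        return (np.asarray(vec, dtype=float) - self.mean_) / self.scale_

    def to_dict(self) -> dict:
        return {"mean": self.mean_.tolist(), "scale": self.scale_.tolist(),
                "fitted": self.fitted}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureNormalizer":
        return cls(mean_=np.asarray(d["mean"], dtype=float),
                   scale_=np.asarray(d["scale"], dtype=float),
                   fitted=bool(d["fitted"]))


def _channel_summary(events: Sequence[EyeEvent]) -> List[float]:
    if not events:
        return [0.0, 0.0, 0.0, 0.0]
    largest = max(events, key=lambda ev: abs(ev.amplitude))
    return [largest.amplitude, largest.duration, largest.interval,
            float(len(events))]


def extract_features(eog_events: Sequence[EyeEvent],
                     strain_events: Sequence[EyeEvent],
                     normalizer: FeatureNormalizer) -> np.ndarray:
    """Assemble the 8-vector ζ and apply the normalizer.

    Layout: (eog_amp, eog_dur, eog_interval, eog_count,
    strain_amp, strain_dur, strain_interval, strain_count).
    """
    raw = np.array(_channel_summary(eog_events) + _channel_summary(strain_events))
    return normalizer.transform(raw)


def raw_feature_vector(eog_events: Sequence[EyeEvent],
                       strain_events: Sequence[EyeEvent]) -> np.ndarray:
    """The pre-normalization ζ vector (zeros for event-free trials)."""
    return np.array(_channel_summary(eog_events) + _channel_summary(strain_events))
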