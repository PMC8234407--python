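"""Trace, manifest and config file I/O (plain CSV / JSON)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Optional, Tuple

import pandas as pd

from .frontend import FrontendConfig
from .kalman import KalmanModel
from .pipeline import PipelineConfig
from .synth import LabeledTrace, TraceConfig
from .wavelets import WaveletConfig

TRACE_COLUMNS = ("t_s", "eog_uV", "strain_rel")


def write_trace(trace: LabeledTrace, path) -> None:
    """Write a trace as CSV with columns ``t_s,eog_uV,strain_rel``."""
    pd.DataFrame({
        "t_s": trace.t, "eog_uV": trace.eog, "strain_rel": trace.strain_rel,
    }).to_csv(path, index=False)


def read_trace(path, state_label: Optional[str] = None) -> LabeledTrace:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace file {path} lacks columns {sorted(missing)}")
    return LabeledTrace(t=df["t_s"].to_numpy(), eog=df["eog_uV"].to_numpy(),
                        strain_rel=df["strain_rel"].to_numpy(),
                        state_label=state_label)


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_dataset(traces: List[LabeledTrace], manifest: pd.DataFrame,
                  out_dir) -> pd.DataFrame:
    """Write each trace to ``trial_<id>.csv`` plus a manifest with paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for trial_id, trace in zip(manifest["trial_id"], traces):
        p = out / f"trial_{trial_id:04d}.csv"
        write_trace(trace, p)
        paths.append(p.name)
    manifest = manifest.assign(path=paths)
    write_manifest(manifest, out / "manifest.csv")
    return manifest


def load_dataset(manifest_path) -> Tuple[List[LabeledTrace], pd.DataFrame]:
    manifest = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    traces = [read_trace(base / row.path, state_label=row.state)
              for row in manifest.itertuples()]
    return traces, manifest


def _filtered_kwargs(cls, d: dict) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    out = {}
    for k, v in d.items():
        out[k] = tuple(v) if isinstance(v, list) else v
    return out


def pipeline_config_from_dict(doc: dict) -> PipelineConfig:
    """Build a PipelineConfig from a JSON document with optional sections
    ``frontend``, ``kalman``, ``wavelet`` and top-level pipeline keys."""
    doc = dict(doc)
    fe = FrontendConfig(**_filtered_kwargs(FrontendConfig, doc.pop("frontend", {})))
    ka = KalmanModel(**_filtered_kwargs(KalmanModel, doc.pop("kalman", {})))
    wv = WaveletConfig(**_filtered_kwargs(WaveletConfig, doc.pop("wavelet", {})))
    return PipelineConfig(frontend=fe, kalman=ka, wavelet=wv,
                          **_filtered_kwargs(PipelineConfig, doc))


def trace_config_from_dict(doc: dict) -> TraceConfig:
    return TraceConfig(**_filtered_kwargs(TraceConfig, doc))


def load_config(path) -> Tuple[TraceConfig, PipelineConfig]:
    """Read a JSON config with optional ``trace`` and pipeline sections."""
    with open(path) as fh:
        doc = json.load(fh)
    trace_cfg = trace_config_from_dict(doc.pop("trace", {}))
    return trace_cfg, pipeline_config_from_dict(doc)
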