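"""File I/O: stimulus specs (JSON), waveforms (WAV/CSV), configs (YAML/JSON)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .design import ZwuisStimulus
from .simulate import InputShaping, SimConfig

__all__ = [
    "save_stimulus",
    "load_stimulus",
    "save_waveform",
    "load_waveform",
    "load_sim_config",
    "save_sim_config",
]


def save_stimulus(stimulus: ZwuisStimulus, path) -> None:
    Path(path).write_text(stimulus.to_json())


def load_stimulus(path) -> ZwuisStimulus:
    return ZwuisStimulus.from_json(Path(path).read_text())


def save_waveform(waveform, sample_rate_hz: float, path) -> None:
    """Write a waveform as float32 WAV or as (time_s, value) CSV by suffix."""
    path = Path(path)
    if path.suffix.lower() == ".wav":
        wavfile.write(path, int(round(sample_rate_hz)), np.asarray(waveform, np.float32))
    elif path.suffix.lower() == ".csv":
        t = np.arange(len(waveform)) / sample_rate_hz
        pd.DataFrame({"time_s": t, "value": waveform}).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported waveform format {path.suffix!r}")


def load_waveform(path):
    """Read a WAV or CSV waveform; returns ``(samples, sample_rate_hz)``."""
    path = Path(path)
    if path.suffix.lower() == ".wav":
        fs, x = wavfile.read(path)
        return np.asarray(x, dtype=float), float(fs)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        t = df.iloc[:, 0].to_numpy()
        fs = 1.0 / np.median(np.diff(t))
        return df.iloc[:, 1].to_numpy(dtype=float), float(fs)
    raise ValueError(f"unsupported waveform format {path.suffix!r}")


def _load_mapping(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yml", ".yaml")):
        return yaml.safe_load(text)
    return json.loads(text)


def load_sim_config(path) -> SimConfig:
    data = _load_mapping(path)
    if "input_shaping" in data and isinstance(data["input_shaping"], dict):
        data["input_shaping"] = InputShaping(**data["input_shaping"])
    if data.get("linear_path_shaping") is not None:
        data["linear_path_shaping"] = InputShaping(**data["linear_path_shaping"])
    return SimConfig(**data)


def save_sim_config(config: SimConfig, path) -> None:
    data = dataclasses.asdict(config)
    path = Path(path)
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(data))
    else:
        path.write_text(json.dumps(data, indent=2))
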