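"""File formats: WAV audio, TSV pupil logs, CSV tables, YAML configs.

Text outputs carry ``# key: value`` header comment lines (config hash,
seed) so that any artifact identifies the run that produced it; readers
skip them. All round trips are exact for float32 WAV and text tables.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from pupilbeat.synth import AudioSignal, RawPupilLog


def config_hash(config_dict: dict) -> str:
    """Short stable hash of a JSON-serializable config mapping."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_wav(path, audio: AudioSignal) -> None:
    wavfile.write(path, int(round(audio.sample_rate)), audio.samples.astype(np.float32))


def read_wav(path) -> AudioSignal:
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        raise ValueError("expected mono audio")
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return AudioSignal(np.asarray(data, dtype=float), float(rate))


def _header_lines(meta: Optional[dict]) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_table(path, df: pd.DataFrame, meta: Optional[dict] = None, sep: str = ",") -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, sep=sep, index=False)


def read_table(path, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


def write_pupil_log(path, log: RawPupilLog, meta: Optional[dict] = None) -> None:
    """Tab-separated ASCII log: time_ms, pupil, blink, saccade, event."""
    header = dict(meta or {})
    header["sample_rate_hz"] = log.sample_rate
    if log.seed is not None:
        header["seed"] = log.seed
    write_table(path, log.to_dataframe(), header, sep="\t")


def read_pupil_log(path) -> RawPupilLog:
    df = read_table(path, sep="\t")
    time_ms = df["time_ms"].to_numpy(dtype=float)
    if np.any(np.diff(time_ms) <= 0):
        raise ValueError("pupil log timestamps must be strictly increasing")
    dt = np.median(np.diff(time_ms))
    rate = 1000.0 / dt
    events: dict[str, list[float]] = {}
    ev = df["event"].fillna("")
    for i, labels in enumerate(ev):
        if labels:
            for label in str(labels).split("|"):
                events.setdefault(label, []).append(time_ms[i] / 1000.0)
    return RawPupilLog(
        time_ms=time_ms,
        pupil=df["pupil"].to_numpy(dtype=float),
        blink=df["blink"].to_numpy(dtype=bool),
        saccade=df["saccade"].to_numpy(dtype=bool),
        sample_rate=rate,
        events=events,
        missing_fraction=float(np.mean(np.isnan(df["pupil"].to_numpy(dtype=float)))),
    )


def write_config(path, config_dict: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_dict, fh, sort_keys=True)


def read_config(path) -> dict:
    with open(path) as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise ValueError("config file must contain a mapping")
    return loaded


def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
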