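"""File I/O: BrainVision triplets, accelerometer/event tables, manifests.

The BrainVision writer/reader supports the subset of the format this
pipeline produces: multiplexed binary IEEE_FLOAT_32 data in microvolts with
marker latencies stored 1-based in samples, which is what the format
specifies.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def write_brainvision(path_base: str | Path, data: np.ndarray, fs: float,
                      ch_names: list[str],
                      events: list[tuple[str, float]] | None = None) -> Path:
    """Write ``<base>.vhdr/.vmrk/.eeg``; data is (n_channels, n_samples) μV."""
    base = Path(path_base)
    base.parent.mkdir(parents=True, exist_ok=True)
    n_ch, _ = data.shape
    if n_ch != len(ch_names):
        raise ValueError("channel count mismatch")
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / fs:.6f}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    lines += [f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(ch_names)]
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        f"DataFile={eeg.name}",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0",
    ]
    for i, (label, lat_s) in enumerate(events or [], start=2):
        pos = int(round(lat_s * fs)) + 1  # 1-based sample position
        mlines.append(f"Mk{i}=Stimulus,{label},{pos},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    data.T.astype("<f4").tofile(eeg)
    return vhdr


def read_brainvision(vhdr_path: str | Path):
    """Read a BrainVision triplet written by :func:`write_brainvision`.

    Returns (data μV (n_ch, n_samp), fs, ch_names, events list[(label, s)]).
    """
    vhdr_path = Path(vhdr_path)
    kv: dict[str, str] = {}
    ch_names: list[str] = []
    for line in vhdr_path.read_text(encoding="utf-8").splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            kv[k.strip()] = v.strip()
            if k.startswith("Ch") and k[2:].isdigit():
                ch_names.append(v.split(",")[0])
    if kv.get("BinaryFormat") != "IEEE_FLOAT_32":
        raise ValueError("unsupported BinaryFormat")
    fs = 1e6 / float(kv["SamplingInterval"])
    n_ch = int(kv["NumberOfChannels"])
    raw = np.fromfile(vhdr_path.parent / kv["DataFile"], dtype="<f4")
    data = raw.reshape(-1, n_ch).T.astype(float)

    events: list[tuple[str, float]] = []
    vmrk = vhdr_path.parent / kv["MarkerFile"]
    for line in vmrk.read_text(encoding="utf-8").splitlines():
        if line.startswith("Mk") and "=" in line:
            fields = line.split("=", 1)[1].split(",")
            if fields[0] == "Stimulus":
                events.append((fields[1], (int(fields[2]) - 1) / fs))
    return data, fs, ch_names, events


def write_accel_table(path: str | Path, t: np.ndarray, vert: np.ndarray,
                      ap: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time": t, "vert": vert, "ap": ap}).to_csv(
        path, sep="\t", index=False, float_format="%.9g")
    return path


def read_accel_table(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return df["time"].to_numpy(), df["vert"].to_numpy(), df["ap"].to_numpy()


def write_events_table(path: str | Path, events: list[tuple[str, float]]) -> Path:
    """BIDS-style events table: onset, duration, trial_type."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"onset": [e[1] for e in events],
         "duration": [0.0] * len(events),
         "trial_type": [e[0] for e in events]}
    ).to_csv(path, sep="\t", index=False, float_format="%.9g")
    return path


def read_events_table(path: str | Path) -> list[tuple[str, float]]:
    df = pd.read_csv(path, sep="\t")
    return list(zip(df["trial_type"].astype(str), df["onset"].astype(float)))


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        return super().default(o)


def write_json(path: str | Path, obj) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder))
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
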