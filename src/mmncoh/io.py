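"""Reading and writing recordings, epochs and event files.

The native on-disk format is a directory holding an ``.npz`` with the voltage
array plus a JSON sidecar with montage, sampling rate, events and provenance
(including simulation ground truth).  EDF files can be read through MNE when
it is installed (``pip install mmncoh[edf]``); EDF export is not provided.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EEGRecording, Epochs
from .montage import Montage


def _montage_to_dict(m: Montage) -> dict:
    return {"labels": list(m.labels), "regions": dict(m.regions),
            "neighbors": {k: list(v) for k, v in m.neighbors.items()}}


def _montage_from_dict(d: dict) -> Montage:
    return Montage(labels=tuple(d["labels"]), regions=dict(d["regions"]),
                   neighbors={k: tuple(v) for k, v in d.get("neighbors", {}).items()})


def save_recording(rec: EEGRecording, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "recording.npz", data=rec.data)
    sidecar = {
        "kind": "recording",
        "fs_hz": rec.fs_hz,
        "montage": _montage_to_dict(rec.montage),
        "bads": sorted(rec.bads),
        "events": [[int(s), str(lab)] for s, lab in rec.events],
        "info": rec.info,
    }
    (directory / "recording.json").write_text(json.dumps(sidecar, indent=1))
    return directory


def load_recording(directory) -> EEGRecording:
    directory = Path(directory)
    sidecar = json.loads((directory / "recording.json").read_text())
    data = np.load(directory / "recording.npz")["data"]
    return EEGRecording(
        data=data,
        montage=_montage_from_dict(sidecar["montage"]),
        fs_hz=sidecar["fs_hz"],
        bads=set(sidecar.get("bads", [])),
        events=[(int(s), lab) for s, lab in sidecar.get("events", [])],
        info=sidecar.get("info", {}),
    )


def save_epochs(ep: Epochs, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "epochs.npz", data=ep.data)
    sidecar = {
        "kind": "epochs",
        "fs_hz": ep.fs_hz,
        "tmin_s": ep.tmin_s,
        "paradigm_id": ep.paradigm_id,
        "montage": _montage_to_dict(ep.montage),
        "bads": sorted(ep.bads),
        "labels": [str(x) for x in ep.labels],
        "rejection_log": ep.rejection_log,
        "info": ep.info,
    }
    (directory / "epochs.json").write_text(json.dumps(sidecar, indent=1))
    return directory


def load_epochs(directory) -> Epochs:
    directory = Path(directory)
    sidecar = json.loads((directory / "epochs.json").read_text())
    data = np.load(directory / "epochs.npz")["data"]
    return Epochs(
        data=data,
        montage=_montage_from_dict(sidecar["montage"]),
        fs_hz=sidecar["fs_hz"],
        tmin_s=sidecar["tmin_s"],
        labels=np.array(sidecar["labels"], dtype=object),
        paradigm_id=sidecar.get("paradigm_id", "resting"),
        bads=set(sidecar.get("bads", [])),
        rejection_log=sidecar.get("rejection_log", {}),
        info=sidecar.get("info", {}),
    )


def read_events_tsv(path) -> pd.DataFrame:
    """Read a paradigm event list (block, onset_s, kind, is_formation)."""
    df = pd.read_csv(path, sep="\t")
    required = {"block", "onset_s", "kind", "is_formation"}
    if not required.issubset(df.columns):
        raise ValueError(f"event file must have columns {sorted(required)}")
    return df


def read_edf(path, montage: Montage | None = None) -> EEGRecording:
    """Read an EDF recording via MNE (optional dependency).

    Channel labels must match the supplied montage; if no montage is given,
    all EDF channels are taken as-is with an 'unknown' region mapped to
    'central' only when present in the default montage.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - exercised only with mne
        raise ImportError("reading EDF requires mne (pip install mmncoh[edf])") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6
    labels = tuple(raw.ch_names)
    if montage is None:
        from .montage import default_montage

        dm = default_montage()
        regions = {lab: dm.regions.get(lab, "central") for lab in labels}
        montage = Montage(labels=labels, regions=regions)
    else:
        order = [labels.index(lab) for lab in montage.labels]
        data_uv = data_uv[order]
    return EEGRecording(data=data_uv, montage=montage, fs_hz=float(raw.info["sfreq"]))
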