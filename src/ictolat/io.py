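"""On-disk formats: EEG matrix dialect, leadfield container, EDF reading.

The package's interchange format for EEG is deliberately plain: a CSV whose
header row holds the 10-20 channel labels (one column per channel, one row
per sample) plus a JSON sidecar carrying the sampling rate and epoch
offset. Leadfields travel as NPZ containers with named arrays. EDF files
are read through mne when it is installed (`pip install ictolat[edf]`).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .inverse import Leadfield
from .preprocess import EEGRecording


def save_eeg_csv(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as samples x channels CSV + `<stem>.json` sidecar."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=list(rec.channel_labels))
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"fs": rec.fs, "t0": rec.t0}))


def load_eeg_csv(path: str | Path) -> EEGRecording:
    """Read the CSV dialect written by :func:`save_eeg_csv`."""
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return EEGRecording(
        data=df.to_numpy().T,
        fs=float(meta["fs"]),
        channel_labels=tuple(df.columns),
        t0=float(meta.get("t0", 0.0)),
    )


def save_leadfield(lf: Leadfield, path: str | Path) -> None:
    """NPZ container with arrays gain, positions, roi_of_source, channel_labels."""
    np.savez(
        Path(path),
        gain=lf.gain,
        positions=lf.positions,
        roi_of_source=lf.roi_of_source.astype(str),
        channel_labels=np.array(lf.channel_labels),
        roi_labels=np.array(sorted(set(lf.roi_of_source.tolist()))),
    )


def load_leadfield(path: str | Path) -> Leadfield:
    with np.load(Path(path), allow_pickle=False) as npz:
        return Leadfield(
            gain=npz["gain"],
            positions=npz["positions"],
            roi_of_source=npz["roi_of_source"],
            channel_labels=tuple(npz["channel_labels"].tolist()),
        )


def read_edf(path: str | Path) -> EEGRecording:
    """Read a standard 16-bit EDF recording (requires mne).

    Channel names are normalized by stripping common "EEG " prefixes and
    reference suffixes so they can be matched against the 10-20 labels.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "EDF reading requires mne; install with `pip install ictolat[edf]`"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = []
    for name in raw.ch_names:
        clean = name.removeprefix("EEG ").split("-")[0].strip()
        labels.append(clean)
    return EEGRecording(
        data=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(labels),
    )


def save_network_json(net, path: str | Path) -> None:
    """Dense JSON dump of a functional network (labels + matrices)."""
    payload = {
        "roi_labels": list(net.roi_labels),
        "adjacency": net.adjacency.tolist(),
        "raw_plv": net.raw_plv.tolist(),
        "n_surrogates": net.n_surrogates,
        "segment_index": net.segment_index,
    }
    Path(path).write_text(json.dumps(payload))


def save_ni_json(res, path: str | Path) -> None:
    """JSON dump of a node-ictogenicity result for one segment."""
    payload = {
        "roi_labels": list(res.roi_labels),
        "ni": res.ni.tolist(),
        "bni_pre": res.bni_pre,
        "bni_post": res.bni_post.tolist(),
        "k_star": res.k_star,
        "n_realizations": res.n_realizations,
    }
    Path(path).write_text(json.dumps(payload))
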