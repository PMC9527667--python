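"""Reading and writing recordings and ground truth.

Recordings round-trip through HDF5 (compact) or CSV + JSON sidecar
(human-readable); clinical EDF/EDF+ files are read through MNE when it is
installed.  Ground truth serializes as JSON next to each segment.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import Recording, Segment

__all__ = [
    "write_recording_hdf5",
    "read_recording_hdf5",
    "write_recording_csv",
    "read_recording_csv",
    "read_edf",
]


def _meta(rec: Recording) -> dict:
    meta = {
        "fs": rec.fs,
        "channel_labels": rec.channel_labels,
        "hemispheres": rec.hemispheres,
        "annotations": [[float(t), lab] for t, lab in rec.annotations],
    }
    if isinstance(rec, Segment):
        meta.update(
            condition=rec.condition,
            onset_time=rec.onset_time,
            segment_id=rec.segment_id,
        )
    return meta


def _build(samples: np.ndarray, meta: dict) -> Recording:
    common = dict(
        samples=samples,
        fs=float(meta["fs"]),
        channel_labels=list(meta["channel_labels"]),
        hemispheres=list(meta["hemispheres"]),
        annotations=[(float(t), str(lab)) for t, lab in meta.get("annotations", [])],
    )
    if "condition" in meta:
        return Segment(
            **common,
            condition=meta["condition"],
            onset_time=float(meta["onset_time"]),
            segment_id=meta.get("segment_id", ""),
        )
    return Recording(**common)


def write_recording_hdf5(rec: Recording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=rec.samples, compression="gzip", shuffle=True)
        f.attrs["meta"] = json.dumps(_meta(rec))


def read_recording_hdf5(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        return _build(f["samples"][()], json.loads(f.attrs["meta"]))


def write_recording_csv(rec: Recording, path: str | Path) -> None:
    """Samples as a channels-in-columns CSV plus a ``.json`` metadata sidecar."""
    path = Path(path)
    pd.DataFrame(rec.samples.T, columns=rec.channel_labels).to_csv(path, index=False)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(_meta(rec), indent=1))


def read_recording_csv(path: str | Path) -> Recording:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    samples = pd.read_csv(path).to_numpy().T
    return _build(samples, meta)


def read_edf(path: str | Path) -> Recording:
    """Read an EDF/EDF+ recording via MNE (optional dependency).

    Hemisphere tags are taken from a leading ``L``/``R`` in each channel
    label when present (``L`` otherwise), and EDF+ annotations are carried
    over as ``(onset_seconds, description)`` pairs.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = list(raw.ch_names)
    hemis = [lab[0].upper() if lab[:1].upper() in ("L", "R") else "L" for lab in labels]
    annotations = [
        (float(on), str(desc)) for on, desc in zip(raw.annotations.onset, raw.annotations.description)
    ]
    return Recording(
        samples=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        channel_labels=labels,
        hemispheres=hemis,
        annotations=annotations,
    )
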