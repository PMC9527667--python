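"""Core data containers shared by every pipeline stage.

A :class:`Recording` is a multichannel intracranial time series with
channel labels, per-channel hemisphere tags and event annotations.
A :class:`Segment` is a fixed-duration epoch of a recording aligned to a
seizure onset (or to a pseudo-onset for interictal epochs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Valid condition labels for an epoch.
CONDITIONS = ("focal", "bilateral", "interictal")

#: Default epoch geometry: 15 min before onset, 10 min after.
PRE_ONSET_S = 900.0
POST_ONSET_S = 600.0
SEGMENT_LENGTH_S = PRE_ONSET_S + POST_ONSET_S


@dataclass
class Recording:
    """Multichannel time series with channel metadata and annotations.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)``.
    fs
        Sampling rate in Hz.
    channel_labels
        One label per channel.
    hemispheres
        One of ``"L"``/``"R"`` per channel.
    annotations
        ``(time_seconds, label)`` pairs, e.g. ``(3600.0, "seizure_onset")``.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    hemispheres: list[str]
    annotations: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (n_channels, n_samples) matrix")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        n = self.samples.shape[0]
        if len(self.channel_labels) != n or len(self.hemispheres) != n:
            raise ValueError("channel_labels/hemispheres length must match channel count")
        bad = set(self.hemispheres) - {"L", "R"}
        if bad:
            raise ValueError(f"hemisphere tags must be 'L' or 'R', got {sorted(bad)}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.fs


@dataclass
class Segment(Recording):
    """A conditioned epoch aligned to a (pseudo-)onset.

    ``onset_time`` is in seconds from segment start (900 s under the
    default 15 min pre / 10 min post geometry).
    """

    condition: str = "interictal"
    onset_time: float = PRE_ONSET_S
    segment_id: str = ""
    #: per-channel AR(1) coefficients, set by prewhitening
    ar1_phi: np.ndarray | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if not 0 <= self.onset_time <= self.duration:
            raise ValueError("onset_time must lie within the segment")

    def with_samples(self, samples: np.ndarray) -> "Segment":
        """Copy of this segment with ``samples`` swapped out."""
        return replace(self, samples=samples)
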