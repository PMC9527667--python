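"""Filtering, AR(1) prewhitening and epoching of multichannel recordings.

Recordings are band-pass filtered (default 1-70 Hz) and notch filtered
(default 60 Hz powerline), prewhitened per channel with a first-order
autoregressive model to suppress autocorrelation-driven spurious
correlation, and cut into 25-min epochs spanning 15 min before to 10 min
after a (pseudo-)onset.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from scipy import signal

from .core import Recording, Segment, PRE_ONSET_S, POST_ONSET_S

logger = logging.getLogger(__name__)

__all__ = ["bandpass_notch", "prewhiten_ar1", "extract_segment", "select_interictal"]


def bandpass_notch(
    rec: Recording,
    low: float = 1.0,
    high: float = 70.0,
    notch: float | None = 60.0,
    order: int = 4,
    notch_q: float = 30.0,
) -> Recording:
    """Zero-phase band-pass plus optional notch filter, channel by channel.

    A 4th-order Butterworth band-pass and an IIR notch (quality factor 30)
    are each applied forward-backward so the passband gain is ~1 and phase
    relationships — which the windowed correlations depend on — are
    preserved.
    """
    nyq = rec.fs / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyq})"
        )
    if notch is not None and not low < notch < high:
        raise ValueError(f"notch {notch} Hz must lie inside the ({low}, {high}) band")

    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    if notch is not None:
        b, a = signal.iirnotch(notch, notch_q, fs=rec.fs)
    # channel loop beats axis=1 filtering on long contiguous rows
    out = np.empty_like(rec.samples)
    for i in range(rec.n_channels):
        y = signal.sosfiltfilt(sos, rec.samples[i])
        if notch is not None:
            y = signal.filtfilt(b, a, y)
        out[i] = y
    return replace(rec, samples=out)


def prewhiten_ar1(seg: Segment) -> Segment:
    """Remove per-channel lag-1 autocorrelation with an AR(1) model.

    phi is the Yule-Walker (lag-1 autocorrelation) estimate on the
    mean-removed channel over the full segment; the channel is replaced by
    the innovation ``x_t - phi * x_{t-1}``.  The first sample is dropped and
    the last repeated so segment length (and downstream window counts) are
    preserved.  Zero-variance channels get ``phi = 0`` and pass through.
    """
    x = seg.samples
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples per channel to prewhiten")
    xc = x - x.mean(axis=1, keepdims=True)
    var = np.einsum("ij,ij->i", xc, xc)
    cov1 = np.einsum("ij,ij->i", xc[:, 1:], xc[:, :-1])
    zero_var = var <= 0
    if np.any(zero_var):
        logger.warning(
            "%d zero-variance channel(s); phi set to 0", int(zero_var.sum())
        )
    phi = np.where(zero_var, 0.0, cov1 / np.where(zero_var, 1.0, var))

    resid = x[:, 1:] - phi[:, None] * x[:, :-1]
    out = np.concatenate([resid, resid[:, -1:]], axis=1)  # pad tail by repetition
    out = np.where(zero_var[:, None], x, out)
    new = seg.with_samples(out)
    new.ar1_phi = phi
    return new


def extract_segment(
    rec: Recording,
    onset: float,
    pre: float = PRE_ONSET_S,
    post: float = POST_ONSET_S,
    condition: str = "focal",
    segment_id: str = "",
) -> Segment:
    """Cut the ``[onset - pre, onset + post)`` epoch around a seizure onset."""
    start, stop = onset - pre, onset + post
    if start < 0 or stop > rec.duration:
        raise ValueError(
            f"requested span [{start}, {stop}) s exceeds recording of {rec.duration} s"
        )
    i0 = int(round(start * rec.fs))
    i1 = i0 + int(round((pre + post) * rec.fs))
    onsets_inside = [
        t for t, lab in rec.annotations if "onset" in lab and start <= t < stop
    ]
    if len(onsets_inside) > 1:
        logger.warning(
            "segment around onset %.1f s contains %d seizure onsets (expected one)",
            onset, len(onsets_inside),
        )
    return Segment(
        samples=rec.samples[:, i0:i1],
        fs=rec.fs,
        channel_labels=rec.channel_labels,
        hemispheres=rec.hemispheres,
        annotations=[(t - start, lab) for t, lab in rec.annotations if start <= t < stop],
        condition=condition,
        onset_time=pre,
        segment_id=segment_id,
    )


def select_interictal(
    rec: Recording,
    seizure_spans: list[tuple[float, float]],
    min_gap: float = 3600.0,
    duration: float = PRE_ONSET_S + POST_ONSET_S,
) -> list[Segment]:
    """Non-overlapping interictal epochs at least ``min_gap`` s from any seizure.

    Every sample of a returned epoch is >= ``min_gap`` seconds from every
    seizure onset and offset; epochs are tagged ``interictal`` with a
    pseudo-onset 15 min in.
    """
    forbidden = [(on - min_gap, off + min_gap) for on, off in seizure_spans]
    out: list[Segment] = []
    t = 0.0
    while t + duration <= rec.duration + 1e-9:
        span = (t, t + duration)
        if any(span[0] < hi and span[1] > lo for lo, hi in forbidden):
            # jump past the blocking forbidden interval
            t = min(hi for lo, hi in forbidden if span[0] < hi and span[1] > lo)
            continue
        i0 = int(round(t * rec.fs))
        i1 = i0 + int(round(duration * rec.fs))
        out.append(
            Segment(
                samples=rec.samples[:, i0:i1],
                fs=rec.fs,
                channel_labels=rec.channel_labels,
                hemispheres=rec.hemispheres,
                annotations=[],
                condition="interictal",
                onset_time=PRE_ONSET_S if duration > PRE_ONSET_S else duration / 2,
                segment_id=f"interictal-{len(out):03d}",
            )
        )
        t += duration
    if not out:
        logger.info("no qualifying interictal span of %.0f s found", duration)
    return out
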