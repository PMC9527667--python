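"""Sliding-window correlation networks from conditioned epochs.

A segment is scanned with 1-s windows stepped by 0.5 s; each window yields
the matrix of pairwise Pearson correlations across channels (a weighted,
symmetric functional-connectivity network).  The raw series is temporally
smoothed by averaging 30-s blocks advanced in 15-s strides — under the
default 25-min geometry this gives 2999 raw and exactly 98 smoothed
matrices — and finally rectified: negative correlations are clipped to
zero, leaving edge weights in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Segment

logger = logging.getLogger(__name__)

__all__ = ["ConnectivitySeries", "sliding_correlation", "smooth", "rectify"]

_CHUNK = 512  # windows per correlation chunk, bounds peak memory


@dataclass
class ConnectivitySeries:
    """Ordered sequence of symmetric zero-diagonal adjacency matrices."""

    matrices: np.ndarray  # (n_windows, N, N)
    window_starts: np.ndarray  # seconds from segment start
    stage: str  # raw | smoothed | rectified
    step: float  # seconds between consecutive window starts
    onset_time: float = 900.0
    zero_variance_windows: int = 0
    segment_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=np.float64)
        self.window_starts = np.asarray(self.window_starts, dtype=np.float64)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must have shape (n_windows, N, N)")
        if len(self.window_starts) != len(self.matrices):
            raise ValueError("one window start per matrix required")

    def __len__(self) -> int:
        return len(self.matrices)

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[1]

    @property
    def onset_relative_minutes(self) -> np.ndarray:
        """Window start times in minutes relative to onset."""
        return (self.window_starts - self.onset_time) / 60.0


def sliding_correlation(
    seg: Segment,
    win: float = 1.0,
    step: float = 0.5,
    region_map: dict[str, list[int]] | None = None,
) -> ConnectivitySeries:
    """Windowed Pearson-correlation matrices over a segment.

    Windows of ``win`` seconds advance by ``step`` seconds; only fully
    contained windows are kept.  Channels with zero variance inside a
    window contribute zero correlations there (counted and logged).  With
    ``region_map`` (region label -> channel indices) correlations are
    averaged within region pairs so nodes become regions; default is one
    node per channel.
    """
    win_n = int(round(win * seg.fs))
    step_n = int(round(step * seg.fs))
    if win_n < 2:
        raise ValueError("window must contain at least 2 samples")
    if seg.n_samples < win_n:
        raise ValueError("segment shorter than one window")

    views = sliding_window_view(seg.samples, win_n, axis=1)[:, ::step_n]  # (N, W, w)
    n_ch, n_win = views.shape[:2]
    mats = np.empty((n_win, n_ch, n_ch))
    degenerate = 0
    for lo in range(0, n_win, _CHUNK):
        hi = min(lo + _CHUNK, n_win)
        block = views[:, lo:hi].astype(np.float64)
        block = block - block.mean(axis=2, keepdims=True)
        norm = np.sqrt(np.einsum("nwt,nwt->nw", block, block))
        bad = norm <= 0
        degenerate += int(bad.any(axis=0).sum())
        z = block / np.where(bad, 1.0, norm)[:, :, None]
        z[bad] = 0.0
        mats[lo:hi] = np.einsum("nwt,mwt->wnm", z, z)

    np.clip(mats, -1.0, 1.0, out=mats)
    idx = np.arange(n_ch)
    mats[:, idx, idx] = 0.0
    if degenerate:
        logger.info("%d window(s) had zero-variance channels", degenerate)

    if region_map is not None:
        mats = _group_regions(mats, region_map)

    return ConnectivitySeries(
        matrices=mats,
        window_starts=np.arange(n_win) * step,
        stage="raw",
        step=step,
        onset_time=seg.onset_time,
        zero_variance_windows=degenerate,
        segment_id=seg.segment_id,
        condition=seg.condition,
    )


def _group_regions(mats: np.ndarray, region_map: dict[str, list[int]]) -> np.ndarray:
    """Average channel-level correlations within region pairs."""
    labels = list(region_map)
    r = len(labels)
    out = np.zeros((mats.shape[0], r, r))
    for a in range(r):
        ia = np.asarray(region_map[labels[a]])
        for b in range(a + 1, r):
            ib = np.asarray(region_map[labels[b]])
            block = mats[:, ia[:, None], ib[None, :]]
            out[:, a, b] = out[:, b, a] = block.mean(axis=(1, 2))
    return out


def smooth(series: ConnectivitySeries, span: float = 30.0, stride: float = 15.0) -> ConnectivitySeries:
    """Average consecutive ``span``-second blocks advanced by ``stride`` s.

    Only full blocks are kept; each smoothed window is stamped with its
    block's first raw window start.  Defaults turn 2999 raw matrices into
    exactly 98 smoothed ones.
    """
    if series.stage not in ("raw", "rectified"):
        raise ValueError(f"smooth expects an unsmoothed series, got stage={series.stage!r}")
    block = span / series.step
    adv = stride / series.step
    if abs(block - round(block)) > 1e-9 or abs(adv - round(adv)) > 1e-9:
        raise ValueError("span and stride must be integer multiples of the raw step")
    block, adv = int(round(block)), int(round(adv))
    n_raw = len(series)
    if block > n_raw:
        raise ValueError("smoothing span exceeds series length")
    n_sm = (n_raw - block) // adv + 1
    mats = np.stack([
        series.matrices[j * adv : j * adv + block].mean(axis=0) for j in range(n_sm)
    ])
    return replace(
        series,
        matrices=mats,
        window_starts=series.window_starts[np.arange(n_sm) * adv],
        stage="smoothed",
        step=stride,
    )


def rectify(series: ConnectivitySeries) -> ConnectivitySeries:
    """Clip negative correlations to zero; weights end in [0, 1]."""
    return replace(series, matrices=np.clip(series.matrices, 0.0, 1.0), stage="rectified")
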