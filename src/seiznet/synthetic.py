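"""Seeded generator of ground-truthed multichannel surrogate ECoG cohorts.

The generator uses a latent-factor signal model: channels belonging to a
community share a band-limited (4-30 Hz) Gaussian latent signal, all
channels share a global latent weighted by a between-community gain, and
each channel receives independent noise.  The pipeline downstream consumes
only second-order statistics (windowed Pearson correlations), so
controllable correlation structure — not biophysical realism — is what the
model provides.  Coupling gains map monotonically onto expected pairwise
correlations:

    corr(i, j | same community k)  = (w_k^2 + b^2) / (w_k^2 + b^2 + s^2)
    corr(i, j | different groups)  =  b^2          / (w_k^2 + b^2 + s^2)

with ``w_k`` the within-community gain, ``b`` the between (global) gain and
``s`` the channel-noise amplitude.  Three conditions are emulated:

* ``focal`` — after onset, the within gain of the onset community rises;
  no contralateral community is touched.
* ``bilateral`` — before onset an optional signature raises within gains
  and lowers the between gain (raising modularity, lowering spectral
  radius); after onset the global between gain rises and, after a
  configurable delay, contralateral communities are recruited.
* ``interictal`` — gains are constant; onset is a pseudo-onset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import signal

from .core import Segment, CONDITIONS

__all__ = [
    "CohortSpec",
    "ScheduleParams",
    "CouplingSchedule",
    "GroundTruth",
    "generate_segment",
    "generate_cohort",
]


@dataclass(frozen=True)
class CohortSpec:
    """Cohort geometry: how many segments per condition, and their shape.

    Defaults mirror the study conditions: 49 focal-remaining-focal and 18
    focal-to-bilateral seizures plus an equal number (67) of interictal
    epochs, each 25 min at 500 Hz with onset 15 min in.
    """

    n_focal: int = 49
    n_bilateral: int = 18
    n_interictal: int = 67
    n_channels: int = 16
    n_communities: int = 4
    hemisphere_split: float = 0.5
    fs: float = 500.0
    segment_length: float = 1500.0
    onset_offset: float = 900.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_focal < 0 or self.n_bilateral < 0 or self.n_interictal < 0:
            raise ValueError("segment counts must be non-negative")
        if self.n_channels < 4:
            raise ValueError("need at least 4 channels")
        if not 0.0 < self.hemisphere_split < 1.0:
            raise ValueError("hemisphere_split must lie in (0, 1)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not 0.0 < self.onset_offset < self.segment_length:
            raise ValueError("onset_offset must lie inside the segment")
        if self.n_communities < 2 or self.n_communities > self.n_channels:
            raise ValueError("n_communities must be in [2, n_channels]")

    @property
    def n_segments(self) -> int:
        return self.n_focal + self.n_bilateral + self.n_interictal

    def hemisphere_tags(self) -> list[str]:
        n_left = int(round(self.hemisphere_split * self.n_channels))
        n_left = min(max(n_left, 2), self.n_channels - 2)
        return ["L"] * n_left + ["R"] * (self.n_channels - n_left)


@dataclass(frozen=True)
class ScheduleParams:
    """Gain amplitudes of the coupling schedules, in channel-noise units.

    ``base_within`` / ``base_between`` set baseline within- and
    between-community correlation; ``preictal_magnitude`` is the relative
    pre-onset perturbation injected for the bilateral class (within gains
    scaled by ``1 + m``, between gain by ``1 - m``); the post-onset gains
    model seizure spread.  All dimensionless relative to ``noise_sd``.
    """

    base_within: float = 0.8
    base_between: float = 0.4
    noise_sd: float = 1.0
    preictal_magnitude: float = 0.4
    post_within_gain: float = 1.2
    post_between_gain: float = 0.8
    spread_delay: float = 30.0
    ramp: float = 15.0


def _ramp_up(t: np.ndarray, t0: float, width: float) -> np.ndarray:
    """Piecewise-linear 0→1 ramp starting at ``t0``, reaching 1 at ``t0+width``."""
    if width <= 0:
        return (t >= t0).astype(float)
    return np.clip((t - t0) / width, 0.0, 1.0)


@dataclass
class CouplingSchedule:
    """Per-community gain time courses for one segment.

    ``within_gain`` has shape ``(n_communities, n_samples)``;
    ``between_gain`` has shape ``(n_samples,)``.  ``communities`` maps a
    label to channel indices; each community is confined to one hemisphere.
    """

    communities: dict[str, list[int]]
    community_hemisphere: dict[str, str]
    within_gain: np.ndarray
    between_gain: np.ndarray
    noise_sd: float
    spread_profile: str
    onset_community: str | None = None

    def __post_init__(self) -> None:
        if np.any(self.within_gain < 0) or np.any(self.between_gain < 0):
            raise ValueError("coupling gains must be non-negative")

    @staticmethod
    def partition_channels(spec: CohortSpec) -> tuple[dict[str, list[int]], dict[str, str]]:
        """Split channels into hemisphere-confined, near-equal communities."""
        tags = spec.hemisphere_tags()
        left = [i for i, h in enumerate(tags) if h == "L"]
        right = [i for i, h in enumerate(tags) if h == "R"]
        k_left = max(1, spec.n_communities // 2)
        k_right = spec.n_communities - k_left
        if k_right == 0:  # pathological split; keep both hemispheres covered
            k_left, k_right = spec.n_communities - 1, 1
        comms: dict[str, list[int]] = {}
        hemi: dict[str, str] = {}
        for j, chunk in enumerate(np.array_split(np.asarray(left), k_left)):
            comms[f"L{j}"] = [int(c) for c in chunk]
            hemi[f"L{j}"] = "L"
        for j, chunk in enumerate(np.array_split(np.asarray(right), k_right)):
            comms[f"R{j}"] = [int(c) for c in chunk]
            hemi[f"R{j}"] = "R"
        if any(len(v) == 0 for v in comms.values()):
            raise ValueError("too many communities for the channel count")
        return comms, hemi

    @classmethod
    def for_condition(
        cls,
        spec: CohortSpec,
        condition: str,
        params: ScheduleParams | None = None,
    ) -> "CouplingSchedule":
        """Build the condition-specific gain schedule for one segment."""
        if condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
        p = params or ScheduleParams()
        comms, hemi = cls.partition_channels(spec)
        labels = list(comms)
        n_t = int(round(spec.segment_length * spec.fs))
        t = np.arange(n_t) / spec.fs
        onset = spec.onset_offset

        within = np.full((len(labels), n_t), p.base_within, dtype=np.float64)
        between = np.full(n_t, p.base_between, dtype=np.float64)
        onset_comm: str | None = None

        if condition != "interictal":
            # onset community: first left-hemisphere community
            onset_comm = next(l for l in labels if hemi[l] == "L")
            k0 = labels.index(onset_comm)
            post = _ramp_up(t, onset, p.ramp)
            within[k0] += p.post_within_gain * post

        if condition == "bilateral":
            if p.preictal_magnitude > 0:
                # pre-onset signature: communities tighten, global coupling drops
                pre = _ramp_up(t, 0.0, p.ramp) * (t < onset)
                within += p.base_within * p.preictal_magnitude * pre
                between -= p.base_between * p.preictal_magnitude * pre
            post = _ramp_up(t, onset, p.ramp)
            between = between + p.post_between_gain * post
            late = _ramp_up(t, onset + p.spread_delay, p.ramp)
            for k, lab in enumerate(labels):
                if hemi[lab] != hemi[onset_comm]:
                    within[k] += p.post_within_gain * late

        return cls(
            communities=comms,
            community_hemisphere=hemi,
            within_gain=np.clip(within, 0.0, None),
            between_gain=np.clip(between, 0.0, None),
            noise_sd=p.noise_sd,
            spread_profile=condition,
            onset_community=onset_comm,
        )


@dataclass
class GroundTruth:
    """What was actually injected into one generated segment."""

    condition: str
    onset_time: float
    seed_key: list[int]
    communities: dict[str, list[int]]
    community_hemisphere: dict[str, str]
    onset_community: str | None
    #: gain courses downsampled to 1 Hz for serialization
    within_gain_1hz: list[list[float]]
    between_gain_1hz: list[float]
    noise_sd: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float,
                        band: tuple[float, float] = (4.0, 30.0)) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band`` Hz."""
    lo, hi = band
    hi = min(hi, 0.45 * fs)  # stay inside Nyquist for low test rates
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_segment(
    spec: CohortSpec,
    schedule: CouplingSchedule,
    condition: str,
    seed: int | tuple[int, ...] | np.random.SeedSequence,
    segment_id: str = "",
) -> tuple[Segment, GroundTruth]:
    """Generate one 25-min surrogate segment plus its ground truth.

    Each channel is the gain-weighted sum of its community latent, the
    global latent and independent white noise, normalized to unit variance
    sample-by-sample so that gains translate directly into correlations.
    Identical inputs give bit-identical output.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    if spec.fs <= 0:
        raise ValueError("sampling rate must be positive")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    n_t = int(round(spec.segment_length * spec.fs))
    labels = list(schedule.communities)
    latents = np.stack(
        [_band_limited_noise(rng, n_t, spec.fs) for _ in labels]
    )  # (K, n_t)
    global_latent = _band_limited_noise(rng, n_t, spec.fs)

    w = schedule.within_gain  # (K, n_t)
    b = schedule.between_gain  # (n_t,)
    s = schedule.noise_sd

    samples = np.empty((spec.n_channels, n_t))
    shared_by_comm = w * latents + b * global_latent  # (K, n_t)
    norm_by_comm = np.sqrt(w**2 + b**2 + s**2)  # (K, n_t)
    for k, lab in enumerate(labels):
        denom = np.where(norm_by_comm[k] > 0, norm_by_comm[k], 1.0)
        for ch in schedule.communities[lab]:
            noise = s * rng.standard_normal(n_t)
            samples[ch] = (shared_by_comm[k] + noise) / denom

    tags = spec.hemisphere_tags()
    seg = Segment(
        samples=samples,
        fs=spec.fs,
        channel_labels=[f"{tags[i]}{i:03d}" for i in range(spec.n_channels)],
        hemispheres=tags,
        annotations=(
            [] if condition == "interictal"
            else [(spec.onset_offset, "seizure_onset")]
        ),
        condition=condition,
        onset_time=spec.onset_offset,
        segment_id=segment_id,
    )

    step = max(1, int(round(spec.fs)))
    gt = GroundTruth(
        condition=condition,
        onset_time=spec.onset_offset,
        seed_key=[int(x) for x in np.atleast_1d(ss.entropy)],
        communities=schedule.communities,
        community_hemisphere=schedule.community_hemisphere,
        onset_community=schedule.onset_community,
        within_gain_1hz=[list(map(float, row[::step])) for row in w],
        between_gain_1hz=list(map(float, b[::step])),
        noise_sd=s,
    )
    return seg, gt


def generate_cohort(
    spec: CohortSpec,
    params: ScheduleParams | None = None,
) -> list[tuple[Segment, GroundTruth]]:
    """Generate the full cohort: focal, bilateral then interictal segments.

    Sub-seeds derive from ``(spec.seed, segment_index)`` so the cohort is a
    pure function of the spec and segments are mutually independent.
    """
    conditions = (
        ["focal"] * spec.n_focal
        + ["bilateral"] * spec.n_bilateral
        + ["interictal"] * spec.n_interictal
    )
    out = []
    for i, cond in enumerate(conditions):
        schedule = CouplingSchedule.for_condition(spec, cond, params)
        seg, gt = generate_segment(
            spec,
            schedule,
            cond,
            seed=np.random.SeedSequence((spec.seed, i)),
            segment_id=f"{cond}-{i:03d}",
        )
        out.append((seg, gt))
    return out
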