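"""Synthetic-data generators for the whole pipeline.

No subject-level recordings are distributed with the study this package
models, so every input is emulated here with planted, fully labelled ground
truth: BOLD cohorts whose response amplitude to a stimulus dimension differs
by sex inside designated regions, stimulus annotation tracks and event
schedules, tissue-probability volumes for mask construction, and gaze streams
whose fixation targets follow group-specific region-of-interest preferences.

Every generator is driven by an explicit integer seed and emits its ground
truth (per-voxel amplitudes, event lists, preference weights) next to the
data, so downstream recovery can always be checked against what was planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .types import (
    FEMALE,
    MALE,
    AnnotationTrack,
    BoldSeries,
    DynamicROI,
    EventTable,
    GazeEvent,
    GazeRecord,
)

__all__ = [
    "EffectRegion",
    "CohortSpec",
    "GazeScenario",
    "generate_cohort",
    "draw_amplitudes",
    "cohort_sexes",
    "generate_annotation_track",
    "generate_event_table",
    "generate_tissue_probability",
    "generate_gaze",
    "default_roi_tracks",
    "default_gaze_scenario",
    "region_block",
]

from .glm import DesignMatrix


def region_block(corner: Sequence[int], size: Sequence[int]) -> np.ndarray:
    """Voxel indices of an axis-aligned block — convenience for effect regions."""
    ranges = [np.arange(c, c + s) for c, s in zip(corner, size)]
    grid = np.meshgrid(*ranges, indexing="ij")
    return np.stack([g.ravel() for g in grid], axis=1)


@dataclass(frozen=True)
class EffectRegion:
    """A voxel set carrying a sex-dependent response amplitude.

    Per-subject amplitude is drawn as Normal(mean_for_sex, subject_sd), so the
    planted between-sex separation is Cohen's d = (amp_male - amp_female) /
    subject_sd — a single knob for classification difficulty.  ``regressor``
    names the design column the region responds to; None binds it to the
    cohort's default regressor of interest.
    """

    name: str
    voxels: np.ndarray  # (k, 3) integer indices
    amp_male: float
    amp_female: float
    subject_sd: float = 0.0
    regressor: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=int)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("voxels must be a (k, 3) index array")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be non-negative")
        object.__setattr__(self, "voxels", v)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated fMRI cohort.

    Defaults mirror the movie paradigm's timing (TR 2.6 s) on a deliberately
    small grid so that leave-one-subject-out decoding with permutation nulls
    runs in seconds; the noise is AR(1) Gaussian with marginal SD
    ``noise_sd`` and lag-1 coefficient ``noise_ar1``.
    """

    n_male: int = 10
    n_female: int = 10
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    tr_seconds: float = 2.6
    n_volumes: int = 200
    effect_regions: tuple[EffectRegion, ...] = ()
    noise_sd: float = 1.0
    noise_ar1: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_male < 1 or self.n_female < 1:
            raise ValueError("need at least one subject per sex")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.noise_ar1 < 1:
            raise ValueError("noise_ar1 must lie in [0, 1)")
        shape = np.asarray(self.grid_shape, int)
        for region in self.effect_regions:
            if np.any(region.voxels < 0) or np.any(region.voxels >= shape):
                raise ValueError(f"effect region {region.name!r} exceeds the grid")
        object.__setattr__(self, "effect_regions", tuple(self.effect_regions))

    @property
    def n_subjects(self) -> int:
        return self.n_male + self.n_female


def _ar1_noise(
    rng: np.random.Generator, shape: tuple[int, ...], n_t: int, sd: float, rho: float
) -> np.ndarray:
    """AR(1) Gaussian noise with marginal SD ``sd``, shaped (*shape, n_t)."""
    if sd == 0:
        return np.zeros(shape + (n_t,))
    innov_sd = sd * math.sqrt(1.0 - rho * rho)
    eps = rng.normal(0.0, innov_sd, size=shape + (n_t,))
    # stationary start so the marginal variance is exact from t=0
    eps[..., 0] = rng.normal(0.0, sd, size=shape)
    return lfilter([1.0], [1.0, -rho], eps, axis=-1)


def cohort_sexes(spec: CohortSpec) -> list[str]:
    """Fixed subject order: males first, then females."""
    return [MALE] * spec.n_male + [FEMALE] * spec.n_female


def draw_amplitudes(spec: CohortSpec) -> list[dict[str | None, np.ndarray]]:
    """Per-subject planted amplitude volumes, keyed by region regressor tag.

    Drawing amplitudes separately from the noise lets two simulated
    experiments share the same subject-level effect topography (pass the
    result to both :func:`generate_cohort` calls) while their measurement
    noise stays independent.
    """
    rng = np.random.default_rng([spec.seed, 1])
    out: list[dict[str | None, np.ndarray]] = []
    for sex in cohort_sexes(spec):
        vols: dict[str | None, np.ndarray] = {}
        for region in spec.effect_regions:
            key = region.regressor
            if key not in vols:
                vols[key] = np.zeros(spec.grid_shape)
            mu = region.amp_male if sex == MALE else region.amp_female
            a = rng.normal(mu, region.subject_sd) if region.subject_sd else mu
            vols[key][tuple(region.voxels.T)] = a
        out.append(vols)
    return out


def generate_cohort(
    spec: CohortSpec,
    design: DesignMatrix,
    regressor: str | None = None,
    amplitudes: list[dict[str | None, np.ndarray]] | None = None,
) -> list[BoldSeries]:
    """Simulate one BOLD series per subject from the forward model.

    Each subject's data are ``sum_r amplitude_r(voxel) * x_r(t) + AR(1)
    noise`` over the effect regions' regressors ``r`` (a region with
    ``regressor=None`` responds to ``regressor``, defaulting to the design's
    first task column).  Regressor tags absent from the design are silently
    inactive, so one amplitude draw can serve designs that model only a
    subset of the stimulus dimensions.  Subjects are emitted males first,
    then females, in a fixed order; planted amplitude volumes travel with
    each series as ``truth_amplitude`` keyed by resolved regressor name.
    """
    if design.n_timepoints != spec.n_volumes:
        raise ValueError(
            f"design has {design.n_timepoints} rows but spec requires "
            f"{spec.n_volumes} volumes"
        )
    default_name = regressor if regressor is not None else design.task_columns[0]
    if amplitudes is None:
        amplitudes = draw_amplitudes(spec)
    if len(amplitudes) != spec.n_subjects:
        raise ValueError("amplitudes list does not match the cohort size")
    noise_rng = np.random.default_rng([spec.seed, 2])
    subjects: list[BoldSeries] = []
    for idx, sex in enumerate(cohort_sexes(spec)):
        truth: dict[str, np.ndarray] = {}
        signal = np.zeros(spec.grid_shape + (spec.n_volumes,))
        for key, amp in amplitudes[idx].items():
            name = default_name if key is None else key
            if name not in design.columns:
                continue
            truth[name] = amp
            signal += amp[..., None] * design.column(name)
        noise = _ar1_noise(
            noise_rng, spec.grid_shape, spec.n_volumes, spec.noise_sd, spec.noise_ar1
        )
        subjects.append(
            BoldSeries(
                data=signal + noise,
                tr_seconds=spec.tr_seconds,
                subject_id=f"sub-{idx + 1:03d}",
                sex=sex,
                truth_amplitude=truth,
            )
        )
    return subjects


def generate_annotation_track(
    n_steps: int,
    step_seconds: float = 4.0,
    bursts: Sequence[tuple[float, float, float]] = (),
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> AnnotationTrack:
    """Piecewise-constant 0–100 rating track with optional Gaussian jitter.

    ``bursts`` are (start s, stop s, level) intervals; a grid point at time t
    takes the burst level when start <= t < stop.  Jittered values are clipped
    back into [0, 100].
    """
    times = np.arange(n_steps) * step_seconds
    span = n_steps * step_seconds
    values = np.zeros(n_steps)
    for start, stop, level in bursts:
        if not 0 <= level <= 100:
            raise ValueError(f"burst level {level} outside [0, 100]")
        if start < 0 or stop > span or start >= stop:
            raise ValueError(f"burst [{start}, {stop}) outside track span [0, {span})")
        values[(times >= start) & (times < stop)] = level
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        values = np.clip(values + rng.normal(0.0, jitter_sd, n_steps), 0.0, 100.0)
    return AnnotationTrack(times=times, values=values)


def generate_event_table(
    n_events: Mapping[str, int],
    duration_seconds: float = 1.5,
    iti_range: tuple[float, float] = (2.0, 3.0),
    seed: int = 0,
) -> EventTable:
    """Randomly ordered event schedule: fixed presentation time, jittered ITI.

    Emulates a rapid event-related picture design (1.5 s presentations
    separated by 2–3 s fixation).
    """
    rng = np.random.default_rng(seed)
    cats = [c for c, n in n_events.items() for _ in range(n)]
    rng.shuffle(cats)
    onsets = []
    t = float(rng.uniform(*iti_range))
    for _ in cats:
        onsets.append(t)
        t += duration_seconds + float(rng.uniform(*iti_range))
    return EventTable(
        frame=pd.DataFrame(
            {"onset": onsets, "duration": duration_seconds, "category": cats}
        )
    )


def generate_tissue_probability(
    grid_shape: tuple[int, int, int],
    gray_voxels: np.ndarray | None = None,
    gray_value: float = 0.9,
    background_value: float = 0.1,
) -> np.ndarray:
    """Gray-matter probability volume: high inside the gray set, low outside.

    Stands in for a segmented average T1: thresholding at the conventional
    0.25 keeps exactly the gray set.  ``gray_voxels=None`` marks the whole
    grid gray.
    """
    if not 0 <= background_value <= 0.25 < gray_value <= 1:
        raise ValueError("need background <= 0.25 < gray_value within [0, 1]")
    prob = np.full(grid_shape, background_value)
    if gray_voxels is None:
        prob[:] = gray_value
    else:
        gv = np.asarray(gray_voxels, int)
        if gv.size:
            prob[tuple(gv.T)] = gray_value
    return prob


# --------------------------------------------------------------------------
# gaze synthesis


def _square(cx: float, cy: float, half: float) -> np.ndarray:
    return np.array(
        [[cx - half, cy - half], [cx + half, cy - half],
         [cx + half, cy + half], [cx - half, cy + half]]
    )


def default_roi_tracks(frame_rate: float = 25.0) -> tuple[DynamicROI, ...]:
    """Static body-region ROIs for two actors (female left, male right).

    Face, chest, genital and buttocks regions per actor, 3°x3° squares —
    geometry is a stand-in for frame-by-frame hand-drawn regions on real
    footage, sufficient for dwell-time analysis.
    """
    rois = []
    for actor_sex, x0 in ((FEMALE, -6.0), (MALE, 6.0)):
        for name, (dx, dy) in {
            "face": (0.0, 5.0),
            "chest": (0.0, 1.5),
            "genital": (0.0, -2.5),
            "buttocks": (2.5, -2.5) if actor_sex == FEMALE else (-2.5, -2.5),
        }.items():
            rois.append(
                DynamicROI(
                    name=name,
                    actor_sex=actor_sex,
                    polygons=(_square(x0 + dx, dy, 1.5),),
                    frame_rate=frame_rate,
                )
            )
    return tuple(rois)


#: Default fixation-target preference weights per viewer group.  The planted
#: asymmetries mirror the dwell pattern this pipeline is built to detect:
#: male viewers favour the female actor's chest (~7% vs ~5% of viewing time)
#: while female viewers favour the male actor's face.
DEFAULT_PREFERENCES: dict[str, dict[str, float]] = {
    MALE: {
        "face_female": 0.12, "face_male": 0.10,
        "chest_female": 0.07, "chest_male": 0.02,
        "genital_female": 0.04, "genital_male": 0.02,
        "buttocks_female": 0.02, "buttocks_male": 0.01,
        "background": 0.60,
    },
    FEMALE: {
        "face_female": 0.11, "face_male": 0.14,
        "chest_female": 0.05, "chest_male": 0.02,
        "genital_female": 0.03, "genital_male": 0.02,
        "buttocks_female": 0.02, "buttocks_male": 0.01,
        "background": 0.60,
    },
}

#: Off-actor anchor points used for "background" fixations.
_BACKGROUND_ANCHORS = np.array(
    [[0.0, 8.0], [0.0, -8.0], [-12.0, 0.0], [12.0, 0.0], [0.0, 0.0]]
)


@dataclass(frozen=True)
class GazeScenario:
    """Conditions of a simulated eye-tracking clip.

    Fixation targets are drawn per fixation from the viewing group's
    preference weights over ROI keys (``"<roi>_<actor_sex>"`` plus
    ``"background"``); saccades follow a symmetric raised-cosine velocity
    profile whose peak velocity (2·amplitude/duration) always clears the
    30°/s detection threshold for amplitudes >= ``min_amplitude_deg``.
    """

    clip_duration: float = 12.0
    sample_rate: float = 1000.0
    roi_tracks: tuple[DynamicROI, ...] = field(default_factory=default_roi_tracks)
    preferences: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_PREFERENCES
    )
    fixation_mean_ms: float = 300.0
    fixation_min_ms: float = 120.0
    fixation_jitter_deg: float = 0.003
    min_amplitude_deg: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0 or self.clip_duration <= 0:
            raise ValueError("sample_rate and clip_duration must be positive")
        keys = {r.key for r in self.roi_tracks} | {"background"}
        for group, weights in self.preferences.items():
            if abs(sum(weights.values()) - 1.0) > 1e-9:
                raise ValueError(f"preference weights for {group!r} must sum to 1")
            unknown = set(weights) - keys
            if unknown:
                raise ValueError(f"unknown ROI keys in preferences: {sorted(unknown)}")


def _saccade_duration_s(amplitude_deg: float) -> float:
    """Main-sequence-flavoured duration: 21 ms + 2.2 ms per degree."""
    return (21.0 + 2.2 * amplitude_deg) / 1000.0


def _threshold_crossing_offset(
    amplitude: float, duration: float, vel_threshold: float
) -> float | None:
    """Time after saccade onset at which the analytic speed crosses threshold.

    The raised-cosine profile has speed v(τ) = Vp (1 - cos(2πτ/D)) / 2 with
    Vp = 2A/D; returns None when the peak never reaches the threshold.
    """
    vp = 2.0 * amplitude / duration
    if vp <= vel_threshold:
        return None
    return duration / (2.0 * math.pi) * math.acos(1.0 - 2.0 * vel_threshold / vp)


def generate_gaze(
    scenario: GazeScenario,
    group: str,
    subject_id: str = "sub-001",
    clip_id: str = "clip-01",
    seed: int | None = None,
    vel_threshold: float = 30.0,
) -> tuple[GazeRecord, list[GazeEvent]]:
    """Simulate one clip's gaze stream for a subject of the given group.

    Returns the sample stream and the ground-truth event list.  Saccade
    ground-truth events carry the *velocity-threshold crossing* span (the
    interval a velocity-threshold detector can in principle recover); the
    kinematic motion span extends one sub-threshold tail on either side.
    Fixation events carry the target ROI key.
    """
    if group not in scenario.preferences:
        raise ValueError(f"no preference weights for group {group!r}")
    rate = scenario.sample_rate
    min_dur = _saccade_duration_s(scenario.min_amplitude_deg)
    if rate * min_dur < 6:
        raise ValueError(
            f"sample_rate {rate} Hz too low to realise the saccade velocity "
            f"profile (minimum saccade lasts {min_dur * 1000:.0f} ms)"
        )
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n = int(round(scenario.clip_duration * rate))
    dt = 1.0 / rate
    x = np.empty(n)
    y = np.empty(n)
    events: list[GazeEvent] = []

    keys = list(scenario.preferences[group])
    weights = np.array([scenario.preferences[group][k] for k in keys])
    roi_by_key = {r.key: r for r in scenario.roi_tracks}

    def pick_target(current: np.ndarray) -> tuple[np.ndarray, str]:
        for _ in range(20):
            key = str(rng.choice(keys, p=weights))
            if key == "background":
                anchor = _BACKGROUND_ANCHORS[rng.integers(len(_BACKGROUND_ANCHORS))]
                target = anchor + rng.uniform(-0.8, 0.8, size=2)
            else:
                poly = roi_by_key[key].polygons[0]
                lo, hi = poly.min(axis=0), poly.max(axis=0)
                target = lo + (hi - lo) * rng.uniform(0.25, 0.75, size=2)
            if np.hypot(*(target - current)) >= scenario.min_amplitude_deg:
                return target, key
        # fall back: push the target outward along x to guarantee amplitude
        return current + np.array([scenario.min_amplitude_deg, 0.0]), "background"

    pos = np.array([0.0, 0.0])
    current_key = "background"
    i = 0
    while i < n:
        # --- fixation at the current position ---
        dur_ms = max(
            scenario.fixation_min_ms, rng.exponential(scenario.fixation_mean_ms)
        )
        n_fix = min(n - i, max(1, int(round(dur_ms / 1000.0 * rate))))
        jitter = np.zeros((n_fix, 2))
        if scenario.fixation_jitter_deg > 0:
            steps = rng.normal(0, scenario.fixation_jitter_deg, size=(n_fix, 2))
            for k in range(1, n_fix):
                jitter[k] = 0.9 * jitter[k - 1] + steps[k]
        x[i : i + n_fix] = pos[0] + jitter[:, 0]
        y[i : i + n_fix] = pos[1] + jitter[:, 1]
        events.append(
            GazeEvent(
                kind="fixation",
                start_ms=i * dt * 1000.0,
                end_ms=(i + n_fix) * dt * 1000.0,
                centroid=(float(pos[0]), float(pos[1])),
                roi=current_key,
            )
        )
        i += n_fix
        if i >= n:
            break
        # --- saccade to a new target ---
        target, next_key = pick_target(pos)
        amp = float(np.hypot(*(target - pos)))
        dur = _saccade_duration_s(amp)
        n_sac = int(round(dur * rate))
        if i + n_sac >= n:
            x[i:] = pos[0]
            y[i:] = pos[1]
            break
        tau = (np.arange(1, n_sac + 1)) * dt
        frac = tau / dur - np.sin(2 * np.pi * tau / dur) / (2 * np.pi)
        seg = pos[None, :] + (target - pos)[None, :] * frac[:, None]
        x[i : i + n_sac] = seg[:, 0]
        y[i : i + n_sac] = seg[:, 1]
        # motion starts between the last fixation sample (i-1) and sample i
        t0_ms = (i - 1) * dt * 1000.0
        off = _threshold_crossing_offset(amp, dur, vel_threshold)
        if off is not None:
            events.append(
                GazeEvent(
                    kind="saccade",
                    start_ms=t0_ms + off * 1000.0,
                    end_ms=t0_ms + (dur - off) * 1000.0,
                )
            )
        pos = target
        current_key = next_key
        i += n_sac

    t_ms = np.arange(n) * dt * 1000.0
    record = GazeRecord(
        t_ms=t_ms,
        x_deg=x,
        y_deg=y,
        valid=np.ones(n, dtype=bool),
        sample_rate=rate,
        subject_id=subject_id,
        clip_id=clip_id,
    )
    return record, events


def default_gaze_scenario(**overrides) -> GazeScenario:
    """The study-condition gaze scenario (1000 Hz, default ROI preferences)."""
    return GazeScenario(**overrides)
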