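"""Shared domain containers used across the simulation and analysis modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MALE = "male"
FEMALE = "female"
SEXES = (FEMALE, MALE)  # alphabetical; classifier decision > 0 means male


@dataclass(frozen=True)
class AnnotationTrack:
    """Dynamic stimulus-content rating on a regular time grid.

    Ratings live on a continuous 0–100 scale sampled every ``times[1]-times[0]``
    seconds (4 s in the movie paradigm this emulates).
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if t.size >= 2:
            steps = np.diff(t)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
                raise ValueError("times must have a constant step")
        if v.size and (v.min() < 0 or v.max() > 100):
            raise ValueError("rating values must lie in [0, 100]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def step_seconds(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0

    @property
    def span_seconds(self) -> float:
        return float(self.times[-1] + self.step_seconds) if self.times.size else 0.0


@dataclass(frozen=True)
class EventTable:
    """Event-related schedule: rows of (onset s, duration s, category)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        required = {"onset", "duration", "category"}
        if not required.issubset(df.columns):
            raise ValueError(f"event table needs columns {sorted(required)}")
        if (df["onset"] < 0).any():
            raise ValueError("event onsets must be non-negative")
        if (df["duration"] <= 0).any():
            raise ValueError("event durations must be positive")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    @property
    def categories(self) -> list[str]:
        return sorted(self.frame["category"].unique())


@dataclass
class BoldSeries:
    """One subject's 4-d BOLD stack (x, y, z, t) with timing and identity."""

    data: np.ndarray
    tr_seconds: float
    subject_id: str
    sex: str = ""
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    #: planted per-voxel response amplitude, keyed by design regressor name
    truth_amplitude: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4-dimensional (x, y, z, t)")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:-1]


@dataclass
class GazeRecord:
    """Raw gaze sample stream in degrees of visual angle at a fixed rate."""

    t_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    valid: np.ndarray
    sample_rate: float
    subject_id: str = ""
    clip_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.t_ms)
        if not (len(self.x_deg) == len(self.y_deg) == len(self.valid) == n):
            raise ValueError("gaze sample arrays must share a common length")
        steps = np.diff(np.asarray(self.t_ms, float))
        if steps.size and (np.any(steps <= 0) or not np.allclose(steps, steps[0])):
            raise ValueError("timestamps must increase with a constant step")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate


@dataclass(frozen=True)
class GazeEvent:
    """A parsed oculomotor event: saccade or fixation, in record time (ms)."""

    kind: str  # "saccade" | "fixation"
    start_ms: float
    end_ms: float
    centroid: tuple[float, float] | None = None
    roi: str | None = None  # generator ground truth only

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass(frozen=True)
class DynamicROI:
    """A named body-region of interest tracked frame-by-frame on an actor.

    ``polygons`` holds one (k, 2) vertex array per video frame (degrees).
    A single-element list denotes a static region reused for every frame.
    """

    name: str
    actor_sex: str
    polygons: tuple[np.ndarray, ...]
    frame_rate: float

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        polys = tuple(np.asarray(p, dtype=float) for p in self.polygons)
        if not polys:
            raise ValueError("at least one frame polygon is required")
        for p in polys:
            if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
                raise ValueError("each polygon needs >= 3 (x, y) vertices")
        object.__setattr__(self, "polygons", polys)

    @property
    def key(self) -> str:
        return f"{self.name}_{self.actor_sex}"

    def polygon_at(self, t_ms: float) -> np.ndarray:
        if len(self.polygons) == 1:
            return self.polygons[0]
        idx = int(np.floor(t_ms / 1000.0 * self.frame_rate))
        return self.polygons[min(max(idx, 0), len(self.polygons) - 1)]

    @property
    def is_static(self) -> bool:
        return len(self.polygons) == 1
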