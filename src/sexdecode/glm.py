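"""First-level GLM: regressor construction and voxel-wise least squares.

The forward model for one subject's run is ``Y = X B + E`` where ``Y`` is the
(volumes x voxels) BOLD matrix, ``X`` the design matrix whose task columns are
stimulus time courses convolved with a canonical haemodynamic response
function (HRF), and ``B`` the voxel-wise coefficients ("beta maps").
Betas are estimated by ordinary least squares; single-subject inference is not
performed here (the maps feed group statistics and pattern classification),
so no prewhitening of the residual autocorrelation is applied.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import AnnotationTrack, BoldSeries, EventTable

__all__ = [
    "Hrf",
    "DesignMatrix",
    "BetaMap",
    "ContrastMap",
    "canonical_hrf",
    "resample_track",
    "convolve",
    "stick_regressors",
    "build_design",
    "fit_glm",
    "contrast",
]

MICROTIME_BINS = 16  # micro-time bins per TR for event onset placement


@dataclass(frozen=True)
class Hrf:
    """Sampled haemodynamic impulse response.

    ``kernel[k]`` is the response at time ``k * dt`` seconds after a unit
    impulse; the peak is normalised to 1 (the GLM absorbs overall scale into
    the betas).
    """

    dt: float
    kernel: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=float)
        if self.dt <= 0:
            raise ValueError("hrf dt must be positive")
        if not np.all(np.isfinite(k)):
            raise ValueError("hrf kernel contains non-finite values")
        object.__setattr__(self, "kernel", k)


def canonical_hrf(
    dt: float,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
    length: float = 32.0,
) -> Hrf:
    """Canonical double-gamma HRF (SPM-convention parameters).

    The kernel is the difference of two gamma densities: a response peaking
    near ``peak_delay - peak_disp`` seconds and an undershoot peaking near
    ``undershoot_delay``, weighted 1 : ``undershoot_ratio``.  Sampled on
    ``[0, length)`` at step ``dt`` and normalised to unit peak.
    """
    if length < 32.0 - 1e-9:
        raise ValueError("hrf support must cover at least 32 s")
    t = np.arange(0.0, length, dt)
    peak = stats.gamma.pdf(t, a=peak_delay / peak_disp, scale=peak_disp)
    undershoot = stats.gamma.pdf(
        t, a=undershoot_delay / undershoot_disp, scale=undershoot_disp
    )
    kernel = peak - undershoot_ratio * undershoot
    kernel = kernel / np.max(kernel)
    return Hrf(dt=dt, kernel=kernel)


def volume_midpoints(tr_seconds: float, n_volumes: int) -> np.ndarray:
    """Acquisition reference times: mid-volume (slice-time-corrected) points."""
    return (np.arange(n_volumes) + 0.5) * tr_seconds


def resample_track(
    track: AnnotationTrack, tr_seconds: float, n_volumes: int
) -> np.ndarray:
    """Resample an annotation track to one value per functional volume.

    Linear interpolation at volume midpoints; times outside the track span
    are held at the nearest endpoint value.
    """
    if len(track.times) == 0:
        raise ValueError("annotation track is empty")
    if tr_seconds <= 0 or n_volumes <= 0:
        raise ValueError("tr_seconds and n_volumes must be positive")
    t_mid = volume_midpoints(tr_seconds, n_volumes)
    return np.interp(t_mid, track.times, track.values)


def convolve(regressor: np.ndarray, hrf: Hrf) -> np.ndarray:
    """Causal discrete convolution of a regressor with the HRF kernel.

    The regressor must be sampled at the kernel's ``dt``.  The result is
    truncated to the regressor's length, so late responses falling beyond the
    run end are dropped.
    """
    reg = np.asarray(regressor, dtype=float)
    if reg.ndim != 1:
        raise ValueError("regressor must be one-dimensional")
    return np.convolve(reg, hrf.kernel)[: reg.size]


def stick_regressors(
    events: EventTable,
    tr_seconds: float,
    n_volumes: int,
    hrf: Hrf | None = None,
) -> pd.DataFrame:
    """Event-related "stick function" regressors, one column per category.

    Each event contributes a unit impulse at its onset, placed on a micro-time
    grid of ``MICROTIME_BINS`` bins per TR (nearest bin), convolved with the
    HRF sampled at the micro-time step, then read out at volume midpoints.
    Simultaneous events of one category superpose.
    """
    dt = tr_seconds / MICROTIME_BINS
    if hrf is None:
        hrf = canonical_hrf(dt)
    elif abs(hrf.dt - dt) > 1e-12:
        raise ValueError(
            f"hrf dt {hrf.dt} does not match micro-time step {dt} "
            f"(= tr / {MICROTIME_BINS})"
        )
    run_end = tr_seconds * n_volumes
    df = events.frame
    if (df["onset"] >= run_end).any():
        bad = df.loc[df["onset"] >= run_end, "onset"].iloc[0]
        raise ValueError(f"event onset {bad} s lies beyond run end {run_end} s")
    n_micro = n_volumes * MICROTIME_BINS
    categories = sorted(df["category"].unique())
    out = {}
    mid_idx = np.arange(n_volumes) * MICROTIME_BINS + MICROTIME_BINS // 2
    for cat in categories:
        impulses = np.zeros(n_micro)
        onsets = df.loc[df["category"] == cat, "onset"].to_numpy(dtype=float)
        bins = np.rint(onsets / dt).astype(int)
        bins = np.clip(bins, 0, n_micro - 1)
        np.add.at(impulses, bins, 1.0)
        conv = np.convolve(impulses, hrf.kernel)[:n_micro]
        out[cat] = conv[mid_idx]
    return pd.DataFrame(out)


@dataclass(frozen=True)
class DesignMatrix:
    """Time-by-regressor design: task columns, drift columns and intercept."""

    matrix: np.ndarray
    columns: tuple[str, ...]
    task_columns: tuple[str, ...]
    tr_seconds: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "columns", tuple(self.columns))
        object.__setattr__(self, "task_columns", tuple(self.task_columns))
        if m.ndim != 2 or m.shape[1] != len(self.columns):
            raise ValueError("matrix shape does not match column names")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("design column names must be unique")
        if "intercept" not in self.columns:
            raise ValueError("design must contain an intercept column")
        for name in self.task_columns:
            if name not in self.columns:
                raise ValueError(f"task column {name!r} not in design")
            if not np.any(m[:, self.columns.index(name)]):
                raise ValueError(f"task column {name!r} is all zero")

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.columns.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=list(self.columns))


def _drift_columns(n_volumes: int, order: int) -> dict[str, np.ndarray]:
    """Legendre polynomial drift regressors on [-1, 1] (order >= 1)."""
    x = np.linspace(-1.0, 1.0, n_volumes)
    return {
        f"drift_{k}": np.polynomial.legendre.Legendre.basis(k)(x)
        for k in range(1, order + 1)
    }


def build_design(
    task: Mapping[str, np.ndarray],
    tr_seconds: float,
    drift_order: int = 1,
) -> DesignMatrix:
    """Assemble a design from named task regressors plus drift and intercept."""
    if not task:
        raise ValueError("at least one task regressor is required")
    lengths = {len(v) for v in task.values()}
    if len(lengths) != 1:
        raise ValueError("task regressors differ in length")
    n = lengths.pop()
    cols: dict[str, np.ndarray] = {k: np.asarray(v, float) for k, v in task.items()}
    cols.update(_drift_columns(n, drift_order))
    cols["intercept"] = np.ones(n)
    matrix = np.column_stack(list(cols.values()))
    return DesignMatrix(
        matrix=matrix,
        columns=tuple(cols),
        task_columns=tuple(task),
        tr_seconds=tr_seconds,
    )


@dataclass
class BetaMap:
    """Voxel-wise OLS coefficients for one subject, plus residual variance."""

    coeffs: np.ndarray  # (n_columns, *spatial_shape)
    columns: tuple[str, ...]
    task_columns: tuple[str, ...]
    resid_var: np.ndarray  # (*spatial_shape,)
    df_resid: int
    subject_id: str
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def volume(self, name: str) -> np.ndarray:
        return self.coeffs[self.columns.index(name)]


@dataclass
class ContrastMap:
    """Contrast-weighted combination of a subject's task betas."""

    data: np.ndarray
    weights: tuple[float, ...]
    task_columns: tuple[str, ...]
    subject_id: str
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


def _collinear_columns(matrix: np.ndarray, columns: Sequence[str]) -> list[str]:
    """Name columns implicated in a rank deficiency via QR pivoting."""
    _, r, piv = _qr_pivoted(matrix)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(matrix.shape) * np.finfo(float).eps
    bad = piv[np.flatnonzero(diag <= tol)]
    small = [columns[i] for i in sorted(bad)]
    return small or list(columns)


def _qr_pivoted(matrix: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(matrix, mode="economic", pivoting=True)
    return q, r, piv


def fit_glm(bold: BoldSeries, design: DesignMatrix) -> BetaMap:
    """Ordinary-least-squares fit of the design to every voxel's time series."""
    data = bold.data
    n_vol = data.shape[-1]
    if design.n_timepoints != n_vol:
        raise ValueError(
            f"design has {design.n_timepoints} rows but BOLD has {n_vol} volumes"
        )
    x = design.matrix
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        names = _collinear_columns(x, design.columns)
        raise ValueError(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(names)
        )
    spatial = data.shape[:-1]
    y = data.reshape(-1, n_vol).T  # (T, V)
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = n_vol - rank
    with np.errstate(invalid="ignore", divide="ignore"):
        rvar = np.einsum("tv,tv->v", resid, resid) / max(dof, 1)
    return BetaMap(
        coeffs=beta.reshape(x.shape[1], *spatial),
        columns=design.columns,
        task_columns=design.task_columns,
        resid_var=rvar.reshape(spatial),
        df_resid=dof,
        subject_id=bold.subject_id,
        affine=bold.affine,
    )


def contrast(betas: BetaMap, weights: Sequence[float]) -> ContrastMap:
    """Weighted sum of task-column beta volumes (e.g. sexual minus landscape)."""
    w = np.asarray(weights, dtype=float)
    if w.size != len(betas.task_columns):
        raise ValueError(
            f"contrast vector length {w.size} does not match "
            f"{len(betas.task_columns)} task columns"
        )
    vol = np.zeros(betas.coeffs.shape[1:])
    for wi, name in zip(w, betas.task_columns):
        vol += wi * betas.volume(name)
    return ContrastMap(
        data=vol,
        weights=tuple(w),
        task_columns=betas.task_columns,
        subject_id=betas.subject_id,
        affine=betas.affine,
    )
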