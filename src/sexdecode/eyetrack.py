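"""Saccade/fixation parsing and dynamic-ROI dwell-time analysis.

Saccades are detected from instantaneous velocity and acceleration computed
by central differences on a lightly smoothed trace, with the conventional
video-oculography thresholds of 30°/s (velocity) and 4000°/s² (acceleration).
Fixations are the complement intervals.  Proportional dwell time per region
of interest is the fixated time spent inside the region's frame-concurrent
polygon, expressed as a percentage of the clip duration (so track loss and
saccadic time dilute every region equally); sex differences in dwell are
assessed with a linear mixed model (ROI x actor sex x subject sex fixed
effects, per-subject random intercept).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
import statsmodels.formula.api as smf
from shapely.geometry import Polygon

from .types import DynamicROI, GazeEvent, GazeRecord

__all__ = [
    "detect_saccades",
    "segment_fixations",
    "dwell_times",
    "analyze_gaze",
    "dwell_group_model",
    "dwell_sex_contrast",
]

VEL_THRESHOLD = 30.0  # deg/s
ACC_THRESHOLD = 4000.0  # deg/s^2


def _smooth3(a: np.ndarray) -> np.ndarray:
    """3-sample moving average with edge replication."""
    padded = np.concatenate([a[:1], a, a[-1:]])
    return np.convolve(padded, np.ones(3) / 3.0, mode="valid")


def gaze_kinematics(gaze: GazeRecord) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample speed (deg/s) and its rate of change (deg/s^2)."""
    dt = 1.0 / gaze.sample_rate
    x = _smooth3(np.asarray(gaze.x_deg, float))
    y = _smooth3(np.asarray(gaze.y_deg, float))
    vx = np.gradient(x, dt)
    vy = np.gradient(y, dt)
    speed = np.hypot(vx, vy)
    acc = np.gradient(speed, dt)
    return speed, acc


def detect_saccades(
    gaze: GazeRecord,
    vel_threshold: float = VEL_THRESHOLD,
    acc_threshold: float = ACC_THRESHOLD,
) -> list[GazeEvent]:
    """Velocity/acceleration-threshold saccade detection.

    A saccade is a maximal run of samples with speed strictly above
    ``vel_threshold`` whose onset half shows acceleration above
    ``acc_threshold`` and whose offset half shows deceleration below
    ``-acc_threshold``.  Returns events in record time (ms).
    """
    valid = np.asarray(gaze.valid, bool)
    if valid.sum() < 3:
        warnings.warn("fewer than 3 valid samples; no saccades detected",
                      RuntimeWarning, stacklevel=2)
        return []
    speed, acc = gaze_kinematics(gaze)
    fast = (speed > vel_threshold) & valid
    t = np.asarray(gaze.t_ms, float)
    events: list[GazeEvent] = []
    edges = np.flatnonzero(np.diff(fast.astype(int)))
    starts = list(edges[fast[edges + 1]] + 1) if edges.size else []
    stops = list(edges[~fast[edges + 1]]) if edges.size else []
    if fast[0]:
        starts = [0] + starts
    if fast[-1]:
        stops = stops + [len(fast) - 1]
    for s, e in zip(starts, stops):
        mid = (s + e) // 2
        onset_ok = np.any(acc[s : mid + 1] > acc_threshold)
        offset_ok = np.any(acc[mid : e + 1] < -acc_threshold)
        if onset_ok and offset_ok:
            events.append(GazeEvent(kind="saccade", start_ms=t[s], end_ms=t[e]))
    return events


def segment_fixations(
    gaze: GazeRecord,
    saccades: Sequence[GazeEvent],
    min_duration_ms: float = 50.0,
) -> list[GazeEvent]:
    """Fixations as inter-saccade intervals of sufficient duration.

    The centroid is the mean valid-sample position within the interval;
    sub-minimum gaps are dropped (they are reported by ``analyze_gaze``).
    """
    t = np.asarray(gaze.t_ms, float)
    valid = np.asarray(gaze.valid, bool)
    bounds = [t[0]]
    for sac in sorted(saccades, key=lambda ev: ev.start_ms):
        bounds.extend([sac.start_ms, sac.end_ms])
    bounds.append(t[-1])
    fixations = []
    for lo, hi in zip(bounds[::2], bounds[1::2]):
        if hi - lo < min_duration_ms:
            continue
        sel = (t >= lo) & (t <= hi) & valid
        if not sel.any():
            continue
        cx = float(np.mean(np.asarray(gaze.x_deg)[sel]))
        cy = float(np.mean(np.asarray(gaze.y_deg)[sel]))
        fixations.append(
            GazeEvent(kind="fixation", start_ms=lo, end_ms=hi, centroid=(cx, cy))
        )
    return fixations


def _points_in_roi(
    roi: DynamicROI, t_ms: np.ndarray, px: np.ndarray, py: np.ndarray
) -> np.ndarray:
    """Boundary-inclusive membership of gaze points in the frame-matched polygon."""
    pts = shapely.points(px, py)
    if roi.is_static:
        return shapely.covers(Polygon(roi.polygons[0]), pts)
    inside = np.zeros(len(t_ms), dtype=bool)
    frame_idx = np.floor(t_ms / 1000.0 * roi.frame_rate).astype(int)
    frame_idx = np.clip(frame_idx, 0, len(roi.polygons) - 1)
    for f in np.unique(frame_idx):
        sel = frame_idx == f
        inside[sel] = shapely.covers(Polygon(roi.polygons[f]), pts[sel])
    return inside


def dwell_times(
    gaze: GazeRecord,
    fixations: Sequence[GazeEvent],
    rois: Sequence[DynamicROI],
    clip_duration_s: float | None = None,
    denominator: str = "clip",
    include_background: bool = False,
) -> pd.DataFrame:
    """Proportional dwell time (%) per ROI for one subject and clip.

    A fixation sample counts toward an ROI when its position lies inside
    (boundary inclusive) the ROI polygon of the concurrent video frame.
    ``denominator="clip"`` divides by the clip duration; ``"fixated"``
    divides by the total valid fixated time instead.  With
    ``include_background`` a pseudo-ROI row collects fixated time inside no
    ROI, so over disjoint ROIs the rows sum to 100% of fixated time (under
    the ``"fixated"`` rule).
    """
    if denominator not in ("clip", "fixated"):
        raise ValueError(f"unknown denominator rule {denominator!r}")
    t = np.asarray(gaze.t_ms, float)
    valid = np.asarray(gaze.valid, bool)
    dt_s = 1.0 / gaze.sample_rate
    in_fix = np.zeros(len(t), dtype=bool)
    for fix in fixations:
        in_fix |= (t >= fix.start_ms) & (t <= fix.end_ms)
    in_fix &= valid
    if clip_duration_s is None:
        clip_duration_s = (t[-1] - t[0]) / 1000.0 + dt_s
    denom_s = clip_duration_s if denominator == "clip" else max(in_fix.sum() * dt_s, dt_s)

    px = np.asarray(gaze.x_deg, float)[in_fix]
    py = np.asarray(gaze.y_deg, float)[in_fix]
    tf = t[in_fix]
    rows = []
    any_inside = np.zeros(len(tf), dtype=bool)
    for roi in rois:
        inside = _points_in_roi(roi, tf, px, py)
        any_inside |= inside
        rows.append(
            {
                "subject_id": gaze.subject_id,
                "clip_id": gaze.clip_id,
                "roi": roi.name,
                "actor_sex": roi.actor_sex,
                "dwell_pct": 100.0 * inside.sum() * dt_s / denom_s,
            }
        )
    if include_background:
        rows.append(
            {
                "subject_id": gaze.subject_id,
                "clip_id": gaze.clip_id,
                "roi": "background",
                "actor_sex": "none",
                "dwell_pct": 100.0 * (~any_inside).sum() * dt_s / denom_s,
            }
        )
    return pd.DataFrame(rows)


def analyze_gaze(
    gaze: GazeRecord,
    rois: Sequence[DynamicROI],
    vel_threshold: float = VEL_THRESHOLD,
    acc_threshold: float = ACC_THRESHOLD,
    min_fixation_ms: float = 50.0,
    clip_duration_s: float | None = None,
    denominator: str = "clip",
) -> tuple[pd.DataFrame, list[GazeEvent], list[GazeEvent]]:
    """Full per-record pipeline: detect, segment, dwell.  Returns
    (dwell table, saccades, fixations)."""
    saccades = detect_saccades(gaze, vel_threshold, acc_threshold)
    fixations = segment_fixations(gaze, saccades, min_fixation_ms)
    table = dwell_times(gaze, fixations, rois, clip_duration_s, denominator)
    return table, saccades, fixations


def dwell_group_model(table: pd.DataFrame):
    """Linear mixed model for dwell: ROI x actor sex x subject sex.

    Fits ``dwell_pct ~ C(roi) * C(actor_sex) * C(subject_sex)`` with a
    per-subject random intercept by REML and returns ``(fit, term_tests)``
    where ``term_tests`` is a tidy frame of Wald chi-square statistics per
    fixed-effect term.  Raises when any design cell is empty.
    """
    required = {"subject_id", "subject_sex", "roi", "actor_sex", "dwell_pct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"dwell table is missing columns {sorted(missing)}")
    cells = table.groupby(["roi", "actor_sex", "subject_sex"], observed=True).size()
    full = pd.MultiIndex.from_product(
        [table["roi"].unique(), table["actor_sex"].unique(),
         table["subject_sex"].unique()],
        names=["roi", "actor_sex", "subject_sex"],
    )
    empty = full.difference(cells.index)
    if len(empty):
        raise ValueError(f"empty design cells: {list(empty)}")
    model = smf.mixedlm(
        "dwell_pct ~ C(roi) * C(actor_sex) * C(subject_sex)",
        data=table,
        groups=table["subject_id"],
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-sample REML convergence chatter
        fit = model.fit(reml=True)
    try:
        tests = fit.wald_test_terms(scalar=True)
        tidy = tests.table.reset_index().rename(
            columns={"index": "term", "statistic": "wald_chi2", "pvalue": "p_value"}
        )
    except ValueError:
        # degenerate data (e.g. constant response): parameter covariance is
        # singular, so every term test is undefined -> NaN statistics
        terms = [t for t in fit.model.data.design_info.term_names]
        tidy = pd.DataFrame(
            {"term": terms, "wald_chi2": np.nan, "p_value": np.nan,
             "df_constraint": np.nan}
        )
    return fit, tidy


def dwell_sex_contrast(fit, roi: str = "chest", actor_sex: str = "female") -> dict:
    """Male-minus-female dwell difference at one (roi, actor-sex) cell.

    Assembles the single-degree-of-freedom contrast from the mixed model's
    fixed effects (every term that distinguishes male from female viewers at
    the given cell) and returns ``{"effect", "z", "p_value"}`` via a Wald
    test.  This targets the planted group preference directly, e.g. the
    male-viewer bias toward the female actor's chest region.
    """
    names = list(fit.model.exog_names)
    r = np.zeros(len(names))
    male_tag = "C(subject_sex)[T.male]"
    for i, name in enumerate(names):
        parts = name.split(":")
        if male_tag not in parts:
            continue
        ok = True
        for part in parts:
            if part == male_tag:
                continue
            if part.startswith("C(roi)"):
                ok &= part == f"C(roi)[T.{roi}]"
            elif part.startswith("C(actor_sex)"):
                ok &= part == f"C(actor_sex)[T.{actor_sex}]"
            else:
                ok = False
        if ok:
            r[i] = 1.0
    if not r.any():
        raise ValueError(f"no fixed-effect terms match roi={roi!r}, "
                         f"actor_sex={actor_sex!r}")
    tt = fit.t_test(r[None, :])
    return {
        "effect": float(np.squeeze(tt.effect)),
        "z": float(np.squeeze(tt.tvalue)),
        "p_value": float(np.squeeze(tt.pvalue)),
    }
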