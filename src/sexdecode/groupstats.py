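"""Second-level group comparison of contrast maps.

Voxel-wise two-sample t statistics between the male and female groups,
cluster-level family-wise-error control by max-cluster-size permutation
(shuffling subject group labels, which is exact under exchangeability), and
per-ROI mean-beta summaries from an integer label volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .glm import ContrastMap

__all__ = ["GroupTMap", "two_sample_tmap", "cluster_fwe", "roi_means"]

#: 26-neighbour connectivity structure for volumetric clustering.
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


def _stack(maps: Iterable[ContrastMap | np.ndarray]) -> np.ndarray:
    arrs = [m.data if isinstance(m, ContrastMap) else np.asarray(m, float) for m in maps]
    return np.stack(arrs, axis=0)


@dataclass
class GroupTMap:
    """Two-sample t statistic volume (group a minus group b)."""

    t: np.ndarray
    df: int
    n_a: int
    n_b: int
    zero_variance: np.ndarray  # voxels where pooled variance was 0 (t set to 0)


def _tmap_from_stack(stack: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t over axis 0; zero-variance voxels -> 0."""
    a = stack[is_a]
    b = stack[~is_a]
    n1, n2 = len(a), len(b)
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    ssa = ((a - ma) ** 2).sum(axis=0)
    ssb = ((b - mb) ** 2).sum(axis=0)
    pooled = (ssa + ssb) / (n1 + n2 - 2)
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (ma - mb) / se
    return np.where(se > 0, t, 0.0)


def two_sample_tmap(
    maps_a: Sequence[ContrastMap | np.ndarray],
    maps_b: Sequence[ContrastMap | np.ndarray],
    mask: np.ndarray | None = None,
) -> GroupTMap:
    """Voxel-wise pooled-variance two-sample t map (a minus b)."""
    a, b = _stack(maps_a), _stack(maps_b)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("groups have mismatched spatial shapes")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two subjects per group")
    stack = np.concatenate([a, b], axis=0)
    is_a = np.zeros(len(stack), dtype=bool)
    is_a[: len(a)] = True
    t = _tmap_from_stack(stack, is_a)
    se_zero = _pooled_se_zero(stack, is_a)
    if se_zero.any():
        warnings.warn(
            f"{int(se_zero.sum())} voxel(s) had zero pooled variance; t set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    if mask is not None:
        t = np.where(mask, t, 0.0)
    return GroupTMap(t=t, df=len(a) + len(b) - 2, n_a=len(a), n_b=len(b),
                     zero_variance=se_zero)


def _pooled_se_zero(stack: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    a, b = stack[is_a], stack[~is_a]
    ssa = ((a - a.mean(axis=0)) ** 2).sum(axis=0)
    ssb = ((b - b.mean(axis=0)) ** 2).sum(axis=0)
    return (ssa + ssb) == 0


def _cluster_sizes(
    tvol: np.ndarray, threshold: float, two_sided: bool
) -> tuple[np.ndarray, np.ndarray, int]:
    """Label supra-threshold clusters; returns (labels, sizes, n_clusters)."""
    supra = np.abs(tvol) > threshold if two_sided else tvol > threshold
    labels, n = ndimage.label(supra, structure=CONNECTIVITY_26)
    if n == 0:
        return labels, np.array([], dtype=int), 0
    sizes = ndimage.sum_labels(supra, labels, index=np.arange(1, n + 1)).astype(int)
    return labels, sizes, n


def cluster_fwe(
    maps_a: Sequence[ContrastMap | np.ndarray],
    maps_b: Sequence[ContrastMap | np.ndarray],
    mask: np.ndarray | None = None,
    forming_threshold_p: float = 0.001,
    two_sided: bool = True,
    n_perm: int = 500,
    seed: int = 0,
    _permutations: Iterable[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Cluster table with permutation-based FWE-corrected p-values.

    Clusters are maximal 26-connected components of voxels whose |t| (or t,
    one-sided) exceeds the t quantile matching ``forming_threshold_p``.  The
    corrected p of a cluster of size s is the +1-smoothed proportion of
    group-label permutations whose *maximum* cluster size reaches s.

    ``_permutations`` injects an explicit sequence of boolean group
    assignments (testing hook; default: seeded random shuffles).
    """
    if _permutations is None and n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    a, b = _stack(maps_a), _stack(maps_b)
    stack = np.concatenate([a, b], axis=0)
    n1 = len(a)
    is_a = np.zeros(len(stack), dtype=bool)
    is_a[:n1] = True
    df = len(stack) - 2
    if two_sided:
        t_thr = stats.t.ppf(1.0 - forming_threshold_p / 2.0, df)
    else:
        t_thr = stats.t.ppf(1.0 - forming_threshold_p, df)

    def masked(t):
        return np.where(mask, t, 0.0) if mask is not None else t

    t_obs = masked(_tmap_from_stack(stack, is_a))
    labels, sizes, n_clusters = _cluster_sizes(t_obs, t_thr, two_sided)

    if _permutations is None:
        rng = np.random.default_rng(seed)
        perms = []
        for _ in range(n_perm):
            perm_is_a = np.zeros(len(stack), dtype=bool)
            perm_is_a[rng.permutation(len(stack))[:n1]] = True
            perms.append(perm_is_a)
    else:
        perms = [np.asarray(p, bool) for p in _permutations]
    max_sizes = np.empty(len(perms), dtype=int)
    for k, perm_is_a in enumerate(perms):
        t_perm = masked(_tmap_from_stack(stack, perm_is_a))
        _, psizes, pn = _cluster_sizes(t_perm, t_thr, two_sided)
        max_sizes[k] = psizes.max() if pn else 0

    rows = []
    for cid in range(1, n_clusters + 1):
        in_cluster = labels == cid
        size = int(sizes[cid - 1])
        tvals = np.where(in_cluster, t_obs, 0.0)
        flat_peak = np.abs(tvals).argmax() if two_sided else tvals.argmax()
        peak_idx = np.unravel_index(flat_peak, t_obs.shape)
        p_fwe = (1 + int((max_sizes >= size).sum())) / (len(perms) + 1)
        rows.append(
            {
                "cluster_id": cid,
                "size": size,
                "peak_t": float(t_obs[peak_idx]),
                "peak_i": int(peak_idx[0]),
                "peak_j": int(peak_idx[1]),
                "peak_k": int(peak_idx[2]),
                "p_fwe": p_fwe,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["cluster_id", "size", "peak_t", "peak_i", "peak_j", "peak_k", "p_fwe"],
    )
    return table.sort_values("size", ascending=False, ignore_index=True)


def roi_means(
    contrast_maps: Sequence[ContrastMap],
    label_volume: np.ndarray,
    groups: Sequence[str] | None = None,
    label_names: dict[int, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject mean contrast value within each labelled ROI.

    Returns ``(per_subject, summary)``: the long per-subject table and a
    group-level summary with means and t-based 95% confidence intervals.
    Label 0 is background and skipped.
    """
    labels = np.asarray(label_volume)
    ids = sorted(int(v) for v in np.unique(labels) if v != 0)
    if not ids:
        raise ValueError("label volume contains no non-zero ROI labels")
    rows = []
    for s, cmap in enumerate(contrast_maps):
        group = groups[s] if groups is not None else ""
        for lid in ids:
            roi = labels == lid
            rows.append(
                {
                    "subject_id": cmap.subject_id,
                    "group": group,
                    "roi": label_names.get(lid, str(lid)) if label_names else str(lid),
                    "mean_beta": float(cmap.data[roi].mean()),
                }
            )
    per_subject = pd.DataFrame(rows)

    def ci(series: pd.Series) -> tuple[float, float]:
        n = len(series)
        m = series.mean()
        if n < 2:
            return (m, m)
        half = stats.t.ppf(0.975, n - 1) * series.std(ddof=1) / np.sqrt(n)
        return (m - half, m + half)

    grp_cols = ["roi"] if groups is None else ["group", "roi"]
    summary_rows = []
    for key, sub in per_subject.groupby(grp_cols):
        lo, hi = ci(sub["mean_beta"])
        row = dict(zip(grp_cols, key if isinstance(key, tuple) else (key,)))
        row.update(
            mean=sub["mean_beta"].mean(), n=len(sub), ci_low=lo, ci_high=hi
        )
        summary_rows.append(row)
    return per_subject, pd.DataFrame(summary_rows)
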