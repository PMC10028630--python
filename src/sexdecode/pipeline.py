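"""Study composition and orchestration.

This module wires the simulation, GLM, group-statistics, MVPA and
eye-tracking modules into the two-experiment protocol the package models:

* a *movie* run whose sexual-content annotation track (0–100, 4-s steps) is
  resampled to the TR and HRF-convolved, together with a nonsexual *control*
  annotation dimension;
* a *picture* run whose sexual/landscape/human picture events are modelled
  with HRF-convolved stick functions, contrasted sexual minus landscape;
* sex decoding within each experiment (linear kernel), cross-experiment
  generalisation (radial-basis kernel), and the control-dimension
  cross-tests that are expected to fail when topographies are disjoint;
* an eye-tracking arm with group-dependent dwell preferences.

`run_stage` provides a file-based, manifest-tracked version of the same flow
for the command line; `demo_end_to_end` runs everything in memory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import glm, groupstats, io, mvpa, synthdata
from .eyetrack import analyze_gaze, dwell_group_model
from .types import FEMALE, MALE, BoldSeries

__all__ = [
    "PipelineConfig",
    "movie_paradigm",
    "picture_paradigm",
    "study_cohort_spec",
    "simulate_study",
    "decode_study",
    "simulate_dwell_table",
    "demo_end_to_end",
    "run_stage",
    "STAGES",
]


# --------------------------------------------------------------------------
# configuration


def _strict_from_dict(cls, data: dict):
    import typing

    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    hints = typing.get_type_hints(cls)
    kwargs = {}
    for f in fields(cls):
        if f.name in data:
            val = data[f.name]
            ftype = hints.get(f.name)
            if dataclasses.is_dataclass(ftype) and isinstance(val, dict):
                val = _strict_from_dict(ftype, val)
            elif isinstance(val, list):
                val = tuple(val)
            kwargs[f.name] = val
    return cls(**kwargs)


@dataclass
class GlmOptions:
    drift_order: int = 1
    hrf_peak_delay: float = 6.0
    hrf_undershoot_delay: float = 16.0
    hrf_undershoot_ratio: float = 1.0 / 6.0


@dataclass
class GroupOptions:
    forming_threshold_p: float = 0.001
    two_sided: bool = True
    n_perm: int = 500
    seed: int = 11


@dataclass
class MvpaOptions:
    mask_threshold: float = 0.25
    kernel: str = "linear"
    cross_kernel: str = "rbf"
    C: float = 1.0
    n_perm: int = 1000
    seed: int = 12
    normalization: str = "per_map"


@dataclass
class EyetrackOptions:
    vel_threshold: float = 30.0
    acc_threshold: float = 4000.0
    min_fixation_ms: float = 50.0
    denominator: str = "clip"
    n_male: int = 15
    n_female: int = 15
    n_clips: int = 4
    clip_duration: float = 12.0
    sample_rate: float = 1000.0
    seed: int = 13


@dataclass
class SimulateOptions:
    n_male: int = 10
    n_female: int = 10
    grid_shape: tuple = (12, 12, 12)
    n_volumes: int = 160
    tr_seconds: float = 2.6
    effect_d: float = 2.0
    subject_sd: float = 0.5
    noise_sd: float = 1.5
    noise_ar1: float = 0.3
    seed: int = 10


@dataclass
class PipelineConfig:
    """Full configuration of a file-based pipeline run."""

    out_root: str = "pipeline_out"
    simulate: SimulateOptions = field(default_factory=SimulateOptions)
    glm: GlmOptions = field(default_factory=GlmOptions)
    group: GroupOptions = field(default_factory=GroupOptions)
    mvpa: MvpaOptions = field(default_factory=MvpaOptions)
    eyetrack: EyetrackOptions = field(default_factory=EyetrackOptions)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _strict_from_dict(cls, data)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: conv(getattr(obj, f.name)) for f in fields(obj)}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return conv(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# --------------------------------------------------------------------------
# paradigms


def movie_paradigm(
    n_volumes: int = 160,
    tr_seconds: float = 2.6,
    seed: int = 0,
    jitter_sd: float = 5.0,
    drift_order: int = 1,
) -> tuple[glm.DesignMatrix, dict]:
    """Movie-run design: sexual and control annotation regressors.

    Nine 12-s sexual-content episodes and nine interleaved control episodes
    (nonsexual vocal interaction), rated 0–100 on a 4-s grid, resampled to
    the TR and convolved with the canonical HRF.
    """
    duration = n_volumes * tr_seconds
    n_steps = int(duration // 4.0)
    span = n_steps * 4.0
    n_clips = 9
    slot = span / n_clips
    sexual_bursts = [(i * slot + 2.0, i * slot + 14.0, 100.0) for i in range(n_clips)]
    control_bursts = [(i * slot + 20.0, i * slot + 32.0, 100.0)
                      for i in range(n_clips) if i * slot + 32.0 < span]
    track_sex = synthdata.generate_annotation_track(
        n_steps, 4.0, sexual_bursts, jitter_sd=jitter_sd, seed=seed
    )
    track_ctl = synthdata.generate_annotation_track(
        n_steps, 4.0, control_bursts, jitter_sd=jitter_sd, seed=seed + 1
    )
    hrf = glm.canonical_hrf(tr_seconds)
    # ratings are rescaled to a 0-1 content fraction so planted amplitudes
    # and noise_sd share one unit (peak BOLD response per full-content epoch)
    task = {
        "sexual": glm.convolve(
            glm.resample_track(track_sex, tr_seconds, n_volumes) / 100.0, hrf
        ),
        "control": glm.convolve(
            glm.resample_track(track_ctl, tr_seconds, n_volumes) / 100.0, hrf
        ),
    }
    design = glm.build_design(task, tr_seconds, drift_order=drift_order)
    return design, {"sexual_track": track_sex, "control_track": track_ctl}


def picture_paradigm(
    n_volumes: int = 160,
    tr_seconds: float = 2.6,
    seed: int = 0,
    drift_order: int = 1,
) -> tuple[glm.DesignMatrix, synthdata.EventTable]:
    """Picture-run design: event-related categories as stick regressors."""
    duration = n_volumes * tr_seconds
    events = synthdata.generate_event_table(
        {"sexual": 24, "landscape": 36, "human": 36}, seed=seed
    )
    frame = events.frame
    frame = frame[frame["onset"] < duration - 20.0].reset_index(drop=True)
    events = synthdata.EventTable(frame=frame)
    sticks = glm.stick_regressors(events, tr_seconds, n_volumes)
    design = glm.build_design(
        {c: sticks[c].to_numpy() for c in sticks.columns},
        tr_seconds,
        drift_order=drift_order,
    )
    return design, events


def study_cohort_spec(
    sim: SimulateOptions, seed: int | None = None, effect_d: float | None = None
) -> synthdata.CohortSpec:
    """Cohort spec with the study's planted regions.

    The sexual dimension drives a 4x4x4 block, the control dimension a
    *disjoint* 4x4x4 block; both carry the same between-sex separation
    (Cohen's d = ``effect_d`` across subjects).
    """
    d = sim.effect_d if effect_d is None else effect_d
    sd = sim.subject_sd
    grid = tuple(sim.grid_shape)
    if min(grid) < 7:
        raise ValueError("grid_shape must be at least 7 per axis for the "
                         "two disjoint 3x3x3 effect regions")
    sexual_corner = tuple(max(1, g // 6) for g in grid)
    control_corner = tuple(g - 4 for g in grid)
    regions = (
        synthdata.EffectRegion(
            "sexual_response",
            synthdata.region_block(sexual_corner, (3, 3, 3)),
            amp_male=d * sd,
            amp_female=0.0,
            subject_sd=sd,
            regressor="sexual",
        ),
        synthdata.EffectRegion(
            "control_response",
            synthdata.region_block(control_corner, (3, 3, 3)),
            amp_male=d * sd,
            amp_female=0.0,
            subject_sd=sd,
            regressor="control",
        ),
    )
    return synthdata.CohortSpec(
        n_male=sim.n_male,
        n_female=sim.n_female,
        grid_shape=tuple(sim.grid_shape),
        tr_seconds=sim.tr_seconds,
        n_volumes=sim.n_volumes,
        effect_regions=regions,
        noise_sd=sim.noise_sd,
        noise_ar1=sim.noise_ar1,
        seed=sim.seed if seed is None else seed,
    )


# --------------------------------------------------------------------------
# in-memory study


@dataclass
class StudyData:
    """Subject-level maps for every decoding setting, plus labels and mask."""

    movie_maps: list[np.ndarray]
    picture_maps: list[np.ndarray]
    control_maps: list[np.ndarray]
    labels: list[str]
    subject_ids: list[str]
    mask: mvpa.GrayMatterMask
    movie_design: glm.DesignMatrix
    picture_design: glm.DesignMatrix
    cohorts: dict[str, list[BoldSeries]]


def simulate_study(
    sim: SimulateOptions,
    seed: int | None = None,
    glm_options: GlmOptions | None = None,
    mask_threshold: float = 0.25,
) -> StudyData:
    """Simulate both experiments for one cohort and run the first level.

    The two experiments share the subject-level effect topography (one
    amplitude draw feeds both forward models) while their acquisition noise
    is independent, which is what makes cross-experiment decoding possible.
    """
    base_seed = sim.seed if seed is None else seed
    opts = glm_options or GlmOptions()
    spec = study_cohort_spec(sim, seed=base_seed)
    movie_design, _ = movie_paradigm(
        sim.n_volumes, sim.tr_seconds, seed=base_seed, drift_order=opts.drift_order
    )
    picture_design, _ = picture_paradigm(
        sim.n_volumes, sim.tr_seconds, seed=base_seed + 1,
        drift_order=opts.drift_order,
    )
    amplitudes = synthdata.draw_amplitudes(spec)
    movie_cohort = synthdata.generate_cohort(spec, movie_design, amplitudes=amplitudes)
    picture_spec = dataclasses.replace(spec, seed=base_seed + 1)
    picture_cohort = synthdata.generate_cohort(
        picture_spec, picture_design, amplitudes=amplitudes
    )

    movie_maps, control_maps, picture_maps = [], [], []
    labels, ids = [], []
    for sub_movie, sub_pic in zip(movie_cohort, picture_cohort):
        beta_m = glm.fit_glm(sub_movie, movie_design)
        movie_maps.append(beta_m.volume("sexual"))
        control_maps.append(beta_m.volume("control"))
        beta_p = glm.fit_glm(sub_pic, picture_design)
        weights = [
            {"sexual": 1.0, "landscape": -1.0}.get(c, 0.0)
            for c in picture_design.task_columns
        ]
        picture_maps.append(glm.contrast(beta_p, weights).data)
        labels.append(sub_movie.sex)
        ids.append(sub_movie.subject_id)

    prob = synthdata.generate_tissue_probability(tuple(sim.grid_shape))
    mask = mvpa.mask_from_probability(prob, mask_threshold)
    return StudyData(
        movie_maps=movie_maps,
        picture_maps=picture_maps,
        control_maps=control_maps,
        labels=labels,
        subject_ids=ids,
        mask=mask,
        movie_design=movie_design,
        picture_design=picture_design,
        cohorts={"movie": movie_cohort, "picture": picture_cohort},
    )


def _cv_report(result: mvpa.CVResult, null: mvpa.PermutationNull | None, p) -> dict:
    out = {
        "accuracy_pct": 100.0 * result.accuracy,
        "kernel": result.kernel,
        "confusion": result.confusion.tolist(),
    }
    if null is not None:
        out.update(
            null_mean_pct=100.0 * float(null.accuracies.mean()),
            null_q95_pct=100.0 * null.q95,
            significant=bool(result.accuracy > null.q95),
            p_value=p,
            n_perm=null.n_perm,
        )
    return out


def decode_study(
    study: StudyData, options: MvpaOptions, n_perm: int | None = None
) -> dict:
    """All four within/cross decoding settings plus control cross-tests."""
    nperm = options.n_perm if n_perm is None else n_perm
    feats = {
        name: mvpa.build_features(
            maps, study.mask, study.labels, subject_ids=study.subject_ids,
            experiment=name, normalization=options.normalization,
        )
        for name, maps in (
            ("movie", study.movie_maps),
            ("picture", study.picture_maps),
            ("control", study.control_maps),
        )
    }
    report: dict = {}
    for name in ("movie", "picture", "control"):
        obs, null, p = mvpa.permutation_test(
            feats[name], kernel=options.kernel, n_perm=nperm,
            seed=options.seed, C=options.C,
        )
        report[f"{name}_loso"] = _cv_report(obs, null, p)
    pairs = [
        ("movie", "picture"), ("picture", "movie"),
        ("control", "movie"), ("movie", "control"),
    ]
    for train, test in pairs:
        obs, null, p = mvpa.cross_permutation_test(
            feats[train], feats[test], kernel=options.cross_kernel,
            n_perm=nperm, seed=options.seed, C=options.C,
        )
        report[f"cross_{train}_to_{test}"] = _cv_report(obs, null, p)

    # weight-map diagnostics against the second-level contrast
    males = [m for m, s in zip(study.movie_maps, study.labels) if s == MALE]
    females = [m for m, s in zip(study.movie_maps, study.labels) if s == FEMALE]
    tmap = groupstats.two_sample_tmap(males, females, study.mask.mask)
    wmap = mvpa.weight_map(feats["movie"], C=options.C)
    report["weight_contrast_r_movie"] = mvpa.weight_contrast_correlation(wmap, tmap)
    males_p = [m for m, s in zip(study.picture_maps, study.labels) if s == MALE]
    females_p = [m for m, s in zip(study.picture_maps, study.labels) if s == FEMALE]
    tmap_p = groupstats.two_sample_tmap(males_p, females_p, study.mask.mask)
    wmap_p = mvpa.weight_map(feats["picture"], C=options.C)
    report["weight_contrast_r_picture"] = mvpa.weight_contrast_correlation(
        wmap_p, tmap_p
    )
    return report


def null_accuracy_distribution(
    seed: int = 0,
    n_male: int = 10,
    n_female: int = 10,
    grid_shape: tuple = (12, 12, 12),
    n_volumes: int = 160,
    n_perm: int = 200,
) -> mvpa.PermutationNull:
    """Label-shuffle null of LOSO accuracy on a cohort with no sex effect.

    Simulates pure AR(1)-noise BOLD for a balanced cohort, runs the full
    first-level GLM and feature construction, and returns the permutation
    null distribution of leave-one-subject-out accuracy.  On null data its
    mean estimates the classifier's chance level (theoretically 50%).
    """
    design, _ = movie_paradigm(n_volumes, 2.6, seed=seed)
    spec = synthdata.CohortSpec(
        n_male=n_male, n_female=n_female, grid_shape=tuple(grid_shape),
        tr_seconds=2.6, n_volumes=n_volumes, effect_regions=(),
        noise_sd=1.5, noise_ar1=0.3, seed=seed,
    )
    cohort = synthdata.generate_cohort(spec, design)
    maps = [glm.fit_glm(s, design).volume("sexual") for s in cohort]
    prob = synthdata.generate_tissue_probability(tuple(grid_shape))
    mask = mvpa.mask_from_probability(prob)
    feats = mvpa.build_features(maps, mask, [s.sex for s in cohort])
    _, null, _ = mvpa.permutation_test(feats, n_perm=n_perm, seed=seed + 1)
    return null


def simulate_dwell_table(
    options: EyetrackOptions, seed: int | None = None
) -> pd.DataFrame:
    """Simulate gaze for two viewer groups and run the full dwell pipeline."""
    base = options.seed if seed is None else seed
    scenario = synthdata.GazeScenario(
        clip_duration=options.clip_duration, sample_rate=options.sample_rate,
        seed=base,
    )
    rois = scenario.roi_tracks
    rows = []
    counter = 0
    seed_rng = np.random.default_rng(base)  # independent stream per record
    for sex, n_subj in ((MALE, options.n_male), (FEMALE, options.n_female)):
        for k in range(n_subj):
            counter += 1
            sid = f"et-{counter:03d}"
            for c in range(options.n_clips):
                record, _ = synthdata.generate_gaze(
                    scenario, sex, subject_id=sid, clip_id=f"clip-{c + 1:02d}",
                    seed=int(seed_rng.integers(2**31 - 1)),
                )
                table, _, _ = analyze_gaze(
                    record, rois,
                    vel_threshold=options.vel_threshold,
                    acc_threshold=options.acc_threshold,
                    min_fixation_ms=options.min_fixation_ms,
                    clip_duration_s=options.clip_duration,
                    denominator=options.denominator,
                )
                table["subject_sex"] = sex
                rows.append(table)
    return pd.concat(rows, ignore_index=True)


def demo_end_to_end(
    seed: int = 0,
    out_dir: str | Path | None = None,
    n_male: int = 20,
    n_female: int = 20,
    n_perm: int = 199,
    group_n_perm: int = 200,
    eyetrack_scale: float = 1.0,
) -> dict:
    """Full synthetic replication of the analysis flow at desk scale.

    Simulates a cohort with shared sexual-effect topography across two
    experiments and a disjoint control topography, then runs group contrasts
    with cluster-FWE, all decoding settings with permutation nulls, the
    weight–contrast correlation, and the eye-tracking dwell analysis.
    """
    t_start = time.time()
    sim = SimulateOptions(n_male=n_male, n_female=n_female, seed=seed)
    study = simulate_study(sim)
    report: dict = {"seed": seed, "n_male": n_male, "n_female": n_female}

    males = [m for m, s in zip(study.movie_maps, study.labels) if s == MALE]
    females = [m for m, s in zip(study.movie_maps, study.labels) if s == FEMALE]
    clusters = groupstats.cluster_fwe(
        males, females, study.mask.mask, n_perm=max(group_n_perm, 100), seed=seed + 7
    )
    report["group_clusters"] = {
        "n_clusters": int(len(clusters)),
        "n_significant": int((clusters["p_fwe"] < 0.05).sum()),
        "largest_size": int(clusters["size"].max()) if len(clusters) else 0,
    }

    report.update(decode_study(study, MvpaOptions(seed=seed + 5), n_perm=n_perm))

    et = EyetrackOptions(
        seed=seed + 9,
        n_male=max(2, int(15 * eyetrack_scale)),
        n_female=max(2, int(15 * eyetrack_scale)),
    )
    dwell = simulate_dwell_table(et)
    chest = dwell[(dwell["roi"] == "chest") & (dwell["actor_sex"] == FEMALE)]
    chest_by_sex = chest.groupby("subject_sex")["dwell_pct"].mean()
    _, terms = dwell_group_model(dwell)
    report["eyetracking"] = {
        "chest_dwell_male_pct": float(chest_by_sex.get(MALE, np.nan)),
        "chest_dwell_female_pct": float(chest_by_sex.get(FEMALE, np.nan)),
        "lmm_terms": terms.to_dict(orient="records"),
    }
    report["wall_clock_s"] = time.time() - t_start
    if out_dir is not None:
        io.write_json(Path(out_dir) / "demo_report.json", report)
    return report


# --------------------------------------------------------------------------
# file-based stages

STAGES = ("simulate", "glm", "group", "mvpa", "eyetrack", "demo", "report")

_DEPENDENCIES = {
    "simulate": (),
    "glm": ("simulate",),
    "group": ("glm",),
    "mvpa": ("glm",),
    "eyetrack": ("simulate",),
    "demo": (),
    "report": (),
}


def _stage_dir(config: PipelineConfig, stage: str) -> Path:
    return Path(config.out_root) / stage


def _write_manifest(config: PipelineConfig, stage: str, outputs: list[Path],
                    seed: int) -> Path:
    from . import __version__

    manifest = {
        "stage": stage,
        "seed": seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "version": __version__,
        "outputs": {
            str(p.relative_to(config.out_root)): io.file_sha256(p) for p in outputs
        },
    }
    return io.write_json(_stage_dir(config, stage) / "manifest.json", manifest)


def _check_dependencies(config: PipelineConfig, stage: str) -> None:
    for dep in _DEPENDENCIES[stage]:
        if not (_stage_dir(config, dep) / "manifest.json").exists():
            raise FileNotFoundError(
                f"stage {stage!r} requires stage {dep!r} to have run first "
                f"(missing {_stage_dir(config, dep) / 'manifest.json'})"
            )


def _stage_simulate(config: PipelineConfig) -> list[Path]:
    out = _stage_dir(config, "simulate")
    sim = config.simulate
    study = simulate_study(sim, glm_options=config.glm,
                           mask_threshold=config.mvpa.mask_threshold)
    outputs = []
    for exp in ("movie", "picture"):
        design = study.movie_design if exp == "movie" else study.picture_design
        outputs.append(io.write_tsv(out / f"design_{exp}.tsv", design.to_frame()))
        for sub in study.cohorts[exp]:
            outputs.append(
                io.save_bold(
                    out / exp / f"{sub.subject_id}_bold.nii.gz",
                    sub.data, sub.tr_seconds,
                    sidecar={
                        "subject_id": sub.subject_id,
                        "sex": sub.sex,
                        "task_columns": list(design.task_columns),
                    },
                )
            )
    prob = synthdata.generate_tissue_probability(tuple(sim.grid_shape))
    outputs.append(io.save_volume(out / "gray_matter_probability.nii.gz", prob))
    subjects = pd.DataFrame(
        {"subject_id": study.subject_ids, "sex": study.labels}
    )
    outputs.append(io.write_tsv(out / "subjects.tsv", subjects))
    # gaze arm
    scenario = synthdata.GazeScenario(
        clip_duration=config.eyetrack.clip_duration, seed=config.eyetrack.seed
    )
    outputs.append(io.save_roi_tracks(out / "roi_tracks.json",
                                      list(scenario.roi_tracks)))
    gaze_rows = []
    counter = 0
    seed_rng = np.random.default_rng(config.eyetrack.seed)
    for sex, n_subj in ((MALE, config.eyetrack.n_male),
                        (FEMALE, config.eyetrack.n_female)):
        for _ in range(n_subj):
            counter += 1
            sid = f"et-{counter:03d}"
            gaze_rows.append({"subject_id": sid, "sex": sex})
            for c in range(config.eyetrack.n_clips):
                record, _ = synthdata.generate_gaze(
                    scenario, sex, subject_id=sid, clip_id=f"clip-{c + 1:02d}",
                    seed=int(seed_rng.integers(2**31 - 1)),
                )
                outputs.append(
                    io.save_gaze_csv(out / "gaze" / f"{sid}_clip-{c + 1:02d}.csv",
                                     record)
                )
    outputs.append(io.write_tsv(out / "gaze_subjects.tsv", pd.DataFrame(gaze_rows)))
    return outputs


def _stage_glm(config: PipelineConfig) -> list[Path]:
    sim_dir = _stage_dir(config, "simulate")
    out = _stage_dir(config, "glm")
    subjects = io.read_tsv(sim_dir / "subjects.tsv")
    outputs = []
    for exp in ("movie", "picture"):
        design_frame = io.read_tsv(sim_dir / f"design_{exp}.tsv")
        # task columns recorded in any subject sidecar
        sample_meta = io.read_json(
            sim_dir / exp / f"{subjects['subject_id'].iloc[0]}_bold.json"
        )
        task_cols = tuple(sample_meta["task_columns"])
        design = glm.DesignMatrix(
            matrix=design_frame.to_numpy(),
            columns=tuple(design_frame.columns),
            task_columns=task_cols,
            tr_seconds=config.simulate.tr_seconds,
        )
        for sid in subjects["subject_id"]:
            data, tr, affine, meta = io.load_bold(sim_dir / exp / f"{sid}_bold.nii.gz")
            bold = BoldSeries(data=data, tr_seconds=tr, subject_id=sid,
                              sex=meta.get("sex", ""), affine=affine)
            betas = glm.fit_glm(bold, design)
            if exp == "movie":
                for col in ("sexual", "control"):
                    outputs.append(
                        io.save_volume(
                            out / exp / f"{sid}_beta_{col}.nii.gz",
                            betas.volume(col), affine,
                            sidecar={"subject_id": sid, "column": col},
                        )
                    )
            else:
                weights = [
                    {"sexual": 1.0, "landscape": -1.0}.get(c, 0.0)
                    for c in design.task_columns
                ]
                cmap = glm.contrast(betas, weights)
                outputs.append(
                    io.save_volume(
                        out / exp / f"{sid}_contrast_sexual-landscape.nii.gz",
                        cmap.data, affine,
                        sidecar={"subject_id": sid, "weights": list(weights),
                                 "task_columns": list(design.task_columns)},
                    )
                )
    return outputs


def _load_maps(config: PipelineConfig) -> tuple[dict, list[str], list[str]]:
    sim_dir = _stage_dir(config, "simulate")
    glm_dir = _stage_dir(config, "glm")
    subjects = io.read_tsv(sim_dir / "subjects.tsv")
    ids = list(subjects["subject_id"])
    labels = list(subjects["sex"])
    maps = {"movie": [], "control": [], "picture": []}
    for sid in ids:
        maps["movie"].append(
            io.load_volume(glm_dir / "movie" / f"{sid}_beta_sexual.nii.gz")[0]
        )
        maps["control"].append(
            io.load_volume(glm_dir / "movie" / f"{sid}_beta_control.nii.gz")[0]
        )
        maps["picture"].append(
            io.load_volume(
                glm_dir / "picture" / f"{sid}_contrast_sexual-landscape.nii.gz"
            )[0]
        )
    return maps, labels, ids


def _stage_group(config: PipelineConfig) -> list[Path]:
    out = _stage_dir(config, "group")
    sim_dir = _stage_dir(config, "simulate")
    maps, labels, _ = _load_maps(config)
    prob, _ = io.load_volume(sim_dir / "gray_matter_probability.nii.gz")
    mask = mvpa.mask_from_probability(prob, config.mvpa.mask_threshold)
    outputs = []
    for exp in ("movie", "picture"):
        males = [m for m, s in zip(maps[exp], labels) if s == MALE]
        females = [m for m, s in zip(maps[exp], labels) if s == FEMALE]
        tmap = groupstats.two_sample_tmap(males, females, mask.mask)
        outputs.append(io.save_volume(out / f"tmap_{exp}.nii.gz", tmap.t))
        table = groupstats.cluster_fwe(
            males, females, mask.mask,
            forming_threshold_p=config.group.forming_threshold_p,
            two_sided=config.group.two_sided,
            n_perm=config.group.n_perm,
            seed=config.group.seed,
        )
        outputs.append(io.write_tsv(out / f"clusters_{exp}.tsv", table))
    return outputs


def _stage_mvpa(config: PipelineConfig) -> list[Path]:
    out = _stage_dir(config, "mvpa")
    sim_dir = _stage_dir(config, "simulate")
    maps, labels, ids = _load_maps(config)
    prob, _ = io.load_volume(sim_dir / "gray_matter_probability.nii.gz")
    mask = mvpa.mask_from_probability(prob, config.mvpa.mask_threshold)
    study = StudyData(
        movie_maps=maps["movie"], picture_maps=maps["picture"],
        control_maps=maps["control"], labels=labels, subject_ids=ids,
        mask=mask, movie_design=None, picture_design=None, cohorts={},
    )
    report = decode_study(study, config.mvpa)
    return [io.write_json(out / "mvpa_report.json", report)]


def _stage_eyetrack(config: PipelineConfig) -> list[Path]:
    out = _stage_dir(config, "eyetrack")
    sim_dir = _stage_dir(config, "simulate")
    rois = io.load_roi_tracks(sim_dir / "roi_tracks.json")
    gaze_subjects = io.read_tsv(sim_dir / "gaze_subjects.tsv")
    et = config.eyetrack
    tables = []
    for _, row in gaze_subjects.iterrows():
        for c in range(et.n_clips):
            clip = f"clip-{c + 1:02d}"
            record = io.load_gaze_csv(
                sim_dir / "gaze" / f"{row.subject_id}_{clip}.csv",
                subject_id=row.subject_id, clip_id=clip,
            )
            table, _, _ = analyze_gaze(
                record, rois,
                vel_threshold=et.vel_threshold,
                acc_threshold=et.acc_threshold,
                min_fixation_ms=et.min_fixation_ms,
                clip_duration_s=et.clip_duration,
                denominator=et.denominator,
            )
            table["subject_sex"] = row.sex
            tables.append(table)
    dwell = pd.concat(tables, ignore_index=True)
    outputs = [io.write_tsv(out / "dwell.tsv", dwell)]
    _, terms = dwell_group_model(dwell)
    outputs.append(io.write_json(out / "lmm_terms.json",
                                 {"terms": terms.to_dict(orient="records")}))
    return outputs


def _stage_demo(config: PipelineConfig) -> list[Path]:
    out = _stage_dir(config, "demo")
    demo_end_to_end(seed=config.simulate.seed, out_dir=out)
    return [out / "demo_report.json"]


def _stage_report(config: PipelineConfig) -> list[Path]:
    out = _stage_dir(config, "report")
    combined: dict = {}
    for stage in ("group", "mvpa", "eyetrack", "demo"):
        mpath = _stage_dir(config, stage) / "manifest.json"
        if not mpath.exists():
            continue
        for rel in io.read_json(mpath)["outputs"]:
            if rel.endswith(".json") and "manifest" not in rel:
                combined[rel] = io.read_json(Path(config.out_root) / rel)
    return [io.write_json(out / "combined_report.json", combined)]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "glm": _stage_glm,
    "group": _stage_group,
    "mvpa": _stage_mvpa,
    "eyetrack": _stage_eyetrack,
    "demo": _stage_demo,
    "report": _stage_report,
}


def run_stage(stage: str, config: PipelineConfig) -> Path:
    """Run one named stage; returns the path of its manifest.

    Declared dependencies must have produced their manifests already
    (simulate -> glm -> {group, mvpa}; simulate -> eyetrack).  Outputs are
    recorded with content hashes so deterministic reruns can be verified.
    """
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    _check_dependencies(config, stage)
    outputs = _STAGE_FUNCS[stage](config)
    seed = {
        "simulate": config.simulate.seed,
        "glm": config.simulate.seed,
        "group": config.group.seed,
        "mvpa": config.mvpa.seed,
        "eyetrack": config.eyetrack.seed,
        "demo": config.simulate.seed,
        "report": 0,
    }[stage]
    return _write_manifest(config, stage, [Path(p) for p in outputs], seed)
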