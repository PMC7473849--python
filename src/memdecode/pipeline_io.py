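"""Configuration, file I/O and end-to-end orchestration.

Volumes travel as 4D NIfTI (x, y, z, frame-or-trial) with the grid's
isotropic voxel size in the affine; schedules as BIDS-style tab-separated
events files; configs and manifests as YAML/JSON. ``run_pipeline`` chains
the stages — simulate cohort → single-trial GLM + residualization →
between-subject searchlight for the four label sets (choice, response,
image type, target side) → ROI extraction → regional evidence analysis →
temporal decoding and generalization — with explicit per-stage seeds and a
manifest of content hashes, so a config reruns to identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import decode_core, glm, regional_stats, searchlight, study_design, synthetic_bold, temporal
from .decode_core import CvScheme
from .glm import BetaSeries, Hrf
from .study_design import SubjectDesign, TrialSchedule, TrialTiming
from .synthetic_bold import NoiseModel, SubjectDataset, VolumeGrid

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "PipelineResult",
    "write_events", "read_events",
    "write_volume", "read_volume",
    "write_subject_dataset", "read_subject_dataset",
    "write_beta_series", "read_beta_series",
]

EVENTS_COLUMNS = [
    "onset", "duration", "run", "stimulus_type", "memory_status", "evidence",
    "image_type", "target_side", "choice", "response", "correct",
]

LABEL_SETS = {
    "choice": ("choice", ("old", "new")),
    "response": ("response", ("eye", "hand")),
    "image_type": ("image_type", ("indoor", "outdoor")),
    "target_side": ("target_side", ("left", "right")),
    "status": ("memory_status", ("old", "new")),
}


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def write_events(schedule: TrialSchedule, path: str | Path) -> Path:
    path = Path(path)
    cols = [c for c in EVENTS_COLUMNS if c in schedule.frame.columns]
    schedule.frame[cols].to_csv(path, sep="\t", index=False)
    return path


def read_events(path: str | Path, tr_s: float = 1.914, session: str = "retrieval") -> TrialSchedule:
    frame = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "run"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"events file {path} is missing columns: {sorted(missing)}")
    if "correct" in frame.columns:
        frame["correct"] = frame["correct"].astype(bool)
    return TrialSchedule(frame, session=session, tr_s=tr_s, timing=TrialTiming(tr_s=tr_s))


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm] * 3 + [1.0])


def write_volume(data_2d: np.ndarray, grid: VolumeGrid, path: str | Path) -> Path:
    """Write frames/trials x in-mask voxels as a 4D NIfTI on the grid."""
    vol = np.zeros(tuple(grid.dims) + (data_2d.shape[0],), dtype=np.float32)
    for i in range(data_2d.shape[0]):
        vol[..., i][grid.mask] = data_2d[i]
    img = nib.Nifti1Image(vol, _affine(grid.voxel_size_mm))
    nib.save(img, str(path))
    return Path(path)


def read_volume(path: str | Path, grid: VolumeGrid) -> np.ndarray:
    vol = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    if vol.ndim == 3:
        vol = vol[..., None]
    if vol.shape[:3] != tuple(grid.dims):
        raise ValueError(f"volume {path} does not match grid dims {grid.dims}")
    return np.stack([vol[..., i][grid.mask] for i in range(vol.shape[3])])


def write_mask(grid: VolumeGrid, path: str | Path) -> Path:
    img = nib.Nifti1Image(grid.mask.astype(np.uint8), _affine(grid.voxel_size_mm))
    nib.save(img, str(path))
    return Path(path)


def read_mask(path: str | Path, voxel_size_mm: float | None = None) -> VolumeGrid:
    img = nib.load(str(path))
    mask = np.asarray(img.dataobj) > 0.5
    vs = voxel_size_mm or float(abs(img.affine[0, 0]))
    return VolumeGrid(mask.shape, vs, mask)


def write_subject_dataset(ds: SubjectDataset, out_dir: str | Path) -> Path:
    """One 4D NIfTI per run + events TSV + JSON sidecar under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_mask(ds.grid, out / "mask.nii")
    for r, run in zip(ds.schedule.runs, ds.runs):
        write_volume(run, ds.grid, out / f"run-{r:02d}_bold.nii")
    write_events(ds.schedule, out / "events.tsv")
    sidecar = dict(
        subject_id=ds.design.subject_id,
        group=ds.design.group,
        mapping=ds.design.mapping,
        tr_s=ds.tr_s,
        runs=list(ds.schedule.runs),
        voxel_size_mm=ds.grid.voxel_size_mm,
    )
    (out / "subject.json").write_text(json.dumps(sidecar, indent=1))
    return out


def read_subject_dataset(path: str | Path) -> SubjectDataset:
    path = Path(path)
    sidecar = json.loads((path / "subject.json").read_text())
    grid = read_mask(path / "mask.nii", sidecar.get("voxel_size_mm"))
    schedule = read_events(path / "events.tsv", tr_s=sidecar["tr_s"])
    runs = [
        read_volume(path / f"run-{r:02d}_bold.nii", grid) for r in sidecar["runs"]
    ]
    design = SubjectDesign(sidecar["subject_id"], sidecar["group"], dict(sidecar["mapping"]))
    return SubjectDataset(design, grid, runs, sidecar["tr_s"], schedule)


def write_beta_series(bs: BetaSeries, grid: VolumeGrid, stem: str | Path) -> Path:
    stem = Path(stem)
    write_volume(bs.data, grid, stem.with_suffix(".nii"))
    bs.meta.to_csv(stem.with_suffix(".tsv"), sep="\t", index=False)
    return stem


def read_beta_series(stem: str | Path, grid: VolumeGrid) -> BetaSeries:
    stem = Path(stem)
    data = read_volume(stem.with_suffix(".nii"), grid)
    meta = pd.read_csv(stem.with_suffix(".tsv"), sep="\t")
    if "correct" in meta.columns:
        meta["correct"] = meta["correct"].astype(bool)
    return BetaSeries(data, meta)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything a full pipeline run depends on, with explicit seeds.

    The reference study design is 24 subjects, 12 runs of 30 trials on a
    whole-brain grid; the defaults here are a desk-scale cohort that keeps
    the same factor structure (see the runtime notes in the docs).
    """

    n_subjects: int = 12
    n_categories: int = 60
    n_runs: int | None = 4  # None = all runs implied by n_categories
    grid_dims: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: float = 3.0
    tr_s: float = 1.914
    pattern_amplitude: float = 3.0
    site_radius: int = 2
    noise_white_sd: float = 1.0
    noise_ar1: float = 0.3
    noise_drift_sd: float = 0.5
    p_correct: dict = field(default_factory=lambda: {
        s: {e: study_design.DEFAULT_P_CORRECT[(s, e)] for e in ("low", "middle", "high")}
        for s in ("old", "new")
    })
    radius: int = 3
    subsample_fraction: float = 0.5
    alpha: float = 0.01
    min_cluster: int = 10
    k_select: int = 50
    C: float = 1.0
    k_folds_within: int = 7
    n_epoch_frames: int = 7
    label_sets: tuple[str, ...] = ("choice", "response", "image_type", "target_side")
    seed: int = 0
    out_dir: str | None = None

    def stage_seed(self, stage: str, extra: int = 0) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}:{extra}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2**31)

    def p_correct_table(self) -> dict:
        return {(s, e): float(p) for s, d in self.p_correct.items() for e, p in d.items()}

    def to_yaml(self, path: str | Path) -> Path:
        d = dataclasses.asdict(self)
        d["grid_dims"] = list(d["grid_dims"])
        d["label_sets"] = list(d["label_sets"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["grid_dims"] = tuple(d["grid_dims"])
        d["label_sets"] = tuple(d["label_sets"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    config: RunConfig
    designs: list
    grid: VolumeGrid
    specs: list
    schedules: dict
    beta_series: dict
    residuals: dict
    accuracy_maps: dict
    roi_sets: dict
    regional: dict
    temporal_between: dict
    temporal_within: dict
    generalization: dict
    manifest: dict


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


def simulate_cohort(config: RunConfig):
    """Stages 1-2: designs, schedules with observer choices, BOLD, GLM products."""
    designs = study_design.assign_groups(config.n_subjects, config.stage_seed("groups"))
    grid = VolumeGrid.ellipsoid(config.grid_dims, config.voxel_size_mm)
    specs = synthetic_bold.default_pattern_suite(
        grid, config.stage_seed("patterns"), config.pattern_amplitude, config.site_radius
    )
    noise = NoiseModel(config.noise_white_sd, config.noise_ar1, drift_sd=config.noise_drift_sd)
    timing = TrialTiming(tr_s=config.tr_s)
    hrf = Hrf()
    p_correct = config.p_correct_table()

    schedules, betas, residuals = {}, {}, {}
    for d in designs:
        sched = study_design.build_retrieval_schedule(
            config.n_categories, config.stage_seed("schedule", d.subject_id), timing
        )
        if config.n_runs is not None:
            keep = sched.frame["run"] < config.n_runs
            sched = TrialSchedule(
                sched.frame[keep].reset_index(drop=True), sched.session, sched.tr_s, sched.timing
            )
        sched = study_design.simulate_observer(
            sched, d, p_correct, config.stage_seed("observer", d.subject_id)
        )
        ds = synthetic_bold.simulate_subject(
            d, sched, specs, noise, hrf, grid, config.stage_seed("bold", d.subject_id)
        )
        data = ds.data
        betas[d.subject_id] = glm.single_trial_betas(data, sched, hrf, config.tr_s)
        design_mat = glm.build_condition_design(sched, hrf, config.tr_s)
        residuals[d.subject_id] = glm.residualize_execution(data, design_mat, config.tr_s)
        schedules[d.subject_id] = sched
        logger.info("subject %d simulated: %d trials, %d frames", d.subject_id, sched.n_trials, data.shape[0])
    return designs, grid, specs, schedules, betas, residuals


def _patterns_for(
    betas: dict, schedules: dict, label_set: str, subject_ids: list
) -> decode_core.LabeledPatterns:
    col, _ = LABEL_SETS[label_set]
    return searchlight.prepare_patterns(
        [betas[s].data for s in subject_ids],
        [schedules[s].frame[col].to_numpy() for s in subject_ids],
        subject_ids,
        [schedules[s].frame for s in subject_ids],
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis chain on a simulated cohort."""
    designs, grid, specs, schedules, betas, residuals = simulate_cohort(config)
    subject_ids = [d.subject_id for d in designs]

    accuracy_maps, roi_sets = {}, {}
    for label_set in config.label_sets:
        patterns = _patterns_for(betas, schedules, label_set, subject_ids)
        amap = searchlight.run_searchlight(
            patterns, grid, config.radius, config.subsample_fraction,
            config.stage_seed("searchlight"), config.C,
        )
        amap.label_set = label_set
        _, p, _ = searchlight.group_test_vs_chance(amap)
        mask = searchlight.fdr_mask(p, config.alpha)
        roi_sets[label_set] = searchlight.cluster_rois(
            mask, grid, config.min_cluster, value_map=amap.mean_map
        )
        accuracy_maps[label_set] = amap
        logger.info("searchlight[%s]: %d ROI(s)", label_set, len(roi_sets[label_set]))

    # Regional evidence analysis on the choice ROIs (plus status control rows).
    regional = {}
    choice_rois = roi_sets.get("choice")
    if choice_rois and len(choice_rois):
        n_rois = len(choice_rois)
        choice_patterns = _patterns_for(betas, schedules, "choice", subject_ids)
        status_patterns = _patterns_for(betas, schedules, "status", subject_ids)
        for roi in choice_rois:
            name = f"choice_roi{roi.label}"
            rows_choice = regional_stats.regional_decode(
                choice_patterns, roi.voxel_ids, name, "choice",
                k_select=config.k_select, C=config.C,
            )
            rows_status = regional_stats.regional_decode(
                status_patterns, roi.voxel_ids, name, "status",
                k_select=config.k_select, C=config.C,
            )
            slope = regional_stats.evidence_slope_test(rows_choice)
            low = regional_stats.low_evidence_tests(rows_choice, rows_status)
            regional[name] = dict(
                rows=pd.concat([rows_choice, rows_status], ignore_index=True),
                slope=slope,
                slope_p_bonferroni=regional_stats.bonferroni(slope.p, n_rois),
                low_evidence=low,
            )

    # Temporal decoding and generalization per discovered ROI.
    temporal_between, temporal_within, generalization = {}, {}, {}
    for label_set in ("choice", "response"):
        rois = roi_sets.get(label_set)
        if not rois or not len(rois):
            continue
        n_rois = len(rois)
        col, _ = LABEL_SETS[label_set]
        for roi in rois:
            name = f"{label_set}_roi{roi.label}"
            eps, labels_all, sids = [], [], []
            for sid in subject_ids:
                ep = temporal.extract_epochs(
                    residuals[sid], schedules[sid], roi.voxel_ids, config.n_epoch_frames
                )
                eps.append(ep)
                labels_all.append(ep.meta[col].to_numpy())
                sids.append(np.full(len(ep.meta), sid, dtype=object))
            stacked = temporal.EpochTensor(
                np.concatenate([e.data for e in eps]),
                eps[0].frame_times_s,
                pd.concat([e.meta for e in eps], ignore_index=True),
            )
            labels = np.concatenate(labels_all)
            sid_arr = np.concatenate(sids)
            temporal_between[name] = temporal.temporal_decode(
                stacked, labels, sid_arr,
                CvScheme("leave_one_subject_out"), config.k_select, config.C, n_rois,
            )
            # within-subject: average subject-wise time courses / matrices
            within_acc, gen_mats = [], []
            for i, sid in enumerate(subject_ids):
                res = temporal.temporal_generalization(
                    eps[i], labels_all[i], sids[i],
                    CvScheme("k_fold_within", k=config.k_folds_within),
                    config.k_select, config.C, n_rois,
                )
                gen_mats.append(res.matrix)
                within_acc.append(res.matrix.diagonal())
            temporal_within[name] = np.array(within_acc)
            generalization[name] = np.array(gen_mats)

    manifest = dict(
        seed=config.seed,
        stage_seeds={s: config.stage_seed(s) for s in ("groups", "patterns", "searchlight")},
        n_subjects=config.n_subjects,
        grid_dims=list(config.grid_dims),
        hashes={
            f"betas_sub{sid}": _hash_array(betas[sid].data) for sid in subject_ids
        },
        accuracy_map_hashes={k: _hash_array(v.values) for k, v in accuracy_maps.items()},
        rois={k: [int(r.size) for r in v] for k, v in roi_sets.items()},
    )

    result = PipelineResult(
        config, designs, grid, specs, schedules, betas, residuals,
        accuracy_maps, roi_sets, regional, temporal_between, temporal_within,
        generalization, manifest,
    )
    if config.out_dir:
        _write_outputs(result)
    return result


def _write_outputs(result: PipelineResult) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out / "config.yaml")
    write_mask(result.grid, out / "mask.nii")
    for sid, sched in result.schedules.items():
        write_events(sched, out / f"sub-{sid:02d}_events.tsv")
        write_beta_series(result.beta_series[sid], result.grid, out / f"sub-{sid:02d}_betas")
    for label_set, amap in result.accuracy_maps.items():
        write_volume(amap.values, result.grid, out / f"accuracy_{label_set}.nii")
        result.roi_sets[label_set].table().to_csv(
            out / f"rois_{label_set}.tsv", sep="\t", index=False
        )
        labels = np.zeros(result.grid.n_voxels)
        for roi in result.roi_sets[label_set]:
            labels[roi.voxel_ids] = roi.label
        write_volume(labels[None, :], result.grid, out / f"roilabels_{label_set}.nii")
    regional_report = {}
    for name, reg in result.regional.items():
        reg["rows"].to_csv(out / f"regional_{name}.tsv", sep="\t", index=False)
        regional_report[name] = dict(
            slope=reg["slope"].slope, stat=reg["slope"].stat, p=reg["slope"].p,
            method=reg["slope"].method, p_bonferroni=reg["slope_p_bonferroni"],
            low_evidence=reg["low_evidence"],
            mean_accuracy_by_evidence=reg["rows"][reg["rows"]["label_set"] != "status"]
            .groupby("evidence")["accuracy"].mean().to_dict(),
        )
    if regional_report:
        (out / "regional_stats.json").write_text(json.dumps(regional_report, indent=1))
    for name, tc in result.temporal_between.items():
        pd.DataFrame(
            dict(frame=np.arange(len(tc.mean)), time_s=tc.frame_times_s,
                 accuracy=tc.mean, p_corrected=tc.p_corrected)
        ).to_csv(out / f"temporal_between_{name}.tsv", sep="\t", index=False)
    for name, acc in result.temporal_within.items():
        pd.DataFrame(
            dict(frame=np.arange(acc.shape[1]), accuracy=acc.mean(axis=0))
        ).to_csv(out / f"temporal_within_{name}.tsv", sep="\t", index=False)
    for name, mats in result.generalization.items():
        np.savetxt(out / f"generalization_{name}.tsv", mats.mean(axis=0),
                   delimiter="\t", fmt="%.4f")
    ground_truth = dict(
        patterns=[
            dict(
                name=s.name, driver=s.driver, amplitude=s.amplitude,
                onset_lag_s=s.onset_lag_s, duration_s=s.duration_s,
                evidence_gain=s.evidence_gain, group_sign=s.group_sign,
                voxel_ids=[int(v) for v in s.voxel_ids],
            )
            for s in result.specs
        ],
    )
    (out / "ground_truth.json").write_text(json.dumps(ground_truth, indent=1))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
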