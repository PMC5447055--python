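"""The 13-step parcellation workflow: configuration, directory layout,
logging, step selection, resumability, and deterministic parallelism.

Steps (numbering fixed by the workflow):

====  ==========================================================
step  action
====  ==========================================================
0     initialize the workspace directory tree
1     image registration              (external stage, ingested)
2     extract seed-voxel coordinates from the mask
3     probabilistic tractography      (external stage, ingested)
4     native + cross-correlation matrices per subject
5     spectral clustering over the k range per subject
6     inverse warping to native space (external stage, ingested)
7     group-level labeling scheme per k
8     propagate the scheme back to each subject (relabeling)
9     probabilistic maps + maximum probability map per k
10    6-neighbor majority noise correction of the MPM
11    validity indices over the k range
12    optimal-k report (votes and suggestion)
====  ==========================================================

Steps 1, 3 and 6 are ingestion points: the pipeline consumes count
profiles already resampled to one common voxel grid (the mask's grid),
as written by :meth:`cbparc.synthetic.PhantomCohort.write` or by any
external tractography tool following the same layout.

Per-subject and per-k work units are independent; results are merged in
a fixed order and label images are written uncompressed, so outputs are
byte-identical for any worker count under a fixed master seed.
"""

from __future__ import annotations

import socket
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from . import connectivity as conn
from . import group as grp
from . import io as cio
from . import maps as cmaps
from . import validity as val
from .parcellate import Parcellation, cluster_solutions

__all__ = ["PipelineConfig", "PipelineError", "RunLog", "Workspace",
           "init_workspace", "run_pipeline", "status"]

EXTERNAL_STEPS = {1, 3, 6}
ALL_STEPS = tuple(range(13))


class PipelineError(RuntimeError):
    """A step could not run; the message names the earliest unmet step."""


@dataclass
class PipelineConfig:
    """Run configuration; numeric defaults are the workflow's standards
    (5,000 samples, 0.04% threshold, 5 mm blocks, k 2-12, 100 split-half
    repetitions)."""

    data_dir: str
    working_dir: str
    roi_name: str = "roi"
    subjects: list[str] | None = None  # None -> discover sub-* dirs
    k_min: int = 2
    k_max: int = 12
    threshold_p: float = conn.DEFAULT_P_MIN
    n_samples: int = conn.DEFAULT_N_SAMPLES
    block_mm: float = conn.DEFAULT_BLOCK_MM
    group_threshold: float = grp.DEFAULT_GROUP_THRESHOLD
    n_reps: int = 100
    connectivity: int = 26
    master_seed: int = 0
    steps: list[int] | None = None  # None -> all 13
    n_workers: int = 1
    n_restarts: int = 100
    vi_sd_factor: float = 1.0
    schemes: tuple[str, ...] = ("split_half", "pairwise", "leave_one_out")
    plots: bool = False

    def __post_init__(self) -> None:
        if self.k_min < 2 or self.k_min > self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")
        if self.steps is not None:
            bad = set(self.steps) - set(ALL_STEPS)
            if bad:
                raise ValueError(f"unknown steps: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def subject_ids(self) -> list[str]:
        if self.subjects is not None:
            return list(self.subjects)
        found = sorted(
            p.name for p in Path(self.data_dir).iterdir()
            if p.is_dir() and (p / f"{self.roi_name}_profile.txt").exists()
        )
        if not found:
            raise PipelineError(
                f"no subject directories with {self.roi_name}_profile.txt "
                f"under {self.data_dir}"
            )
        return found

    def ks(self) -> list[int]:
        return list(range(self.k_min, self.k_max + 1))


@dataclass
class RunLog:
    """One record per executed step (start time, elapsed, host, status)."""

    records: list[dict] = field(default_factory=list)

    def add(self, step: int, status: str, message: str = "",
            start: float | None = None) -> None:
        now = time.time()
        self.records.append(
            dict(step=step,
                 start=time.strftime(
                     "%Y-%m-%dT%H:%M:%S",
                     time.localtime(start if start is not None else now)),
                 elapsed=round(now - (start if start is not None else now), 3),
                 host=socket.gethostname(), status=status, message=message)
        )

    def write(self, path: str | Path) -> None:
        with open(path, "a", encoding="utf-8") as fh:
            for r in self.records:
                fh.write(
                    f"step={r['step']}\tstart={r['start']}\t"
                    f"elapsed={r['elapsed']}s\thost={r['host']}\t"
                    f"status={r['status']}\t{r['message']}\n"
                )


class Workspace:
    """Directory and file-name conventions of one ROI's workspace."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.root = Path(config.working_dir) / config.roi_name
        self.roi_dir = self.root / "ROI"
        self.log_dir = self.root / "log"
        self.data_dir = Path(config.data_dir)
        self._roi = config.roi_name

    def subject_dir(self, subject: str) -> Path:
        return self.root / subject

    # -- ingested inputs
    def mask_path(self) -> Path:
        for ext in (".nii", ".nii.gz"):
            p = self.data_dir / f"{self._roi}_mask{ext}"
            if p.exists():
                return p
        return self.data_dir / f"{self._roi}_mask.nii"

    def profile_path(self, subject: str) -> Path:
        return self.data_dir / subject / f"{self._roi}_profile.txt"

    # -- step outputs
    def seeds_path(self) -> Path:
        return self.roi_dir / f"{self._roi}_seeds.txt"

    def native_path(self, subject: str) -> Path:
        return self.subject_dir(subject) / f"{self._roi}_native_matrix.txt"

    def corr_path(self, subject: str) -> Path:
        return self.subject_dir(subject) / f"{self._roi}_corr_matrix.txt"

    def parcellation_path(self, subject: str, k: int) -> Path:
        return self.subject_dir(subject) / f"{self._roi}_k{k}_parcellation.nii"

    def scheme_path(self, k: int) -> Path:
        return self.roi_dir / f"{self._roi}_k{k}_group_scheme.nii"

    def relabeled_path(self, subject: str, k: int) -> Path:
        return self.subject_dir(subject) / f"{self._roi}_k{k}_relabeled.nii"

    def permutation_path(self, subject: str, k: int) -> Path:
        return self.subject_dir(subject) / f"{self._roi}_k{k}_permutation.txt"

    def pm_path(self, k: int, label: int) -> Path:
        return self.roi_dir / f"{self._roi}_k{k}_c{label}_pm.nii"

    def mpm_path(self, k: int) -> Path:
        return self.roi_dir / f"{self._roi}_k{k}_mpm.nii"

    def mpm_corrected_path(self, k: int) -> Path:
        return self.roi_dir / f"{self._roi}_k{k}_mpm_corrected.nii"

    def tie_path(self, k: int) -> Path:
        return self.roi_dir / f"{self._roi}_k{k}_mpm_ties.txt"

    def validity_path(self) -> Path:
        return self.roi_dir / f"{self._roi}_validity.tsv"

    def report_path(self) -> Path:
        return self.roi_dir / f"{self._roi}_report.txt"

    def log_path(self) -> Path:
        return self.log_dir / f"{self._roi}.log"


def init_workspace(config: PipelineConfig) -> Workspace:
    """Create ROI/, log/ and per-subject subdirectories (idempotent)."""
    if not Path(config.data_dir).exists():
        raise PipelineError(f"data_dir {config.data_dir} does not exist")
    ws = Workspace(config)
    ws.roi_dir.mkdir(parents=True, exist_ok=True)
    ws.log_dir.mkdir(parents=True, exist_ok=True)
    for subject in config.subject_ids():
        ws.subject_dir(subject).mkdir(parents=True, exist_ok=True)
    return ws


# ---------------------------------------------------------------------------
# step validators (used for status reporting and resumability)


def _valid_matrix(path: Path) -> bool:
    try:
        cio.read_matrix(path)
        return True
    except (OSError, ValueError):
        return False


def _valid_label(path: Path) -> bool:
    try:
        cio.read_label_volume(path)
        return True
    except (OSError, ValueError):
        return False


def _step_complete(step: int, ws: Workspace) -> bool:
    cfg = ws.config
    subjects = cfg.subject_ids()
    ks = cfg.ks()
    if step == 0:
        return ws.roi_dir.is_dir() and ws.log_dir.is_dir() and all(
            ws.subject_dir(s).is_dir() for s in subjects
        )
    if step in EXTERNAL_STEPS:
        if step == 3:
            return all(ws.profile_path(s).exists() for s in subjects)
        return True  # registration/warping assumed done upstream
    if step == 2:
        return ws.seeds_path().exists()
    if step == 4:
        return all(
            _valid_matrix(ws.native_path(s)) and _valid_matrix(ws.corr_path(s))
            for s in subjects
        )
    if step == 5:
        return all(
            _valid_label(ws.parcellation_path(s, k))
            for s in subjects for k in ks
        )
    if step == 7:
        return all(_valid_label(ws.scheme_path(k)) for k in ks)
    if step == 8:
        return all(
            _valid_label(ws.relabeled_path(s, k))
            for s in subjects for k in ks
        )
    if step == 9:
        return all(_valid_label(ws.mpm_path(k)) for k in ks)
    if step == 10:
        return all(_valid_label(ws.mpm_corrected_path(k)) for k in ks)
    if step == 11:
        return ws.validity_path().exists()
    if step == 12:
        return ws.report_path().exists()
    return False


def status(config: PipelineConfig) -> dict[int, str]:
    """Per-step completion summary for an existing workspace."""
    ws = Workspace(config)
    if not ws.root.exists():
        raise PipelineError(f"no workspace at {ws.root}")
    out = {}
    for step in ALL_STEPS:
        if step in EXTERNAL_STEPS and step != 3:
            out[step] = "external"
        else:
            out[step] = "complete" if _step_complete(step, ws) else "pending"
    return out


# ---------------------------------------------------------------------------
# step implementations


def _load_seed_context(ws: Workspace):
    mask = cio.read_label_volume(ws.mask_path())
    seeds = cio.extract_seed_coordinates(mask)
    return mask, seeds


def _subject_matrices(profile_path, seeds_coords, shape, voxel_size, cfg_dict):
    counts = cio.read_matrix(profile_path)
    if counts.shape != (len(seeds_coords), int(np.prod(shape))):
        raise PipelineError(
            f"{profile_path}: expected {len(seeds_coords)}x"
            f"{int(np.prod(shape))} profile matrix, got {counts.shape}"
        )
    profiles = [
        conn.ConnectivityProfile(tuple(c), counts[i], tuple(shape),
                                 cfg_dict["n_samples"])
        for i, c in enumerate(seeds_coords)
    ]
    native = conn.build_native_matrix(
        profiles, p_min=cfg_dict["threshold_p"],
        block_mm=cfg_dict["block_mm"], voxel_size_mm=tuple(voxel_size),
    )
    return native, conn.cross_correlation(native)


def _subject_clustering(corr_path, k_min, k_max, seed, n_restarts):
    corr = cio.read_matrix(corr_path)
    return cluster_solutions(corr, k_min, k_max, seed=seed,
                             n_restarts=n_restarts)


def _require(step: int, ws: Workspace) -> None:
    if not _step_complete(step, ws):
        raise PipelineError(f"step {step} outputs missing or invalid; run it "
                            "first")


def run_pipeline(config: PipelineConfig) -> RunLog:
    """Execute the selected steps in order, logging each one.

    Steps whose outputs already validate are skipped (resumability); the
    external stages 1, 3 and 6 are logged as such.  A failing step halts
    its dependents.
    """
    log = RunLog()
    steps = sorted(set(config.steps if config.steps is not None else ALL_STEPS))
    ws = Workspace(config)
    try:
        for step in steps:
            start = time.time()
            if step in EXTERNAL_STEPS:
                log.add(step, "external",
                        "registration/tractography handled outside; "
                        "ingesting precomputed inputs", start)
                continue
            if step != 0 and _step_complete(step, ws):
                log.add(step, "skipped", "valid outputs present", start)
                continue
            _run_step(step, ws, config)
            log.add(step, "ok", "", start)
    except Exception as exc:
        log.add(step, "failed", str(exc), start)
        if ws.log_dir.is_dir():
            log.write(ws.log_path())
        raise
    if ws.log_dir.is_dir():
        log.write(ws.log_path())
    return log


def _run_step(step: int, ws: Workspace, cfg: PipelineConfig) -> None:
    subjects = cfg.subject_ids()
    ks = cfg.ks()

    if step == 0:
        init_workspace(cfg)
        return

    if step == 2:
        if not ws.mask_path().exists():
            raise PipelineError(f"seed mask {ws.mask_path()} missing (step 1)")
        mask, seeds = _load_seed_context(ws)
        cio.write_coordinates(seeds, ws.seeds_path())
        return

    if step == 4:
        _require(2, ws)
        mask, seeds = _load_seed_context(ws)
        for s in subjects:
            if not ws.profile_path(s).exists():
                raise PipelineError(
                    f"profile matrix for {s} missing (external step 3)"
                )
        cfg_dict = dict(n_samples=cfg.n_samples, threshold_p=cfg.threshold_p,
                        block_mm=cfg.block_mm)
        results = Parallel(n_jobs=cfg.n_workers)(
            delayed(_subject_matrices)(
                ws.profile_path(s), seeds.coordinates, mask.shape,
                mask.voxel_size_mm, cfg_dict,
            )
            for s in subjects
        )
        for s, (native, corr) in zip(subjects, results):
            cio.write_matrix(native, ws.native_path(s))
            cio.write_matrix(corr, ws.corr_path(s))
        return

    if step == 5:
        _require(4, ws)
        mask, seeds = _load_seed_context(ws)
        results = Parallel(n_jobs=cfg.n_workers)(
            delayed(_subject_clustering)(
                ws.corr_path(s), cfg.k_min, cfg.k_max, cfg.master_seed,
                cfg.n_restarts,
            )
            for s in subjects
        )
        for s, solutions in zip(subjects, results):
            for k, labels in solutions.items():
                parc = Parcellation(seeds, labels, k)
                cio.write_label_volume(parc.to_volume(),
                                       ws.parcellation_path(s, k))
        return

    if step == 7:
        _require(5, ws)
        mask, seeds = _load_seed_context(ws)
        for k in ks:
            parcs = [
                Parcellation.from_volume(
                    cio.read_label_volume(ws.parcellation_path(s, k)), seeds)
                for s in subjects
            ]
            sim = grp.coincidence_matrix(parcs, threshold=cfg.group_threshold)
            scheme = grp.group_scheme(sim, k, seed=cfg.master_seed,
                                      seed_set=seeds)
            cio.write_label_volume(scheme.to_volume(), ws.scheme_path(k))
        return

    if step == 8:
        _require(7, ws)
        mask, seeds = _load_seed_context(ws)
        for k in ks:
            scheme = Parcellation.from_volume(
                cio.read_label_volume(ws.scheme_path(k)), seeds)
            parcs = [
                Parcellation.from_volume(
                    cio.read_label_volume(ws.parcellation_path(s, k)), seeds)
                for s in subjects
            ]
            relabeled, perms = grp.relabel_subjects(scheme, parcs)
            for s, parc, perm in zip(subjects, relabeled, perms):
                cio.write_label_volume(parc.to_volume(),
                                       ws.relabeled_path(s, k))
                cio.write_matrix(perm[None, :].astype(float),
                                 ws.permutation_path(s, k))
        return

    if step == 9:
        _require(8, ws)
        mask, seeds = _load_seed_context(ws)
        for k in ks:
            parcs = [
                Parcellation.from_volume(
                    cio.read_label_volume(ws.relabeled_path(s, k)), seeds)
                for s in subjects
            ]
            pm = cmaps.probability_maps(parcs)
            for c in range(1, k + 1):
                cio.write_probability_volume(pm.probs[c - 1], pm.affine,
                                             ws.pm_path(k, c))
            mpm = cmaps.maximum_probability_map(pm)
            cio.write_label_volume(mpm.volume, ws.mpm_path(k))
            with open(ws.tie_path(k), "w", encoding="utf-8") as fh:
                for x, y, z in mpm.tie_broken:
                    fh.write(f"{x} {y} {z}\n")
        return

    if step == 10:
        _require(9, ws)
        for k in ks:
            mpm = cmaps.MaximumProbabilityMap(
                cio.read_label_volume(ws.mpm_path(k)))
            corrected = cmaps.remove_noise_voxels(mpm)
            cio.write_label_volume(corrected.volume, ws.mpm_corrected_path(k))
        return

    if step == 11:
        _require(8, ws)
        _require(4, ws)
        mask, seeds = _load_seed_context(ws)
        relabeled_by_k = {
            k: [
                Parcellation.from_volume(
                    cio.read_label_volume(ws.relabeled_path(s, k)), seeds)
                for s in subjects
            ]
            for k in ks
        }
        natives = [cio.read_matrix(ws.native_path(s)) for s in subjects]
        report = val.validity_report(
            relabeled_by_k, natives=natives, schemes=cfg.schemes,
            n_reps=cfg.n_reps, seed=cfg.master_seed + 11,
        )
        report.table.to_csv(ws.validity_path(), sep="\t", index=False,
                            float_format="%.10g")
        return

    if step == 12:
        _require(11, ws)
        table = val.ValidityReport(pd.read_csv(ws.validity_path(), sep="\t"))
        suggestion = val.suggest_k(table, vi_sd_factor=cfg.vi_sd_factor)
        with open(ws.report_path(), "w", encoding="utf-8") as fh:
            fh.write(f"suggested_k\t{suggestion.k}\n")
            for name, votes in sorted(suggestion.votes.items()):
                fh.write(f"votes_{name}\t{' '.join(map(str, votes))}\n")
        if cfg.plots:
            _write_plots(ws, table)
        return

    raise PipelineError(f"unknown step {step}")


def _write_plots(ws: Workspace, report: val.ValidityReport) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # plotting is optional
        return
    for name in report.table["index"].unique():
        ks, means = report.series(name)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(ks, means, marker="o")
        ax.set_xlabel("k")
        ax.set_ylabel(name)
        fig.tight_layout()
        fig.savefig(ws.roi_dir / f"{ws.config.roi_name}_{name}.png", dpi=100)
        plt.close(fig)
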