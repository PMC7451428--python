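"""End-to-end orchestration: simulate/load -> preprocess -> connectivity ->
group inference -> clinical associations, with on-disk dataset layout,
run-directory outputs, provenance and a plain-text report.

The in-memory entry point is :func:`analyze_cohort`; :func:`run_pipeline`
wraps it with I/O so a full run (including a simulated cohort) reproduces
bit-identically under a fixed configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .clinical import association_battery
from .cohort import Cohort, CohortConfig, SubjectData, SubjectRecord, generate_cohort
from .connectivity import (
    BRAIN_TO_SEED,
    SEED_TO_BRAIN,
    blockwise_task_pc,
    cpc_map,
    seed_pc_map,
)
from .design import TaskDesign
from .inference import (
    GroupDesign,
    activation_control,
    alphasim_extent_threshold,
    cluster_mean_cpc,
    cohens_d_from_t,
    estimate_smoothness,
    extract_clusters,
    one_sample_cluster_t,
    voxelwise_group_t,
)
from .preprocess import (
    SeedSpec,
    build_task_regressors,
    discard_initial_volumes,
    extract_seed_ts,
    nuisance_regress,
    scrub_interpolate,
    spatial_smooth,
    temporal_bandpass,
)
from .volumes import ConfoundSet, Volume4D

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "analyze_cohort", "run_pipeline",
           "load_dataset", "write_dataset", "report"]

_DIRECTIONS = (SEED_TO_BRAIN, BRAIN_TO_SEED)


@dataclass
class RunConfig:
    """Everything a run needs; defaults follow the emulated study protocol."""

    # input: either a dataset directory or a simulation request
    dataset_dir: str | None = None
    simulate: bool = True
    demo: bool = True  # desk-scale simulated cohort (12+12, 16x18x16)
    # seed region; None centre = the simulated cohort's seed-node position
    seed_center: tuple[float, float, float] | None = None
    seed_radius: float = 6.0
    # preprocessing
    n_discard: int = 5
    scrub_threshold: float = 0.5
    smooth_fwhm: float = 8.0
    band: tuple[float, float] = (0.01, 0.08)
    # connectivity (GCM)
    lag: int = 1
    condition: str = "2-back"
    zscore_blocks: bool = True
    # inference
    voxel_p: float = 0.01
    cluster_alpha: float = 0.05
    n_iter: int = 1000
    connectivity: int = 26
    # randomness
    rng_seed: int = 0

    def to_yaml(self) -> str:
        d = asdict(self)
        d["seed_center"] = list(self.seed_center) if self.seed_center else None
        d["band"] = list(self.band)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        if d.get("seed_center") is not None:
            d["seed_center"] = tuple(d["seed_center"])
        if d.get("band") is not None:
            d["band"] = tuple(d["band"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# per-subject connectivity


@dataclass
class SubjectMaps:
    record: SubjectRecord
    cpc: dict  # direction -> (V,) in-mask CPC values
    activation_beta: np.ndarray  # (V,) 2-back GLM beta map (in-mask)
    seed_activation: float


def _preprocess_subject(sub: SubjectData, cfg: RunConfig, design: TaskDesign,
                        seed: SeedSpec):
    rest, conf_rest = discard_initial_volumes(sub.rest, sub.confounds_rest, cfg.n_discard)
    rest = scrub_interpolate(rest, conf_rest.fd, cfg.scrub_threshold)
    rest = spatial_smooth(rest, cfg.smooth_fwhm)
    rest = temporal_bandpass(rest, *cfg.band)
    rest = nuisance_regress(rest, conf_rest.regressors())

    task = scrub_interpolate(sub.task, sub.confounds_task.fd, cfg.scrub_threshold)
    task = spatial_smooth(task, cfg.smooth_fwhm)
    task_cols, labels = build_task_regressors(design, task.tr, task.n_vols)
    # per-subject activation betas (2-back regressor) before the task signal
    # is regressed out — used by the activation-confound control
    beta_map, seed_beta = _activation_betas(task, task_cols, labels, sub.confounds_task, seed)
    task = nuisance_regress(task, np.hstack([sub.confounds_task.regressors(), task_cols]))
    return rest, task, beta_map, seed_beta


def _activation_betas(task: Volume4D, task_cols: np.ndarray, labels: list[str],
                      conf: ConfoundSet, seed: SeedSpec) -> tuple[np.ndarray, float]:
    X = np.column_stack([np.ones(task.n_vols), conf.regressors(), task_cols])
    Y = task.masked_series().T
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    j = 1 + conf.regressors().shape[1] + labels.index("2-back")
    beta_map = beta[j]
    from .preprocess import seed_voxel_indices

    idx = seed_voxel_indices(task, seed)
    flat_mask = task.mask[idx[:, 0], idx[:, 1], idx[:, 2]]
    grid_beta = task.map_like(beta_map)
    seed_beta = float(grid_beta[idx[:, 0], idx[:, 1], idx[:, 2]].mean())
    return beta_map, seed_beta


def subject_connectivity(sub: SubjectData, cfg: RunConfig, design: TaskDesign,
                         seed: SeedSpec) -> SubjectMaps:
    """Preprocess one subject and compute CPC maps in both directions."""
    rest, task, beta_map, seed_beta = _preprocess_subject(sub, cfg, design, seed)
    seed_rest = extract_seed_ts(rest, seed)
    seed_task = extract_seed_ts(task, seed)
    cpc = {}
    for direction in _DIRECTIONS:
        pc_rest = seed_pc_map(rest, seed_rest, direction, lag=cfg.lag)
        pc_task = blockwise_task_pc(
            task, seed_task, design, condition=cfg.condition, direction=direction,
            lag=cfg.lag, zscore_blocks=cfg.zscore_blocks,
        )
        cpc[direction] = cpc_map(pc_task, pc_rest).flat()
    return SubjectMaps(record=sub.record, cpc=cpc, activation_beta=beta_map,
                       seed_activation=seed_beta)


# ---------------------------------------------------------------------------
# group stage


@dataclass
class DirectionResult:
    direction: str
    t_map: np.ndarray  # 3-D grid
    df: int
    fwhm_mm: np.ndarray
    extent_threshold: int
    null_maxima: np.ndarray
    clusters: pd.DataFrame
    cluster_means: pd.DataFrame  # subjects x clusters
    one_sample: pd.DataFrame
    activation_adjusted: pd.DataFrame


@dataclass
class PipelineResult:
    config: RunConfig
    mask: np.ndarray
    affine: np.ndarray
    records: pd.DataFrame
    directions: dict
    associations: pd.DataFrame
    cpc_stacks: dict = field(default_factory=dict)


def analyze_cohort(
    subjects,
    design: TaskDesign,
    cfg: RunConfig,
    seed: SeedSpec,
) -> PipelineResult:
    """Run the full analysis over an iterable of SubjectData.

    Subjects are consumed one at a time so cohorts never need to be held in
    memory as volumes; only the per-subject CPC vectors are kept.
    """
    maps: list[SubjectMaps] = []
    mask = affine = None
    for sub in subjects:
        if mask is None:
            mask = sub.rest.mask.copy()
            affine = sub.rest.affine.copy()
        m = subject_connectivity(sub, cfg, design, seed)
        maps.append(m)
        log.info("processed %s", m.record.id)
    if len(maps) < 4:
        raise ValueError("need at least 4 subjects for group inference")
    records = pd.DataFrame([asdict(m.record) for m in maps])
    gdesign = GroupDesign.from_records([m.record for m in maps])
    rng = np.random.default_rng(np.random.SeedSequence(cfg.rng_seed).spawn(1)[0])
    vs = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))

    directions = {}
    cpc_stacks = {}
    for direction in _DIRECTIONS:
        stack = np.stack([m.cpc[direction] for m in maps])  # (n, V)
        cpc_stacks[direction] = stack
        t_flat, df, resid = voxelwise_group_t(stack, gdesign)
        resid_maps = np.stack([_grid(mask, r) for r in resid])
        fwhm = estimate_smoothness(resid_maps, mask, vs)
        extent, null_max = alphasim_extent_threshold(
            mask, fwhm, vs, voxel_p=cfg.voxel_p, alpha=cfg.cluster_alpha,
            n_iter=cfg.n_iter, connectivity=cfg.connectivity, rng=rng,
        )
        t_map = _grid(mask, t_flat)
        clusters = extract_clusters(
            t_map, df, mask, affine, voxel_p=cfg.voxel_p,
            extent_threshold=extent, connectivity=cfg.connectivity,
            null_maxima=null_max,
        )
        label_map = clusters.attrs["label_map"]
        cmeans = {}
        one_rows, act_rows = [], []
        n_sz = int((records["group"] == "SZ").sum())
        n_hc = len(records) - n_sz
        for _, row in clusters.iterrows():
            cname = f"{direction}_c{int(row.label)}"
            vals = cluster_mean_cpc(stack, mask, label_map == int(row.label))
            cmeans[cname] = vals
            for grp in ("SZ", "HC"):
                gv = vals[(records["group"] == grp).to_numpy()]
                res = one_sample_cluster_t(gv)
                one_rows.append({"cluster": cname, "group": grp, "t": res.statistic,
                                 "df": res.df, "p": res.p,
                                 "mean": float(gv.mean()), "sd": float(gv.std(ddof=1))})
            seed_act = np.array([m.seed_activation for m in maps])
            clus_act = cluster_mean_cpc(
                np.stack([m.activation_beta for m in maps]), mask,
                label_map == int(row.label))
            try:
                res = activation_control(vals, gdesign, np.column_stack([seed_act, clus_act]))
                act_rows.append({"cluster": cname, "t": res.statistic, "df": res.df,
                                 "p": res.p, "d": res.effect_size})
            except ValueError as e:  # collinear activation covariates
                log.warning("activation control skipped for %s: %s", cname, e)
        clusters = clusters.assign(
            cohens_d=[cohens_d_from_t(t, n_sz, n_hc) for t in clusters["peak_t"]]
        )
        clusters.attrs["label_map"] = label_map
        clusters.attrs["df"] = df
        directions[direction] = DirectionResult(
            direction=direction,
            t_map=t_map,
            df=df,
            fwhm_mm=fwhm,
            extent_threshold=extent,
            null_maxima=null_max,
            clusters=clusters,
            cluster_means=pd.DataFrame(cmeans, index=records["id"]),
            one_sample=pd.DataFrame(one_rows, columns=["cluster", "group", "t", "df",
                                                       "p", "mean", "sd"]),
            activation_adjusted=pd.DataFrame(act_rows, columns=["cluster", "t", "df",
                                                                "p", "d"]),
        )

    all_means = pd.concat(
        [directions[d].cluster_means for d in _DIRECTIONS], axis=1
    )
    assoc_columns = ["cluster", "variable", "method", "group", "r", "n", "p",
                     "threshold", "significant", "test"]
    if all_means.shape[1]:
        associations = association_battery(all_means.reset_index(drop=True), records)
    else:
        associations = pd.DataFrame(columns=assoc_columns)
    return PipelineResult(config=cfg, mask=mask, affine=affine, records=records,
                          directions=directions, associations=associations,
                          cpc_stacks=cpc_stacks)


def _grid(mask: np.ndarray, flat: np.ndarray) -> np.ndarray:
    out = np.zeros(mask.shape)
    out[mask] = flat
    return out


# ---------------------------------------------------------------------------
# dataset layout


def write_dataset(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort to the on-disk layout read by :func:`load_dataset`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.records_frame().to_csv(out / "participants.tsv", sep="\t", index=False)
    cohort.design.to_frame().to_csv(out / "task_design.tsv", sep="\t", index=False)
    meta = {
        "tr": cohort.config.tr,
        "n_sessions": cohort.design.n_sessions,
        "session_duration": cohort.design.session_duration,
        "seed_node_position": list(
            cohort.config.node_positions[cohort.config.planted_edge[0]]
        ),
        "rng_seed": cohort.rng_seed,
    }
    (out / "dataset.json").write_text(json.dumps(meta, indent=2))
    (out / "ground_truth.json").write_text(cohort.ground_truth.to_json())
    import nibabel as nib

    for i in range(len(cohort)):
        sub = cohort.subject(i)
        d = out / sub.record.id
        d.mkdir(exist_ok=True)
        nib.save(sub.rest.to_nifti(), d / "rest_bold.nii.gz")
        nib.save(sub.task.to_nifti(), d / "task_bold.nii.gz")
        sub.confounds_rest.to_frame().to_csv(d / "rest_confounds.tsv", sep="\t", index=False)
        sub.confounds_task.to_frame().to_csv(d / "task_confounds.tsv", sep="\t", index=False)
    return out


class LoadedCohort:
    """Lazy reader for the documented dataset layout."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        part = self.root / "participants.tsv"
        if not part.exists():
            raise FileNotFoundError(f"missing participants.tsv in {self.root}")
        self.participants = pd.read_csv(part, sep="\t")
        for col in ("id", "group"):
            if col not in self.participants.columns:
                raise ValueError(f"participants.tsv missing required column '{col}'")
        meta_path = self.root / "dataset.json"
        if not meta_path.exists():
            raise FileNotFoundError(f"missing dataset.json in {self.root}")
        self.meta = json.loads(meta_path.read_text())
        ddf = pd.read_csv(self.root / "task_design.tsv", sep="\t")
        self.design = TaskDesign.from_frame(
            ddf, int(self.meta["n_sessions"]), float(self.meta["session_duration"])
        )
        gt = self.root / "ground_truth.json"
        self.ground_truth = None
        if gt.exists():
            from .cohort import GroundTruth

            self.ground_truth = GroundTruth.from_json(gt.read_text())
        self._affine = None

    def __len__(self) -> int:
        return len(self.participants)

    def subject(self, i: int) -> SubjectData:
        row = self.participants.iloc[i]
        d = self.root / str(row["id"])
        for f in ("rest_bold.nii.gz", "task_bold.nii.gz",
                  "rest_confounds.tsv", "task_confounds.tsv"):
            if not (d / f).exists():
                raise FileNotFoundError(f"subject {row['id']}: missing {f}")
        tr = float(self.meta["tr"])
        rest = Volume4D.from_nifti(str(d / "rest_bold.nii.gz"))
        task = Volume4D.from_nifti(str(d / "task_bold.nii.gz"))
        for name, vol in (("rest", rest), ("task", task)):
            # header TR must agree with the dataset-level metadata
            if abs(vol.tr - tr) > 1e-4:
                raise ValueError(
                    f"subject {row['id']}: {name} TR {vol.tr} != dataset TR {tr}"
                )
            if self._affine is None:
                self._affine = vol.affine
            elif not np.allclose(vol.affine, self._affine, atol=1e-4):
                raise ValueError(f"subject {row['id']}: affine mismatch")
        cr = ConfoundSet.from_frame(pd.read_csv(d / "rest_confounds.tsv", sep="\t"))
        ct = ConfoundSet.from_frame(pd.read_csv(d / "task_confounds.tsv", sep="\t"))
        if len(cr) != rest.n_vols or len(ct) != task.n_vols:
            raise ValueError(f"subject {row['id']}: confound rows != volume count")
        kw = {k: row[k] for k in SubjectRecord.__dataclass_fields__ if k in row.index}
        kw["id"] = str(row["id"])
        record = SubjectRecord(**kw)
        return SubjectData(record, rest, task, cr, ct)

    def __iter__(self):
        for i in range(len(self)):
            yield self.subject(i)


def load_dataset(root: str | Path) -> LoadedCohort:
    """Open a dataset directory, validating layout and cross-subject consistency."""
    return LoadedCohort(root)


# ---------------------------------------------------------------------------
# full run with I/O


def run_pipeline(cfg: RunConfig, out_dir: str | Path,
                 cohort_config: CohortConfig | None = None) -> PipelineResult:
    """Execute simulate/load -> analysis -> write all outputs to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.simulate:
        ccfg = cohort_config or (CohortConfig.demo() if cfg.demo else CohortConfig())
        cohort = generate_cohort(ccfg, rng_seed=cfg.rng_seed)
        subjects = iter(cohort)
        design = cohort.design
        seed_center = cfg.seed_center or tuple(
            ccfg.node_positions[ccfg.planted_edge[0]]
        )
        (out / "ground_truth.json").write_text(cohort.ground_truth.to_json())
    else:
        if cfg.dataset_dir is None:
            raise ValueError("dataset_dir required when simulate is false")
        loaded = load_dataset(cfg.dataset_dir)
        subjects = iter(loaded)
        design = loaded.design
        seed_center = cfg.seed_center or tuple(loaded.meta["seed_node_position"])
    seed = SeedSpec(center=tuple(seed_center), radius=cfg.seed_radius)

    result = analyze_cohort(subjects, design, cfg, seed)
    _write_outputs(result, out)
    prov = {
        "config_hash": cfg.config_hash(),
        "rng_seed": cfg.rng_seed,
        "version": _pkg_version,
        "n_subjects": int(len(result.records)),
        "seed_center": list(seed.center),
        "seed_radius": seed.radius,
    }
    (out / "provenance.json").write_text(json.dumps(prov, indent=2))
    (out / "config.yaml").write_text(cfg.to_yaml())
    return result


def _write_outputs(result: PipelineResult, out: Path) -> None:
    import nibabel as nib

    result.records.to_csv(out / "participants.tsv", sep="\t", index=False)
    frames = []
    for direction, dres in result.directions.items():
        img = nib.Nifti1Image(dres.t_map.astype(np.float32), result.affine)
        nib.save(img, out / f"group_t_{direction}.nii.gz")
        lab = dres.clusters.attrs["label_map"]
        nib.save(nib.Nifti1Image(lab.astype(np.int16), result.affine),
                 out / f"clusters_{direction}.nii.gz")
        tab = dres.clusters.assign(direction=direction)
        tab.to_csv(out / f"clusters_{direction}.tsv", sep="\t", index=False)
        pd.DataFrame({"max_extent": dres.null_maxima}).to_csv(
            out / f"null_max_extent_{direction}.tsv", sep="\t", index=False)
        dres.cluster_means.to_csv(out / f"cluster_means_{direction}.tsv", sep="\t")
        dres.one_sample.to_csv(out / f"one_sample_{direction}.tsv", sep="\t", index=False)
        dres.activation_adjusted.to_csv(
            out / f"activation_control_{direction}.tsv", sep="\t", index=False)
        frames.append(tab)
    if result.associations is not None:
        result.associations.to_csv(out / "associations.tsv", sep="\t", index=False)
    meta = {
        d: {"df": int(r.df), "extent_threshold": int(r.extent_threshold),
            "fwhm_mm": [float(f) for f in r.fwhm_mm]}
        for d, r in result.directions.items()
    }
    (out / "inference.json").write_text(json.dumps(meta, indent=2))


def report(run_dir: str | Path) -> str:
    """Render a deterministic plain-text summary of a completed run."""
    run = Path(run_dir)
    needed = ["participants.tsv", "inference.json"]
    missing = [f for f in needed if not (run / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run: missing {missing}")
    meta = json.loads((run / "inference.json").read_text())
    part = pd.read_csv(run / "participants.tsv", sep="\t")
    lines = ["Rest-to-task CPC analysis report", "=" * 34, ""]
    n_sz = int((part["group"] == "SZ").sum())
    n_hc = int((part["group"] == "HC").sum())
    lines.append(f"Subjects: {n_sz} SZ / {n_hc} HC")
    for direction, m in meta.items():
        lines.append("")
        lines.append(f"Direction: {direction} "
                     f"(df={m['df']}, extent threshold K>={m['extent_threshold']})")
        ctab = run / f"clusters_{direction}.tsv"
        clusters = pd.read_csv(ctab, sep="\t") if ctab.exists() else pd.DataFrame()
        if clusters.empty:
            lines.append("  no suprathreshold clusters")
            continue
        one_path = run / f"one_sample_{direction}.tsv"
        one = pd.read_csv(one_path, sep="\t") if one_path.exists() else pd.DataFrame()
        header = f"  {'Area':<22}{'SZ mean (SD)':<18}{'HC mean (SD)':<18}" \
                 f"{'T':>7}{'p':>11}{'d':>7}  {'MNI':<15}{'K':>5}"
        lines.append(header)
        for _, row in clusters.iterrows():
            cname = f"{direction}_c{int(row.label)}"
            gm = {}
            for grp in ("SZ", "HC"):
                sel = one[(one["cluster"] == cname) & (one["group"] == grp)]
                gm[grp] = (f"{sel['mean'].iloc[0]:.3f} ({sel['sd'].iloc[0]:.2f})"
                           if len(sel) else "n/a")
            mni = f"{row.peak_x:.0f},{row.peak_y:.0f},{row.peak_z:.0f}"
            lines.append(
                f"  {cname:<22}{gm['SZ']:<18}{gm['HC']:<18}"
                f"{row.peak_t:>7.2f}{row.peak_p:>11.2e}{row.cohens_d:>7.2f}"
                f"  {mni:<15}{int(row.extent):>5}"
            )
    assoc_path = run / "associations.tsv"
    if assoc_path.exists():
        assoc = pd.read_csv(assoc_path, sep="\t")
        sig = assoc[assoc["significant"] == True] if len(assoc) else assoc  # noqa: E712
        lines.append("")
        lines.append(f"Associations: {len(assoc)} tests, {len(sig)} significant")
        for _, row in sig.iterrows():
            lines.append(
                f"  {row.cluster}: {row.variable} [{row.method}, {row.group}] "
                f"r={row.r:.3f} n={int(row.n)} p={row.p:.4f} (< {row.threshold})"
            )
    text = "\n".join(lines) + "\n"
    (run / "report.txt").write_text(text)
    return text
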