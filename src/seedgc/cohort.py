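"""Synthetic two-group cohort generator with known ground truth.

Latent node dynamics follow a switching first-order vector autoregression:

    x_t = A_state x_{t-1} + eps_t,   eps_t ~ N(0, noise_sd^2 I)

with ``A_rest`` outside task conditions and the subject's group-specific
task matrix inside high-load (2-back) condition windows. Node series are
embedded into a 4D volume as Gaussian spatial profiles around configured
MNI positions, with i.i.d. voxel noise, an additive global nuisance signal,
HRF-convolved task activation on configured nodes, and recorded motion
parameters — so every downstream stage of the pipeline (preprocessing,
path-coefficient estimation, group inference, clinical association) has a
parameter-recovery oracle with the planted truth stored alongside the data.

The default configuration mirrors the emulated study: TR 2.5 s, 240 rest
volumes (5 discarded), two task sessions of seven 110-s blocks, groups of
29 patients (SZ) and 31 controls (HC) differing only in the rest-to-task
change of a configured directed edge, and behaviour scores coupled to the
per-subject planted change of path coefficient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .design import TaskDesign, generate_task_design
from .hrf import HRFParams, canonical_hrf
from .volumes import ConfoundSet, Volume4D

__all__ = [
    "NetworkSpec",
    "SubjectRecord",
    "GroundTruth",
    "CohortConfig",
    "Cohort",
    "SubjectData",
    "simulate_var_system",
    "embed_in_volume",
    "generate_cohort",
    "planted_shift_for_effect_size",
]


# ---------------------------------------------------------------------------
# network specification


@dataclass
class NetworkSpec:
    """Directed lag-1 network: seed plus K target nodes.

    Coefficient matrices are (K+1) x (K+1) with rows as receivers; all must
    be stationary (spectral radius < 1) with diagonals in [0, 1).
    """

    node_ids: list[str]
    positions: np.ndarray  # (K+1, 3) MNI mm
    A_rest: np.ndarray
    A_task_SZ: np.ndarray
    A_task_HC: np.ndarray
    noise_sd: np.ndarray | float = 1.0

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (n_nodes, 3)")
        for name in ("A_rest", "A_task_SZ", "A_task_HC"):
            A = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, A)
            if A.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
            d = np.diag(A)
            if np.any(d < 0) or np.any(d >= 1):
                raise ValueError(f"{name} diagonal entries must lie in [0, 1)")
            if spectral_radius(A) >= 1:
                raise ValueError(f"{name} is non-stationary (spectral radius >= 1)")
        self.noise_sd = np.broadcast_to(np.asarray(self.noise_sd, dtype=float), (n,)).copy()
        if np.any(self.noise_sd <= 0):
            raise ValueError("noise_sd must be positive")

    def task_matrix(self, group: str) -> np.ndarray:
        if group == "SZ":
            return self.A_task_SZ
        if group == "HC":
            return self.A_task_HC
        raise ValueError("group must be 'SZ' or 'HC'")


def spectral_radius(A: np.ndarray) -> float:
    return float(np.abs(np.linalg.eigvals(A)).max())


@dataclass
class SubjectRecord:
    """Demographics, motion summaries, behaviour and symptom scores."""

    id: str
    group: str  # SZ | HC
    age: float
    gender: str  # F | M
    handedness: str  # L | R
    mean_fd_rest: float
    mean_fd_task: float
    hit_rate: float  # percent
    psychomotor_poverty: float = np.nan
    disorganization: float = np.nan
    reality_distortion: float = np.nan
    sspi_total: float = np.nan
    sofas: float = np.nan
    dose_ddd: float = np.nan
    lifetime_exposure: float = np.nan

    def __post_init__(self) -> None:
        if self.group not in ("SZ", "HC"):
            raise ValueError("group must be SZ or HC")
        if not (0.0 <= self.hit_rate <= 100.0):
            raise ValueError("hit_rate must be in [0, 100]")
        if self.mean_fd_rest < 0 or self.mean_fd_task < 0:
            raise ValueError("mean FD must be non-negative")


@dataclass
class GroundTruth:
    """Everything planted during generation, for recovery checks."""

    node_ids: list[str]
    positions: np.ndarray
    planted_edge: tuple[str, str]  # (source, target)
    rest_coefficient: float
    group_shift: float  # SZ task-coefficient shift relative to HC
    effect_size: float  # requested group CPC effect size d
    behaviour_coupling: float
    symptom_coupling: float
    subject_ids: list[str]
    subject_rest_coeff: np.ndarray  # realized edge weight at rest, per subject
    subject_task_coeff: np.ndarray  # realized edge weight during 2-back
    config_seed: int

    @property
    def subject_cpc(self) -> np.ndarray:
        return self.subject_task_coeff - self.subject_rest_coeff

    def target_position(self) -> np.ndarray:
        return self.positions[self.node_ids.index(self.planted_edge[1])]

    def to_json(self) -> str:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["planted_edge"] = tuple(d["planted_edge"])
        for k in ("positions", "subject_rest_coeff", "subject_task_coeff"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


# ---------------------------------------------------------------------------
# configuration


def _default_positions() -> dict[str, tuple[float, float, float]]:
    # seed at the right anterior insula coordinate; targets scattered across
    # the default 24x28x24 grid at 3 mm (mm range ±34.5 / ±40.5 / ±34.5)
    return {
        "seed": (33.0, 21.0, -3.0),
        "target": (-33.0, 48.0, 24.0),
        "null_a": (-21.0, -51.0, 6.0),
        "null_b": (24.0, -36.0, -12.0),
    }


@dataclass
class CohortConfig:
    """Study conditions for the generator; defaults emulate the full design."""

    n_sz: int = 29
    n_hc: int = 31
    grid_shape: tuple[int, int, int] = (24, 28, 24)
    voxel_size: float = 3.0
    spatial_sd: float = 4.0  # mm, Gaussian node profile
    voxel_noise_sd: float = 0.3
    tr: float = 2.5
    n_rest_vols: int = 240
    n_discard: int = 5
    n_blocks_per_session: int = 7
    n_sessions: int = 2
    node_positions: dict = field(default_factory=_default_positions)
    diag_coefficient: float = 0.3
    noise_sd: float = 1.0
    planted_edge: tuple[str, str] = ("seed", "target")
    rest_coefficient: float = 0.0
    group_effect_size: float = 1.2  # group CPC effect size d on the planted edge
    edge_subject_sd: float = 0.25  # between-subject SD of the true task coefficient
    behaviour_coupling: float = 0.5  # cohort-level r: planted CPC vs hit rate
    symptom_coupling: float = 0.5  # within-SZ r: planted CPC vs psychomotor poverty
    activation_amplitude: dict = field(default_factory=lambda: {"seed": 0.5, "target": 0.5})
    global_signal_sd: float = 0.2
    motion_step_sd_mm: float = 0.02
    motion_step_sd_rad: float = 0.0004
    band: tuple[float, float] = (0.01, 0.08)

    @classmethod
    def demo(cls) -> "CohortConfig":
        """Desk-scale cohort: 12+12 subjects on a 16x18x16 grid."""
        return cls(
            n_sz=12,
            n_hc=12,
            grid_shape=(16, 18, 16),
            node_positions={
                "seed": (12.0, 9.0, -3.0),
                "target": (-12.0, -9.0, 9.0),
                "null_a": (12.0, -15.0, 9.0),
            },
        )

    def validate(self) -> None:
        if self.n_sz < 1 or self.n_hc < 1:
            raise ValueError("group sizes must be >= 1")
        if abs(self.behaviour_coupling) >= 1 or abs(self.symptom_coupling) >= 1:
            raise ValueError("coupling |r| must be < 1")
        if self.edge_subject_sd < 0:
            raise ValueError("edge_subject_sd must be non-negative")

    @property
    def n_subjects(self) -> int:
        return self.n_sz + self.n_hc

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        aff[:3, 3] = -(np.asarray(self.grid_shape) - 1) / 2.0 * self.voxel_size
        return aff


def planted_shift_for_effect_size(cfg: CohortConfig) -> float:
    """Task-coefficient shift producing the requested group CPC effect size.

    The observed CPC spread combines the between-subject SD of the true
    coefficient with the estimation error of both states:

      SE_rest  ~ 1 / sqrt(T_eff - 3), with T_eff reduced by the rest
                 band-pass to the retained fraction of the spectrum;
      SE_task  ~ 1 / sqrt(n_block - 5) / sqrt(B) after per-block detrending.

    The planted shift is d times the resulting SD. All quantities are on the
    z-scored coefficient scale (unitless).
    """
    T_rest = cfg.n_rest_vols - cfg.n_discard
    nyq = 0.5 / cfg.tr
    frac = (cfg.band[1] - cfg.band[0]) / nyq
    t_eff = max(T_rest * frac, 8.0)
    se_rest = 1.0 / np.sqrt(t_eff - 3.0)
    n_block = int(round(30.0 / cfg.tr))
    n_blocks = cfg.n_blocks_per_session * cfg.n_sessions
    se_task = 1.0 / np.sqrt(max(n_block - 5, 2)) / np.sqrt(n_blocks)
    sd_cpc = float(np.sqrt(cfg.edge_subject_sd**2 + se_rest**2 + se_task**2))
    return cfg.group_effect_size * sd_cpc


# ---------------------------------------------------------------------------
# latent dynamics


def _volume_states(design: TaskDesign, tr: float, n_vols: int,
                   condition: str = "2-back") -> np.ndarray:
    """Boolean per-volume task-state flag: midpoint inside a condition window."""
    mid = (np.arange(n_vols) + 0.5) * tr
    flag = np.zeros(n_vols, dtype=bool)
    for start, end in design.condition_windows(condition):
        flag |= (mid >= start) & (mid < end)
    return flag


def simulate_var_system(
    spec: NetworkSpec,
    design: TaskDesign | None,
    n_rest_vols: int,
    tr: float,
    rng_seed: int | np.random.Generator = 0,
    group: str = "HC",
    burn_in: int = 100,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Simulate latent node series for rest and (optionally) task.

    Rest uses ``A_rest`` throughout. During the task run a volume evolves
    under the group's task matrix iff its acquisition midpoint falls inside
    a 2-back condition window; instruction/interval/other-load periods use
    ``A_rest``. Returns ``(rest (n_nodes, T_rest), task (n_nodes, T_task))``;
    task is None when no design is given.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    n = len(spec.node_ids)
    sd = spec.noise_sd

    def run(matrices: list[np.ndarray]) -> np.ndarray:
        T = len(matrices)
        out = np.empty((n, T))
        x = np.zeros(n)
        for _ in range(burn_in):
            x = spec.A_rest @ x + rng.standard_normal(n) * sd
        for t, A in enumerate(matrices):
            x = A @ x + rng.standard_normal(n) * sd
            out[:, t] = x
        return out

    rest = run([spec.A_rest] * n_rest_vols)
    task = None
    if design is not None:
        n_task = int(round(design.total_duration / tr))
        A_task = spec.task_matrix(group)
        flags = _volume_states(design, tr, n_task)
        task = run([A_task if f else spec.A_rest for f in flags])
    return rest, task


def embed_in_volume(
    latent: np.ndarray,
    positions: np.ndarray,
    grid_shape: tuple[int, int, int],
    voxel_size: float,
    spatial_sd: float,
    voxel_noise_sd: float,
    rng_seed: int | np.random.Generator = 0,
    tr: float = 2.5,
    node_ids: list[str] | None = None,
    affine: np.ndarray | None = None,
) -> Volume4D:
    """Write latent node series into a 4D grid as Gaussian spatial profiles.

    Each node contributes ``exp(-d^2 / (2 sd^2)) * x_node(t)`` at distance d
    (mm) from its position, so the node's nearest voxel carries the latent
    series at profile scale ~1. I.i.d. Gaussian voxel noise is added. The
    affine maps voxel indices to MNI mm with the grid centred at the origin
    unless an affine is supplied.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    latent = np.asarray(latent, dtype=float)
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if latent.ndim != 2 or latent.shape[0] != positions.shape[0]:
        raise ValueError("latent must be (n_nodes, T) aligned with positions")
    if affine is None:
        affine = np.eye(4)
        affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_size
        affine[:3, 3] = -(np.asarray(grid_shape) - 1) / 2.0 * voxel_size
    inv = np.linalg.inv(affine)
    grid = np.asarray(grid_shape)
    idx = np.indices(grid_shape).reshape(3, -1).T  # (V, 3)
    mm = (affine[:3, :3] @ idx.T).T + affine[:3, 3]
    T = latent.shape[1]
    data = rng.standard_normal((*grid_shape, T)) * voxel_noise_sd
    flat = data.reshape(-1, T)
    for i, pos in enumerate(positions):
        ijk = inv[:3, :3] @ pos + inv[:3, 3]
        if np.any(ijk < -0.5) or np.any(ijk > grid - 0.5):
            name = node_ids[i] if node_ids else f"node {i}"
            raise ValueError(f"position of {name} at {tuple(pos)} mm lies outside the grid")
        d2 = ((mm - pos) ** 2).sum(axis=1)
        profile = np.exp(-d2 / (2.0 * spatial_sd**2))
        flat += np.outer(profile, latent[i])
    return Volume4D(data=data, affine=affine, tr=tr)


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class SubjectData:
    record: SubjectRecord
    rest: Volume4D
    task: Volume4D
    confounds_rest: ConfoundSet
    confounds_task: ConfoundSet


def _exact_corr_mix(target: np.ndarray, r: float, rng: np.random.Generator) -> np.ndarray:
    """A standardized vector whose sample correlation with ``target`` is exactly r."""
    n = target.size
    zc = (target - target.mean())
    s = zc.std()
    if s == 0:
        return rng.standard_normal(n)
    zc = zc / s
    e = rng.standard_normal(n)
    e = e - e.mean()
    e = e - (e @ zc) / (zc @ zc) * zc
    e_sd = e.std()
    e = e / e_sd if e_sd > 0 else e
    return r * zc + np.sqrt(1.0 - r * r) * e


def _random_walk(T: int, step_sd: float, rng: np.random.Generator) -> np.ndarray:
    return np.cumsum(rng.standard_normal(T) * step_sd)


class Cohort:
    """A reproducible synthetic cohort; subject volumes are built on demand.

    Records, the task design and the ground truth are materialised at
    construction; the (large) 4D volumes for each subject are generated
    lazily and deterministically from per-subject seeds, so iterating twice
    over the same cohort yields bit-identical data.
    """

    def __init__(self, config: CohortConfig, rng_seed: int = 0):
        config.validate()
        self.config = config
        self.rng_seed = int(rng_seed)
        root = np.random.SeedSequence(self.rng_seed)
        # fixed spawn layout: 0 design, 1 records/behaviour, 2.. subjects
        self._seeds = root.spawn(2 + config.n_subjects)
        self.design = generate_task_design(
            config.n_blocks_per_session,
            config.n_sessions,
            np.random.default_rng(self._seeds[0]),
        )
        self._build_truth_and_records()

    # -- planted parameters -------------------------------------------------
    def _build_truth_and_records(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(self._seeds[1])
        n = cfg.n_subjects
        groups = ["SZ"] * cfg.n_sz + ["HC"] * cfg.n_hc
        ids = [f"sub-{i + 1:03d}" for i in range(n)]
        shift = planted_shift_for_effect_size(cfg)
        jitter = rng.standard_normal(n) * cfg.edge_subject_sd
        task_coeff = cfg.rest_coefficient + jitter + np.where(
            np.asarray(groups) == "SZ", shift, 0.0
        )
        rest_coeff = np.full(n, cfg.rest_coefficient)
        cpc = task_coeff - rest_coeff

        ages = np.clip(rng.normal(33.5, 9.0, n), 18, 62)
        genders = np.where(rng.random(n) < 0.23, "F", "M")
        handed = np.where(rng.random(n) < 0.13, "L", "R")

        hit = 76.0 + 6.0 * _exact_corr_mix(cpc, cfg.behaviour_coupling, rng)
        hit = np.clip(hit, 0.0, 100.0)

        sz_mask = np.asarray(groups) == "SZ"
        pmp = np.full(n, np.nan)
        pmp[sz_mask] = np.clip(
            5.0 + 2.0 * _exact_corr_mix(cpc[sz_mask], cfg.symptom_coupling, rng), 0, None
        )
        disorg = np.full(n, np.nan)
        disorg[sz_mask] = np.clip(rng.normal(4.0, 2.0, sz_mask.sum()), 0, None)
        reality = np.full(n, np.nan)
        reality[sz_mask] = np.clip(rng.normal(4.0, 2.0, sz_mask.sum()), 0, None)
        sspi = np.full(n, np.nan)
        sspi[sz_mask] = np.clip(rng.normal(20.0, 6.0, sz_mask.sum()), 0, None)
        sofas = np.full(n, np.nan)
        sofas[sz_mask] = np.clip(rng.normal(45.0, 10.0, sz_mask.sum()), 0, 100)
        dose = np.full(n, np.nan)
        dose[sz_mask] = np.clip(rng.normal(1.5, 1.0, sz_mask.sum()), 0.1, None)
        lifetime = np.full(n, np.nan)
        lifetime[sz_mask] = np.clip(rng.normal(6100.0, 5000.0, sz_mask.sum()), 100, None)

        self._groups = groups
        self._ids = ids
        self._demo = dict(
            ages=ages, genders=genders, handed=handed, hit=hit, pmp=pmp,
            disorg=disorg, reality=reality, sspi=sspi, sofas=sofas,
            dose=dose, lifetime=lifetime,
        )
        self.ground_truth = GroundTruth(
            node_ids=list(cfg.node_positions.keys()),
            positions=np.asarray(list(cfg.node_positions.values()), dtype=float),
            planted_edge=cfg.planted_edge,
            rest_coefficient=cfg.rest_coefficient,
            group_shift=shift,
            effect_size=cfg.group_effect_size,
            behaviour_coupling=cfg.behaviour_coupling,
            symptom_coupling=cfg.symptom_coupling,
            subject_ids=ids,
            subject_rest_coeff=rest_coeff,
            subject_task_coeff=task_coeff,
            config_seed=self.rng_seed,
        )

    def network_spec_for(self, subject_index: int) -> NetworkSpec:
        cfg = self.config
        gt = self.ground_truth
        node_ids = gt.node_ids
        n = len(node_ids)
        src = node_ids.index(cfg.planted_edge[0])
        tgt = node_ids.index(cfg.planted_edge[1])
        A_rest = np.eye(n) * cfg.diag_coefficient
        A_rest[tgt, src] = gt.subject_rest_coeff[subject_index]
        A_task = np.eye(n) * cfg.diag_coefficient
        A_task[tgt, src] = gt.subject_task_coeff[subject_index]
        for name, A in (("A_rest", A_rest), ("A_task", A_task)):
            if spectral_radius(A) >= 1:
                raise ValueError(f"planted {name} is non-stationary")
        # the subject's own matrix serves for both group slots; simulation
        # selects by the subject's group label
        return NetworkSpec(
            node_ids=node_ids,
            positions=gt.positions,
            A_rest=A_rest,
            A_task_SZ=A_task,
            A_task_HC=A_task,
            noise_sd=cfg.noise_sd,
        )

    # -- records ------------------------------------------------------------
    def records(self) -> list[SubjectRecord]:
        out = []
        d = self._demo
        for i, (sid, grp) in enumerate(zip(self._ids, self._groups)):
            fd_rest, fd_task = self._mean_fds(i)
            out.append(
                SubjectRecord(
                    id=sid,
                    group=grp,
                    age=float(d["ages"][i]),
                    gender=str(d["genders"][i]),
                    handedness=str(d["handed"][i]),
                    mean_fd_rest=fd_rest,
                    mean_fd_task=fd_task,
                    hit_rate=float(d["hit"][i]),
                    psychomotor_poverty=float(d["pmp"][i]),
                    disorganization=float(d["disorg"][i]),
                    reality_distortion=float(d["reality"][i]),
                    sspi_total=float(d["sspi"][i]),
                    sofas=float(d["sofas"][i]),
                    dose_ddd=float(d["dose"][i]),
                    lifetime_exposure=float(d["lifetime"][i]),
                )
            )
        return out

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records()])

    # -- subject-level generation -------------------------------------------
    def _subject_rng(self, i: int) -> np.random.Generator:
        return np.random.default_rng(self._seeds[2 + i])

    def _motion_and_confounds(self, rng: np.random.Generator, T: int,
                              global_sig: np.ndarray) -> ConfoundSet:
        cfg = self.config
        motion = np.column_stack(
            [_random_walk(T, cfg.motion_step_sd_mm, rng) for _ in range(3)]
            + [_random_walk(T, cfg.motion_step_sd_rad, rng) for _ in range(3)]
        )
        tissue = np.column_stack(
            [
                global_sig + rng.standard_normal(T) * 0.02,
                0.7 * global_sig + rng.standard_normal(T) * 0.05,
                0.5 * global_sig + rng.standard_normal(T) * 0.05,
            ]
        )
        return ConfoundSet(motion, tissue)

    def _mean_fds(self, i: int) -> tuple[float, float]:
        # regenerate only the motion draws (cheap) to report mean FD in records
        sub = self.subject(i, volumes=False)
        return sub.confounds_rest.mean_fd, sub.confounds_task.mean_fd

    def subject(self, i: int, volumes: bool = True) -> SubjectData:
        """Generate subject ``i``; deterministic in (config, rng_seed, i)."""
        cfg = self.config
        rng = self._subject_rng(i)
        spec = self.network_spec_for(i)
        group = self._groups[i]
        n_task = int(round(self.design.total_duration / cfg.tr))

        rest_latent, task_latent = simulate_var_system(
            spec, self.design, cfg.n_rest_vols, cfg.tr, rng, group=group
        )
        # additive HRF-lagged task activation on configured nodes
        if cfg.activation_amplitude and task_latent is not None:
            act = self._activation_profile(n_task)
            for node, amp in cfg.activation_amplitude.items():
                if node in spec.node_ids and amp:
                    task_latent[spec.node_ids.index(node)] += amp * act

        g_rest = _random_walk(cfg.n_rest_vols, cfg.global_signal_sd, rng) * 0.1
        g_task = _random_walk(n_task, cfg.global_signal_sd, rng) * 0.1
        conf_rest = self._motion_and_confounds(rng, cfg.n_rest_vols, g_rest)
        conf_task = self._motion_and_confounds(rng, n_task, g_task)

        record = self.records_light(i)
        record.mean_fd_rest = conf_rest.mean_fd
        record.mean_fd_task = conf_task.mean_fd
        if not volumes:
            return SubjectData(record, None, None, conf_rest, conf_task)

        rest_vol = embed_in_volume(
            rest_latent, spec.positions, cfg.grid_shape,
            cfg.voxel_size, cfg.spatial_sd, cfg.voxel_noise_sd, rng,
            tr=cfg.tr, node_ids=spec.node_ids, affine=cfg.affine(),
        )
        rest_vol.data += g_rest[None, None, None, :]
        task_vol = embed_in_volume(
            task_latent, spec.positions, cfg.grid_shape,
            cfg.voxel_size, cfg.spatial_sd, cfg.voxel_noise_sd, rng,
            tr=cfg.tr, node_ids=spec.node_ids, affine=cfg.affine(),
        )
        task_vol.data += g_task[None, None, None, :]
        return SubjectData(record, rest_vol, task_vol, conf_rest, conf_task)

    def records_light(self, i: int) -> SubjectRecord:
        d = self._demo
        return SubjectRecord(
            id=self._ids[i],
            group=self._groups[i],
            age=float(d["ages"][i]),
            gender=str(d["genders"][i]),
            handedness=str(d["handed"][i]),
            mean_fd_rest=0.0,
            mean_fd_task=0.0,
            hit_rate=float(d["hit"][i]),
            psychomotor_poverty=float(d["pmp"][i]),
            disorganization=float(d["disorg"][i]),
            reality_distortion=float(d["reality"][i]),
            sspi_total=float(d["sspi"][i]),
            sofas=float(d["sofas"][i]),
            dose_ddd=float(d["dose"][i]),
            lifetime_exposure=float(d["lifetime"][i]),
        )

    def _activation_profile(self, n_vols: int) -> np.ndarray:
        from .preprocess import build_task_regressors

        cols, labels = build_task_regressors(self.design, self.config.tr, n_vols,
                                             labels=["2-back"])
        return cols[:, 0]

    def __len__(self) -> int:
        return self.config.n_subjects

    def __iter__(self):
        for i in range(len(self)):
            yield self.subject(i)


def generate_cohort(config: CohortConfig | None = None, rng_seed: int = 0) -> Cohort:
    """Build a reproducible cohort (records + ground truth now, volumes lazily)."""
    return Cohort(config or CohortConfig(), rng_seed)
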