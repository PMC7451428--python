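"""Parameter-recovery and calibration studies for the pipeline.

Each function runs a self-contained simulation experiment against the
package's own estimators: estimator consistency on the latent VAR, null
calibration of the voxelwise group test, familywise-error control of the
Monte-Carlo cluster-extent threshold, direction specificity of the CPC
maps, and end-to-end recovery of a planted rest-to-task edge change on a
desk-scale cohort. They are used by the test suite and the reproduction
script, and are useful for re-validating the pipeline after changes.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats

from .cohort import Cohort, CohortConfig, NetworkSpec, generate_cohort, simulate_var_system
from .connectivity import SEED_TO_BRAIN, BRAIN_TO_SEED, path_coefficient
from .inference import GroupDesign, alphasim_extent_threshold, voxelwise_group_t, _max_cluster_size
from .pipeline import RunConfig, SeedSpec, analyze_cohort, subject_connectivity
from .clinical import correlate

__all__ = [
    "var_recovery",
    "null_group_rejection",
    "alphasim_fwer",
    "direction_specificity",
    "endtoend_recovery",
]


def _two_node_spec(b: float, diag: float = 0.0) -> NetworkSpec:
    A = np.array([[diag, 0.0], [b, diag]])
    return NetworkSpec(
        node_ids=["seed", "target"],
        positions=np.zeros((2, 3)),
        A_rest=A,
        A_task_SZ=A,
        A_task_HC=A,
    )


def var_recovery(rng_seed: int = 0, n_reps: int = 100, T: int = 235,
                 b: float = 0.4) -> float:
    """Mean recovered lag-1 path coefficient for a planted cross-influence.

    Simulates a two-node VAR(1) with seed -> target coefficient ``b`` (zero
    diagonals, unit innovations) and estimates the path coefficient on each
    draw. With z-scored series the estimand is b / sqrt(1 + b^2).
    """
    spec = _two_node_spec(b)
    rng = np.random.default_rng(rng_seed)
    vals = np.empty(n_reps)
    for i in range(n_reps):
        rest, _ = simulate_var_system(spec, None, T, tr=2.5, rng_seed=rng)
        vals[i] = path_coefficient(rest[0], rest[1])
    return float(vals.mean())


def null_group_rejection(rng_seed: int = 0, n_subjects: int = 60,
                         n_vox: int = 5000, voxel_p: float = 0.01) -> float:
    """Voxelwise rejection rate of the covariate-adjusted group t under the null.

    CPC-like maps are pure noise with no group effect; the design carries the
    standard covariates (group, age, gender, two mean-FD columns). The rate
    should match the nominal two-sided ``voxel_p``.
    """
    rng = np.random.default_rng(rng_seed)
    n1 = n_subjects // 2
    X = np.column_stack(
        [
            np.ones(n_subjects),
            np.r_[np.ones(n1), -np.ones(n_subjects - n1)],
            rng.normal(33.5, 9.0, n_subjects),
            (rng.random(n_subjects) < 0.25).astype(float),
            rng.gamma(4.0, 0.025, n_subjects),
            rng.gamma(4.0, 0.025, n_subjects),
        ]
    )
    design = GroupDesign(matrix=X, columns=["intercept", "group", "age", "gender",
                                            "fd_rest", "fd_task"],
                         subject_ids=[f"s{i}" for i in range(n_subjects)])
    Y = rng.standard_normal((n_subjects, n_vox))
    t, df, _ = voxelwise_group_t(Y, design)
    t_crit = stats.t.isf(voxel_p / 2.0, df)
    return float((np.abs(t) > t_crit).mean())


def alphasim_fwer(rng_seed: int = 0, n_iter: int = 1000, n_null: int = 500,
                  shape: tuple[int, int, int] = (16, 18, 16),
                  voxel_size: float = 3.0, fwhm: float = 8.0,
                  voxel_p: float = 0.01, alpha: float = 0.05,
                  connectivity: int = 26) -> float:
    """Familywise false-positive rate of the extent threshold on fresh null maps.

    Derives the cluster-extent threshold by Monte Carlo, then applies it to
    independent smooth-noise maps generated the same way; the fraction with
    any surviving cluster estimates the familywise error, which should not
    exceed ``alpha`` beyond binomial noise.
    """
    mask = np.ones(shape, dtype=bool)
    vs = np.full(3, voxel_size)
    rng = np.random.default_rng(rng_seed)
    k, _ = alphasim_extent_threshold(
        mask, fwhm, vs, voxel_p=voxel_p, alpha=alpha, n_iter=n_iter,
        connectivity=connectivity, rng=rng,
    )
    sigma = (fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))) / vs
    z_crit = stats.norm.isf(voxel_p / 2.0)
    hits = 0
    for _ in range(n_null):
        noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma,
                                        mode="constant")
        vals = noise[mask]
        z = np.zeros(shape)
        z[mask] = (vals - vals.mean()) / vals.std()
        if _max_cluster_size(z >= z_crit, z <= -z_crit, connectivity) >= k:
            hits += 1
    return hits / n_null


def _node_region_mask(mask: np.ndarray, affine: np.ndarray, pos: np.ndarray,
                      radius_mm: float) -> np.ndarray:
    """Voxels within ``radius_mm`` of a node position (in-mask)."""
    idx = np.indices(mask.shape).reshape(3, -1).T
    mm = (affine[:3, :3] @ idx.T).T + affine[:3, 3]
    d = np.linalg.norm(mm - np.asarray(pos), axis=1).reshape(mask.shape)
    return (d <= radius_mm) & mask


def _target_flat_index(cohort: Cohort, mask: np.ndarray, affine: np.ndarray) -> int:
    """In-mask flat index of the voxel nearest the planted target node."""
    pos = cohort.ground_truth.target_position()
    inv = np.linalg.inv(affine)
    ijk = np.round(inv[:3, :3] @ pos + inv[:3, 3]).astype(int)
    grid = np.full(mask.shape, -1, dtype=int)
    grid[mask] = np.arange(int(mask.sum()))
    return int(grid[tuple(ijk)])


def direction_specificity(rng_seed: int = 0, n_subjects: int = 32) -> float:
    """Cohort-mean |CPC| ratio at the target: seed-to-brain over brain-to-seed.

    Plants only a seed -> target task influence (every subject carries the
    same shift; the between-subject jitter is switched off because it is
    orthogonal to directional asymmetry and only adds noise to the ratio)
    and compares the magnitude of the recovered change at the target voxel
    across directions; a directional estimator should concentrate the
    signal in the seed-to-brain map.
    """
    from .cohort import planted_shift_for_effect_size

    cfg = CohortConfig.demo()
    target_shift = planted_shift_for_effect_size(cfg)
    cfg.n_sz = n_subjects  # every subject carries the planted task edge
    cfg.n_hc = 1
    cfg.edge_subject_sd = 0.0
    # keep the same planted task-coefficient shift as the recovery study
    cfg.group_effect_size *= target_shift / planted_shift_for_effect_size(cfg)
    cohort = generate_cohort(cfg, rng_seed=rng_seed)
    run_cfg = RunConfig(rng_seed=rng_seed)
    seed_spec = SeedSpec(center=tuple(cfg.node_positions["seed"]))
    sums = {SEED_TO_BRAIN: 0.0, BRAIN_TO_SEED: 0.0}
    idx = None
    n_used = 0
    for i in range(cfg.n_sz):
        sub = cohort.subject(i)
        if idx is None:
            idx = _target_flat_index(cohort, sub.rest.mask, sub.rest.affine)
        m = subject_connectivity(sub, run_cfg, cohort.design, seed_spec)
        for d in sums:
            sums[d] += m.cpc[d][idx]
        n_used += 1
    mean_s2b = abs(sums[SEED_TO_BRAIN] / n_used)
    mean_b2s = abs(sums[BRAIN_TO_SEED] / n_used)
    return float(mean_s2b / max(mean_b2s, 1e-12))


def endtoend_recovery(rng_seed: int = 0, n_runs: int = 25,
                      n_iter: int = 500) -> tuple[float, float]:
    """End-to-end recovery rates over repeated desk-scale cohorts.

    Each run generates a fresh 12+12 cohort with the planted rest-to-task
    edge change (group effect size d = 1.2) and behaviour coupling r = 0.5,
    runs the full pipeline, and scores (a) whether a corrected seed-to-brain
    cluster overlaps the planted target node and (b) whether the pooled
    hit-rate association is significant for a target-overlapping cluster.
    Returns ``(cluster_rate, behaviour_rate)``.
    """
    seeds = np.random.SeedSequence(rng_seed).generate_state(n_runs) % (2**31)
    cluster_hits = 0
    behav_hits = 0
    for run_seed in seeds:
        cfg = CohortConfig.demo()
        cohort = generate_cohort(cfg, rng_seed=int(run_seed))
        run_cfg = RunConfig(rng_seed=int(run_seed), n_iter=n_iter)
        seed_spec = SeedSpec(center=tuple(cfg.node_positions["seed"]))
        result = analyze_cohort(iter(cohort), cohort.design, run_cfg, seed_spec)
        dres = result.directions[SEED_TO_BRAIN]
        label_map = dres.clusters.attrs["label_map"]
        # the planted node is a Gaussian blob (sd = spatial_sd); a cluster
        # overlaps it if it touches the profile >= 0.5 region (FWHM/2)
        pos = cohort.ground_truth.target_position()
        node_region = _node_region_mask(result.mask, result.affine, pos,
                                        cfg.spatial_sd * np.sqrt(2 * np.log(2)))
        overlapping = []
        for _, row in dres.clusters.iterrows():
            if row.sign > 0 and ((label_map == int(row.label)) & node_region).any():
                overlapping.append(f"{SEED_TO_BRAIN}_c{int(row.label)}")
        if overlapping:
            cluster_hits += 1
            assoc = result.associations
            hit_rows = assoc[
                (assoc["variable"] == "hit_rate")
                & (assoc["group"] == "all")
                & (assoc["cluster"].isin(overlapping))
            ]
            if bool(hit_rows["significant"].any()):
                behav_hits += 1
    return cluster_hits / n_runs, behav_hits / n_runs
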