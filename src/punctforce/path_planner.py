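"""Straight-path planning from skin voxels to bile-duct centerline targets.

Candidate trajectories run from every exposed skin voxel to every voxel of
the target-structure centerline. Two hard constraints dismiss candidates
outright (score infinity): a risk structure (bone, blood vessel) blocking
the line of sight before the target, and an insertion length above 90 mm.
Two soft criteria, each normalized to [0, 1], score the survivors: the
minimal Euclidean clearance from the shaft to any risk structure, and the
number of target voxels traversed by the shaft (favouring deep, well-aligned
duct penetration). The path quality is the weighted sum

    Q = sum_i alpha_i * C_i,    alpha_i = 1/2,

so a feasible path scores ``Q = (C3 + C4) / 2`` with ``Q = infinity``
flagging infeasibility. For each skin voxel the best-scoring candidate is
kept; accepted paths must further pass the quality filter ``Q >= 0.4``,
which removes trajectories squeezing past ribs or vessels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.morphology import skeletonize

from .tissue_model import AIR, SKIN, PatientModel
from .volumes import Trajectory, Volume3D, voxel_to_world

__all__ = [
    "PlannerConfig",
    "PathScore",
    "PlannedPath",
    "extract_centerline",
    "skin_voxels",
    "cast_ray",
    "score_path",
    "plan_all",
    "paths_to_csv",
]


@dataclass(frozen=True)
class PlannerConfig:
    """Planner settings.

    ``d_cap_mm`` and ``n_cap`` cap the soft-criterion normalizations: risk
    clearances beyond ``d_cap_mm`` and target-voxel counts beyond ``n_cap``
    saturate at score 1 (bounded, monotone, data-independent).
    ``skin_stride`` subsamples the skin voxel set for scaled-down runs.
    """

    max_length: float = 90.0
    quality_threshold: float = 0.4
    d_cap_mm: float = 10.0
    n_cap: int = 10
    skin_stride: int = 1
    step_fraction: float = 0.5  # ray-casting step, fraction of min voxel size

    def __post_init__(self):
        if self.d_cap_mm <= 0 or self.n_cap <= 0:
            raise ValueError("normalization caps must be positive")
        if not (0 < self.step_fraction <= 0.5):
            raise ValueError("ray step must be at most half a voxel")


@dataclass(frozen=True)
class PathScore:
    """Criterion scores of one candidate path.

    ``c1`` (visibility) and ``c2`` (length) are 0 or infinity; ``c3`` (risk
    clearance) and ``c4`` (target penetration) lie in [0, 1]. Higher Q is
    better; infinity marks infeasibility.
    """

    c1: float
    c2: float
    c3: float
    c4: float

    @property
    def q(self) -> float:
        if math.isinf(self.c1) or math.isinf(self.c2):
            return math.inf
        return 0.5 * (self.c1 + self.c2 + self.c3 + self.c4)

    @property
    def feasible(self) -> bool:
        return math.isfinite(self.q)


@dataclass(frozen=True)
class PlannedPath:
    """An accepted skin-to-target trajectory with its score."""

    trajectory: Trajectory
    skin_voxel: tuple[int, int, int]
    target_voxel: tuple[int, int, int]
    score: PathScore


def _distance_ridge_axis(mask: np.ndarray) -> np.ndarray:
    """Per-component axis chain: one max-clearance voxel per axial slab.

    Deterministic stand-in used when topological thinning collapses a
    structure to the empty set (which happens for perfectly symmetric
    even-diameter tubes). Each connected component is sliced perpendicular
    to its principal axis; per slab the voxel with the largest Euclidean
    clearance from the background is kept (ties: smallest (x, y, z) index).
    """
    from scipy.ndimage import label as cc_label

    out = np.zeros_like(mask)
    lbl, n = cc_label(mask)
    for c in range(1, n + 1):
        comp = lbl == c
        idx = np.argwhere(comp)  # argwhere is lexicographically sorted
        centred = idx - idx.mean(axis=0)
        _, _, vt = np.linalg.svd(centred.astype(float), full_matrices=False)
        slab = np.floor(centred @ vt[0]).astype(int)
        edt = distance_transform_edt(comp)
        clearance = edt[idx[:, 0], idx[:, 1], idx[:, 2]]
        for s in np.unique(slab):
            rows = np.flatnonzero(slab == s)
            best = rows[int(np.argmax(clearance[rows]))]
            out[tuple(idx[best])] = True
    return out


def extract_centerline(target_mask: Volume3D) -> np.ndarray:
    """1-voxel-wide skeleton of a target structure, as an (N, 3) index array.

    3D topological thinning; if the thinning collapses the (non-empty)
    structure entirely — possible for exactly even-diameter symmetric
    tubes — a distance-ridge axis chain is used instead. The voxel list is
    sorted by (z, y, x) for determinism. Raises for an empty mask.
    """
    mask = np.asarray(target_mask.values).astype(bool)
    if not mask.any():
        raise ValueError("target mask is empty")
    skel = skeletonize(mask)
    if not skel.any():
        skel = _distance_ridge_axis(mask)
    idx = np.argwhere(skel)
    order = np.lexsort((idx[:, 0], idx[:, 1], idx[:, 2]))  # sort by (z, y, x)
    return idx[order]


def skin_voxels(labels: Volume3D, skin_code: int = SKIN, air_code: int = AIR) -> np.ndarray:
    """Outermost skin voxels: skin-labelled with a 6-connected air neighbour."""
    values = labels.values
    is_skin = values == skin_code
    exposed = np.zeros_like(is_skin)
    for axis in range(3):
        for shift in (1, -1):
            neighbour = np.roll(values == air_code, shift, axis=axis)
            # roll wraps around; voxels at the volume border have no
            # neighbour on the far side, so mask the wrapped slice out.
            sl = [slice(None)] * 3
            sl[axis] = 0 if shift == 1 else -1
            neighbour[tuple(sl)] = False
            exposed |= neighbour
    idx = np.argwhere(is_skin & exposed)
    order = np.lexsort((idx[:, 0], idx[:, 1], idx[:, 2]))
    return idx[order]


def cast_ray(
    start_voxel, end_voxel, labels: Volume3D, step_fraction: float = 0.5
) -> tuple[list[tuple[int, float]], float]:
    """March a straight ray between two voxel centers by nearest-voxel steps.

    Returns the ordered tissue crossings as ``(label, entry depth mm)`` pairs
    (the first pair is the start label at depth 0) and the Euclidean length.
    Step size is at most ``step_fraction`` of the smallest voxel axis.
    """
    start_w = voxel_to_world(start_voxel, labels)
    end_w = voxel_to_world(end_voxel, labels)
    length = float(np.linalg.norm(end_w - start_w))
    step = step_fraction * min(labels.spacing)
    n = max(2, int(math.ceil(length / step)) + 1)
    depths = np.linspace(0.0, length, n)
    if length == 0:
        points = start_w[None, :]
        depths = depths[:1]
    else:
        direction = (end_w - start_w) / length
        points = start_w[None, :] + depths[:, None] * direction[None, :]
    labs = labels.values_at(points)
    crossings = [(int(labs[0]), 0.0)]
    change = np.flatnonzero(np.diff(labs) != 0) + 1
    for i in change:
        crossings.append((int(labs[i]), float(depths[i])))
    return crossings, length


def score_path(
    crossings: list[tuple[int, float]],
    length: float,
    cfg: PlannerConfig,
    *,
    risk_codes,
    target_codes,
    min_risk_dist_mm: float | None = None,
    n_target_voxels: int | None = None,
) -> PathScore:
    """Score one candidate path from its tissue crossings.

    ``min_risk_dist_mm`` (smallest shaft-to-risk clearance) and
    ``n_target_voxels`` (target voxels traversed) feed the soft criteria;
    when omitted they default to full clearance and zero penetration.
    """
    risk_codes = set(risk_codes)
    target_codes = set(target_codes)
    target_depth = None
    for code, depth in crossings:
        if code in target_codes:
            target_depth = depth
            break
    blocked = any(
        code in risk_codes and (target_depth is None or depth < target_depth)
        for code, depth in crossings
    )
    c1 = math.inf if (target_depth is None or blocked) else 0.0
    c2 = math.inf if length > cfg.max_length else 0.0
    if min_risk_dist_mm is None:
        c3 = 1.0
    else:
        c3 = float(np.clip(min_risk_dist_mm / cfg.d_cap_mm, 0.0, 1.0))
    n_hit = 0 if n_target_voxels is None else n_target_voxels
    c4 = float(np.clip(n_hit / cfg.n_cap, 0.0, 1.0))
    return PathScore(c1=c1, c2=c2, c3=c3, c4=c4)


def plan_all(model: PatientModel, cfg: PlannerConfig | None = None) -> list[PlannedPath]:
    """Best accepted path per skin voxel, to any target centerline voxel.

    Candidates are rays from each (strided) skin voxel to every centerline
    voxel of the target structure; the best finite-Q candidate per skin
    voxel survives if ``Q >= quality_threshold``. Ties are broken by the
    smallest (z, y, x) target voxel. Deterministic output ordering (skin
    voxels by (z, y, x)). Returns an empty list, with a warning, when no
    feasible path exists.
    """
    cfg = cfg or PlannerConfig()
    labels = model.labels
    values = labels.values
    table = model.table
    risk_codes = np.array(table.risk_codes(), dtype=values.dtype)
    target_codes = np.array(table.target_codes(), dtype=values.dtype)

    target_mask = np.isin(values, target_codes)
    if not target_mask.any():
        warnings.warn("no target structure in label volume; no paths planned")
        return []
    centerline = extract_centerline(
        Volume3D(target_mask.astype(np.uint8), labels.spacing, labels.origin)
    )
    targets_w = centerline.astype(float) * labels.spacing_arr + labels.origin_arr

    risk_mask = np.isin(values, risk_codes)
    risk_dist = (
        distance_transform_edt(~risk_mask, sampling=labels.spacing)
        if risk_mask.any()
        else None
    )

    skins = skin_voxels(labels)
    if cfg.skin_stride > 1:
        skins = skins[:: cfg.skin_stride]

    spacing = labels.spacing_arr
    origin = labels.origin_arr
    shape = np.asarray(labels.shape)
    step = cfg.step_fraction * float(min(labels.spacing))
    accepted: list[PlannedPath] = []

    for sv in skins:
        entry_w = sv.astype(float) * spacing + origin
        all_vecs = targets_w - entry_w[None, :]
        all_lengths = np.linalg.norm(all_vecs, axis=1)
        reach = (all_lengths > 0) & (all_lengths <= cfg.max_length)
        if not reach.any():
            continue
        cand = np.flatnonzero(reach)
        vecs, lengths = all_vecs[cand], all_lengths[cand]
        m = max(2, int(math.ceil(lengths.max() / step)) + 1)
        frac = np.linspace(0.0, 1.0, m)
        pts = entry_w[None, None, :] + frac[None, :, None] * vecs[:, None, :]
        ci = (pts - origin) / spacing
        idx = np.floor(ci + 0.5).astype(np.intp)
        np.clip(idx, 0, shape - 1, out=idx)
        ix, iy, iz = idx[..., 0], idx[..., 1], idx[..., 2]

        is_t = target_mask[ix, iy, iz]
        is_r = risk_mask[ix, iy, iz]
        has_t = is_t.any(axis=1)
        first_t = np.argmax(is_t, axis=1)
        before = np.arange(m)[None, :] < first_t[:, None]
        feasible = has_t & ~(is_r & before).any(axis=1)
        if not feasible.any():
            continue

        if risk_dist is None:
            c3 = np.ones(len(cand))
        else:
            d = risk_dist[ix, iy, iz]
            c3 = np.clip(d.min(axis=1) / cfg.d_cap_mm, 0.0, 1.0)
        # Distinct target voxels traversed: along a straight ray voxels are
        # visited consecutively, so count target samples whose voxel differs
        # from the previous sample's.
        lin = np.ravel_multi_index((ix, iy, iz), labels.shape)
        new_vox = np.ones_like(lin, dtype=bool)
        new_vox[:, 1:] = lin[:, 1:] != lin[:, :-1]
        n_hit = (is_t & new_vox).sum(axis=1)
        c4 = np.clip(n_hit / cfg.n_cap, 0.0, 1.0)

        q = np.where(feasible, 0.5 * (c3 + c4), -np.inf)
        best = int(np.argmax(q))  # first max -> smallest (z,y,x) target
        if q[best] < cfg.quality_threshold:
            continue
        tv = centerline[cand[best]]
        traj = Trajectory(
            entry=entry_w,
            direction=vecs[best] / lengths[best],
            length=float(lengths[best]),
            max_length=cfg.max_length,
        )
        accepted.append(
            PlannedPath(
                trajectory=traj,
                skin_voxel=tuple(int(v) for v in sv),
                target_voxel=tuple(int(v) for v in tv),
                score=PathScore(
                    c1=0.0, c2=0.0, c3=float(c3[best]), c4=float(c4[best])
                ),
            )
        )

    if not accepted:
        warnings.warn("no feasible path found; returning an empty path set")
    return accepted


def paths_to_csv(paths: list[PlannedPath], path, header_lines=None) -> None:
    """Accepted paths as CSV (entry mm, direction, length, C3, C4, Q)."""
    import pandas as pd

    rows = []
    for p in paths:
        t = p.trajectory
        rows.append(
            {
                "entry_x_mm": t.entry[0],
                "entry_y_mm": t.entry[1],
                "entry_z_mm": t.entry[2],
                "dir_x": t.direction[0],
                "dir_y": t.direction[1],
                "dir_z": t.direction[2],
                "length_mm": t.length,
                "target_i": p.target_voxel[0],
                "target_j": p.target_voxel[1],
                "target_k": p.target_voxel[2],
                "C3": p.score.c3,
                "C4": p.score.c4,
                "Q": p.score.q,
            }
        )
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)
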