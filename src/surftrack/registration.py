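"""Robust weighted point-to-plane ICP and the rough-to-fine multiscale wrapper.

The registration estimates the rigid transform ``T`` minimizing

    Cost(T) = sum over correspondences (p, q) of  w_pq * ((p - T q) . n_p)^2

where ``p`` and ``n_p`` are a target-surface point and its normal, ``q`` is
the corresponding reference-surface point and ``w_pq`` is an IRLS weight from
the generalized robust loss family of Barron (a single shape parameter
``alpha`` interpolating quadratic, pseudo-Huber, Cauchy and heavier-tailed
penalties; ``alpha = 2`` recovers the unweighted quadratic loss).

The multiscale wrapper runs ICP on a 5-level pyramid of voxel-downsampled
clouds, from 0.2 points/cm^2 up to 100 points/cm^2, chaining each level's
estimate into the next as its starting point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .cloud import (
    EmptyCloudError,
    SurfaceCloud,
    downsample,
    voxel_edge_mm,
)
from .transforms import RigidTransform

__all__ = [
    "RobustLossParams",
    "Correspondences",
    "RegistrationResult",
    "MultiscaleSchedule",
    "ReferencePyramid",
    "NoCorrespondencesError",
    "DegenerateGeometryError",
    "barron_weight",
    "find_correspondences",
    "solve_increment",
    "solve_point_to_plane",
    "icp",
    "multiscale_register",
    "default_schedule",
]

log = logging.getLogger(__name__)

DEFAULT_DENSITIES = tuple(float(d) for d in np.geomspace(0.2, 100.0, 5))


class NoCorrespondencesError(RuntimeError):
    """No target point found a reference neighbor within the gating distance."""


class DegenerateGeometryError(RuntimeError):
    """The normal equations are rank-deficient (e.g. all normals parallel)."""


@dataclass(frozen=True)
class RobustLossParams:
    """Barron loss parameters: shape ``alpha`` and scale ``c`` (mm, > 0)."""

    alpha: float = 1.0
    c: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha):
            raise ValueError("alpha must be finite")
        if self.c <= 0:
            raise ValueError("scale c must be positive")


def barron_weight(residual, params: RobustLossParams):
    """IRLS weight of Barron's general loss, normalized so weight(0) = 1.

    ``w(r) = ((r/c)^2 / |alpha - 2| + 1) ** (alpha/2 - 1)`` for alpha != 2;
    the quadratic limit alpha = 2 gives ``w = 1`` exactly.  For alpha < 2 the
    weight is monotone non-increasing in |r|, which is what makes mismatched
    or deforming surface patches lose influence.
    """
    r = np.asarray(residual, dtype=float)
    a, c = params.alpha, params.c
    if a == 2.0:
        return np.ones_like(r) if r.ndim else 1.0
    w = ((r / c) ** 2 / abs(a - 2.0) + 1.0) ** (a / 2.0 - 1.0)
    return w if r.ndim else float(w)


@dataclass
class Correspondences:
    """Matched pairs: target points/normals, reference points, residuals, weights.

    The residual is the signed plane distance ``(p - T q) . n_p`` for the
    iterate ``T`` current when the set was built.
    """

    p: np.ndarray        # (M, 3) target points
    n_p: np.ndarray      # (M, 3) target unit normals
    q: np.ndarray        # (M, 3) reference points (untransformed)
    residual: np.ndarray  # (M,) mm
    weight: np.ndarray    # (M,) in (0, 1]

    def __len__(self) -> int:
        return len(self.p)

    def cost(self, t: RigidTransform, weight: np.ndarray | None = None) -> float:
        """Weighted point-to-plane cost at ``t`` on this fixed set (mm^2)."""
        w = self.weight if weight is None else weight
        r = np.einsum("ij,ij->i", self.p - t.apply(self.q), self.n_p)
        return float(np.sum(w * r * r))


@dataclass
class RegistrationResult:
    transform: RigidTransform
    final_cost: float
    iterations_used: list[int] = field(default_factory=list)
    correspondence_count: list[int] = field(default_factory=list)
    converged: bool = False


@dataclass(frozen=True)
class MultiscaleSchedule:
    """Ordered (density pts/cm^2, max correspondence distance mm, max iters)."""

    levels: tuple[tuple[float, float, int], ...]

    def __post_init__(self) -> None:
        d = [lv[0] for lv in self.levels]
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("level densities must be strictly increasing")


def default_schedule(max_iter: int = 30) -> MultiscaleSchedule:
    """Five levels log-spaced from 0.2 to 100 points/cm^2.

    The correspondence gate is 4 voxel edges per level, so coarse levels
    tolerate a large initial error while fine levels reject spurious pairs.
    """
    levels = tuple(
        (d, 4.0 * voxel_edge_mm(d), max_iter) for d in DEFAULT_DENSITIES
    )
    return MultiscaleSchedule(levels)


def default_loss_for_density(density: float, alpha: float = 1.0) -> RobustLossParams:
    """Scale tied to resolution: c = max(2 voxel edges, 1 mm)."""
    return RobustLossParams(alpha=alpha, c=max(2.0 * voxel_edge_mm(density), 1.0))


def find_correspondences(
    target: SurfaceCloud,
    reference: SurfaceCloud,
    t: RigidTransform,
    max_dist: float,
    loss: RobustLossParams | None = None,
    reference_tree: cKDTree | None = None,
) -> Correspondences:
    """Nearest-neighbor pairing of target points to the transformed reference.

    For each valid target point ``p`` the nearest ``T q`` within ``max_dist``
    is found via a KD-tree; since rigid maps preserve distances the query runs
    as ``T^-1 p`` against a tree over the *untransformed* reference, letting
    callers reuse one tree across iterations and frames.  Pairs beyond
    ``max_dist`` are rejected; the result may be empty (the ICP loop treats
    an empty set as an error with level context).
    """
    if len(target) == 0 or len(reference) == 0:
        raise EmptyCloudError("cannot match empty clouds")
    if target.normals is None:
        raise ValueError("target cloud must carry normals (point-to-plane)")
    loss = loss or RobustLossParams()

    tmask = target.valid
    p = target.points[tmask]
    n_p = target.normals[tmask]
    if len(p) == 0:
        empty = np.zeros((0, 3))
        return Correspondences(empty, empty, empty, np.zeros(0), np.zeros(0))

    tree = reference_tree if reference_tree is not None else cKDTree(reference.points)
    back = t.inverse().apply(p)
    dist, idx = tree.query(back, distance_upper_bound=max_dist)
    ok = np.isfinite(dist)
    p, n_p = p[ok], n_p[ok]
    q = reference.points[idx[ok]]
    residual = np.einsum("ij,ij->i", p - t.apply(q), n_p)
    weight = barron_weight(residual, loss)
    return Correspondences(p, n_p, q, residual, weight)


def _increment_from_params(omega: np.ndarray, trans: np.ndarray,
                           pivot: np.ndarray) -> RigidTransform:
    """Rigid map rotating by ``omega`` (rotvec) about ``pivot`` then shifting."""
    R = Rotation.from_rotvec(omega).as_matrix()
    return RigidTransform(R, pivot + trans - R @ pivot)


def solve_increment(corr: Correspondences,
                    t: RigidTransform | None = None) -> RigidTransform:
    """One damped Gauss-Newton step of the weighted point-to-plane problem.

    Solves the 6x6 normal equations of the small-angle linearization around
    the current iterate and returns the incremental transform (to be composed
    on the left of the current estimate).  A halving line search on the same
    correspondence set, with weights held fixed, guarantees the returned
    increment does not increase the weighted cost.
    """
    if len(corr) < 6:
        raise DegenerateGeometryError(
            f"need at least 6 correspondences, have {len(corr)}")
    t = t or RigidTransform.identity()

    q_t = t.apply(corr.q)
    pivot = q_t.mean(axis=0)
    lever = np.cross(q_t - pivot, corr.n_p)   # d residual / d omega (negated)
    A = np.hstack([lever, corr.n_p])          # (M, 6)
    r = np.einsum("ij,ij->i", corr.p - q_t, corr.n_p)
    w = corr.weight

    H = A.T @ (A * w[:, None])
    g = A.T @ (w * r)
    evals = np.linalg.eigvalsh(H)
    if evals[0] <= 1e-12 * max(evals[-1], np.finfo(float).tiny):
        raise DegenerateGeometryError(
            "rank-deficient point-to-plane system (normals do not span 3-D)")
    x = np.linalg.solve(H, g)
    omega, trans = x[:3], x[3:]

    cost0 = float(np.sum(w * r * r))
    step = 1.0
    for _ in range(25):
        inc = _increment_from_params(step * omega, step * trans, pivot)
        if corr.cost(inc @ t) <= cost0 + 1e-15:
            return inc
        step *= 0.5
    return RigidTransform.identity()


def solve_point_to_plane(corr: Correspondences, max_iter: int = 50,
                         tol: float = 1e-12) -> tuple[RigidTransform, float]:
    """Minimize the point-to-plane cost on a FIXED correspondence set.

    Iterates :func:`solve_increment` (weights fixed) to convergence; used for
    diagnostics and as the single-level solver the tests compare against a
    direct 6-parameter nonlinear minimizer.
    """
    t = RigidTransform.identity()
    for _ in range(max_iter):
        inc = solve_increment(corr, t)
        t = (inc @ t).orthonormalized()
        if inc.translation_norm() < tol and np.radians(inc.rotation_angle_deg()) < tol:
            break
    return t, corr.cost(t)


def icp(
    target: SurfaceCloud,
    reference: SurfaceCloud,
    init: RigidTransform | None = None,
    loss: RobustLossParams | None = None,
    max_dist: float = 10.0,
    max_iter: int = 30,
    tol_mm: float = 0.01,
    tol_deg: float = 0.01,
    reference_tree: cKDTree | None = None,
) -> RegistrationResult:
    """Robust point-to-plane ICP from ``init``.

    Alternates correspondence search, IRLS reweighting and a Gauss-Newton
    increment; stops when the increment falls below ``tol_mm`` / ``tol_deg``
    or after ``max_iter`` sweeps.
    """
    t = init or RigidTransform.identity()
    loss = loss or RobustLossParams()
    if reference_tree is None:
        reference_tree = cKDTree(reference.points)

    converged = False
    iters = 0
    corr = None
    for iters in range(1, max_iter + 1):
        corr = find_correspondences(target, reference, t, max_dist, loss,
                                    reference_tree)
        if len(corr) == 0:
            raise NoCorrespondencesError(
                f"no correspondences within max_dist={max_dist:g} mm")
        inc = solve_increment(corr, t)
        t = (inc @ t).orthonormalized()
        if inc.translation_norm() < tol_mm and inc.rotation_angle_deg() < tol_deg:
            converged = True
            break

    final = find_correspondences(target, reference, t, max_dist, loss,
                                 reference_tree)
    return RegistrationResult(
        transform=t,
        final_cost=final.cost(t),
        iterations_used=[iters],
        correspondence_count=[len(final)],
        converged=converged,
    )


class ReferencePyramid:
    """Reference cloud downsampled to each schedule density, with KD-trees.

    Building this once per session makes sequential tracking cheap: the trees
    never change because correspondence queries run in the reference frame.
    """

    def __init__(self, reference: SurfaceCloud, schedule: MultiscaleSchedule):
        self.schedule = schedule
        self.clouds: list[SurfaceCloud] = []
        self.trees: list[cKDTree] = []
        for density, _, _ in schedule.levels:
            c = downsample(reference, density)
            self.clouds.append(c)
            self.trees.append(cKDTree(c.points))


def multiscale_register(
    target: SurfaceCloud,
    reference: SurfaceCloud | ReferencePyramid,
    init: RigidTransform | None = None,
    schedule: MultiscaleSchedule | None = None,
    loss_alpha: float = 1.0,
    tol_mm: float = 0.01,
    tol_deg: float = 0.01,
) -> RegistrationResult:
    """Rough-to-fine registration over the downsampling pyramid.

    Each level runs :func:`icp` on both clouds downsampled to the level's
    density, warm-started from the previous level's estimate.  Target normals
    are computed once at full resolution and carried through the voxel
    averaging, avoiding coarse-level normal bias.  The loss scale per level is
    ``max(2 voxel edges, 1 mm)``.
    """
    schedule = schedule or default_schedule()
    if isinstance(reference, ReferencePyramid):
        pyramid = reference
        if pyramid.schedule.levels != schedule.levels:
            raise ValueError("reference pyramid was built for a different schedule")
    else:
        pyramid = ReferencePyramid(reference, schedule)

    if target.normals is None:
        raise ValueError("target cloud must carry normals (point-to-plane)")

    t = init or RigidTransform.identity()
    result = RegistrationResult(t, np.inf)
    # Build the target pyramid fine-to-coarse: the finest level reduces the
    # full cloud once, and each coarser level reduces the previous output
    # (voxel centroids nest well enough and the repeated reduction is cheap).
    densities = [lv[0] for lv in schedule.levels]
    pyr_tgt: list[SurfaceCloud] = [None] * len(densities)
    cur = target
    for li in range(len(densities) - 1, -1, -1):
        cur = downsample(cur, densities[li])
        pyr_tgt[li] = cur

    for li, (density, max_dist, max_iter) in enumerate(schedule.levels):
        tgt = pyr_tgt[li]
        loss = default_loss_for_density(density, alpha=loss_alpha)
        try:
            res = icp(tgt, pyramid.clouds[li], init=t, loss=loss,
                      max_dist=max_dist, max_iter=max_iter,
                      tol_mm=tol_mm, tol_deg=tol_deg,
                      reference_tree=pyramid.trees[li])
        except (NoCorrespondencesError, DegenerateGeometryError) as exc:
            raise type(exc)(
                f"level {li} (density {density:g} pts/cm^2, "
                f"max_dist {max_dist:g} mm): {exc}") from exc
        t = res.transform
        result.transform = t
        result.final_cost = res.final_cost
        result.iterations_used.extend(res.iterations_used)
        result.correspondence_count.extend(res.correspondence_count)
        result.converged = res.converged
        log.debug(
            "level %d: density=%g corr=%d iters=%d cost=%.4g",
            li, density, res.correspondence_count[0],
            res.iterations_used[0], res.final_cost,
        )
    return result
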