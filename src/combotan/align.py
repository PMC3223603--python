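"""Rigid-body superposition of conformer pairs.

Two optimizations are provided: shape-optimized (maximize the atom
Gaussian overlap V_AB) and color-optimized (maximize the type-matched
feature overlap).  Each runs a deterministic multi-start local search:
both conformers are moved to their inertial (principal-axes) frames, the
four proper axis-flip relative poses seed an L-BFGS refinement over the 6
rigid degrees of freedom with analytic gradients, and the best final pose
wins (ties resolved by the other channel's overlap, then by the
lexicographically smaller rotation quaternion).

All six similarity measures (ST, CT, ComboT at either optimal pose) are
assembled per pair into a SimilarityRecord.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.optimize import minimize

from ._kernels import kappa_from_radius
from .color import color_overlap, color_tanimoto_at, combo_tanimoto
from .config import DEFAULT_CONFIG, ScoringConfig
from .molecules import FEATURE_TYPES, Conformer
from .shape import pair_overlap, shape_tanimoto
from .transforms import RigidTransform

__all__ = [
    "RigidTransform",
    "SimilarityRecord",
    "MEASURES",
    "principal_pose",
    "optimize_shape",
    "optimize_color",
    "score_pair",
    "score_matrix",
    "pair_count",
]

#: the six similarity measures, in canonical column order
MEASURES = ("st_stopt", "ct_stopt", "combo_stopt", "st_ctopt", "ct_ctopt", "combo_ctopt")

_FLIPS = (
    np.eye(3),
    np.diag([1.0, -1.0, -1.0]),   # pi about x
    np.diag([-1.0, 1.0, -1.0]),   # pi about y
    np.diag([-1.0, -1.0, 1.0]),   # pi about z
)


@dataclass(frozen=True)
class SimilarityRecord:
    """The six scores and the two optimal poses for one conformer pair."""

    cid_a: int
    cid_b: int
    st_stopt: float
    ct_stopt: float
    combo_stopt: float
    st_ctopt: float
    ct_ctopt: float
    combo_ctopt: float
    transform_stopt: RigidTransform
    transform_ctopt: RigidTransform
    converged: bool = True

    def score(self, measure: str) -> float:
        if measure not in MEASURES:
            raise KeyError(f"unknown measure {measure!r}")
        return getattr(self, measure)


@dataclass(frozen=True)
class OptimizeResult:
    """Outcome of one superposition optimization."""

    transform: RigidTransform
    st: float
    ct: float
    combo: float
    converged: bool


def _density_moment(conf: Conformer, config: ScoringConfig):
    """Density centroid and second-moment matrix used for inertial poses."""
    pos = conf.coords()
    radii = conf.radii()
    kappas = np.atleast_1d(kappa_from_radius(radii, config.amplitude))
    weights = 4.0 / 3.0 * np.pi * radii**3
    centroid = (weights[:, None] * pos).sum(axis=0) / weights.sum()
    d = pos - centroid
    m = np.einsum("i,ij,ik->jk", weights, d, d)
    m += np.diag(np.full(3, float(np.sum(weights / (2.0 * kappas)))))
    return centroid, m


def principal_pose(conf: Conformer, config: ScoringConfig = DEFAULT_CONFIG.scoring) -> RigidTransform:
    """Transform moving the density centroid to the origin and the principal
    axes onto x, y, z in descending variance order.

    Deterministic sign convention: each principal axis is oriented so its
    largest-magnitude component is positive; the third axis is then flipped
    if needed to keep the rotation proper.  A spherically symmetric
    conformer (e.g. a single atom) maps to the identity rotation.
    """
    centroid, m = _density_moment(conf, config)
    evals, evecs = np.linalg.eigh(m)
    # stable sort keeps eigh's ordering for degenerate (tied) eigenvalues
    order = np.argsort(-evals, kind="stable")
    axes = evecs[:, order]
    for k in range(3):
        col = axes[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            axes[:, k] = -col
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    rotation = axes.T
    return RigidTransform(rotation, -rotation @ centroid)


def _skew(w: np.ndarray) -> np.ndarray:
    return np.array(
        [[0.0, -w[2], w[1]], [w[2], 0.0, -w[0]], [-w[1], w[0], 0.0]]
    )


def _right_jacobian(w: np.ndarray) -> np.ndarray:
    """Right Jacobian of SO(3) at rotation vector w (series form near 0)."""
    theta = float(np.linalg.norm(w))
    big_w = _skew(w)
    if theta < 1e-8:
        return np.eye(3) - 0.5 * big_w + big_w @ big_w / 6.0
    a = (1.0 - np.cos(theta)) / theta**2
    b = (theta - np.sin(theta)) / theta**3
    return np.eye(3) - a * big_w + b * (big_w @ big_w)


def _rodrigues(w: np.ndarray) -> np.ndarray:
    """Rotation matrix of a rotation vector (hand-rolled for speed)."""
    theta2 = float(w @ w)
    k = _skew(w)
    if theta2 < 1e-20:
        return np.eye(3) + k + 0.5 * (k @ k)
    theta = np.sqrt(theta2)
    return np.eye(3) + (np.sin(theta) / theta) * k + ((1.0 - np.cos(theta)) / theta2) * (k @ k)


class _RigidObjective:
    """Negative Gaussian overlap between fixed point blocks of A and moving
    blocks of B, as a function of a 6-vector (rotation vector, translation)
    relative to a start pose.  Rotation is taken about the centroid of B's
    start-transformed points, which decouples the two parameter triples.

    Blocks are fused into single point arrays with the pair prefactors of
    cross-block (cross-type) pairs zeroed, so each evaluation is one
    vectorized pass.
    """

    def __init__(
        self,
        blocks_a: Sequence[tuple[np.ndarray, np.ndarray]],
        blocks_b: Sequence[tuple[np.ndarray, np.ndarray]],
        config: ScoringConfig,
    ):
        self.config = config
        self.pos_a = np.vstack([p for p, _ in blocks_a]) if blocks_a else np.zeros((0, 3))
        self.pos_b = np.vstack([p for p, _ in blocks_b]) if blocks_b else np.zeros((0, 3))
        kap_a = np.concatenate([k for _, k in blocks_a]) if blocks_a else np.zeros(0)
        kap_b = np.concatenate([k for _, k in blocks_b]) if blocks_b else np.zeros(0)
        ksum = kap_a[:, None] + kap_b[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            self.gamma = np.where(ksum > 0, kap_a[:, None] * kap_b[None, :] / ksum, 1.0)
            self.coeff = config.amplitude**2 * np.where(ksum > 0, (np.pi / ksum) ** 1.5, 0.0)
        # zero out cross-block pairs
        if len(blocks_a) > 1:
            mask = np.zeros_like(self.coeff, dtype=bool)
            ia = 0
            ib = 0
            for (pa, _), (pb, _) in zip(blocks_a, blocks_b):
                mask[ia : ia + len(pa), ib : ib + len(pb)] = True
                ia += len(pa)
                ib += len(pb)
            self.coeff = np.where(mask, self.coeff, 0.0)

    def set_start(self, start: RigidTransform) -> None:
        self.start = start
        moved = start.apply(self.pos_b) if len(self.pos_b) else self.pos_b
        self.center = moved.mean(axis=0) if len(moved) else np.zeros(3)
        self.u = moved - self.center

    def value_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        w, tau = x[:3], x[3:]
        q = _rodrigues(w)
        if len(self.pos_a) == 0 or len(self.u) == 0:
            return 0.0, np.zeros(6)
        y = self.u @ q.T + (self.center + tau)
        diff = self.pos_a[:, None, :] - y[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        e = self.coeff * np.exp(-self.gamma * d2)
        value = float(e.sum())
        weight = 2.0 * self.gamma * e
        g = np.einsum("ij,ijk->jk", weight, diff)   # dV/dy_j
        d_tau = g.sum(axis=0)
        h = g @ q                                    # Q^T g_j, row-wise
        u = self.u
        torque = np.array(
            [
                np.dot(u[:, 1], h[:, 2]) - np.dot(u[:, 2], h[:, 1]),
                np.dot(u[:, 2], h[:, 0]) - np.dot(u[:, 0], h[:, 2]),
                np.dot(u[:, 0], h[:, 1]) - np.dot(u[:, 1], h[:, 0]),
            ]
        )
        d_w = _right_jacobian(w).T @ torque
        return -value, -np.concatenate([d_w, d_tau])

    def transform_at(self, x: np.ndarray) -> RigidTransform:
        w, tau = x[:3], x[3:]
        q = _rodrigues(w)
        rot = q @ self.start.rotation
        trans = q @ self.start.translation + self.center + tau - q @ self.center
        return RigidTransform(rot, trans)


@dataclass(frozen=True)
class _Candidate:
    value: float
    transform: RigidTransform
    converged: bool


def _local_optimize(obj: _RigidObjective, start: RigidTransform, config: ScoringConfig) -> _Candidate:
    obj.set_start(start)
    res = minimize(
        obj.value_and_grad,
        np.zeros(6),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": config.max_iterations, "ftol": config.ftol, "gtol": config.gtol},
    )
    return _Candidate(value=-float(res.fun), transform=obj.transform_at(res.x), converged=bool(res.success))


def _select(candidates: Sequence[_Candidate], secondary=None) -> _Candidate:
    """Best objective wins; ties are resolved by the secondary overlap (the
    other channel's objective at the candidate pose, which settles
    degenerate optima such as a single shared feature point), then by the
    lexicographically smaller quaternion."""
    best = max(c.value for c in candidates)
    tol = 1e-9 * max(1.0, abs(best))
    tied = [c for c in candidates if c.value >= best - tol]
    if secondary is not None and len(tied) > 1:
        scored = [(secondary(c.transform), c) for c in tied]
        best2 = max(s for s, _ in scored)
        tol2 = 1e-9 * max(1.0, abs(best2))
        tied = [c for s, c in scored if s >= best2 - tol2]
    return min(tied, key=lambda c: tuple(c.transform.quaternion()))



def _shape_overlap_at(conf_a: Conformer, conf_b: Conformer, config: ScoringConfig):
    return lambda t: pair_overlap(conf_a, conf_b, t, config)


def _color_overlap_at(conf_a: Conformer, conf_b: Conformer, config: ScoringConfig):
    return lambda t: sum(color_overlap(conf_a, conf_b, t, config).v_ab.values())


def _shape_blocks(conf: Conformer, config: ScoringConfig):
    kap = np.atleast_1d(kappa_from_radius(conf.radii(), config.amplitude))
    return [(conf.coords(), kap)]


def _color_blocks(conf_a: Conformer, conf_b: Conformer, config: ScoringConfig):
    kappa = kappa_from_radius(config.color_radius, config.amplitude)
    blocks_a, blocks_b, shared = [], [], []
    for ftype in FEATURE_TYPES:
        pa = conf_a.feature_coords(ftype)
        pb = conf_b.feature_coords(ftype)
        if len(pa) and len(pb):
            blocks_a.append((pa, np.full(len(pa), kappa)))
            blocks_b.append((pb, np.full(len(pb), kappa)))
            shared.append(ftype)
    return blocks_a, blocks_b, shared


def _base_starts(conf_a: Conformer, conf_b: Conformer, config: ScoringConfig) -> list[RigidTransform]:
    """Four proper axis-flip relative poses in the joint principal frame."""
    pa = principal_pose(conf_a, config)
    pb = principal_pose(conf_b, config)
    pa_inv = pa.inverse()
    return [pa_inv.compose(RigidTransform(f, np.zeros(3))).compose(pb) for f in _FLIPS]


def _color_centroid_starts(
    conf_a: Conformer, conf_b: Conformer, base: RigidTransform, shared: Sequence[str]
) -> list[RigidTransform]:
    """One translation-adjusted start per shared feature type, aligning that
    type's centroids at the base pose."""
    starts = []
    for ftype in shared:
        ca = conf_a.feature_coords(ftype).mean(axis=0)
        cb = base.apply(conf_b.feature_coords(ftype)).mean(axis=0)
        starts.append(RigidTransform(base.rotation, base.translation + (ca - cb)))
    return starts


def _evaluate(conf_a: Conformer, conf_b: Conformer, cand: _Candidate, config: ScoringConfig) -> OptimizeResult:
    st = shape_tanimoto(conf_a, conf_b, cand.transform, config)
    ct = color_tanimoto_at(conf_a, conf_b, cand.transform, config)
    return OptimizeResult(
        transform=cand.transform, st=st, ct=ct, combo=combo_tanimoto(st, ct), converged=cand.converged
    )


def optimize_shape(
    conf_a: Conformer,
    conf_b: Conformer,
    config: ScoringConfig = DEFAULT_CONFIG.scoring,
    extra_starts: Iterable[RigidTransform] = (),
) -> OptimizeResult:
    """Shape-optimized superposition; CT is evaluated at the ST-optimal pose."""
    obj = _RigidObjective(_shape_blocks(conf_a, config), _shape_blocks(conf_b, config), config)
    starts = _base_starts(conf_a, conf_b, config) + list(extra_starts)
    cands = [_local_optimize(obj, s, config) for s in starts]
    best = _select(cands, secondary=_color_overlap_at(conf_a, conf_b, config))
    return _evaluate(conf_a, conf_b, best, config)


def optimize_color(
    conf_a: Conformer,
    conf_b: Conformer,
    config: ScoringConfig = DEFAULT_CONFIG.scoring,
    extra_starts: Iterable[RigidTransform] = (),
) -> OptimizeResult:
    """Color-optimized superposition; ST is evaluated at the CT-optimal pose.

    When either conformer has no features (or no shared feature type gives
    any color signal), the shape-optimized pose is returned with CT = 0.
    """
    blocks_a, blocks_b, shared = _color_blocks(conf_a, conf_b, config)
    base = _base_starts(conf_a, conf_b, config)
    if not blocks_a:
        res = optimize_shape(conf_a, conf_b, config, extra_starts)
        return OptimizeResult(res.transform, res.st, 0.0, res.st, res.converged)
    obj = _RigidObjective(blocks_a, blocks_b, config)
    starts = base + _color_centroid_starts(conf_a, conf_b, base[0], shared) + list(extra_starts)
    cands = [_local_optimize(obj, s, config) for s in starts]
    best = _select(cands, secondary=_shape_overlap_at(conf_a, conf_b, config))
    return _evaluate(conf_a, conf_b, best, config)


def score_pair(
    conf_a: Conformer,
    conf_b: Conformer,
    config: ScoringConfig = DEFAULT_CONFIG.scoring,
) -> SimilarityRecord:
    """All six similarity measures for one pair of distinct compounds.

    The two optimizers cross-seed each other's final poses (iterated to a
    fixed point), which makes the argmax inequalities st_stopt >= st_ctopt
    and ct_ctopt >= ct_stopt hold by construction rather than only
    statistically.  Output is symmetric in the input order; the record is
    stored with cid_a < cid_b.
    """
    if conf_a.cid == conf_b.cid:
        raise ValueError(f"self-pair: cid {conf_a.cid}")
    if conf_a.cid > conf_b.cid:
        conf_a, conf_b = conf_b, conf_a

    shape_obj = _RigidObjective(_shape_blocks(conf_a, config), _shape_blocks(conf_b, config), config)
    base = _base_starts(conf_a, conf_b, config)
    color_secondary = _color_overlap_at(conf_a, conf_b, config)
    shape_secondary = _shape_overlap_at(conf_a, conf_b, config)
    shape_cands = [_local_optimize(shape_obj, s, config) for s in base]
    best_shape = _select(shape_cands, secondary=color_secondary)

    blocks_a, blocks_b, shared = _color_blocks(conf_a, conf_b, config)
    has_color = bool(blocks_a)
    if has_color:
        color_obj = _RigidObjective(blocks_a, blocks_b, config)
        color_starts = base + _color_centroid_starts(conf_a, conf_b, base[0], shared)
        color_cands = [_local_optimize(color_obj, s, config) for s in color_starts]
        # cross-seed to a fixed point so neither optimum can sit strictly
        # above the other's evaluation pose
        seeded_color: set[int] = set()
        seeded_shape: set[int] = set()
        for _ in range(5):
            changed = False
            if id(best_shape) not in seeded_color:
                seeded_color.add(id(best_shape))
                color_cands.append(_local_optimize(color_obj, best_shape.transform, config))
                changed = True
            best_color = _select(color_cands, secondary=shape_secondary)
            if id(best_color) not in seeded_shape:
                seeded_shape.add(id(best_color))
                shape_cands.append(_local_optimize(shape_obj, best_color.transform, config))
                changed = True
            new_best_shape = _select(shape_cands, secondary=color_secondary)
            if not changed and new_best_shape is best_shape:
                break
            best_shape = new_best_shape
        best_color = _select(color_cands, secondary=shape_secondary)
    else:
        best_color = best_shape

    s_res = _evaluate(conf_a, conf_b, best_shape, config)
    c_res = _evaluate(conf_a, conf_b, best_color, config)
    ct_ctopt = c_res.ct if has_color else 0.0
    return SimilarityRecord(
        cid_a=conf_a.cid,
        cid_b=conf_b.cid,
        st_stopt=s_res.st,
        ct_stopt=s_res.ct,
        combo_stopt=combo_tanimoto(s_res.st, s_res.ct),
        st_ctopt=c_res.st,
        ct_ctopt=ct_ctopt,
        combo_ctopt=combo_tanimoto(c_res.st, ct_ctopt),
        transform_stopt=s_res.transform,
        transform_ctopt=c_res.transform,
        converged=s_res.converged and c_res.converged,
    )


def pair_count(n: int) -> int:
    """Number of unordered pairs among n compounds."""
    return n * (n - 1) // 2


def score_matrix(
    conformers: Sequence[Conformer],
    pairs: Iterable[tuple[int, int]] | None = None,
    config: ScoringConfig = DEFAULT_CONFIG.scoring,
) -> Iterator[SimilarityRecord]:
    """Stream SimilarityRecords for the requested cid pairs (default: all
    unordered pairs, each exactly once)."""
    by_cid: dict[int, Conformer] = {}
    for conf in conformers:
        if conf.cid in by_cid:
            raise ValueError(f"duplicate cid {conf.cid}")
        by_cid[conf.cid] = conf
    if pairs is None:
        cids = sorted(by_cid)
        pairs = ((a, b) for i, a in enumerate(cids) for b in cids[i + 1 :])
    for ca, cb in pairs:
        yield score_pair(by_cid[ca], by_cid[cb], config)
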