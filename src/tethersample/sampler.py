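"""Monte Carlo growth of tethered-chain conformations.

Each conformation is grown domain by domain from the tether outward.
The first domain's direction comes from a hemisphere polar draw (uniform
on the half-sphere above the tile) with a uniform azimuth about +z.
Every subsequent direction deviates from the previous one by a sampled
joint angle phi, with the azimuth about the previous direction uniform:
the new direction is picked uniformly on the rim of the cone of
half-angle phi around the previous unit vector v.  Concretely, the rim
is the circle with centre c = v (1 + cos phi) and radius sin phi in the
plane spanned by an orthonormal pair (a, b) perpendicular to v; a point
p(theta) on that circle yields the next unit direction u = p - v, which
satisfies u . v = cos phi exactly.

Joint coordinates are reconstructed as tether + cumulative sum of
(length_k * u_k).  Whole conformations with any post-tether joint at
z <= z_floor are rejected and regrown ("rejection sampling"); the tether
itself lies on the tile plane and is exempt.

``sample_ensemble`` grows conformations in vectorized batches, which is
how ensembles of 1e5-1e6 structures stay cheap; ``grow_structure`` is
the scalar reference path for single draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import biophysics as bp
from .biophysics import JointKind, ModelConfig
from .errors import SamplingError
from .structures import SampledStructure, StructureSpec, prepare

__all__ = [
    "ConeFrame",
    "SamplingReport",
    "EnsembleResult",
    "orthonormal_frame",
    "next_direction",
    "grow_structure",
    "sample_ensemble",
    "DEFAULT_REJECTION_CAP",
]

#: Consecutive whole-structure rejections tolerated before aborting.
DEFAULT_REJECTION_CAP = 10_000

_UNIT_TOL = 1e-9


def orthonormal_frame(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to each other and to the unit vector ``v``.

    Picks a non-zero component v_i of v (the largest in magnitude, for
    stability), sets the other two components of ``a`` to 1, solves
    a_i = (-a_j v_j - a_k v_k) / v_i so that a . v = 0, normalizes, and
    takes ``b`` as the normalized cross product a x v.
    """
    v = np.asarray(v, dtype=float)
    norm = float(np.linalg.norm(v))
    if norm == 0.0:
        raise ValueError("cannot build a frame around the zero vector")
    if abs(norm - 1.0) > _UNIT_TOL:
        raise ValueError(f"v must be a unit vector (|v| = {norm!r})")
    i = int(np.argmax(np.abs(v)))
    a = np.ones(3)
    a[i] = -(v.sum() - v[i]) / v[i]
    a /= np.linalg.norm(a)
    b = np.cross(a, v)
    b /= np.linalg.norm(b)
    return a, b


@dataclass(frozen=True)
class ConeFrame:
    """Parametric circle of directions deviating by ``phi`` from ``v``.

    The circle is the rim of the cone of half-angle phi about the unit
    vector v (placed at the origin): centre ``c = v (1 + cos phi)``,
    radius ``r_circ = sin phi``, in-plane orthonormal axes ``a`` and
    ``b``.  ``point(theta)`` evaluates the parametric equation; the
    next direction is point(theta) - v.
    """

    v: np.ndarray
    phi: float
    c: np.ndarray = field(init=False)
    a: np.ndarray = field(init=False)
    b: np.ndarray = field(init=False)
    r_circ: float = field(init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.v, dtype=float)
        a, b = orthonormal_frame(v)
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "c", v * (1.0 + np.cos(self.phi)))
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "r_circ", float(np.sin(self.phi)))

    def point(self, theta: float) -> np.ndarray:
        return self.c + self.a * (self.r_circ * np.cos(theta)) + self.b * (
            self.r_circ * np.sin(theta)
        )


def next_direction(v: np.ndarray, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Unit direction deviating from ``v`` by exactly ``phi``, uniform in azimuth."""
    frame = ConeFrame(v=v, phi=float(phi))
    theta = rng.uniform(0.0, 2.0 * np.pi)
    u = frame.point(theta) - frame.v
    return u / np.linalg.norm(u)


@dataclass
class SamplingReport:
    """Acceptance bookkeeping for one ensemble."""

    n_requested: int = 0
    n_rejected: int = 0

    @property
    def discard_ratio(self) -> float:
        """Rejected conformations per accepted one."""
        if self.n_requested == 0:
            return 0.0
        return self.n_rejected / self.n_requested


# --- vectorized internals -------------------------------------------------


def _orthonormal_frames(V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise orthonormal frames for an (m, 3) array of unit vectors."""
    m = V.shape[0]
    rows = np.arange(m)
    i = np.argmax(np.abs(V), axis=1)
    vi = V[rows, i]
    A = np.ones_like(V)
    A[rows, i] = -(V.sum(axis=1) - vi) / vi
    A /= np.linalg.norm(A, axis=1, keepdims=True)
    B = np.cross(A, V)
    B /= np.linalg.norm(B, axis=1, keepdims=True)
    return A, B


def _next_directions(V: np.ndarray, phi: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Row-wise cone construction: directions deviating from V by phi."""
    A, B = _orthonormal_frames(V)
    cos_phi = np.cos(phi)[:, None]
    r = np.sin(phi)[:, None]
    C = V * (1.0 + cos_phi)
    P = C + A * (r * np.cos(theta)[:, None]) + B * (r * np.sin(theta)[:, None])
    U = P - V
    U /= np.linalg.norm(U, axis=1, keepdims=True)
    return U


def _sample_lengths(
    spec: StructureSpec, config: ModelConfig, rng: np.random.Generator, m: int
) -> np.ndarray:
    """(m, n_domains) array of domain lengths for ``m`` conformations."""
    cols = []
    for d in spec.domains:
        if d.kind == "ds":
            cols.append(np.full(m, bp.sample_ds_length(d.n_nt, config.constants)))
        elif config.ss_length_model is bp.SsLengthModel.UNIFORM:
            cols.append(bp.sample_ss_length_uniform(d.n_nt, config.constants, rng, size=m))
        else:
            cols.append(bp.sample_ss_length_wlc(d.n_nt, config.constants, rng, size=m))
    return np.column_stack(cols)


def _grow_batch(
    spec: StructureSpec, config: ModelConfig, rng: np.random.Generator, m: int
) -> np.ndarray:
    """Grow ``m`` conformations without the surface test; (m, J+1, 3) coords."""
    joints = spec.joints()
    lengths = _sample_lengths(spec, config, rng, m)
    n_dom = len(spec.domains)
    U = np.empty((m, n_dom, 3))
    for k, joint in enumerate(joints):
        phi = np.asarray(bp.sample_deviation_angle(joint, config, rng, size=m))
        if k == 0:
            az = rng.uniform(0.0, 2.0 * np.pi, size=m)
            sin_phi = np.sin(phi)
            U[:, 0, 0] = sin_phi * np.cos(az)
            U[:, 0, 1] = sin_phi * np.sin(az)
            U[:, 0, 2] = np.cos(phi)
        else:
            theta = rng.uniform(0.0, 2.0 * np.pi, size=m)
            U[:, k] = _next_directions(U[:, k - 1], phi, theta)
    steps = lengths[:, :, None] * U
    coords = np.empty((m, n_dom + 1, 3))
    coords[:, 0] = np.asarray(spec.tether)
    coords[:, 1:] = np.asarray(spec.tether) + np.cumsum(steps, axis=1)
    return coords


def grow_structure(
    spec: StructureSpec,
    config: ModelConfig,
    rng: np.random.Generator,
    max_rejections: int = DEFAULT_REJECTION_CAP,
) -> tuple[SampledStructure, int]:
    """Grow one accepted conformation; returns it with the rejection count.

    The whole structure is regrown whenever any post-tether joint lands
    at z <= z_floor; after ``max_rejections`` consecutive rejections a
    :class:`SamplingError` is raised (this indicates a configuration
    whose acceptance region is unreachable, e.g. an excessive z_floor).
    """
    spec = prepare(spec)
    rejected = 0
    while True:
        coords = _grow_batch(spec, config, rng, 1)[0]
        if np.all(coords[1:, 2] > config.z_floor):
            i = spec.reactive_index
            rp = 0.5 * (coords[i] + coords[i + 1])
            return SampledStructure(joint_coords=coords, reactive_point=rp), rejected
        rejected += 1
        if rejected >= max_rejections:
            raise SamplingError(
                f"structure {spec.name!r}: {rejected} consecutive rejections; "
                f"z_floor={config.z_floor} may be unreachable for this chain"
            )


@dataclass(frozen=True)
class EnsembleResult:
    """Accepted conformations of one structure under one model."""

    spec: StructureSpec  # the prepared (truncated + condensed) spec actually sampled
    config: ModelConfig
    reactive_points: np.ndarray  # (n, 3)
    report: SamplingReport
    joint_coords: np.ndarray | None = None  # (n, J+1, 3) when kept

    @property
    def n(self) -> int:
        return self.reactive_points.shape[0]


def sample_ensemble(
    spec: StructureSpec,
    config: ModelConfig,
    n: int,
    rng: np.random.Generator,
    keep_coords: bool = True,
    max_rejections: int = DEFAULT_REJECTION_CAP,
) -> EnsembleResult:
    """Sample ``n`` accepted conformations of ``spec`` under ``config``.

    The spec is truncated and condensed first (idempotent, so passing an
    already-prepared spec is fine).  Conformations are grown in batches
    and rejected wholesale when any post-tether joint dips to
    z <= z_floor.
    """
    if n < 1:
        raise ValueError(f"ensemble size must be >= 1, got {n}")
    spec = prepare(spec)
    i = spec.reactive_index
    report = SamplingReport(n_requested=n)
    accepted_coords: list[np.ndarray] = []
    need = n
    consecutive = 0
    while need > 0:
        coords = _grow_batch(spec, config, rng, need)
        ok = np.all(coords[:, 1:, 2] > config.z_floor, axis=1)
        n_ok = int(ok.sum())
        report.n_rejected += need - n_ok
        if n_ok == 0:
            consecutive += need
            if consecutive >= max_rejections:
                raise SamplingError(
                    f"structure {spec.name!r}: {consecutive} consecutive rejections; "
                    f"z_floor={config.z_floor} may be unreachable for this chain"
                )
        else:
            consecutive = 0
            accepted_coords.append(coords[ok])
            need -= n_ok
    all_coords = np.concatenate(accepted_coords, axis=0)
    reactive_points = 0.5 * (all_coords[:, i] + all_coords[:, i + 1])
    return EnsembleResult(
        spec=spec,
        config=config,
        reactive_points=reactive_points,
        report=report,
        joint_coords=all_coords if keep_coords else None,
    )
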