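"""Generation, voxelization and import of 3D tissue structures.

Tissue is modeled as a cubic, periodic simulation universe of edge length
``box_size`` (µm) containing geometric primitives — infinite cylinders and
capsule segments for vessels, spheres and ellipsoids for cells.  A
:class:`Scene` holds the continuous primitives; :func:`voxelize` discretizes
it into a :class:`TissueModel`, an ``N³`` labeled grid (0 = extravascular
extracellular space, 1 = intravascular, 2 = intracellular) that downstream
solvers consume as the binary indicator function of each compartment.

Generators provided:

* randomly oriented cylinders at a target volume fraction (classic vessel
  model),
* non-overlapping sphere packings (random sequential addition, or an FCC
  lattice thinned to a target fraction),
* non-overlapping random ellipsoid packings (collective rearrangement with
  gradual inflation; reaches fractions > 0.65),
* fractal binary vascular trees obeying Murray's law at every bifurcation,
* ellipsoids packed around a fixed vascular scene (tumor-tissue model).

All generators are deterministic given their seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

LABEL_EES = 0
LABEL_VASCULAR = 1
LABEL_CELL = 2

__all__ = [
    "LABEL_EES",
    "LABEL_VASCULAR",
    "LABEL_CELL",
    "Cylinder",
    "Sphere",
    "Ellipsoid",
    "Capsule",
    "Scene",
    "TissueModel",
    "TreeParams",
    "PackingError",
    "generate_random_cylinders",
    "generate_sphere_packing",
    "generate_ellipsoid_packing",
    "generate_fractal_tree",
    "pack_cells_around_vessels",
    "voxelize",
    "volume_fraction",
    "import_mask",
    "save_mask",
    "subdivide_mask",
    "ellipsoids_overlap",
]


class PackingError(RuntimeError):
    """A packing / growth target could not be reached; carries the achieved fraction."""

    def __init__(self, message: str, achieved: float | None = None):
        super().__init__(message)
        self.achieved = achieved


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Cylinder:
    """Infinite cylinder through ``point`` along unit vector ``direction``."""

    point: tuple[float, float, float]
    direction: tuple[float, float, float]
    radius: float
    label: int = LABEL_VASCULAR

    def contains(self, pts: np.ndarray) -> np.ndarray:
        p = np.asarray(self.point)
        u = np.asarray(self.direction)
        d = pts - p
        proj = d @ u
        perp2 = np.einsum("ij,ij->i", d, d) - proj**2
        return perp2 <= self.radius**2 + 1e-12


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float
    label: int = LABEL_CELL

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d = pts - np.asarray(self.center)
        return np.einsum("ij,ij->i", d, d) <= self.radius**2

    @property
    def bounding_radius(self) -> float:
        return self.radius


@dataclass(frozen=True)
class Ellipsoid:
    """Ellipsoid with semi-axes ``semiaxes`` (µm); ``rotation`` maps body → world."""

    center: tuple[float, float, float]
    semiaxes: tuple[float, float, float]
    rotation: tuple  # 3x3 nested tuple, rows
    label: int = LABEL_CELL

    def contains(self, pts: np.ndarray) -> np.ndarray:
        R = np.asarray(self.rotation)
        a = np.asarray(self.semiaxes)
        local = (pts - np.asarray(self.center)) @ R  # world -> body frame
        return np.einsum("ij,ij->i", local / a, local / a) <= 1.0

    @property
    def bounding_radius(self) -> float:
        return float(max(self.semiaxes))

    def quadric(self, scale: float = 1.0) -> np.ndarray:
        """Homogeneous 4×4 quadric Q with XᵀQX < 0 strictly inside."""
        R = np.asarray(self.rotation)
        a = np.asarray(self.semiaxes) * scale
        E = R @ np.diag(1.0 / a**2) @ R.T
        c = np.asarray(self.center)
        Q = np.empty((4, 4))
        Q[:3, :3] = E
        Q[:3, 3] = -E @ c
        Q[3, :3] = -E @ c
        Q[3, 3] = c @ E @ c - 1.0
        return Q


@dataclass(frozen=True)
class Capsule:
    """Cylinder segment with spherical caps, from ``p0`` to ``p1``."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float
    label: int = LABEL_VASCULAR

    def contains(self, pts: np.ndarray) -> np.ndarray:
        a = np.asarray(self.p0)
        b = np.asarray(self.p1)
        ab = b - a
        L2 = ab @ ab
        if L2 == 0.0:
            d = pts - a
            return np.einsum("ij,ij->i", d, d) <= self.radius**2
        t = np.clip((pts - a) @ ab / L2, 0.0, 1.0)
        closest = a + t[:, None] * ab
        d = pts - closest
        return np.einsum("ij,ij->i", d, d) <= self.radius**2


Primitive = Cylinder | Sphere | Ellipsoid | Capsule

_PRIM_KINDS = {"Cylinder": Cylinder, "Sphere": Sphere, "Ellipsoid": Ellipsoid, "Capsule": Capsule}


@dataclass
class Scene:
    """Continuous tissue structure: primitives in a periodic cubic box (µm)."""

    primitives: list
    box_size: float
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def enc(p):
            d = dataclasses.asdict(p)
            d["kind"] = type(p).__name__
            return d

        payload = {
            "box_size": self.box_size,
            "seed": self.seed,
            "metadata": self.metadata,
            "primitives": [enc(p) for p in self.primitives],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "Scene":
        payload = json.loads(Path(path).read_text())

        def dec(d):
            d = dict(d)
            kind = _PRIM_KINDS[d.pop("kind")]
            for k, v in d.items():
                if isinstance(v, list):
                    d[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v) if any(
                        isinstance(x, list) for x in v
                    ) else tuple(v)
            return kind(**d)

        return cls(
            primitives=[dec(d) for d in payload["primitives"]],
            box_size=payload["box_size"],
            seed=payload.get("seed"),
            metadata=payload.get("metadata", {}),
        )


@dataclass
class TissueModel:
    """Labeled voxel grid: 0 = EES, 1 = intravascular, 2 = intracellular."""

    labels: np.ndarray  # (N, N, N) integer grid
    voxel_size: float  # µm

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or len(set(self.labels.shape)) != 1:
            raise ValueError("labels must be a cubic 3D grid")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def box_size(self) -> float:
        return self.labels.shape[0] * self.voxel_size

    def volume_fraction(self, label: int) -> float:
        return float(np.count_nonzero(self.labels == label)) / self.labels.size


def volume_fraction(model: TissueModel, label: int) -> float:
    """Fraction of voxels carrying ``label``."""
    return model.volume_fraction(label)


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------


def _voxel_centers_1d(n: int, voxel_size: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * voxel_size


def _paint_primitive(labels: np.ndarray, prim: Primitive, voxel_size: float, periodic: bool = True) -> None:
    """Set ``labels`` to prim.label wherever the voxel center lies inside the
    primitive (or one of its periodic images)."""
    n = labels.shape[0]
    box = n * voxel_size
    if isinstance(prim, Cylinder):
        # infinite line: scan full grid in z-slabs, no wrapping needed
        xs = _voxel_centers_1d(n, voxel_size)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        for k in range(n):
            pts = np.column_stack([X.ravel(), Y.ravel(), np.full(n * n, xs[k])])
            inside = prim.contains(pts).reshape(n, n)
            labels[:, :, k][inside] = prim.label
        return

    # finite primitive: bounding box + periodic images
    if isinstance(prim, Sphere):
        lo = np.asarray(prim.center) - prim.radius
        hi = np.asarray(prim.center) + prim.radius
    elif isinstance(prim, Ellipsoid):
        r = prim.bounding_radius
        lo = np.asarray(prim.center) - r
        hi = np.asarray(prim.center) + r
    elif isinstance(prim, Capsule):
        lo = np.minimum(prim.p0, prim.p1) - prim.radius
        hi = np.maximum(prim.p0, prim.p1) + prim.radius
    else:  # pragma: no cover
        raise TypeError(f"unknown primitive {type(prim)}")

    if periodic:
        shifts_per_axis = []
        for ax in range(3):
            kmin = int(np.floor(lo[ax] / box))
            kmax = int(np.floor(hi[ax] / box))
            shifts_per_axis.append([-k * box for k in range(kmin, kmax + 1)])
    else:
        shifts_per_axis = [[0.0], [0.0], [0.0]]

    xs = _voxel_centers_1d(n, voxel_size)
    for sx in shifts_per_axis[0]:
        for sy in shifts_per_axis[1]:
            for sz in shifts_per_axis[2]:
                shift = np.array([sx, sy, sz])
                slo, shi = lo + shift, hi + shift
                i0 = np.maximum(np.floor(slo / voxel_size - 0.5).astype(int), 0)
                i1 = np.minimum(np.ceil(shi / voxel_size - 0.5).astype(int) + 1, n)
                if np.any(i0 >= i1):
                    continue
                gx, gy, gz = np.meshgrid(
                    xs[i0[0] : i1[0]], xs[i0[1] : i1[1]], xs[i0[2] : i1[2]], indexing="ij"
                )
                pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) - shift
                inside = prim.contains(pts).reshape(gx.shape)
                sub = labels[i0[0] : i1[0], i0[1] : i1[1], i0[2] : i1[2]]
                sub[inside] = prim.label


def voxelize(
    scene: Scene, grid_shape: int, voxel_size: float | None = None, periodic: bool = True
) -> TissueModel:
    """Discretize a scene onto an ``N³`` grid by voxel-center containment.

    Intravascular primitives take precedence over intracellular ones where
    compartments collide.  Finite primitives crossing a box face are wrapped
    periodically unless ``periodic=False``.
    """
    if voxel_size is None:
        voxel_size = scene.box_size / grid_shape
    if abs(grid_shape * voxel_size - scene.box_size) > 1e-6 * scene.box_size:
        raise ValueError("grid_shape * voxel_size must equal scene.box_size")
    labels = np.zeros((grid_shape,) * 3, dtype=np.int8)
    # paint low precedence first so that vascular overwrites cellular
    for prim in scene.primitives:
        if prim.label == LABEL_CELL:
            _paint_primitive(labels, prim, voxel_size, periodic)
    for prim in scene.primitives:
        if prim.label == LABEL_VASCULAR:
            _paint_primitive(labels, prim, voxel_size, periodic)
    return TissueModel(labels, voxel_size)


# ---------------------------------------------------------------------------
# Random rotations / helper RNG utilities
# ---------------------------------------------------------------------------


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _min_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.round(d / box)


# ---------------------------------------------------------------------------
# Random cylinders
# ---------------------------------------------------------------------------


def generate_random_cylinders(
    radius: float,
    volume_fraction: float,
    box_size: float,
    seed: int,
    check_grid: int = 128,
    max_cylinders: int = 10000,
) -> Scene:
    """Randomly oriented, randomly positioned infinite cylinders.

    Cylinders are added one at a time until the voxelized vascular volume
    fraction (measured on a ``check_grid³`` tracking grid) first reaches or
    exceeds ``volume_fraction``.
    """
    if not 0 <= volume_fraction < 1:
        raise ValueError("volume_fraction must lie in [0, 1)")
    if radius >= box_size / 2:
        raise ValueError("cylinder radius must be < box_size/2")
    rng = np.random.default_rng(seed)
    prims: list[Cylinder] = []
    if volume_fraction == 0:
        return Scene(prims, box_size, seed)
    labels = np.zeros((check_grid,) * 3, dtype=np.int8)
    vsz = box_size / check_grid
    target_count = volume_fraction * check_grid**3
    while len(prims) < max_cylinders:
        cyl = Cylinder(
            point=tuple(rng.uniform(0, box_size, 3)),
            direction=tuple(_random_unit_vector(rng)),
            radius=radius,
        )
        prims.append(cyl)
        _paint_primitive(labels, cyl, vsz)
        if np.count_nonzero(labels) >= target_count:
            return Scene(prims, box_size, seed)
    raise PackingError(
        f"target fraction {volume_fraction} unreachable within {max_cylinders} cylinders",
        achieved=np.count_nonzero(labels) / labels.size,
    )


# ---------------------------------------------------------------------------
# Ellipsoid overlap machinery (exact algebraic separation test)
# ---------------------------------------------------------------------------


def ellipsoids_overlap(e1: Ellipsoid, e2: Ellipsoid, scale: float = 1.0) -> bool:
    """Exact overlap test for two ellipsoids (interiors intersect).

    Uses the algebraic separation condition on the generalized eigenvalues of
    the pair of quadrics: two ellipsoids are disjoint iff the characteristic
    polynomial det(λQ₁ − Q₂) has two distinct positive real roots; an external
    tangency gives a positive double root.  Touching is reported as
    non-overlapping.
    """
    lam = _pair_eigenvalues(e1.quadric(scale)[None], e2.quadric(scale)[None])[0]
    return bool(_overlap_from_eigs(lam[None])[0])


def _pair_eigenvalues(Q1: np.ndarray, Q2: np.ndarray) -> np.ndarray:
    """Roots λ of the characteristic polynomial det(λQ1 + Q2) = 0, batched."""
    M = -np.linalg.solve(Q1, Q2)  # roots of det(λI − (−Q1⁻¹Q2))
    return np.linalg.eigvals(M)


def _overlap_from_eigs(lams: np.ndarray, tol: float = 1e-7) -> np.ndarray:
    """True where the root quadruple indicates interpenetration.

    With both quadrics normalized to be negative inside, det(λQ1 + Q2) = 0
    always has two negative roots; the ellipsoids are disjoint iff it also
    has two distinct positive real roots (a positive double root is external
    tangency).  A complex-conjugate pair, or fewer than two distinct positive
    real roots, means the interiors intersect.  Near-tangent pairs within
    ``tol`` are conservatively reported as overlapping.
    """
    real = np.abs(lams.imag) <= tol * np.maximum(1.0, np.abs(lams.real))
    pos_real = real & (lams.real > tol)
    n_pos = pos_real.sum(axis=1)
    disjoint = n_pos >= 2
    # require the two positive roots to be distinct (not a tangency double root)
    if np.any(disjoint):
        idx = np.nonzero(disjoint)[0]
        for i in idx:
            roots = np.sort(lams[i].real[pos_real[i]])
            if roots[-1] - roots[0] <= tol * max(1.0, roots[-1]):
                disjoint[i] = False
    return ~disjoint


def _directional_radius(E: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Half-width of ellipsoid(s) with shape matrix E along unit direction u."""
    return 1.0 / np.sqrt(np.einsum("ni,nij,nj->n", u, E, u))


class _EllipsoidPacker:
    """Collective-rearrangement packer with gradual inflation.

    Ellipsoids are placed at random, shrunk by a scale factor, overlap-relaxed
    by pairwise push-apart displacements, and inflated stepwise to full size.
    Optional fixed capsule obstacles (vessels) are avoided with a conservative
    center-to-axis clearance test.
    """

    def __init__(
        self,
        ellipsoids: list[Ellipsoid],
        box: float,
        rng: np.random.Generator,
        obstacles: Sequence[Capsule | Cylinder] = (),
        max_sweeps: int = 40000,
        accept_scale: float = 0.995,
    ):
        self.box = box
        self.rng = rng
        self.obstacles = list(obstacles)
        self.max_sweeps = max_sweeps
        self.accept_scale = accept_scale
        self.centers = np.array([e.center for e in ellipsoids])
        self.semiaxes = np.array([e.semiaxes for e in ellipsoids])
        self.rots = np.array([np.asarray(e.rotation) for e in ellipsoids])
        self.labels = [e.label for e in ellipsoids]
        # unit-scale shape matrices E = R diag(1/a²) Rᵀ
        inv_a2 = 1.0 / self.semiaxes**2
        self.E_unit = np.einsum("nij,nj,nkj->nik", self.rots, inv_a2, self.rots)
        self.rmax = self.semiaxes.max(axis=1)
        self.is_sphere = np.allclose(self.semiaxes, self.semiaxes[:, :1])

    def _quadrics(self, idx: np.ndarray, scale: float) -> np.ndarray:
        E = self.E_unit[idx] / scale**2
        c = self.centers[idx]
        n = len(idx)
        Q = np.zeros((n, 4, 4))
        Q[:, :3, :3] = E
        Ec = np.einsum("nij,nj->ni", E, c)
        Q[:, :3, 3] = -Ec
        Q[:, 3, :3] = -Ec
        Q[:, 3, 3] = np.einsum("ni,ni->n", c, Ec) - 1.0
        return Q

    def _candidate_pairs(self, scale: float):
        n = len(self.centers)
        d = self.centers[:, None, :] - self.centers[None, :, :]
        d = _min_image(d, self.box)
        dist = np.sqrt(np.einsum("nmi,nmi->nm", d, d))
        cut = scale * (self.rmax[:, None] + self.rmax[None, :])
        i, j = np.nonzero(np.triu(dist < cut, k=1))
        return i, j, d[i, j], dist[i, j]

    def _exact_pairs(self, scale: float):
        """Pairs whose interiors truly intersect (algebraic separation test),
        with their minimum-image center offsets and distances."""
        i, j, dvec, dist = self._candidate_pairs(scale)
        if len(i) == 0:
            return i, j, np.empty((0, 3)), np.empty(0)
        if self.is_sphere:
            r = self.semiaxes[:, 0]
            mask = dist < scale * (r[i] + r[j]) * (1 - 1e-12)
        else:
            # inner-sphere quick accept, exact algebraic test for the rest.
            # Pair test uses minimum-image geometry: shift j's center next to i.
            rmin = self.semiaxes.min(axis=1)
            sure = dist < scale * (rmin[i] + rmin[j])
            mask = sure.copy()
            rest = ~sure
            if np.any(rest):
                ii, jj = i[rest], j[rest]
                Qi = self._quadrics(ii, scale)
                Qj = self._quadrics(jj, scale)
                shift = (self.centers[ii] - dvec[rest]) - self.centers[jj]
                Qj = _translate_quadrics(Qj, shift)
                lams = _pair_eigenvalues(Qi, Qj)
                mask[rest] = _overlap_from_eigs(lams)
        return i[mask], j[mask], dvec[mask], dist[mask]

    def _obstacle_pushes(self, scale: float) -> np.ndarray:
        """Conservative clearance from capsule obstacles.

        Keeps every ellipsoid center at least (scaled capsule radius +
        scaled support half-width) from the obstacle axis.  The obstacle
        radius inflates with the same scale factor as the ellipsoids, so the
        early low-density phase is unobstructed and the constraint becomes
        exact at full scale — packing cells and vessels as if both grew
        together."""
        push = np.zeros_like(self.centers)
        for obs in self.obstacles:
            if isinstance(obs, Capsule):
                a, b = np.asarray(obs.p0), np.asarray(obs.p1)
            else:  # infinite cylinder: long segment through the box
                p = np.asarray(obs.point)
                u = np.asarray(obs.direction)
                a, b = p - 10 * self.box * u, p + 10 * self.box * u
            ab = b - a
            L2 = ab @ ab
            # consider periodic images of the centers
            best_vec = None
            best_dist = None
            for img in _image_shifts(self.box):
                c = self.centers + img
                t = np.clip((c - a) @ ab / L2, 0.0, 1.0) if L2 > 0 else np.zeros(len(c))
                closest = a + t[:, None] * ab
                v = c - closest
                dd = np.linalg.norm(v, axis=1)
                if best_dist is None:
                    best_dist, best_vec = dd, v
                else:
                    better = dd < best_dist
                    best_dist = np.where(better, dd, best_dist)
                    best_vec[better] = v[better]
            u_out = best_vec / np.maximum(best_dist, 1e-9)[:, None]
            # support half-width h(u) = ‖diag(a)·Rᵀu‖: every ellipsoid point
            # projects at least −h(u) along u, so center distance ≥ r+h(u)
            # from the axis certifies no overlap with the capsule
            h = np.linalg.norm(
                self.semiaxes * np.einsum("nji,nj->ni", self.rots, u_out), axis=1
            )
            clearance = scale * (obs.radius + h)
            pen = clearance - best_dist
            hit = pen > 0
            if np.any(hit):
                push[hit] += 1.05 * pen[hit][:, None] * u_out[hit]
        return push

    def _apply_torques(self, pairs_i, pairs_j, u, scale: float) -> None:
        """Rotate overlapping ellipsoids to shrink their extent along the
        contact direction (long axis turns away from the center line).

        Translation-only dynamics jams near the sphere random-close-packing
        fraction; this orientational response is what lets ellipsoids exceed
        it.  Each member of an overlapping pair receives a small rotation
        about (long_axis × u), with the sign chosen to reduce the directional
        radius along u.
        """
        if self.is_sphere:
            return
        contacts: dict[int, np.ndarray] = {}
        for a, b, uu in zip(pairs_i, pairs_j, u):
            contacts.setdefault(int(a), uu)
            contacts.setdefault(int(b), uu)
        for q, uu in contacts.items():
            long_ax = self.rots[q][:, int(np.argmax(self.semiaxes[q]))]
            w = np.cross(long_ax, uu)
            nw = np.linalg.norm(w)
            if nw < 1e-9:
                w = np.cross(long_ax, self.rng.normal(size=3))
                nw = np.linalg.norm(w)
                if nw < 1e-9:
                    continue
            w /= nw
            best_E, best_R = self.E_unit[q], self.rots[q]
            r0 = 1.0 / np.sqrt(uu @ (self.E_unit[q] / scale**2) @ uu)
            best_r = r0
            for ang in (0.08, -0.08):
                K = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
                R = (np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * K @ K) @ self.rots[q]
                E = R @ np.diag(1.0 / self.semiaxes[q] ** 2) @ R.T
                r = 1.0 / np.sqrt(uu @ (E / scale**2) @ uu)
                if r < best_r:
                    best_r, best_E, best_R = r, E, R
            self.E_unit[q], self.rots[q] = best_E, best_R

    def relax(self, scale: float, sweeps_budget: int, floor: float = 0.02) -> tuple[bool, int]:
        """Push-apart sweeps at fixed scale; (overlap-free?, sweeps used).

        Each sweep finds the truly-overlapping pairs with the exact algebraic
        test, displaces both members apart along their center line (step from
        the directional-radius penetration estimate, floored at ``floor``
        relative to the smaller bounding radius so near-tangent contacts
        still separate) and applies the orientational response.
        """
        for sweep in range(sweeps_budget):
            i, j, dvec, dist = self._exact_pairs(scale)
            push = self._obstacle_pushes(scale)
            if len(i) == 0 and not push.any():
                return True, sweep
            if len(i):
                u = dvec / np.maximum(dist, 1e-9)[:, None]
                zero = dist <= 1e-9
                if np.any(zero):
                    u[zero] = self.rng.normal(size=(int(zero.sum()), 3))
                    u[zero] /= np.linalg.norm(u[zero], axis=1, keepdims=True)
                # directional radius is even in u, so one evaluation per ellipsoid
                ri = _directional_radius(self.E_unit[i] / scale**2, u)
                rj = _directional_radius(self.E_unit[j] / scale**2, u)
                depth = np.maximum(
                    ri + rj - dist, floor * scale * np.minimum(self.rmax[i], self.rmax[j])
                )
                step = 0.5 * depth[:, None] * u
                np.add.at(push, i, step / 2)
                np.add.at(push, j, -step / 2)
                self._apply_torques(i, j, u, scale)
            self.centers = np.mod(self.centers + push, self.box)
        return False, sweeps_budget

    def _vf(self, scale: float) -> float:
        vol = (4 / 3) * np.pi * np.prod(self.semiaxes * scale, axis=1).sum()
        return vol / self.box**3

    def pack(self, start_scale: float = 1.0) -> list[Ellipsoid]:
        """Inflate from start_scale to 1.0, relaxing overlaps at each step.

        The inflation increment adapts: it shrinks when relaxation stalls
        (so each growth step stays absorbable — a fixed step produces a
        limit cycle of grow / overlap burst / anneal near jamming) and
        recovers when relaxation succeeds quickly.  The push floor anneals
        downward during a stall so the dynamics can settle, and deflation
        never drops below the last overlap-free scale.
        """
        scale = min(start_scale, 1.0)
        sweeps_left = self.max_sweeps
        stall = 0
        grow = 0.02
        best = None  # (scale, centers, rots, E_unit) of densest clean state
        while sweeps_left > 0:
            floor = 0.02 if stall == 0 else max(0.002, 0.02 / (1 + stall))
            ok, used = self.relax(scale, min(60, sweeps_left), floor=floor)
            sweeps_left -= max(used, 1)
            if scale >= 1.0 and ok:
                return self._to_ellipsoids(1.0)
            if ok:
                stall = 0
                if best is None or scale > best[0]:
                    best = (scale, self.centers.copy(), self.rots.copy(), self.E_unit.copy())
                scale = min(1.0, scale * (1.0 + grow))
                if used < 30:
                    grow = min(0.02, grow * 1.3)
            else:
                stall += 1
                grow = max(0.0008, grow * 0.65)
                if stall % 5 == 0 and best is not None:
                    # deflate slightly (never below the densest clean scale)
                    # and keep relaxing; positions are left as they are
                    scale = max(best[0], scale * 0.997)
        if best is not None and best[0] >= self.accept_scale:
            # densest clean state is within tolerance of the target: keep it,
            # with the ellipsoids permanently shrunk by the remaining factor
            _, self.centers, self.rots, self.E_unit = best
            return self._to_ellipsoids(best[0])
        raise PackingError(
            f"packing did not converge; achieved fraction {self._vf(scale):.4f}",
            achieved=self._vf(scale),
        )

    def _to_ellipsoids(self, scale: float) -> list[Ellipsoid]:
        return [
            Ellipsoid(tuple(c), tuple(np.asarray(a) * scale), tuple(map(tuple, R)), label=l)
            for c, a, R, l in zip(self.centers, self.semiaxes, self.rots, self.labels)
        ]


def _translate_quadrics(Q: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Apply a translation to batched homogeneous quadrics (X → X − shift)."""
    n = len(Q)
    T = np.tile(np.eye(4), (n, 1, 1))
    T[:, :3, 3] = -shift
    return np.einsum("nji,njk,nkl->nil", T, Q, T)


def _image_shifts(box: float) -> list[np.ndarray]:
    out = []
    for sx in (-box, 0.0, box):
        for sy in (-box, 0.0, box):
            for sz in (-box, 0.0, box):
                out.append(np.array([sx, sy, sz]))
    return out


# ---------------------------------------------------------------------------
# Sphere packing
# ---------------------------------------------------------------------------

_FCC_LIMIT = np.pi / np.sqrt(18.0)
_RSA_LIMIT = 0.38


def generate_sphere_packing(
    radius: float,
    volume_fraction: float,
    mode: str = "random",
    box_size: float = 100.0,
    seed: int = 0,
    label: int = LABEL_CELL,
) -> Scene:
    """Non-overlapping equal spheres at a target volume fraction.

    ``random`` uses random sequential addition with rejection (capped at the
    RSA saturation limit ≈ 0.38), with push-apart relaxation sweeps as a
    fallback when insertion stalls.  ``fcc`` places spheres on a face-centered
    cubic lattice and thins it at random down to the target fraction.
    """
    rng = np.random.default_rng(seed)
    vol_sphere = (4 / 3) * np.pi * radius**3
    if volume_fraction == 0:
        return Scene([], box_size, seed)
    if mode == "fcc":
        if volume_fraction > _FCC_LIMIT + 1e-12:
            raise PackingError(
                f"fcc packing limit is π/√18 ≈ {_FCC_LIMIT:.4f}; requested {volume_fraction}"
            )
        a = 2 * np.sqrt(2) * radius
        ncells = int(np.floor(box_size / a + 1e-9))
        if ncells < 1:
            raise PackingError("box too small for one FCC unit cell at this radius")
        a_eff = box_size / ncells  # stretch to fill the box periodically
        basis = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]])
        cells = np.array([[i, j, k] for i in range(ncells) for j in range(ncells) for k in range(ncells)])
        sites = ((cells[:, None, :] + basis[None, :, :]).reshape(-1, 3)) * a_eff
        max_vf = len(sites) * vol_sphere / box_size**3
        if volume_fraction > max_vf + 1e-12:
            raise PackingError(
                f"fcc lattice commensurate with this box reaches only {max_vf:.4f}",
                achieved=max_vf,
            )
        n_keep = int(round(volume_fraction * box_size**3 / vol_sphere))
        keep = rng.choice(len(sites), size=min(n_keep, len(sites)), replace=False)
        prims = [Sphere(tuple(sites[k]), radius, label=label) for k in keep]
        return Scene(prims, box_size, seed)

    if mode != "random":
        raise ValueError("mode must be 'random' or 'fcc'")
    if volume_fraction > _RSA_LIMIT:
        raise PackingError(
            f"random sequential addition saturates near {_RSA_LIMIT}; requested {volume_fraction}"
        )
    n_target = int(round(volume_fraction * box_size**3 / vol_sphere))
    centers: list[np.ndarray] = []
    arr = np.empty((0, 3))
    attempts = 0
    max_attempts = 200 * max(n_target, 1) + 20000
    while len(centers) < n_target and attempts < max_attempts:
        c = rng.uniform(0, box_size, 3)
        attempts += 1
        if len(centers):
            d = _min_image(arr - c, box_size)
            if np.min(np.einsum("ij,ij->i", d, d)) < (2 * radius) ** 2:
                continue
        centers.append(c)
        arr = np.asarray(centers)
    if len(centers) < n_target:
        # relaxation fallback: drop remaining spheres in anywhere and push apart
        extra = rng.uniform(0, box_size, (n_target - len(centers), 3))
        arr = np.vstack([arr, extra]) if len(centers) else extra
        ell = [
            Ellipsoid(tuple(c), (radius,) * 3, tuple(map(tuple, np.eye(3))), label=label)
            for c in arr
        ]
        packer = _EllipsoidPacker(ell, box_size, rng)
        packed = packer.pack(start_scale=0.9)
        prims = [Sphere(e.center, radius, label=label) for e in packed]
        return Scene(prims, box_size, seed)
    prims = [Sphere(tuple(c), radius, label=label) for c in centers]
    return Scene(prims, box_size, seed)


# ---------------------------------------------------------------------------
# Ellipsoid packing
# ---------------------------------------------------------------------------


def generate_ellipsoid_packing(
    mean_radius: float,
    volume_fraction: float,
    box_size: float,
    seed: int,
    aspect_ratios: tuple[float, float, float] | None = None,
    radius_spread: float = 0.1,
    label: int = LABEL_CELL,
    max_sweeps: int = 15000,
    attempts: int = 3,
) -> Scene:
    """Non-overlapping randomly oriented ellipsoids at a target fraction.

    Semi-axes are drawn so the equivalent-sphere radius (abc)^{1/3} is uniform
    in mean_radius·(1 ± radius_spread); by default each cell is a mildly
    prolate spheroid with transverse/long axis ratio uniform in [0.6, 0.9]
    (``aspect_ratios`` pins the relative axes instead).  Strongly flattened
    cells shrink the smallest structural dimension and with it the spin-echo
    relaxivity; mildly prolate shapes add orientational field heterogeneity
    without that penalty.  Packing uses collective rearrangement with
    inflation and an exact algebraic pair-overlap test, and reaches fractions
    above 0.65.

    Convergence time is heavy-tailed across random initial arrangements, so
    after ``max_sweeps`` relaxation sweeps without success the arrangement is
    redrawn (up to ``attempts`` times, deterministically derived from the
    seed) rather than ground down.
    """
    if not 0 <= volume_fraction <= 0.70:
        raise ValueError("ellipsoid packing supports fractions in [0, 0.70]")
    if volume_fraction == 0:
        return Scene([], box_size, seed)
    mean_vol = (4 / 3) * np.pi * mean_radius**3
    n = max(1, int(round(volume_fraction * box_size**3 / mean_vol)))
    last_err: PackingError | None = None
    for attempt in range(attempts):
        rng = np.random.default_rng((seed + 900001 * attempt) % (2**31 - 1))
        ells = []
        for _ in range(n):
            if aspect_ratios is None:
                a = rng.uniform(0.6, 0.9)
                rel = np.array([a, a, 1.0])
            else:
                rel = np.asarray(aspect_ratios, dtype=float)
            req = mean_radius * rng.uniform(1 - radius_spread, 1 + radius_spread)
            axes = rel * req / np.prod(rel) ** (1 / 3)  # (abc)^{1/3} = req
            ells.append(
                Ellipsoid(
                    tuple(rng.uniform(0, box_size, 3)),
                    tuple(axes),
                    tuple(map(tuple, _random_rotation(rng))),
                    label=label,
                )
            )
        # normalize the sampled volumes so the analytic total hits the target
        # exactly (otherwise the n-cell volume sum carries ~1-2% sampling noise)
        actual_vf = sum((4 / 3) * np.pi * np.prod(e.semiaxes) for e in ells) / box_size**3
        norm = (volume_fraction / actual_vf) ** (1 / 3)
        ells = [
            Ellipsoid(e.center, tuple(np.asarray(e.semiaxes) * norm), e.rotation, label=e.label)
            for e in ells
        ]
        start = min(1.0, (0.25 / volume_fraction) ** (1 / 3))
        packer = _EllipsoidPacker(ells, box_size, rng, max_sweeps=max_sweeps)
        try:
            packed = packer.pack(start_scale=start)
            return Scene(packed, box_size, seed)
        except PackingError as err:
            last_err = err
    raise last_err


# ---------------------------------------------------------------------------
# Fractal vascular tree
# ---------------------------------------------------------------------------


@dataclass
class TreeParams:
    """Parameters of the bifurcating fractal vessel tree.

    At every junction the parent of radius r_p splits into daughters with
    r_p³ = r_d1³ + r_d2³ (Murray's law); the bifurcation index α = r_d1/r_d2
    is drawn from ``bifurcation_index_range``.  Daughter directions deviate
    from the parent by angles drawn from ``branching_angle_range`` (degrees),
    at azimuths set by ``rotation_angle_rule`` ("uniform", or a fixed
    increment in degrees).  ``branching_reference`` selects the axis the
    branching angle is measured from: "parent" (each daughter deviates from
    its own parent; orientations decorrelate within a few generations) or
    "root" (every segment's direction deviates from the tree's root axis, so
    a narrow angle range yields a strongly aligned, anisotropic network and a
    wide range an isotropic one).  Segment length =
    length_to_radius_ratio · radius.
    Growth stops when the voxelized vascular fraction reaches
    ``target_volume_fraction`` or every tip has shrunk below ``radius_min``.
    """

    root_radius: float = 40.0
    radius_min: float = 5.0
    radius_max: float = 80.0
    branching_angle_range: tuple[float, float] = (25.0, 140.0)
    rotation_angle_rule: str | float = "uniform"
    bifurcation_index_range: tuple[float, float] = (0.7, 1.0)
    target_volume_fraction: float = 0.02
    length_to_radius_ratio: float = 8.0
    branching_reference: str = "parent"  # or "root"
    root_direction: tuple[float, float, float] | None = None  # None = random
    seed: int = 0
    max_retries: int = 8

    def validate(self) -> None:
        if not 0 < self.target_volume_fraction < 1:
            raise ValueError("target_volume_fraction must be in (0, 1)")
        lo, hi = self.branching_angle_range
        if not (0 <= lo <= hi <= 180):
            raise ValueError("branching_angle_range must lie within [0°, 180°]")
        if self.radius_min > self.radius_max:
            raise ValueError("radius_min must be ≤ radius_max")
        if self.branching_reference not in ("parent", "root"):
            raise ValueError("branching_reference must be 'parent' or 'root'")


def _perpendicular(u: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = np.cross(u, ref)
    return v / np.linalg.norm(v)


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    return (
        v * np.cos(angle)
        + np.cross(axis, v) * np.sin(angle)
        + axis * (axis @ v) * (1 - np.cos(angle))
    )


def _segments_collide(seg: Capsule, others: Iterable[Capsule], skip: set[int], box: float) -> bool:
    a0, a1 = np.asarray(seg.p0), np.asarray(seg.p1)
    for idx, other in enumerate(others):
        if idx in skip:
            continue
        d = _segment_segment_distance(a0, a1, np.asarray(other.p0), np.asarray(other.p1))
        if d < 0.95 * (seg.radius + other.radius):
            return True
    return False


def _segment_segment_distance(p1, q1, p2, q2) -> float:
    """Minimum distance between segments [p1,q1] and [p2,q2]."""
    d1, d2 = q1 - p1, q2 - p2
    r = p1 - p2
    a, e, f = d1 @ d1, d2 @ d2, d2 @ r
    if a <= 1e-12 and e <= 1e-12:
        return float(np.linalg.norm(r))
    if a <= 1e-12:
        t = np.clip(f / e, 0, 1)
        return float(np.linalg.norm(r - t * d2))
    c = d1 @ r
    if e <= 1e-12:
        s = np.clip(-c / a, 0, 1)
        return float(np.linalg.norm(r + s * d1))
    b = d1 @ d2
    denom = a * e - b * b
    s = np.clip((b * f - c * e) / denom, 0, 1) if denom > 1e-12 else 0.0
    t = (b * s + f) / e
    if t < 0:
        t, s = 0.0, np.clip(-c / a, 0, 1)
    elif t > 1:
        t, s = 1.0, np.clip((b - c) / a, 0, 1)
    return float(np.linalg.norm(p1 + s * d1 - (p2 + t * d2)))


def generate_fractal_tree(
    params: TreeParams, box_size: float, check_grid: int = 64, max_roots: int = 20
) -> Scene:
    """Fractal vessel network obeying Murray's law at every bifurcation.

    Grows a binary tree breadth-first from a random root segment.  Because
    Murray's law conserves Σr³ across a bifurcation, one tree contributes
    roughly its root volume per generation and may exhaust (all tips below
    ``radius_min``) before the target fraction is met; additional trees are
    then seeded from new roots (up to ``max_roots``) until the voxelized
    vascular fraction reaches the target.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    segments: list[Capsule] = []
    bifurcations: list[tuple[float, float, float]] = []
    labels_grid = np.zeros((check_grid,) * 3, dtype=np.int8)
    vsz = box_size / check_grid
    target_count = params.target_volume_fraction * check_grid**3
    lo = np.deg2rad(params.branching_angle_range[0])
    hi = np.deg2rad(params.branching_angle_range[1])
    phi_state = 0.0
    done = False

    for _root_i in range(max_roots):
        root_r = min(params.root_radius, params.radius_max)
        root = None
        for _try in range(20 * params.max_retries):
            start = rng.uniform(0.15 * box_size, 0.85 * box_size, 3)
            if params.root_direction is not None:
                direction = np.asarray(params.root_direction, dtype=float)
                direction = direction / np.linalg.norm(direction)
            else:
                direction = _random_unit_vector(rng)
            cand = Capsule(
                tuple(start),
                tuple(start + direction * params.length_to_radius_ratio * root_r),
                root_r,
            )
            if not _segments_collide(cand, segments, set(), box_size):
                root = cand
                break
        if root is None:
            break
        segments.append(root)
        _paint_primitive(labels_grid, root, vsz)
        if np.count_nonzero(labels_grid) >= target_count:
            done = True
            break

        root_dir = direction
        tips: list[int] = [len(segments) - 1]
        while tips and not done:
            new_tips: list[int] = []
            for tip_idx in tips:
                parent = segments[tip_idx]
                rp = parent.radius
                alpha = rng.uniform(*params.bifurcation_index_range)
                rd2 = rp / (1 + alpha**3) ** (1 / 3)
                rd1 = alpha * rd2
                daughters = [rd for rd in (rd1, rd2) if rd >= params.radius_min]
                if not daughters:
                    continue
                if params.branching_reference == "root":
                    u = root_dir
                else:
                    u = np.asarray(parent.p1) - np.asarray(parent.p0)
                    u = u / np.linalg.norm(u)
                if isinstance(params.rotation_angle_rule, (int, float)):
                    phi_state += np.deg2rad(float(params.rotation_angle_rule))
                    phi0 = phi_state
                else:
                    phi0 = rng.uniform(0, 2 * np.pi)
                placed_any = False
                for k, rd in enumerate(daughters):
                    for _try in range(params.max_retries):
                        theta = rng.uniform(lo, hi)
                        phi = phi0 + np.pi * k + (rng.uniform(-0.5, 0.5) if _try else 0.0)
                        perp = _rotate_about(_perpendicular(u), u, phi)
                        new_dir = _rotate_about(u, np.cross(u, perp), theta)
                        new_dir /= np.linalg.norm(new_dir)
                        p0 = np.asarray(parent.p1)
                        p1 = p0 + new_dir * params.length_to_radius_ratio * rd
                        cand = Capsule(tuple(p0), tuple(p1), rd)
                        skip = {tip_idx}
                        # siblings share the junction point; exempt the one just placed
                        if placed_any:
                            skip.add(len(segments) - 1)
                        if _segments_collide(cand, segments, skip, box_size):
                            continue
                        segments.append(cand)
                        new_tips.append(len(segments) - 1)
                        placed_any = True
                        _paint_primitive(labels_grid, cand, vsz)
                        if np.count_nonzero(labels_grid) >= target_count:
                            done = True
                        break
                    if done:
                        break
                if placed_any:
                    bifurcations.append((rp, rd1, rd2))
                if done:
                    break
            tips = new_tips
        if done:
            break
    achieved = np.count_nonzero(labels_grid) / labels_grid.size
    if not done and achieved < 0.5 * params.target_volume_fraction:
        raise PackingError(
            f"vascular network growth terminated at fraction {achieved:.4f} "
            f"(target {params.target_volume_fraction})",
            achieved=achieved,
        )
    return Scene(segments, box_size, params.seed, metadata={"bifurcations": bifurcations})


# ---------------------------------------------------------------------------
# Cells around vessels
# ---------------------------------------------------------------------------


def pack_cells_around_vessels(
    vessel_scene: Scene,
    cell_mean_radius: float,
    target_cell_fraction: float,
    seed: int,
    aspect_ratios: tuple[float, float, float] | None = None,
    max_sweeps: int = 15000,
    attempts: int = 3,
) -> Scene:
    """Pack ellipsoidal cells around a fixed vascular scene.

    Cells never intersect each other (exact pair test) nor the vessels
    (conservative bounding-radius clearance from each vessel axis).  The
    combined scene carries both compartment labels.  As in
    :func:`generate_ellipsoid_packing`, a stalled arrangement is redrawn up
    to ``attempts`` times before the target is declared infeasible.
    """
    if target_cell_fraction == 0:
        return Scene(list(vessel_scene.primitives), vessel_scene.box_size, seed,
                     metadata=dict(vessel_scene.metadata))
    box = vessel_scene.box_size
    mean_vol = (4 / 3) * np.pi * cell_mean_radius**3
    n = max(1, int(round(target_cell_fraction * box**3 / mean_vol)))
    obstacles = [p for p in vessel_scene.primitives if isinstance(p, (Capsule, Cylinder))]
    last_err: PackingError | None = None
    def _clear_of_vessels(c: np.ndarray) -> bool:
        for obs in obstacles:
            if isinstance(obs, Capsule):
                a, bb = np.asarray(obs.p0), np.asarray(obs.p1)
            else:
                pt, u = np.asarray(obs.point), np.asarray(obs.direction)
                a, bb = pt - 10 * box * u, pt + 10 * box * u
            if _segment_segment_distance(c, c, a, bb) < obs.radius:
                return False
        return True

    for attempt in range(attempts):
        rng = np.random.default_rng((seed + 900001 * attempt) % (2**31 - 1))
        ells = []
        for _ in range(n):
            if aspect_ratios is None:
                a = rng.uniform(0.6, 0.9)
                rel = np.array([a, a, 1.0])
            else:
                rel = np.asarray(aspect_ratios)
            req = cell_mean_radius * rng.uniform(0.9, 1.1)
            axes = rel * req / np.prod(rel) ** (1 / 3)
            # seed centers outside the vessel lumen so the early dynamics
            # need not expel cells from inside the obstacles
            for _try in range(50):
                c = rng.uniform(0, box, 3)
                if _clear_of_vessels(c):
                    break
            ells.append(
                Ellipsoid(
                    tuple(c),
                    tuple(axes),
                    tuple(map(tuple, _random_rotation(rng))),
                    label=LABEL_CELL,
                )
            )
        actual_vf = sum((4 / 3) * np.pi * np.prod(e.semiaxes) for e in ells) / box**3
        norm = (target_cell_fraction / actual_vf) ** (1 / 3)
        ells = [
            Ellipsoid(e.center, tuple(np.asarray(e.semiaxes) * norm), e.rotation, label=e.label)
            for e in ells
        ]
        start = min(1.0, (0.2 / target_cell_fraction) ** (1 / 3))
        packer = _EllipsoidPacker(ells, box, rng, obstacles=obstacles, max_sweeps=max_sweeps)
        try:
            packed = packer.pack(start_scale=start)
            prims = list(vessel_scene.primitives) + packed
            return Scene(prims, box, seed, metadata=dict(vessel_scene.metadata))
        except PackingError as err:
            last_err = err
    raise last_err


# ---------------------------------------------------------------------------
# Mask I/O
# ---------------------------------------------------------------------------


def save_mask(model: TissueModel, path: str | Path) -> None:
    """Write a labeled mask as NIfTI, TIFF stack, or raw binary + JSON sidecar."""
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([model.voxel_size, model.voxel_size, model.voxel_size, 1.0])
        nib.save(nib.Nifti1Image(model.labels.astype(np.uint8), affine), str(path))
    elif suffix.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(str(path), model.labels.astype(np.uint8))
    elif suffix.endswith(".raw"):
        model.labels.astype(np.uint8).tofile(path)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {"shape": list(model.grid_shape), "dtype": "uint8", "voxel_size": model.voxel_size}
            )
        )
    else:
        raise ValueError(f"unsupported mask format: {path.name}")


def import_mask(
    path: str | Path,
    voxel_size: float | None = None,
    label_convention: dict | None = None,
) -> TissueModel:
    """Read a 3D labeled/binary mask from NIfTI, TIFF stack, or raw + sidecar.

    ``label_convention`` optionally maps stored values to compartment labels
    (e.g. {255: 1}).  Binary masks default to 0 = EES, nonzero = vascular.
    """
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if voxel_size is None:
            voxel_size = float(img.header.get_zooms()[0])
    elif suffix.endswith((".tif", ".tiff")):
        import tifffile

        data = tifffile.imread(str(path))
        if voxel_size is None:
            raise ValueError("voxel_size required for TIFF masks")
    elif suffix.endswith(".raw"):
        sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text())
        data = np.fromfile(path, dtype=meta["dtype"]).reshape(meta["shape"])
        if voxel_size is None:
            voxel_size = float(meta["voxel_size"])
    else:
        raise ValueError(f"unsupported mask format: {path.name}")
    if data.ndim != 3:
        raise ValueError("mask must be a 3D array")
    data = np.asarray(data)
    if label_convention:
        out = np.zeros(data.shape, dtype=np.int8)
        for stored, lab in label_convention.items():
            out[data == stored] = lab
        data = out
    else:
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, [0, 1, 2])):
            if len(uniq) <= 2:
                data = (data != 0).astype(np.int8) * LABEL_VASCULAR
            else:
                raise ValueError(
                    "mask is not binary and no label_convention mapping was given"
                )
    return TissueModel(data.astype(np.int8), float(voxel_size))


def subdivide_mask(model: TissueModel, block_size: int) -> list[tuple[TissueModel, float]]:
    """Cut a large mask into cubic MR-voxel-sized blocks.

    Returns (block, vascular volume fraction) pairs in raster order.  The grid
    must divide evenly into cubic blocks.
    """
    n = model.grid_shape[0]
    if n % block_size != 0:
        raise ValueError(f"grid of {n}³ does not divide into cubic {block_size}³ blocks")
    k = n // block_size
    out = []
    for i in range(k):
        for j in range(k):
            for m in range(k):
                sub = model.labels[
                    i * block_size : (i + 1) * block_size,
                    j * block_size : (j + 1) * block_size,
                    m * block_size : (m + 1) * block_size,
                ]
                block = TissueModel(sub.copy(), model.voxel_size)
                out.append((block, block.volume_fraction(LABEL_VASCULAR)))
    return out
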