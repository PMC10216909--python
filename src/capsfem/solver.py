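"""Static large-deformation membrane finite-element solver.

Total-Lagrangian, constant-strain triangle membranes: each element carries a
2x2 in-plane Green-Lagrange strain computed from the metric of its deformed
edge vectors expressed in a reference tangent basis.  Hyperelastic regions
are incompressible with the thickness stretch eliminated analytically
(lambda3 = 1/(lambda1 lambda2)); the labrum uses a plane-stress Saint
Venant-Kirchhoff law.  Loads are a follower (pressure) load on the deformed
surface, optional frictionless penalty contact against a rigid humeral-head
sphere, and prescribed motion of the attachment rings (fixed scapular side,
rigid rotation of the humeral side).

Equilibrium at each rotation step is found by damped Newton iteration with an
adaptively regularized tangent (a Levenberg-style diagonal shift handles the
indefinite tangents produced by the softening axillary-pouch constants and
by membrane compression) and a backtracking line search on the residual
norm.  The tangent is assembled from central finite differences of the
analytic element force vectors, so the converged solution accuracy is set by
the analytic residual alone.  The solver is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .geometry import CapsuleMesh, rotate_about_axis
from .materials import LinearElasticMaterial, RegionMaterial

logger = logging.getLogger(__name__)

__all__ = [
    "Sphere",
    "LoadCase",
    "SolveState",
    "StrainField",
    "SolverError",
    "default_schedule",
    "element_strain",
    "element_internal_force",
    "pressure_load",
    "contact_force",
    "strain_field",
    "total_strain_energy",
    "MembraneModel",
    "solve_equilibrium",
    "solve_static",
]


@dataclass(frozen=True)
class Sphere:
    """Analytic rigid sphere (humeral head) for penalty contact."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.radius <= 0.0:
            raise ValueError("sphere radius must be positive")


@dataclass(frozen=True)
class LoadCase:
    """Boundary conditions and loads for one capsule scenario.

    Angles in degrees, pressure in MPa (0.7 kPa synovial pressure = 7e-4).
    ``released_nodes`` are attachment nodes excluded from the fixed sets
    (the lesion); they must be a subset of the nodes the fixed sets pin.
    """

    rotation_schedule: tuple = tuple(np.linspace(0.0, 30.0, 11))
    rotation_axis: np.ndarray = (0.0, -np.sin(np.radians(60.0)), -np.cos(np.radians(60.0)))
    rotation_center: np.ndarray = (0.0, 0.0, 10.0)
    internal_pressure: float = 7e-4
    humeral_head: Sphere | None = None
    contact_stiffness: float = 10.0  # N/mm per node
    fixed_sets: tuple = ("glenoid_ring",)
    driven_set: str = "humeral_ring"
    released_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    def __post_init__(self) -> None:
        sched = np.asarray(self.rotation_schedule, dtype=float)
        if len(sched) == 0 or sched[0] != 0.0:
            raise ValueError("rotation schedule must start at 0 degrees")
        if np.any(np.diff(sched) <= 0.0):
            raise ValueError("rotation schedule must be strictly increasing")
        object.__setattr__(self, "rotation_schedule", tuple(sched))
        axis = np.asarray(self.rotation_axis, dtype=float)
        if np.linalg.norm(axis) < 1e-12:
            raise ValueError("rotation axis is degenerate")
        object.__setattr__(self, "rotation_axis", axis / np.linalg.norm(axis))
        object.__setattr__(
            self, "rotation_center", np.asarray(self.rotation_center, dtype=float)
        )
        object.__setattr__(
            self, "released_nodes", np.asarray(self.released_nodes, dtype=np.int64)
        )
        if self.contact_stiffness <= 0.0:
            raise ValueError("contact penalty stiffness must be positive")


def default_schedule(target_deg: float = 30.0, n_steps: int = 10) -> tuple:
    """Monotone rotation schedule 0 -> target in ``n_steps`` increments."""
    if target_deg == 0.0:
        return (0.0,)
    return tuple(np.linspace(0.0, float(target_deg), n_steps + 1))


@dataclass
class SolveState:
    """Converged (or last attempted) configuration at one rotation step."""

    displacements: np.ndarray  # (N, 3) mm
    converged: bool
    residual_norm: float
    step_angle: float
    n_iterations: int = 0


@dataclass
class StrainField:
    """Per-element in-plane Green-Lagrange strain state."""

    green_lagrange: np.ndarray  # (E, 2, 2)
    max_principal: np.ndarray  # (E,)
    min_principal: np.ndarray  # (E,)
    region_of_element: np.ndarray
    element_areas: np.ndarray  # reference areas, mm^2


class SolverError(RuntimeError):
    """Non-convergence; carries the states solved so far and diagnostics."""

    def __init__(self, message, states=None, history=None):
        super().__init__(message)
        self.states = states or []
        self.history = history or []


# ---------------------------------------------------------------------------
# Element kinematics
# ---------------------------------------------------------------------------


def _tangent_frame(ref_nodes: np.ndarray, triangles: np.ndarray):
    """Reference in-plane edge matrices R (upper triangular), inverses, areas."""
    u1 = ref_nodes[triangles[:, 1]] - ref_nodes[triangles[:, 0]]
    u2 = ref_nodes[triangles[:, 2]] - ref_nodes[triangles[:, 0]]
    l1 = np.linalg.norm(u1, axis=1)
    if np.any(l1 < 1e-14):
        raise ValueError("degenerate reference triangle (zero edge)")
    e1 = u1 / l1[:, None]
    n = np.cross(u1, u2)
    nn = np.linalg.norm(n, axis=1)
    if np.any(nn < 1e-14):
        raise ValueError("degenerate reference triangle (zero area)")
    e2 = np.cross(n / nn[:, None], e1)
    r12 = np.einsum("ij,ij->i", u2, e1)
    r22 = np.einsum("ij,ij->i", u2, e2)
    R = np.zeros((len(triangles), 2, 2))
    R[:, 0, 0] = l1
    R[:, 0, 1] = r12
    R[:, 1, 1] = r22
    Rinv = np.zeros_like(R)
    Rinv[:, 0, 0] = 1.0 / l1
    Rinv[:, 0, 1] = -r12 / (l1 * r22)
    Rinv[:, 1, 1] = 1.0 / r22
    areas = 0.5 * nn
    return R, Rinv, areas


def _metric(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    G = np.empty(d1.shape[:-1] + (2, 2))
    G[..., 0, 0] = np.einsum("...i,...i", d1, d1)
    G[..., 0, 1] = G[..., 1, 0] = np.einsum("...i,...i", d1, d2)
    G[..., 1, 1] = np.einsum("...i,...i", d2, d2)
    return G


def element_strain(reference_triangle, deformed_triangle) -> np.ndarray:
    """In-plane Green-Lagrange tensor of the affine map between two triangles.

    Computed from the difference of edge metrics in the reference tangent
    basis, E = Rinv^T (G_def - G_ref) Rinv / 2, which is exactly zero for an
    identical (or rigidly moved) triangle and objective by construction.
    """
    ref = np.asarray(reference_triangle, dtype=float).reshape(3, 3)
    cur = np.asarray(deformed_triangle, dtype=float).reshape(3, 3)
    tri = np.array([[0, 1, 2]])
    _, Rinv, _ = _tangent_frame(ref, tri)
    Ri = Rinv[0]
    Gr = _metric(ref[1] - ref[0], ref[2] - ref[0])
    Gd = _metric(cur[1] - cur[0], cur[2] - cur[0])
    return 0.5 * Ri.T @ (Gd - Gr) @ Ri


# ---------------------------------------------------------------------------
# Constitutive response on the membrane
# ---------------------------------------------------------------------------


def _second_pk(material, E: np.ndarray) -> np.ndarray:
    """In-plane second Piola-Kirchhoff stress from the in-plane GL strain.

    Incompressible hyperelastic: S = 2 W1 (I - C^-1/det C) (+ I2 terms when
    the model has them), with the thickness stretch lambda3^2 = 1/det C.
    Linear-elastic (labrum): plane-stress Saint Venant-Kirchhoff.
    """
    C = 2.0 * E.copy()
    C[..., 0, 0] += 1.0
    C[..., 1, 1] += 1.0
    if isinstance(material, LinearElasticMaterial):
        lam = material.plane_stress_lambda
        mu = material.shear_modulus
        trE = E[..., 0, 0] + E[..., 1, 1]
        S = 2.0 * mu * E
        S[..., 0, 0] += lam * trE
        S[..., 1, 1] += lam * trE
        return S
    detC = C[..., 0, 0] * C[..., 1, 1] - C[..., 0, 1] * C[..., 1, 0]
    if np.any(detC <= 0.0):
        bad = np.flatnonzero(np.atleast_1d(detC) <= 0.0)
        raise FloatingPointError(
            f"non-physical in-plane compression (det C <= 0) in elements {bad[:10]}"
        )
    trC = C[..., 0, 0] + C[..., 1, 1]
    i1 = trC + 1.0 / detC
    Cinv = np.empty_like(C)
    Cinv[..., 0, 0] = C[..., 1, 1]
    Cinv[..., 1, 1] = C[..., 0, 0]
    Cinv[..., 0, 1] = -C[..., 0, 1]
    Cinv[..., 1, 0] = -C[..., 1, 0]
    Cinv /= detC[..., None, None]
    W1 = np.asarray(material.dW_dI1(i1))
    eye = np.zeros_like(C)
    eye[..., 0, 0] = eye[..., 1, 1] = 1.0
    S = 2.0 * W1[..., None, None] * (eye - Cinv / detC[..., None, None])
    W2 = np.asarray(material.dW_dI2(i1))
    if np.any(W2 != 0.0):
        S += 2.0 * W2[..., None, None] * (
            detC[..., None, None] * Cinv
            + eye / detC[..., None, None]
            - (trC / detC)[..., None, None] * Cinv
        )
    return S


def _energy_density(material, E: np.ndarray) -> np.ndarray:
    C = 2.0 * E.copy()
    C[..., 0, 0] += 1.0
    C[..., 1, 1] += 1.0
    if isinstance(material, LinearElasticMaterial):
        lam = material.plane_stress_lambda
        mu = material.shear_modulus
        trE = E[..., 0, 0] + E[..., 1, 1]
        sqE = np.einsum("...ij,...ij", E, E)
        return 0.5 * lam * trE**2 + mu * sqE
    detC = C[..., 0, 0] * C[..., 1, 1] - C[..., 0, 1] * C[..., 1, 0]
    if np.any(detC <= 0.0):
        raise FloatingPointError("non-physical in-plane compression (det C <= 0)")
    trC = C[..., 0, 0] + C[..., 1, 1]
    i1 = trC + 1.0 / detC
    if hasattr(material, "c3") or not hasattr(material, "energy"):
        return np.asarray(material.energy(i1))
    i2 = detC + trC / detC
    return np.asarray(material.energy(i1, i2))


# ---------------------------------------------------------------------------
# Assembled model
# ---------------------------------------------------------------------------


class MembraneModel:
    """Precomputed element data binding a mesh to its regional materials."""

    def __init__(self, mesh: CapsuleMesh, materials: Mapping[str, RegionMaterial]):
        mesh.validate()
        self.mesh = mesh
        self.triangles = mesh.triangles
        _, self.Rinv, self.areas = _tangent_frame(mesh.nodes, mesh.triangles)
        d1 = mesh.nodes[self.triangles[:, 1]] - mesh.nodes[self.triangles[:, 0]]
        d2 = mesh.nodes[self.triangles[:, 2]] - mesh.nodes[self.triangles[:, 0]]
        self.G_ref = _metric(d1, d2)
        self.thickness = mesh.thickness_of_element
        missing = [r for r in mesh.regions() if r not in materials]
        if missing:
            raise ValueError(f"no material given for regions: {missing}")
        self.material_of_element = np.array(
            [materials[r].material for r in mesh.region_of_element], dtype=object
        )
        self.groups = [
            (materials[r].material, mesh.elements_of_region(r)) for r in mesh.regions()
        ]
        self._ha = (self.thickness * self.areas)[:, None]

    # -- strain ------------------------------------------------------------

    def strains_from_coords(self, tri_coords: np.ndarray) -> np.ndarray:
        """(E, 2, 2) GL strain from per-element node coordinates (E, 3, 3)."""
        Gd = _metric(
            tri_coords[:, 1] - tri_coords[:, 0], tri_coords[:, 2] - tri_coords[:, 0]
        )
        return 0.5 * np.einsum(
            "eji,ejk,ekl->eil", self.Rinv, Gd - self.G_ref, self.Rinv
        )

    def strains(self, x: np.ndarray) -> np.ndarray:
        return self.strains_from_coords(x[self.triangles])

    # -- internal forces ---------------------------------------------------

    def element_internal_forces(self, tri_coords: np.ndarray) -> np.ndarray:
        """(E, 3, 3) nodal internal forces from element coords (E, 3, 3)."""
        E = self.strains_from_coords(tri_coords)
        S = np.empty_like(E)
        for mat, idx in self.groups:
            S[idx] = _second_pk(mat, E[idx])
        M = np.einsum("eij,ejk,elk->eil", self.Rinv, S, self.Rinv)
        d1 = tri_coords[:, 1] - tri_coords[:, 0]
        d2 = tri_coords[:, 2] - tri_coords[:, 0]
        g1 = self._ha * (M[:, 0, 0, None] * d1 + M[:, 0, 1, None] * d2)
        g2 = self._ha * (M[:, 0, 1, None] * d1 + M[:, 1, 1, None] * d2)
        f = np.empty_like(tri_coords)
        f[:, 1] = g1
        f[:, 2] = g2
        f[:, 0] = -(g1 + g2)
        return f

    def internal_forces(self, x: np.ndarray) -> np.ndarray:
        f = np.zeros_like(x)
        fe = self.element_internal_forces(x[self.triangles])
        np.add.at(f, self.triangles, fe)
        return f

    def strain_energy(self, x: np.ndarray) -> float:
        E = self.strains(x)
        total = 0.0
        for mat, idx in self.groups:
            w = _energy_density(mat, E[idx])
            total += float(np.sum(w * self.thickness[idx] * self.areas[idx]))
        return total


# ---------------------------------------------------------------------------
# External loads
# ---------------------------------------------------------------------------


def _element_pressure_forces(tri_coords: np.ndarray, pressure: float) -> np.ndarray:
    """Follower pressure nodal forces per element, (E, 3, 3).

    Discretized conservatively as p times the gradient of the enclosed
    volume, f_a = (p/6) x_b x x_c (cyclic).  On interior nodes this is
    identical to the familiar p * (current area) * normal / 3 rule (the edge
    terms cancel around every interior node); it differs only on free
    boundary nodes, where it corresponds to closing the pressurized cavity,
    and it makes the pressure an exact potential load.
    """
    a, b, c = tri_coords[:, 0], tri_coords[:, 1], tri_coords[:, 2]
    f = np.empty_like(tri_coords)
    f[:, 0] = np.cross(b, c)
    f[:, 1] = np.cross(c, a)
    f[:, 2] = np.cross(a, b)
    return (pressure / 6.0) * f


def _assemble_pressure(nodes: np.ndarray, triangles: np.ndarray, pressure: float) -> np.ndarray:
    """Assembled conservative pressure loads (solver-internal)."""
    f = np.zeros_like(nodes, dtype=float)
    fe = _element_pressure_forces(np.asarray(nodes, float)[triangles], pressure)
    np.add.at(f, triangles, fe)
    return f


def pressure_load(nodes: np.ndarray, triangles: np.ndarray, pressure: float) -> np.ndarray:
    """Follower-pressure nodal loads: p * (current area) * normal / 3 per node.

    This is the classical lumped follower load.  It agrees with the
    solver-internal conservative (volume-gradient) variant on every interior
    node and on closed surfaces; the two differ only in how the pressure
    edge force of an open boundary is attributed.
    """
    x = np.asarray(nodes, dtype=float)
    nvec = np.cross(
        x[triangles[:, 1]] - x[triangles[:, 0]],
        x[triangles[:, 2]] - x[triangles[:, 0]],
    )
    f = np.zeros_like(x)
    fe = np.repeat(((pressure / 6.0) * nvec)[:, None, :], 3, axis=1)
    np.add.at(f, triangles, fe)
    return f


def contact_force(
    nodes: np.ndarray, sphere: Sphere, penalty_stiffness: float
) -> np.ndarray:
    """Frictionless radial penalty force on nodes penetrating the sphere."""
    if penalty_stiffness <= 0.0:
        raise ValueError("penalty stiffness must be positive")
    x = np.asarray(nodes, dtype=float)
    rel = x - sphere.center
    r = np.linalg.norm(rel, axis=-1)
    depth = np.maximum(sphere.radius - r, 0.0)
    f = np.zeros_like(x)
    mask = depth > 0.0
    if np.any(mask):
        f[mask] = (penalty_stiffness * depth[mask] / r[mask])[:, None] * rel[mask]
    return f


# ---------------------------------------------------------------------------
# Equilibrium solve
# ---------------------------------------------------------------------------


def _assemble_tangent(model, x, pressure, sphere, k_contact, fd_step):
    """Dense tangent by central finite differences of analytic element forces."""
    n_dof = x.size
    K = np.zeros((n_dof, n_dof))
    tri = model.triangles
    coords = x[tri]
    blocks = np.zeros((len(tri), 9, 9))
    for a in range(3):
        for k in range(3):
            dp = coords.copy()
            dm = coords.copy()
            dp[:, a, k] += fd_step
            dm[:, a, k] -= fd_step
            col = model.element_internal_forces(dp) - model.element_internal_forces(dm)
            if pressure != 0.0:
                col -= _element_pressure_forces(dp, pressure) - _element_pressure_forces(
                    dm, pressure
                )
            blocks[:, :, 3 * a + k] = col.reshape(len(tri), 9) / (2.0 * fd_step)
    dofs = (3 * tri[:, :, None] + np.arange(3)[None, None, :]).reshape(len(tri), 9)
    np.add.at(K, (dofs[:, :, None], dofs[:, None, :]), blocks)
    if sphere is not None:
        rel = x - sphere.center
        r = np.linalg.norm(rel, axis=1)
        near = np.flatnonzero(r < sphere.radius + 10.0 * fd_step)
        for i in near:
            for k in range(3):
                xp, xm = x[i].copy(), x[i].copy()
                xp[k] += fd_step
                xm[k] -= fd_step
                df = contact_force(xp[None], sphere, k_contact)[0] - contact_force(
                    xm[None], sphere, k_contact
                )[0]
                K[3 * i : 3 * i + 3, 3 * i + k] -= df / (2.0 * fd_step)
    return K


def _enclosed_volume(x: np.ndarray, triangles: np.ndarray) -> float:
    """Signed volume swept by the oriented surface (pressure potential / p)."""
    a, b, c = x[triangles[:, 0]], x[triangles[:, 1]], x[triangles[:, 2]]
    return float(np.einsum("ij,ij->", a, np.cross(b, c))) / 6.0


def solve_equilibrium(
    model: MembraneModel,
    x0: np.ndarray,
    free_mask: np.ndarray,
    pressure: float = 0.0,
    sphere: Sphere | None = None,
    contact_stiffness: float = 10.0,
    tol_rel: float = 1e-6,
    max_iter: int = 50,
) -> tuple[np.ndarray, dict]:
    """Equilibrium on the free dofs: damped Newton with energy globalization.

    ``x0`` must already carry the prescribed node positions; ``free_mask`` is
    an (N, 3) boolean array of unconstrained dofs.  A regularized damped
    Newton iteration is tried first; if it stalls — the softening regional
    constants and membrane compression make the tangent indefinite — the
    total potential (strain energy - pressure * enclosed volume + contact
    penalty) is minimized by L-BFGS to globalize, and Newton then polishes.
    Convergence requires the free-dof residual norm to fall below
    ``tol_rel`` times a reference force (the larger of the external load
    norm and the predictor residual norm).
    """
    x = x0.copy()
    free = free_mask.ravel()
    tri = model.triangles
    fd_step = 1e-6 * max(np.sqrt(2.0 * float(np.mean(model.areas))), 1e-3)

    def residual(xc):
        r = model.internal_forces(xc)
        if pressure != 0.0:
            r -= _assemble_pressure(xc, tri, pressure)
        if sphere is not None:
            r -= contact_force(xc, sphere, contact_stiffness)
        return r.ravel()[free]

    def external_norm(xc):
        f = np.zeros_like(xc)
        if pressure != 0.0:
            f += _assemble_pressure(xc, tri, pressure)
        if sphere is not None:
            f += contact_force(xc, sphere, contact_stiffness)
        return float(np.linalg.norm(f.ravel()[free]))

    def potential(xc):
        p = model.strain_energy(xc)
        if pressure != 0.0:
            p -= pressure * _enclosed_volume(xc, tri)
        if sphere is not None:
            r = np.linalg.norm(xc - sphere.center, axis=1)
            depth = np.maximum(sphere.radius - r, 0.0)
            p += 0.5 * contact_stiffness * float(np.sum(depth**2))
        return p

    def _lbfgs_globalize(x_in, maxiter=4000):
        from scipy.optimize import minimize

        def fun(q):
            xc = x_in.copy()
            xc.ravel()[free] = q
            try:
                return potential(xc), residual(xc)
            except FloatingPointError:
                return 1e30, np.zeros(int(free.sum()))

        sol = minimize(
            fun,
            x_in.ravel()[free],
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-16, "gtol": 1e-12},
        )
        x_out = x_in.copy()
        x_out.ravel()[free] = sol.x
        return x_out

    R = residual(x)
    rnorm = float(np.linalg.norm(R))
    ref = max(external_norm(x), rnorm)
    if ref == 0.0:
        return x, {"converged": True, "iterations": 0, "residual_norm": 0.0,
                   "history": [0.0]}
    tol = tol_rel * ref
    history = [rnorm]
    mu = 0.0
    it = 0
    globalized = 0
    while rnorm > tol and it < max_iter:
        K = _assemble_tangent(model, x, pressure, sphere, contact_stiffness, fd_step)
        Kff = K[np.ix_(free, free)]
        dscale = max(float(np.mean(np.abs(np.diag(Kff)))), 1e-12)
        accepted = False
        for _ in range(15):
            A = Kff + (mu + 1e-10) * dscale * np.eye(Kff.shape[0])
            try:
                dx = np.linalg.solve(A, -R)
            except np.linalg.LinAlgError:
                mu = max(10.0 * mu, 1e-6)
                continue
            alpha = 1.0
            while alpha > 2.0**-11:
                x_try = x.copy()
                x_try.ravel()[free] += alpha * dx
                try:
                    R_try = residual(x_try)
                except FloatingPointError:
                    alpha *= 0.5
                    continue
                r_try = float(np.linalg.norm(R_try))
                if r_try < rnorm * (1.0 - 1e-4 * alpha) or r_try < tol:
                    x, R, rnorm = x_try, R_try, r_try
                    accepted = True
                    break
                alpha *= 0.5
            if accepted:
                mu = mu / 3.0 if mu > 1e-8 else 0.0
                break
            mu = max(10.0 * mu, 1e-6)
        stalled = (not accepted) or (
            len(history) >= 5 and rnorm > 0.5 * history[-5]
        )
        if stalled and globalized < 4:
            # indefinite tangent (material softening / membrane compression):
            # globalize by minimizing the total potential, then keep polishing
            globalized += 1
            x = _lbfgs_globalize(x)
            R = residual(x)
            rnorm = float(np.linalg.norm(R))
            mu = 0.0
        elif not accepted:
            break
        history.append(rnorm)
        it += 1
    return x, {
        "converged": bool(rnorm <= tol),
        "iterations": it,
        "residual_norm": rnorm,
        "history": history,
    }


def solve_static(
    mesh: CapsuleMesh,
    materials: Mapping[str, RegionMaterial],
    load_case: LoadCase,
    tol_rel: float = 1e-6,
    max_iter: int = 50,
) -> list[SolveState]:
    """March the rotation schedule, solving a static equilibrium per step.

    The humeral-ring nodes follow the rigid rotation map exactly; fixed-set
    nodes (minus any released lesion nodes) stay at their reference
    positions.  Each step starts from the previous converged state.  Raises
    :class:`SolverError` with diagnostics on non-convergence.
    """
    model = MembraneModel(mesh, materials)
    fixed = set()
    for name in load_case.fixed_sets:
        if name not in mesh.node_sets:
            raise ValueError(f"mesh has no node set {name!r}")
        fixed.update(mesh.node_sets[name].tolist())
    released = set(load_case.released_nodes.tolist())
    if not released <= fixed:
        raise ValueError("released nodes must be a subset of the fixed sets")
    fixed -= released
    if load_case.driven_set not in mesh.node_sets:
        raise ValueError(f"mesh has no node set {load_case.driven_set!r}")
    driven = mesh.node_sets[load_case.driven_set]

    free_mask = np.ones_like(mesh.nodes, dtype=bool)
    fixed_idx = np.array(sorted(fixed), dtype=np.int64)
    if len(fixed_idx):
        free_mask[fixed_idx] = False
    free_mask[driven] = False

    X = mesh.nodes
    x = X.copy()
    states: list[SolveState] = []
    for angle in load_case.rotation_schedule:
        x0 = x.copy()
        if len(fixed_idx):
            x0[fixed_idx] = X[fixed_idx]
        x0[driven] = rotate_about_axis(
            X[driven],
            load_case.rotation_axis,
            np.radians(angle),
            center=load_case.rotation_center,
        )
        x, info = solve_equilibrium(
            model,
            x0,
            free_mask,
            pressure=load_case.internal_pressure,
            sphere=load_case.humeral_head,
            contact_stiffness=load_case.contact_stiffness,
            tol_rel=tol_rel,
            max_iter=max_iter,
        )
        state = SolveState(
            displacements=x - X,
            converged=info["converged"],
            residual_norm=info["residual_norm"],
            step_angle=float(angle),
            n_iterations=info["iterations"],
        )
        logger.info(
            "step %.2f deg: %d Newton iterations, residual %.3e",
            angle,
            info["iterations"],
            info["residual_norm"],
        )
        states.append(state)
        if not info["converged"]:
            raise SolverError(
                f"no convergence at {angle} deg after {info['iterations']} "
                f"iterations (residual {info['residual_norm']:.3e}); "
                f"history={['%.2e' % h for h in info['history'][-6:]]}",
                states=states,
                history=info["history"],
            )
    return states


# ---------------------------------------------------------------------------
# Per-element convenience operations and post-processing
# ---------------------------------------------------------------------------


def element_internal_force(
    material, thickness: float, reference_triangle, deformed_triangle
) -> np.ndarray:
    """Nodal internal force vectors (3, 3) of a single membrane triangle."""
    ref = np.asarray(reference_triangle, dtype=float).reshape(1, 3, 3)
    cur = np.asarray(deformed_triangle, dtype=float).reshape(1, 3, 3)
    tri = np.array([[0, 1, 2]])
    mesh = CapsuleMesh(
        ref[0],
        tri,
        np.array(["one"], dtype=object),
        np.array([thickness]),
        {},
    )
    model = MembraneModel(mesh, {"one": RegionMaterial(material, thickness)})
    return model.element_internal_forces(cur)[0]


def strain_field(mesh: CapsuleMesh, displacements: np.ndarray) -> StrainField:
    """Green-Lagrange strain tensors and principal strains for a solved state."""
    model = MembraneModel(
        mesh,
        {
            r: RegionMaterial(LinearElasticMaterial(1.0, 0.3), 1.0)
            for r in mesh.regions()
        },
    )
    E = model.strains(mesh.nodes + np.asarray(displacements, dtype=float))
    mean = 0.5 * (E[:, 0, 0] + E[:, 1, 1])
    rad = np.sqrt(0.25 * (E[:, 0, 0] - E[:, 1, 1]) ** 2 + E[:, 0, 1] ** 2)
    return StrainField(
        green_lagrange=E,
        max_principal=mean + rad,
        min_principal=mean - rad,
        region_of_element=mesh.region_of_element,
        element_areas=model.areas,
    )


def total_strain_energy(
    mesh: CapsuleMesh,
    materials: Mapping[str, RegionMaterial],
    displacements: np.ndarray,
) -> float:
    """Total membrane strain energy (N*mm) of a displaced configuration."""
    model = MembraneModel(mesh, materials)
    return model.strain_energy(mesh.nodes + np.asarray(displacements, dtype=float))
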