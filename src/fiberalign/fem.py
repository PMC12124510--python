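"""Plane-stress neo-Hookean FE model of cell-contraction-driven shrinkage.

The dog-bone construct's cell-laden central strip (4 mm wide, 10 mm
between the anchor bars, 1 mm thick) is meshed with bilinear
quadrilaterals and deforms because the embedded cells contract the gel.  Contraction is imposed as a stress-free
linear shrinkage strain ``eps_s`` through a multiplicative split of the
deformation gradient,

    F = F_e F_s,   F_s = (1 - eps_s) I  in cell-laden elements,

so an unconstrained patch shrinks to in-plane stretch (1 - eps_s) with
zero stress.  The elastic part carries a compressible neo-Hookean strain
energy (shear term in the isochoric first invariant, volumetric penalty
in (J_el - 1)^2):

    psi = E / (4 (1 + nu)) (I1_bar - 3) + E / (6 (1 - 2 nu)) (J_el - 1)^2

with E = 700 Pa and nu = 0.4 for collagen gel.  Plane stress is enforced
pointwise: the out-of-plane elastic stretch at each quadrature point is
solved by a scalar Newton iteration so the transverse stress vanishes.

The two anchor-interface ends are fully fixed; the long lateral edges
are free, so the strip necks as it contracts.  The total-Lagrangian equilibrium is solved
by ramped load increments with a Newton iteration per increment; the
internal-force vector is the analytic gradient of the total strain energy
(the plane-stress condensation drops out by the envelope theorem), and
the tangent is assembled by forward differences of the element forces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


class FEMError(RuntimeError):
    pass


class NewtonDivergence(FEMError):
    """Newton iteration failed to converge at the current load level."""


# ---------------------------------------------------------------------------
# geometry, material, load, mesh
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Geometry:
    """Dog-bone construct geometry, mm.

    The cell-laden gauge strip is ``center_w`` wide (x) and ``center_h``
    long (y); the 2 x 10 mm anchor bars lie across its two short ends,
    10 mm apart, so y is the inter-anchor / contraction axis (at 90
    degrees in the angle convention) and the two long edges are free.
    """

    center_w: float = 4.0
    center_h: float = 10.0
    wing_h: float = 2.0
    thickness: float = 1.0
    element_size_um: float = 100.0
    include_wings: bool = False

    def __post_init__(self) -> None:
        if min(self.center_w, self.center_h, self.wing_h, self.thickness,
               self.element_size_um) <= 0:
            raise FEMError("all geometry dimensions must be positive")

    @property
    def h(self) -> float:
        """Element edge length in mm."""
        return self.element_size_um / 1000.0


@dataclass(frozen=True)
class Material:
    E: float = 700.0   # Pa
    nu: float = 0.4

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise FEMError("E must be positive")
        if not 0.0 <= self.nu < 0.5:
            raise FEMError("nu must lie in [0, 0.5)")

    @property
    def c1(self) -> float:
        return self.E / (4.0 * (1.0 + self.nu))

    @property
    def c2(self) -> float:
        return self.E / (6.0 * (1.0 - 2.0 * self.nu))


@dataclass(frozen=True)
class ShrinkageLoad:
    """Positive shrinkage magnitude; stress-free stretch is (1 - eps_s)."""

    eps_s: float
    ramp_steps: int = 20

    def __post_init__(self) -> None:
        if not 0.0 <= self.eps_s < 1.0:
            raise FEMError("eps_s must lie in [0, 1)")
        if self.ramp_steps < 1:
            raise FEMError("ramp_steps must be >= 1")


CELL, WING = 1, 0


@dataclass
class Mesh:
    """Structured bilinear-quad mesh with region and boundary tags."""

    nodes: np.ndarray          # (nn, 2) reference coordinates, mm
    elements: np.ndarray       # (nel, 4) CCW connectivity
    region: np.ndarray         # (nel,) CELL or WING
    fixed_nodes: np.ndarray    # node ids with both dofs pinned
    geometry: Geometry
    nx: int                    # elements along x
    ny: int                    # elements along y (cell region only)
    y0: float = 0.0            # y of the cell region's lower edge
    #: optional explicit list of pinned global dofs (2*node + component);
    #: overrides fixed_nodes when set (e.g. to constrain rigid modes only)
    fixed_dofs: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def cell_boundary_loop(self) -> np.ndarray:
        """Node ids tracing the cell-region boundary counter-clockwise."""
        g = self.geometry
        nny = round((self.nodes[:, 1].max() - self.nodes[:, 1].min()) / g.h) + 1

        def nid(ix: int, iy: int) -> int:
            return ix * nny + iy

        iy_lo = round((0.0 - self.nodes[:, 1].min()) / g.h)
        iy_hi = iy_lo + self.ny
        loop = ([nid(ix, iy_lo) for ix in range(self.nx + 1)]
                + [nid(self.nx, iy) for iy in range(iy_lo + 1, iy_hi + 1)]
                + [nid(ix, iy_hi) for ix in range(self.nx - 1, -1, -1)]
                + [nid(0, iy) for iy in range(iy_hi - 1, iy_lo, -1)])
        return np.asarray(loop, dtype=int)


def build_mesh(geometry: Geometry) -> Mesh:
    """Structured quad mesh of the central region (plus wings if requested).

    With ``include_wings=False`` only the cell-laden strip is meshed and
    the two anchor-interface ends (y = 0 and y = center_h) are fully
    fixed; the lateral edges are free.  With wings included, passive
    (non-contracting) wing material extends the mesh beyond both ends and
    is pinned on its outer edges instead (for sensitivity analysis).
    """
    g = geometry
    h = g.h
    nx = g.center_w / h
    ny = g.center_h / h
    nw = g.wing_h / h
    for val, name in ((nx, "center_w"), (ny, "center_h"),
                      (nw, "wing_h") if g.include_wings else (1.0, "")):
        if name and abs(val - round(val)) > 1e-9:
            raise FEMError(f"element size {g.element_size_um} um does not "
                           f"divide {name}")
    nx, ny, nw = round(nx), round(ny), round(nw)

    y_lo = -g.wing_h if g.include_wings else 0.0
    ny_total = ny + 2 * nw if g.include_wings else ny
    nny = ny_total + 1

    xs = np.linspace(0.0, g.center_w, nx + 1)
    ys = np.linspace(y_lo, y_lo + ny_total * h, nny)
    nodes = np.column_stack([np.repeat(xs, nny), np.tile(ys, nx + 1)])

    elems, region = [], []
    for ix in range(nx):
        for iy in range(ny_total):
            n00 = ix * nny + iy
            elems.append([n00, n00 + nny, n00 + nny + 1, n00 + 1])
            yc = ys[iy] + 0.5 * h
            region.append(CELL if 0.0 < yc < g.center_h else WING)
    elements = np.asarray(elems, dtype=int)
    region = np.asarray(region, dtype=np.int8)

    ycoord = nodes[:, 1]
    if g.include_wings:
        fixed = np.where((np.abs(ycoord - ys[0]) < 1e-12)
                         | (np.abs(ycoord - ys[-1]) < 1e-12))[0]
    else:
        fixed = np.where((np.abs(ycoord) < 1e-12)
                         | (np.abs(ycoord - g.center_h) < 1e-12))[0]
    return Mesh(nodes=nodes, elements=elements, region=region,
                fixed_nodes=fixed, geometry=g, nx=nx, ny=ny, y0=0.0)


# ---------------------------------------------------------------------------
# element kinematics and constitutive response
# ---------------------------------------------------------------------------

_GP = 1.0 / np.sqrt(3.0)
#: 2x2 Gauss points on the reference square, weights all 1
QUAD_POINTS = np.array([[-_GP, -_GP], [_GP, -_GP], [_GP, _GP], [-_GP, _GP]])


def shape_gradients_ref(xi: float, eta: float) -> np.ndarray:
    """d N_a / d (xi, eta) for the 4-node bilinear quad, shape (4, 2)."""
    return 0.25 * np.array([
        [-(1 - eta), -(1 - xi)],
        [+(1 - eta), -(1 + xi)],
        [+(1 + eta), +(1 + xi)],
        [-(1 + eta), +(1 - xi)],
    ])


def _precompute(mesh: Mesh, points: np.ndarray = QUAD_POINTS):
    """Per-element, per-point shape-function gradients in reference coords.

    Returns ``dNdX`` of shape (nel, nq, 4, 2) and ``detJ`` (nel, nq).
    Fully general (isoparametric), so rigidly rotated meshes work too.
    """
    Xe = mesh.nodes[mesh.elements]                     # (nel, 4, 2)
    dN_ref = np.stack([shape_gradients_ref(*p) for p in points])  # (nq,4,2)
    J = np.einsum("qak,eai->eqki", dN_ref, Xe)          # (nel, nq, 2, 2)
    detJ = J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]
    if np.any(detJ <= 0):
        raise FEMError("inverted element in reference configuration")
    Jinv = np.empty_like(J)
    Jinv[..., 0, 0] = J[..., 1, 1]
    Jinv[..., 0, 1] = -J[..., 0, 1]
    Jinv[..., 1, 0] = -J[..., 1, 0]
    Jinv[..., 1, 1] = J[..., 0, 0]
    Jinv /= detJ[..., None, None]
    # J holds (dX/dxi)^T, so its inverse is (dxi/dX)^T: contract over the
    # second index to get dN_a/dX_i = dN_a/dxi_k * dxi_k/dX_i
    dNdX = np.einsum("qak,eqik->eqai", dN_ref, Jinv)
    return dNdX, detJ


def deformation_gradients(mesh: Mesh, u: np.ndarray,
                          dNdX: np.ndarray | None = None) -> np.ndarray:
    """Total in-plane F at every quadrature point, shape (nel, nq, 2, 2)."""
    if dNdX is None:
        dNdX, _ = _precompute(mesh)
    ue = u[mesh.elements]                               # (nel, 4, 2)
    F = np.einsum("eai,eqaj->eqij", ue, dNdX)
    F[..., 0, 0] += 1.0
    F[..., 1, 1] += 1.0
    return F


def _solve_plane_stress_stretch(ip: np.ndarray, A2: np.ndarray, mat: Material,
                                tol: float = 1e-12,
                                max_iter: int = 100) -> np.ndarray:
    """Out-of-plane elastic stretch lam3 with zero transverse stress.

    ``ip`` is ||Fe2||_F^2 (in-plane first invariant part) and ``A2`` is
    det(Fe2); solves d psi / d lam3 = 0 by damped, clipped Newton.
    """
    c1, c2 = mat.c1, mat.c2
    lam = np.full_like(A2, 1.0)
    scale = max(c1, c2)
    for _ in range(max_iter):
        Am = A2 ** (-2.0 / 3.0)
        I1 = ip + lam * lam
        g = (c1 * (2.0 * lam * Am * lam ** (-2.0 / 3.0)
                   - (2.0 / 3.0) * Am * lam ** (-5.0 / 3.0) * I1)
             + 2.0 * c2 * (A2 * lam - 1.0) * A2)
        gp = (c1 * Am * ((10.0 / 9.0) * lam ** (-8.0 / 3.0) * I1
                         - (2.0 / 3.0) * lam ** (-2.0 / 3.0))
              + 2.0 * c2 * A2 * A2)
        step = g / gp
        np.clip(step, -0.5 * lam, 0.5 * lam, out=step)
        lam = lam - step
        if np.max(np.abs(g)) < tol * scale:
            break
    return lam


def _piola_inplane(Fe2: np.ndarray, lam3: np.ndarray,
                   mat: Material) -> np.ndarray:
    """First Piola stress d psi / d Fe2 at the plane-stress stretch."""
    c1, c2 = mat.c1, mat.c2
    A2 = Fe2[..., 0, 0] * Fe2[..., 1, 1] - Fe2[..., 0, 1] * Fe2[..., 1, 0]
    Je = A2 * lam3
    ip = np.einsum("...ij,...ij->...", Fe2, Fe2)
    I1 = ip + lam3 * lam3
    FinvT = np.empty_like(Fe2)
    FinvT[..., 0, 0] = Fe2[..., 1, 1]
    FinvT[..., 0, 1] = -Fe2[..., 1, 0]
    FinvT[..., 1, 0] = -Fe2[..., 0, 1]
    FinvT[..., 1, 1] = Fe2[..., 0, 0]
    FinvT /= A2[..., None, None]
    Jm23 = Je ** (-2.0 / 3.0)
    P = (2.0 * c1 * Jm23[..., None, None] * Fe2
         + ((-2.0 / 3.0) * c1 * I1 * Jm23
            + 2.0 * c2 * (Je - 1.0) * Je)[..., None, None] * FinvT)
    return P


def _psi(Fe2: np.ndarray, lam3: np.ndarray, mat: Material) -> np.ndarray:
    A2 = Fe2[..., 0, 0] * Fe2[..., 1, 1] - Fe2[..., 0, 1] * Fe2[..., 1, 0]
    Je = A2 * lam3
    I1 = np.einsum("...ij,...ij->...", Fe2, Fe2) + lam3 * lam3
    return (mat.c1 * (Je ** (-2.0 / 3.0) * I1 - 3.0)
            + mat.c2 * (Je - 1.0) ** 2)


def _lam_s(mesh: Mesh, eps_s: float) -> np.ndarray:
    """Per-element stress-free stretch: 1 - eps_s in cell, 1 in wings."""
    lam = np.ones(mesh.n_elements)
    lam[mesh.region == CELL] = 1.0 - eps_s
    return lam


def _element_forces(mesh: Mesh, mat: Material, eps_s: float, u: np.ndarray,
                    dNdX: np.ndarray, detJ: np.ndarray) -> np.ndarray:
    """Internal nodal forces per element, shape (nel, 4, 2).

    Raises NewtonDivergence if any quadrature point has det F <= 0.
    """
    F2 = deformation_gradients(mesh, u, dNdX)
    detF = F2[..., 0, 0] * F2[..., 1, 1] - F2[..., 0, 1] * F2[..., 1, 0]
    if not np.all(np.isfinite(detF)) or np.any(detF <= 0.0):
        raise NewtonDivergence("element inversion (det F <= 0)")
    lam_s = _lam_s(mesh, eps_s)                         # (nel,)
    Fe2 = F2 / lam_s[:, None, None, None]
    A2 = detF / lam_s[:, None] ** 2
    ip = np.einsum("eqij,eqij->eq", Fe2, Fe2)
    lam3 = _solve_plane_stress_stretch(ip, A2, mat)
    Pe = _piola_inplane(Fe2, lam3, mat)
    # energy density per reference volume is Js * psi;  dFe2/dF2 = 1/lam_s
    Js = lam_s ** 3
    w = (Js / lam_s)[:, None] * detJ * mesh.geometry.thickness
    return np.einsum("eq,eqij,eqaj->eai", w, Pe, dNdX)


def total_energy(mesh: Mesh, mat: Material, eps_s: float,
                 u: np.ndarray) -> float:
    """Total strain energy of the configuration ``u`` under load ``eps_s``."""
    dNdX, detJ = _precompute(mesh)
    F2 = deformation_gradients(mesh, u, dNdX)
    lam_s = _lam_s(mesh, eps_s)
    Fe2 = F2 / lam_s[:, None, None, None]
    detF = F2[..., 0, 0] * F2[..., 1, 1] - F2[..., 0, 1] * F2[..., 1, 0]
    A2 = detF / lam_s[:, None] ** 2
    ip = np.einsum("eqij,eqij->eq", Fe2, Fe2)
    lam3 = _solve_plane_stress_stretch(ip, A2, mat)
    psi = _psi(Fe2, lam3, mat)
    Js = lam_s ** 3
    return float(np.sum(Js[:, None] * psi * detJ) * mesh.geometry.thickness)


def internal_force(mesh: Mesh, mat: Material, eps_s: float,
                   u: np.ndarray) -> np.ndarray:
    """Assembled global internal-force vector (gradient of total energy)."""
    dNdX, detJ = _precompute(mesh)
    fe = _element_forces(mesh, mat, eps_s, u, dNdX, detJ)
    f = np.zeros(2 * mesh.n_nodes)
    edof = (2 * mesh.elements[:, :, None]
            + np.arange(2)[None, None, :]).reshape(-1)
    np.add.at(f, edof, fe.reshape(-1))
    return f


# ---------------------------------------------------------------------------
# Newton solver
# ---------------------------------------------------------------------------

@dataclass
class DisplacementField:
    u: np.ndarray              # (nn, 2) nodal displacements, mm
    eps_s: float
    converged: bool
    residual_norm: float
    newton_iters: int = 0


def _assemble_tangent(mesh: Mesh, mat: Material, eps_s: float, u: np.ndarray,
                      dNdX: np.ndarray, detJ: np.ndarray,
                      f_el0: np.ndarray) -> sp.csr_matrix:
    """Global tangent by forward differences of element internal forces."""
    nel = mesh.n_elements
    h = 1e-7 * max(1.0, float(np.max(np.abs(u))) if u.size else 1.0)
    Kel = np.empty((nel, 8, 8))
    ue = u[mesh.elements]
    for k in range(8):
        a, i = divmod(k, 2)
        du = np.zeros((4, 2))
        du[a, i] = h
        # perturb the element-local copy of the displacement
        F2 = np.einsum("eai,eqaj->eqij", ue + du, dNdX)
        F2[..., 0, 0] += 1.0
        F2[..., 1, 1] += 1.0
        lam_s = _lam_s(mesh, eps_s)
        Fe2 = F2 / lam_s[:, None, None, None]
        detF = F2[..., 0, 0] * F2[..., 1, 1] - F2[..., 0, 1] * F2[..., 1, 0]
        if np.any(detF <= 0.0):
            raise NewtonDivergence("element inversion while assembling tangent")
        A2 = detF / lam_s[:, None] ** 2
        ip = np.einsum("eqij,eqij->eq", Fe2, Fe2)
        lam3 = _solve_plane_stress_stretch(ip, A2, mat)
        Pe = _piola_inplane(Fe2, lam3, mat)
        Js = lam_s ** 3
        w = (Js / lam_s)[:, None] * detJ * mesh.geometry.thickness
        f_pert = np.einsum("eq,eqij,eqaj->eai", w, Pe, dNdX)
        Kel[:, :, k] = (f_pert - f_el0).reshape(nel, 8) / h
    edof = (2 * mesh.elements[:, :, None]
            + np.arange(2)[None, None, :]).reshape(nel, 8)
    rows = np.repeat(edof[:, :, None], 8, axis=2).reshape(-1)
    cols = np.repeat(edof[:, None, :], 8, axis=1).reshape(-1)
    n = 2 * mesh.n_nodes
    return sp.coo_matrix((Kel.reshape(-1), (rows, cols)),
                         shape=(n, n)).tocsr()


def _free_dofs(mesh: Mesh) -> np.ndarray:
    free = np.ones(2 * mesh.n_nodes, dtype=bool)
    if mesh.fixed_dofs is not None:
        free[np.asarray(mesh.fixed_dofs, int)] = False
    else:
        free[2 * mesh.fixed_nodes] = False
        free[2 * mesh.fixed_nodes + 1] = False
    return np.where(free)[0]


def _newton(mesh: Mesh, mat: Material, eps_s: float, u: np.ndarray,
            rtol: float = 1e-8, max_iter: int = 30) -> tuple[np.ndarray, float, int]:
    """Solve equilibrium at fixed eps_s starting from u; returns (u, |r|, iters)."""
    dNdX, detJ = _precompute(mesh)
    free = _free_dofs(mesh)
    g = mesh.geometry
    # absolute floor on the force norm: a tiny fraction of a characteristic
    # membrane force E * t * L
    f_ref = mat.E * g.thickness * max(g.center_w, g.center_h)
    atol = 1e-12 * f_ref
    u = u.copy()
    r0 = None
    for it in range(max_iter):
        fe = _element_forces(mesh, mat, eps_s, u, dNdX, detJ)
        f = np.zeros(2 * mesh.n_nodes)
        edof = (2 * mesh.elements[:, :, None]
                + np.arange(2)[None, None, :]).reshape(-1)
        np.add.at(f, edof, fe.reshape(-1))
        r = f[free]
        rnorm = float(np.linalg.norm(r))
        if r0 is None:
            r0 = max(rnorm, atol)
        if rnorm <= max(rtol * r0, atol):
            return u, rnorm, it
        if not np.isfinite(rnorm) or rnorm > 1e6 * r0:
            raise NewtonDivergence(f"residual diverged: |r| = {rnorm:.3e}")
        K = _assemble_tangent(mesh, mat, eps_s, u, dNdX, detJ, fe)
        Kff = K[free][:, free].tocsc()
        try:
            du = spla.splu(Kff).solve(-r)
        except RuntimeError as exc:
            raise NewtonDivergence(f"singular tangent: {exc}") from exc
        u_flat = u.reshape(-1)
        u_flat[free] += du
    raise NewtonDivergence(
        f"no convergence in {max_iter} Newton iterations (|r| = {rnorm:.3e})")


def _ramp_solve(mesh: Mesh, mat: Material, eps_targets: np.ndarray,
                u0: np.ndarray | None = None, eps_start: float = 0.0,
                max_halvings: int = 5,
                rtol: float = 1e-8) -> dict[float, DisplacementField]:
    """Solve a sequence of increasing load levels with warm starts.

    Between consecutive targets the increment is halved (up to
    ``max_halvings`` times) whenever Newton diverges or an element inverts.
    """
    u = np.zeros((mesh.n_nodes, 2)) if u0 is None else u0.copy()
    eps_prev = eps_start
    out: dict[float, DisplacementField] = {}
    for eps in eps_targets:
        pending = [float(eps)]
        halvings = 0
        while pending:
            target = pending[-1]
            try:
                u_new, rnorm, iters = _newton(mesh, mat, target, u, rtol=rtol)
            except NewtonDivergence:
                halvings += 1
                if halvings > max_halvings:
                    raise NewtonDivergence(
                        f"load step to eps_s = {target} failed after "
                        f"{max_halvings} halvings")
                pending.append(0.5 * (eps_prev + target))
                continue
            u, eps_prev = u_new, target
            pending.pop()
            if not pending:
                out[float(eps)] = DisplacementField(
                    u=u.copy(), eps_s=float(eps), converged=True,
                    residual_norm=rnorm, newton_iters=iters)
    return out


def solve_contraction(mesh: Mesh, mat: Material,
                      load: ShrinkageLoad) -> DisplacementField:
    """Equilibrium displacement field at shrinkage eps_s, ramped from zero."""
    if load.eps_s == 0.0:
        return DisplacementField(u=np.zeros((mesh.n_nodes, 2)), eps_s=0.0,
                                 converged=True, residual_norm=0.0)
    targets = np.linspace(0.0, load.eps_s, load.ramp_steps + 1)[1:]
    fields = _ramp_solve(mesh, mat, targets)
    return fields[float(load.eps_s)]


# ---------------------------------------------------------------------------
# area shrinkage and strain fitting
# ---------------------------------------------------------------------------

def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def area_shrinkage(mesh: Mesh, field: DisplacementField) -> float:
    """1 - (deformed area) / (reference area) of the cell-laden region."""
    if not field.converged:
        raise FEMError("area_shrinkage requires a converged field")
    loop = mesh.cell_boundary_loop()
    ref = mesh.nodes[loop]
    deformed = ref + field.u[loop]
    return 1.0 - _polygon_area(deformed) / _polygon_area(ref)


@dataclass
class ShrinkageFit:
    eps_best: float
    target: float
    shrinkage_by_eps: dict[float, float]
    field_best: DisplacementField
    fields: dict[float, DisplacementField] = field(default_factory=dict)


def fit_shrinkage_strain(target_area_shrinkage: float, mesh: Mesh,
                         mat: Material,
                         sweep: np.ndarray | None = None,
                         ramp_steps_per_increment: int = 2) -> ShrinkageFit:
    """Best-fit eps_s on a grid by matching simulated to measured area loss.

    The grid is swept by continuation: each level warm-starts from the
    previous converged state, so the whole sweep costs one ramped solve.
    Ties in |predicted - target| break toward the smaller eps_s.
    """
    if not 0.0 <= target_area_shrinkage < 1.0:
        raise FEMError("target area shrinkage must lie in [0, 1)")
    if sweep is None:
        sweep = np.round(np.arange(0.0, 0.7001, 0.05), 10)
    sweep = np.sort(np.unique(np.asarray(sweep, float)))
    if sweep[0] < 0.0 or sweep[-1] >= 1.0:
        raise FEMError("sweep grid must lie within [0, 1)")

    fields: dict[float, DisplacementField] = {}
    if sweep[0] == 0.0:
        fields[0.0] = DisplacementField(u=np.zeros((mesh.n_nodes, 2)),
                                        eps_s=0.0, converged=True,
                                        residual_norm=0.0)
    # refine the ramp between grid points for robustness at large shrinkage
    targets = []
    prev = 0.0
    for eps in sweep[sweep > 0.0]:
        targets.extend(np.linspace(prev, eps,
                                   ramp_steps_per_increment + 1)[1:].tolist())
        prev = eps
    solved = _ramp_solve(mesh, mat, np.asarray(targets))
    for eps in sweep[sweep > 0.0]:
        fields[float(eps)] = solved[float(eps)]

    shrink = {eps: area_shrinkage(mesh, f) for eps, f in fields.items()}
    errs = {eps: abs(s - target_area_shrinkage) for eps, s in shrink.items()}
    eps_best = min(sorted(errs), key=lambda e: (errs[e], e))
    return ShrinkageFit(eps_best=float(eps_best),
                        target=target_area_shrinkage,
                        shrinkage_by_eps=shrink,
                        field_best=fields[eps_best], fields=fields)


# ---------------------------------------------------------------------------
# VTK export (legacy ASCII unstructured grid)
# ---------------------------------------------------------------------------

def write_vtk(path, mesh: Mesh, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write the mesh with nodal/element fields as legacy ASCII VTK."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nn, nel = mesh.n_nodes, mesh.n_elements
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfiberalign mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {nn} double\n")
        for x, y in mesh.nodes:
            fh.write(f"{x} {y} 0.0\n")
        fh.write(f"CELLS {nel} {5 * nel}\n")
        for conn in mesh.elements:
            fh.write("4 " + " ".join(map(str, conn)) + "\n")
        fh.write(f"CELL_TYPES {nel}\n")
        fh.write("\n".join(["9"] * nel) + "\n")   # VTK_QUAD
        if point_data:
            fh.write(f"POINT_DATA {nn}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 2:
                    fh.write(f"VECTORS {name} double\n")
                    for row in arr:
                        fh.write(f"{row[0]} {row[1]} 0.0\n")
                else:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(map(str, arr)) + "\n")
        if cell_data:
            fh.write(f"CELL_DATA {nel}\n")
            for name, arr in cell_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(map(str, np.asarray(arr))) + "\n")
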