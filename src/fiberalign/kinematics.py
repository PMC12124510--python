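"""Local alignment measures derived from the FE displacement field.

A material circle of radius r = 0.05 mm seeded at a point deforms under
the local deformation gradient F into an ellipse.  From the polar
decomposition F = R U (U = sqrt(F^T F) symmetric positive-definite, R a
rotation) the ellipse semi-axes are r times the principal stretches; the
local alignment factor is their ratio

    alpha = b / a = lam_max / lam_min  (>= 1, 1 = isotropic)

and the model alignment angle beta_model is the orientation of the
deformed major axis — the principal direction of F F^T with the largest
eigenvalue (equivalently R applied to U's major eigenvector) — on the
axial circle [0, 180), with the inter-anchor axis at 90 degrees.

To bridge to the discrete-fiber alignment index, N = 150 fibers are
seeded at uniform angles, each tangent is pushed forward through F, and
S = 2<cos 2 theta> - 1 is recomputed from the deformed angles.  For a
pure stretch with axis ratio alpha and uniformly distributed fibers this
converges to the closed form S = (alpha - 1)/(alpha + 1) as N grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem import (Mesh, DisplacementField, FEMError, _precompute,
                  deformation_gradients, CELL, QUAD_POINTS,
                  shape_gradients_ref)
from .fiber_stats import FiberSet, alignment_index

DEFAULT_SEED_RADIUS_MM = 0.05
DEFAULT_N_FIBERS = 150


class KinematicsError(ValueError):
    pass


@dataclass
class PointKinematics:
    F: np.ndarray
    U: np.ndarray
    R: np.ndarray
    a: float                  # minor semi-axis, units of seed radius r
    b: float                  # major semi-axis
    alpha: float              # b / a >= 1
    beta_model_deg: float     # [0, 180); NaN when isotropic
    isotropic: bool = False


def polar_decompose(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right polar decomposition F = R U via eigendecomposition of F^T F."""
    F = np.asarray(F, float)
    detF = np.linalg.det(F)
    if detF <= 0:
        raise KinematicsError(f"polar decomposition needs det F > 0, "
                              f"got {detF}")
    C = F.T @ F
    w, V = np.linalg.eigh(C)
    U = (V * np.sqrt(w)) @ V.T
    R = F @ np.linalg.inv(U)
    return U, R


def ellipse_from_F(F: np.ndarray, r: float = DEFAULT_SEED_RADIUS_MM,
                   iso_rtol: float = 1e-9
                   ) -> tuple[float, float, float, float]:
    """(a, b, alpha, beta_model_deg) of the deformed material circle.

    ``beta_model_deg`` is NaN for an isotropic F (lam_max == lam_min),
    where the major-axis direction is undefined.
    """
    F = np.asarray(F, float)
    if np.linalg.det(F) <= 0:
        raise KinematicsError("ellipse_from_F needs det F > 0")
    Uleft, s, _ = np.linalg.svd(F)
    lam_max, lam_min = float(s[0]), float(s[1])
    a, b = r * lam_min, r * lam_max
    alpha = lam_max / lam_min
    if lam_max - lam_min <= iso_rtol * lam_max:
        return a, b, 1.0, float("nan")
    beta = float(np.degrees(np.arctan2(Uleft[1, 0], Uleft[0, 0])) % 180.0)
    return a, b, alpha, beta


def point_kinematics(F: np.ndarray,
                     r: float = DEFAULT_SEED_RADIUS_MM) -> PointKinematics:
    U, R = polar_decompose(F)
    a, b, alpha, beta = ellipse_from_F(F, r)
    return PointKinematics(F=np.asarray(F, float), U=U, R=R, a=a, b=b,
                           alpha=alpha, beta_model_deg=beta,
                           isotropic=np.isnan(beta))


def embed_and_deform_fibers(F: np.ndarray,
                            n: int = DEFAULT_N_FIBERS) -> FiberSet:
    """Seed n uniform fiber directions, push tangents through F, re-wrap.

    Reference directions are theta_i = i * 180 / n; each unit tangent is
    mapped to F t and the deformed axial angle recorded.
    """
    F = np.asarray(F, float)
    if np.linalg.det(F) <= 0:
        raise KinematicsError("fiber transport needs det F > 0")
    theta = np.arange(n) * 180.0 / n
    t = np.stack([np.cos(np.radians(theta)), np.sin(np.radians(theta))])
    d = F @ t
    angles = np.degrees(np.arctan2(d[1], d[0])) % 180.0
    return FiberSet(angles_deg=angles)


def equivalent_alignment_index(F: np.ndarray, n: int = DEFAULT_N_FIBERS) -> float:
    """Alignment index S of n embedded fibers deformed by F."""
    return alignment_index(embed_and_deform_fibers(F, n)).S


def closed_form_S(alpha: float) -> float:
    """Limit of the embedded-fiber S for uniform fibers under pure stretch
    with axis ratio alpha: S = (alpha - 1) / (alpha + 1)."""
    return (alpha - 1.0) / (alpha + 1.0)


def _axial_mean(angles_deg: np.ndarray) -> float:
    ok = np.isfinite(angles_deg)
    if not ok.any():
        return float("nan")
    a = np.radians(2.0 * angles_deg[ok])
    return float(np.degrees(np.arctan2(np.sin(a).mean(), np.cos(a).mean()))
                 * 0.5 % 180.0)


def deformation_gradient_at(mesh: Mesh, field: DisplacementField,
                            points: np.ndarray) -> list[np.ndarray]:
    """Total F at arbitrary reference points inside the meshed domain.

    Bilinear elements reproduce affine fields exactly, so an affine
    displacement yields the exact constant F at every query point.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    g = mesh.geometry
    h = g.h
    ymin = float(mesh.nodes[:, 1].min())
    ny_total = round((mesh.nodes[:, 1].max() - ymin) / h)
    out = []
    for x, y in pts:
        if not (-1e-9 <= x <= g.center_w + 1e-9
                and ymin - 1e-9 <= y <= ymin + ny_total * h + 1e-9):
            raise KinematicsError(f"point ({x}, {y}) outside reference domain")
        ix = min(int(np.floor(x / h)), mesh.nx - 1)
        iy = min(int(np.floor((y - ymin) / h)), ny_total - 1)
        e = ix * ny_total + iy
        x0, y0 = mesh.nodes[mesh.elements[e, 0]]
        xi = 2.0 * (x - x0) / h - 1.0
        eta = 2.0 * (y - y0) / h - 1.0
        dN_ref = shape_gradients_ref(xi, eta)
        Xe = mesh.nodes[mesh.elements[e]]
        J = dN_ref.T @ Xe
        dNdX = dN_ref @ np.linalg.inv(J).T
        ue = field.u[mesh.elements[e]]
        F = np.eye(2) + ue.T @ dNdX
        out.append(F)
    return out


@dataclass
class RegionKinematics:
    """Quadrature-averaged alignment measures of one sampling element."""

    location: str
    element: int
    centroid: np.ndarray
    alpha: float
    beta_model_deg: float
    S: float
    F_mean: np.ndarray


@dataclass
class AlignmentMap:
    """Per-element alpha / beta / gamma over the cell-laden region."""

    element_ids: np.ndarray
    centroids: np.ndarray
    alpha: np.ndarray
    beta_model_deg: np.ndarray
    gamma_model: np.ndarray
    regions: dict[str, RegionKinematics]

    def max_elements(self) -> np.ndarray:
        """Elements attaining gamma_model = 1 (all reported on ties)."""
        return self.element_ids[np.isclose(self.gamma_model, 1.0, atol=1e-12)]

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "element": self.element_ids,
            "x_mm": self.centroids[:, 0], "y_mm": self.centroids[:, 1],
            "alpha": self.alpha, "beta_model_deg": self.beta_model_deg,
            "gamma_model": self.gamma_model,
        })


def default_sampling_points(mesh: Mesh) -> dict[str, np.ndarray]:
    """Reference coordinates of the CE / ME / MC sampling elements.

    The edge locations (CE, ME) sit in the element row adjoining the free
    lateral edge of the strip — where the edge fields of view are imaged —
    with CE one element inset from the anchor interface and ME at the
    strip's mid-length; MC is the central element.  The CE corner is the
    one whose deformed major-axis angle falls in the upper half-plane
    (90-180 degrees), matching the construct-image convention of the
    corner-edge field of view; ``alignment_map`` resolves the corner by
    mirror symmetry.
    """
    g = mesh.geometry
    h = g.h
    return {
        "CE": np.array([0.5 * h, g.center_h - 1.5 * h]),   # top-left corner
        "ME": np.array([0.5 * h, 0.5 * g.center_h]),
        "MC": np.array([0.5 * g.center_w, 0.5 * g.center_h]),
    }


def _element_of_point(mesh: Mesh, p: np.ndarray) -> int:
    g = mesh.geometry
    h = g.h
    ymin = float(mesh.nodes[:, 1].min())
    ny_total = round((mesh.nodes[:, 1].max() - ymin) / h)
    ix = min(int(np.floor(p[0] / h)), mesh.nx - 1)
    iy = min(int(np.floor((p[1] - ymin) / h)), ny_total - 1)
    return ix * ny_total + iy


def alignment_map(mesh: Mesh, field: DisplacementField,
                  n_fibers: int = DEFAULT_N_FIBERS,
                  sampling_points: dict[str, np.ndarray] | None = None
                  ) -> AlignmentMap:
    """Per-element (quadrature-averaged) alpha, beta, gamma and region values.

    alpha and beta are averaged over each element's 2x2 Gauss points
    (beta axially); the per-region equivalent S uses ``n_fibers`` embedded
    fibers at the element's quadrature-mean F.  gamma_model = alpha /
    max(alpha) over the cell-laden region.
    """
    if not field.converged:
        raise FEMError("alignment_map requires a converged field")
    F = deformation_gradients(mesh, field.u)            # (nel, nq, 2, 2)
    cell = np.where(mesh.region == CELL)[0]
    nq = F.shape[1]
    alpha_q = np.empty((cell.size, nq))
    beta_q = np.empty((cell.size, nq))
    for j, e in enumerate(cell):
        for q in range(nq):
            _, _, al, be = ellipse_from_F(F[e, q])
            alpha_q[j, q], beta_q[j, q] = al, be
    alpha_el = alpha_q.mean(axis=1)
    beta_el = np.array([_axial_mean(row) for row in beta_q])
    gamma = alpha_el / alpha_el.max()
    centroids = mesh.nodes[mesh.elements[cell]].mean(axis=1)

    pts = dict(sampling_points or default_sampling_points(mesh))
    regions: dict[str, RegionKinematics] = {}
    cell_pos = {int(e): j for j, e in enumerate(cell)}
    for loc, p in pts.items():
        e = _element_of_point(mesh, np.asarray(p, float))
        if e not in cell_pos:
            raise KinematicsError(f"sampling point for {loc} lies outside "
                                  "the cell-laden region")
        j = cell_pos[e]
        Fm = F[e].mean(axis=0)
        regions[loc] = RegionKinematics(
            location=loc, element=int(e), centroid=centroids[j],
            alpha=float(alpha_el[j]), beta_model_deg=float(beta_el[j]),
            S=equivalent_alignment_index(Fm, n_fibers), F_mean=Fm)

    # resolve the CE mirror ambiguity: all four corners are equivalent up to
    # reflection; report the one whose beta lies in (90, 180), matching the
    # image convention (corner-edge fibers tilt into the upper half-plane)
    if "CE" in regions and np.isfinite(regions["CE"].beta_model_deg) \
            and regions["CE"].beta_model_deg < 90.0:
        g = mesh.geometry
        p = pts["CE"]
        mirrored = np.array([g.center_w - p[0], p[1]])
        e = _element_of_point(mesh, mirrored)
        if e in cell_pos:
            j = cell_pos[e]
            Fm = F[e].mean(axis=0)
            regions["CE"] = RegionKinematics(
                location="CE", element=int(e), centroid=centroids[j],
                alpha=float(alpha_el[j]), beta_model_deg=float(beta_el[j]),
                S=equivalent_alignment_index(Fm, n_fibers), F_mean=Fm)

    return AlignmentMap(element_ids=cell, centroids=centroids,
                        alpha=alpha_el, beta_model_deg=beta_el,
                        gamma_model=gamma, regions=regions)
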