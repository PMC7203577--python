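"""Mesh alignment, fiber rules, strain extraction, volumes and thickness.

This module implements the image-derived kinematics pipeline: long-axis and
circumferential co-registration of a diastolic mesh series, the rule-based
myofiber/sheet architecture, per-element deformation gradients from the
co-registered templates, Green--Lagrange circumferential/longitudinal
strains averaged over 3 layers x 20 circumferential regions, and the
cavity/wall volume and wall-thickness measures used by the markers.

Units: lengths cm, volumes mL (1 cm^3 = 1 mL), angles degrees at the API.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .mesh import LVMesh, hex_volumes, surface_volume, triangulate_quads

__all__ = [
    "RegionalStrainField",
    "align_long_axis",
    "align_circumferential",
    "assign_fibers",
    "local_directions",
    "deformation_gradient",
    "strain_components",
    "select_layer_rings",
    "regional_strains",
    "chamber_volume",
    "wall_volume",
    "epi_capped_volume",
    "median_wall_thickness",
]


# ---------------------------------------------------------------------------
# alignment


def align_long_axis(series: Sequence[LVMesh], annulus_distances) -> list[LVMesh]:
    """Shift each frame toward the annulus ring by ``d_t - min(d_i)``.

    ``annulus_distances`` holds the basal-slice-to-annulus distance of each
    frame; the frame with the smallest distance stays put and every other
    frame is translated along the long axis (+z) by its excess distance.
    """
    d = np.asarray(annulus_distances, dtype=float)
    if d.ndim != 1 or len(d) != len(series):
        raise ValueError("need one annulus distance per frame")
    if np.any(d < 0):
        raise ValueError("annulus distances must be non-negative")
    shifts = d - d.min()
    out = []
    for mesh, s in zip(series, shifts):
        pts = mesh.points.copy()
        pts[:, 2] += s
        out.append(mesh.with_points(pts))
    return out


def align_circumferential(mesh: LVMesh, reference_v1: float) -> LVMesh:
    """Rotate about the long axis so the v1 insertion point sits at
    ``reference_v1`` degrees."""
    if mesh.v1_node < 0:
        raise ValueError("mesh carries no v1 insertion-point annotation")
    delta = np.radians(reference_v1 - mesh.insertion_angle("v1"))
    c, s = np.cos(delta), np.sin(delta)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return mesh.with_points(mesh.points @ rot.T)


# ---------------------------------------------------------------------------
# fiber architecture


def _element_triads(mesh: LVMesh):
    """Orthonormal (c, r, l) per element: circumferential, transmural
    (endo -> epi), longitudinal l = r x c."""
    pts = mesh.points[mesh.hexes]  # (E, 8, 3)
    s_nodes = mesh.node_s[mesh.hexes]  # (E, 8)
    # transmural direction: from the endo-side node group (larger s) to the
    # epi-side group; robust to any bottom/top quad swap
    order = np.argsort(s_nodes, axis=1)
    lo = np.take_along_axis(pts, order[:, :4, None], axis=1).mean(axis=1)  # epi side
    hi = np.take_along_axis(pts, order[:, 4:, None], axis=1).mean(axis=1)  # endo side
    r = lo - hi
    r /= np.linalg.norm(r, axis=1, keepdims=True)

    cen = pts.mean(axis=1)
    th = np.arctan2(cen[:, 1], cen[:, 0])
    c_raw = np.stack([-np.sin(th), np.cos(th), np.zeros_like(th)], axis=1)
    c = c_raw - np.einsum("ij,ij->i", c_raw, r)[:, None] * r
    nrm = np.linalg.norm(c, axis=1, keepdims=True)
    bad = nrm[:, 0] < 1e-8
    if np.any(bad):
        # element centred on the axis: any horizontal direction normal to r
        alt = np.cross(r[bad], np.array([0.0, 0.0, 1.0]))
        alt_n = np.linalg.norm(alt, axis=1, keepdims=True)
        alt = np.where(alt_n > 1e-8, alt / np.maximum(alt_n, 1e-12), [1.0, 0.0, 0.0])
        c[bad] = alt
        nrm = np.linalg.norm(c, axis=1, keepdims=True)
    c /= nrm
    l = np.cross(r, c)
    return c, r, l


def local_directions(mesh: LVMesh):
    """Public accessor for the per-element (c, r, l) triads."""
    return _element_triads(mesh)


def assign_fibers(
    mesh: LVMesh,
    fiber_endo: float = 60.0,
    fiber_epi: float = -60.0,
    sheet_endo: float = 45.0,
    sheet_epi: float = -45.0,
) -> LVMesh:
    """Rule-based fiber/sheet assignment.

    Helix and sheet angles vary linearly across the wall with the
    transmural coordinate s (0 = epicardium, 1 = endocardium):
    alpha(s) = fiber_epi + (fiber_endo - fiber_epi) s, and analogously for
    the sheet angle.  The fiber lies in the circumferential-longitudinal
    plane; the sheet is built orthogonal to the fiber so f0 . s0 = 0 to
    machine precision.
    """
    c, r, l = _element_triads(mesh)
    s_elem = mesh.node_s[mesh.hexes].mean(axis=1)
    alpha = np.radians(fiber_epi + (fiber_endo - fiber_epi) * s_elem)[:, None]
    beta = np.radians(sheet_epi + (sheet_endo - sheet_epi) * s_elem)[:, None]
    f0 = np.cos(alpha) * c + np.sin(alpha) * l
    f0 /= np.linalg.norm(f0, axis=1, keepdims=True)
    t = np.cross(r, f0)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    s0 = np.cos(beta) * r + np.sin(beta) * t
    out = mesh.copy()
    out.fiber = f0
    out.sheet = s0
    return out


# ---------------------------------------------------------------------------
# deformation and strain


def _ls_operators(ref: LVMesh):
    """Per-element least-squares operators G with F = sum_n d_n (G_n)^T."""
    X = ref.points[ref.hexes]
    D = X - X.mean(axis=1, keepdims=True)
    M = np.einsum("eni,enj->eij", D, D)
    try:
        Minv = np.linalg.inv(M)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate element: rank-deficient node configuration") from exc
    return np.einsum("eij,enj->eni", Minv, D)


def deformation_gradient(ref: LVMesh, deformed, elements=None) -> np.ndarray:
    """Best-fit affine deformation gradient per element.

    F minimises the residual of the element's eight node displacements,
    so affine motions are recovered exactly.  ``deformed`` may be a mesh or
    a node-position array with the reference connectivity.
    """
    pts = deformed.points if isinstance(deformed, LVMesh) else np.asarray(deformed)
    if pts.shape != ref.points.shape:
        raise ValueError("meshes are not co-registered (node count differs)")
    hexes = ref.hexes if elements is None else ref.hexes[np.atleast_1d(elements)]
    X = ref.points[hexes]
    x = pts[hexes]
    D = X - X.mean(axis=1, keepdims=True)
    d = x - x.mean(axis=1, keepdims=True)
    M = np.einsum("eni,enj->eij", D, D)
    cond_bad = np.abs(np.linalg.det(M)) < 1e-12
    if np.any(cond_bad):
        raise ValueError("degenerate element: rank-deficient node configuration")
    G = np.einsum("eij,enj->eni", np.linalg.inv(M), D)
    F = np.einsum("eni,enj->eij", d, G)
    if np.any(np.linalg.det(F) <= 0):
        raise ValueError("non-positive Jacobian in deformation gradient")
    return F if elements is None or np.ndim(elements) else F[0]


def strain_components(F: np.ndarray, c: np.ndarray, l: np.ndarray):
    """Green--Lagrange strains E_cc = c.(1/2(F^T F - I))c and E_ll likewise."""
    F = np.asarray(F)
    single = F.ndim == 2
    F = F.reshape(-1, 3, 3)
    c = np.asarray(c).reshape(-1, 3)
    l = np.asarray(l).reshape(-1, 3)
    E = 0.5 * (np.einsum("eki,ekj->eij", F, F) - np.eye(3))
    ecc = np.einsum("ei,eij,ej->e", c, E, c)
    ell = np.einsum("ei,eij,ej->e", l, E, l)
    if single:
        return float(ecc[0]), float(ell[0])
    return ecc, ell


# ---------------------------------------------------------------------------
# regional averaging


@dataclass
class RegionalStrainField:
    """Regional-average strains, shape (n_layer, n_reg, n_frames)."""

    E_cc: np.ndarray
    E_ll: np.ndarray
    layer_rings: np.ndarray
    n_layer: int
    n_reg: int

    @property
    def n_frames(self) -> int:
        return self.E_cc.shape[2]


def select_layer_rings(mesh: LVMesh, n_layer: int = 3) -> np.ndarray:
    """Longitudinal element rings closest to 25/50/75% of the long-axis span
    (basal, mid-ventricular and apical short-axis layers)."""
    cen_z = mesh.element_centroids()[:, 2]
    ring_ids = np.unique(mesh.elem_ring[mesh.elem_ring >= 0])
    ring_z = np.array(
        [cen_z[mesh.elem_ring == i].mean() for i in ring_ids]
    )
    z_top = mesh.base_z
    z_bot = mesh.points[:, 2].min()
    fracs = (np.arange(1, n_layer + 1)) / (n_layer + 1)
    chosen = []
    for f in fracs:
        target = z_top - f * (z_top - z_bot)
        order = np.argsort(np.abs(ring_z - target))
        pick = next(int(ring_ids[k]) for k in order if int(ring_ids[k]) not in chosen)
        chosen.append(pick)
    return np.asarray(sorted(chosen))


def _region_of_elements(mesh: LVMesh, elements: np.ndarray, n_reg: int) -> np.ndarray:
    """Circumferential region index (0-based, counter-clockwise from v1)."""
    cen = mesh.points[mesh.hexes[elements]].mean(axis=1)
    th = np.degrees(np.arctan2(cen[:, 1], cen[:, 0])) % 360.0
    v1 = mesh.insertion_angle("v1")
    rel = (th - v1) % 360.0
    return np.minimum((rel / (360.0 / n_reg)).astype(int), n_reg - 1)


def regional_strains(
    series: Sequence, ref: LVMesh, n_layer: int = 3, n_reg: int = 20
) -> RegionalStrainField:
    """Layer x region arithmetic means of element strains, per frame.

    ``series`` is a sequence of co-registered meshes (or node-position
    arrays); the first entry need not be the reference -- strains are always
    measured against ``ref`` (early-diastole).
    """
    rings = select_layer_rings(ref, n_layer)
    c, _, l = _element_triads(ref)
    ecc = np.zeros((n_layer, n_reg, len(series)))
    ell = np.zeros_like(ecc)
    layer_elems, layer_regs = [], []
    for k, ring in enumerate(rings):
        elems = np.flatnonzero(ref.elem_ring == ring)
        regs = _region_of_elements(ref, elems, n_reg)
        counts = np.bincount(regs, minlength=n_reg)
        if np.any(counts == 0):
            empty = int(np.flatnonzero(counts == 0)[0]) + 1
            raise ValueError(
                f"empty strain region {empty} in layer {k + 1}: mesh too coarse"
            )
        layer_elems.append(elems)
        layer_regs.append(regs)

    for j, frame in enumerate(series):
        pts = frame.points if isinstance(frame, LVMesh) else np.asarray(frame)
        for k in range(n_layer):
            elems = layer_elems[k]
            F = deformation_gradient(ref, pts, elems)
            e_c, e_l = strain_components(F, c[elems], l[elems])
            regs = layer_regs[k]
            cnt = np.bincount(regs, minlength=n_reg)
            ecc[k, :, j] = np.bincount(regs, weights=e_c, minlength=n_reg) / cnt
            ell[k, :, j] = np.bincount(regs, weights=e_l, minlength=n_reg) / cnt
    return RegionalStrainField(ecc, ell, rings, n_layer, n_reg)


# ---------------------------------------------------------------------------
# volumes and thickness


def _capped_surface_tris(mesh: LVMesh, faces: np.ndarray, ring: np.ndarray):
    tris = triangulate_quads(faces)
    ring = np.asarray(ring)
    fan = np.stack(
        [
            np.repeat(ring[0], len(ring) - 2),
            ring[1:-1],
            ring[2:],
        ],
        axis=1,
    )
    return np.concatenate([tris, fan], axis=0)


def _check_watertight(tris: np.ndarray) -> None:
    edges = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    if np.any(counts != 2):
        raise ValueError("capped surface is not watertight")


def chamber_volume(mesh: LVMesh) -> float:
    """LV cavity volume (mL): endocardial surface capped by the basal polygon."""
    tris = _capped_surface_tris(mesh, mesh.endo_faces, mesh.endo_basal_ring)
    _check_watertight(tris)
    v = surface_volume(mesh.points, tris)
    if v <= 0:
        raise ValueError("non-positive chamber volume")
    return float(v)


def epi_capped_volume(mesh: LVMesh) -> float:
    """Volume enclosed by the capped epicardial surface (mL)."""
    tris = _capped_surface_tris(mesh, mesh.epi_faces, mesh.epi_basal_ring)
    _check_watertight(tris)
    return float(surface_volume(mesh.points, tris))


def wall_volume(mesh: LVMesh) -> float:
    """Myocardial wall volume (mL) as the sum of hexahedral cell volumes."""
    vols = hex_volumes(mesh.points, mesh.hexes)
    if np.any(vols <= 0):
        raise ValueError(f"inverted element {int(np.argmin(vols))}")
    return float(vols.sum())


def _point_triangle_distance(p, a, b, c):
    """Exact distances from points p to triangles (a, b, c), elementwise."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = np.where(np.abs(va + vb + vc) < 1e-300, 1.0, va + vb + vc)
    v = vb / denom
    w = vc / denom
    closest = a + v[:, None] * ab + w[:, None] * ac  # interior candidate

    # vertex regions
    closest = np.where(((d1 <= 0) & (d2 <= 0))[:, None], a, closest)
    closest = np.where(((d3 >= 0) & (d4 <= d3))[:, None], b, closest)
    closest = np.where(((d6 >= 0) & (d5 <= d6))[:, None], c, closest)
    # edge AB
    vab = np.clip(np.where(np.abs(d1 - d3) > 1e-300, d1 / (d1 - d3 + 1e-300), 0), 0, 1)
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    closest = np.where(on_ab[:, None], a + vab[:, None] * ab, closest)
    # edge AC
    wac = np.clip(np.where(np.abs(d2 - d6) > 1e-300, d2 / (d2 - d6 + 1e-300), 0), 0, 1)
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    closest = np.where(on_ac[:, None], a + wac[:, None] * ac, closest)
    # edge BC
    wbc = np.clip(
        np.where(np.abs((d4 - d3) + (d5 - d6)) > 1e-300,
                 (d4 - d3) / ((d4 - d3) + (d5 - d6) + 1e-300), 0), 0, 1)
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    closest = np.where(on_bc[:, None], b + wbc[:, None] * (c - b), closest)
    return np.linalg.norm(p - closest, axis=1)


def median_wall_thickness(mesh: LVMesh, k_candidates: int = 6) -> float:
    """Median distance from epicardial vertices to the endocardial surface (cm).

    Each epicardial vertex is measured to its exact nearest point on the
    triangulated endocardium; candidate triangles are pruned with a KD-tree
    over endocardial vertices.
    """
    from scipy.spatial import cKDTree

    tris = triangulate_quads(mesh.endo_faces)
    uniq, inv = np.unique(tris, return_inverse=True)
    tris_c = inv.reshape(tris.shape)
    verts = mesh.points[uniq]
    epi_pts = mesh.points[mesh.epi_nodes]

    # vertex -> incident triangles (padded)
    n_tri = len(tris_c)
    incident = [[] for _ in range(len(verts))]
    for t in range(n_tri):
        for v in tris_c[t]:
            incident[v].append(t)
    max_inc = max(len(lst) for lst in incident)
    inc_pad = np.full((len(verts), max_inc), -1, dtype=int)
    for v, lst in enumerate(incident):
        inc_pad[v, : len(lst)] = lst

    k = min(k_candidates, len(verts))
    _, nn = cKDTree(verts).query(epi_pts, k=k)
    nn = np.atleast_2d(nn)
    cand = inc_pad[nn].reshape(len(epi_pts), -1)  # (P, k*max_inc)

    dmin = np.full(len(epi_pts), np.inf)
    valid_any = cand >= 0
    ccand = np.where(valid_any, cand, 0)
    P = np.repeat(epi_pts, cand.shape[1], axis=0)
    A = verts[tris_c[ccand.ravel(), 0]]
    B = verts[tris_c[ccand.ravel(), 1]]
    C = verts[tris_c[ccand.ravel(), 2]]
    d = _point_triangle_distance(P, A, B, C).reshape(cand.shape)
    d[~valid_any] = np.inf
    dmin = d.min(axis=1)
    return float(np.median(dmin))
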