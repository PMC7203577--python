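"""Parametric LV template geometry.

The template is a truncated prolate spheroid: the endocardial and
epicardial surfaces are confocal-axis spheroids sharing a flat basal plane,
meshed as a structured ring lattice closed at the apex by a structured quad
cap (so no element degenerates at the pole).  The construction is fully
analytic, which gives closed-form cavity volumes for testing, and the two
surfaces carry a fixed, co-registered vertex ordering so that cohorts of
templates can be stacked directly into shape matrices.

With the default resolution (``n_circ=20``, ``n_long=143``) each surface
holds 2,896 vertices, i.e. 5,792 for endo+epi combined and a 17,376
dimensional coordinate representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .mesh import LVMesh, hex_volumes

__all__ = [
    "LVTemplateSpec",
    "generate_template",
    "default_template_spec",
    "coarse_template_spec",
]


@dataclass
class LVTemplateSpec:
    """Geometry and resolution of a synthetic LV template.

    Lengths in cm.  ``wall_thickness_profile`` maps the longitudinal
    coordinate (0 = base, 1 = apex) to a wall thickness; when omitted the
    epicardium is an independent spheroid through ``epi_base_radius`` with
    apical thickness equal to the basal thickness.
    ``truncation_fraction`` is the kept fraction of the (epicardial)
    semi-axis above the equator; 0 truncates at the equator (hemispheroid).
    """

    endo_base_radius: float = 2.2
    epi_base_radius: float = 3.0
    apex_to_base_length: float = 8.0
    wall_thickness_profile: Optional[Callable[[float], float]] = None
    n_circ: int = 20
    n_long: int = 143
    n_trans: int = 3
    truncation_fraction: float = 0.35
    cap_fraction: float = 0.12
    v1_deg: float = 198.0
    v2_deg: float = 342.0

    def validate(self) -> None:
        for name in ("endo_base_radius", "epi_base_radius", "apex_to_base_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epi_base_radius <= self.endo_base_radius:
            raise ValueError("epi_base_radius must exceed endo_base_radius")
        if self.n_circ < 8 or self.n_circ % 4 != 0:
            raise ValueError("n_circ must be >= 8 and divisible by 4 (apex cap)")
        if self.n_long < 3:
            raise ValueError("n_long must be >= 3 (three strain layers)")
        if self.n_trans < 1:
            raise ValueError("n_trans must be >= 1")
        if not 0.0 <= self.truncation_fraction < 0.95:
            raise ValueError("truncation_fraction must lie in [0, 0.95)")
        if not 0.02 <= self.cap_fraction <= 0.5:
            raise ValueError("cap_fraction must lie in [0.02, 0.5]")
        if self.wall_thickness_profile is not None:
            for ell in (0.0, 0.5, 1.0):
                if self.wall_thickness_profile(ell) <= 0:
                    raise ValueError(
                        "wall_thickness_profile must be positive everywhere"
                    )

    # number of vertices on one surface (endo or epi)
    @property
    def surface_vertex_count(self) -> int:
        m = self.n_circ // 4 + 1
        return self.n_circ * (self.n_long + 1) + (m - 2) ** 2


def default_template_spec(**overrides) -> LVTemplateSpec:
    """Dense template used for shape analysis (5,792 surface vertices)."""
    return LVTemplateSpec(**overrides)


def coarse_template_spec(n_long: int = 6, **overrides) -> LVTemplateSpec:
    """Coarse template used by the reduced-order mechanics and inference."""
    return LVTemplateSpec(n_long=n_long, **overrides)


# ---------------------------------------------------------------------------


def _spheroid_geometry(spec: LVTemplateSpec):
    """Semi-axes and basal-plane height of the endo/epi spheroids."""
    f = spec.truncation_fraction
    L = spec.apex_to_base_length
    h = f * L / (1.0 + f)
    c_ep = L - h
    if spec.wall_thickness_profile is not None:
        t_apex = spec.wall_thickness_profile(1.0)
    else:
        t_apex = spec.epi_base_radius - spec.endo_base_radius
    c_en = c_ep - t_apex
    if c_en <= 0:
        raise ValueError("apex_to_base_length too small for the wall thickness")
    a_ep = spec.epi_base_radius / np.sqrt(1.0 - (h / c_ep) ** 2)
    a_en = spec.endo_base_radius / np.sqrt(1.0 - (h / c_en) ** 2)
    return a_en, c_en, a_ep, c_ep, h


def _cap_grid_fractions(n_circ: int):
    """Coons-patch (radius fraction, angle) of the cap-interior grid points.

    The apex cap is an m x m structured grid (m = n_circ/4 + 1) whose
    boundary is the last lateral ring.  Interior points are placed by
    transfinite interpolation of the boundary polygon in the projection
    plane and then mapped back onto the spheroid.
    """
    m = n_circ // 4 + 1
    theta = 2.0 * np.pi * np.arange(n_circ) / n_circ
    ring = np.stack([np.cos(theta), np.sin(theta)], axis=1)  # unit-radius ring

    # grid boundary traversal -> ring index
    bidx = np.full((m, m), -1, dtype=int)
    for p in range(m):
        bidx[p, 0] = p
    for q in range(1, m):
        bidx[m - 1, q] = (m - 1) + q
    for p in range(m - 2, -1, -1):
        bidx[p, m - 1] = 2 * (m - 1) + (m - 1 - p)
    for q in range(m - 2, 0, -1):
        bidx[0, q] = 3 * (m - 1) + (m - 1 - q)

    pts = np.zeros((m, m, 2))
    mask = bidx >= 0
    pts[mask] = ring[bidx[mask]]
    xi = np.arange(m) / (m - 1)
    for p in range(1, m - 1):
        for q in range(1, m - 1):
            s, t = xi[p], xi[q]
            val = (
                (1 - t) * pts[p, 0]
                + t * pts[p, m - 1]
                + (1 - s) * pts[0, q]
                + s * pts[m - 1, q]
                - (
                    (1 - s) * (1 - t) * pts[0, 0]
                    + s * (1 - t) * pts[m - 1, 0]
                    + s * t * pts[m - 1, m - 1]
                    + (1 - s) * t * pts[0, m - 1]
                )
            )
            pts[p, q] = val

    interior = [(p, q) for p in range(1, m - 1) for q in range(1, m - 1)]
    r_frac = np.array([min(1.0, np.hypot(*pts[p, q])) for p, q in interior])
    ang = np.array([np.arctan2(pts[p, q][1], pts[p, q][0]) for p, q in interior])
    return m, bidx, interior, r_frac, ang


def generate_template(spec: LVTemplateSpec) -> LVMesh:
    """Build the hexahedral wall mesh of a truncated prolate-spheroid LV."""
    spec.validate()
    a_en, c_en, a_ep, c_ep, h = _spheroid_geometry(spec)
    nc, nl, nt = spec.n_circ, spec.n_long, spec.n_trans
    m, bidx, interior, cap_r, cap_ang = _cap_grid_fractions(nc)
    n_capint = (m - 2) ** 2
    n_level = nc * (nl + 1) + n_capint

    ell_cap = 1.0 - spec.cap_fraction
    theta = 2.0 * np.pi * np.arange(nc) / nc

    def surface_point(a, c, ub, ell, th):
        """Point on a spheroid surface at longitudinal fraction ell."""
        u = ub + ell * (np.pi - ub)
        return np.stack(
            [a * np.sin(u) * np.cos(th), a * np.sin(u) * np.sin(th), c * np.cos(u)],
            axis=-1,
        )

    ub_en = np.arccos(np.clip(h / c_en, -1, 1))
    ub_ep = np.arccos(np.clip(h / c_ep, -1, 1))

    # longitudinal fractions of lateral rings (ring 0 = base, ring nl = cap rim)
    ring_ell = np.linspace(0.0, ell_cap, nl + 1)
    cap_ell = ell_cap + (1.0 - ell_cap) * (1.0 - cap_r)

    ells = np.concatenate(
        [np.repeat(ring_ell, nc), cap_ell]
    )  # per level-local node, shape (n_level,)
    thetas = np.concatenate([np.tile(theta, nl + 1), cap_ang])

    endo = surface_point(a_en, c_en, ub_en, ells, thetas)
    if spec.wall_thickness_profile is None:
        epi = surface_point(a_ep, c_ep, ub_ep, ells, thetas)
    else:
        # offset the endocardium along its outward normal, blending the
        # normal to horizontal near the base so the basal ring stays planar
        u = ub_en + ells * (np.pi - ub_en)
        nvec = np.stack(
            [
                np.sin(u) * np.cos(thetas) / a_en,
                np.sin(u) * np.sin(thetas) / a_en,
                np.cos(u) / c_en,
            ],
            axis=-1,
        )
        blend = np.clip(ells / 0.15, 0.0, 1.0)
        nvec[:, 2] *= blend
        nvec /= np.linalg.norm(nvec, axis=1, keepdims=True)
        w = np.array([spec.wall_thickness_profile(e) for e in ells])
        epi = endo + w[:, None] * nvec
        epi[: nc, 2] = h  # keep the basal ring exactly in the basal plane

    # transmural node levels: t = 0 endo ... t = nt epi
    points = np.concatenate(
        [endo + (t / nt) * (epi - endo) for t in range(nt + 1)], axis=0
    )
    node_ell = np.tile(ells, nt + 1)
    node_s = np.repeat(1.0 - np.arange(nt + 1) / nt, n_level)

    def nid(t, local):
        return t * n_level + local

    def lat(i, j):
        return i * nc + (j % nc)

    cap_local = {pq: nc * (nl + 1) + k for k, pq in enumerate(interior)}

    def cap_node(p, q):
        if bidx[p, q] >= 0:
            return lat(nl, bidx[p, q])
        return cap_local[(p, q)]

    # ----- elements ---------------------------------------------------
    hexes, elem_ring, elem_circ, elem_trans = [], [], [], []
    for t in range(nt):
        for i in range(nl):
            for j in range(nc):
                bot = [lat(i, j), lat(i, j + 1), lat(i + 1, j + 1), lat(i + 1, j)]
                hexes.append([nid(t, n) for n in bot] + [nid(t + 1, n) for n in bot])
                elem_ring.append(i)
                elem_circ.append(j)
                elem_trans.append(t)
        for p in range(m - 1):
            for q in range(m - 1):
                bot = [
                    cap_node(p, q),
                    cap_node(p + 1, q),
                    cap_node(p + 1, q + 1),
                    cap_node(p, q + 1),
                ]
                hexes.append([nid(t, n) for n in bot] + [nid(t + 1, n) for n in bot])
                elem_ring.append(-1)
                elem_circ.append(-1)
                elem_trans.append(t)
    hexes = np.asarray(hexes, dtype=np.int64)

    # enforce positive cell volumes (swap bottom/top quads where needed)
    vols = hex_volumes(points, hexes)
    flip = vols < 0
    hexes[flip] = hexes[flip][:, [4, 5, 6, 7, 0, 1, 2, 3]]
    vols = hex_volumes(points, hexes)
    if np.any(vols <= 0):
        raise ValueError("template produced a degenerate (non-positive) element")

    # ----- surfaces ----------------------------------------------------
    def surface_quads(t):
        quads = []
        for i in range(nl):
            for j in range(nc):
                quads.append(
                    [
                        nid(t, lat(i, j)),
                        nid(t, lat(i, j + 1)),
                        nid(t, lat(i + 1, j + 1)),
                        nid(t, lat(i + 1, j)),
                    ]
                )
        for p in range(m - 1):
            for q in range(m - 1):
                quads.append(
                    [
                        nid(t, cap_node(p, q)),
                        nid(t, cap_node(p + 1, q)),
                        nid(t, cap_node(p + 1, q + 1)),
                        nid(t, cap_node(p, q + 1)),
                    ]
                )
        return np.asarray(quads, dtype=np.int64)

    endo_nodes = np.arange(n_level, dtype=np.int64)
    epi_nodes = np.arange(nt * n_level, (nt + 1) * n_level, dtype=np.int64)
    basal_nodes = np.concatenate(
        [np.arange(t * n_level, t * n_level + nc) for t in range(nt + 1)]
    )

    j1 = int(round(spec.v1_deg / (360.0 / nc))) % nc
    j2 = int(round(spec.v2_deg / (360.0 / nc))) % nc

    mesh = LVMesh(
        points=points,
        hexes=hexes,
        endo_nodes=endo_nodes,
        epi_nodes=epi_nodes,
        endo_faces=surface_quads(0),
        epi_faces=surface_quads(nt),
        basal_nodes=basal_nodes,
        endo_basal_ring=np.arange(nc, dtype=np.int64),
        epi_basal_ring=np.arange(nt * n_level, nt * n_level + nc, dtype=np.int64),
        node_ell=node_ell,
        node_s=node_s,
        elem_ring=np.asarray(elem_ring),
        elem_circ=np.asarray(elem_circ),
        elem_trans=np.asarray(elem_trans),
        base_z=float(h),
        n_circ=nc,
        n_long=nl,
        n_trans=nt,
        v1_node=int(nid(nt, lat(0, j1))),
        v2_node=int(nid(nt, lat(0, j2))),
        meta={
            "spec": {
                "endo_base_radius": spec.endo_base_radius,
                "epi_base_radius": spec.epi_base_radius,
                "apex_to_base_length": spec.apex_to_base_length,
                "truncation_fraction": spec.truncation_fraction,
                "n_circ": nc,
                "n_long": nl,
                "n_trans": nt,
            },
            "semi_axes": {"a_en": a_en, "c_en": c_en, "a_ep": a_ep, "c_ep": c_ep},
        },
    )
    return mesh
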