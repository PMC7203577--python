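"""Left-ventricle wall meshes.

The package represents the LV wall as a structured hexahedral mesh between
an endocardial and an epicardial surface, truncated by a flat basal plane.
All coordinates are in centimetres with the long axis along +z and the
basal plane at ``z = base_z``; the apex points toward -z.  Node bookkeeping
(surface sets, basal ring, transmural/longitudinal coordinates, insertion
point markers) is carried on the mesh so that downstream stages (alignment,
fiber rules, strain regions, reduced-order mechanics) never have to guess
topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["LVMesh", "triangulate_quads", "surface_volume", "hex_volumes"]


def triangulate_quads(quads: np.ndarray) -> np.ndarray:
    """Split quads into triangle pairs along a globally consistent diagonal.

    The diagonal always passes through the quad corner holding the smallest
    node id, so a face shared by two hexahedra (or by a hexahedron and a
    surface) is triangulated identically on both sides.  This makes volume
    computations by the divergence theorem exactly additive.
    """
    quads = np.asarray(quads)
    amin = np.argmin(quads, axis=1)
    # roll each quad so the smallest id sits first, preserving orientation
    idx = (amin[:, None] + np.arange(4)[None, :]) % 4
    q = np.take_along_axis(quads, idx, axis=1)
    t1 = q[:, [0, 1, 2]]
    t2 = q[:, [0, 2, 3]]
    return np.concatenate([t1, t2], axis=0)


def surface_volume(points: np.ndarray, tris: np.ndarray, signed: bool = False) -> float:
    """Volume enclosed by a closed triangulated surface (divergence theorem)."""
    a = points[tris[:, 0]]
    b = points[tris[:, 1]]
    c = points[tris[:, 2]]
    v = np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0
    return v if signed else abs(v)


_HEX_FACES = np.array(
    [
        [0, 3, 2, 1],
        [4, 5, 6, 7],
        [0, 1, 5, 4],
        [1, 2, 6, 5],
        [2, 3, 7, 6],
        [3, 0, 4, 7],
    ]
)


def hex_volumes(points: np.ndarray, hexes: np.ndarray) -> np.ndarray:
    """Signed volumes of hexahedral cells via their (consistently
    triangulated) boundary faces."""
    vols = np.zeros(len(hexes))
    for face in _HEX_FACES:
        quads = hexes[:, face]
        n = len(quads)
        tris = triangulate_quads(quads)
        a = points[tris[:, 0]]
        b = points[tris[:, 1]]
        c = points[tris[:, 2]]
        contrib = np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
        vols += contrib[:n] + contrib[n:]
    return vols


@dataclass
class LVMesh:
    """Template-registered LV wall mesh.

    Attributes
    ----------
    points : (N, 3) float array, cm
    hexes : (E, 8) int array, VTK node ordering
    endo_nodes, epi_nodes : node-id arrays of the two surfaces (disjoint)
    endo_faces, epi_faces : (F, 4) surface quads (subset of hex faces)
    basal_nodes : node ids lying in the basal plane (all transmural levels)
    endo_basal_ring, epi_basal_ring : ordered basal rings of each surface
    node_ell : longitudinal coordinate per node, 0 = base, 1 = apex
    node_s : transmural coordinate per node, 1 = endocardium, 0 = epicardium
    elem_ring : longitudinal element ring index (-1 for apex-cap elements)
    elem_circ : circumferential element index (-1 for apex-cap elements)
    elem_trans : transmural element layer index (0 = endocardial layer)
    v1_node, v2_node : node ids marking the right-ventricular insertion
        points on the epicardial basal ring (v1 inferior, v2 anterior)
    fiber, sheet : optional per-element unit vectors (rule-based)
    """

    points: np.ndarray
    hexes: np.ndarray
    endo_nodes: np.ndarray
    epi_nodes: np.ndarray
    endo_faces: np.ndarray
    epi_faces: np.ndarray
    basal_nodes: np.ndarray
    endo_basal_ring: np.ndarray
    epi_basal_ring: np.ndarray
    node_ell: np.ndarray
    node_s: np.ndarray
    elem_ring: np.ndarray
    elem_circ: np.ndarray
    elem_trans: np.ndarray
    base_z: float
    n_circ: int
    n_long: int
    n_trans: int
    v1_node: int
    v2_node: int
    fiber: Optional[np.ndarray] = None
    sheet: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def n_elements(self) -> int:
        return len(self.hexes)

    @property
    def surface_nodes(self) -> np.ndarray:
        return np.concatenate([self.endo_nodes, self.epi_nodes])

    def copy(self) -> "LVMesh":
        return replace(
            self,
            points=self.points.copy(),
            fiber=None if self.fiber is None else self.fiber.copy(),
            sheet=None if self.sheet is None else self.sheet.copy(),
            meta=dict(self.meta),
        )

    def with_points(self, points: np.ndarray) -> "LVMesh":
        out = replace(self, points=np.asarray(points, dtype=float))
        if out.points.shape != self.points.shape:
            raise ValueError("replacement points must match node count")
        return out

    # ------------------------------------------------------------------
    def insertion_angle(self, which: str = "v1") -> float:
        """Angle (degrees, [0, 360)) of an insertion-point marker node."""
        node = self.v1_node if which == "v1" else self.v2_node
        if node < 0:
            raise ValueError(f"mesh carries no {which} insertion-point annotation")
        x, y = self.points[node, :2]
        return float(np.degrees(np.arctan2(y, x)) % 360.0)

    def element_centroids(self) -> np.ndarray:
        return self.points[self.hexes].mean(axis=1)

    def surface_coordinates(self) -> np.ndarray:
        """Flattened (x, y, z) coordinates of endo then epi surface vertices."""
        ids = self.surface_nodes
        return self.points[ids].reshape(-1)
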