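"""Synthetic brain surface: icosphere triangulation, dual mesh, territories.

The real cortical surface is replaced by a geodesic sphere.  The pial
vessel network is the dual graph of the triangulation (one node per
triangle, one edge per shared triangle edge), which away from territory
seams is 3-regular — a hexagonal-type mesh.  Perfusion territories are
fixed angular sectors approximating the eight major regions: six cerebral
lobes (left/right x anterior/middle/posterior), cerebellum and brainstem.
"""

from __future__ import annotations

import numpy as np

from .network import BRAIN_TERRITORIES


def icosphere(refinement: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit icosphere: (vertices (V,3), faces (F,3)); F = 20 * 4**refinement."""
    if refinement < 0:
        raise ValueError("refinement must be >= 0")
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=int)
    for _ in range(refinement):
        verts, faces = _subdivide(verts, faces)
    return verts, faces


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vlist = list(verts)
    midpoint: dict[tuple[int, int], int] = {}

    def mid(i: int, j: int) -> int:
        key = (min(i, j), max(i, j))
        if key not in midpoint:
            p = vlist[i] + vlist[j]
            vlist.append(p / np.linalg.norm(p))
            midpoint[key] = len(vlist) - 1
        return midpoint[key]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        new_faces.extend([[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]])
    return np.array(vlist), np.array(new_faces, dtype=int)


def dual_mesh(verts: np.ndarray, faces: np.ndarray,
              radius: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Dual graph of a closed triangulation.

    Returns (centroids (F,3) projected onto the sphere of ``radius``,
    dual_edges (E,2) as face-index pairs, one per shared triangle edge).
    On a closed surface every triangle has three neighbours, so the dual
    is 3-regular.
    """
    centroids = verts[faces].mean(axis=1)
    centroids *= radius / np.linalg.norm(centroids, axis=1, keepdims=True)
    edge_to_faces: dict[tuple[int, int], list[int]] = {}
    for fi, (a, b, c) in enumerate(faces):
        for i, j in ((a, b), (b, c), (c, a)):
            key = (min(i, j), max(i, j))
            edge_to_faces.setdefault(key, []).append(fi)
    dual_edges = []
    for fs in edge_to_faces.values():
        if len(fs) == 2:
            dual_edges.append(fs)
    return centroids, np.array(sorted(map(tuple, dual_edges)), dtype=int)


# angular-sector thresholds on the unit sphere (z up, y anterior, x right);
# the brainstem cap and cerebellar band are sized to roughly their share of
# real cortical surface (about 5% and 15%)
_Z_BRAINSTEM = -0.9
_Z_CEREBELLUM = -0.6
_Y_ANTERIOR = 0.35


def assign_territories(points: np.ndarray) -> np.ndarray:
    """Territory label per point by fixed angular sector.

    The bottom cap is the brainstem, the band above it the cerebellum; the
    remaining cap splits left/right by x and anterior/middle/posterior by y
    into the six cerebral territories.
    """
    p = np.asarray(points, dtype=float)
    u = p / np.linalg.norm(p, axis=1, keepdims=True)
    out = np.empty(len(u), dtype=object)
    z, y, x = u[:, 2], u[:, 1], u[:, 0]
    out[z < _Z_BRAINSTEM] = "brainstem"
    out[(z >= _Z_BRAINSTEM) & (z < _Z_CEREBELLUM)] = "cerebellum"
    cerebral = z >= _Z_CEREBELLUM
    side = np.where(x >= 0, "R", "L")
    lobe = np.where(y > _Y_ANTERIOR, "ACA", np.where(y < -_Y_ANTERIOR, "PCA", "MCA"))
    for i in np.nonzero(cerebral)[0]:
        out[i] = f"{side[i]}-{lobe[i]}"
    assert set(np.unique(out)) <= set(BRAIN_TERRITORIES)
    return out
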