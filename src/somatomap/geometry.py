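"""Surface-based map geometry: areas, digit locations, distances, overlap."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

from .datatypes import CortexPatch


def triangle_areas(patch: CortexPatch) -> np.ndarray:
    """Area of every face (mm^2); degenerate faces have area 0."""
    v = patch.vertices
    a = v[patch.faces[:, 1]] - v[patch.faces[:, 0]]
    b = v[patch.faces[:, 2]] - v[patch.faces[:, 0]]
    return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


def vertex_areas(patch: CortexPatch, warn_degenerate: bool = False) -> np.ndarray:
    """Per-vertex surface area: 1/3 of each incident triangle's area.

    Summing over all vertices recovers the total mesh area exactly.
    """
    tri = triangle_areas(patch)
    if warn_degenerate and np.any(tri == 0.0):
        import warnings
        warnings.warn("mesh contains zero-area (degenerate) faces")
    out = np.zeros(patch.n_vertices)
    for k in range(3):
        np.add.at(out, patch.faces[:, k], tri / 3.0)
    return out


def roi_surface_area(patch: CortexPatch, mask: np.ndarray) -> float:
    """Summed vertex-wise area of a significant map / ROI (mm^2)."""
    mask = np.asarray(mask)
    if mask.dtype == bool:
        if mask.shape != (patch.n_vertices,):
            raise ValueError("boolean mask length must match vertex count")
        idx = np.flatnonzero(mask)
    else:
        idx = mask.astype(int)
        if idx.size and (idx.min() < 0 or idx.max() >= patch.n_vertices):
            raise ValueError("mask indexes vertices outside the mesh")
    return float(vertex_areas(patch)[idx].sum())


@dataclass
class DigitROI:
    """One digit's significant vertex set with its per-vertex statistic."""

    digit: int
    vertex_indices: np.ndarray
    statistic: np.ndarray
    missing: bool = field(default=False)

    def __post_init__(self):
        self.vertex_indices = np.asarray(self.vertex_indices, int)
        self.statistic = np.asarray(self.statistic, float)
        if len(self.vertex_indices) == 0:
            self.missing = True
        elif len(self.statistic) != len(self.vertex_indices):
            raise ValueError("one statistic per ROI vertex required")

    @property
    def peak_vertex(self) -> int:
        """Vertex with the maximal statistic (ties: lowest vertex index)."""
        if self.missing:
            raise ValueError(f"digit D{self.digit} ROI is empty")
        order = np.argsort(self.vertex_indices)  # deterministic tie-break
        vi, st = self.vertex_indices[order], self.statistic[order]
        return int(vi[np.argmax(st)])


def digit_location(roi: DigitROI, patch: CortexPatch,
                   mode: str = "peak") -> np.ndarray:
    """3D location of a digit representation.

    ``peak``: coordinates of the max-statistic vertex.  ``center``:
    statistic-weighted centroid of the ROI coordinates.
    """
    if roi.missing:
        return np.full(3, np.nan)
    coords = patch.vertices[roi.vertex_indices]
    if mode == "peak":
        return patch.vertices[roi.peak_vertex].copy()
    if mode == "center":
        w = roi.statistic
        if np.all(w == 0):
            w = np.ones_like(w)
        return (coords * w[:, None]).sum(axis=0) / w.sum()
    raise ValueError("mode must be 'peak' or 'center'")


def _edge_graph(patch: CortexPatch) -> sparse.csr_matrix:
    e = patch.edges()
    w = np.linalg.norm(patch.vertices[e[:, 0]] - patch.vertices[e[:, 1]], axis=1)
    n = patch.n_vertices
    g = sparse.coo_matrix((w, (e[:, 0], e[:, 1])), shape=(n, n))
    return (g + g.T).tocsr()


def cortical_distance(patch: CortexPatch, loc_a, loc_b,
                      kind: str = "euclidean") -> float:
    """Distance between two digit locations in mm.

    ``euclidean``: straight-line 3D distance between two coordinates (or
    vertex indices).  ``geodesic``: length of the shortest path along
    mesh edges (Dijkstra) between two *vertex indices*; disconnected
    vertices yield inf.
    """
    if kind == "euclidean":
        a = patch.vertices[loc_a] if np.isscalar(loc_a) else np.asarray(loc_a, float)
        b = patch.vertices[loc_b] if np.isscalar(loc_b) else np.asarray(loc_b, float)
        return float(np.sqrt(np.sum((a - b) ** 2)))
    if kind == "geodesic":
        if not (np.isscalar(loc_a) and np.isscalar(loc_b)):
            raise ValueError("geodesic distance requires vertex indices")
        d = dijkstra(_edge_graph(patch), directed=False,
                     indices=int(loc_a))[int(loc_b)]
        return float(d)  # inf when disconnected
    raise ValueError("kind must be 'euclidean' or 'geodesic'")


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Overlap of two vertex sets: 2|A n B| / (|A| + |B|).

    1 means identical sets, 0 disjoint sets; two empty sets are undefined
    (NaN).
    """
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError("masks live on different vertex sets")
    denom = a.sum() + b.sum()
    if denom == 0:
        return np.nan
    return float(2.0 * np.sum(a & b) / denom)
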