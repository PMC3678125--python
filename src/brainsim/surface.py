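"""Toy-scale cortical surface support: meshes, region mappings and
instantaneous local-coupling kernels.

Surface simulations place one network node per mesh vertex (plus one node
per non-cortical region); neighbouring vertices interact through a sparse
local kernel evaluated on inter-vertex distance, with zero conduction
delay (short distances make propagation effectively instantaneous).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import sparse
from scipy.spatial.distance import cdist

from .exceptions import DimensionError

__all__ = ["Mesh", "RegionSurface", "build_local_kernel", "make_grid_mesh"]


@dataclass
class Mesh:
    """Triangular mesh: ``vertices`` (n, 3) in mm, ``triangles`` (m, 3) indices."""

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise DimensionError(f"vertices must be (n, 3), got {self.vertices.shape}")
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise DimensionError("triangle index out of range")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]


@dataclass
class RegionSurface:
    """A mesh plus the mapping from vertices to connectome regions.

    ``region_mapping[v]`` is the region index of vertex ``v``.  Regions
    absent from the mapping (e.g. subcortical structures) are treated as
    non-cortical and appended to the node list as single point nodes.
    """

    mesh: Mesh
    region_mapping: np.ndarray

    def __post_init__(self):
        self.region_mapping = np.asarray(self.region_mapping, dtype=np.int64)
        if self.region_mapping.size != self.mesh.n_vertices:
            raise DimensionError(
                "region_mapping length must equal the number of vertices"
            )


def build_local_kernel(
    mesh: Mesh | np.ndarray,
    equation: Callable[[np.ndarray], np.ndarray],
    cutoff: float,
    include_self: bool = True,
) -> sparse.csr_matrix:
    """Sparse instantaneous coupling kernel between nearby vertices.

    ``K[i, j] = equation(|r_i - r_j|)`` for pairs within ``cutoff`` mm,
    zero elsewhere; the diagonal is kept or zeroed per ``include_self``.
    Dense distance evaluation — intended for toy meshes (<= ~10^3 vertices).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    vertices = mesh.vertices if isinstance(mesh, Mesh) else np.asarray(mesh, float)
    d = cdist(vertices, vertices)
    mask = d <= cutoff
    if not include_self:
        np.fill_diagonal(mask, False)
    k = np.zeros_like(d)
    k[mask] = np.asarray(equation(d[mask]))
    return sparse.csr_matrix(k)


def make_grid_mesh(nx: int = 5, ny: int = 5, spacing: float = 2.0) -> Mesh:
    """Small planar triangulated grid, handy for tests and examples."""
    xs, ys = np.meshgrid(np.arange(nx) * spacing, np.arange(ny) * spacing)
    vertices = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(nx * ny)])
    tris = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            v0 = j * nx + i
            tris.append([v0, v0 + 1, v0 + nx])
            tris.append([v0 + 1, v0 + nx + 1, v0 + nx])
    return Mesh(vertices=vertices, triangles=np.array(tris))
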