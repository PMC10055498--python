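"""Nested icosahedral tessellations of the sphere and the index maps built on them.

The whole architecture is driven by the combinatorics of recursively
subdivided icosahedra (icospheres).  An order-``k`` icosphere ``I_k`` has
``10*4^k + 2`` vertices, ``20*4^k`` faces and ``30*4^k`` edges.  The
subdivision here follows a fixed canonical convention:

* the base icosahedron has its two poles on the +/- z axis;
* subdividing appends edge-midpoint vertices *after* the existing vertices,
  so the order-(k-1) vertices are a prefix of the order-k vertices with
  identical indices and coordinates (mesh nesting);
* the four children of face ``f`` are stored at indices ``4f .. 4f+3``.

The child-indexing convention makes every derived index map trivial
arithmetic: the descendants of face ``f`` at ``d`` levels down occupy the
contiguous run ``[4^d * f, 4^d * (f+1))``, so attention windows are
contiguous runs of the token sequence and patch merging is a stride-4
reshape.  The geometric tests verify that this arithmetic agrees with
explicit spherical-triangle containment.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "IcosphereMesh",
    "PatchPartition",
    "WindowMap",
    "build_icosphere",
    "face_children",
    "face_parent",
    "build_patch_partition",
    "build_window_map",
    "vertex_counts",
]

# golden-ratio icosahedron, rotated so two vertices sit on the +/- z poles
_PHI = (1.0 + np.sqrt(5.0)) / 2.0


def _base_icosahedron() -> tuple[np.ndarray, np.ndarray]:
    # 12 vertices of a regular icosahedron built from three golden rectangles,
    # then rotated about y so that vertex 0 -> +z pole and vertex 3 -> -z pole.
    v = np.array(
        [
            [-1, _PHI, 0], [1, _PHI, 0], [-1, -_PHI, 0], [1, -_PHI, 0],
            [0, -1, _PHI], [0, 1, _PHI], [0, -1, -_PHI], [0, 1, -_PHI],
            [_PHI, 0, -1], [_PHI, 0, 1], [-_PHI, 0, -1], [-_PHI, 0, 1],
        ],
        dtype=np.float64,
    )
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    # rotate vertex 0 to +z (its antipode, vertex 3, lands on -z)
    z = v[0]
    axis = np.cross(z, [0.0, 0.0, 1.0])
    axis /= np.linalg.norm(axis)
    ang = np.arccos(np.clip(z @ [0.0, 0.0, 1.0], -1, 1))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
    v = v @ R.T
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return v, f


@dataclass(frozen=True)
class IcosphereMesh:
    """An order-``k`` icosphere: unit vertices and outward-oriented faces."""

    order: int
    vertices: np.ndarray  # (|V_k|, 3) float64, unit norm
    faces: np.ndarray  # (|F_k|, 3) int64

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def face_centroids(self, *, normalized: bool = True) -> np.ndarray:
        c = self.vertices[self.faces].mean(axis=1)
        if normalized:
            c = c / np.linalg.norm(c, axis=1, keepdims=True)
        return c

    def edges(self) -> np.ndarray:
        """Unique undirected edges, each as a sorted vertex pair."""
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)


def vertex_counts(order: int) -> tuple[int, int, int]:
    """(|V_k|, |F_k|, E_k) for an order-``k`` icosphere."""
    return 10 * 4**order + 2, 20 * 4**order, 30 * 4**order


def _subdivide(vertices: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One canonical 4-fold subdivision step.

    Midpoint vertices are appended after the existing vertices, ordered by
    first occurrence when scanning faces in order and, within a face, the
    edges (v0,v1), (v1,v2), (v2,v0).  Face ``f``'s children land at
    ``4f..4f+3``: the three corner triangles (in corner order) then the
    central triangle.
    """
    n_old = vertices.shape[0]
    # per-face edges in canonical scan order -> (3F, 2) sorted keys
    e = np.concatenate(
        [faces[:, [0, 1]][:, None], faces[:, [1, 2]][:, None], faces[:, [2, 0]][:, None]],
        axis=1,
    ).reshape(-1, 2)
    key = np.sort(e, axis=1)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    # renumber unique edges by first occurrence so ordering is canonical
    rank = np.argsort(np.argsort(first, kind="stable"), kind="stable")
    mid_id = n_old + rank[inverse]  # (3F,) midpoint vertex index per face-edge
    order_of_unique = np.argsort(first, kind="stable")
    mids = vertices[key[first][order_of_unique]].mean(axis=1)
    mids /= np.linalg.norm(mids, axis=1, keepdims=True)
    new_vertices = np.concatenate([vertices, mids])

    m = mid_id.reshape(-1, 3)  # m01, m12, m20 per face
    a, b, c = faces[:, 0], faces[:, 1], faces[:, 2]
    children = np.stack(
        [
            np.stack([a, m[:, 0], m[:, 2]], axis=1),
            np.stack([b, m[:, 1], m[:, 0]], axis=1),
            np.stack([c, m[:, 2], m[:, 1]], axis=1),
            np.stack([m[:, 0], m[:, 1], m[:, 2]], axis=1),
        ],
        axis=1,
    )  # (F, 4, 3)
    return new_vertices, children.reshape(-1, 3)


@lru_cache(maxsize=16)
def build_icosphere(order: int) -> IcosphereMesh:
    """Build the canonical order-``order`` icosphere (deterministic, cached)."""
    if not isinstance(order, (int, np.integer)) or isinstance(order, bool):
        raise TypeError(f"order must be an integer, got {order!r}")
    if order < 0:
        raise ValueError(f"icosphere order must be >= 0, got {order}")
    v, f = _base_icosahedron()
    for _ in range(order):
        v, f = _subdivide(v, f)
    v.setflags(write=False)
    f.setflags(write=False)
    return IcosphereMesh(order=int(order), vertices=v, faces=f)


def face_children(face_id: int, order: int) -> np.ndarray:
    """Order-(order+1) face ids covering face ``face_id`` of the order-``order`` mesh."""
    n = 20 * 4**order
    if not 0 <= face_id < n:
        raise ValueError(f"face_id {face_id} out of range for order {order} ({n} faces)")
    return np.arange(4 * face_id, 4 * face_id + 4, dtype=np.int64)

def face_parent(face_id: int) -> int:
    return int(face_id) // 4


@dataclass(frozen=True)
class PatchPartition:
    """Per coarse face, the 6 fine-mesh vertex ids forming its patch.

    Vertex order within a patch: the 3 parent corners then the 3 edge
    midpoints, with midpoint ``i`` opposite corner ``i``.
    """

    fine_order: int
    coarse_order: int
    patch_vertex_ids: np.ndarray  # (|F_coarse|, 6) int64

    @property
    def n_patches(self) -> int:
        return int(self.patch_vertex_ids.shape[0])

    @property
    def patch_size(self) -> int:
        return int(self.patch_vertex_ids.shape[1])


def build_patch_partition(fine: IcosphereMesh, coarse: IcosphereMesh) -> PatchPartition:
    """Map each coarse face to the 6 fine vertices it covers.

    Relies on nesting: a coarse face's corner ids are valid fine-mesh ids,
    and its edge midpoints are the extra vertex shared by its corner-child
    faces on the fine mesh.
    """
    if fine.order != coarse.order + 1:
        raise ValueError(
            f"fine order must be coarse order + 1, got {fine.order} vs {coarse.order}"
        )
    F = coarse.n_faces
    fine_faces = fine.faces.reshape(F, 4, 3)
    corners = coarse.faces  # (F, 3): a, b, c
    central = fine_faces[:, 3]  # (m01, m12, m20)
    m01, m12, m20 = central[:, 0], central[:, 1], central[:, 2]
    # midpoint opposite corner i: opposite a(=v0) is m12, opposite b is m20, opposite c is m01
    patch = np.stack([corners[:, 0], corners[:, 1], corners[:, 2], m12, m20, m01], axis=1)
    return PatchPartition(
        fine_order=fine.order, coarse_order=coarse.order, patch_vertex_ids=patch
    )


@dataclass(frozen=True)
class WindowMap:
    """Assignment of token-sequence positions to non-overlapping attention windows.

    ``window_of[p] = p // window_size`` under the canonical face ordering;
    the geometric tests confirm this equals assigning each position's face
    centroid to the coarse window face containing it.  ``shift`` is the
    cyclic roll (in positions) used by shifted-window attention.
    """

    level: int
    seq_len: int
    window_size: int
    n_windows: int
    shift: int
    grid_order: int  # grid indexing the sequence
    window_grid_order: int  # grid whose faces are the windows; -1 => global

    @property
    def window_of(self) -> np.ndarray:
        return np.arange(self.seq_len, dtype=np.int64) // self.window_size

    @property
    def is_global(self) -> bool:
        return self.n_windows == 1


def build_window_map(level: int, shift_fraction: float = 0.5, input_order: int = 6) -> WindowMap:
    """Window map for encoder level ``level`` of a model on an order-``input_order`` mesh.

    At level ``l`` the token sequence is indexed by the faces of
    ``I_{input_order - l}``.  When that grid order ``g`` is >= 3 the windows
    are the faces of ``I_{g-3}`` (64 positions each); otherwise attention is
    global (a single window over the whole sequence, with no shift).  For
    the standard ico6 model this yields 64-patch windows at levels 1-3 and
    global attention over the 320 ico2 patches at level 4.
    """
    if level not in (1, 2, 3, 4):
        raise ValueError(f"level must be in 1..4, got {level}")
    if not 0.0 <= shift_fraction < 1.0:
        raise ValueError(f"shift_fraction must be in [0, 1), got {shift_fraction}")
    g = input_order - level
    if g < 0:
        raise ValueError(f"input_order {input_order} too small for level {level}")
    seq_len = 20 * 4**g
    if g >= 3:
        window_grid = g - 3
        window_size = 64
        shift = int(round(shift_fraction * window_size))
    else:
        window_grid = -1
        window_size = seq_len
        shift = 0
    return WindowMap(
        level=level,
        seq_len=seq_len,
        window_size=window_size,
        n_windows=seq_len // window_size,
        shift=shift,
        grid_order=g,
        window_grid_order=window_grid,
    )
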