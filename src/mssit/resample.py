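"""Barycentric resampling between spherical meshes and surface augmentations.

Resampling interprets every target point as a ray from the origin; the value
is the barycentric interpolation of the three vertices of the source face the
ray hits.  Weights are convex, so constants are reproduced exactly and each
output channel stays within the input range.

Two augmentations mirror the training recipe for cortical surfaces:

* random rotations, per-axis angles uniform in [-max_deg, +max_deg],
  composed in fixed x -> y -> z order;
* elastic warps, displacing the vertices of a coarse (default ico2) grid by
  tangential vectors of at most ``warp_max_fraction`` (default 1/8) of each
  vertex's mean neighbour distance, interpolated to the full-resolution grid
  online.  The 1/8 bound keeps the warp diffeomorphic (no folded faces).

Labels are transformed with nearest-corner (mode of the barycentric corners)
assignment: they are categorical, so interpolation would be meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .icosphere import IcosphereMesh, build_icosphere
from .surface_io import SurfaceSignal

__all__ = [
    "AugmentationConfig",
    "find_faces",
    "barycentric_matrix",
    "barycentric_resample",
    "random_rotation",
    "elastic_warp",
    "augment",
]


@dataclass
class AugmentationConfig:
    """Augmentation hyperparameters.

    Defaults follow the training recipe: augmentation applied with
    probability 0.8; if applied, rotation or elastic warp with equal
    probability; rotations up to 30 degrees per axis (use 15 for
    segmentation); warps displace the ico2 grid by at most 1/8 of the
    neighbour distance.
    """

    apply_probability: float = 0.8
    rotation_share: float = 0.5
    max_rotation_deg: float = 30.0
    warp_grid_order: int = 2
    warp_max_fraction: float = 1.0 / 8.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.apply_probability <= 1.0:
            raise ValueError("apply_probability must be in [0, 1]")
        if not 0.0 <= self.rotation_share <= 1.0:
            raise ValueError("rotation_share must be in [0, 1]")
        if self.max_rotation_deg < 0:
            raise ValueError("max_rotation_deg must be >= 0")
        if not 0.0 <= self.warp_max_fraction < 1.0:
            raise ValueError("warp_max_fraction must be in [0, 1)")


def find_faces(
    vertices: np.ndarray,
    faces: np.ndarray,
    points: np.ndarray,
    *,
    centroid_tree: cKDTree | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Locate, for each unit point, the source face hit by the ray from the origin.

    Returns (face_ids (P,), barycentric weights (P, 3)).  Candidate faces
    come from a KD-tree over normalised face centroids; the containing face
    is the candidate whose barycentric coordinates of the ray intersection
    are least negative (exactly non-negative for the true face, up to
    rounding at shared edges).
    """
    points = np.asarray(points, dtype=np.float64)
    tri = vertices[faces]  # (F, 3, 3)
    cent = tri.mean(axis=1)
    cent /= np.linalg.norm(cent, axis=1, keepdims=True)
    tree = centroid_tree if centroid_tree is not None else cKDTree(cent)

    P = points.shape[0]
    face_ids = np.full(P, -1, dtype=np.int64)
    weights = np.zeros((P, 3), dtype=np.float64)
    todo = np.arange(P)
    k = 8
    while todo.size:
        if k > faces.shape[0]:
            raise RuntimeError("face lookup failed: mesh may not be star-shaped")
        _, cand = tree.query(points[todo], k=min(k, faces.shape[0]))
        cand = np.atleast_2d(cand)
        # Solve tri[c].T @ w = p for each candidate; w/sum(w) are the
        # barycentric coords of the ray-plane intersection.
        A = np.swapaxes(tri[cand], -1, -2)  # (n, k, 3, 3)
        try:
            w = np.linalg.solve(A, np.broadcast_to(points[todo][:, None, :, None], A.shape[:2] + (3, 1)))
        except np.linalg.LinAlgError as exc:
            raise ArithmeticError(f"degenerate source face among candidates: {exc}") from exc
        w = w[..., 0]
        s = w.sum(axis=-1, keepdims=True)
        w = np.divide(w, s, out=np.full_like(w, -np.inf), where=np.abs(s) > 1e-300)
        score = w.min(axis=-1)  # (n, k): >= ~0 inside
        best = score.argmax(axis=1)
        rows = np.arange(todo.size)
        ok = score[rows, best] > -1e-9
        hit = todo[ok]
        face_ids[hit] = cand[rows[ok], best[ok]]
        wh = w[rows[ok], best[ok]]
        wh = np.clip(wh, 0.0, None)
        weights[hit] = wh / wh.sum(axis=1, keepdims=True)
        todo = todo[~ok]
        k *= 4
    return face_ids, weights


def barycentric_matrix(
    source_vertices: np.ndarray, source_faces: np.ndarray, target_points: np.ndarray
) -> sparse.csr_matrix:
    """Sparse (T x V) interpolation operator: rows are convex weights over one face."""
    face_ids, w = find_faces(source_vertices, source_faces, target_points)
    T = target_points.shape[0]
    rows = np.repeat(np.arange(T), 3)
    cols = source_faces[face_ids].ravel()
    return sparse.csr_matrix((w.ravel(), (rows, cols)), shape=(T, source_vertices.shape[0]))


def barycentric_resample(
    signal: SurfaceSignal,
    source_mesh: IcosphereMesh | tuple[np.ndarray, np.ndarray],
    target_points: np.ndarray,
) -> SurfaceSignal:
    """Resample a signal from a closed spherical mesh onto arbitrary unit points."""
    if isinstance(source_mesh, IcosphereMesh):
        v, f = source_mesh.vertices, source_mesh.faces
    else:
        v, f = source_mesh
    if signal.n_vertices != v.shape[0]:
        raise ValueError(
            f"signal has {signal.n_vertices} rows but source mesh has {v.shape[0]} vertices"
        )
    W = barycentric_matrix(v, f, np.asarray(target_points, dtype=np.float64))
    return SurfaceSignal(
        values=W @ signal.values,
        channel_names=list(signal.channel_names),
        mesh_order=signal.mesh_order,
    )


@lru_cache(maxsize=8)
def _centroid_tree(order: int) -> cKDTree:
    return cKDTree(build_icosphere(order).face_centroids())


def _resample_on_icosphere(
    values: np.ndarray,
    mesh: IcosphereMesh,
    sample_points: np.ndarray,
    labels: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Pull back values (and labels, nearest-corner) through sample_points."""
    face_ids, w = find_faces(
        mesh.vertices, mesh.faces, sample_points, centroid_tree=_centroid_tree(mesh.order)
    )
    corners = mesh.faces[face_ids]  # (V, 3)
    out = np.einsum("vc,vck->vk", w, values[corners])
    new_labels = None
    if labels is not None:
        new_labels = labels[corners[np.arange(corners.shape[0]), w.argmax(axis=1)]]
    return out, new_labels


def _euler_rotation(angles_deg: np.ndarray) -> Rotation:
    # fixed composition order: x, then y, then z
    return Rotation.from_euler("xyz", angles_deg, degrees=True)


def random_rotation(
    signal: SurfaceSignal,
    mesh: IcosphereMesh,
    max_deg: float,
    rng: np.random.Generator,
    labels: np.ndarray | None = None,
) -> SurfaceSignal | tuple[SurfaceSignal, np.ndarray]:
    """Rotate a surface signal by a random rotation with per-axis angles in [-max_deg, max_deg].

    The output at vertex ``v`` is the input interpolated at ``R^{-1} v``, so
    the signal appears rotated by ``R``.  With ``labels`` given, the same
    transform is applied to them with nearest-corner assignment and a
    ``(signal, labels)`` pair is returned.
    """
    angles = rng.uniform(-max_deg, max_deg, size=3)
    R = _euler_rotation(angles)
    if max_deg == 0:
        out_vals, out_labels = signal.values.copy(), None if labels is None else labels.copy()
    else:
        pts = R.inv().apply(np.array(mesh.vertices))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        out_vals, out_labels = _resample_on_icosphere(signal.values, mesh, pts, labels)
    out = SurfaceSignal(out_vals, list(signal.channel_names), signal.mesh_order)
    return out if labels is None else (out, out_labels)


@lru_cache(maxsize=8)
def _warp_cache(grid_order: int, mesh_order: int):
    """Coarse-grid neighbour scales and the coarse->fine interpolation operator."""
    coarse = build_icosphere(grid_order)
    fine = build_icosphere(mesh_order)
    e = coarse.edges()
    d = np.arccos(np.clip(np.einsum("ij,ij->i", coarse.vertices[e[:, 0]], coarse.vertices[e[:, 1]]), -1, 1))
    scale = np.zeros(coarse.n_vertices)
    deg = np.zeros(coarse.n_vertices)
    np.add.at(scale, e[:, 0], d)
    np.add.at(scale, e[:, 1], d)
    np.add.at(deg, e[:, 0], 1)
    np.add.at(deg, e[:, 1], 1)
    scale /= deg  # mean great-circle distance to neighbours
    W = barycentric_matrix(coarse.vertices, coarse.faces, fine.vertices)
    return coarse, scale, W


def sample_coarse_displacements(
    grid_order: int, max_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Random tangential displacement per coarse-grid vertex, norm <= max_fraction * neighbour distance."""
    coarse_mesh, nbr_scale, _ = _warp_cache(grid_order, grid_order)
    v = coarse_mesh.vertices
    raw = rng.standard_normal(v.shape)
    tang = raw - (np.einsum("ij,ij->i", raw, v))[:, None] * v
    norm = np.linalg.norm(tang, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    mag = rng.uniform(0.0, 1.0, size=(v.shape[0], 1)) * max_fraction * nbr_scale[:, None]
    return tang / norm * mag


def warp_vertices(
    mesh: IcosphereMesh, config: AugmentationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Warped copies of the mesh vertices (unit norm) under a random elastic warp."""
    if mesh.order <= config.warp_grid_order:
        raise ValueError("mesh order must exceed warp_grid_order")
    coarse, _, W = _warp_cache(config.warp_grid_order, mesh.order)
    disp_coarse = sample_coarse_displacements(config.warp_grid_order, config.warp_max_fraction, rng)
    warped_coarse = coarse.vertices + disp_coarse
    warped_coarse /= np.linalg.norm(warped_coarse, axis=1, keepdims=True)
    disp_fine = W @ (warped_coarse - coarse.vertices)
    warped = mesh.vertices + disp_fine
    warped /= np.linalg.norm(warped, axis=1, keepdims=True)
    return warped


def elastic_warp(
    signal: SurfaceSignal,
    mesh: IcosphereMesh,
    config: AugmentationConfig,
    rng: np.random.Generator,
    labels: np.ndarray | None = None,
) -> SurfaceSignal | tuple[SurfaceSignal, np.ndarray]:
    """Elastic warp: pull the signal back through randomly warped vertex positions."""
    if config.warp_max_fraction == 0:
        out = SurfaceSignal(signal.values.copy(), list(signal.channel_names), signal.mesh_order)
        return out if labels is None else (out, labels.copy())
    pts = warp_vertices(mesh, config, rng)
    out_vals, out_labels = _resample_on_icosphere(signal.values, mesh, pts, labels)
    out = SurfaceSignal(out_vals, list(signal.channel_names), signal.mesh_order)
    return out if labels is None else (out, out_labels)


def choose_transform(config: AugmentationConfig, rng: np.random.Generator) -> str:
    """Draw the augmentation decision: 'none', 'rotate' or 'warp'.

    With probability ``apply_probability`` one transform is applied, chosen
    as a rotation with probability ``rotation_share`` else a warp.
    """
    if rng.random() < config.apply_probability:
        return "rotate" if rng.random() < config.rotation_share else "warp"
    return "none"


def augment(
    signal: SurfaceSignal,
    config: AugmentationConfig,
    rng: np.random.Generator,
    mesh: IcosphereMesh | None = None,
    labels: np.ndarray | None = None,
) -> SurfaceSignal | tuple[SurfaceSignal, np.ndarray]:
    """Apply at most one random transform: rotation or warp, per the configured shares."""
    if mesh is None:
        if signal.mesh_order == "native":
            raise ValueError("augment needs an icosphere mesh; pass mesh= for native signals")
        mesh = build_icosphere(int(signal.mesh_order))
    choice = choose_transform(config, rng)
    if choice == "rotate":
        return random_rotation(signal, mesh, config.max_rotation_deg, rng, labels=labels)
    if choice == "warp":
        return elastic_warp(signal, mesh, config, rng, labels=labels)
    out = SurfaceSignal(signal.values.copy(), list(signal.channel_names), signal.mesh_order)
    return out if labels is None else (out, labels.copy())
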