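"""Seeded synthetic spherical datasets with known structure.

These generators stand in for cortical-surface datasets so the whole
pipeline is testable without downloads.  They emulate the *format* and the
learnable structure of such data — smooth multi-channel fields whose
statistics depend on a scalar phenotype, and geodesic region parcellations
with region-dependent intensity levels — not realistic cortical folding.

Regression: each subject gets a scalar target ``t`` (by default in a
PMA-like 26-45 week range) and channels built from real spherical harmonics
up to degree 8 whose coefficients depend affinely (hence monotonically) on
``t``, plus i.i.d. Gaussian vertex noise.

Segmentation: a fixed nearest-seed (great-circle Voronoi) parcellation
shared by all subjects; channels are region-dependent mean levels plus a
smooth within-region harmonic field and noise; a small per-subject random
rotation (jitter) is applied consistently to channels and labels by
evaluating both analytically at the rotated positions.

All generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.spatial.transform import Rotation
from scipy.special import sph_harm_y

from .icosphere import build_icosphere
from .surface_io import LabelMap, SurfaceSignal, write_labels, write_metric, write_surface

__all__ = [
    "SyntheticSpec",
    "spherical_harmonic_basis",
    "make_regression_dataset",
    "make_parcellation_dataset",
    "make_native_mesh",
]


@dataclass
class SyntheticSpec:
    n_subjects: int = 20
    mesh_order: int = 4
    n_channels: int = 4
    task: str = "regression"
    n_regions: int = 8
    noise_sd: float = 0.1
    seed: int = 0
    # regression extras
    target_range: tuple[float, float] = (26.0, 45.0)  # PMA-like weeks
    target_dist: str = "uniform"  # or "skewed" (two-component mixture)
    # segmentation extras
    smooth_sd: float = 0.25
    jitter_deg: float = 3.0
    max_degree: int = 8

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 2 <= self.mesh_order <= 6:
            raise ValueError("mesh_order must be in [2, 6]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.task not in ("regression", "segmentation"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.task == "segmentation":
            if self.n_regions < 2:
                raise ValueError("n_regions must be >= 2")
            n_vert = 10 * 4**self.mesh_order + 2
            if self.n_regions > n_vert:
                raise ValueError("n_regions exceeds vertex count")


def spherical_harmonic_basis(points: np.ndarray, max_degree: int) -> np.ndarray:
    """Real spherical harmonics evaluated at unit points -> (P, (max_degree+1)^2)."""
    points = np.asarray(points, dtype=np.float64)
    theta = np.arccos(np.clip(points[:, 2], -1.0, 1.0))  # polar
    phi = np.arctan2(points[:, 1], points[:, 0])  # azimuth
    cols = []
    for n in range(max_degree + 1):
        for m in range(-n, n + 1):
            y = sph_harm_y(n, abs(m), theta, phi)
            if m > 0:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * y.real)
            elif m < 0:
                cols.append(np.sqrt(2.0) * (-1.0) ** m * y.imag)
            else:
                cols.append(y.real)
    return np.stack(cols, axis=1)


def _harmonic_coefficients(rng: np.random.Generator, n_channels: int, max_degree: int):
    """Per-channel base and slope coefficient vectors, damped with degree.

    The DC slope is fixed positive so that any area average of every channel
    is a strictly increasing function of the normalised target.
    """
    nb = (max_degree + 1) ** 2
    degs = np.concatenate([[n] * (2 * n + 1) for n in range(max_degree + 1)])
    damp = 1.0 / (1.0 + degs)
    base = rng.standard_normal((n_channels, nb)) * damp
    slope = rng.standard_normal((n_channels, nb)) * damp * 2.0
    slope[:, 0] = 2.0
    return base, slope


def _draw_targets(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    lo, hi = spec.target_range
    if spec.target_dist == "uniform":
        return rng.uniform(lo, hi, size=spec.n_subjects)
    if spec.target_dist == "skewed":
        # term-age-heavy mixture: most subjects near the top of the range
        split = lo + 0.6 * (hi - lo)
        hi_part = rng.random(spec.n_subjects) < 0.8
        t = np.where(
            hi_part,
            rng.uniform(split, hi, size=spec.n_subjects),
            rng.uniform(lo, split, size=spec.n_subjects),
        )
        return t
    raise ValueError(f"unknown target_dist {spec.target_dist!r}")


def regression_channel_values(
    points: np.ndarray, t: float, spec: SyntheticSpec,
    base: np.ndarray, slope: np.ndarray, rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Noise-free (rng=None) or noisy channel values at unit points for target t."""
    lo, hi = spec.target_range
    z = (t - lo) / (hi - lo)
    Y = spherical_harmonic_basis(points, spec.max_degree)
    vals = Y @ (base + z * slope).T  # (P, C)
    if rng is not None and spec.noise_sd > 0:
        vals = vals + rng.normal(0.0, spec.noise_sd, size=vals.shape)
    return vals


def make_regression_dataset(spec: SyntheticSpec, out_dir: str | Path) -> Path:
    """Write GIFTI metrics + a CSV manifest for a synthetic regression cohort."""
    if spec.task != "regression":
        raise ValueError("spec.task must be 'regression'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    mesh = build_icosphere(spec.mesh_order)
    base, slope = _harmonic_coefficients(rng, spec.n_channels, spec.max_degree)
    targets = _draw_targets(rng, spec)
    Y = spherical_harmonic_basis(mesh.vertices, spec.max_degree)
    lo, hi = spec.target_range
    rows = []
    names = [f"channel_{c}" for c in range(spec.n_channels)]
    for i, t in enumerate(targets):
        z = (t - lo) / (hi - lo)
        vals = Y @ (base + z * slope).T
        if spec.noise_sd > 0:
            vals = vals + rng.normal(0.0, spec.noise_sd, size=vals.shape)
        path = out_dir / f"sub-{i:04d}.shape.gii"
        write_metric(SurfaceSignal(vals, names, spec.mesh_order), path)
        rows.append({"subject_id": f"sub-{i:04d}", "metric_path": path.name, "target": t})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def region_seed_points(rng: np.random.Generator, n_regions: int) -> np.ndarray:
    pts = rng.standard_normal((n_regions, 3))
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def _labels_at(points: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    # nearest seed by great-circle distance == largest dot product
    return np.argmax(points @ seeds.T, axis=1).astype(np.int64)


def make_parcellation_dataset(spec: SyntheticSpec, out_dir: str | Path) -> Path:
    """Write GIFTI metrics + labels + a CSV manifest for a synthetic parcellation cohort."""
    if spec.task != "segmentation":
        raise ValueError("spec.task must be 'segmentation'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    mesh = build_icosphere(spec.mesh_order)
    seeds = region_seed_points(rng, spec.n_regions)
    region_means = rng.standard_normal((spec.n_regions, spec.n_channels)) * 2.0
    table = {
        k: (f"region_{k}", ((k * 37 % 255) / 255.0, (k * 91 % 255) / 255.0,
                            (k * 151 % 255) / 255.0, 1.0))
        for k in range(spec.n_regions)
    }
    names = [f"channel_{c}" for c in range(spec.n_channels)]
    rows = []
    for i in range(spec.n_subjects):
        angles = rng.uniform(-spec.jitter_deg, spec.jitter_deg, size=3)
        R = Rotation.from_euler("xyz", angles, degrees=True)
        pts = R.inv().apply(np.array(mesh.vertices))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        labels = _labels_at(pts, seeds)
        vals = region_means[labels]
        if spec.smooth_sd > 0:
            coef = rng.standard_normal(((spec.max_degree + 1) ** 2, spec.n_channels))
            Y = spherical_harmonic_basis(pts, spec.max_degree)
            vals = vals + spec.smooth_sd * (Y @ coef)
        if spec.noise_sd > 0:
            vals = vals + rng.normal(0.0, spec.noise_sd, size=vals.shape)
        mp = out_dir / f"sub-{i:04d}.shape.gii"
        lp = out_dir / f"sub-{i:04d}.label.gii"
        write_metric(SurfaceSignal(vals, names, spec.mesh_order), mp)
        write_labels(LabelMap(labels, table), lp)
        rows.append({"subject_id": f"sub-{i:04d}", "metric_path": mp.name, "label_path": lp.name})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def make_native_mesh(
    spec: SyntheticSpec, out_dir: str | Path | None = None
) -> tuple[np.ndarray, np.ndarray, SurfaceSignal]:
    """A non-icosahedral sphere mesh (jittered vertices, convex-hull retriangulation)
    carrying a smooth harmonic metric, for exercising resampling to icospheres."""
    rng = np.random.default_rng(spec.seed)
    base = build_icosphere(spec.mesh_order)
    v = np.array(base.vertices)
    jitter = rng.standard_normal(v.shape) * 0.02
    jitter -= (np.einsum("ij,ij->i", jitter, v))[:, None] * v
    v = v + jitter
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    hull = ConvexHull(v)
    faces = hull.simplices.astype(np.int64)
    # orient all faces outward
    tri = v[faces]
    sign = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2]))
    faces[sign < 0] = faces[sign < 0][:, [0, 2, 1]]
    coef = rng.standard_normal((9, spec.n_channels))  # degree <= 2
    vals = spherical_harmonic_basis(v, 2) @ coef
    signal = SurfaceSignal(vals, mesh_order="native")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_surface(v, faces, out_dir / "native.surf.gii")
        write_metric(signal, out_dir / "native.shape.gii")
    return v, faces, signal
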