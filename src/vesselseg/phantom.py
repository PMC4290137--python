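"""Synthetic branching-vessel phantoms with known ground truth.

The generator emulates an angiographic test volume: a branching tubular
structure on a dark background, with the tube interior at a peak intensity of
500, an intensity ramp through 250 exactly at the tube surface, branch-wise
dimming to simulate intensity inhomogeneity (thin branches losing contrast),
and optional zero-mean Gaussian noise defined on the [0, 1]-normalized
intensity scale.  The ground-truth mask is purely geometric (all voxels
within the tube radius of the centerline tree), so noise never alters it.

The default volume is 100x70x106 voxels; pass a smaller shape for quick runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import ParameterError
from .io import BinaryMask, ImageVolume

__all__ = [
    "Branch",
    "PhantomSpec",
    "GroundTruth",
    "default_tree",
    "generate_phantom",
    "add_gaussian_noise",
]

RAMP_HALF_WIDTH = 1.0  # voxels; realizes the boundary isovalue at the tube surface
# Centerlines are resampled at 0.25-voxel steps, which inflates point-to-curve
# distances by up to (0.125)^2/(2 r); the slack keeps exact-surface voxels inside.
_SAMPLING_SLACK = 0.01


@dataclass
class Branch:
    """One vessel branch: a centerline polyline with per-point radii.

    ``dim`` in (0, 1] multiplies the branch's intensities to simulate
    intensity inhomogeneity (a dim branch "disconnects" in a MIP while its
    geometry, hence the ground truth, is unchanged).
    """

    points: np.ndarray  # (N, 3) voxel coordinates
    radii: np.ndarray  # (N,) voxels
    dim: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, float))
        self.radii = np.atleast_1d(np.asarray(self.radii, float))
        if self.points.shape[0] != self.radii.shape[0] or self.points.shape[1] != 3:
            raise ParameterError("branch needs matching (N,3) points and (N,) radii")
        if (self.radii <= 0).any():
            raise ParameterError("branch radii must be positive")
        if not 0 < self.dim <= 1:
            raise ParameterError("dim factor must lie in (0, 1]")


@dataclass
class PhantomSpec:
    """Full description of a synthetic vessel phantom."""

    shape: tuple[int, int, int] = (100, 70, 106)
    centerline_tree: list[Branch] = field(default_factory=list)
    peak_intensity: float = 500.0
    boundary_intensity: float = 250.0
    background_intensity: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if not (
            self.peak_intensity > self.boundary_intensity > self.background_intensity
        ):
            raise ParameterError("need peak > boundary > background intensity")
        if not self.centerline_tree:
            self.centerline_tree = default_tree(self.shape, self.rng_seed)

    @classmethod
    def default(cls, shape=(100, 70, 106), rng_seed: int = 0) -> "PhantomSpec":
        return cls(shape=shape, rng_seed=rng_seed)


@dataclass
class GroundTruth:
    """A clean phantom volume together with its exact vessel mask."""

    mask: BinaryMask
    volume: ImageVolume
    spec: PhantomSpec


def _taper(r0: float, r1: float, n: int) -> np.ndarray:
    return np.linspace(r0, r1, n)


def _polyline(start, direction, length, n, bend=0.0, bend_axis=0) -> np.ndarray:
    """Straight-ish polyline with an optional gentle sinusoidal bend."""
    t = np.linspace(0.0, 1.0, n)
    pts = np.asarray(start, float)[None, :] + t[:, None] * length * np.asarray(
        direction, float
    )
    if bend:
        pts[:, bend_axis] += bend * np.sin(np.pi * t)
    return pts


def _clip_branch(points: np.ndarray, radii: np.ndarray, shape) -> tuple:
    """Truncate a polyline where it would leave the domain with < radius margin."""
    hi = np.asarray(shape, float) - 1.0
    margin = radii + RAMP_HALF_WIDTH
    ok = ((points >= margin[:, None]) & (points <= hi[None, :] - margin[:, None])).all(
        axis=1
    )
    if not ok[0]:
        raise ParameterError("branch start lies outside the usable domain")
    n = int(np.argmin(ok)) if not ok.all() else len(ok)
    if n < 2:
        raise ParameterError("branch too short after clipping to the domain")
    return points[:n], radii[:n]


def default_tree(shape: Sequence[int], rng_seed: int = 0) -> list[Branch]:
    """A reproducible Y-branching vessel tree scaled to ``shape``.

    A curved trunk of radius 4 runs along the z axis; two generations of
    daughter branches leave at roughly 40 degrees with a 0.75 radius ratio,
    so the tree tapers from the 4-voxel trunk caliber down to 1.5 voxels at
    the terminal tips (within-branch taper is mild, as in real vessels --
    caliber is lost mainly across bifurcations).  One first-generation branch is
    dimmed to 0.45 of full intensity so it appears disconnected in a MIP
    while remaining part of the ground truth.  Deterministic for a given
    seed (the seed only jitters branch azimuths slightly).
    """
    shape = tuple(int(s) for s in shape)
    X, Y, Z = shape
    if min(X, Y) < 24 or Z < 32:
        raise ParameterError(f"shape {shape} too small for the default tree")
    rng = np.random.default_rng(rng_seed)
    # Radii are absolute voxel calibers (a vessel does not thin because the
    # grid shrinks); only the branch lengths scale with the volume.
    TERMINAL_RADIUS = 1.5

    branches: list[Branch] = []
    # trunk: gentle bend in x, radius 4 tapering to the terminal caliber
    n_trunk = max(int(0.84 * Z), 16)
    z0 = max(0.08 * Z, 4.0 + RAMP_HALF_WIDTH)  # keep the root inside the margin
    trunk_pts = _polyline(
        (0.5 * X, 0.5 * Y, z0), (0, 0, 1), min(0.84 * Z, Z - 1 - z0), n_trunk,
        bend=0.06 * X,
    )
    trunk_r = _taper(4.0, 3.0, n_trunk)
    trunk_pts, trunk_r = _clip_branch(trunk_pts, trunk_r, shape)
    branches.append(Branch(trunk_pts, trunk_r, dim=1.0))

    def daughter(parent: Branch, t_frac: float, azimuth: float, dim: float, gen: int):
        idx = min(int(t_frac * (len(parent.points) - 1)), len(parent.points) - 2)
        start = parent.points[idx]
        tangent = parent.points[idx + 1] - parent.points[idx]
        tangent = tangent / np.linalg.norm(tangent)
        # lateral direction at ~40 degrees off the parent tangent
        lateral = np.array([np.cos(azimuth), np.sin(azimuth), 0.0])
        lateral -= lateral @ tangent * tangent
        nl = np.linalg.norm(lateral)
        if nl < 1e-9:
            lateral = np.array([1.0, 0.0, 0.0])
            nl = 1.0
        lateral /= nl
        ang = np.deg2rad(40.0)
        direction = np.cos(ang) * tangent + np.sin(ang) * lateral
        direction /= np.linalg.norm(direction)
        r0 = max(0.75 * parent.radii[idx], TERMINAL_RADIUS)
        r1 = max(0.75 * r0, TERMINAL_RADIUS) if gen == 1 else TERMINAL_RADIUS
        length = (0.34 if gen == 1 else 0.22) * Z
        n = max(int(length), 12)
        pts = _polyline(start, direction, length, n)
        radii = _taper(r0, r1, n)
        pts, radii = _clip_branch(pts, radii, shape)
        return Branch(pts, radii, dim=dim)

    jitter = rng.uniform(-0.2, 0.2, size=4)
    trunk = branches[0]
    b1 = daughter(trunk, 0.40, 0.0 + jitter[0], dim=0.45, gen=1)  # dimmed branch
    b2 = daughter(trunk, 0.65, np.pi + jitter[1], dim=1.0, gen=1)
    branches += [b1, b2]
    branches.append(daughter(b1, 0.55, np.pi / 2 + jitter[2], dim=0.45, gen=2))
    branches.append(daughter(b2, 0.55, -np.pi / 2 + jitter[3], dim=1.0, gen=2))
    return branches


def _branch_profile(
    s: np.ndarray, f: float, peak: float, boundary: float, background: float
) -> np.ndarray:
    """Intensity vs signed surface distance s = d - r for one branch.

    f*peak deep inside, a linear ramp through f*boundary exactly at the
    surface (s = 0), background beyond one ramp half-width outside.
    """
    w = RAMP_HALF_WIDTH
    inner, outer = np.clip(-s / w, 0, 1), np.clip(s / w, 0, 1)
    inside_val = f * boundary + (f * peak - f * boundary) * inner
    outside_val = f * boundary + (background - f * boundary) * outer
    return np.where(s <= 0, inside_val, outside_val)


def generate_phantom(spec: PhantomSpec) -> GroundTruth:
    """Render a clean phantom volume and its exact ground-truth mask.

    Each branch is densely resampled along its centerline; a voxel's signed
    surface distance to the branch is d - r with d the distance to the
    nearest centerline sample and r that sample's radius.  The mask is the
    union over branches of {d <= r}; the intensity is the maximum of the
    per-branch profiles.  Deterministic for a given spec.
    """
    shape = spec.shape
    hi = np.asarray(shape, float)
    vol = np.full(shape, float(spec.background_intensity))
    mask = np.zeros(shape, bool)

    for branch in spec.centerline_tree:
        if (branch.points < 0).any() or (branch.points >= hi[None, :]).any():
            raise ParameterError("centerline tree leaves the volume domain")
        samples, radii = _densify(branch.points, branch.radii, ds=0.25)
        rmax = float(radii.max())
        pad = rmax + RAMP_HALF_WIDTH + 1.0
        lo_idx = np.maximum(np.floor(samples.min(axis=0) - pad), 0).astype(int)
        hi_idx = np.minimum(np.ceil(samples.max(axis=0) + pad) + 1, hi).astype(int)
        grids = np.meshgrid(
            *[np.arange(lo_idx[a], hi_idx[a]) for a in range(3)], indexing="ij"
        )
        coords = np.stack([g.ravel() for g in grids], axis=1).astype(float)
        d, idx = cKDTree(samples).query(coords, workers=-1)
        s = d - radii[idx]
        box = tuple(slice(lo_idx[a], hi_idx[a]) for a in range(3))
        profile = _branch_profile(
            s,
            branch.dim,
            spec.peak_intensity,
            spec.boundary_intensity,
            spec.background_intensity,
        ).reshape(grids[0].shape)
        vol[box] = np.maximum(vol[box], profile)
        mask[box] |= (s <= _SAMPLING_SLACK).reshape(grids[0].shape)

    volume = ImageVolume(vol)
    return GroundTruth(BinaryMask(mask.astype(np.uint8)), volume, spec)


def _densify(points: np.ndarray, radii: np.ndarray, ds: float) -> tuple:
    """Resample a polyline (and its radii) at arc-length step <= ds."""
    out_p, out_r = [points[:1]], [radii[:1]]
    for a in range(len(points) - 1):
        seg = points[a + 1] - points[a]
        n = max(int(np.ceil(np.linalg.norm(seg) / ds)), 1)
        t = np.linspace(0, 1, n + 1)[1:]
        out_p.append(points[a] + t[:, None] * seg)
        out_r.append(radii[a] + t * (radii[a + 1] - radii[a]))
    return np.concatenate(out_p), np.concatenate(out_r)


def add_gaussian_noise(
    volume: ImageVolume,
    variance: float,
    rng_seed: int,
    peak: float = 500.0,
) -> ImageVolume:
    """Corrupt a volume with zero-mean Gaussian noise.

    Noise variances are defined on the [0, 1]-normalized intensity scale
    (intensities divided by ``peak``): at raw units of several hundred a
    variance of 0.01 would be invisible.  The noisy normalized volume is
    clipped to [0, 1.2] -- the ceiling above 1 keeps noise overshoot inside
    vessels from being half-truncated -- then mapped back to raw units.
    Deterministic for a given seed.
    """
    if variance < 0:
        raise ParameterError("noise variance must be nonnegative")
    if variance == 0:
        return ImageVolume(volume.data.copy(), volume.spacing, volume.origin)
    rng = np.random.default_rng(rng_seed)
    normed = volume.data.astype(np.float64) / peak
    noisy = normed + np.sqrt(variance) * rng.standard_normal(volume.shape)
    return ImageVolume(np.clip(noisy, 0.0, 1.2) * peak, volume.spacing, volume.origin)
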