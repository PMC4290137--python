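"""The hybrid level-set evolution engine.

The energy being minimized couples a region term, which pushes the contour
outward wherever the intensity exceeds a lower-bound threshold, with the
geodesic active contour edge term, which regularizes the surface and halts it
at strong gradients.  In the *localized* model the lower bound is the
spatially varying map mu(u) = k*(K_sigma * I)(u); the *original* hybrid
baseline uses a single preset global threshold mu.  Both run through the same
code path -- the baseline is simply a constant threshold map -- so comparisons
isolate exactly the effect of localization.

Per iteration (forward Euler in time, time step dt):

1. reinitialize phi to a signed distance function (SDF);
2. obtain the threshold map mu(u) (precomputed once: it depends only on I);
3. region force  delta_eps(phi) * (I - mu);
4. phi' = phi + dt * alpha * delta_eps(phi) * (I - mu);
5. reinitialize phi' to an SDF;
6. phi  = phi' + dt * beta * delta_eps(phi') * div(g(|grad I|) grad phi').

Step 6 evaluates delta_eps and grad phi on the freshly reinitialized phi'
(the reinitialization in step 5 exists to precondition it); set
``stale_curvature_field=True`` to use the pre-region-update field instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInterfaceError, NumericalFailureError, ParameterError
from .io import BinaryMask, ImageVolume
from .numerics import (
    EdgeMap,
    LevelSetField,
    ThresholdMap,
    edge_indicator,
    edge_weighted_divergence,
    local_threshold_map,
    reinitialize_sdf,
    signed_distance_from_mask,
    smoothed_dirac,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationConfig",
    "BallSeed",
    "initialize_phi",
    "extract_mask",
    "normalize_intensity",
    "evolve",
    "HybridLevelSet",
    "SegmentationResult",
]


@dataclass
class SegmentationConfig:
    """Evolution parameters.

    Defaults are the reference parameter set used for every experiment:
    dt=4.0, alpha=0.01, beta=0.5, sigma=3.0, eps=1.0, k=0.9.

    Parameters
    ----------
    dt : float
        Time step of the forward-Euler update.
    alpha : float
        Weight of the region (threshold) force.
    beta : float
        Weight of the geodesic edge force.
    sigma : float
        Gaussian scale (voxels) of the local threshold map.
    eps : float
        Width of the smoothed Heaviside/Dirac pair.
    k : float
        Threshold adjustment coefficient in [0.5, 1] (warned outside).
    c : float
        Edge-indicator scope, applied to gradients of the [0,1]-rescaled
        image; the default 400 puts g = 1/2 at a gradient of 5% of the
        dynamic range per voxel, so flat regions keep g ~ 1 while object
        boundaries drive g ~ 0.
    sigma_edge : float
        Gaussian pre-smoothing (voxels) for the edge indicator.
    max_iters, tol_voxels : int
        Stop when the mask changes by <= tol_voxels voxels for 3 consecutive
        iterations, or at max_iters.
    global_mu : float or None
        When set, run the ORIGINAL hybrid model with this constant threshold.
    normalize : bool
        Affinely rescale intensities to [0, 1] before evolving (thresholds
        such as global_mu are then in normalized units).
    stale_curvature_field : bool
        Evaluate step 6 on the pre-region-update field (literal step list).
    """

    dt: float = 4.0
    alpha: float = 0.01
    beta: float = 0.5
    sigma: float = 3.0
    eps: float = 1.0
    k: float = 0.9
    c: float = 400.0
    sigma_edge: float = 1.0
    max_iters: int = 500
    tol_voxels: int = 0
    global_mu: float | None = None
    normalize: bool = False
    stale_curvature_field: bool = False

    def __post_init__(self) -> None:
        for name in ("dt", "alpha", "beta", "sigma", "eps", "c"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.sigma_edge < 0:
            raise ParameterError("sigma_edge must be nonnegative")
        if self.max_iters < 1:
            raise ParameterError("max_iters must be a positive integer")
        if self.tol_voxels < 0:
            raise ParameterError("tol_voxels must be nonnegative")
        if not 0.5 <= self.k <= 1.0:
            warnings.warn(
                f"adjustment coefficient k={self.k} outside recommended [0.5, 1]",
                stacklevel=2,
            )

    @property
    def model_name(self) -> str:
        return "original_hybrid" if self.global_mu is not None else "localized_hybrid"

    def to_dict(self) -> dict:
        return asdict(self)

    def to_file(self, path) -> None:
        """Write the configuration as a flat key-value YAML file."""
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path) -> "SegmentationConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass(frozen=True)
class BallSeed:
    """A spherical seed region: center in 0-based voxel coordinates, radius in voxels."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ParameterError("seed radius must be positive")


SeedLike = BallSeed | BinaryMask | np.ndarray


def _seed_field(seed: SeedLike, shape: tuple[int, int, int]) -> np.ndarray:
    """Signed field positive inside one seed primitive (exact SDF for balls)."""
    if isinstance(seed, BallSeed):
        center = np.asarray(seed.center, float)
        if ((center < 0) | (center >= np.asarray(shape))).any():
            raise ParameterError(f"seed center {seed.center} outside volume {shape}")
        grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
        r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
        return seed.radius - r
    data = seed.data if isinstance(seed, BinaryMask) else np.asarray(seed)
    if data.shape != shape:
        raise ParameterError("mask seed shape does not match the volume")
    if not data.any():
        raise ParameterError("mask seed is empty")
    if data.all():
        # covers the whole domain: no interface can exist
        raise DegenerateInterfaceError("mask seed covers the entire domain")
    return signed_distance_from_mask(data.astype(bool))


def initialize_phi(shape: Sequence[int], seeds: Sequence[SeedLike]) -> LevelSetField:
    """Build the initial phi as the signed distance to the union of seed regions.

    The union is taken as the pointwise maximum of per-seed signed fields
    (exact where seeds are disjoint, a tight lower bound inside overlaps --
    immediately corrected by the first reinitialization of the loop).
    """
    shape = tuple(int(s) for s in shape)
    seeds = list(seeds)
    if not seeds:
        raise ParameterError("at least one seed is required")
    phi = _seed_field(seeds[0], shape)
    for seed in seeds[1:]:
        phi = np.maximum(phi, _seed_field(seed, shape))
    if not (phi >= 0).any():
        raise ParameterError("no seed voxel falls inside the volume domain")
    return LevelSetField(phi, is_sdf=True)


def extract_mask(phi: LevelSetField, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    """Binarize phi: 1 where phi >= 0 (inside), else 0."""
    return BinaryMask((phi.data >= 0).astype(np.uint8), spacing)


def normalize_intensity(volume: ImageVolume) -> ImageVolume:
    """Affinely map intensities onto [0, 1]."""
    lo, hi = volume.intensity_range
    if hi <= lo:
        raise ParameterError("cannot normalize a constant volume")
    return ImageVolume((volume.data - lo) / (hi - lo), volume.spacing, volume.origin)


@dataclass
class EvolutionTrace:
    """Per-iteration observability records."""

    records: list = field(default_factory=list)

    def append(self, iteration: int, interior: int, changed: int, band_residual: float):
        self.records.append(
            {
                "iteration": iteration,
                "interior_voxels": int(interior),
                "changed_voxels": int(changed),
                "band_mean_abs_I_minus_mu": float(band_residual),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        cols = ["iteration", "interior_voxels", "changed_voxels", "band_mean_abs_I_minus_mu"]
        return pd.DataFrame(self.records, columns=cols)

    def __len__(self) -> int:
        return len(self.records)


def evolve(
    volume: ImageVolume,
    phi0: LevelSetField,
    config: SegmentationConfig | None = None,
) -> tuple[LevelSetField, BinaryMask, pd.DataFrame]:
    """Run the hybrid level-set evolution (see module docstring for the scheme).

    Returns the final field, the extracted mask and a per-iteration trace.
    The evolution is fully deterministic: identical inputs give bit-identical
    results.
    """
    cfg = config or SegmentationConfig()
    if phi0.data.shape != volume.data.shape:
        raise ParameterError("phi and volume shapes differ")

    if cfg.normalize:
        volume = normalize_intensity(volume)
    I = volume.data.astype(np.float64)

    # Image-derived quantities are fixed during evolution: mu depends only on
    # I, sigma, k, and the edge map only on I, c, sigma_edge.
    if cfg.global_mu is not None:
        mu = np.full_like(I, float(cfg.global_mu))
    else:
        mu = local_threshold_map(volume, cfg.sigma, cfg.k).data
    lo, hi = volume.intensity_range
    # c is defined against gradients of the [0,1]-rescaled image (scale-free)
    edge_input = (I - lo) / (hi - lo) if hi > lo else I
    edge = edge_indicator(edge_input, cfg.c, cfg.sigma_edge)

    dirac_max = 1.0 / (np.pi * cfg.eps)
    if cfg.dt * cfg.beta * dirac_max > 1.0 / 6.0 and not getattr(
        evolve, "_warned_diffusion", False
    ):
        evolve._warned_diffusion = True  # once per process; the message is advisory
        logger.warning(
            "edge-term diffusion number dt*beta*max(delta_eps)=%.3f exceeds 1/6; "
            "per-iteration reinitialization keeps the scheme bounded",
            cfg.dt * cfg.beta * dirac_max,
        )

    phi = LevelSetField(phi0.data.copy(), phi0.is_sdf)
    prev_mask = phi.data >= 0
    trace = EvolutionTrace()
    quiet_iters = 0

    for it in range(cfg.max_iters):
        try:
            phi = reinitialize_sdf(phi)  # step 1
        except DegenerateInterfaceError as exc:
            raise DegenerateInterfaceError(
                f"interface vanished at iteration {it}", iteration=it
            ) from exc

        delta_k = smoothed_dirac(phi.data, cfg.eps)
        region = delta_k * (I - mu)  # step 3
        phi_prime = phi.data + cfg.dt * cfg.alpha * region  # step 4

        try:
            phi_prime_sdf = signed_distance_from_mask(phi_prime >= 0)  # step 5
        except DegenerateInterfaceError as exc:
            raise DegenerateInterfaceError(
                f"interface vanished at iteration {it}", iteration=it
            ) from exc

        if cfg.stale_curvature_field:
            delta6, grad_field = delta_k, phi
        else:
            grad_field = LevelSetField(phi_prime_sdf, is_sdf=True)
            delta6 = smoothed_dirac(phi_prime_sdf, cfg.eps)
        curv = edge_weighted_divergence(grad_field, edge)
        new_phi = phi_prime_sdf + cfg.dt * cfg.beta * delta6 * curv  # step 6

        if not np.isfinite(new_phi).all():
            raise NumericalFailureError(
                f"non-finite values at iteration {it}", iteration=it
            )
        phi = LevelSetField(new_phi, is_sdf=False)

        mask = phi.data >= 0
        changed = int((mask != prev_mask).sum())
        band = np.abs(phi.data) <= 2.0 * cfg.eps
        band_residual = float(np.abs(I - mu)[band].mean()) if band.any() else 0.0
        trace.append(it, int(mask.sum()), changed, band_residual)
        logger.debug(
            "iter %d: interior=%d changed=%d", it, int(mask.sum()), changed
        )
        prev_mask = mask

        if changed <= cfg.tol_voxels:
            quiet_iters += 1
            if quiet_iters >= 3:
                break
        else:
            quiet_iters = 0

    return phi, extract_mask(phi, volume.spacing), trace.to_frame()


class HybridLevelSet:
    """Hybrid level-set segmentation model over a 3D volume.

    The model couples a region force, driven by locally computed lower-bound
    thresholds (or a preset global threshold for the original baseline), with
    a geodesic active contour edge force.  Construct it from an image volume
    and one or more seed regions, then call :meth:`fit`.

    Parameters
    ----------
    volume : ImageVolume
        The image to segment (vessels bright on dark background).
    seeds : sequence of BallSeed, BinaryMask or ndarray
        Initial regions strictly inside the target structure.
    config : SegmentationConfig, optional
        Evolution parameters; keyword overrides are applied on top.

    Examples
    --------
    >>> model = HybridLevelSet(volume, [BallSeed((50, 35, 20), 3)])
    >>> res = model.fit()
    >>> res.mask.volume_voxels()
    """

    def __init__(
        self,
        volume: ImageVolume,
        seeds: Sequence[SeedLike],
        config: SegmentationConfig | None = None,
        **overrides,
    ):
        self.volume = volume
        self.seeds = list(seeds)
        base = config or SegmentationConfig()
        self.config = replace(base, **overrides) if overrides else base

    @classmethod
    def from_files(cls, volume_path, seeds, config_path=None, **overrides):
        """Build a model from a volume file and optional config file."""
        from .io import read_volume

        cfg = SegmentationConfig.from_file(config_path) if config_path else None
        return cls(read_volume(volume_path), seeds, cfg, **overrides)

    def initial_phi(self) -> LevelSetField:
        return initialize_phi(self.volume.shape, self.seeds)

    def fit(self, phi0: LevelSetField | None = None) -> "SegmentationResult":
        """Run the evolution to convergence (or max_iters) and return results."""
        phi0 = phi0 if phi0 is not None else self.initial_phi()
        phi, mask, trace = evolve(self.volume, phi0, self.config)
        return SegmentationResult(self, phi, mask, trace)


class SegmentationResult:
    """Results of a fitted hybrid level-set segmentation.

    Attributes
    ----------
    phi : LevelSetField
        Final level-set field.
    mask : BinaryMask
        Extracted segmentation (phi >= 0).
    trace : pandas.DataFrame
        Per-iteration interior size, changed-voxel counts and band residual.
    """

    def __init__(self, model: HybridLevelSet, phi, mask, trace: pd.DataFrame):
        self.model = model
        self.config = model.config
        self.phi = phi
        self.mask = mask
        self.trace = trace

    @property
    def n_iterations(self) -> int:
        return len(self.trace)

    @property
    def converged(self) -> bool:
        """True when the run stopped on the quiet-mask rule before max_iters."""
        if self.n_iterations >= self.config.max_iters:
            return False
        tail = self.trace["changed_voxels"].tail(3)
        return len(tail) == 3 and (tail <= self.config.tol_voxels).all()

    def dice(self, reference: BinaryMask) -> float:
        from .metrics import dice_coefficient

        return dice_coefficient(self.mask, reference)

    def segmentation_error(self, reference: BinaryMask) -> float:
        from .metrics import segmentation_error

        return segmentation_error(self.mask, reference)

    def mip(self, axis: int = 2) -> np.ndarray:
        """Maximum intensity projection of the binary mask."""
        return self.mask.data.max(axis=axis)

    def summary(self) -> str:
        """Human-readable run summary."""
        c = self.config
        rows = [
            ("Model:", c.model_name),
            ("Volume shape:", "x".join(map(str, self.model.volume.shape))),
            ("Iterations:", f"{self.n_iterations} (converged={self.converged})"),
            ("Interior voxels:", f"{self.mask.volume_voxels()}"),
            ("dt / alpha / beta:", f"{c.dt} / {c.alpha} / {c.beta}"),
            ("sigma / eps / k / c:", f"{c.sigma} / {c.eps} / {c.k} / {c.c}"),
        ]
        if c.global_mu is not None:
            rows.append(("Global threshold mu:", f"{c.global_mu}"))
        width = max(len(r[0]) for r in rows) + 2
        lines = ["Hybrid level-set segmentation results", "=" * 42]
        lines += [f"{k:<{width}}{v}" for k, v in rows]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<SegmentationResult {self.config.model_name} "
            f"iters={self.n_iterations} voxels={self.mask.volume_voxels()}>"
        )
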