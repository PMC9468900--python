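"""Fitting objective: spectral correlation, connectome-smoothed spatial
correlation, and their unweighted sum.

The *spectral correlation* is the Pearson r between modeled and target dB
spectra computed per region across frequency bins, averaged over regions.
The *spatial correlation* compares the regional alpha-band (8-12 Hz by
default) raw-power profiles x (model) and y (target) through the connectome:

    s = x~^T M y~,   M = rownorm(C_rownorm + w I)

where C_rownorm is the row-degree-normalized structural matrix, w >= 0
controls neighborhood smoothing (w -> infinity recovers plain Pearson r),
and x~, y~ are mean-centered, unit-norm profiles.  The combined objective is
the unweighted sum of the two terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .connectome_io import RegionalPSD, SpatialProfile, row_degree_normalize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ObjectiveConfig:
    """Smoothing weight, band, cost mode and profile normalization."""

    w: float = 10.0
    band: tuple[float, float] = (8.0, 12.0)
    cost_mode: str = "combined"  # | "spectral_only" | "spatial_only"
    normalize_profiles: bool = True

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ValueError("w must be >= 0")
        if self.cost_mode not in ("combined", "spectral_only", "spatial_only"):
            raise ValueError(f"unknown cost_mode {self.cost_mode!r}")


@dataclass
class ObjectiveValue:
    spectral_r: float
    per_region_r: np.ndarray
    spatial_s: float
    combined: float
    cost_mode: str = "combined"

    def cost(self) -> float:
        """The scalar actually maximized under the configured cost mode."""
        if self.cost_mode == "spectral_only":
            return self.spectral_r
        if self.cost_mode == "spatial_only":
            return self.spatial_s
        return self.combined

    def to_dict(self) -> dict:
        return {
            "spectral_r": self.spectral_r,
            "spatial_s": self.spatial_s,
            "combined": self.combined,
            "cost_mode": self.cost_mode,
            "per_region_r": [float(r) for r in self.per_region_r],
        }


def _check_aligned(model: RegionalPSD, target: RegionalPSD) -> None:
    if model.region_labels != target.region_labels:
        mism = next(
            (a, b)
            for a, b in zip(model.region_labels, target.region_labels)
            if a != b
        ) if len(model.region_labels) == len(target.region_labels) else None
        raise ValueError(f"region labels differ between model and target: {mism}")
    if model.frequencies_hz.shape != target.frequencies_hz.shape or not np.allclose(
        model.frequencies_hz, target.frequencies_hz
    ):
        raise ValueError("frequency grids differ between model and target")


def spectral_correlation(
    model_db: RegionalPSD, target_db: RegionalPSD
) -> tuple[float, np.ndarray]:
    """Mean and per-region Pearson r between dB spectra across frequency bins.

    Regions where either spectrum has zero variance have undefined r; they
    are excluded from the mean with a warning and reported as NaN.
    """
    _check_aligned(model_db, target_db)
    if model_db.scale != "dB" or target_db.scale != "dB":
        raise ValueError("spectral_correlation expects dB spectra")
    X = model_db.values - model_db.values.mean(axis=1, keepdims=True)
    Y = target_db.values - target_db.values.mean(axis=1, keepdims=True)
    sx = np.linalg.norm(X, axis=1)
    sy = np.linalg.norm(Y, axis=1)
    valid = (sx > 0) & (sy > 0)
    r = np.full(X.shape[0], np.nan)
    r[valid] = np.sum(X[valid] * Y[valid], axis=1) / (sx[valid] * sy[valid])
    r[valid] = np.clip(r[valid], -1.0, 1.0)
    if not np.all(valid):
        logger.warning(
            "%d zero-variance region(s) excluded from spectral correlation",
            int(np.sum(~valid)),
        )
    if not np.any(valid):
        raise ValueError("no region with nonzero variance in both spectra")
    return float(np.mean(r[valid])), r


def smoothing_matrix(C_rownorm: np.ndarray, w: float) -> np.ndarray:
    """M = row-normalized (C_rownorm + w I); row-stochastic for any w >= 0."""
    C_rownorm = np.asarray(C_rownorm, dtype=float)
    return row_degree_normalize(C_rownorm + w * np.eye(C_rownorm.shape[0]))


def spatial_correlation(
    x: SpatialProfile,
    y: SpatialProfile,
    C_rownorm: np.ndarray,
    w: float = 10.0,
    normalize_profiles: bool = True,
) -> float:
    """Connectome-smoothed correlation x~^T M y~ of two regional profiles.

    With ``normalize_profiles`` (default) both profiles are mean-centered and
    scaled to unit Euclidean norm first, so the w -> infinity limit equals the
    plain Pearson correlation; constant profiles are rejected.  Turning the
    flag off evaluates the raw bilinear form x^T M y.
    """
    if x.region_labels != y.region_labels:
        raise ValueError("profile region labels differ")
    xv = np.asarray(x.values, dtype=float)
    yv = np.asarray(y.values, dtype=float)
    if C_rownorm.shape != (xv.size, xv.size):
        raise ValueError("smoothing matrix shape does not match profiles")
    if normalize_profiles:
        xv = xv - xv.mean()
        yv = yv - yv.mean()
        nx, ny = np.linalg.norm(xv), np.linalg.norm(yv)
        if nx == 0 or ny == 0:
            raise ValueError("constant profile has no spatial correlation")
        xv, yv = xv / nx, yv / ny
    M = smoothing_matrix(C_rownorm, w)
    return float(xv @ M @ yv)


def combined_objective(
    model_db: RegionalPSD,
    model_profile: SpatialProfile,
    target_db: RegionalPSD,
    target_profile: SpatialProfile,
    C_rownorm: np.ndarray,
    config: ObjectiveConfig | None = None,
) -> ObjectiveValue:
    """Evaluate the configured objective on model outputs vs targets.

    ``combined`` returns spectral_r + spatial_s; the single-term modes
    evaluate both components (for reporting) but expose only their own term
    through :meth:`ObjectiveValue.cost`.
    """
    config = config or ObjectiveConfig()
    mean_r, per_region = spectral_correlation(model_db, target_db)
    s = spatial_correlation(
        model_profile,
        target_profile,
        C_rownorm,
        w=config.w,
        normalize_profiles=config.normalize_profiles,
    )
    return ObjectiveValue(
        spectral_r=mean_r,
        per_region_r=per_region,
        spatial_s=s,
        combined=mean_r + s,
        cost_mode=config.cost_mode,
    )


def fisher_z(r: float) -> float:
    """Fisher's r-to-z transform, z = atanh(r); requires |r| < 1."""
    r = float(r)
    if abs(r) >= 1.0:
        raise ValueError("|r| must be < 1 for Fisher z")
    return float(np.arctanh(r))
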