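"""Global parameter inference: fit the seven SGM parameters to a target PSD.

The search maximizes the configured objective (spectral correlation,
connectome-smoothed spatial correlation, or their sum) over bounded,
physiologically plausible ranges with a seeded simulated-annealing-style
global optimizer (:func:`scipy.optimize.dual_annealing`, which ends with a
local polish) or a multistart local alternative.  Parameter points where the
linearized local model has a pole, or where the eigenmode resolvent is
singular, are infeasible: they receive cost -inf and are counted, not fatal.

The public surface is the scikit-learn-style :class:`SGMEstimator`
(``fit`` / ``predict`` / ``score``, fitted attributes with trailing
underscores); :func:`fit_sgm` is a thin functional wrapper over it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize
from sklearn.base import BaseEstimator

from .connectome_io import ConnectomeGraph, RegionalPSD, SpatialProfile, row_degree_normalize
from .forward_model import NoiseModel, SpectralCache, band_power, forward_psd, from_db, to_db
from .local_model import (
    FREE_PARAMETER_NAMES,
    SGMParameters,
    UnstableParametersError,
    stability_check,
)
from .objective import ObjectiveConfig, ObjectiveValue, combined_objective

logger = logging.getLogger(__name__)

#: physiologically plausible default search box for the seven free parameters
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "tau_e": (0.005, 0.030),
    "tau_i": (0.005, 0.200),
    "tau_G": (0.005, 0.030),
    "g_ee": (0.0, 2.0),
    "g_ei": (0.0, 5.0),
    "g_ii": (0.0, 5.0),
    "alpha": (0.1, 1.0),
}

_INFEASIBLE_PENALTY = 1e6


def mid_bound_parameters(
    bounds: dict[str, tuple[float, float]] | None = None, speed_v: float = 5.0
) -> SGMParameters:
    """Parameters at the centre of the search box (used as ground truth in
    the synthetic recovery experiments)."""
    bounds = bounds or DEFAULT_BOUNDS
    mid = [(bounds[n][0] + bounds[n][1]) / 2.0 for n in FREE_PARAMETER_NAMES]
    return SGMParameters.from_free_values(mid, speed_v=speed_v)


@dataclass(frozen=True)
class FitConfig:
    """Search configuration: bounds, budget, seed, cost mode, optimizer."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    max_evaluations: int = 2000
    seed: int = 0
    objective: ObjectiveConfig = field(default_factory=ObjectiveConfig)
    optimizer: str = "annealing"  # | "multistart_local"
    speed_v: float = 5.0
    normalization: str = "symmetric_degree"
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        if self.max_evaluations <= 0:
            raise ValueError("max_evaluations must be > 0")
        if self.optimizer not in ("annealing", "multistart_local"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        for name in FREE_PARAMETER_NAMES:
            lo, hi = self.bounds[name]
            if not lo < hi:
                raise ValueError(f"invalid bounds for {name}: [{lo}, {hi}]")

    def bounds_array(self) -> list[tuple[float, float]]:
        return [tuple(self.bounds[n]) for n in FREE_PARAMETER_NAMES]


@dataclass
class FitResult:
    best_params: SGMParameters
    objective: ObjectiveValue
    n_evaluations: int
    n_infeasible: int
    seed: int
    trace: np.ndarray  # (n_evaluations, 2): evaluation index, cost
    converged: bool

    def to_dict(self) -> dict:
        return {
            "best_params": {
                n: getattr(self.best_params, n)
                for n in FREE_PARAMETER_NAMES + ("speed_v",)
            },
            "objective": self.objective.to_dict(),
            "n_evaluations": self.n_evaluations,
            "n_infeasible": self.n_infeasible,
            "seed": self.seed,
            "converged": self.converged,
            "best_cost": float(np.nanmax(self.trace[:, 1]))
            if len(self.trace)
            else None,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


class _CostEvaluator:
    """Maps a free-parameter vector to (cost, ObjectiveValue), with caching
    of the connectome eigendecompositions and bookkeeping of the trace."""

    def __init__(
        self,
        graph: ConnectomeGraph,
        target_db: RegionalPSD,
        target_profile: SpatialProfile,
        config: FitConfig,
    ):
        self.graph = graph
        self.target_db = target_db
        self.target_profile = target_profile
        self.config = config
        self.grid = target_db.frequencies_hz
        self.cache = SpectralCache(
            graph, self.grid, config.speed_v, config.normalization
        )
        self.C_rownorm = row_degree_normalize(graph.C)
        self.trace: list[tuple[int, float]] = []
        self.n_infeasible = 0

    def evaluate(self, theta: np.ndarray) -> tuple[float, ObjectiveValue | None]:
        params = SGMParameters.from_free_values(theta, speed_v=self.config.speed_v)
        ok, _ = stability_check(params, self.grid)
        if not ok:
            return -np.inf, None
        try:
            psd = forward_psd(
                self.graph,
                params,
                self.grid,
                noise=self.config.noise,
                normalization=self.config.normalization,
                cache=self.cache,
            )
            model_db = to_db(psd)
            model_profile = band_power(psd, self.config.objective.band)
            value = combined_objective(
                model_db,
                model_profile,
                self.target_db,
                self.target_profile,
                self.C_rownorm,
                self.config.objective,
            )
        except (UnstableParametersError, ValueError):
            return -np.inf, None
        return value.cost(), value

    def __call__(self, theta: np.ndarray) -> float:
        """Penalized negative cost for the minimizer."""
        cost, _ = self.evaluate(theta)
        if not np.isfinite(cost):
            self.n_infeasible += 1
            self.trace.append((len(self.trace), -np.inf))
            return _INFEASIBLE_PENALTY
        self.trace.append((len(self.trace), cost))
        return -cost


def _run_annealing(ev: _CostEvaluator, config: FitConfig) -> tuple[np.ndarray, bool]:
    rng = np.random.default_rng(config.seed)
    res = scipy.optimize.dual_annealing(
        ev,
        bounds=ev.config.bounds_array(),
        maxfun=config.max_evaluations,
        maxiter=max(1, config.max_evaluations),
        rng=rng,
    )
    return np.asarray(res.x, dtype=float), bool(res.success)


def _run_multistart(ev: _CostEvaluator, config: FitConfig) -> tuple[np.ndarray, bool]:
    rng = np.random.default_rng(config.seed)
    bounds = np.array(ev.config.bounds_array())
    n_starts = max(1, min(8, config.max_evaluations // 150))
    per_start = max(10, config.max_evaluations // n_starts)
    best_x, best_val = None, np.inf
    for _ in range(n_starts):
        x0 = rng.uniform(bounds[:, 0], bounds[:, 1])
        res = scipy.optimize.minimize(
            ev,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={"maxfev": per_start, "xatol": 1e-6, "fatol": 1e-8},
        )
        if res.fun < best_val:
            best_x, best_val = res.x, res.fun
    return np.asarray(best_x, dtype=float), True


class SGMEstimator(BaseEstimator):
    """Scikit-learn-style estimator fitting SGM parameters to a target PSD.

    Parameters
    ----------
    graph : ConnectomeGraph
        The structural connectome on which the forward model is evaluated.
    bounds : dict, optional
        Per-parameter [lo, hi] search bounds (default: DEFAULT_BOUNDS).
    w : float
        Spatial smoothing weight in the bilinear form (default 10).
    band : tuple
        Band (Hz) whose regional raw power defines the spatial profile.
    cost_mode : str
        "combined" (default), "spectral_only" or "spatial_only".
    max_evaluations : int
        Objective-evaluation budget for the global search.
    optimizer : str
        "annealing" (default) or "multistart_local".
    seed : int
        Seed for every source of randomness; identical seed + inputs give an
        identical fit.

    Attributes
    ----------
    params_ : SGMParameters
        Best-fitting parameters.
    result_ : FitResult
        Full optimization record (objective components, trace, counters).
    """

    def __init__(
        self,
        graph: ConnectomeGraph | None = None,
        bounds: dict | None = None,
        w: float = 10.0,
        band: tuple[float, float] = (8.0, 12.0),
        cost_mode: str = "combined",
        normalize_profiles: bool = True,
        max_evaluations: int = 2000,
        optimizer: str = "annealing",
        seed: int = 0,
        speed_v: float = 5.0,
        normalization: str = "symmetric_degree",
    ):
        self.graph = graph
        self.bounds = bounds
        self.w = w
        self.band = band
        self.cost_mode = cost_mode
        self.normalize_profiles = normalize_profiles
        self.max_evaluations = max_evaluations
        self.optimizer = optimizer
        self.seed = seed
        self.speed_v = speed_v
        self.normalization = normalization

    def _fit_config(self) -> FitConfig:
        return FitConfig(
            bounds=dict(self.bounds) if self.bounds else dict(DEFAULT_BOUNDS),
            max_evaluations=self.max_evaluations,
            seed=self.seed,
            objective=ObjectiveConfig(
                w=self.w,
                band=self.band,
                cost_mode=self.cost_mode,
                normalize_profiles=self.normalize_profiles,
            ),
            optimizer=self.optimizer,
            speed_v=self.speed_v,
            normalization=self.normalization,
        )

    def fit(self, X: RegionalPSD, y: SpatialProfile | None = None) -> "SGMEstimator":
        """Fit the seven global parameters to a target dB PSD.

        Parameters
        ----------
        X : RegionalPSD (dB)
            Target spectra; its frequency grid becomes the model grid.
        y : SpatialProfile, optional
            Target band-power profile; derived from X when omitted.
        """
        if self.graph is None:
            raise ValueError("SGMEstimator requires a graph")
        if not isinstance(X, RegionalPSD) or X.scale != "dB":
            raise ValueError("X must be a RegionalPSD in dB scale")
        if X.region_labels != self.graph.region_labels:
            mism = [
                (a, b)
                for a, b in zip(X.region_labels, self.graph.region_labels)
                if a != b
            ]
            raise ValueError(
                f"target region labels do not match connectome (first mismatch: "
                f"{mism[0] if mism else 'length differs'})"
            )
        config = self._fit_config()
        if y is None:
            y = band_power(from_db(X), config.objective.band)
        ev = _CostEvaluator(self.graph, X, y, config)
        if config.optimizer == "annealing":
            best_x, converged = _run_annealing(ev, config)
        else:
            best_x, converged = _run_multistart(ev, config)
        best_cost, best_value = ev.evaluate(best_x)
        if best_value is None:
            # optimizer returned an infeasible point: fall back to the best
            # feasible point seen in the trace, if any
            finite = [t for t in ev.trace if np.isfinite(t[1])]
            if not finite:
                raise RuntimeError("no feasible parameter point found")
            raise RuntimeError(
                "optimizer terminated on an infeasible point despite feasible "
                "evaluations; re-run with a larger budget"
            )
        self.params_ = SGMParameters.from_free_values(best_x, speed_v=config.speed_v)
        trace = np.array(ev.trace, dtype=float).reshape(-1, 2)
        self.result_ = FitResult(
            best_params=self.params_,
            objective=best_value,
            n_evaluations=len(ev.trace),
            n_infeasible=ev.n_infeasible,
            seed=config.seed,
            trace=trace,
            converged=converged,
        )
        self._cache = ev.cache
        self._config = config
        return self

    def predict(self, X: RegionalPSD | None = None) -> RegionalPSD:
        """Model dB PSD at the fitted parameters (on the fitted grid)."""
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")
        psd = forward_psd(
            self.graph,
            self.params_,
            self._cache.grid,
            normalization=self.normalization,
            cache=self._cache,
        )
        return to_db(psd)

    def score(self, X: RegionalPSD, y: SpatialProfile | None = None) -> float:
        """Configured objective of the fitted model against a target PSD."""
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")
        config = self._fit_config()
        if y is None:
            y = band_power(from_db(X), config.objective.band)
        psd = forward_psd(
            self.graph, self.params_, X.frequencies_hz, normalization=self.normalization
        )
        value = combined_objective(
            to_db(psd),
            band_power(psd, config.objective.band),
            X,
            y,
            row_degree_normalize(self.graph.C),
            config.objective,
        )
        return value.cost()


def fit_sgm(
    graph: ConnectomeGraph,
    target_psd_db: RegionalPSD,
    target_band_profile: SpatialProfile | None = None,
    config: FitConfig | None = None,
) -> FitResult:
    """Functional wrapper over :class:`SGMEstimator`; returns the FitResult."""
    config = config or FitConfig()
    est = SGMEstimator(
        graph=graph,
        bounds=dict(config.bounds),
        w=config.objective.w,
        band=config.objective.band,
        cost_mode=config.objective.cost_mode,
        normalize_profiles=config.objective.normalize_profiles,
        max_evaluations=config.max_evaluations,
        optimizer=config.optimizer,
        seed=config.seed,
        speed_v=config.speed_v,
        normalization=config.normalization,
    )
    est.fit(target_psd_db, target_band_profile)
    return est.result_


def w_selection_harness(
    graph: ConnectomeGraph,
    targets: Sequence[tuple[RegionalPSD, SpatialProfile | None]],
    w_grid: Sequence[float] = (0.0, 0.01, 0.1, 1.0, 10.0),
    base_config: FitConfig | None = None,
) -> pd.DataFrame:
    """One fit per (w, target) with a shared seed; returns the per-w objective
    components for user-level comparison of smoothing weights."""
    if len(w_grid) == 0:
        raise ValueError("w_grid must be non-empty")
    if len(targets) == 0:
        raise ValueError("at least one target required")
    base_config = base_config or FitConfig()
    rows = []
    for w in w_grid:
        obj = ObjectiveConfig(
            w=float(w),
            band=base_config.objective.band,
            cost_mode=base_config.objective.cost_mode,
            normalize_profiles=base_config.objective.normalize_profiles,
        )
        cfg = FitConfig(
            bounds=base_config.bounds,
            max_evaluations=base_config.max_evaluations,
            seed=base_config.seed,
            objective=obj,
            optimizer=base_config.optimizer,
            speed_v=base_config.speed_v,
            normalization=base_config.normalization,
        )
        for i, (target_db, profile) in enumerate(targets):
            result = fit_sgm(graph, target_db, profile, cfg)
            rows.append(
                {
                    "w": float(w),
                    "target": i,
                    "spectral_r": result.objective.spectral_r,
                    "spatial_s": result.objective.spatial_s,
                    "combined": result.objective.combined,
                }
            )
    return pd.DataFrame(rows)
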