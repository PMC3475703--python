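"""System-noise (noise floor) estimation from the CV~mean relationship.

Array intensities below some level are background-dominated: their
coefficient of variation (CV = sd/mean across samples) rises steeply as the
mean falls, while well-measured probes show a roughly constant CV. The
system-noise floor is defined as the lowest mean expression value at which
the LOWESS fit of CV against mean stops changing slope, i.e. where the
smoothed curve turns from non-linear to linear.

Procedure
---------
1. per-probe mean, sd (denominator n-1) and CV over all samples pooled;
2. LOWESS of CV on log-mean, evaluated on an even log-mean grid between the
   1st and 99th percentile of probe means;
3. local slopes of the fitted curve by central finite differences; the
   "linear regime" is the longest terminal run of grid points whose slopes
   all lie within +/- tau * max|slope| of that run's median slope, and the
   floor is the grid mean at the start of that run (optionally snapped up to
   the nearest observed probe mean, the value used downstream).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import ExpressionMatrix

__all__ = [
    "compute_probe_stats",
    "fit_cv_mean",
    "estimate_system_noise",
    "estimate_noise_floor",
    "NoiseModel",
    "plot_cv_mean",
]

DEFAULT_LOWESS_FRAC = 0.15
DEFAULT_GRID_SIZE = 200
DEFAULT_SLOPE_TOLERANCE = 0.1
DEFAULT_MIN_SUFFIX_FRACTION = 0.25


class NoLinearRegimeError(RuntimeError):
    """Raised when no qualifying terminal linear run exists on the grid."""


def compute_probe_stats(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-probe mean, sd and CV pooled over all samples of both groups.

    Returns a DataFrame indexed by probe id with columns ``mean``, ``sd``,
    ``cv`` and ``cv_defined``. Probes with mean 0 have undefined CV (NaN,
    flagged ``cv_defined=False``) and are excluded from the LOWESS fit.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples to compute sd")
    v = matrix.values.to_numpy(dtype=float)
    mean = v.mean(axis=1)
    sd = v.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return pd.DataFrame(
        {"mean": mean, "sd": sd, "cv": cv, "cv_defined": mean > 0},
        index=matrix.probe_ids,
    )


def fit_cv_mean(
    stats: pd.DataFrame,
    lowess_frac: float = DEFAULT_LOWESS_FRAC,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> tuple[np.ndarray, np.ndarray]:
    """LOWESS of CV on log-mean, evaluated on an even log-mean grid.

    The grid spans the 1st-99th percentile of the usable probe means (mean
    and sd both positive), with ``grid_size`` points equally spaced in
    log-mean. Returns ``(grid_means, fitted_cv)``.
    """
    usable = stats[(stats["mean"] > 0) & (stats["sd"] > 0)]
    if len(usable) < 50:
        raise ValueError(
            f"need >=50 probes with defined CV for the fit, got {len(usable)}"
        )
    mean = usable["mean"].to_numpy(dtype=float)
    cv = usable["cv"].to_numpy(dtype=float)
    if not (np.isfinite(mean).all() and np.isfinite(cv).all()):
        raise ValueError("non-finite probe statistics passed to fit_cv_mean")
    log_mean = np.log(mean)
    lo, hi = np.percentile(log_mean, [1.0, 99.0])
    if not hi > lo:
        raise ValueError("degenerate mean distribution: empty log-mean range")
    log_grid = np.linspace(lo, hi, grid_size)
    fitted = lowess(
        cv, log_mean, frac=lowess_frac, xvals=log_grid, return_sorted=False
    )
    if not np.isfinite(fitted).all():
        raise ValueError("LOWESS produced non-finite values; check the input")
    return np.exp(log_grid), np.asarray(fitted, dtype=float)


@dataclass
class NoiseModel:
    """Estimated noise floor plus the diagnostics behind it."""

    noise_floor: float  # value used downstream (snapped if means available)
    noise_floor_grid: float  # raw grid changepoint
    grid: np.ndarray = field(repr=False)
    fitted_cv: np.ndarray = field(repr=False)
    slopes: np.ndarray = field(repr=False)
    linear_suffix_start: int = 0
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "noise_floor": self.noise_floor,
            "noise_floor_grid": self.noise_floor_grid,
            "grid": self.grid.tolist(),
            "fitted_cv": self.fitted_cv.tolist(),
            "slopes": self.slopes.tolist(),
            "linear_suffix_start": int(self.linear_suffix_start),
            "settings": self.settings,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseModel":
        return cls(
            noise_floor=float(d["noise_floor"]),
            noise_floor_grid=float(d["noise_floor_grid"]),
            grid=np.asarray(d["grid"], dtype=float),
            fitted_cv=np.asarray(d["fitted_cv"], dtype=float),
            slopes=np.asarray(d["slopes"], dtype=float),
            linear_suffix_start=int(d["linear_suffix_start"]),
            settings=dict(d.get("settings", {})),
        )

    @classmethod
    def load(cls, path: str | Path) -> "NoiseModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def estimate_system_noise(
    grid: np.ndarray,
    fitted_cv: np.ndarray,
    slope_tolerance: float = DEFAULT_SLOPE_TOLERANCE,
    min_suffix_fraction: float = DEFAULT_MIN_SUFFIX_FRACTION,
    observed_means: np.ndarray | None = None,
    settings: dict | None = None,
) -> NoiseModel:
    """Locate the non-linear -> linear changepoint of the fitted CV curve.

    Slopes are central finite differences of ``fitted_cv`` against log-mean.
    The linear suffix is the longest terminal run whose slopes all lie within
    ``+/- slope_tolerance * max|slope|`` of the run's own median slope; it
    must cover at least ``min_suffix_fraction`` of the grid. The floor is the
    grid mean at the first index of that run; if ``observed_means`` is given
    it is snapped to the nearest observed probe mean at or above the grid
    value ("lowest observed mean expression value").
    """
    grid = np.asarray(grid, dtype=float)
    fitted_cv = np.asarray(fitted_cv, dtype=float)
    if grid.ndim != 1 or grid.shape != fitted_cv.shape or grid.size < 5:
        raise ValueError("grid and fitted_cv must be matching 1-D arrays (>=5 points)")
    n = grid.size
    slopes = np.gradient(fitted_cv, np.log(grid))
    # absolute epsilon keeps an exactly-flat curve (slopes ~ rounding noise)
    # classified as fully linear
    band = slope_tolerance * np.max(np.abs(slopes)) + 1e-12 * max(
        1.0, float(np.max(np.abs(fitted_cv)))
    )

    start: int | None = None
    for i in range(n - 1):
        suffix = slopes[i:]
        if np.max(np.abs(suffix - np.median(suffix))) <= band:
            start = i
            break
    min_len = int(np.ceil(min_suffix_fraction * n))
    if start is None or n - start < min_len:
        raise NoLinearRegimeError(
            "no terminal linear regime found on the CV~mean curve "
            f"(required >= {min_len}/{n} grid points); widen slope_tolerance "
            "or inspect the CV~mean scatter"
        )

    nu_grid = float(grid[start])
    nu = nu_grid
    if observed_means is not None:
        obs = np.asarray(observed_means, dtype=float)
        above = obs[obs >= nu_grid]
        if above.size:
            nu = float(above.min())
    return NoiseModel(
        noise_floor=nu,
        noise_floor_grid=nu_grid,
        grid=grid,
        fitted_cv=fitted_cv,
        slopes=slopes,
        linear_suffix_start=start,
        settings=dict(settings or {}),
    )


def estimate_noise_floor(
    matrix: ExpressionMatrix,
    lowess_frac: float = DEFAULT_LOWESS_FRAC,
    grid_size: int = DEFAULT_GRID_SIZE,
    slope_tolerance: float = DEFAULT_SLOPE_TOLERANCE,
    min_suffix_fraction: float = DEFAULT_MIN_SUFFIX_FRACTION,
) -> NoiseModel:
    """Full pipeline: probe stats -> CV~mean LOWESS -> changepoint."""
    stats = compute_probe_stats(matrix)
    grid, fitted = fit_cv_mean(stats, lowess_frac=lowess_frac, grid_size=grid_size)
    return estimate_system_noise(
        grid,
        fitted,
        slope_tolerance=slope_tolerance,
        min_suffix_fraction=min_suffix_fraction,
        observed_means=stats.loc[stats["cv_defined"], "mean"].to_numpy(),
        settings={
            "lowess_frac": lowess_frac,
            "grid_size": grid_size,
            "slope_tolerance": slope_tolerance,
            "min_suffix_fraction": min_suffix_fraction,
        },
    )


def plot_cv_mean(
    stats: pd.DataFrame, model: NoiseModel, path: str | Path
) -> Path:
    """Diagnostic scatter of CV~mean with the LOWESS curve and the floor."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    usable = stats[(stats["mean"] > 0) & (stats["sd"] > 0)]
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(usable["mean"], usable["cv"], s=3, alpha=0.25, color="gray",
               label="probes")
    ax.plot(model.grid, model.fitted_cv, color="crimson", lw=2, label="LOWESS")
    ax.axvline(model.noise_floor, color="navy", ls="--",
               label=f"noise floor = {model.noise_floor:.3g}")
    ax.set_xscale("log")
    ax.set_xlabel("probe mean intensity")
    ax.set_ylabel("CV (sd/mean)")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
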