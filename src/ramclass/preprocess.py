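"""Spectral preprocessing: truncate, baseline-correct, normalize, average.

The processing chain applies, in order:

1. truncation to a Raman-shift window (default 400-1800 cm^-1, closed),
2. polynomial baseline removal with an iterative asymmetric-cost fit in the
   style of the Goldindec algorithm (order 3, estimated peak ratio 0.5,
   smoothing window 5 by default),
3. vector (unit Euclidean norm) normalization,
4. averaging of scan replicates per specimen (or per individual).

Because normalization precedes averaging, an averaged spectrum has Euclidean
norm <= 1 rather than exactly 1; a post-average renormalization flag is
provided but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import minimize

from .io import Spectrum, SpectralDataset


class BaselineConvergenceError(RuntimeError):
    """Raised when the iterative baseline fit fails to settle."""


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    trunc_low, trunc_high : cm^-1 window kept by truncation (closed interval).
    poly_order : degree of the baseline polynomial.
    peak_ratio : estimated fraction of grid points occupied by peaks, in (0,1);
        sets the residual threshold above which points are treated as peaks.
    smooth_window : odd moving-average width used on the working copy that
        drives peak detection inside the baseline fit.
    normalize : apply vector normalization after baseline correction.
    average_by : 'specimen', 'individual', or 'none' — replicate averaging key.
    renormalize_after_average : restore unit norm after averaging (off by
        default; the printed chain averages normalized spectra as-is).
    below_weight : asymmetry factor; points falling below the fitted baseline
        are penalized this much more than points above it.
    threshold_rounds : number of outer rounds over which the peak threshold
        is re-estimated from the current fit.
    max_iter, tol : inner-optimizer iteration cap and the relative-change
        tolerance at which the outer rounds stop early.
    """

    trunc_low: float = 400.0
    trunc_high: float = 1800.0
    poly_order: int = 3
    peak_ratio: float = 0.5
    smooth_window: int = 5
    normalize: bool = True
    average_by: str = "specimen"
    renormalize_after_average: bool = False
    below_weight: float = 100.0
    threshold_rounds: int = 6
    max_iter: int = 200
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if not self.trunc_low < self.trunc_high:
            raise ValueError("trunc_low must be < trunc_high")
        if self.poly_order < 0:
            raise ValueError("poly_order must be >= 0")
        if not 0 < self.peak_ratio < 1:
            raise ValueError("peak_ratio must be in (0, 1)")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be an odd integer >= 1")
        if self.average_by not in ("specimen", "individual", "none"):
            raise ValueError("average_by must be 'specimen', 'individual' or 'none'")
        if self.below_weight < 1:
            raise ValueError("below_weight must be >= 1")
        if self.threshold_rounds < 1:
            raise ValueError("threshold_rounds must be >= 1")

    @classmethod
    def from_file(cls, path) -> "PreprocessConfig":
        """Load from a YAML or JSON key-value file mirroring the field names."""
        with open(Path(path)) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def truncate(s: Spectrum, low: float, high: float) -> Spectrum:
    """Restrict a spectrum to grid points in the closed interval [low, high]."""
    if not low < high:
        raise ValueError("low must be < high")
    keep = (s.wavenumbers >= low) & (s.wavenumbers <= high)
    if keep.sum() < 2:
        raise ValueError(
            f"truncation to [{low}, {high}] keeps {int(keep.sum())} grid points (need >= 2)"
        )
    return s.replace(wavenumbers=s.wavenumbers[keep], intensities=s.intensities[keep])


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window == 1:
        return y.copy()
    kernel = np.ones(window)
    sums = np.convolve(y, kernel, mode="same")
    counts = np.convolve(np.ones_like(y), kernel, mode="same")
    return sums / counts


def smooth(s: Spectrum, window: int) -> Spectrum:
    """Moving-average smoothing; edge windows shrink to the available points."""
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    if window > len(s.wavenumbers):
        raise ValueError("smoothing window exceeds spectrum length")
    return s.replace(intensities=_moving_average(s.intensities, window))


def _baseline_arrays(grid: np.ndarray, y: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Asymmetric truncated-cost polynomial baseline on one intensity vector.

    The baseline polynomial minimizes an asymmetric truncated quadratic cost
    of the residual r = y - p(w): below the fit the cost is
    ``below_weight * r^2`` (the baseline should stay under the data); above
    the fit it is the saturating s^2 (r/s)^2 / (1 + (r/s)^2), quadratic for
    small r but bounded for r >> s, so peaks cannot pull the fit upward. The
    peak threshold s is the (1 - peak_ratio) quantile of the positive
    residuals of a moving-average-smoothed working copy (smoothing keeps
    noise out of the threshold; the cost itself acts on the raw
    intensities). Starting from the ordinary least-squares fit, each outer
    round freezes s and minimizes the cost exactly (L-BFGS with the analytic
    gradient, over the polynomial coefficients in a scaled coordinate), then
    re-estimates s; rounds stop early once the fit change drops below the
    configured tolerance. Deterministic for fixed input.
    """
    n = len(grid)
    if cfg.poly_order >= n:
        raise ValueError("poly_order must be smaller than the number of grid points")
    # scale the abscissa to [-1, 1] for a well-conditioned Vandermonde matrix
    t = 2.0 * (grid - grid[0]) / (grid[-1] - grid[0]) - 1.0
    V = np.polynomial.polynomial.polyvander(t, cfg.poly_order)
    y_work = _moving_average(y, min(cfg.smooth_window, n if n % 2 else n - 1))
    scale = float(np.max(np.abs(y))) or 1.0
    bw = cfg.below_weight

    coef, *_ = np.linalg.lstsq(V, y, rcond=None)
    fit = V @ coef
    for _ in range(cfg.threshold_rounds):
        r_work = y_work - fit
        pos = r_work[r_work > 0]
        thr = float(np.quantile(pos, 1.0 - cfg.peak_ratio)) if pos.size else 0.0
        thr = max(thr, 1e-9 * scale)

        def cost_grad(c, thr=thr):
            r = y - V @ c
            below = r < 0
            u = r / thr
            cost = np.where(below, bw * r * r, thr * thr * u * u / (1.0 + u * u))
            psi = np.where(below, 2.0 * bw * r, 2.0 * r / (1.0 + u * u) ** 2)
            return float(cost.sum()), -(V.T @ psi)

        res = minimize(
            cost_grad,
            coef,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": cfg.max_iter, "ftol": 1e-12, "gtol": 1e-10},
        )
        # status 2 is the line search hitting the precision floor at the optimum
        if res.status not in (0, 2):
            raise BaselineConvergenceError(
                f"baseline cost minimization stopped after {res.nit} iterations: {res.message}"
            )
        coef = res.x
        new_fit = V @ coef
        delta = float(np.max(np.abs(new_fit - fit))) / scale
        fit = new_fit
        if delta < cfg.tol:
            break
    return fit


def goldindec_baseline(s: Spectrum, cfg: PreprocessConfig | None = None):
    """Estimate and subtract a polynomial baseline from a spectrum.

    Returns ``(baseline, corrected)`` where ``baseline`` is the fitted
    polynomial evaluated on the grid and ``corrected`` is the spectrum with
    the baseline removed (metadata preserved). Deterministic for fixed input.
    """
    cfg = cfg or PreprocessConfig()
    baseline = _baseline_arrays(s.wavenumbers, s.intensities, cfg)
    corrected = s.replace(intensities=s.intensities - baseline)
    return baseline, corrected


def vector_normalize(s: Spectrum) -> Spectrum:
    """Scale intensities to unit Euclidean norm."""
    norm = float(np.linalg.norm(s.intensities))
    if norm == 0.0:
        raise ValueError(f"cannot vector-normalize the all-zero spectrum {s.scan_id!r}")
    return s.replace(intensities=s.intensities / norm)


def average_replicates(d: SpectralDataset, by: str = "specimen") -> SpectralDataset:
    """Pointwise mean of replicate scans per specimen (or per individual).

    Output metadata: scan_id becomes the group key and replicate_index the
    member count. Class labels must be unanimous within a group.
    """
    if by not in ("specimen", "individual"):
        raise ValueError("by must be 'specimen' or 'individual'")
    key = f"{by}_id"
    keys = d.meta[key].astype(str)
    if (keys.str.len() == 0).any():
        raise ValueError(f"empty {key} in metadata")
    rows, meta_rows = [], []
    for gid in keys.unique():  # first-appearance order
        idx = np.flatnonzero((keys == gid).to_numpy())
        labels = set(d.meta["class_label"].iloc[idx].astype(str))
        if len(labels) > 1:
            raise ValueError(f"group {gid!r} has conflicting class labels: {sorted(labels)}")
        sub = d.meta.iloc[idx[0]]
        rows.append(d.matrix[idx].mean(axis=0))
        meta_rows.append(
            {
                "scan_id": gid,
                "specimen_id": str(sub["specimen_id"]) if by == "individual" else gid,
                "individual_id": str(sub["individual_id"]),
                "class_label": labels.pop(),
                "replicate_index": len(idx),
            }
        )
    return SpectralDataset(d.grid, np.vstack(rows), pd.DataFrame(meta_rows))


def resample_to_grid(s: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linear interpolation onto a target grid inside the source span."""
    grid = np.asarray(grid, dtype=float)
    if grid.min() < s.wavenumbers[0] or grid.max() > s.wavenumbers[-1]:
        raise ValueError(
            f"target grid [{grid.min()}, {grid.max()}] outside source span "
            f"[{s.wavenumbers[0]}, {s.wavenumbers[-1]}]; extrapolation is not done"
        )
    return s.replace(wavenumbers=grid, intensities=np.interp(grid, s.wavenumbers, s.intensities))


def run_preprocess(d: SpectralDataset, cfg: PreprocessConfig | None = None):
    """Run the full chain: truncate, baseline, normalize, average.

    Returns ``(processed, log)`` where log records the scan count after each
    step. Smoothing per the config is used only inside baseline estimation.
    """
    cfg = cfg or PreprocessConfig()
    log: list[tuple[str, int]] = []

    keep = (d.grid >= cfg.trunc_low) & (d.grid <= cfg.trunc_high)
    if keep.sum() < 2:
        raise ValueError(
            f"truncation to [{cfg.trunc_low}, {cfg.trunc_high}] keeps "
            f"{int(keep.sum())} grid points (need >= 2)"
        )
    grid = d.grid[keep]
    mat = d.matrix[:, keep]
    log.append(("truncate", mat.shape[0]))

    corrected = np.empty_like(mat)
    for i in range(mat.shape[0]):
        corrected[i] = mat[i] - _baseline_arrays(grid, mat[i], cfg)
    log.append(("baseline", corrected.shape[0]))

    if cfg.normalize:
        norms = np.linalg.norm(corrected, axis=1)
        zero = np.flatnonzero(norms == 0)
        if zero.size:
            sid = d.meta["scan_id"].iloc[int(zero[0])]
            raise ValueError(f"cannot vector-normalize the all-zero spectrum {sid!r}")
        corrected = corrected / norms[:, None]
    log.append(("normalize", corrected.shape[0]))

    out = SpectralDataset(grid, corrected, d.meta)
    if cfg.average_by != "none":
        out = average_replicates(out, by=cfg.average_by)
        if cfg.renormalize_after_average:
            norms = np.linalg.norm(out.matrix, axis=1)
            out = SpectralDataset(out.grid, out.matrix / norms[:, None], out.meta)
    log.append(("average", out.n_scans))
    return out, log
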