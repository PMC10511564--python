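"""T1 estimation from magnitude inversion-recovery samples.

Magnitude reconstruction discards the sign of the longitudinal
magnetization, so samples acquired before the zero crossing appear
rectified.  The fitter restores polarity by exhaustive search: for each
candidate flip point ``k`` in ``0..n`` the first ``k`` samples are
negated and the signed three-parameter model ``A - B exp(-TI/T1*)`` is
fitted by bounded least squares; the candidate with the lowest residual
sum of squares wins, ties broken toward smaller ``k``.  The corrected
relaxation time is ``T1 = T1* (B/A - 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .phantom import ImageSeries

__all__ = ["FitResult", "T1Map", "fit_ir_magnitude", "fit_t1_map", "roi_t1_summary"]

T1_STAR_BOUNDS_MS = (50.0, 5000.0)
_MAX_NFEV = 500


@dataclass(frozen=True)
class FitResult:
    """Three-parameter IR fit with Look-Locker-corrected T1."""

    a: float
    b: float
    t1_star_ms: float
    rss: float
    converged: bool
    polarity_index: int

    @property
    def t1_ms(self) -> float:
        return self.t1_star_ms * (self.b / self.a - 1.0)


@dataclass(frozen=True)
class T1Map:
    """Per-pixel fit output; values are NaN outside the mask."""

    t1_ms: np.ndarray
    t1_star_ms: np.ndarray
    a: np.ndarray
    b: np.ndarray
    rss: np.ndarray
    converged: np.ndarray  # bool; False where not fitted or not converged
    mask: np.ndarray


def _initial_guess(ti: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Start values: A from the late plateau, B from the rectified first
    sample, T1* from a log-linear fit of the post-null tail."""
    a0 = max(float(np.max(np.abs(y))), 1e-12)
    b0 = a0 + abs(float(y[0]))
    resid = a0 - y
    ok = resid > 1e-12 * a0
    if ok.sum() >= 2:
        slope = np.polyfit(ti[ok], np.log(resid[ok]), 1)[0]
        t1s0 = -1.0 / slope if slope < 0 else 1000.0
    else:
        t1s0 = 1000.0
    t1s0 = min(max(t1s0, T1_STAR_BOUNDS_MS[0] * 1.01), T1_STAR_BOUNDS_MS[1] * 0.99)
    return a0, b0, t1s0


def fit_ir_magnitude(ti_list_ms, si_list) -> FitResult:
    """Fit ``|A - B exp(-TI/T1*)|`` to magnitude samples.

    Requires at least 4 samples with strictly increasing TIs and
    non-negative signals.  An all-zero signal yields a non-converged
    :class:`FitResult` (NaN parameters), not an exception, so per-pixel
    maps stay rectangular.
    """
    ti = np.asarray(ti_list_ms, dtype=float)
    y = np.asarray(si_list, dtype=float)
    if ti.size < 4:
        raise ValueError(f"need >= 4 samples for a 3-parameter fit, got {ti.size}")
    if ti.shape != y.shape:
        raise ValueError("ti_list and si_list must have equal length")
    if np.any(np.diff(ti) <= 0):
        raise ValueError("ti_list must be strictly increasing")
    if np.any(y < 0):
        raise ValueError("magnitude signals must be non-negative")
    if np.all(y == 0):
        return FitResult(math.nan, math.nan, math.nan, math.nan, False, 0)

    eps = 1e-12
    lb = [eps, eps, T1_STAR_BOUNDS_MS[0]]
    ub = [np.inf, np.inf, T1_STAR_BOUNDS_MS[1]]
    best: tuple[float, np.ndarray, int, bool] | None = None  # (rss, params, k, ok)
    for k in range(ti.size + 1):
        signed = y.copy()
        signed[:k] *= -1.0
        a0, b0, t1s0 = _initial_guess(ti, signed)
        x0 = np.clip([a0, b0, t1s0], lb, ub)

        def resid(p, signed=signed):
            return p[0] - p[1] * np.exp(-ti / p[2]) - signed

        sol = least_squares(
            resid, x0, bounds=(lb, ub), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=_MAX_NFEV,
        )
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] * (1.0 - 1e-12):
            best = (rss, sol.x, k, bool(sol.success))
    rss, params, k, ok = best
    return FitResult(
        a=float(params[0]), b=float(params[1]), t1_star_ms=float(params[2]),
        rss=rss, converged=ok, polarity_index=k,
    )


def fit_t1_map(series: ImageSeries, mask: np.ndarray) -> T1Map:
    """Apply :func:`fit_ir_magnitude` to every pixel inside ``mask``."""
    if series.data.shape[0] < 4:
        raise ValueError("series needs >= 4 inversion times")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.data.shape[1:]:
        raise ValueError("mask shape must match the image grid")
    if not mask.any():
        raise ValueError("mask is empty")
    shape = mask.shape
    t1 = np.full(shape, np.nan)
    t1s = np.full(shape, np.nan)
    a = np.full(shape, np.nan)
    b = np.full(shape, np.nan)
    rss = np.full(shape, np.nan)
    conv = np.zeros(shape, dtype=bool)
    ti = np.asarray(series.ti_list_ms)
    rows, cols = np.nonzero(mask)
    for r, c in zip(rows, cols):
        fit = fit_ir_magnitude(ti, series.data[:, r, c])
        t1s[r, c] = fit.t1_star_ms
        a[r, c] = fit.a
        b[r, c] = fit.b
        rss[r, c] = fit.rss
        conv[r, c] = fit.converged
        if fit.converged:
            t1[r, c] = fit.t1_ms
    return T1Map(t1_ms=t1, t1_star_ms=t1s, a=a, b=b, rss=rss, converged=conv, mask=mask)


def roi_t1_summary(t1_map: T1Map, roi: np.ndarray, ddof: int = 1) -> dict:
    """Mean and SD of corrected T1 over converged pixels of an ROI.

    Returns ``{"mean_ms", "sd_ms", "n", "n_excluded"}``; non-converged
    pixels are excluded and counted.  Raises if the ROI is empty, leaves
    the fitted mask, or contains no converged pixel.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    if np.any(roi & ~t1_map.mask):
        raise ValueError("ROI extends outside the fitted mask")
    ok = roi & t1_map.converged
    n_excluded = int(roi.sum() - ok.sum())
    if not ok.any():
        raise ValueError(f"no converged pixels in ROI ({n_excluded} excluded)")
    vals = t1_map.t1_ms[ok]
    sd = float(np.std(vals, ddof=ddof)) if vals.size > ddof else 0.0
    return {
        "mean_ms": float(np.mean(vals)),
        "sd_ms": sd,
        "n": int(vals.size),
        "n_excluded": n_excluded,
    }
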