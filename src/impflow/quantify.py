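"""Graphical CBF quantification and its competing formulations.

The core estimator plots, per frame,

    y = Cb(t) / (λ l(t))        against        x = ∫₀ᵗ Cr dτ / l(t)

where ``Cb`` is the brain curve, ``Cr`` the pulmonary-artery curve and
``l`` the visible-lung curve.  Under the microsphere model the points lie
on a straight line of slope F (the cerebral blood flow, mL/g/min) and
intercept −F/(αP), so CBF is read off a least-squares fit of the linear
section — no arterial sampling, no empirical regression formula, and no
sensitivity to the lung washout rate, because the lung retention term is
carried explicitly instead of being folded into a pseudo-input.

For comparison the module also implements:

* the Gjedde–Patlak-style plot that treats the pulmonary-artery curve
  itself as the input (``gp_points``).  Its slope F_GP systematically
  underestimates F because tracer retained in the lungs never reaches the
  brain; the exact relation is F = F_GP / (1 − κ) with κ the terminal
  lung fraction of the dose (``gp_to_cbf_exact``);
* the lung-washout estimate of the cumulated arterial input used by the
  non-invasive microsphere (NIMS) method, which normalises by the peak
  lung content L_max instead of the dose D and therefore underestimates
  the cumulated input whenever κ > 0 (``nims_cumulated_input``);
* distribution of a mean CBF value over a brain image proportionally to
  counts, producing a regional CBF map (``mean_to_regional``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .tacs import cumulative_integral
from .types import TAC, DataError

__all__ = [
    "PlotSeries",
    "LineFit",
    "cbf_plot_points",
    "gp_points",
    "fit_linear_section",
    "estimate_alpha_P",
    "gp_terminal_index",
    "gp_to_cbf_exact",
    "NIMSInput",
    "nims_cumulated_input",
    "mean_to_regional",
]

#: default lipophilic fraction of the tracer (octanol-extraction value)
DEFAULT_LAMBDA = 0.8


@dataclass(frozen=True)
class PlotSeries:
    """Per-frame points of a graphical plot, with exclusion bookkeeping.

    ``frame_indices`` maps each kept point back to the frame index of the
    source TACs; ``excluded`` lists frames dropped for a nonpositive (or
    numerically negligible) denominator.
    """

    x: np.ndarray
    y: np.ndarray
    times: np.ndarray
    frame_indices: np.ndarray
    excluded: np.ndarray
    x_label: str = "x"
    y_label: str = "y"

    def __post_init__(self) -> None:
        if not (len(self.x) == len(self.y) == len(self.times)
                == len(self.frame_indices)):
            raise DataError("PlotSeries arrays must have equal length")

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class LineFit:
    """Least-squares line through the selected window of a plot.

    For the CBF plot the slope *is* the flow estimate (mL/g/min in
    calibrated mode, a relative index otherwise) and the intercept has
    −F/(αP) semantics; for the GP plot the slope is the F_GP index.
    ``window`` holds the (first, last) frame indices actually used.
    """

    slope: float
    intercept: float
    window: tuple[int, int]
    r2: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise DataError("a line fit needs at least 3 points")
        if not 0 <= self.r2 <= 1 + 1e-12:
            raise DataError("r2 must lie in [0, 1]")


def _check_shared_grid(*tacs: TAC) -> None:
    first = tacs[0]
    for other in tacs[1:]:
        if not first.same_grid(other):
            raise DataError("TACs must share one time grid")


def cbf_plot_points(cr: TAC, cb: TAC, lung: TAC,
                    lambda_lipo: float = DEFAULT_LAMBDA) -> PlotSeries:
    """Build the CBF plot: y = Cb/(λ·l), x = ∫Cr/l.

    Frames where the lung curve is nonpositive (before tracer arrival)
    are excluded and recorded.  In calibrated units y is in 1/g and x in
    min/mL; with relative (uncalibrated) curves both are dimensionless
    and the fitted slope is a relative index.
    """
    _check_shared_grid(cr, cb, lung)
    if not 0 < lambda_lipo <= 1:
        raise DataError("lambda_lipo must be in (0, 1]")
    cum_cr = cumulative_integral(cr).values
    lv = lung.values
    usable = lv > 0
    if not usable.any():
        raise DataError("all lung values are nonpositive; nothing to plot")
    idx = np.flatnonzero(usable)
    return PlotSeries(
        x=cum_cr[idx] / lv[idx],
        y=cb.values[idx] / (lambda_lipo * lv[idx]),
        times=cr.times[idx],
        frame_indices=idx,
        excluded=np.flatnonzero(~usable),
        x_label="int_Cr/l",
        y_label="Cb/(lambda*l)",
    )


def gp_points(cr: TAC, cb: TAC, cr_floor_frac: float = 1e-2) -> PlotSeries:
    """Build the Gjedde–Patlak-style plot: y = Cb/Cr, x = ∫Cr/Cr.

    The pulmonary-artery curve stands in for the input function, so only
    frames with appreciable Cr are usable: frames with Cr below
    ``cr_floor_frac`` of the Cr peak (late frames, where the bolus has
    passed) are excluded and recorded.
    """
    _check_shared_grid(cr, cb)
    cum_cr = cumulative_integral(cr).values
    crv = cr.values
    peak = crv.max()
    if peak <= 0:
        raise DataError("Cr curve is nonpositive everywhere; GP plot undefined")
    usable = crv > cr_floor_frac * peak
    idx = np.flatnonzero(usable)
    if idx.size == 0:
        raise DataError("no usable frames for the GP plot")
    return PlotSeries(
        x=cum_cr[idx] / crv[idx],
        y=cb.values[idx] / crv[idx],
        times=cr.times[idx],
        frame_indices=idx,
        excluded=np.flatnonzero(~usable),
        x_label="int_Cr/Cr",
        y_label="Cb/Cr",
    )


class _OLS(NamedTuple):
    slope: float
    intercept: float
    r2: float


def _ols(x: np.ndarray, y: np.ndarray) -> _OLS:
    if np.ptp(x) == 0:
        raise DataError("degenerate fit: x has zero variance")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        # constant y: perfect horizontal line
        r2 = 1.0 if ss_res <= 1e-20 * max(1.0, abs(y[0])) else 0.0
    else:
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
    return _OLS(float(slope), float(intercept), min(r2, 1.0))


def fit_linear_section(points: PlotSeries, strategy: str = "auto",
                       window: tuple[int, int] | None = None,
                       r2_threshold: float = 0.99, min_points: int = 5,
                       min_start_time: float | None = None) -> LineFit:
    """Fit the linear section of a graphical plot by ordinary least squares.

    ``strategy="fixed_window"`` fits exactly the given (first, last) point
    index window (inclusive).  ``strategy="auto"`` selects the longest
    trailing window with r² ≥ ``r2_threshold`` and at least ``min_points``
    points, optionally starting no earlier than ``min_start_time``
    (e.g. the end of the pulmonary-artery bolus); among equal-length
    candidates the later-starting one wins.

    Raises
    ------
    DataError
        If fewer than 3 points are usable, no window reaches the r²
        threshold, or x is degenerate.
    """
    n = len(points)
    if n < 3:
        raise DataError("need at least 3 plot points")
    if strategy == "fixed_window":
        if window is None:
            raise DataError("fixed_window strategy requires a window")
        i0, i1 = window
        if not (0 <= i0 < i1 < n):
            raise DataError(f"window {window} outside series of length {n}")
        sl = slice(i0, i1 + 1)
        if i1 - i0 + 1 < 3:
            raise DataError("window must contain at least 3 points")
        ols = _ols(points.x[sl], points.y[sl])
        return LineFit(ols.slope, ols.intercept,
                       (int(points.frame_indices[i0]),
                        int(points.frame_indices[i1])),
                       ols.r2, i1 - i0 + 1)
    if strategy != "auto":
        raise DataError(f"unknown fit strategy {strategy!r}")
    min_points = max(min_points, 3)
    start0 = 0
    if min_start_time is not None:
        start0 = int(np.searchsorted(points.times, min_start_time))
    last_err: DataError | None = None
    for s in range(start0, n - min_points + 1):
        try:
            ols = _ols(points.x[s:], points.y[s:])
        except DataError as err:
            last_err = err
            continue
        if ols.r2 >= r2_threshold:
            return LineFit(ols.slope, ols.intercept,
                           (int(points.frame_indices[s]),
                            int(points.frame_indices[-1])),
                           ols.r2, n - s)
    if last_err is not None and n - start0 < min_points:
        raise last_err
    raise DataError(
        f"no trailing window of >= {min_points} points reaches "
        f"r2 >= {r2_threshold}"
    )


def estimate_alpha_P(fit: LineFit) -> float:
    """Recover αP (mL/min) from a CBF-plot fit: αP = −slope/intercept.

    The intercept of the CBF plot is −F/(αP); a nonnegative intercept is
    non-physical and rejected.
    """
    if fit.intercept >= 0:
        raise DataError(
            f"non-physical fit: intercept {fit.intercept:.3g} must be "
            "negative (−F/(αP))"
        )
    return -fit.slope / fit.intercept


def gp_terminal_index(cb_end: float, P: float, D: float,
                      lambda_lipo: float = DEFAULT_LAMBDA) -> float:
    """Terminal-uptake GP index F_GP = Cb(∞)·P / (λ·D).

    Equals the asymptotic slope Cb(∞)/(λ∫Cr) since P∫Cr = D once the
    bolus has passed.  λ keeps the index on the same convention as the
    flow equation Cb = Fλ∫Ca, so that F = F_GP/(1−κ) holds exactly.
    """
    if P <= 0 or D <= 0:
        raise DataError("P and D must be positive")
    return cb_end * P / (lambda_lipo * D)


def gp_to_cbf_exact(f_gp: float, kappa: float) -> float:
    """Exact correction of the GP index for lung retention: F = F_GP/(1−κ).

    κ is the terminal fraction of the dose retained in the lungs; the GP
    plot overestimates the cumulated input by exactly that fraction.
    F ≥ F_GP, with equality iff κ = 0.
    """
    if not 0 <= kappa < 1:
        raise DataError(f"kappa must lie in [0, 1), got {kappa}")
    return f_gp / (1.0 - kappa)


class NIMSInput(NamedTuple):
    """Cumulated arterial input estimates from lung washout (Bq·min/mL)."""

    estimate: TAC   # D·(1 − L/L_max)/P — the classic NIMS form
    exact: TAC      # (D − L)/P — valid once the whole bolus is in the lungs


def nims_cumulated_input(L: TAC, L_max: float, D: float, P: float) -> NIMSInput:
    """Estimate ∫₀ᵗ Ca dτ from the whole-lung curve.

    Returns both the NIMS form D·(1 − L/L_max)/P and the exact form
    (D − L)/P obtained by substituting the dose D for the lung peak
    L_max.  Because lung washout starts before the lung peak, L_max < D,
    so the NIMS form underestimates the true cumulated input whenever
    any tracer is retained in the lungs; the exact form is valid for
    times after the bolus has fully entered the lungs.
    """
    if L_max <= 0:
        raise DataError("L_max must be positive")
    if D <= 0 or P <= 0:
        raise DataError("D and P must be positive")
    unit = "Bq*min/mL"
    est = D * (1.0 - L.values / L_max) / P
    exact = (D - L.values) / P
    return NIMSInput(TAC(L.times, est, unit), TAC(L.times, exact, unit))


def mean_to_regional(mcbf: float, brain_image: np.ndarray,
                     mask: np.ndarray | None = None) -> np.ndarray:
    """Distribute a mean CBF over a brain image proportionally to counts.

    Each voxel gets ``mcbf × voxel / mean(voxels in mask)``, so the mean
    of the output over the mask equals ``mcbf`` exactly and the map
    inherits the image's relative contrast.
    """
    if mcbf <= 0:
        raise DataError("mCBF must be positive")
    img = np.asarray(brain_image, dtype=float)
    if mask is None:
        mask = np.ones(img.shape, dtype=bool)
    m = img[mask].mean() if mask.any() else 0.0
    if m <= 0:
        raise DataError("brain image mean over the mask must be positive")
    return mcbf * img / m
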