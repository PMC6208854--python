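"""Time–activity curve processing.

The clinical protocol derives ROI curves from the planar frames, smooths
them with a low-pass filter to tame counting noise, shifts the common
time axis so the bolus arrival in the pulmonary artery defines t = 0,
and forms the running integral that the graphical plot needs on its
abscissa.
"""

from __future__ import annotations

from typing import Mapping, NamedTuple

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .simulate import PlanarPhantom
from .types import TAC, DataError

__all__ = [
    "extract_roi_tac",
    "lowpass_smooth",
    "time_zero_adjust",
    "TimeZeroResult",
    "cumulative_integral",
    "calibrate_tac",
]


def extract_roi_tac(phantom: PlanarPhantom, roi_name: str) -> TAC:
    """Sum counts inside a named ROI mask for every frame.

    Returns a TAC in counts at the frame mid-times.
    """
    try:
        mask = phantom.roi_masks[roi_name]
    except KeyError:
        raise DataError(
            f"unknown ROI {roi_name!r}; available: "
            f"{sorted(phantom.roi_masks)}"
        ) from None
    if not mask.any():
        raise DataError(f"ROI mask {roi_name!r} is empty")
    values = phantom.frames[:, mask].sum(axis=1).astype(float)
    return TAC(phantom.grid.mid_times, values, "counts")


def lowpass_smooth(tac: TAC, window: int = 3) -> TAC:
    """Centred moving average of odd ``window`` frames.

    At the edges the window shrinks symmetrically, so the output has the
    same length and times, a constant series passes unchanged, and no
    phase shift is introduced.  ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise DataError("smoothing window must be an odd positive integer")
    n = len(tac)
    if window > n:
        raise DataError(f"window {window} exceeds series length {n}")
    half = window // 2
    v = tac.values
    out = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = v[i - k: i + k + 1].mean()
    return tac.with_values(out)


class TimeZeroResult(NamedTuple):
    """Zero-adjusted curves plus the applied shift diagnostics."""

    tacs: dict[str, TAC]
    offset_min: float     # time subtracted from every curve
    onset_index: int      # frame index of the detected bolus arrival


def time_zero_adjust(tacs: Mapping[str, TAC], onset_frac: float = 0.05,
                     reference: str = "pulmonary_artery") -> TimeZeroResult:
    """Shift all curves so the bolus arrival in the reference ROI is t = 0.

    The onset frame is the first frame whose reference value exceeds
    ``onset_frac`` of the reference peak ("activity rose sharply").  One
    common offset — the start of that frame — is subtracted from every
    curve, and the frames before it are dropped from all curves
    identically, so relative timing is preserved exactly.
    """
    if not 0 < onset_frac < 1:
        raise DataError("onset_frac must lie in (0, 1)")
    if reference not in tacs:
        raise DataError(f"reference curve {reference!r} not among inputs")
    ref = tacs[reference]
    peak = ref.values.max()
    if peak <= 0:
        raise DataError("reference curve is flat; no bolus onset detectable")
    idx = int(np.argmax(ref.values > onset_frac * peak))
    grids_ok = all(ref.same_grid(t) for t in tacs.values())
    if not grids_ok:
        raise DataError("all curves must share one time grid")
    # the onset frame maps to time zero; its mid-time keeps the half-frame lag
    if idx == 0:
        return TimeZeroResult(dict(tacs), 0.0, 0)
    # offset = start of the onset frame = midpoint between neighbouring mids
    offset = float(0.5 * (ref.times[idx - 1] + ref.times[idx]))
    out = {
        name: TAC(t.times[idx:] - offset, t.values[idx:], t.unit)
        for name, t in tacs.items()
    }
    return TimeZeroResult(out, offset, idx)


def cumulative_integral(tac: TAC) -> TAC:
    """Running trapezoidal integral ∫₀ᵗ of a TAC, in unit × min.

    An implicit (t = 0, value 0) anchor is prepended: activity is zero
    before injection, so the first frame contributes a triangle from the
    origin.  Output has the same length and times as the input and is
    nondecreasing for nonnegative input.
    """
    t = tac.times
    v = tac.values
    if t[0] < 0:
        raise DataError("cannot anchor the integral: times start before 0")
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        v = np.concatenate([[0.0], v])
        out = cumulative_trapezoid(v, t)[...]
    else:
        out = cumulative_trapezoid(v, t, initial=0.0)
    return TAC(tac.times, out, tac.integral_unit())


def calibrate_tac(tac: TAC, factor: float, frame_duration: np.ndarray | float,
                  unit: str) -> TAC:
    """Convert ROI counts back to a physical quantity.

    Inverts the rendering model ``counts = factor × quantity × Δt``.
    """
    if tac.unit != "counts":
        raise DataError(f"expected a counts TAC, got unit {tac.unit!r}")
    if factor <= 0:
        raise DataError("calibration factor must be positive")
    dt = np.broadcast_to(np.asarray(frame_duration, float), tac.values.shape)
    return TAC(tac.times, tac.values / (factor * dt), unit)
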