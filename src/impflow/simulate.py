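r"""Forward kinetic model for dynamic planar 123I-IMP studies.

The tracer is injected as an intravenous bolus, transits the pulmonary
artery (concentration ``Cr``, Bq/mL), is trapped in the lung endothelium
(content ``L``, Bq) and washes out into the systemic arterial blood
(concentration ``Ca``, Bq/mL) at rate ``k_lung``, from where the brain
takes it up (tissue concentration ``Cb``, Bq/g).  The model equations are

.. math::

    dL/dt  &= P\,C_r(t) - k_{lung} L(t), \qquad C_a = k_{lung} L / P \\
    dC_b/dt &= E F \lambda\, C_a(t) - k_2 C_b(t)

with ``P`` the right-ventricular cardiac output (mL/min), ``F`` the
cerebral blood flow (mL/g/min), ``λ`` the lipophilic fraction and ``E``
the first-pass extraction.  By construction Fick's principle holds:
``L(t) = P (∫Cr − ∫Ca)``.  The *microsphere* model is the special case
``E = 1, k2 = 0``, for which ``Cb(t) = F λ ∫₀ᵗ Ca dτ``.

The pulmonary-artery input is a gamma-variate pulse of compact effective
support, normalised so that the whole dose passes the pulmonary artery:
``P ∫ Cr = D``.  The lung equation is solved in closed form against this
pulse (regularised lower incomplete gamma function), so frame-sampled
curves carry no ODE-solver error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special
from scipy.stats import gamma as gamma_dist

from .types import TAC, ConfigError, DataError, TimeGrid

__all__ = [
    "BolusParams",
    "CalibFactors",
    "KineticParams",
    "StudyTACs",
    "PlanarPhantom",
    "gamma_variate_bolus",
    "simulate_study",
    "render_phantom",
    "default_roi_masks",
]

#: mass fraction of the bolus allowed beyond its recorded support end T1
_BOLUS_TAIL_FRAC = 1e-6


@dataclass(frozen=True)
class BolusParams:
    """Gamma-variate pulmonary-artery bolus: onset (min), shape, scale (min)."""

    onset_min: float = 0.1
    shape: float = 3.0
    scale_min: float = 0.05

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale_min <= 0:
            raise ConfigError("bolus shape and scale must be positive")
        if self.onset_min < 0:
            raise ConfigError("bolus onset must be >= 0")

    def support_end(self) -> float:
        """Time T1 (min) by which all but a 1e-6 mass fraction has passed."""
        return self.onset_min + float(
            gamma_dist.ppf(1.0 - _BOLUS_TAIL_FRAC, a=self.shape,
                           scale=self.scale_min)
        )


@dataclass(frozen=True)
class CalibFactors:
    """Counts-per-physical-unit factors of the planar camera.

    ROI counts in a frame of duration Δt (min) are modelled as
    ``c · quantity · Δt``: ``c_r`` (counts·mL/Bq/min) for the
    pulmonary-artery concentration, ``c_b`` (counts·g/Bq/min) for the
    brain concentration, ``c_l`` (counts/Bq/min) for the visible-lung
    content.  Defaults give clinically plausible planar count levels for
    a 222 MBq dose (PA peak ≈ 4×10³, lungs ≈ 2×10⁴ counts/frame).
    """

    c_r: float = 0.5
    c_b: float = 50.0
    c_l: float = 6.0e-3

    def __post_init__(self) -> None:
        if min(self.c_r, self.c_b, self.c_l) <= 0:
            raise ConfigError("calibration factors must be positive")


@dataclass(frozen=True)
class KineticParams:
    """Ground-truth physiology and acquisition constants.

    Defaults are a physiologic mid-range fixture: F = 0.4 mL/g/min,
    cardiac output P = 5000 mL/min, lipophilic fraction λ = 0.8, visible
    lung fraction α = 0.5, lung washout 0.15/min, complete extraction,
    no brain efflux, 222 MBq dose.
    """

    F: float = 0.4                 # CBF, mL/g/min
    P: float = 5000.0              # right-ventricular cardiac output, mL/min
    lambda_lipo: float = 0.8       # lipophilic fraction
    alpha: float = 0.5             # visible fraction of the lungs
    k_lung: float = 0.15           # lung washout rate, 1/min
    k2: float = 0.0                # brain efflux rate, 1/min
    E: float = 1.0                 # first-pass extraction
    D: float = 222e6               # injected dose, Bq
    brain_mass: float = 1400.0     # g
    bolus: BolusParams = field(default_factory=BolusParams)
    calib: CalibFactors = field(default_factory=CalibFactors)
    scatter_frac: float = 0.0      # lung counts leaking into the PA ROI

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ConfigError("F must be >= 0")
        if self.P <= 0 or self.D <= 0 or self.brain_mass <= 0:
            raise ConfigError("P, D and brain_mass must be positive")
        if not 0 < self.lambda_lipo <= 1:
            raise ConfigError("lambda_lipo must be in (0, 1]")
        if not 0 < self.alpha <= 1:
            raise ConfigError("alpha must be in (0, 1]")
        if self.k_lung < 0 or self.k2 < 0:
            raise ConfigError("k_lung and k2 must be >= 0")
        if not 0 < self.E <= 1:
            raise ConfigError("E must be in (0, 1]")
        if self.scatter_frac < 0:
            raise ConfigError("scatter_frac must be >= 0")

    @property
    def distribution_volume(self) -> float:
        """Brain distribution volume K1/k2 = E·F·λ/k2 (mL/g); inf if k2 = 0."""
        if self.k2 == 0:
            return math.inf
        return self.E * self.F * self.lambda_lipo / self.k2


@dataclass(frozen=True)
class StudyTACs:
    """The five coupled study curves on one frame grid, plus κ.

    ``kappa`` is the fraction of the dose still in the lungs at the last
    frame, L(end)/D — the exact correction factor between the GP index
    and true CBF.  ``t1`` records the bolus support end (min).
    """

    grid: TimeGrid
    Cr: TAC      # Bq/mL, pulmonary artery
    Ca: TAC      # Bq/mL, systemic artery
    L: TAC       # Bq, whole lungs
    l: TAC       # Bq, visible lungs (= alpha * L)
    Cb: TAC      # Bq/g, brain
    kappa: float
    t1: float
    params: KineticParams | None = None

    def __post_init__(self) -> None:
        for name in ("Cr", "Ca", "L", "l", "Cb"):
            tac: TAC = getattr(self, name)
            if len(tac) != self.grid.n_frames:
                raise DataError(f"curve {name} does not match the grid")
            if np.any(tac.values < -1e-12 * max(1.0, tac.values.max(initial=0.0))):
                raise DataError(f"curve {name} has negative values")
        # kappa = 1 is the degenerate no-washout limit (k_lung = 0)
        if not 0 <= self.kappa <= 1:
            raise DataError("kappa must lie in [0, 1]")


@dataclass(frozen=True)
class PlanarPhantom:
    """Synthetic multi-frame planar count image with named ROI masks."""

    frames: np.ndarray                 # (n_frames, ny, nx) counts
    pixel_size: float                  # mm
    roi_masks: dict[str, np.ndarray]   # boolean masks
    grid: TimeGrid
    truth: StudyTACs
    noise: str = "none"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[0] != self.grid.n_frames:
            raise DataError("frames must be (n_frames, ny, nx)")
        if np.any(self.frames < 0):
            raise DataError("counts must be nonnegative")
        pa = self.roi_masks.get("pulmonary_artery")
        br = self.roi_masks.get("brain")
        if pa is not None and br is not None and np.any(pa & br):
            raise DataError("pulmonary_artery and brain masks must be disjoint")


# ---------------------------------------------------------------------------
# bolus

def _bolus_conc(t: np.ndarray, bolus: BolusParams, D: float, P: float) -> np.ndarray:
    """Pulmonary-artery concentration Cr(t) (Bq/mL) of the gamma bolus."""
    u = np.asarray(t, float) - bolus.onset_min
    out = np.zeros_like(u)
    pos = u > 0
    out[pos] = (D / P) * gamma_dist.pdf(u[pos], a=bolus.shape,
                                        scale=bolus.scale_min)
    return out


def gamma_variate_bolus(grid: TimeGrid, bolus: BolusParams,
                        dose: float, cardiac_output: float) -> TAC:
    """Sample the normalised gamma-variate bolus at frame mid-times.

    The pulse is scaled so that ``cardiac_output * ∫Cr dt = dose``, i.e.
    the whole injected dose passes the pulmonary artery.

    Raises
    ------
    ConfigError
        If the dose is not positive (a zero-amplitude bolus cannot be
        normalised) or the bolus support extends past the grid end, which
        would break the "entire dose in the lungs" premise.
    """
    if dose <= 0:
        raise ConfigError("injected dose must be positive")
    if cardiac_output <= 0:
        raise ConfigError("cardiac output must be positive")
    t1 = bolus.support_end()
    if t1 > grid.end_time:
        raise ConfigError(
            f"bolus support ends at {t1:.3g} min, beyond the grid end "
            f"{grid.end_time:.3g} min"
        )
    return TAC(grid.mid_times, _bolus_conc(grid.mid_times, bolus, dose,
                                           cardiac_output), "Bq/mL")


# ---------------------------------------------------------------------------
# lung and brain kinetics

def _lung_content(t: np.ndarray, p: KineticParams) -> np.ndarray:
    """Closed-form L(t) (Bq) for the lung washout ODE driven by the bolus.

    With bolus rate β = 1/scale and washout k, for k < β:

        L(t) = D e^{-k u} (β/(β-k))^a  P(a, (β-k) u),   u = t - onset

    where P is the regularised lower incomplete gamma function.  For
    k ≥ β the same quantity is computed by an exact piecewise-linear
    exponential recursion on a fine grid.
    """
    a = p.bolus.shape
    beta = 1.0 / p.bolus.scale_min
    k = p.k_lung
    u = np.asarray(t, float) - p.bolus.onset_min
    out = np.zeros_like(u)
    pos = u > 0
    if k < beta:
        ratio = (beta / (beta - k)) ** a if k > 0 else 1.0
        out[pos] = (p.D * np.exp(-k * u[pos]) * ratio
                    * special.gammainc(a, (beta - k) * u[pos]))
        return out
    # fast-washout fallback: exact update for piecewise-linear inflow
    tmax = float(np.max(u[pos], initial=0.0)) + p.bolus.onset_min
    fine = np.linspace(0.0, tmax, 20001)
    inflow = p.P * _bolus_conc(fine, p.bolus, p.D, p.P)
    L_fine = _linear_filter(fine, inflow, k)
    out[pos] = np.interp(np.asarray(t, float)[pos], fine, L_fine)
    return out


def _cum_bolus(t: np.ndarray, p: KineticParams) -> np.ndarray:
    """∫₀ᵗ Cr dτ (Bq·min/mL), exact."""
    u = np.asarray(t, float) - p.bolus.onset_min
    out = np.zeros_like(u)
    pos = u > 0
    out[pos] = (p.D / p.P) * special.gammainc(p.bolus.shape,
                                              u[pos] / p.bolus.scale_min)
    return out


def _linear_filter(t: np.ndarray, f: np.ndarray, k: float,
                   gain: float = 1.0) -> np.ndarray:
    """Solve dy/dt = gain·f(t) − k·y, y(0)=0, exactly for piecewise-linear f."""
    y = np.zeros_like(f)
    h = np.diff(t)
    kh = k * h
    with np.errstate(invalid="ignore", divide="ignore"):
        E = np.exp(-kh)
        # ∫0^h e^{-k(h-s)} s/h ds  and  ∫0^h e^{-k(h-s)} (1-s/h) ds
        B = np.where(kh > 1e-8, (kh - (1.0 - E)) / (k * kh), h / 2.0)
        A = np.where(kh > 1e-8, (1.0 - E * (1.0 + kh)) / (k * kh), h / 2.0)
    for n in range(len(h)):
        y[n + 1] = y[n] * E[n] + gain * (A[n] * f[n] + B[n] * f[n + 1])
    return y


def simulate_study(params: KineticParams, grid: TimeGrid,
                   model: str = "microsphere",
                   fine_per_frame: int = 50) -> StudyTACs:
    """Simulate the coupled lung/artery/brain kinetics on a frame grid.

    Frame values are the mid-frame instantaneous quantities.  With
    ``model="microsphere"`` extraction is forced to 1 and brain efflux to
    0, so ``Cb = F λ ∫Ca`` exactly; ``model="one_tissue"`` honours the
    ``E`` and ``k2`` of ``params``.

    Parameters
    ----------
    fine_per_frame : int
        Internal sub-frame resolution used only where a closed form is
        unavailable (the one-tissue brain convolution).
    """
    if model not in ("microsphere", "one_tissue"):
        raise ConfigError(f"unknown model {model!r}")
    t1 = params.bolus.support_end()
    if t1 > grid.end_time:
        raise ConfigError(
            f"bolus support ({t1:.3g} min) exceeds the grid end "
            f"({grid.end_time:.3g} min); the whole dose must enter the lungs "
            "during the acquisition"
        )
    mids = grid.mid_times

    L = _lung_content(mids, params)
    Cr = _bolus_conc(mids, params.bolus, params.D, params.P)
    Ca = params.k_lung * L / params.P
    # Fick's principle: ∫Ca = (P ∫Cr − L)/P, both terms closed-form;
    # clamp the catastrophic-cancellation residue (the k_lung = 0 limit
    # has ∫Ca identically zero)
    if params.k_lung == 0.0:
        cum_ca = np.zeros_like(L)
    else:
        cum_ca = np.maximum(
            (_cum_bolus(mids, params) * params.P - L) / params.P, 0.0)

    if model == "microsphere" or params.k2 == 0.0:
        eff = 1.0 if model == "microsphere" else params.E
        Cb = eff * params.F * params.lambda_lipo * cum_ca
    else:
        # one-tissue brain: exponential convolution on a fine grid
        h_fine = float(np.min(grid.frame_duration)) / fine_per_frame
        for name, rate in (("k2", params.k2), ("k_lung", params.k_lung)):
            if rate * h_fine > 0.1:
                raise ConfigError(
                    f"rate {name}={rate:.3g}/min too fast for the internal "
                    f"step {h_fine:.3g} min; increase fine_per_frame"
                )
        fine = np.linspace(0.0, grid.end_time,
                           fine_per_frame * grid.n_frames + 1)
        Ca_fine = params.k_lung * _lung_content(fine, params) / params.P
        Cb_fine = _linear_filter(fine, Ca_fine, params.k2,
                                 gain=params.E * params.F * params.lambda_lipo)
        Cb = np.interp(mids, fine, Cb_fine)

    kappa = float(L[-1] / params.D)
    return StudyTACs(
        grid=grid,
        Cr=TAC(mids, Cr, "Bq/mL"),
        Ca=TAC(mids, Ca, "Bq/mL"),
        L=TAC(mids, L, "Bq"),
        l=TAC(mids, params.alpha * L, "Bq"),
        Cb=TAC(mids, Cb, "Bq/g"),
        kappa=kappa,
        t1=t1,
        params=params,
    )


# ---------------------------------------------------------------------------
# phantom rendering

#: default planar pixel pitch of the gamma camera, mm
DEFAULT_PIXEL_MM = 4.4181


def _ellipse(shape: tuple[int, int], center: tuple[float, float],
             radii: tuple[float, float]) -> np.ndarray:
    ii, jj = np.mgrid[0:shape[0], 0:shape[1]]
    return (((ii - center[0]) / radii[0]) ** 2
            + ((jj - center[1]) / radii[1]) ** 2) <= 1.0


def default_roi_masks(shape: tuple[int, int] = (128, 128)) -> dict[str, np.ndarray]:
    """Fixed elliptical ROI masks: brain (top), two lungs, PA trunk between.

    Geometry is schematic — only the ROI sums matter downstream — but the
    three masks are pairwise disjoint as extraction requires.
    """
    ny, nx = shape
    brain = _ellipse(shape, (0.16 * ny, 0.50 * nx), (0.11 * ny, 0.14 * nx))
    lung_r = _ellipse(shape, (0.61 * ny, 0.31 * nx), (0.17 * ny, 0.125 * nx))
    lung_l = _ellipse(shape, (0.61 * ny, 0.69 * nx), (0.17 * ny, 0.125 * nx))
    pa = _ellipse(shape, (0.52 * ny, 0.50 * nx), (0.03 * ny, 0.025 * nx))
    lungs = (lung_r | lung_l) & ~pa
    return {"pulmonary_artery": pa & ~brain, "brain": brain, "lungs": lungs}


def render_phantom(study: StudyTACs, params: KineticParams,
                   noise: str = "none", seed: int | None = None,
                   shape: tuple[int, int] = (128, 128),
                   roi_masks: dict[str, np.ndarray] | None = None,
                   pixel_size: float = DEFAULT_PIXEL_MM) -> PlanarPhantom:
    """Render a dynamic planar count-image stack from simulated curves.

    Expected ROI counts per frame are ``calib × quantity × Δt``; the PA
    ROI additionally receives ``scatter_frac`` of the lung-ROI counts
    (scatter contamination).  Counts are spread uniformly over the mask
    pixels.  With ``noise="poisson"`` each pixel is an independent
    Poisson draw from a generator seeded by ``seed``; with ``"none"``
    the expected (float) counts are stored so the noiseless round trip
    is exact.
    """
    if noise not in ("none", "poisson"):
        raise ConfigError(f"unknown noise model {noise!r}")
    if roi_masks is None:
        roi_masks = default_roi_masks(shape)
    grid = study.grid
    dt = grid.frame_duration  # (n_frames,)
    c = params.calib

    lung_counts = c.c_l * study.l.values * dt
    expected = {
        "pulmonary_artery": c.c_r * study.Cr.values * dt
        + params.scatter_frac * lung_counts,
        "brain": c.c_b * study.Cb.values * dt,
        "lungs": lung_counts,
    }
    for name, ex in expected.items():
        if np.any(ex < 0):
            raise DataError(f"negative expected counts in ROI {name}")
        if np.any(ex > 2 ** 53):
            raise DataError(f"expected counts overflow in ROI {name}")

    frames = np.zeros((grid.n_frames,) + tuple(shape), dtype=float)
    rng = np.random.default_rng(seed)
    for name, ex in expected.items():
        mask = roi_masks[name]
        npix = int(mask.sum())
        if npix == 0:
            raise DataError(f"ROI mask {name} is empty")
        per_pix = ex / npix  # (n_frames,)
        if noise == "poisson":
            block = rng.poisson(np.broadcast_to(per_pix[:, None],
                                                (grid.n_frames, npix)))
            frames[:, mask] = block
        else:
            frames[:, mask] = per_pix[:, None]
    if noise == "poisson":
        frames = frames.astype(np.int64)

    return PlanarPhantom(frames=frames, pixel_size=pixel_size,
                         roi_masks=dict(roi_masks), grid=grid, truth=study,
                         noise=noise, seed=seed)
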