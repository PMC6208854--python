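"""End-to-end study orchestration.

``run_study`` takes one configuration — a simulated phantom, a phantom
on disk, or pre-extracted TAC CSV — and runs the clinical analysis
chain in protocol order: ROI extraction, low-pass smoothing, time-zero
adjustment, graphical plot, linear-section fit.  ``compare_methods``
correlates two result fields across a batch the way method-comparison
studies do (Pearson r with the exact t-transform p-value, plus the
inter-method regression and identity-line residuals).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
from scipy import stats

from . import io as iomod
from .quantify import (DEFAULT_LAMBDA, estimate_alpha_P, fit_linear_section,
                       gp_points, gp_terminal_index, gp_to_cbf_exact,
                       cbf_plot_points)
from .simulate import (KineticParams, PlanarPhantom, render_phantom,
                       simulate_study)
from .tacs import (calibrate_tac, cumulative_integral, extract_roi_tac,
                   lowpass_smooth, time_zero_adjust)
from .types import TAC, ConfigError, DataError, TimeGrid

__all__ = [
    "ProcessOptions", "FitOptions", "StudyConfig", "StudyResult",
    "ComparisonReport", "run_study", "compare_methods",
    "estimate_bolus_end",
]

logger = logging.getLogger("impflow")


@dataclass(frozen=True)
class ProcessOptions:
    """TAC conditioning knobs (protocol order: smooth, then zero-adjust)."""

    smooth_window: int = 3
    onset_frac: float = 0.05


@dataclass(frozen=True)
class FitOptions:
    lambda_lipo: float = DEFAULT_LAMBDA
    strategy: str = "auto"
    window: tuple[int, int] | None = None
    r2_threshold: float = 0.99
    min_points: int = 5


@dataclass(frozen=True)
class StudyConfig:
    """One study: exactly one input source plus processing options.

    Sources (mutually exclusive): ``simulate`` (kinetic parameters for a
    synthetic study), ``phantom`` (path stem of a phantom on disk),
    ``tacs`` (path of a TAC CSV with Cr/Cb/l columns or calibrated
    equivalents).
    """

    study_id: str = "study"
    simulate: KineticParams | None = None
    model: str = "one_tissue"
    noise: str = "none"
    seed: int | None = None
    n_frames: int = 60
    frame_s: float = 2.0
    phantom: str | None = None
    tacs: str | None = None
    process: ProcessOptions = field(default_factory=ProcessOptions)
    fit: FitOptions = field(default_factory=FitOptions)

    def __post_init__(self) -> None:
        sources = [s is not None for s in (self.simulate, self.phantom,
                                           self.tacs)]
        if sum(sources) != 1:
            raise ConfigError(
                "config must name exactly one input source: simulate "
                "parameters, a phantom stem, or a TAC CSV"
            )

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "StudyConfig":
        d = dict(d)
        try:
            if isinstance(d.get("simulate"), Mapping):
                d["simulate"] = iomod.params_from_dict(d["simulate"])
            if isinstance(d.get("process"), Mapping):
                d["process"] = ProcessOptions(**d["process"])
            if isinstance(d.get("fit"), Mapping):
                fd = dict(d["fit"])
                if fd.get("window") is not None:
                    fd["window"] = tuple(fd["window"])
                d["fit"] = FitOptions(**fd)
            return cls(**d)
        except TypeError as err:
            raise ConfigError(f"bad config: {err}") from err


@dataclass(frozen=True)
class StudyResult:
    """Scalar outputs of one study, traceable to the underlying fits."""

    study_id: str
    F_graphical: float            # slope of the CBF plot (mL/g/min or relative)
    intercept: float
    r2: float
    window: tuple[int, int]
    alphaP_estimate: float | None
    F_gp_index: float | None     # fitted GP-plot slope
    F_gp_terminal: float | None  # terminal-uptake GP index (needs P, D)
    kappa: float | None          # terminal lung fraction, if truth known
    F_gp_corrected: float | None  # F_gp_terminal / (1 - kappa)
    truth_F: float | None
    calibration_mode: str        # "calibrated" | "relative"
    parameters: dict             # every default that fired

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ComparisonReport:
    """Pearson correlation between two result fields across a batch."""

    n: int
    field_a: str
    field_b: str
    pearson_r: float
    p_value: float
    slope: float
    intercept: float
    identity_bias: float   # mean(a - b)
    identity_rmsd: float   # rms(a - b)
    table: list[dict]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def estimate_bolus_end(cr: TAC, mass_frac: float = 0.99) -> float:
    """Time by which ``mass_frac`` of the pulmonary-artery bolus has passed.

    Used to anchor the auto linear-window search: the plot can only be
    linear once the bolus term has stopped growing.
    """
    cum = cumulative_integral(cr).values
    total = cum[-1]
    if total <= 0:
        raise DataError("Cr integral is nonpositive; no bolus present")
    return float(cr.times[np.searchsorted(cum, mass_frac * total)])


def _load_curves(config: StudyConfig) -> tuple[dict[str, TAC], str, dict]:
    """Resolve the input source to (curves, calibration_mode, context).

    Curves are named Cr, Cb, l (physical units in calibrated mode).
    Context carries truth values (kappa, F, P, D, t1) where known.
    """
    ctx: dict[str, Any] = {}
    if config.simulate is not None:
        params = config.simulate
        grid = TimeGrid.default(config.n_frames, config.frame_s)
        study = simulate_study(params, grid, model=config.model)
        phantom = render_phantom(study, params, noise=config.noise,
                                 seed=config.seed)
        curves = _curves_from_phantom(phantom, params)
        ctx.update(kappa=study.kappa, truth_F=params.F, P=params.P,
                   D=params.D, t1=study.t1)
        return curves, "calibrated", ctx
    if config.phantom is not None:
        phantom = iomod.read_phantom(config.phantom)
        params = phantom.truth.params
        curves = _curves_from_phantom(phantom, params)
        ctx.update(kappa=phantom.truth.kappa, truth_F=params.F, P=params.P,
                   D=params.D, t1=phantom.truth.t1)
        return curves, "calibrated", ctx
    tacs = iomod.read_tacs(config.tacs)
    name_map = {"Cr": ("Cr", "pulmonary_artery"), "Cb": ("Cb", "brain"),
                "l": ("l", "lungs")}
    curves = {}
    for target, aliases in name_map.items():
        for alias in aliases:
            if alias in tacs:
                curves[target] = tacs[alias]
                break
        else:
            raise DataError(
                f"TAC file {config.tacs} lacks a {target} curve "
                f"(accepted column names: {aliases})"
            )
    physical = all(curves[k].unit != "counts" and curves[k].unit !=
                   "dimensionless" for k in curves)
    return curves, ("calibrated" if physical else "relative"), ctx


def _curves_from_phantom(phantom: PlanarPhantom,
                         params: KineticParams) -> dict[str, TAC]:
    dt = phantom.grid.frame_duration
    c = params.calib
    return {
        "Cr": calibrate_tac(extract_roi_tac(phantom, "pulmonary_artery"),
                            c.c_r, dt, "Bq/mL"),
        "Cb": calibrate_tac(extract_roi_tac(phantom, "brain"),
                            c.c_b, dt, "Bq/g"),
        "l": calibrate_tac(extract_roi_tac(phantom, "lungs"),
                           c.c_l, dt, "Bq"),
    }


def run_study(config: StudyConfig, outdir: str | Path | None = None) -> StudyResult:
    """Run the full analysis chain for one study.

    Deterministic for a fixed config and seed.  If ``outdir`` is given,
    the smoothed curves, plot series and fit report are written there.
    """
    curves, calib_mode, ctx = _load_curves(config)
    popt, fopt = config.process, config.fit

    smoothed = {k: lowpass_smooth(v, popt.smooth_window)
                for k, v in curves.items()}
    adjusted = time_zero_adjust(
        {"pulmonary_artery": smoothed["Cr"], "brain": smoothed["Cb"],
         "lungs": smoothed["l"]},
        onset_frac=popt.onset_frac)
    cr = adjusted.tacs["pulmonary_artery"]
    cb = adjusted.tacs["brain"]
    lung = adjusted.tacs["lungs"]
    logger.info("%s: onset frame %d (offset %.4g min)", config.study_id,
                adjusted.onset_index, adjusted.offset_min)

    points = cbf_plot_points(cr, cb, lung, lambda_lipo=fopt.lambda_lipo)
    bolus_end = estimate_bolus_end(cr)
    try:
        fit = fit_linear_section(points, strategy=fopt.strategy,
                                 window=fopt.window,
                                 r2_threshold=fopt.r2_threshold,
                                 min_points=fopt.min_points,
                                 min_start_time=(bolus_end
                                                 if fopt.strategy == "auto"
                                                 else None))
    except DataError as err:
        if fopt.strategy != "auto":
            raise
        # no window reaches the r2 threshold (e.g. scatter-contaminated
        # Cr curves the plot); fall back to the trailing half of the plot
        n = len(points)
        fit = fit_linear_section(points, strategy="fixed_window",
                                 window=(n // 2, n - 1))
        logger.warning("%s: auto window failed (%s); fitted trailing half "
                       "(r2=%.4f)", config.study_id, err, fit.r2)
    try:
        alphaP = estimate_alpha_P(fit)
    except DataError:
        alphaP = None
        logger.warning("%s: nonnegative intercept; alphaP not estimated",
                       config.study_id)

    # GP comparator: usable only while Cr is appreciable
    f_gp_index = None
    try:
        gp = gp_points(cr, cb)
        try:
            gp_fit = fit_linear_section(gp, strategy="auto",
                                        r2_threshold=fopt.r2_threshold,
                                        min_points=fopt.min_points)
        except DataError:
            gp_fit = fit_linear_section(gp, strategy="fixed_window",
                                        window=(0, len(gp) - 1))
        f_gp_index = gp_fit.slope
    except DataError as err:
        logger.warning("%s: GP plot unavailable (%s)", config.study_id, err)

    f_gp_term = kappa = f_gp_corr = None
    if {"P", "D"} <= ctx.keys():
        f_gp_term = gp_terminal_index(float(cb.values[-1]), ctx["P"],
                                      ctx["D"], fopt.lambda_lipo)
        if "kappa" in ctx:
            kappa = ctx["kappa"]
            f_gp_corr = gp_to_cbf_exact(f_gp_term, kappa)

    result = StudyResult(
        study_id=config.study_id,
        F_graphical=fit.slope,
        intercept=fit.intercept,
        r2=fit.r2,
        window=fit.window,
        alphaP_estimate=alphaP,
        F_gp_index=f_gp_index,
        F_gp_terminal=f_gp_term,
        kappa=kappa,
        F_gp_corrected=f_gp_corr,
        truth_F=ctx.get("truth_F"),
        calibration_mode=calib_mode,
        parameters={
            "smooth_window": popt.smooth_window,
            "onset_frac": popt.onset_frac,
            "onset_index": adjusted.onset_index,
            "offset_min": adjusted.offset_min,
            "lambda": fopt.lambda_lipo,
            "fit_strategy": fopt.strategy,
            "r2_threshold": fopt.r2_threshold,
            "min_points": fopt.min_points,
            "bolus_end_min": bolus_end,
            "seed": config.seed,
            "noise": config.noise,
        },
    )
    if outdir is not None:
        _write_artifacts(result, points, fit, smoothed, Path(outdir))
    return result


def _write_artifacts(result: StudyResult, points, fit, smoothed,
                     outdir: Path) -> None:
    import pandas as pd

    outdir.mkdir(parents=True, exist_ok=True)
    sid = result.study_id
    for name, tac in smoothed.items():
        iomod.write_tac_csv(tac, outdir / f"{sid}_smoothed_{name}.csv")
    in_window = ((points.frame_indices >= fit.window[0])
                 & (points.frame_indices <= fit.window[1]))
    pd.DataFrame({"x": points.x, "y": points.y, "time_min": points.times,
                  "in_window": in_window.astype(int)}
                 ).to_csv(outdir / f"{sid}_plot.csv", index=False,
                          float_format="%.17g")
    report = {"method": "graphical", "provenance": result.parameters,
              **{k: v for k, v in result.to_dict().items()
                 if k != "parameters"}}
    iomod.write_json(report, outdir / f"{sid}_fit.json")


def compare_methods(results: Sequence[StudyResult], field_a: str,
                    field_b: str) -> ComparisonReport:
    """Correlate two scalar fields across a batch of study results.

    Pearson r with the exact t-transform p-value (n − 2 degrees of
    freedom), the ordinary regression of b on a, and identity-line
    residual summaries.
    """
    pairs = []
    table = []
    for r in results:
        a, b = getattr(r, field_a), getattr(r, field_b)
        if a is None or b is None or not (np.isfinite(a) and np.isfinite(b)):
            logger.warning("%s: missing %s/%s; excluded from comparison",
                           r.study_id, field_a, field_b)
            continue
        pairs.append((float(a), float(b)))
        table.append({"study_id": r.study_id, field_a: float(a),
                      field_b: float(b)})
    if len(pairs) < 3:
        raise DataError(f"need >= 3 paired values, got {len(pairs)}")
    a, b = np.array(pairs).T
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DataError("zero variance in one of the compared fields")
    pres = stats.pearsonr(a, b)
    reg = stats.linregress(a, b)
    diff = a - b
    return ComparisonReport(
        n=len(pairs), field_a=field_a, field_b=field_b,
        pearson_r=float(pres.statistic), p_value=float(pres.pvalue),
        slope=float(reg.slope), intercept=float(reg.intercept),
        identity_bias=float(diff.mean()),
        identity_rmsd=float(np.sqrt((diff ** 2).mean())),
        table=table,
    )
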