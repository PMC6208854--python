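# Methods

## Model

The package models a dynamic planar ¹²³I-IMP study as three coupled
linear stages driven by a bolus injection:

1. **Pulmonary-artery input.** The concentration in the pulmonary
   artery trunk is a gamma-variate pulse
   `Cr(t) = (D/P) · Γpdf(t − t₀; a, s)`, normalised so the whole
   injected dose passes the artery: `P ∫Cr = D`. The pulse has compact
   effective support; its recorded end `T1` is the time by which all but
   a 10⁻⁶ mass fraction has passed. A simulation whose bolus support
   exceeds the acquisition is rejected, because the method's algebra
   assumes the entire dose reaches the lungs during the scan.
2. **Lungs.** First-pass endothelial trapping followed by monoexponential
   washout: `dL/dt = P·Cr − k_lung·L`, with the systemic arterial
   concentration `Ca = k_lung·L/P`. Fick's principle
   `L = P(∫Cr − ∫Ca)` then holds identically.
3. **Brain.** One-tissue kinetics
   `dCb/dt = E·F·λ·Ca − k2·Cb`. The *microsphere* model is the special
   case `E = 1, k2 = 0`, giving `Cb = Fλ∫Ca`; it is the regime the
   graphical method assumes and is a good approximation for ¹²³I-IMP
   over the first two minutes (extraction near 1, distribution volume
   ≈ 30 mL/g so efflux is second-order early on).

The estimator plots `Cb/(λl)` against `∫Cr/l` (with `l = αL` the
visible-lung curve) and reads CBF off the slope of the linear section;
the intercept `−F/(αP)` yields the visible cardiac output `αP`.

## Parameters

| parameter | meaning | unit | default | rationale |
|---|---|---|---|---|
| `F` | cerebral blood flow | mL/g/min | 0.4 | normal grey/white average |
| `P` | right-ventricular cardiac output | mL/min | 5000 | normal adult |
| `lambda_lipo` | lipophilic tracer fraction | – | 0.8 | octanol-extraction value; treated as constant |
| `alpha` | visible lung fraction | – | 0.5 | planar camera sees roughly half the lung volume |
| `k_lung` | lung washout rate | 1/min | 0.15 | mid-range; clinically highly variable (the point of the method) |
| `E`, `k2` | extraction, brain efflux | –, 1/min | 1, 0 | microsphere regime; `k2 = EFλ/30` reproduces a distribution volume of 30 |
| `D` | injected dose | Bq | 222 MBq | standard clinical activity |
| bolus | gamma-variate (onset, shape, scale) | min | (0.1, 3, 0.05) | IV bolus dispersed over ~20 s of pulmonary transit |
| grid | frame timing | – | 60 × 2 s | standard dynamic planar protocol |
| `calib` | counts per physical unit per ROI | see docstring | PA peak ≈ 4×10³, lungs ≈ 2×10⁴, brain ≈ 5×10³ counts/frame | clinically plausible planar count levels |
| `scatter_frac` | lung counts leaking into PA ROI | – | 0 | bias experiments use 0.05 |

Processing defaults: moving-average smoothing window 3 frames, bolus
onset threshold 5% of the pulmonary-artery peak, automatic linear
window at r² ≥ 0.99 with ≥ 5 points. All are exposed in
`ProcessOptions`/`FitOptions` and echoed in every report.

## Numerical choices

* **Closed-form kinetics.** The lung ODE driven by a gamma-variate has
  the closed form `L(t) = D e^{-ku}(β/(β−k))^a P(a, (β−k)u)` (regularised
  lower incomplete gamma, `β = 1/scale`, `u = t − onset`), valid for
  `k_lung < β`; the cumulated arterial input follows exactly from
  Fick's principle, so microsphere simulations carry no solver error.
  For `k_lung ≥ β` (washout faster than the bolus) and for the
  one-tissue brain convolution, an exact piecewise-linear exponential
  update is used on a 50×-per-frame internal grid.
* **Frame semantics.** Frame values are mid-frame instantaneous
  quantities; rendered counts are `calib × quantity × Δt`. This makes
  the noiseless render → extract → calibrate round trip exact.
* **Integration.** Running integrals use the trapezoid rule with an
  implicit `(t = 0, 0)` anchor (activity is zero before injection).
  At 2 s frames the default bolus integrates to ~7×10⁻⁴ relative error,
  which bounds the quadrature contribution to the slope.
* **Degenerate inputs.** `k_lung = 0` gives `Ca ≡ 0`, `κ = 1` exactly
  (clamped cancellation noise); a flat reference curve, an all-zero
  lung curve, zero-variance abscissa and a nonnegative intercept are
  all rejected with specific errors.
* **κ convention.** κ is the lung dose fraction at the *last frame*
  (two minutes), and the terminal GP index is evaluated at the same
  instant, so the identity `F = F_GP/(1 − κ)` is exact at any
  post-bolus time, not only asymptotically.
* **λ convention.** The terminal GP index is defined as
  `Cb·P/(λD)` — the same λ that appears in the flow equation — so the
  κ correction recovers `F` itself rather than `λF`. The GP *plot*
  (`Cb/Cr` vs `∫Cr/Cr`) is kept λ-free, as that method is conventionally
  stated; only the index used in the exact correction carries λ.
* **Window selection.** "Auto" picks the longest trailing window with
  r² ≥ 0.99 (≥ 5 points) starting no earlier than the estimated bolus
  end (99% of the Cr mass). Among equal-length candidates the
  later-starting wins — later frames are deeper in the linear regime.
  If no window qualifies (e.g. scatter-contaminated input curves the
  plot), the pipeline fits the trailing half of the plot and logs a
  warning; least squares is unweighted throughout, matching a
  plot-and-read-the-slope analysis.
* **Calibration modes.** Cross-ROI conversion of planar counts to
  absolute units (Bq/mL artery vs Bq lungs vs Bq/g brain, with
  different attenuation paths) is not derivable from the data, so
  results are flagged `calibrated` only when per-ROI factors are known
  (simulator truth or user-supplied); otherwise the slope is reported
  as a `relative` index.

## What the simulator does and does not emulate

It emulates: bolus dispersion, lung trapping/washout, flow-proportional
brain uptake with optional incomplete extraction and efflux, per-ROI
calibration, Poisson counting noise at clinical levels, and a uniform
scatter leak from the lung ROI into the pulmonary-artery ROI
(`scatter_frac` is a fraction of lung *counts*, so its severity scales
with the lung/PA calibration ratio — at the defaults, 5% leakage is a
severe contamination and collapses the fitted slope).

It does not emulate: anatomically realistic geometry (masks are
schematic ellipses; only ROI sums matter), attenuation and collimator
response, patient motion, recirculation of the tracer, time-varying
lipophilic fraction, or heterogeneous lung disease. Passing recovery
tests therefore demonstrates correctness of the estimator's
mathematics and its noise behaviour, not robustness to every clinical
confounder — in particular absolute accuracy on real planar data still
hinges on the unresolved cross-ROI calibration/attenuation question.

## Validation problem sizes

The acceptance script and test suite use the fixture protocol
(60 × 2 s frames; 3 min where a later time point is probed), a 3 × 3
flow × lung-visibility grid, four washout rates spanning κ ≈ 0.11–0.62,
a 500-replicate Poisson Monte-Carlo on 128 × 128 phantoms, and 10×
temporal refinement for oracle comparisons. These sizes make every
check sharp (Monte-Carlo standard error ≈ 0.08% of F) while keeping a
full run in the tens of seconds.

## Known limitations

* The linear-section choice is heuristic; very fast washout shortens
  the usable post-bolus section at two minutes.
* `estimate_bolus_end` assumes the pulmonary-artery curve returns to
  (near) baseline; a strong persistent pedestal defeats it and triggers
  the trailing-half fallback.
* The comparison operations treat each study as one scalar pair; slice
  semantics of regional maps are the caller's concern.
* Decay correction is omitted: ¹²³I decay over two minutes is ~0.25%
  and cancels in the ratios.
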