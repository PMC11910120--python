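# Methods

## The measurement model

The method images indicator-doped hydrogel columns in glass vials while the
water above them is gassed with CO₂.  Dissolved CO₂ hydrates to carbonic
acid, which dissociates and releases protons; bromothymol blue (pKa ≈ 7.1)
captures them and flips from its blue (deprotonated) to its yellow
(protonated) form.  The visible blue/yellow interface is a moving iso-pH
surface, and its depth below the reference position is the measured signal.

Two kinetic quantities are derived at every usable timepoint:

- interface velocity `Vᵢ = |x₀ − xₜ| / t` (m/s), and
- pseudo diffusion coefficient `D_pseudo = (x₀ − xₜ)² / (2t)` (m²/s).

`D_pseudo` is *pseudo* because the front is a threshold on a concentration
profile, not a tracer displacement; it is a comparative figure of merit
between gels, not an absolute effective diffusivity.  For a front that
follows `depth = sqrt(2 D t)` exactly, the per-time coefficient is constant;
for the concave-in-√t trajectories seen late in real measurements (front
slows as the reservoir gradient flattens and the gel bottom nears), the
per-time coefficient decreases with time.

The reference `x₀` is taken from a pre-gassing frame acquired at t = 0.
When that frame shows no detectable interface — the normal case, since the
gel is uniformly blue before gassing — `x₀` falls back to the known gel
surface row.  Displacement is defined as `(row − x₀)·mm_per_px` with
downward motion positive; apparent upward motion is flagged rather than
silently negated.

Replicates are aggregated in two stages: mean of the per-time coefficients
within a vial, then mean ± sample standard deviation (n−1) across vials.
The porosity estimate `θ = (wet − dry)/wet` operates on weights and is
labelled gravimetric accordingly.

## Carbonate chemistry

Speciation solves the proton charge balance

    [H⁺] + [BH⁺] + Z = [HCO₃⁻] + 2[CO₃²⁻] + [OH⁻]

for a given dissolved-CO₂ level, by a bracketed root search (Brent) on
[10⁻¹⁴, 1] mol/L at near-machine tolerance; the right-hand side is strictly
decreasing in [H⁺], so the positive root is unique.  Defaults are handbook
constants: Ka1 = 4.45·10⁻⁷, Ka2 = 4.69·10⁻¹¹, Kw = 10⁻¹⁴ mol²/L².  The
second dissociation contributes ~10⁻⁴ pH units at millimolar CO₂ and is off
by default.  `[BH⁺]` is an optional immobile weak-base buffer
(`EquilibriumSystem.buffered()` models a gel activated with ~24 mM TRIS,
pKa 8.07, counter-ion charge `Z` solved so the CO₂-free gel sits at pH 8.0).
The buffer matters for the forward model: plain CO₂-in-water never rises
above pH 7, so an unbuffered column could not host a bromothymol-blue front
at all.  Activity corrections, ionic strength and temperature dependence are
out of scope.

## Forward models for front motion

Two generators drive the synthetic benchmark:

1. **Square-root law** — depth `= sqrt(2 D_pseudo t)`, the exact inverse of
   the pseudo-diffusion definition.  Used for parameter-recovery benchmarks,
   because the quantity the pipeline should recover is, by construction, the
   generator input.
2. **Diffusion + chemistry** — a semi-infinite 1-D diffusion model (closed
   form `c = c₀·erfc(x / 2√(Dt))`, plus an explicit FTCS finite-difference
   solver with Dirichlet top / zero-flux bottom for finite domains) whose
   concentration field is speciated node by node; the front is the
   interpolated depth where pH crosses the indicator pKa.  Under the erfc
   profile that depth is proportional to √t exactly (similarity variable),
   and it deepens with the boundary concentration c₀ — the qualitative
   Fick-compliance property the benchmark asserts.  The FTCS stability bound
   `dt ≤ dx²/(2D)` is enforced with an error that names the admissible step.
   Reaction consumption of CO₂ by dye and buffer is neglected (the dye is
   micromolar; the buffer shifts, but does not arrest, the front).

The boundary concentration c₀ defaults to 0.033 mol/L (CO₂ solubility near
1 atm, 25 °C) and is a nominal free parameter: the partial pressure actually
reaching the gel surface is not identifiable from the published protocol.

## Synthetic image generator

The renderer emulates the optical path of the acquisition rig: a backlit
vial with a water band whose meniscus drops by 0.5 mm/h (evaporation), a gel
column rendered row by row, a yellow filter foil that multiplies the blue
channel by (1 − strength), a small vertical illumination gradient, and
additive Gaussian sensor noise (sd 0.02 of full scale, clipped), applied in
that order.  Geometry defaults model the published rig: 6 mm inner-diameter
vials, 150 µL gel ⇒ 5.3 mm column, 0.0681 mm/px.

Gel rows mix the indicator's acid and base colours with a logistic weight in
`(row_depth − front_depth)`; the logistic scale is `transition_width / 6`,
so one transition width (default 0.4 mm ≈ 6 px) spans the 5–95% mix range.
`front_depth = 0` and `front_depth = gel_height` render exactly uniform
base- and acid-coloured columns.  Fronts beyond the gel bottom are clamped
and flagged in the ground truth.  All randomness flows from a single seed;
per-vial noise streams in composites are spawned deterministically, so equal
configurations give bit-identical output.

Colours (blue ≈ (0.10, 0.35, 0.70), yellow ≈ (0.92, 0.85, 0.15)) and the
filter strength are nominal.  The default strength 0.76 is a deliberate
calibration: it places the Otsu boundary between the two filtered colours in
saturation space at the 50/50-mix row, making the rendered front and the
detected front agree to within pixel quantization.  The generator reproduces
what the detection pipeline must cope with — it does **not** model lens
distortion beyond a user-suppliable homography, hydrodynamic fingering
(absent in gels), radiometric camera response, or the preparative
variability of real replicates.  Passing recovery benchmarks therefore shows
the *pipeline* is unbiased under realistic optics and noise, not that real
gels have the nominal coefficients.

## Detection pipeline

Per frame and vial: projective rectification (inverse-homography warp,
bilinear; identity is a no-op) → ROI crop of the gel column → HSV saturation
`S = (max − min)/max` (ratio-based, hence invariant to uniform brightness
scaling) → Otsu binarization → per-row foreground fraction, moving-average
smoothed (5-row window, truncated at edges) → topmost crossing of the 0.5
level scanning down from the gel surface, linearly interpolated between the
bracketing rows.

Numerical choices worth recording:

- **Otsu on exact values.** The threshold maximizes between-class variance
  over cuts between consecutive distinct values rather than over a 256-bin
  histogram; on near-noise-free frames, binned histograms let the threshold
  snap unpredictably inside the inter-mode gap (≈ ±1 px localization
  wobble).  Ties are broken by the middle of the maximizing range.
- **Contrast guards.** A constant image cannot be thresholded
  (`no_interface`).  Additionally, frames whose two Otsu classes are closer
  than `min_contrast` (default 0.2) in mean saturation — uniformly blue
  pre-gassing frames, or fully converted gels where only noise is split —
  are flagged `no_interface` instead of yielding spurious crossings.  The
  same value guards the profile range before crossing detection.
- **Quantization limit.** With zero noise every row is uniform, the binary
  profile is a step, and the interpolated crossing is quantized to
  half-integer rows; localization error is bounded by half a pixel plus a
  small (< 0.1 px) threshold wobble.  On a 0.25 mm depth grid the maximum
  error with the frozen defaults is 0.38 px.  With the default 2% noise the
  profile ramp carries genuine sub-pixel information and typical errors are
  below 0.15 px.
- **Flags, not exceptions.** Missing interfaces propagate as per-point
  flags; the analysis stage excludes flagged points and t = 0, and requires
  at least two usable points.

Near the gel bottom (front within about a transition width of the column
end) the blue class vanishes and localization degrades; the class-separation
guard flags such frames, which is why agarose-like runs effectively use the
300–1200 s frames — mirroring the real measurement, where the agarose gel
had essentially converted within the hour.

## Benchmark conditions

Parameter-recovery runs use the published acquisition protocol: 10 vials,
frames at 0, 300, …, 3600 s, noise sd 0.02, default geometry, with the
tabulated agarose-like (11.55·10⁻⁹ m²/s) and silica-like (0.34·10⁻⁹ m²/s)
coefficients as generator inputs.  The Fick-compliance ladder uses the
diffusion+chemistry generator at c₀ ∈ {0.008, 0.017, 0.033, 0.066} mol/L
with frames to 900 s (keeping all fronts inside the gel).  These sizes run
in seconds on one CPU; they are the package's chosen benchmark scale, and
the recovered quantities are computed, never asserted.

## Known limitations

- `D_pseudo` depends on the indicator threshold and gel buffering; absolute
  transport coefficients require a reaction–diffusion treatment that is out
  of scope.
- Only projective rectification is supported; radial lens distortion must be
  corrected upstream or absorbed into the homography.
- One front per vial: multi-front situations report the topmost crossing
  with a multiplicity count, nothing more.
- The gravimetric porosity treats weights as volume proxies (unit gel
  density), as the underlying protocol does.
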