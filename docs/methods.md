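# Methods

This note documents the models implemented in `filaquant`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a user should know before trusting a
number.

## Cell-image pipeline

### Synthetic micrographs

`simulate.generate_cell_image` emulates a two-channel high-content field of
transfected cells expressing a fluorescently tagged filament-forming
enzyme. Nuclei are bright discs (radius 3–4.5 µm) in the nuclear channel;
the reporter channel carries, per cell, either filament-like objects —
thick quadratic-Bézier polylines, length 8–16 µm, thickness 0.6–1.0 µm,
gentle outward curvature, confined to the cytoplasmic annulus — or small
puncta (discs of 0.6–1.2 µm, 3–8 per cell), plus a faint nuclear ghost
(30% of signal) standing in for diffuse reporter that makes nuclei visible
in the transfection channel. Gaussian read noise (default sd 0.02 on a
signal of 1.0) is added last. The default pixel size is 0.3 µm/px (typical
20× high-content sampling), making the 10 µm perimeter threshold ≈ 33 px.

Cells sit on a jittered grid whose pitch is at least twice the cell extent
(default 15 µm), so cells never overlap and segmentation is identifiable;
an impossible density raises an error rather than degrading silently.
Exactly `round-half-up(n_cells × frac_filamented)` cells are filamented,
which makes label counts testable without tolerance. Each image in a set
draws from its own RNG stream derived from `(seed, image index)`, so
subsets regenerate identically in any order.

What the generator does **not** emulate: optics (no point-spread function,
so object edges are sharp), photobleaching, 3D structure, touching or
overlapping cells, intensity heterogeneity between cells, and real
object-size distributions — object geometry ranges are free parameters, not
calibrated to any measured data. Passing recovery tests therefore shows the
pipeline is correct and well-conditioned on clean geometry, not that it
matches the error rates to be expected on real micrographs.

### Segmentation

Nuclei are detected on the sum of the two percentile-rescaled channels
(1st/99.5th percentiles — a fixed, image-derived rule so the "consistent
contrast adjustment" is reproducible), Gaussian-blurred with σ = 3 px. The
blurred sum of a transfected field is trimodal — background, blurred
cytoplasmic structures, nuclei — and a plain Otsu cut admits filament
remnants as spurious nuclei; the nucleus threshold is therefore the upper
cut of a three-class multi-Otsu (nuclei are the brightest class), falling
back to Otsu for images with too few grey levels. Components under
`min_nucleus_area` (50 px²) are dropped; nuclei are 8-connected.

Cytoplasms grow from nucleus labels by nearest-seed expansion
(`skimage.segmentation.expand_labels`) to a radius of 25 µm; contested
pixels join the nearest nucleus. The cytoplasm excludes the nucleus
*dilated by 6 px* (≈ 2σ of the detection blur): the detected nucleus
boundary under-covers the true one by about the blur width, and without
the margin the leftover ring of nuclear-localised reporter fragments into
spurious "objects" that dilute the classifier vote.

The reporter channel is percentile-rescaled, CLAHE-equalised
(kernel 127 px, clip limit 0.01 — the reference scikit-image default; a
higher clip amplifies background noise into foreground after global
thresholding), then binarised by global Otsu (recorded in the config;
`mean` and `triangle` are available). Objects are 4-connected components
within a cytoplasm, split at cytoplasm boundaries, size-filtered at
3 px² — small enough to keep diffraction-limited puncta.

### Morphometry and classification

The box-count fractal dimension of an object is the negative OLS slope of
log N(ε) against log ε over box sizes {2, 3, 4, 6, 8, 12, 16, 32, 64}
(px), the counting grid anchored at the object's bounding-box origin (a
single fixed offset; anchoring makes D exactly translation-invariant).
Box sizes larger than the object are retained and count one box — this is
what sends a point-like object to D = 0 and keeps small puncta well below
the 0.7 threshold, while a 1-px-wide line gives D = 1 and a filled square
D = 2. When the bounding box is smaller than the third box size the value
is flagged as resting on few informative sizes. Repeated counts across
sizes are kept (no deduplication).

Perimeter is, by default, the exposed-pixel-edge count of the 4-connected
object times the pixel size (a 1-px object has 4 steps; an n×n square 4n);
a 4-direction Crofton estimate is available as `perimeter_method="crofton"`.
The edge-count convention was chosen because it is exact and
scale-homogeneous on the rectilinear shapes used as oracles.

A cell is `filamented` if objects with D ≥ 0.7 strictly outnumber the
rest, `punctuated` if strictly fewer, and `tie` otherwise — including
cells with no detected objects; the same majority rule with perimeter ≥
10 µm yields `longer`/`shorter`/`tie`. Ties are excluded from both
numerator and denominator of every reported fraction.

### Condition statistics

The replicate unit is the image (field of view): per image, fraction =
filamented/(filamented+punctuated); images whose cells are all ties are
excluded. Condition summaries report mean ± s.e.m. over images. One-way
ANOVA is computed from the standard between/within decomposition; a
degenerate dataset with zero within-group variance returns p = 0 (or
p = 1 when groups are identical) with a `degenerate` flag instead of NaN,
so extreme synthetic inputs do not crash pipelines. Tukey HSD uses the
studentised-range distribution (scipy), with the same degenerate-variance
policy. Null simulations (in the acceptance suite) check the type-I error
of the ANOVA at α = 0.05 and the family-wise error of Tukey over three
groups.

## Helical geometry

A filament is generated from a protomer by the screw operator: unit k is
the protomer rotated k·twist about z and translated k·rise along z. Twist
is signed — negative means left-handed when the translation is taken
positive, matching the cryo-EM deposition convention, and is reported in
(−180°, 180°]. D1 point symmetry adds, per unit, the C2 mate about an
axis perpendicular to the helix axis through the unit origin.

Recovery inverts this: for each successive unit pair, a Kabsch
least-squares superposition gives (R, t); the rotation angle comes from
the trace, the axis from the antisymmetric part (eigen-decomposition at
the 180° corner case), the translation is t projected on the axis, and the
sign of the angle follows the right-hand rule about the axis oriented with
positive translation. Rotations below 1e−5 rad are treated as pure
translations — the threshold sits well above the ~1e−7 rad numerical noise
of the superposition and below any physically meaningful twist. The
filament twist/rise are the circular mean of per-pair angles and the mean
translation; per-pair transforms (with residual RMSD) are returned so
spread can be inspected. Near ±180° (the activated architecture, −178.6°)
the sign is taken from the antisymmetric part when it is resolvable; at
exactly 180° the handedness is genuinely ambiguous from a single pair.

`infer_units_by_axis` bridges deposited coordinate files to recovery: chain
centroids are projected on the first principal axis of their spread and
grouped N-at-a-time (N = 2 for a filament of dimers) in axis order; chains
with non-modal atom counts are dropped so units stay comparable
atom-by-atom. No sequence alignment is attempted — units must contain
identically ordered atoms.

SASA is Shrake–Rupley with probe 1.4 Å, 960 golden-section spiral points
per atom, and a fixed radii table (C 1.70, N 1.55, O 1.52, S 1.80, others
1.80 Å); the fixed point set makes results bit-reproducible. Buried
interface area is SASA(A) + SASA(B) − SASA(A∪B), reported as the total
over both sides (not halved). Against the closed-form two-overlapping-
spheres answer the 960-point estimate is within 2% down to sliver
overlaps.

## Binding and activity models

All fits are unweighted nonlinear least squares (scipy `curve_fit` /
`least_squares`, trust-region-reflective with bounds), started from fixed
data-driven multi-start grids so a given dataset always yields the same
fit. Parameter standard errors come from the Jacobian at the optimum.

* **Michaelis–Menten** v = V_max·S/(K_m+S); needs ≥ 4 distinct substrate
  levels.
* **Hill activation** v = v_b + (v_max−v_b)·Sⁿ/(K_actⁿ+Sⁿ); the exponent
  is bounded to (0.2, 10]; a fitted K_act outside the assayed range is
  flagged, not silently returned. At n = 1 and v_b → 0 the model reduces
  identically to Michaelis–Menten.
* **Thermal activation** is a logistic between plateaus; T_m is the
  inflection. Fits whose 10–90% transition (≈ 4.4 × slope) exceeds the
  assayed span are rejected as monotone-without-inflection.
* **ITC two sets of sites.** Each injection of volume dV first expels
  dV/V₀ of cell content (displacement dilution), then delivers ligand.
  Free ligand x solves X_tot = x + M_tot·Σᵢ NᵢKᵢx/(1+Kᵢx) by Brent
  bracketing on [0, X_tot] to ~1e−14 relative tolerance, making
  bound + free = total hold to better than 1e−10. Cell heat content is
  Q = V₀·M_tot·Σᵢ NᵢΔHᵢ·θᵢ and the observed heat of injection j is
  ΔQⱼ = Qⱼ − Qⱼ₋₁ + (dVⱼ/V₀)(Qⱼ+Qⱼ₋₁)/2, the last term compensating heat
  content expelled with the displaced volume. Fits run over (Nᵢ, log₁₀Kᵢ,
  ΔHᵢ) with a 16-point multi-start over K orderings and enthalpy splits;
  classes are reported sorted by K_d ascending, and ΔG = −RT ln K and
  −TΔS = ΔG − ΔH are derived at the experiment temperature. The standard
  schedule is one 0.4 µl pre-injection plus 44 × 0.8 µl from a 500 µM
  syringe into a 200 µl cell at 25 °C; the pre-injection is simulated but
  excluded from fitting by default (standard calorimetry practice). Heat
  of dilution: the mean of a supplied blank titration is subtracted, else
  the mean of the final three injections.

  *Identifiability caveat.* With two overlapping binding events of
  opposing enthalpy (+2 / −8 kcal·mol⁻¹) at K_d 160/600 nM, a single
  titration with 0.1 µcal noise does not pin the tight site's K_d: a
  linearised error analysis at the truth gives a 1σ relative uncertainty
  near 80–100% for K_d1 with all six parameters free, and ≈ 38% when the
  stoichiometry N is shared across classes (`share_n=True`, recommended
  for this regime; the cell concentration matters — 60 µM is used, the
  top of the typical 30–60 µM range). Recovery of K_d1 to better than
  ~40% from one such titration should not be expected at this noise
  level; the acceptance suite runs the scenario unmodified and reports
  whatever one titration yields.
* **SEC.** K_av = (V_e−V₀)/(V_t−V₀); log₁₀(MW) is linear in K_av over the
  standards; samples eluting at/before the void volume get no estimate,
  and estimates outside the standards' K_av range are flagged as
  extrapolation.

## Problem sizes

Defaults keep every check cheap on one CPU: classifier recovery uses 20
fields of 25 cells (500 cells, ~10 s); monotonicity uses 5 single-field
cohorts per fraction; null calibrations use 1000 simulated 3×6 datasets;
helical round-trips use 30-atom pseudo-protomers and 5 units; ITC fits use
the full 45-injection schedule.

## Known limitations

* The expanded-cytoplasm construction (nearest-seed, 25 µm radius,
  perinuclear margin) is a declared convention; real pipelines sometimes
  limit growth by a cytoplasmic stain, which is not modelled.
* Box-count D uses a single grid offset; offset averaging is not
  implemented (the anchored single-offset variant is what the oracles and
  the translation-invariance property assume).
* Segmentation assumes non-touching cells (guaranteed by the generator);
  there is no splitting of merged nuclei.
* The ITC model treats site classes as independent (no cooperativity
  between classes) and the dilution model is the simple displacement
  approximation.
* SASA radii are element-based only (no atom-type refinement); absolute
  SASA values carry the usual few-percent method dependence, which the
  ±15% tolerance on interface burial absorbs.
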