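# filaquant

Quantitative analysis of enzyme filamentation, built around the cell biology
and biophysics of cystathionine beta-synthase (CBS) — a metabolic enzyme that
polymerises into helical filaments whose architecture switches when the
allosteric activator S-adenosyl-L-methionine (SAM) binds its regulatory
(Bateman) domain.

The package is aimed at groups who need to (i) score filamented vs punctate
reporter morphology in high-content micrographs, (ii) reason about helical
filament geometry from coordinate models, and (iii) fit the standard
activation/binding models of allosteric filament-forming enzymes — with a
first-class synthetic-data generator so every stage is testable with known
ground truth.

## What it computes

**Cell-morphology classifier** (`simulate`, `segmentation`, `morphometry`,
`cohort`). Nuclei are detected on the blurred (σ = 3 px) sum of the nuclear
and reporter channels; a cytoplasm is delimited per cell by nearest-seed
expansion; the reporter channel is contrast-stretched, CLAHE-enhanced and
binarised; each cytoplasmic object gets a box-count fractal dimension

    D = −slope of log N(ε) vs log ε,

where N(ε) counts occupied ε×ε boxes anchored at the object's bounding box,
and a perimeter in µm. A cell is *filamented* when most of its objects have
D ≥ 0.7 (and *longer* when most perimeters ≥ 10 µm); equal counts are ties
and drop out of the per-condition percentages. Condition differences are
tested with one-way ANOVA and Tukey HSD over per-image fractions.

**Helical geometry** (`helix`). Filaments are built from a protomer and a
screw operator (twist θ in degrees — negative = left-handed — and rise in Å),
optionally with D1 point symmetry (a two-fold axis perpendicular to the
helix axis). The inverse problem is solved by Kabsch superposition of
successive units followed by screw-axis decomposition; subunits per turn is
360/|θ|; interface burial is

    BSA = SASA(A) + SASA(B) − SASA(A∪B)

with an in-repo Shrake–Rupley SASA (probe 1.4 Å, 960 sphere points, fixed
radii). The CBS reference points are the basal filament (θ = −108°, rise
51 Å, three dimers per turn) and the SAM-activated filament (θ = −178.6°,
rise 46.7 Å, two dimers per turn).

**Binding and activity models** (`binding`). H₂S-rate linear calibration;
Michaelis–Menten; Hill activation
v = v_b + (v_max − v_b)·Sⁿ/(K_actⁿ + Sⁿ); logistic thermal-activation curve
with midpoint T_m; a two-sets-of-sites isothermal titration calorimetry
(ITC) forward model with displacement dilution and bracketed free-ligand
root-finding, plus its least-squares fit reporting N, K_d, ΔH, ΔG and −TΔS
per site class; and SEC molecular-weight estimation from the partition
coefficient K_av.

## Worked example

```python
import numpy as np
from filaquant.simulate import ImageSimConfig, make_toy_protomer
from filaquant.pipeline import simulate_and_classify
from filaquant.helix import (HelicalParams, apply_helical_symmetry,
                             recover_helical_params, dimers_per_turn)

# classify four simulated fields generated at a 65% filamented fraction
cfg = ImageSimConfig(n_cells=25, frac_filamented=0.65, seed=11)
summary, cells = simulate_and_classify(cfg, n_images=4)
print(f"cells classified: {summary.n_cells_classified}")
print(f"measured filamented fraction: {summary.frac_filamented:.3f} "
      f"+/- {summary.sem:.3f} (truth 0.65)")

# build a basal-architecture filament and recover its screw parameters
protomer = make_toy_protomer(30, spread=12.0, seed=1)
fil = apply_helical_symmetry(
    protomer, HelicalParams(twist=-108, rise=51, point_group="D1"), n_units=5)
params, transforms = recover_helical_params(fil)
units, nearest = dimers_per_turn(params.twist)
print(f"recovered twist {params.twist:.1f} deg, rise {params.rise:.1f} A")
print(f"subunits per turn: {units:.2f} -> {nearest} dimers per turn")
```

prints

```
cells classified: 100
measured filamented fraction: 0.630 +/- 0.010 (truth 0.65)
recovered twist -108.0 deg, rise 51.0 A
subunits per turn: 3.33 -> 3 dimers per turn
```

The measured fraction is the mean over images of
filamented/(filamented+punctuated); 0.630 against a ground truth of 0.65
reflects a handful of borderline cells whose object majority flips under
noise. The screw recovery is exact on noiseless coordinates, and −108°
per dimer gives 360/108 = 3.33 subunits per turn — three dimers per
helical turn, the low-activity architecture; −178.6° gives two, the
SAM-activated one.

A thin CLI mirrors the library:
`filaquant simulate-images`, `filaquant segment`, `filaquant summarize`,
`filaquant fit hill --data assay.csv`, `filaquant helix-build`,
`filaquant helix-recover`, `filaquant helix-interface`.

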