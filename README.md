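# mwbreast

Analysis toolkit for azimuthal (coronal-plane) microwave breast imaging.
A multi-bistatic scanner records the complex transmission coefficient
S21(n, m, p, f) between a transmitting antenna on a 30 cm circle (5
sections x 2 doublet positions) and a receiving antenna visiting 80
azimuths on a 7 cm circle, over 1-9 GHz. This package implements the full
analysis chain from those records to a malignancy call per breast:

1. **Huygens-principle (HP) reconstruction.** After doublet subtraction
   (removing every transmit-independent artefact), the internal field is
   synthesized on a polar grid (1 mm radial, 3 degree azimuthal sampling),

   E(ρ, φ; m; f) ∝ Σₙ [S21ⁿₘ,₁(f) − S21ⁿₘ,₂(f)] · G(k₁ |ρₙ − ρ|),

   with G the zeroth-order cylindrical back-propagation kernel and k₁ the
   complex wavenumber of an assumed homogeneous medium. The intensity map
   I(ρ, φ) = Σₘ Σ_f |E|² sums sections and frequencies incoherently;
   varying the assumed conductivity σ ∈ {0.01, 0.20, 0.40, 0.60} S/m gives
   the conductivity-weighted image family (0.40 S/m is the working
   default). Maps are interpolated onto a 141x141 Cartesian grid (1 mm).

2. **PCNN segmentation.** A simplified pulse-coupled neural network
   (V_T = 20, β = 3, α_T = 0.2) produces one binary mask per iteration for
   a fixed 32-iteration budget; the iteration-5 mask localizes the
   highest-intensity region, whose centroid assigns an upper/lower zone.

3. **Quartile thresholding.** Each map is Gaussian-smoothed (σ = 30 px,
   replicate padding), summarized by its in-disc intensity quartiles
   (Q1, Q2, Q3), and the cohort threshold θ is the average of the two
   groups' mean Q3. A breast is called malignant-finding (MF) when its
   median exceeds θ (Q2 > θ); ties and lower medians are NF+BF.

4. **Evaluation.** Confusion matrix with MF positive, sensitivity and
   specificity in percent, and upper/lower lesion-zone agreement.

Because clinical recordings are not publicly deposited, the package ships
first-class synthetic generators: a single-scattering (Born-type) S21
forward model on the exact acquisition geometry, and a Gaussian-blob
intensity-map cohort generator with controlled MF/NF+BF contrast. A
verbatim transcription of the 61-breast clinical roster (35 patients) is
packaged for the roster-derived statistics.

## Worked example

Run the synthetic study — generate a 49 NF+BF + 11 MF cohort at effect
size 3, segment every image, fit the Q3-average threshold and score
against the generated ground truth:

```sh
mwbreast run --seed 1
```

```json
{
  "config": {"n_nfbf": 49, "n_mf": 11, "effect_size": 3.0, "seed": 1,
             "conductivity_label": "sigma3"},
  "threshold": 1367.5016768942744,
  "mean_q3_nfbf": 1136.6187631492626,
  "mean_q3_mf": 1598.3845906392862,
  "confusion": {"tp": 11, "fn": 0, "fp": 0, "tn": 49},
  "sensitivity_pct": 100.0,
  "specificity_pct": 100.0,
  "zone_agreement": 0.9833
}
```

The fitted threshold (1367.5 a.u.) sits between the two groups' mean upper
quartiles; at this separation every malignant breast's median crosses it
(11/11 true positives, 49/49 true negatives) and the PCNN iteration-5
zone matches the planted lesion zone for 59 of 60 breasts.

The same stages are scriptable from Python:

```python
from mwbreast import (build_geometry, simulate_s21, PhantomSpec, Inclusion,
                      MediumModel, reconstruct, polar_to_cartesian, segment)

geometry = build_geometry().decimated(250e6)     # 33-point frequency grid
phantom = PhantomSpec(inclusions=(Inclusion(center_rho=0.03, center_phi=90.0),))
dataset = simulate_s21(phantom, geometry)
polar = reconstruct(dataset, MediumModel(conductivity=0.40))
print(polar.argmax_polar())                      # -> (0.07, 90.0)
stack = segment(polar_to_cartesian(polar))
print(stack.regions[0].zone)                     # -> 'upper'
```

The intensity peak lands on the scatterer azimuth (90 degrees, exact to
the 3 degree bin); the range coordinate is biased toward the receiver ring
at lossy weightings — reconstructing with the matched medium
(`conductivity=0`) recovers the range as well (peak at ρ = 0.03 m).

Other subcommands: `simulate`, `reconstruct`, `segment`, `classify`,
`evaluate`, `roster-stats` (see `mwbreast --help`).

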