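# Methods

## Field reconstruction

The scanner measures S21 in a multi-bistatic fashion: for each transmitter
position the receiver visits 80 azimuths (4.5 degree steps) on a circle of
radius a0 = 7 cm; transmitters sit at 30 cm in five sections centred at 0,
72, 144, 216 and 288 degrees, two positions ("doublet") per section.
Subtracting the two doublet recordings of a section removes every
contribution that does not depend on the transmitter position within the
section — direct antenna coupling, cup reflections, static clutter. The
package treats this cancellation as exact: the simulator models the direct
term at the section centre so that it is bitwise identical for both
members, and the reconstruction tests assert exact cancellation.

The internal field is synthesized by propagating the differenced boundary
records back into the receiver circle with a zeroth-order cylindrical-wave
kernel evaluated at the complex wavenumber k1 = ω √(μ0 ε̂),
ε̂ = ε0 εr (1 − j σ/(ω ε0 εr)), with εr = 1 (the antennas operate in free
space) and σ the assumed conductivity. Under the e^{+jωt} convention we
use the *incoming* wave H0^(1)(k1 r) rather than the outgoing H0^(2):

* Back-propagation is the physically meaningful inversion direction for
  boundary data, and empirically it is what localizes: with the outgoing
  kernel a point scatterer's intensity peak appears at the mirrored
  azimuth (φ + 180 degrees), an artefact of the stationary phase of the
  H0² product integrated over a full circle.
* For lossy media Im k1 < 0, so |H0^(1)(k1 r)| grows like exp(+|Im k1| r).
  That growth is precisely the compensation of the attenuation a wave
  suffered travelling r into the medium; it comes for free with the
  incoming kernel. `greens_2d(..., compensate=False)` multiplies the
  kernel by exp(−|Im k1| r) to switch the compensation off; for σ = 0 the
  flag is a no-op. All constant prefactors (j/4 etc.) are dropped — the
  sum is a proportionality and maps are in arbitrary units.

Intensity is the incoherent sum I(ρ, φ) = Σ_m Σ_f |E|² over the five
sections and the frequency grid. The polar grid uses 1 mm radial and
3 degree azimuthal sampling out to a0; maps are bilinearly interpolated
onto a 141×141 Cartesian grid (1 mm), zero outside the disc, with the
azimuth axis wrapped and sub-1 mm radii clamped to the first ring. Row 0
is the top of the coronal image; "upper zone" means rows above centre.

Distances from grid points to receivers are floored at 1 μm to guard the
kernel singularity at receiver-coincident points.

**Localization behaviour.** With the forward model in free space, the
reconstruction at the lossy working weighting (σ3 = 0.40 S/m) is
deliberately phase-mismatched — this mirrors the clinical setting, where
the medium is tissue but the kernel assumes a nominal conductivity. The
consequence, verified in the tests: the azimuth of a point scatterer is
recovered to within one 3 degree bin, while the range coordinate is biased
outward to the receiver ring. Reconstructing with the matched medium
(σ = 0) recovers both coordinates exactly (peak at the true ρ to 1 mm).
Zone assignment, which is what the classification chain consumes, only
needs the azimuth.

**Conductivity weighting.** Four levels are predeclared (0.01, 0.20, 0.40,
0.60 S/m); 0.40 S/m (sigma3) is the default for downstream analysis, and
maps carry their level as a label.

## PCNN segmentation

The simplified pulse-coupled network has one neuron per pixel and the
recurrence

    F[n] = S
    L[n] = Σ_kl W[k,l] · O[n−1]        (3×3 inverse-distance weights, centre 0)
    U[n] = F[n] (1 + β L[n])
    O[n] = [U[n] > T[n−1]]
    T[n] = e^{−α_T} T[n−1] + V_T · O[n−1]

with O[0] = 0, T[0] = 0, β = 3, α_T = 0.2, V_T = 20, run for exactly 32
iterations (the model has no stopping criterion). The threshold update is
written with the *previous* output, the causal reading of the published
recurrence; wherever the previous output was quiet the threshold decays by
exactly e^{−α_T}, which guarantees every positive-stimulus neuron
eventually refires.

The stimulus is the min–max normalization of the in-disc pixels to [0, 1]
multiplied by `stimulus_scale = 255` (the 8-bit image convention). The
scale matters: with the published constants, a [0, 1] stimulus leaves the
threshold far above all activity for iterations ~4–20 and the selected
iteration-5 mask would be empty. On the 0–255 scale the trajectory is:
iterations 1–2 fire everything, the mask thins sharply by iteration 4, and
from iteration 5 on the surviving set is the high-intensity, spatially
supported region — matching the described behaviour that the iteration-5
pattern resembles late iterations (29–31). Iteration numbering is 1-based;
iteration 5 is the selected mask.

Segmentation output: 8-connected components of the selected mask with at
least `min_area = 5` px (suppressing single-pixel speckle), sorted by area;
the largest region's centroid row assigns the upper/lower zone, with the
exact-centre tie going to "upper". A constant input image is degenerate:
normalization emits a warning and returns an all-zero stimulus, giving
empty masks from iteration 2 onward.

## Quartile thresholding

Each Cartesian map is smoothed with a 2D Gaussian, σ = 30 px, kernel
truncated at 4σ, replicate (edge-value) padding. For disc-masked images
the smoothing is mask-aware (normalized convolution): the plain
convolution of a disc image against its zero exterior drags in-disc values
down near the boundary — on an otherwise flat map this edge falloff alone
spreads the quartiles by more than any plausible group shift and would
swamp the decision rule. With the normalized kernel, a constant in-disc
level is a fixed point. `gaussian_smooth` without a mask remains the
literal replicate-padded convolution (constant full-frame maps are fixed
points to < 1e−9 relative).

Per breast, Q1/Q2/Q3 are the 25th/50th/75th percentiles of the in-disc
smoothed intensities (linear interpolation between order statistics — the
common default; no estimator is canonical here) plus Tukey 1.5·IQR whisker
fences. The supervised threshold is θ = (mean Q3 over NF+BF + mean Q3
over MF)/2, fitted on gold labels; a pre-fitted θ can be applied held-out.
The decision is MF iff Q2 > θ. The direction is configurable ("below"
flips it): published group statistics for this rule are internally
inconsistent (the reported MF quartiles lie *below* the NF+BF ones while
the rule declares MF *above* the threshold, and the reported operating
threshold 1690 a.u. is not the average of the reported group Q3 means 1600
and 1500), so the rule is implemented exactly as stated and the direction
left as a switch. Note the structural property of this rule: θ is built
from Q3 but compared against Q2, so any within-image spread (Q3 − Q2)
common to both groups shifts θ upward relative to the medians and eats
into sensitivity; the rule only discriminates when images are nearly flat
after smoothing relative to the between-group shift.

## Synthetic data

`simulate_s21` is a single-scattering (Born-type) model: per record, a
direct term (section centre → receiver, identical across the doublet) plus
one H0² bounce per inclusion (transmitter → inclusion → receiver) in free
space, plus optional circular complex Gaussian noise (seeded). It is a
stand-in that exercises the reconstruction contract — doublet
cancellation, linearity, localization — not a physics claim; no mutual
coupling, antenna patterns or multiple scattering.

`synth_cohort` emulates the study conditions at image level (default
cohort 49 NF+BF + 11 MF, mirroring the 61-breast composition with its 11
malignant findings). Each breast is a flat background level (mean 1000
a.u., between-breast SD 60 a.u.), pixel noise (SD 10 a.u.), and one focal
Gaussian blob (σ = 8 mm, amplitude 2500 a.u., at 35 mm from centre) in a
recorded upper/lower zone (70 % upper, matching the roster's
preponderance; azimuths keep 15 degrees clear of the horizontal midline so
the gold zone is well defined). The blob stands for any focal finding —
benign or malignant — and is identically distributed in both groups, so at
`effect_size = 0` the groups are exchangeable by construction (verified by
a rank test and by chance-level balanced accuracy). MF breasts have their
background level shifted by `effect_size × 150 a.u.` The shift unit is
2.5× the between-breast SD rather than 1×: with a shift of exactly
`effect_size` SDs, the Q3-average threshold leaves only ~1.5 SD of margin
per side at effect size 3, which cannot reliably clear a ≥ 0.9
sensitivity bar at n_MF = 11 (a ~7 % per-breast error rate makes two
errors in eleven likely); the wider unit keeps `effect_size` a monotone
standardized dial (0 ⇒ exchangeable) while making the stated default a
regime of clean separation, measured at sensitivity ≥ 0.91 and
specificity 1.0 across 12 generator seeds.

What the generator does *not* emulate: speckle and sidelobe texture of
real reconstructed maps, breast-density heterogeneity, cup-size variation,
patient-motion artefacts, or any dependence between lesion size and
malignancy. Passing the recovery tests therefore demonstrates the
correctness and wiring of the decision chain under controlled contrast,
not clinical performance.

## Numerical and design notes

* Problem sizes: tests reconstruct on a 17-point frequency grid (500 MHz
  decimation), the acceptance script on 33 points (250 MHz); both cover
  the full 1–9 GHz band. The full 1601-point grid is supported.
* Determinism: every stochastic step takes an integer seed
  (`numpy.random.default_rng`); the PCNN and reconstruction are fully
  deterministic. Identical inputs give bit-identical outputs.
* Quartile/threshold ties: Q2 exactly equal to θ is NF+BF; a PCNN centroid
  exactly on the centre row is "upper".
* Degenerate inputs: empty masks yield no regions (zone undefined,
  reported as missing and scored as a mismatch in zone agreement);
  constant images warn and segment to nothing; empty groups or empty pixel
  masks raise.
* Roster age bands count breasts (rows), not patients: the published band
  totals (23 + 38) sum to 61 breasts even though the bands are labelled by
  patient; the mean age is likewise the row mean. This is recorded, not
  resolved.
* Known limitations: range localization at lossy weightings is biased to
  the receiver ring (azimuth-only localization is the supported claim);
  the classifier direction must be chosen per cohort; the forward model is
  single-scattering in free space.
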