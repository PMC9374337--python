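# Methods

## Displacement model

A particle undergoing free planar Brownian motion with diffusion
coefficient D, observed over a lag Δt, has a displacement length
distributed as Rayleigh, p(r) = (2r/4DΔt)·exp(−r²/4DΔt). Two corrections
adapt this to stroboscopic single-molecule data:

1. **Linear background.** Peak pairing is all-pairs within a radius
   r_max: every first-frame peak is matched to *every* second-frame peak
   within r_max, without deduplication. Misassigned pairs of independent
   detections that are uniform over an area have a pair-distance density
   proportional to r at short range, so a k·r term with k ≥ 0 (nm⁻²)
   absorbs them. This is why ambiguity resolution is deliberately *not*
   performed at the pairing stage.
2. **Truncation.** Displacements beyond r_max are never observed (and are
   filtered with an inclusive boundary, r ≤ r_max), so the density is
   renormalized on [0, r_max]; the normalizer is
   1 − exp(−r_max²/4DΔt) + k·r_max²/2.

D and k are estimated by maximum likelihood. Internally the optimizer
works in (log D, w) where w ∈ [0, 1) is the mixture weight of the
background component — an exact reparametrization of (D, k) that keeps
both coordinates well scaled and the constraints simple (L-BFGS-B,
function tolerance 1e-13; initialization D₀ = mean(r²)/4Δt from the
method of moments, w₀ = 0.05). With the background fixed to zero the
profile likelihood is one-dimensional and solved by Brent's method.
Standard errors come from a finite-difference observed-information
matrix in (log D, w), delta-transformed to (D, k). Fits that fail to
converge are flagged and excluded from downstream ensembles.

Fixed-zero background is used for simulation-derived displacements
(pairings are exact by construction); the free background is the default
for experimental-style localization streams, for both region fits and
per-pixel maps.

Defaults: Δt = 1.5 ms, r_max = 600 nm. The pairing radius corresponds to
D = r_max²/(2·2·Δt) = 60 μm²/s, several times faster than any protein
measured, so genuine displacements are essentially never truncated.

## Confined-diffusion simulator

Cells are modelled as spherocylinders (cylinder of radius R capped by
two hemispheres; "length" is end-to-end including caps — the convention
used for measured cell lengths, which include the poles). Particles
start uniformly distributed (the stationary law of reflected Brownian
motion) and take Gaussian steps with per-axis SD √(2·D·δt) at
δt = 0.1 ms; a step ending outside the compartment is folded back by
specular reflection across the tangent plane at the nearest boundary
point, iterated until interior. For step SDs ≪ R (at D = 20 μm²/s the
step SD is 63 nm against R ≥ 205 nm) a single reflection almost always
suffices, and the scheme converges to reflected Brownian motion as
δt → 0. Positions are recorded after steps 1..N (no t = 0 row), so a 2-s
run at 0.1-ms steps yields 20,000 rows and, by the Markov property,
pairing row i with row i+15 yields 19,985 displacements per particle at
an effective 1.5-ms lag. The Markov-consistency property test verifies
that these lag-15 displacements are statistically indistinguishable from
direct 1.5-ms steps.

The synthetic localization stream emulates the acquisition geometry: one
(configurable) emitter per frame couple, drawn from the stationary
distribution, displaced by 15 reflected sub-steps, localized in both
frames with isotropic Gaussian noise (default SD 20 nm, a typical
single-molecule localization precision; configurable). Spurious
co-detections are Poisson per frame couple and uniform over the cell's
projected footprint — the mechanism that produces the linear background.
An optional pole-slowdown factor scales the diffusivity of emitters
starting in the outer 20% of the cell length, so a genuine (not
confinement-induced) pole slowdown can be planted and recovered in
tests. What the generator does **not** model: photophysics
(photoconversion and bleaching kinetics), camera/PSF image formation,
z-dependent detection, drift. Passing tests therefore demonstrate
correctness of the analysis chain on ideal stroboscopic data, not
robustness to those instrumental effects.

## Confinement-bias benchmark

For a given input D_sim, displacements whose origins fall in a chosen
region are pooled and fitted with the background fixed to zero. Regions:
the whole compartment, the cylindrical section (|x| ≤ L/2 − R), and a
centermost window of 150 nm (long axis) × 100 nm (across). The window's
axis order is a convention; both orders give indistinguishable
center-region results. The benchmark conditions are 25 particles × 2 s ×
0.1 ms steps per input value — enough for ~500,000 displacements per
condition, making the pooled-fit standard error negligible against the
bias being measured. At the median geometry (R = 0.45 μm, L = 2.25 μm)
the whole-compartment estimate underestimates the input by ≈ 7% at
D_sim = 2.5 μm²/s and ≈ 15% at 10 μm²/s, while the center window stays
within a few percent up to 2.5 μm²/s; bias grows monotonically with
D_sim and D_app never exceeds D_sim beyond statistical error.

The pole/center ensemble samples a heterogeneous population (defaults
for the ensemble analysis: diameters uniform in 0.41–2.34 μm, lengths in
1.1–3.64 μm with length ≥ diameter enforced by rejection, D uniform in
0.5–20 μm²/s; the population generator itself defaults to a 0.2 μm lower
diameter bound, the wider of the two ranges in use). Each cell is
simulated, partitioned into 20%-length poles and center using the
extreme displacement origins — exactly as the experimental pipeline
measures cell length — and each region fitted independently (minimum 100
displacements per region, which caps the region-estimate error near
10%). The per-cell ratio is mean(D_pole_left, D_pole_right)/D_center;
the ensemble mean over 40 cells is ≈ 0.90–0.94 depending on the seed, an
intentionally scaled-down population (the reference analysis used ~350
cells) chosen to keep a full run under a minute on one CPU.

## Segmentation choices

Voronoi clustering keeps points whose polygon area is below 2× the
median finite polygon area of the field, joins kept points through
shared Voronoi edges, and discards components under 500 points. The
threshold factor and minimum size are configuration parameters; the
defaults were chosen once against labelled synthetic two-cell fields
(≥ 99% membership agreement). A consequence of any density cut is that
the lowest-density boundary ring of a uniformly filled cell cloud
(~10–15% of its points) falls below the threshold; the retained core is
what gets rotated and measured. Cell rotation uses the leading
eigenvector of the origin-coordinate covariance; the angle is defined
mod π and reported in (−π/2, π/2], and clusters with near-equal
eigenvalues are flagged as axis-ambiguous rather than rejected. Region
boundaries are inclusive toward the poles (a tie at a boundary belongs
to the pole) — an arbitrary but fixed convention. Cell length and width
are measured on displacement origins, not on all localizations. QC
criteria that require visual inspection in practice (field-edge
truncation, touching cells, division, aggregation) are accepted as
caller-supplied flags, not inferred.

## Mass-scaling statistics

Complex mass is (monomer + tag) × oligomeric state with the mEos3.2 tag
at 25.7 kDa, assuming every subunit carries a tag; tabulated values are
rounded to 0.1 kDa, so recomputation is checked at that tolerance. The
D–mass power law is fitted by nonlinear least squares on the linear
scale, initialized from the log-log regression, with parameter errors
from the covariance diagonal. The reference analysis weights points by
the per-construct SD of the measured diffusion coefficients
(`sigma` in `fit_power_law`); weighting matters — the unweighted fit
over the same ten constructs gives β ≈ −0.48, the SD-weighted fit
β ≈ −0.54. The fitted subset for the headline exponent is the ten
non-heterologous constructs (nine native proteins plus free mEos3.2);
the all-twelve fit is exposed alongside.

The perceived-viscosity model inverts Stokes–Einstein,
η = k_B·T/(6π·D·r), with the hydrodynamic radius derived from mass via a
partial specific volume (defaults: T = 294.15 K, v̄ = 0.73 cm³/g, both
configurable — typical values for globular proteins at the 21 °C stage
temperature). For data following D ∝ M^β exactly, the viscosity exponent
is −β − 1/3; with β = −0.54 this gives ≈ 0.21. On the packaged panel the
weighted fit gives an exponent near 0.2 with roughly 10–16 cP across
26–319 kDa; these derived values depend on the assumed v̄ and T and are
reported, not asserted, by the test suite.

Spearman correlations use mean ranks for ties; a permutation p-value is
available for small panels. The Mann–Whitney U test uses the exact null
when both samples are tie-free and n_a·n_b ≤ 10⁴, otherwise the normal
approximation with tie correction; Shapiro–Wilk follows its standard
contract (3 ≤ n ≤ 5000). An F test for nested power-law fits is exposed
as a thin utility over residual sums of squares.

## Degenerate inputs and numerical conventions

Zero-diffusion simulations leave particles exactly at their start
points. Empty displacement sets, single-point geometry measurements,
constant samples for rank/normality statistics, and pole fractions
≥ 0.5 raise errors rather than returning silently wrong values.
Undefined loneliness (no recorded interactors) is NaN, not infinity.
Internal units are nm and seconds; diffusion coefficients are reported
in μm²/s. All random draws flow from explicit integer seeds
(numpy `default_rng`); population- and ensemble-level runs derive
per-cell seeds from a single `SeedSequence`.

## Known limitations

* The simulator's specular fold is exact only in the small-step limit;
  at the default δt the residual discretization error is far below the
  biases being measured.
* The Voronoi density threshold is a documented assumption; real
  fields of view with strong background may need a different factor.
* A genuine biological pole slowdown — stronger than confinement alone —
  cannot be reproduced from confinement-only simulation; what is
  testable in silico is the confinement-only baseline ratio and the
  recovery of a slowdown deliberately planted by the stream generator.
* Multi-component displacement mixtures, anomalous-diffusion exponents
  and z-dependent corrections are out of scope; fits are single
  component by design.
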