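# smdmap

Single-molecule displacement mapping (SMdM) of protein diffusion in
confined bacterial cells.

## The problem

SMdM measures diffusion by stroboscopic illumination: two short laser
pulses straddle the boundary between consecutive camera frames, so each
photoactivated emitter is localized twice, a fixed lag Δt apart
(1.5 ms here). Accumulating many such displacements, binned by their
starting position, yields spatially resolved diffusion maps at
50–200 nm — fine enough to section a bacterium into cell poles and cell
center.

In a compartment as small as *E. coli*, however, the cell membrane
reflects particles within the observation lag, so displacement-based
estimates systematically *underestimate* the true diffusion coefficient,
more strongly for faster particles and near the boundary. This package
implements the full analysis chain and the simulation machinery needed to
quantify that confinement bias:

* **simulation** — Brownian walks inside reflective spherocylinders,
  lag-subsampled into displacement sets; synthetic stroboscopic
  localization streams with localization noise and spurious co-detections;
* **extraction** — odd/even frame pairing and all-pairs peak matching
  within a 600 nm radius;
* **segmentation** — Voronoi-density cell detection, rotation onto the
  covariance major axis, QC by displacement count (2,000–20,000 per
  cell), pole/center partitioning (outer 20% of the cell length per pole);
* **fitting** — maximum-likelihood estimation of the apparent diffusion
  coefficient from the truncated, background-corrected planar
  displacement density

  p(r) = [ (2r/4DΔt) e^(−r²/4DΔt) + k·r ] / [ 1 − e^(−r_max²/4DΔt) + k·r_max²/2 ],  0 ≤ r ≤ r_max,

  where the linear k·r term absorbs misassigned pairs and the density is
  renormalized on [0, r_max = 600 nm]; per-pixel diffusion maps and
  per-region estimates;
* **scaling statistics** — complex mass ((monomer + tag) × oligomeric
  state), loneliness (copy number over summed interactor copy numbers),
  Spearman correlations, the power law D = αM^β, pole/center ratio
  ensembles, Stokes–Einstein "perceived viscosity" η(M), and the
  Mann–Whitney / Shapiro–Wilk utilities used for group comparisons.

The modelling surface follows the statsmodels idiom: `DisplacementModel`
is built from data and `fit()` returns a `DisplacementFitResults` with
estimates, standard errors from the observed information, log-likelihood
and a `summary()` table; `PowerLawModel`/`PowerLawResults` do the same
for the mass-scaling fit.

## Worked example

Simulate a confined walk in the median cell geometry (radius 0.45 μm,
end-to-end length 2.25 μm), pool all lag-15 (1.5 ms) displacements and
fit them (background fixed to zero — simulated pairings are exact):

```python
from smdmap import DisplacementModel
from smdmap.confinement import REFERENCE_CELL, simulated_displacements

disp = simulated_displacements(5.0, REFERENCE_CELL, n_particles=25, seed=7)
print(DisplacementModel.from_dataframe(disp, background=False).fit().summary())
```

```
Displacement MLE fit
============================================
n displacements                       499619
lag time (ms)                          1.500
D (um^2/s)                            4.4768
SE(D)                                 0.0063
k (nm^-2)                          0.000e+00
SE(k)                                    nan
log-likelihood                  -2849330.173
converged                               True
```

The input was D = 5 μm²/s; the whole-compartment estimate is 4.48 μm²/s,
a ~10% underestimation caused purely by reflections off the membrane —
the confinement bias the package quantifies.

Fit the diffusion–mass power law over the packaged protein panel (the
ten non-heterologous constructs, weighted by the per-construct SDs):

```python
from smdmap import load_protein_panel, fit_power_law

panel = load_protein_panel()
native = panel[~panel.heterologous]
mass = (native.mw_kda + native.tag_mw_kda) * native.oligomeric_state
print(fit_power_law(mass, native.d_mean, sigma=native.d_sd).summary())
```

```
Power-law fit  y = alpha * x^beta
============================================
n points                                  10
alpha                                68.4548
SE(alpha)                            14.6836
beta                                 -0.5387
SE(beta)                              0.0507
RSS                                   5.6080
converged                               True
```

The exponent β ≈ −0.54 ± 0.05 is markedly steeper than the −1/3 expected
from Stokes–Einstein with a mass-derived radius, which is the signature
of a mass-dependent ("perceived") cytoplasmic viscosity.

A `smdmap` command-line tool chains the stages
(`simulate`, `stream`, `extract`, `segment`, `fit-map`, `fit-regions`,
`scaling`, `benchmark-confinement`); run `smdmap --help`.

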