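# Methods

This note documents the models implemented in `palaeocoast`, the defaults
and numerical conventions that matter, what the synthetic generators do
and do not emulate, and the design choices made where conventions in the
field genuinely diverge.

## Radiocarbon calibration (`calib`)

Calendar time is integer years cal BP (before AD 1950), grids ascending
(youngest cell first) and aligned to multiples of the grid step so that
per-date densities add cell-by-cell without interpolation.

The calibrated density at grid age θ is proportional to
`exp(−(r − ΔR − μ(θ))² / 2σ²(θ))` with
`σ²(θ) = σ_lab² + σ_ΔR² + σ_c(θ)²`. We deliberately use a constant-σ
Gaussian kernel without a `1/σ(θ)` prefactor; with the (near-)constant
curve errors used throughout, the two conventions are numerically
indistinguishable, and the simpler kernel makes the flat-curve limit
exactly uniform. μ and σ_c are interpolated linearly between knots —
standard practice, and adequate at the decadal knot spacing of real
curves.

Densities are trimmed to the smallest contiguous span holding ≥ 1 − 10⁻⁵
of the mass (at most half of the trim budget from each tail) and then
renormalized; this bounds memory in null simulations without visibly
moving medians, modes or HPD bounds. A determination whose maximum
unnormalized density is below 10⁻³⁰⁰ raises a calibration failure rather
than returning numerical noise.

Marine samples are handled curve-agnostically: a per-date reservoir
offset ΔR ± σ_ΔR is subtracted from the determination; no curve identity
or regional ΔR constant is baked in. Back-calibration (`uncalibrate`)
returns μ(θ) plus Gaussian noise with sd `sqrt(σ_c² + σ_lab²)`,
deterministic given a seed.

HPD intervals accumulate grid cells in order of descending density; ties
are broken by grid position (stable sort), which pins results for exact
tests.

## SPD and the uniform-calendar null (`spd`)

SPDs are plain sums of unit-mass densities — no site/phase binning and no
taphonomic correction; the total therefore equals the number of dates
(optionally normalized to 1). The null model draws the same number of
dates uniformly over a window deliberately wider (8100–3500 cal BP) than
the analysis window (8000–4000), resampling laboratory errors with
replacement from the observed errors — the simplest faithful reading of
"an error distribution similar to the real data".

The envelope stores the pointwise mean and a central percentile band
(default 95%) over simulations. In the far spill-over tails, where almost
all simulated SPDs are exactly zero, a finite-sample percentile can fall
below the mean; the band is widened pointwise there so
`lower ≤ mean ≤ upper` holds everywhere. Deviation calls are restricted
to the null window, require a minimum run length (default 50 yr) and flag
runs within 100 yr of the window edges, where calibration spill-over
biases the uniform null.

## WA-PLS (`wapls`)

Assemblages are closed to relative composition before fitting, as is
conventional for percentage diatom data; every output is then invariant
to rescaling any assemblage by a positive constant. Components follow the
standard iteration — taxon scores as weighted averages of the current
environmental residual, sample scores as weighted averages of taxon
scores, orthogonalization against earlier components, and weighted
least-squares regression of the environment on the component scores
(inverse deshrinking). Component 1 reproduces classical weighted
averaging with inverse deshrinking, which the tests assert against an
independent implementation at 10⁻⁸.

The fitted model is stored as one effective taxon-coefficient vector and
intercept per component count, so prediction needs only relative
composition; fossil taxa unknown to the training set are dropped with a
warning and rows renormalize implicitly. A component whose sample scores
have numerically zero variance (< 10⁻¹⁰ of the environmental scale)
raises an error naming the component.

Bootstrap cross-validation resamples samples with replacement and
predicts out-of-bag samples; RMSEP is the root mean square of all pooled
out-of-bag errors (the s1/s2 decomposition — within-sample spread of
bootstrap predictions, and RMSE of the per-sample mean prediction — is
reported alongside, since both conventions circulate in the transfer-
function literature). Cycles with fewer than two distinct environmental
values, no out-of-bag samples, or a degenerate component are redrawn (at
most 10 times each, counted).

Salinity is modelled on the square-root scale by default ("sqrt units");
reconstructions are squared before subtracting the modern reference, and
the bootstrap RMSEP at the chosen component count is propagated to the
raw scale by the delta method (se ≈ 2·|estimate_sqrt|·se_sqrt). The
modern reference is user-supplied per site; no constant is assumed.

## Stratigraphy (`strat`)

Age-depth models are piecewise linear through dated control points,
validated against depth and age reversals; extrapolation beyond the dated
span is refused. The accumulation rate at a knot takes the shallower
(younger) segment's slope. Fluxes are concentration × SAR in the proxy's
native concentration unit — no dry-bulk-density mass-accumulation
correction is applied, matching the concentration bases of the source
records.

Composites z-standardize each site within the analysis window (default
8000–4000 cal BP; sample sd), pool all points, and smooth with lowess:
tricube weights, local linear fits, 3 robustifying iterations, fraction
0.1, evaluated on a 10-yr grid (statsmodels implementation). Only the
span is a stated convention of the source analysis; the remaining lowess
details are conventional defaults recorded here for reproducibility.
Production phases are maximal grid runs with the smooth > 0.5 sd lasting
≥ 100 yr — a package convention for operationalizing "production phase",
flagged as such in run reports, not a published criterion.

## Isotopes (`isotopes`)

Periods are contiguous (label, old, young) intervals; an age belongs to
the period with `old ≥ age > young`, so a shared boundary goes to the
younger period (e.g. 5900 cal BP is earlier Neolithic, not Ertebølle).
Box-plot summaries report n, mean, min, q1, median, q3 and max per group
and isotope, with quartiles by the inclusive (linear-interpolation)
method — pinned because published figures rarely state it. Humans and
dogs are summarized separately by default; `pool_taxa` reproduces the
pooled view.

The mixing model is linear with two endmembers per isotope, clipped to
[0, 1] with a flag. The shipped defaults — δ¹³C −12/−21‰, δ²H +70/−10‰
(marine/terrestrial) — are package conventions for regional collagen, not
published constants, and must be reviewed per application; δ¹⁵N is
trophic-level enriched and excluded from mixing by default.

## Synthetic data (`synthetic`)

All generators are pure functions of (parameters, seed) and serialize
their latent truth. Defaults encode the stated study world: production
pulses at 7600–7100 and 6400–5900 cal BP at 3:1 odds against background,
231-date archives with lab errors of 40–80 ¹⁴C yr, a 150 × 40
Gaussian-niche training set on a 0–30 salinity gradient (tolerances
1.5–4, peak expected count 80, Poisson noise), cores with constant
0.05 cm yr⁻¹ accumulation and lognormal concentration noise (σ = 0.5),
and isotope mixtures with Gaussian noise (σ = 0.5‰). Niche widths and
noise levels were chosen once as field-realistic values and not revisited.

What the generators do *not* emulate: reservoir ecology of marine
samples, taphonomic loss and sampling bias of date archives, curve
plateaux of the severity seen in real calibration curves, bioturbation
smoothing of proxies, secondary environmental gradients beyond niche
noise, and covariance between isotope systems. A green test therefore
establishes correctness of the estimators under a known, well-behaved
data-generating process — not robustness to every pathology of real
archives.

`synthetic_isotope_compilation` deserves a separate caveat: the
underlying multi-site collagen compilation is not publicly archived, so
this stand-in reproduces only its published group sizes and group means
exactly (spread is invented, Gaussian σ = 1‰ recentred per group). Tests
against it validate the summary and mixing machinery, not the real data.

## Numerical and reproducibility notes

* Every stochastic routine takes an integer seed (or Generator) and is
  bit-reproducible from it; pipeline outputs embed the seed and a config
  hash and contain no timestamps, so identical configs give identical
  bytes.
* Calibration restricts evaluation to ±8 combined σ around the matching
  calendar ages when the curve mean is monotone (the density outside is
  < e⁻³²); tests assert equality with full-grid evaluation at 10⁻⁶.
* The null engine's 1000-simulation, 231-date configuration runs in tens
  of seconds on one CPU; acceptance-scale tests use 200 simulations.

## Known limitations

* No Bayesian age-depth models (Bacon/OxCal-style), wiggle-matching or
  phase models; the piecewise-linear model propagates no age uncertainty
  into fluxes.
* The SPD null is uniform only; growth-model nulls (exponential/logistic)
  and site binning are out of scope.
* WA-PLS is the only transfer-function family; no MAT or ML response
  surfaces, and no significance test of reconstructions.
* Mixing is two-endmember per isotope with no trophic enrichment
  correction or Bayesian treatment of endmember uncertainty.
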