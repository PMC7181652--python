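# palaeocoast

Quantitative tools for testing whether pulses of coastal marine production
coincide with shell-midden accumulation and pre-agricultural population
growth, built for palaeoecologists and archaeometricians working with
radiocarbon date archives, sediment-core proxies, diatom transfer
functions and bone-collagen stable isotopes.

## What it computes

**Radiocarbon calibration and SPDs.** A date *r ± σ_lab* is calibrated
against a curve (μ(θ), σ_c(θ)) via the Gaussian kernel

    p(θ) ∝ exp( −(r − ΔR − μ(θ))² / 2(σ_lab² + σ_ΔR² + σ_c(θ)²) ),

normalized to unit mass on a 1-yr calendar grid (cal BP). The summed
probability distribution (SPD) of a date set is the cell-wise sum of the
per-date densities — a proxy for dated-event frequency. Its significance
is assessed against a Monte-Carlo null: n dates drawn *uniformly* in
calendar time over a fixed window, lab errors resampled from the observed
errors, back-calibrated (μ(θ) plus combined noise) and re-summed; runs of
the observed SPD outside the pointwise percentile band of the simulations
are reported as deviations.

**WA-PLS salinity reconstruction.** Weighted-averaging partial least
squares predicts (square-root) salinity from diatom assemblage
composition; component scores are iterative weighted averages with
inverse deshrinking, cross-validated by bootstrap (out-of-bag RMSEP,
with the s1/s2 decomposition). Reconstructions are back-transformed and
expressed as deviations from a modern reference salinity.

**Proxy fluxes and composites.** Piecewise-linear age-depth models turn
proxy concentrations into fluxes (concentration × sediment accumulation
rate); multi-site series are z-standardized within an analysis window,
pooled, smoothed with robust lowess (span 0.1), and sustained excursions
above a threshold are reported as production phases.

**Isotope diet partitioning.** δ¹³C/δ¹⁵N/δ²H collagen values are grouped
by cultural period (Kongemose 8400–7400, Ertebølle 7400–5900, earlier
Neolithic 5900–5000, later Neolithic 5000–4000 cal BP), summarized as
box-plot statistics, and converted to marine-resource fractions with a
two-endmember mixing model f = (δ − δ_terr)/(δ_marine − δ_terr).

Every input class has a seeded synthetic generator
(`palaeocoast.synthetic`) that serializes its latent truth, so the whole
pipeline is testable offline.

## Worked example

```sh
palaeocoast simulate --outdir demo --seed 7      # synthetic input bundle
palaeocoast run --config demo/config.yaml       # all stages
```

or, from Python, the equivalent of what `scripts/acceptance.py` runs:

```python
from palaeocoast import spd, synthetic

curve = synthetic.make_calcurve(span=(9000, 3000), seed=1)
ds, truth = synthetic.sample_dates(
    synthetic.pulse_intensity((8100, 3500)), 231,
    synthetic.DEFAULT_ERROR_POOL, curve, seed=2)
observed = spd.sum_spd(ds, curve)
null = spd.simulate_null(231, ds.errors, (8100, 3500), curve,
                         n_sims=200, seed=3)
for d in spd.spd_deviations(observed, null):
    print(d.sign, d.old, d.young)
```

A run of `python scripts/acceptance.py --seed 1 --out results/acceptance.json`
prints:

```
SPD: 231 dates, 200-sim null; deviations:
  + 7660-7105 cal BP
  - 6696-6489 cal BP
  + 6383-5988 cal BP
  ...
WA-PLS: apparent r2 = 0.992, RMSEP(1) = 0.210, RMSEP(2) = 0.119 (sqrt units, 200 cycles)
composite phases: 7540-7150, 6350-6030
isotopes: 86 samples, Mesolithic mean f_marine(d13C) = 0.885, 10 summary rows
```

The two `+` SPD deviations and the two composite phases recover the
production pulses injected at 7600–7100 and 6400–5900 cal BP: dates and
cores were simulated with 3× intensity inside those windows, and both the
null-model test and the z-score composite locate them. The WA-PLS line
shows the transfer function is learnable on the synthetic training set
and that a second component improves out-of-bag prediction. The isotope
line converts a strongly marine Mesolithic δ¹³C signature (−13‰ against
−12/−21‰ endmembers) into a marine diet fraction near 8/9.

## Acceptance script

`scripts/acceptance.py --seed <int> --out <path>` regenerates the
synthetic bundle from the seed, executes every pipeline stage at a scale
that completes in about a minute (200-simulation null, 200 bootstrap
cycles), prints the headline numbers, and writes the JSON manifest to
`--out`.

## Layout

| module | contents |
|---|---|
| `palaeocoast.calib` | curves, calibration, back-calibration, HPD intervals |
| `palaeocoast.spd` | SPD summation, uniform-calendar null, deviation calls |
| `palaeocoast.wapls` | WA-PLS fit/predict, bootstrap RMSEP, reconstruction |
| `palaeocoast.strat` | age-depth models, fluxes, z-score composites, phases |
| `palaeocoast.isotopes` | period summaries, two-endmember diet mixing |
| `palaeocoast.synthetic` | seeded generators + ground truth |
| `palaeocoast.cli` / `pipeline` | `palaeocoast` subcommands and the `run` driver |

See `docs/methods.md` for model assumptions, parameter defaults and known
limitations.
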