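"""Synthetic-data generators with serialized ground truth.

Every pipeline input class can be generated with known latent parameters
so each analysis stage is testable offline:

* wiggly monotone calibration curves with constant curve error;
* radiocarbon date archives drawn from piecewise-constant (boxcar pulse)
  occupation intensities, with lab errors resampled from an empirical-like
  pool (~40-80 14C yr) and determinations back-calibrated through the
  curve;
* Gaussian-niche (unimodal) species x salinity training sets;
* sediment cores with constant accumulation and boxcar production pulses,
  with multiplicative lognormal noise;
* two-endmember isotope mixtures with period-dependent marine fractions
  (additive Gaussian noise).

Generators are pure functions of (parameters, seed); each returns its
latent truth as a ``SyntheticTruth`` that can be serialized next to the
dataset and used to re-derive expected pipeline outputs exactly.

The default pulse windows (7600-7100 and 6400-5900 cal BP, 3:1 odds
against background) mirror the marine production phases the pipeline is
designed to recover; default lab errors, niche widths and noise levels are
chosen to resemble shell-midden date archives and coastal diatom/pigment
records (see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .calib import C14Date, CalibrationCurve, curve_at
from .errors import ParameterError
from .isotopes import DEFAULT_MIXING, DEFAULT_PERIODS, MixingConfig, PeriodTable
from .spd import DateSet
from .strat import CoreRecord
from .wapls import TrainingSet

__all__ = [
    "SyntheticTruth",
    "PULSE_P1",
    "PULSE_P2",
    "DEFAULT_ERROR_POOL",
    "make_calcurve",
    "identity_curve",
    "pulse_intensity",
    "sample_dates",
    "make_training_set",
    "make_core",
    "make_isotope_samples",
    "synthetic_isotope_compilation",
]

# marine production pulse windows used as the standard simulation scenario
PULSE_P1 = (7600.0, 7100.0)
PULSE_P2 = (6400.0, 5900.0)

# empirical-like lab-error pool for shell dates (~+/-40-80 14C yr)
DEFAULT_ERROR_POOL = tuple(float(e) for e in range(40, 81, 5))


@dataclass
class SyntheticTruth:
    """Latent parameters behind one generated dataset."""

    kind: str
    seed: int | None
    params: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {"kind": self.kind, "seed": self.seed, "params": self.params},
            indent=2, default=_jsonable, ensure_ascii=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# calibration curves
# ---------------------------------------------------------------------------

def make_calcurve(span: tuple[float, float] = (12000.0, 0.0),
                  wiggle_amp: float = 30.0, wiggle_period: float = 800.0,
                  sigma: float = 15.0, seed: int | None = 0,
                  knot_step: float = 5.0, noise_amp: float = 5.0,
                  noise_smooth: float = 60.0) -> CalibrationCurve:
    """Wiggly, strictly monotone synthetic calibration curve.

    mu(theta) = theta + wiggle_amp * sin(2*pi*theta / wiggle_period) plus a
    smooth seeded noise track (white noise Gaussian-smoothed over
    ``noise_smooth`` calendar years, scaled to sd ``noise_amp``); the curve
    error is constant ``sigma``.  Parameter combinations that break strict
    monotonicity of mu are rejected.
    """
    old, young = float(span[0]), float(span[1])
    if not old > young:
        raise ParameterError("span must be (old, young) with old > young")
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    if wiggle_amp > 0 and 2.0 * np.pi * wiggle_amp / wiggle_period >= 1.0:
        raise ParameterError(
            "wiggle_amp/wiggle_period too steep: d(mu)/d(theta) would dip "
            "below zero (need 2*pi*amp/period < 1)")
    theta = np.arange(young, old + knot_step * 1e-9, knot_step)
    mu = theta.copy()
    if wiggle_amp > 0:
        mu = mu + wiggle_amp * np.sin(2.0 * np.pi * theta / wiggle_period)
    if noise_amp > 0:
        rng = np.random.default_rng(seed)
        raw = rng.normal(0.0, 1.0, size=theta.size)
        smooth = gaussian_filter1d(raw, noise_smooth / knot_step,
                                   mode="nearest")
        sd = smooth.std()
        if sd > 0:
            mu = mu + smooth * (noise_amp / sd)
    if np.any(np.diff(mu) <= 0):
        raise ParameterError("generated curve is not strictly monotone; "
                             "reduce wiggle_amp or noise_amp")
    return CalibrationCurve(theta, mu, np.full(theta.size, float(sigma)),
                            name="synthetic", kind="atmospheric")


def identity_curve(span: tuple[float, float] = (12000.0, 0.0),
                   sigma: float = 0.0,
                   knot_step: float = 50.0) -> CalibrationCurve:
    """Analytic curve with mu(theta) = theta and constant error."""
    old, young = float(span[0]), float(span[1])
    theta = np.arange(young, old + knot_step * 1e-9, knot_step)
    return CalibrationCurve(theta, theta.copy(),
                            np.full(theta.size, float(sigma)),
                            name="identity", kind="atmospheric")


# ---------------------------------------------------------------------------
# date archives
# ---------------------------------------------------------------------------

def pulse_intensity(window: tuple[float, float],
                    pulses: Sequence[tuple[float, float]] = (PULSE_P1, PULSE_P2),
                    odds: float = 3.0
                    ) -> list[tuple[tuple[float, float], float]]:
    """Piecewise-constant intensity: background 1, ``odds`` inside pulses."""
    old, young = float(window[0]), float(window[1])
    edges = sorted({old, young} | {b for p in pulses for b in p},
                   reverse=True)
    segs = []
    for a, b in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (a + b)
        rate = odds if any(po >= mid >= py for po, py in pulses) else 1.0
        segs.append(((a, b), rate))
    return segs


def sample_dates(intensity: Sequence[tuple[tuple[float, float], float]],
                 n: int, error_pool: Sequence[float],
                 curve: CalibrationCurve, seed: int | None = None,
                 label: str = "synthetic dates"
                 ) -> tuple[DateSet, SyntheticTruth]:
    """Draw a date archive from a piecewise-constant calendar intensity.

    Calendar ages are sampled from the normalized intensity (windows are
    (old, young) pairs with relative rates), each age receives a lab error
    resampled from ``error_pool`` and is back-calibrated: the simulated
    determination is mu(age) plus Gaussian noise with sd
    sqrt(sigma_c^2 + sigma_lab^2).
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if not intensity:
        raise ParameterError("intensity must be non-empty")
    windows = [(float(w[0]), float(w[1])) for w, _ in intensity]
    rates = np.array([float(r) for _, r in intensity])
    if np.any(rates <= 0):
        raise ParameterError("intensity rates must be > 0")
    lo, hi = curve.span
    for old, young in windows:
        if not old > young:
            raise ParameterError("intensity windows must be (old, young)")
        if young < lo or old > hi:
            raise ParameterError("intensity window outside curve span")
    widths = np.array([old - young for old, young in windows])
    weights = rates * widths
    weights = weights / weights.sum()

    rng = np.random.default_rng(seed)
    which = rng.choice(len(windows), size=n, p=weights)
    u = rng.uniform(0.0, 1.0, size=n)
    olds = np.array([w[0] for w in windows])
    youngs = np.array([w[1] for w in windows])
    true_ages = youngs[which] + u * (olds[which] - youngs[which])

    pool = np.asarray(error_pool, dtype=float)
    sigmas = rng.choice(pool, size=n, replace=True)
    mu, sigc = curve_at(curve, true_ages)
    c14 = mu + rng.normal(0.0, 1.0, size=n) * np.sqrt(
        np.asarray(sigc) ** 2 + sigmas ** 2)
    dates = [C14Date(lab_id=f"SIM-{i:04d}", c14_age=float(c14[i]),
                     c14_error=float(sigmas[i]), material="synthetic shell")
             for i in range(n)]
    truth = SyntheticTruth(kind="date_archive", seed=seed, params={
        "intensity": [[list(w), r] for w, r in zip(windows, rates)],
        "n": n, "true_ages": true_ages, "sigmas": sigmas,
        "curve": curve.name,
    })
    return DateSet(dates=dates, label=label), truth


# ---------------------------------------------------------------------------
# training sets
# ---------------------------------------------------------------------------

def make_training_set(n_samples: int = 150, n_taxa: int = 40,
                      gradient: tuple[float, float] = (0.0, 30.0),
                      max_abundance: float = 80.0,
                      tolerance_range: tuple[float, float] = (1.5, 4.0),
                      count_model: str = "poisson",
                      transform: str = "sqrt",
                      seed: int | None = 0
                      ) -> tuple[TrainingSet, SyntheticTruth]:
    """Gaussian-niche species counts along a salinity gradient.

    Sample salinities and taxon optima are uniform on ``gradient``; niche
    tolerances are uniform on ``tolerance_range``; the expected abundance
    is ``max_abundance * exp(-(x - u)^2 / (2 t^2))`` with optional Poisson
    count noise.  All-zero rows are redrawn; all-zero taxa are dropped.
    """
    if n_taxa < 2:
        raise ParameterError("n_taxa must be >= 2")
    lo, hi = float(gradient[0]), float(gradient[1])
    if not hi > lo:
        raise ParameterError("gradient must be non-degenerate")
    if count_model not in ("poisson", "none"):
        raise ParameterError("count_model must be 'poisson' or 'none'")
    rng = np.random.default_rng(seed)
    env = rng.uniform(lo, hi, size=n_samples)
    optima = rng.uniform(lo, hi, size=n_taxa)
    tols = rng.uniform(float(tolerance_range[0]), float(tolerance_range[1]),
                       size=n_taxa)
    lam = max_abundance * np.exp(
        -((env[:, None] - optima[None, :]) ** 2) / (2.0 * tols[None, :] ** 2))
    if count_model == "poisson":
        Y = rng.poisson(lam).astype(float)
        for _ in range(100):
            zero_rows = np.flatnonzero(Y.sum(axis=1) == 0)
            if zero_rows.size == 0:
                break
            Y[zero_rows] = rng.poisson(lam[zero_rows]).astype(float)
        else:
            # pathological niche config: pin the largest expected cell to 1
            for i in np.flatnonzero(Y.sum(axis=1) == 0):
                Y[i, int(np.argmax(lam[i]))] = 1.0
    else:
        Y = lam
    keep = Y.sum(axis=0) > 0
    names = [f"taxon_{k:03d}" for k in range(n_taxa)]
    ts = TrainingSet(abundances=Y[:, keep], env=env,
                     taxon_names=[n for n, k in zip(names, keep) if k],
                     sample_ids=[f"S{i:03d}" for i in range(n_samples)],
                     transform=transform)
    truth = SyntheticTruth(kind="training_set", seed=seed, params={
        "env": env, "optima": optima[keep], "tolerances": tols[keep],
        "optima_all": optima, "gradient": [lo, hi],
        "max_abundance": max_abundance, "count_model": count_model,
        "taxon_names": ts.taxon_names,
    })
    return ts, truth


# ---------------------------------------------------------------------------
# sediment cores
# ---------------------------------------------------------------------------

def make_core(site: str = "SYN",
              pulses: Sequence[tuple[float, float]] = (PULSE_P1, PULSE_P2),
              base_flux: float = 100.0, pulse_multiplier: float = 3.0,
              sar: float = 0.05, noise_sd: float = 0.5,
              window: tuple[float, float] = (8000.0, 4000.0),
              sample_step: float = 20.0, proxy: str = "pigments",
              seed: int | None = 0
              ) -> tuple[CoreRecord, list[tuple[float, float, float]],
                         SyntheticTruth]:
    """Core with constant accumulation and boxcar production pulses.

    Ages on a regular ``sample_step`` grid are mapped to depths through the
    constant SAR (depth 0 at the young end); the latent flux is
    ``base_flux`` outside pulses and ``base_flux * pulse_multiplier``
    inside, and the stored concentration is flux / SAR times lognormal
    noise (sigma ``noise_sd`` on the log scale).  Control points are exact.
    """
    if sar <= 0:
        raise ParameterError("sar must be > 0")
    old, young = float(window[0]), float(window[1])
    rng = np.random.default_rng(seed)
    ages = np.arange(young, old + sample_step * 1e-9, sample_step)
    depths = (ages - young) * sar
    in_pulse = np.zeros(ages.size, dtype=bool)
    for po, py in pulses:
        in_pulse |= (ages >= py) & (ages <= po)
    flux_true = np.where(in_pulse, base_flux * pulse_multiplier, base_flux)
    noise = np.exp(rng.normal(0.0, noise_sd, size=ages.size)) \
        if noise_sd > 0 else 1.0
    conc = flux_true / sar * noise
    record = CoreRecord(site=site, depths=depths, values={proxy: conc},
                        units={proxy: "nmol g-1"})
    mid = ages.size // 2
    controls = [(float(depths[0]), float(ages[0]), 30.0),
                (float(depths[mid]), float(ages[mid]), 30.0),
                (float(depths[-1]), float(ages[-1]), 30.0)]
    truth = SyntheticTruth(kind="core", seed=seed, params={
        "site": site, "pulses": [list(p) for p in pulses],
        "base_flux": base_flux, "pulse_multiplier": pulse_multiplier,
        "sar": sar, "noise_sd": noise_sd, "window": [old, young],
        "ages": ages, "true_flux": flux_true, "proxy": proxy,
    })
    return record, controls, truth


# ---------------------------------------------------------------------------
# isotope samples
# ---------------------------------------------------------------------------

def make_isotope_samples(period_fractions: Mapping[str, float] | None = None,
                         n_per_period: Mapping[str, int] | int = 20,
                         cfg: MixingConfig = DEFAULT_MIXING,
                         table: PeriodTable = DEFAULT_PERIODS,
                         noise_sd: float = 0.5, taxon: str = "human",
                         seed: int | None = 0):
    """Two-endmember isotope mixtures with period-dependent marine fraction.

    For each period with marine fraction f, every configured isotope gets
    delta = terrestrial + f * (marine - terrestrial) + N(0, noise_sd).
    Default fractions follow the regional pattern of a strongly marine
    Mesolithic diet giving way to a terrestrial Neolithic one.

    Returns (DataFrame in the standard isotope-table layout, truth).
    """
    if period_fractions is None:
        period_fractions = {"Kongemose": 8.0 / 9.0, "Ertebølle": 8.0 / 9.0,
                            "earlier Neolithic": 1.0 / 9.0,
                            "later Neolithic": 1.0 / 9.0}
    for label, f in period_fractions.items():
        if not 0.0 <= f <= 1.0:
            raise ParameterError(f"{label}: fraction must be in [0, 1]")
    bounds = {p[0]: (p[1], p[2]) for p in table.periods}
    rng = np.random.default_rng(seed)
    rows = []
    for label, f in period_fractions.items():
        if label not in bounds:
            raise ParameterError(f"unknown period {label!r}")
        n = n_per_period[label] if isinstance(n_per_period, Mapping) \
            else int(n_per_period)
        old, young = bounds[label]
        mid = 0.5 * (old + young)
        for i in range(n):
            row = {"id": f"{label[:4]}-{i:03d}", "taxon": taxon,
                   "period": label, "age_calbp": mid,
                   "d13c": np.nan, "d15n": np.nan, "d2h": np.nan}
            for iso, (marine, terr) in cfg.endmembers.items():
                row[iso] = terr + f * (marine - terr) + \
                    rng.normal(0.0, noise_sd)
            rows.append(row)
    import pandas as pd
    df = pd.DataFrame(rows)
    truth = SyntheticTruth(kind="isotopes", seed=seed, params={
        "period_fractions": dict(period_fractions),
        "noise_sd": noise_sd,
        "endmembers": {k: list(v) for k, v in cfg.endmembers.items()},
    })
    return df, truth


def synthetic_isotope_compilation(seed: int | None = 0, spread: float = 1.0):
    """SYNTHETIC stand-in for the (undeposited) regional collagen compilation.

    The real multi-site compilation of Mesolithic/Neolithic human collagen
    measurements is not publicly archived, so this generator constructs a
    stand-in whose group sizes and group means equal the published summary
    signature of that compilation:

    * delta13C: Kongemose (n=14) and Ertebølle (n=12) at -13 permil;
      earlier Neolithic (n=42) and later Neolithic (n=18) at -20 permil;
    * delta15N: Mesolithic groups at 13 permil, Neolithic at 9.5 permil;
    * delta2H: 4 Mesolithic samples at +66 permil, 8 Neolithic at -5.

    Within-group spread is Gaussian with sd ``spread`` (permil), recentred
    so each group mean is exact.  Only the stated group means and counts
    are faithful; covariance structure, site identity and measurement
    error are invented.
    """
    import pandas as pd
    rng = np.random.default_rng(seed)
    groups = [  # (period, n, d13c mean, d15n mean)
        ("Kongemose", 14, -13.0, 13.0),
        ("Ertebølle", 12, -13.0, 13.0),
        ("earlier Neolithic", 42, -20.0, 9.5),
        ("later Neolithic", 18, -20.0, 9.5),
    ]
    bounds = {p[0]: (p[1], p[2]) for p in DEFAULT_PERIODS.periods}

    def centred(n, mean):
        x = rng.normal(0.0, spread, size=n)
        return mean + x - x.mean()

    rows = []
    for period, n, mc, mn in groups:
        old, young = bounds[period]
        d13c = centred(n, mc)
        d15n = centred(n, mn)
        for i in range(n):
            rows.append({"id": f"{period[:4]}-{i:03d}", "taxon": "human",
                         "period": period, "age_calbp": 0.5 * (old + young),
                         "d13c": d13c[i], "d15n": d15n[i], "d2h": np.nan})
    df = pd.DataFrame(rows)
    # delta2H subset: 4 Mesolithic (Ertebølle) and 8 Neolithic (earlier)
    d2h_meso = centred(4, 66.0)
    d2h_neo = centred(8, -5.0)
    idx_meso = df.index[df["period"] == "Ertebølle"][:4]
    idx_neo = df.index[df["period"] == "earlier Neolithic"][:8]
    df.loc[idx_meso, "d2h"] = d2h_meso
    df.loc[idx_neo, "d2h"] = d2h_neo
    truth = SyntheticTruth(kind="isotope_compilation_standin", seed=seed,
                           params={
                               "groups": [list(g) for g in groups],
                               "d2h": {"Mesolithic": [4, 66.0],
                                       "Neolithic": [8, -5.0]},
                               "spread": spread,
                           })
    return df, truth
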