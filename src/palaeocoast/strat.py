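"""Age-depth models, proxy fluxes and multi-site z-score composites.

Sediment-core proxy concentrations (e.g. pigment nmol per g, diatom valves
per g, molluscs per 100 ml) become deposition fluxes by multiplying with
the local sediment accumulation rate (SAR, cm per yr) from a
piecewise-linear age-depth model.  Fluxes from several sites are made
comparable by z-standardizing each site within a common analysis window,
pooling the (age, z) points, and smoothing with robust locally weighted
regression (lowess); sustained excursions of the smooth above a threshold
delimit production phases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

from .errors import (
    CurveRangeError,
    StandardizationError,
    ValidationError,
)

__all__ = [
    "AgeDepthModel",
    "CoreRecord",
    "FluxSeries",
    "CompositeSeries",
    "build_age_model",
    "age_at_depth",
    "sar_at_depth",
    "compute_flux",
    "composite_zscores",
    "detect_production_phases",
    "load_core",
    "load_control_points",
]


@dataclass
class AgeDepthModel:
    """Piecewise-linear age-depth relation through dated control points."""

    depths: np.ndarray        # cm, strictly increasing
    ages: np.ndarray          # cal BP, strictly increasing with depth
    age_sigmas: np.ndarray
    method: str = "piecewise-linear"

    @property
    def span(self) -> tuple[float, float]:
        return float(self.depths[0]), float(self.depths[-1])


@dataclass
class CoreRecord:
    """Depth-resolved proxy concentrations for one site."""

    site: str
    depths: np.ndarray                     # cm, strictly increasing
    values: dict[str, np.ndarray]          # proxy name -> concentrations
    units: dict[str, str] | None = None

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        if np.any(np.diff(self.depths) <= 0):
            raise ValidationError(f"{self.site}: depths must be strictly increasing")
        for name, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.depths.shape:
                raise ValidationError(f"{self.site}/{name}: length mismatch")
            if np.any(v < 0):
                raise ValidationError(f"{self.site}/{name}: concentrations < 0")
            self.values[name] = v


@dataclass
class FluxSeries:
    """Proxy flux (concentration x SAR) against calendar age."""

    site: str
    proxy: str
    ages: np.ndarray          # cal BP
    flux: np.ndarray
    sar: np.ndarray           # cm/yr at each sample
    unit: str = ""


@dataclass
class CompositeSeries:
    """Pooled per-site z-scores with a lowess smooth."""

    points: pd.DataFrame      # columns: site, age, z
    smooth_age: np.ndarray    # ascending cal BP grid
    smooth_z: np.ndarray
    span: float
    window: tuple[float, float]


# ---------------------------------------------------------------------------
# age-depth modelling
# ---------------------------------------------------------------------------

def build_age_model(points: Sequence[tuple[float, float, float]]
                    ) -> AgeDepthModel:
    """Validate control points and store the piecewise-linear interpolant.

    ``points`` are (depth cm, age cal BP, age sigma yr) tuples; ages must
    increase strictly with depth (no reversals).
    """
    pts = sorted((float(d), float(a), float(s)) for d, a, s in points)
    if len(pts) < 2:
        raise ValidationError("age model needs at least 2 control points")
    depths = np.array([p[0] for p in pts])
    ages = np.array([p[1] for p in pts])
    sigmas = np.array([p[2] for p in pts])
    if np.any(np.diff(depths) <= 0):
        raise ValidationError("duplicate control-point depths")
    rev = np.flatnonzero(np.diff(ages) <= 0)
    if rev.size:
        pairs = [f"({depths[i]:g} cm, {ages[i]:g} BP) -> "
                 f"({depths[i + 1]:g} cm, {ages[i + 1]:g} BP)" for i in rev]
        raise ValidationError("age reversal(s) in control points: "
                              + "; ".join(pairs))
    return AgeDepthModel(depths=depths, ages=ages, age_sigmas=sigmas)


def _check_span(adm: AgeDepthModel, depth) -> np.ndarray:
    d = np.asarray(depth, dtype=float)
    lo, hi = adm.span
    if np.any(d < lo) or np.any(d > hi):
        raise CurveRangeError(
            f"depth outside modelled span [{lo}, {hi}] cm (no extrapolation)")
    return d


def age_at_depth(adm: AgeDepthModel, depth):
    """Interpolated calendar age at depth(s); extrapolation refused."""
    d = _check_span(adm, depth)
    out = np.interp(d, adm.depths, adm.ages)
    return float(out) if np.isscalar(depth) else out


def sar_at_depth(adm: AgeDepthModel, depth):
    """Sediment accumulation rate (cm/yr): local segment slope d(depth)/d(age).

    At a knot the shallower (younger) segment's slope applies.
    """
    d = _check_span(adm, depth)
    seg = np.clip(np.searchsorted(adm.depths, d, side="left") - 1,
                  0, adm.depths.size - 2)
    slopes = np.diff(adm.depths) / np.diff(adm.ages)
    out = slopes[seg]
    return float(out) if np.isscalar(depth) else out


# ---------------------------------------------------------------------------
# flux and compositing
# ---------------------------------------------------------------------------

def compute_flux(record: CoreRecord, adm: AgeDepthModel,
                 proxy: str) -> FluxSeries:
    """flux_i = concentration_i * SAR(depth_i), with ages from the model."""
    if proxy not in record.values:
        raise KeyError(f"proxy {proxy!r} not in core {record.site!r} "
                       f"(has {sorted(record.values)})")
    lo, hi = adm.span
    bad = np.flatnonzero((record.depths < lo) | (record.depths > hi))
    if bad.size:
        raise CurveRangeError(
            f"{record.site}: sample depths {record.depths[bad].tolist()} cm "
            f"outside age-model span [{lo}, {hi}] cm")
    sar = sar_at_depth(adm, record.depths)
    ages = age_at_depth(adm, record.depths)
    conc_unit = (record.units or {}).get(proxy, "")
    unit = f"{conc_unit} x cm yr-1".strip()
    return FluxSeries(site=record.site, proxy=proxy, ages=ages,
                      flux=record.values[proxy] * sar, sar=sar, unit=unit)


def _zscore(x: np.ndarray, site: str, ddof: int = 1) -> np.ndarray:
    sd = float(np.std(x, ddof=ddof))
    if sd == 0 or not np.isfinite(sd):
        raise StandardizationError(
            f"site {site!r}: zero variance in window, cannot z-standardize")
    return (x - float(np.mean(x))) / sd


def composite_zscores(series: Sequence[FluxSeries],
                      window: tuple[float, float],
                      span: float = 0.1,
                      grid_step: float = 10.0,
                      robust_iter: int = 3) -> CompositeSeries:
    """Pool per-site z-scores inside a window and smooth with lowess.

    Each series is restricted to ``window = (old, young)`` and standardized
    to mean 0, sd 1 within it; all (age, z) points are pooled and a robust
    locally-weighted linear regression (tricube weights, fraction ``span``,
    ``robust_iter`` robustifying iterations) is evaluated on a
    ``grid_step``-yr calendar grid.
    """
    old, young = float(window[0]), float(window[1])
    if not old > young:
        raise ValidationError("window must be (old, young) with old > young")
    if len(series) == 0:
        raise ValidationError("need at least one flux series")
    frames = []
    for fs in series:
        m = (fs.ages >= young) & (fs.ages <= old)
        if int(m.sum()) < 3:
            raise ValidationError(
                f"site {fs.site!r}: fewer than 3 samples inside window")
        frames.append(pd.DataFrame({
            "site": fs.site,
            "age": fs.ages[m],
            "z": _zscore(fs.flux[m], fs.site),
        }))
    points = pd.concat(frames, ignore_index=True).sort_values(
        "age", kind="stable", ignore_index=True)
    grid = np.arange(young, old + grid_step * 1e-9, grid_step)
    smooth = _lowess(points["z"].to_numpy(), points["age"].to_numpy(),
                     frac=span, it=robust_iter, xvals=grid)
    return CompositeSeries(points=points, smooth_age=grid, smooth_z=smooth,
                           span=span, window=(old, young))


def detect_production_phases(cs: CompositeSeries, threshold_sd: float = 0.5,
                             min_duration: float = 100.0
                             ) -> list[tuple[float, float]]:
    """Intervals (old, young) where the smoothed composite exceeds a threshold.

    Maximal grid runs with smooth > ``threshold_sd`` are kept when they
    span at least ``min_duration`` calendar years, and reported oldest
    first.  The threshold convention (0.5 sd, 100 yr) is a package default
    for operationalizing "production phase", not a literature constant.
    """
    mask = cs.smooth_z > threshold_sd
    idx = np.flatnonzero(mask)
    phases: list[tuple[float, float]] = []
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        for a, b in zip(starts, ends):
            young_age = float(cs.smooth_age[idx[a]])
            old_age = float(cs.smooth_age[idx[b]])
            if old_age - young_age >= min_duration:
                phases.append((old_age, young_age))
    phases.sort(key=lambda p: -p[0])
    return phases


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def load_core(path, site: str | None = None) -> CoreRecord:
    """CSV layout: depth_cm, then one column per proxy."""
    df = pd.read_csv(path, comment="#")
    if df.columns[0] != "depth_cm":
        raise ValidationError("core CSV must start with a depth_cm column")
    values = {str(c): df[c].to_numpy(dtype=float) for c in df.columns[1:]}
    return CoreRecord(site=site or "core",
                      depths=df["depth_cm"].to_numpy(dtype=float),
                      values=values)


def load_control_points(path) -> list[tuple[float, float, float]]:
    """CSV layout: depth_cm, cal_bp, sigma."""
    df = pd.read_csv(path, comment="#")
    need = {"depth_cm", "cal_bp", "sigma"}
    if not need <= set(df.columns):
        raise ValidationError(f"control-point CSV needs columns {sorted(need)}")
    return [(float(r.depth_cm), float(r.cal_bp), float(r.sigma))
            for r in df.itertuples(index=False)]
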