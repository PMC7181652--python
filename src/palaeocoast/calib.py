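"""Radiocarbon calibration.

Calendar ages are expressed in calendar years before present (cal BP,
present = AD 1950).  A calibration curve tabulates the conventional
radiocarbon age mu(theta) and its one-sigma uncertainty sigma_c(theta) at
a set of calendar-age knots; between knots both are interpolated linearly.

Calibrating a determination ``r +/- sigma_lab`` against a curve places, at
every grid age theta, the Gaussian likelihood

    L(theta) = exp( -(r - dR - mu(theta))^2 /
                    (2 * (sigma_lab^2 + sigma_dR^2 + sigma_c(theta)^2)) )

which is normalized over the grid to a unit-mass probability distribution
(mass per grid cell).  ``dR`` is an optional marine reservoir offset
subtracted from the determination before matching.

Grids are ascending in cal BP (index 0 = youngest cell) and aligned to
integer multiples of the grid step so that densities from different dates
can be added cell-by-cell without interpolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    CalibrationError,
    CurveFormatError,
    CurveRangeError,
    ValidationError,
)

__all__ = [
    "CalibrationCurve",
    "C14Date",
    "CalibratedDensity",
    "load_curve",
    "write_curve",
    "curve_at",
    "calibrate",
    "uncalibrate",
    "hpd_interval",
    "load_dates",
    "write_dates",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CalibrationCurve:
    """Tabulated mapping from calendar age to conventional 14C age.

    Parameters
    ----------
    cal_age, c14_age, curve_sigma
        Knot columns; ``cal_age`` must be strictly increasing (cal BP).
        ``curve_sigma`` is the one-sigma curve uncertainty in 14C yr and
        may be zero (useful for analytic test curves).
    kind
        ``"atmospheric"`` or ``"marine"``.  Marine curves are calibrated
        with a per-date reservoir offset (``C14Date.delta_r``).
    """

    cal_age: np.ndarray
    c14_age: np.ndarray
    curve_sigma: np.ndarray
    name: str = "curve"
    kind: str = "atmospheric"
    _grid_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.cal_age = np.asarray(self.cal_age, dtype=float)
        self.c14_age = np.asarray(self.c14_age, dtype=float)
        self.curve_sigma = np.asarray(self.curve_sigma, dtype=float)
        if self.cal_age.ndim != 1 or self.cal_age.size < 2:
            raise ValidationError("calibration curve needs at least 2 knots")
        if self.c14_age.shape != self.cal_age.shape or \
                self.curve_sigma.shape != self.cal_age.shape:
            raise ValidationError("curve columns must have equal length")
        d = np.diff(self.cal_age)
        if np.any(d <= 0):
            raise ValidationError("cal_age knots must be strictly increasing")
        if np.any(self.curve_sigma < 0):
            raise ValidationError("curve_sigma must be non-negative")
        if self.kind not in ("atmospheric", "marine"):
            raise ValidationError(f"unknown curve kind {self.kind!r}")
        # monotone mu enables a fast search window during calibration
        self._mu_monotone = bool(np.all(np.diff(self.c14_age) > 0))

    @property
    def span(self) -> tuple[float, float]:
        """(youngest, oldest) calendar age covered by the curve."""
        return float(self.cal_age[0]), float(self.cal_age[-1])

    def gridded(self, grid_step: float = 1.0):
        """Curve mean/sigma evaluated on the aligned calendar grid.

        The grid consists of integer multiples of ``grid_step`` inside the
        curve span, shared by every density built from this curve.
        """
        key = float(grid_step)
        if key not in self._grid_cache:
            lo, hi = self.span
            start = np.ceil(lo / key) * key
            grid = np.arange(start, hi + key * 1e-9, key)
            mu = np.interp(grid, self.cal_age, self.c14_age)
            sig = np.interp(grid, self.cal_age, self.curve_sigma)
            self._grid_cache[key] = (grid, mu, sig)
        return self._grid_cache[key]


@dataclass(frozen=True)
class C14Date:
    """A conventional radiocarbon determination.

    ``delta_r`` (and its error) express a local marine reservoir offset in
    14C yr, subtracted from ``c14_age`` prior to calibration; both default
    to zero for terrestrial samples.
    """

    lab_id: str
    c14_age: float
    c14_error: float
    delta_r: float = 0.0
    delta_r_error: float = 0.0
    material: str = ""

    def __post_init__(self):
        if not self.c14_error > 0:
            raise ValidationError(f"{self.lab_id}: c14_error must be > 0")
        if self.delta_r_error < 0:
            raise ValidationError(f"{self.lab_id}: delta_r_error must be >= 0")


@dataclass
class CalibratedDensity:
    """Probability mass per calendar grid cell for one calibrated date."""

    grid_start: float            # cal BP of the first (youngest) cell
    grid_step: float
    mass: np.ndarray             # sums to 1

    def __post_init__(self):
        self.mass = np.asarray(self.mass, dtype=float)
        if np.any(self.mass < 0):
            raise ValidationError("density mass must be non-negative")
        if abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValidationError("density mass must sum to 1 within 1e-9")

    @property
    def ages(self) -> np.ndarray:
        return self.grid_start + self.grid_step * np.arange(self.mass.size)

    def median(self) -> float:
        cum = np.cumsum(self.mass)
        return float(self.ages[int(np.searchsorted(cum, 0.5))])

    def mode(self) -> float:
        return float(self.ages[int(np.argmax(self.mass))])

    def mean(self) -> float:
        return float(np.sum(self.ages * self.mass))

    def sd(self) -> float:
        m = self.mean()
        return float(np.sqrt(np.sum((self.ages - m) ** 2 * self.mass)))


# ---------------------------------------------------------------------------
# curve I/O
# ---------------------------------------------------------------------------

def load_curve(path, name: str | None = None,
               kind: str = "atmospheric") -> CalibrationCurve:
    """Read a calibration curve from a text file.

    Accepts the common curve dialect: lines starting with ``#`` and blank
    lines ignored, remaining lines comma- or whitespace-separated with the
    first three columns interpreted as (cal BP, 14C age BP, curve error).
    Rows may appear in either calendar order (curve files are customarily
    written oldest-first); knots are sorted ascending on load.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",") if "," in line else line.split()
            if len(parts) < 3:
                raise CurveFormatError(
                    f"{path.name}:{lineno}: expected >=3 columns, got {len(parts)}")
            try:
                rows.append(tuple(float(p) for p in parts[:3]))
            except ValueError as exc:
                raise CurveFormatError(
                    f"{path.name}:{lineno}: unparseable value ({exc})") from None
    if len(rows) < 2:
        raise CurveFormatError(f"{path.name}: fewer than 2 data rows")
    arr = np.asarray(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    if np.any(np.diff(arr[:, 0]) == 0):
        raise ValidationError(f"{path.name}: duplicate cal BP knots")
    return CalibrationCurve(arr[:, 0], arr[:, 1], arr[:, 2],
                            name=name or path.stem, kind=kind)


def write_curve(curve: CalibrationCurve, path) -> None:
    """Write a curve in the same text dialect ``load_curve`` reads.

    Knots are written oldest-first with full float precision so that a
    write/read cycle round-trips bit-identically.
    """
    with open(path, "w") as fh:
        fh.write(f"# calibration curve: {curve.name} ({curve.kind})\n")
        fh.write("# cal_bp,c14_bp,sigma\n")
        for i in range(curve.cal_age.size - 1, -1, -1):
            fh.write(f"{float(curve.cal_age[i])!r},{float(curve.c14_age[i])!r},"
                     f"{float(curve.curve_sigma[i])!r}\n")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def curve_at(curve: CalibrationCurve, cal_age):
    """Interpolated (mu, sigma_c) at one or many calendar ages."""
    ages = np.asarray(cal_age, dtype=float)
    lo, hi = curve.span
    if np.any(ages < lo) or np.any(ages > hi):
        raise CurveRangeError(
            f"calendar age outside curve span [{lo}, {hi}]")
    mu = np.interp(ages, curve.cal_age, curve.c14_age)
    sig = np.interp(ages, curve.cal_age, curve.curve_sigma)
    if np.isscalar(cal_age) or ages.ndim == 0:
        return float(mu), float(sig)
    return mu, sig


def _trim(mass: np.ndarray, trim_mass: float) -> tuple[int, int]:
    """Indices (i0, i1) of the retained slice after tail trimming.

    Removes the smallest leading and trailing runs of cells whose combined
    mass does not exceed ``trim_mass`` (at most half from each tail), so
    the retained contiguous span holds >= 1 - trim_mass of the mass.
    """
    half = trim_mass / 2.0
    cum = np.cumsum(mass)
    i0 = int(np.searchsorted(cum, half, side="right"))
    rcum = np.cumsum(mass[::-1])
    n_drop_tail = int(np.searchsorted(rcum, half, side="right"))
    i1 = max(mass.size - n_drop_tail, i0 + 1)
    return i0, i1


def calibrate(date: C14Date, curve: CalibrationCurve, grid_step: float = 1.0,
              trim_mass: float = 1e-5) -> CalibratedDensity:
    """Calibrate one determination to a calendar-age probability density.

    The unnormalized density follows the Gaussian kernel described in the
    module docstring; the result is normalized to unit mass and trimmed to
    the smallest contiguous span holding at least ``1 - trim_mass`` of the
    mass (then renormalized).

    Raises
    ------
    CalibrationError
        If the determination is inconsistent with the curve everywhere
        (maximum unnormalized density below 1e-300).
    """
    grid, mu, sig = curve.gridded(grid_step)
    r = date.c14_age - date.delta_r
    var_base = date.c14_error ** 2 + date.delta_r_error ** 2

    if curve._mu_monotone:
        # restrict the evaluation to +/- 8 combined sigma around the match;
        # density outside is < exp(-32) and far below trim_mass resolution
        s = float(np.sqrt(var_base + float(sig.max()) ** 2))
        lo = int(np.searchsorted(mu, r - 8.0 * s)) - 1
        hi = int(np.searchsorted(mu, r + 8.0 * s)) + 1
        lo = max(lo, 0)
        hi = min(hi, grid.size)
        if hi <= lo:
            lo, hi = max(0, min(lo, grid.size - 1)), min(grid.size, lo + 1)
    else:
        lo, hi = 0, grid.size

    var = var_base + sig[lo:hi] ** 2
    logd = -((r - mu[lo:hi]) ** 2) / (2.0 * var)
    if logd.size == 0 or float(logd.max()) < np.log(1e-300):
        raise CalibrationError(
            f"{date.lab_id}: determination {date.c14_age}+/-{date.c14_error} "
            f"is inconsistent with curve {curve.name!r} everywhere")
    mass = np.exp(logd)
    mass /= mass.sum()
    i0, i1 = _trim(mass, trim_mass)
    mass = mass[i0:i1]
    mass = mass / mass.sum()
    return CalibratedDensity(grid_start=float(grid[lo + i0]),
                             grid_step=float(grid_step), mass=mass)


def uncalibrate(cal_age, curve: CalibrationCurve, sigma_lab: float,
                rng) -> float | np.ndarray:
    """Back-calibrate calendar age(s) to simulated 14C determination(s).

    Returns ``mu(cal_age)`` plus Gaussian noise with standard deviation
    ``sqrt(sigma_c(cal_age)^2 + sigma_lab^2)``.  ``rng`` is an integer seed
    or a ``numpy.random.Generator``; results are deterministic given the
    seed.  ``sigma_lab`` may be a scalar or an array matching ``cal_age``.
    """
    gen = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    sigma_lab = np.asarray(sigma_lab, dtype=float)
    if np.any(sigma_lab <= 0):
        raise ValidationError("sigma_lab must be > 0")
    mu, sigc = curve_at(curve, cal_age)
    sd = np.sqrt(np.asarray(sigc) ** 2 + sigma_lab ** 2)
    out = mu + gen.normal(0.0, 1.0, size=np.shape(mu)) * sd
    if np.isscalar(cal_age):
        return float(out)
    return out


def hpd_interval(d: CalibratedDensity,
                 mass: float = 0.954) -> list[tuple[float, float]]:
    """Highest-posterior-density interval set.

    Grid cells are accumulated in order of descending density until the
    requested mass is reached; contiguous selected cells are merged into
    closed intervals ``(young, old)`` in cal BP, returned youngest-first.
    """
    if not 0.0 < mass < 1.0:
        raise ValidationError("mass must be in (0, 1)")
    order = np.argsort(-d.mass, kind="stable")
    cum = np.cumsum(d.mass[order])
    k = int(np.searchsorted(cum, mass)) + 1
    sel = np.sort(order[:k])
    ages = d.ages
    breaks = np.flatnonzero(np.diff(sel) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [sel.size - 1]))
    return [(float(ages[sel[a]]), float(ages[sel[b]]))
            for a, b in zip(starts, ends)]


# ---------------------------------------------------------------------------
# date-list I/O
# ---------------------------------------------------------------------------

def load_dates(path) -> list[C14Date]:
    """Read a CSV date list.

    Required columns: ``lab_id, c14_age, c14_error``.  Optional columns
    ``delta_r, delta_r_error, material`` default to 0/0/"".
    """
    df = pd.read_csv(path, comment="#")
    required = {"lab_id", "c14_age", "c14_error"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"date CSV missing columns: {sorted(missing)}")
    dates = []
    for row in df.itertuples(index=False):
        dates.append(C14Date(
            lab_id=str(row.lab_id),
            c14_age=float(row.c14_age),
            c14_error=float(row.c14_error),
            delta_r=float(getattr(row, "delta_r", 0.0) or 0.0),
            delta_r_error=float(getattr(row, "delta_r_error", 0.0) or 0.0),
            material=str(getattr(row, "material", "") or ""),
        ))
    return dates


def write_dates(dates: Sequence[C14Date], path, header: str = "") -> None:
    df = pd.DataFrame([dataclasses.asdict(d) for d in dates])
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
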