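"""Stable-isotope diet partitioning for human and dog bone collagen.

delta13C (VPDB), delta15N (AIR) and delta2H (VSMOW) values of collagen
track the marine versus terrestrial contribution to protein intake.
Samples are grouped by cultural period (either an explicit label or an
age placed into a period table), summarized with box-plot statistics, and
converted to a marine-resource fraction with a two-endmember linear
mixing model

    f_marine = (delta - delta_terrestrial) / (delta_marine - delta_terrestrial)

clipped to [0, 1].  Endmember values must be configured; the defaults
shipped here (delta13C -12/-21 permil, delta2H +70/-10 permil) are package
conventions for collagen in this region, not universal constants.
delta15N is trophic-level enriched and excluded from mixing by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, CurveRangeError, ValidationError

__all__ = [
    "IsotopeSample",
    "PeriodTable",
    "MixingConfig",
    "MixingFraction",
    "DEFAULT_PERIODS",
    "DEFAULT_MIXING",
    "ISOTOPES",
    "assign_period",
    "summarize_by_period",
    "mixing_fraction",
    "marine_fractions",
    "load_isotopes",
]

logger = logging.getLogger(__name__)

ISOTOPES = ("d13c", "d15n", "d2h")


@dataclass(frozen=True)
class IsotopeSample:
    """One collagen measurement; at least one isotope must be present."""

    id: str
    taxon: str = "human"              # "human" or "dog"
    period: str | None = None
    age: float | None = None          # cal BP
    d13c: float | None = None
    d15n: float | None = None
    d2h: float | None = None

    def __post_init__(self):
        if self.d13c is None and self.d15n is None and self.d2h is None:
            raise ValidationError(f"{self.id}: no isotope value present")


@dataclass(frozen=True)
class PeriodTable:
    """Ordered, contiguous cultural periods, oldest first.

    Each period is (label, old_bound, young_bound) in cal BP with
    old_bound > young_bound; consecutive periods share a boundary.  An age
    belongs to the period with old_bound >= age > young_bound (the shared
    boundary goes to the *younger* period, whose old_bound is inclusive).
    """

    periods: tuple[tuple[str, float, float], ...]

    def __post_init__(self):
        if not self.periods:
            raise ValidationError("period table is empty")
        prev_young = None
        for label, old, young in self.periods:
            if not old > young:
                raise ValidationError(f"{label}: old_bound must exceed young_bound")
            if prev_young is not None and old != prev_young:
                raise ValidationError(
                    f"{label}: periods must be contiguous and non-overlapping")
            prev_young = young

    @property
    def span(self) -> tuple[float, float]:
        return self.periods[0][1], self.periods[-1][2]

    @property
    def labels(self) -> list[str]:
        return [p[0] for p in self.periods]


DEFAULT_PERIODS = PeriodTable((
    ("Kongemose", 8400.0, 7400.0),
    ("Ertebølle", 7400.0, 5900.0),
    ("earlier Neolithic", 5900.0, 5000.0),
    ("later Neolithic", 5000.0, 4000.0),
))

MESOLITHIC = ("Kongemose", "Ertebølle")
NEOLITHIC = ("earlier Neolithic", "later Neolithic")


@dataclass(frozen=True)
class MixingConfig:
    """Per-isotope (marine, terrestrial) endmember delta values (permil)."""

    endmembers: dict[str, tuple[float, float]]

    def __post_init__(self):
        for iso, (marine, terr) in self.endmembers.items():
            if marine == terr:
                raise ValidationError(f"{iso}: endmembers must be distinct")


DEFAULT_MIXING = MixingConfig({
    "d13c": (-12.0, -21.0),
    "d2h": (70.0, -10.0),
})


@dataclass(frozen=True)
class MixingFraction:
    fraction: float
    clipped: bool


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def assign_period(age: float, table: PeriodTable = DEFAULT_PERIODS) -> str:
    """Label of the period containing ``age`` (old inclusive, young exclusive)."""
    old_span, young_span = table.span
    for label, old, young in table.periods:
        if old >= age > young:
            return label
    if age == young_span:              # youngest bound closes the table
        return table.periods[-1][0]
    raise CurveRangeError(
        f"age {age} cal BP outside period table span "
        f"({old_span}-{young_span})")


def _as_frame(samples) -> pd.DataFrame:
    if isinstance(samples, pd.DataFrame):
        df = samples.copy()
    else:
        df = pd.DataFrame([{
            "id": s.id, "taxon": s.taxon, "period": s.period,
            "age_calbp": s.age, "d13c": s.d13c, "d15n": s.d15n, "d2h": s.d2h,
        } for s in samples])
    for col in ("period", "taxon"):
        if col not in df.columns:
            df[col] = None
    for iso in ISOTOPES:
        if iso not in df.columns:
            df[iso] = np.nan
    return df


def _resolve_periods(df: pd.DataFrame, table: PeriodTable) -> pd.DataFrame:
    """Fill missing period labels from ages; drop unplaceable samples."""
    df = df.copy()
    known = set(table.labels)
    out_rows = []
    for i, row in df.iterrows():
        period = row.get("period")
        if isinstance(period, str) and period in known:
            out_rows.append(i)
            continue
        age = row.get("age_calbp")
        if age is not None and np.isfinite(age):
            try:
                df.at[i, "period"] = assign_period(float(age), table)
                out_rows.append(i)
                continue
            except CurveRangeError:
                pass
        logger.info("sample %s: no usable period or age; skipped",
                    row.get("id"))
    return df.loc[out_rows]


def summarize_by_period(samples, table: PeriodTable = DEFAULT_PERIODS,
                        pool_taxa: bool = False,
                        isotopes: Sequence[str] = ISOTOPES) -> pd.DataFrame:
    """Box-plot summaries (n, mean, min, q1, median, q3, max) per group.

    Groups are (taxon, period) or period alone with ``pool_taxa=True``;
    each isotope is summarized over the samples carrying it.  Quartiles use
    the inclusive (linear interpolation) method.  Empty groups are omitted.
    """
    df = _resolve_periods(_as_frame(samples), table)
    if df.empty:
        raise ValidationError("no samples could be placed in a period")
    keys = ["period"] if pool_taxa else ["taxon", "period"]
    rows = []
    for gkey, g in df.groupby(keys, dropna=False, sort=False):
        gkey = gkey if isinstance(gkey, tuple) else (gkey,)
        for iso in isotopes:
            vals = g[iso].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
            rows.append({
                **dict(zip(keys, gkey)),
                "isotope": iso, "n": int(vals.size),
                "mean": float(vals.mean()), "min": float(vals.min()),
                "q1": float(q1), "median": float(med), "q3": float(q3),
                "max": float(vals.max()),
            })
    out = pd.DataFrame(rows)
    order = {label: i for i, label in enumerate(table.labels)}
    if not out.empty:
        out = out.sort_values(
            keys + ["isotope"],
            key=lambda s: s.map(order) if s.name == "period" else s,
            kind="stable", ignore_index=True)
    return out


def mixing_fraction(delta: float, cfg: MixingConfig = DEFAULT_MIXING,
                    isotope: str = "d13c") -> MixingFraction:
    """Marine fraction of one delta value under the two-endmember model."""
    if isotope not in cfg.endmembers:
        raise ConfigurationError(
            f"no endmembers configured for isotope {isotope!r}")
    marine, terr = cfg.endmembers[isotope]
    f = (float(delta) - terr) / (marine - terr)
    clipped = f < 0.0 or f > 1.0
    return MixingFraction(fraction=float(np.clip(f, 0.0, 1.0)),
                          clipped=clipped)


def marine_fractions(samples, cfg: MixingConfig = DEFAULT_MIXING,
                     table: PeriodTable = DEFAULT_PERIODS,
                     isotopes: Iterable[str] | None = None) -> pd.DataFrame:
    """Tidy per-sample marine fractions for every configured isotope."""
    df = _resolve_periods(_as_frame(samples), table)
    isos = list(isotopes) if isotopes is not None else \
        [i for i in ISOTOPES if i in cfg.endmembers]
    rows = []
    for _, row in df.iterrows():
        for iso in isos:
            delta = row.get(iso)
            if delta is None or not np.isfinite(delta):
                continue
            mf = mixing_fraction(float(delta), cfg, iso)
            rows.append({"id": row["id"], "taxon": row["taxon"],
                         "period": row["period"], "isotope": iso,
                         "delta": float(delta), "f_marine": mf.fraction,
                         "clipped": mf.clipped})
    return pd.DataFrame(rows)


def load_isotopes(path) -> pd.DataFrame:
    """CSV layout: id,taxon,period,age_calbp,d13c,d15n,d2h (blanks allowed)."""
    df = pd.read_csv(path, comment="#")
    if "id" not in df.columns:
        raise ValidationError("isotope CSV needs an 'id' column")
    return _as_frame(df)
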