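"""Rarefaction of survey effort: 15 temporal schemes and spatial transect subsets.

Temporal schemes thin the full nightly record to monthly (M), quarterly (Q) or
biannual (B) sampling blocks at five intensities (1-5); spatial schemes keep a
deterministic, evenly spread subset of transects and reuse it every night.
Rarefied capture/effort tables are rebuilt into monthly CPUE panels.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cpue import monthly_cpue
from .simulate import SimConfig

logger = logging.getLogger(__name__)

INTERVAL_DAYS = {"M": 30, "Q": 90, "B": 180}
WEEKS_PER_BLOCK = {1: 4, 2: 4, 3: 2, 4: 1, 5: 1}
NIGHTS_PER_WEEK = {1: 2, 2: 1, 3: 1, 4: 2, 5: 1}
TEMPORAL_CODES = tuple(f"{iv}{k}" for iv in "MQB" for k in range(1, 6))

_WINDOW_DAYS = 28  # four 7-day weeks sampled at the head of each block


@dataclass(frozen=True)
class TemporalScheme:
    """One of the 15 codes: sampling interval x (weeks per block, nights per week)."""

    code: str

    def __post_init__(self):
        if self.code not in TEMPORAL_CODES:
            raise ValueError(f"unknown temporal scheme {self.code!r}; valid: {TEMPORAL_CODES}")

    @property
    def interval_days(self) -> int:
        return INTERVAL_DAYS[self.code[0]]

    @property
    def weeks_per_block(self) -> int:
        return WEEKS_PER_BLOCK[int(self.code[1])]

    @property
    def nights_per_week(self) -> int:
        return NIGHTS_PER_WEEK[int(self.code[1])]


@dataclass(frozen=True)
class SpatialScheme:
    """A fixed transect subset (1-based ids) with its enclosure coverage."""

    n_kept: int
    transect_ids: tuple
    coverage_fraction: float

    @property
    def label(self) -> str:
        return f"{round(100 * self.coverage_fraction):02d}"


def coverage_fraction(n_transects: int, config: SimConfig = SimConfig()) -> float:
    """Unrounded fraction of the enclosure covered by *n_transects* transects
    (strip width plus detection buffer on each side)."""
    if n_transects < 0:
        raise ValueError(f"n_transects must be >= 0, got {n_transects}")
    return (
        n_transects * config.transect_length * config.effective_transect_width
    ) / config.area_m2


def coverage_percent(n_transects: int, config: SimConfig = SimConfig()) -> int:
    """Coverage to the nearest percent, as printed in scheme labels."""
    return round(100 * coverage_fraction(n_transects, config))


def apply_spatial_scheme(n_keep: int, transect_order=None, config: SimConfig = SimConfig()) -> SpatialScheme:
    """Evenly spread, deterministic subset of transects, reused across nights.

    Keeps the transects at indices ``floor(i * T / n_keep)`` for
    ``i = 0..n_keep-1`` over the ordered transect list — for 14 of 29 this is
    the alternating first, third, fifth... pattern.
    """
    if transect_order is None:
        transect_order = list(range(1, config.n_transects + 1))
    total = len(transect_order)
    if not 1 <= n_keep <= total:
        raise ValueError(f"n_keep must be in [1, {total}], got {n_keep}")
    idx = [math.floor(i * total / n_keep) for i in range(n_keep)]
    kept = tuple(transect_order[j] for j in idx)
    return SpatialScheme(
        n_kept=n_keep,
        transect_ids=kept,
        coverage_fraction=coverage_fraction(n_keep, config),
    )


def spatial_scheme_from_spec(spec, config: SimConfig = SimConfig()) -> SpatialScheme:
    """Resolve a transect count (e.g. 14) or percent string (e.g. '25%' or 25.0)
    into a SpatialScheme. Integers <= n_transects are counts; percents are
    matched to the transect count whose rounded coverage equals them."""
    if isinstance(spec, SpatialScheme):
        return spec
    if isinstance(spec, str):
        m = re.fullmatch(r"(\d+)\s*%", spec.strip())
        if m:
            return _scheme_for_percent(int(m.group(1)), config)
        spec = int(spec)
    if isinstance(spec, float) or (isinstance(spec, int) and spec > config.n_transects):
        return _scheme_for_percent(int(round(spec)), config)
    return apply_spatial_scheme(int(spec), config=config)


def _scheme_for_percent(pct: int, config: SimConfig) -> SpatialScheme:
    for n in range(config.n_transects, 0, -1):
        if coverage_percent(n, config) == pct:
            return apply_spatial_scheme(n, config=config)
    raise ValueError(f"no transect count gives {pct}% coverage under this geometry")


def apply_temporal_scheme(
    survey_nights,
    scheme: TemporalScheme | str,
    seed: int = 0,
    start_offset_days: int | None = None,
):
    """Thin a sorted record of survey nights to one temporal scheme.

    Sampled blocks are calendar months stepped by the scheme interval (every
    month, every 3rd, every 6th). A week-phase start offset is drawn once
    (seeded) and anchors the 7-day week bins inside every sampled month; bins
    never cross the month boundary. A week qualifies if it holds at least the
    scheme's nights-per-week; the earliest qualifying weeks (up to
    weeks-per-block) contribute their earliest nights. Months with no
    qualifying week contribute nothing.
    """
    if isinstance(scheme, str):
        scheme = TemporalScheme(scheme)
    nights = pd.DatetimeIndex(sorted(pd.to_datetime(pd.Index(survey_nights)).unique()))
    if len(nights) == 0:
        logger.warning("apply_temporal_scheme: empty survey-night record")
        return pd.DatetimeIndex([])
    if start_offset_days is None:
        start_offset_days = int(np.random.default_rng(seed).integers(0, 7))
    step = scheme.interval_days // 30
    first_month, last_month = pd.Period(nights[0], "M"), pd.Period(nights[-1], "M")
    retained = []
    month = first_month
    while month <= last_month:
        m_end = month.end_time.normalize() + pd.Timedelta(days=1)
        weeks_kept = 0
        for w in range(_WINDOW_DAYS // 7):
            if weeks_kept >= scheme.weeks_per_block:
                break
            lo = month.start_time + pd.Timedelta(days=start_offset_days + 7 * w)
            hi = min(lo + pd.Timedelta(days=7), m_end)
            if lo >= m_end:
                break
            in_week = nights[(nights >= lo) & (nights < hi)]
            if len(in_week) >= scheme.nights_per_week:
                retained.extend(in_week[: scheme.nights_per_week])
                weeks_kept += 1
        month += step
    return pd.DatetimeIndex(sorted(retained))


def _visual_nights(effort: pd.DataFrame) -> pd.DatetimeIndex:
    vis = effort[effort["method"] == "visual"]
    return pd.DatetimeIndex(sorted(pd.to_datetime(vis["date"]).unique()))


def _transect_number(location_id: pd.Series) -> pd.Series:
    return location_id.str.extract(r"(\d+)", expand=False).astype(float)


def rarefy_tables(
    captures: pd.DataFrame,
    effort: pd.DataFrame,
    retained_nights: pd.DatetimeIndex,
    spatial: SpatialScheme,
    config: SimConfig = SimConfig(),
):
    """Filter visual captures/effort to retained nights and transects.

    Effort km is rescaled to the retained transect count; trap records pass
    through untouched (rarefaction applies to visual surveys only).
    """
    caps = captures.copy()
    caps["date"] = pd.to_datetime(caps["date"])
    eff = effort.copy()
    eff["date"] = pd.to_datetime(eff["date"])
    nights = pd.DatetimeIndex(retained_nights)

    vis = caps["method"] == "visual"
    keep_caps = ~vis | (
        caps["date"].isin(nights)
        & _transect_number(caps["location_id"]).isin(spatial.transect_ids)
    )
    caps = caps[keep_caps].reset_index(drop=True)

    vis_eff = eff["method"] == "visual"
    eff = eff[~vis_eff | eff["date"].isin(nights)].reset_index(drop=True)
    still_vis = eff["method"] == "visual"
    eff.loc[still_vis, "n_transects"] = spatial.n_kept
    eff.loc[still_vis, "km"] = spatial.n_kept * config.km_per_transect
    return caps, eff


def rebuild_panel(
    truth: pd.DataFrame,
    captures: pd.DataFrame,
    effort: pd.DataFrame,
    temporal: TemporalScheme | str | None = None,
    spatial: SpatialScheme | int | str | None = None,
    config: SimConfig = SimConfig(),
    seed: int = 0,
    start_offset_days: int | None = None,
) -> pd.DataFrame:
    """Rarefied monthly panel: truth joined with visual CPUE recomputed after
    applying the temporal and spatial filters. Identity filters reproduce the
    unrarefied visual panel."""
    nights = _visual_nights(effort)
    if temporal is not None:
        nights = apply_temporal_scheme(
            nights, temporal, seed=seed, start_offset_days=start_offset_days
        )
    if spatial is None:
        spatial = apply_spatial_scheme(config.n_transects, config=config)
    else:
        spatial = spatial_scheme_from_spec(spatial, config)
    caps, eff = rarefy_tables(captures, effort, nights, spatial, config)
    mc = monthly_cpue(caps, eff, "visual")
    truth = truth.copy()
    truth["month"] = pd.PeriodIndex(truth["month"], freq="M")
    panel = truth.merge(mc, on="month", how="inner")
    return panel.reset_index(drop=True)
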