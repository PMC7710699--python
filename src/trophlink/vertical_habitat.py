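"""Vertical distribution and habitat analysis.

Diel classification (day is one hour after sunrise to one hour before
sunset; night is one hour after sunset to one hour before sunrise; dawn and
dusk tows are twilight and discarded), catch-per-unit-effort standardized
to a 120 m2 net-mouth area, 100-m depth-stratum abundance and size tables,
and temperature/oxygen habitat envelopes from mean CTD profiles.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_io import CTDProfile, Dataset

STANDARD_MOUTH_AREA_M2 = 120.0


def default_strata() -> list[tuple[float, float]]:
    """Half-open 100-m bins tiling 10-1000 m: [10,100), [100,200), ..."""
    edges = [10.0] + [float(x) for x in range(100, 1001, 100)]
    return list(zip(edges[:-1], edges[1:]))


def classify_diel(sample_time: dt.datetime, sunrise: dt.time,
                  sunset: dt.time) -> str:
    """Label a timestamp day / night / twilight for the station's solar times."""
    if sunrise is None or sunset is None:
        raise ValueError("missing solar times")
    if sunrise >= sunset:
        raise ValueError("sunrise must precede sunset")
    day = sample_time.date()
    one_h = dt.timedelta(hours=1)
    t = sample_time
    rise = dt.datetime.combine(day, sunrise)
    setl = dt.datetime.combine(day, sunset)
    if rise + one_h <= t <= setl - one_h:
        return "day"
    # night wraps midnight: after sunset+1h, or before sunrise-1h
    if t >= setl + one_h or t <= rise - one_h:
        return "night"
    return "twilight"


def label_trawls(ds: Dataset) -> Dataset:
    """Fill each trawl's diel_period from its station's solar times (in place)."""
    stations = ds.station_by_id()
    for t in ds.trawls:
        stn = stations.get(t.station_id)
        if stn is None:
            raise KeyError(f"trawl {t.trawl_id}: unknown station {t.station_id}")
        t.diel_period = classify_diel(t.start_time, stn.sunrise, stn.sunset)
    return ds


def cpue(count: float, weight_kg: float, duration_h: float,
         mouth_area_m2: float) -> tuple[float, float]:
    """Standardized CPUE: (individuals/h, kg/h) scaled to a 120 m2 mouth."""
    if duration_h <= 0:
        raise ValueError("duration_h must be > 0")
    if mouth_area_m2 <= 0:
        raise ValueError("mouth_area_m2 must be > 0")
    scale = STANDARD_MOUTH_AREA_M2 / mouth_area_m2
    return (count / duration_h * scale, weight_kg / duration_h * scale)


def _stratum_of(depth: float,
                strata: Sequence[tuple[float, float]]) -> Optional[tuple[float, float]]:
    for lo, hi in strata:
        if lo <= depth < hi:
            return (lo, hi)
    # allow the deepest bound itself to close the last bin
    if strata and depth == strata[-1][1]:
        return strata[-1]
    return None


def stratify(ds: Dataset,
             strata: Optional[Sequence[tuple[float, float]]] = None) -> pd.DataFrame:
    """Mean standardized CPUE per (stratum, diel period).

    Trawls are assigned to the stratum containing their target-depth
    midpoint; twilight or unlabeled trawls are excluded. Unsampled cells are
    emitted with ``n_trawls`` 0 and missing CPUE (missing, not zero).
    """
    strata = list(strata) if strata is not None else default_strata()
    spec_by_trawl: dict[str, list] = {}
    for s in ds.specimens:
        spec_by_trawl.setdefault(s.trawl_id, []).append(s)

    cells: dict[tuple[tuple[float, float], str], dict] = {
        (st, period): {"cpue_n": [], "cpue_w": [], "sl": [], "tw": []}
        for st in strata for period in ("day", "night")}
    for t in ds.trawls:
        if t.diel_period not in ("day", "night"):
            continue
        st = _stratum_of(t.midpoint_depth_m, strata)
        if st is None:
            continue
        specs = spec_by_trawl.get(t.trawl_id, [])
        n = len(specs)
        w_kg = sum(s.total_weight_g for s in specs) / 1000.0
        cn, cw = cpue(n, w_kg, t.duration_h, t.mouth_area_m2)
        cell = cells[(st, t.diel_period)]
        cell["cpue_n"].append(cn)
        cell["cpue_w"].append(cw)
        cell["sl"].extend(s.standard_length_cm for s in specs)
        cell["tw"].extend(s.total_weight_g for s in specs)

    rows = []
    for (lo, hi), period in ((st, p) for st in strata for p in ("day", "night")):
        cell = cells[((lo, hi), period)]
        n_trawls = len(cell["cpue_n"])
        rows.append({
            "stratum_lower_m": lo, "stratum_upper_m": hi, "period": period,
            "n_trawls": n_trawls,
            "cpue_n": np.mean(cell["cpue_n"]) if n_trawls else np.nan,
            "cpue_w": np.mean(cell["cpue_w"]) if n_trawls else np.nan,
            "mean_SL_cm": np.mean(cell["sl"]) if cell["sl"] else np.nan,
            "mean_TW_g": np.mean(cell["tw"]) if cell["tw"] else np.nan,
        })
    return pd.DataFrame(rows)


def size_by_depth(ds: Dataset,
                  strata: Optional[Sequence[tuple[float, float]]] = None) -> pd.DataFrame:
    """Length/weight summaries per (stratum, period) for boxplot-style reporting."""
    strata = list(strata) if strata is not None else default_strata()
    trawl_by_id = ds.trawl_by_id()
    buckets: dict[tuple[tuple[float, float], str], list] = {}
    for s in ds.specimens:
        t = trawl_by_id.get(s.trawl_id)
        if t is None or t.diel_period not in ("day", "night"):
            continue
        st = _stratum_of(t.midpoint_depth_m, strata)
        if st is None:
            continue
        buckets.setdefault((st, t.diel_period), []).append(s)

    rows = []
    for st in strata:
        for period in ("day", "night"):
            specs = buckets.get((st, period), [])
            sl = np.array([s.standard_length_cm for s in specs])
            tw = np.array([s.total_weight_g for s in specs])
            rows.append({
                "stratum_lower_m": st[0], "stratum_upper_m": st[1],
                "period": period, "n": len(specs),
                "mean_SL_cm": sl.mean() if len(sl) else np.nan,
                "median_SL_cm": np.median(sl) if len(sl) else np.nan,
                "q25_SL_cm": np.percentile(sl, 25) if len(sl) else np.nan,
                "q75_SL_cm": np.percentile(sl, 75) if len(sl) else np.nan,
                "mean_TW_g": tw.mean() if len(tw) else np.nan,
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class HabitatEnvelope:
    temp_min: float
    temp_max: float
    oxy_min: float
    oxy_max: float
    depth_min: float
    depth_max: float

    def __post_init__(self) -> None:
        if (self.temp_min > self.temp_max or self.oxy_min > self.oxy_max
                or self.depth_min > self.depth_max):
            raise ValueError("envelope min must be <= max per variable")


def mean_profile(profiles: Sequence[CTDProfile],
                 grid_step_m: float = 1.0) -> pd.DataFrame:
    """Across-station mean temperature/oxygen on a common depth grid.

    Each cast is linearly interpolated onto the grid and contributes only
    over its observed depth range; the mean is taken depth-wise over the
    contributing casts.
    """
    if not profiles:
        raise ValueError("no CTD profiles")
    zmin = min(p.depth_m[0] for p in profiles)
    zmax = max(p.depth_m[-1] for p in profiles)
    grid = np.arange(zmin, zmax + grid_step_m / 2, grid_step_m)
    temp = np.full((len(profiles), len(grid)), np.nan)
    oxy = np.full((len(profiles), len(grid)), np.nan)
    for i, p in enumerate(profiles):
        z = np.asarray(p.depth_m)
        inside = (grid >= z[0]) & (grid <= z[-1])
        temp[i, inside] = np.interp(grid[inside], z, p.temperature_C)
        oxy[i, inside] = np.interp(grid[inside], z, p.oxygen_ml_l)
    with np.errstate(invalid="ignore"):
        return pd.DataFrame({
            "depth_m": grid,
            "temperature_C": np.nanmean(temp, axis=0),
            "oxygen_ml_l": np.nanmean(oxy, axis=0),
            "n_casts": np.sum(~np.isnan(temp), axis=0),
        })


def habitat_envelope(occupied: Sequence[tuple[float, float]],
                     profiles: Sequence[CTDProfile]) -> HabitatEnvelope:
    """Temperature/oxygen extrema of the mean profile over occupied depths."""
    if not occupied:
        raise ValueError("no occupied depth interval")
    prof = mean_profile(profiles)
    z = prof["depth_m"].to_numpy()
    mask = np.zeros(len(z), dtype=bool)
    for lo, hi in occupied:
        if lo > hi:
            raise ValueError("occupied interval reversed")
        if lo < z[0] - 1e-9 or hi > z[-1] + 1e-9:
            raise ValueError(
                f"occupied interval [{lo}, {hi}] outside profile coverage "
                f"[{z[0]}, {z[-1]}]")
        mask |= (z >= lo) & (z <= hi)
    t = prof["temperature_C"].to_numpy()[mask]
    o = prof["oxygen_ml_l"].to_numpy()[mask]
    return HabitatEnvelope(
        temp_min=float(np.nanmin(t)), temp_max=float(np.nanmax(t)),
        oxy_min=float(np.nanmin(o)), oxy_max=float(np.nanmax(o)),
        depth_min=float(min(lo for lo, _ in occupied)),
        depth_max=float(max(hi for _, hi in occupied)))


def occupied_intervals(cpue_table: pd.DataFrame) -> list[tuple[float, float]]:
    """Depth strata with any positive catch, merged into contiguous intervals."""
    hit = cpue_table[(cpue_table["n_trawls"] > 0) & (cpue_table["cpue_n"] > 0)]
    strata = sorted({(r.stratum_lower_m, r.stratum_upper_m)
                     for r in hit.itertuples()})
    merged: list[list[float]] = []
    for lo, hi in strata:
        if merged and abs(merged[-1][1] - lo) < 1e-9:
            merged[-1][1] = hi
        else:
            merged.append([lo, hi])
    return [(a, b) for a, b in merged]
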