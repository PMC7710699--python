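"""Synthetic deep-sea survey generator.

Emulates the statistical structure the downstream analysis assumes for a
tropical western-Atlantic micronekton survey targeting the viperfish
(*Chauliodus sloani*):

* per-taxon carbon/nitrogen isotope distributions of the consumer, its
  candidate prey, predators and lower-trophic-level groups;
* stomach-content composition dominated by myctophids, with a realistic
  vacuity rate;
* hydrographic structure — a 28 degC mixed layer to ~50 m, a sharp
  thermocline to 130 m with a 12.3 degC drop, oxygen minima near 100, 300
  and 450 m — and
* a vertical abundance field peaking at 700-900 m by day and 600-700 m at
  night, with larger fish deeper.

Every generator takes an explicit integer seed; one global seed expands to
per-component child streams through fixed ``numpy`` ``SeedSequence`` spawn
keys, so adding a generator never perturbs existing streams.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .data_io import (
    CTDProfile,
    Dataset,
    IsotopeSample,
    PreyItem,
    SpecimenRecord,
    StationRecord,
    StomachRecord,
    TrawlEvent,
)

# Fixed spawn keys: one sub-stream per component of the survey.
_STREAMS = {"ctd": 0, "isotopes": 1, "stomachs": 2, "trawls": 3, "stations": 4}


def child_rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[component],)))


# ---------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class SourceSpec:
    """Per-taxon isotope distribution (means/SDs in permil, C:N by mass)."""

    taxon: str
    group: str
    mean_d13C: float
    sd_d13C: float
    mean_d15N: float
    sd_d15N: float
    mean_CN: Optional[float]
    sd_CN: float
    n_default: int

    def __post_init__(self) -> None:
        if min(self.sd_d13C, self.sd_d15N, self.sd_CN) < 0:
            raise ValueError("SDs must be >= 0")
        if self.n_default < 1:
            raise ValueError("n_default must be >= 1")


# Survey-wide default source table: viperfish size classes, potential
# predators, candidate prey, and lower-trophic-level (LTL) end-members.
DEFAULT_SOURCES: tuple[SourceSpec, ...] = (
    SourceSpec("Chauliodus sloani (>15 cm)", "consumer-large", -18.3, 0.1, 11.1, 0.7, 3.3, 0.1, 10),
    SourceSpec("Chauliodus sloani (<15 cm)", "consumer-small", -18.3, 0.2, 9.3, 0.6, 3.3, 0.1, 17),
    SourceSpec("Ectreposebastes imus", "bathypelagic-predator", -19.1, 0.3, 12.8, 0.2, 4.3, 0.2, 5),
    SourceSpec("Sphyraena barracuda", "epipelagic-predator", -16.2, 0.4, 10.7, 0.5, 3.2, 0.1, 7),
    SourceSpec("Coryphaena hippurus", "epipelagic-predator", -16.4, 0.4, 11.3, 0.6, 3.2, 0.1, 6),
    SourceSpec("Elagatis bipinnulata", "epipelagic-predator", -19.3, 0.2, 9.3, 0.5, 3.4, 0.2, 6),
    SourceSpec("Acanthocybium solandri", "epipelagic-predator", -16.8, 0.4, 11.0, 1.0, 3.2, 0.1, 8),
    SourceSpec("Katsuwonus pelamis", "epipelagic-predator", -17.2, 0.4, 10.2, 1.0, 3.2, 0.1, 3),
    SourceSpec("Thunnus albacares", "epipelagic-predator", -17.3, 0.2, 10.7, 1.0, 3.1, 0.1, 12),
    SourceSpec("Diaphus brachycephalus", "prey", -18.9, 0.3, 9.9, 0.8, 3.4, 0.1, 10),
    SourceSpec("Diaphus fragilis", "prey", -18.2, 0.3, 10.2, 0.5, 3.4, 0.1, 11),
    SourceSpec("Diaphus mollis", "prey", -19.2, 0.2, 10.5, 0.7, 3.4, 0.1, 5),
    SourceSpec("Hygophum taaningi", "prey", -18.2, 0.2, 10.0, 0.6, 3.3, 0.1, 9),
    SourceSpec("Lampanyctus nobilis", "prey", -18.2, 0.2, 9.5, 0.3, 3.3, 0.1, 7),
    SourceSpec("Lepidophanes guentheri", "prey", -18.2, 0.2, 9.8, 0.7, 3.3, 0.1, 13),
    SourceSpec("Symbolophorus rufinus", "prey", -19.3, 0.2, 9.3, 0.5, 3.4, 0.1, 6),
    SourceSpec("Promethichthys prometheus", "prey", -18.4, 0.2, 10.0, 0.1, 3.3, 0.1, 3),
    SourceSpec("Teleostei larvae 15-20 mm", "prey", -18.5, 0.4, 7.1, 0.6, 3.2, 0.1, 6),
    SourceSpec("Teleostei larvae 5-10 mm", "prey", -19.6, 0.1, 5.9, 0.2, 3.2, 0.1, 10),
    SourceSpec("Euphausia gibboides", "prey", -19.3, 1.0, 6.9, 0.2, 3.2, 0.1, 6),
    SourceSpec("Euphausia sp.", "prey", -19.4, 0.5, 7.3, 0.8, 3.2, 0.1, 3),
    SourceSpec("Pasiphaeidae sp.", "prey", -19.1, 0.0, 6.0, 0.1, 3.1, 0.1, 3),
    SourceSpec("Phronima sp.", "prey", -19.0, 0.1, 5.8, 0.1, 3.6, 0.2, 3),
    SourceSpec("Abylopsis tetragona", "LTL", -17.8, 0.2, 7.2, 1.0, 3.3, 0.1, 3),
    SourceSpec("Siphonophorae sp.", "LTL", -19.2, 0.0, 9.1, 0.2, 3.4, 0.1, 3),
    SourceSpec("Salpa sp.", "LTL", -19.8, 0.5, 5.4, 0.1, 4.5, 0.7, 6),
    SourceSpec("Soestia zonaria", "LTL", -20.2, 0.2, 3.7, 0.5, 3.3, 0.1, 6),
    SourceSpec("Pyrosoma atlanticum", "LTL", -18.5, 0.2, 2.9, 0.6, 5.4, 0.2, 11),
    SourceSpec("Zooplankton", "LTL", -19.4, 0.3, 3.0, 0.6, 4.5, 0.5, 19),
    SourceSpec("POM", "POM", -22.4, 0.6, 2.8, 1.2, None, 0.0, 17),
)

# Default stomach composition: per-category encounter probability (pooled
# numerical share) and lognormal weight parameters (grams). Mean item weights
# follow the pooled weight-to-count ratios of the diet table so that %W comes
# out myctophid-dominated with realistic skew.
DEFAULT_COMPOSITION: dict[str, dict] = {
    "Euphausiidae": {"p": 0.030, "mean_w": 0.02, "sigma": 0.4},
    "Decapoda": {"p": 0.030, "mean_w": 0.03, "sigma": 0.4},
    "Chauliodus sloani": {"p": 0.030, "mean_w": 0.25, "sigma": 0.5},
    "Cyclothone spp.": {"p": 0.030, "mean_w": 0.15, "sigma": 0.5},
    "Gempylidae": {"p": 0.030, "mean_w": 0.07, "sigma": 0.5},
    "Diaphus sp.": {"p": 0.060, "mean_w": 1.20, "sigma": 0.5},
    "Hygophum sp.": {"p": 0.030, "mean_w": 0.35, "sigma": 0.5},
    "Myctophidae": {"p": 0.272, "mean_w": 0.41, "sigma": 0.5},
    "Unidentified Teleostei": {"p": 0.488, "mean_w": 0.20, "sigma": 0.5},
}

DEFAULT_VACUITY = 0.61  # pooled-period fraction of empty stomachs


@dataclass(frozen=True)
class HydroSpec:
    """Anchor-point description of the mean hydrographic structure.

    Temperature: flat mixed layer, linear-in-anchor thermocline, then a
    monotone decay through ``deep_anchors`` to ``deep_temp_at_1000m``.
    Oxygen: near-surface plateau with dips at the configured minima and a
    slow deep increase. Profiles are monotone-cubic (PCHIP) through the
    anchors, plus optional white noise.
    """

    surface_temp: float = 28.0
    mixed_layer_depth: float = 50.0
    thermocline_bottom: float = 130.0
    thermocline_drop: float = 12.3
    deep_temp_at_1000m: float = 4.8
    deep_anchors: tuple[tuple[float, float], ...] = ((400.0, 11.5), (700.0, 7.0))
    oxygen_surface: float = 4.6
    oxygen_minima: tuple[tuple[float, float], ...] = ((100.0, 2.4), (300.0, 2.4), (450.0, 2.4))
    oxygen_deep_at_1000m: float = 3.8
    noise_sd_temp: float = 0.15
    noise_sd_oxygen: float = 0.05
    noise_sd_salinity: float = 0.02
    noise_sd_fluorescence: float = 0.02

    def __post_init__(self) -> None:
        if self.mixed_layer_depth >= self.thermocline_bottom:
            raise ValueError("mixed_layer_depth must be < thermocline_bottom")
        if self.thermocline_drop <= 0:
            raise ValueError("thermocline_drop must be > 0")

    def temperature_anchors(self) -> tuple[np.ndarray, np.ndarray]:
        t_bottom = self.surface_temp - self.thermocline_drop
        depths = [0.0, self.mixed_layer_depth, self.thermocline_bottom]
        temps = [self.surface_temp, self.surface_temp, t_bottom]
        for d, t in self.deep_anchors:
            depths.append(d)
            temps.append(t)
        depths.append(1000.0)
        temps.append(self.deep_temp_at_1000m)
        return np.asarray(depths), np.asarray(temps)

    def oxygen_anchors(self) -> tuple[np.ndarray, np.ndarray]:
        pts = [(0.0, self.oxygen_surface), (self.mixed_layer_depth, self.oxygen_surface)]
        minima = sorted(self.oxygen_minima)
        for i, (d, v) in enumerate(minima):
            pts.append((d, v))
            nxt = minima[i + 1][0] if i + 1 < len(minima) else 550.0
            if nxt - d > 60:  # partial recovery between successive minima
                pts.append(((d + nxt) / 2.0, v + 0.6))
        pts.append((550.0, 2.6))
        pts.append((700.0, 3.3))
        pts.append((1000.0, self.oxygen_deep_at_1000m))
        pts = sorted(set(pts))
        arr = np.asarray(pts)
        return arr[:, 0], arr[:, 1]


@dataclass(frozen=True)
class VerticalDistSpec:
    """Relative abundance weights and mean-length offsets per 100-m stratum.

    Defaults place all catch between 400 and 1000 m with the daytime mode in
    700-900 m and the night mode in 600-700 m; length offsets put larger fish
    below 500 m, more strongly by day than by night.
    """

    day_weights: Mapping[float, float] = field(default_factory=lambda: {
        400.0: 0.5, 500.0: 0.8, 600.0: 1.2, 700.0: 3.0, 800.0: 3.0, 900.0: 1.0})
    night_weights: Mapping[float, float] = field(default_factory=lambda: {
        400.0: 1.0, 500.0: 1.5, 600.0: 3.0, 700.0: 0.9, 800.0: 0.9, 900.0: 0.7})
    day_sl_offset: Mapping[float, float] = field(default_factory=lambda: {
        400.0: -3.0, 500.0: 0.0, 600.0: 0.5, 700.0: 1.0, 800.0: 1.5, 900.0: 2.0})
    night_sl_offset: Mapping[float, float] = field(default_factory=lambda: {
        400.0: -0.5, 500.0: 0.0, 600.0: 0.1, 700.0: 0.2, 800.0: 0.3, 900.0: 0.5})
    base_sl_cm: float = 13.0
    sl_sd_cm: float = 2.5
    sl_range_cm: tuple[float, float] = (7.0, 25.0)
    catch_rate_per_weight: float = 25.0  # expected fish per trawl-hour at weight 1

    def weights(self, period: str) -> Mapping[float, float]:
        w = self.day_weights if period == "day" else self.night_weights
        if all(v == 0 for v in w.values()):
            raise ValueError(f"all-zero abundance weights for period '{period}'")
        if any(v < 0 for v in w.values()):
            raise ValueError("abundance weights must be >= 0")
        return w

    def sl_offsets(self, period: str) -> Mapping[float, float]:
        return self.day_sl_offset if period == "day" else self.night_sl_offset


# ---------------------------------------------------------------------------
# Generators


def make_ctd_profile(spec: HydroSpec, depth_grid: Sequence[float], seed: int,
                     station_id: str = "ST01") -> CTDProfile:
    """One CTD cast on ``depth_grid`` (strictly increasing, metres)."""
    z = np.asarray(depth_grid, dtype=float)
    if z.ndim != 1 or len(z) == 0 or np.any(np.diff(z) <= 0) or np.any(z < 0):
        raise ValueError("depth_grid must be strictly increasing and non-negative")
    rng = np.random.default_rng(seed)

    zt, tt = spec.temperature_anchors()
    temp = PchipInterpolator(zt, tt, extrapolate=True)(z)
    zo, oo = spec.oxygen_anchors()
    oxy = PchipInterpolator(zo, oo, extrapolate=True)(z)
    # Salinity: subsurface maximum inside the thermocline (80-120 m band).
    zs = np.array([0.0, 80.0, 100.0, 120.0, 300.0, 1000.0])
    ss = np.array([36.0, 36.4, 36.5, 36.3, 34.9, 34.6])
    sal = PchipInterpolator(zs, ss, extrapolate=True)(z)
    # Fluorescence maximum at the upper limit of the thermocline.
    fluo = 0.05 + 0.95 * np.exp(-0.5 * ((z - spec.mixed_layer_depth - 10) / 15.0) ** 2)

    temp = temp + rng.normal(0, spec.noise_sd_temp, len(z))
    oxy = np.maximum(oxy + rng.normal(0, spec.noise_sd_oxygen, len(z)), 0.05)
    sal = sal + rng.normal(0, spec.noise_sd_salinity, len(z))
    fluo = np.maximum(fluo + rng.normal(0, spec.noise_sd_fluorescence, len(z)), 0.0)

    return CTDProfile(
        station_id=station_id, depth_m=z.tolist(),
        temperature_C=temp.tolist(), oxygen_ml_l=oxy.tolist(),
        salinity=sal.tolist(), fluorescence=fluo.tolist())


def make_isotope_samples(specs: Sequence[SourceSpec], n_per_taxon: int,
                         seed: int) -> list[IsotopeSample]:
    """Draw ``n_per_taxon`` independent normal samples per taxon and axis.

    The generator draws each isotope axis independently (only marginal
    mean +/- SD are specified for the field populations); pass
    ``n_per_taxon`` <= 0 to raise.
    """
    if n_per_taxon < 1:
        raise ValueError("n_per_taxon must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[IsotopeSample] = []
    for spec in specs:
        d13 = rng.normal(spec.mean_d13C, spec.sd_d13C, n_per_taxon)
        d15 = rng.normal(spec.mean_d15N, spec.sd_d15N, n_per_taxon)
        if spec.mean_CN is None:
            cn = [None] * n_per_taxon
        else:
            cn = np.maximum(rng.normal(spec.mean_CN, spec.sd_CN, n_per_taxon), 0.5)
        for i in range(n_per_taxon):
            out.append(IsotopeSample(
                sample_id=f"{spec.taxon}-{i:05d}", taxon=spec.taxon,
                group=spec.group, d13C=float(d13[i]), d15N=float(d15[i]),
                CN_mass=None if cn[i] is None else float(cn[i])))
    return out


def make_stomach_contents(composition: Mapping[str, Mapping] | None,
                          n_stomachs: int, vacuity: float, seed: int,
                          specimen_ids: Optional[Sequence[str]] = None,
                          ) -> list[StomachRecord]:
    """Simulate ``n_stomachs`` examined stomachs.

    Each stomach is empty with probability ``vacuity``; otherwise it holds
    1 + Poisson(0.35) prey items with categories multinomial in the
    composition probabilities and item weights lognormal per category.
    """
    if composition is None:
        composition = DEFAULT_COMPOSITION
    if not 0 <= vacuity <= 1:
        raise ValueError("vacuity must be in [0, 1]")
    cats = list(composition)
    probs = np.array([composition[c]["p"] for c in cats], dtype=float)
    total = probs.sum()
    if abs(total - 1.0) > 1e-9:
        if abs(total - 1.0) > 0.05:
            raise ValueError(f"composition probabilities sum to {total:.4f}, not 1")
        probs = probs / total  # tolerate tiny drift from table rounding
    rng = np.random.default_rng(seed)
    if specimen_ids is None:
        specimen_ids = [f"SP{i:05d}" for i in range(n_stomachs)]

    records: list[StomachRecord] = []
    for i in range(n_stomachs):
        sid = str(specimen_ids[i])
        if rng.uniform() < vacuity:
            records.append(StomachRecord(specimen_id=sid, is_empty=True, items=[]))
            continue
        n_items = 1 + rng.poisson(0.35)
        items = []
        for _ in range(n_items):
            c = cats[rng.choice(len(cats), p=probs)]
            mw, sg = composition[c]["mean_w"], composition[c]["sigma"]
            mu = np.log(mw) - 0.5 * sg ** 2  # lognormal with mean mw
            w = float(rng.lognormal(mu, sg))
            items.append(PreyItem(category=c, count=1, weight_g=round(w, 4)))
        records.append(StomachRecord(specimen_id=sid, is_empty=False, items=items))
    return records


def make_trawl_catches(vd: VerticalDistSpec,
                       effort_plan: Sequence[tuple[float, float, str, int]],
                       seed: int,
                       station_id: str = "ST01",
                       date: dt.date = dt.date(2017, 4, 20),
                       duration_h: float = 0.5,
                       mouth_area_m2: float = 120.0,
                       ) -> tuple[list[TrawlEvent], list[SpecimenRecord]]:
    """Simulate trawls and their viperfish catches.

    ``effort_plan`` rows are ``(stratum_lower, stratum_upper, period,
    n_trawls)``. Catch counts are Poisson with mean proportional to the
    stratum's abundance weight times tow duration; standard lengths are
    normal around the period/stratum offset, truncated to the plausible
    size range, and weights follow a cubic length-weight relation with
    lognormal scatter.
    """
    if not effort_plan:
        raise ValueError("effort plan is empty")
    rng = np.random.default_rng(seed)
    trawls: list[TrawlEvent] = []
    specimens: list[SpecimenRecord] = []
    k = 0
    sp = 0
    for lower, upper, period, n_trawls in effort_plan:
        weights = vd.weights(period)
        offsets = vd.sl_offsets(period)
        w = float(weights.get(lower, 0.0))
        off = float(offsets.get(lower, 0.0))
        for _ in range(int(n_trawls)):
            k += 1
            hour = 12 if period == "day" else 23
            start = dt.datetime.combine(date, dt.time(hour, 0))
            tid = f"TR{k:04d}"
            trawls.append(TrawlEvent(
                trawl_id=tid, station_id=station_id, start_time=start,
                end_time=start + dt.timedelta(hours=duration_h),
                depth_min_m=lower + 10, depth_max_m=upper - 10,
                mouth_area_m2=mouth_area_m2, diel_period=period))
            n_fish = rng.poisson(vd.catch_rate_per_weight * w * duration_h)
            for _ in range(n_fish):
                sp += 1
                sl = float(np.clip(rng.normal(vd.base_sl_cm + off, vd.sl_sd_cm),
                                   *vd.sl_range_cm))
                tw = 0.0019 * sl ** 3.1 * float(rng.lognormal(0, 0.1))
                specimens.append(SpecimenRecord(
                    specimen_id=f"VP{sp:05d}", trawl_id=tid,
                    taxon="Chauliodus sloani",
                    standard_length_cm=round(sl, 1),
                    total_weight_g=round(tw, 2)))
    return trawls, specimens


DEFAULT_EFFORT: tuple[tuple[float, float, str, int], ...] = tuple(
    (lo, lo + 100.0, period, 2)
    for period in ("day", "night")
    for lo in (10.0,) + tuple(np.arange(100.0, 1000.0, 100.0))
    if not (period == "night" and lo in (200.0, 700.0))  # unsampled at night
)


def make_survey(seed: int,
                sources: Sequence[SourceSpec] = DEFAULT_SOURCES,
                n_isotopes_per_taxon: Optional[int] = None,
                composition: Optional[Mapping[str, Mapping]] = None,
                n_stomachs: int = 197,
                vacuity: float = DEFAULT_VACUITY,
                hydro: HydroSpec = HydroSpec(),
                vertical: VerticalDistSpec = VerticalDistSpec(),
                effort_plan: Sequence[tuple[float, float, str, int]] = DEFAULT_EFFORT,
                n_stations: int = 6) -> Dataset:
    """Compose a fully linked synthetic survey Dataset.

    ``n_isotopes_per_taxon=None`` uses each taxon's default field sample
    size; stomachs are attached to simulated viperfish specimens (capped at
    the number caught).
    """
    ds = Dataset()
    st_rng = child_rng(seed, "stations")
    for i in range(n_stations):
        ds.stations.append(StationRecord(
            station_id=f"ST{i + 1:02d}",
            latitude=float(-3.8 + st_rng.normal(0, 0.3)),
            longitude=float(-32.4 + st_rng.normal(0, 0.3)),
            date=dt.date(2017, 4, 10) + dt.timedelta(days=int(i * 4)),
            sunrise=dt.time(5, 40), sunset=dt.time(17, 30)))

    grid = np.arange(5.0, 1001.0, 5.0)
    ctd_seeds = np.random.SeedSequence(seed, spawn_key=(_STREAMS["ctd"],)).generate_state(n_stations)
    for i, stn in enumerate(ds.stations):
        ds.ctd.append(make_ctd_profile(hydro, grid, int(ctd_seeds[i]) % (2 ** 31),
                                       station_id=stn.station_id))

    tr_seed = int(child_rng(seed, "trawls").integers(2 ** 31))
    trawls, specimens = make_trawl_catches(vertical, effort_plan, tr_seed,
                                           station_id=ds.stations[0].station_id)
    # spread trawls over stations round-robin so station links are exercised
    for i, t in enumerate(trawls):
        t.station_id = ds.stations[i % n_stations].station_id
    ds.trawls = trawls
    ds.specimens = specimens

    if n_stomachs > 0 and specimens:
        n_exam = min(n_stomachs, len(specimens))
        sto_seed = int(child_rng(seed, "stomachs").integers(2 ** 31))
        ids = [s.specimen_id for s in specimens[:n_exam]]
        ds.stomachs = make_stomach_contents(composition, n_exam, vacuity,
                                            sto_seed, specimen_ids=ids)

    iso_seed = int(child_rng(seed, "isotopes").integers(2 ** 31))
    if n_isotopes_per_taxon is None:
        samples: list[IsotopeSample] = []
        sub = np.random.SeedSequence(iso_seed).generate_state(len(sources))
        for j, spec in enumerate(sources):
            samples.extend(make_isotope_samples([spec], spec.n_default,
                                                int(sub[j]) % (2 ** 31)))
        ds.isotopes = samples
    else:
        ds.isotopes = make_isotope_samples(sources, n_isotopes_per_taxon, iso_seed)
    return ds
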