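"""Gut-content statistics: vacuity, dietary importance indices, niche breadth.

The vacuity index is VI = Nv/Ne * 100 (empty over examined stomachs).
Dietary importance of each prey category is summarised by the frequency of
occurrence (%FO, share of stomachs-with-content containing the category),
numerical abundance (%N, share of prey individuals) and weight percentage
(%W, share of total prey mass). Niche breadth uses Levin's standardized
index B_j = (1/(n-1)) * (1/sum(p_i^2) - 1) on the weight proportions p_i,
which is 0 for a single-prey diet and 1 for uniform use of all n categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data_io import SpecimenRecord, StomachRecord

L50_CM = 15.0  # viperfish length at sexual maturity, used to split size classes


class EmptyInputError(ValueError):
    pass


@dataclass(frozen=True)
class StomachSummary:
    """Counts of examined (Ne), empty (Nv) and content (NSC) stomachs."""

    Ne: int
    Nv: int

    def __post_init__(self) -> None:
        if self.Ne < 0 or self.Nv < 0 or self.Nv > self.Ne:
            raise ValueError("need 0 <= Nv <= Ne")

    @property
    def NSC(self) -> int:
        return self.Ne - self.Nv


def summarize_stomachs(stomachs: Iterable[StomachRecord]) -> StomachSummary:
    stomachs = list(stomachs)
    return StomachSummary(Ne=len(stomachs), Nv=sum(s.is_empty for s in stomachs))


def vacuity_index(summary: StomachSummary) -> float:
    """Percent of examined stomachs that are empty; reported tables round to int."""
    if summary.Ne == 0:
        raise EmptyInputError("vacuity index undefined for zero examined stomachs")
    return 100.0 * summary.Nv / summary.Ne


def diet_indices(stomachs: Sequence[StomachRecord]) -> pd.DataFrame:
    """Per-category %FO, %N, %W over the stomachs-with-content.

    Returns a frame with columns ``category, FO_pct, N_pct, W_pct`` in a
    stable (first-appearance) category order. %N and %W each sum to 100.
    """
    full = [s for s in stomachs if not s.is_empty]
    if not full:
        raise EmptyInputError("no stomach with content")
    nsc = len(full)
    order: list[str] = []
    occ: dict[str, int] = {}
    n: dict[str, int] = {}
    w: dict[str, float] = {}
    for s in full:
        cats_here = set()
        for it in s.items:
            if it.category not in occ:
                order.append(it.category)
                occ[it.category] = 0
                n[it.category] = 0
                w[it.category] = 0.0
            cats_here.add(it.category)
            n[it.category] += it.count
            w[it.category] += it.weight_g
        for c in cats_here:
            occ[c] += 1
    total_n = sum(n.values())
    total_w = sum(w.values())
    if total_w <= 0:
        raise EmptyInputError("total prey weight is zero; %W undefined")
    return pd.DataFrame({
        "category": order,
        "FO_pct": [100.0 * occ[c] / nsc for c in order],
        "N_pct": [100.0 * n[c] / total_n for c in order],
        "W_pct": [100.0 * w[c] / total_w for c in order],
    })


def levins_index(weight_proportions: Sequence[float], n: Optional[int] = None) -> float:
    """Levin's standardized niche breadth B_j on [0, 1].

    ``weight_proportions`` must be non-negative and sum to 1. ``n`` is the
    number of prey categories used for standardization; it defaults to the
    length of the proportion vector and must cover every nonzero category.
    """
    p = np.asarray(weight_proportions, dtype=float)
    if np.any(p < 0):
        raise ValueError("proportions must be >= 0")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {p.sum():.12g}, not 1")
    if n is None:
        n = len(p)
    if n < 2:
        raise ValueError("need at least 2 prey categories")
    if n < np.count_nonzero(p):
        raise ValueError("n smaller than the number of nonzero categories")
    return float((1.0 / (n - 1)) * (1.0 / np.sum(p ** 2) - 1.0))


def split_size_classes(specimens: Iterable[SpecimenRecord],
                       l50_cm: float = L50_CM) -> dict[str, list[SpecimenRecord]]:
    """Partition into small (SL < L50), large (SL >= L50) and pooled.

    The boundary length (exactly L50) goes to the large class; pooled is the
    union in input order.
    """
    out: dict[str, list[SpecimenRecord]] = {"small": [], "large": [], "pooled": []}
    for s in specimens:
        out["small" if s.standard_length_cm < l50_cm else "large"].append(s)
        out["pooled"].append(s)
    return out


@dataclass
class DietIndexTable:
    """Diet table for one analysis group (a size class or pooled sizes)."""

    group: str
    summary: Optional[StomachSummary]
    rows: pd.DataFrame  # empty frame when no stomach has content
    VI_pooled: Optional[float]
    VI_day: Optional[float]
    VI_night: Optional[float]
    Bj: Optional[float]
    n_categories_used: int = 0
    is_empty: bool = False


def _vi_or_none(stomachs: Sequence[StomachRecord]) -> Optional[float]:
    if not stomachs:
        return None
    return vacuity_index(summarize_stomachs(stomachs))


def diet_table(stomachs: Sequence[StomachRecord],
               specimens: Sequence[SpecimenRecord],
               diel_by_specimen: Optional[Mapping[str, str]] = None,
               l50_cm: float = L50_CM,
               levins_n: Optional[int] = None) -> dict[str, DietIndexTable]:
    """Full diet tables per size class and pooled.

    ``diel_by_specimen`` maps specimen id -> day/night label; day/night
    vacuity cells are reported as missing (None) when a group has no
    stomach for that period — missing is distinct from zero. ``levins_n``
    optionally fixes Levin's n to a study-wide category count.
    """
    by_spec = {s.specimen_id: s for s in specimens}
    unknown = [st.specimen_id for st in stomachs if st.specimen_id not in by_spec]
    if unknown:
        raise KeyError(f"stomachs reference unknown specimens: {unknown[:5]}")
    classes = split_size_classes(specimens, l50_cm)
    tables: dict[str, DietIndexTable] = {}
    for group, members in classes.items():
        ids = {m.specimen_id for m in members}
        sto = [s for s in stomachs if s.specimen_id in ids]
        if not sto:
            tables[group] = DietIndexTable(
                group=group, summary=None, rows=pd.DataFrame(
                    columns=["category", "FO_pct", "N_pct", "W_pct"]),
                VI_pooled=None, VI_day=None, VI_night=None, Bj=None,
                is_empty=True)
            continue
        summary = summarize_stomachs(sto)
        vi_day = vi_night = None
        if diel_by_specimen is not None:
            day = [s for s in sto if diel_by_specimen.get(s.specimen_id) == "day"]
            night = [s for s in sto if diel_by_specimen.get(s.specimen_id) == "night"]
            vi_day = _vi_or_none(day)
            vi_night = _vi_or_none(night)
        if summary.NSC > 0:
            rows = diet_indices(sto)
            p = rows["W_pct"].to_numpy() / 100.0
            n_used = levins_n if levins_n is not None else len(rows)
            bj = levins_index(p / p.sum(), n=n_used) if n_used >= 2 else None
        else:
            rows = pd.DataFrame(columns=["category", "FO_pct", "N_pct", "W_pct"])
            bj, n_used = None, 0
        tables[group] = DietIndexTable(
            group=group, summary=summary, rows=rows,
            VI_pooled=vacuity_index(summary), VI_day=vi_day, VI_night=vi_night,
            Bj=bj, n_categories_used=n_used, is_empty=False)
    return tables


def diet_table_frame(tables: Mapping[str, DietIndexTable]) -> pd.DataFrame:
    """Flatten diet tables to one tidy frame (percentages to 1 decimal, VI to int)."""
    frames = []
    for group, t in tables.items():
        if t.is_empty or t.rows.empty:
            continue
        df = t.rows.copy().round({"FO_pct": 1, "N_pct": 1, "W_pct": 1})
        df.insert(0, "group", group)
        df["VI_pct"] = round(t.VI_pooled) if t.VI_pooled is not None else pd.NA
        df["Bj"] = round(t.Bj, 2) if t.Bj is not None else pd.NA
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["group", "category", "FO_pct", "N_pct",
                                     "W_pct", "VI_pct", "Bj"])
    return pd.concat(frames, ignore_index=True)
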