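"""Stable-isotope preprocessing.

Covers the delta notation, lipid screening/normalization of delta13C via the
C:N mass ratio, and the per-taxon source summaries that feed the trophic
position and mixing models and the carbon-nitrogen biplot.

Lipid-rich tissue (C:N > 3.5 by mass) is depleted in 13C; such samples are
normalized with the aquatic-animal relation

    delta_shift = -3.32 + 0.99 * C:N

added to the measured delta13C. The correction always starts from the raw
measurement, so applying it twice equals applying it once, and it never
touches delta15N. POM is excluded from the animal correction (it is
acidified at the bench instead).
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Optional

import pandas as pd
from pydantic import BaseModel, Field

from .data_io import Dataset, IsotopeSample

logger = logging.getLogger("trophlink")

CN_THRESHOLD = 3.5
# VPDB 13C/12C and atmospheric-N2 15N/14N reference ratios.
R_STANDARD_C = 0.0112372
R_STANDARD_N = 0.0036765


def delta_from_ratios(r_sample: float, r_standard: float) -> float:
    """delta value in permil: (Rsample/Rstandard - 1) * 1000."""
    if r_standard <= 0:
        raise ValueError("R_standard must be > 0")
    return (r_sample / r_standard - 1.0) * 1000.0


def lipid_shift(cn_mass: float) -> float:
    """Additive delta13C change attributed to lipids at a given C:N."""
    return -3.32 + 0.99 * cn_mass


def lipid_screen_and_correct(sample: IsotopeSample,
                             threshold: float = CN_THRESHOLD) -> IsotopeSample:
    """Normalize delta13C when C:N strictly exceeds the threshold.

    Returns a new sample; the raw delta13C is preserved in ``d13C_raw``.
    Samples without C:N pass through unchanged with a logged warning, and
    POM is never corrected by the animal equation.
    """
    if sample.group == "POM":
        return sample.model_copy()
    if sample.CN_mass is None:
        logger.warning("sample %s: no C:N ratio, passed through unscreened",
                       sample.sample_id)
        return sample.model_copy()
    raw = sample.d13C_raw if sample.d13C_raw is not None else sample.d13C
    if sample.CN_mass > threshold:
        return sample.model_copy(update={
            "d13C": raw + lipid_shift(sample.CN_mass),
            "d13C_raw": raw,
            "lipid_corrected": True,
        })
    return sample.model_copy(update={"d13C": raw, "lipid_corrected": False,
                                     "d13C_raw": sample.d13C_raw})


class SourceSummary(BaseModel):
    """Per-taxon isotope summary: n, mean and sample SD per axis (permil)."""

    taxon: str
    group: Optional[str] = None
    n: int = Field(ge=1)
    mean_d13C: float
    sd_d13C: Optional[float] = None  # None when n = 1
    mean_d15N: float
    sd_d15N: Optional[float] = None


def _mean_sd(values: list[float]) -> tuple[float, Optional[float]]:
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        return mean, None
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def summarize_sources(samples: Iterable[IsotopeSample],
                      screen: bool = True) -> list[SourceSummary]:
    """Per-taxon mean and sample SD (n-1) per axis, after lipid screening.

    Single-sample taxa report a missing SD rather than zero; downstream
    Bayesian modules then require an explicit SD floor.
    """
    groups: dict[str, list[IsotopeSample]] = {}
    order: list[str] = []
    for s in samples:
        s2 = lipid_screen_and_correct(s) if screen else s
        if s2.taxon not in groups:
            groups[s2.taxon] = []
            order.append(s2.taxon)
        groups[s2.taxon].append(s2)
    out = []
    for taxon in order:
        ss = groups[taxon]
        m13, s13 = _mean_sd([x.d13C for x in ss])
        m15, s15 = _mean_sd([x.d15N for x in ss])
        out.append(SourceSummary(
            taxon=taxon, group=ss[0].group, n=len(ss),
            mean_d13C=m13, sd_d13C=s13, mean_d15N=m15, sd_d15N=s15))
    return out


def corrected_frame(samples: Iterable[IsotopeSample]) -> pd.DataFrame:
    """Screen every sample and return the corrected long-format table."""
    rows = [lipid_screen_and_correct(s).model_dump() for s in samples]
    return pd.DataFrame(rows)


def summaries_frame(summaries: Iterable[SourceSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.model_dump() for s in summaries])


def biplot_table(ds: Dataset) -> pd.DataFrame:
    """One row per taxon with group labels and axis means/SDs, plot-ready."""
    if not ds.isotopes:
        return pd.DataFrame(columns=["taxon", "group", "n", "mean_d13C",
                                     "sd_d13C", "mean_d15N", "sd_d15N"])
    df = summaries_frame(summarize_sources(ds.isotopes))
    return df[["taxon", "group", "n", "mean_d13C", "sd_d13C",
               "mean_d15N", "sd_d15N"]]
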