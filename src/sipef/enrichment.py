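"""The taxon-specific enrichment factor (EF) and its gates.

For a genus g and one (soil, day) cell the EF contrasts the genus's
heavy-pool share between the 13C treatment and the 12C control:

    EF = h13 / (h13 + l13)  -  h12 / (h12 + l12)

where h and l are the genus's relative abundances in the heavy and light
pooled fractions of one replicate.  The within-isotope normalisation makes
the statistic a share in [0, 1], so EF is bounded in [-1, 1]; the 12C term
subtracts the genus's baseline buoyant-density leakage into the heavy window
(GC content, diffusion), which a labelled genus exceeds.

Replicate variability is propagated by combinatorial subtraction: EF is
computed for every pairing of a 13C replicate with a 12C replicate (9 pairs
for triplicates) and summarised by their mean and SD per day.  A genus is
called enriched when its mean EF exceeds a threshold on at least one day and
its EF values change significantly through time (one-way ANOVA on the
pairwise values with day as factor).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm

from .core_io import SampleMeta
from .errors import DataLossWarning, ValidationError
from .preprocess import AbundanceTable

__all__ = [
    "HeavyShare",
    "EFSeries",
    "heavy_share",
    "ef_pairs",
    "ef_timecourse",
    "anova_oneway",
    "anova_time",
    "classify_enriched",
    "ef_table",
]

EF_THRESHOLD = 0.015
ANOVA_ALPHA = 0.05


@dataclass(frozen=True)
class HeavyShare:
    """A genus's share of its abundance found in the heavy pool.

    ``p = ra_heavy / (ra_heavy + ra_light)``; undefined (``defined=False``)
    when the genus is absent from both pools or a pooled sample is missing.
    """

    genus: str
    soil: str
    isotope: str
    replicate: int
    day: int
    p: float
    defined: bool

    def __post_init__(self) -> None:
        if self.defined and not 0.0 <= self.p <= 1.0:
            raise ValidationError(f"heavy share {self.p} outside [0, 1]")


@dataclass
class EFSeries:
    """Per-day combinatorial EF values for one genus in one soil.

    ``shares13``/``shares12`` carry the defined per-replicate heavy shares
    behind each day's pairwise values; the through-time significance test
    runs on these independent units.
    """

    genus: str
    soil: str
    days: list[int]
    pairs: list[np.ndarray]  # per day, the pairwise EF values (row-major 13C x 12C)
    heavy_ra_mean: list[float]  # mean 13C heavy-pool relative abundance per day
    shares13: list[np.ndarray] = field(default_factory=list)
    shares12: list[np.ndarray] = field(default_factory=list)
    anova_p: float | None = None
    enriched: bool = False
    day_enriched: list[bool] = field(default_factory=list)
    day_displayed: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.days):
            raise ValidationError("one pair list required per day")
        self.pairs = [np.asarray(p, dtype=float) for p in self.pairs]
        for arr in self.pairs:
            if arr.size and (arr.min() < -1 - 1e-12 or arr.max() > 1 + 1e-12):
                raise ValidationError("EF values must lie in [-1, 1]")

    @property
    def means(self) -> list[float]:
        return [float(p.mean()) if p.size else math.nan for p in self.pairs]

    @property
    def sds(self) -> list[float]:
        return [float(p.std(ddof=1)) if p.size > 1 else math.nan for p in self.pairs]

    @property
    def n_pairs(self) -> list[int]:
        return [int(p.size) for p in self.pairs]


def heavy_share(
    ab: AbundanceTable,
    sheet: Sequence[SampleMeta],
    genus: str,
    soil: str,
    isotope: str,
    replicate: int,
    day: int,
) -> HeavyShare:
    """Heavy-pool share of one genus for one replicate microcosm at one day."""
    lookup = {
        (m.soil, m.isotope, m.pool, m.replicate, m.day): m.sample_id for m in sheet
    }
    ras: dict[str, float | None] = {}
    for pool in ("heavy", "light"):
        sid = lookup.get((soil, isotope, pool, replicate, day))
        if sid is None or sid not in ab.samples:
            ras[pool] = None
        else:
            ras[pool] = ab.abundance(genus, sid)
    if ras["heavy"] is None or ras["light"] is None:
        warnings.warn(
            f"missing pooled sample for {genus} {soil}/{isotope} "
            f"rep {replicate} day {day}; heavy share undefined",
            DataLossWarning,
            stacklevel=2,
        )
        return HeavyShare(genus, soil, isotope, replicate, day, math.nan, False)
    total = ras["heavy"] + ras["light"]
    if total == 0:
        return HeavyShare(genus, soil, isotope, replicate, day, math.nan, False)
    return HeavyShare(genus, soil, isotope, replicate, day, ras["heavy"] / total, True)


def ef_pairs(p13: Sequence[HeavyShare], p12: Sequence[HeavyShare]) -> np.ndarray:
    """All pairwise EF values p13_i - p12_j, row-major (13C index outer).

    Undefined shares are skipped; an empty result is returned with a warning
    when no defined pairing exists.
    """
    a = np.array([s.p for s in p13 if s.defined], dtype=float)
    b = np.array([s.p for s in p12 if s.defined], dtype=float)
    if a.size == 0 or b.size == 0:
        warnings.warn("no defined (13C, 12C) replicate pair", DataLossWarning, stacklevel=2)
        return np.empty(0, dtype=float)
    return np.subtract.outer(a, b).ravel()


def ef_timecourse(
    ab: AbundanceTable,
    sheet: Sequence[SampleMeta],
    genus: str,
    soil: str,
    days: Sequence[int] | None = None,
) -> EFSeries:
    """Assemble the per-day combinatorial EF series for one genus and soil."""
    if genus not in ab.taxa:
        raise KeyError(f"genus {genus!r} not in abundance table")
    in_table = set(ab.samples)
    soil_sheet = [m for m in sheet if m.soil == soil and m.sample_id in in_table]
    if days is None:
        days = sorted({m.day for m in soil_sheet if m.isotope in ("13C", "12C")})
    pairs: list[np.ndarray] = []
    shares13: list[np.ndarray] = []
    shares12: list[np.ndarray] = []
    heavy_ra: list[float] = []
    for day in days:
        shares: dict[str, list[HeavyShare]] = {}
        for isotope in ("13C", "12C"):
            reps = sorted(
                {m.replicate for m in soil_sheet if m.isotope == isotope and m.day == day}
            )
            shares[isotope] = [
                heavy_share(ab, soil_sheet, genus, soil, isotope, rep, day)
                for rep in reps
            ]
        if shares["13C"] and shares["12C"]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", DataLossWarning)
                day_pairs = ef_pairs(shares["13C"], shares["12C"])
        else:
            day_pairs = np.empty(0)
        pairs.append(day_pairs)
        shares13.append(np.array([s.p for s in shares["13C"] if s.defined]))
        shares12.append(np.array([s.p for s in shares["12C"] if s.defined]))
        heavy_cols = [
            m.sample_id
            for m in soil_sheet
            if m.isotope == "13C" and m.pool == "heavy" and m.day == day
        ]
        heavy_ra.append(
            float(np.mean([ab.abundance(genus, s) for s in heavy_cols]))
            if heavy_cols
            else math.nan
        )
    return EFSeries(
        genus=genus,
        soil=soil,
        days=list(days),
        pairs=pairs,
        heavy_ra_mean=heavy_ra,
        shares13=shares13,
        shares12=shares12,
    )


def anova_oneway(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA; returns (F, two-sided p).

    The degenerate case of identical values in every group is defined as
    F = 0, p = 1; zero within-group variance with distinct group means gives
    F = inf, p = 0.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if np.asarray(g).size]
    if len(groups) < 2:
        return math.nan, math.nan
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0:
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p = stats.f_oneway(*groups)
    if math.isnan(p):
        # zero within-group variance with distinct group means
        return math.inf, 0.0
    return float(f_stat), float(p)


def anova_time(series: EFSeries, method: str = "interaction") -> float:
    """Significance of change of the EF through time.

    ``method="interaction"`` (default): the EF at day d is the difference of
    the mean 13C and mean 12C heavy shares, so "EF changes through time" is
    the day x isotope interaction in a two-way fixed-effects ANOVA on the
    per-replicate heavy shares.  The shares are the independent experimental
    units (one per microcosm), giving the test its nominal size.

    ``method="pairs"``: one-way ANOVA with day as factor over the per-day
    pairwise EF values.  The 9 pairwise values per day re-use 3 + 3 shares,
    so this variant is anticonservative under the null; it is retained for
    comparison with pipelines that group on the combinatorial values.

    Returns the two-sided p-value; NaN (the gate then fails conservatively)
    when the design cannot support the test (fewer than two usable days, or
    no residual degrees of freedom).
    """
    if method == "pairs":
        groups = [p for p in series.pairs if p.size >= 2]
        if len(groups) < 2:
            return math.nan
        return anova_oneway(groups)[1]
    if method != "interaction":
        raise ValidationError(f"unknown anova method {method!r}")

    rows: list[tuple[float, int, str]] = []
    usable_days = 0
    for day, s13, s12 in zip(series.days, series.shares13, series.shares12):
        if s13.size and s12.size:
            usable_days += 1
            rows.extend((p, day, "13C") for p in s13)
            rows.extend((p, day, "12C") for p in s12)
    if usable_days < 2:
        return math.nan
    values = np.array([r[0] for r in rows])
    if np.ptp(values) == 0:
        return 1.0
    n_cells = 2 * usable_days
    if len(rows) - n_cells < 1:  # no residual degrees of freedom
        return math.nan
    frame = pd.DataFrame(rows, columns=["p", "day", "iso"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.ols("p ~ C(day) * C(iso)", data=frame).fit()
        table = anova_lm(model, typ=2)
    p_int = float(table.loc["C(day):C(iso)", "PR(>F)"])
    if math.isnan(p_int) and float(table.loc["C(day):C(iso)", "sum_sq"]) > 1e-18:
        return 0.0  # zero residual variance with a real interaction effect
    return p_int


def classify_enriched(
    series: EFSeries,
    ef_threshold: float = EF_THRESHOLD,
    alpha: float = ANOVA_ALPHA,
    min_display_ra: float = 0.005,
) -> EFSeries:
    """Apply the enrichment gates and set the flags on a copy of the series.

    A genus is enriched iff its mean EF exceeds ``ef_threshold`` (strict) on
    at least one day AND the ANOVA-through-time p-value is below ``alpha``
    (strict).  The per-day display flag marks days where the genus's mean
    heavy-fraction relative abundance exceeds ``min_display_ra``.
    """
    if series.anova_p is None:
        series = replace(series, anova_p=anova_time(series))
    means = series.means
    day_flags = [bool(not math.isnan(m) and m > ef_threshold) for m in means]
    displayed = [
        bool(not math.isnan(ra) and ra > min_display_ra) for ra in series.heavy_ra_mean
    ]
    p = series.anova_p
    enriched = any(day_flags) and (p is not None and not math.isnan(p) and p < alpha)
    return replace(
        series,
        enriched=bool(enriched),
        day_enriched=day_flags,
        day_displayed=displayed,
    )


def ef_table(series_list: Sequence[EFSeries]) -> pd.DataFrame:
    """Long-format EF results: one row per (genus, soil, day)."""
    rows = []
    for s in series_list:
        for day, mean, sd, n, flag, disp, ra in zip(
            s.days,
            s.means,
            s.sds,
            s.n_pairs,
            s.day_enriched or [False] * len(s.days),
            s.day_displayed or [False] * len(s.days),
            s.heavy_ra_mean,
        ):
            rows.append(
                {
                    "genus": s.genus,
                    "soil": s.soil,
                    "day": day,
                    "ef_mean": mean,
                    "ef_sd": sd,
                    "n_pairs": n,
                    "anova_p": s.anova_p,
                    "enriched": s.enriched,
                    "day_enriched": flag,
                    "day_displayed": disp,
                    "heavy_ra_mean": ra,
                }
            )
    return pd.DataFrame(rows)
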