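"""Rarefaction, genus aggregation, relative abundance and taxon filters.

The enrichment-factor statistic downstream consumes genus-level relative
abundances from count tables rarefied to an even depth.  The filters here
reproduce the standard SIP-amplicon gates: a genus enters the analysis only
if it is non-negligible on average (mean relative abundance) and observed in
enough samples (prevalence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import CountTable, SampleMeta
from .errors import DataLossWarning, ValidationError

__all__ = [
    "AbundanceTable",
    "FilterParams",
    "rarefy",
    "aggregate_to_genus",
    "relative_abundance",
    "filter_taxa",
    "display_filter",
]


@dataclass
class AbundanceTable:
    """Taxon-by-sample relative abundances.

    A freshly computed table has columns summing to 1 (or 0 for an empty
    sample); a filtered view is a row subset whose values stay relative to
    the full community, so column sums may fall below 1 but never exceed it.
    """

    taxa: list[str]
    samples: list[str]
    values: np.ndarray
    rank: str = "genus"

    def __post_init__(self) -> None:
        self.taxa = [str(t) for t in self.taxa]
        self.samples = [str(s) for s in self.samples]
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.taxa), len(self.samples)):
            raise ValidationError("values shape does not match taxa x samples")
        if values.size:
            if values.min() < 0 or values.max() > 1 + 1e-9:
                raise ValidationError("relative abundances must lie in [0, 1]")
            sums = values.sum(axis=0)
            if np.any(sums > 1 + 1e-9):
                bad = [s for s, t in zip(self.samples, sums) if t > 1 + 1e-9]
                raise ValidationError(f"column sums exceed 1: {bad[:5]}")
        self.values = values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.samples)

    def abundance(self, taxon: str, sample: str) -> float:
        try:
            i = self.taxa.index(taxon)
            j = self.samples.index(sample)
        except ValueError as exc:
            raise KeyError(f"({taxon!r}, {sample!r}) not in table") from exc
        return float(self.values[i, j])

    def select_taxa(self, keep: Sequence[str]) -> "AbundanceTable":
        idx = {t: i for i, t in enumerate(self.taxa)}
        rows = [idx[t] for t in keep]
        return AbundanceTable(list(keep), self.samples, self.values[rows], rank=self.rank)


@dataclass(frozen=True)
class FilterParams:
    """Abundance/prevalence gates applied across all experimental samples.

    A taxon is kept iff its mean relative abundance exceeds ``min_mean_ra``
    (strict) and it is present (nonzero) either in a fraction of samples
    exceeding ``min_prevalence`` (strict) or in at least ``min_samples``
    samples.  The two prevalence phrasings are equivalent on a full design
    and are combined with OR so either reading passes identical data.
    """

    min_mean_ra: float = 0.005
    min_prevalence: float = 0.06
    min_samples: int = 3

    def __post_init__(self) -> None:
        if self.min_mean_ra < 0 or self.min_prevalence < 0 or self.min_samples < 0:
            raise ValidationError("filter thresholds must be non-negative")


def rarefy(table: CountTable, depth: int, seed: int = 1) -> CountTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped with a warning.
    Sampling is multivariate hypergeometric per sample, deterministic for a
    given seed and input (samples are processed in column order).
    """
    if int(depth) != depth or depth < 1:
        raise ValidationError(f"rarefaction depth must be a positive integer, got {depth!r}")
    depth = int(depth)
    rng = np.random.default_rng(seed)
    kept_samples: list[str] = []
    kept_cols: list[np.ndarray] = []
    for j, sample in enumerate(table.samples):
        col = table.counts[:, j]
        total = int(col.sum())
        if total < depth:
            warnings.warn(
                f"sample {sample!r} has {total} reads (< depth {depth}); dropped",
                DataLossWarning,
                stacklevel=2,
            )
            continue
        if total == depth:
            kept_cols.append(col.copy())
        else:
            kept_cols.append(rng.multivariate_hypergeometric(col, depth))
        kept_samples.append(sample)
    counts = (
        np.column_stack(kept_cols)
        if kept_cols
        else np.zeros((len(table.taxa), 0), dtype=np.int64)
    )
    return CountTable(list(table.taxa), kept_samples, counts, rank=table.rank)


def aggregate_to_genus(table: CountTable, taxonomy: Mapping[str, str]) -> CountTable:
    """Sum ASV counts within genera; unlabelled ASVs map to 'unclassified:<id>'.

    Per-sample totals are conserved.  Genus order follows first appearance in
    the input taxon order.
    """
    genera: list[str] = []
    index: dict[str, int] = {}
    rows = np.zeros((0, len(table.samples)), dtype=np.int64)
    out = []
    for i, taxon in enumerate(table.taxa):
        genus = taxonomy.get(taxon) or f"unclassified:{taxon}"
        if genus not in index:
            index[genus] = len(genera)
            genera.append(genus)
            out.append(np.zeros(len(table.samples), dtype=np.int64))
        out[index[genus]] += table.counts[i]
    counts = (
        np.vstack(out) if out else np.zeros((0, len(table.samples)), dtype=np.int64)
    )
    return CountTable(genera, list(table.samples), counts, rank="genus")


def relative_abundance(table: CountTable) -> AbundanceTable:
    """Divide each sample column by its total; all-zero columns stay zero."""
    counts = table.counts.astype(float)
    sums = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(sums > 0, counts / np.where(sums > 0, sums, 1.0), 0.0)
    return AbundanceTable(list(table.taxa), list(table.samples), values, rank=table.rank)


def filter_taxa(ab: AbundanceTable, params: FilterParams | None = None) -> AbundanceTable:
    """Apply the mean-abundance and prevalence gates (see FilterParams)."""
    if params is None:
        params = FilterParams()
    if not ab.samples:
        return ab
    mean_ra = ab.values.mean(axis=1)
    nonzero = (ab.values > 0).sum(axis=1)
    prevalence = nonzero / len(ab.samples)
    keep_mask = (mean_ra > params.min_mean_ra) & (
        (prevalence > params.min_prevalence) | (nonzero >= params.min_samples)
    )
    keep = [t for t, k in zip(ab.taxa, keep_mask) if k]
    return ab.select_taxa(keep)


def display_filter(
    ab: AbundanceTable,
    sheet: Sequence[SampleMeta],
    min_ra: float = 0.005,
) -> list[str]:
    """Display-only rule: taxa whose mean relative abundance exceeds
    ``min_ra`` at at least one time point (mean over samples of a day).

    This reproduces the figure-caption convention; the analysis filter is
    :func:`filter_taxa`.
    """
    by_id = {m.sample_id: m for m in sheet}
    days = sorted({by_id[s].day for s in ab.samples if s in by_id})
    keep: list[str] = []
    for i, taxon in enumerate(ab.taxa):
        for day in days:
            cols = [j for j, s in enumerate(ab.samples) if by_id.get(s) and by_id[s].day == day]
            if cols and ab.values[i, cols].mean() > min_ra:
                keep.append(taxon)
                break
    return keep
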