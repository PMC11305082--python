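"""Inoculum tracking and the predation vs cross-feeding classification.

The inoculated consortium (by default a Sphingobium and a Burkholderia
strain) is tracked by matching amplicon sequence variants (ASVs) to the
strains' reference 16S rRNA sequences at high identity.  The course of the
matched relative abundances across days is tested with a Friedman test and
Conover all-pairs post hocs (complete blocks: every replicate observed at
every day).  A genus enriched in labelled carbon is then classified:
a negative and significant Kendall rank correlation (tau, p < 0.01) between
its abundance and an inoculum genus's abundance indicates predation (the
consumer rises as the inoculum declines); otherwise cross-feeding is assumed.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from scipy import stats

from .core_io import SampleMeta
from .errors import DataLossWarning, ValidationError
from .preprocess import AbundanceTable

__all__ = [
    "InoculumMatch",
    "TrophicResult",
    "FriedmanResult",
    "match_inoculum_asvs",
    "sequence_identity",
    "inoculum_series",
    "friedman_conover",
    "kendall_classify",
]

MIN_IDENTITY = 0.995
KENDALL_ALPHA = 0.01
_VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class InoculumMatch:
    """Best-reference alignment identity for one ASV."""

    asv_id: str
    reference: str
    identity: float
    matched: bool


@dataclass(frozen=True)
class TrophicResult:
    """Kendall correlation between an enriched genus and an inoculum genus."""

    genus: str
    soil: str
    partner: str
    tau: float
    p: float
    call: str  # "predation" | "cross_feeding"


class FriedmanResult(NamedTuple):
    statistic: float
    pvalue: float
    posthoc: pd.DataFrame | None  # Conover all-pairs p-values, days x days


def _make_aligner(free_end_gaps: bool) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    if free_end_gaps:
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def sequence_identity(a: str, b: str, free_end_gaps: bool = False) -> float:
    """Global-alignment identity: identical columns / total alignment columns.

    Gap columns count against identity.  Amplicons of the same locus should
    align end to end; set ``free_end_gaps=True`` to ignore terminal overhangs.
    """
    a = a.strip().upper()
    b = b.strip().upper()
    if not a or not b:
        raise ValidationError("empty sequence")
    for seq in (a, b):
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValidationError(f"non-nucleotide characters {sorted(bad)}")
    aligner = _make_aligner(free_end_gaps)
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / columns


def match_inoculum_asvs(
    asv_records,
    references,
    min_identity: float = MIN_IDENTITY,
    free_end_gaps: bool = False,
) -> list[InoculumMatch]:
    """Match each ASV to its best inoculum reference sequence.

    ``asv_records`` and ``references`` are iterables of Bio.SeqRecord (e.g.
    from ``SeqIO.parse(path, "fasta")``) or (id, sequence) pairs.  An ASV is
    matched when its best identity strictly exceeds ``min_identity``.
    """
    refs = [_as_pair(r) for r in references]
    if not refs:
        raise ValidationError("no reference sequences given")
    out: list[InoculumMatch] = []
    for rec in asv_records:
        asv_id, seq = _as_pair(rec)
        best_ref, best_ident = None, -1.0
        for ref_id, ref_seq in refs:
            ident = sequence_identity(seq, ref_seq, free_end_gaps=free_end_gaps)
            if ident > best_ident:
                best_ref, best_ident = ref_id, ident
        out.append(
            InoculumMatch(
                asv_id=asv_id,
                reference=best_ref,
                identity=best_ident,
                matched=best_ident > min_identity,
            )
        )
    return out


def _as_pair(record) -> tuple[str, str]:
    if isinstance(record, tuple):
        return str(record[0]), str(record[1])
    return str(record.id), str(record.seq)


def load_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def inoculum_series(
    ab: AbundanceTable,
    sheet: Sequence[SampleMeta],
    matches: Sequence[InoculumMatch],
    pool: str = "heavy",
    isotope: str = "13C",
    reference_genus: dict[str, str] | None = None,
) -> dict[tuple[str, str, int, int], float]:
    """Summed matched-ASV relative abundance per (genus, soil, day, replicate).

    Restricted to samples of the requested pool and isotope.  The genus label
    of a match defaults to the reference id's leading token (before the first
    underscore); pass ``reference_genus`` to override.
    """
    matched = [m for m in matches if m.matched]
    if not matched:
        raise ValidationError("no matched ASVs")
    genus_of = {
        m.asv_id: (reference_genus or {}).get(m.reference, m.reference.split("_")[0])
        for m in matched
    }
    taxon_index = {t: i for i, t in enumerate(ab.taxa)}
    out: dict[tuple[str, str, int, int], float] = {}
    for m in sheet:
        if m.pool != pool or m.isotope != isotope or m.sample_id not in ab.samples:
            continue
        j = ab.samples.index(m.sample_id)
        for asv_id, genus in genus_of.items():
            i = taxon_index.get(asv_id)
            value = float(ab.values[i, j]) if i is not None else 0.0
            key = (genus, m.soil, m.day, m.replicate)
            out[key] = out.get(key, 0.0) + value
    return out


def friedman_conover(values: np.ndarray | pd.DataFrame) -> FriedmanResult:
    """Friedman test across days with Conover all-pairs post hocs.

    ``values`` is replicates (blocks) x days; the design must be complete.
    Incomplete blocks (any missing observation) return an undefined result
    with a warning, mirroring how lost gradient fractions preclude the test.
    """
    if isinstance(values, pd.DataFrame):
        day_labels = list(values.columns)
        arr = values.to_numpy(dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
        day_labels = list(range(arr.shape[1])) if arr.ndim == 2 else []
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        warnings.warn("need >=2 replicates and >=2 days", DataLossWarning, stacklevel=2)
        return FriedmanResult(math.nan, math.nan, None)
    if np.isnan(arr).any():
        warnings.warn(
            "incomplete block design (missing observation); Friedman test undefined",
            DataLossWarning,
            stacklevel=2,
        )
        return FriedmanResult(math.nan, math.nan, None)
    n, k = arr.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, arr)
    rank_sums = ranks.sum(axis=0)
    if np.ptp(arr) == 0:
        posthoc = pd.DataFrame(1.0, index=day_labels, columns=day_labels)
        return FriedmanResult(0.0, 1.0, posthoc)
    if k >= 3:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            statistic, pvalue = stats.friedmanchisquare(*(arr[:, j] for j in range(k)))
    else:
        # two-day case: tie-adjusted Friedman chi-square computed directly
        a1 = float((ranks**2).sum())
        c1 = n * k * (k + 1) ** 2 / 4.0
        if a1 == c1:
            statistic, pvalue = 0.0, 1.0
        else:
            statistic = (k - 1) * float(
                ((rank_sums - n * (k + 1) / 2.0) ** 2).sum()
            ) / (a1 - c1)
            pvalue = stats.chi2.sf(statistic, k - 1)
    posthoc = _conover_posthoc(ranks, rank_sums, float(statistic), day_labels)
    return FriedmanResult(float(statistic), float(pvalue), posthoc)


def _conover_posthoc(
    ranks: np.ndarray, rank_sums: np.ndarray, t1: float, day_labels: list
) -> pd.DataFrame:
    """Conover's all-pairs comparisons on Friedman rank sums (t-form)."""
    n, k = ranks.shape
    a1 = float((ranks**2).sum())
    c1 = n * k * (k + 1) ** 2 / 4.0
    df = (n - 1) * (k - 1)
    scale = 1.0 - t1 / (n * (k - 1))
    var = 2.0 * n * (a1 - c1) * max(scale, 0.0) / df
    se = math.sqrt(var) if var > 0 else 0.0
    p = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        diff = abs(rank_sums[i] - rank_sums[j])
        if se == 0.0:
            pij = 0.0 if diff > 0 else 1.0
        else:
            pij = 2.0 * stats.t.sf(diff / se, df)
        p[i, j] = p[j, i] = min(1.0, pij)
    return pd.DataFrame(p, index=day_labels, columns=day_labels)


def kendall_classify(
    predator: Sequence[float],
    inoculum: Sequence[float],
    alpha: float = KENDALL_ALPHA,
    genus: str = "",
    soil: str = "",
    partner: str = "",
) -> TrophicResult:
    """Kendall tau-b between paired abundance series and the trophic call.

    Exact two-sided p-value for n <= 10 without ties; normal approximation
    otherwise.  Predation is called iff tau < 0 and p < alpha (both strict);
    cross-feeding is assumed otherwise, including for undefined tau.
    """
    x = np.asarray(predator, dtype=float)
    y = np.asarray(inoculum, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("series must be 1-D and paired")
    if x.size < 3:
        raise ValidationError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant series; tau undefined", DataLossWarning, stacklevel=2)
        return TrophicResult(genus, soil, partner, math.nan, math.nan, "cross_feeding")
    has_ties = len(set(x)) < x.size or len(set(y)) < y.size
    method = "exact" if (x.size <= 10 and not has_ties) else "asymptotic"
    tau, p = stats.kendalltau(x, y, method=method)
    call = "predation" if (tau < 0 and p < alpha) else "cross_feeding"
    return TrophicResult(genus, soil, partner, float(tau), float(p), call)
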