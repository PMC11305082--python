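"""Data model and I/O for SIP amplicon experiments.

A SIP (stable isotope probing) amplicon experiment is a factorial design:
soil x isotope (13C treatment / 12C control / none) x gradient pool
(heavy / light) x replicate x sampling day.  Counts live in a taxon-by-sample
table; sample annotations live in a sample sheet.  This module reads both,
validates them individually and against each other, and bundles them for the
downstream enrichment-factor computation.

On-disk dialects: count tables are TSV (rows = taxa, first column = taxon id,
header = sample ids) or BIOM v1.0 JSON (read-only); sample sheets and all
outputs are TSV.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DesignWarning, FormatError, ValidationError

SOILS = ("ST", "LT")
ISOTOPES = ("13C", "12C", "none")
POOLS = ("heavy", "light", "unfractionated")

__all__ = [
    "SampleMeta",
    "CountTable",
    "ExperimentBundle",
    "read_count_table",
    "write_count_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "validate_design",
]


@dataclass(frozen=True)
class SampleMeta:
    """Annotation of one sequenced (pooled-fraction) sample.

    ``recovery`` is the proportion of loaded DNA recovered after gradient
    fractionation, used by the QC exclusion rule; ``None`` when not measured.
    """

    sample_id: str
    soil: str
    isotope: str
    pool: str
    replicate: int
    day: int
    recovery: float | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be a non-empty string")
        if self.soil not in SOILS:
            raise ValidationError(
                f"unknown soil {self.soil!r} for sample {self.sample_id!r}; "
                f"expected one of {SOILS}"
            )
        if self.isotope not in ISOTOPES:
            raise ValidationError(
                f"unknown isotope {self.isotope!r} for sample {self.sample_id!r}"
            )
        if self.pool not in POOLS:
            raise ValidationError(
                f"unknown pool {self.pool!r} for sample {self.sample_id!r}"
            )
        if int(self.replicate) != self.replicate or self.replicate < 1:
            raise ValidationError(
                f"replicate must be a positive integer, got {self.replicate!r}"
            )
        if int(self.day) != self.day or self.day < 0:
            raise ValidationError(f"day must be a non-negative integer, got {self.day!r}")
        if self.recovery is not None and not 0.0 <= self.recovery <= 1.0:
            raise ValidationError(
                f"recovery must lie in [0, 1], got {self.recovery!r} "
                f"for sample {self.sample_id!r}"
            )

    @property
    def key(self) -> tuple:
        """Design cell coordinates (soil, isotope, pool, replicate, day)."""
        return (self.soil, self.isotope, self.pool, self.replicate, self.day)


def _check_unique(values: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for v in values:
        if v in seen:
            raise ValidationError(f"duplicate {what}: {v!r}")
        seen.add(v)


@dataclass
class CountTable:
    """Integer taxon-by-sample count matrix at ASV or genus rank."""

    taxa: list[str]
    samples: list[str]
    counts: np.ndarray  # shape (n_taxa, n_samples), non-negative integers
    rank: str = "asv"

    def __post_init__(self) -> None:
        self.taxa = [str(t) for t in self.taxa]
        self.samples = [str(s) for s in self.samples]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.taxa), len(self.samples)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.samples)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise ValidationError("counts must be integral")
        if counts.size and counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        self.counts = counts.astype(np.int64)
        _check_unique(self.taxa, "taxon id")
        _check_unique(self.samples, "sample id")
        if self.rank not in ("asv", "genus"):
            raise ValidationError(f"rank must be 'asv' or 'genus', got {self.rank!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxa, columns=self.samples)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, rank: str = "asv") -> "CountTable":
        return cls(
            taxa=list(frame.index.astype(str)),
            samples=list(frame.columns.astype(str)),
            counts=frame.to_numpy(),
            rank=rank,
        )

    def select_samples(self, keep: Iterable[str]) -> "CountTable":
        keep = list(keep)
        idx = {s: j for j, s in enumerate(self.samples)}
        missing = [s for s in keep if s not in idx]
        if missing:
            raise ValidationError(f"samples not in table: {missing}")
        cols = [idx[s] for s in keep]
        return CountTable(self.taxa, keep, self.counts[:, cols], rank=self.rank)


@dataclass
class ExperimentBundle:
    """Validated pairing of a count table with its sample sheet.

    ``depth`` is the even sequencing depth after rarefaction; ``None`` for a
    pre-rarefaction bundle with ragged column sums.  ``warnings`` holds the
    replicate-deficiency records emitted by :func:`validate_design`.
    """

    table: CountTable
    sheet: list[SampleMeta]
    depth: int | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_id = {m.sample_id: m for m in self.sheet}
        if len(by_id) != len(self.sheet):
            raise ValidationError("duplicate sample_id in sheet")
        missing = [s for s in self.table.samples if s not in by_id]
        if missing:
            raise ValidationError(f"table samples absent from sheet: {missing}")
        keys = [m.key for m in self.sheet]
        if len(set(keys)) != len(keys):
            dup = [k for k in keys if keys.count(k) > 1][0]
            raise ValidationError(
                f"(soil, isotope, pool, replicate, day) not unique: {dup}"
            )
        if self.depth is not None:
            if self.depth < 1:
                raise ValidationError("depth must be positive")
            sums = self.table.sample_sums()
            if self.table.samples and not np.all(sums == self.depth):
                bad = [
                    s for s, t in zip(self.table.samples, sums) if t != self.depth
                ]
                raise ValidationError(
                    f"column sums differ from declared depth {self.depth}: {bad[:5]}"
                )

    @property
    def meta(self) -> dict[str, SampleMeta]:
        return {m.sample_id: m for m in self.sheet}

    def subset_sheet(self, **criteria) -> list[SampleMeta]:
        """Sheet rows matching all given field=value criteria."""
        out = []
        for m in self.sheet:
            if all(getattr(m, k) == v for k, v in criteria.items()):
                out.append(m)
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, format: str = "tsv", rank: str = "asv") -> CountTable:
    """Read a taxon-by-sample count table from TSV or BIOM v1.0 JSON.

    TSV dialect: taxa as rows, first column = taxon id, header row = sample
    ids.  Non-integer or negative cells are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "tsv":
        return _read_count_tsv(path, rank)
    if format == "biom":
        return _read_count_biom(path, rank)
    raise ValidationError(f"unknown count-table format {format!r}")


def _read_count_tsv(path: Path, rank: str) -> CountTable:
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty count table: {path}") from exc
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"malformed count table {path}: {exc}") from exc
    if frame.columns.size == 0:
        raise FormatError(f"count table has no sample columns: {path}")
    if frame.columns.duplicated().any() or frame.columns.str.match(r"^Unnamed").any():
        raise FormatError(f"malformed header in {path}")
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValidationError(f"duplicate taxon id {dup!r} in {path}")
    values = frame.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        raise ValidationError(f"non-numeric cells in {path}")
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"missing or non-finite cells in {path}")
    if np.any(values != np.floor(values)):
        raise ValidationError(f"non-integer counts in {path}")
    if values.min(initial=0) < 0:
        raise ValidationError(f"negative counts in {path}")
    return CountTable.from_frame(frame, rank=rank)


def _read_count_biom(path: Path, rank: str) -> CountTable:
    """Minimal reader for the BIOM v1.0 JSON dialect (dense and sparse)."""
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid BIOM JSON: {path}") from exc
    for key in ("rows", "columns", "data", "matrix_type", "shape"):
        if key not in doc:
            raise FormatError(f"BIOM file missing field {key!r}: {path}")
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    n, m = doc["shape"]
    if (n, m) != (len(taxa), len(samples)):
        raise FormatError(f"BIOM shape mismatch in {path}")
    counts = np.zeros((n, m), dtype=float)
    if doc["matrix_type"] == "dense":
        counts[:] = np.asarray(doc["data"], dtype=float)
    elif doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            counts[int(i), int(j)] = v
    else:
        raise FormatError(f"unsupported BIOM matrix_type {doc['matrix_type']!r}")
    if np.any(counts != np.floor(counts)) or counts.min(initial=0) < 0:
        raise ValidationError(f"non-integral or negative counts in {path}")
    return CountTable(taxa, samples, counts, rank=rank)


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="taxon_id")


_SHEET_COLUMNS = ("sample_id", "soil", "isotope", "pool", "replicate", "day")

_ISOTOPE_ALIASES = {"13c": "13C", "12c": "12C", "none": "none", "na": "none"}


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read a sample sheet TSV; enum tokens are validated case-insensitively."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty sample sheet: {path}") from exc
    missing = [c for c in _SHEET_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns {missing}: {path}")
    sheet: list[SampleMeta] = []
    for _, row in frame.iterrows():
        isotope = str(row["isotope"]).strip().lower()
        if isotope not in _ISOTOPE_ALIASES:
            raise ValidationError(f"unknown isotope token {row['isotope']!r}")
        recovery = None
        if "recovery" in frame.columns and pd.notna(row.get("recovery")):
            recovery = float(row["recovery"])
        try:
            replicate = int(row["replicate"])
            day = int(row["day"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"non-integer replicate/day in row {row['sample_id']!r}"
            ) from exc
        sheet.append(
            SampleMeta(
                sample_id=str(row["sample_id"]).strip(),
                soil=str(row["soil"]).strip().upper(),
                isotope=_ISOTOPE_ALIASES[isotope],
                pool=str(row["pool"]).strip().lower(),
                replicate=replicate,
                day=day,
                recovery=recovery,
            )
        )
    _check_unique([m.sample_id for m in sheet], "sample_id")
    return sheet


def write_sample_sheet(sheet: Sequence[SampleMeta], path: str | Path) -> None:
    rows = []
    for m in sheet:
        rows.append(
            {
                "sample_id": m.sample_id,
                "soil": m.soil,
                "isotope": m.isotope,
                "pool": m.pool,
                "replicate": m.replicate,
                "day": m.day,
                "recovery": "" if m.recovery is None else m.recovery,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def validate_design(
    table: CountTable,
    sheet: Sequence[SampleMeta],
    depth: int | None = None,
    expected_replicates: int = 3,
) -> ExperimentBundle:
    """Pair a count table with its sheet and audit the factorial design.

    Design cells (soil, isotope, day, pool) with fewer than
    ``expected_replicates`` sequenced samples produce a warning record, not an
    error: SIP studies routinely lose single gradient fractions and proceed.
    """
    sheet = list(sheet)
    in_table = set(table.samples)
    records: list[str] = []
    cells: dict[tuple, int] = {}
    for m in sheet:
        if m.sample_id not in in_table or m.pool == "unfractionated":
            continue
        if m.isotope == "none":
            continue
        cell = (m.soil, m.isotope, m.day, m.pool)
        cells[cell] = cells.get(cell, 0) + 1
    for cell in sorted(cells):
        n = cells[cell]
        if n < expected_replicates:
            soil, isotope, day, pool = cell
            msg = (
                f"design cell soil={soil} isotope={isotope} day={day} pool={pool} "
                f"has {n} replicate(s), expected {expected_replicates}"
            )
            records.append(msg)
            warnings.warn(msg, DesignWarning, stacklevel=2)
    bundle = ExperimentBundle(
        table=table,
        sheet=sorted(sheet, key=lambda m: m.sample_id),
        depth=depth,
        warnings=records,
    )
    return bundle
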