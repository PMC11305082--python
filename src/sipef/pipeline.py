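"""One-shot orchestration: pooling QC -> preprocess -> EF -> trophic calls.

The pipeline runs the stages in a fixed order, retains every intermediate
table as TSV so any stage can be re-run in isolation, and records every
parameter, seed, warning and dropped sample in a machine-readable run log.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import core_io, fractionation, preprocess, trophic
from .enrichment import ANOVA_ALPHA, EF_THRESHOLD, EFSeries, classify_enriched, ef_table, ef_timecourse
from .errors import ConfigurationError
from .preprocess import AbundanceTable, FilterParams
from .trophic import KENDALL_ALPHA

__all__ = ["PipelineConfig", "run_pipeline", "analyze_bundle"]


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run; loadable from YAML."""

    counts: str
    sheet: str
    outdir: str
    counts_format: str = "tsv"
    taxonomy: str | None = None  # 2-column TSV taxon -> genus
    fraction_profiles: str | None = None
    asv_fasta: str | None = None
    reference_fasta: str | None = None
    depth: int | None = None
    rarefaction_seed: int = 1
    heavy_window: tuple[float, float] = (1.720, 1.735)
    light_window: tuple[float, float] = (1.700, 1.715)
    recovery_threshold: float = 0.35
    min_mean_ra: float = 0.005
    min_prevalence: float = 0.06
    min_samples: int = 3
    ef_threshold: float = EF_THRESHOLD
    anova_alpha: float = ANOVA_ALPHA
    kendall_alpha: float = KENDALL_ALPHA
    min_identity: float = 0.995
    overwrite: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("heavy_window", "light_window"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def validate_paths(self) -> None:
        for key in ("counts", "sheet", "taxonomy", "fraction_profiles", "asv_fasta", "reference_fasta"):
            value = getattr(self, key)
            if value is not None and not Path(value).exists():
                raise ConfigurationError(f"{key} file does not exist: {value}")


def analyze_bundle(
    bundle: core_io.ExperimentBundle,
    params: FilterParams | None = None,
    ef_threshold: float = EF_THRESHOLD,
    anova_alpha: float = ANOVA_ALPHA,
    soils: Sequence[str] | None = None,
) -> tuple[list[EFSeries], AbundanceTable]:
    """Relative abundance -> taxon filter -> classified EF series per
    (genus, soil).  The bundle must hold a genus-rank, even-depth table."""
    ab = preprocess.relative_abundance(bundle.table)
    filtered = preprocess.filter_taxa(ab, params)
    if soils is None:
        soils = sorted({m.soil for m in bundle.sheet})
    results: list[EFSeries] = []
    for genus in filtered.taxa:
        for soil in soils:
            series = ef_timecourse(filtered, bundle.sheet, genus, soil)
            if not any(p.size for p in series.pairs):
                continue
            results.append(
                classify_enriched(series, ef_threshold=ef_threshold, alpha=anova_alpha)
            )
    return results, filtered


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the run-log dictionary."""
    config.validate_paths()
    outdir = Path(config.outdir)
    if outdir.exists() and any(outdir.iterdir()) and not config.overwrite:
        raise ConfigurationError(
            f"output directory {outdir} is not empty; pass overwrite=true to replace"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"stages": [], "warnings": [], "parameters": _params_of(config)}

    def record(stage: str, **info) -> None:
        log["stages"].append({"stage": stage, **info})

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        table = core_io.read_count_table(config.counts, format=config.counts_format)
        sheet = core_io.read_sample_sheet(config.sheet)
        record("load", n_taxa=len(table.taxa), n_samples=len(table.samples))

        # recovery QC: drop fractionated samples recovering too little DNA
        excluded = [
            m.sample_id
            for m in sheet
            if m.recovery is not None
            and fractionation.flag_low_recovery(m.recovery, config.recovery_threshold)
        ]
        if excluded:
            keep = [s for s in table.samples if s not in set(excluded)]
            table = table.select_samples(keep)
        record("recovery_qc", excluded=excluded, threshold=config.recovery_threshold)

        if config.depth is not None:
            table = preprocess.rarefy(table, config.depth, seed=config.rarefaction_seed)
            record("rarefy", depth=config.depth, seed=config.rarefaction_seed,
                   n_samples=len(table.samples))

        if config.taxonomy is not None:
            tax = pd.read_csv(config.taxonomy, sep="\t", header=None, dtype=str)
            genus_table = preprocess.aggregate_to_genus(
                table, dict(zip(tax[0], tax[1]))
            )
        else:
            genus_table = table
        sheet_kept = [m for m in sheet if m.sample_id in set(genus_table.samples)]
        bundle = core_io.validate_design(genus_table, sheet_kept, depth=config.depth)
        core_io.write_count_table(genus_table, outdir / "genus_counts.tsv")
        record("aggregate", n_genera=len(genus_table.taxa), design_warnings=bundle.warnings)

        params = FilterParams(
            min_mean_ra=config.min_mean_ra,
            min_prevalence=config.min_prevalence,
            min_samples=config.min_samples,
        )
        results, filtered = analyze_bundle(
            bundle, params, ef_threshold=config.ef_threshold, anova_alpha=config.anova_alpha
        )
        filtered.to_frame().to_csv(outdir / "filtered_abundance.tsv", sep="\t",
                                   index_label="taxon_id")
        ef_frame = ef_table(results)
        ef_frame.to_csv(outdir / "ef_table.tsv", sep="\t", index=False, float_format="%.10g")
        enriched = sorted({s.genus for s in results if s.enriched})
        record("ef", n_series=len(results), enriched=enriched)

        # trophic stage requires ASV-level data plus reference sequences
        if config.asv_fasta and config.reference_fasta:
            _run_trophic(config, table, sheet_kept, results, outdir, record)

        log["warnings"] = [f"{w.category.__name__}: {w.message}" for w in caught]

    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return log


def _run_trophic(config, asv_table, sheet, results, outdir, record) -> None:
    matches = trophic.match_inoculum_asvs(
        trophic.load_fasta(config.asv_fasta),
        trophic.load_fasta(config.reference_fasta),
        min_identity=config.min_identity,
    )
    pd.DataFrame([m.__dict__ for m in matches]).to_csv(
        outdir / "inoculum_matches.tsv", sep="\t", index=False
    )
    asv_ab = preprocess.relative_abundance(asv_table)
    matched = [m for m in matches if m.matched]
    if not matched:
        record("trophic", note="no ASV matched any reference; stage skipped")
        return
    series = trophic.inoculum_series(asv_ab, sheet, matches)
    tracking = pd.DataFrame(
        [
            {"genus": g, "soil": s, "day": d, "replicate": r, "relative_abundance": v}
            for (g, s, d, r), v in sorted(series.items())
        ]
    )
    tracking.to_csv(outdir / "inoculum_tracking.tsv", sep="\t", index=False)

    genus_ab = preprocess.relative_abundance(asv_table)
    calls = []
    inoc_genera = sorted({key[0] for key in series})
    enriched_series = [s for s in results if s.enriched]
    by_id = {m.sample_id: m for m in sheet}
    for s in enriched_series:
        keys = sorted(
            {
                (m.day, m.replicate)
                for m in sheet
                if m.soil == s.soil and m.isotope == "13C" and m.pool == "heavy"
            }
        )
        for partner in inoc_genera:
            pred = []
            inoc = []
            for day, rep in keys:
                sid = next(
                    (
                        m.sample_id
                        for m in sheet
                        if m.soil == s.soil and m.isotope == "13C"
                        and m.pool == "heavy" and m.day == day and m.replicate == rep
                    ),
                    None,
                )
                if sid is None or sid not in genus_ab.samples or (partner, s.soil, day, rep) not in series:
                    continue
                if s.genus not in genus_ab.taxa:
                    continue
                pred.append(genus_ab.abundance(s.genus, sid))
                inoc.append(series[(partner, s.soil, day, rep)])
            if len(pred) >= 3:
                calls.append(
                    trophic.kendall_classify(
                        pred, inoc, alpha=config.kendall_alpha,
                        genus=s.genus, soil=s.soil, partner=partner,
                    )
                )
    pd.DataFrame([c.__dict__ for c in calls]).to_csv(
        outdir / "trophic_calls.tsv", sep="\t", index=False
    )
    record("trophic", n_matches=len(matched), n_calls=len(calls))


def _params_of(config: PipelineConfig) -> dict:
    return {k: getattr(config, k) for k in config.__dataclass_fields__}
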