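"""Seeded generator of SIP amplicon experiments with known ground truth.

The generator emulates the factorial microcosm design the pipeline targets:
two soils x {13C treatment, 12C control} x replicates x sampling days, each
microcosm sequenced as a heavy and a light pooled gradient fraction at fixed
depth.  Mechanism per microcosm:

1. Community proportions are drawn from a Dirichlet centred on a per-soil
   log-normal baseline (replicate noise).
2. A pool of template molecules is drawn multinomially from the proportions.
3. Each genus's templates are split between the heavy and the light pool by
   a Bernoulli density model: a genus whose biomass is unlabelled still
   leaks into the heavy window with a genus-specific baseline probability q0
   (emulating GC-content-driven buoyant-density variation); a 13C-treatment
   genus with labelled biomass fraction lambda(t) pools heavy with
   probability q0 + (1 - q0) * lambda(t).
4. Each pooled fraction is sequenced by drawing exactly ``depth`` reads
   without replacement from its templates (mirroring rarefied data).

Inoculum genera start fully labelled at a configured day-0 abundance; their
total abundance decays through incubation while growth on soil carbon
dilutes the label into the light pool.

Ground truth (which genera incorporated label, and the expected heavy-pool
share per isotope and day) is emitted alongside the bundle so detection
performance of the enrichment-factor gates can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import CountTable, ExperimentBundle, SampleMeta, validate_design
from .enrichment import EFSeries
from .errors import ValidationError

__all__ = [
    "Incorporator",
    "InoculumGenus",
    "SimConfig",
    "SimTruth",
    "RecoveryMetrics",
    "simulate_experiment",
    "split_reads",
    "evaluate_recovery",
    "default_incorporators",
]

TEMPLATE_FACTOR = 20  # template molecules per sequenced read, before subsampling


@dataclass(frozen=True)
class Incorporator:
    """A genus assimilating labelled carbon: lambda maps day -> labelled
    biomass fraction in [0, 1]."""

    genus: str
    lam: Mapping[int, float]

    def lam_at(self, day: int) -> float:
        return float(self.lam.get(day, 0.0))


@dataclass(frozen=True)
class InoculumGenus:
    """An inoculated, initially fully labelled genus.

    ``initial_ra``: day-0 relative abundance in the community;
    ``decay``: per-day survival factor of total abundance (abundance at day t
    is initial_ra * decay**t);
    ``growth_light``: per-day label-dilution rate; the labelled biomass
    fraction at day t is exp(-growth_light * t) (0 = no growth in situ, the
    label stays heavy).
    """

    genus: str
    initial_ra: float
    decay: float = 0.9
    growth_light: float = 0.0


@dataclass
class SimConfig:
    """Study-design parameters for the simulator (defaults emulate the
     2-soil x 2-isotope x 3-replicate x 4-day SIP design)."""

    n_genera: int = 60
    n_replicates: int = 3
    days: tuple[int, ...] = (0, 7, 15, 30)
    depth: int = 20000
    soils: tuple[str, ...] = ("ST", "LT")
    baseline_mu: float = 0.0
    baseline_sigma: float = 2.0
    soil_sigma: float = 0.7
    dirichlet_conc: float = 300.0
    incorporator_share: float = 0.08
    q0_range: tuple[float, float] = (0.05, 0.20)
    incorporators: list[Incorporator] = field(default_factory=list)
    inoculum: list[InoculumGenus] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genera < 1 or self.n_replicates < 1 or self.depth < 1:
            raise ValidationError("n_genera, n_replicates and depth must be positive")
        if list(self.days) != sorted(set(self.days)):
            raise ValidationError("days must be sorted ascending without duplicates")
        lo, hi = self.q0_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError("q0_range must lie within [0, 1]")
        if not 0.0 <= self.incorporator_share < 1.0:
            raise ValidationError("incorporator_share must lie in [0, 1)")
        if self.dirichlet_conc <= 0 or self.baseline_sigma < 0:
            raise ValidationError("dirichlet_conc must be positive, sigma non-negative")
        names = self.genus_names()
        for inc in self.incorporators:
            if inc.genus not in names:
                raise ValidationError(f"incorporator genus {inc.genus!r} not in community")
            if any(not 0.0 <= v <= 1.0 for v in inc.lam.values()):
                raise ValidationError("lambda values must lie in [0, 1]")
        total_inoc = sum(g.initial_ra for g in self.inoculum)
        if not 0.0 <= total_inoc < 1.0:
            raise ValidationError("total inoculum initial_ra must lie in [0, 1)")

    def genus_names(self) -> list[str]:
        return [f"g{i:03d}" for i in range(self.n_genera)]


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator.

    ``incorporator``: genus -> bool (background incorporators only; inoculum
    genera are listed separately since they are labelled by construction);
    ``lam``: genus -> {day: labelled fraction};
    ``expected_heavy_share``: genus -> {(isotope, day): expected p};
    ``q0``: genus -> baseline heavy-pool leakage.
    """

    incorporator: dict[str, bool]
    lam: dict[str, dict[int, float]]
    expected_heavy_share: dict[str, dict[tuple[str, int], float]]
    q0: dict[str, float]
    inoculum_genera: list[str] = field(default_factory=list)

    def positives(self) -> set[str]:
        return {g for g, flag in self.incorporator.items() if flag}


class RecoveryMetrics:
    """Sensitivity / specificity / FDR of incorporator detection."""

    def __init__(self, sensitivity: float, specificity: float, fdr: float):
        self.sensitivity = sensitivity
        self.specificity = specificity
        self.fdr = fdr

    def __iter__(self):
        return iter((self.sensitivity, self.specificity, self.fdr))

    def __repr__(self) -> str:
        return (
            f"RecoveryMetrics(sensitivity={self.sensitivity:.3f}, "
            f"specificity={self.specificity:.3f}, fdr={self.fdr:.3f})"
        )


def default_incorporators(
    config_or_names, n: int = 10, lam: Mapping[int, float] | None = None
) -> list[Incorporator]:
    """Convenience: the first ``n`` genera as incorporators with a shared
    lambda profile (default: label appears by day 7 and reaches 0.6 by day
    15, i.e. a strong consumer of labelled biomass)."""
    if lam is None:
        lam = {0: 0.0, 7: 0.3, 15: 0.6, 30: 0.6}
    names = (
        config_or_names.genus_names()
        if isinstance(config_or_names, SimConfig)
        else list(config_or_names)
    )
    return [Incorporator(g, dict(lam)) for g in names[:n]]


def split_reads(totals: np.ndarray, p_heavy: np.ndarray, rng: np.random.Generator):
    """Split each genus's template molecules between pools.

    Returns (heavy, light) integer arrays with heavy + light == totals
    element-wise (conservation).
    """
    totals = np.asarray(totals, dtype=np.int64)
    heavy = rng.binomial(totals, np.asarray(p_heavy, dtype=float))
    return heavy, totals - heavy


def _heavy_prob(q0: float, lam: float) -> float:
    return q0 + (1.0 - q0) * lam


def simulate_experiment(config: SimConfig) -> tuple[ExperimentBundle, SimTruth]:
    """Generate a complete SIP experiment bundle plus its ground truth.

    Fully deterministic for a given config (one seeded Generator consumed in
    a fixed sample order).
    """
    rng = np.random.default_rng(config.seed)
    names = config.genus_names()
    n = config.n_genera
    lam_of = {inc.genus: dict(inc.lam) for inc in config.incorporators}
    inoc_of = {g.genus: g for g in config.inoculum}
    background = [g for g in names if g not in inoc_of]

    # genus-level density leakage: a genus property, shared across soils
    lo, hi = config.q0_range
    q0 = dict(zip(names, rng.uniform(lo, hi, size=n)))

    # per-soil baseline community: a shared genus-level log-normal effect
    # modulated per soil (soils share regional taxa but differ in detail);
    # incorporators are pinned to a minor equal share of the total
    # (consumers of labelled biomass are minor community members)
    inc_genera = [g for g in background if g in lam_of]
    bulk = [g for g in background if g not in lam_of]
    shared = rng.normal(config.baseline_mu, config.baseline_sigma, size=len(bulk))
    baseline: dict[str, np.ndarray] = {}
    for soil in config.soils:
        w = np.exp(shared + rng.normal(0.0, config.soil_sigma, size=len(bulk)))
        props = np.empty(len(background))
        inc_share = config.incorporator_share if inc_genera else 0.0
        for i, g in enumerate(background):
            if g in lam_of:
                props[i] = inc_share / len(inc_genera)
        bulk_props = w / w.sum() * (1.0 - inc_share)
        props[[background.index(g) for g in bulk]] = bulk_props
        baseline[soil] = props

    n_templates = TEMPLATE_FACTOR * config.depth
    columns: dict[str, np.ndarray] = {}
    sheet: list[SampleMeta] = []

    for soil in config.soils:
        for isotope in ("13C", "12C"):
            for rep in range(1, config.n_replicates + 1):
                for day in config.days:
                    inoc_ra = {
                        g: spec.initial_ra * spec.decay**day
                        for g, spec in inoc_of.items()
                    }
                    total_inoc = sum(inoc_ra.values())
                    weights = np.empty(n)
                    bg_idx = [names.index(g) for g in background]
                    weights[bg_idx] = baseline[soil] * (1.0 - total_inoc)
                    for g, ra in inoc_ra.items():
                        weights[names.index(g)] = ra
                    alpha = np.clip(weights, 1e-12, None) * config.dirichlet_conc
                    props = rng.dirichlet(alpha)

                    p_heavy = np.empty(n)
                    for i, g in enumerate(names):
                        if g in inoc_of:
                            if isotope == "13C":
                                label = math.exp(-inoc_of[g].growth_light * day)
                            else:
                                label = 0.0
                        elif isotope == "13C":
                            label = lam_of.get(g, {}).get(day, 0.0)
                        else:
                            label = 0.0
                        p_heavy[i] = _heavy_prob(q0[g], label)

                    templates = rng.multinomial(n_templates, props)
                    heavy, light = split_reads(templates, p_heavy, rng)
                    for pool, pool_counts in (("heavy", heavy), ("light", light)):
                        sid = f"{soil}_{isotope}_r{rep}_d{day}_{pool}"
                        columns[sid] = _sequence_pool(pool_counts, config.depth, rng)
                        sheet.append(
                            SampleMeta(
                                sample_id=sid,
                                soil=soil,
                                isotope=isotope,
                                pool=pool,
                                replicate=rep,
                                day=day,
                            )
                        )

    sample_ids = [m.sample_id for m in sheet]
    counts = np.column_stack([columns[s] for s in sample_ids])
    table = CountTable(names, sample_ids, counts, rank="genus")
    bundle = validate_design(table, sheet, depth=config.depth)

    truth = SimTruth(
        incorporator={g: g in lam_of for g in names},
        lam={g: lam_of.get(g, {}) for g in names},
        expected_heavy_share={
            g: {
                (iso, day): _heavy_prob(
                    q0[g],
                    (
                        math.exp(-inoc_of[g].growth_light * day)
                        if g in inoc_of and iso == "13C"
                        else lam_of.get(g, {}).get(day, 0.0) if iso == "13C" else 0.0
                    ),
                )
                for iso in ("13C", "12C")
                for day in config.days
            }
            for g in names
        },
        q0=dict(q0),
        inoculum_genera=list(inoc_of),
    )
    return bundle, truth


def _sequence_pool(templates: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Draw exactly ``depth`` reads without replacement from a pool's
    template molecules (multinomial fallback if the pool is smaller)."""
    total = int(templates.sum())
    if total >= depth:
        return rng.multivariate_hypergeometric(templates, depth)
    props = templates / total if total > 0 else np.full(len(templates), 1.0 / len(templates))
    return rng.multinomial(depth, props)


def evaluate_recovery(
    ef_results: Sequence[EFSeries], truth: SimTruth
) -> RecoveryMetrics:
    """Score incorporator detection against simulator ground truth.

    The universe is the set of genera carried by ``ef_results`` (i.e. genera
    that passed the abundance/prevalence filter), excluding inoculum genera
    (labelled by construction, not detections).  A genus counts as detected
    when it is classified enriched in at least one soil.
    """
    genera = {s.genus for s in ef_results} - set(truth.inoculum_genera)
    if not genera & set(truth.incorporator):
        raise ValidationError("ef_results and truth share no genera")
    detected = {s.genus for s in ef_results if s.enriched} & genera
    positives = truth.positives() & genera
    negatives = genera - truth.positives()
    tp = len(detected & positives)
    fp = len(detected & negatives)
    tn = len(negatives - detected)
    sensitivity = tp / len(positives) if positives else math.nan
    specificity = tn / len(negatives) if negatives else math.nan
    fdr = fp / (tp + fp) if (tp + fp) else 0.0
    return RecoveryMetrics(sensitivity, specificity, fdr)
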