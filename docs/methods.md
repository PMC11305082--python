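# Methods

## The experiment the package models

A bacterial consortium grown on ¹³C substrate is inoculated into soil
microcosms. At each sampling day, community DNA is separated on a CsCl
density gradient into ~12 fractions; fractions are pooled into a *heavy*
window (1.720–1.735 g ml⁻¹), where ¹³C-labelled DNA bands, and a *light*
window (1.700–1.715 g ml⁻¹), where unlabelled DNA bands, and each pool is
amplicon-sequenced as one library. Parallel microcosms receive the same
consortium grown on ¹²C substrate; they control for everything that puts
unlabelled DNA into the heavy window (GC content, diffusion, gradient
imperfections). The design is factorial: soil × isotope × replicate ×
day × pool.

Window boundaries are treated as closed intervals on both ends; the ranges
are quoted without stated openness and the inclusive reading is the least
surprising. Samples recovering less than 35% (strict) of loaded DNA after
fractionation are excluded before analysis. Conversion of refractive index
to density is out of scope; densities are taken as given.

## Preprocessing

Counts are rarefied to an even depth by sampling without replacement
(multivariate hypergeometric per sample), with a user seed (default 1).
Samples below the target depth are dropped with a warning rather than an
error — losing single gradient fractions is routine and the analysis
proceeds on what remains. ASVs are aggregated to genus by a user-supplied
taxonomy map (unmapped ASVs become `unclassified:<id>`; per-sample totals
are conserved). Relative abundances are computed per library (column).

Genera enter the EF analysis only if, across **all** experimental samples
(both soils, isotopes and pools), mean relative abundance exceeds 0.005
(strict) and the genus is present either in more than 6% of samples or in
at least 3 samples. The two prevalence phrasings are equivalent on a full
96-sample design and are combined with OR so either reading passes the same
data; the at-least-one-time-point abundance rule seen in figure legends is
exposed separately as a display-only filter (`display_filter`) and plays no
role in the statistics.

## The enrichment factor and its gates

For genus g, soil s, day d and replicate pairing (i, j):

EF_ij(g, s, d) = p13_i − p12_j, where p = ra_heavy / (ra_heavy + ra_light)

is the genus's *heavy share* computed from within-pool relative abundances
of one replicate's two libraries. p is undefined when the genus is absent
from both pools or a pooled library is missing; undefined replicates are
skipped, so a lost fraction reduces the number of pairings from 9 to 6
rather than invalidating the day. EF is bounded in [−1, 1] and is exactly 0
whenever the two shares coincide.

The enrichment call uses two strict gates: mean EF > 0.015 on at least one
day, and significant change of the EF through time at α = 0.05. No
multiple-testing correction across genera is applied by default (a
Benjamini–Hochberg option exists but is off), matching common practice for
this statistic.

### Why the through-time test runs on heavy shares, not pairwise EF values

The 9 pairwise EF values of a day are built from only 3 + 3 independent
heavy shares. Feeding them into a one-way ANOVA as if they were 9
independent observations inflates the evidence massively: in simulation,
that test rejects a true null ~56% of the time at α = 0.05 (and ~18% even
when EF is reduced to 3 per-replicate values by subtracting the control
mean, because the shared control mean correlates the day's observations).
Since EF(d) is by construction the difference of the mean ¹³C and mean ¹²C
heavy shares at day d, "EF changes through time" is exactly the
day × isotope interaction in a two-way fixed-effects ANOVA on the shares —
one observation per microcosm, the true experimental unit. That test holds
its nominal size (measured ~5% under the null) and is the default
(`anova_time(series)`); the one-way ANOVA over the combinatorial values is
retained as `anova_time(series, method="pairs")` for comparison, and the
plain one-way ANOVA itself is exposed as `anova_oneway`. Degenerate inputs
are defined explicitly: identical values everywhere → F = 0, p = 1; zero
residual variance with a real effect → p = 0; fewer than two usable days or
no residual degrees of freedom → p undefined and the gate fails
conservatively.

## Inoculum tracking and trophic classification

ASVs are assigned to the inoculum strains by global pairwise alignment
(match +1, mismatch −1, gap open −2, extend −0.5); identity is the number
of identical columns divided by the total number of alignment columns, so
gap columns count against identity. Amplicons of the same locus should
align end to end; a free-end-gap variant is available for data with
overhangs. An ASV is matched when its best-reference identity strictly
exceeds 0.995 — for a 250-nt amplicon, one substitution passes (0.996), two
fail (0.992).

The matched-ASV abundance course is tested with a Friedman test (blocks =
replicates, treatments = days) and Conover all-pairs post hocs on the
within-block rank sums (t distribution with (n−1)(k−1) df; Holm adjustment
available but off by default). The test requires complete blocks; a missing
observation returns an undefined result with a warning instead of silently
dropping a block. For untied data the statistic equals the classical
closed form 12/(nk(k+1))·ΣR_j² − 3n(k+1).

Each enriched genus is correlated (Kendall τ-b, tie-corrected) with each
inoculum genus over paired (day, replicate) observations of heavy-pool
¹³C-treatment relative abundances — the fraction in which both the
consumer's label and the inoculum reside; the pool and isotope are
configurable. The p-value is exact (permutation distribution) for n ≤ 10
without ties and a normal approximation otherwise; the n = 10 switch point
is this package's choice. τ < 0 with p < 0.01 (both strict) is labelled
*predation*, everything else *cross-feeding* — an operational label, not a
mechanistic claim. Note that with only 4 paired observations even perfect
discordance gives an exact two-sided p of 2/24 ≈ 0.083, so predation can
never be called from a single replicate's 4-day course.

## The simulator

`simulate_experiment` generates the full factorial design with known
ground truth. Per microcosm: community proportions are drawn from a
Dirichlet centred on the soil's baseline composition; a template pool of
20 × depth molecules is drawn multinomially; each genus's templates are
split between heavy and light by a Bernoulli density model; each pool is
then sequenced by drawing exactly `depth` reads without replacement,
mirroring rarefied libraries. All randomness flows from one seeded
generator in fixed order, so identical configs give byte-identical output.

The heavy-split probability is q0 + (1 − q0)·λ(t): q0 is a genus-specific
baseline leakage into the heavy window drawn once from U(0.05, 0.20)
(emulating GC-driven buoyant-density variation — this gives the ¹²C
subtraction real work), and λ(t) ∈ [0, 1] is the labelled biomass fraction
(0 for control treatments and unlabelled genera). Inoculum genera start
fully labelled at a configured day-0 abundance; abundance decays as
decay^t and growth on soil carbon dilutes the label as exp(−growth·t),
which reproduces the qualitative rise-then-fall of inoculum reads in the
light pool.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| n_genera | 60 | enough for a realistic filter pass (~25–35 genera) at desk scale |
| n_replicates | 3 | triplicate microcosms, the design's standard |
| days | 0, 7, 15, 30 | the incubation sampling schedule |
| depth | 20,000 reads | the order of rarefied 16S library sizes |
| baseline | log-normal μ=0, σ=2.0 | heavy-tailed soil community rank-abundance |
| soil_sigma | 0.7 | per-soil modulation of a shared genus effect; soils share regional taxa, fully independent communities would make the global abundance filter admit genera that are pure noise in one soil |
| dirichlet_conc | 300 | moderate replicate-to-replicate community similarity |
| q0_range | U(0.05, 0.20) | baseline heavy-window leakage |
| incorporator_share | 0.08 total | consumers of labelled biomass are minor community members (each ~0.8%, above the 0.5% filter) |

The simulator emulates pooled heavy/light counts only. It does not model
gradient physics, primer bias, 18S-vs-16S differences, chimeras, or an
explicit carbon-budget food web (cross-feeding appears only as late-onset
λ(t)). Passing recovery tests therefore demonstrate the statistic's
behaviour under multinomial sequencing noise and compositional closure,
not robustness to real-data artefacts upstream of the count table.

## False discoveries under strong labelling

Two structural properties of the EF statistic, quantified by the seeded
ensembles (20 seeds of the default design):

1. **Null behaviour is controlled.** With no labelled genera, ~5–6% of
   filtered genera are classified enriched in at least one soil — the
   product of the calibrated α = 0.05 time gate and the EF > 0.015
   threshold.

2. **Strong labelling of some taxa poisons the rest.** Sequencing a pool is
   a closed composition: when ~8% of the community moves into the heavy
   window (10 incorporators at λ = 0.6), every unlabelled genus's ¹³C heavy
   share is genuinely depressed at labelled days. Their EF therefore
   *really does* change through time, and the ANOVA gate passes them
   legitimately; false-positive control then rests entirely on the per-day
   EF > 0.015 gate. But at 20,000 reads a genus near the 0.5% abundance
   filter has ~100–200 reads per pool, putting the standard error of its
   day-mean EF at ~0.02–0.03 — above the 0.015 threshold. Measured over
   seeds 1–20: sensitivity 1.0, but FDR ≈ 0.33. No free parameter removes
   this: detectable incorporators must clear the abundance filter, which
   fixes their compositional footprint, and the threshold, depth and
   replicate count are the method's defining constants. The practical
   implication for real studies is that reported incorporators whose
   abundance sits near the filter boundary carry a substantial noise risk,
   and that the EF threshold is only meaningful for taxa sequenced deeply
   enough that 0.015 exceeds their EF standard error.

## Problem sizes

The test suite and the acceptance script use the full default design
(60 genera × 96 samples × 20,000 reads) for the two 20-seed ensembles,
a 1001 × 1001 grid for the EF bounds, 1,000 random replicate
configurations for the pairing oracle, and reduced designs (20–25 genera,
3,000–4,000 reads) for end-to-end pipeline and CLI checks; the whole suite
runs in well under a minute plus ~20 s per ensemble.

## Known limitations

- BIOM support covers the v1.0 JSON dialect only (read-only); TSV is the
  canonical format.
- Pooling treats each pooled extract as one sequencing library; fractions
  are not weighted by DNA mass within a pool.
- The EF is a relative-abundance-shift statistic, not a quantitative
  estimate of atom-fraction excess (no qSIP model).
- Kendall-based predation calls are correlational; with typical n
  (replicates × days ≤ 12) the exact test has limited resolution.
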