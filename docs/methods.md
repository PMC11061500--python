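# Methods

This note records the modelling choices behind `hybridabc`: the generative
model, its priors and defaults, the summary statistics, the random-forest
machinery, what the synthetic data do and do not emulate, and the numerical
decisions a maintainer would want spelled out.

## Demographic model

Five demes are sampled at the present: the two geographic groups of the
maternal-range parent (`PAM_N`, `PAM_S`), the two hybrid groups (`HYB_N`,
`HYB_S`), and the second parent (`HIM`).  Backward in time a scenario is a
sorted list of instantaneous events over these demes plus three ancestors
(`PAM_anc`, `HYB_anc`, `ANC`):

- a **merge** moves all lineages of two demes into their ancestral deme,
  which has its own effective size;
- an **admixture** routes each lineage of a hybrid deme independently to
  the `PAM`-side parent with probability r1, else to `HIM`.

Scenarios 1–3 (multiple-event origins) give each hybrid group its own
admixture pulse from its regional parent at the hybridization time, after
which the parental groups merge; hybrids therefore inherit the parental
north/south structure.  Scenarios 4–6 (single-event origins) first merge
the hybrid groups into one ancestor (simultaneously with the parental
merge, since a single time parameter governs "diversification"), then apply
one admixture pulse.  Within each triplet, hybridization and
diversification move between the post-glacial time box (t1/t2) and the
glacial one (t3/t4).  Every scenario ends with the deep parental merge into
`ANC` at t5.  Ties at identical event times are resolved in list order,
admixtures before merges; this matters only for the single-event scenarios,
where the hybrid merge must precede (backward in time) the pulse.

All scenarios reduce the sampled demes to a single ancestor; the
`DemographicScenario` constructor verifies this symbolically, so malformed
custom scenarios fail fast.

## Priors and defaults

| parameter | prior | notes |
|---|---|---|
| t1, t2 | U(10, 25000) generations | post-glacial box; t1 < t2 when used jointly (rejection) |
| t3, t4 | U(25000, 50000) | glacial box; t3 < t4 when used jointly |
| t5 | U(100000, 200000) | upper bound configurable to 750000 / 1250000 |
| r1 | U(0.01, 0.99) | admixture fraction from the PAM side |
| N (each lineage) | U(10, 100000) diploids | drawn independently per lineage |
| generation time | 2 years | multiplies generations into calendar years |

The effective-size prior deserves emphasis: it is **not** fixed by the
study design and scenario-choice calibration is sensitive to it.  The
default U(10, 100000), uniform and independent per lineage, is this
package's choice and fully configurable through `PriorSpec`.

## SNP locus model

Loci are unlinked: one independent tree per SNP, no recombination, no
selection, no missing data.  Coalescence in a deme of diploid size N runs
at rate k(k−1)/2 · 1/(2N) per generation (continuous-time approximation of
Wright–Fisher).  Diploid dosages pair the two gene copies of each
individual.  Acceptance of a locus is conditioned on pooled minor-allele
frequency ≥ 0.05 by rejection of the whole locus (resimulating the tree),
the simplest unbiased scheme, with a 10,000-attempt cap per locus; a cap
hit raises an error naming the scenario and sizes, signalling a parameter
draw under which such loci are vanishingly rare, and the reference-table
builder logs it and resamples the draw.

Two single-mutation placements are implemented:

- `per_tree` (default): every tree receives exactly one mutation on a
  branch drawn proportionally to branch length.  This is the
  fixed-segregating-sites device used by coalescent SNP simulators.  Its
  derived-allele spectrum is E[Lᵢ/L], which over-represents singletons by
  several percent relative to the classical neutral law (short trees carry
  their mutation as surely as long ones).
- `length_biased`: trees are first accepted with probability L/L_cap
  (L_cap = pilot-run mean + 40 pair-coalescence scales of the largest deme,
  so the truncated tail has probability < 1e−15), then mutated as above.
  This is the low-mutation-rate limit of infinite-sites mutation
  conditioned on one segregating site, whose spectrum is E[Lᵢ]/E[L] = the
  1/i law exactly.  It costs roughly the inverse acceptance rate (about an
  order of magnitude) and is used where agreement with the classical
  neutral spectrum is the point, e.g. the site-frequency-spectrum check.

Reference tables use `per_tree` for speed; the distinction is irrelevant to
MAF-conditioned, model-comparison use because every scenario is simulated
under the same scheme.

`HIM` is sampled as a single diploid (two gene copies), matching the one
successfully genotyped herbarium specimen; statistics involving it use
n = 2 sample-size corrections and are inherently high-variance.

## Summary statistics

The original analysis tool does not publish the summary set it uses for SNP
data, so this package defines its own compact, admixture-informative
registry (version `v1`), identical for observed and simulated data and
recorded in reference-table provenance:

- per group: proportion of polymorphic loci; mean and variance across loci
  of unbiased expected heterozygosity ĥ = 2p(1−p)·n/(n−1);
- per group pair: Hudson FST as a ratio of averages across loci,
  1 − mean(Hw)/mean(Hb) with Hw the mean corrected within-group
  heterozygosity and Hb = p_A(1−p_B) + p_B(1−p_A); and Nei's standard
  distance −ln I, capped at 10 when the genetic identity underflows;
- admixture block: f3(HYB_g; PAM_g, HIM) for each geographic group, with
  the small-sample correction h_T/n_T subtracted for the target (the
  uncorrected product is available via `corrected=False`; note that the
  corrected estimator is strictly negative when target and source are
  literally the same sample — the correction is designed for independent
  samples); and f4(PAM_N, PAM_S; HYB_pooled, HIM).

Loci with no data in a group are dropped pairwise, per statistic.  For the
five-deme design this yields 38 statistics; `compute_summaries` is pure and
order-invariant in loci.

## Random-forest ABC

- **Model choice**: `RandomForestClassifier` (500 trees by default) on the
  summary columns, optionally augmented with K−1 linear-discriminant axes
  fitted on the reference table (toggleable; on by default).  Vote
  fractions are per-tree plurality votes on the observed vector.
- **Posterior probability**: regression forest trained on the out-of-bag
  misclassification indicator; posterior = 1 − predicted error at the
  observed point (the OOB-error-regression scheme of the ABC-RF
  literature).  The prior error rate is the overall OOB misclassification.
- **Parameter estimation**: quantile regression forests.  For each
  parameter, an RF regression on the summaries; the posterior is the
  training responses weighted by the frequency of sharing a leaf with the
  observed point (equal weight per tree, uniform within a leaf; bootstrap
  multiplicities are not tracked — a recognized simplification of the
  original in-bag-weighted estimator); weighted 5%/50%/95% quantiles are
  reported.  `min_samples_leaf` defaults to 5.
- **Replication**: R independent reference tables (default profile 10),
  each with its own forest; means and standard deviations (ddof = 1) of
  vote fractions and posterior probabilities; combined vote mass for
  arbitrary scenario subsets (the {1, 3} multi-event pair being the one of
  scientific interest).

Recommended table sizes are 2,000–20,000 simulations per scenario (the
builder warns outside this range); 10,000 is the full-analysis profile.
Interactive and test profiles use 300–2,000 simulations per scenario and
50–338 loci — calibration experiments here use the cluster design scaled to
50 loci with 500 simulations per scenario and 300 trees, which one CPU
completes in about two minutes.

Seed policy: every public entry point takes one master seed; reference-table
row i of scenario s uses `default_rng([seed, s, i])`, replicate r derives
`SeedSequence([seed, r])`, so any row or replicate is independently
reproducible and whole analyses are bit-identical under a fixed seed.

## Study designs and synthetic data

Two designs mirror the study: `cluster` (118 individuals at 338 loci;
per-deme split 41/40 PAM, 18/18 HYB, 1 HIM — the published totals are
81/36/1 and the per-deme split is this package's default) and `population`
(27 individuals at 181 loci; split 7/6/7/6/1, invented, configurable).  MAF
threshold 0.05 in both.

The synthetic-data module generates pseudo-observed datasets with truth
records for calibration, genotype fixtures with planted failure counts for
every filter step (so the expected retention after each step is known by
construction), and aligned chloroplast panels (default length 926, the
intergenic-spacer read length) with four planted diagnostic substitutions
plus 4 bp and 6 bp indel events — the 6 bp insertion carried by the PAM
class — and hybrid cohorts of 20 HIM-maternal and 2 PAM-maternal
individuals by default.

What the generator does **not** emulate: read-level genotyping error and
missingness patterns of real reduced-representation data, allele-frequency
spectra of the deposited matrices, linkage, or polyploid dosage ambiguity
(inputs are assumed pre-subsampled to biallelic diploid dosages).  Passing
tests therefore demonstrate internal correctness and method calibration
under the stated model, not robustness to those real-data features.

## Filtering cascade

Order: locus reproducibility → locus call rate → individual call rate →
monomorphic removal → one-random-SNP-per-clone thinning → within-group
polymorphism → pooled MAF.  Call rates are recomputed on the surviving
matrix at each step, so order matters.  All thresholds are inclusive (≥);
in particular MAF ≥ 0.05 keeps a locus at exactly 0.05.  The within-group
polymorphism filter defaults to the strict reading (a locus must segregate
in **every** named group); a weak mode drops only loci monomorphic in all
named groups simultaneously, since the verbal description of this step
admits both readings.  Thinning is the only randomized step and is isolated
on its own seed.  Dosages count the alternate allele as supplied; alleles
are never re-polarized.

## Chloroplast direction calling

Diagnostic substitutions require fixity within each parental class and no
gaps/N at the column; within-class polymorphism skips the column (counted
for audit).  Indel events are maximal runs of columns gapped in exactly one
class and count as **one** vote regardless of length.  Classification is a
majority vote over scorable events with a per-event agreement vector;
gap/N in the query at a substitution site, or a mixed indel span, make that
event unscorable (counted against neither class).  Ties or fewer than
`min_sites` (default 2) scorable events yield `ambiguous`.  Two concatenated
markers are scored as one partition via an offset-preserving concatenation.

## Numerical choices and degenerate inputs

- Missing dosage sentinel is a single int8 value; partially called
  heterozygotes are not modelled.
- Hudson FST is returned raw (slightly negative under panmixia is
  expected); single-locus FST values are only defined where Hb > 0.
- Nei identity underflow is capped at distance 10.
- Empty filter results are permitted with a warning (0-locus datasets stay
  well-formed).
- `r1 = 1` (or 0) is outside the prior but constructible with
  `build_scenario(..., validate=False)` for reduction studies; the
  admixture then degenerates into a merge.
- NaN statistics (possible in pathological small-group tables) are imputed
  by reference-table column means before forest fitting, identically for
  table rows and the observed vector.
- numba kernels use their own legacy numpy random state, seeded explicitly
  per call, so library users' global numpy state is never touched.

## Known limitations

- The summary-statistic registry is a deliberate substitution for the
  original tool's unpublished internal summaries; printed vote percentages
  of the original study are therefore reproducible only approximately even
  with the deposited data.
- Effective-size priors and per-deme sample splits are package defaults
  where the study does not print them.
- No continuous migration, growth, bottlenecks, linked loci, or selection;
  scenarios contain only instantaneous splits and pulses.
- The quantile-forest weights ignore bootstrap multiplicities, and
  posterior probabilities inherit the regression forest's smoothing; both
  are standard, documented approximations.
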