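# Methods

This note documents the statistical model, the defaults and the design
choices behind `diadetect`, and what the synthetic-data validation does
and does not demonstrate about real data.

## Detection model

The analysis treats per-sample protein detection as the primary
observable. A protein is "detected" in a run when it retains at least
one quantified precursor after filtering (all of precursor q-value,
protein-group q-value and global q-value ≤ 0.01, inclusive, and no
protein-group accession in the contaminant list). Group-level counts
K₁ ~ Bin(n₁, p₁), K₂ ~ Bin(n₂, p₂) are modelled as independent
binomials — an idealisation that ignores run-to-run correlation
(shared LC-MS drift, batch effects), which the reference workflow
mitigates by single-batch acquisition and randomized run order.

### Classification rules

Evidence tiers resolve fractional thresholds against actual group
sizes with a ceiling, reproducing the reference integer cut-offs at
n = 4/5:

| tier | group-1 preferred | group-2 preferred |
|---|---|---|
| Strong | K₁ ≥ ⌈0.75·n₁⌉ and K₂ ≤ 1 | K₂ ≥ ⌈0.80·n₂⌉ and K₁ ≤ 1 |
| Moderate | K₁ ≥ ⌈0.50·n₁⌉ and K₂ ≤ 1 | K₂ ≥ ⌈0.60·n₂⌉ and K₁ ≤ 1 |
| Weak | detected ≥ 2 in some group, below Moderate, or ≥ 2 in both groups |

A Weak call requires a preferred group, taken as the group with the
strictly higher detection *fraction*; equal fractions yield
(None, None), which keeps "evidence implies preference" an invariant.
The headline preference sets (Venn counts) use the looser
≥2-in-one / ≤1-in-other rule; their universe is every protein detected
in ≥ 2 replicates of at least one group, so the three sets partition
it by construction. Proteins seen 1/n₁ and ≤1/n₂ are outside the
universe — they support neither presence nor absence. The top-k
"group-specific" list further requires zero detections in the opposite
group and ranks by preferred-group count, ties broken
lexicographically (the ranking is a package convention; no ordering is
canonical for tied counts).

## maxLFQ quantification

For each protein, pairwise sample ratios are medians of per-precursor
log₂ ratios over shared precursors (minimum 1 shared precursor by
default, configurable to 2; even-length medians average the two
central values). The per-sample log₂ profile minimises
Σ(x_i − x_j − r_ij)² within each connected component of the
sample-sharing graph, solved by LAPACK least squares with an explicit
centering row (the difference equations are translation-invariant, so
the gauge must be pinned). Each component is anchored so its mean log₂
abundance equals the mean of its observed log₂ precursor intensities;
components are never linked by imputation — fabricating cross-component
ratios would manufacture fold-changes. Consequences that the tests
assert: a single-precursor protein reproduces that precursor exactly;
scaling one sample scales its protein column identically; results are
invariant to precursor/sample order. Zero, negative or missing
quantities are dropped before the log transform. No between-run
normalisation is applied (deliberately mirroring a default DIA-NN
workflow); the matrix is relative within components, not absolute.

## Exact power and sample size

Power for a two-binomial detection design is computed by complete
enumeration of all (n₁+1)(n₂+1) outcomes; group sizes are capped at 50
(the intended regime is desk-scale animal studies; approximations are
out of scope). Fisher one-sided p-values are hypergeometric tail sums
evaluated in exact rational arithmetic, and α is interpreted through
its decimal representation, so boundary tables — e.g. the 3-vs-0 table
at n = 3 with p = 1/20 at α = 0.05 — are decided exactly rather than
by floating-point luck. Binomial weights for the region sum are
evaluated in log space. The attained size reported with each result is
the supremum of the rejection probability over the null line
p₁ = p₂ ∈ {0.05, …, 0.95}; the conditional test keeps it ≤ α at every
design enumerated in the tests.

Under the one-sided Fisher rule at α = 0.05, the reference 4-vs-5
design gives power 1.0 for an all-vs-none effect (1.0 vs 0.0) and
0.37152 for 75 % vs 20 % detection; the smallest equal allocation
reaching 0.8 power for the latter is n = 12/group. Published summaries
of the same design quote ≈38 % and n = 12–15 without naming the test;
one-sided Fisher enumeration lands within rounding distance of both,
but an unconditional or mid-p variant could equally have produced
them, so the package exposes `fisher_mid_p` and `rule_based`
alternatives rather than forcing agreement. Sample-size search scans n
upward from 2 — exact-test power is not monotone in n, so scanning,
not bisection, guarantees the minimum.

## Cohort statistics

- **Identification counts**: Shapiro–Wilk per group is reported as an
  advisory normality check; the comparison itself is always the
  two-sided pooled-variance Student's t-test (matching the reference
  workflow, which reports both). Zero variance in both groups with
  equal means returns t = 0, p = 1 by convention.
- **PCA**: complete-case proteins on log₂ scale by default — no values
  are fabricated; half-minimum imputation is available behind a flag.
  Mean-centred samples × proteins SVD via scikit-learn; scores are
  sign-indeterminate, which downstream code must tolerate.
- **BAL table**: combined per-cycle means are unweighted means of the
  two sex means; overall values are means of the six per-cycle values.
  All derived cells use exact decimal arithmetic rounded to one
  decimal half away from zero — banker's rounding or binary-float
  naive rounding both mis-round cases like 118.65.
- **Correlations**: Spearman by default (rank-based is the defensible
  choice at n = 4–5), Pearson optional. For n ≤ 8 the p-value is an
  exact permutation p over all n! orderings, one-sided in the
  direction of the observed coefficient (a perfectly monotone n = 4
  pair gives p = 1/24); beyond that, the asymptotic p is used.
  Zero-variance inputs return an explicit undefined result.

## Synthetic data generator

The generator emulates the structure the analysis assumes, not raw
spectra. Defaults mirror the reference study shape: 9 runs (4
dependent, 5 non-dependent; 5 female, 4 male) and four protein classes
— 60 dependence markers (p_detect 0.90/0.05), 30 control markers
(0.05/0.90), 300 shared background proteins (0.95/0.95) and 7
contaminants carrying accessions from the bundled *synthetic* cRAP
FASTA — giving ≈300–340 proteins and ≈1500 precursors per run,
with precursor multiplicity 1 + Poisson(4) (≈5 precursors/protein).

Missingness has two layers. The Bernoulli detection layer per
protein × sample is the *contractual* detection probability that the
power module reasons about. On top of it, precursor log₂ intensities
(protein mean, per-run SD 1.2–1.5 around class means 16.5–20.5, plus
per-precursor offset SD 1.0 and noise SD 0.4) are left-censored at
LOD 12, adding MNAR texture without materially distorting the
contractual rates (censoring at these defaults removes ≪1 % of rows).
A 5 % q-value mixture puts rows above the 0.01 threshold so the
filters are exercised; raising it can only remove emitted rows, a
monotonicity the tests check. Behaviour tables give dependent animals
escalation ratios ~N(1.8, 0.3) and per-cycle BALs inside the
150–250 mg/dL vapour-target window; non-dependent animals escalate at
~N(1.0, 0.1) with zero BAL. A named protein's log₂ abundance can be
planted into a drinking metric at an exact sample correlation for
testing the correlation machinery. All draws flow from one
`numpy.random.default_rng(seed)`; identical seeds give byte-identical
files.

What passing on synthetic data shows: the pipeline's bookkeeping,
rule logic and power arithmetic are internally consistent, and
end-to-end class recovery matches the analytic rule-based power within
Monte-Carlo error. What it does not show: robustness to correlated
runs, retention-time drift, interference, shared-peptide protein
inference, or real contaminant profiles — none of which the generator
simulates.

## In-silico digestion

Trypsin/P (cleave after every K/R, no proline exception) is the
default because it matches the reference search settings; classic
trypsin is a flag. N-terminal methionine excision, enabled in typical
searches, is mirrored by indexing peptides from both the intact and
Met-excised sequence forms (default on). Index length bounds default
to 6–30 residues, the typical detectable tryptic range. Cross-species
uniqueness of a peptide is exact string lookup in two indexes built
with identical settings; the test suite uses small synthetic host and
foreign proteome fixtures, and runs against full reference proteomes
require downloading those FASTAs and are therefore not part of the
default suite.

## Problem sizes used in validation

The shipped tests run the generator at its default ≈400-protein scale
(once, session-scoped) plus reduced 30–1000-protein configurations for
targeted properties; maxLFQ is checked against a dense least-squares
oracle on ~150 random instances up to 5 samples × 6 precursors; the
Monte-Carlo power check uses 10,000 replicates; permutation-p
enumeration is exercised at n = 5. These sizes give 3-SE margins well
below the effects being verified while keeping the whole suite under
half a minute on a laptop-class core.

## Known limitations

- Independence across runs and proteins is assumed throughout the
  power machinery; no multiplicity correction is offered because the
  reference analysis treats the rule as a screen, not a test family.
- Protein groups are compared as opaque strings; no parsimony
  re-grouping across runs.
- The maxLFQ matrix is relative; absolute (iBAQ-style) quantities are
  out of scope.
- Quantitative differential abundance testing is deliberately absent:
  the method's premise is that binary detection, not abundance, is the
  reliable signal at this scale.
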