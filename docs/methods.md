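# Methods

## Scope

`lifegap` quantifies how much each age group and cause-of-death category
contributes to the difference in life expectancy (LE) and lifespan
inequality (LI) between a fixed reference population and a comparator,
with causes classified by avoidability and an optional recalibration of
mortality levels to an external life table. All analyses are strictly
sex-stratified and run on the abridged age ladder 0, 1–4, 5–9, …, 85+
(19 groups, the WHO mortality-database resolution).

## Data model and conventions

**Counts and exposure.** Input deaths are non-negative integers per
(country, year, sex, age group, ICD-10 code); populations are mid-year
person counts. Pooling a multi-year period sums deaths and sums annual
mid-year populations, so each calendar year contributes one person-year
per person — the standard period approximation. Central death rates are
pooled deaths over pooled person-years.

**WHO wide dialect.** Files with numbered age-bucket columns are read
against a user-supplied age-format map. Buckets finer than the ladder
(e.g. single years 1–4) are summed upward; buckets coarser than the
ladder are rejected rather than disaggregated, since any split would
impose an age model the data do not contain. Unknown-age buckets are
dropped with a logged count; redistribution of unknown-age or
ill-defined deaths is out of scope.

**Avoidability classification.** An ordered table of inclusive ICD-10
range rules maps each 3-character code stem (4-character codes are
truncated) to one of five mutually exclusive categories: only treatable,
only preventable, both treatable and preventable, ischaemic heart
disease, or non-avoidable; a terminal catch-all guarantees
exhaustiveness, and earlier rules win overlaps. The age cap (default 75)
is applied by age-group *lower bound*: deaths in [75, 80) and older are
always non-avoidable, deaths in [70, 75) can be avoidable — the natural
rendering of "avoidable up to age 74" on a 5-year ladder. The shipped
default rule file covers the major avoidable-cause families (injuries,
drug- and alcohol-related deaths, maternal and perinatal causes,
diabetes, hypertensive disease, lung cancer, IHD, infectious and
respiratory disease); it is a synthetic working default, clearly labelled
as such, and any production analysis should substitute the full
OECD/Eurostat list via `load_scheme`.

## Life table

For closed intervals the m→q conversion is Greville's
`q = n·m / (1 + (n − a)·m)`; q is clamped to [0, 1] with a logged warning
if an extreme rate overshoots. The `a` (nax) conventions, selectable via
`ax_rule`:

- `standard` (default): infant a₀ from the two-branch Coale–Demeny
  approximation keyed on m₀ (sex-specific coefficients; the sexes are
  averaged when no sex is given), a = 1.5 years on [1, 5), a = n/2 for
  other closed intervals;
- `midpoint`: a = n/2 everywhere (used by the closed-form test oracles).

The open interval has q = 1, a = 1/m∞ and L = l/m∞ (constant hazard
beyond 85). LE at birth is T₀/l₀. Results are invariant to the radix.
LE and LI are mildly sensitive to the a₀ convention (of order 0.1 years
for high-mortality schedules), which is why the rule is exposed rather
than hard-coded.

**Lifespan inequality** is the standard deviation of the life-table
age-at-death distribution, taken unconditionally from birth: closed
intervals are point masses d at exact age x + a; the open interval
contributes its mass at mean age 85 + 1/m∞ and adds the exponential
within-interval variance (1/m∞)². Ignoring within-interval spread in the
closed 5-year groups follows the dominant convention in the
lifespan-variation literature; it understates the total variance by a
bounded amount (at most n²/4 per interval) that cancels almost entirely
in cross-country differences. The mean is computed from the masses
themselves, which coincides with e₀ on a birth-anchored ladder but keeps
the SD translation-invariant on shifted ladders.

The SD has the threshold-age property: raising mortality below a
threshold age raises the SD, above it lowers the SD. The test suite
verifies the sensitivity changes sign exactly once along age on a
Gompertz schedule.

## Decomposition

The gap Δ = f(θ_ref) − f(θ_cmp), where θ is the flattened age × cause
rate matrix and f is LE or LI of the row-sum (all-cause) schedule, is
decomposed by the continuous-change (stepwise-replacement) method: the
straight line from θ_cmp to θ_ref is split into `n_steps` equal
sub-steps; within each, every covariate's contribution is the central
difference of f from moving that covariate alone across the sub-step
while all covariates sit at the sub-step midpoint. Contributions are
summed over sub-steps and reshaped to age × cause.

Key properties, all test-enforced:

- contributions + residual ≡ Δ (identity, with residual ≡ Δ − Σc);
- covariates equal in both populations contribute *exactly* zero;
- swapping the populations negates every contribution;
- the residual decays as O(1/n_steps²) for smooth f.

The path is linear on the rate scale (robust to zero rates). The default
`n_steps = 20` follows common practice for this method; at that setting
the relative residual is below 1e-6 for realistic country pairs. The
absolute residual scales with the cube of the pair's separation: a pair
differing only in one cause block (factor 2 on preventable at ages
15–49) shows residuals of order 1e-8 (LE) to 1e-7 (LI) years, while a
pair differing ~10% in every cell with a 1.6-year gap shows ~5e-6 years.
The residual is always reported and never redistributed across cells.

Sign convention: contributions sum to f(reference) − f(comparator), so
cells where the reference has *lower* mortality contribute positively to
its LE advantage.

## External-table recalibration

Where vital-registration coverage is doubtful, cause-specific rates can
be recalibrated to an external all-cause schedule m\*: implied population
P(a) = D(a)/m\*(a), then r(a, c) = D(a, c)/P(a) = m\*(a)·D(a, c)/D(a).
Row sums equal m\* exactly wherever deaths were recorded and the
within-age cause mix is preserved; recalibrating a table to its own
all-cause rates is the identity. Age groups with zero recorded deaths
get zero rates with a logged note (their cause mix is undefined;
borrowing a neighbour's mix was rejected as invention). External tables
must cover the full ladder — coarser tables are rejected, not
interpolated.

## Synthetic data

The generator exists to give every pipeline stage inputs with *known*
structure, not to mimic any particular country. The all-cause hazard is
Gompertz–Makeham, `h(x) = c + A·e^{Bx}`, plus an infant excess on [0, 1),
evaluated at interval midpoints (85+ at age 90); defaults
(c = 5e-4, A = 3e-5, B = 0.095, infant excess 0.012) give e₀ ≈ 76 years
and SD ≈ 18 years — the order of magnitude of a middle-income country.
Cause shares may be constant or age-dependent and must sum to one at
every age. Scenarios inject multiplicative rate differences into named
(country, cause, age-range) blocks before Poisson counts are drawn
against the supplied person-years.

Each (country, year, age, cause) cell draws from its own RNG substream
derived from the master seed (via a seed sequence keyed on the cell
labels), so adding a cause or year never perturbs other cells' draws,
and runs are bit-reproducible.

What the generator does *not* emulate: registration incompleteness,
garbage coding, age heaping, cohort effects, or migration. Passing tests
therefore demonstrate the correctness of the arithmetic pipeline on
well-behaved inputs, not robustness to real-world data pathologies.

## Pipeline and outputs

A run reads long-format counts, pools the configured years, collapses
causes through the scheme, computes per-stratum life tables, and writes a
summary CSV (levels plus signed reference-minus-comparator gaps) and one
contribution CSV per (measure, comparator, sex), each with a metadata
header (measure, total gap, residual, step count, countries). A
companion "display" file rounds to 0.1 years for presentation.
Presentation aggregation into user-chosen age bins and cause groups is
sum-preserving by construction. With an external table configured, a
parallel sensitivity bundle is produced. All outputs are deterministic:
identical config and seed yield byte-identical files. Errors abort the
run with the failing stage and stratum named, removing partial outputs.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
two countries × two years × 19 age groups × 5 causes, populations of
2×10⁵–5×10⁵ person-years per age group (10⁹ for the noise-free-limit
check), 500 replicates for the Monte-Carlo mean check, and decomposition
step counts between 2 and 2000 (the fine-path oracle). These sizes make
the whole suite run in well under a minute while leaving every assertion
statistically comfortable.

## Known limitations

- The shipped avoidability scheme is a deliberately small default, not
  the official OECD/Eurostat list; conclusions about specific causes
  require the real list.
- Only the SD is offered as the inequality measure (no e-dagger, Gini or
  IQR), and only the Horiuchi path decomposition (no Arriaga/Pollard).
- No uncertainty intervals: inputs are treated as complete enumerations.
- Deaths of unknown age or sex are dropped with a logged count rather
  than redistributed.
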