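# Methods

## The counting model

Everything rests on the deduplicated case. A FAERS-style database holds
multiple versions of one case (shared CASEID); `faersig` keeps the version
with the latest FDA receipt date, breaking ties toward the higher
PRIMARYID, and drops rows of discarded versions from every other table.
Partial FDA dates (YYYY or YYYYMM) are padded with 01 *for ordering only* —
padding never enters onset arithmetic.

A case belongs to the target drug when at least one DRUG row matches a name
synonym (uppercased, trimmed, exact — substring matching invites false
inclusions, and the synonym list is configuration) with an accepted role
code. The default role set is {PS}: analyses of "main suspect" reports;
`--roles PS,SS` widens it. The counting unit is the unique (case, term)
pair: a case contributes a PT once however often it is listed, and at SOC
level contributes a SOC once however many of its PTs map there (a
`--pair-level-soc` flag switches to PT-in-SOC pair counting, since
reasonable studies have used either convention).

## Disproportionality statistics

For term *t*, with a/b/c/d the target-drug-with-*t* / target-drug-other /
other-drug-with-*t* / other-drug-other case counts and N their sum:

* **ROR** = ad/bc, CI = exp(ln ROR ± 1.96·s), s = √(1/a+1/b+1/c+1/d).
  Any zero cell leaves the statistic undefined (NaN). No continuity
  correction by default — the a ≥ 3 screening gate makes a = 0 moot and
  zero b/c/d cells are vanishingly rare at database scale — but
  `--continuity-correction` adds 0.5 to every cell for users who want it.
* **PRR** = a(c+d)/(c(a+b)) with the uncorrected Pearson χ² (identical to
  the (ad−bc)²N/((a+b)(c+d)(a+c)(b+d)) form; the test suite checks the
  equivalence) and its 1-df upper-tail p-value from `scipy.stats.chi2`.
* **BCPNN.** The point information component is the plug-in
  IC = log₂(aN/((a+c)(a+b))). The interval bound IC025 = E(IC) − 2·√V(IC)
  uses the closed-form moment approximation of the original Bayesian
  confidence propagation neural network: Beta(1,1) priors on both margins
  and a joint-cell Beta prior with γ chosen so E(IC) ≈ 0 under
  independence. The moments live in one function (`bcpnn_moments`) so a
  Monte-Carlo posterior can be swapped in; the tests cross-check the
  closed form against an independent sampler of the same posterior
  (agreement to approximation accuracy: ~0.1 bits on E(IC), ~15% on the
  standard deviation for small tables).
* **EBGM (plug-in).** The observed/expected ratio aN/((a+c)(a+b)) — equal
  to 2^IC by construction — with a log-normal lower bound EBGM05. This is
  deliberately *not* a full gamma-Poisson shrinkage (MGPS) mixture fit; the
  name "plug-in" in docstrings marks the distinction. The point value only
  needs a > 0; the bound needs all cells positive.

Screening: ROR flag ⇔ lower CI bound > 1 and a ≥ 3; PRR flag ⇔ PRR ≥ 2, χ²
≥ 4, a ≥ 3; BCPNN flag ⇔ IC025 > 0; MGPS flag ⇔ EBGM05 > 2. Undefined
statistics never flag. The reported table is the four-algorithm
intersection cut at n ≥ 11 (configurable), sorted by SOC, then descending
n, then term — a fully deterministic order. Venn counts tally exact flag
subsets among terms flagged by at least one algorithm.

**Multiplicity.** The only p-value the method produces is the χ² one, so
Bonferroni adjustment applies to it: the family is every term with a ≥ 3 at
the analyzed level and a term is significant when p ≤ α/m. Applied per
level (PT and SOC analyses have separate families).

## Time-to-onset

Onset = event date − earliest day-precision therapy start among rows linked
to a target-drug sequence, one value per case (the `--per-event` flag
replicates it over the case's distinct PTs, since report-level sources are
ambiguous about the unit). Exclusions carry exactly one coded reason:
`missing-date` (either date absent, including no day-precision start),
`imprecise-date` (a date known only to month/year, or a malformed digit
string — treated as an incorrect date), `event-before-start`. Quartiles use
linear interpolation between order statistics — the convention under which
integer day counts yield fractional IQR endpoints (….25/.75) as published
onset analyses show. Year bins are half-open [0,1), [1,3), … [11,∞) with a
365.25-day year.

## Percentages and grouping conventions

Percentages are computed in exact decimal arithmetic and rounded half-up at
the printed precision (1 decimal for characteristics tables, 2 for onset
bins), so binary-float ties cannot round down. Age units convert as DEC×10,
YR×1, MON÷12, WK÷52.1775, DY÷365.25, HR÷8766; weight LBS×0.45359237. Group
boundaries mirror the printed labels: age <18 = [0,18), 18~65 = [18,65],
>65 beyond; weight <50 = [0,50), 50~100 = [50,100], >100 beyond. The
serious-outcome block's denominator is the number of outcome *rows* plus
one Unknown per case with no outcome row; the indication block counts
distinct (case, indication) pairs linked to the target drug's sequence
numbers. Report year is the FDA receipt year (always populated), not the
event year.

## The synthetic generator

`faersig.synthetic` draws each case independently: target-drug membership
~ Bernoulli(f); PT set ~ independent per-term Bernoullis over a vocabulary,
with the *odds* of injected terms multiplied by the configured true odds
ratio among target cases. Empty PT sets are resampled, which is exactly
conditioning on ≥ 1 term; `true_contingency` gives the conditional cell
probabilities in closed form (p/Z normalization), and because the
normalizers cancel in the odds, the case-level reporting odds ratio equals
the injected odds ratio *exactly* — clean ground truth for recovery
experiments. Duplicate versions (default probability 0.20, echoing the
roughly one-in-five version redundancy of real extracts) share the CASEID
with a later, equal or earlier FDA date; the generator records the version
its own reading of the dedup rule keeps. Onset times are log-normal
(default μ = 7.29, σ = 1.2 on the day scale: median ≈ 1,466 days with an
IQR spanning roughly 500–3,000 days, matching the long-onset profile of a
chronic enzyme-replacement setting); date-order violations, month/year
truncations and missing dates are injected at configurable rates (defaults
0.02 / 0.10 / 0.05) and labelled with the exact exclusion reason the
pipeline must assign. Demographics default to a pediatric-skewed,
consumer-heavy reporting population; all distributions are configuration,
not constants.

What the generator does **not** emulate: drug-name misspellings and free
text, realistic co-prescription structure, masking/competition between
signals, reporting-rate drift over calendar time, and correlated PTs
within a case. Tests passing on synthetic data therefore demonstrate the
*pipeline arithmetic* — counting, dedup rule, exclusion logic, statistics —
not robustness to real-world coding noise.

## Problem sizes and numerical choices

The acceptance experiments use 10,000 cases for deduplication ground truth,
5,000 for onset exclusions, and 100 replicates of 20,000 cases (background
probability 0.01, injected odds ratio 10, 5% target-drug fraction — about
a ≈ 95 expected) for the recovery study; these sizes give stable per-cell
counts while a full run stays under a minute. Statistics are evaluated in
scalar double precision; oracle-equivalence tests require agreement with
direct formula evaluation to 12 significant digits. Table files are UTF-8
with a latin-1 fallback; header matching is case-insensitive; cells are
whitespace-trimmed and kept as strings until an analysis interprets them.

## Known limitations

* EBGM05 here is a log-normal plug-in bound, not the posterior 5th
  percentile of a fitted gamma-Poisson mixture; at very small a it is less
  conservative than true MGPS shrinkage.
* The BCPNN interval is a moment approximation; for a ≤ 3 its IC025 can
  differ from an exact posterior quantile by a few tenths of a bit.
* Deduplication implements only the CASEID/FDA_DT/PRIMARYID rule; no
  probabilistic duplicate detection across distinct CASEIDs.
* PT→SOC mapping must be supplied by the user (MedDRA licensing); lookups
  are strict and fail listing every unmapped term rather than guessing.
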