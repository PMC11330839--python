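# faersig

Disproportionality signal detection for FAERS-style spontaneous
adverse-event reports.

Post-marketing drug safety studies mine the FDA Adverse Event Reporting
System (FAERS): quarterly `$`-delimited extracts of individual case safety
reports (DEMO, DRUG, REAC, OUTC, INDI, THER tables), where one case may
appear as several report versions and events are coded as MedDRA Preferred
Terms (PTs) grouped into System Organ Classes (SOCs). `faersig` packages
the full workflow of such a study — built around an enzyme-replacement
therapy (galsulfase/Naglazyme, used in mucopolysaccharidosis VI) but
configurable for any target drug:

* **Ingestion & deduplication** — parse quarterly ASCII tables, keep one
  version per CASEID (latest FDA receipt date, ties to the higher
  PRIMARYID), discard rows orphaned by deduplication.
* **Case selection** — exact name matching (generic + brand synonyms)
  against drug name or active ingredient, filtered by role code (primary
  suspect by default), and formation of the unique case–event pairs all
  counting rests on.
* **Signal statistics** — for each PT or SOC the 2×2 table
  (a, b, c, d) of target-drug/other-drug × target-event/other-event report
  counts, and four measures:

  | algorithm | statistic | signal criterion |
  |---|---|---|
  | ROR  | ad/bc, 95% CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)) | CI lower bound > 1 and a ≥ 3 |
  | PRR  | a(c+d)/(c(a+b)), Pearson χ² (1 df, uncorrected) | PRR ≥ 2, χ² ≥ 4, a ≥ 3 |
  | BCPNN | IC = log₂(aN/((a+c)(a+b))), IC025 = E(IC) − 2·√V(IC) | IC025 > 0 |
  | MGPS (plug-in) | EBGM = aN/((a+c)(a+b)), log-normal EBGM05 | EBGM05 > 2 |

  plus the four-algorithm intersection with an n ≥ 11 reporting cut,
  Venn-style per-algorithm counts, and Bonferroni adjustment of the χ²
  p-values across all terms with a ≥ 3.
* **Descriptives** — sex / age group / weight group / reporter occupation /
  country / serious-outcome / indication blocks with half-up-rounded
  percentages, yearly report counts, and subgroup partitions (sex,
  occupation) for stratified reruns.
* **Time-to-onset** — days from the earliest day-precision therapy start of
  the target drug to the event date; records with missing or imprecise
  dates or an event before the start are excluded with coded reasons;
  summaries use linear-interpolation quartiles and half-open year bins
  (365.25-day years).
* **Synthetic FAERS generator** — quarterly file sets drawn from an
  explicit generative model with injected drug–event signals of known odds
  ratio, duplicate report versions, partial dates and date-order errors,
  each labelled in a ground-truth sidecar, so every stage is testable
  without the multi-gigabyte real database.

## Worked example

Simulate 5,000 cases with one injected signal (true odds ratio 8 on the
vocabulary term "Synthetic PT A1"), then run the pipeline:

```python
from faersig.synthetic import SimulationConfig, InjectedSignal, simulate, write_dataset
cfg = SimulationConfig(seed=42, n_cases=5000,
                       injected_signals=[InjectedSignal("Synthetic PT A1", 8.0)])
write_dataset(simulate(cfg), "data", split_quarters=False)
```

```sh
$ faersig ingest --quarters data/23q4 --out store
{"reports_before_dedup": 5990, "reports_after_dedup": 5000, "distinct_caseids": 5000}

$ faersig signals --store store --meddra data/meddra_map.tsv --level pt \
      --out signals.tsv --venn venn.tsv
51 terms; 1 flagged by all four; 1 with n >= 11 -> signals.tsv

$ faersig onset --store store --out onset.tsv --bins bins.tsv
n=200 median=1392 d IQR=(506.50, 3155.50); excluded 43
({"imprecise-date": 25, "missing-date": 13, "event-before-start": 5})
```

The 990 duplicate report versions collapse to one per case; of 51 observed
terms exactly one — the injected one — passes all four screening criteria:

```
term                      Synthetic PT A1
n                                     131
ror                              8.891824      # true odds ratio: 8
ror_lo                           6.805723
ror_hi                          11.617360
prr                              4.637384
chi2                           350.053248
ic                               1.978470
ic025                            1.616924
ebgm                             3.940750
ebgm05                           3.016215
flagged_by_all                       True
bonferroni_significant               True
```

Here n = a = 131 target-drug reports mention the term; the ROR interval
(6.8, 11.6) covers the injected odds ratio, and the shrinkage-style
observed/expected measures (IC, EBGM) sit lower, as they should for a term
this common in the background. The onset line reports the median and
interquartile range in days over the cases whose dates survive the
exclusion rules, with each exclusion reason tallied.

`faersig describe` emits the clinical-characteristics table (counts and
percentages per block) and yearly report counts; `faersig simulate` is the
CLI front end of the generator.

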