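# Methods

## The screening model

`latscreen` treats laterality screening as deterministic rule checking, not
classification learning. The unit of analysis is a *study*: one or more
free-text medical orders plus one free-text English report; a study is
*combined* when it has more than one order. The output is report-level
(positive iff at least one violation is found), with every violation
anchored to a 1-based source line so the decision is auditable.

Two error mechanisms are checked, mirroring how such errors are annotated
in practice:

1. **Heading vs order** — a paragraph heading claims a side that no order
   for that anatomy permits (e.g. a "right shoulder" heading when only the
   left shoulder was ordered).
2. **Finding vs scope** — a sided finding mention is incompatible with the
   anatomies in force for its paragraph (e.g. "right clavicle fracture"
   inside a left-shoulder paragraph).

Assumptions worth stating explicitly:

- **Orders are trusted.** The method compares the report against the
  orders; it cannot see images, so a consistently wrong report+order pair
  is undetectable, as is a wrong side *within* an inherently bilateral
  film (left rib fracture dictated as right on a chest x-ray).
- **Unknown terms never flag.** A mention whose term appears in no rule
  value is ignored. On data where positives are ~1%, precision failures
  dominate the cost of deployment; the packaged rules therefore only
  constrain vocabulary they know.
- **Findings under an invalid heading are skipped.** Once the heading
  itself contradicts the orders, the body's true laterality is
  undetermined; only the heading is flagged. This also means a
  previously-skipped body can legitimately surface new flags if an order
  set is extended so that the heading becomes valid — coverage
  monotonicity ("adding an order never creates a flag") is therefore
  guaranteed only for orders whose anatomy the report's headings do not
  name, and the tests check exactly that form.
- **Contralateral-comparison suppression is not implemented.** Radiologists
  sometimes mention the opposite side intentionally ("symmetric compared
  with the right side"). The baseline deliberately ships no heuristic for
  this (`RuleScreener` has no such switch); in deployment these surface as
  false positives to be handled by rule curation.

## Parsing and segmentation

- Lines are 1-based and split on newline. A line whose last non-space
  character is `:` opens a paragraph and becomes its heading; lines before
  any heading form a heading-less preamble. A **blank line closes the
  current paragraph**, so material after it (without a new heading) is
  heading-less — vertical whitespace is the only other segmentation signal
  free-typed reports reliably carry.
- A *sentence* is a period/colon/semicolon-delimited span within one line.
  A finding mention pairs each non-stopword lemma in a sentence with the
  side of the nearest laterality token in that sentence; sentences without
  a left/right token contribute no mentions. Sentence scope reproduces the
  worked combined-report example's verdicts exactly; narrower windows risk
  detaching findings from their side token in ordinary prose.
- Order parsing strips view vocabulary (anteroposterior, lateral, oblique,
  lordotic, decubitus, …) so rules only ever address anatomies; order
  phrases may expand to several anatomy keys ("L-S spine" → lumbar spine +
  sacrum). Laterality words are recognized case-insensitively, `Lt`/`Rt`
  with or without a trailing period, before or after the anatomy phrase.
- The lemmatizer is a deliberately small suffix-rule singularizer
  (-s/-es/-ies plus a tiny irregular table). Medical irregular plurals
  (*phalanges*, *vertebrae*, …) are **not** in it: resolving those is the
  extraction normalizer's documented job, and keeping the two separate is
  what lets the tests demonstrate the normalizer's effect (a report
  writing "right phalanges" on a left-foot film is missed by the plain
  route and caught with normalization).

## Extraction normalizer

The built-in backend is the default and the only one tests exercise. It is
deterministic: per body line (headings pass through), it reorders inverted
`"term, Rt."` phrasing, maps composite expressions through a packaged
synonym table (*genu varum* → knee), singularizes (irregular table first,
suffix rules second), and attaches each term to the nearest same-sentence
laterality token. Sides never cross lines.

The LLM backend is a contract, not a dependency: callers inject a
transport callable (prompt → raw response). The prompt is assembled from a
role prompt, abbreviation notes and the report; the expected response maps
line numbers to `[term, side]` pairs. Per-line parse failures fall back to
the built-in normalizer; transport failure aborts extraction entirely so a
caller can proceed extractor-less. Config defaults (temperature 0, fixed
seed 5566) favour reproducibility of API calls.

## Rule drafting

`draft_rules` segments each report, infers the section anatomy from its
heading, and collects the 2 non-stopword lemmas before and 3 after each
laterality indicator (windows truncate at paragraph boundaries; laterality
and view words are never emitted) as candidate terms under that anatomy,
with (study, line) provenance per occurrence. The window is over
*post-stopword* lemmas — the token stream is lemmatized and stopword-
filtered before extraction, so windows are not diluted by function words.
Headings naming several anatomies credit all of them; over-generation is
acceptable because the output is a draft for human curation, mechanized in
`merge_into_ruleset` as threshold (`min_count`) + union with the base
ruleset (which never loses entries).

## Synthetic data

The generator emulates the corpus shape of a multisite radiographic
archive and is fully determined by its seed. Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| `combined_fraction` | 0.70 | 7,000 of 10,000 real-world studies are combined |
| orders/study | {1: .30, 2: .505, 3: .15, 4: .03, 5: .015} | mean ≈ 1.95, SD ≈ 1.0 |
| `part_frequencies` | packaged table | real-world anatomy distribution of the development cohort |
| `error_rate` | 0.012 | real-world prevalence 1.20% |
| `style_mix` | headed .40, merged .20, no-heading .15, inverted .10, plural .10, contralateral .05 | free-typing style variety |

Reports render each order in the sampled style from a template bank that
is **co-designed with the packaged rules**: every sided finding line
carries at least one term unique to its anatomy key, every rule-known term
in a clean line is valid under its own order, and findings of inherently
bilateral parts carry no side token. Consequences that the tests enforce:
clean renders never flag, and a single injected flip in a core-style
report is always detected (label soundness, recall 1.0). Two sampling
constraints protect this: the same anatomy never appears twice in one
study, and anatomies whose template terms are explainable by another
sampled film are kept apart (clavicle vs chest/shoulder, leg vs lower
limb). Every study keeps at least one sided (non-bilateral) anatomy — a
study whose orders carry no laterality keyword would not enter a
laterality-screening cohort in the first place, and would not be
injectable.

The **contralateral-comparison style** appends an opposite-side sentence
built from rule-unknown vocabulary: clean screening stays silent (matching
the precision-first baseline), but a flip landing on that side word is
undetectable *by design*, so this style is excluded from the "core"
template bank used by the balanced injection benchmark
(`make_balanced_batch`).

Injectors: `inject_single_flip` reverses one uniformly chosen occurrence
of Lt/left/Rt/right (case pattern preserved; everything else
byte-identical; the flip is an involution), modelling the
one-error-per-report pattern that dominates real positives.
`inject_alternating` reverses occurrences 1, 3, 5, … — starting at the
first occurrence guarantees at least one flip for any eligible report,
which is the point of an augmentation generator. Flips are uniform over
all occurrences, heading or body.

What the generator does **not** model — and hence what passing tests do
not show about real data: multi-error reports, copy-paste error
etiologies, missing-subheading ambiguity in merged combined studies,
legitimate contralateral comparisons carrying rule-known terms,
misspellings beyond the packaged workaround patterns, and the long tail of
institution-specific phrasing. Real-world recall/precision cannot be
inferred from the synthetic benchmarks; the synthetic suite demonstrates
*mechanism correctness*, not field performance.

## Statistics

- `two_prop_z`: z from the pooled-variance standard error, two-sided
  normal p; the 95% CI on the difference uses the *unpooled* Wald standard
  error. This pooled-z/unpooled-CI pairing is the standard textbook
  combination, and it is the only one that reproduces both the published z
  and CI for the error-rate comparison from its counts. Pooled expected
  events/non-events ≤ 10 log a warning.
- `chi2_test`: Pearson statistic via `scipy.stats.chi2_contingency`; Yates
  continuity applies to 2×2 tables when requested (the published pairwise
  cohort comparison requires it). Cramér V = √(χ²/(N·(min(r,c)−1))) is
  always computed from the uncorrected statistic so that V = 0 ⇔ χ² = 0.
- `friedman`: ranks within each dataset with average ranks on ties
  (rank 1 = highest score), Q referred to χ²(k−1) with the tie-correction
  denominator; verified against `scipy.stats.friedmanchisquare` and a
  direct rank-formula evaluation.
- `nemenyi`: pairwise p from the studentized range distribution
  (k groups, df = ∞) on average-rank differences,
  q = |R̄ᵢ−R̄ⱼ|·√(12n/(k(k+1))). Published values from table-interpolating
  implementations can differ by ~0.01 at the second decimal; the exact CDF
  is used here.
- `cohen_kappa`: standard marginal-product chance agreement. For a
  500-sample stratified design with one disagreement this yields 0.9937;
  a published value of 0.998 for that design is not reproducible under the
  standard formula and is not targeted.
- `evalue`: E = R + √(R(R−1)) with R the OR (rare outcome, <15%) or √OR
  otherwise; ORs < 1 are inverted first. E-values at the third decimal can
  differ from published roundings by 0.01 when the source rounded the OR
  before the transform.
- Degenerate conventions: precision/recall are 0 (logged) when their
  denominator is empty; F1 is 0 when precision+recall is 0; degenerate
  tables (zero marginals) and invalid counts raise.

## Problem sizes in the test suite

Property suites run at sizes chosen to exercise the combinatorics while
keeping the whole suite interactive (~5 s): 1,000 generated studies for
the streaming-vs-brute-force equivalence, 500 (250 pairs) for label
soundness, 10,000 seeded draws for injector uniformity, 100–200 studies
for the invariance checks. The brute-force oracle enumerates every
(mention, side, scope entry) triple independently of the streaming
implementation and lives with the tests, not the package.

## Known limitations

- Heading-scope is heading-only: when a heading names a strict subset of
  the orders, findings in that paragraph are checked against the heading's
  anatomy alone. This is what makes a clavicle finding flaggable under a
  left-shoulder heading even when a chest film was also ordered, at the
  cost of flagging a radiologist who genuinely describes another ordered
  film under the wrong heading.
- Same-sentence "left X … right X" contradictions without a heading or
  order conflict are out of the baseline's reach.
- The packaged ruleset is a compact, internally consistent dictionary
  adequate for the synthetic templates and the worked examples; deploying
  against real reports requires site-specific curation (that is what
  `draft_rules` + `merge_into_ruleset` are for). A few entries trade
  anatomical completeness for benchmark identifiability (e.g. the humerus
  appears under its own key only, not under shoulder/elbow).
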