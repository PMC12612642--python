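# latscreen

Laterality errors — reporting a *right* tibia fracture on a *left* knee
x-ray — are rare but dangerous defects of free-text radiology reports, and
they are hardest to catch in **combined radiographic reports**, where one
free-typed document covers several orders with different anatomies and
sides. `latscreen` screens such reports before sign-off: given a study's
medical orders and its report, it returns a report-level binary decision
(*contains at least one laterality error*) together with line-anchored,
human-readable evidence suitable for inline highlighting.

The core is a dictionary look-up rule engine. An expert ruleset maps each
anatomy key to the finding terms its images can legitimately show
(`knee → femur, tibia, patella, …`; terms may repeat across keys, e.g.
`fibula` under both `knee` and `leg`). A report is segmented into
paragraphs at colon-terminated headings; each paragraph receives a *scope*
of `(anatomy, allowed sides)` pairs — from its heading when the heading is
consistent with the orders, from all orders when it has no heading. A sided
finding mention `(term, side)` is valid iff some scope entry knows the term
and allows the side; inherently bilateral parts (chest, pelvis, spine, …)
allow either side. A heading whose own side contradicts the orders is
itself an error, and findings beneath it are left unevaluated. Formally,
with rules *R*, a mention (*t*, *s*) in scope *S* flags iff

    t ∈ ⋃ R[k]   and   ¬∃ (k, A) ∈ S : t ∈ R[k] ∧ s ∈ A

Around the engine the package provides

- a pluggable **extraction normalizer** (deterministic built-in backend;
  LLM backend via an injected transport) that standardizes terminology —
  singularizing plurals (*phalanges → phalanx*), resolving composites
  (*genu varum → knee*), reordering inverted `"term, Rt."` phrasing —
  before rule matching;
- **automated rule drafting** from unlabeled reports (window of 2
  non-stopword lemmas before / 3 after each laterality indicator, paired
  with the section's heading anatomy) for expert curation;
- a seeded **synthetic-study generator** with two error injectors: a
  single uniformly chosen side-word reversal (balanced test sets) and an
  alternating reversal of every second side word (training augmentation),
  plus sentence-pair export for contradiction-style fine-tuning;
- the **evaluation statistics** used to compare screening methods:
  precision/recall/F1 with combined/noncombined subgroups, two-proportion
  z test, chi-square ± Yates with Cramér V, Friedman + Nemenyi on
  method × dataset score grids, Cohen's κ, and E-value sensitivity
  analysis.

## Worked example

A single study ordered as a chest x-ray (posteroanterior) plus a **left**
shoulder x-ray, with a combined report whose lines 1–6 read:

```text
1  Chest posteroanterior view and left shoulder anteroposterior view shows:
2  Right clavicle fracture.
3  Left shoulder anteroposterior view shows:
4  Right clavicle fracture.
5  Right shoulder anteroposterior view shows:
6  Right clavicle fracture.
   (blank line — ends the right-shoulder paragraph)
8  Right rib fracture.
```

```python
from latscreen import combined_example_study, screen_study

pred = screen_study(combined_example_study())
print("positive:", pred.positive)
for f in pred.flags:
    print(f"line {f.line} [{f.kind}] {f.message}")
```

prints

```text
positive: True
line 4 [finding_vs_scope] right clavicle, fracture not reportable under scope shoulder:left
line 5 [heading_vs_order] heading names right shoulder but orders specify: left shoulder; unspecified chest
```

Line 2 is *not* flagged (a chest film inherently shows both clavicles, and
chest is in the line-1 heading's scope), line 4 is flagged against its
left-shoulder heading, line 5's heading contradicts the order, line 6 is
skipped because its heading is invalid, and the final heading-less rib line
is valid through the chest order.

The same engine drives the sklearn-style estimator:

```python
from latscreen import RuleScreener, make_balanced_batch

batch = make_balanced_batch(250, seed=0)          # 500 studies, 50/50 classes
screener = RuleScreener(extractor="builtin").fit([])
y_pred = screener.predict([ls.study for ls in batch])
```

and the CLI:

```sh
latscreen synth --n 200 --seed 1 --mode test2 --out reports.jsonl
latscreen check --reports reports.jsonl --out pred.jsonl --extractor builtin
latscreen eval --pred pred.jsonl --gold reports.jsonl
```

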