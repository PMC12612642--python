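"""Automated drafting of expert rules from unlabeled reports.

Hand-curating anatomy -> finding-term dictionaries is the main cost of a
rule-based screener.  This module mechanizes the first draft: reports are
segmented by their headings, each section's anatomy is inferred from the
heading, and the words around every laterality indicator (2 non-stopword
lemmas before, 3 after) become candidate finding terms for that anatomy,
with per-occurrence provenance so a curator can audit every candidate.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .lexicon import Lexicon, Study, parse_heading, segment_report, tokenize_normalize
from .rules import ExpertRuleSet

logger = logging.getLogger(__name__)

WINDOW_BEFORE = 2
WINDOW_AFTER = 3


@dataclass
class DraftRuleSet:
    """Candidate terms per anatomy key with occurrence counts and provenance."""

    candidates: dict[str, Counter] = field(default_factory=dict)
    provenance: dict[tuple[str, str], list[tuple[str, int]]] = field(default_factory=dict)

    def add(self, key: str, term: str, study_id: str, line: int) -> None:
        self.candidates.setdefault(key, Counter())[term] += 1
        self.provenance.setdefault((key, term), []).append((study_id, line))

    def to_dict(self) -> dict:
        return {
            "candidates": {k: dict(c) for k, c in sorted(self.candidates.items())},
            "provenance": {
                f"{k}::{t}": v for (k, t), v in sorted(self.provenance.items())
            },
        }


def draft_rules(studies: list[Study], lexicon: Lexicon) -> DraftRuleSet:
    """Draft candidate expert rules from a corpus of studies.

    Windows are computed over non-stopword lemmas of each paragraph body and
    truncate at paragraph boundaries; laterality and view terms are never
    emitted as candidates.  Sections whose heading names no recognizable
    anatomy are skipped (logged) — multi-part headings contribute their
    window terms to every named key, leaving pruning to the curator.
    """
    draft = DraftRuleSet()
    for study in studies:
        seg = segment_report(study.report_text, lexicon)
        for para in seg.paragraphs:
            if para.heading is None:
                continue
            keys = sorted(
                {k for parts, _ in parse_heading(para.heading, lexicon) for k in parts}
            )
            if not keys:
                logger.info(
                    "study %s line %s: heading anatomy not inferable, section skipped",
                    study.study_id,
                    para.heading_line,
                )
                continue
            stream = []  # (lemma, line, is_laterality, is_view)
            for line_no, line in para.body:
                for t in tokenize_normalize(line, lexicon):
                    if t.is_stopword:
                        continue
                    stream.append(
                        (t.lemma, line_no, t.is_laterality, t.lemma in lexicon.view_terms)
                    )
            for i, (_, _, is_lat, _) in enumerate(stream):
                if not is_lat:
                    continue
                lo = max(0, i - WINDOW_BEFORE)
                hi = min(len(stream), i + WINDOW_AFTER + 1)
                for j in range(lo, hi):
                    lemma, line_no, lat_j, view_j = stream[j]
                    if j == i or lat_j or view_j:
                        continue
                    for key in keys:
                        draft.add(key, lemma, study.study_id, line_no)
    return draft


def merge_into_ruleset(
    draft: DraftRuleSet, base: ExpertRuleSet, min_count: int = 1
) -> ExpertRuleSet:
    """Append drafted terms seen >= ``min_count`` times to the base rules.

    The base never loses entries; a term drafted under several keys is
    appended under each (overlap across keys is legal).
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    rules = {k: list(v) for k, v in base.rules.items()}
    for key, counter in sorted(draft.candidates.items()):
        target = rules.setdefault(key, [])
        for term, count in sorted(counter.items()):
            if count >= min_count and term not in target:
                target.append(term)
    return ExpertRuleSet(
        rules={k: tuple(v) for k, v in rules.items()},
        bilateral_parts=base.bilateral_parts,
        workaround_patterns=base.workaround_patterns,
    )
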