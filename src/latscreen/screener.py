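"""Report-level laterality screening.

``RuleScreener`` is the user-facing estimator: given studies (orders + free
text report) it predicts, per study, whether the report contains at least one
laterality error, and exposes the line-anchored evidence behind each positive
call.  The pipeline per study is

    workarounds -> (optional extraction normalization) -> segmentation ->
    per-paragraph scope resolution -> finding checks

Findings under an *invalid* heading are skipped rather than flagged — when
the heading itself contradicts the order, the body's true laterality cannot
be determined, so only the heading is reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .extraction import (
    ExtractionEntity,
    SynonymTable,
    extract_builtin,
    load_default_synonyms,
)
from .lexicon import (
    LEFT,
    RIGHT,
    Lexicon,
    Study,
    load_default_lexicon,
    segment_report,
    tokenize_normalize,
)
from .rules import (
    ErrorFlag,
    ExpertRuleSet,
    FINDING_VS_SCOPE,
    Prediction,
    Scope,
    all_orders_scope,
    apply_workarounds,
    check_finding,
    load_default_ruleset,
    validate_heading,
)


@dataclass
class StudyError:
    """A study that could not be screened (e.g. unparseable order)."""

    study_id: str
    reason: str


def _line_mentions(
    line: str, lexicon: Lexicon
) -> list[tuple[str, str]]:
    """Sided finding mentions of one body line, extractor-less route.

    A mention is a (lemma, side) pair inside a sentence (period/colon/
    semicolon-delimited span) that contains a left/right token; each lemma
    attaches to the nearest laterality token in the sentence.
    """
    mentions: list[tuple[str, str]] = []
    for sent in re.split(r"[.;:]", line):
        toks = tokenize_normalize(sent, lexicon)
        lat = [(i, t.side) for i, t in enumerate(toks) if t.is_laterality]
        sided = [(i, s) for i, s in lat if s in (LEFT, RIGHT)]
        if not sided:
            continue
        for i, t in enumerate(toks):
            if t.is_laterality or t.is_stopword:
                continue
            pos, side = min(lat, key=lambda ps: abs(ps[0] - i))
            if side in (LEFT, RIGHT):
                mentions.append((t.lemma, side))
    return mentions


def _check_mentions(
    mentions: list[tuple[str, str]],
    line_no: int,
    scope: Scope,
    ruleset: ExpertRuleSet,
) -> list[ErrorFlag]:
    """Check mentions of one line, aggregating one flag per offending side."""
    offending: dict[str, list[str]] = {}
    for term, side in mentions:
        flag = check_finding(term, side, scope, ruleset, line=line_no)
        if flag is not None:
            offending.setdefault(side, []).append(term)
    flags = []
    for side in sorted(offending):
        terms = sorted(set(offending[side]))
        flags.append(
            ErrorFlag(
                line=line_no,
                kind=FINDING_VS_SCOPE,
                side=side,
                finding_term=terms[0],
                message=(
                    f"{side} {', '.join(terms)} not reportable under scope "
                    + "; ".join(f"{k}:{'/'.join(sorted(s))}" for k, s in scope.entries)
                ),
                evidence=scope.entries,
            )
        )
    return flags


def screen_study(
    study: Study,
    ruleset: Optional[ExpertRuleSet] = None,
    lexicon: Optional[Lexicon] = None,
    extraction: Optional[Sequence[ExtractionEntity]] = None,
) -> Prediction:
    """Screen one study; thin functional wrapper over :class:`RuleScreener`.

    ``extraction``, when given, supplies per-line normalized entities that
    replace the raw-token finding mentions of paragraph bodies.
    """
    screener = RuleScreener(ruleset=ruleset, lexicon=lexicon, extractor="none")
    screener.fit([])
    return screener._screen(study, extraction)


class RuleScreener:
    """Dictionary look-up laterality-error classifier (sklearn-style).

    Parameters
    ----------
    ruleset : ExpertRuleSet, optional
        Expert rules; the packaged default when omitted.
    lexicon : Lexicon, optional
        Surface-form lexicons; the packaged default when omitted.
    extractor : {"none", "builtin"} or callable
        Report normalization backend.  ``"builtin"`` runs the deterministic
        normalizer; a callable must map a report string to a list of
        :class:`ExtractionEntity`.
    synonyms : SynonymTable, optional
        Synonym table for the builtin extractor.
    draft : bool
        When True, ``fit`` drafts candidate rules from the training studies
        and merges terms seen at least ``min_count`` times into the ruleset.
    min_count : int
        Occurrence threshold for merging drafted rules.
    """

    def __init__(
        self,
        ruleset: Optional[ExpertRuleSet] = None,
        lexicon: Optional[Lexicon] = None,
        extractor: Union[str, callable] = "none",
        synonyms: Optional[SynonymTable] = None,
        draft: bool = False,
        min_count: int = 2,
    ):
        self.ruleset = ruleset
        self.lexicon = lexicon
        self.extractor = extractor
        self.synonyms = synonyms
        self.draft = draft
        self.min_count = min_count

    _param_names = ("ruleset", "lexicon", "extractor", "synonyms", "draft", "min_count")

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params) -> "RuleScreener":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting ---------------------------------------------------------

    def fit(self, X: Sequence[Study], y=None) -> "RuleScreener":
        """Resolve configuration; optionally draft rules from ``X``."""
        if not (self.extractor in ("none", "builtin") or callable(self.extractor)):
            raise ValueError(f"unknown extractor {self.extractor!r}")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        self.lexicon_ = self.lexicon or load_default_lexicon()
        self.synonyms_ = self.synonyms or load_default_synonyms()
        base = self.ruleset or load_default_ruleset()
        if self.draft and len(X) > 0:
            from .induction import draft_rules, merge_into_ruleset

            drafted = draft_rules(list(X), self.lexicon_)
            base = merge_into_ruleset(drafted, base, min_count=self.min_count)
        self.ruleset_ = base
        return self

    def _require_fitted(self):
        if not hasattr(self, "ruleset_"):
            raise RuntimeError("RuleScreener is not fitted; call fit() first")

    # -- screening -------------------------------------------------------

    def _extraction_for(self, text: str) -> Optional[list[ExtractionEntity]]:
        if self.extractor == "none":
            return None
        if self.extractor == "builtin":
            return extract_builtin(text, self.lexicon_, self.synonyms_)
        return self.extractor(text)

    def _screen(
        self, study: Study, extraction: Optional[Sequence[ExtractionEntity]] = None
    ) -> Prediction:
        ruleset, lexicon = self.ruleset_, self.lexicon_
        text = apply_workarounds(study.report_text, ruleset)
        if extraction is None:
            extraction = self._extraction_for(text)
        by_line: Optional[dict[int, list[ExtractionEntity]]] = None
        if extraction is not None:
            by_line = {}
            for e in extraction:
                by_line.setdefault(e.line, []).append(e)

        seg = segment_report(text, lexicon)
        base_scope = all_orders_scope(study.orders, ruleset)
        flags: list[ErrorFlag] = []
        for para in seg.paragraphs:
            if para.heading is not None:
                res = validate_heading(
                    para.heading,
                    study.orders,
                    ruleset,
                    lexicon,
                    heading_line=para.heading_line,
                )
                if isinstance(res, ErrorFlag):
                    flags.append(res)
                    continue  # body under an invalid heading: undetermined
                scope = res
            else:
                scope = base_scope
            for line_no, line in para.body:
                if not line.strip():
                    continue
                if by_line is not None:
                    mentions = [
                        (e.term, e.side)
                        for e in by_line.get(line_no, [])
                        if e.side in (LEFT, RIGHT)
                    ]
                else:
                    mentions = _line_mentions(line, lexicon)
                flags.extend(_check_mentions(mentions, line_no, scope, ruleset))
        flags.sort(key=lambda f: (f.line, f.kind, f.side))
        return Prediction(
            study_id=study.study_id, positive=bool(flags), flags=tuple(flags)
        )

    def predict_flags(
        self, X: Sequence[Study]
    ) -> tuple[list[Prediction], list[StudyError]]:
        """Screen studies, collecting per-study errors instead of raising."""
        self._require_fitted()
        preds: list[Prediction] = []
        errors: list[StudyError] = []
        for study in X:
            try:
                preds.append(self._screen(study))
            except Exception as exc:
                errors.append(StudyError(study_id=study.study_id, reason=str(exc)))
        return preds, errors

    def predict(self, X: Sequence[Study]) -> np.ndarray:
        """Binary prediction per study: True = laterality error present."""
        self._require_fitted()
        return np.array([self._screen(s).positive for s in X], dtype=bool)
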