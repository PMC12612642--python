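"""Information-extraction normalizer for report preprocessing.

The rule checker consumes per-line ``(term, side)`` entities.  The built-in
backend standardizes heterogeneous phrasing deterministically: plural terms
become singular (including medical irregulars such as *phalanges* →
*phalanx*), composite expressions map to their anatomy (*genu varum* →
*knee*), and inverted ``"term, Rt."`` phrasings are reordered.  An LLM
backend with the same contract can be plugged in through an injected
transport; lines whose LLM output fails to parse fall back to the built-in
normalizer so the pipeline degrades gracefully.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Optional

from .lexicon import BILATERAL, LEFT, RIGHT, Lexicon, Token, lemmatize, tokenize_normalize

logger = logging.getLogger(__name__)

_INVERTED_RE = re.compile(r"(?i)^(.*?),\s*(lt|rt|left|right)\.?\s*$")

DEFAULT_ROLE_PROMPT = (
    "You are a radiologist. Extract every anatomical location (bones, joints,"
    " organs) and finding from the report below, together with its laterality."
    " Express all results in singular nouns whenever possible. Answer with a"
    " JSON object mapping 1-based line numbers to lists of [term, side] pairs,"
    " side one of left/right/bilateral/none."
)
DEFAULT_ABBREVIATION_NOTES = (
    "Conventions: 'Lt' means left, 'Rt' means right; views such as"
    " anteroposterior or lateral are not findings."
)


class ExtractionUnavailableError(RuntimeError):
    """The configured extraction backend could not produce any result."""


@dataclass(frozen=True)
class ExtractionEntity:
    line: int  # 1-based
    term: str  # lowercase singular lemma
    side: str  # left | right | bilateral | none
    source_span: tuple[int, int] = (0, 0)

    def __post_init__(self):
        if not self.term:
            raise ValueError("entity term must be non-empty")


@dataclass(frozen=True)
class SynonymTable:
    irregular_plurals: dict[str, str]
    composites: dict[str, tuple[str, ...]]

    @classmethod
    def from_dict(cls, d: dict) -> "SynonymTable":
        return cls(
            irregular_plurals={k.lower(): v for k, v in d["irregular_plurals"].items()},
            composites={k.lower(): tuple(v) for k, v in d["composites"].items()},
        )

    @classmethod
    def from_json(cls, path) -> "SynonymTable":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def load_default_synonyms() -> SynonymTable:
    text = resources.files("latscreen.data").joinpath("synonyms.json").read_text("utf-8")
    return SynonymTable.from_dict(json.loads(text))


@dataclass(frozen=True)
class ExtractorConfig:
    """Backend configuration; defaults mirror a reproducible API setup."""

    backend: str = "builtin"  # builtin | llm
    model_name: str = ""
    temperature: float = 0.0
    seed: int = 5566
    role_prompt: str = DEFAULT_ROLE_PROMPT
    abbreviation_notes: str = DEFAULT_ABBREVIATION_NOTES

    def __post_init__(self):
        if self.backend not in ("builtin", "llm"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.backend == "llm" and not self.model_name:
            raise ValueError("backend='llm' requires model_name")


def singularize(word: str, synonyms: SynonymTable) -> str:
    w = word.lower()
    return synonyms.irregular_plurals.get(w, lemmatize(w))


def _extract_line(
    lineno: int, line: str, lexicon: Lexicon, synonyms: SynonymTable
) -> list[ExtractionEntity]:
    line = _INVERTED_RE.sub(r"\2 \1", line)
    entities: list[ExtractionEntity] = []
    # sentence = period/colon/semicolon-delimited span within the line
    for sent in re.split(r"[.;:]", line):
        toks = tokenize_normalize(sent, lexicon)
        if not toks:
            continue
        # side attachment: nearest laterality token within the sentence
        lat_positions = [
            (i, t.side) for i, t in enumerate(toks) if t.is_laterality
        ]

        def side_for(i: int) -> str:
            if not lat_positions:
                return "none"
            pos, side = min(lat_positions, key=lambda ps: abs(ps[0] - i))
            return side

        i = 0
        maxlen = max((len(p.split()) for p in synonyms.composites), default=1)
        while i < len(toks):
            t = toks[i]
            if t.is_laterality or t.is_stopword or t.lemma in lexicon.view_terms:
                i += 1
                continue
            matched = False
            for n in range(min(maxlen, len(toks) - i), 1, -1):
                phrase = " ".join(tok.text.lower() for tok in toks[i : i + n])
                if phrase in synonyms.composites:
                    span = (toks[i].start, toks[i + n - 1].start + len(toks[i + n - 1].text))
                    for term in synonyms.composites[phrase]:
                        entities.append(
                            ExtractionEntity(lineno, term, side_for(i), span)
                        )
                    i += n
                    matched = True
                    break
            if matched:
                continue
            single = toks[i].text.lower()
            if single in synonyms.composites:
                for term in synonyms.composites[single]:
                    entities.append(
                        ExtractionEntity(
                            lineno, term, side_for(i), (t.start, t.start + len(t.text))
                        )
                    )
            else:
                entities.append(
                    ExtractionEntity(
                        lineno,
                        singularize(t.text, synonyms),
                        side_for(i),
                        (t.start, t.start + len(t.text)),
                    )
                )
            i += 1
    return entities


def extract_builtin(
    report: str,
    lexicon: Lexicon,
    synonyms: Optional[SynonymTable] = None,
) -> list[ExtractionEntity]:
    """Deterministic normalization of body lines into per-line entities.

    Heading lines (colon-terminated) pass through untouched — heading
    validation is order-driven — and entity sides come only from laterality
    tokens on the same line.
    """
    synonyms = synonyms or load_default_synonyms()
    entities: list[ExtractionEntity] = []
    for lineno, line in enumerate(report.split("\n"), start=1):
        if not line.strip() or lexicon.is_heading(line):
            continue
        entities.extend(_extract_line(lineno, line, lexicon, synonyms))
    return entities


def _parse_llm_entities(
    payload, lineno: int
) -> Optional[list[tuple[str, str]]]:
    if not isinstance(payload, list):
        return None
    out = []
    for item in payload:
        if not (isinstance(item, (list, tuple)) and len(item) == 2):
            return None
        term, side = item
        if not isinstance(term, str) or not term or side not in (
            "left",
            "right",
            "bilateral",
            "none",
        ):
            return None
        out.append((term.lower(), side))
    return out


def extract_llm(
    report: str,
    config: ExtractorConfig,
    transport: Callable[[str], str],
    lexicon: Optional[Lexicon] = None,
    synonyms: Optional[SynonymTable] = None,
) -> list[ExtractionEntity]:
    """Extract entities through an injected LLM transport.

    ``transport`` receives the assembled prompt and returns the raw model
    response.  The expected response is a JSON object mapping line numbers to
    ``[term, side]`` lists; lines that are missing or fail validation fall
    back to the built-in normalizer for that line.  A transport failure
    raises :class:`ExtractionUnavailableError` with no partial result.
    """
    from .lexicon import load_default_lexicon

    lexicon = lexicon or load_default_lexicon()
    synonyms = synonyms or load_default_synonyms()
    prompt = "\n\n".join(
        [config.role_prompt, config.abbreviation_notes, report]
    )
    try:
        response = transport(prompt)
    except Exception as exc:  # transport contract: any failure is fatal
        raise ExtractionUnavailableError(str(exc)) from exc

    try:
        parsed = json.loads(response)
        if not isinstance(parsed, dict):
            parsed = {}
    except (TypeError, ValueError):
        parsed = {}

    entities: list[ExtractionEntity] = []
    for lineno, line in enumerate(report.split("\n"), start=1):
        if not line.strip() or lexicon.is_heading(line):
            continue
        pairs = _parse_llm_entities(parsed.get(str(lineno)), lineno)
        if pairs is None:
            logger.info("line %d: LLM output unusable, built-in fallback", lineno)
            entities.extend(_extract_line(lineno, line, lexicon, synonyms))
        else:
            entities.extend(
                ExtractionEntity(lineno, term, side) for term, side in pairs
            )
    return entities


class BuiltinNormalizer:
    """sklearn-style transformer over raw report strings.

    ``transform`` maps a list of reports to a list of entity lists; it is
    stateless, so ``fit`` only validates parameters.
    """

    def __init__(self, lexicon=None, synonyms=None):
        self.lexicon = lexicon
        self.synonyms = synonyms

    def get_params(self, deep: bool = True) -> dict:
        return {"lexicon": self.lexicon, "synonyms": self.synonyms}

    def set_params(self, **params) -> "BuiltinNormalizer":
        for k, v in params.items():
            if k not in ("lexicon", "synonyms"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "BuiltinNormalizer":
        from .lexicon import load_default_lexicon

        self.lexicon_ = self.lexicon or load_default_lexicon()
        self.synonyms_ = self.synonyms or load_default_synonyms()
        return self

    def transform(self, X: list[str]) -> list[list[ExtractionEntity]]:
        if not hasattr(self, "lexicon_"):
            self.fit()
        return [extract_builtin(report, self.lexicon_, self.synonyms_) for report in X]

    def fit_transform(self, X: list[str], y=None) -> list[list[ExtractionEntity]]:
        return self.fit(X, y).transform(X)
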