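"""Lexicons, order parsing, tokenization and report segmentation.

Radiographic studies pair free-text physician *orders* (anatomy + views +
side, e.g. ``"Rt knee anteroposterior+lateral view"``) with one free-text
report.  This module turns both into structured form: orders become
``(parts, side)`` records with view information stripped, and reports are
split into colon-headed paragraphs with 1-based line numbers so that every
downstream flag can point back at a source line.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

LEFT = "left"
RIGHT = "right"
BILATERAL = "bilateral"
UNSPECIFIED = "unspecified"

_WORD_RE = re.compile(r"[A-Za-z][A-Za-z\-']*")

# Minimal irregular table for the lightweight lemmatizer.  Medical irregular
# plurals (phalanges, vertebrae, ...) deliberately live in the extraction
# synonym table instead: terminology standardization is the normalizer's job.
_IRREGULAR_LEMMAS = {
    "men": "man",
    "women": "woman",
    "children": "child",
    "teeth": "tooth",
}


class UnparseableOrderError(ValueError):
    """Raised when an order contains no recognizable anatomy phrase."""

    def __init__(self, text: str):
        super().__init__(f"no recognizable anatomy phrase in order: {text!r}")
        self.text = text


def lemmatize(word: str) -> str:
    """Lowercase and singularize a token with simple suffix rules.

    Handles regular English plurals (-s, -es, -ies) only; words ending in
    -ss/-us/-is are left alone (``pelvis``, ``talus``).
    """
    w = word.lower()
    if w in _IRREGULAR_LEMMAS:
        return _IRREGULAR_LEMMAS[w]
    if len(w) > 4 and w.endswith("ies"):
        return w[:-3] + "y"
    if len(w) > 3 and (
        w.endswith("ses") or w.endswith("xes") or w.endswith("ches") or w.endswith("shes")
    ):
        return w[:-2]
    if len(w) > 3 and w.endswith("s") and not (
        w.endswith("ss") or w.endswith("us") or w.endswith("is")
    ):
        return w[:-1]
    return w


@dataclass(frozen=True)
class Lexicon:
    """Surface-form lexicons shared by every pipeline stage."""

    laterality_terms: dict[str, str]
    view_terms: frozenset[str]
    stopwords: frozenset[str]
    order_part_synonyms: dict[str, tuple[str, ...]]
    heading_cues: tuple[str, ...]
    _heading_res: tuple[re.Pattern, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        required = {"lt", "rt", "left", "right", "bilateral"}
        missing = required - {k.lower() for k in self.laterality_terms}
        if missing:
            raise ValueError(f"laterality_terms missing required forms: {sorted(missing)}")
        for phrase, keys in self.order_part_synonyms.items():
            if not keys:
                raise ValueError(f"order_part_synonyms[{phrase!r}] is empty")
        object.__setattr__(
            self, "_heading_res", tuple(re.compile(c) for c in self.heading_cues)
        )

    @property
    def anatomy_keys(self) -> frozenset[str]:
        return frozenset(k for keys in self.order_part_synonyms.values() for k in keys)

    def side_of(self, token: str) -> Optional[str]:
        """Side meaning of a token, or None if it is not a laterality term."""
        return self.laterality_terms.get(token.lower().rstrip("."))

    def is_heading(self, line: str) -> bool:
        return any(r.search(line) for r in self._heading_res)

    @classmethod
    def from_dict(cls, d: dict) -> "Lexicon":
        return cls(
            laterality_terms={k.lower(): v for k, v in d["laterality_terms"].items()},
            view_terms=frozenset(t.lower() for t in d["view_terms"]),
            stopwords=frozenset(w.lower() for w in d["stopwords"]),
            order_part_synonyms={
                k.lower(): tuple(v) for k, v in d["order_part_synonyms"].items()
            },
            heading_cues=tuple(d["heading_cues"]),
        )

    @classmethod
    def from_json(cls, path) -> "Lexicon":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def load_default_lexicon() -> Lexicon:
    text = resources.files("latscreen.data").joinpath("lexicon.json").read_text("utf-8")
    return Lexicon.from_dict(json.loads(text))


@dataclass(frozen=True)
class Order:
    """A parsed medical order: anatomy keys plus the ordered side."""

    raw_text: str
    parts: frozenset[str]
    side: str  # left | right | bilateral | unspecified

    def render(self) -> str:
        """Canonical view-stripped form, e.g. ``"right knee"``."""
        side = "" if self.side == UNSPECIFIED else self.side + " "
        return side + ", ".join(sorted(self.parts))


@dataclass
class Study:
    study_id: str
    orders: list[Order]
    report_text: str
    gold_positive: Optional[bool] = None
    site: Optional[str] = None

    def __post_init__(self):
        if not self.orders:
            raise ValueError(f"study {self.study_id}: at least one order required")

    @property
    def combined(self) -> bool:
        return len(self.orders) > 1


@dataclass
class Paragraph:
    heading: Optional[str]
    heading_line: Optional[int]  # 1-based
    body: list[tuple[int, str]]  # (1-based line number, text)


@dataclass
class SegmentedReport:
    paragraphs: list[Paragraph]

    def lines(self) -> list[tuple[int, str]]:
        out = []
        for p in self.paragraphs:
            if p.heading is not None:
                out.append((p.heading_line, p.heading))
            out.extend(p.body)
        return sorted(out)


@dataclass(frozen=True)
class Token:
    text: str
    lemma: str
    line: int  # 1-based
    start: int  # char offset within the line
    is_laterality: bool
    side: Optional[str]
    is_stopword: bool


def tokenize_normalize(text: str, lexicon: Lexicon) -> list[Token]:
    """Tokenize a (possibly multi-line) text into lemmatized tokens.

    Laterality tagging is case-insensitive; stopwords are flagged but kept so
    that positional windows can be computed over non-stopword lemmas.
    """
    tokens: list[Token] = []
    for lineno, line in enumerate(text.split("\n"), start=1):
        for m in _WORD_RE.finditer(line):
            word = m.group(0)
            side = lexicon.side_of(word)
            lemma = word.lower() if side is not None else lemmatize(word)
            tokens.append(
                Token(
                    text=word,
                    lemma=lemma,
                    line=lineno,
                    start=m.start(),
                    is_laterality=side is not None,
                    side=side,
                    is_stopword=lemma in lexicon.stopwords,
                )
            )
    return tokens


def _match_parts(lemmas: list[str], lexicon: Lexicon) -> set[str]:
    """Greedy longest-phrase match of anatomy synonyms over a lemma list."""
    parts: set[str] = set()
    maxlen = max((len(p.split()) for p in lexicon.order_part_synonyms), default=1)
    i = 0
    while i < len(lemmas):
        matched = False
        for n in range(min(maxlen, len(lemmas) - i), 0, -1):
            phrase = " ".join(lemmas[i : i + n])
            if phrase in lexicon.order_part_synonyms:
                parts.update(lexicon.order_part_synonyms[phrase])
                i += n
                matched = True
                break
        if not matched:
            i += 1
    return parts


def _sides_to_order_side(sides: set[str]) -> str:
    if BILATERAL in sides or {LEFT, RIGHT} <= sides:
        return BILATERAL
    if LEFT in sides:
        return LEFT
    if RIGHT in sides:
        return RIGHT
    return UNSPECIFIED


def parse_order(text: str, lexicon: Lexicon) -> Order:
    """Parse one order: strip views, pull the side, expand anatomy synonyms.

    Raises :class:`UnparseableOrderError` when no anatomy phrase is found.
    """
    if not text or not text.strip():
        raise UnparseableOrderError(text)
    cleaned = re.sub(r"[+/]", " ", text)
    toks = tokenize_normalize(cleaned, lexicon)
    sides = {t.side for t in toks if t.is_laterality}
    lemmas = [
        t.lemma for t in toks if not t.is_laterality and t.lemma not in lexicon.view_terms
    ]
    parts = _match_parts(lemmas, lexicon)
    if not parts:
        raise UnparseableOrderError(text)
    return Order(raw_text=text, parts=frozenset(parts), side=_sides_to_order_side(sides))


def parse_heading(heading: str, lexicon: Lexicon) -> list[tuple[frozenset[str], str]]:
    """Split a heading into conjunct segments of (anatomy parts, side).

    ``"Chest PA view and left shoulder AP view shows:"`` yields
    ``[({chest}, unspecified), ({shoulder}, left)]``.  Segments with no
    recognizable anatomy are dropped.
    """
    text = heading.strip()
    text = re.sub(r":\s*$", "", text)
    text = re.sub(r"\bshows?\s*$", "", text, flags=re.IGNORECASE)
    segments = re.split(r",|;|\band\b", text, flags=re.IGNORECASE)
    out: list[tuple[frozenset[str], str]] = []
    for seg in segments:
        if not seg.strip():
            continue
        cleaned = re.sub(r"[+/]", " ", seg)
        toks = tokenize_normalize(cleaned, lexicon)
        sides = {t.side for t in toks if t.is_laterality}
        lemmas = [
            t.lemma
            for t in toks
            if not t.is_laterality and t.lemma not in lexicon.view_terms
        ]
        parts = _match_parts(lemmas, lexicon)
        if parts:
            out.append((frozenset(parts), _sides_to_order_side(sides)))
    return out


def segment_report(text: str, lexicon: Lexicon) -> SegmentedReport:
    """Split a report into paragraphs on colon-terminated headings.

    A line matching a heading cue opens a new paragraph and becomes its
    heading; lines before any heading form a heading-less preamble.  A blank
    line closes the current paragraph, so material following it (without a
    new heading) forms a fresh heading-less paragraph — free-text reports use
    vertical whitespace as their only other segmentation signal.
    """
    if not text:
        raise ValueError("cannot segment empty text")
    paragraphs: list[Paragraph] = []
    cur: Optional[Paragraph] = None
    closed = False
    for i, line in enumerate(text.split("\n"), start=1):
        if lexicon.is_heading(line):
            cur = Paragraph(heading=line, heading_line=i, body=[])
            paragraphs.append(cur)
            closed = False
        elif not line.strip():
            if cur is None:
                cur = Paragraph(None, None, [])
                paragraphs.append(cur)
            cur.body.append((i, line))
            closed = True
        else:
            if cur is None or closed:
                cur = Paragraph(None, None, [])
                paragraphs.append(cur)
                closed = False
            cur.body.append((i, line))
    return SegmentedReport(paragraphs=paragraphs)
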