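"""Dictionary look-up laterality checking.

The expert ruleset maps each anatomy key to the finding terms its images can
legitimately show (``knee -> femur, tibia, patella, ...``); a term may appear
under several keys (``fibula`` under both ``knee`` and ``leg``).  A paragraph's
*scope* is the set of ``(anatomy key, allowed sides)`` pairs derived either
from its validated heading or, for heading-less paragraphs, from all orders.
A sided finding mention is valid iff some scope entry both knows the term and
allows the side; inherently bilateral parts (a chest film shows both
clavicles) allow either side regardless of the ordered side.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Union

from .lexicon import (
    BILATERAL,
    LEFT,
    RIGHT,
    UNSPECIFIED,
    Lexicon,
    Order,
    parse_heading,
)

HEADING_VS_ORDER = "heading_vs_order"
FINDING_VS_SCOPE = "finding_vs_scope"
WITHIN_REPORT = "within_report"


@dataclass(frozen=True)
class ExpertRuleSet:
    rules: dict[str, tuple[str, ...]]
    bilateral_parts: frozenset[str]
    workaround_patterns: tuple[tuple[str, str], ...] = ()
    _term_index: dict[str, frozenset[str]] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        index: dict[str, set[str]] = {}
        for key, terms in self.rules.items():
            if not terms:
                raise ValueError(f"rules[{key!r}] is empty")
            for t in terms:
                if t != t.lower():
                    raise ValueError(f"rule term not lowercase: {t!r}")
                index.setdefault(t, set()).add(key)
        object.__setattr__(
            self, "_term_index", {t: frozenset(ks) for t, ks in index.items()}
        )

    def keys_for_term(self, term: str) -> frozenset[str]:
        return self._term_index.get(term, frozenset())

    def knows_term(self, term: str) -> bool:
        return term in self._term_index

    @classmethod
    def from_dict(cls, d: dict) -> "ExpertRuleSet":
        return cls(
            rules={k: tuple(v) for k, v in d["rules"].items()},
            bilateral_parts=frozenset(d.get("bilateral_parts", [])),
            workaround_patterns=tuple(
                (w["pattern"], w["replacement"]) for w in d.get("workarounds", [])
            ),
        )

    @classmethod
    def from_json(cls, path) -> "ExpertRuleSet":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "rules": {k: list(v) for k, v in self.rules.items()},
            "bilateral_parts": sorted(self.bilateral_parts),
            "workarounds": [
                {"pattern": p, "replacement": r} for p, r in self.workaround_patterns
            ],
        }


def load_default_ruleset() -> ExpertRuleSet:
    text = resources.files("latscreen.data").joinpath("rules.json").read_text("utf-8")
    return ExpertRuleSet.from_dict(json.loads(text))


@dataclass(frozen=True)
class Scope:
    """Anatomy keys in force for a paragraph with their permissible sides."""

    entries: tuple[tuple[str, frozenset[str]], ...]
    source: str  # "heading" | "all-orders"

    def allows(self, key: str, side: str) -> bool:
        return any(k == key and side in sides for k, sides in self.entries)


@dataclass(frozen=True)
class ErrorFlag:
    line: int  # 1-based
    kind: str  # heading_vs_order | finding_vs_scope | within_report
    side: str  # left | right
    message: str
    finding_term: Optional[str] = None
    evidence: tuple[tuple[str, frozenset[str]], ...] = ()

    def __post_init__(self):
        if self.kind == HEADING_VS_ORDER and self.finding_term is not None:
            raise ValueError("heading_vs_order flags carry no finding term")


@dataclass(frozen=True)
class Prediction:
    study_id: str
    positive: bool
    flags: tuple[ErrorFlag, ...]

    def __post_init__(self):
        if self.positive != bool(self.flags):
            raise ValueError("positive must mirror flag presence")


def apply_workarounds(text: str, ruleset: ExpertRuleSet) -> str:
    """Rewrite nonstandard phrasings line by line.

    Each pattern is applied within single lines only, so line count and
    numbering are preserved (inverted ``"genuvarum, Rt."`` becomes
    ``"Rt genu varum"`` on the same line).
    """
    if not ruleset.workaround_patterns:
        return text
    lines = text.split("\n")
    out = []
    for line in lines:
        for pattern, repl in ruleset.workaround_patterns:
            line = re.sub(pattern, repl, line)
        out.append(line)
    return "\n".join(out)


def _order_sides(order: Order, part: str, ruleset: ExpertRuleSet) -> frozenset[str]:
    if part in ruleset.bilateral_parts or order.side in (BILATERAL, UNSPECIFIED):
        return frozenset({LEFT, RIGHT})
    return frozenset({order.side})


def all_orders_scope(orders: list[Order], ruleset: ExpertRuleSet) -> Scope:
    entries: dict[str, set[str]] = {}
    for order in orders:
        for part in order.parts:
            entries.setdefault(part, set()).update(_order_sides(order, part, ruleset))
    return Scope(
        entries=tuple(sorted((k, frozenset(v)) for k, v in entries.items())),
        source="all-orders",
    )


def validate_heading(
    heading: str,
    orders: list[Order],
    ruleset: ExpertRuleSet,
    lexicon: Lexicon,
    heading_line: int = 0,
) -> Union[Scope, ErrorFlag]:
    """Check a paragraph heading against the orders.

    Every sided, non-bilateral part named by the heading must be backed by an
    order for that part whose side permits it; otherwise the heading itself is
    a laterality error (e.g. a "right shoulder" heading when only a left
    shoulder was ordered).  A heading naming no recognizable anatomy falls
    back to the all-orders scope.
    """
    segments = parse_heading(heading, lexicon)
    if not segments:
        return all_orders_scope(orders, ruleset)

    entries: dict[str, set[str]] = {}
    for parts, side in segments:
        for part in parts:
            matching = [o for o in orders if part in o.parts]
            if part in ruleset.bilateral_parts:
                entries.setdefault(part, set()).update({LEFT, RIGHT})
                continue
            if side in (LEFT, RIGHT):
                permitted = any(
                    o.side == side or o.side in (BILATERAL, UNSPECIFIED)
                    for o in matching
                )
                if not permitted:
                    ordered = sorted(
                        {f"{o.side} {p}" for o in orders for p in o.parts}
                    )
                    return ErrorFlag(
                        line=heading_line,
                        kind=HEADING_VS_ORDER,
                        side=side,
                        message=(
                            f"heading names {side} {part} but orders specify: "
                            + "; ".join(ordered)
                        ),
                        evidence=tuple(
                            (p, _order_sides(o, p, ruleset))
                            for o in orders
                            for p in o.parts
                        ),
                    )
                entries.setdefault(part, set()).add(side)
            else:
                sides: set[str] = set()
                for o in matching:
                    sides.update(_order_sides(o, part, ruleset))
                entries.setdefault(part, set()).update(sides or {LEFT, RIGHT})
    return Scope(
        entries=tuple(sorted((k, frozenset(v)) for k, v in entries.items())),
        source="heading",
    )


def check_finding(
    term: str, side: str, scope: Scope, ruleset: ExpertRuleSet, line: int = 0
) -> Optional[ErrorFlag]:
    """Validate one sided finding mention against the paragraph scope.

    Returns None when valid.  Terms absent from every rule value never flag:
    unknown vocabulary is treated as out of the checker's competence, which
    keeps precision high on heavily imbalanced data.
    """
    if side not in (LEFT, RIGHT):
        return None
    keys = ruleset.keys_for_term(term)
    if not keys:
        return None
    for key, sides in scope.entries:
        if key in keys and side in sides:
            return None
    return ErrorFlag(
        line=line,
        kind=FINDING_VS_SCOPE,
        side=side,
        finding_term=term,
        message=(
            f"{side} {term!s} is not reportable under scope "
            + "; ".join(f"{k}:{'/'.join(sorted(s))}" for k, s in scope.entries)
        ),
        evidence=scope.entries,
    )
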