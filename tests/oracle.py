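"""Brute-force laterality checker used as an independent test oracle.

Re-derives the screening semantics with naive nested loops and regexes:
paragraphs are rebuilt line by line, every heading (part, side) claim is
checked against every order, and every (finding lemma, side word, scope
entry) triple is enumerated directly against the rules dictionary.  Shares
only the data containers with the streaming implementation.
"""

from __future__ import annotations

import re

from latscreen import ExpertRuleSet, Lexicon, Study, lemmatize

_WORD = re.compile(r"[A-Za-z][A-Za-z\-']*")


def _words(text: str) -> list[str]:
    return _WORD.findall(text)


def _side_of(word: str, lexicon: Lexicon):
    return lexicon.laterality_terms.get(word.lower().rstrip("."))


def _heading_claims(heading: str, lexicon: Lexicon):
    """(part, side) claims of a heading, one segment per conjunct."""
    text = re.sub(r":\s*$", "", heading.strip())
    text = re.sub(r"\bshows?\s*$", "", text, flags=re.I)
    claims = []
    for seg in re.split(r",|;|\band\b", text, flags=re.I):
        lemmas, side = [], "unspecified"
        for w in _words(re.sub(r"[+/]", " ", seg)):
            s = _side_of(w, lexicon)
            if s is not None:
                side = s if side == "unspecified" else "bilateral"
            elif lemmatize(w) not in lexicon.view_terms:
                lemmas.append(lemmatize(w))
        parts = set()
        i = 0
        while i < len(lemmas):
            hit = None
            for n in (3, 2, 1):
                phrase = " ".join(lemmas[i : i + n])
                if phrase in lexicon.order_part_synonyms:
                    hit = lexicon.order_part_synonyms[phrase]
                    i += n
                    break
            if hit is None:
                i += 1
            else:
                parts.update(hit)
        if parts:
            claims.append((parts, side))
    return claims


def _scope_of_orders(orders, ruleset: ExpertRuleSet):
    scope = {}
    for o in orders:
        for part in o.parts:
            if part in ruleset.bilateral_parts or o.side in ("bilateral", "unspecified"):
                sides = {"left", "right"}
            else:
                sides = {o.side}
            scope.setdefault(part, set()).update(sides)
    return scope


def _term_ok(term, side, scope, ruleset):
    known = any(term in terms for terms in ruleset.rules.values())
    if not known:
        return True
    for part, sides in scope.items():
        if term in ruleset.rules.get(part, ()) and side in sides:
            return True
    return False


def brute_force_flags(
    study: Study, ruleset: ExpertRuleSet, lexicon: Lexicon
) -> set[tuple[int, str, str]]:
    """Set of (line, kind, side) the rules imply, by exhaustive enumeration."""
    text = study.report_text
    for pattern, repl in ruleset.workaround_patterns:
        text = "\n".join(re.sub(pattern, repl, ln) for ln in text.split("\n"))

    # paragraph reconstruction: heading lines open paragraphs, blank lines close
    paragraphs, cur, closed = [], None, False
    for i, line in enumerate(text.split("\n"), start=1):
        if re.search(r":\s*$", line):
            cur = {"heading": (i, line), "body": []}
            paragraphs.append(cur)
            closed = False
        elif not line.strip():
            closed = True
        else:
            if cur is None or closed:
                cur = {"heading": None, "body": []}
                paragraphs.append(cur)
                closed = False
            cur["body"].append((i, line))

    flags = set()
    base_scope = _scope_of_orders(study.orders, ruleset)
    for para in paragraphs:
        scope = base_scope
        if para["heading"] is not None:
            hline, htext = para["heading"]
            claims = _heading_claims(htext, lexicon)
            invalid = False
            entries = {}
            for parts, side in claims:
                for part in parts:
                    if part in ruleset.bilateral_parts:
                        entries.setdefault(part, set()).update({"left", "right"})
                        continue
                    same = [o for o in study.orders if part in o.parts]
                    if side in ("left", "right"):
                        if not any(
                            o.side in (side, "bilateral", "unspecified") for o in same
                        ):
                            flags.add((hline, "heading_vs_order", side))
                            invalid = True
                        else:
                            entries.setdefault(part, set()).add(side)
                    else:
                        got = set()
                        for o in same:
                            got.update(
                                {"left", "right"}
                                if o.side in ("bilateral", "unspecified")
                                else {o.side}
                            )
                        entries.setdefault(part, set()).update(got or {"left", "right"})
            if invalid:
                continue
            scope = entries if claims else base_scope
        for lineno, line in para["body"]:
            for sent in re.split(r"[.;:]", line):
                ws = _words(sent)
                sides = [
                    (j, _side_of(w, lexicon))
                    for j, w in enumerate(ws)
                    if _side_of(w, lexicon) is not None
                ]
                if not any(s in ("left", "right") for _, s in sides):
                    continue
                for j, w in enumerate(ws):
                    if _side_of(w, lexicon) is not None:
                        continue
                    lemma = lemmatize(w)
                    if lemma in lexicon.stopwords:
                        continue
                    _, side = min(sides, key=lambda ps: abs(ps[0] - j))
                    if side in ("left", "right") and not _term_ok(
                        lemma, side, scope, ruleset
                    ):
                        flags.add((lineno, "finding_vs_scope", side))
    return flags
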