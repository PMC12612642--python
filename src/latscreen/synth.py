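"""Seeded synthetic radiographic studies and laterality-error injectors.

Hospital report corpora cannot be redistributed, so this module emulates
their shape: studies with one or more view-bearing orders, free-text English
reports in several reporting styles (colon-terminated headings per order,
merged combined paragraphs, heading-less notes, inverted ``"term, Rt."``
phrasing, plural findings, contralateral comparison sentences), a
configurable combined fraction, and a low default error prevalence.  Error
injection follows two schemes: a single uniformly chosen side-word reversal
(balanced test-set construction) and an alternating reversal of every second
side word (training-data augmentation for contradiction models).

The template bank is co-designed with the packaged expert rules: every sided
finding line carries at least one term unique to its anatomy key, so a
single injected flip in a *core-style* report is always detectable by the
packaged ruleset; clean renders never flag.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

from .lexicon import Lexicon, Order, Study, load_default_lexicon, parse_order

_FLIP_RE = re.compile(r"(?i)\b(lt|rt|left|right)\b")
_SWAP = {"lt": "rt", "rt": "lt", "left": "right", "right": "left"}

CORE_STYLES = ("headed", "merged", "noheading", "inverted", "plural")
ALL_STYLES = CORE_STYLES + ("contralateral",)


class NotInjectableError(ValueError):
    """Report contains no reversible laterality token."""


def _match_case(template: str, word: str) -> str:
    if template.isupper():
        return word.upper()
    if template[0].isupper():
        return word.capitalize()
    return word


def flip_token(report: str, index: int) -> str:
    """Reverse the side of the ``index``-th (0-based) laterality token."""
    matches = list(_FLIP_RE.finditer(report))
    if not matches:
        raise NotInjectableError("no laterality token to flip")
    if not 0 <= index < len(matches):
        raise IndexError(f"token index {index} out of range (n={len(matches)})")
    m = matches[index]
    swapped = _match_case(m.group(0), _SWAP[m.group(0).lower()])
    return report[: m.start()] + swapped + report[m.end() :]


def inject_single_flip(report: str, rng_seed: int) -> tuple[str, int]:
    """Reverse one uniformly chosen occurrence of Lt/left/Rt/right.

    The swap preserves the case pattern of the original token; everything
    else is byte-identical.  Returns the patched report and the 0-based
    index of the flipped occurrence.
    """
    matches = list(_FLIP_RE.finditer(report))
    if not matches:
        raise NotInjectableError("no laterality token to flip")
    idx = int(np.random.default_rng(rng_seed).integers(len(matches)))
    return flip_token(report, idx), idx


def inject_alternating(report: str) -> str:
    """Reverse laterality occurrences 1, 3, 5, ... (1-based reading order)."""
    matches = list(_FLIP_RE.finditer(report))
    if not matches:
        raise NotInjectableError("no laterality token to flip")
    out = []
    pos = 0
    for i, m in enumerate(matches):
        out.append(report[pos : m.start()])
        word = m.group(0)
        out.append(_match_case(word, _SWAP[word.lower()]) if i % 2 == 0 else word)
        pos = m.end()
    out.append(report[pos:])
    return "".join(out)


# --------------------------------------------------------------------------
# template bank

# Sided finding templates; "{Side}"/"{side}" expand to e.g. "Left"/"left".
# Every line contains an anchor term unique to its key in the packaged rules.
_SIDED_TEMPLATES: dict[str, list[str]] = {
    "ankle": [
        "Fracture of the {side} medial malleolus.",
        "{Side} ankle joint effusion.",
        "Soft tissue swelling of the {side} ankle.",
    ],
    "calcaneus": [
        "{Side} calcaneus plantar spur.",
        "No displaced fracture of the {side} calcaneus.",
    ],
    "clavicle": [
        "Fracture of the {side} clavicle middle third.",
        "{Side} clavicle fracture with callus formation.",
    ],
    "elbow": [
        "{Side} elbow joint effusion.",
        "Fracture of the {side} olecranon.",
    ],
    "femur": [
        "Fracture of the {side} femoral shaft.",
        "{Side} femoral shaft fracture with angulation.",
    ],
    "finger": [
        "Fracture of the {side} fifth finger.",
        "{Side} finger flexion deformity.",
    ],
    "foot": [
        "Fracture of the {side} foot fifth metatarsal.",
        "{Side} hallux valgus deformity.",
    ],
    "forearm": [
        "Fracture of the {side} forearm.",
        "{Side} forearm plate and screw fixation.",
    ],
    "hand": [
        "Fracture of the {side} hand fifth metacarpal.",
        "{Side} hand fifth metacarpal base fracture.",
    ],
    "hip": [
        "{Side} hip joint space narrowing.",
        "Fracture of the {side} acetabulum.",
    ],
    "humerus": [
        "Fracture of the {side} humeral shaft.",
        "{Side} humerus greater tuberosity fracture.",
    ],
    "knee": [
        "{Side} knee joint effusion.",
        "Fracture of the {side} patella.",
        "{Side} genu varum deformity.",
        "Osteoarthritis of the {side} knee.",
    ],
    "leg": [
        "Fracture of the {side} leg.",
        "Tibial shaft fracture of the {side} leg.",
    ],
    "lower limb": [
        "Fracture of the {side} lower limb.",
    ],
    "scapula": [
        "Fracture of the {side} scapula body.",
        "{Side} scapula fracture without displacement.",
    ],
    "shoulder": [
        "{Side} shoulder joint effusion.",
        "Dislocation of the {side} shoulder.",
        "{Side} acromioclavicular joint widening.",
    ],
    "temporomandibular joint": [
        "Flattening of the {side} temporomandibular condyle.",
    ],
    "wrist": [
        "Fracture of the {side} scaphoid.",
        "{Side} wrist joint space narrowing.",
    ],
}

# Plural-style variants (regular plurals the lemmatizer resolves).
_PLURAL_TEMPLATES: dict[str, str] = {
    key: "Old healed fractures of the {side} " + key + "."
    for key in _SIDED_TEMPLATES
}
_PLURAL_TEMPLATES["foot"] = "Old healed fractures of the {side} metatarsals."
_PLURAL_TEMPLATES["hand"] = "Old healed fractures of the {side} metacarpals."

# Inverted nonstandard phrasings, normalized by the packaged workarounds.
_INVERTED_TEMPLATES: dict[str, str] = {
    "ankle": "Medial malleolus fracture, {Ab}.",
    "calcaneus": "Calcaneus fracture, {Ab}.",
    "clavicle": "Clavicle fracture, {Ab}.",
    "elbow": "Olecranon fracture, {Ab}.",
    "femur": "Femoral shaft fracture, {Ab}.",
    "finger": "Fifth finger fracture, {Ab}.",
    "foot": "Foot fifth metatarsal fracture, {Ab}.",
    "forearm": "Forearm fracture, {Ab}.",
    "hand": "Hand fifth metacarpal fracture, {Ab}.",
    "hip": "Acetabulum fracture, {Ab}.",
    "humerus": "Humeral shaft fracture, {Ab}.",
    "knee": "Genuvarum, {Ab}.",
    "leg": "Leg fracture, {Ab}.",
    "lower limb": "Lower limb fracture, {Ab}.",
    "scapula": "Scapula fracture, {Ab}.",
    "shoulder": "Acromion fracture, {Ab}.",
    "temporomandibular joint": "Temporomandibular condyle flattening, {Ab}.",
    "wrist": "Scaphoid fracture, {Ab}.",
}

# Findings for inherently bilateral parts carry no laterality token.
_BILATERAL_TEMPLATES: dict[str, list[str]] = {
    "abdomen": ["Nonspecific bowel gas pattern.", "No evidence of ileus."],
    "chest": [
        "No active lung lesion.",
        "Mild cardiomegaly.",
        "No definite pneumothorax.",
    ],
    "cervical spine": [
        "Straightening of the cervical spine curvature.",
        "Mild cervical spondylosis.",
    ],
    "coccyx": ["No displaced coccyx fracture."],
    "lumbar spine": ["Mild lumbar spondylosis.", "Preserved disc height."],
    "neck": ["Patent airway.", "Unremarkable prevertebral soft tissue."],
    "pelvis": [
        "No definite fracture of the pelvis.",
        "Degenerative change of the symphysis pubis.",
    ],
    "sacrum": ["No definite sacrum fracture."],
    "skull": ["No definite skull fracture."],
    "thoracic spine": ["Mild compression deformity.", "Normal alignment."],
}

# Chest uses posteroanterior; everything else anteroposterior.
_VIEWS = {"chest": "posteroanterior"}

# Clavicle findings are also explainable by chest or shoulder films, so a
# flip there would be undetectable; the sampler keeps them apart.  Likewise
# "leg" findings are covered by a lower-limb film.
_PART_CONFLICTS = {
    "clavicle": {"chest", "shoulder"},
    "chest": {"clavicle"},
    "shoulder": {"clavicle"},
    "leg": {"lower limb"},
    "lower limb": {"leg"},
}


def load_default_part_frequencies() -> dict[str, float]:
    text = resources.files("latscreen.data").joinpath(
        "part_frequencies.json"
    ).read_text("utf-8")
    return json.loads(text)


@dataclass
class GeneratorConfig:
    """Study-generator settings.

    Defaults emulate the corpus shape of a multisite radiographic archive:
    70% combined studies, ~1.95 orders per study, anatomy frequencies from a
    real-world distribution, and 1.2% error prevalence.
    """

    n_studies: int = 100
    seed: int = 0
    combined_fraction: float = 0.7
    orders_per_study_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.30, 2: 0.505, 3: 0.15, 4: 0.03, 5: 0.015}
    )
    part_frequencies: Optional[dict[str, float]] = None
    style_mix: dict[str, float] = field(
        default_factory=lambda: {
            "headed": 0.40,
            "merged": 0.20,
            "noheading": 0.15,
            "inverted": 0.10,
            "plural": 0.10,
            "contralateral": 0.05,
        }
    )
    error_rate: float = 0.012

    def __post_init__(self):
        if not 0 <= self.combined_fraction <= 1:
            raise ValueError("combined_fraction must be in [0,1]")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be in [0,1]")
        for name, dist in (
            ("orders_per_study_distribution", self.orders_per_study_distribution),
            ("style_mix", self.style_mix),
        ):
            total = sum(dist.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"{name} must sum to 1 (got {total})")
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"{name} has negative probability")
        unknown = set(self.style_mix) - set(ALL_STYLES)
        if unknown:
            raise ValueError(f"unknown styles: {sorted(unknown)}")


@dataclass
class LabeledStudy:
    study: Study
    gold_positive: bool
    injected_token_index: Optional[int] = None
    style: str = ""

    def __post_init__(self):
        if self.gold_positive != (self.injected_token_index is not None):
            raise ValueError("gold_positive must mirror injection bookkeeping")


def _sample_dist(rng: np.random.Generator, dist: dict) -> object:
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


class StudyGenerator:
    """Seeded generator of rule-consistent synthetic studies."""

    def __init__(self, config: GeneratorConfig, lexicon: Optional[Lexicon] = None):
        self.config = config
        self.lexicon = lexicon or load_default_lexicon()
        self.part_frequencies = (
            config.part_frequencies or load_default_part_frequencies()
        )
        self.sided_parts = [
            p for p in self.part_frequencies if p in _SIDED_TEMPLATES
        ]
        self.bilateral_parts = [
            p for p in self.part_frequencies if p in _BILATERAL_TEMPLATES
        ]
        missing = set(self.part_frequencies) - set(_SIDED_TEMPLATES) - set(
            _BILATERAL_TEMPLATES
        )
        if missing:
            raise ValueError(f"no templates for parts: {sorted(missing)}")

    # -- sampling --------------------------------------------------------

    def _sample_parts(self, rng: np.random.Generator, n: int) -> list[str]:
        parts: list[str] = []
        names = list(self.part_frequencies.keys())
        probs = np.array([self.part_frequencies[p] for p in names])
        probs = probs / probs.sum()
        guard = 0
        while len(parts) < n and guard < 200:
            guard += 1
            p = names[int(rng.choice(len(names), p=probs))]
            if p in parts:
                continue
            if any(p in _PART_CONFLICTS.get(q, ()) for q in parts):
                continue
            parts.append(p)
        # guarantee at least one sided part so the report is injectable
        if all(p in _BILATERAL_TEMPLATES for p in parts):
            candidates = [
                p
                for p in self.sided_parts
                if p not in parts
                and not any(p in _PART_CONFLICTS.get(q, ()) for q in parts)
            ]
            parts[-1] = candidates[int(rng.integers(len(candidates)))]
        return parts

    def _order_text(self, part: str, side: Optional[str]) -> str:
        view = _VIEWS.get(part, "anteroposterior")
        title = part.capitalize() if side is None else part
        if side is None:
            return f"{title} {view} view"
        ab = {"left": "Lt", "right": "Rt"}[side]
        return f"{ab} {part} {view}+lateral view"

    def _heading_phrase(self, part: str, side: Optional[str]) -> str:
        view = _VIEWS.get(part, "anteroposterior")
        if side is None:
            return f"{part.capitalize()} {view} view"
        return f"{side.capitalize()} {part} {view} view"

    def _finding_lines(
        self, rng: np.random.Generator, part: str, side: Optional[str], style: str
    ) -> list[str]:
        if side is None:
            pool = _BILATERAL_TEMPLATES[part]
            k = 1 + int(rng.integers(2)) if len(pool) > 1 else 1
            picks = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
            return [pool[int(i)] for i in sorted(picks)]
        if style == "plural":
            return [
                _PLURAL_TEMPLATES[part].format(
                    side=side, Side=side.capitalize()
                )
            ]
        if style == "inverted":
            ab = {"left": "Lt", "right": "Rt"}[side]
            return [_INVERTED_TEMPLATES[part].format(Ab=ab)]
        pool = _SIDED_TEMPLATES[part]
        k = 1 + int(rng.integers(2)) if len(pool) > 1 else 1
        picks = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
        return [
            pool[int(i)].format(side=side, Side=side.capitalize())
            for i in sorted(picks)
        ]

    def _render_report(
        self,
        rng: np.random.Generator,
        parts_sides: list[tuple[str, Optional[str]]],
        style: str,
    ) -> str:
        base_style = "headed" if style == "contralateral" else style
        if base_style == "merged" and len(parts_sides) < 2:
            base_style = "headed"
        sections: list[str] = []
        if base_style in ("headed", "plural"):
            for part, side in parts_sides:
                heading = self._heading_phrase(part, side) + " shows:"
                body = self._finding_lines(rng, part, side, base_style)
                sections.append("\n".join([heading] + body))
            report = "\n\n".join(sections)
        elif base_style == "merged":
            heading = (
                " and ".join(self._heading_phrase(p, s) for p, s in parts_sides)
                + " shows:"
            )
            body: list[str] = []
            for part, side in parts_sides:
                body.extend(self._finding_lines(rng, part, side, "headed"))
            report = "\n".join([heading] + body)
        else:  # noheading, inverted
            body = []
            for part, side in parts_sides:
                body.extend(self._finding_lines(rng, part, side, base_style))
            report = "\n".join(body)
        if style == "contralateral":
            sided = [(p, s) for p, s in parts_sides if s is not None]
            part, side = sided[int(rng.integers(len(sided)))]
            opp = _SWAP[side]
            report += (
                f"\n\nSymmetric appearance in comparison with the {opp} side."
            )
        return report

    # -- public API ------------------------------------------------------

    def generate(self, styles: tuple[str, ...] = ALL_STYLES) -> list[LabeledStudy]:
        """Generate ``config.n_studies`` studies, reproducibly from the seed."""
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        mix = {s: p for s, p in cfg.style_mix.items() if s in styles and p > 0}
        if not mix:
            raise ValueError(f"style_mix has no mass on styles {styles}")
        out: list[LabeledStudy] = []
        for i in range(cfg.n_studies):
            combined = bool(rng.random() < cfg.combined_fraction)
            if combined:
                dist = {
                    k: v
                    for k, v in cfg.orders_per_study_distribution.items()
                    if k >= 2 and v > 0
                }
                n_orders = int(_sample_dist(rng, dist)) if dist else 2
            else:
                n_orders = 1
            parts = self._sample_parts(rng, n_orders)
            parts_sides: list[tuple[str, Optional[str]]] = []
            for p in parts:
                if p in _BILATERAL_TEMPLATES:
                    parts_sides.append((p, None))
                else:
                    parts_sides.append((p, ["left", "right"][int(rng.integers(2))]))
            style = str(_sample_dist(rng, mix))
            report = self._render_report(rng, parts_sides, style)
            orders = [
                parse_order(self._order_text(p, s), self.lexicon)
                for p, s in parts_sides
            ]
            study = Study(
                study_id=f"SYN-{cfg.seed}-{i:05d}",
                orders=orders,
                report_text=report,
                gold_positive=False,
            )
            labeled = LabeledStudy(study=study, gold_positive=False, style=style)
            if rng.random() < cfg.error_rate:
                flip_seed = int(rng.integers(2**31))
                patched, idx = inject_single_flip(report, flip_seed)
                study.report_text = patched
                study.gold_positive = True
                labeled.gold_positive = True
                labeled.injected_token_index = idx
            out.append(labeled)
        return out


def generate_studies(config: GeneratorConfig) -> list[LabeledStudy]:
    """Functional wrapper over :class:`StudyGenerator`."""
    return StudyGenerator(config).generate()


def make_balanced_batch(
    n_pairs: int, seed: int, styles: tuple[str, ...] = CORE_STYLES
) -> list[LabeledStudy]:
    """Clean studies paired with their single-flip twins (50/50 classes).

    Core styles only by default: the contralateral-comparison style contains
    a side word that no expert rule constrains, so a flip landing on it is
    undetectable by design and has no place in an injection benchmark.
    """
    cfg = GeneratorConfig(n_studies=n_pairs, seed=seed, error_rate=0.0)
    clean = StudyGenerator(cfg).generate(styles=styles)
    rng = np.random.default_rng(seed + 1)
    out: list[LabeledStudy] = []
    for ls in clean:
        out.append(ls)
        patched, idx = inject_single_flip(
            ls.study.report_text, int(rng.integers(2**31))
        )
        twin = Study(
            study_id=ls.study.study_id + "-flip",
            orders=ls.study.orders,
            report_text=patched,
            gold_positive=True,
        )
        out.append(
            LabeledStudy(
                study=twin, gold_positive=True, injected_token_index=idx, style=ls.style
            )
        )
    return out


def export_sentence_pairs(studies: list[LabeledStudy]) -> list[dict]:
    """Premise/hypothesis records for contradiction-style fine-tuning.

    The premise renders the orders with view information stripped; the
    hypothesis is the report; laterality errors map to ``contradiction``.
    """
    records = []
    for ls in studies:
        premise = "; ".join(o.render() for o in ls.study.orders)
        records.append(
            {
                "study_id": ls.study.study_id,
                "premise": premise,
                "hypothesis": ls.study.report_text,
                "label": "contradiction" if ls.gold_positive else "non-contradiction",
            }
        )
    return records


# --------------------------------------------------------------------------
# canonical fixtures

def combined_example_study() -> Study:
    """The worked combined-report example: chest PA + left shoulder AP.

    Line 2's right clavicle is valid (a chest film shows both clavicles);
    line 4 contradicts the left-shoulder heading above it; the line-5
    heading contradicts the order itself, so line 6 cannot be evaluated; the
    heading-less final line is valid via the chest order.
    """
    lexicon = load_default_lexicon()
    report = "\n".join(
        [
            "Chest posteroanterior view and left shoulder anteroposterior view shows:",
            "Right clavicle fracture.",
            "Left shoulder anteroposterior view shows:",
            "Right clavicle fracture.",
            "Right shoulder anteroposterior view shows:",
            "Right clavicle fracture.",
            "",
            "Right rib fracture.",
        ]
    )
    return Study(
        study_id="EXAMPLE-COMBINED",
        orders=[
            parse_order("Chest posteroanterior view", lexicon),
            parse_order("Lt shoulder anteroposterior view", lexicon),
        ],
        report_text=report,
    )


def plural_mechanism_study() -> Study:
    """Fixture for the terminology-standardization mechanism.

    The report states a right-sided finding on a left-foot film using an
    irregular plural ("phalanges") that the plain lemmatizer cannot map to
    the rule term "phalanx"; only the extraction normalizer resolves it, so
    the study is a false negative without extraction and a true positive
    with it.
    """
    lexicon = load_default_lexicon()
    report = "\n".join(
        [
            "Left foot anteroposterior and oblique view shows:",
            "Osteopenia of the right phalanges.",
        ]
    )
    return Study(
        study_id="EXAMPLE-PLURAL",
        orders=[parse_order("Lt foot anteroposterior+oblique view", lexicon)],
        report_text=report,
        gold_positive=True,
    )
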