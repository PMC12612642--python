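"""JSON-lines input/output for studies and predictions."""

from __future__ import annotations

import json
from typing import Optional

from .lexicon import Lexicon, Study, load_default_lexicon, parse_order
from .rules import Prediction
from .synth import LabeledStudy


def study_from_record(record: dict, lexicon: Lexicon) -> Study:
    """Build a Study from one JSONL record: study_id, orders, report, ..."""
    orders = [parse_order(text, lexicon) for text in record["orders"]]
    return Study(
        study_id=str(record["study_id"]),
        orders=orders,
        report_text=record["report"],
        gold_positive=record.get("gold_positive"),
        site=record.get("site"),
    )


def read_studies_jsonl(path, lexicon: Optional[Lexicon] = None) -> list[Study]:
    lexicon = lexicon or load_default_lexicon()
    studies = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                studies.append(study_from_record(json.loads(line), lexicon))
    return studies


def labeled_study_to_record(ls: LabeledStudy) -> dict:
    record = {
        "study_id": ls.study.study_id,
        "orders": [o.raw_text for o in ls.study.orders],
        "report": ls.study.report_text,
        "gold_positive": bool(ls.gold_positive),
    }
    if ls.injected_token_index is not None:
        record["injected_token_index"] = ls.injected_token_index
    if ls.style:
        record["style"] = ls.style
    return record


def write_studies_jsonl(path, studies: list[LabeledStudy]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ls in studies:
            fh.write(json.dumps(labeled_study_to_record(ls)) + "\n")


def prediction_to_record(pred: Prediction) -> dict:
    return {
        "study_id": pred.study_id,
        "positive": pred.positive,
        "flags": [
            {
                "line": f.line,
                "kind": f.kind,
                "side": f.side,
                "finding_term": f.finding_term,
                "message": f.message,
            }
            for f in pred.flags
        ],
    }


def write_predictions_jsonl(path, preds: list[Prediction]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pred in preds:
            fh.write(json.dumps(prediction_to_record(pred)) + "\n")


def read_predictions_jsonl(path) -> list[dict]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(json.loads(line))
    return out
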