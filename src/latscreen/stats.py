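"""Screening metrics and the comparison statistics for method evaluation.

Report-level screening is a binary classification on heavily imbalanced
data, so the layer reports precision/recall/F1 overall and per subgroup
(combined vs noncombined studies), and implements the comparison procedures
such an evaluation needs: the two-proportion z test (pooled-variance z, Wald
interval on the difference), Pearson chi-square with optional Yates
correction and Cramér V, the Friedman rank test with the Nemenyi post hoc on
method x dataset score grids, Cohen's kappa for interrater agreement, and
the E-value sensitivity bound for unmeasured confounding of an observed
odds ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .lexicon import Study
from .rules import Prediction

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: Optional[float] = None
    df: Optional[float] = None
    effect_size: Optional[float] = None
    ci: Optional[tuple[float, float]] = None

    def __post_init__(self):
        if self.p_value is not None and not 0 <= self.p_value <= 1:
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")
        if self.ci is not None and self.ci[0] > self.ci[1]:
            raise ValueError("ci bounds out of order")


def prf(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall and F1, with the all-zero convention metric = 0."""
    if counts.tp + counts.fp > 0:
        precision = counts.tp / (counts.tp + counts.fp)
    else:
        logger.info("no positive predictions; precision := 0")
        precision = 0.0
    if counts.tp + counts.fn > 0:
        recall = counts.tp / (counts.tp + counts.fn)
    else:
        logger.info("no positive gold labels; recall := 0")
        recall = 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def two_prop_z(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Two-proportion z test.

    z uses the pooled-variance standard error; the 95% CI on the difference
    uses the unpooled (Wald) standard error.  ``effect_size`` holds the raw
    difference p1 - p2.
    """
    if min(n1, n2) <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("event counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    expected = [pooled * n1, (1 - pooled) * n1, pooled * n2, (1 - pooled) * n2]
    if min(expected) <= 10:
        logger.warning("expected events/non-events <= 10; z approximation weak")
    se_pooled = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    diff = p1 - p2
    z = diff / se_pooled if se_pooled > 0 else 0.0
    p = 2 * sps.norm.sf(abs(z))
    se_unpooled = math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    crit = sps.norm.ppf(0.975)
    ci = (diff - crit * se_unpooled, diff + crit * se_unpooled)
    return TestResult(statistic=z, p_value=p, effect_size=diff, ci=ci)


def cramers_v(chi2: float, n: int, r: int, c: int) -> float:
    return math.sqrt(chi2 / (n * (min(r, c) - 1)))


def chi2_test(table, continuity: bool = False) -> TestResult:
    """Pearson chi-square on an r x c table with Cramér V effect size.

    Yates continuity correction applies only to 2x2 tables.  V is computed
    from the uncorrected statistic.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("table must be at least 2x2")
    if (t < 0).any() or t.sum() <= 0:
        raise ValueError("table must be non-negative with positive total")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero marginal row or column")
    correction = bool(continuity) and t.shape == (2, 2)
    chi2, p, df, _ = sps.chi2_contingency(t, correction=correction)
    chi2_raw, _, _, _ = sps.chi2_contingency(t, correction=False)
    v = cramers_v(chi2_raw, int(t.sum()), *t.shape)
    return TestResult(statistic=float(chi2), p_value=float(p), df=df, effect_size=v)


def _average_ranks(scores: np.ndarray) -> np.ndarray:
    """Average rank per method across blocks; rank 1 = highest score."""
    # rank within each dataset column-block; ties share average ranks
    ranks = np.apply_along_axis(sps.rankdata, 0, -scores)
    return ranks.mean(axis=1)


def friedman(scores) -> tuple[TestResult, np.ndarray]:
    """Friedman rank test on a methods x datasets score matrix.

    Returns the test result (Q against chi-square with k-1 df, with tie
    correction) and the average rank per method (1 = best).
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim != 2 or s.shape[0] < 2 or s.shape[1] < 2:
        raise ValueError("need >= 2 methods and >= 2 datasets")
    k, n = s.shape
    ranks = np.apply_along_axis(sps.rankdata, 0, -s)  # k x n, 1 = highest score
    rank_sums = ranks.sum(axis=1)
    q = 12.0 / (n * k * (k + 1)) * (rank_sums**2).sum() - 3 * n * (k + 1)
    # tie correction (Iman-Davenport denominator form)
    ties = 0.0
    for j in range(n):
        _, counts = np.unique(s[:, j], return_counts=True)
        ties += (counts**3 - counts).sum()
    denom = 1 - ties / (n * k * (k**2 - 1))
    if denom > 0:
        q = q / denom
    p = float(sps.chi2.sf(q, k - 1))
    return (
        TestResult(statistic=float(q), p_value=p, df=k - 1),
        ranks.mean(axis=1),
    )


def nemenyi(scores) -> np.ndarray:
    """Nemenyi post hoc pairwise p-values on a methods x datasets matrix.

    Average-rank differences are referred to the studentized range
    distribution with k groups and infinite degrees of freedom; the grid is
    symmetric with unit diagonal.
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim != 2 or s.shape[0] < 2 or s.shape[1] < 2:
        raise ValueError("need >= 2 methods and >= 2 datasets")
    k, n = s.shape
    avg = _average_ranks(s)
    grid = np.ones((k, k))
    scale = math.sqrt(12.0 * n / (k * (k + 1)))
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(avg[i] - avg[j]) * scale
            p = float(np.clip(sps.studentized_range.sf(q, k, np.inf), 0, 1))
            grid[i, j] = grid[j, i] = p
    return grid


def cohen_kappa(table) -> TestResult:
    """Cohen's kappa from a square rater-agreement contingency table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("agreement table must be square")
    total = t.sum()
    if total <= 0:
        raise ValueError("empty agreement table")
    po = np.trace(t) / total
    pe = float((t.sum(axis=0) / total) @ (t.sum(axis=1) / total))
    if pe >= 1.0:
        raise ValueError("undefined kappa: chance agreement is 1")
    kappa = (po - pe) / (1 - pe)
    return TestResult(statistic=float(kappa), effect_size=float(kappa))


def evalue(or_value: float, rare_outcome: bool) -> float:
    """E-value of an observed odds ratio point estimate.

    For a rare outcome (<15%) the OR approximates the risk ratio and is used
    directly; otherwise the square root of the OR is used.  ORs below 1 are
    inverted first.  E = R + sqrt(R * (R - 1)).
    """
    if not or_value > 0:
        raise ValueError("odds ratio must be positive")
    if or_value < 1:
        or_value = 1.0 / or_value
    r = or_value if rare_outcome else math.sqrt(or_value)
    if r < 1:
        r = 1.0
    return r + math.sqrt(r * (r - 1))


def confusion_from_predictions(
    preds: Sequence[Prediction], gold: Sequence[bool]
) -> ConfusionCounts:
    tp = fp = fn = tn = 0
    for pred, g in zip(preds, gold):
        if pred.positive and g:
            tp += 1
        elif pred.positive and not g:
            fp += 1
        elif not pred.positive and g:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


def evaluate_run(
    preds: Sequence[Prediction],
    studies: Sequence[Study],
    gold: Optional[Sequence[bool]] = None,
) -> dict:
    """Metrics overall and per combined/noncombined subgroup.

    ``gold`` defaults to each study's ``gold_positive``; predictions align to
    studies by ``study_id``.
    """
    by_id = {s.study_id: s for s in studies}
    if gold is None:
        gold_map = {}
        for s in studies:
            if s.gold_positive is None:
                raise ValueError(f"study {s.study_id} has no gold label")
            gold_map[s.study_id] = bool(s.gold_positive)
    else:
        gold_map = {s.study_id: bool(g) for s, g in zip(studies, gold)}
    strata: dict[str, ConfusionCounts] = {
        "overall": ConfusionCounts(),
        "combined": ConfusionCounts(),
        "noncombined": ConfusionCounts(),
    }
    for pred in preds:
        study = by_id.get(pred.study_id)
        if study is None or pred.study_id not in gold_map:
            raise ValueError(f"prediction for unknown study {pred.study_id!r}")
        g = gold_map[pred.study_id]
        one = confusion_from_predictions([pred], [g])
        strata["overall"] += one
        strata["combined" if study.combined else "noncombined"] += one
    out = {}
    for name, counts in strata.items():
        precision, recall, f1 = prf(counts)
        out[name] = {
            "counts": {
                "tp": counts.tp,
                "fp": counts.fp,
                "fn": counts.fn,
                "tn": counts.tn,
            },
            "precision": precision,
            "recall": recall,
            "f1": f1,
        }
    return out
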