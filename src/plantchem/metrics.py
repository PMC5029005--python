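"""Evaluation statistics: precision/recall/F1, percent agreement, kappa.

Percentages are reported to one decimal place with half-up rounding, the
convention of the corpus evaluation tables.  Cohen's kappa corrects the
observed agreement p_o for the chance agreement p_e implied by the
annotators' marginals: kappa = (p_o - p_e) / (1 - p_e).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .model import EvalResult, Label

__all__ = [
    "evaluate",
    "prf_from_pr",
    "simple_agreement",
    "cohens_kappa",
    "compare_annotations",
    "AgreementResult",
    "round_pct",
]


def round_pct(value: float, decimals: int = 1) -> float:
    """Half-up rounding to ``decimals`` places (table convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def evaluate(
    predicted: Sequence[Label | str], gold: Sequence[Label | str]
) -> EvalResult:
    """Confusion counts of predicted vs gold POS/NEG labels (aligned lists)."""
    if len(predicted) != len(gold):
        raise ValidationError(
            f"predicted ({len(predicted)}) and gold ({len(gold)}) label lists "
            "differ in length"
        )
    tp = fp = fn = tn = 0
    for p, g in zip(predicted, gold):
        p, g = Label(p), Label(g)
        if p is Label.UNLABELED or g is Label.UNLABELED:
            raise ValidationError("evaluate requires POS/NEG labels only")
        if p is Label.POS:
            if g is Label.POS:
                tp += 1
            else:
                fp += 1
        elif g is Label.POS:
            fn += 1
        else:
            tn += 1
    return EvalResult(tp=tp, fp=fp, fn=fn, tn=tn)


def prf_from_pr(precision_pct: float, recall_pct: float, decimals: int = 1) -> float:
    """F1 (harmonic mean) from precision/recall given as percentages."""
    for v in (precision_pct, recall_pct):
        if not 0 <= v <= 100:
            raise ValidationError(f"percentage {v} outside [0, 100]")
    if precision_pct + recall_pct == 0:
        warnings.warn("P = R = 0; F defined as 0.0", stacklevel=2)
        return 0.0
    f = 2 * precision_pct * recall_pct / (precision_pct + recall_pct)
    return round_pct(f, decimals)


def simple_agreement(agreements: int, disagreements: int, decimals: int = 1) -> float:
    """Percent agreement: agreements / (agreements + disagreements) x 100."""
    if agreements < 0 or disagreements < 0:
        raise ValidationError("counts must be non-negative")
    total = agreements + disagreements
    if total == 0:
        raise ValidationError("agreements and disagreements are both zero")
    return round_pct(100.0 * agreements / total, decimals)


def cohens_kappa(confusion) -> float:
    """Chance-corrected agreement from a square label-by-label matrix.

    Rows index one annotator's labels, columns the other's.  Raises on the
    degenerate case p_e = 1 (both annotators constant on the same label).
    """
    m = np.asarray(confusion, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError("confusion matrix must be square")
    total = m.sum()
    if total <= 0:
        raise ValidationError("confusion matrix has zero total")
    p_o = np.trace(m) / total
    p_e = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / total**2
    if p_e >= 1.0:
        raise ValidationError("kappa undefined: chance agreement p_e = 1")
    return float((p_o - p_e) / (1.0 - p_e))


@dataclass(frozen=True)
class AgreementResult:
    """Agreement between two annotators over aligned items."""

    agreements: int
    disagreements: int
    percent: float
    confusion: tuple[tuple[int, ...], ...] | None = None
    kappa: float | None = None


def compare_annotations(
    labels_a: Sequence[Label | str],
    labels_b: Sequence[Label | str],
    with_kappa: bool = True,
) -> AgreementResult:
    """Percent agreement (and kappa) for two aligned label sequences."""
    if len(labels_a) != len(labels_b):
        raise ValidationError("annotator label lists differ in length")
    if not labels_a:
        raise ValidationError("no items to compare")
    a = [x.value if isinstance(x, Label) else str(x) for x in labels_a]
    b = [x.value if isinstance(x, Label) else str(x) for x in labels_b]
    categories = sorted(set(a) | set(b))
    index = {c: i for i, c in enumerate(categories)}
    m = np.zeros((len(categories), len(categories)), dtype=int)
    for x, y in zip(a, b):
        m[index[x], index[y]] += 1
    agreements = int(np.trace(m))
    disagreements = len(a) - agreements
    kappa = None
    if with_kappa:
        try:
            kappa = cohens_kappa(m)
        except ValidationError:
            kappa = None
    return AgreementResult(
        agreements=agreements,
        disagreements=disagreements,
        percent=simple_agreement(agreements, disagreements),
        confusion=tuple(tuple(int(v) for v in row) for row in m),
        kappa=kappa,
    )
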