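"""Predicting protein loss from mutation annotations, and benchmarking the
predictions against observed abundance.

Two prediction routes exist:

* missense alleles: a precomputed structural-stability change (FoldX total
  energy, kcal/mol) above a destabilization threshold (default
  1.58 kcal/mol) predicts loss;
* truncating alleles (frameshift/nonsense): a nonsense-mediated-decay (NMD)
  annotation predicts loss; NMD-escaping alleles are indeterminate.

Splicing, exon-skip, in-frame deletion, transcriptional-dysregulation and
synonymous-splice alleles have no principled predictor here and map to
``indeterminate`` — never guessed.

The benchmark restricts to missense records with a definite observed-loss
label (yes/no) and reports the confusion counts with sensitivity and
specificity (undefined ratios reported as None rather than 0/0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from sklearn.base import BaseEstimator

from .io import MutationRecord
from .matrix import ValidationError


@dataclass
class StabilityRule:
    """Destabilization threshold on the FoldX total-energy change."""

    ddg_threshold: float = 1.58

    def __post_init__(self) -> None:
        if self.ddg_threshold <= 0:
            raise ValidationError("ddg_threshold must be positive")


@dataclass
class PredictionOutcome:
    predicted_loss: str  # loss | retained | indeterminate
    basis: str  # ddg | nmd_rule | none


@dataclass
class ConfusionSummary:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def sensitivity(self) -> float | None:
        pos = self.tp + self.fn
        return self.tp / pos if pos else None

    @property
    def specificity(self) -> float | None:
        neg = self.tn + self.fp
        return self.tn / neg if neg else None

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "fp": self.fp,
            "tn": self.tn,
            "n": self.n,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def predict_loss(record: MutationRecord, rule: StabilityRule | None = None) -> PredictionOutcome:
    """Predict whether one allele abolishes its protein."""
    rule = rule or StabilityRule()
    if record.consequence == "missense":
        if record.ddg is None:
            return PredictionOutcome("indeterminate", "none")
        if record.ddg > rule.ddg_threshold:
            return PredictionOutcome("loss", "ddg")
        return PredictionOutcome("retained", "ddg")
    if record.consequence in ("frameshift", "nonsense"):
        if record.nmd_annotation == "NMD":
            return PredictionOutcome("loss", "nmd_rule")
        if record.nmd_annotation == "NMD_escaping":
            return PredictionOutcome("indeterminate", "nmd_rule")
        return PredictionOutcome("indeterminate", "none")
    return PredictionOutcome("indeterminate", "none")


def evaluate_missense_predictions(
    records: Sequence[MutationRecord],
    rule: StabilityRule | None = None,
    reduced_counts_as_loss: bool = False,
) -> ConfusionSummary:
    """Confusion summary of stability-based predictions for missense alleles.

    Only records with consequence=missense and a definite observed-loss
    label enter the evaluation; ``not_determined`` rows are excluded, and
    ``reduced_but_detectable`` rows count as loss only when the flag says
    so (excluded by default).
    """
    rule = rule or StabilityRule()
    accepted_loss = {"yes", "no"}
    if reduced_counts_as_loss:
        accepted_loss.add("reduced_but_detectable")
    tp = fn = fp = tn = 0
    n_evaluable = 0
    for record in records:
        if record.consequence != "missense":
            continue
        if record.observed_loss not in accepted_loss:
            continue
        n_evaluable += 1
        observed = record.observed_loss in ("yes", "reduced_but_detectable")
        predicted = predict_loss(record, rule).predicted_loss == "loss"
        if observed and predicted:
            tp += 1
        elif observed and not predicted:
            fn += 1
        elif not observed and predicted:
            fp += 1
        else:
            tn += 1
    if n_evaluable == 0:
        raise ValidationError("no evaluable missense records")
    return ConfusionSummary(tp, fn, fp, tn)


class StabilityLossPredictor(BaseEstimator):
    """Estimator facade over the loss-prediction rules.

    ``predict(records)`` maps each mutation record to a PredictionOutcome;
    ``evaluate(records)`` benchmarks the missense predictions against
    observed loss and stores the result in ``confusion_``.
    """

    def __init__(self, ddg_threshold: float = 1.58, reduced_counts_as_loss: bool = False):
        self.ddg_threshold = ddg_threshold
        self.reduced_counts_as_loss = reduced_counts_as_loss

    def _rule(self) -> StabilityRule:
        return StabilityRule(self.ddg_threshold)

    def fit(self, records: Sequence[MutationRecord] | None = None, y=None):
        self._rule()
        return self

    def predict(self, records: Sequence[MutationRecord]) -> list[PredictionOutcome]:
        rule = self._rule()
        return [predict_loss(r, rule) for r in records]

    def evaluate(self, records: Sequence[MutationRecord]) -> ConfusionSummary:
        self.confusion_ = evaluate_missense_predictions(
            records, self._rule(), self.reduced_counts_as_loss
        )
        return self.confusion_
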