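"""Consensus pseudo-score, in-vitro confirmation bookkeeping and class summaries.

The pseudo-score S aggregates the six method scores for a drug–target pair
into one normalized confidence in [0, 1]. S ≥ 0.55 is significant. S = 1.00
is reserved for the certainty rule: the query is a training-set member with
the same mechanism of action, or most methods (≥ 5 of 6 by default, each at
the significance threshold) agree on the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .library import to_pactivity
from .predict import METHODS

SIGNIFICANCE_THRESHOLD = 0.55

STATUS_CONFIRMED = "confirmed_in_vitro"
STATUS_UNCONFIRMED = "predicted_unconfirmed"


class ConsensusError(ValueError):
    pass


@dataclass
class TargetPrediction:
    """One drug–target pair with per-method scores and the consensus verdict."""

    drug_id: str
    target_id: str
    method_scores: dict[str, float]
    pseudo_score: float
    target_class: str = ""
    status: str = STATUS_UNCONFIRMED
    best_pactivity: float | None = None

    @property
    def significant(self) -> bool:
        return self.pseudo_score >= SIGNIFICANCE_THRESHOLD


def aggregate(method_scores: dict[str, float], in_training_set: bool = False,
              same_moa: bool = False, weights: dict[str, float] | None = None,
              majority_count: int = 5,
              threshold: float = SIGNIFICANCE_THRESHOLD) -> float:
    """Consensus pseudo-score for one drug–target pair.

    Certainty rule: a training-set member with the same mechanism of action,
    or ≥ ``majority_count`` of the six methods each scoring ≥ ``threshold``,
    yields S = 1.00. Otherwise S is the weighted mean over all six methods
    (absent methods contribute 0 at full weight), clipped to [0, 1].
    """
    if weights is None:
        weights = {m: 1.0 for m in METHODS}
    if any(w < 0 for w in weights.values()):
        raise ConsensusError("negative method weights")
    unknown = set(method_scores) - set(METHODS)
    if unknown:
        raise ConsensusError(f"unknown methods: {sorted(unknown)}")
    if in_training_set and same_moa:
        return 1.0
    n_sig = sum(1 for m in METHODS if method_scores.get(m, 0.0) >= threshold)
    if n_sig >= majority_count:
        return 1.0
    wsum = sum(weights.get(m, 1.0) for m in METHODS)
    if wsum == 0:
        return 0.0
    s = sum(weights.get(m, 1.0) * method_scores.get(m, 0.0) for m in METHODS) / wsum
    return min(max(s, 0.0), 1.0)


def mark_confirmed(predictions: list[TargetPrediction],
                   activities: pd.DataFrame) -> list[TargetPrediction]:
    """Set status and best measured pActivity from the activity table.

    A prediction is confirmed iff any activity record exists for the
    (drug, target) pair; the best pActivity is the maximum over records.
    """
    best: dict[tuple[str, str], float] = {}
    for row in activities.itertuples(index=False):
        key = (str(row.compound_id), str(row.target_id))
        pact = float(getattr(row, "pactivity", float("nan")))
        if math.isnan(pact):
            pact = to_pactivity(float(row.value_nm))
        if key not in best or pact > best[key]:
            best[key] = pact
    for pred in predictions:
        key = (pred.drug_id, pred.target_id)
        if key in best:
            pred.status = STATUS_CONFIRMED
            pred.best_pactivity = best[key]
        else:
            pred.status = STATUS_UNCONFIRMED
            pred.best_pactivity = None
    return predictions


def floor_percent(confirmed: int, total: int) -> int:
    """Integer percent, floored — the convention that reproduces the printed
    per-class confirmation percentages."""
    if total <= 0:
        raise ConsensusError("total must be positive")
    return math.floor(100 * confirmed / total)


@dataclass(frozen=True)
class ClassSummary:
    target_class: str
    total: int
    unconfirmed: int
    confirmed: int
    percent_confirmed: int


def summarize_by_class(predictions: list[TargetPrediction]) -> list[ClassSummary]:
    """Per-class totals and floored confirmation percent; classes with zero
    predictions are omitted."""
    by_class: dict[str, list[TargetPrediction]] = {}
    for p in predictions:
        if not p.target_class:
            raise ConsensusError(f"prediction {p.drug_id}->{p.target_id} lacks a class")
        by_class.setdefault(p.target_class, []).append(p)
    out = []
    for cls in sorted(by_class):
        preds = by_class[cls]
        confirmed = sum(1 for p in preds if p.status == STATUS_CONFIRMED)
        out.append(ClassSummary(
            target_class=cls, total=len(preds),
            unconfirmed=len(preds) - confirmed, confirmed=confirmed,
            percent_confirmed=floor_percent(confirmed, len(preds))))
    return out


@dataclass(frozen=True)
class AffinityBins:
    """Nested potency bins over confirmed interactions.

    ``below_100nM``: pActivity > 7 (strict); ``from_10_to_1nM``:
    pActivity ∈ [8, 9); ``below_1nM``: pActivity ≥ 9.
    """

    below_100nM: int
    from_10_to_1nM: int
    below_1nM: int


def affinity_bins(pactivities: list[float]) -> AffinityBins:
    return AffinityBins(
        below_100nM=sum(1 for p in pactivities if p > 7.0),
        from_10_to_1nM=sum(1 for p in pactivities if 8.0 <= p < 9.0),
        below_1nM=sum(1 for p in pactivities if p >= 9.0),
    )


@dataclass(frozen=True)
class PerDrugStats:
    n_drugs: int
    n_interactions: int
    mean_per_drug: float
    floor_per_drug: int
    round_per_drug: int


def per_drug_stats(predictions: list[TargetPrediction] | None = None,
                   n_interactions: int | None = None,
                   n_drugs: int | None = None) -> PerDrugStats:
    """Average interactions per drug, reported as float, floor and round.

    Accepts either a prediction list or raw (interaction, drug) counts so the
    same arithmetic serves computed and printed inputs.
    """
    if predictions is not None:
        n_interactions = len(predictions)
        n_drugs = len({p.drug_id for p in predictions})
    if not n_drugs:
        return PerDrugStats(0, n_interactions or 0, 0.0, 0, 0)
    mean = n_interactions / n_drugs
    return PerDrugStats(n_drugs=n_drugs, n_interactions=n_interactions,
                        mean_per_drug=mean, floor_per_drug=math.floor(mean),
                        round_per_drug=round(mean))


# ---------------------------------------------------------------------------
# tabular export

def predictions_frame(predictions: list[TargetPrediction]) -> pd.DataFrame:
    """Wide TSV-ready frame: one row per pair, per-method columns, stable order."""
    rows = []
    for p in sorted(predictions, key=lambda q: (q.drug_id, q.target_id)):
        row = {"drug_id": p.drug_id, "target_id": p.target_id,
               "target_class": p.target_class}
        for m in METHODS:
            row[f"score_{m.lower()}"] = round(p.method_scores.get(m, 0.0), 6)
        row["pseudo_score"] = round(p.pseudo_score, 6)
        row["significant"] = p.significant
        row["status"] = p.status
        row["best_pic50"] = ("" if p.best_pactivity is None
                             else round(p.best_pactivity, 4))
        rows.append(row)
    return pd.DataFrame(rows)


def class_summary_frame(summaries: list[ClassSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "target_class": s.target_class, "total_predicted": s.total,
        "predicted_unconfirmed": s.unconfirmed, "confirmed": s.confirmed,
        "percent_confirmed": s.percent_confirmed} for s in summaries])
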