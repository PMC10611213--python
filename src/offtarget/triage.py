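"""Clinical-exposure-aware repurposing triage.

Potency and exposure live on the same −log10 molar scale: pIC50 > 6.0 means
sub-micromolar potency, and pIC50 ≥ pCmax means the free plasma concentration
at the clinical dose can engage the target. A predicted off-target is worth
pursuing when three criteria hold — literature evidence linking it to a
therapeutic outcome, expression in the relevant tissues, and a consensus
pseudo-score > 0.55 — and the measured potency is sub-micromolar; criteria
met but weak potency routes to potency optimization instead.

The direction of the engagement comparison follows the worked exposure
table (sub-µM potency at or above exposure ⇒ engaged); the accompanying
prose inverts it, and that conflict is documented in the methods note.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .consensus import STATUS_CONFIRMED, TargetPrediction

log = logging.getLogger("offtarget.triage")

SUB_UM_CUTOFF = 6.0            # pIC50 above this = sub-micromolar potency
SCORE_CRITERION = 0.55         # composite-score criterion (strict >)

#: Default pharmacological safety liabilities (binding only; functional
#: direction is never predicted): 5-HT2B, PPARγ, hERG, cKIT.
DEFAULT_LIABILITY_TARGETS = frozenset({"HTR2B", "PPARG", "KCNH2", "KIT"})

VERDICTS = ("pursue", "optimize_potency", "deprioritize")


class TriageError(ValueError):
    pass


def compute_pcmax(cmax_um: float) -> float:
    """pCmax = −log10(Cmax in mol/L) = 6 − log10(Cmax in µM), rounded to two
    decimals with half-away-from-zero rounding."""
    if cmax_um <= 0:
        raise TriageError(f"Cmax must be positive, got {cmax_um}")
    value = 6.0 - math.log10(cmax_um)
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DrugExposure:
    drug_id: str
    cmax_um: float
    intended_targets: tuple[str, ...] = ()
    dose_note: str = ""

    @property
    def pcmax(self) -> float:
        return compute_pcmax(self.cmax_um)


@dataclass(frozen=True)
class EvidenceFlag:
    target_id: str
    disease: str
    source: str

    @property
    def present(self) -> bool:
        return bool(self.source)


def exposure_flags(pactivity: float, pcmax: float
                   ) -> tuple[bool, bool, float]:
    """(sub-µM flag, engaged flag, signed margin = pIC50 − pCmax)."""
    if not (math.isfinite(pactivity) and math.isfinite(pcmax)):
        raise TriageError("pActivity and pCmax must be finite")
    sub_um = pactivity > SUB_UM_CUTOFF
    engaged = pactivity >= pcmax
    return sub_um, engaged, pactivity - pcmax


@dataclass
class TriageRecord:
    drug_id: str
    target_id: str
    pseudo_score: float
    pactivity: float | None
    pcmax: float | None
    sub_um: bool
    engaged: bool
    margin: float | None
    evidence_ok: bool
    expression_ok: bool
    score_ok: bool
    verdict: str
    rationale: str
    safety_flag: bool = False


def three_criteria_verdict(prediction: TargetPrediction,
                           evidence_present: bool,
                           expression_ok: bool,
                           pcmax: float | None = None) -> TriageRecord:
    """Apply the three repurposing criteria plus the potency gate.

    pursue        — evidence AND expression AND pseudo-score > 0.55 AND sub-µM
    optimize_potency — the three criteria hold but potency is not sub-µM
    deprioritize  — any criterion fails
    """
    score_ok = prediction.pseudo_score > SCORE_CRITERION
    pact = prediction.best_pactivity
    sub_um = pact is not None and pact > SUB_UM_CUTOFF
    engaged = (pact is not None and pcmax is not None and pact >= pcmax)
    margin = (pact - pcmax) if (pact is not None and pcmax is not None) else None

    criteria = evidence_present and expression_ok and score_ok
    if criteria and sub_um:
        verdict, why = "pursue", "all criteria met with sub-µM potency"
    elif criteria:
        verdict, why = "optimize_potency", ("criteria met but measured potency "
                                            "is µM or weaker (or unmeasured)")
    else:
        missing = [name for ok, name in ((evidence_present, "evidence"),
                                         (expression_ok, "expression"),
                                         (score_ok, "score>0.55")) if not ok]
        verdict, why = "deprioritize", f"criteria failed: {', '.join(missing)}"
    return TriageRecord(
        drug_id=prediction.drug_id, target_id=prediction.target_id,
        pseudo_score=prediction.pseudo_score, pactivity=pact, pcmax=pcmax,
        sub_um=sub_um, engaged=engaged, margin=margin,
        evidence_ok=evidence_present, expression_ok=expression_ok,
        score_ok=score_ok, verdict=verdict, rationale=why)


def safety_liability_screen(predictions: list[TargetPrediction],
                            liabilities: frozenset[str] = DEFAULT_LIABILITY_TARGETS
                            ) -> list[TargetPrediction]:
    """Subset of predictions against safety-liability targets.

    Flagging is binding-only: the framework does not predict agonism vs
    antagonism, so these are routed to functional follow-up, never rejected.
    """
    flagged = [p for p in predictions if p.target_id in liabilities]
    for p in flagged:
        log.info("safety_review: %s -> %s (binding only; functional direction "
                 "not predicted)", p.drug_id, p.target_id)
    return flagged


# ---------------------------------------------------------------------------
# I/O

def load_exposure(path) -> dict[str, DrugExposure]:
    """Exposure CSV with columns drug_id, cmax_um, intended_targets[, dose_note]."""
    df = pd.read_csv(path, dtype={"drug_id": str})
    need = {"drug_id", "cmax_um", "intended_targets"}
    if not need.issubset(df.columns):
        raise TriageError(f"exposure table must have columns {sorted(need)}")
    out = {}
    for row in df.itertuples(index=False):
        targets = tuple(t.strip() for t in str(row.intended_targets).split(";")
                        if t.strip())
        out[str(row.drug_id)] = DrugExposure(
            drug_id=str(row.drug_id), cmax_um=float(row.cmax_um),
            intended_targets=targets,
            dose_note=str(getattr(row, "dose_note", "") or ""))
    return out


def load_evidence(path) -> dict[str, EvidenceFlag]:
    """Evidence CSV with columns target_id, disease, source."""
    df = pd.read_csv(path, dtype=str)
    need = {"target_id", "disease", "source"}
    if not need.issubset(df.columns):
        raise TriageError(f"evidence table must have columns {sorted(need)}")
    out = {}
    for row in df.itertuples(index=False):
        if not str(row.source).strip():
            raise TriageError(f"evidence row for {row.target_id} lacks a source")
        out[str(row.target_id)] = EvidenceFlag(
            target_id=str(row.target_id), disease=str(row.disease),
            source=str(row.source))
    return out


# ---------------------------------------------------------------------------
# report

@dataclass(frozen=True)
class ReportRow:
    drug_id: str
    intended_targets: tuple[str, ...]
    cmax_um: float | None
    pcmax: float | None
    n_sub_um_offtargets: int
    key_offtargets: tuple[str, ...]
    warning: str = ""


def build_report(predictions: list[TargetPrediction],
                 exposures: dict[str, DrugExposure]) -> list[ReportRow]:
    """One row per drug: exposure, count of off-targets with measured
    pIC50 > 6.0, and the key off-target list ranked by engagement margin
    (descending), ties broken by target id. Drugs without an exposure record
    get a blank pCmax and a warning; no prediction is lost or duplicated."""
    by_drug: dict[str, list[TargetPrediction]] = {}
    for p in predictions:
        by_drug.setdefault(p.drug_id, []).append(p)
    rows = []
    for drug_id in sorted(set(by_drug) | set(exposures)):
        preds = by_drug.get(drug_id, [])
        exp = exposures.get(drug_id)
        warning = ""
        if exp is None:
            warning = "no exposure record; pCmax blank"
            log.warning("drug %s: %s", drug_id, warning)
        if not preds:
            warning = (warning + "; " if warning else "") + "no predictions"
        pcmax = exp.pcmax if exp else None
        measured = [p for p in preds
                    if p.status == STATUS_CONFIRMED and p.best_pactivity is not None]
        sub_um = [p for p in measured if p.best_pactivity > SUB_UM_CUTOFF]

        def sort_key(p: TargetPrediction):
            margin = (p.best_pactivity - pcmax) if pcmax is not None else p.best_pactivity
            return (-margin, p.target_id)

        ranked = tuple(p.target_id for p in sorted(sub_um, key=sort_key))
        rows.append(ReportRow(
            drug_id=drug_id,
            intended_targets=exp.intended_targets if exp else (),
            cmax_um=exp.cmax_um if exp else None,
            pcmax=pcmax, n_sub_um_offtargets=len(sub_um),
            key_offtargets=ranked, warning=warning))
    return rows


def report_frame(rows: list[ReportRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "drug_id": r.drug_id,
        "intended_targets": ";".join(r.intended_targets),
        "cmax_um": "" if r.cmax_um is None else r.cmax_um,
        "pcmax": "" if r.pcmax is None else f"{r.pcmax:.2f}",
        "n_offtargets_pic50_gt6": r.n_sub_um_offtargets,
        "key_offtargets": ";".join(r.key_offtargets),
        "warning": r.warning} for r in rows])
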