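"""Reader-study evaluation: dichotomization, consensus, diagnostic metrics,
interrater agreement and detection-rate comparisons.

Readers score each case on a 4-level confidence scale (1 = lesion definitively
present … 4 = definitively not present) and mark the suspected lesion.  Calls
are dichotomized to positive (confidence 1-2) vs negative (3-4); on a
truly positive case a true positive additionally requires a correct mark,
and a correctly marked case read with confidence 3-4 counts as not marked.
A wrong-location positive call on a positive case counts as a false negative
only (the specificity denominator is the negative-control cases).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats
from statsmodels.stats import inter_rater

from .errors import UndefinedStatisticError, ValidationError
from .images import SegmentationMask

CONDITIONS = ("unprocessed", "window", "fsnlb")
POSITIVE_CONFIDENCES = (1, 2)
MARK_TOLERANCE_MM = 2.0


@dataclass
class ReaderCall:
    """One reader's call on one case under one display condition."""

    case_id: str
    reader_id: str
    condition: str
    confidence: int
    mark_correct: bool | None = None  # meaningful only when a mark was placed

    def __post_init__(self) -> None:
        if self.confidence not in (1, 2, 3, 4):
            raise ValidationError(
                f"confidence must be in {{1, 2, 3, 4}}, got {self.confidence}"
            )
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")

    @property
    def positive(self) -> bool:
        return self.confidence in POSITIVE_CONFIDENCES


@dataclass
class CaseTruth:
    """Ground truth for one case."""

    case_id: str
    infarct_present: bool
    lesion_mask: SegmentationMask | None = None

    def __post_init__(self) -> None:
        if self.infarct_present and self.lesion_mask is None:
            raise ValidationError(f"{self.case_id}: positive case requires a lesion mask")
        if not self.infarct_present and self.lesion_mask is not None:
            raise ValidationError(f"{self.case_id}: negative case must not carry a lesion mask")


def mark_is_correct(mark_mm, lesion_mask: SegmentationMask,
                    tolerance_mm: float = MARK_TOLERANCE_MM) -> bool:
    """A mark is correct if it falls inside the lesion dilated by ``tolerance_mm``."""
    pt = np.asarray(mark_mm, dtype=float)
    if pt.shape != (3,):
        raise ValidationError(f"mark must be a 3-vector in mm, got shape {pt.shape}")
    coords = lesion_mask.coords_mm()
    return bool(np.min(np.linalg.norm(coords - pt, axis=1)) <= tolerance_mm +
                float(np.max(lesion_mask.spacing)) / 2.0)


def dichotomize(call: ReaderCall, truth: CaseTruth) -> str:
    """Classify one call as TP / FP / TN / FN."""
    if call.case_id != truth.case_id:
        raise ValidationError(
            f"case ids differ: call {call.case_id!r} vs truth {truth.case_id!r}"
        )
    if truth.infarct_present:
        if call.positive and call.mark_correct:
            return "TP"
        return "FN"
    return "FP" if call.positive else "TN"


def consensus(calls: list[ReaderCall], truth: CaseTruth) -> str:
    """Majority-vote consensus of exactly three readers for one case/condition.

    The consensus is positive when at least two readers call positive; on a
    positive case a consensus TP additionally requires at least two positive
    calls with correct localization.
    """
    if len(calls) != 3:
        raise ValidationError(f"consensus requires exactly 3 reader calls, got {len(calls)}")
    ids = {c.case_id for c in calls}
    if len(ids) != 1 or calls[0].case_id != truth.case_id:
        raise ValidationError(f"consensus calls must share the truth's case id, got {ids}")
    positive_votes = sum(c.positive for c in calls)
    called_positive = positive_votes >= 2
    if truth.infarct_present:
        correct_votes = sum(bool(c.positive and c.mark_correct) for c in calls)
        return "TP" if correct_votes >= 2 else "FN"
    return "FP" if called_positive else "TN"


def _pct_half_up(num: int, den: int) -> int | None:
    if den == 0:
        return None
    return int(np.floor(100.0 * num / den + 0.5))


@dataclass
class DiagnosticSummary:
    """Contingency counts with derived metrics (integer percent, half-up)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} count must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def sensitivity_pct(self) -> int | None:
        return _pct_half_up(self.tp, self.tp + self.fn)

    @property
    def specificity_pct(self) -> int | None:
        return _pct_half_up(self.tn, self.tn + self.fp)

    @property
    def ppv_pct(self) -> int | None:
        return _pct_half_up(self.tp, self.tp + self.fp)

    @property
    def npv_pct(self) -> int | None:
        return _pct_half_up(self.tn, self.tn + self.fn)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "ppv_pct": self.ppv_pct,
            "npv_pct": self.npv_pct,
        }


def diagnostic_metrics(outcomes: list[str]) -> DiagnosticSummary:
    """Tally TP/FP/TN/FN outcome labels into a :class:`DiagnosticSummary`."""
    allowed = {"TP", "FP", "TN", "FN"}
    bad = set(outcomes) - allowed
    if bad:
        raise ValidationError(f"unknown outcome labels: {sorted(bad)}")
    return DiagnosticSummary(
        tp=outcomes.count("TP"),
        fp=outcomes.count("FP"),
        tn=outcomes.count("TN"),
        fn=outcomes.count("FN"),
    )


def fleiss_kappa(ratings) -> float:
    """Fleiss kappa for a cases x raters matrix of categorical ratings.

    kappa = (P_bar - P_bar_e) / (1 - P_bar_e); undefined when every rating
    falls in a single category (chance agreement is 1).
    """
    arr = np.asarray(ratings)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError(
            f"ratings must be a cases x raters matrix with >= 2 of each, got {arr.shape}"
        )
    table, _ = inter_rater.aggregate_raters(arr)
    if table.shape[1] < 2:
        raise UndefinedStatisticError(
            "all ratings fall in one category; Fleiss kappa is undefined"
        )
    kappa = float(inter_rater.fleiss_kappa(table, method="fleiss"))
    if not np.isfinite(kappa):
        raise UndefinedStatisticError("Fleiss kappa is undefined for this matrix")
    return kappa


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table (zero margin -> 1)."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValidationError(f"table must be 2x2, got {arr.shape}")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        if np.any(arr != np.floor(arr)) or np.any(arr < 0):
            raise ValidationError("table entries must be non-negative integers")
        arr = arr.astype(int)
    return float(_scipy_stats.fisher_exact(arr, alternative="two-sided")[1])


def compare_detection(a: DiagnosticSummary, b: DiagnosticSummary,
                      on: str = "sensitivity") -> float:
    """Fisher exact comparison of two conditions' detection or specificity rates."""
    if on == "sensitivity":
        table = [[a.tp, a.fn], [b.tp, b.fn]]
    elif on == "specificity":
        table = [[a.tn, a.fp], [b.tn, b.fp]]
    else:
        raise ValidationError(f"can compare 'sensitivity' or 'specificity', not {on!r}")
    return fisher_exact(np.asarray(table, dtype=int))


# -- reader-study driver ----------------------------------------------------

@dataclass
class ReaderStudyResult:
    per_condition: dict[str, DiagnosticSummary]
    kappa: dict[str, float | None]
    per_window: pd.DataFrame | None
    comparisons: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "per_condition": {k: v.to_dict() for k, v in self.per_condition.items()},
            "fleiss_kappa": self.kappa,
            "per_window": None if self.per_window is None
            else self.per_window.to_dict(orient="records"),
            "fisher_comparisons": self.comparisons,
        }


def evaluate_reader_study(
    calls: list[ReaderCall],
    truths: dict[str, CaseTruth],
    onset_hours: dict[str, float] | None = None,
) -> ReaderStudyResult:
    """Consensus metrics, per-condition Fleiss kappa and Fisher comparisons.

    ``calls`` must contain exactly three reader calls per case and condition.
    When ``onset_hours`` maps positive case ids to onset-to-CT hours, a
    per-time-window true-positive table is included.
    """
    from .quantify import assign_time_window, WINDOW_LABELS

    by_cond: dict[str, dict[str, list[ReaderCall]]] = {}
    for call in calls:
        if call.case_id not in truths:
            raise ValidationError(f"call references unknown case {call.case_id!r}")
        by_cond.setdefault(call.condition, {}).setdefault(call.case_id, []).append(call)

    per_condition: dict[str, DiagnosticSummary] = {}
    kappas: dict[str, float | None] = {}
    case_outcomes: dict[str, dict[str, str]] = {}
    for cond, by_case in by_cond.items():
        outcomes = {}
        for cid, case_calls in by_case.items():
            outcomes[cid] = consensus(case_calls, truths[cid])
        case_outcomes[cond] = outcomes
        per_condition[cond] = diagnostic_metrics(list(outcomes.values()))
        matrix = np.array(
            [
                [1 if c.positive else 0 for c in sorted(cc, key=lambda c: c.reader_id)]
                for cid, cc in sorted(by_case.items())
            ]
        )
        try:
            kappas[cond] = fleiss_kappa(matrix)
        except UndefinedStatisticError:
            kappas[cond] = None

    per_window = None
    if onset_hours is not None:
        rows = []
        for label in WINDOW_LABELS:
            row: dict[str, object] = {"time_window": label}
            for cond, outcomes in case_outcomes.items():
                cids = [
                    cid for cid in outcomes
                    if truths[cid].infarct_present and cid in onset_hours
                    and assign_time_window(onset_hours[cid]) == label
                ]
                row[f"{cond}_tp"] = sum(outcomes[c] == "TP" for c in cids)
                row[f"{cond}_n"] = len(cids)
            rows.append(row)
        per_window = pd.DataFrame(rows)

    comparisons: dict[str, float] = {}
    conds = [c for c in CONDITIONS if c in per_condition]
    for i, a in enumerate(conds):
        for b in conds[i + 1:]:
            comparisons[f"{a}_vs_{b}_sensitivity"] = compare_detection(
                per_condition[a], per_condition[b], "sensitivity"
            )
            comparisons[f"{a}_vs_{b}_specificity"] = compare_detection(
                per_condition[a], per_condition[b], "specificity"
            )
    return ReaderStudyResult(per_condition, kappas, per_window, comparisons)


# -- CSV interfaces ---------------------------------------------------------

def calls_from_csv(path: str | Path, truths: dict[str, CaseTruth]) -> list[ReaderCall]:
    """Read reader calls (case_id, reader_id, condition, confidence, mark_x/y/z mm).

    Mark correctness is resolved against the truth lesion masks with the
    standard 2 mm pointing tolerance; empty mark columns mean no mark placed.
    """
    df = pd.read_csv(path)
    required = {"case_id", "reader_id", "condition", "confidence"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    calls = []
    for r in df.itertuples():
        cid = str(r.case_id)
        mark_correct: bool | None = None
        if {"mark_x", "mark_y", "mark_z"} <= set(df.columns):
            mark = (getattr(r, "mark_x"), getattr(r, "mark_y"), getattr(r, "mark_z"))
            if all(pd.notna(v) for v in mark):
                truth = truths.get(cid)
                if truth is not None and truth.infarct_present:
                    mark_correct = mark_is_correct(mark, truth.lesion_mask)
                else:
                    mark_correct = False
        calls.append(
            ReaderCall(
                case_id=cid,
                reader_id=str(r.reader_id),
                condition=str(r.condition),
                confidence=int(r.confidence),
                mark_correct=mark_correct,
            )
        )
    return calls


def truth_from_csv(path: str | Path, mask_root: str | Path | None = None) -> dict[str, CaseTruth]:
    """Read case truth (case_id, infarct_present, lesion_mask path)."""
    from . import io as _io

    df = pd.read_csv(path)
    required = {"case_id", "infarct_present"}
    if required - set(df.columns):
        raise ValidationError(f"{path}: needs columns {sorted(required)}")
    root = Path(mask_root) if mask_root is not None else Path(path).parent
    truths = {}
    for r in df.itertuples():
        present = bool(int(r.infarct_present))
        mask = None
        if present:
            mask_path = getattr(r, "lesion_mask", None)
            if mask_path is None or pd.isna(mask_path):
                raise ValidationError(f"{r.case_id}: positive case needs a lesion_mask path")
            mask = _io.read_mask(root / str(mask_path), role="lesion")
        truths[str(r.case_id)] = CaseTruth(str(r.case_id), present, mask)
    return truths
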