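from math import comb

import numpy as np
import pytest

from rssi_nwu.errors import UndefinedStatisticError, ValidationError
from rssi_nwu.evaluate import (
    CaseTruth,
    DiagnosticSummary,
    ReaderCall,
    compare_detection,
    consensus,
    diagnostic_metrics,
    dichotomize,
    evaluate_reader_study,
    fisher_exact,
    fleiss_kappa,
    mark_is_correct,
)
from rssi_nwu.images import SegmentationMask


def _call(case="c1", conf=2, mark=True, reader="r1", cond="unprocessed"):
    return ReaderCall(case, reader, cond, conf, mark)


def _lesion_mask():
    data = np.zeros((10, 10, 10))
    data[4:6, 4:6, 4:6] = 1
    return SegmentationMask(data, np.eye(4), "lesion")


POS = CaseTruth("c1", True, _lesion_mask())
NEG = CaseTruth("c1", False, None)


class TestDichotomize:
    @pytest.mark.parametrize(
        "conf, mark, truth, expected",
        [
            (1, True, POS, "TP"),
            (2, True, POS, "TP"),
            (3, True, POS, "FN"),  # correct mark but low confidence: not marked
            (4, True, POS, "FN"),
            (2, False, POS, "FN"),  # wrong location counts as miss, not FP
            (1, None, NEG, "FP"),
            (2, None, NEG, "FP"),
            (3, None, NEG, "TN"),
            (4, None, NEG, "TN"),
        ],
    )
    def test_confidence_and_localization_rule(self, conf, mark, truth, expected):
        assert dichotomize(_call(conf=conf, mark=mark), truth) == expected

    def test_invalid_confidence_rejected(self):
        with pytest.raises(ValidationError, match="confidence"):
            ReaderCall("c1", "r1", "unprocessed", 5)

    def test_mismatched_case_ids_rejected(self):
        with pytest.raises(ValidationError, match="case id"):
            dichotomize(_call(case="other"), POS)


class TestConsensus:
    def test_majority_positive_with_correct_marks_is_tp(self):
        calls = [_call(conf=1, reader="r1"), _call(conf=2, reader="r2"),
                 _call(conf=4, mark=None, reader="r3")]
        assert consensus(calls, POS) == "TP"

    def test_majority_negative_on_negative_case_is_tn(self):
        calls = [_call(conf=3, mark=None, reader="r1"),
                 _call(conf=4, mark=None, reader="r2"),
                 _call(conf=2, mark=None, reader="r3")]
        assert consensus(calls, NEG) == "TN"

    def test_positive_majority_without_localization_majority_is_fn(self):
        calls = [_call(conf=1, mark=False, reader="r1"),
                 _call(conf=2, mark=False, reader="r2"),
                 _call(conf=1, mark=True, reader="r3")]
        assert consensus(calls, POS) == "FN"

    def test_two_calls_rejected(self):
        with pytest.raises(ValidationError, match="3 reader"):
            consensus([_call(reader="r1"), _call(reader="r2")], POS)


class TestDiagnosticMetrics:
    def test_study_contingency_counts(self):
        outcomes = ["TP"] * 11 + ["FN"] * 23 + ["TN"] * 21 + ["FP"] * 1
        s = diagnostic_metrics(outcomes)
        assert (s.sensitivity_pct, s.specificity_pct) == (32, 95)
        assert (s.ppv_pct, s.npv_pct) == (92, 48)

    def test_zero_sensitivity(self):
        s = diagnostic_metrics(["FN"] * 4 + ["TN"] * 2)
        assert s.sensitivity_pct == 0

    def test_perfect_outcomes(self):
        s = diagnostic_metrics(["TP"] * 3 + ["TN"] * 3)
        assert (s.sensitivity_pct, s.specificity_pct, s.ppv_pct, s.npv_pct) == (
            100, 100, 100, 100,
        )

    def test_undefined_metric_marked_unavailable(self):
        s = diagnostic_metrics(["TP", "FN"])
        assert s.specificity_pct is None
        assert s.npv_pct == 0  # tn/(tn+fn) = 0/1 is defined

    def test_order_invariance(self):
        a = ["TP", "FN", "TN", "FP", "TP"]
        assert diagnostic_metrics(a).to_dict() == diagnostic_metrics(a[::-1]).to_dict()

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            diagnostic_metrics(["TP", "XX"])


def _fleiss_oracle(ratings):
    """Brute-force evaluation of kappa = (P_bar - P_e) / (1 - P_e)."""
    ratings = [list(row) for row in ratings]
    cats = sorted({v for row in ratings for v in row})
    n = len(ratings[0])
    counts = [[row.count(c) for c in cats] for row in ratings]
    p_i = [(sum(c * c for c in row) - n) / (n * (n - 1)) for row in counts]
    p_bar = sum(p_i) / len(p_i)
    totals = [sum(row[j] for row in counts) for j in range(len(cats))]
    grand = sum(totals)
    p_e = sum((t / grand) ** 2 for t in totals)
    return (p_bar - p_e) / (1 - p_e)


class TestFleissKappa:
    FIXTURE = [[1, 1, 2], [2, 2, 2], [1, 2, 3], [3, 3, 2]]

    def test_matches_brute_force_formula(self):
        assert fleiss_kappa(self.FIXTURE) == pytest.approx(
            _fleiss_oracle(self.FIXTURE), abs=1e-12
        )

    def test_perfect_agreement_with_multiple_categories(self):
        ratings = [[1, 1, 1], [2, 2, 2], [1, 1, 1]]
        assert fleiss_kappa(ratings) == pytest.approx(1.0)

    def test_single_category_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            fleiss_kappa([[1, 1, 1], [1, 1, 1]])

    def test_invariant_to_category_relabeling(self):
        relabeled = [[{1: 7, 2: 5, 3: 9}[v] for v in row] for row in self.FIXTURE]
        assert fleiss_kappa(relabeled) == pytest.approx(fleiss_kappa(self.FIXTURE))

    def test_requires_matrix(self):
        with pytest.raises(ValidationError):
            fleiss_kappa([[1, 2, 3]])


def _fisher_oracle(table):
    """Exhaustive two-sided Fisher p: sum of hypergeometric probabilities
    no larger than the observed table's, over all tables with fixed margins."""
    (a, b), (c, d) = table
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


class TestFisherExact:
    def test_detection_rates_not_significantly_different(self):
        # unprocessed (11/34) vs FSNLB-optimized (14/34) detections
        assert fisher_exact([[11, 23], [14, 20]]) > 0.05

    def test_identical_rows_give_p_one(self):
        assert fisher_exact([[7, 3], [7, 3]]) == pytest.approx(1.0)

    def test_diagonal_table_enumeration(self):
        assert fisher_exact([[5, 0], [0, 5]]) == pytest.approx(2 / 252, abs=1e-12)

    def test_zero_margin_gives_p_one(self):
        assert fisher_exact([[0, 0], [3, 5]]) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 11, size=(2, 2))
        while table.sum() == 0 or table.sum() > 40:
            table = rng.integers(0, 11, size=(2, 2))
        assert fisher_exact(table) == pytest.approx(
            _fisher_oracle(table.tolist()), rel=1e-9
        )

    def test_non_integer_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact([[1.5, 2.0], [3.0, 4.0]])


class TestMarkCorrectness:
    def test_inside_lesion(self):
        assert mark_is_correct((4.5, 4.5, 4.5), _lesion_mask())

    def test_within_two_mm_tolerance(self):
        assert mark_is_correct((7.0, 5.0, 5.0), _lesion_mask())

    def test_far_away_is_wrong(self):
        assert not mark_is_correct((0.0, 0.0, 0.0), _lesion_mask())


class TestReaderStudy:
    def _build(self):
        truths, calls, hours = {}, [], {}
        for i in range(6):
            cid = f"p{i}"
            truths[cid] = CaseTruth(cid, True, _lesion_mask())
            hours[cid] = 3.0 + 6.0 * i % 30
        for i in range(4):
            truths[f"n{i}"] = CaseTruth(f"n{i}", False, None)
        for cond in ("unprocessed", "fsnlb"):
            for cid, truth in truths.items():
                detected = truth.infarct_present and (cond == "fsnlb" or cid != "p0")
                for r in ("r1", "r2", "r3"):
                    conf = 2 if detected else 4
                    calls.append(ReaderCall(cid, r, cond, conf,
                                            True if detected else None))
        return calls, truths, hours

    def test_per_condition_metrics_and_additivity(self):
        calls, truths, hours = self._build()
        # fix truth case ids for the masks built above
        result = evaluate_reader_study(calls, truths, hours)
        un = result.per_condition["unprocessed"]
        fs = result.per_condition["fsnlb"]
        assert (un.tp, fs.tp) == (5, 6)
        assert un.tn == fs.tn == 4
        table = result.per_window
        assert table[table.columns[1]].dtype.kind in "iu"
        for cond in ("unprocessed", "fsnlb"):
            assert table[f"{cond}_tp"].sum() == result.per_condition[cond].tp

    def test_fisher_comparison_keys_present(self):
        calls, truths, hours = self._build()
        result = evaluate_reader_study(calls, truths, hours)
        assert "unprocessed_vs_fsnlb_sensitivity" in result.comparisons
        assert 0.0 <= result.comparisons["unprocessed_vs_fsnlb_sensitivity"] <= 1.0

    def test_compare_detection_uses_counts(self):
        a = DiagnosticSummary(11, 1, 21, 23)
        b = DiagnosticSummary(14, 3, 19, 20)
        assert compare_detection(a, b, "sensitivity") == pytest.approx(
            fisher_exact([[11, 23], [14, 20]])
        )
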