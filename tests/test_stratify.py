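"""Patient scoring, cut-off scanning/selection, evaluation, robustness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tilstrat.classifier import PatchPrediction
from tilstrat.stratify import (
    PatientScore,
    evaluate,
    predict_outcome,
    scan_rc,
    score_patients,
    select_rc,
    subsample_robustness,
)

from _helpers import OracleModel, toy_patch


def _preds(pid, labels):
    return [
        PatchPrediction(pid, 0, i, 0.9 if lab == "poor" else 0.1, lab)
        for i, lab in enumerate(labels)
    ]


def _scores(d):
    return [PatientScore(pid, 100, r) for pid, r in d.items()]


def _brute_force_best_accuracy(values, is_poor):
    """Independent exhaustive scan: every value +- epsilon and all midpoints."""
    vals = np.asarray(values, float)
    cand = set([0.0, 1.0])
    for v in vals:
        cand.update([max(v - 1e-9, 0), min(v + 1e-9, 1), v])
    for a in vals:
        for b in vals:
            cand.add((a + b) / 2)
    best = 0.0
    for c in cand:
        best = max(best, float(((vals < c) == is_poor).mean()))
    return best


class TestScorePatients:
    def test_examples(self):
        preds = (
            _preds("A", ["good"] * 4)
            + _preds("B", ["good", "good", "good", "poor"])
            + _preds("C", ["poor"] * 3)
        )
        scores = {s.patient_id: s.r_good for s in score_patients(preds)}
        assert scores == {"A": 1.0, "B": 0.75, "C": 0.0}

    def test_order_and_duplication_invariance(self, rng):
        labels = ["good" if rng.random() < 0.6 else "poor" for _ in range(20)]
        preds = _preds("A", labels)
        r1 = score_patients(preds)[0].r_good
        shuffled = [preds[i] for i in rng.permutation(20)]
        assert score_patients(shuffled)[0].r_good == r1
        assert score_patients(preds + preds)[0].r_good == pytest.approx(r1)


class TestScanRc:
    def test_separated_scores_perfect_interval(self):
        scores = _scores({"g1": 0.8, "g2": 0.9, "p1": 0.1, "p2": 0.2})
        truths = {"g1": "good", "g2": "good", "p1": "poor", "p2": "poor"}
        scan = scan_rc(scores, truths)
        assert scan.max_accuracy == 1.0
        assert (scan.lo, scan.hi) == (0.2, 0.8)

    def test_interleaved_scores_half_accuracy(self):
        scores = _scores({"g1": 0.1, "g2": 0.3, "p1": 0.2, "p2": 0.4})
        truths = {"g1": "good", "g2": "good", "p1": "poor", "p2": "poor"}
        assert scan_rc(scores, truths).max_accuracy == 0.5

    def test_extreme_pair_full_interval(self):
        scan = scan_rc(
            _scores({"g": 1.0, "p": 0.0}), {"g": "good", "p": "poor"}
        )
        assert scan.max_accuracy == 1.0
        assert (scan.lo, scan.hi) == (0.0, 1.0)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="outcome group"):
            scan_rc(_scores({"a": 0.5}), {"a": "good"})

    @given(
        n_good=st.integers(1, 8),
        n_poor=st.integers(1, 8),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=120, deadline=None)
    def test_matches_brute_force_enumeration(self, n_good, n_poor, seed):
        rng = np.random.default_rng(seed)
        # quantized scores produce plenty of ties across patients
        vals = np.round(rng.random(n_good + n_poor), 1)
        truths = {f"x{i}": ("good" if i < n_good else "poor") for i in range(len(vals))}
        scores = [PatientScore(f"x{i}", 10, v) for i, v in enumerate(vals)]
        scan = scan_rc(scores, truths)
        is_poor = np.array([truths[f"x{i}"] == "poor" for i in range(len(vals))])
        assert scan.max_accuracy == pytest.approx(
            _brute_force_best_accuracy(vals, is_poor)
        )
        # the reported interval's midpoint attains the reported accuracy
        mid_acc = ((vals < scan.midpoint) == is_poor).mean()
        assert mid_acc == pytest.approx(scan.max_accuracy)


class TestSelectRc:
    def _scan(self, lo, hi, acc):
        from tilstrat.stratify import ThresholdScan

        return ThresholdScan(
            candidates=np.array([]), accuracies=np.array([]), lo=lo, hi=hi, max_accuracy=acc
        )

    def test_mean_of_perfect_midpoints(self):
        sel = select_rc([self._scan(0.2, 0.4, 1.0), self._scan(0.3, 0.5, 1.0)])
        assert sel.rc_final == pytest.approx(0.35)

    def test_single_realization_midpoint(self):
        sel = select_rc([self._scan(0.14, 0.40, 1.0)])
        assert sel.rc_final == pytest.approx(0.27)

    def test_imperfect_realizations_excluded(self):
        sel = select_rc(
            [
                self._scan(0.2, 0.4, 1.0),
                self._scan(0.6, 0.8, 0.9),
                self._scan(0.3, 0.5, 1.0),
            ]
        )
        assert sel.used == [True, False, True]
        assert sel.rc_final == pytest.approx(0.35)

    def test_identical_realizations(self):
        sel = select_rc([self._scan(0.1, 0.3, 0.95)] * 3)
        assert sel.rc_final == pytest.approx(0.2)

    def test_rc_within_interval_hull(self):
        scans = [self._scan(0.2, 0.4, 1.0), self._scan(0.35, 0.6, 1.0)]
        sel = select_rc(scans)
        assert 0.2 <= sel.rc_final <= 0.6

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_rc([])


class TestPredictOutcome:
    @pytest.mark.parametrize(
        "r,rc,expected",
        [(0.0, 0.30, "poor"), (1.0, 0.30, "good"), (0.30, 0.30, "good")],
    )
    def test_rule_and_tie(self, r, rc, expected):
        assert predict_outcome(PatientScore("x", 5, r), rc) == expected

    def test_invalid_rc(self):
        with pytest.raises(ValueError):
            predict_outcome(PatientScore("x", 5, 0.5), 0.0)


class TestEvaluate:
    def test_reference_confusion_matrix(self):
        """tp=6, fp=6, fn=0, tn=17 -> recall 1.0, precision 0.5, acc 23/29."""
        preds, truths = {}, {}
        for i in range(6):
            preds[f"tp{i}"], truths[f"tp{i}"] = "poor", "poor"
        for i in range(6):
            preds[f"fp{i}"], truths[f"fp{i}"] = "poor", "good"
        for i in range(17):
            preds[f"tn{i}"], truths[f"tn{i}"] = "good", "good"
        cm = evaluate(preds, truths)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (6, 6, 0, 17)
        assert cm.recall == 1.0
        assert cm.precision == 0.5
        assert cm.accuracy == pytest.approx(23 / 29)

    def test_perfect_predictions(self):
        preds = {f"p{i}": ("poor" if i < 4 else "good") for i in range(10)}
        cm = evaluate(preds, dict(preds))
        assert cm.recall == cm.precision == cm.accuracy == 1.0

    def test_id_mismatch_rejected(self):
        with pytest.raises(ValueError, match="ids differ"):
            evaluate({"a": "good"}, {"b": "good"})


class TestRobustness:
    def _patient(self, n_cols, poor_cols=(), seed=0):
        """Grid of toy patches; columns in poor_cols get stroma-located CD8."""
        rng = np.random.default_rng(seed)
        return [
            toy_patch(c in poor_cols, rng, "pt", row=r, col=c)
            for c in range(n_cols)
            for r in range(2)
        ]

    def test_full_fraction_identity(self):
        patches = self._patient(4)
        rep = subsample_robustness(patches, 1.0, "random", OracleModel(), 0.5)
        assert rep.subsample_outcomes == [rep.full_outcome]
        assert rep.agreement_rate == 1.0

    def test_homogeneous_patient_stable_under_random_halves(self):
        patches = self._patient(6)  # uniformly "good" patches
        rep = subsample_robustness(
            patches, 0.5, "random", OracleModel(), 0.5, n_repeats=10, seed=1
        )
        assert rep.full_outcome == "good"
        assert rep.agreement_rate >= 0.9

    def test_heterogeneous_halves_discordant(self):
        """Left columns good-like, right columns poor-like: the two
        contiguous halves predict opposite outcomes."""
        patches = self._patient(6, poor_cols=(3, 4, 5))
        rep = subsample_robustness(
            patches, 0.5, "contiguous", OracleModel(), 0.5
        )
        assert set(rep.subsample_outcomes) == {"good", "poor"}

    def test_too_few_patches_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            subsample_robustness(self._patient(1)[:2], 0.5, "random", OracleModel(), 0.5)

    def test_deterministic_given_seed(self):
        patches = self._patient(5, poor_cols=(2,))
        a = subsample_robustness(patches, 0.5, "random", OracleModel(), 0.5, seed=4)
        b = subsample_robustness(patches, 0.5, "random", OracleModel(), 0.5, seed=4)
        assert a.subsample_outcomes == b.subsample_outcomes
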