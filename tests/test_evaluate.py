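"""Metric contracts: sensitivity arithmetic, candidate matching, FROC/CPM
(including a hand-computed micro-cohort oracle), classifier metrics and the
diameter breakdown table."""

import numpy as np
import pandas as pd
import pytest

from nodulenet import evaluate as ev
from nodulenet.core import NoduleAnnotation


def _cands(rows):
    return pd.DataFrame(rows, columns=["seriesuid", "coordX", "coordY", "coordZ", "probability"])


def _ann(scan, x, d=10.0, y=0.0, z=0.0):
    return NoduleAnnotation(scan_id=scan, center_world=(x, y, z), diameter_mm=d)


# ---------------------------------------------------------------------------
# Sensitivity arithmetic
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "detected,missed,expected",
    [(551, 8, 98.6), (518, 41, 92.7), (168, 30, 84.8), (18, 0, 100.0), (0, 5, 0.0)],
)
def test_sensitivity_from_counts(detected, missed, expected):
    assert ev.sensitivity_from_counts(detected, missed) == expected


def test_sensitivity_undefined_for_zero_total():
    with pytest.raises(ValueError):
        ev.sensitivity_from_counts(0, 0)


def test_sensitivity_rounding_is_half_up():
    # 193/198 = 97.4747... -> 97.5 under half-up rounding
    assert ev.sensitivity_from_counts(193, 5) == 97.5


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def test_match_detections_basic_cases():
    ann = [_ann("s1", 0.0)]
    exact = _cands([{"seriesuid": "s1", "coordX": 0, "coordY": 0, "coordZ": 0, "probability": 0.9}])
    m = ev.match_detections(exact, ann)
    assert m.n_tp == 1 and m.n_fp == 0 and m.annotation_hit.all()
    far = _cands([{"seriesuid": "s1", "coordX": 99, "coordY": 0, "coordZ": 0, "probability": 0.9}])
    assert ev.match_detections(far, ann).n_fp == 1
    wrong_scan = _cands(
        [{"seriesuid": "s2", "coordX": 0, "coordY": 0, "coordZ": 0, "probability": 0.9}]
    )
    assert ev.match_detections(wrong_scan, ann).n_fp == 1


def test_double_detection_counts_one_tp_one_fp():
    ann = [_ann("s1", 0.0)]
    two = _cands(
        [
            {"seriesuid": "s1", "coordX": 0, "coordY": 0, "coordZ": 0, "probability": 0.9},
            {"seriesuid": "s1", "coordX": 1, "coordY": 0, "coordZ": 0, "probability": 0.8},
        ]
    )
    m = ev.match_detections(two, ann)
    assert m.n_tp == 1 and m.n_fp == 1


def test_fixed_radius_override():
    ann = [_ann("s1", 0.0, d=4.0)]  # radius 2 mm
    c = _cands([{"seriesuid": "s1", "coordX": 3, "coordY": 0, "coordZ": 0, "probability": 0.9}])
    assert ev.match_detections(c, ann).n_tp == 0
    assert ev.match_detections(c, ann, hit_radius_mm=5.0).n_tp == 1


# ---------------------------------------------------------------------------
# FROC / CPM
# ---------------------------------------------------------------------------

def test_froc_perfect_scorer_has_cpm_one():
    ann = [_ann("s1", 0.0), _ann("s2", 0.0)]
    cands = _cands(
        [
            {"seriesuid": "s1", "coordX": 0, "coordY": 0, "coordZ": 0, "probability": 0.9},
            {"seriesuid": "s2", "coordX": 0, "coordY": 0, "coordZ": 0, "probability": 0.8},
            {"seriesuid": "s1", "coordX": 500, "coordY": 0, "coordZ": 0, "probability": 0.1},
        ]
    )
    res = ev.froc(cands, ann, n_scans=2)
    assert res.cpm == pytest.approx(1.0)
    assert all(s == 1.0 for s in res.rate_sensitivities.values())


def test_froc_empty_scorer_has_cpm_zero():
    res = ev.froc(_cands([]), [_ann("s1", 0.0)], n_scans=1)
    assert res.cpm == 0.0


def test_froc_requires_annotations():
    with pytest.raises(ValueError):
        ev.froc(_cands([]), [], n_scans=1)


def test_froc_micro_cohort_matches_hand_computation():
    """2 scans, 3 nodules, 4 detections; the by-hand FROC table:

    threshold sweep (scores desc): 0.9 TP, 0.7 FP, 0.6 TP, 0.2 FP
      after 0.9: sens 1/3, FP/scan 0
      after 0.7: sens 1/3, FP/scan 0.5
      after 0.6: sens 2/3, FP/scan 0.5
      after 0.2: sens 2/3, FP/scan 1.0
    """
    ann = [_ann("s1", 0.0), _ann("s1", 50.0), _ann("s2", 0.0)]
    cands = _cands(
        [
            {"seriesuid": "s1", "coordX": 0, "coordY": 0, "coordZ": 0, "probability": 0.9},
            {"seriesuid": "s1", "coordX": 200, "coordY": 0, "coordZ": 0, "probability": 0.7},
            {"seriesuid": "s2", "coordX": 1, "coordY": 0, "coordZ": 0, "probability": 0.6},
            {"seriesuid": "s2", "coordX": 300, "coordY": 0, "coordZ": 0, "probability": 0.2},
        ]
    )
    res = ev.froc(cands, ann, n_scans=2)
    expected_points = [(0.0, 1 / 3), (0.5, 1 / 3), (0.5, 2 / 3), (1.0, 2 / 3)]
    assert np.allclose(res.points, expected_points)
    # interpolated rates: sens(1/8)=interp between (0,1/3)... but the curve
    # starts at (0, 1/3): rate 1/8 interpolates (0,1/3)-(0.5,1/3) -> 1/3
    assert res.rate_sensitivities[1 / 8] == pytest.approx(1 / 3)
    assert res.rate_sensitivities[1.0] == pytest.approx(2 / 3)
    assert res.rate_sensitivities[8.0] == pytest.approx(2 / 3)  # beyond curve


def test_froc_monotone_and_invariant_to_score_rescaling():
    rng = np.random.default_rng(0)
    ann = [_ann(f"s{i}", 0.0) for i in range(3)]
    rows = []
    for i in range(3):
        for j in range(6):
            rows.append(
                {
                    "seriesuid": f"s{i}",
                    "coordX": float(rng.choice([0, 100, 200])),
                    "coordY": 0.0,
                    "coordZ": 0.0,
                    "probability": float(rng.uniform()),
                }
            )
    cands = _cands(rows)
    res = ev.froc(cands, ann, n_scans=3)
    sens = [s for _, s in res.points]
    assert all(b >= a - 1e-12 for a, b in zip(sens, sens[1:]))
    # strictly increasing transform of the scores leaves the FROC unchanged
    warped = cands.copy()
    warped["probability"] = np.tanh(3 * warped["probability"]) ** 3
    res2 = ev.froc(warped, ann, n_scans=3)
    assert res2.cpm == pytest.approx(res.cpm)
    assert np.allclose(res2.points, res.points)


@pytest.mark.parametrize(
    "column,expected",
    [
        ((0.461, 0.583, 0.69, 0.77, 0.837, 0.868, 0.902), 0.730),
        ((0.521, 0.632, 0.75, 0.843, 0.872, 0.898, 0.916), 0.776),
        ((0.516, 0.627, 0.745, 0.82, 0.867, 0.894, 0.909), 0.768),
        ((0.671, 0.737, 0.81, 0.838, 0.881, 0.897, 0.92), 0.822),
        ((0.677, 0.741, 0.816, 0.85, 0.89, 0.905, 0.925), 0.829),
        ((1.0,) * 7, 1.0),
    ],
)
def test_cpm_from_sensitivities(column, expected):
    assert ev.cpm_from_sensitivities(column) == expected


def test_cpm_requires_exactly_seven():
    with pytest.raises(ValueError):
        ev.cpm_from_sensitivities([0.5] * 6)


# ---------------------------------------------------------------------------
# Classifier metrics
# ---------------------------------------------------------------------------

def test_classifier_metrics_cases():
    perfect = ev.classifier_metrics([1, 0, 1, 0], [1, 0, 1, 0])
    assert perfect == {"accuracy": 100.0, "sensitivity": 100.0, "specificity": 100.0}
    all_pos = ev.classifier_metrics([1, 1, 1, 1], [1, 1, 0, 0])
    assert all_pos["accuracy"] == 50.0
    assert all_pos["sensitivity"] == 100.0
    assert all_pos["specificity"] == 0.0
    single = ev.classifier_metrics([1, 1], [1, 1])
    assert np.isnan(single["specificity"])


def test_classifier_metrics_match_direct_counting():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, size=10)
    p = rng.integers(0, 2, size=10)
    m = ev.classifier_metrics(p, y)
    tp = np.sum((p == 1) & (y == 1))
    tn = np.sum((p == 0) & (y == 0))
    assert m["accuracy"] == pytest.approx(100 * (tp + tn) / 10, abs=0.01)


# ---------------------------------------------------------------------------
# Diameter breakdown
# ---------------------------------------------------------------------------

def test_diameter_breakdown_bins_and_total():
    ann = [
        _ann("s", 0.0, d=4.0),
        _ann("s", 100.0, d=5.0),   # 5 mm -> left-closed 5-10 bin
        _ann("s", 200.0, d=12.0),
        _ann("s", 300.0, d=25.0),
    ]
    cands = _cands(
        [
            {"seriesuid": "s", "coordX": x, "coordY": 0, "coordZ": 0, "probability": 0.9}
            for x in (0.0, 200.0, 300.0)
        ]
    )
    match = ev.match_detections(cands, ann)
    table = ev.diameter_breakdown(match, ann)
    rows = {r.diameter_mm: r for r in table.itertuples()}
    assert rows["3-5"].detected == 1 and rows["3-5"].missed == 0
    assert rows["5-10"].detected == 0 and rows["5-10"].missed == 1
    assert rows[">20"].detected == 1
    assert rows["Total"].detected == sum(
        rows[k].detected for k in ("3-5", "5-10", "10-20", ">20")
    )
    assert rows["Total"].sensitivity == 75.0
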