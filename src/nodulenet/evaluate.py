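"""Detection and classification metrics: sensitivity tables, candidate
matching, FROC curves and the CPM summary.

The hit criterion follows the LUNA16 challenge convention: a candidate
counts for an annotation when its centre lies within the nodule radius
(diameter / 2, in mm) of the annotation centre. Matching is greedy in
descending score and each annotation is credited at most once; surplus
candidates on an already-credited nodule count as false positives.

The CPM (competition performance metric) is the mean sensitivity at the
seven false-positive rates {1/8, 1/4, 1/2, 1, 2, 4, 8} per scan, read off
the FROC curve with linear interpolation between operating points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import NoduleAnnotation

__all__ = [
    "CPM_RATES",
    "FROCResult",
    "MatchResult",
    "sensitivity_from_counts",
    "match_detections",
    "froc",
    "cpm_from_sensitivities",
    "classifier_metrics",
    "diameter_breakdown",
    "plot_froc",
    "DIAMETER_BINS",
]

CPM_RATES = (1 / 8, 1 / 4, 1 / 2, 1.0, 2.0, 4.0, 8.0)
DIAMETER_BINS = ((3.0, 5.0), (5.0, 10.0), (10.0, 20.0), (20.0, float("inf")))


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class FROCResult:
    """FROC operating points plus the seven-rate sensitivities and CPM."""

    points: list[tuple[float, float]]  # (FP/scan, sensitivity), FP ascending
    rate_sensitivities: dict[float, float]
    cpm: float

    def __post_init__(self) -> None:
        sens = [s for _, s in self.points]
        if any(not 0 <= s <= 1 for s in sens):
            raise ValueError("sensitivities must lie in [0, 1]")


@dataclass
class MatchResult:
    """Bookkeeping of one candidates-vs-annotations matching pass."""

    annotation_hit: np.ndarray  # (n_annotations,) bool
    detection_is_tp: np.ndarray  # (n_detections,) bool, score-descending order
    detection_order: np.ndarray  # indices sorting the input by descending score
    n_tp: int
    n_fp: int

    @property
    def n_detected(self) -> int:
        return int(self.annotation_hit.sum())


def sensitivity_from_counts(detected: int, missed: int, decimals: int = 1) -> float:
    """Sensitivity as a percentage, 100 * detected / (detected + missed)."""
    if detected < 0 or missed < 0:
        raise ValueError("counts must be non-negative")
    total = detected + missed
    if total == 0:
        raise ValueError("sensitivity undefined for zero nodules")
    return _round_half_up(100.0 * detected / total, decimals)


def _require_candidates(candidates: pd.DataFrame) -> pd.DataFrame:
    cols = ["seriesuid", "coordX", "coordY", "coordZ", "probability"]
    missing = [c for c in cols if c not in candidates.columns]
    if missing:
        raise ValueError(f"candidates missing column(s): {', '.join(missing)}")
    return candidates


def match_detections(
    candidates: pd.DataFrame,
    annotations: Sequence[NoduleAnnotation],
    hit_radius_mm: Optional[float] = None,
) -> MatchResult:
    """Greedily match scored world-space candidates to annotations.

    ``hit_radius_mm`` overrides the default nodule-radius criterion with a
    fixed radius. A candidate hits an annotation of the same scan when its
    centre lies within the hit radius; each annotation is credited once, to
    its highest-scoring hit.
    """
    candidates = _require_candidates(candidates)
    order = np.argsort(-candidates["probability"].to_numpy(), kind="stable")
    ann_hit = np.zeros(len(annotations), dtype=bool)
    det_tp = np.zeros(len(candidates), dtype=bool)
    centers = np.array([a.center_world for a in annotations]).reshape(-1, 3)
    radii = np.array(
        [hit_radius_mm if hit_radius_mm is not None else a.diameter_mm / 2 for a in annotations]
    )
    scan_ids = np.array([a.scan_id for a in annotations])
    xyz = candidates[["coordX", "coordY", "coordZ"]].to_numpy(dtype=float)
    cand_scan = candidates["seriesuid"].astype(str).to_numpy()
    for rank, ci in enumerate(order):
        if not len(annotations):
            break
        d = np.linalg.norm(centers - xyz[ci], axis=1)
        eligible = (~ann_hit) & (d <= radii) & (scan_ids == cand_scan[ci])
        if eligible.any():
            ann_hit[np.flatnonzero(eligible)[d[eligible].argmin()]] = True
            det_tp[rank] = True
    n_tp = int(det_tp.sum())
    return MatchResult(
        annotation_hit=ann_hit,
        detection_is_tp=det_tp,
        detection_order=order,
        n_tp=n_tp,
        n_fp=len(candidates) - n_tp,
    )


def froc(
    candidates: pd.DataFrame,
    annotations: Sequence[NoduleAnnotation],
    n_scans: int,
    rates: Sequence[float] = CPM_RATES,
    hit_radius_mm: Optional[float] = None,
) -> FROCResult:
    """FROC curve and CPM from scored candidates across a scan cohort.

    The score threshold sweeps every distinct candidate score; sensitivity
    at each target rate is linearly interpolated between the bracketing
    operating points (0 at rate 0; the final sensitivity beyond the curve).
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    if not len(annotations):
        raise ValueError("no annotations to evaluate against")
    candidates = _require_candidates(candidates)
    match = match_detections(candidates, annotations, hit_radius_mm)
    scores = candidates["probability"].to_numpy(dtype=float)[match.detection_order]
    is_tp = match.detection_is_tp
    points: list[tuple[float, float]] = []
    n_ann = len(annotations)
    if len(scores):
        tp_cum = np.cumsum(is_tp)
        fp_cum = np.cumsum(~is_tp)
        # operating point after the last candidate of each distinct score
        distinct_ends = np.flatnonzero(np.diff(scores, append=-np.inf) != 0)
        for i in distinct_ends:
            points.append((fp_cum[i] / n_scans, tp_cum[i] / n_ann))
    fp_axis = np.array([0.0] + [p[0] for p in points])
    sens_axis = np.array([0.0] + [p[1] for p in points])
    rate_sens = {}
    for r in rates:
        if len(points) and r >= fp_axis[-1]:
            rate_sens[r] = float(sens_axis[-1])
        else:
            rate_sens[r] = float(np.interp(r, fp_axis, sens_axis))
    cpm = float(np.mean(list(rate_sens.values())))
    return FROCResult(points=points, rate_sensitivities=rate_sens, cpm=cpm)


def cpm_from_sensitivities(sensitivities: Sequence[float], decimals: int = 3) -> float:
    """CPM = arithmetic mean of the seven fixed-rate sensitivities."""
    if len(sensitivities) != 7:
        raise ValueError(f"expected 7 sensitivities, got {len(sensitivities)}")
    s = np.asarray(sensitivities, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("sensitivities must lie in [0, 1]")
    return _round_half_up(float(s.mean()), decimals)


def classifier_metrics(
    predictions: Sequence[int], labels: Sequence[int], decimals: int = 2
) -> dict[str, float]:
    """Accuracy / sensitivity / specificity as percentages.

    With single-class labels the undefined rate comes back as ``nan``.
    """
    p = np.asarray(predictions).astype(int)
    y = np.asarray(labels).astype(int)
    if p.shape != y.shape:
        raise ValueError("predictions and labels must have the same length")
    tp = int(((p == 1) & (y == 1)).sum())
    tn = int(((p == 0) & (y == 0)).sum())
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    return {
        "accuracy": _round_half_up(100.0 * (tp + tn) / len(y), decimals),
        "sensitivity": _round_half_up(100.0 * tp / n_pos, decimals) if n_pos else float("nan"),
        "specificity": _round_half_up(100.0 * tn / n_neg, decimals) if n_neg else float("nan"),
    }


def plot_froc(
    results: "FROCResult | dict[str, FROCResult]",
    path: str,
    title: str = "FROC",
) -> None:
    """Write an FROC curve figure (log-scaled FP/scan axis) to ``path``.

    Accepts one result or a name -> result mapping for model comparison.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(results, FROCResult):
        results = {"model": results}
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for name, res in results.items():
        fp = [max(p, 1 / 16) for p, _ in res.points]
        sens = [s for _, s in res.points]
        ax.plot(fp, sens, marker="o", ms=3, label=f"{name} (CPM {res.cpm:.3f})")
    ax.set_xscale("log", base=2)
    ax.set_xticks(list(CPM_RATES))
    ax.set_xticklabels(["1/8", "1/4", "1/2", "1", "2", "4", "8"])
    ax.set_xlabel("False positives per scan")
    ax.set_ylabel("Sensitivity")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.grid(alpha=0.3)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def diameter_breakdown(
    match: MatchResult,
    annotations: Sequence[NoduleAnnotation],
    bins: Sequence[tuple[float, float]] = DIAMETER_BINS,
) -> pd.DataFrame:
    """Detected/missed/sensitivity per diameter bin plus a Total row.

    Bins are left-closed, right-open ([lo, hi)), except the last which is
    unbounded above; so a 5 mm nodule falls in the 5-10 mm bin.
    """
    rows = []
    diameters = np.array([a.diameter_mm for a in annotations])
    hits = match.annotation_hit
    for lo, hi in bins:
        in_bin = (diameters >= lo) & (diameters < hi)
        det = int(hits[in_bin].sum())
        mis = int(in_bin.sum()) - det
        label = f"{lo:g}-{hi:g}" if np.isfinite(hi) else f">{lo:g}"
        rows.append(
            {
                "diameter_mm": label,
                "detected": det,
                "missed": mis,
                "sensitivity": sensitivity_from_counts(det, mis) if det + mis else float("nan"),
            }
        )
    det_t = sum(r["detected"] for r in rows)
    mis_t = sum(r["missed"] for r in rows)
    rows.append(
        {
            "diameter_mm": "Total",
            "detected": det_t,
            "missed": mis_t,
            "sensitivity": sensitivity_from_counts(det_t, mis_t) if det_t + mis_t else float("nan"),
        }
    )
    return pd.DataFrame(rows)
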