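"""Compute an FROC curve and CPM for a hand-built candidate list, and plot
it the way detection studies report it."""

import pandas as pd

from nodulenet import evaluate
from nodulenet.core import NoduleAnnotation

annotations = [
    NoduleAnnotation("scan-a", (0.0, 0.0, 0.0), 10.0),
    NoduleAnnotation("scan-a", (50.0, 0.0, 0.0), 6.0),
    NoduleAnnotation("scan-b", (0.0, 0.0, 0.0), 14.0),
]
candidates = pd.DataFrame(
    [
        # (scan, x, y, z, score): two hits, one miss, two false positives
        {"seriesuid": "scan-a", "coordX": 1.0, "coordY": 0, "coordZ": 0, "probability": 0.95},
        {"seriesuid": "scan-b", "coordX": 2.0, "coordY": 0, "coordZ": 0, "probability": 0.80},
        {"seriesuid": "scan-a", "coordX": 200.0, "coordY": 0, "coordZ": 0, "probability": 0.60},
        {"seriesuid": "scan-b", "coordX": 300.0, "coordY": 0, "coordZ": 0, "probability": 0.40},
    ]
)

result = evaluate.froc(candidates, annotations, n_scans=2)
print("FROC operating points (FP/scan, sensitivity):")
for fp, sens in result.points:
    print(f"  ({fp:.2f}, {sens:.3f})")
print("sensitivity at the seven CPM rates:")
for rate, sens in result.rate_sensitivities.items():
    print(f"  {rate:>5}: {sens:.3f}")
print(f"CPM = {result.cpm:.3f}")

evaluate.plot_froc(result, "scratch/example_froc.png", title="Hand-built cohort")
print("curve written to scratch/example_froc.png")

# A candidate hits a nodule when its centre lies within the nodule radius;
# the CPM is the mean sensitivity at 1/8 ... 8 FP/scan, so a scorer that
# ranks all true nodules above all false positives approaches CPM 1.
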