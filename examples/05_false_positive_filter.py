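"""Train the desk-scale 3D multiscale-merge classifier on phantom patches
and fuse its single-scale variants with AdaBoost weights.

Takes a few minutes on one CPU core (3D convolutions at three patch scales).
"""

import numpy as np

from nodulenet import fpfilter, phantom

spec = fpfilter.MSMSpec.tiny()
train = phantom.generate_multiscale_dataset(0, 12, 12, difficulty=0.0)
held = phantom.generate_multiscale_dataset(99, 8, 8, difficulty=0.0)

msm = fpfilter.build_msm(spec, seed=0)
log = fpfilter.train_classifier(
    msm, train, fpfilter.TrainConfig(epochs=10, batch_size=6, seed=0)
)
probs = fpfilter.predict_proba(msm, held)
labels = np.array([c.label for c in held])
print(f"MSM training accuracy {log[-1]['accuracy']:.3f}; "
      f"held-out accuracy {(probs.argmax(1) == labels).mean():.3f}")

weights = fpfilter.crossval_weights(
    train, n_folds=2, seed=0, spec=spec,
    config=fpfilter.TrainConfig(epochs=8, batch_size=6, seed=0),
)
for i, (a, e) in enumerate(zip(weights.alphas, weights.epsilons), 1):
    print(f"CNN{i}: held-out error eps = {e:.3f} -> fusion weight alpha = {a:.3f}")

# alpha = 0.5 ln((1-eps)/eps): an accurate member gets a large positive
# weight, a coin-flip member gets ~0, and the fused score is the raw
# weighted sum alpha1*p1 + alpha2*p2 + alpha3*p3.
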