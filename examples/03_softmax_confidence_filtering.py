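"""Softmax confidences and strict threshold filtering.

A closed-set identifier ends in a softmax over the K individuals; the
maximum output is the prediction's confidence. Pseudo-labeling keeps an
unlabeled image only if that confidence is strictly above a threshold, so
threshold 0 admits everything and the training-set size shrinks toward
the labeled pool as the threshold approaches 1.
"""

import numpy as np

from herdid import DEFAULT_THRESHOLD_GRID, filter_confident, softmax
from herdid.classify import ConfidenceVector

cv = softmax([1.0, 2.0, 3.0])
print(f"softmax(1, 2, 3) = {np.round(cv.p, 5)}")
print(f"predicted class {cv.predicted_label} with confidence {cv.confidence:.5f}")

rng = np.random.default_rng(0)
predictions = []
for i in range(500):
    z = rng.normal(0, 4, size=10)  # logit spread controls confidence spread
    c = softmax(z)
    predictions.append((f"img{i:03d}", c))

print("\nthreshold  kept")
for t in DEFAULT_THRESHOLD_GRID:
    kept = filter_confident(predictions, t)
    print(f"{t:<10} {len(kept)}")

# The kept-count column reproduces the characteristic near-exponential decay
# of training-set size as the confidence threshold approaches 1.
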