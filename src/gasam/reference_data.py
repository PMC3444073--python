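"""Published reference confusion matrices for the 13-species study system.

Average spectral-angle-mapper confusion matrices (over 40 genetic-algorithm
runs, 17 leaves per species per half) reported for the thirteen broadleaf
species of the laboratory leaf-emissivity discrimination study this package
models. Rows are true species, columns predicted. They serve as arithmetic
fixtures: recomputing 100 * trace / total must reproduce the published
overall accuracies.
"""
from __future__ import annotations

import numpy as np

from .sam import ConfusionMatrix

#: Species order of the published matrices.
REFERENCE_LABELS = (
    "PL", "RH", "SP", "TP", "AP", "AN", "CS", "FJ", "GB", "HH", "IL", "LS", "PO",
)

_TRAINING_COUNTS = [
    [17, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    [0, 15, 0, 0, 0, 0, 0, 1, 0, 0, 0, 1, 0],
    [0, 0, 15, 0, 0, 0, 0, 0, 0, 0, 2, 0, 0],
    [0, 0, 0, 17, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 17, 0, 0, 0, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 17, 0, 0, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 2, 15, 0, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 0, 0, 17, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 0, 0, 0, 17, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 17, 0, 0, 0],
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 17, 0, 0],
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 16, 0],
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 17],
]

_TESTING_COUNTS = [
    [12, 0, 0, 0, 0, 0, 0, 0, 0, 0, 2, 3, 0],
    [0, 13, 0, 4, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    [0, 0, 12, 0, 0, 0, 5, 0, 0, 0, 0, 0, 0],
    [0, 2, 0, 12, 0, 0, 0, 0, 0, 0, 0, 3, 0],
    [0, 0, 0, 0, 17, 0, 0, 0, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 17, 0, 0, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 0, 17, 0, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 0, 0, 17, 0, 0, 0, 0, 0],
    [0, 0, 0, 1, 0, 0, 0, 0, 16, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 17, 0, 0, 0],
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 17, 0, 0],
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 17, 0],
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 17],
]


def reference_training_confusion() -> ConfusionMatrix:
    """Published average training-set confusion matrix (accuracy 96.83%)."""
    return ConfusionMatrix(
        labels=REFERENCE_LABELS, counts=np.array(_TRAINING_COUNTS, dtype=int)
    )


def reference_testing_confusion() -> ConfusionMatrix:
    """Published average testing-set confusion matrix.

    Its exact recomputed accuracy is 100*201/221 = 90.95%; the published
    headline figure of 90.50% reflects rounding of the underlying 40-run
    average rather than this printed matrix.
    """
    return ConfusionMatrix(
        labels=REFERENCE_LABELS, counts=np.array(_TESTING_COUNTS, dtype=int)
    )
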