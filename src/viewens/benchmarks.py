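"""Published reference operating points for nine ECG screening test sets.

These are the reported per-dataset results (percentages) of a
large-scale normal/abnormal ECG screening evaluation on nine test
partitions (DS1..DS9) drawn from different collection sites.  Four
classifier variants are tabulated: a single network scored on one fixed
crop ("simple"), the same network under test-time crop averaging
("subview"), the self-validated variant under crop averaging
("implicit"), and the probability-averaged fusion of the last two
("fusion").

They serve two purposes here: worked examples whose derived quantities
(GMean and Acc identities, mean +/- SD summaries, exact paired
signed-rank p-values) validate the metrics suite, and realistic inputs
for the reporting helpers.  They are *inputs*, not outputs, of this
package.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DATASETS",
    "EXPLICIT_SIMPLE",
    "EXPLICIT_SUBVIEW",
    "IMPLICIT_SIMPLE",
    "IMPLICIT_SUBVIEW",
    "FUSION",
    "CLASS_COUNTS",
]

DATASETS = tuple(f"DS{i}" for i in range(1, 10))

# columns: Sp%, Se%, GMean%, Acc%, AUC
EXPLICIT_SIMPLE = {
    "sp": np.array([88.84, 88.63, 86.58, 82.75, 79.52, 81.98, 77.81, 78.31, 83.97]),
    "se": np.array([76.95, 79.55, 77.69, 84.81, 86.20, 84.90, 84.71, 84.74, 75.40]),
    "gmean": np.array([82.68, 83.97, 82.01, 83.77, 82.79, 83.43, 81.19, 81.47, 79.57]),
    "acc": np.array([85.41, 85.99, 84.03, 83.91, 83.23, 83.57, 81.28, 81.71, 81.48]),
    "auc": np.array([0.9034, 0.9174, 0.8972, 0.9096, 0.9084, 0.9101, 0.8905, 0.8913, 0.8661]),
}

EXPLICIT_SUBVIEW = {
    "sp": np.array([89.85, 89.92, 87.81, 83.67, 80.70, 82.80, 78.60, 79.46, 84.62]),
    "se": np.array([76.81, 80.05, 78.03, 85.09, 86.64, 85.49, 85.17, 85.23, 76.04]),
    "gmean": np.array([83.07, 84.84, 82.77, 84.38, 83.62, 84.13, 81.82, 82.30, 80.22]),
    "acc": np.array([86.09, 87.05, 85.01, 84.47, 84.00, 84.26, 81.90, 82.51, 82.13]),
    "auc": np.array([0.9123, 0.9272, 0.9074, 0.9153, 0.9144, 0.9169, 0.8964, 0.8976, 0.8778]),
}

IMPLICIT_SIMPLE = {
    "sp": np.array([91.74, 91.73, 89.30, 87.31, 85.80, 86.98, 83.71, 83.53, 87.07]),
    "se": np.array([73.25, 76.51, 74.65, 82.30, 82.18, 81.30, 80.09, 80.40, 71.34]),
    "gmean": np.array([81.97, 83.77, 81.64, 84.77, 83.97, 84.09, 81.88, 81.95, 78.81]),
    "acc": np.array([86.40, 87.30, 85.10, 84.49, 83.79, 83.90, 81.89, 81.87, 82.51]),
    "auc": np.array([0.9047, 0.9228, 0.9030, 0.9131, 0.9067, 0.9098, 0.8872, 0.8891, 0.8635]),
}

IMPLICIT_SUBVIEW = {
    "sp": np.array([92.58, 92.45, 90.23, 88.15, 86.78, 88.21, 84.19, 84.79, 87.24]),
    "se": np.array([73.52, 76.40, 74.88, 82.30, 82.34, 81.60, 80.46, 80.97, 70.91]),
    "gmean": np.array([82.50, 84.04, 82.20, 85.18, 84.53, 84.84, 82.30, 82.86, 78.65]),
    "acc": np.array([87.08, 87.78, 85.84, 84.85, 84.31, 84.62, 82.31, 82.77, 82.51]),
    "auc": np.array([0.9149, 0.9318, 0.9112, 0.9192, 0.9135, 0.9168, 0.8943, 0.8962, 0.8733]),
}

FUSION = {
    "sp": np.array([91.81, 91.47, 89.57, 86.64, 84.69, 86.31, 82.08, 82.69, 86.46]),
    "se": np.array([74.96, 78.27, 76.29, 84.18, 84.82, 83.81, 83.02, 83.32, 73.37]),
    "gmean": np.array([82.96, 84.61, 82.66, 85.40, 84.76, 85.05, 82.55, 83.00, 79.64]),
    "acc": np.array([86.95, 87.64, 85.76, 85.25, 84.76, 84.96, 82.55, 83.02, 82.66]),
    "auc": np.array([0.9172, 0.9324, 0.9122, 0.9215, 0.9187, 0.9213, 0.9000, 0.9011, 0.8806]),
}

#: (normals, abnormals) per test partition.
CLASS_COUNTS = {
    "DS1": (8387, 3402),
    "DS2": (25020, 10249),
    "DS3": (16210, 6508),
    "DS4": (4911, 6352),
    "DS5": (10351, 12948),
    "DS6": (9703, 11529),
    "DS7": (9713, 9831),
    "DS8": (6944, 7781),
    "DS9": (2289, 935),
}
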