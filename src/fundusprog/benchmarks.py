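"""Published AREDS benchmark statistics used as reference inputs.

These are the printed summary tables of the AREDS-trained reference
model for the three studied visit gaps (T = 4, 6, 8 in 6-month units):
raw pair-label counts of the full cohort, and the validation/test
confusion matrices and AUC values of the trained classifier.  The
package recomputes every derived quantity (proportions, accuracies,
binarized sensitivity/specificity, cross-gap means) from these counts;
nothing here is a result of this package's own training.
"""

from __future__ import annotations

import numpy as np

#: total number of AREDS participants and the subject-level split sizes
N_SUBJECTS = 4628
SPLIT_SIZES = (4166, 232, 230)

#: raw pair-label counts per gap: {T: (n_y0, n_y1, n_y2)}
PAIR_COUNTS = {
    4: (42205, 1683, 6432),
    6: (35706, 1999, 5157),
    8: (29835, 2180, 4170),
}

#: printed pair-label percentages per gap (one decimal as published)
PAIR_PERCENTS = {
    4: (83.9, 3.3, 12.8),
    6: (83.3, 4.6, 12.1),
    8: (82.5, 6.0, 11.5),
}

#: validation/test confusion matrices of the reference classifier
#: (rows = actual 3-class label, columns = predicted)
CONFUSION_VAL = {
    4: np.array([[327, 114, 7], [24, 62, 10], [10, 55, 278]]),
    6: np.array([[290, 125, 10], [19, 78, 20], [4, 38, 233]]),
    8: np.array([[283, 93, 10], [25, 96, 16], [3, 20, 198]]),
}
CONFUSION_TEST = {
    4: np.array([[329, 100, 10], [16, 58, 10], [12, 54, 295]]),
    6: np.array([[274, 103, 9], [15, 74, 19], [3, 48, 232]]),
    8: np.array([[257, 91, 14], [14, 82, 21], [2, 24, 213]]),
}

#: printed accuracies alongside the matrices.  Note: the T=8 validation
#: accuracy as printed (0.7724) is inconsistent with its own matrix,
#: whose trace/total is 577/744 = 0.7755; all five other entries agree
#: with their matrices to 4 decimals.
ACCURACY_VAL = {4: 0.752, 6: 0.7356, 8: 0.7724}
ACCURACY_TEST = {4: 0.7715, 6: 0.7465, 8: 0.7688}

#: printed Hand-Till multiclass AUC values
AUC_VAL = {4: 0.8832, 6: 0.9059, 8: 0.9199}
AUC_TEST = {4: 0.896, 6: 0.8988, 8: 0.9209}

#: headline cross-gap means of the test metrics
MEAN_TEST_ACCURACY = 0.762
MEAN_TEST_AUC = 0.905

#: binarized current-visit grading triples derived from the test
#: matrices, per gap: (sensitivity, specificity, accuracy)
BINARIZED_TEST = {
    4: (0.817, 0.962, 0.902),
    6: (0.819, 0.943, 0.898),
    8: (0.891, 0.926, 0.915),
}
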