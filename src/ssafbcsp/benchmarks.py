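"""Published per-subject benchmark results on BCI Competition IV-2a.

Cross-session (train on session T, test on session E) four-class
motor-imagery accuracies in percent for subjects A01-A09, as reported in
the literature for the uniform-bank FBCSP-SVM baseline, three deep
decoders, and the sparrow-search-optimized FBCSP pipeline with three
classifier backends. These are reference numbers for table arithmetic
(column means, standard deviations, kappa) — nothing in the decoding
pipeline depends on them.
"""

from __future__ import annotations

SUBJECTS = ("A01", "A02", "A03", "A04", "A05", "A06", "A07", "A08", "A09")

#: Cross-session accuracy (%) per subject, uniform filter-bank CSP + SVM.
FBCSP_SVM = (77.78, 55.56, 79.51, 63.19, 53.47, 46.88, 86.81, 81.25, 68.06)

#: Deep ConvNet baseline.
DEEP_CONVNET = (78.13, 45.14, 85.42, 67.01, 77.43, 53.13, 86.46, 78.13, 79.17)

#: EEGNet-8,2 baseline.
EEGNET = (79.51, 61.11, 88.54, 71.53, 71.18, 59.03, 71.53, 80.56, 75.35)

#: FBCNet baseline.
FBCNET = (85.42, 60.42, 90.63, 76.39, 74.31, 53.82, 84.38, 79.51, 80.90)

#: Sparrow-search-optimized filter bank, LDA / SVM / KNN classifiers.
SSA_FBCSP_LDA = (92.01, 77.43, 93.40, 91.67, 86.81, 82.64, 94.79, 95.14, 95.49)
SSA_FBCSP_SVM = (88.89, 77.08, 90.28, 88.54, 76.74, 78.13, 92.36, 93.06, 91.32)
SSA_FBCSP_KNN = (86.81, 67.71, 92.01, 85.42, 69.79, 71.18, 92.01, 89.58, 92.01)

#: Chance agreement for the balanced four-class task.
P_E_FOUR_CLASS = 0.25

#: Session layout of the dataset: trials per session, sessions per subject.
TRIALS_PER_SESSION = 288
SESSIONS_PER_SUBJECT = 2
N_SUBJECTS = len(SUBJECTS)
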