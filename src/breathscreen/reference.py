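"""Published reference results from the clinical breath-screening study.

The clinical GC/MS cohort behind this pipeline was never deposited, but
the study's printed result tables — the top-10 VOC combinations ranked by
ACC, TPR and TNR, with their rates rounded to one decimal — are public.
They are transcribed here as plain data so that the ranking, frequency
and metric-identity machinery can be exercised and checked against the
printed numbers without any model training.

Each rank-table entry is ``(rank, acc, tpr, tnr, subset)`` with rates in
percent. Note: the printed TNR-ranked table's first row (ACC 84.6 with
TPR 82.2 / TNR 89.7) is internally inconsistent with the cohort sizes
(the implied integer counts give ACC 83.8); it is transcribed verbatim
and not used for arithmetic checks.
"""

from __future__ import annotations

import pandas as pd

#: enrolled cohort: class sizes, stage mix, smoking mix
N_CANCER = 107
N_HEALTHY = 29
STAGE_COUNTS = {"I": 55, "II": 15, "III": 28, "IV": 9}
SMOKING_COUNTS_CANCER = {"smoker": 47, "ex-smoker": 15, "nonsmoker": 45}
SMOKING_COUNTS_HEALTHY = {"smoker": 5, "ex-smoker": 3, "nonsmoker": 21}

#: headline result: five VOCs suffice for 89.0% LOOCV screening accuracy
BEST_ACC_SUBSET = ("CHN", "Methanol", "CH3CN", "Isoprene", "1-Propanol")
#: best-TPR five-VOC combination (used for the stage-distance analysis)
BEST_TPR_SUBSET = ("Butane", "Ethanol", "Acetone", "C2H3CN", "Toluene")

#: top-10 five-VOC combinations ranked by ACC
TOP10_ACC_5VOC = [
    (1, 89.0, 92.5, 75.9, ("CHN", "Methanol", "CH3CN", "Isoprene", "1-Propanol")),
    (2, 88.2, 91.6, 75.9, ("CHN", "CH3CN", "C2H3CN", "Isoprene", "CHCl3")),
    (2, 88.2, 93.5, 69.0, ("Methanol", "Acetone", "C2H3CN", "Isoprene", "1-Propanol")),
    (2, 88.2, 91.6, 75.9, ("Methanol", "Isoprene", "Xylene", "Unknown-1", "C8H17OH")),
    (2, 88.2, 92.5, 72.4, ("Butane", "CH3CN", "Isoprene", "1-Propanol", "Xylene")),
    (6, 86.8, 91.6, 69.0, ("CHN", "Methanol", "CH3CN", "1-Propanol", "Methylcyclohexane")),
    (6, 86.8, 89.7, 75.9, ("CHN", "Butane", "CH3CN", "Isoprene", "CHCl3")),
    (6, 86.8, 92.5, 65.5, ("C2H3CN", "Isoprene", "1-Propanol", "Unknown-1", "C8H17OH")),
    (9, 86.0, 91.6, 65.5, ("CHN", "Ethanol", "Isoprene", "1-Propanol", "Toluene")),
    (9, 86.0, 87.9, 79.3, ("CHN", "CH3CN", "Isoprene", "CHCl3", "Xylene")),
]

#: top-10 five-VOC combinations ranked by TPR
TOP10_TPR_5VOC = [
    (1, 84.6, 94.4, 48.3, ("Butane", "Ethanol", "Acetone", "C2H3CN", "Toluene")),
    (2, 88.2, 93.5, 69.0, ("Methanol", "Acetone", "C2H3CN", "Isoprene", "1-Propanol")),
    (3, 86.0, 92.5, 62.1, ("Ethanol", "CH3CN", "C2H3CN", "Isoprene", "1-Propanol")),
    (3, 89.0, 92.5, 75.9, ("CHN", "Methanol", "CH3CN", "Isoprene", "1-Propanol")),
    (3, 84.6, 92.5, 55.2, ("CHN", "Ethanol", "C2H3CN", "1-Propanol", "CHCl3")),
    (3, 88.2, 92.5, 72.4, ("Butane", "CH3CN", "Isoprene", "1-Propanol", "Xylene")),
    (3, 85.3, 92.5, 58.6, ("Ethanol", "CH3CN", "Acetone", "2-Propanol", "C2H3CN")),
    (3, 85.3, 92.5, 58.6, ("Ethanol", "CH3CN", "Methylcyclohexane", "Unknown-1", "C8H17OH")),
    (3, 86.8, 92.5, 65.5, ("C2H3CN", "Isoprene", "1-Propanol", "Unknown-1", "C8H17OH")),
    (10, 86.8, 91.6, 69.0, ("CHN", "Methanol", "CH3CN", "1-Propanol", "Methylcyclohexane")),
]

#: top-10 four-VOC combinations ranked by TNR
TOP10_TNR_4VOC = [
    (1, 84.6, 82.2, 89.7, ("CHN", "Isoprene", "Xylene", "Limonene")),
    (2, 89.0, 86.9, 86.2, ("CHN", "CH3CN", "Isoprene", "CHCl3")),
    (2, 88.2, 76.6, 86.2, ("CHN", "Methanol", "2-Propanol", "Nonanal")),
    (2, 84.6, 78.5, 86.2, ("CHN", "CH3CN", "CHCl3", "Dichlorobenzene")),
    (5, 88.2, 77.6, 82.8, ("CHN", "Methanol", "CH3CN", "C2H3CN")),
    (5, 85.3, 79.4, 82.8, ("CHN", "Methanol", "Isoprene", "Limonene")),
    (5, 86.0, 72.9, 82.8, ("Methanol", "CH3CN", "Isoprene", "Limonene")),
    (5, 85.3, 78.5, 82.8, ("CH3CN", "Acetone", "Unknown-1", "C8H17OH")),
    (5, 86.8, 71.0, 82.8, ("CH3CN", "Isoprene", "Methylcyclohexane", "Nonanal")),
    (10, 86.8, 83.2, 79.3, ("CHN", "Methanol", "CH3CN", "CHCl3")),
]

#: the eight VOCs most frequent across the three rankings, and the
#: published LOOCV rates quoted for training on all eight together
EIGHT_VOC_PANEL = ("Isoprene", "CHN", "1-Propanol", "CH3CN", "Methanol",
                   "C2H3CN", "Ethanol", "CHCl3")
EIGHT_VOC_RATES = {"acc": 84.6, "tpr": 91.6, "tnr": 58.6}


def rank_table_frame(rows) -> pd.DataFrame:
    """A transcribed rank table as the same DataFrame layout
    :func:`breathscreen.search.rank_subsets` produces."""
    return pd.DataFrame(
        {
            "rank": [r[0] for r in rows],
            "acc": [r[1] for r in rows],
            "tpr": [r[2] for r in rows],
            "tnr": [r[3] for r in rows],
            "subset": [tuple(r[4]) for r in rows],
        }
    )
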