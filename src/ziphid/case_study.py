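"""Published reference confusion tables from the western North Atlantic
beaked-whale case study.

Two bin-count tables accompany the field evaluation of the classification
pipelines on two months of HARP data: the targeted pipeline with a hard
negative filter across all case-study sites, and the three-way comparison at
site Wilmington Canyon (WC) between the targeted pipelines (hard negative
filter, Th; moderate negative filter, Tm) and the generalized pipeline (G).
Values are counts of 5-minute bins per (manually labeled true class,
predicted class); italicized truth rows of the originals (ambiguous manual
annotations such as "Mm | Me", and the unannotated "No label" row) are kept
as extra rows so column sums reproduce the published false-positive counts.

These tables are reference inputs for the metric computations in
:mod:`ziphid.evaluation`; they are not produced by this package's pipelines.
"""

from __future__ import annotations

import pandas as pd

from .evaluation import ConfusionMatrix

__all__ = [
    "case_study_confusion",
    "wc_confusion",
    "CASE_STUDY_BEAKED_CLASSES",
    "WC_BEAKED_CLASSES",
]

#: beaked whale classes with manually annotated bins in the all-site table
CASE_STUDY_BEAKED_CLASSES = ["Mb", "Zc", "Mm", "Me", "Md"]
#: beaked whale classes with manually annotated bins at site WC
WC_BEAKED_CLASSES = ["Mb", "Zc", "Mm"]

_PRED_CLASSES = [
    "Mb", "Zc", "Mm", "Me", "Md", "BWG",
    "De spp", "Gg", "Ko spp", "Pm & Boat", "ES ping", "No label",
]

# Targeted pipeline with hard negative filter, all case-study sites.
_CASE_STUDY_ROWS = {
    "Mb":        [766, 1, 14, 1, 2, 6, 27, 1, 3, 2, 0, 30],
    "Zc":        [1, 1188, 20, 13, 6, 20, 61, 20, 1, 1, 3, 12],
    "Mm":        [4, 6, 315, 11, 0, 5, 9, 1, 3, 0, 0, 5],
    "Me":        [3, 51, 486, 2563, 4, 82, 32, 3, 7, 0, 1, 0],
    "Md":        [0, 0, 0, 1, 2, 1, 3, 0, 0, 0, 0, 0],
    "Mm | Me":   [0, 1, 32, 5, 0, 3, 2, 0, 0, 0, 0, 0],
    "Md | Me":   [0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0],
    "likely Me": [0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0],
    "likely Md": [0, 0, 0, 0, 0, 1, 1, 0, 1, 0, 0, 0],
    "No label":  [28, 604, 809, 231, 713, 2671, 4309, 2195, 165, 22, 97, 4772],
}

# Site WC, three pipelines: Th (hard filter), Tm (moderate filter), G
# (generalized). Predicted-class column order as in the all-site table.
_WC_ROWS = {
    "Th": {
        "Mb":       [393, 1, 6, 0, 0, 2, 12, 0, 0, 0, 0, 11],
        "Zc":       [0, 326, 2, 2, 0, 4, 27, 7, 1, 1, 3, 5],
        "Mm":       [4, 2, 143, 9, 0, 0, 4, 1, 2, 0, 0, 3],
        "Mm | Me":  [0, 0, 9, 2, 0, 0, 0, 0, 0, 0, 0, 0],
        "No label": [9, 160, 22, 21, 55, 176, 1147, 161, 4, 33, 47, 891],
    },
    "Tm": {
        "Mb":       [391, 0, 26, 5, 0, 0, 23, 1, 3, 2, 0, 17],
        "Zc":       [1, 304, 1, 0, 0, 0, 42, 1, 0, 1, 4, 42],
        "Mm":       [5, 0, 147, 2, 0, 0, 5, 0, 1, 0, 0, 14],
        "Mm | Me":  [0, 0, 8, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        "No label": [244, 269, 216, 41, 30, 99, 10837, 1102, 306, 6642, 225, 1435],
    },
    "G": {
        "Mb":       [391, 0, 23, 3, 0, 0, 27, 0, 4, 4, 0, 22],
        "Zc":       [2, 286, 1, 0, 1, 0, 75, 5, 0, 4, 4, 36],
        "Mm":       [6, 0, 142, 2, 0, 0, 13, 2, 1, 0, 0, 14],
        "Mm | Me":  [0, 0, 8, 0, 0, 0, 2, 0, 0, 0, 0, 2],
        "No label": [218, 257, 205, 40, 28, 119, 10749, 1071, 220, 7246, 272, 711],
    },
}


def case_study_confusion() -> ConfusionMatrix:
    """All-site confusion table of the targeted pipeline with the hard
    negative filter (counts of 5-minute bins)."""
    df = pd.DataFrame.from_dict(_CASE_STUDY_ROWS, orient="index", columns=_PRED_CLASSES)
    return ConfusionMatrix(df)


def wc_confusion(pipeline: str) -> ConfusionMatrix:
    """Site-WC confusion table for one pipeline: ``"Th"`` (targeted, hard
    filter), ``"Tm"`` (targeted, moderate filter) or ``"G"`` (generalized)."""
    if pipeline not in _WC_ROWS:
        raise KeyError(f"pipeline must be one of {sorted(_WC_ROWS)}")
    df = pd.DataFrame.from_dict(_WC_ROWS[pipeline], orient="index", columns=_PRED_CLASSES)
    return ConfusionMatrix(df)
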