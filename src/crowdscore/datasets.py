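"""Published golden fixtures: 3-class concordance matrices for ER scoring.

These are the reported confusion matrices from a large crowdsourced ER
(estrogen receptor) scoring study of breast-cancer tissue microarray
images: 1,853 patients scored by an expert pathologist (the "actual"
axis: Neg / Low Pos / Pos, coded A / B / C) and re-scored three ways —
crowdsourced image-level labels (majority vote), crowdsourced nucleus
counts (median-count positivity index), and a commercial automated
image-analysis pipeline.

They serve as in-repo golden data for the metrics module: percent
agreement, margin bookkeeping and 2-class collapse are checked against
the values the matrices imply (3-class agreements 1316/1853, 1419/1853,
1290/1853).

Known inconsistency in the published table: the automated block's
printed predicted-Negative margin (113) does not equal its own column
sum (131); the matrix cells are taken as authoritative.
"""

from __future__ import annotations

from .metrics import ConfusionMatrix

__all__ = [
    "THREE_CLASS_CODES",
    "REFERENCE_CLASS_COUNTS",
    "N_PATIENTS",
    "crowd_image_confusion",
    "crowd_nuclei_confusion",
    "automated_confusion",
]

#: Codes A/B/C correspond to pathologist Neg / Low Pos / Pos.
THREE_CLASS_CODES = ("A", "B", "C")

#: Reference (pathologist) patient counts per class: Neg, Low Pos, Pos.
REFERENCE_CLASS_COUNTS = (452, 222, 1179)

N_PATIENTS = 1853


def crowd_image_confusion() -> ConfusionMatrix:
    """Pathologist vs crowdsourced image labeling (majority vote), 3-class."""
    return ConfusionMatrix(
        THREE_CLASS_CODES,
        [
            [151, 174, 127],
            [15, 47, 160],
            [13, 48, 1118],
        ],
    )


def crowd_nuclei_confusion() -> ConfusionMatrix:
    """Pathologist vs crowdsourced nucleus counting (median positivity index)."""
    return ConfusionMatrix(
        THREE_CLASS_CODES,
        [
            [235, 145, 72],
            [21, 50, 151],
            [11, 34, 1134],
        ],
    )


def automated_confusion() -> ConfusionMatrix:
    """Pathologist vs automated image-analysis pipeline, 3-class."""
    return ConfusionMatrix(
        THREE_CLASS_CODES,
        [
            [113, 125, 214],
            [11, 37, 174],
            [7, 32, 1140],
        ],
    )
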