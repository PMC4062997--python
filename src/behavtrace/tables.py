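"""Activity vocabulary and per-volunteer repetition bookkeeping.

Twelve indoor activities of daily living, coded ``1a``..``6b``: the letter
suffix marks the two phases (execution / return) of six elementary movements.
The repetition table lists how many times each of the 20 volunteers
(V1..V20) performed each activity; it drives the learning/testing split
bookkeeping (10 draws per (activity, subject) cell).
"""

from __future__ import annotations

import pandas as pd

#: Activity codes in canonical order.
ACTIVITY_CODES: tuple[str, ...] = (
    "1a", "1b", "2a", "2b", "3a", "3b", "4a", "4b", "5a", "5b", "6a", "6b",
)

ACTIVITY_DESCRIPTIONS: dict[str, str] = {
    "1a": "Going from stand to squat pose",
    "1b": "Going from squat to stand pose",
    "2a": "Sitting on the chair from stand pose",
    "2b": "Standing up from the chair to stand pose",
    "3a": "Reaching forward with the left upper limb (sagittal plane, stand)",
    "3b": "Return from reaching forward with the left upper limb",
    "4a": "Reaching upward with the left upper limb (sagittal plane, stand)",
    "4b": "Return from reaching upward with the left upper limb",
    "5a": "Bending forward the trunk from stand pose",
    "5b": "Straightening the trunk from bend to stand pose",
    "6a": "Single step for the right lower limb (support phase, right)",
    "6b": "Single step for the left lower limb (support phase, left)",
}

#: Movement class (0-based, 6 classes) for each activity code: the a/b pair
#: of one movement collapses to a single elementary pose class.
MOVEMENT_CLASS: dict[str, int] = {c: int(c[0]) - 1 for c in ACTIVITY_CODES}

#: Elementary pose classes for state vectors: six movements + "undetermined".
POSE_CLASSES: tuple[str, ...] = ("1", "2", "3", "4", "5", "6", "undetermined")
UNDETERMINED: int = 6  # index of the "undetermined" class
N_POSES: int = 7

SUBJECT_IDS: tuple[str, ...] = tuple(f"V{i}" for i in range(1, 21))

_REPS = [
    # 1a  1b  2a  2b  3a  3b  4a  4b  5a  5b  6a  6b
    [30, 30, 28, 28, 31, 31, 36, 36, 30, 30, 19, 19],  # V1
    [30, 30, 31, 31, 30, 30, 30, 30, 30, 30, 25, 25],  # V2
    [30, 30, 32, 32, 30, 30, 30, 30, 30, 30, 31, 31],  # V3
    [28, 28, 31, 31, 30, 30, 46, 46, 40, 40, 28, 28],  # V4
    [29, 29, 30, 30, 30, 30, 31, 31, 30, 30, 27, 27],  # V5
    [31, 31, 30, 30, 33, 33, 30, 30, 30, 30, 21, 21],  # V6
    [29, 29, 30, 30, 31, 31, 30, 30, 31, 31, 22, 22],  # V7
    [27, 27, 30, 30, 29, 29, 28, 28, 30, 30, 23, 23],  # V8
    [30, 30, 30, 30, 31, 31, 30, 30, 31, 31, 24, 24],  # V9
    [29, 29, 32, 32, 30, 30, 33, 33, 33, 33, 28, 28],  # V10
    [30, 30, 29, 29, 30, 30, 31, 31, 37, 37, 29, 29],  # V11
    [30, 30, 33, 33, 30, 30, 29, 29, 30, 30, 29, 29],  # V12
    [30, 30, 30, 30, 32, 32, 31, 31, 37, 37, 29, 29],  # V13
    [30, 30, 30, 30, 30, 30, 30, 30, 41, 41, 35, 35],  # V14
    [30, 30, 30, 30, 30, 30, 30, 30, 30, 30, 32, 32],  # V15
    [29, 29, 29, 29, 30, 30, 30, 30, 29, 29, 30, 30],  # V16
    [30, 30, 21, 21, 32, 32, 30, 30, 30, 30, 28, 28],  # V17
    [30, 30, 30, 30, 31, 31, 30, 30, 30, 30, 40, 40],  # V18
    [30, 30, 30, 30, 30, 30, 30, 30, 30, 30, 40, 40],  # V19
    [30, 30, 30, 30, 30, 30, 30, 30, 30, 30, 35, 35],  # V20
]


def repetition_counts() -> pd.DataFrame:
    """Per-(subject, activity) repetition counts, subjects as rows."""
    return pd.DataFrame(_REPS, index=list(SUBJECT_IDS), columns=list(ACTIVITY_CODES))
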