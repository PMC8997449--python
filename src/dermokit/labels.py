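"""The ten diagnostic categories and their benign/malignant partition.

Categories are ordered by increasing risk; actinic keratosis counts as
malignant (pre-cancerous / in-situ squamous cell carcinoma).
"""

from __future__ import annotations

from typing import Sequence

BENIGN_CLASSES = (
    "vascular lesions",
    "nevus",
    "solar lentigo",
    "dermatofibroma",
    "seborrheic keratosis",
    "benign keratosis",
)

MALIGNANT_CLASSES = (
    "actinic keratosis",
    "basal cell carcinoma",
    "squamous cell carcinoma",
    "melanoma",
)

CLASS_NAMES = BENIGN_CLASSES + MALIGNANT_CLASSES


def label_to_index(label: str, class_names: Sequence[str] = CLASS_NAMES) -> int:
    try:
        return list(class_names).index(label)
    except ValueError:
        raise ValueError(f"unknown class label {label!r}") from None


def index_to_label(index: int, class_names: Sequence[str] = CLASS_NAMES) -> str:
    if not 0 <= index < len(class_names):
        raise ValueError(f"class index {index} out of range")
    return class_names[index]
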