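"""Fixed tissue-class code table shared by every stage of the pipeline.

Codes 1-6 are the six annotated tissue types of a breast-biopsy H&E
section; code 7 (border) is never annotated directly but derived from the
perimeter of epithelial components so that touching acini can be separated
in segmentation output. Code 0 marks unannotated / background pixels.
"""

from __future__ import annotations

BACKGROUND = 0
EPITHELIUM = 1
INTRALOBULAR_STROMA = 2
EXTRALOBULAR_STROMA = 3
LUMEN = 4
ADIPOSE = 5
VESSEL = 6
BORDER = 7

CLASS_NAMES: dict[int, str] = {
    BACKGROUND: "background",
    EPITHELIUM: "epithelium",
    INTRALOBULAR_STROMA: "intralobular_stroma",
    EXTRALOBULAR_STROMA: "extralobular_stroma",
    LUMEN: "lumen",
    ADIPOSE: "adipose",
    VESSEL: "vessel",
    BORDER: "border",
}

NAME_TO_CODE: dict[str, int] = {v: k for k, v in CLASS_NAMES.items()}

#: The six classes a human annotator may draw (border is derived).
ANNOTATABLE = (
    EPITHELIUM,
    INTRALOBULAR_STROMA,
    EXTRALOBULAR_STROMA,
    LUMEN,
    ADIPOSE,
    VESSEL,
)

#: Classes reported in segmentation evaluation (border merged away first).
EVALUATED = ANNOTATABLE

ALL_CODES = tuple(CLASS_NAMES)

#: Default aliases for annotation dialects ("capillary" for vessel, "fat"
#: for adipose ...); users may extend via the ``aliases`` argument of
#: :func:`tdluquant.annotations.read_annotations`.
DEFAULT_ALIASES: dict[str, str] = {
    "capillary": "vessel",
    "small vessel": "vessel",
    "fat": "adipose",
    "adipose tissue": "adipose",
    "stroma intralobular": "intralobular_stroma",
    "stroma extralobular": "extralobular_stroma",
}
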