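"""Nine quantitative involution features of a segmented TDLU region.

The feature set: TDLU area, acini count, epithelial area, epithelial to
intralobular-stroma area ratio, small-vessel count, small-vessel area,
adipose area, mean acinar size, and count of acini with a large lumen.
TDLU area is the sum of epithelial, luminal and intralobular-stroma pixel
areas. An acinus is a connected epithelial component whose area strictly
exceeds 800 pixels (once the derived border class has been merged back
into intralobular stroma), counted as a single unit however lobulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import classes as C
from .annotations import LabelMap

__all__ = [
    "AcinusComponent",
    "merge_border",
    "find_acini",
    "compute_features",
    "summarize_subjects",
    "FEATURE_NAMES",
]

FEATURE_NAMES = (
    "tdlu_area",
    "acini_count",
    "epithelial_area",
    "epithelial_to_stromal_ratio",
    "vessel_count",
    "vessel_area",
    "adipose_area",
    "mean_acinar_size",
    "large_lumen_acini_count",
)

DEFAULT_MIN_ACINUS_AREA_PX = 800
DEFAULT_LARGE_LUMEN_THRESHOLD_PX = 800


@dataclass(frozen=True)
class AcinusComponent:
    """One counted acinus: an epithelial connected component > 800 px."""

    component_id: int
    pixel_area: int
    contained_lumen_area: int
    centroid: tuple[float, float]  # (x, y)


def merge_border(label_map: LabelMap) -> LabelMap:
    """Recode every border (7) pixel to intralobular stroma (2).

    This mirrors the counting pipeline: the border class exists to separate
    touching acini in segmentation output and is folded back into the
    intralobular stroma before any area is measured. Idempotent.
    """
    codes = label_map.codes.copy()
    codes[codes == C.BORDER] = C.INTRALOBULAR_STROMA
    return LabelMap(codes, label_map.resolution)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError("connectivity must be 4 or 8")


def find_acini(
    label_map: LabelMap,
    min_area_px: int = DEFAULT_MIN_ACINUS_AREA_PX,
    connectivity: int = 8,
) -> list[AcinusComponent]:
    """Connected epithelial components with area strictly above threshold.

    Requires the border class to have been merged first (counting on an
    unmerged map would fragment acini along their carved perimeters).
    ``contained_lumen_area`` is the number of lumen pixels lying in the
    topological holes of the component — acini are rings around lumens.
    """
    codes = label_map.codes
    if (codes == C.BORDER).any():
        raise ValueError("merge_border must be applied before counting acini")
    epi = codes == C.EPITHELIUM
    labeled, n = ndimage.label(epi, structure=_structure(connectivity))
    if n == 0:
        return []
    areas = ndimage.sum_labels(epi, labeled, index=np.arange(1, n + 1))
    lumen = codes == C.LUMEN
    out: list[AcinusComponent] = []
    objects = ndimage.find_objects(labeled)
    cid = 0
    for comp in range(1, n + 1):
        area = int(areas[comp - 1])
        if area <= min_area_px:
            continue
        sl = objects[comp - 1]
        comp_mask = labeled[sl] == comp
        holes = ndimage.binary_fill_holes(comp_mask) & ~comp_mask
        lum_area = int(np.count_nonzero(holes & lumen[sl]))
        cy, cx = ndimage.center_of_mass(comp_mask)
        cid += 1
        out.append(
            AcinusComponent(
                component_id=cid,
                pixel_area=area,
                contained_lumen_area=lum_area,
                centroid=(float(cx + sl[1].start), float(cy + sl[0].start)),
            )
        )
    return out


def compute_features(
    label_map: LabelMap,
    resolution: float | None = None,
    large_lumen_threshold_px: int = DEFAULT_LARGE_LUMEN_THRESHOLD_PX,
    min_acinus_area_px: int = DEFAULT_MIN_ACINUS_AREA_PX,
    connectivity: int = 8,
) -> pd.Series:
    """Compute the nine features of one TDLU-region label map.

    Areas are raw per-class pixel counts; ``mean_acinar_size`` is the total
    area of counted acinar components divided by their number (0 when no
    acinus passes the threshold); the epithelial/stromal ratio is NaN when
    the region has no intralobular stroma. The exact identity
    ``tdlu_area = epithelial + lumen + intralobular`` holds by construction
    and is asserted on every call.
    """
    merged = merge_border(label_map)
    resolution = resolution if resolution is not None else merged.resolution
    counts = merged.class_pixel_counts()
    epithelial_area = counts[C.EPITHELIUM]
    intralobular_area = counts[C.INTRALOBULAR_STROMA]
    lumen_area = counts[C.LUMEN]
    tdlu_area = epithelial_area + lumen_area + intralobular_area

    acini = find_acini(merged, min_acinus_area_px, connectivity)
    acini_count = len(acini)
    acinar_total = sum(a.pixel_area for a in acini)
    large_lumen = sum(
        1 for a in acini if a.contained_lumen_area >= large_lumen_threshold_px
    )

    features = pd.Series(
        {
            "tdlu_area": float(tdlu_area),
            "acini_count": float(acini_count),
            "epithelial_area": float(epithelial_area),
            "epithelial_to_stromal_ratio": (
                epithelial_area / intralobular_area if intralobular_area > 0 else np.nan
            ),
            "vessel_count": float(
                ndimage.label(merged.codes == C.VESSEL, structure=_structure(connectivity))[1]
            ),
            "vessel_area": float(counts[C.VESSEL]),
            "adipose_area": float(counts[C.ADIPOSE]),
            "mean_acinar_size": float(acinar_total / acini_count) if acini_count else 0.0,
            "large_lumen_acini_count": float(large_lumen),
        }
    )
    assert features["tdlu_area"] == float(
        epithelial_area + lumen_area + intralobular_area
    )
    return features


def features_um2(features: pd.Series, resolution: float) -> pd.Series:
    """Convert the pixel-area features to um^2 (counts and ratio unchanged)."""
    area_feats = (
        "tdlu_area",
        "epithelial_area",
        "vessel_area",
        "adipose_area",
        "mean_acinar_size",
    )
    out = features.copy()
    for name in area_feats:
        out[name] = features[name] * resolution**2
    return out


def summarize_subjects(
    per_tdlu: pd.DataFrame, subject_col: str = "subject_id"
) -> pd.DataFrame:
    """Mean feature vector per subject across that subject's included TDLUs.

    Missing epithelial/stromal ratios are excluded pairwise from the ratio
    mean; a subject with zero included TDLUs simply does not appear (the
    caller drops such subjects from downstream analysis).
    """
    if per_tdlu.empty:
        raise ValueError("no TDLUs to summarize")
    cols = [c for c in FEATURE_NAMES if c in per_tdlu.columns]
    return per_tdlu.groupby(subject_col)[cols].mean().reset_index()
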