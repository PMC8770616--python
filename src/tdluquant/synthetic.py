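"""Synthetic H&E-like lobule scenes with exact ground truth.

Generates square RGB images of a single terminal duct lobular unit (TDLU)
embedded in extralobular stroma, together with the pixel-exact 7-class
label map and the true values of the nine involution features. The
geometry follows the involution axis: a level-0 (non-involuted) lobule has
many acini, a level-5 (fully involuted) lobule has few small ones.

Each acinus is an epithelial annulus around a lumen disc, sized so its
epithelial component still exceeds the 800-pixel counting threshold after
the 3-pixel border class is carved from its perimeter. Acini are placed
without touching, so connected-component counts recover the drawn counts
exactly. Colors are a fixed per-class mean RGB plus Gaussian stain noise —
deliberately simple, so intensity augmentation during CNN training has
something to normalize.

The module also generates multi-reader score panels with controllable
disagreement and per-subject clinical tables with a planted linear effect
structure, mirroring the reader study and the association analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import disk as _disk

from . import classes as C
from .annotations import LabelMap, build_border_class

__all__ = [
    "SceneParams",
    "SceneTruth",
    "SceneGenerationError",
    "LEVEL_ACINI_RANGES",
    "draw_n_acini",
    "generate_scene",
    "generate_dataset",
    "generate_reader_panel",
    "generate_clinical_table",
    "CLASS_COLORS",
]


class SceneGenerationError(RuntimeError):
    """Raised when the requested geometry cannot be placed on the canvas."""


#: Acini-count range drawn for each involution level, following the
#: reader-study bins (0: >40, 1-2: 26-39, 3-4: 10-25, 5: <10). Levels that
#: share a bin share the full count distribution: the 1-vs-2 and 3-vs-4
#: distinctions rest on qualitative cues (acinar packing, stromal density,
#: basement-membrane thickening) that readers can see but the nine
#: quantitative features cannot, so the generated morphometry carries only
#: bin-level information about them — as in the real study.
LEVEL_ACINI_RANGES: dict[int, tuple[int, int]] = {
    0: (41, 52),
    1: (26, 39),
    2: (26, 39),
    3: (10, 25),
    4: (10, 25),
    5: (3, 9),
}

#: Mean 8-bit RGB per tissue class (H&E-like palette).
CLASS_COLORS: dict[int, tuple[int, int, int]] = {
    C.BACKGROUND: (255, 255, 255),
    C.EPITHELIUM: (126, 62, 148),
    C.INTRALOBULAR_STROMA: (228, 156, 190),
    C.EXTRALOBULAR_STROMA: (246, 188, 208),
    C.LUMEN: (242, 246, 252),
    C.ADIPOSE: (252, 232, 205),
    C.VESSEL: (196, 88, 96),
    C.BORDER: (96, 44, 110),
}


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic lobule scene."""

    canvas_size: int = 1024
    resolution: float = 0.495  # um per pixel
    involution_level: int = 3
    n_acini: int | None = None  # drawn from the level's range when None
    acinus_radius_range: tuple[float, float] = (24.0, 36.0)
    lumen_fraction: float = 0.42  # mean lumen radius as fraction of acinus radius
    n_vessels: int = 2
    vessel_caliber: float = 25.0  # um (capillary scale)
    fat_fraction: float = 0.12  # target adipose cover of the canvas
    stain_noise_sd: float = 8.0
    border_width_px: int = 3
    min_acinus_area_px: int = 800
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.involution_level <= 5:
            raise ValueError("involution_level must be in 0..5")
        lo, hi = LEVEL_ACINI_RANGES[self.involution_level]
        if self.n_acini is not None and not lo <= self.n_acini <= hi:
            # allow any count consistent with the coarse reader bin
            bin_ok = {
                0: self.n_acini > 40,
                1: 26 <= self.n_acini <= 39,
                2: 26 <= self.n_acini <= 39,
                3: 10 <= self.n_acini <= 25,
                4: 10 <= self.n_acini <= 25,
                5: 0 < self.n_acini < 10,
            }[self.involution_level]
            if not bin_ok:
                raise ValueError(
                    f"n_acini={self.n_acini} inconsistent with involution level "
                    f"{self.involution_level} bin"
                )
        if self.acinus_radius_range[0] < 10:
            raise ValueError("acinus radius too small to exceed the area threshold")


@dataclass
class SceneTruth:
    """Ground truth of one generated scene."""

    label_map: LabelMap
    true_features: "pd.Series"
    involution_level: int
    acinus_centers: list[tuple[float, float]] = field(default_factory=list)


def draw_n_acini(level: int, rng: np.random.Generator) -> int:
    lo, hi = LEVEL_ACINI_RANGES[level]
    return int(rng.integers(lo, hi + 1))


def _max_lumen_fraction(radius: float, border_px: int, min_area: float) -> float:
    """Largest lumen fraction keeping post-border epithelial area above threshold."""
    inner_sq = (radius - border_px) ** 2 - (min_area + 100.0) / math.pi
    if inner_sq <= 1.0:
        return 0.15
    return max(0.15, (math.sqrt(inner_sq) - border_px) / radius)


def _place_discs(
    rng: np.random.Generator,
    n: int,
    radii: np.ndarray,
    center: tuple[float, float],
    region_radius: float,
    gap: float,
    occupied: list[tuple[float, float, float]],
    max_tries: int = 400,
) -> list[tuple[float, float]]:
    """Rejection-sample non-overlapping disc centers inside a circular region."""
    placed: list[tuple[float, float]] = []
    for i in range(n):
        r = radii[i]
        ok = False
        for _ in range(max_tries):
            rho = region_radius * math.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2.0 * math.pi)
            cy = center[0] + rho * math.sin(theta)
            cx = center[1] + rho * math.cos(theta)
            if rho + r + gap > region_radius:
                continue
            if all(
                math.hypot(cy - oy, cx - ox) >= r + orad + gap
                for oy, ox, orad in occupied
            ):
                placed.append((cy, cx))
                occupied.append((cy, cx, r))
                ok = True
                break
        if not ok:
            raise SceneGenerationError(
                f"could not place disc {i + 1}/{n} of radius {r:.0f} px in a "
                f"region of radius {region_radius:.0f} px — reduce n_acini, "
                "acinus_radius_range, or enlarge canvas_size"
            )
    return placed


def generate_scene(params: SceneParams) -> tuple[np.ndarray, SceneTruth]:
    """Render one lobule scene; returns (RGB uint8 image, SceneTruth).

    Deterministic for a given ``params`` (including seed): two calls with
    the same parameters produce bit-identical images and label maps.
    """
    rng = np.random.default_rng(params.seed)
    size = params.canvas_size
    n_acini = (
        params.n_acini
        if params.n_acini is not None
        else draw_n_acini(params.involution_level, rng)
    )

    radii = rng.uniform(*params.acinus_radius_range, size=n_acini)
    fracs = np.empty(n_acini)
    for i, r in enumerate(radii):
        fmax = _max_lumen_fraction(r, params.border_width_px, params.min_acinus_area_px)
        fracs[i] = min(max(rng.normal(params.lumen_fraction, 0.09), 0.18), fmax)

    # lobule sized to hold the acini at a fixed packing fraction; involuted
    # lobules (few acini) come out smaller, as in real tissue
    packing = 0.30
    acini_area = float(np.sum(np.pi * radii**2))
    base_lobule = max(math.sqrt(acini_area / packing / math.pi), 3.2 * radii.max())
    max_radius = size / 2.0 - 12.0
    if base_lobule > max_radius:
        raise SceneGenerationError(
            f"lobule of radius {base_lobule:.0f} px (n_acini={n_acini}, "
            f"radii up to {radii.max():.0f}) exceeds canvas {size}; enlarge "
            "canvas_size or shrink acinus_radius_range"
        )
    center = (size / 2.0, size / 2.0)
    vessel_radius = params.vessel_caliber / 2.0 / params.resolution

    # bounded whole-layout retries, growing the lobule slightly each time
    for attempt in range(4):
        lobule_radius = min(base_lobule * 1.06**attempt, max_radius)
        occupied: list[tuple[float, float, float]] = []
        try:
            acinus_centers = _place_discs(
                rng, n_acini, radii, center, lobule_radius - 4.0, 3.0, occupied
            )
            vessel_centers = _place_discs(
                rng,
                params.n_vessels,
                np.full(params.n_vessels, vessel_radius),
                center,
                min(lobule_radius * 1.25, max_radius),
                3.0,
                occupied,
            )
            break
        except SceneGenerationError:
            if attempt == 3:
                raise

    codes = np.full((size, size), C.EXTRALOBULAR_STROMA, dtype=np.uint8)

    yy, xx = np.ogrid[:size, :size]
    lobule_mask = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= lobule_radius**2
    codes[lobule_mask] = C.INTRALOBULAR_STROMA

    # adipose blobs in the extralobular compartment
    target_fat = params.fat_fraction * size * size
    fat_pixels = 0
    for _ in range(200):
        if fat_pixels >= target_fat:
            break
        br = rng.uniform(30.0, 90.0)
        by = rng.uniform(0, size)
        bx = rng.uniform(0, size)
        if math.hypot(by - center[0], bx - center[1]) < lobule_radius + 0.3 * br:
            continue
        rr, cc = _disk((by, bx), br, shape=(size, size))
        sel = codes[rr, cc] == C.EXTRALOBULAR_STROMA
        fat_pixels += int(sel.sum())
        codes[rr[sel], cc[sel]] = C.ADIPOSE

    vessel_area = 0
    for cy, cx in vessel_centers:
        rr, cc = _disk((cy, cx), vessel_radius, shape=(size, size))
        codes[rr, cc] = C.VESSEL
        vessel_area += len(rr)

    lumen_px_per_acinus: list[int] = []
    for (cy, cx), r, f in zip(acinus_centers, radii, fracs):
        rr, cc = _disk((cy, cx), r, shape=(size, size))
        codes[rr, cc] = C.EPITHELIUM
        lr, lc = _disk((cy, cx), f * r, shape=(size, size))
        codes[lr, lc] = C.LUMEN
        lumen_px_per_acinus.append(len(lr))

    label_map = build_border_class(
        LabelMap(codes, params.resolution), params.border_width_px
    )

    counts = label_map.class_pixel_counts()
    epithelial_area = counts[C.EPITHELIUM]
    intralobular_area = counts[C.INTRALOBULAR_STROMA] + counts[C.BORDER]
    lumen_area = counts[C.LUMEN]
    large_lumen = sum(
        1 for px in lumen_px_per_acinus if px >= params.min_acinus_area_px
    )
    true_features = pd.Series(
        {
            "tdlu_area": float(epithelial_area + lumen_area + intralobular_area),
            "acini_count": float(n_acini),
            "epithelial_area": float(epithelial_area),
            "epithelial_to_stromal_ratio": (
                epithelial_area / intralobular_area if intralobular_area else np.nan
            ),
            "vessel_count": float(len(vessel_centers)),
            "vessel_area": float(counts[C.VESSEL]),
            "adipose_area": float(counts[C.ADIPOSE]),
            "mean_acinar_size": float(epithelial_area / n_acini),
            "large_lumen_acini_count": float(large_lumen),
        }
    )

    rgb = _render_rgb(label_map.codes, params.stain_noise_sd, rng)
    truth = SceneTruth(
        label_map=label_map,
        true_features=true_features,
        involution_level=params.involution_level,
        acinus_centers=acinus_centers,
    )
    return rgb, truth


def _render_rgb(
    codes: np.ndarray, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    palette = np.zeros((8, 3), dtype=np.float32)
    for code, color in CLASS_COLORS.items():
        palette[code] = color
    img = palette[codes]
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Dataset manifests
# ---------------------------------------------------------------------------

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


def generate_dataset(
    n_scenes: int,
    level_mix: dict[int, float] | None,
    seed: int,
    out_dir,
    base_params: SceneParams | None = None,
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
) -> pd.DataFrame:
    """Write ``n_scenes`` image/label pairs plus a manifest CSV.

    ``level_mix`` maps involution level to probability (uniform over 0-5
    when None). Scenes are written as PNGs under ``out_dir``; the manifest
    holds scene_id, paths, a seeded train/val/test split, the level and the
    true feature values. Returns the manifest as a DataFrame.
    """
    from pathlib import Path

    from PIL import Image

    from .annotations import write_label_map

    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    levels = np.arange(6)
    if level_mix is None:
        probs = np.full(6, 1 / 6)
    else:
        probs = np.array([level_mix.get(k, 0.0) for k in levels], dtype=float)
        if not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("level_mix must sum to 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    base = base_params or SceneParams()

    # quota-based split assignment (shuffled), so small datasets still get
    # non-empty val and test splits
    n_val = max(1, round(split_fractions[1] * n_scenes)) if n_scenes >= 3 else 0
    n_test = max(1, round(split_fractions[2] * n_scenes)) if n_scenes >= 3 else 0
    splits = (
        ["train"] * (n_scenes - n_val - n_test) + ["val"] * n_val + ["test"] * n_test
    )
    splits = list(np.asarray(splits)[rng.permutation(n_scenes)])

    rows = []
    for i in range(n_scenes):
        level = int(rng.choice(levels, p=probs))
        scene_seed = int(rng.integers(0, 2**31 - 1))
        params = replace(base, involution_level=level, n_acini=None, seed=scene_seed)
        rgb, truth = generate_scene(params)
        image_path = out_dir / f"scene_{i:04d}.png"
        label_path = out_dir / f"scene_{i:04d}_labels.png"
        Image.fromarray(rgb).save(str(image_path))
        write_label_map(truth.label_map, label_path)
        split = splits[i]
        row = {
            "scene_id": f"scene_{i:04d}",
            "image_path": str(image_path),
            "label_path": str(label_path),
            "split": split,
            "involution_level": level,
        }
        row.update({k: truth.true_features[k] for k in FEATURE_NAMES})
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# Reader panels
# ---------------------------------------------------------------------------

def generate_reader_panel(
    true_scores,
    reader_error_sd: float,
    ungradable_rate: float,
    n_readers: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a k-reader involution-score panel.

    Each reader's score is the true 0-5 score plus rounded Gaussian noise,
    clamped to [0, 5]; each (reader, TDLU) pair is independently flagged
    ungradable at ``ungradable_rate``, in which case the score is missing.
    Columns: tdlu_id, true_score, reader_<i>, gradable_<i>.
    """
    if not 0 <= ungradable_rate < 1:
        raise ValueError("ungradable_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    true_scores = np.asarray(true_scores, dtype=int)
    n = len(true_scores)
    data: dict[str, object] = {
        "tdlu_id": [f"tdlu_{i:04d}" for i in range(n)],
        "true_score": true_scores,
    }
    for r in range(1, n_readers + 1):
        noise = rng.normal(0.0, reader_error_sd, size=n) if reader_error_sd else 0.0
        scores = np.clip(np.rint(true_scores + noise), 0, 5).astype(int)
        gradable = rng.uniform(size=n) >= ungradable_rate
        data[f"reader_{r}"] = np.where(gradable, scores.astype(float), np.nan)
        data[f"gradable_{r}"] = gradable
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------

#: Attribute vocabulary of the association analysis (name -> kind).
CLINICAL_ATTRIBUTES = {
    "case_status": "binary",  # control=0, case=1
    "involution": "ordinal",  # none < partial < complete
    "histology": "ordinal",  # NP < PDWA < AH
    "density": "binary",  # low=0, high=1
    "parous": "binary",  # no=0, yes=1
    "menopause": "binary",  # pre=0, post=1
    "hrt": "ordinal",  # never < former < current
    "er_status": "binary",  # negative=0, positive=1 (cases only)
    "bbd_bc_risk": "numeric",
    "gail_risk": "numeric",
}

#: Default per-year standardized age slope on involution-linked features:
#: aging shrinks lobules (fewer, smaller acini; lower epithelial load).
DEFAULT_AGE_EFFECT = {
    "acini_count": -0.045,
    "tdlu_area": -0.04,
    "epithelial_area": -0.04,
    "mean_acinar_size": -0.03,
    "large_lumen_acini_count": -0.02,
}

_FEATURE_SCALE = {
    "tdlu_area": (420_000.0, 130_000.0),
    "acini_count": (22.0, 11.0),
    "epithelial_area": (65_000.0, 24_000.0),
    "epithelial_to_stromal_ratio": (0.35, 0.10),
    "vessel_count": (2.0, 1.1),
    "vessel_area": (4_000.0, 1_600.0),
    "adipose_area": (120_000.0, 40_000.0),
    "mean_acinar_size": (2_600.0, 700.0),
    "large_lumen_acini_count": (1.5, 1.2),
}


def generate_clinical_table(
    n_subjects: int,
    effect_spec: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    age_effect: dict[str, float] | None = None,
    involution_missing_rate: float = 0.05,
    feature_noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Simulate a per-subject clinical table with planted feature effects.

    ``effect_spec`` maps attribute name -> {feature name -> standardized
    effect per coded unit of the attribute}; ``age_effect`` maps feature
    name -> standardized slope per year of age (defaults to a mild
    involution-with-age signal; pass ``{}`` for an age-free null table).
    Mean features are linear in coded age/attributes plus Gaussian noise so
    that the association analysis can recover the planted signs.
    """
    effect_spec = effect_spec or {}
    for attr in effect_spec:
        if attr not in CLINICAL_ATTRIBUTES:
            raise ValueError(
                f"unknown attribute {attr!r}; expected one of "
                f"{sorted(CLINICAL_ATTRIBUTES)}"
            )
    age_eff = DEFAULT_AGE_EFFECT if age_effect is None else age_effect
    rng = np.random.default_rng(seed)

    n_cases = n_subjects // 2
    case = np.zeros(n_subjects, dtype=int)
    case[:n_cases] = 1
    rng.shuffle(case)

    age = np.clip(np.rint(rng.normal(52.0, 9.0, n_subjects)), 35, 74).astype(int)
    menopause = (age + rng.normal(0.0, 4.0, n_subjects) > 51).astype(int)
    parous = (rng.uniform(size=n_subjects) < 0.8).astype(int)
    density = (rng.uniform(size=n_subjects) < 0.5).astype(int)
    hrt = rng.choice(3, size=n_subjects, p=[0.5, 0.25, 0.25])
    histology = rng.choice(3, size=n_subjects, p=[0.38, 0.45, 0.17])
    involution = rng.choice(3, size=n_subjects, p=[0.22, 0.50, 0.28]).astype(float)
    involution[rng.uniform(size=n_subjects) < involution_missing_rate] = np.nan
    er = np.where(
        case == 1, (rng.uniform(size=n_subjects) < 0.8).astype(float), np.nan
    )
    bbd_bc_risk = np.clip(
        rng.normal(0.025, 0.012, n_subjects) + 0.0004 * (age - 52), 0.001, 0.3
    )
    gail_risk = np.clip(
        rng.normal(0.02, 0.01, n_subjects) + 0.0004 * (age - 52), 0.001, 0.3
    )

    coded = {
        "case_status": case,
        "involution": involution,
        "histology": histology,
        "density": density,
        "parous": parous,
        "menopause": menopause,
        "hrt": hrt,
        "er_status": er,
        "bbd_bc_risk": (bbd_bc_risk - bbd_bc_risk.mean()) / bbd_bc_risk.std(),
        "gail_risk": (gail_risk - gail_risk.mean()) / gail_risk.std(),
    }

    table = pd.DataFrame(
        {
            "subject_id": [f"subj_{i:04d}" for i in range(n_subjects)],
            "case_status": np.where(case == 1, "case", "control"),
            "age": age,
            "involution": pd.Series(involution).map(
                {0.0: "none", 1.0: "partial", 2.0: "complete"}
            ),
            "histology": pd.Series(histology).map({0: "NP", 1: "PDWA", 2: "AH"}),
            "density": np.where(density == 1, "high", "low"),
            "parous": np.where(parous == 1, "yes", "no"),
            "menopause": np.where(menopause == 1, "post", "pre"),
            "hrt": pd.Series(hrt).map({0: "never", 1: "former", 2: "current"}),
            "er_status": pd.Series(er).map({0.0: "negative", 1.0: "positive"}),
            "bbd_bc_risk": bbd_bc_risk,
            "gail_risk": gail_risk,
        }
    )

    for feat in FEATURE_NAMES:
        mu, sd = _FEATURE_SCALE[feat]
        latent = rng.normal(0.0, feature_noise_sd, n_subjects)
        latent = latent + age_eff.get(feat, 0.0) * (age - 52.0)
        for attr, feats in effect_spec.items():
            if feat in feats:
                values = np.nan_to_num(np.asarray(coded[attr], dtype=float))
                latent = latent + feats[feat] * values
        table[feat] = mu + sd * latent
    return table
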