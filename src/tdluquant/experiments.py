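"""Desk-scale study runs exercising the full pipeline on synthetic data.

These functions reproduce, at CPU scale, the three quantitative
experiments of the involution-quantification workflow: training and
evaluating the tissue segmenter, scoring involution against a noisy
four-reader consensus, and calibrating the clinical association test.
They are used by the acceptance script and the acceptance test suite; all
randomness is derived from a single seed.
"""

from __future__ import annotations

import tempfile
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .clinical import associate, van_der_waerden
from .evaluation import cohens_kappa, dice_report
from .features import compute_features
from .scoring import consensus_table, exclusion_filter, fit_and_crossvalidate
from .segmentation import SegConfig, predict, train
from .synthetic import (
    SceneParams,
    generate_clinical_table,
    generate_reader_panel,
    generate_scene,
)

__all__ = [
    "CONSENSUS_LEVEL_COUNTS",
    "READER_STUDY_TOTAL",
    "READER_STUDY_RETAINED",
    "STUDY_CHARACTERISTIC_COUNTS",
    "study_records",
    "characteristics_experiment",
    "segmentation_experiment",
    "scoring_experiment",
    "retention_experiment",
    "calibration_experiment",
]

#: Consensus involution-level distribution of the four-reader study that
#: the synthetic scoring experiment emulates (level -> number of TDLUs).
CONSENSUS_LEVEL_COUNTS: dict[int, int] = {0: 90, 1: 46, 2: 51, 3: 68, 4: 166, 5: 151}

#: TDLUs scored in the reader study, and the number retained after
#: excluding every image any reader judged ungradable.
READER_STUDY_TOTAL = 705
READER_STUDY_RETAINED = 572

#: CPU-scale segmentation configuration: a compact U-Net (3 pooling
#: levels, 16 base filters) trained on 128-px patches for 8 epochs.
SCALED_SEG_CONFIG = dict(
    patch_size=128,
    depth=3,
    base_filters=16,
    epochs=8,
    batch_size=4,
    n_patches_per_scene=8,
    learning_rate=2e-3,
)


#: Marginal counts of the case-control analysis set the pipeline was built
#: around (87 cases / 87 controls): histology and prior qualitative
#: involution per stratum, used to rebuild the characteristics table.
STUDY_CHARACTERISTIC_COUNTS = {
    "case": {
        "histology": {"NP": 26, "PDWA": 42, "AH": 19},
        "involution": {"none": 22, "partial": 44, "complete": 14, None: 7},
    },
    "control": {
        "histology": {"NP": 40, "PDWA": 37, "AH": 10},
        "involution": {"none": 15, "partial": 39, "complete": 31, None: 2},
    },
}


def study_records() -> pd.DataFrame:
    """Synthetic per-subject records with the analysis set's exact marginals."""
    rows = []
    for status, counts in STUDY_CHARACTERISTIC_COUNTS.items():
        hist = [h for h, k in counts["histology"].items() for _ in range(k)]
        inv = [v for v, k in counts["involution"].items() for _ in range(k)]
        for i, (h, v) in enumerate(zip(hist, inv)):
            rows.append(
                {
                    "subject_id": f"{status}_{i:03d}",
                    "case_status": status,
                    "age": 52,
                    "histology": h,
                    "involution": v,
                }
            )
    return pd.DataFrame(rows)


def _pct(cell: str) -> float:
    return float(cell.split("(")[1].rstrip("%)"))


def characteristics_experiment() -> dict:
    """Recompute the characteristics-table percentages from subject records.

    Percentages for the prior involution rows use the non-missing
    denominator (subjects with involution data).
    """
    from .clinical import table3_summary

    records = study_records()
    table = table3_summary(records).set_index(["section", "label"])
    return {
        "n_subjects": len(records),
        "ah_total_percent": _pct(table.loc[("histology", "Atypical hyperplasia"), "total"]),
        "involution_complete_controls_percent": _pct(
            table.loc[("involution", "Complete"), "control"]
        ),
        "involution_complete_total_percent": _pct(
            table.loc[("involution", "Complete"), "total"]
        ),
        "table": table,
    }


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31 - 1))


def segmentation_experiment(
    seed: int,
    n_scenes: int = 60,
    epochs: int = 8,
    out_dir: str | Path | None = None,
) -> dict:
    """Train the U-Net on synthetic scenes and evaluate held-out Dice.

    Generates ``n_scenes`` scenes (40 train / 8 val / 12 test at the
    default 60), trains the scaled CPU configuration, and reports pooled
    per-class and pixel-weighted Dice on the test split.
    """
    from .annotations import read_label_map
    from .synthetic import generate_dataset

    if out_dir is None:
        tmp = tempfile.TemporaryDirectory()
        out_dir = tmp.name
    manifest = generate_dataset(
        n_scenes,
        level_mix=None,
        seed=_sub_seed(seed, 1),
        out_dir=out_dir,
        split_fractions=(2 / 3, 2 / 15, 1 / 5),
    )
    config = SegConfig(
        seed=_sub_seed(seed, 2), **{**SCALED_SEG_CONFIG, "epochs": epochs}
    )
    segmenter = train(config, manifest)

    from PIL import Image

    pairs = []
    for _, row in manifest[manifest["split"] == "test"].iterrows():
        rgb = np.asarray(Image.open(row["image_path"]).convert("RGB"))
        truth = read_label_map(row["label_path"])
        pairs.append((predict(segmenter, rgb), truth))
    report = dice_report(pairs, n_boot=200, seed=_sub_seed(seed, 3))
    return {
        "weighted_dice": report.weighted_mean,
        "per_class_dice": report.per_class,
        "n_train": int((manifest["split"] == "train").sum()),
        "n_test": len(pairs),
        "epochs": epochs,
        "history": segmenter.history,
    }


def scoring_experiment(
    seed: int,
    level_counts: dict[int, int] | None = None,
    reader_error_sd: float = 0.7,
) -> dict:
    """Random-forest involution scoring against a noisy reader consensus.

    Renders one synthetic TDLU scene per consensus-level slot (572 at the
    default mix), computes the nine features from each ground-truth label
    map, simulates a four-reader panel with the given per-reader score
    noise, forms the majority-vote consensus, and cross-validates the
    500-tree forest tenfold against it.
    """
    level_counts = level_counts or CONSENSUS_LEVEL_COUNTS
    rng = np.random.default_rng(_sub_seed(seed, 10))
    levels = np.repeat(list(level_counts), list(level_counts.values()))
    rng.shuffle(levels)
    base = SceneParams()
    rows = []
    for lv in levels:
        params = replace(
            base, involution_level=int(lv), seed=int(rng.integers(2**31 - 1))
        )
        _, truth = generate_scene(params)
        rows.append(truth.true_features)
    features = pd.DataFrame(rows).reset_index(drop=True)
    panel = generate_reader_panel(
        levels, reader_error_sd, ungradable_rate=0.0, seed=_sub_seed(seed, 11)
    )
    cons = consensus_table(panel)
    predictions, _model = fit_and_crossvalidate(
        features, cons["consensus_score"], seed=_sub_seed(seed, 12)
    )
    return {
        "linear_kappa": cohens_kappa(
            predictions["predicted"], predictions["consensus"], "linear"
        ).kappa,
        "unweighted_kappa": cohens_kappa(
            predictions["predicted"], predictions["consensus"], "unweighted"
        ).kappa,
        "consensus_vs_truth_linear_kappa": cohens_kappa(
            cons["consensus_score"], levels, "linear"
        ).kappa,
        "n_tdlus": len(levels),
    }


def retention_experiment(
    seed: int,
    n_tdlus: int = READER_STUDY_TOTAL,
    n_retained: int = READER_STUDY_RETAINED,
) -> dict:
    """Exclusion-filter arithmetic on a panel with a fixed retained count.

    Builds a four-reader panel in which exactly ``n_retained`` of
    ``n_tdlus`` TDLUs are graded by all four readers (the ungradable slots
    are spread randomly), runs the filter, and reports the retained
    percentage.
    """
    rng = np.random.default_rng(_sub_seed(seed, 20))
    true_scores = rng.integers(0, 6, size=n_tdlus)
    panel = generate_reader_panel(true_scores, 0.7, 0.0, seed=_sub_seed(seed, 21))
    dropped = rng.permutation(n_tdlus)[: n_tdlus - n_retained]
    for idx in dropped:
        reader = int(rng.integers(1, 5))
        panel.loc[idx, f"gradable_{reader}"] = False
        panel.loc[idx, f"reader_{reader}"] = np.nan
    retained, fraction = exclusion_filter(panel)
    return {
        "n_total": n_tdlus,
        "n_retained": len(retained),
        "retained_percent": 100.0 * fraction,
    }


def calibration_experiment(
    seed: int,
    n_null: int = 1000,
    n_subjects: int = 120,
    planted_effect: float = -1.0,
) -> dict:
    """Type-I error of the association test, and planted-effect recovery.

    Runs ``n_null`` null simulations (no planted effects, no age trend)
    testing one feature-attribute pair at alpha 0.05, then a single table
    with a planted standardized menopause effect on acini count to check
    sign and significance recovery.
    """
    rejections = 0
    for i in range(n_null):
        table = generate_clinical_table(
            n_subjects, effect_spec=None, seed=_sub_seed(seed, 1000 + i), age_effect={}
        )
        cell = associate(
            van_der_waerden(table["acini_count"]), "density", table, adjust_age=False
        )
        rejections += cell.p_value < 0.05
    planted = generate_clinical_table(
        200,
        effect_spec={"menopause": {"acini_count": planted_effect}},
        seed=_sub_seed(seed, 30),
    )
    cell = associate(
        van_der_waerden(planted["acini_count"]),
        "menopause",
        planted,
        adjust_age=True,
        feature_name="acini_count",
    )
    return {
        "type_i_error_rate": rejections / n_null,
        "n_null": n_null,
        "planted_sign": cell.sign,
        "planted_p": cell.p_value,
    }
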