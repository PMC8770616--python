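"""Reader-score handling and feature-based involution scoring.

Implements the 0-5 involution scale of the four-reader study: the coarse
acini-count bins, majority-vote consensus with ceiling-of-mean tie breaks,
leave-one-reader-out consensus, the "any reader ungradable" exclusion
filter, and a 500-tree random forest mapping the nine quantitative
features to the six-level score, evaluated with stratified tenfold
cross-validation against the readers' consensus.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusResult",
    "acini_bin_score",
    "consensus",
    "leave_one_reader_consensus",
    "exclusion_filter",
    "consensus_table",
    "fit_and_crossvalidate",
]


def acini_bin_score(acini_count: int) -> str:
    """Coarse involution level from an acini count.

    Bins: more than 40 acini -> level 0; 26-39 -> levels 1-2; 10-25 ->
    levels 3-4; fewer than 10 -> level 5 (the split within a shared bin is
    a qualitative reader judgement, not derivable from the count alone).
    """
    if acini_count < 0:
        raise ValueError("acini_count must be non-negative")
    if acini_count > 40:
        return "0"
    if acini_count >= 26:
        return "1-2"
    if acini_count >= 10:
        return "3-4"
    return "5"


@dataclass(frozen=True)
class ConsensusResult:
    consensus_score: int
    rule_used: str  # unanimous | majority | tie_average


def _ceil_mean(scores) -> int:
    return -(-sum(scores) // len(scores))


def consensus(scores, tie211: str = "majority") -> ConsensusResult:
    """Consensus of exactly four reader scores.

    A value held by at least three readers is the consensus (majority;
    unanimous when all four agree). A 2-2 or 1-1-1-1 split has no majority
    and takes the rounded-up average. A 2-1-1 split is treated as a
    majority of the unique mode by default; ``tie211="average"`` routes it
    to the rounded-up average instead (sensitivity analysis).
    """
    scores = list(scores)
    if len(scores) != 4 or any(s is None or (isinstance(s, float) and math.isnan(s)) for s in scores):
        raise ValueError("consensus requires exactly 4 present scores; filter first")
    scores = [int(s) for s in scores]
    counts = Counter(scores)
    top, top_n = counts.most_common(1)[0]
    if top_n == 4:
        return ConsensusResult(top, "unanimous")
    if top_n == 3:
        return ConsensusResult(top, "majority")
    if top_n == 2 and sorted(counts.values()) == [1, 1, 2] and tie211 == "majority":
        return ConsensusResult(top, "majority")
    return ConsensusResult(_ceil_mean(scores), "tie_average")


def leave_one_reader_consensus(scores, held_out: int) -> int:
    """Consensus of the three readers other than ``held_out`` (0-based).

    Majority when any value is held by at least two of the three; a
    three-way split takes the rounded-up average.
    """
    scores = list(scores)
    if len(scores) != 4:
        raise ValueError("expected exactly 4 reader scores")
    others = [int(s) for i, s in enumerate(scores) if i != held_out]
    counts = Counter(others)
    top, top_n = counts.most_common(1)[0]
    if top_n >= 2:
        return top
    return _ceil_mean(others)


def exclusion_filter(panels: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Keep only TDLUs graded by every reader.

    ``panels`` is a reader-panel table with ``gradable_<i>`` columns (as
    written by the synthetic generator or read from CSV). Returns the
    retained rows and the retained fraction rounded to the nearest percent
    (on the 0-1 scale, e.g. 0.81 for 81%).
    """
    gradable_cols = [c for c in panels.columns if c.startswith("gradable_")]
    if not gradable_cols:
        raise ValueError("panel table has no gradable_<i> columns")
    keep = panels[gradable_cols].all(axis=1)
    retained = panels.loc[keep].reset_index(drop=True)
    fraction = round(len(retained) / len(panels), 2) if len(panels) else 0.0
    return retained, fraction


def consensus_table(panels: pd.DataFrame, tie211: str = "majority") -> pd.DataFrame:
    """Per-TDLU consensus scores for an all-gradable panel table."""
    reader_cols = sorted(
        (c for c in panels.columns if c.startswith("reader_")),
        key=lambda c: int(c.split("_")[1]),
    )
    records = []
    for _, row in panels.iterrows():
        res = consensus([row[c] for c in reader_cols], tie211=tie211)
        records.append(
            {
                "tdlu_id": row.get("tdlu_id"),
                "consensus_score": res.consensus_score,
                "rule_used": res.rule_used,
            }
        )
    return pd.DataFrame(records)


def fit_and_crossvalidate(
    features: pd.DataFrame,
    labels,
    n_trees: int = 500,
    folds: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, RandomForestClassifier]:
    """Stratified k-fold out-of-fold predictions plus a final refit model.

    ``features`` holds the nine quantitative features (one TDLU per row)
    and ``labels`` the consensus scores. Each fold fits a 500-tree random
    forest (library default parameters otherwise) on 90% of the data and
    predicts the held-out 10%, so every TDLU is predicted exactly once
    out-of-fold. Returns a DataFrame (row index, fold, predicted,
    consensus) and the model refit on all data.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two score classes to fit")
    min_class = int(np.bincount(y).max(initial=0) and np.bincount(y)[np.bincount(y) > 0].min())
    if min_class < folds:
        logger.warning(
            "smallest class has %d samples; reducing folds from %d", min_class, folds
        )
        folds = max(2, min_class)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.full(len(y), -1, dtype=int)
    fold_of = np.full(len(y), -1, dtype=int)
    for k, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        model = RandomForestClassifier(n_estimators=n_trees, random_state=seed + k)
        model.fit(X[train_idx], y[train_idx])
        pred[test_idx] = model.predict(X[test_idx])
        fold_of[test_idx] = k
    final = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    final.fit(X, y)
    out = pd.DataFrame(
        {"fold": fold_of, "predicted": pred, "consensus": y},
        index=features.index if hasattr(features, "index") else None,
    )
    return out, final
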