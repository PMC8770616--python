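"""Associations between per-subject mean features and clinical attributes.

Each feature is first transformed to rank-based inverse-normal (van der
Waerden) scores to neutralize skew, then regressed on one clinical
attribute at a time (optionally age-adjusted) with ordinary least squares.
The result is a signed p-value matrix in heat-map form: one cell per
(feature, attribute) pair, unadjusted for multiplicity, with the sign of
the attribute coefficient. ER status is analyzed among cases only
(controls have no tumor to type).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, rankdata

from .synthetic import CLINICAL_ATTRIBUTES, FEATURE_NAMES

__all__ = [
    "van_der_waerden",
    "AssociationCell",
    "associate",
    "association_matrix",
    "plot_association_heatmap",
    "table3_summary",
]

#: Numeric coding of the attribute vocabulary; ordered categories are coded
#: as an ordinal trend 0/1/2.
ATTRIBUTE_CODING: dict[str, dict[str, float]] = {
    "case_status": {"control": 0, "case": 1},
    "involution": {"none": 0, "partial": 1, "complete": 2},
    "histology": {"NP": 0, "PDWA": 1, "AH": 2},
    "density": {"low": 0, "high": 1},
    "parous": {"no": 0, "yes": 1},
    "menopause": {"pre": 0, "post": 1},
    "hrt": {"never": 0, "former": 1, "current": 2},
    "er_status": {"negative": 0, "positive": 1},
}


def validate_clinical_table(records: pd.DataFrame) -> list[str]:
    """Validate a clinical table against the expected schema.

    Returns a list of problems (empty when valid): missing columns,
    unknown category levels, out-of-range ages or risk scores. Missing
    values are allowed everywhere except subject_id/case_status/age.
    """
    problems: list[str] = []
    required = ["subject_id", "case_status", "age"]
    for col in required:
        if col not in records.columns:
            problems.append(f"missing required column {col!r}")
        elif records[col].isna().any():
            problems.append(f"column {col!r} has missing values")
    for attr, coding in ATTRIBUTE_CODING.items():
        if attr not in records.columns:
            problems.append(f"missing attribute column {attr!r}")
            continue
        bad = set(records[attr].dropna().unique()) - set(coding)
        if bad:
            problems.append(f"column {attr!r} has unknown levels {sorted(map(str, bad))}")
    for risk in ("bbd_bc_risk", "gail_risk"):
        if risk not in records.columns:
            problems.append(f"missing attribute column {risk!r}")
        else:
            vals = pd.to_numeric(records[risk], errors="coerce").dropna()
            if ((vals < 0) | (vals > 1)).any():
                problems.append(f"column {risk!r} outside [0, 1]")
    if "age" in records.columns:
        ages = pd.to_numeric(records["age"], errors="coerce").dropna()
        if ((ages < 18) | (ages > 100)).any():
            problems.append("implausible ages outside 18-100")
    return problems


def van_der_waerden(values) -> np.ndarray:
    """Rank-based inverse normal scores Phi^-1(r / (n + 1)).

    Ranks are computed among non-missing values with ties receiving
    average ranks; missing entries stay missing. The scores behave like
    z-scores from a standard normal.
    """
    values = np.asarray(values, dtype=float)
    mask = ~np.isnan(values)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("need at least 2 non-missing values")
    out = np.full(values.shape, np.nan)
    ranks = rankdata(values[mask], method="average")
    out[mask] = norm.ppf(ranks / (n + 1))
    return out


@dataclass(frozen=True)
class AssociationCell:
    feature: str
    attribute: str
    sign: int  # -1, 0, +1
    p_value: float
    adjusted: bool
    n: int


def _coded_attribute(records: pd.DataFrame, attribute: str) -> pd.Series:
    if attribute not in CLINICAL_ATTRIBUTES:
        raise ValueError(f"unknown attribute {attribute!r}")
    col = records[attribute]
    if CLINICAL_ATTRIBUTES[attribute] == "numeric":
        return pd.to_numeric(col, errors="coerce")
    coding = ATTRIBUTE_CODING[attribute]
    return col.map(coding)


def associate(
    feature_scores,
    attribute: str,
    records: pd.DataFrame,
    adjust_age: bool = False,
    feature_name: str = "feature",
) -> AssociationCell:
    """OLS association of transformed feature scores with one attribute.

    ``feature_scores`` are the van der Waerden scores of one feature,
    aligned with ``records`` rows. Subjects missing the attribute or the
    feature are dropped (complete-case per cell); ER status additionally
    restricts to cases. Two-sided p-value and sign come from the attribute
    coefficient of ``score ~ attribute (+ age)``.
    """
    x = _coded_attribute(records, attribute).to_numpy(dtype=float)
    y = np.asarray(feature_scores, dtype=float)
    keep = ~np.isnan(x) & ~np.isnan(y)
    if attribute == "er_status":
        keep &= (records["case_status"] == "case").to_numpy()
    age = records["age"].to_numpy(dtype=float)
    if adjust_age:
        keep &= ~np.isnan(age)
    n = int(keep.sum())
    if n < 10:
        raise ValueError(
            f"fewer than 10 complete cases for attribute {attribute!r} (n={n})"
        )
    xk = x[keep]
    if np.all(xk == xk[0]):
        return AssociationCell(feature_name, attribute, 0, np.nan, adjust_age, n)
    design = xk[:, None] if not adjust_age else np.column_stack([xk, age[keep]])
    model = sm.OLS(y[keep], sm.add_constant(design)).fit()
    coef = float(model.params[1])
    p = float(model.pvalues[1])
    return AssociationCell(
        feature=feature_name,
        attribute=attribute,
        sign=int(np.sign(coef)),
        p_value=p,
        adjusted=adjust_age,
        n=n,
    )


def association_matrix(
    records: pd.DataFrame,
    features=FEATURE_NAMES,
    attributes=tuple(CLINICAL_ATTRIBUTES),
    adjust_age: bool = True,
) -> pd.DataFrame:
    """Signed p-value matrix over all (feature, attribute) pairs.

    Returns a tidy DataFrame with one row per cell (feature, attribute,
    sign, p_value, n, adjusted). p-values are reported unadjusted for
    multiple testing, in keeping with the exploratory character of the
    analysis.
    """
    cells = []
    for feat in features:
        scores = van_der_waerden(records[feat])
        for attr in attributes:
            cell = associate(scores, attr, records, adjust_age, feature_name=feat)
            cells.append(cell.__dict__)
    return pd.DataFrame(cells)


def plot_association_heatmap(matrix: pd.DataFrame, path=None):
    """Render the signed p-value matrix as a heat map.

    Cell text is the p-value to 3 decimals; blue shades mark negative
    associations, red shades positive, deeper color for smaller p.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot_p = matrix.pivot(index="feature", columns="attribute", values="p_value")
    pivot_s = matrix.pivot(index="feature", columns="attribute", values="sign")
    signed = pivot_s * (1 - pivot_p.clip(upper=1.0))
    fig, ax = plt.subplots(figsize=(1.1 * len(pivot_p.columns) + 2, 0.6 * len(pivot_p) + 2))
    im = ax.imshow(signed.to_numpy(dtype=float), cmap="bwr", vmin=-1, vmax=1)
    ax.set_xticks(range(len(pivot_p.columns)), pivot_p.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(pivot_p.index)), pivot_p.index)
    for i in range(len(pivot_p.index)):
        for j in range(len(pivot_p.columns)):
            p = pivot_p.iloc[i, j]
            if np.isfinite(p):
                ax.text(j, i, f"{p:.3f}", ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="sign x (1 - p)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def _fmt(count: int, denom: int) -> str:
    pct = 100.0 * count / denom if denom else 0.0
    return f"{count} ({pct:.1f}%)"


def table3_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Characteristics table by case/control status.

    Reports age median/range and age-category, histology and prior
    involution counts with percentages. Involution percentages use the
    non-missing denominator; the missing count is shown as its own row.
    """
    strata = {
        "case": records[records["case_status"] == "case"],
        "control": records[records["case_status"] == "control"],
        "total": records,
    }
    rows: list[dict[str, str]] = []

    def add(section: str, label: str, fn) -> None:
        rows.append(
            {"section": section, "label": label}
            | {name: fn(df) for name, df in strata.items()}
        )

    add("n", "N", lambda df: str(len(df)))
    add("age", "Median", lambda df: f"{df['age'].median():.0f}")
    add("age", "Range", lambda df: f"({df['age'].min()}-{df['age'].max()})")
    age_cats = [
        ("<45 years", lambda a: a < 45),
        ("45-55 years", lambda a: (a >= 45) & (a <= 55)),
        (">55 years", lambda a: a > 55),
    ]
    for label, pred in age_cats:
        add(
            "age category",
            label,
            lambda df, pred=pred: _fmt(int(pred(df["age"]).sum()), len(df)),
        )
    for label, value in [
        ("Non-proliferative", "NP"),
        ("Proliferative disease without atypia", "PDWA"),
        ("Atypical hyperplasia", "AH"),
    ]:
        add(
            "histology",
            label,
            lambda df, v=value: _fmt(int((df["histology"] == v).sum()), len(df)),
        )
    add(
        "involution",
        "Involution data missing",
        lambda df: str(int(df["involution"].isna().sum())),
    )
    for label, value in [
        ("None", "none"),
        ("Partial", "partial"),
        ("Complete", "complete"),
    ]:
        add(
            "involution",
            label,
            lambda df, v=value: _fmt(
                int((df["involution"] == v).sum()),
                int(df["involution"].notna().sum()),
            ),
        )
    return pd.DataFrame(rows)
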