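"""Cohort assembly, standardization, group statistics and feature reduction.

A cohort is a per-subject table of the eight oximetry features with an
optional AHI column and healthy/at-risk label.  Before modelling, features
are z-scored; highly collinear features (|r| > 0.9, e.g. the desaturation
rates at neighbouring depths) are reduced to one representative per
transitively-correlated cluster, and non-parametric group comparisons
(Shapiro-Wilk, Mann-Whitney U) characterise the healthy vs at-risk split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_selection import mutual_info_classif

from .desat import AT_RISK, HEALTHY
from .signal_io import FEATURE_COLUMNS

__all__ = [
    "CohortTable",
    "Standardizer",
    "fit_standardizer",
    "apply_standardizer",
    "correlation_matrix",
    "reduce_by_correlation",
    "select_by_mutual_information",
    "group_compare",
]

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class CohortTable:
    """Feature matrix for a cohort of subjects.

    Wraps a DataFrame whose columns include the canonical eight features,
    and optionally ``subject_id``, ``ahi`` and ``label``.  Rows with any
    missing feature value are dropped on construction (with a logged count).
    """

    data: pd.DataFrame
    feature_names: List[str] = field(default_factory=lambda: list(FEATURE_COLUMNS))

    def __post_init__(self) -> None:
        missing_cols = [c for c in self.feature_names if c not in self.data.columns]
        if missing_cols:
            raise ValueError(f"cohort table missing feature columns {missing_cols}")
        n0 = len(self.data)
        keep = self.data[self.feature_names].notna().all(axis=1)
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} of {n0} rows with missing features")
            self.data = self.data.loc[keep]
        self.data = self.data.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def labels(self) -> Optional[pd.Series]:
        return self.data["label"] if "label" in self.data.columns else None

    @property
    def X(self) -> np.ndarray:
        return self.data[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> Optional[np.ndarray]:
        if self.labels is None:
            return None
        return (self.labels == AT_RISK).to_numpy().astype(int)

    def subset(self, index: Sequence[int]) -> "CohortTable":
        return CohortTable(self.data.iloc[list(index)].reset_index(drop=True),
                           list(self.feature_names))


@dataclass
class Standardizer:
    """Per-feature z-score parameters (sample SD, ddof=1)."""

    means: Dict[str, float]
    stds: Dict[str, float]
    fitted_on: str = ""

    @property
    def feature_names(self) -> List[str]:
        return list(self.means)


def fit_standardizer(table: CohortTable, fitted_on: str = "") -> Standardizer:
    """Fit z-score parameters; zero-variance features are dropped with a warning."""
    if table.n < 2:
        raise ValueError("need at least 2 rows to fit a standardizer")
    means, stds = {}, {}
    for name in table.feature_names:
        col = table.data[name].to_numpy(dtype=float)
        sd = float(np.std(col, ddof=1))
        if sd == 0:
            warnings.warn(f"feature {name!r} has zero variance; dropped from standardizer")
            continue
        means[name] = float(col.mean())
        stds[name] = sd
    return Standardizer(means, stds, fitted_on)


def apply_standardizer(standardizer: Standardizer, table: CohortTable) -> CohortTable:
    """Apply stored z-score parameters (no refit); keeps non-feature columns."""
    df = table.data.copy()
    for name in standardizer.feature_names:
        df[name] = (df[name] - standardizer.means[name]) / standardizer.stds[name]
    kept = [n for n in table.feature_names if n in standardizer.means]
    return CohortTable(df, kept)


def correlation_matrix(
    table: CohortTable, method: str = "pearson", include_ahi: bool = True
) -> pd.DataFrame:
    """Pairwise feature correlations, optionally including the AHI column.

    Constant columns yield NaN entries (reported as missing, not zero).
    """
    if table.n < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    cols = list(table.feature_names)
    if include_ahi and "ahi" in table.data.columns:
        cols = cols + ["ahi"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return table.data[cols].corr(method=method)


def reduce_by_correlation(
    table: CohortTable, threshold: float = 0.9, method: str = "pearson"
) -> List[str]:
    """Collapse transitively |r|-correlated feature clusters to one member.

    Features are grouped by the transitive closure of |r| > threshold.
    Within a cluster the feature with the largest |correlation with AHI| is
    retained (ties and missing AHI fall back to canonical feature order).
    Output order is canonical, independent of row order.
    """
    corr = correlation_matrix(table, method=method, include_ahi=True)
    names = list(table.feature_names)
    # union-find over features
    parent = {n: n for n in names}

    def find(a: str) -> str:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, a in enumerate(names):
        for b in names[i + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) > threshold:
                parent[find(a)] = find(b)

    clusters: Dict[str, List[str]] = {}
    for n in names:
        clusters.setdefault(find(n), []).append(n)

    has_ahi = "ahi" in corr.columns
    retained = []
    for members in clusters.values():
        members = sorted(members, key=names.index)
        if has_ahi and len(members) > 1:
            ahi_r = {
                m: abs(corr.loc[m, "ahi"]) if np.isfinite(corr.loc[m, "ahi"]) else -1.0
                for m in members
            }
            best = max(members, key=lambda m: (ahi_r[m], -names.index(m)))
        else:
            best = members[0]
        retained.append(best)
    return sorted(retained, key=names.index)


def select_by_mutual_information(
    table: CohortTable, k: Optional[int] = None, seed: int = 0
) -> List[str]:
    """Retain the k features with highest mutual information with the label.

    Uses the k-nearest-neighbour MI estimator with a fixed seed.  Ties and
    the all-uninformative case fall back to canonical feature order.  By
    default k is the number of features surviving :func:`reduce_by_correlation`.
    """
    if table.labels is None:
        raise ValueError("mutual-information selection requires a labeled table")
    if k is None:
        k = len(reduce_by_correlation(table))
    k = min(k, len(table.feature_names))
    mi = mutual_info_classif(table.X, table.y, random_state=seed)
    order = sorted(range(len(mi)), key=lambda i: (-mi[i], i))
    chosen = sorted(order[:k])
    return [table.feature_names[i] for i in chosen]


def group_compare(table: CohortTable) -> pd.DataFrame:
    """Per-feature healthy vs at-risk comparison.

    Returns one row per feature: group means ± SD, Shapiro-Wilk normality
    p-value (whole cohort), Mann-Whitney U p-value, and a significance flag
    at p ≤ 0.05.
    """
    if table.labels is None:
        raise ValueError("group comparison requires a labeled table")
    healthy = table.data[table.labels == HEALTHY]
    at_risk = table.data[table.labels == AT_RISK]
    if len(healthy) < 3 or len(at_risk) < 3:
        raise ValueError("both groups need at least 3 rows")
    rows = []
    for name in table.feature_names:
        h = healthy[name].to_numpy(dtype=float)
        r = at_risk[name].to_numpy(dtype=float)
        both = np.concatenate([h, r])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shapiro_p = float(stats.shapiro(both).pvalue) if np.std(both) > 0 else 1.0
            if np.all(h == h[0]) and np.all(r == r[0]) and h[0] == r[0]:
                mw_p = 1.0
            else:
                mw_p = float(stats.mannwhitneyu(h, r, alternative="two-sided").pvalue)
        rows.append(
            {
                "feature": name,
                "healthy_mean": h.mean(),
                "healthy_sd": h.std(ddof=1),
                "at_risk_mean": r.mean(),
                "at_risk_sd": r.std(ddof=1),
                "shapiro_p": shapiro_p,
                "mannwhitney_p": mw_p,
                "significant": mw_p <= SIGNIFICANCE_LEVEL,
            }
        )
    return pd.DataFrame(rows).set_index("feature")
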