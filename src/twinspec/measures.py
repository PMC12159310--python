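"""From raw informant reports to analysis variables.

This module turns the long observed table into the per-twin analysis
columns the specification curve consumes: multi-informant composites
(mean of available member reports, single available report used as-is),
the combined twin perception of parental nurturance, log normalization
of right-skewed antisocial-behavior scores, and full-sample
standardization.

Composites whose members span different instruments (e.g. a parent
checklist and the child interview) average *standardized* member scores,
since raw scores on different instruments are not commensurable;
composites within one instrument average raw scores.  Either way the
analysis column is standardized afterwards, so the distinction matters
only for the relative weighting of members.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CompositeRule",
    "ASB_INFORMANT_MEMBERS",
    "NURTURANCE_INFORMANT_MEMBERS",
    "to_wide",
    "build_composite",
    "combine_twin_parent_reports",
    "log_normalize",
    "skewness",
    "standardize",
    "LogTransformer",
    "Standardizer",
    "assemble_asb_column",
    "assemble_parenting_column",
    "ColumnError",
]


class ColumnError(ValueError):
    """Raised for degenerate or missing analysis columns."""


# instrument of each (measure, informant) report, for the mixed-instrument rule
def _instrument(measure: str, informant: str) -> str:
    if measure.startswith("cbcl"):
        return "trf" if informant == "teacher" else "cbcl"
    if measure == "interview":
        return "scica"
    return measure


#: Member reports of each antisocial-behavior informant variant, as
#: (measure, informant) pairs; ``{m}`` is the checklist scale in play.
#: The child member of the family/all composites is the interview score.
ASB_INFORMANT_MEMBERS = {
    "mother": [("{m}", "mother")],
    "father": [("{m}", "father")],
    "teacher": [("{m}", "teacher")],
    "twin": [("interview", "twin")],
    "family": [("{m}", "mother"), ("{m}", "father"), ("interview", "twin")],
    "adults": [("{m}", "mother"), ("{m}", "father"), ("{m}", "teacher")],
    "all": [("{m}", "mother"), ("{m}", "father"), ("{m}", "teacher"),
            ("interview", "twin")],
}

#: Member reports of each nurturance informant variant; ``twin`` is the
#: combined twin perception across both parents.
NURTURANCE_INFORMANT_MEMBERS = {
    "mother": ["mother"],
    "father": ["father"],
    "twin": ["twin"],
    "adults": ["mother", "father"],
    "all": ["mother", "father", "twin"],
}


@dataclass(frozen=True)
class CompositeRule:
    """An informant composite: ordered members for one trait."""

    composite_id: str
    members: tuple[tuple[str, str], ...]
    trait: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ColumnError(f"composite {self.composite_id} has no members")


def to_wide(dataset: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long observed table to one row per twin.

    Columns become a (measure_id, informant_id) MultiIndex; the row index
    is (family_id, zygosity, twin_index).  Duplicate report keys are an
    error.
    """
    dup = dataset.duplicated(
        subset=["family_id", "twin_index", "measure_id", "informant_id"])
    if dup.any():
        raise ValueError(f"{int(dup.sum())} duplicate (family, twin, measure, "
                         f"informant) report keys in dataset")
    wide = dataset.pivot(
        index=["family_id", "zygosity", "twin_index"],
        columns=["measure_id", "informant_id"], values="value")
    return wide.sort_index()


def build_composite(scores: pd.DataFrame, rule: CompositeRule | None = None) -> pd.Series:
    """Average available member scores per twin.

    Mean of the nonmissing member columns; if exactly one member report
    is available that report is used; if none, the composite is missing.
    """
    if scores.shape[1] == 0:
        raise ColumnError("composite requires at least one member column")
    return scores.mean(axis=1, skipna=True)


def combine_twin_parent_reports(about_mother: pd.Series,
                                about_father: pd.Series) -> pd.Series:
    """Combine a twin's reports of maternal and paternal nurturance.

    The two strongly correlated reports are averaged into one overall
    perception of parent-child involvement; a single available report is
    used as-is, and the result is missing only when both are.
    """
    return pd.concat([about_mother, about_father], axis=1).mean(axis=1, skipna=True)


def log_normalize(values: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Natural log of (1 + raw score) for nonnegative, right-skewed scores."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("log normalization requires nonnegative scores")
    if isinstance(values, pd.Series):
        return pd.Series(np.log1p(arr), index=values.index, name=values.name)
    return np.log1p(arr)


def skewness(values) -> float:
    """Adjusted Fisher-Pearson sample skewness (the common software default)."""
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if arr.size < 3:
        raise ValueError(f"skewness requires >= 3 nonmissing values; got {arr.size}")
    if np.var(arr) == 0:
        raise ValueError("skewness undefined for a zero-variance sample")
    return float(stats.skew(arr, bias=False))


def standardize(column: pd.Series, name: str | None = None,
                ddof: int = 1) -> pd.Series:
    """Z-score over nonmissing entries; missing entries are preserved.

    Uses the full pooled sample (both zygosities) and, by default, the
    sample-SD convention (``ddof=1``).
    """
    label = name or column.name or "<unnamed>"
    vals = column.astype(float)
    mu = vals.mean(skipna=True)
    sd = vals.std(skipna=True, ddof=ddof)
    if not np.isfinite(sd) or sd == 0:
        raise ColumnError(f"column {label!r} has zero variance; cannot standardize")
    return (vals - mu) / sd


class LogTransformer(BaseEstimator, TransformerMixin):
    """Stateless log1p transformer for nonnegative score columns."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if np.any(X < 0):
            raise ValueError("log normalization requires nonnegative scores")
        self.n_features_in_ = X.shape[1] if X.ndim == 2 else 1
        return self

    def transform(self, X):
        return np.log1p(np.asarray(X, dtype=float))


class Standardizer(BaseEstimator, TransformerMixin):
    """Columnwise z-scoring that preserves NaN (missing reports).

    Unlike a plain scaler, zero-variance columns raise with the column
    position named, matching the pipeline's hard standardization
    contract.
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.mean_ = np.nanmean(X, axis=0)
        self.scale_ = np.nanstd(X, axis=0, ddof=self.ddof)
        bad = np.flatnonzero(~np.isfinite(self.scale_) | (self.scale_ == 0))
        if bad.size:
            raise ColumnError(f"zero-variance column(s) at position(s) {bad.tolist()}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[:, None]
        Z = (X - self.mean_) / self.scale_
        return Z[:, 0] if squeeze else Z


# ---------------------------------------------------------------------------
# analysis-column assembly


def _get_report(wide: pd.DataFrame, measure: str, informant: str) -> pd.Series:
    key = (measure, informant)
    if key not in wide.columns:
        raise ColumnError(f"dataset has no report for measure={measure!r}, "
                          f"informant={informant!r}")
    return wide[key]


def _nurturance_base(wide: pd.DataFrame, informant: str,
                     measure: str = "peq_nurturance") -> pd.Series:
    if informant == "twin":
        return combine_twin_parent_reports(
            _get_report(wide, measure, "twin_about_mother"),
            _get_report(wide, measure, "twin_about_father"))
    return _get_report(wide, measure, informant)


def assemble_asb_column(wide: pd.DataFrame, measure: str, informant: str,
                        normalization: str = "raw") -> pd.Series:
    """Build the standardized antisocial-behavior analysis column.

    Resolves the informant variant to its member reports for ``measure``,
    applies log normalization first when requested, standardizes members
    before averaging when the composite mixes instruments, and
    standardizes the final column over the pooled sample.
    """
    if informant not in ASB_INFORMANT_MEMBERS:
        raise ColumnError(f"unknown antisocial-behavior informant {informant!r}")
    if normalization not in ("raw", "log"):
        raise ColumnError(f"unknown normalization {normalization!r}")
    members = [(m.format(m=measure), i)
               for m, i in ASB_INFORMANT_MEMBERS[informant]]
    cols = []
    for mem_measure, mem_informant in members:
        col = _get_report(wide, mem_measure, mem_informant)
        if normalization == "log":
            col = log_normalize(col)
        cols.append(col.rename(f"{mem_measure}:{mem_informant}"))
    instruments = {_instrument(m, i) for m, i in members}
    if len(cols) > 1 and len(instruments) > 1:
        cols = [standardize(c) for c in cols]
    composite = build_composite(pd.concat(cols, axis=1))
    return standardize(composite, name=f"asb:{measure}:{informant}:{normalization}")


def assemble_parenting_column(wide: pd.DataFrame, informant: str,
                              measure: str = "peq_nurturance") -> pd.Series:
    """Build the standardized parenting analysis column (nurturance by
    default; pass ``measure='peq_conflict'`` for harshness)."""
    if informant not in NURTURANCE_INFORMANT_MEMBERS:
        raise ColumnError(f"unknown parenting informant {informant!r}")
    bases = [_nurturance_base(wide, m, measure).rename(f"{measure}:{m}")
             for m in NURTURANCE_INFORMANT_MEMBERS[informant]]
    composite = build_composite(pd.concat(bases, axis=1))
    return standardize(composite, name=f"parenting:{measure}:{informant}")
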