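"""Statistical primitives for the twin-differences design.

Co-twin difference scores are formed as Twin A minus Twin B where the
A/B labels are assigned at random within each family.  Because the
population mean of a difference score is zero by construction under
random labeling, difference correlations are computed from moments about
the origin; this also makes every estimate exactly invariant to the
labeling seed (relabeling a family flips both differences together).

Phenotypic (individual-level) associations are estimated with a linear
mixed model carrying a single normal random intercept per family,
fitted by maximum likelihood; confidence intervals are Wald intervals
and, for correlations, Fisher-transform intervals with the normal
critical value 1.96.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "EffectEstimate",
    "DifferenceTable",
    "assign_twin_labels",
    "compute_difference_scores",
    "diff_correlation",
    "RandomInterceptRegressor",
    "mlm_phenotypic",
    "p_to_signed_z",
    "steiger_dependent_z",
    "pair_discordance",
    "discordance_ratio",
    "DataError",
    "ConvergenceError",
]

P_FLOOR = 1e-15  # p-values are floored here before z-conversion
Z_CRIT = 1.96


class DataError(ValueError):
    """Raised for data that violates a structural precondition."""


class ConvergenceError(RuntimeError):
    """Raised when a mixed-model fit does not converge."""


@dataclass(frozen=True)
class EffectEstimate:
    """One specification's effect estimate.

    ``estimate`` is a correlation r (twin-difference level) or a
    standardized regression slope b (phenotypic level); ``n`` counts
    families for r and twins for b.
    """

    kind: str  # "diff_correlation" | "mlm_beta"
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if not self.ci_low - 1e-12 <= self.estimate <= self.ci_high + 1e-12:
            raise ValueError(f"estimate {self.estimate} outside CI "
                             f"({self.ci_low}, {self.ci_high})")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1]; got {self.p}")
        min_n = 3 if self.kind == "diff_correlation" else 4
        if self.n < min_n:
            raise ValueError(f"n={self.n} too small for kind={self.kind!r}")

    @property
    def sign(self) -> int:
        return 0 if self.estimate == 0 else (1 if self.estimate > 0 else -1)

    @property
    def signed_z(self) -> float:
        return p_to_signed_z(self.p, self.sign)


@dataclass
class DifferenceTable:
    """Per-family co-twin differences for one (x, y) variable pair."""

    data: pd.DataFrame  # columns: family_id, zygosity, dx, dy
    n_excluded: int
    assignment_seed: int | None = None


def assign_twin_labels(dataset: pd.DataFrame,
                       seed: int | np.random.SeedSequence) -> pd.Series:
    """Randomly assign Twin A within each family.

    Returns a Series indexed by family_id whose value is the twin_index
    (1 or 2) playing the role of Twin A.  Deterministic given the seed;
    every family must contribute exactly two twins.
    """
    counts = dataset.groupby("family_id")["twin_index"].nunique()
    bad = counts[counts != 2]
    if len(bad):
        raise DataError(f"families without exactly two twins: "
                        f"{bad.index.tolist()[:5]}")
    families = np.sort(counts.index.to_numpy())
    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed))
    a_twin = rng.integers(1, 3, size=len(families))
    return pd.Series(a_twin, index=pd.Index(families, name="family_id"),
                     name="a_twin")


def compute_difference_scores(
    per_twin: pd.DataFrame,
    x_column: str,
    y_column: str,
    assignment: pd.Series,
) -> DifferenceTable:
    """Form Delta = (Twin A) - (Twin B) for both variables.

    ``per_twin`` must carry one row per twin with columns family_id,
    zygosity, twin_index plus the two variables.  Families with any
    missing value among the four scores are excluded (complete-pairs
    rule); the exclusion count is recorded on the returned table.
    """
    df = per_twin[["family_id", "zygosity", "twin_index", x_column, y_column]]
    wide = df.pivot(index="family_id", columns="twin_index",
                    values=[x_column, y_column])
    zyg = df.drop_duplicates("family_id").set_index("family_id")["zygosity"]
    a = assignment.reindex(wide.index)
    if a.isna().any():
        raise DataError("assignment does not cover every family in the data")
    sign = np.where(a.to_numpy() == 1, 1.0, -1.0)
    dx = (wide[(x_column, 1)] - wide[(x_column, 2)]).to_numpy() * sign
    dy = (wide[(y_column, 1)] - wide[(y_column, 2)]).to_numpy() * sign
    out = pd.DataFrame({
        "family_id": wide.index.to_numpy(),
        "zygosity": zyg.reindex(wide.index).to_numpy(),
        "dx": dx, "dy": dy,
    })
    complete = out[["dx", "dy"]].notna().all(axis=1)
    table = out[complete].reset_index(drop=True)
    return DifferenceTable(data=table, n_excluded=int((~complete).sum()))


def _fisher_interval(r: float, n: int) -> tuple[float, float, float]:
    """(ci_low, ci_high, p) from the Fisher transform at n families."""
    if abs(r) >= 1.0 - 1e-12:
        return r, r, 0.0
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    lo, hi = math.tanh(z - Z_CRIT * se), math.tanh(z + Z_CRIT * se)
    p = 2.0 * stats.norm.sf(abs(z) / se)
    return lo, hi, float(p)


def diff_correlation(table: DifferenceTable, zygosity: str) -> EffectEstimate:
    """Correlate co-twin differences within one zygosity group.

    The correlation is computed from moments about the origin (difference
    scores are mean-zero by construction under random A/B labeling),
    with a Fisher-transform 95% CI and two-sided normal p-value.
    """
    sub = table.data[table.data["zygosity"] == zygosity]
    n = len(sub)
    if n < 4:
        raise DataError(f"need >= 4 complete {zygosity} families; got {n}")
    dx = sub["dx"].to_numpy()
    dy = sub["dy"].to_numpy()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        raise DataError(f"no co-twin discordance in {zygosity} differences; "
                        f"correlation undefined")
    r = float(dx @ dy) / math.sqrt(sxx * syy)
    lo, hi, p = _fisher_interval(r, n)
    return EffectEstimate(kind="diff_correlation", estimate=r,
                          ci_low=lo, ci_high=hi, p=p, n=n)


class RandomInterceptRegressor(BaseEstimator, RegressorMixin):
    """Linear regression with a normal random intercept per family.

    Fits ``y = b0 + b1 * x + u_family + eps`` by maximum likelihood
    (statsmodels ``MixedLM``); with standardized inputs the slope is a
    standardized beta.  When the between-family variance is estimated at
    zero the slope coincides with the pooled OLS slope.

    Attributes (after ``fit``)
    --------------------------
    coef_ : ndarray of shape (1,)      fixed slope
    intercept_ : float
    ci_ : (low, high) 95% Wald interval for the slope
    pvalue_ : two-sided normal p-value for the slope
    group_var_ : estimated random-intercept variance
    nobs_ : number of twins entering the fit
    """

    def fit(self, X, y, groups=None):
        x = np.asarray(X, dtype=float).reshape(len(y), -1)
        if x.shape[1] != 1:
            raise ValueError("exactly one predictor is supported")
        y = np.asarray(y, dtype=float)
        if groups is None:
            raise ValueError("groups (family ids) are required")
        groups = np.asarray(groups)
        if len(np.unique(groups)) < 2:
            raise DataError("need >= 2 families for a random-intercept model")
        if np.std(x[:, 0]) == 0:
            raise DataError("predictor has zero variance")
        exog = np.column_stack([np.ones(len(y)), x[:, 0]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = MixedLM(y, exog, groups=groups).fit(reml=False)
            except Exception as exc:  # pragma: no cover - statsmodels internals
                raise ConvergenceError(f"mixed model failed to fit: {exc}") from exc
        beta = float(res.params[1])
        se = float(res.bse[1])
        if not np.isfinite(se):
            raise ConvergenceError("mixed model produced a non-finite slope SE")
        self.coef_ = np.array([beta])
        self.intercept_ = float(res.params[0])
        self.ci_ = (beta - Z_CRIT * se, beta + Z_CRIT * se)
        self.pvalue_ = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 0.0
        self.group_var_ = float(np.asarray(res.cov_re)[0, 0])
        self.nobs_ = int(len(y))
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1, 1)
        return self.intercept_ + x[:, 0] * self.coef_[0]


def mlm_phenotypic(x: pd.Series, y: pd.Series,
                   family_ids: pd.Series | np.ndarray) -> EffectEstimate:
    """Individual-level association with family-clustered twins.

    Available-case analysis: twins missing either variable are dropped,
    then the random-intercept model is fitted on the rest.
    """
    df = pd.DataFrame({"x": np.asarray(x, dtype=float),
                       "y": np.asarray(y, dtype=float),
                       "g": np.asarray(family_ids)}).dropna(subset=["x", "y"])
    if len(df) < 4:
        raise DataError(f"need >= 4 twins with both variables; got {len(df)}")
    try:
        reg = RandomInterceptRegressor().fit(df[["x"]], df["y"], groups=df["g"])
    except DataError as exc:
        raise DataError(f"{exc} (x={x.name!r}, y={y.name!r})") from exc
    return EffectEstimate(kind="mlm_beta", estimate=float(reg.coef_[0]),
                          ci_low=reg.ci_[0], ci_high=reg.ci_[1],
                          p=reg.pvalue_, n=reg.nobs_)


def p_to_signed_z(p: float, effect_sign: int) -> float:
    """Convert a two-sided p-value to a signed standard-normal z.

    |z| is the upper-tail quantile at p/2 (so p = 0.05 gives |z| = 1.96)
    and the sign of the effect is attached; p is floored at ``P_FLOOR``
    to keep aggregated z-scores finite.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1]; got {p}")
    if effect_sign not in (-1, 0, 1):
        raise ValueError(f"effect_sign must be -1, 0 or +1; got {effect_sign}")
    z = float(stats.norm.isf(max(p, P_FLOOR) / 2.0))
    return float(effect_sign) * z


def _steiger_z_core(r12, r13, r23, n):
    """Vectorized Steiger Z1* with pooled mean correlation."""
    r12, r13, r23 = (np.asarray(v, dtype=float) for v in (r12, r13, r23))
    rbar = 0.5 * (r12 + r13)
    rbar2 = rbar * rbar
    psi = r23 * (1.0 - 2.0 * rbar2) - 0.5 * rbar2 * (1.0 - 2.0 * rbar2 - r23 * r23)
    s = psi / (1.0 - rbar2) ** 2
    num = (np.arctanh(r12) - np.arctanh(r13)) * np.sqrt(n - 3.0)
    return num / np.sqrt(np.maximum(2.0 - 2.0 * s, 1e-300))


def steiger_dependent_z(r12: float, r13: float, r23: float,
                        n: int) -> tuple[float, float]:
    """Compare two dependent correlations sharing variable 1.

    Implements Steiger's Z1* with the pooled mean correlation
    r_bar = (r12 + r13)/2:

        z = (atanh(r12) - atanh(r13)) * sqrt(n - 3) / sqrt(2 - 2*s),
        s = psi / (1 - r_bar^2)^2,
        psi = r23 (1 - 2 r_bar^2) - (r_bar^2 / 2)(1 - 2 r_bar^2 - r23^2).

    Returns (z, two-sided p).
    """
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must be in (-1, 1); got {r}")
    if n < 4:
        raise ValueError(f"n must be >= 4; got {n}")
    corr = np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise ValueError(f"correlations ({r12}, {r13}, {r23}) do not form a "
                         f"positive semi-definite matrix")
    if r12 == r13:
        return 0.0, 1.0
    z = float(_steiger_z_core(r12, r13, r23, n))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, p


def pair_discordance(per_twin: pd.DataFrame, column: str) -> tuple[float, float, float]:
    """Mean absolute co-twin difference, phenotypic SD and their ratio.

    Quantifies how discordant co-twins are on a measure relative to the
    spread among unrelated individuals: returns
    ``(mean |twin1 - twin2|, pooled SD, ratio)``.
    """
    wide = per_twin.pivot(index="family_id", columns="twin_index", values=column)
    diffs = (wide[1] - wide[2]).abs().dropna()
    sd = per_twin[column].std(ddof=1)
    if len(diffs) == 0 or not np.isfinite(sd) or sd == 0:
        raise DataError(f"cannot compute discordance for column {column!r}")
    mean_diff = float(diffs.mean())
    return mean_diff, float(sd), mean_diff / float(sd)


def discordance_ratio(mean_abs_difference: float, phenotypic_sd: float) -> float:
    """Co-twin discordance as a percentage of the phenotypic SD."""
    if phenotypic_sd <= 0:
        raise ValueError("phenotypic SD must be positive")
    if mean_abs_difference < 0:
        raise ValueError("mean absolute difference must be nonnegative")
    return 100.0 * mean_abs_difference / phenotypic_sd
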