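"""Specification-curve execution, aggregation and etiologic classification.

The analytic multiverse crosses antisocial-behavior measure, informant
variant, nurturance informant variant and normalization; phenotypic
cells are estimated with a family-clustered random-intercept model and
twin-difference cells with co-twin difference correlations run
separately by zygosity.

Curve summaries follow the study's aggregation rules: medians are
unweighted, means (of estimates, CI bounds and signed z-scores) are
weighted by each cell's analyzed sample size.  A curve is deemed
significant only when four indicators agree — neither the mean nor the
median CI covers zero, the median p-value is below alpha, and the
magnitude of the average signed z exceeds the critical value; when the
indicators disagree the effect is conservatively called nonsignificant.

The pattern of phenotypic / MZ / DZ decisions is then mapped onto the
canonical etiologic scenarios (environmental, genetic, genetic plus
shared-environmental), and two parenting dimensions can be contrasted
cell-by-cell with the Steiger dependent-correlation test.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import measures
from .config import ConfigError, default_config, validate_config
from .inference import (EffectEstimate, assign_twin_labels,
                        compute_difference_scores, diff_correlation,
                        mlm_phenotypic, p_to_signed_z, steiger_dependent_z)

__all__ = [
    "Specification",
    "CurveSummary",
    "Decision",
    "ScenarioLabel",
    "enumerate_specifications",
    "run_specification",
    "summarize_curve",
    "decide_significance",
    "classify_scenario",
    "compare_parenting_dimensions",
    "SpecificationCurve",
    "write_report",
]

RESULT_COLUMNS = ["spec_id", "analysis_level", "asb_measure", "asb_informant",
                  "nurturance_informant", "normalization", "zygosity",
                  "kind", "estimate", "ci_low", "ci_high", "p", "n"]


@dataclass(frozen=True)
class Specification:
    """One cell of the analytic multiverse."""

    asb_measure: str
    asb_informant: str
    nurturance_informant: str
    normalization: str
    analysis_level: str
    zygosity: str = "not_applicable"

    def __post_init__(self) -> None:
        if (self.asb_measure == "interview") != (self.asb_informant == "twin"):
            raise ConfigError("the interview measure pairs exactly with the "
                              "twin self-report informant")
        if self.analysis_level == "phenotypic":
            if self.zygosity != "not_applicable":
                raise ConfigError("phenotypic specifications carry no zygosity")
        elif self.analysis_level == "twin_difference":
            if self.zygosity not in ("MZ", "DZ"):
                raise ConfigError("twin-difference specifications need "
                                  "zygosity MZ or DZ")
        else:
            raise ConfigError(f"unknown analysis level {self.analysis_level!r}")

    @property
    def spec_id(self) -> str:
        return ":".join([self.analysis_level, self.asb_measure,
                         self.asb_informant, self.nurturance_informant,
                         self.normalization, self.zygosity])


@dataclass(frozen=True)
class CurveSummary:
    """Aggregate statistics over one set of specification results."""

    median_es: float
    mean_es: float
    median_ci_low: float
    median_ci_high: float
    mean_ci_low: float
    mean_ci_high: float
    median_p: float
    pct_p_lt_05: float
    avg_z: float
    k: int
    total_n: int


@dataclass(frozen=True)
class Decision:
    """The four-indicator significance decision for one curve."""

    mean_ci_excludes_0: bool
    median_ci_excludes_0: bool
    median_p_lt_05: bool
    avg_abs_z_gt_196: bool

    @property
    def indicators(self) -> dict[str, bool]:
        return asdict(self)

    @property
    def significant(self) -> bool:
        return all(asdict(self).values())


@dataclass(frozen=True)
class ScenarioLabel:
    """Etiologic classification from the phenotypic/MZ/DZ decision pattern."""

    label: str
    phenotypic: Decision
    mz: Decision
    dz: Decision


def enumerate_specifications(config: Mapping[str, Any] | None,
                             analysis_level: str) -> list[Specification]:
    """Deterministic lexicographic enumeration of the analysis grid.

    Axis order: antisocial-behavior measure, its informant variant,
    nurturance informant, normalization, then (twin-difference level
    only) zygosity.
    """
    cfg = validate_config(dict(config) if config is not None else default_config())
    if analysis_level not in ("phenotypic", "twin_difference"):
        raise ConfigError(f"unknown analysis level {analysis_level!r}")
    zygosities = (["not_applicable"] if analysis_level == "phenotypic"
                  else ["MZ", "DZ"])
    specs = []
    for measure, informants in cfg["asb_measures"].items():
        for asb_informant in informants:
            for nurt in cfg["nurturance_informants"]:
                for norm in cfg["normalizations"]:
                    for zyg in zygosities:
                        specs.append(Specification(
                            asb_measure=measure, asb_informant=asb_informant,
                            nurturance_informant=nurt, normalization=norm,
                            analysis_level=analysis_level, zygosity=zyg))
    return specs


def run_specification(
    wide: pd.DataFrame,
    spec: Specification,
    assignment: pd.Series | None = None,
    parenting_measure: str = "peq_nurturance",
) -> EffectEstimate:
    """Estimate one specification on the wide per-twin table.

    Phenotypic cells fit the random-intercept model of antisocial
    behavior on nurturance; twin-difference cells form complete-pair
    difference scores under ``assignment`` and correlate them within the
    cell's zygosity.
    """
    asb = measures.assemble_asb_column(wide, spec.asb_measure,
                                       spec.asb_informant, spec.normalization)
    parenting = measures.assemble_parenting_column(
        wide, spec.nurturance_informant, parenting_measure)
    per_twin = wide.index.to_frame(index=False)
    per_twin["asb"] = asb.to_numpy()
    per_twin["parenting"] = parenting.to_numpy()
    if spec.analysis_level == "phenotypic":
        return mlm_phenotypic(per_twin["parenting"].rename("parenting"),
                              per_twin["asb"].rename("asb"),
                              per_twin["family_id"])
    if assignment is None:
        raise ConfigError(f"specification {spec.spec_id} needs a twin A/B "
                          f"assignment")
    table = compute_difference_scores(per_twin, "parenting", "asb", assignment)
    return diff_correlation(table, spec.zygosity)


def _as_results_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    rows = [{"estimate": r.estimate, "ci_low": r.ci_low, "ci_high": r.ci_high,
             "p": r.p, "n": r.n} for r in results]
    return pd.DataFrame(rows)


def summarize_curve(results, subset: pd.Series | None = None) -> CurveSummary:
    """Aggregate a set of specification results.

    Medians (of estimates, CI bounds and p) are unweighted; means of
    estimates and CI bounds, and the average signed z, are weighted by
    the per-cell sample size.  ``pct_p_lt_05`` uses the strict
    inequality p < 0.05.
    """
    df = _as_results_frame(results)
    if subset is not None:
        df = df[np.asarray(subset, dtype=bool)]
    if len(df) == 0:
        raise ValueError("cannot summarize an empty set of results")
    w = df["n"].to_numpy(dtype=float)
    est = df["estimate"].to_numpy(dtype=float)
    signs = np.sign(est).astype(int)
    z = np.array([p_to_signed_z(p, s) for p, s in zip(df["p"], signs)])
    wmean = lambda v: float(np.average(v, weights=w))
    return CurveSummary(
        median_es=float(df["estimate"].median()),
        mean_es=wmean(est),
        median_ci_low=float(df["ci_low"].median()),
        median_ci_high=float(df["ci_high"].median()),
        mean_ci_low=wmean(df["ci_low"].to_numpy(dtype=float)),
        mean_ci_high=wmean(df["ci_high"].to_numpy(dtype=float)),
        median_p=float(df["p"].median()),
        pct_p_lt_05=float(100.0 * (df["p"] < 0.05).mean()),
        avg_z=wmean(z),
        k=int(len(df)),
        total_n=int(df["n"].sum()),
    )


def decide_significance(summary: CurveSummary, alpha: float = 0.05,
                        z_crit: float = 1.96) -> Decision:
    """Apply the four-indicator rule; significant only if all agree."""
    def excludes_zero(lo: float, hi: float) -> bool:
        return lo > 0.0 or hi < 0.0

    return Decision(
        mean_ci_excludes_0=excludes_zero(summary.mean_ci_low, summary.mean_ci_high),
        median_ci_excludes_0=excludes_zero(summary.median_ci_low,
                                           summary.median_ci_high),
        median_p_lt_05=summary.median_p < alpha,
        avg_abs_z_gt_196=abs(summary.avg_z) > z_crit,
    )


def classify_scenario(pheno: Decision, mz: Decision, dz: Decision) -> ScenarioLabel:
    """Map the decision pattern onto the etiologic scenarios.

    A significant association at every level is environmental in origin;
    significant phenotypic and DZ but not MZ indicates genetic mediation
    (evocative gene-environment correlation); significant only at the
    phenotypic level indicates genetic plus shared-environmental origins.
    A significant MZ association without a DZ one fits no scenario and
    is labeled inconsistent; no phenotypic association means there is
    nothing to decompose.
    """
    if not pheno.significant:
        label = "no_association"
    elif mz.significant and dz.significant:
        label = "environmental"
    elif dz.significant:
        label = "genetic"
    elif not mz.significant:
        label = "genetic_plus_shared_environmental"
    else:
        label = "inconsistent"
    return ScenarioLabel(label=label, phenotypic=pheno, mz=mz, dz=dz)


def compare_parenting_dimensions(
    results_dim1: pd.DataFrame,
    results_dim2: pd.DataFrame,
    r23,
    n=None,
) -> tuple[pd.DataFrame, dict[str, dict[str, float | bool]]]:
    """Contrast two parenting dimensions cell-by-cell and in summary.

    Both result frames must cover the same specifications (matched on
    ``spec_id``) with the antisocial-behavior variable in common, so the
    two correlations are dependent.  ``r23`` is the correlation between
    the two parenting (difference) scores — a scalar or a per-spec
    mapping — and ``n`` optionally overrides the per-cell sample size
    (default: the smaller of the two cells').

    Returns the per-cell frame with (z, p, significant) and a summary
    dict applying the same test to the unweighted-median and weighted-
    mean correlations at the median per-cell n.
    """
    d1 = results_dim1.set_index("spec_id")
    d2 = results_dim2.set_index("spec_id")
    if set(d1.index) != set(d2.index) or d1.index.has_duplicates:
        raise ValueError("parenting-dimension result sets do not cover the "
                         "same specifications")
    d2 = d2.reindex(d1.index)

    def _lookup(mapping, spec_id, default=None):
        if isinstance(mapping, Mapping):
            if spec_id not in mapping:
                raise ValueError(f"no value supplied for spec {spec_id!r}")
            return mapping[spec_id]
        return mapping if mapping is not None else default

    rows = []
    for spec_id in d1.index:
        r12 = float(d1.loc[spec_id, "estimate"])
        r13 = float(d2.loc[spec_id, "estimate"])
        r23_i = float(_lookup(r23, spec_id))
        n_i = int(_lookup(n, spec_id,
                          min(d1.loc[spec_id, "n"], d2.loc[spec_id, "n"])))
        z, p = steiger_dependent_z(r12, r13, r23_i, n_i)
        rows.append({"spec_id": spec_id, "r_dim1": r12, "r_dim2": r13,
                     "r23": r23_i, "n": n_i, "z": z, "p": p,
                     "significant": p < 0.05})
    per_spec = pd.DataFrame(rows)

    n_summary = int(per_spec["n"].median())
    r23_summary = float(per_spec["r23"].median())
    s1 = summarize_curve(d1.reset_index())
    s2 = summarize_curve(d2.reset_index())
    summary: dict[str, dict[str, float | bool]] = {}
    for stat, r12_s, r13_s in (("median", s1.median_es, s2.median_es),
                               ("mean", s1.mean_es, s2.mean_es)):
        z, p = steiger_dependent_z(r12_s, r13_s, r23_summary, n_summary)
        summary[stat] = {"r_dim1": r12_s, "r_dim2": r13_s, "z": z, "p": p,
                         "n": n_summary, "significant": p < 0.05}
    return per_spec, summary


class SpecificationCurve(BaseEstimator):
    """Run the full analytic multiverse on an observed twin dataset.

    Parameters
    ----------
    config : dict or None
        Analysis grid and thresholds (:func:`twinspec.config.default_config`
        when None).
    levels : sequence of str
        Analysis levels to run, from {"phenotypic", "twin_difference"}.
    seed : int
        Seed for the random co-twin A/B labeling.
    parenting_measure : str
        Parenting scale to use as the predictor.

    Attributes (after ``fit``)
    --------------------------
    results_ : DataFrame with one row per executed specification.
    summaries_ : dict mapping curve key ("phenotypic", "MZ", "DZ") to
        its :class:`CurveSummary`.
    decisions_ : dict mapping curve key to its :class:`Decision`.
    scenario_ : :class:`ScenarioLabel` (when all three curves were run).
    assignment_ : the per-family Twin A labels used.
    """

    def __init__(self, config: dict | None = None,
                 levels: Sequence[str] = ("phenotypic", "twin_difference"),
                 seed: int = 0, parenting_measure: str = "peq_nurturance"):
        self.config = config
        self.levels = levels
        self.seed = seed
        self.parenting_measure = parenting_measure

    def fit(self, dataset: pd.DataFrame, y=None):
        cfg = validate_config(dict(self.config) if self.config is not None
                              else default_config())
        wide = measures.to_wide(dataset)
        self.assignment_ = assign_twin_labels(dataset, self.seed)

        rows = []
        for level in self.levels:
            for spec in enumerate_specifications(cfg, level):
                est = run_specification(wide, spec, self.assignment_,
                                        self.parenting_measure)
                rows.append({"spec_id": spec.spec_id,
                             "analysis_level": spec.analysis_level,
                             "asb_measure": spec.asb_measure,
                             "asb_informant": spec.asb_informant,
                             "nurturance_informant": spec.nurturance_informant,
                             "normalization": spec.normalization,
                             "zygosity": spec.zygosity,
                             "kind": est.kind, "estimate": est.estimate,
                             "ci_low": est.ci_low, "ci_high": est.ci_high,
                             "p": est.p, "n": est.n})
        self.results_ = pd.DataFrame(rows, columns=RESULT_COLUMNS)

        self.summaries_ = {}
        self.decisions_ = {}
        for key, mask in self._curve_masks().items():
            summary = summarize_curve(self.results_, mask)
            self.summaries_[key] = summary
            self.decisions_[key] = decide_significance(summary, cfg["alpha"],
                                                       cfg["z_crit"])
        if {"phenotypic", "MZ", "DZ"} <= set(self.decisions_):
            self.scenario_ = classify_scenario(self.decisions_["phenotypic"],
                                               self.decisions_["MZ"],
                                               self.decisions_["DZ"])
        return self

    def _curve_masks(self) -> dict[str, pd.Series]:
        masks = {}
        if "phenotypic" in self.levels:
            masks["phenotypic"] = self.results_["analysis_level"] == "phenotypic"
        if "twin_difference" in self.levels:
            for zyg in ("MZ", "DZ"):
                masks[zyg] = self.results_["zygosity"] == zyg
        return masks

    def summary_table(self, curve: str) -> pd.DataFrame:
        """Grouped summary in the layout of the study's curve tables.

        One row overall, then rows grouped by antisocial-behavior
        measure, by its informant variant, by nurturance informant, and
        by normalization, each row aggregating the matching subset of
        the given curve ("phenotypic", "MZ" or "DZ").
        """
        mask = self._curve_masks()[curve]
        df = self.results_[mask]
        rows = [("overall", "overall", summarize_curve(df))]
        for axis in ("asb_measure", "asb_informant", "nurturance_informant",
                     "normalization"):
            for value in df[axis].unique():
                rows.append((axis, value, summarize_curve(df, df[axis] == value)))
        out = pd.DataFrame([{"group_axis": a, "group_value": v, **asdict(s)}
                            for a, v, s in rows])
        out.insert(0, "curve", curve)
        return out


def write_report(curve: SpecificationCurve, outdir: str | Path,
                 alpha: float = 0.05) -> dict[str, Path]:
    """Write per-specification results, grouped tables, decisions and the
    specification-curve plot.

    Produces ``results.csv``, ``summary_tables.csv``, ``decisions.json``
    and ``curve_plot.png`` under ``outdir``; CSV/JSON output is
    byte-stable for a fixed dataset, config and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"results": outdir / "results.csv",
             "summaries": outdir / "summary_tables.csv",
             "decisions": outdir / "decisions.json",
             "plot": outdir / "curve_plot.png"}

    curve.results_.to_csv(paths["results"], index=False)
    tables = pd.concat([curve.summary_table(key) for key in curve.summaries_],
                       ignore_index=True)
    tables.to_csv(paths["summaries"], index=False)

    payload: dict[str, Any] = {
        key: {"summary": asdict(curve.summaries_[key]),
              "indicators": curve.decisions_[key].indicators,
              "significant": curve.decisions_[key].significant}
        for key in curve.summaries_}
    if hasattr(curve, "scenario_"):
        payload["scenario"] = curve.scenario_.label
    paths["decisions"].write_text(json.dumps(payload, indent=2, sort_keys=True))

    _plot_curve(curve.results_, paths["plot"], alpha)
    return paths


def _plot_curve(results: pd.DataFrame, path: Path, alpha: float) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    keys = [k for k in ("phenotypic", "MZ", "DZ")
            if ((results["analysis_level"] == "phenotypic") if k == "phenotypic"
                else (results["zygosity"] == k)).any()]
    fig, axes = plt.subplots(1, max(len(keys), 1),
                             figsize=(4.0 * max(len(keys), 1), 3.2),
                             sharey=True, squeeze=False)
    for ax, key in zip(axes[0], keys):
        mask = ((results["analysis_level"] == "phenotypic") if key == "phenotypic"
                else (results["zygosity"] == key))
        df = results[mask].sort_values("estimate").reset_index(drop=True)
        x = np.arange(len(df))
        sig = df["p"] < alpha
        ax.vlines(x, df["ci_low"], df["ci_high"], color="0.8", lw=1)
        ax.scatter(x[~sig], df.loc[~sig, "estimate"], s=8, color="0.5",
                   label="p >= 0.05")
        ax.scatter(x[sig], df.loc[sig, "estimate"], s=8, color="crimson",
                   label="p < 0.05")
        ax.axhline(0.0, color="k", lw=0.7)
        ax.set_title(key)
        ax.set_xlabel("specification (sorted)")
    axes[0][0].set_ylabel("effect size")
    axes[0][-1].legend(frameon=False, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
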