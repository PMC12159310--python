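"""Multiverse enumeration, aggregation, decisions, classification, reports."""

import itertools
import json

import numpy as np
import pandas as pd
import pytest

import twinspec as ts
from twinspec.config import ConfigError
from twinspec.inference import EffectEstimate
from twinspec.speccurve import (CurveSummary, Decision, Specification,
                                classify_scenario, compare_parenting_dimensions,
                                decide_significance, enumerate_specifications,
                                run_specification, summarize_curve,
                                write_report)


def _estimate(estimate=0.1, p=0.2, n=100, half_width=0.15,
              kind="diff_correlation"):
    return EffectEstimate(kind=kind, estimate=estimate,
                          ci_low=estimate - half_width,
                          ci_high=estimate + half_width, p=p, n=n)


def _summary(mean_ci=(-0.2, -0.1), median_ci=(-0.2, -0.1), median_p=0.01,
             avg_z=-3.0):
    return CurveSummary(median_es=-0.15, mean_es=-0.15,
                        median_ci_low=median_ci[0], median_ci_high=median_ci[1],
                        mean_ci_low=mean_ci[0], mean_ci_high=mean_ci[1],
                        median_p=median_p, pct_p_lt_05=80.0, avg_z=avg_z,
                        k=10, total_n=1000)


# ---- enumeration -----------------------------------------------------------

def test_default_grid_counts():
    assert len(enumerate_specifications(None, "phenotypic")) == 130
    assert len(enumerate_specifications(None, "twin_difference")) == 260


def test_minimal_grid_single_cell():
    cfg = ts.default_config()
    cfg["asb_measures"] = {"cbcl_aggression": ["mother"]}
    cfg["nurturance_informants"] = ["mother"]
    cfg["normalizations"] = ["raw"]
    assert len(enumerate_specifications(cfg, "phenotypic")) == 1


def test_enumeration_is_deterministic():
    a = enumerate_specifications(None, "twin_difference")
    b = enumerate_specifications(None, "twin_difference")
    assert [s.spec_id for s in a] == [s.spec_id for s in b]
    assert len({s.spec_id for s in a}) == len(a)


def test_empty_axis_rejected():
    cfg = ts.default_config()
    cfg["nurturance_informants"] = []
    with pytest.raises(ConfigError):
        enumerate_specifications(cfg, "phenotypic")


def test_specification_invariants():
    with pytest.raises(ConfigError, match="interview"):
        Specification("interview", "mother", "mother", "raw", "phenotypic")
    with pytest.raises(ConfigError, match="zygosity"):
        Specification("interview", "twin", "mother", "raw", "phenotypic",
                      zygosity="MZ")
    with pytest.raises(ConfigError, match="MZ or DZ"):
        Specification("interview", "twin", "mother", "raw", "twin_difference")


# ---- aggregation -----------------------------------------------------------

def test_single_result_summary_echoes_fields():
    est = _estimate(estimate=-0.12, p=0.004, n=250)
    s = summarize_curve([est])
    assert s.median_es == s.mean_es == est.estimate
    assert s.median_ci_low == s.mean_ci_low == est.ci_low
    assert s.median_p == est.p
    assert s.pct_p_lt_05 == 100.0
    assert s.k == 1


def test_weighted_mean_unweighted_median():
    res = [_estimate(estimate=0.0, n=100), _estimate(estimate=0.4, n=300)]
    s = summarize_curve(res)
    assert s.mean_es == pytest.approx(0.3)       # n-weighted
    assert s.median_es == pytest.approx(0.2)     # plain median
    equal = [_estimate(estimate=0.1, n=50), _estimate(estimate=0.3, n=50)]
    assert summarize_curve(equal).mean_es == pytest.approx(0.2)


def test_pct_p_threshold_is_strict():
    res = [_estimate(p=0.01, n=100), _estimate(p=0.20, n=100)]
    assert summarize_curve(res).pct_p_lt_05 == pytest.approx(50.0)
    at_bound = [_estimate(p=0.05, n=100)]
    assert summarize_curve(at_bound).pct_p_lt_05 == 0.0


def test_avg_z_is_signed_and_weighted():
    res = [_estimate(estimate=-0.2, p=0.05, n=100),
           _estimate(estimate=-0.2, p=0.05, n=300)]
    s = summarize_curve(res)
    assert s.avg_z == pytest.approx(-1.96, abs=0.005)


def test_empty_subset_rejected():
    with pytest.raises(ValueError, match="empty"):
        summarize_curve([_estimate()], subset=pd.Series([False]))


# ---- decision rule ---------------------------------------------------------

def test_decision_requires_all_four_indicators():
    assert decide_significance(_summary()).significant
    assert not decide_significance(_summary(median_p=0.10)).significant
    assert not decide_significance(_summary(mean_ci=(-0.2, 0.01))).significant
    assert not decide_significance(_summary(avg_z=-1.5)).significant


def test_decision_uses_absolute_average_z():
    """Positive effects with avg_z > +1.96 count as significant too."""
    s = CurveSummary(median_es=0.15, mean_es=0.15, median_ci_low=0.1,
                     median_ci_high=0.2, mean_ci_low=0.1, mean_ci_high=0.2,
                     median_p=0.01, pct_p_lt_05=90.0, avg_z=3.0, k=5,
                     total_n=500)
    assert decide_significance(s).significant


def test_decision_monotone_under_sharpening():
    """Shrinking CIs toward the estimate and p toward 0 never turns a
    significant curve nonsignificant."""
    base = _summary()
    assert decide_significance(base).significant
    sharpened = CurveSummary(
        median_es=base.median_es, mean_es=base.mean_es,
        median_ci_low=base.median_es - 0.01, median_ci_high=base.median_es + 0.01,
        mean_ci_low=base.mean_es - 0.01, mean_ci_high=base.mean_es + 0.01,
        median_p=base.median_p / 10, pct_p_lt_05=100.0,
        avg_z=base.avg_z * 2, k=base.k, total_n=base.total_n)
    assert decide_significance(sharpened).significant


# ---- scenario classification ----------------------------------------------

def _decision(sig: bool) -> Decision:
    return Decision(mean_ci_excludes_0=sig, median_ci_excludes_0=sig,
                    median_p_lt_05=sig, avg_abs_z_gt_196=sig)


@pytest.mark.parametrize("pattern, expected", [
    ((True, True, True), "environmental"),
    ((True, False, True), "genetic"),
    ((True, False, False), "genetic_plus_shared_environmental"),
    ((True, True, False), "inconsistent"),
    ((False, True, True), "no_association"),
    ((False, False, False), "no_association"),
])
def test_classification_of_decision_patterns(pattern, expected):
    pheno, mz, dz = (_decision(s) for s in pattern)
    assert classify_scenario(pheno, mz, dz).label == expected


# ---- running specifications ------------------------------------------------

def test_run_specification_missing_column_errors(scenario1_dataset):
    wide = ts.to_wide(scenario1_dataset.query("informant_id != 'teacher'"))
    spec = Specification("cbcl_aggression", "teacher", "mother", "raw",
                         "phenotypic")
    with pytest.raises(ts.measures.ColumnError, match="teacher"):
        run_specification(wide, spec)


def test_twin_difference_spec_needs_assignment(scenario1_dataset):
    wide = ts.to_wide(scenario1_dataset)
    spec = Specification("cbcl_aggression", "mother", "mother", "raw",
                         "twin_difference", zygosity="MZ")
    with pytest.raises(ConfigError, match="assignment"):
        run_specification(wide, spec)


def test_fitted_curve_shape_and_kinds(small_curve):
    results = small_curve.results_
    assert len(results) == 12 + 24
    assert set(results.loc[results.analysis_level == "phenotypic", "kind"]) == {"mlm_beta"}
    assert set(results.loc[results.analysis_level == "twin_difference", "kind"]) == {"diff_correlation"}
    assert results["spec_id"].is_unique


def test_environmental_scenario_recovered_on_fixture(small_curve):
    """Under the environmental generating scenario every level should be
    detected at study scale with the compact grid."""
    assert small_curve.scenario_.label == "environmental"
    assert all(d.significant for d in small_curve.decisions_.values())
    # negative associations, as generated
    assert (small_curve.results_["estimate"] < 0).all()


def test_grouped_tables_consistent_with_direct_summaries(small_curve):
    """Every grouped row equals summarize_curve on the matching subset."""
    for key in ("phenotypic", "MZ", "DZ"):
        table = small_curve.summary_table(key)
        mask = (small_curve.results_["analysis_level"] == "phenotypic"
                if key == "phenotypic"
                else small_curve.results_["zygosity"] == key)
        df = small_curve.results_[mask]
        for _, row in table.iterrows():
            if row["group_axis"] == "overall":
                sub = df
            else:
                sub = df[df[row["group_axis"]] == row["group_value"]]
            expected = summarize_curve(sub)
            assert row["mean_es"] == pytest.approx(expected.mean_es)
            assert row["median_p"] == pytest.approx(expected.median_p)
            assert row["avg_z"] == pytest.approx(expected.avg_z)
            assert row["k"] == expected.k


def test_sklearn_estimator_protocol(small_grid_config):
    curve = ts.SpecificationCurve(config=small_grid_config, seed=3)
    params = curve.get_params()
    assert params["seed"] == 3
    clone = ts.SpecificationCurve(**params)
    assert clone.get_params() == params


# ---- dimension comparison --------------------------------------------------

def _results_frame(estimates, n=400):
    return pd.DataFrame({
        "spec_id": [f"spec{i}" for i in range(len(estimates))],
        "estimate": estimates,
        "ci_low": [e - 0.1 for e in estimates],
        "ci_high": [e + 0.1 for e in estimates],
        "p": [0.5] * len(estimates),
        "n": [n] * len(estimates),
    })


def test_identical_dimensions_never_flagged():
    res = _results_frame([-0.05, 0.02, 0.1])
    per_spec, summary = compare_parenting_dimensions(res, res.copy(), r23=0.3)
    assert (per_spec["z"] == 0).all()
    assert not per_spec["significant"].any()
    assert summary["median"]["z"] == 0 and summary["mean"]["z"] == 0


def test_mismatched_specification_sets_rejected():
    r1 = _results_frame([0.1, 0.2])
    r2 = _results_frame([0.1, 0.2, 0.3])
    with pytest.raises(ValueError, match="same specifications"):
        compare_parenting_dimensions(r1, r2, r23=0.3)


def test_tiny_n_rejected():
    r = _results_frame([0.1])
    with pytest.raises(ValueError, match="n must be"):
        compare_parenting_dimensions(r, _results_frame([0.3]), r23=0.3, n=3)


def test_contrast_power_between_scenarios():
    """MZ differences under a genetic+shared scenario (true r = 0) vs an
    environmental one (true r = 0.19): the summary contrast should flag a
    difference in most study-scale replicates (Monte-Carlo oracle on the
    implied trivariate normal of difference scores)."""
    n_pairs, r_harsh, r23 = 425, 0.19, 0.3
    sigma = np.array([[1.0, 0.0, r_harsh],
                      [0.0, 1.0, r23],
                      [r_harsh, r23, 1.0]])
    L = np.linalg.cholesky(sigma)
    rng = np.random.default_rng(2024)
    flagged = 0
    n_reps = 100
    for _ in range(n_reps):
        X = rng.standard_normal((n_pairs, 3)) @ L.T
        c = np.corrcoef(X, rowvar=False)
        r1 = _results_frame([c[0, 1]], n=n_pairs)   # nurturance vs ASB
        r2 = _results_frame([c[0, 2]], n=n_pairs)   # harshness vs ASB
        _, summary = compare_parenting_dimensions(r1, r2, r23=c[1, 2])
        if summary["median"]["significant"]:
            flagged += 1
    assert flagged >= 80


# ---- reporting -------------------------------------------------------------

def test_report_files_and_determinism(small_curve, tmp_path):
    paths = write_report(small_curve, tmp_path / "a")
    results = pd.read_csv(paths["results"])
    assert len(results) == len(small_curve.results_)
    payload = json.loads(paths["decisions"].read_text())
    assert payload["scenario"] == small_curve.scenario_.label
    assert set(payload) >= {"phenotypic", "MZ", "DZ"}
    assert paths["plot"].exists()

    paths2 = write_report(small_curve, tmp_path / "b")
    assert paths2["results"].read_bytes() == paths["results"].read_bytes()
    assert paths2["decisions"].read_bytes() == paths["decisions"].read_bytes()
    assert paths2["summaries"].read_bytes() == paths["summaries"].read_bytes()


def test_overall_summary_row_matches_decisions(small_curve, tmp_path):
    table = small_curve.summary_table("MZ")
    overall = table[table.group_axis == "overall"].iloc[0]
    assert overall["k"] == small_curve.summaries_["MZ"].k
    assert overall["mean_es"] == pytest.approx(small_curve.summaries_["MZ"].mean_es)
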