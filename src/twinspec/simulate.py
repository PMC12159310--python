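"""Synthetic twin-pair data under a bivariate ACE model.

Two layers:

1. :func:`simulate_biometric_pairs` draws latent standardized trait
   values for family-clustered twin pairs.  Additive-genetic factors are
   shared with coefficient 1 (MZ) or split into a shared and a
   twin-specific half-variance part (DZ), shared-environmental factors
   are common to the pair, and nonshared factors are twin-specific; the
   cross-trait correlations r_A, r_C, r_E are imposed pairwise between
   like factors.

2. :func:`render_observed` passes latents through a measurement layer
   emulating a multi-informant study: each (measure, informant) report is
   a reliability-weighted latent plus independent noise, optionally put
   through a monotone exponential transform to induce the right skew
   typical of raw antisocial-behavior scores, rescaled into the
   instrument's range, and deleted completely at random at the
   informant's missingness rate.

The observed table (the ``TwinDataset`` of the pipeline) is a long
pandas DataFrame with columns ``family_id, zygosity, twin_index,
measure_id, informant_id, value``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .params import BiometricParams, ParameterError, ScenarioPreset

__all__ = [
    "ReportSpec",
    "MeasurementModel",
    "simulate_biometric_pairs",
    "render_observed",
    "make_twin_dataset",
    "write_dataset",
    "read_dataset",
    "DATASET_COLUMNS",
]

DATASET_COLUMNS = ["family_id", "zygosity", "twin_index",
                   "measure_id", "informant_id", "value"]

# Linear scores are mapped onto instrument ranges over +/- 4 latent SD;
# values beyond are clipped (keeps the map fixed, rank-preserving and
# independent of the realized sample).
_CLIP_SD = 4.0


def _corr_pair(rng: np.random.Generator, n: int, r: float) -> np.ndarray:
    """n draws of a bivariate standard normal with correlation r, shape (n, 2)."""
    z = rng.standard_normal((n, 2))
    out = np.empty_like(z)
    out[:, 0] = z[:, 0]
    out[:, 1] = r * z[:, 0] + math.sqrt(max(0.0, 1.0 - r * r)) * z[:, 1]
    return out


def simulate_biometric_pairs(
    params: BiometricParams,
    n_mz: int,
    n_dz: int,
    seed: int | np.random.SeedSequence,
) -> pd.DataFrame:
    """Draw latent trait values for ``n_mz`` MZ and ``n_dz`` DZ twin pairs.

    Returns a DataFrame with one row per twin and columns
    ``family_id, zygosity, twin_index, x, y`` where ``x`` is the
    parenting-received latent and ``y`` the antisocial-behavior latent,
    both standardized in the population.
    """
    if n_mz < 0 or n_dz < 0:
        raise ValueError(f"pair counts must be nonnegative; got {n_mz}, {n_dz}")
    if not isinstance(params, BiometricParams):
        raise ParameterError("params must be a BiometricParams instance")
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rng = np.random.default_rng(ss)

    n = n_mz + n_dz
    zyg = np.repeat(["MZ", "DZ"], [n_mz, n_dz])
    is_dz = (zyg == "DZ")[:, None]

    # factor draws: columns are (trait x, trait y)
    a_shared = _corr_pair(rng, n, params.r_A)
    a_uniq1 = _corr_pair(rng, n, params.r_A)
    a_uniq2 = _corr_pair(rng, n, params.r_A)
    c_shared = _corr_pair(rng, n, params.r_C)
    e1 = _corr_pair(rng, n, params.r_E)
    e2 = _corr_pair(rng, n, params.r_E)

    half = math.sqrt(0.5)
    a1 = np.where(is_dz, half * a_shared + half * a_uniq1, a_shared)
    a2 = np.where(is_dz, half * a_shared + half * a_uniq2, a_shared)

    paths = np.array([[params.a_x, params.a_y],
                      [params.c_x, params.c_y],
                      [params.e_x, params.e_y]])

    def _trait(a: np.ndarray, e: np.ndarray) -> np.ndarray:
        return a * paths[0] + c_shared * paths[1] + e * paths[2]

    t1 = _trait(a1, e1)
    t2 = _trait(a2, e2)

    fam = np.arange(n)
    frames = []
    for idx, t in ((1, t1), (2, t2)):
        frames.append(pd.DataFrame({
            "family_id": fam, "zygosity": zyg,
            "twin_index": idx, "x": t[:, 0], "y": t[:, 1],
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["family_id", "twin_index"], ignore_index=True)


@dataclass(frozen=True)
class ReportSpec:
    """Measurement properties of one (measure, informant) report.

    reliability : proportion of latent-trait variance in the observed
        score, in (0, 1].
    skew : exponential-transform rate; 0 disables the skew transform.
    missing_rate : per-report probability the score is absent, in [0, 1).
    scale_range : (min, max) of the reported instrument scale.
    """

    trait: str
    reliability: float = 0.7
    skew: float = 0.0
    missing_rate: float = 0.0
    scale_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.reliability <= 1.0:
            raise ParameterError(f"reliability must be in (0, 1]; got {self.reliability}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ParameterError(f"missing_rate must be in [0, 1); got {self.missing_rate}")
        lo, hi = self.scale_range
        if not lo < hi:
            raise ParameterError(f"scale_range min must be < max; got {self.scale_range}")
        if self.trait not in ("x", "y"):
            raise ParameterError(f"trait must be 'x' or 'y'; got {self.trait!r}")


@dataclass(frozen=True)
class MeasurementModel:
    """Mapping from (measure_id, informant_id) to a :class:`ReportSpec`."""

    reports: Mapping[tuple[str, str], ReportSpec]

    def __post_init__(self) -> None:
        if not self.reports:
            raise ParameterError("measurement model must define at least one report")

    @classmethod
    def study_default(cls, reliability: float = 0.7,
                      asb_skew: float = 0.6) -> "MeasurementModel":
        """Measurement layer emulating the study's instruments.

        Antisocial behavior (trait y): two parent-checklist scales and a
        teacher report form (right-skewed raw counts) plus a child
        interview; parenting received (trait x): a nurturance scale rated
        by each parent and by the twin about each parent.  Missingness
        rates follow the reported informant coverage: ~99% mother, ~83%
        father and teacher, ~98-97% twin self/parent reports.
        """
        reports: dict[tuple[str, str], ReportSpec] = {}
        asb = {"mother": 0.01, "father": 0.171, "teacher": 0.17}
        for measure, rng_ in (("cbcl_aggression", (0.0, 36.0)),
                              ("cbcl_rulebreaking", (0.0, 34.0))):
            for informant, miss in asb.items():
                reports[(measure, informant)] = ReportSpec(
                    trait="y", reliability=reliability, skew=asb_skew,
                    missing_rate=miss, scale_range=rng_)
        reports[("interview", "twin")] = ReportSpec(
            trait="y", reliability=reliability, skew=asb_skew,
            missing_rate=0.012, scale_range=(0.0, 46.0))
        nurt = {"mother": 0.024, "father": 0.176,
                "twin_about_mother": 0.026, "twin_about_father": 0.056}
        for informant, miss in nurt.items():
            reports[("peq_nurturance", informant)] = ReportSpec(
                trait="x", reliability=reliability, skew=0.0,
                missing_rate=miss, scale_range=(0.0, 24.0))
        return cls(reports=reports)

    def with_harshness(self) -> "MeasurementModel":
        """Add a parent-child conflict (harshness) scale mirroring nurturance."""
        reports = dict(self.reports)
        for (measure, informant), spec in self.reports.items():
            if measure == "peq_nurturance":
                reports[("peq_conflict", informant)] = replace(spec)
        return MeasurementModel(reports=reports)


def _linear_to_scale(linear: np.ndarray, spec: ReportSpec) -> np.ndarray:
    """Map standardized linear scores into the instrument range.

    With a positive skew rate the map is ``exp(skew * s)`` followed by a
    fixed affine rescaling (exponential over +/- 4 SD onto the range),
    which induces right skew while preserving ranks; otherwise the map
    is affine over +/- 4 SD.  Values beyond +/- 4 SD are clipped.
    """
    lo, hi = spec.scale_range
    s = np.clip(linear, -_CLIP_SD, _CLIP_SD)
    if spec.skew > 0:
        u = np.exp(spec.skew * s)
        ulo, uhi = math.exp(-spec.skew * _CLIP_SD), math.exp(spec.skew * _CLIP_SD)
        return lo + (u - ulo) * (hi - lo) / (uhi - ulo)
    return lo + (s + _CLIP_SD) * (hi - lo) / (2.0 * _CLIP_SD)


def render_observed(
    pairs: pd.DataFrame,
    measurement: MeasurementModel,
    seed: int | np.random.SeedSequence,
) -> pd.DataFrame:
    """Render per-informant observed scores from latent twin pairs.

    Each report is ``sqrt(rel) * latent + sqrt(1-rel) * noise`` (so the
    observed cross-trait correlation is the latent correlation attenuated
    by ``sqrt(rel_x * rel_y)``), then skewed/rescaled per its
    :class:`ReportSpec` and masked missing completely at random.

    Returns the long-format observed table; rows with missing reports are
    kept with ``value`` = NaN so informant coverage is explicit.
    """
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    noise_rng = np.random.default_rng(ss.spawn(1)[0])
    miss_rng = np.random.default_rng(ss.spawn(1)[0])

    n = len(pairs)
    frames = []
    # deterministic report order: sorted keys
    for (measure, informant) in sorted(measurement.reports):
        spec = measurement.reports[(measure, informant)]
        latent = pairs[spec.trait].to_numpy()
        w = math.sqrt(spec.reliability)
        linear = w * latent + math.sqrt(1.0 - spec.reliability) * noise_rng.standard_normal(n)
        value = _linear_to_scale(linear, spec)
        if spec.missing_rate > 0:
            value = np.where(miss_rng.random(n) < spec.missing_rate, np.nan, value)
        frames.append(pd.DataFrame({
            "family_id": pairs["family_id"].to_numpy(),
            "zygosity": pairs["zygosity"].to_numpy(),
            "twin_index": pairs["twin_index"].to_numpy(),
            "measure_id": measure,
            "informant_id": informant,
            "value": value,
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["measure_id", "informant_id", "family_id", "twin_index"],
                           ignore_index=True)


def make_twin_dataset(
    preset: ScenarioPreset | BiometricParams,
    n_mz: int = 426,
    n_dz: int = 604,
    seed: int | np.random.SeedSequence = 0,
    measurement: MeasurementModel | None = None,
) -> pd.DataFrame:
    """Simulate a complete observed twin dataset at study scale.

    Default pair counts (426 MZ, 604 DZ) match the pooled two-arm study
    sample.  A single master seed deterministically spawns substreams for
    the latent draw and the measurement layer.
    """
    params = preset.params if isinstance(preset, ScenarioPreset) else preset
    measurement = measurement or MeasurementModel.study_default()
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    latent_ss, obs_ss = ss.spawn(2)
    pairs = simulate_biometric_pairs(params, n_mz, n_dz, latent_ss)
    return render_observed(pairs, measurement, obs_ss)


def write_dataset(dataset: pd.DataFrame, path: str | Path,
                  sidecar: Mapping | None = None) -> None:
    """Write the long-format table as CSV (empty field for missing values).

    If ``sidecar`` metadata is given (e.g. the generating parameters) it
    is written next to the CSV as ``<path>.json``.
    """
    path = Path(path)
    dataset.to_csv(path, index=False, columns=DATASET_COLUMNS, na_rep="")
    if sidecar is not None:
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2,
                                                        sort_keys=True))


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read a long-format twin dataset CSV written by :func:`write_dataset`."""
    df = pd.read_csv(path, dtype={"zygosity": str, "measure_id": str,
                                  "informant_id": str})
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset file {path} lacks required columns: {missing}")
    return df
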