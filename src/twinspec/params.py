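"""Biometric (ACE) generating parameters and etiologic scenario presets.

The generating model for each trait is the standard univariate decomposition

    T = a*A + c*C + e*E,      a^2 + c^2 + e^2 = 1,

with additive-genetic (A), shared-environmental (C) and nonshared-
environmental (E) standard-normal factors.  Co-twins share A with
correlation 1 (MZ) or 0.5 (DZ), share C completely, and have independent
E.  The two traits -- parenting received (x) and child antisocial
behavior (y) -- are linked only through correlations between like
factors: corr(A_x, A_y) = r_A, corr(C_x, C_y) = r_C, corr(E_x, E_y) = r_E.

Under this model the implied cross-trait correlations have closed forms:

    individual level:  r_xy      = a_x*a_y*r_A + c_x*c_y*r_C + e_x*e_y*r_E
    MZ difference:     r_MZdiff  = r_E
    DZ difference:     r_DZdiff  = (a_x*a_y*r_A + 2*e_x*e_y*r_E)
                                   / sqrt((a_x^2+2*e_x^2)*(a_y^2+2*e_y^2))

Three presets encode the canonical etiologic scenarios for a
phenotypic parenting-behavior association:

* ``scenario1_environmental`` -- the association is carried entirely by
  nonshared-environmental overlap (r_E != 0, r_A = r_C = 0), so it
  survives within both MZ and DZ pairs.
* ``scenario2_genetic`` -- purely genetic / evocative gene-environment
  correlation (r_A != 0, r_C = r_E = 0): present at the individual level
  and within DZ pairs, absent within MZ pairs.
* ``scenario3_genetic_shared`` -- genetic plus shared-environmental
  overlap (r_A != 0, r_C != 0, r_E = 0): present at the individual
  level only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "BiometricParams",
    "ScenarioPreset",
    "SCENARIO_LABELS",
    "scenario_preset",
    "ParameterError",
]

_UNIT_TOL = 1e-9

#: Default variance shares for the parenting-received trait: the share of
#: variance in parental warmth/involvement attributable to the child's own
#: genes (~26%) and to the shared rearing environment (~39%) in
#: meta-analytic estimates for child-based designs.
DEFAULT_X_VARIANCES = (0.26, 0.39, 0.35)

#: Default variance shares for childhood antisocial behavior (a2, c2, e2).
DEFAULT_Y_VARIANCES = (0.50, 0.20, 0.30)

SCENARIO_LABELS = (
    "scenario1_environmental",
    "scenario2_genetic",
    "scenario3_genetic_shared",
)

_SCENARIO_ALIASES = {
    "scenario1": "scenario1_environmental",
    "scenario2": "scenario2_genetic",
    "scenario3": "scenario3_genetic_shared",
}


class ParameterError(ValueError):
    """Raised for infeasible or inconsistent generating parameters."""


@dataclass(frozen=True)
class BiometricParams:
    """Path coefficients and cross-trait factor correlations.

    Parameters
    ----------
    a_x, c_x, e_x : float
        Path coefficients for trait X (parenting received); squares must
        sum to one.
    a_y, c_y, e_y : float
        Path coefficients for trait Y (child antisocial behavior).
    r_A, r_C, r_E : float
        Correlations between the like factors of the two traits,
        each in [-1, 1].
    """

    a_x: float
    c_x: float
    e_x: float
    a_y: float
    c_y: float
    e_y: float
    r_A: float = 0.0
    r_C: float = 0.0
    r_E: float = 0.0

    def __post_init__(self) -> None:
        for trait, (a, c, e) in (("x", (self.a_x, self.c_x, self.e_x)),
                                 ("y", (self.a_y, self.c_y, self.e_y))):
            total = a * a + c * c + e * e
            if abs(total - 1.0) > _UNIT_TOL:
                raise ParameterError(
                    f"path coefficients for trait {trait} must satisfy "
                    f"a^2+c^2+e^2=1; got {total:.12f}"
                )
            if e <= 0:
                raise ParameterError(
                    f"nonshared path e_{trait} must be positive; got {e}"
                )
        for name, r in (("r_A", self.r_A), ("r_C", self.r_C), ("r_E", self.r_E)):
            if not -1.0 <= r <= 1.0:
                raise ParameterError(f"{name} must lie in [-1, 1]; got {r}")

    @classmethod
    def from_variance_components(
        cls,
        x_variances: tuple[float, float, float] = DEFAULT_X_VARIANCES,
        y_variances: tuple[float, float, float] = DEFAULT_Y_VARIANCES,
        r_A: float = 0.0,
        r_C: float = 0.0,
        r_E: float = 0.0,
    ) -> "BiometricParams":
        """Build from (a2, c2, e2) variance shares instead of path coefficients."""
        ax2, cx2, ex2 = x_variances
        ay2, cy2, ey2 = y_variances
        for shares in (x_variances, y_variances):
            if any(s < 0 for s in shares):
                raise ParameterError(f"variance shares must be nonnegative: {shares}")
            if abs(sum(shares) - 1.0) > 1e-6:
                raise ParameterError(f"variance shares must sum to 1: {shares}")
        return cls(
            a_x=math.sqrt(ax2), c_x=math.sqrt(cx2), e_x=math.sqrt(ex2),
            a_y=math.sqrt(ay2), c_y=math.sqrt(cy2), e_y=math.sqrt(ey2),
            r_A=r_A, r_C=r_C, r_E=r_E,
        )

    # ---- closed-form implied correlations -------------------------------

    def individual_correlation(self) -> float:
        """Expected individual-level cross-trait correlation."""
        return (self.a_x * self.a_y * self.r_A
                + self.c_x * self.c_y * self.r_C
                + self.e_x * self.e_y * self.r_E)

    def mz_difference_correlation(self) -> float:
        """Expected correlation of MZ co-twin difference scores (equals r_E)."""
        return self.r_E

    def dz_difference_correlation(self) -> float:
        """Expected correlation of DZ co-twin difference scores."""
        num = self.a_x * self.a_y * self.r_A + 2.0 * self.e_x * self.e_y * self.r_E
        den = math.sqrt((self.a_x ** 2 + 2.0 * self.e_x ** 2)
                        * (self.a_y ** 2 + 2.0 * self.e_y ** 2))
        return num / den

    def cotwin_correlation(self, trait: str, zygosity: str) -> float:
        """Expected co-twin correlation for one trait (a^2+c^2 MZ, a^2/2+c^2 DZ)."""
        a, c = (self.a_x, self.c_x) if trait == "x" else (self.a_y, self.c_y)
        share = 1.0 if zygosity == "MZ" else 0.5
        return share * a * a + c * c


@dataclass(frozen=True)
class ScenarioPreset:
    """A labeled etiologic scenario with its generating parameters."""

    label: str
    params: BiometricParams
    sign: int = -1
    effect_size: float = 0.10

    def __post_init__(self) -> None:
        p = self.params
        if self.label == "scenario1_environmental":
            ok = p.r_E != 0 and p.r_A == 0 and p.r_C == 0
        elif self.label == "scenario2_genetic":
            ok = p.r_A != 0 and p.r_C == 0 and p.r_E == 0
        elif self.label == "scenario3_genetic_shared":
            ok = p.r_A != 0 and p.r_C != 0 and p.r_E == 0
        else:
            raise ParameterError(f"unknown scenario label: {self.label!r}")
        if not ok:
            raise ParameterError(
                f"cross-trait correlations {p.r_A, p.r_C, p.r_E} violate the "
                f"{self.label} pattern"
            )


def scenario_preset(
    label: str,
    effect_size: float = 0.10,
    sign: int = -1,
    x_variances: tuple[float, float, float] = DEFAULT_X_VARIANCES,
    y_variances: tuple[float, float, float] = DEFAULT_Y_VARIANCES,
) -> ScenarioPreset:
    """Build a scenario preset whose individual-level correlation is
    ``sign * effect_size``.

    The cross-trait factor correlations are obtained by inverting the
    closed form ``r_xy = a_x a_y r_A + c_x c_y r_C + e_x e_y r_E`` under
    the scenario's zero pattern; for scenario 3 the target correlation is
    split evenly between the genetic and shared-environmental routes.

    Raises
    ------
    ParameterError
        If the label is unknown or the requested effect size would
        require a factor correlation outside [-1, 1].
    """
    label = _SCENARIO_ALIASES.get(label, label)
    if label not in SCENARIO_LABELS:
        raise ParameterError(f"unknown scenario label: {label!r}")
    if sign not in (-1, 1):
        raise ParameterError(f"sign must be +1 or -1; got {sign}")
    if effect_size < 0:
        raise ParameterError(f"effect_size must be nonnegative; got {effect_size}")

    base = BiometricParams.from_variance_components(x_variances, y_variances)
    target = sign * effect_size

    def _invert(product: float, route: str, share: float = 1.0) -> float:
        if product <= 0:
            raise ParameterError(
                f"route {route} has zero path-coefficient product; cannot "
                f"carry the cross-trait association"
            )
        r = share * target / product
        if abs(r) > 1.0:
            raise ParameterError(
                f"effect_size {effect_size} infeasible through route {route}: "
                f"requires |r| = {abs(r):.3f} > 1"
            )
        return r

    if label == "scenario1_environmental":
        params = replace(base, r_E=_invert(base.e_x * base.e_y, "E"))
    elif label == "scenario2_genetic":
        params = replace(base, r_A=_invert(base.a_x * base.a_y, "A"))
    else:
        params = replace(
            base,
            r_A=_invert(base.a_x * base.a_y, "A", 0.5),
            r_C=_invert(base.c_x * base.c_y, "C", 0.5),
        )
    return ScenarioPreset(label=label, params=params, sign=sign,
                          effect_size=effect_size)
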