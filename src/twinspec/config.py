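"""Analysis-grid configuration: axes of the specification multiverse.

The default grid reproduces the study design: three antisocial-behavior
measures with their admissible informant variants (the two checklist
scales each take six variants, the child interview only the twin
self-report), five nurturance informant variants, and two
normalizations — (2 x 6 + 1) x 5 x 2 = 130 phenotypic cells, doubled to
260 at the twin-difference level by the two zygosities.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

from .measures import ASB_INFORMANT_MEMBERS, NURTURANCE_INFORMANT_MEMBERS

__all__ = ["default_config", "recovery_config", "load_config", "validate_config",
           "ConfigError"]

_CBCL_INFORMANTS = ["mother", "father", "teacher", "family", "adults", "all"]


class ConfigError(ValueError):
    """Raised for an invalid analysis configuration."""


def default_config() -> dict[str, Any]:
    """The study's full analysis grid plus decision-rule thresholds."""
    return {
        "asb_measures": {
            "cbcl_aggression": list(_CBCL_INFORMANTS),
            "cbcl_rulebreaking": list(_CBCL_INFORMANTS),
            "interview": ["twin"],
        },
        "nurturance_informants": ["mother", "father", "twin", "adults", "all"],
        "normalizations": ["raw", "log"],
        "alpha": 0.05,
        "z_crit": 1.96,
    }


def recovery_config() -> dict[str, Any]:
    """Compact one-cell grid used by the scenario-recovery suites.

    All-informant composites maximize measurement reliability and log
    normalization linearizes the skewed raw antisocial-behavior scores,
    so a single cell carries the design's power at study scale.
    """
    cfg = default_config()
    cfg["asb_measures"] = {"cbcl_aggression": ["all"]}
    cfg["nurturance_informants"] = ["all"]
    cfg["normalizations"] = ["log"]
    return cfg


def validate_config(config: dict[str, Any]) -> dict[str, Any]:
    """Validate axes and thresholds; returns the config for chaining."""
    if not isinstance(config.get("asb_measures"), dict) or not config["asb_measures"]:
        raise ConfigError("config must list at least one antisocial-behavior "
                          "measure under 'asb_measures'")
    for measure, informants in config["asb_measures"].items():
        if not informants:
            raise ConfigError(f"measure {measure!r} lists no informant variants")
        for informant in informants:
            if informant not in ASB_INFORMANT_MEMBERS:
                raise ConfigError(f"unknown antisocial-behavior informant "
                                  f"{informant!r} for measure {measure!r}")
            if (measure == "interview") != (informant == "twin"):
                raise ConfigError(
                    f"informant {informant!r} is incompatible with measure "
                    f"{measure!r}: the twin self-report pairs only with the "
                    f"interview measure")
    if not config.get("nurturance_informants"):
        raise ConfigError("config lists no nurturance informant variants")
    for informant in config["nurturance_informants"]:
        if informant not in NURTURANCE_INFORMANT_MEMBERS:
            raise ConfigError(f"unknown nurturance informant {informant!r}")
    norms = config.get("normalizations")
    if not norms or any(n not in ("raw", "log") for n in norms):
        raise ConfigError("'normalizations' must be a nonempty subset of "
                          "['raw', 'log']")
    alpha = config.get("alpha", 0.05)
    if not 0 < alpha < 1:
        raise ConfigError(f"alpha must be in (0, 1); got {alpha}")
    if config.get("z_crit", 1.96) <= 0:
        raise ConfigError("z_crit must be positive")
    return config


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Load a JSON config file (defaults when path is None) and validate."""
    if path is None:
        return default_config()
    cfg = default_config()
    with open(path) as fh:
        user = json.load(fh)
    cfg.update(user)
    return validate_config(cfg)
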