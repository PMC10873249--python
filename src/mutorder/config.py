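"""TOML run configuration for both model families.

A config file has an optional ``[bistable]`` section (cubic
coefficients, Boolean regulation and optional coupled-cascade
parameters), an optional ``[moran]`` section (a scenario preset name or
explicit parameters) and top-level ``seed`` / ``output`` keys.  Unknown
keys are rejected with the offending key path in the message.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

from .bistable import AutoregCubic, CoupledModelSpec, RegulationSpec
from .moran import MoranParameters, make_scenario

__all__ = ["ConfigError", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid or unparseable run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration."""

    bistable_cubic: AutoregCubic | None
    regulation: RegulationSpec | None
    coupled: CoupledModelSpec | None
    moran: MoranParameters | None
    seed: int
    classification_tol: float
    survival_tol: float
    min_steps: int
    output: str | None


def _reject_unknown(section: Mapping[str, Any], allowed: set[str], path: str) -> None:
    for key in section:
        if key not in allowed:
            raise ConfigError(f"unknown configuration key {path}{key!r}")


def _parse_bistable(section: Mapping[str, Any]):
    _reject_unknown(
        section, {"cubic", "basal", "jak2", "tet2", "coupled"}, "bistable."
    )
    cubic = AutoregCubic(tuple(section.get("cubic", (-1.0, 6.0, -10.0, 4.0))))
    regulation = None
    if any(k in section for k in ("basal", "jak2", "tet2")):
        try:
            regulation = RegulationSpec(
                basal=float(section["basal"]),
                jak2=float(section.get("jak2", 0.0)),
                tet2=float(section.get("tet2", 0.0)),
            )
        except KeyError as exc:
            raise ConfigError(f"bistable.{exc.args[0]} is required") from None
    coupled = None
    if "coupled" in section:
        sub = section["coupled"]
        _reject_unknown(sub, {"basal", "direct_jak2", "coupling"}, "bistable.coupled.")
        if regulation is None:
            raise ConfigError("bistable.coupled requires a regulation spec")
        coupled = CoupledModelSpec(
            regulation=regulation,
            cubic=cubic,
            basal=float(sub.get("basal", 1.0)),
            direct_jak2=float(sub.get("direct_jak2", -1.0)),
            coupling=float(sub.get("coupling", 1.0)),
        )
    return cubic, regulation, coupled


def _parse_moran(section: Mapping[str, Any]) -> MoranParameters:
    allowed = {
        "scenario",
        "n",
        "birth",
        "death",
        "m_oj",
        "m_ot",
        "m_jjt",
        "m_ttj",
    }
    _reject_unknown(section, allowed, "moran.")
    n = int(section.get("n", 100))
    if "scenario" in section:
        extra = allowed - {"scenario", "n"}
        for key in extra:
            if key in section:
                raise ConfigError(
                    f"moran.{key} conflicts with moran.scenario; use one or the other"
                )
        try:
            return make_scenario(str(section["scenario"]), n=n)
        except ValueError as exc:
            raise ConfigError(f"moran.scenario: {exc}") from None
    try:
        return MoranParameters(
            birth=tuple(section["birth"]),
            death=tuple(section.get("death", (1.0,) * 5)),
            m_oj=float(section["m_oj"]),
            m_ot=float(section["m_ot"]),
            m_jjt=float(section["m_jjt"]),
            m_ttj=float(section["m_ttj"]),
            n=n,
        )
    except KeyError as exc:
        raise ConfigError(f"moran.{exc.args[0]} is required") from None
    except ValueError as exc:
        raise ConfigError(f"moran: {exc}") from None


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML run configuration."""
    path = Path(path)
    try:
        with path.open("rb") as fh:
            data = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc

    _reject_unknown(
        data,
        {
            "bistable",
            "moran",
            "seed",
            "output",
            "classification_tol",
            "survival_tol",
            "min_steps",
        },
        "",
    )
    if "bistable" not in data and "moran" not in data:
        raise ConfigError("config must contain a [bistable] or [moran] section")

    cubic = regulation = coupled = moran = None
    if "bistable" in data:
        cubic, regulation, coupled = _parse_bistable(data["bistable"])
    if "moran" in data:
        moran = _parse_moran(data["moran"])

    tol = float(data.get("classification_tol", 0.05))
    if tol <= 0:
        raise ConfigError("classification_tol must be positive")
    survival_tol = float(data.get("survival_tol", 1e-8))
    if not 0.0 < survival_tol < 1.0:
        raise ConfigError("survival_tol must lie in (0, 1)")
    min_steps = int(data.get("min_steps", 400))
    if min_steps < 0:
        raise ConfigError("min_steps must be non-negative")

    return RunConfig(
        bistable_cubic=cubic,
        regulation=regulation,
        coupled=coupled,
        moran=moran,
        seed=int(data.get("seed", 0)),
        classification_tol=tol,
        survival_tol=survival_tol,
        min_steps=min_steps,
        output=data.get("output"),
    )
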