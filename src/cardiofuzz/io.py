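"""Load and save Mamdani system definitions as JSON documents.

A system file declares the two input variables, the output variable
(each with a closed universe and 4-knot terms, optionally flagged as a
left/right shoulder), the rule list as label pairs, the COG sample
count, and optional human-readable display names for output labels.
Validation happens in two layers: document shape via pydantic models,
then cross-references (dangling labels, duplicate antecedents) via the
engine's own constructors.  An incomplete rule grid is legal for the
engine and only triggers a warning — grid completeness is a property of
the packaged heart-rate systems, not an engine requirement.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Dict, List, Literal, Mapping, Optional, Tuple, Union

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .engine import (
    DEFAULT_COG_SAMPLES,
    ConfigurationError,
    FuzzyRule,
    MamdaniSystem,
    RuleBase,
)
from .membership import LinguisticVariable, PiecewiseLinearMF

__all__ = ["load_system", "save_system", "system_to_dict", "IncompleteRuleGridWarning"]


class IncompleteRuleGridWarning(UserWarning):
    """The rule list does not cover every input-term combination."""


class TermSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    label: str
    knots: Tuple[float, float, float, float]
    shoulder: Optional[Literal["left", "right"]] = None

    @model_validator(mode="after")
    def _check_shoulder(self) -> "TermSpec":
        a, b, c, d = self.knots
        if self.shoulder == "left" and a != b:
            raise ValueError(f"term {self.label!r}: left shoulder requires knots a == b")
        if self.shoulder == "right" and c != d:
            raise ValueError(f"term {self.label!r}: right shoulder requires knots c == d")
        return self


class VariableSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    universe: Tuple[float, float]
    terms: List[TermSpec] = Field(min_length=1)


class RuleSpec(BaseModel):
    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    antecedent: Dict[str, str] = Field(alias="if")
    consequent: str = Field(alias="then")


class SystemSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    description: Optional[str] = None
    inputs: List[VariableSpec] = Field(min_length=2, max_length=2)
    output: VariableSpec
    rules: List[RuleSpec] = Field(min_length=1)
    cog_samples: int = DEFAULT_COG_SAMPLES
    display: Dict[str, List[str]] = Field(default_factory=dict)


def _build_variable(spec: VariableSpec) -> LinguisticVariable:
    terms = tuple((t.label, PiecewiseLinearMF(*t.knots)) for t in spec.terms)
    return LinguisticVariable(name=spec.name, universe=tuple(spec.universe), terms=terms)


def load_system(source: Union[str, Path, Mapping]) -> MamdaniSystem:
    """Build a validated :class:`MamdaniSystem` from a JSON file or dict."""
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            document = json.load(fh)
    else:
        document = dict(source)
    try:
        spec = SystemSpec.model_validate(document)
    except ValidationError as exc:
        raise ConfigurationError(f"invalid system definition: {exc}") from exc

    inputs = tuple(_build_variable(v) for v in spec.inputs)
    output = _build_variable(spec.output)
    try:
        rules = tuple(
            FuzzyRule(
                antecedent=tuple(sorted(r.antecedent.items())),
                consequent=(output.name, r.consequent),
            )
            for r in spec.rules
        )
        system = MamdaniSystem(
            name=spec.name,
            inputs=inputs,  # type: ignore[arg-type]
            output=output,
            rule_base=RuleBase(rules),
            cog_samples=spec.cog_samples,
            display_names={k: tuple(v) for k, v in spec.display.items()},
        )
    except ValueError as exc:  # includes ConfigurationError
        raise ConfigurationError(str(exc)) from exc

    if not system.is_complete_grid:
        warnings.warn(
            f"system {system.name!r}: rule list does not cover the full "
            f"{len(inputs[0].labels)}x{len(inputs[1].labels)} input grid",
            IncompleteRuleGridWarning,
            stacklevel=2,
        )
    return system


def _term_dict(label: str, mf: PiecewiseLinearMF) -> dict:
    shoulder = "left" if mf.is_left_shoulder else "right" if mf.is_right_shoulder else None
    out = {"label": label, "knots": [mf.a, mf.b, mf.c, mf.d]}
    if shoulder:
        out["shoulder"] = shoulder
    return out


def _variable_dict(var: LinguisticVariable) -> dict:
    return {
        "name": var.name,
        "universe": list(var.universe),
        "terms": [_term_dict(label, mf) for label, mf in var.terms],
    }


def system_to_dict(system: MamdaniSystem) -> dict:
    """Serializable document equivalent to the system (load/save round-trip)."""
    return {
        "name": system.name,
        "inputs": [_variable_dict(v) for v in system.inputs],
        "output": _variable_dict(system.output),
        "rules": [
            {"if": dict(rule.antecedent), "then": rule.consequent[1]}
            for rule in system.rule_base
        ],
        "cog_samples": system.cog_samples,
        "display": {k: list(v) for k, v in system.display_names.items()},
    }


def save_system(system: MamdaniSystem, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(system_to_dict(system), fh, indent=2, sort_keys=True)
        fh.write("\n")
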