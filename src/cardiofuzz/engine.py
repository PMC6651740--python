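"""Two-input, one-output Mamdani inference with centre-of-gravity output.

The engine implements exactly what the packaged heart-rate systems need:
crisp (singleton) inputs, AND = min over the two antecedent clauses,
min implication (each rule clips its consequent set at the rule's firing
level), max aggregation across rules, and discrete centre-of-gravity
(COG) defuzzification

    y* = sum_i mu(y_i) * y_i / sum_i mu(y_i)

over evenly spaced samples of the output universe.  Rule weights, OR
antecedents, fuzzy-set inputs and alternative defuzzifiers are out of
scope by design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Tuple

import numpy as np

from .membership import LinguisticVariable

__all__ = [
    "ConfigurationError",
    "NoRuleFiredError",
    "FuzzyRule",
    "RuleBase",
    "AggregatedOutput",
    "MamdaniSystem",
    "defuzzify_cog",
]

DEFAULT_COG_SAMPLES = 1201
MIN_COG_SAMPLES = 101


class ConfigurationError(ValueError):
    """A system definition is internally inconsistent (dangling label, ...)."""


class NoRuleFiredError(RuntimeError):
    """All rule activations are zero, so the COG is undefined."""


@dataclass(frozen=True)
class FuzzyRule:
    """IF (var1 is t1) AND (var2 is t2) ... THEN (out_var is t_out)."""

    antecedent: Tuple[Tuple[str, str], ...]
    consequent: Tuple[str, str]

    def __post_init__(self) -> None:
        if not self.antecedent:
            raise ConfigurationError("rule needs at least one antecedent clause")
        names = [var for var, _ in self.antecedent]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"rule references a variable twice: {names}")

    @property
    def antecedent_key(self) -> frozenset:
        return frozenset(self.antecedent)


@dataclass(frozen=True)
class RuleBase:
    rules: Tuple[FuzzyRule, ...]

    def __post_init__(self) -> None:
        seen = set()
        for rule in self.rules:
            key = rule.antecedent_key
            if key in seen:
                raise ConfigurationError(f"duplicate rule antecedent {sorted(rule.antecedent)}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self) -> Iterator[FuzzyRule]:
        return iter(self.rules)

    def consequent_for(self, antecedent: Mapping[str, str]) -> str:
        """Crisp rule lookup: the consequent label for an exact antecedent."""
        key = frozenset(antecedent.items())
        for rule in self.rules:
            if rule.antecedent_key == key:
                return rule.consequent[1]
        raise KeyError(f"no rule with antecedent {dict(antecedent)}")


@dataclass
class AggregatedOutput:
    """Clipped-and-merged fuzzy output: per-term firing levels + envelope."""

    activations: Dict[str, float]
    output_var: LinguisticVariable

    def envelope(self, y):
        """max over terms of min(activation, term membership at y)."""
        arr = np.asarray(y, dtype=float)
        mu = np.zeros_like(arr)
        for label, level in self.activations.items():
            if level > 0.0:
                mu = np.maximum(mu, np.minimum(level, self.output_var[label](arr)))
        return float(mu) if np.isscalar(y) or arr.ndim == 0 else mu

    @property
    def fired(self) -> Dict[str, float]:
        return {label: lvl for label, lvl in self.activations.items() if lvl > 0.0}


def defuzzify_cog(agg: AggregatedOutput, output_var: LinguisticVariable | None = None,
                  cog_samples: int = DEFAULT_COG_SAMPLES) -> float:
    """Discrete centre of gravity of the aggregated envelope.

    Samples the output universe at ``cog_samples`` evenly spaced points
    (endpoints included) and returns the weighted mean of the sample
    locations.  Raises :class:`NoRuleFiredError` on an all-zero envelope
    rather than silently returning anything.
    """
    var = output_var if output_var is not None else agg.output_var
    if cog_samples < MIN_COG_SAMPLES:
        raise ConfigurationError(f"cog_samples must be >= {MIN_COG_SAMPLES}, got {cog_samples}")
    lo, hi = var.universe
    ys = np.linspace(lo, hi, cog_samples)
    mu = agg.envelope(ys)
    total = float(mu.sum())
    if total <= 0.0:
        raise NoRuleFiredError(f"no rule fired for output {var.name!r}; centre of gravity undefined")
    return float((mu * ys).sum() / total)


@dataclass(frozen=True)
class MamdaniSystem:
    """A complete two-input Mamdani system: variables, rules, COG resolution."""

    name: str
    inputs: Tuple[LinguisticVariable, LinguisticVariable]
    output: LinguisticVariable
    rule_base: RuleBase
    cog_samples: int = DEFAULT_COG_SAMPLES
    display_names: Mapping[str, Tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.inputs) != 2:
            raise ConfigurationError(f"{self.name}: engine supports exactly two inputs")
        if self.cog_samples < MIN_COG_SAMPLES:
            raise ConfigurationError(f"{self.name}: cog_samples must be >= {MIN_COG_SAMPLES}")
        by_name = {var.name: var for var in self.inputs}
        if len(by_name) != 2:
            raise ConfigurationError(f"{self.name}: input variables share a name")
        for rule in self.rule_base:
            for var_name, label in rule.antecedent:
                var = by_name.get(var_name)
                if var is None:
                    raise ConfigurationError(f"{self.name}: rule references unknown input {var_name!r}")
                if label not in var.labels:
                    raise ConfigurationError(f"{self.name}: {var_name!r} has no term {label!r}")
            out_name, out_label = rule.consequent
            if out_name != self.output.name:
                raise ConfigurationError(f"{self.name}: rule concludes unknown output {out_name!r}")
            if out_label not in self.output.labels:
                raise ConfigurationError(f"{self.name}: output has no term {out_label!r}")

    @property
    def input_names(self) -> Tuple[str, str]:
        return (self.inputs[0].name, self.inputs[1].name)

    @property
    def is_complete_grid(self) -> bool:
        """True when every input-term combination appears exactly once."""
        v1, v2 = self.inputs
        wanted = {frozenset({(v1.name, l1), (v2.name, l2)})
                  for l1 in v1.labels for l2 in v2.labels}
        have = {rule.antecedent_key for rule in self.rule_base}
        return wanted == have

    def fuzzify_inputs(self, readings: Mapping[str, float]) -> Dict[str, Dict[str, float]]:
        degrees: Dict[str, Dict[str, float]] = {}
        for var in self.inputs:
            if var.name not in readings:
                raise ConfigurationError(f"{self.name}: missing input {var.name!r}")
            degrees[var.name] = var.fuzzify(readings[var.name])
        unknown = set(readings) - set(self.input_names)
        if unknown:
            raise ConfigurationError(f"{self.name}: unknown input(s) {sorted(unknown)}")
        return degrees

    def fire_rules(self, readings: Mapping[str, float]) -> AggregatedOutput:
        """Singleton fuzzification + min-AND firing + max aggregation per term."""
        degrees = self.fuzzify_inputs(readings)
        activations = {label: 0.0 for label in self.output.labels}
        for rule in self.rule_base:
            level = min(degrees[var][label] for var, label in rule.antecedent)
            out_label = rule.consequent[1]
            if level > activations[out_label]:
                activations[out_label] = level
        return AggregatedOutput(activations=activations, output_var=self.output)

    def evaluate(self, readings: Mapping[str, float],
                 cog_samples: int | None = None) -> float:
        """Crisp output: fuzzify -> fire rules -> COG defuzzify."""
        agg = self.fire_rules(readings)
        n = self.cog_samples if cog_samples is None else cog_samples
        return defuzzify_cog(agg, self.output, n)
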