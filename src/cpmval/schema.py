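"""Predictor schemas for cohort tables.

A :class:`PredictorSchema` declares, for every predictor a model may use,
its type, units, allowed numeric range, the "non-deviant" (normal) value
used for single imputation of missing findings, and any alias column names
under which the variable may appear in a raw cohort file (proxy mapping).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

__all__ = ["Variable", "PredictorSchema", "SchemaError"]


class SchemaError(ValueError):
    """Raised when a schema invariant is violated or a variable cannot be resolved."""


@dataclass(frozen=True)
class Variable:
    """One predictor variable.

    Parameters
    ----------
    name
        Canonical column name.
    kind
        ``"binary"``, ``"continuous"`` or ``"categorical"``.
    units
        Free-text units (``"°C"``, ``"mg/L"``, ``"/min"``, ``"years"``...).
    non_deviant_default
        The normal (non-pathological) value substituted for a missing
        finding; ``None`` means the variable has no declared default and
        may not be imputed.
    allowed_range
        Inclusive numeric bounds for binary/continuous variables; ``None``
        disables range checking.  For categorical variables the allowed
        *levels* go here as a tuple of strings.
    aliases
        Alternative column names accepted on input and renamed to ``name``.
    """

    name: str
    kind: str = "continuous"
    units: str = ""
    non_deviant_default: Any = None
    allowed_range: tuple | None = None
    aliases: tuple = ()

    def __post_init__(self):
        if self.kind not in ("binary", "continuous", "categorical"):
            raise SchemaError(f"variable {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "binary" and self.allowed_range is None:
            object.__setattr__(self, "allowed_range", (0, 1))
        if self.non_deviant_default is not None and not self.value_allowed(self.non_deviant_default):
            raise SchemaError(
                f"variable {self.name!r}: non_deviant_default {self.non_deviant_default!r} "
                f"outside allowed_range {self.allowed_range!r}"
            )

    def value_allowed(self, value) -> bool:
        if self.allowed_range is None:
            return True
        if self.kind == "categorical":
            return value in self.allowed_range
        lo, hi = self.allowed_range
        try:
            return lo <= float(value) <= hi
        except (TypeError, ValueError):
            return False


@dataclass
class PredictorSchema:
    """An ordered collection of :class:`Variable` definitions.

    Invariants: names are unique and every alias maps to exactly one
    variable (and never shadows a canonical name).
    """

    variables: list[Variable] = field(default_factory=list)

    def __post_init__(self):
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate variable names: {dup}")
        seen: dict[str, str] = {}
        for v in self.variables:
            for a in v.aliases:
                if a in names:
                    raise SchemaError(f"alias {a!r} of {v.name!r} shadows a canonical name")
                if a in seen:
                    raise SchemaError(f"alias {a!r} maps to both {seen[a]!r} and {v.name!r}")
                seen[a] = v.name

    def __iter__(self):
        return iter(self.variables)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    def __getitem__(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise SchemaError(f"variable {name!r} not in schema")

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def alias_map(self) -> dict[str, str]:
        """Mapping alias -> canonical name (canonical names map to themselves)."""
        out = {v.name: v.name for v in self.variables}
        for v in self.variables:
            for a in v.aliases:
                out[a] = v.name
        return out

    def resolve_aliases(self, columns: list[str]) -> dict[str, str]:
        """Rename plan for a raw header: idempotent (canonical names pass through)."""
        amap = self.alias_map()
        return {c: amap[c] for c in columns if c in amap and amap[c] != c}

    def to_dict(self) -> dict:
        return {
            "variables": [
                {
                    "name": v.name,
                    "kind": v.kind,
                    "units": v.units,
                    "non_deviant_default": v.non_deviant_default,
                    "allowed_range": list(v.allowed_range) if v.allowed_range is not None else None,
                    "aliases": list(v.aliases),
                }
                for v in self.variables
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PredictorSchema":
        return cls(
            [
                Variable(
                    name=e["name"],
                    kind=e.get("kind", "continuous"),
                    units=e.get("units", ""),
                    non_deviant_default=e.get("non_deviant_default"),
                    allowed_range=tuple(e["allowed_range"]) if e.get("allowed_range") is not None else None,
                    aliases=tuple(e.get("aliases", ())),
                )
                for e in d["variables"]
            ]
        )
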