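"""Declarative project configuration.

One human-editable YAML file declares the screening schema, the duplicate
criteria, the decision mode and (optionally) the quota rules and simulator
parameters. Loading validates everything up front — unknown fields in a
criterion or quota rule, infeasible quota minimums, bad enum values — and
errors name the offending key, so a misconfigured project fails before any
records are touched.

Example::

    timezone: America/New_York
    seed: 7
    dedup_mode: review
    schema:
      - {name: first_name, role: identifier, normalizer: text}
      - {name: last_name,  role: identifier, normalizer: text}
      - {name: email,      role: identifier, normalizer: email}
      - {name: phone,      role: identifier, normalizer: phone}
      - {name: cpd_bin,    role: demographic, normalizer: exact}
    criteria:
      window_days: 183
      rules:
        - {label: name,  fields: [first_name, last_name]}
        - {label: email, fields: [email]}
        - {label: phone, fields: [phone]}
    quota:
      total_n: 143
      rules:
        - {label: cpd_1_5, when: {cpd_bin: "1-5"}, bound: min, amount: 23, kind: count}
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError

from .matching import CriteriaSet, MatchCriterion
from .quota import QuotaConfigSpec, QuotaPredicate, QuotaRule
from .schema import MISSING, ConfigError, FieldSpec, Schema, normalize_value
from .simulate import SimParams

__all__ = ["ProjectConfig", "load_config", "validate_config"]


class _FieldModel(BaseModel):
    name: str
    role: Literal["identifier", "eligibility", "demographic", "other"] = "other"
    normalizer: Literal["exact", "text", "email", "phone", "date"] = "exact"


class _CriterionModel(BaseModel):
    label: str
    fields: list[str] = Field(min_length=1)


class _CriteriaModel(BaseModel):
    window_days: int = Field(default=183, ge=1)
    rules: list[_CriterionModel] = Field(min_length=1)


class _QuotaRuleModel(BaseModel):
    label: str
    when: dict[str, str] = Field(min_length=1)
    bound: Literal["min", "max", "minimum", "maximum"]
    amount: float = Field(gt=0)
    kind: Literal["count", "percent"] = "count"


class _QuotaModel(BaseModel):
    total_n: int = Field(ge=1)
    block_size: Optional[int] = None
    check_time: Literal["screening", "enrollment"] = "screening"
    reserve_mode: Literal["independent", "exact"] = "independent"
    rules: list[_QuotaRuleModel] = Field(default_factory=list)


class _SimModel(BaseModel):
    n_identities: int = 300
    fraud_fraction: float = 0.10
    mistake_fraction: float = 0.08
    fraud_resubmissions: tuple[int, int] = (2, 15)
    mutation_probs: Optional[dict[str, float]] = None
    fraud_gap_model: Optional[dict[int, float]] = None
    mistake_gap_model: Optional[dict[int, float]] = None
    category_mix: Optional[dict[str, dict[str, float]]] = None
    start: str = "2024-01-01"


class _ProjectModel(BaseModel):
    schema_: list[_FieldModel] = Field(alias="schema", min_length=1)
    criteria: _CriteriaModel
    dedup_mode: Literal["auto", "review"] = "review"
    quota: Optional[_QuotaModel] = None
    simulate: Optional[_SimModel] = None
    timezone: Optional[str] = None
    seed: int = 0


@dataclass(frozen=True)
class ProjectConfig:
    """Validated project configuration with domain objects built."""

    schema: Schema
    criteria: CriteriaSet
    dedup_mode: Literal["auto", "review"]
    quota: Optional[QuotaConfigSpec]
    sim_params: Optional[SimParams]
    timezone: Optional[str]
    seed: int


def _build(model: _ProjectModel) -> ProjectConfig:
    schema = Schema(
        tuple(FieldSpec(f.name, f.role, f.normalizer) for f in model.schema_)
    )
    criteria = CriteriaSet(
        criteria=tuple(
            MatchCriterion(c.label, tuple(c.fields)) for c in model.criteria.rules
        ),
        window_days=model.criteria.window_days,
    )
    criteria.validate(schema)

    quota_spec: Optional[QuotaConfigSpec] = None
    if model.quota is not None:
        rules = []
        for rm in model.quota.rules:
            conditions = []
            for fname, raw in rm.when.items():
                if fname not in schema:
                    raise ConfigError(
                        f"quota rule {rm.label!r} references unknown field {fname!r}"
                    )
                canon = normalize_value(schema[fname], raw)
                if canon is MISSING:
                    raise ConfigError(
                        f"quota rule {rm.label!r}: empty value for field {fname!r}"
                    )
                conditions.append((fname, str(canon)))
            bound = "minimum" if rm.bound in ("min", "minimum") else "maximum"
            rules.append(
                QuotaRule(
                    label=rm.label,
                    predicate=QuotaPredicate(tuple(conditions)),
                    bound=bound,
                    amount=rm.amount,
                    amount_kind=rm.kind,
                )
            )
        quota_spec = QuotaConfigSpec(
            total_n=model.quota.total_n,
            rules=tuple(rules),
            block_size=model.quota.block_size,
            check_time=model.quota.check_time,
            reserve_mode=model.quota.reserve_mode,
        )
        quota_spec.validate(schema)

    sim_params: Optional[SimParams] = None
    if model.simulate is not None:
        sm = model.simulate
        kwargs: dict = {
            "n_identities": sm.n_identities,
            "fraud_fraction": sm.fraud_fraction,
            "mistake_fraction": sm.mistake_fraction,
            "fraud_resubmissions": sm.fraud_resubmissions,
            "start": sm.start,
            "seed": model.seed,
        }
        for opt in (
            "mutation_probs",
            "fraud_gap_model",
            "mistake_gap_model",
            "category_mix",
        ):
            if getattr(sm, opt) is not None:
                kwargs[opt] = getattr(sm, opt)
        sim_params = SimParams(**kwargs)

    return ProjectConfig(
        schema=schema,
        criteria=criteria,
        dedup_mode=model.dedup_mode,
        quota=quota_spec,
        sim_params=sim_params,
        timezone=model.timezone,
        seed=model.seed,
    )


def load_config(path: str | Path) -> ProjectConfig:
    """Load and fully validate a project config. Raises ConfigError with a
    message naming the offending key on any inconsistency."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        model = _ProjectModel.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return _build(model)


def validate_config(path: str | Path) -> list[str]:
    """Structured validation: returns a list of error strings, empty if ok."""
    try:
        load_config(path)
    except (ConfigError, OSError, yaml.YAMLError) as exc:
        return [str(exc)]
    return []
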