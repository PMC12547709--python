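"""Covariate schema: names, kinds, units and levels of the model inputs.

The default schema carries the ten baseline covariates used for
gastrostomy-timing prediction in ALS: six continuous (age at onset,
diagnostic delay, ALSFRS-R slope, FVC %predicted, premorbid weight,
weight at diagnosis), two binary (sex, C9orf72 status) and two
categorical (site of onset, cohort).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

CONTINUOUS = "continuous"
BINARY = "binary"
CATEGORICAL = "categorical"

_KINDS = (CONTINUOUS, BINARY, CATEGORICAL)
_ROLES = ("baseline", "longitudinal-derived", "outcome", "id", "meta")


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate's declaration.

    Parameters
    ----------
    name : str
        Column name, unique within a schema.
    kind : {"continuous", "binary", "categorical"}
    unit : str
        Free-text unit, e.g. ``"kg"`` or ``"points/month"``.
    levels : tuple of str, optional
        Ordered labels for binary/categorical covariates; the first level
        is the reference level used when encoding.
    role : {"baseline", "longitudinal-derived", "outcome", "id", "meta"}
    """

    name: str
    kind: str
    unit: str = ""
    levels: tuple = ()
    role: str = "baseline"

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.role not in _ROLES:
            raise ValueError(f"unknown covariate role {self.role!r}")
        if self.kind == CONTINUOUS and self.levels:
            raise ValueError(f"continuous covariate {self.name!r} must not declare levels")
        if self.kind in (BINARY, CATEGORICAL) and len(self.levels) < 2:
            raise ValueError(f"{self.kind} covariate {self.name!r} needs >=2 levels")
        if self.kind == BINARY and len(self.levels) != 2:
            raise ValueError(f"binary covariate {self.name!r} needs exactly 2 levels")
        object.__setattr__(self, "levels", tuple(self.levels))


def check_schema(schema: list[CovariateSpec]) -> None:
    names = [s.name for s in schema]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate covariate names in schema: {dupes}")


def default_schema() -> list[CovariateSpec]:
    """The ten baseline ALS covariates of the gastrostomy-timing model."""
    return [
        CovariateSpec("age_onset", CONTINUOUS, "years"),
        CovariateSpec("diagnostic_delay", CONTINUOUS, "months"),
        CovariateSpec("alsfrs_slope", CONTINUOUS, "points/month"),
        CovariateSpec("fvc_pct", CONTINUOUS, "% predicted"),
        CovariateSpec("premorbid_weight", CONTINUOUS, "kg"),
        CovariateSpec("weight_dx", CONTINUOUS, "kg"),
        CovariateSpec("sex", BINARY, levels=("female", "male")),
        CovariateSpec("c9orf72", BINARY, levels=("negative", "positive")),
        CovariateSpec("site_onset", CATEGORICAL, levels=("spinal", "bulbar", "other")),
        CovariateSpec("cohort", CATEGORICAL, levels=("A", "B", "C")),
    ]


def baseline_names(schema: list[CovariateSpec]) -> list[str]:
    return [s.name for s in schema if s.role in ("baseline", "longitudinal-derived")]


def schema_to_yaml(schema: list[CovariateSpec]) -> str:
    return yaml.safe_dump(
        [
            {
                "name": s.name,
                "kind": s.kind,
                "unit": s.unit,
                "levels": list(s.levels),
                "role": s.role,
            }
            for s in schema
        ],
        sort_keys=False,
    )


def schema_from_yaml(text: str) -> list[CovariateSpec]:
    raw = yaml.safe_load(text)
    schema = [
        CovariateSpec(
            d["name"],
            d["kind"],
            d.get("unit", ""),
            tuple(d.get("levels", ()) or ()),
            d.get("role", "baseline"),
        )
        for d in raw
    ]
    check_schema(schema)
    return schema
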