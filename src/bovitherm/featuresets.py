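"""Benchmark feature-set registry.

Five groups of feature sets are benchmarked against the CBT target:

- ``environment``: ENV (environment + time zone) and ANM (ENV + animal vars)
- ``irtmax`` / ``irtave``: one set per infrared ROI, each with animal vars
- ``index``: one set per thermal-comfort index, each with animal vars
- ``flux``: one set per heat-flux variable, each with animal vars

Animal variables are MY, DOL, PA, BP; every non-ENV set also carries TZ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import ROIS
from .thermal import FLUX_NAMES, INDEX_NAMES

__all__ = ["FeatureSetSpec", "build_registry", "materialize", "registry_to_json"]

ENV_COLUMNS = ["Ta", "Tbg", "RH", "U", "Qsr", "TZ"]
ANIMAL_COLUMNS = ["MY", "DOL", "PA", "BP"]
TARGET = "CBT"

GROUPS = ("environment", "irtmax", "irtave", "index", "flux")


@dataclass(frozen=True)
class FeatureSetSpec:
    """A named, ordered list of input columns plus the target column."""

    name: str
    group: str
    columns: tuple[str, ...]
    target: str = TARGET

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.target in self.columns:
            raise ValueError("target must not appear among feature columns")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError(f"duplicate columns in spec {self.name!r}")


def _single_feature_spec(name: str, group: str, column: str) -> FeatureSetSpec:
    return FeatureSetSpec(
        name=name, group=group,
        columns=tuple([column] + ANIMAL_COLUMNS + ["TZ"]),
    )


def build_registry(
    roi_list: tuple[str, ...] = ROIS,
    index_list: tuple[str, ...] = INDEX_NAMES,
    flux_list: tuple[str, ...] = FLUX_NAMES,
    groups: tuple[str, ...] = GROUPS,
) -> list[FeatureSetSpec]:
    """Build the full registry; size = 2 + 2*|roi| + |index| + |flux|."""
    for roi in roi_list:
        if roi not in ROIS:
            raise ValueError(f"unknown ROI {roi!r}")
    for idx in index_list:
        if idx not in INDEX_NAMES:
            raise ValueError(f"unknown comfort index {idx!r}")
    for flux in flux_list:
        if flux not in FLUX_NAMES:
            raise ValueError(f"unknown flux variable {flux!r}")

    registry: list[FeatureSetSpec] = []
    if "environment" in groups:
        registry.append(
            FeatureSetSpec("ENV", "environment", tuple(ENV_COLUMNS))
        )
        registry.append(
            FeatureSetSpec("ANM", "environment", tuple(ENV_COLUMNS + ANIMAL_COLUMNS))
        )
    if "irtmax" in groups:
        for roi in roi_list:
            registry.append(
                _single_feature_spec(f"IRTmax_{roi}", "irtmax", f"IRTmax_{roi}")
            )
    if "irtave" in groups:
        for roi in roi_list:
            registry.append(
                _single_feature_spec(f"IRTave_{roi}", "irtave", f"IRTave_{roi}")
            )
    if "index" in groups:
        for idx in index_list:
            registry.append(_single_feature_spec(idx, "index", idx))
    if "flux" in groups:
        for flux in flux_list:
            registry.append(_single_feature_spec(flux, "flux", flux))

    names = [s.name for s in registry]
    assert len(set(names)) == len(names), "registry names must be unique"
    return registry


def materialize(table: pd.DataFrame, spec: FeatureSetSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Extract (X, y) for one feature set from a fully preprocessed table."""
    missing_cols = [c for c in spec.columns if c not in table.columns]
    if missing_cols:
        raise ValueError(f"spec {spec.name!r}: missing columns {missing_cols}")
    if spec.target not in table.columns:
        raise ValueError(f"target column {spec.target!r} not in table")
    X = table.loc[:, list(spec.columns)].copy()
    if X.isna().to_numpy().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"spec {spec.name!r}: residual missing cells in {bad}")
    if not all(pd.api.types.is_numeric_dtype(X[c]) for c in X.columns):
        raise ValueError(f"spec {spec.name!r}: non-numeric feature columns; encode first")
    y = table[spec.target].to_numpy(float)
    return X, y


def registry_to_json(registry: list[FeatureSetSpec], path=None) -> str:
    payload = json.dumps(
        [
            {"name": s.name, "group": s.group, "columns": list(s.columns),
             "target": s.target}
            for s in registry
        ],
        indent=2,
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(payload)
    return payload
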