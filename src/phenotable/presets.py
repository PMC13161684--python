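"""Preset registry: ready-made harmonization configurations per export layout.

Each preset names the tables a tool writes, which columns are identifying
keys, and how the compartment tables link together.  Presets are code-defined
and versioned with the package; they can be completely or partially
overridden at call time (:func:`merge_overrides`) or loaded from a YAML/JSON
config file (:func:`preset_from_config`).

The CellProfiler-style presets join at cytoplasm grain: the cytoplasm table
carries parent identifiers for both the cell and nucleus segmented from the
same object, so one output row corresponds to one linked cell.  The image
table is inner-joined (every object belongs to an image); the sibling
compartments are left-joined so segmentation orphans surface as nulls rather
than silently dropping rows.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from pathlib import Path
from typing import Mapping

import yaml

from .model import (
    JoinClause,
    Preset,
    PresetValidationError,
    SOURCE_KINDS,
    UnknownPresetError,
)

__all__ = [
    "get_preset",
    "preset_names",
    "merge_overrides",
    "validate_preset",
    "preset_from_config",
]


def _cellprofiler_joins(*, image_keys=("ImageNumber",)) -> list[JoinClause]:
    clauses: list[JoinClause] = []
    for key in image_keys:
        clauses.append(JoinClause("cytoplasm", key, "image", key, "inner"))
    for role, parent in (("cells", "Parent_Cells"), ("nuclei", "Parent_Nuclei")):
        for key in image_keys:
            clauses.append(JoinClause("cytoplasm", key, role, key, "left"))
        clauses.append(JoinClause("cytoplasm", parent, role, "ObjectNumber", "left"))
    return clauses


def _build_registry() -> dict[str, Preset]:
    cp_identifying = [
        "ImageNumber",
        "ObjectNumber",
        "Parent_Cells",
        "Parent_Nuclei",
    ]
    registry = {}

    registry["cellprofiler_csv"] = Preset(
        name="cellprofiler_csv",
        source_kind="delimited-text",
        table_selectors={
            "image": "Image",
            "cells": "Cells",
            "nuclei": "Nuclei",
            "cytoplasm": "Cytoplasm",
        },
        base_table="cytoplasm",
        identifying_columns=list(cp_identifying),
        joins=_cellprofiler_joins(),
    )

    registry["cellprofiler_sqlite"] = Preset(
        name="cellprofiler_sqlite",
        source_kind="sqlite-db",
        table_selectors={
            "image": "Per_Image",
            "cells": "Per_Cells",
            "nuclei": "Per_Nuclei",
            "cytoplasm": "Per_Cytoplasm",
        },
        base_table="cytoplasm",
        identifying_columns=list(cp_identifying),
        joins=_cellprofiler_joins(),
    )

    registry["deepprofiler"] = Preset(
        name="deepprofiler",
        source_kind="array-archive",
        table_selectors={"profile": "*"},
        base_table="profile",
        identifying_columns=["ObjectNumber", "ImageNumber"],
        joins=[],
        feature_name_prefix="Efficientnet",
    )

    registry["in-carta"] = Preset(
        name="in-carta",
        source_kind="delimited-text",
        table_selectors={"objects": "*"},
        base_table="objects",
        identifying_columns=["ObjectID", "OBJECT ID", "Row", "Column", "FOV"],
        joins=[],
    )

    # Legacy layout written by the deprecated cytominer-database ingest tool:
    # lowercase table names and a TableNumber batching key ahead of ImageNumber.
    registry["cell-health-cellprofiler-to-cytominer-database"] = Preset(
        name="cell-health-cellprofiler-to-cytominer-database",
        source_kind="sqlite-db",
        table_selectors={
            "image": "image",
            "cells": "cells",
            "nuclei": "nuclei",
            "cytoplasm": "cytoplasm",
        },
        base_table="cytoplasm",
        identifying_columns=["TableNumber"] + list(cp_identifying),
        joins=_cellprofiler_joins(image_keys=("TableNumber", "ImageNumber")),
    )
    return registry


_REGISTRY: dict[str, Preset] = _build_registry()


def preset_names() -> list[str]:
    """Registered preset names, in registration order."""
    return list(_REGISTRY)


def get_preset(name: str) -> Preset:
    """Return a copy of the named preset.

    Mutating the returned object does not alter the registry.
    """
    try:
        preset = _REGISTRY[name]
    except KeyError:
        raise UnknownPresetError(
            f"unknown preset {name!r}; available presets: {', '.join(_REGISTRY)}"
        ) from None
    return preset.copy()


def validate_preset(preset: Preset) -> list[str]:
    """Check all preset invariants; return human-readable violations.

    An empty list means the preset is internally valid.  Violations are
    returned, never raised, so callers can aggregate them.
    """
    violations: list[str] = []
    if not preset.name:
        violations.append("name: must be non-empty")
    if preset.source_kind not in SOURCE_KINDS:
        violations.append(
            f"source_kind: {preset.source_kind!r} not one of {SOURCE_KINDS}"
        )
    if not preset.table_selectors:
        violations.append("table_selectors: must name at least one table")
    if preset.base_table not in preset.table_selectors:
        violations.append(
            f"base_table: {preset.base_table!r} is not in table_selectors"
        )
    for clause in preset.joins:
        for side in (clause.left_table, clause.right_table):
            if side not in preset.table_selectors:
                violations.append(
                    f"joins: clause {clause.left_table}.{clause.left_column} -> "
                    f"{clause.right_table}.{clause.right_column} references "
                    f"table {side!r} absent from table_selectors"
                )
    seen = set()
    for col in preset.identifying_columns:
        if col in seen:
            violations.append(f"identifying_columns: duplicate entry {col!r}")
        seen.add(col)
    if preset.chunk_size < 1:
        violations.append(f"chunk_size: must be >= 1, got {preset.chunk_size}")
    if preset.type_policy not in ("strict-fail", "coerce-null"):
        violations.append(f"type_policy: unknown policy {preset.type_policy!r}")
    if preset.float_width not in (4, 8):
        violations.append(f"float_width: must be 4 or 8, got {preset.float_width}")
    return violations


_PRESET_FIELDS = {f.name for f in dataclasses.fields(Preset)}


def _coerce_joins(value) -> list[JoinClause]:
    out = []
    for item in value:
        if isinstance(item, JoinClause):
            out.append(item)
        elif isinstance(item, Mapping):
            out.append(JoinClause(**item))
        else:
            raise PresetValidationError(f"cannot interpret join clause {item!r}")
    return out


def merge_overrides(preset: Preset, overrides: Mapping[str, object]) -> Preset:
    """Return a new preset equal to ``preset`` except where overridden.

    Overrides win field-by-field (left-biased on the override side); the
    merged preset is re-validated and a :class:`PresetValidationError` is
    raised if any invariant breaks, naming the offending field/clause.
    """
    unknown = set(overrides) - _PRESET_FIELDS
    if unknown:
        raise PresetValidationError(
            f"unknown preset field(s) in overrides: {sorted(unknown)}"
        )
    merged = preset.copy()
    for key, value in overrides.items():
        if key == "joins":
            value = _coerce_joins(value)
        elif key == "table_selectors":
            value = dict(value)
        elif key == "identifying_columns":
            value = list(value)
        setattr(merged, key, copy.deepcopy(value))
    violations = validate_preset(merged)
    if violations:
        raise PresetValidationError(
            "overrides produce an invalid preset: " + "; ".join(violations)
        )
    return merged


def preset_from_config(path) -> Preset:
    """Load a preset (or overrides onto a named base) from YAML or JSON.

    The file uses the same field names as :class:`Preset`.  If it contains
    a ``base_preset`` key, the remaining fields are applied as overrides to
    that registry preset; otherwise the file must define a full preset.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise PresetValidationError(f"config {path} does not define a mapping")
    data = dict(data)
    base_name = data.pop("base_preset", None)
    if base_name is not None:
        return merge_overrides(get_preset(base_name), data)
    if "joins" in data:
        data["joins"] = _coerce_joins(data["joins"])
    preset = Preset(**data)
    violations = validate_preset(preset)
    if violations:
        raise PresetValidationError(
            f"config {path} defines an invalid preset: " + "; ".join(violations)
        )
    return preset
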