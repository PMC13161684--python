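"""Source discovery: walk an input tree, classify and group feature files.

Export directories from image-analysis tools routinely hold extra material
(images, logs, thumbnails).  Discovery keeps only files matching the active
preset's selectors, assigns each a compartment role, and groups sources for
independent processing — one group per immediate parent directory for
multi-file layouts, one group per database file for SQLite layouts.
Matching is case-insensitive on filename stems since exports differ in
casing across tool versions.
"""

from __future__ import annotations

import dataclasses
import fnmatch
import logging
import sqlite3
from pathlib import Path
from typing import Dict, List

from .model import (
    EXTENSION_KINDS,
    EmptySourceSetError,
    Preset,
    SourceSpec,
    UnsupportedFormatError,
    ensure_path,
)

logger = logging.getLogger(__name__)

__all__ = ["SourceGroupMap", "discover_sources", "infer_source_kind"]


@dataclasses.dataclass
class SourceGroupMap:
    """Discovered sources, partitioned into independently-processed groups."""

    groups: Dict[str, List[SourceSpec]]

    def __len__(self) -> int:
        return len(self.groups)

    def all_sources(self) -> List[SourceSpec]:
        return [s for specs in self.groups.values() for s in specs]


def infer_source_kind(path) -> str:
    """Map a file extension to its source kind (case-insensitive)."""
    suffix = ensure_path(path).suffix.lower()
    try:
        return EXTENSION_KINDS[suffix]
    except KeyError:
        supported = ", ".join(sorted(EXTENSION_KINDS))
        raise UnsupportedFormatError(
            f"unsupported format {suffix!r} for {path}; supported extensions: {supported}"
        ) from None


def _match_role(name: str, preset: Preset) -> str | None:
    """First selector role whose pattern matches ``name`` (case-insensitive)."""
    for role, pattern in preset.table_selectors.items():
        if fnmatch.fnmatch(name.lower(), pattern.lower()):
            return role
    return None


def _sqlite_tables(path: Path) -> list[str]:
    with sqlite3.connect(f"file:{path}?mode=ro", uri=True) as conn:
        rows = conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table' ORDER BY name"
        ).fetchall()
    return [r[0] for r in rows]


def discover_sources(root, preset: Preset) -> SourceGroupMap:
    """Discover and group all preset-matching sources under ``root``.

    Returns a :class:`SourceGroupMap` keyed by the relative parent directory
    (multi-file layouts) or by the database file's relative path (SQLite).
    Deterministic: repeated calls on an unchanged tree yield identical maps
    (lexicographic path ordering throughout).

    Raises
    ------
    FileNotFoundError
        If ``root`` does not exist.
    EmptySourceSetError
        If no file under ``root`` matches the preset's selectors.
    """
    root = ensure_path(root)
    if not root.exists():
        raise FileNotFoundError(f"source root {root} does not exist")

    if root.is_file():
        candidates = [root]
        base = root.parent
    else:
        candidates = sorted(p for p in root.rglob("*") if p.is_file())
        base = root

    groups: Dict[str, List[SourceSpec]] = {}
    ignored = 0

    def group_key_for(path: Path, per_file: bool) -> str:
        rel = path.relative_to(base) if path != root else Path(path.name)
        key = str(rel) if per_file else str(rel.parent)
        return key or "."

    for path in candidates:
        try:
            kind = infer_source_kind(path)
        except UnsupportedFormatError:
            ignored += 1
            continue
        if kind != preset.source_kind:
            ignored += 1
            continue

        if kind == "sqlite-db":
            key = group_key_for(path, per_file=True)
            specs = []
            for table in _sqlite_tables(path):
                role = _match_role(table, preset)
                if role is not None:
                    specs.append(
                        SourceSpec(
                            path=str(path),
                            kind=kind,
                            table_name=table,
                            group_key=key,
                            role=role,
                        )
                    )
            if specs:
                groups.setdefault(key, []).extend(specs)
            else:
                ignored += 1
        else:
            role = _match_role(path.stem, preset)
            if role is None:
                ignored += 1
                continue
            key = group_key_for(path, per_file=False)
            spec = SourceSpec(
                path=str(path),
                kind=kind,
                table_name=path.stem,
                group_key=key,
                role=role,
            )
            groups.setdefault(key, []).append(spec)

    if ignored:
        logger.info("discovery ignored %d non-matching file(s) under %s", ignored, root)

    if not groups:
        tried = ", ".join(
            f"{role}={pat!r}" for role, pat in preset.table_selectors.items()
        )
        raise EmptySourceSetError(
            f"no sources under {root} match preset {preset.name!r} selectors ({tried})"
        )

    # one source per role per group for delimited multi-file layouts
    if preset.source_kind == "delimited-text":
        for key, specs in groups.items():
            roles = [s.role for s in specs]
            dupes = sorted({r for r in roles if roles.count(r) > 1})
            if dupes:
                raise EmptySourceSetError(
                    f"group {key!r} has multiple files for role(s) {dupes}; "
                    "delimited layouts allow one file per compartment role"
                )

    ordered = {k: sorted(groups[k], key=lambda s: (s.path, s.table_name)) for k in sorted(groups)}
    return SourceGroupMap(groups=ordered)
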