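"""Readers and writers for the package's delimited/structured text formats.

All tables are UTF-8 comma-separated with header rows.  Compatibility
matrices are written with rows = maternal strain and columns = paternal
strain (stated in the header comment of every output to avoid the classic
transposition mistake); cells are ``C`` / ``I`` / ``?``.  Strain-set cells
in crossing tables are semicolon-joined labels.  Worlds (strain parameters
plus host background) use a YAML mapping.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from .core import HostBackground, Strain
from .fitting import COMPATIBLE, CompatibilityMatrix, UNKNOWN
from .levels import CrossRecord
from .synth import World

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_world",
    "write_world",
    "read_crosses",
    "write_crosses",
]

log = logging.getLogger(__name__)

_ORIENTATION_NOTE = "# rows = maternal (female), columns = paternal (male)\n"


def read_matrix(path: Union[str, Path],
                suicidal=frozenset()) -> CompatibilityMatrix:
    """Read a compatibility matrix CSV (rows maternal, columns paternal).

    Cells must be ``C``, ``I`` or ``?``; an omitted diagonal entry (``?``)
    defaults to compatible with a logged warning (self-rescue assumption).
    """
    df = pd.read_csv(path, index_col=0, dtype=str, comment="#").fillna(UNKNOWN)
    strains = tuple(str(s) for s in df.index)
    if tuple(str(s) for s in df.columns) != strains:
        raise ValueError(f"{path}: row and column strain labels differ")
    cells = []
    for i, mat in enumerate(strains):
        row = []
        for j, pat in enumerate(strains):
            c = str(df.iat[i, j]).strip()
            if c not in ("C", "I", "?"):
                raise ValueError(
                    f"{path}: bad cell {c!r} at row {mat!r}, column {pat!r}")
            if i == j and c == UNKNOWN and mat not in suicidal:
                log.warning("%s: missing diagonal for %s, defaulting to "
                            "compatible (self-rescue)", path, mat)
                c = COMPATIBLE
            row.append(c)
        cells.append(tuple(row))
    return CompatibilityMatrix(strains, tuple(cells), frozenset(suicidal))


def write_matrix(matrix: CompatibilityMatrix, path: Union[str, Path]) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_ORIENTATION_NOTE)
        matrix.to_frame().to_csv(fh)


def _strain_from_mapping(label: str, spec: dict) -> Strain:
    gk = spec.get("gk_factors")
    locks = spec.get("locks")
    keys = spec.get("keys")
    return Strain(
        id=label,
        gk=tuple(gk) if gk is not None else None,
        locks=frozenset(str(x) for x in locks) if locks is not None else None,
        keys=frozenset(str(x) for x in keys) if keys is not None else None,
        suicidal=bool(spec.get("suicidal", False)),
    )


def read_world(path: Union[str, Path]) -> World:
    """Read a strain-parameter world from YAML.

    Schema::

        family: goalkeeper | mistiming | lockkey
        seed: 42                     # optional
        host: {id: host, h: [1, 0]}  # optional, defaults to zero
        strains:
          wRi: {gk_factors: [2, 1]}
          wTei: {locks: [1, 2], keys: [1, 2, 3]}
    """
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    try:
        family = data["family"]
        strains = tuple(_strain_from_mapping(str(label), spec or {})
                        for label, spec in data["strains"].items())
    except KeyError as exc:
        raise ValueError(f"{path}: missing field {exc.args[0]!r}") from None
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: {exc}") from None
    hspec = data.get("host") or {}
    host = HostBackground(id=str(hspec.get("id", "host")),
                          h=tuple(hspec.get("h", (0, 0))))
    return World(strains, host, family, seed=data.get("seed"))


def write_world(world: World, path: Union[str, Path]) -> None:
    strains = {}
    for s in world.strains:
        spec = {}
        if s.gk is not None:
            spec["gk_factors"] = [float(q) if isinstance(q, float) else int(q)
                                  for q in s.gk]
        if s.locks is not None:
            spec["locks"] = sorted(s.locks)
        if s.keys is not None:
            spec["keys"] = sorted(s.keys)
        if s.suicidal:
            spec["suicidal"] = True
        strains[s.id] = spec
    data = {
        "family": world.family,
        "seed": world.seed,
        "host": {"id": world.host.id, "h": [float(q) if isinstance(q, float)
                                            else int(q) for q in world.host.h]},
        "strains": strains,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


_CROSS_COLUMNS = ["maternal_strains", "paternal_strains",
                  "raw_mortality_pct", "control_mortality_pct"]


def _parse_labels(cell) -> frozenset:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    text = str(cell).strip()
    if not text:
        return frozenset()
    return frozenset(x.strip() for x in text.split(";") if x.strip())


def read_crosses(path: Union[str, Path]) -> list:
    """Read a crossing dataset CSV into :class:`CrossRecord` objects.

    Columns: ``maternal_strains`` and ``paternal_strains`` (semicolon-joined
    labels, empty = uninfected), ``raw_mortality_pct``,
    ``control_mortality_pct``.  Percentages are range-checked.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _CROSS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(CrossRecord(
                maternal=_parse_labels(getattr(row, "maternal_strains")),
                paternal=_parse_labels(getattr(row, "paternal_strains")),
                raw_mortality=float(getattr(row, "raw_mortality_pct")),
                control_mortality=float(getattr(row, "control_mortality_pct")),
            ))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {row_no}: {exc}") from None
    return records


def write_crosses(records, path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        [{"maternal_strains": ";".join(sorted(r.maternal)),
          "paternal_strains": ";".join(sorted(r.paternal)),
          "raw_mortality_pct": r.raw_mortality,
          "control_mortality_pct": r.control_mortality}
         for r in records], columns=_CROSS_COLUMNS)
    df.to_csv(path, index=False)
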