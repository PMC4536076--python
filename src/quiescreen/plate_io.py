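"""Reading, validation and writing of long-format 96-well plate tables.

The canonical on-disk format is a tidy delimited table (comma by default,
tab accepted), UTF-8, with header::

    plate_id,row,col,role,compound_id,concentration_uM,condition,luminescence

``row`` is a plate letter A-H, ``col`` an integer 1-12.  A compact ``well``
column ("A1".."H12") is accepted in place of the split pair.  Roles are one
of ``compound``, ``neg_ctrl``, ``pos_ctrl``, ``empty``; anything else is
rejected rather than coerced, since silently miscoded control wells would
corrupt the Z' statistic downstream.

A wide 8x12 grid importer is provided for plate-reader exports but converts
immediately to the long form: every downstream statistic is per-well.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .exceptions import SchemaError, ValidationError

ROWS = tuple("ABCDEFGH")
COLS = tuple(range(1, 13))
ROLES = frozenset({"compound", "neg_ctrl", "pos_ctrl", "empty"})

#: canonical column order of the long format
COLUMNS = [
    "plate_id",
    "row",
    "col",
    "role",
    "compound_id",
    "concentration_uM",
    "condition",
    "luminescence",
]


@dataclass
class PlateTable:
    """A validated collection of well records plus free-form metadata.

    ``data`` holds one row per well with the columns in :data:`COLUMNS`.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def plate_ids(self) -> list[str]:
        return sorted(self.data["plate_id"].unique())

    def wells(self, plate_id: str) -> pd.DataFrame:
        return self.data[self.data["plate_id"] == plate_id]

    def __len__(self) -> int:  # number of well records
        return len(self.data)


def _split_compact_well(df: pd.DataFrame) -> pd.DataFrame:
    well = df["well"].astype(str).str.strip()
    df = df.drop(columns=["well"])
    df["row"] = well.str[0].str.upper()
    df["col"] = pd.to_numeric(well.str[1:], errors="coerce")
    return df


def validate_table(df: pd.DataFrame, require_controls: bool = True) -> pd.DataFrame:
    """Enforce the well-record invariants; return the normalized frame.

    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` for invariant violations.
    """
    df = df.copy()
    if "well" in df.columns and not {"row", "col"} <= set(df.columns):
        df = _split_compact_well(df)
    for col in COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    df = df[COLUMNS]

    df["plate_id"] = df["plate_id"].astype(str)
    df["row"] = df["row"].astype(str).str.upper()
    df["col"] = pd.to_numeric(df["col"]).astype(int)
    df["role"] = df["role"].astype(str)
    df["concentration_uM"] = pd.to_numeric(df["concentration_uM"])
    df["luminescence"] = pd.to_numeric(df["luminescence"])

    bad_rows = sorted(set(df["row"]) - set(ROWS))
    if bad_rows:
        raise ValidationError(f"row letters outside A-H: {bad_rows}")
    bad_cols = sorted(set(df["col"]) - set(COLS))
    if bad_cols:
        raise ValidationError(f"column numbers outside 1-12: {bad_cols}")
    bad_roles = sorted(set(df["role"]) - ROLES)
    if bad_roles:
        raise ValidationError(
            f"unknown well roles {bad_roles}; expected one of {sorted(ROLES)}"
        )

    dup = df.duplicated(subset=["plate_id", "row", "col"], keep=False)
    if dup.any():
        coords = df.loc[dup, ["plate_id", "row", "col"]].drop_duplicates()
        listing = ", ".join(
            f"{p} {r}{c}" for p, r, c in coords.itertuples(index=False)
        )
        raise ValidationError(f"duplicate wells: {listing}")

    if (df["luminescence"] < 0).any():
        n = int((df["luminescence"] < 0).sum())
        raise ValidationError(f"{n} wells with negative luminescence")

    cmp = df["role"] == "compound"
    if cmp.any():
        missing = cmp & (df["compound_id"].isna() | (df["compound_id"] == ""))
        if missing.any():
            raise ValidationError(
                f"{int(missing.sum())} compound wells without compound_id"
            )
        nonpos = cmp & ~(df["concentration_uM"] > 0)
        if nonpos.any():
            raise ValidationError(
                f"{int(nonpos.sum())} compound wells with concentration <= 0"
            )

    if require_controls:
        counts = (
            df.groupby("plate_id")["role"]
            .value_counts()
            .unstack(fill_value=0)
            .reindex(columns=["neg_ctrl", "pos_ctrl"], fill_value=0)
        )
        short = counts[(counts["neg_ctrl"] < 2) | (counts["pos_ctrl"] < 2)]
        if len(short):
            raise ValidationError(
                "plates without >=2 wells of each control role "
                f"(needed for variance estimates): {sorted(short.index)}"
            )
    return df.reset_index(drop=True)


def read_plate_table(
    path: str | Path | io.IOBase,
    sep: str | None = None,
    require_controls: bool = True,
    metadata: Mapping | None = None,
) -> PlateTable:
    """Read and validate a long-format plate table.

    ``sep=None`` sniffs the delimiter (comma or tab).
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    df = validate_table(df, require_controls=require_controls)
    return PlateTable(df, dict(metadata or {}))


def write_plate_table(table: PlateTable, path: str | Path, sep: str = ",") -> None:
    """Write the canonical long format; floats use repr so that a
    write->read round trip is field-for-field exact."""
    table.data.to_csv(path, sep=sep, index=False)


def read_plate_grid(
    path: str | Path,
    plate_id: str,
    role_map: Mapping[str, str],
    compound_map: Mapping[str, tuple[str, float]] | None = None,
    condition: str = "proliferating",
    sep: str | None = None,
) -> PlateTable:
    """Import a wide 8x12 luminescence grid and convert to long form.

    The grid file has row letters as the first column and columns 1..12 as
    headers.  ``role_map`` maps compact well names ("A1") to roles; wells not
    listed default to ``compound``.  ``compound_map`` maps well names to
    (compound_id, concentration_uM) pairs for compound wells.
    """
    grid = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c", index_col=0)
    compound_map = compound_map or {}
    records = []
    for row in grid.index:
        for col in grid.columns:
            well = f"{str(row).upper()}{int(col)}"
            # wells not assigned a role or a compound are imported as empty
            role = role_map.get(well, "compound" if well in compound_map else "empty")
            compound_id, conc = compound_map.get(well, (None, None))
            records.append(
                {
                    "plate_id": plate_id,
                    "row": str(row).upper(),
                    "col": int(col),
                    "role": role,
                    "compound_id": compound_id,
                    "concentration_uM": conc,
                    "condition": condition,
                    "luminescence": float(grid.loc[row, col]),
                }
            )
    df = validate_table(pd.DataFrame(records), require_controls=False)
    return PlateTable(df, {"source": str(path)})


@dataclass
class LayoutSpec:
    """Expected per-plate role counts (screen default: 12 neg, 4 pos, 80 cpd)."""

    n_neg: int = 12
    n_pos: int = 4
    n_compound: int = 80


def validate_layout(table: PlateTable, expected: LayoutSpec | None = None) -> pd.DataFrame:
    """Report per-plate role counts and deviations from the expected layout.

    Purely diagnostic — never mutates data.  The returned frame has one row
    per plate with observed counts, a ``deviations`` string (empty when
    conforming) and ``qc_possible`` (False when a control role is absent,
    which makes downstream Z'/normalization impossible).
    """
    expected = expected or LayoutSpec()
    out = []
    for pid in table.plate_ids:
        wells = table.wells(pid)
        counts = wells["role"].value_counts()
        n_neg = int(counts.get("neg_ctrl", 0))
        n_pos = int(counts.get("pos_ctrl", 0))
        n_cpd = int(counts.get("compound", 0))
        dev = []
        if n_neg != expected.n_neg:
            dev.append(f"neg_ctrl expected {expected.n_neg}, observed {n_neg}")
        if n_pos != expected.n_pos:
            dev.append(f"pos_ctrl expected {expected.n_pos}, observed {n_pos}")
        if n_cpd != expected.n_compound:
            dev.append(f"compound expected {expected.n_compound}, observed {n_cpd}")
        qc_possible = n_neg >= 2 and n_pos >= 2
        if not qc_possible:
            dev.append("downstream QC impossible (missing control wells)")
        out.append(
            {
                "plate_id": pid,
                "n_neg_ctrl": n_neg,
                "n_pos_ctrl": n_pos,
                "n_compound": n_cpd,
                "n_wells": len(wells),
                "deviations": "; ".join(dev),
                "qc_possible": qc_possible,
            }
        )
    return pd.DataFrame(out)


def write_run_summary(path: str | Path, summary: Mapping) -> None:
    """Persist a machine-readable run summary as JSON."""
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
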