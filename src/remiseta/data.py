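"""Data model and I/O for limb-by-group setation count tables.

One specimen is a matrix of nonnegative setal counts: one row per trunk
limb (numbered from 2, the first post-maxilliped limb), one column per
setal group (1-20). Posterior limbs may lack whole ramal segments, in
which case the corresponding group block is recorded as missing (``(-)``
in the canonical table format); counts read from damaged or ambiguous
material carry an uncertainty flag (``n?``).

The printed count tables of the two reference specimens (A, the specimen
with the most trunk somites, and F, the one with the fewest) ship as
bundled fixtures.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .scheme import DEFAULT_SCHEME, SetalGroupScheme

__all__ = [
    "Cell",
    "LimbRow",
    "SetationMatrix",
    "ParseError",
    "parse_setation_table",
    "write_setation_table",
    "load_fixture",
    "to_grid",
    "segment_sums",
    "infer_ramal_segmentation",
    "matrix_to_json",
    "matrix_from_json",
]

MISSING_TOKEN = "(-)"
_ROW_LABEL_RE = re.compile(r"^(\d+)([rl])$")
_UNCERTAIN_RE = re.compile(r"^(\d+)\?$")


class ParseError(ValueError):
    """Malformed setation table."""


@dataclass(frozen=True)
class Cell:
    """One count: a nonnegative integer, possibly uncertain, or missing.

    ``value is None`` marks a missing cell (the whole ramal segment is
    absent on that limb); uncertain cells keep their parsed integer.
    """

    value: int | None
    uncertain: bool = False

    def __post_init__(self) -> None:
        if self.value is not None and self.value < 0:
            raise ValueError(f"negative count {self.value}")
        if self.value is None and self.uncertain:
            raise ValueError("a missing cell cannot be uncertain")

    @property
    def is_missing(self) -> bool:
        return self.value is None

    def token(self) -> str:
        if self.value is None:
            return MISSING_TOKEN
        return f"{self.value}?" if self.uncertain else str(self.value)

    @classmethod
    def from_token(cls, token: str) -> "Cell":
        token = token.strip()
        if token == MISSING_TOKEN:
            return cls(None)
        m = _UNCERTAIN_RE.match(token)
        if m:
            return cls(int(m.group(1)), uncertain=True)
        if token.isdigit():
            return cls(int(token))
        raise ParseError(f"cannot parse cell token {token!r}")


@dataclass(frozen=True)
class LimbRow:
    """Counts of one limb: trunk-limb number, body side, and 20 cells."""

    limb_index: int
    side: str  # "right" | "left"
    cells: tuple[Cell, ...]

    def __post_init__(self) -> None:
        if self.side not in ("right", "left"):
            raise ValueError(f"side must be 'right' or 'left', got {self.side!r}")

    @property
    def label(self) -> str:
        return f"{self.limb_index}{self.side[0]}"


@dataclass
class SetationMatrix:
    """One specimen's ordered limb rows plus bookkeeping of discarded duplicates.

    ``rows`` holds one row per represented trunk limb, in anatomical
    order; when the source table listed both sides of a limb, the
    first-listed row is retained and the other kept in ``discarded``
    (with its original position) so the table can be re-serialized
    token-identically.
    """

    specimen_id: str
    rows: list[LimbRow]
    discarded: list[tuple[int, LimbRow]] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = self.limb_indices
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("limb indices must be strictly increasing")

    @property
    def limb_indices(self) -> list[int]:
        return [r.limb_index for r in self.rows]

    @property
    def n_trunk_somites(self) -> int:
        return self.rows[-1].limb_index if self.rows else 0

    @property
    def n_groups(self) -> int:
        return len(self.rows[0].cells) if self.rows else 0


def _parse_label(label: str) -> tuple[int, str]:
    m = _ROW_LABEL_RE.match(label.strip())
    if not m:
        raise ParseError(f"row label {label!r} does not match '<limb><r|l>'")
    return int(m.group(1)), {"r": "right", "l": "left"}[m.group(2)]


def parse_setation_table(
    text: str, specimen_id: str = "", keep_duplicates: bool = False
) -> SetationMatrix:
    """Parse a canonical TSV setation table.

    Expected layout: a header ``limb\\tg1...\\tg20`` and one row per limb
    labeled ``<n>r`` or ``<n>l``. Cell tokens are nonnegative integers,
    ``(-)`` for a missing segment, and ``<n>?`` for an uncertain count.
    When a limb number occurs twice (both sides listed), the first row is
    retained and the duplicate recorded, unless ``keep_duplicates``.
    """
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2 or df.columns[0].strip().lower() != "limb":
        raise ParseError("missing header: first column must be 'limb'")
    n_groups = df.shape[1] - 1
    if n_groups != 20:
        raise ParseError(f"expected 20 group columns, found {n_groups}")
    if df.shape[0] == 0:
        raise ParseError("no limb rows")

    parsed: list[LimbRow] = []
    for _, rec in df.iterrows():
        limb_index, side = _parse_label(rec.iloc[0])
        cells = []
        for col, tok in zip(df.columns[1:], rec.iloc[1:]):
            try:
                cells.append(Cell.from_token(tok))
            except ParseError as exc:
                raise ParseError(
                    f"row {rec.iloc[0]!r}, column {col!r}: {exc}"
                ) from None
        parsed.append(LimbRow(limb_index, side, tuple(cells)))

    if keep_duplicates:
        # callers opting in get every printed row; downstream grids then
        # carry one row per printed line rather than per limb
        seen_labels = set()
        rows = []
        for row in parsed:
            if row.label in seen_labels:
                raise ParseError(f"row label {row.label!r} occurs twice")
            seen_labels.add(row.label)
            rows.append(row)
        mat = SetationMatrix.__new__(SetationMatrix)
        mat.specimen_id = specimen_id
        mat.rows = rows
        mat.discarded = []
        return mat

    seen: dict[int, LimbRow] = {}
    rows, discarded = [], []
    for pos, row in enumerate(parsed):
        if row.limb_index in seen:
            discarded.append((pos, row))
        else:
            seen[row.limb_index] = row
            rows.append(row)
    return SetationMatrix(specimen_id, rows, discarded)


def write_setation_table(matrix: SetationMatrix, include_discarded: bool = True) -> str:
    """Serialize to the canonical TSV, reinserting discarded duplicate rows."""
    header = "limb\t" + "\t".join(f"g{i}" for i in range(1, 21))
    rows = list(matrix.rows)
    if include_discarded:
        for pos, row in sorted(matrix.discarded):
            rows.insert(pos, row)
    lines = [header]
    for row in rows:
        lines.append(row.label + "\t" + "\t".join(c.token() for c in row.cells))
    return "\n".join(lines) + "\n"


def load_fixture(
    specimen_id: str, include_bud: bool = True, keep_duplicates: bool = False
) -> SetationMatrix:
    """Load a bundled specimen table ("A" or "F").

    ``include_bud`` drops the terminal limb-bud row (the posteriormost,
    nearly asetose limb) when False; ``keep_duplicates`` retains the
    second-listed side of limbs counted on both sides.
    """
    if specimen_id not in ("A", "F"):
        raise KeyError(f"unknown specimen {specimen_id!r}; bundled fixtures are 'A' and 'F'")
    text = (
        resources.files("remiseta.fixtures")
        .joinpath(f"specimen_{specimen_id}.tsv")
        .read_text(encoding="utf-8")
    )
    mat = parse_setation_table(text, specimen_id, keep_duplicates=keep_duplicates)
    if not include_bud:
        last = max(r.limb_index for r in mat.rows)
        mat.rows = [r for r in mat.rows if r.limb_index != last]
        mat.discarded = [(p, r) for p, r in mat.discarded if r.limb_index != last]
    return mat


def to_grid(
    matrix: SetationMatrix, missing_policy: str = "zero"
) -> tuple[np.ndarray, np.ndarray]:
    """Numeric (n_limbs, 20) grid plus boolean mask of usable entries.

    Under ``zero`` missing cells become 0 and the mask is all-true (a
    limb that never formed a segment genuinely bears no setae there);
    under ``mask`` they are excluded from fitting. Uncertain counts are
    used at face value either way.
    """
    if missing_policy not in ("zero", "mask"):
        raise ValueError(f"missing_policy must be 'zero' or 'mask', got {missing_policy!r}")
    n = len(matrix.rows)
    grid = np.zeros((n, matrix.n_groups))
    mask = np.ones((n, matrix.n_groups), dtype=bool)
    for i, row in enumerate(matrix.rows):
        for j, cell in enumerate(row.cells):
            if cell.is_missing:
                if missing_policy == "mask":
                    mask[i, j] = False
            else:
                grid[i, j] = cell.value
    return grid, mask


def segment_sums(
    matrix: SetationMatrix, scheme: SetalGroupScheme = DEFAULT_SCHEME
) -> pd.DataFrame:
    """Per-limb setal totals for each ramal segment and the grand total.

    Missing cells count as zero. Columns are the scheme's segment labels
    plus ``"sum"``; the index is the limb number.
    """
    grid, _ = to_grid(matrix, "zero")
    out = {}
    for (ramus, seg, groups), label in zip(scheme.blocks, scheme.segment_labels):
        cols = [g - 1 for g in groups]
        out[label] = grid[:, cols].sum(axis=1)
    out["sum"] = grid.sum(axis=1)
    return pd.DataFrame(out, index=pd.Index(matrix.limb_indices, name="limb"))


def infer_ramal_segmentation(
    row: LimbRow, scheme: SetalGroupScheme = DEFAULT_SCHEME
) -> tuple[int, int]:
    """Count present exopod and endopod segments of one limb.

    A ramal segment counts as present iff at least one of its groups has
    a recorded (non-missing) count; a zero count still attests the
    segment exists. Protopod segments bear no setae and cannot be
    inferred this way.
    """
    counts = {"exopod": 0, "endopod": 0}
    for ramus, _, groups in scheme.blocks:
        if any(not row.cells[g - 1].is_missing for g in groups):
            counts[ramus] += 1
    return counts["exopod"], counts["endopod"]


def matrix_to_json(matrix: SetationMatrix) -> str:
    """JSON export with explicit missing/uncertain flags."""

    def row_obj(row: LimbRow) -> dict:
        return {
            "limb": row.limb_index,
            "side": row.side,
            "cells": [
                {"value": c.value, "uncertain": c.uncertain} for c in row.cells
            ],
        }

    obj = {
        "specimen_id": matrix.specimen_id,
        "rows": [row_obj(r) for r in matrix.rows],
        "discarded": [
            {"position": p, **row_obj(r)} for p, r in matrix.discarded
        ],
    }
    return json.dumps(obj, indent=2)


def matrix_from_json(text: str) -> SetationMatrix:
    obj = json.loads(text)

    def mk_row(rec: dict) -> LimbRow:
        cells = tuple(
            Cell(c["value"], c.get("uncertain", False)) for c in rec["cells"]
        )
        return LimbRow(rec["limb"], rec["side"], cells)

    return SetationMatrix(
        obj["specimen_id"],
        [mk_row(r) for r in obj["rows"]],
        [(r["position"], mk_row(r)) for r in obj.get("discarded", [])],
    )
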