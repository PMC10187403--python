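"""Reading and writing spotted antibody-array data.

Two spot-level dialects are supported: the GenePix Results text format
(an ATF header followed by a tab-delimited table, one file per array) and a
plain long-format delimited table that may hold several arrays.  A separate
design table maps each array to its sample annotation: genotype
(``metrs`` = MetRS(L274G)-expressing, ``control`` = unmodified), co-culture
condition (``baseline`` vs ``stimulated``, e.g. co-culture with naive vs
LPS-treated monocytes),
replicate number and BCA-determined loaded protein concentration.

Coordinates are 1-based (block, row, column), following the GenePix
convention.  A single fluorescence channel is assumed (streptavidin-Cy3);
when a file carries several "F* Median"/"B* Median" column pairs the first
is used and the rest are ignored with a logged warning.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

ROLES = ("target", "pos_control", "neg_control", "blank")
GENOTYPES = ("metrs", "control")
CONDITIONS = ("baseline", "stimulated")

_FG_PATTERN = re.compile(r"^F\S* Median$")
_BG_PATTERN = re.compile(r"^B\S* Median$")


class FormatError(ValueError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class LayoutError(ValueError):
    """Spot coordinates or probe layout are internally inconsistent."""


def infer_role(probe_id: str) -> str:
    """Map a probe id to its spot role by naming convention.

    Ids beginning with ``POS`` are positive controls, ``NEG`` negative
    controls, ``BLANK`` (or an empty id) blanks; anything else is a target
    antibody.  An explicit role column in the input always overrides this.
    """
    u = probe_id.strip().upper()
    if not u or u.startswith("BLANK"):
        return "blank"
    if u.startswith("POS"):
        return "pos_control"
    if u.startswith("NEG"):
        return "neg_control"
    return "target"


@dataclass(frozen=True)
class SpotRecord:
    """One scanned spot: position, probe identity/role, median intensities, flag.

    ``flag`` follows the GenePix convention: 0 means unflagged, negative
    values mark a bad spot that is excluded from duplicate averaging.
    """

    array_id: str
    block: int
    row: int
    col: int
    probe_id: str
    probe_role: str
    fg_median: float
    bg_median: float
    flag: int = 0

    def __post_init__(self) -> None:
        if self.block < 1 or self.row < 1 or self.col < 1:
            raise ValueError(
                f"spot coordinates must be >= 1, got "
                f"({self.block}, {self.row}, {self.col})"
            )
        if self.probe_role not in ROLES:
            raise ValueError(f"unknown probe_role {self.probe_role!r}")
        if self.probe_role != "blank" and not self.probe_id.strip():
            raise ValueError("probe_id must be non-empty for non-blank spots")
        if self.fg_median < 0 or self.bg_median < 0:
            raise ValueError(
                f"negative intensity for probe {self.probe_id!r} "
                f"(fg={self.fg_median}, bg={self.bg_median})"
            )


@dataclass(frozen=True)
class SampleMeta:
    """Per-array experimental annotation."""

    array_id: str
    sample_id: str
    genotype: str
    condition: str
    replicate: int
    protein_conc: float

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(
                f"unknown genotype {self.genotype!r}; expected one of {GENOTYPES}"
            )
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if not self.protein_conc > 0:
            raise ValueError(
                f"protein_conc must be > 0 for array {self.array_id!r}, "
                f"got {self.protein_conc}"
            )


def _check_unique_coords(spots: Sequence[SpotRecord]) -> None:
    seen: dict[tuple[str, int, int, int], str] = {}
    for s in spots:
        key = (s.array_id, s.block, s.row, s.col)
        if key in seen:
            raise LayoutError(
                f"duplicate spot coordinates {key[1:]} on array {s.array_id!r}"
            )
        seen[key] = s.probe_id


# ---------------------------------------------------------------------------
# GPR / ATF dialect
# ---------------------------------------------------------------------------

def read_gpr(path: str | Path, array_id: str) -> list[SpotRecord]:
    """Read one array from a GenePix Results (ATF) text file.

    The file must begin with an ATF header: a line starting with ``ATF``, a
    line with the optional-header-record count and column count, that many
    ``"Key=Value"`` lines, then a tab-delimited table with at least Block,
    Row, Column, ID (or Name), a foreground-median and a background-median
    column.  A Flags column is optional (default 0); an explicit Role column
    overrides name-based role inference.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("ATF"):
        raise FormatError(f"{path}: not an ATF file (missing 'ATF' signature)")
    if len(lines) < 2:
        raise FormatError(f"{path}: truncated ATF header")
    try:
        n_header = int(lines[1].split("\t")[0])
    except ValueError as exc:
        raise FormatError(f"{path}: malformed ATF header-count line") from exc
    header_line_idx = 2 + n_header
    if header_line_idx >= len(lines):
        raise FormatError(f"{path}: ATF header longer than file")
    columns = [c.strip().strip('"') for c in lines[header_line_idx].split("\t")]
    rows = [ln.split("\t") for ln in lines[header_line_idx + 1 :] if ln.strip()]
    return _spots_from_table(columns, rows, path, array_id=array_id)


def _resolve_column(columns: list[str], names: Iterable[str], path: Path) -> int:
    for name in names:
        if name in columns:
            return columns.index(name)
    raise FormatError(f"{path}: missing mandatory column {'/'.join(names)!r}")


def _resolve_channel(columns: list[str], pattern: re.Pattern, path: Path) -> int:
    matches = [i for i, c in enumerate(columns) if pattern.match(c)]
    if not matches:
        raise FormatError(
            f"{path}: no column matching {pattern.pattern!r} "
            "(foreground/background median)"
        )
    if len(matches) > 1:
        log.warning(
            "%s: multiple channels found (%s); using %r",
            path,
            ", ".join(columns[i] for i in matches),
            columns[matches[0]],
        )
    return matches[0]


def _spots_from_table(
    columns: list[str],
    rows: list[list[str]],
    path: Path,
    array_id: str,
) -> list[SpotRecord]:
    i_block = _resolve_column(columns, ("Block",), path)
    i_row = _resolve_column(columns, ("Row",), path)
    i_col = _resolve_column(columns, ("Column",), path)
    i_id = _resolve_column(columns, ("ID", "Name"), path)
    i_fg = _resolve_channel(columns, _FG_PATTERN, path)
    i_bg = _resolve_channel(columns, _BG_PATTERN, path)
    i_flag = columns.index("Flags") if "Flags" in columns else None
    i_role = columns.index("Role") if "Role" in columns else None

    spots = []
    for r in rows:
        probe_id = r[i_id].strip().strip('"')
        role = r[i_role].strip().strip('"') if i_role is not None else ""
        spots.append(
            SpotRecord(
                array_id=array_id,
                block=int(r[i_block]),
                row=int(r[i_row]),
                col=int(r[i_col]),
                probe_id=probe_id,
                probe_role=role if role else infer_role(probe_id),
                fg_median=float(r[i_fg]),
                bg_median=float(r[i_bg]),
                flag=int(float(r[i_flag])) if i_flag is not None else 0,
            )
        )
    _check_unique_coords(spots)
    return spots


def write_gpr(spots: Sequence[SpotRecord], path: str | Path) -> None:
    """Write one array's spots as a minimal single-channel GPR/ATF file.

    Float intensities are serialized with ``repr`` (shortest round-trip
    form), so write-then-read is exact.
    """
    path = Path(path)
    arrays = {s.array_id for s in spots}
    if len(arrays) != 1:
        raise ValueError(f"write_gpr expects exactly one array, got {sorted(arrays)}")
    header = ["Block", "Row", "Column", "ID", "Role", "F532 Median", "B532 Median", "Flags"]
    with path.open("w", encoding="utf-8") as fh:
        fh.write("ATF\t1.0\n")
        fh.write(f"1\t{len(header)}\n")
        fh.write('"Type=SecretomicsArray V1.0"\n')
        fh.write("\t".join(f'"{h}"' for h in header) + "\n")
        for s in spots:
            fh.write(
                f"{s.block}\t{s.row}\t{s.col}\t{s.probe_id}\t{s.probe_role}\t"
                f"{s.fg_median!r}\t{s.bg_median!r}\t{s.flag}\n"
            )


# ---------------------------------------------------------------------------
# Long-format table (multi-array)
# ---------------------------------------------------------------------------

_LONG_COLUMNS = (
    "array_id",
    "block",
    "row",
    "col",
    "probe_id",
    "probe_role",
    "fg_median",
    "bg_median",
    "flag",
)


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_long_table(path: str | Path) -> list[SpotRecord]:
    """Read spots for one or more arrays from a long-format delimited table.

    A blank ``probe_role`` cell falls back to name-based role inference; a
    blank ``flag`` cell defaults to 0.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=_delimiter_for(path))
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        missing = [c for c in _LONG_COLUMNS[:-1] if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s) {missing}")
        spots = []
        for r in reader:
            probe_id = (r["probe_id"] or "").strip()
            role = (r.get("probe_role") or "").strip()
            flag_cell = (r.get("flag") or "").strip()
            spots.append(
                SpotRecord(
                    array_id=r["array_id"].strip(),
                    block=int(r["block"]),
                    row=int(r["row"]),
                    col=int(r["col"]),
                    probe_id=probe_id,
                    probe_role=role if role else infer_role(probe_id),
                    fg_median=float(r["fg_median"]),
                    bg_median=float(r["bg_median"]),
                    flag=int(float(flag_cell)) if flag_cell else 0,
                )
            )
    _check_unique_coords(spots)
    return spots


def write_long_table(spots: Sequence[SpotRecord], path: str | Path) -> None:
    """Write spots (any number of arrays) as a long-format delimited table."""
    path = Path(path)
    delim = _delimiter_for(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(_LONG_COLUMNS)
        for s in spots:
            writer.writerow(
                [
                    s.array_id,
                    s.block,
                    s.row,
                    s.col,
                    s.probe_id,
                    s.probe_role,
                    repr(s.fg_median),
                    repr(s.bg_median),
                    s.flag,
                ]
            )


# ---------------------------------------------------------------------------
# Design table
# ---------------------------------------------------------------------------

_DESIGN_COLUMNS = (
    "array_id",
    "sample_id",
    "genotype",
    "condition",
    "replicate",
    "protein_conc",
)


def read_design(path: str | Path) -> list[SampleMeta]:
    """Read the array-to-sample design table.

    Genotype and condition tokens are normalized to lowercase; unknown
    tokens, non-positive concentrations and duplicate array ids are errors.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=_delimiter_for(path))
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        missing = [c for c in _DESIGN_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s) {missing}")
        meta = [
            SampleMeta(
                array_id=r["array_id"].strip(),
                sample_id=r["sample_id"].strip(),
                genotype=r["genotype"].strip().lower(),
                condition=r["condition"].strip().lower(),
                replicate=int(r["replicate"]),
                protein_conc=float(r["protein_conc"]),
            )
            for r in reader
        ]
    ids = [m.array_id for m in meta]
    dupes = sorted({a for a in ids if ids.count(a) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicate array_id(s) in design: {dupes}")
    return meta


def write_design(meta: Sequence[SampleMeta], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=_delimiter_for(path), lineterminator="\n")
        writer.writerow(_DESIGN_COLUMNS)
        for m in meta:
            writer.writerow(
                [
                    m.array_id,
                    m.sample_id,
                    m.genotype,
                    m.condition,
                    m.replicate,
                    repr(m.protein_conc),
                ]
            )
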