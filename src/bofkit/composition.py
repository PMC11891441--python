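"""Composition workbook parsing and validation.

A biomass-composition dataset is a workbook with one sheet per
pseudo-reaction to generate.  Each sheet carries two header-labelled
tables:

* a **composition table** (columns ``metabolite_id``, ``name`` (optional),
  ``value``, ``unit``) listing the building blocks consumed by the
  pseudo-reaction — model metabolites, or the names of deeper sheets
  (pool references);
* an optional **maintenance table** (columns ``maintenance_metabolite_id``,
  ``maintenance_name`` (optional), ``maintenance_coefficient``,
  ``maintenance_unit``) whose signed coefficients are used directly as
  stoichiometric coefficients (negative = consumed, positive = produced).

The same schema is accepted as a directory of TSV files, one
``<sheet>.tsv`` per composition table plus an optional
``<sheet>.maintenance.tsv`` (plain column names ``metabolite_id``,
``name``, ``coefficient``, ``unit``).

Column resolution is by header name, not cell coordinates; extra columns
are ignored.  Sheet name = pool name = base ID of the generated
pseudo-entities.  The top (level 1) sheet is detected as the unique sheet
referenced by no other sheet.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import openpyxl

from . import gem_io
from .errors import SchemaError, SpecError
from .gem_io import ModelHandle

logger = logging.getLogger(__name__)

TAG_PATTERN = re.compile(r"^[A-Za-z0-9_]+$")

MAX_DEPTH = 3


class Unit(str, Enum):
    """Accepted composition-table units.

    Mass units are per gram dry weight; molar units are either absolute
    (per gDW) or relative (per mole of the pool being defined).  Within one
    sheet every composition row must use the same unit.
    """

    G_PER_GDW = "g_per_gDW"
    MG_PER_GDW = "mg_per_gDW"
    PERCENT_DW_MASS = "percent_DW_mass"
    MMOL_PER_GDW = "mmol_per_gDW"
    UMOL_PER_GDW = "umol_per_gDW"
    MOL_PER_MOL = "mol_per_mol"
    PERCENT_MOL = "percent_mol"

    @property
    def is_mass(self) -> bool:
        return self in (Unit.G_PER_GDW, Unit.MG_PER_GDW, Unit.PERCENT_DW_MASS)


class MaintenanceUnit(str, Enum):
    """Maintenance coefficients are never converted: they are applied
    directly as stoichiometric coefficients in the declared basis."""

    MMOL_PER_GDW = "mmol_per_gDW"
    MOL_PER_MOL_POOL = "mol_per_mol_pool"


@dataclass
class CompositionEntry:
    metabolite_id: str
    value: float
    unit: Unit
    name: str = ""


@dataclass
class MaintenanceEntry:
    metabolite_id: str
    coefficient: float
    unit: MaintenanceUnit
    name: str = ""


@dataclass
class PseudoReactionSpec:
    """One sheet: a pool name plus its composition and maintenance rows."""

    pool_name: str
    level: int
    entries: list[CompositionEntry]
    maintenance: list[MaintenanceEntry] = field(default_factory=list)


@dataclass
class BofSpec:
    """Validated hierarchy of pseudo-reaction specs (a tree, depth <= 3)."""

    top: PseudoReactionSpec
    pools: dict[str, PseudoReactionSpec]
    tag: str
    compartment: str
    sheet_order: list[str] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return max((s.level for s in self.all_specs()), default=1)

    def all_specs(self) -> list[PseudoReactionSpec]:
        ordered = self.sheet_order or [self.top.pool_name, *self.pools]
        by_name = {self.top.pool_name: self.top, **self.pools}
        return [by_name[n] for n in ordered]

    def children_of(self, spec: PseudoReactionSpec) -> list[str]:
        return [e.metabolite_id for e in spec.entries if e.metabolite_id in self.pools]


@dataclass
class RawSheet:
    """Parsed-but-unvalidated sheet content (strings and numbers only)."""

    name: str
    composition_rows: list[dict]
    maintenance_rows: list[dict]


COMPOSITION_COLUMNS = ("metabolite_id", "name", "value", "unit")
MAINTENANCE_COLUMNS = (
    "maintenance_metabolite_id",
    "maintenance_name",
    "maintenance_coefficient",
    "maintenance_unit",
)

_REQUIRED_COMPOSITION = ("metabolite_id", "value", "unit")
_REQUIRED_MAINTENANCE = ("maintenance_metabolite_id", "maintenance_coefficient", "maintenance_unit")


def _is_blank(value) -> bool:
    return value is None or (isinstance(value, str) and not value.strip())


def _as_number(value, sheet: str, row: int, column: str) -> float:
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if isinstance(value, str):
        try:
            return float(value.strip())
        except ValueError:
            pass
    raise SchemaError(
        f"sheet {sheet!r}, row {row}: non-numeric {column} cell {value!r}"
    )


def _parse_sheet_rows(sheet_name: str, header: list, rows: list[list]) -> RawSheet:
    columns = {str(h).strip(): i for i, h in enumerate(header) if not _is_blank(h)}
    for col in _REQUIRED_COMPOSITION:
        if col not in columns:
            raise SchemaError(f"sheet {sheet_name!r} is missing mandatory column {col!r}")
    has_maintenance = "maintenance_metabolite_id" in columns
    if has_maintenance:
        for col in _REQUIRED_MAINTENANCE:
            if col not in columns:
                raise SchemaError(
                    f"sheet {sheet_name!r} has a maintenance table but is missing "
                    f"column {col!r}"
                )

    def cell(row: list, col: str):
        idx = columns.get(col)
        if idx is None or idx >= len(row):
            return None
        return row[idx]

    composition, maintenance = [], []
    for i, row in enumerate(rows, start=2):  # row 1 is the header
        mid = cell(row, "metabolite_id")
        if not _is_blank(mid):
            composition.append(
                {
                    "metabolite_id": str(mid).strip(),
                    "name": "" if _is_blank(cell(row, "name")) else str(cell(row, "name")).strip(),
                    "value": _as_number(cell(row, "value"), sheet_name, i, "value"),
                    "unit": "" if _is_blank(cell(row, "unit")) else str(cell(row, "unit")).strip(),
                    "row": i,
                }
            )
        if has_maintenance:
            mmid = cell(row, "maintenance_metabolite_id")
            if not _is_blank(mmid):
                mname = cell(row, "maintenance_name")
                maintenance.append(
                    {
                        "metabolite_id": str(mmid).strip(),
                        "name": "" if _is_blank(mname) else str(mname).strip(),
                        "coefficient": _as_number(
                            cell(row, "maintenance_coefficient"),
                            sheet_name,
                            i,
                            "maintenance_coefficient",
                        ),
                        "unit": ""
                        if _is_blank(cell(row, "maintenance_unit"))
                        else str(cell(row, "maintenance_unit")).strip(),
                        "row": i,
                    }
                )
    return RawSheet(sheet_name, composition, maintenance)


def load_workbook(path: str | Path) -> list[RawSheet]:
    """Load an XLSX workbook, or a directory of equivalent TSV files, into
    raw sheets (one per pseudo-reaction), in workbook sheet order (TSV
    directories are read in sorted filename order)."""
    path = Path(path)
    if path.is_dir():
        return _load_tsv_directory(path)
    if not path.exists():
        raise SchemaError(f"composition file not found: {path}")
    try:
        wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    except Exception as exc:
        raise SchemaError(f"cannot read workbook {path}: {exc}") from exc
    sheets = []
    try:
        for ws in wb.worksheets:
            rows = [list(r) for r in ws.iter_rows(values_only=True)]
            if not rows:
                raise SchemaError(f"sheet {ws.title!r} is empty (no header row)")
            sheets.append(_parse_sheet_rows(ws.title, rows[0], rows[1:]))
    finally:
        wb.close()
    return sheets


def _read_tsv(path: Path) -> list[list[str]]:
    lines = path.read_text().splitlines()
    return [line.split("\t") for line in lines if line.strip()]


def _load_tsv_directory(path: Path) -> list[RawSheet]:
    comp_files = sorted(p for p in path.glob("*.tsv") if not p.name.endswith(".maintenance.tsv"))
    if not comp_files:
        raise SchemaError(f"no .tsv sheets found in directory {path}")
    sheets = []
    for comp in comp_files:
        sheet_name = comp.stem
        rows = _read_tsv(comp)
        if not rows:
            raise SchemaError(f"sheet {sheet_name!r} is empty (no header row)")
        header = [h.strip() for h in rows[0]]
        body = rows[1:]
        maint_path = comp.with_name(f"{sheet_name}.maintenance.tsv")
        if maint_path.exists():
            mrows = _read_tsv(maint_path)
            mheader = [f"maintenance_{h.strip()}" for h in mrows[0]] if mrows else []
            # paste the two tables side by side so one parser handles both;
            # composition cells are padded/clipped to the header width so
            # maintenance columns land at fixed offsets
            width = len(header)
            merged_header = header + mheader
            comp_parts = [(r + [""] * width)[:width] for r in body]
            mbody = mrows[1:]
            merged = []
            for i in range(max(len(comp_parts), len(mbody))):
                left = comp_parts[i] if i < len(comp_parts) else [""] * width
                right = mbody[i] if i < len(mbody) else []
                merged.append(left + right)
            sheets.append(_parse_sheet_rows(sheet_name, merged_header, merged))
        else:
            sheets.append(_parse_sheet_rows(sheet_name, header, body))
    return sheets


def build_spec(
    raw_sheets: list[RawSheet],
    tag: str,
    compartment: str,
    model: ModelHandle,
) -> BofSpec:
    """Validate raw sheets against the model and assemble a :class:`BofSpec`.

    Every failure is collected and reported together in one
    :class:`SpecError` so the workbook can be fixed in a single pass.
    Zero-valued composition rows are dropped with a logged notice;
    duplicated metabolite IDs within a sheet are an error (never summed).
    """
    failures: list[str] = []

    if not tag or not TAG_PATTERN.match(tag):
        failures.append(f"tag {tag!r} is invalid: only [A-Za-z0-9_]+ is allowed")
    if compartment not in model.compartments:
        failures.append(
            f"compartment {compartment!r} not in model (available: "
            f"{sorted(model.compartments)})"
        )

    sheet_names = [s.name for s in raw_sheets]
    if len(set(sheet_names)) != len(sheet_names):
        failures.append(f"duplicate sheet names: {sheet_names}")
    name_set = set(sheet_names)

    # --- reference graph: which sheets consume which other sheets --------
    referenced_by: dict[str, list[str]] = {n: [] for n in name_set}
    for sheet in raw_sheets:
        for row in sheet.composition_rows:
            child = row["metabolite_id"]
            if child in name_set:
                if child == sheet.name:
                    failures.append(f"sheet {sheet.name!r} references itself")
                else:
                    referenced_by[child].append(sheet.name)

    roots = [n for n in sheet_names if not referenced_by[n]]
    root: str | None = None
    if len(roots) == 1:
        root = roots[0]
    elif len(roots) == 0:
        failures.append("pool reference graph has no root: the sheets form a cycle")
    else:
        failures.append(
            f"pool reference graph has multiple roots {sorted(roots)}; exactly one "
            "top-level sheet must be referenced by no other sheet"
        )
    for name, parents in referenced_by.items():
        if len(parents) > 1:
            failures.append(
                f"pool {name!r} is referenced from multiple sheets {sorted(parents)}; "
                "the hierarchy must be a tree"
            )

    # --- level assignment by BFS from the root ---------------------------
    levels: dict[str, int] = {}
    if root is not None:
        levels[root] = 1
        frontier = [root]
        by_name = {s.name: s for s in raw_sheets}
        while frontier:
            nxt = []
            for parent in frontier:
                for row in by_name[parent].composition_rows:
                    child = row["metabolite_id"]
                    if child in name_set and child != parent and child not in levels:
                        levels[child] = levels[parent] + 1
                        nxt.append(child)
            frontier = nxt
        unreachable = name_set - set(levels)
        if unreachable:
            failures.append(
                f"sheet(s) {sorted(unreachable)} are not reachable from the top sheet "
                f"{root!r} (cycle or orphan)"
            )
        too_deep = [n for n, lv in levels.items() if lv > MAX_DEPTH]
        if too_deep:
            failures.append(
                f"hierarchy exceeds the maximum depth of {MAX_DEPTH} levels at "
                f"{sorted(too_deep)}"
            )

    # --- per-sheet validation --------------------------------------------
    specs: dict[str, PseudoReactionSpec] = {}
    for sheet in raw_sheets:
        entries: list[CompositionEntry] = []
        seen_ids: set[str] = set()
        units_used: set[str] = set()
        for row in sheet.composition_rows:
            mid = row["metabolite_id"]
            if mid in seen_ids:
                failures.append(
                    f"sheet {sheet.name!r}: duplicate metabolite {mid!r} in the "
                    "composition table (rows are never summed)"
                )
                continue
            seen_ids.add(mid)
            try:
                unit = Unit(row["unit"])
            except ValueError:
                failures.append(
                    f"sheet {sheet.name!r}, row {row['row']}: unknown unit "
                    f"{row['unit']!r} (accepted: {[u.value for u in Unit]})"
                )
                continue
            units_used.add(unit.value)
            value = row["value"]
            if value < 0:
                failures.append(
                    f"sheet {sheet.name!r}, row {row['row']}: negative value {value} "
                    f"for {mid!r}"
                )
                continue
            if value == 0:
                logger.info(
                    "sheet %r: dropping zero-valued entry %r", sheet.name, mid
                )
                continue
            entries.append(CompositionEntry(mid, value, unit, row["name"]))
            if mid not in name_set:
                if gem_io.check_metabolites_exist(model, [mid]):
                    failures.append(
                        f"sheet {sheet.name!r}: metabolite {mid!r} not found in the "
                        "model (identifiers must match the model exactly)"
                    )
        if len(units_used) > 1:
            failures.append(
                f"sheet {sheet.name!r} mixes units {sorted(units_used)}; all "
                "composition rows of one sheet must share a single unit"
            )
        if not entries:
            failures.append(
                f"sheet {sheet.name!r} has no usable composition row (empty or all-zero)"
            )

        maintenance: list[MaintenanceEntry] = []
        for row in sheet.maintenance_rows:
            mid = row["metabolite_id"]
            if mid in name_set:
                failures.append(
                    f"sheet {sheet.name!r}: maintenance species {mid!r} is a pool "
                    "name; maintenance rows must reference model metabolites"
                )
                continue
            if gem_io.check_metabolites_exist(model, [mid]):
                failures.append(
                    f"sheet {sheet.name!r}: maintenance metabolite {mid!r} not found "
                    "in the model"
                )
                continue
            try:
                unit = MaintenanceUnit(row["unit"])
            except ValueError:
                failures.append(
                    f"sheet {sheet.name!r}, row {row['row']}: unknown maintenance "
                    f"unit {row['unit']!r} (accepted: "
                    f"{[u.value for u in MaintenanceUnit]})"
                )
                continue
            coeff = row["coefficient"]
            if coeff == 0:
                logger.info(
                    "sheet %r: dropping zero-coefficient maintenance row %r",
                    sheet.name,
                    mid,
                )
                continue
            maintenance.append(MaintenanceEntry(mid, coeff, unit, row["name"]))

        specs[sheet.name] = PseudoReactionSpec(
            pool_name=sheet.name,
            level=levels.get(sheet.name, 0),
            entries=entries,
            maintenance=maintenance,
        )

    if failures:
        raise SpecError(failures)

    assert root is not None
    return BofSpec(
        top=specs[root],
        pools={n: s for n, s in specs.items() if n != root},
        tag=tag,
        compartment=compartment,
        sheet_order=sheet_names,
    )


# --------------------------------------------------------------------------
# Template generation

_TEMPLATE_SHEETS = {
    1: ["BIOMASS"],
    2: ["BIOMASS", "DNA", "PROTEIN"],
    3: ["BIOMASS", "DNA", "PROTEIN", "LIPIDS", "PC", "PE"],
}


def write_template(levels: int, path: str | Path) -> None:
    """Write a blank composition workbook of the requested depth (1-3).

    Sheets carry only the documented header row; the example sheet set for
    depth 3 mirrors the conventional BIOMASS / DNA / PROTEIN / LIPIDS /
    PC / PE structure.
    """
    from .errors import ConfigError

    if levels not in _TEMPLATE_SHEETS:
        raise ConfigError(f"levels must be 1, 2 or 3, got {levels}")
    wb = openpyxl.Workbook()
    wb.remove(wb.active)
    header = list(COMPOSITION_COLUMNS) + [""] + list(MAINTENANCE_COLUMNS)
    for sheet_name in _TEMPLATE_SHEETS[levels]:
        ws = wb.create_sheet(sheet_name)
        ws.append(header)
    wb.save(str(path))
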