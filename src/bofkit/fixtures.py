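"""Deterministic toy models and composition workbooks for tests, demos and
the acceptance report.  Everything is generated from a seed — no downloads,
no bundled binary files.

The synthetic formulas are small, exactly representable compositions
(CxHyNzOwPv); no real biochemistry is claimed.  The cofactor five-some
(atp/h2o/adp/pi/h) is elementally and charge self-balanced, so maintenance
rows built from it contribute zero net mass and keep generated reactions
balanced.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import cobra
import openpyxl

from .composition import COMPOSITION_COLUMNS, MAINTENANCE_COLUMNS, Unit
from .gem_io import ModelHandle

#: ATP hydrolysis set: atp + h2o -> adp + pi + h, balanced in elements and charge.
COFACTORS = {
    "atp_c": ("C10H12N5O13P3", -4),
    "h2o_c": ("H2O", 0),
    "adp_c": ("C10H12N5O10P2", -3),
    "pi_c": ("HO4P", -2),
    "h_c": ("H", 1),
}

#: sheet hierarchy per depth; parents listed before children
POOL_TREES = {
    1: {"BIOMASS": []},
    2: {"BIOMASS": ["DNA", "PROTEIN"], "DNA": [], "PROTEIN": []},
    3: {
        "BIOMASS": ["DNA", "PROTEIN", "LIPIDS"],
        "DNA": [],
        "PROTEIN": [],
        "LIPIDS": ["PC", "PE"],
        "PC": [],
        "PE": [],
    },
}

#: monomer ID prefix per leaf sheet
MONOMER_PREFIX = {
    "BIOMASS": "mono",
    "DNA": "dntp",
    "PROTEIN": "aa",
    "PC": "pc",
    "PE": "pe",
}

DEFAULT_UNITS = {
    "BIOMASS": Unit.G_PER_GDW,
    "DNA": Unit.MOL_PER_MOL,
    "PROTEIN": Unit.MMOL_PER_GDW,
    "LIPIDS": Unit.G_PER_GDW,
    "PC": Unit.MOL_PER_MOL,
    "PE": Unit.PERCENT_MOL,
}


@dataclass
class FixtureConfig:
    levels: int = 3
    n_monomers: int = 4
    seed: int = 0
    include_maintenance: bool = True
    make_feasible: bool = False
    total_mass: float = 0.97
    with_charges: bool = True
    corrupt_unit_mix: bool = False
    units: dict[str, Unit] = field(default_factory=dict)

    def __post_init__(self):
        if self.levels not in POOL_TREES:
            raise ValueError(f"levels must be in {sorted(POOL_TREES)}")
        if self.n_monomers < 1:
            raise ValueError("n_monomers must be >= 1")

    @property
    def tree(self) -> dict[str, list[str]]:
        return POOL_TREES[self.levels]

    def leaf_sheets(self) -> list[str]:
        return [name for name, kids in self.tree.items() if not kids]

    def monomer_ids(self, sheet: str) -> list[str]:
        prefix = MONOMER_PREFIX[sheet]
        return [f"{prefix}{i}_c" for i in range(1, self.n_monomers + 1)]


def _monomer_formula(rng: random.Random) -> str:
    c = rng.randint(2, 12)
    h = rng.randint(4, 20)
    n = rng.randint(0, 4)
    o = rng.randint(1, 8)
    p = rng.randint(0, 2)
    parts = [f"C{c}", f"H{h}"]
    if n:
        parts.append(f"N{n}")
    parts.append(f"O{o}")
    if p:
        parts.append(f"P{p}")
    return "".join(parts)


def make_toy_model(cfg: FixtureConfig) -> ModelHandle:
    """Build a one-compartment toy model with monomers for every leaf sheet
    plus the balanced cofactor set; deterministic for a given seed.

    Always includes one ATP-maintenance reaction so the model has at least
    one reaction.  With ``make_feasible`` an exchange reaction is opened
    for every metabolite, which guarantees a strictly positive optimum for
    any mass-consistent objective.
    """
    rng = random.Random(cfg.seed)
    model = cobra.Model(f"toy_gem_seed{cfg.seed}")
    model.compartments = {"c": "cytosol"}

    mets = []
    for sheet in cfg.leaf_sheets():
        for mid in cfg.monomer_ids(sheet):
            met = cobra.Metabolite(
                mid,
                formula=_monomer_formula(rng),
                compartment="c",
                name=mid[:-2].upper(),
            )
            if cfg.with_charges:
                met.charge = rng.randint(-2, 0)
            mets.append(met)
    for mid, (formula, charge) in COFACTORS.items():
        met = cobra.Metabolite(mid, formula=formula, compartment="c", name=mid[:-2].upper())
        if cfg.with_charges:
            met.charge = charge
        mets.append(met)
    model.add_metabolites(mets)

    atpm = cobra.Reaction("ATPM", name="ATP maintenance")
    atpm.bounds = (0.0, 1000.0)
    model.add_reactions([atpm])
    atpm.add_metabolites(
        {
            model.metabolites.atp_c: -1,
            model.metabolites.h2o_c: -1,
            model.metabolites.adp_c: 1,
            model.metabolites.pi_c: 1,
            model.metabolites.h_c: 1,
        }
    )

    if cfg.make_feasible:
        exchanges = []
        for met in list(model.metabolites):
            rxn = cobra.Reaction(f"EX_{met.id}", name=f"{met.id} exchange")
            rxn.bounds = (-1000.0, 1000.0)
            exchanges.append((rxn, met))
        model.add_reactions([r for r, _ in exchanges])
        for rxn, met in exchanges:
            rxn.add_metabolites({met: -1})

    return ModelHandle(model)


def _random_split(rng: random.Random, n: int) -> list[float]:
    weights = [rng.uniform(0.5, 1.5) for _ in range(n)]
    total = sum(weights)
    return [w / total for w in weights]


def _maintenance_rows(scale: float, unit: str) -> list[tuple[str, float, str]]:
    return [
        ("atp_c", -scale, unit),
        ("h2o_c", -scale, unit),
        ("adp_c", scale, unit),
        ("pi_c", scale, unit),
        ("h_c", scale, unit),
    ]


def make_composition(
    cfg: FixtureConfig,
    model: ModelHandle,
    path: str | Path,
) -> Path:
    """Write a composition workbook matching ``make_toy_model(cfg)``.

    Level-1 values sum to ``cfg.total_mass`` grams per gDW (default 0.97,
    to exercise the normalization); deeper sheets use the per-sheet units
    of ``DEFAULT_UNITS`` unless overridden via ``cfg.units``.  With
    ``corrupt_unit_mix`` the first DNA row gets a different unit, which
    spec validation must reject.
    """
    del model  # same cfg produces a matching model; handle kept for symmetry
    rng = random.Random(cfg.seed + 1)
    path = Path(path)
    units = {**DEFAULT_UNITS, **cfg.units}
    tree = cfg.tree

    wb = openpyxl.Workbook()
    wb.remove(wb.active)
    header = list(COMPOSITION_COLUMNS) + [""] + list(MAINTENANCE_COLUMNS)

    for sheet, kids in tree.items():
        ws = wb.create_sheet(sheet)
        ws.append(header)
        unit = units[sheet]
        if kids:
            constituents = list(kids)
            if sheet == "BIOMASS":
                # a plain model metabolite alongside pools is allowed
                constituents.append(cfg.monomer_ids("BIOMASS" if cfg.levels == 1 else "PROTEIN")[0])
        else:
            constituents = cfg.monomer_ids(sheet)
        fractions = _random_split(rng, len(constituents))
        if sheet == "BIOMASS":
            values = [f * cfg.total_mass for f in fractions]
            if unit is Unit.MG_PER_GDW:
                values = [v * 1000.0 for v in values]
            elif unit is Unit.PERCENT_DW_MASS:
                values = [v * 100.0 for v in values]
        elif unit is Unit.PERCENT_MOL:
            values = [f * 100.0 for f in fractions]
        else:
            values = fractions

        rows: list[list] = []
        for mid, value in zip(constituents, values):
            row_unit = unit.value
            if cfg.corrupt_unit_mix and sheet == "DNA" and not rows:
                row_unit = (
                    Unit.G_PER_GDW.value if unit is not Unit.G_PER_GDW else Unit.MOL_PER_MOL.value
                )
            rows.append([mid, mid.rsplit("_", 1)[0].upper(), value, row_unit])

        maint: list[tuple[str, float, str]] = []
        if cfg.include_maintenance:
            if sheet == "BIOMASS":
                maint = _maintenance_rows(20.0, "mmol_per_gDW")
            elif not kids:
                maint = _maintenance_rows(1.5, "mol_per_mol_pool")
        for i in range(max(len(rows), len(maint))):
            left = rows[i] if i < len(rows) else ["", "", "", ""]
            if i < len(maint):
                mid, coeff, munit = maint[i]
                right = [mid, mid[:-2].upper(), coeff, munit]
            else:
                right = ["", "", "", ""]
            ws.append(left + [""] + right)

    path.parent.mkdir(parents=True, exist_ok=True)
    wb.save(str(path))
    return path


def make_composition_tsv(cfg: FixtureConfig, model: ModelHandle, directory: str | Path) -> Path:
    """Same dataset as :func:`make_composition`, in the TSV-directory layout."""
    import tempfile

    from .composition import load_workbook

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with tempfile.TemporaryDirectory() as tmp:
        xlsx = Path(tmp) / "composition.xlsx"
        make_composition(cfg, model, xlsx)
        sheets = load_workbook(xlsx)
    for sheet in sheets:
        lines = ["\t".join(COMPOSITION_COLUMNS)]
        for row in sheet.composition_rows:
            lines.append(
                "\t".join([row["metabolite_id"], row["name"], repr(row["value"]), row["unit"]])
            )
        (directory / f"{sheet.name}.tsv").write_text("\n".join(lines) + "\n")
        if sheet.maintenance_rows:
            mlines = ["\t".join(["metabolite_id", "name", "coefficient", "unit"])]
            for row in sheet.maintenance_rows:
                mlines.append(
                    "\t".join(
                        [row["metabolite_id"], row["name"], repr(row["coefficient"]), row["unit"]]
                    )
                )
            (directory / f"{sheet.name}.maintenance.tsv").write_text("\n".join(mlines) + "\n")
    return directory
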