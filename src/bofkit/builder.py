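"""Convert a validated composition spec into stoichiometric coefficients
and tagged pseudo-reactions, and insert them into (or remove them from) a
model.

Coefficient pipeline
--------------------
* Pool sheets (levels 2-3) are resolved bottom-up into **mole fractions**
  (mol per mol of pool): molar units are normalized to sum 1; mass units
  are first divided by the constituent molar mass.
* The top sheet (level 1) is resolved into **mmol per gDW**: every entry
  is expressed as a mass, the total recovered mass is rescaled to exactly
  1 g of dry weight, and each mass fraction is divided by the component
  molar mass.
* Maintenance rows are never converted or rescaled — their signed values
  (negative = consumed, positive = produced) are applied directly as
  stoichiometric coefficients.

Every generated pseudo-reaction produces exactly 1 unit of its pool
pseudo-metabolite.  Pseudo-metabolite formulas and charges are computed as
the *net* of their producing reaction (sum over consumed species minus sum
over produced species), which makes every generated reaction elementally
and charge balanced by construction whenever all constituent formulas and
charges are known.

Polymers are treated as one monomer long: no condensation water is
subtracted, and any dehydration or energy cost must be supplied as
maintenance rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .chem import Formula, format_formula, molar_mass, weighted_combine
from .composition import BofSpec, MaintenanceUnit, PseudoReactionSpec, Unit
from .errors import ChemistryError, CollisionError, ConversionError, NotFoundError, SpecError
from .gem_io import ModelHandle

logger = logging.getLogger(__name__)

#: total recovered mass outside this window triggers a warning before the
#: normalization to 1 gDW is applied
MASS_RECOVERY_WARN_WINDOW = (0.8, 1.25)

DEFAULT_BOUNDS = (0.0, 1000.0)


@dataclass
class PoolResult:
    """Resolved level 2-3 sheet: mole fractions plus the net pool formula."""

    pool_name: str
    mole_fractions: dict[str, float]
    pool_formula: Formula | None
    pool_molar_mass: float | None
    maintenance_coeffs: dict[str, float] = field(default_factory=dict)
    raw_values: dict[str, tuple[float, str]] = field(default_factory=dict)


@dataclass
class TopResult:
    """Resolved level-1 sheet: final coefficients in mmol per gDW."""

    coefficients: dict[str, float]
    mass_fractions: dict[str, float]
    scale_factor: float
    maintenance_coeffs: dict[str, float] = field(default_factory=dict)
    raw_values: dict[str, tuple[float, str]] = field(default_factory=dict)
    component_molar_masses: dict[str, float] = field(default_factory=dict)


@dataclass
class ReportRow:
    reaction_id: str
    pool_name: str
    species_id: str
    provenance: str  # composition | maintenance | product
    raw_value: float | None
    raw_unit: str
    intermediate: float | None  # mass fraction (g/gDW) or mole fraction
    final_coefficient: float
    final_unit: str


@dataclass
class CoefficientReport:
    """Per-reaction, per-species trace from raw input to final coefficient."""

    rows: list[ReportRow]
    scale_factor: float
    pool_molar_masses: dict[str, float | None]
    tag: str

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(r) for r in self.rows])

    def to_tsv(self, path: str | Path) -> None:
        frame = self.to_frame()
        with open(path, "w") as fh:
            fh.write(f"# tag: {self.tag}\n")
            fh.write(f"# scale_factor: {self.scale_factor!r}\n")
            for pool, mw in self.pool_molar_masses.items():
                fh.write(f"# pool_molar_mass\t{pool}\t{'' if mw is None else repr(mw)}\n")
            frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    def to_xlsx(self, path: str | Path) -> None:
        import openpyxl

        wb = openpyxl.Workbook()
        summary = wb.active
        summary.title = "SUMMARY"
        summary.append(["tag", self.tag])
        summary.append(["scale_factor", self.scale_factor])
        summary.append([])
        summary.append(["pool", "molar_mass_g_per_mol"])
        for pool, mw in self.pool_molar_masses.items():
            summary.append([pool, mw])
        header = [
            "species_id",
            "provenance",
            "raw_value",
            "raw_unit",
            "intermediate",
            "final_coefficient",
            "final_unit",
        ]
        for rid in dict.fromkeys(r.reaction_id for r in self.rows):
            ws = wb.create_sheet(rid[:31])  # sheet-name length cap
            ws.append(header)
            for row in self.rows:
                if row.reaction_id == rid:
                    ws.append(
                        [
                            row.species_id,
                            row.provenance,
                            row.raw_value,
                            row.raw_unit,
                            row.intermediate,
                            row.final_coefficient,
                            row.final_unit,
                        ]
                    )
        wb.save(str(path))


# --------------------------------------------------------------------------
# constituent lookup helpers


def _constituent_formula(
    met_id: str, children: dict[str, PoolResult], model: ModelHandle
) -> Formula | None:
    if met_id in children:
        return children[met_id].pool_formula
    met = model.get_metabolite(met_id)
    return met.formula if met is not None else None


def _constituent_molar_mass(
    met_id: str, children: dict[str, PoolResult], model: ModelHandle
) -> float | None:
    if met_id in children:
        return children[met_id].pool_molar_mass
    met = model.get_metabolite(met_id)
    if met is None or met.formula is None:
        return None
    try:
        return molar_mass(met.formula)
    except ChemistryError:
        return None


def _net_formula(
    consumed: list[tuple[float, str]],
    maintenance: dict[str, float],
    children: dict[str, PoolResult],
    model: ModelHandle,
) -> Formula | None:
    """Net elemental content of a reaction's product pseudo-metabolite:
    sum of consumed species minus sum of produced species."""
    terms: list[tuple[float, Formula]] = []
    for coeff, met_id in consumed:
        f = _constituent_formula(met_id, children, model)
        if f is None:
            return None
        terms.append((coeff, f))
    for met_id, signed in maintenance.items():
        f = _constituent_formula(met_id, children, model)
        if f is None:
            return None
        # signed: negative = consumed (adds to the pool), positive = produced
        terms.append((-signed, f))
    return weighted_combine(terms)


# --------------------------------------------------------------------------
# resolution


def resolve_pool(
    spec: PseudoReactionSpec,
    children: dict[str, PoolResult],
    model: ModelHandle,
) -> PoolResult:
    """Resolve a level 2-3 sheet to mole fractions summing to 1.

    Molar units are normalized directly; mass units are converted to moles
    through the constituent molar mass first (model formula, or the child
    pool's computed molar mass).
    """
    moles: dict[str, float] = {}
    missing_mass: list[str] = []
    for entry in spec.entries:
        if entry.unit.is_mass:
            mw = _constituent_molar_mass(entry.metabolite_id, children, model)
            if mw is None or mw <= 0:
                missing_mass.append(entry.metabolite_id)
                continue
            moles[entry.metabolite_id] = entry.value / mw
        else:
            moles[entry.metabolite_id] = entry.value
    if missing_mass:
        raise ConversionError(
            f"sheet {spec.pool_name!r} uses a mass unit but no molar mass is "
            f"available for: {', '.join(missing_mass)}"
        )
    total = sum(moles.values())
    if total <= 0:
        raise ConversionError(f"sheet {spec.pool_name!r} resolves to an empty pool")
    fractions = {m: v / total for m, v in moles.items()}

    maintenance: dict[str, float] = {}
    for m in spec.maintenance:
        if m.unit is not MaintenanceUnit.MOL_PER_MOL_POOL:
            logger.warning(
                "sheet %r: maintenance row %r is declared in %s on a pool-level "
                "sheet; the value is still applied directly as a coefficient",
                spec.pool_name,
                m.metabolite_id,
                m.unit.value,
            )
        maintenance[m.metabolite_id] = maintenance.get(m.metabolite_id, 0.0) + m.coefficient

    consumed = [(fractions[e.metabolite_id], e.metabolite_id) for e in spec.entries]
    pool_formula = _net_formula(consumed, maintenance, children, model)
    if pool_formula is None:
        logger.warning(
            "sheet %r: formula unknown for at least one species; pool formula "
            "and molar mass left undefined",
            spec.pool_name,
        )
    pool_mw: float | None = None
    if pool_formula is not None:
        try:
            pool_mw = molar_mass(pool_formula)
        except ChemistryError as exc:
            logger.warning("sheet %r: %s", spec.pool_name, exc)
        else:
            if pool_mw <= 0:
                logger.warning(
                    "sheet %r: computed non-positive pool molar mass %g; treating "
                    "as unknown",
                    spec.pool_name,
                    pool_mw,
                )
                pool_mw = None
    return PoolResult(
        pool_name=spec.pool_name,
        mole_fractions=fractions,
        pool_formula=pool_formula,
        pool_molar_mass=pool_mw,
        maintenance_coeffs=maintenance,
        raw_values={e.metabolite_id: (e.value, e.unit.value) for e in spec.entries},
    )


def _entry_mass(entry_value: float, unit: Unit, mw: float | None) -> float | None:
    """Mass in g (per gDW for absolute units; relative otherwise — the
    subsequent normalization makes the distinction irrelevant)."""
    if unit is Unit.G_PER_GDW:
        return entry_value
    if unit is Unit.MG_PER_GDW:
        return entry_value / 1000.0
    if unit is Unit.PERCENT_DW_MASS:
        return entry_value / 100.0
    if mw is None:
        return None
    if unit is Unit.MMOL_PER_GDW:
        return entry_value / 1000.0 * mw
    if unit is Unit.UMOL_PER_GDW:
        return entry_value / 1e6 * mw
    if unit is Unit.MOL_PER_MOL:
        return entry_value * mw
    if unit is Unit.PERCENT_MOL:
        return entry_value / 100.0 * mw
    raise ValueError(f"unhandled unit {unit}")  # pragma: no cover


def resolve_top(
    spec: PseudoReactionSpec,
    pools: dict[str, PoolResult],
    model: ModelHandle,
) -> TopResult:
    """Resolve the level-1 sheet to final coefficients in mmol per gDW.

    Entries are converted to masses, normalized so the total recovered
    mass is exactly 1 g of dry weight (the scale factor is logged, with a
    warning when it falls outside {0.8..1.25}), then divided by molar
    masses.  Maintenance rows pass through unconverted and unscaled.
    """
    masses: dict[str, float] = {}
    mws: dict[str, float] = {}
    missing: list[str] = []
    for entry in spec.entries:
        mw = _constituent_molar_mass(entry.metabolite_id, pools, model)
        if mw is not None:
            mws[entry.metabolite_id] = mw
        mass = _entry_mass(entry.value, entry.unit, mw)
        if mass is None or mw is None:
            missing.append(entry.metabolite_id)
            continue
        masses[entry.metabolite_id] = mass
    if missing:
        raise ConversionError(
            "cannot normalize to 1 gDW: molar mass unknown for top-level "
            f"component(s): {', '.join(missing)}"
        )
    total = sum(masses.values())
    if total <= 0:
        raise ConversionError("total recovered mass is zero; nothing to normalize")
    scale_factor = 1.0 / total
    lo, hi = MASS_RECOVERY_WARN_WINDOW
    if not (lo <= scale_factor <= hi):
        logger.warning(
            "total recovered mass %.4g g per gDW is far from 1 g (scale factor "
            "%.4g); coefficients are normalized to 1 gDW regardless",
            total,
            scale_factor,
        )
    else:
        logger.info("total recovered mass %.6g g per gDW; scale factor %.6g", total, scale_factor)
    mass_fractions = {m: v * scale_factor for m, v in masses.items()}
    coefficients = {m: mass_fractions[m] * 1000.0 / mws[m] for m in mass_fractions}

    maintenance: dict[str, float] = {}
    for m in spec.maintenance:
        if m.unit is not MaintenanceUnit.MMOL_PER_GDW:
            logger.warning(
                "sheet %r: maintenance row %r is declared in %s on the top-level "
                "sheet; the value is still applied directly as a coefficient",
                spec.pool_name,
                m.metabolite_id,
                m.unit.value,
            )
        maintenance[m.metabolite_id] = maintenance.get(m.metabolite_id, 0.0) + m.coefficient

    return TopResult(
        coefficients=coefficients,
        mass_fractions=mass_fractions,
        scale_factor=scale_factor,
        maintenance_coeffs=maintenance,
        raw_values={e.metabolite_id: (e.value, e.unit.value) for e in spec.entries},
        component_molar_masses=mws,
    )


def resolve_all(spec: BofSpec, model: ModelHandle) -> tuple[TopResult, dict[str, PoolResult]]:
    """Resolve every sheet bottom-up (deepest level first)."""
    pool_results: dict[str, PoolResult] = {}
    for pspec in sorted(spec.pools.values(), key=lambda s: -s.level):
        children = {c: pool_results[c] for c in spec.children_of(pspec)}
        pool_results[pspec.pool_name] = resolve_pool(pspec, children, model)
    top = resolve_top(spec.top, pool_results, model)
    return top, pool_results


# --------------------------------------------------------------------------
# availability flags


def check_availability(
    spec: BofSpec,
    model: ModelHandle,
    formulas_available: bool | None,
    charges_available: bool | None,
) -> None:
    """Enforce the user's formula/charge availability assertions.

    ``True`` is a promise: a missing formula/charge on any model metabolite
    consumed in the BOF is then an error, not a warning.  ``False`` or
    ``None`` (auto-detect) never fail here.
    """
    if not formulas_available and not charges_available:
        return
    met_ids = sorted(
        {
            e.metabolite_id
            for s in spec.all_specs()
            for e in s.entries
            if e.metabolite_id not in spec.pools
        }
        | {m.metabolite_id for s in spec.all_specs() for m in s.maintenance}
    )
    failures = []
    for mid in met_ids:
        met = model.get_metabolite(mid)
        if met is None:
            continue
        if formulas_available and not met.formula_string:
            failures.append(f"formula asserted available but missing for {mid!r}")
        if charges_available and met.charge is None:
            failures.append(f"charge asserted available but missing for {mid!r}")
    if failures:
        raise SpecError(failures)


# --------------------------------------------------------------------------
# assembly


def _generated_ids(spec: BofSpec, compartment_suffix: bool) -> dict[str, tuple[str, str]]:
    """pool name -> (metabolite ID, reaction ID)."""
    out = {}
    for s in spec.all_specs():
        base = f"{s.pool_name}_{spec.tag}"
        met_id = f"{base}_{spec.compartment}" if compartment_suffix else base
        out[s.pool_name] = (met_id, base)
    return out


def assemble_bof(
    spec: BofSpec,
    top: TopResult,
    pools: dict[str, PoolResult],
    model: ModelHandle,
    set_objective: bool = False,
    compartment_suffix: bool = False,
) -> CoefficientReport:
    """Create the tagged pseudo-metabolites and pseudo-reactions in place.

    The operation is atomic: all generated IDs are checked for collisions
    before anything is added, so a failure leaves the model untouched.
    Each reaction consumes its constituents at the resolved coefficients,
    applies maintenance rows at their signed values, and produces exactly
    1 unit of its pool pseudo-metabolite with bounds [0, 1000].  The model
    objective is only changed when ``set_objective`` is given.
    """
    ids = _generated_ids(spec, compartment_suffix)
    collisions = []
    for met_id, rxn_id in ids.values():
        if model.get_metabolite(met_id) is not None:
            collisions.append(met_id)
        if model.has_reaction(rxn_id):
            collisions.append(rxn_id)
    if collisions:
        raise CollisionError(
            "generated IDs already exist in the model (pick another tag): "
            + ", ".join(sorted(set(collisions)))
        )

    rows: list[ReportRow] = []
    ordered = spec.all_specs()

    # metabolites first (formulas netted per producing reaction)
    for s in ordered:
        met_id, _ = ids[s.pool_name]
        if s.pool_name in pools:
            result = pools[s.pool_name]
            formula = result.pool_formula
        else:
            consumed = [(coeff, mid) for mid, coeff in top.coefficients.items()]
            formula = _net_formula(consumed, top.maintenance_coeffs, pools, model)
            if formula is None:
                logger.warning(
                    "top sheet %r: formula unknown for at least one species; "
                    "pseudo-metabolite formula left undefined",
                    s.pool_name,
                )
        charge = formula.charge if formula is not None else None
        model.add_pseudo_metabolite(
            met_id,
            name=f"{s.pool_name} pseudo-metabolite ({spec.tag})",
            compartment=spec.compartment,
            formula=formula,
            charge=charge,
        )

    # reactions in sheet order
    for s in ordered:
        met_id, rxn_id = ids[s.pool_name]
        if s.pool_name in pools:
            result = pools[s.pool_name]
            coeffs = result.mole_fractions
            maint = result.maintenance_coeffs
            unit = "mol/mol_pool"
            raw = result.raw_values
            intermediates = result.mole_fractions
        else:
            coeffs = top.coefficients
            maint = top.maintenance_coeffs
            unit = "mmol/gDW"
            raw = top.raw_values
            intermediates = top.mass_fractions
        stoich: dict[str, float] = {}
        for mid, c in coeffs.items():
            target = ids[mid][0] if mid in ids else mid
            stoich[target] = stoich.get(target, 0.0) - c
            rv, ru = raw[mid]
            rows.append(
                ReportRow(rxn_id, s.pool_name, mid, "composition", rv, ru,
                          intermediates[mid], -c, unit)
            )
        for mid, c in maint.items():
            stoich[mid] = stoich.get(mid, 0.0) + c
            rows.append(
                ReportRow(rxn_id, s.pool_name, mid, "maintenance", c,
                          unit, None, c, unit)
            )
        stoich[met_id] = stoich.get(met_id, 0.0) + 1.0
        rows.append(ReportRow(rxn_id, s.pool_name, met_id, "product", None, "", None, 1.0, unit))
        model.add_reaction(
            rxn_id,
            name=f"{s.pool_name} pseudo-reaction ({spec.tag})",
            stoichiometry=stoich,
            lower_bound=DEFAULT_BOUNDS[0],
            upper_bound=DEFAULT_BOUNDS[1],
        )

    if set_objective:
        model.set_objective(ids[spec.top.pool_name][1])

    return CoefficientReport(
        rows=rows,
        scale_factor=top.scale_factor,
        pool_molar_masses={p: r.pool_molar_mass for p, r in pools.items()},
        tag=spec.tag,
    )


def build_bof(
    model: ModelHandle,
    spec: BofSpec,
    set_objective: bool = False,
    compartment_suffix: bool = False,
    formulas_available: bool | None = None,
    charges_available: bool | None = None,
) -> CoefficientReport:
    """End-to-end: availability check, resolution, assembly."""
    check_availability(spec, model, formulas_available, charges_available)
    top, pools = resolve_all(spec, model)
    return assemble_bof(
        spec,
        top,
        pools,
        model,
        set_objective=set_objective,
        compartment_suffix=compartment_suffix,
    )


# --------------------------------------------------------------------------
# removal and flattening


def remove_bof(model: ModelHandle, tag: str) -> None:
    """Remove every reaction suffixed ``_<tag>`` plus the now-orphaned
    pseudo-metabolites with the same suffix; unsets the objective (with a
    warning) if a removed reaction carried it."""
    suffix = f"_{tag}"
    rxn_ids = [r for r in model.reactions if r.endswith(suffix)]
    if not rxn_ids:
        raise NotFoundError(f"no reaction with tag suffix {suffix!r} found in the model")
    objective = model.objective
    if objective in rxn_ids:
        logger.warning(
            "removed reaction %r was the model objective; the objective is now unset",
            objective,
        )
        model.set_objective(None)
    model.remove_reactions(rxn_ids)
    orphaned = [
        m.id
        for m in model.cobra_model.metabolites
        if (m.id.endswith(suffix) or f"{suffix}_" in m.id) and not m.reactions
    ]
    if orphaned:
        model.remove_metabolites(orphaned)


def flatten_bof(
    spec: BofSpec, top: TopResult, pools: dict[str, PoolResult]
) -> dict[str, float]:
    """Collapse the hierarchy into net model-metabolite consumption in mmol
    per gDW (consumption positive, net production negative).

    Pool coefficients multiply through the tree; maintenance rows of pool
    sheets are scaled by their pool's consumption, top-level maintenance
    passes through as-is.
    """
    out: dict[str, float] = {}

    def add(mid: str, amount: float) -> None:
        out[mid] = out.get(mid, 0.0) + amount

    def expand(pool_name: str, rate: float) -> None:
        result = pools[pool_name]
        for mid, frac in result.mole_fractions.items():
            if mid in pools:
                expand(mid, rate * frac)
            else:
                add(mid, rate * frac)
        for mid, c in result.maintenance_coeffs.items():
            add(mid, -c * rate)

    for mid, coeff in top.coefficients.items():
        if mid in pools:
            expand(mid, coeff)
        else:
            add(mid, coeff)
    for mid, c in top.maintenance_coeffs.items():
        add(mid, -c)
    return out
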