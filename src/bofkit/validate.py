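"""Post-generation quality control for tagged pseudo-reaction sets:
elemental/charge balance, a mass-closure audit of the top reaction, and an
LP growth-feasibility check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from optlang.exceptions import SolverError

from .chem import molar_mass
from .errors import ChemistryError, EnvironmentError_, NotFoundError
from .gem_io import ModelHandle

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE = 1e-6


@dataclass
class ReactionBalance:
    reaction_id: str
    element_imbalances: dict[str, float]
    element_status: str  # balanced | imbalanced | unknown
    charge_imbalance: float | None
    charge_status: str
    status: str

    def to_dict(self) -> dict:
        return {
            "reaction_id": self.reaction_id,
            "element_imbalances": self.element_imbalances,
            "element_status": self.element_status,
            "charge_imbalance": self.charge_imbalance,
            "charge_status": self.charge_status,
            "status": self.status,
        }


@dataclass
class BalanceReport:
    tag: str
    reactions: dict[str, ReactionBalance]
    biomass_mass_g: float | None
    top_reaction_id: str | None
    consumed_sums: dict[str, float] = field(default_factory=dict)

    @property
    def all_balanced(self) -> bool:
        return all(r.status == "balanced" for r in self.reactions.values())

    @property
    def any_imbalanced(self) -> bool:
        return any(r.status == "imbalanced" for r in self.reactions.values())

    def to_dict(self) -> dict:
        return {
            "tag": self.tag,
            "top_reaction_id": self.top_reaction_id,
            "biomass_mass_g_per_flux": self.biomass_mass_g,
            "all_balanced": self.all_balanced,
            "reactions": {rid: r.to_dict() for rid, r in self.reactions.items()},
            "consumed_coefficient_sums": self.consumed_sums,
        }

    def to_text(self) -> str:
        lines = [f"balance report for tag {self.tag!r}"]
        for rid, r in self.reactions.items():
            lines.append(f"  {rid}: {r.status}")
            if r.status == "imbalanced":
                bad = {e: v for e, v in r.element_imbalances.items() if v != 0.0}
                lines.append(f"    element imbalances: {bad}")
                if r.charge_status == "imbalanced":
                    lines.append(f"    charge imbalance: {r.charge_imbalance}")
        if self.biomass_mass_g is not None:
            lines.append(f"  biomass mass per unit flux: {self.biomass_mass_g:.9g} g")
        return "\n".join(lines)


def tagged_reactions(model: ModelHandle, tag: str) -> list[str]:
    suffix = f"_{tag}"
    return [rid for rid in model.reactions if rid.endswith(suffix)]


def find_top_reaction(model: ModelHandle, tag: str) -> str:
    """The top reaction of a tagged BOF is the tagged reaction whose
    produced (coefficient +1) tagged pseudo-metabolite is consumed by no
    other tagged reaction."""
    suffix = f"_{tag}"
    rxns = tagged_reactions(model, tag)
    if not rxns:
        raise NotFoundError(f"no reaction with tag suffix {suffix!r} found in the model")
    reactions = model.reactions
    consumed_elsewhere: set[str] = set()
    produced: dict[str, str] = {}
    for rid in rxns:
        for mid, coeff in reactions[rid].stoichiometry.items():
            if suffix in mid:
                if coeff > 0:
                    produced[rid] = mid
                elif coeff < 0:
                    consumed_elsewhere.add(mid)
    tops = [rid for rid, mid in produced.items() if mid not in consumed_elsewhere]
    if len(tops) != 1:
        raise NotFoundError(
            f"cannot identify a unique top reaction for tag {tag!r} (candidates: {tops})"
        )
    return tops[0]


def balance_check(
    model: ModelHandle,
    tag: str,
    tol: float = DEFAULT_TOLERANCE,
    maintenance_ids: dict[str, set[str]] | None = None,
) -> BalanceReport:
    """Check elemental and charge balance of every tagged reaction.

    Per reaction the signed stoichiometry-weighted sum of each element's
    count and of charges is computed independently of how the reaction was
    generated; |net| <= ``tol`` counts as balanced.  A reaction is
    ``unknown`` when some participant lacks a formula (element rows) or a
    charge (charge row) and nothing else failed.

    Also reports the net mass consumed per unit flux of the top reaction
    (substrates minus non-pool products) and, per reaction, the summed
    consumed coefficients — excluding maintenance species when
    ``maintenance_ids`` (reaction ID -> species IDs) is provided.
    """
    rxn_ids = tagged_reactions(model, tag)
    if not rxn_ids:
        raise NotFoundError(f"no reaction with tag suffix '_{tag}' found in the model")
    metabolites = model.metabolites
    reactions = model.reactions
    out: dict[str, ReactionBalance] = {}
    for rid in rxn_ids:
        stoich = reactions[rid].stoichiometry
        element_net: dict[str, float] = {}
        charge_net = 0.0
        formulas_ok = True
        charges_ok = True
        for mid, coeff in stoich.items():
            met = metabolites[mid]
            f = met.formula
            if f is None:
                formulas_ok = False
            else:
                for element, count in f.counts.items():
                    element_net[element] = element_net.get(element, 0.0) + coeff * count
            if met.charge is None:
                charges_ok = False
            else:
                charge_net += coeff * met.charge
        if not formulas_ok:
            element_status = "unknown"
        elif all(abs(v) <= tol for v in element_net.values()):
            element_status = "balanced"
        else:
            element_status = "imbalanced"
        if not charges_ok:
            charge_status = "unknown"
        elif abs(charge_net) <= tol:
            charge_status = "balanced"
        else:
            charge_status = "imbalanced"
        if "imbalanced" in (element_status, charge_status):
            status = "imbalanced"
        elif "unknown" in (element_status, charge_status):
            status = "unknown"
        else:
            status = "balanced"
        out[rid] = ReactionBalance(
            reaction_id=rid,
            element_imbalances=element_net,
            element_status=element_status,
            charge_imbalance=charge_net if charges_ok else None,
            charge_status=charge_status,
            status=status,
        )

    top_rid: str | None
    biomass_mass: float | None = None
    try:
        top_rid = find_top_reaction(model, tag)
    except NotFoundError:
        top_rid = None
    if top_rid is not None:
        suffix = f"_{tag}"
        total = 0.0
        known = True
        for mid, coeff in reactions[top_rid].stoichiometry.items():
            if coeff > 0 and suffix in mid:
                continue  # the produced pool pseudo-metabolite itself
            f = metabolites[mid].formula
            if f is None:
                known = False
                break
            try:
                mw = molar_mass(f)
            except ChemistryError:
                known = False
                break
            total += -coeff * mw / 1000.0
        biomass_mass = total if known else None

    consumed_sums: dict[str, float] = {}
    for rid in rxn_ids:
        skip = (maintenance_ids or {}).get(rid, set())
        consumed_sums[rid] = sum(
            -c for mid, c in reactions[rid].stoichiometry.items() if c < 0 and mid not in skip
        )

    return BalanceReport(
        tag=tag,
        reactions=out,
        biomass_mass_g=biomass_mass,
        top_reaction_id=top_rid,
        consumed_sums=consumed_sums,
    )


def growth_check(model: ModelHandle, tag: str) -> float:
    """Maximal flux through the tagged top reaction under the model's
    existing bounds (FBA).

    Runs on a copy, so the caller's model — objective and bounds included —
    is never modified.  If nothing consumes the top pseudo-metabolite a
    temporary demand reaction is added on the copy so the pool can leave
    the system.  An infeasible LP reports 0.0 (with a log diagnostic)
    rather than raising.
    """
    top_rid = find_top_reaction(model, tag)  # raises NotFoundError if absent
    work = model.copy()
    cmodel = work.cobra_model
    top_rxn = cmodel.reactions.get_by_id(top_rid)
    suffix = f"_{tag}"
    tagged_products = [
        met for met, coeff in top_rxn.metabolites.items() if coeff > 0 and suffix in met.id
    ]
    if not tagged_products:
        raise NotFoundError(f"top reaction {top_rid!r} produces no tagged pseudo-metabolite")
    product = tagged_products[0]
    if all(r.id == top_rid for r in product.reactions):
        demand = cmodel.add_boundary(product, type="demand")
        logger.info("added temporary demand %s for the growth check", demand.id)
    work.set_objective(top_rid)
    try:
        solution = cmodel.optimize()
    except SolverError as exc:  # pragma: no cover - solver missing/broken
        raise EnvironmentError_(f"LP solver failure: {exc}") from exc
    if solution.status != "optimal":
        logger.warning("FBA status %r for tag %r; reporting growth 0", solution.status, tag)
        return 0.0
    return float(solution.objective_value)
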