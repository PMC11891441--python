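"""Read/write genome-scale models (SBML L3+FBC, COBRA-JSON) and expose a
thin, dictionary-like view over metabolites, reactions and compartments.

The handle wraps a :class:`cobra.Model`; cobrapy (backed by libsbml) does
the heavy lifting for both dialects, while this layer adds the contracts
the rest of the package relies on: lazy formula parsing with warnings
instead of load-time failures, exact case-sensitive ID lookup, and an
explicit zero-compartment check.

SBML caveat: the FBC extension stores charges as integers.  Saving a model
whose metabolite charges are not whole numbers to SBML rounds them to the
nearest integer with a warning; COBRA-JSON preserves fractional charges.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import cobra
import cobra.io
from optlang.symbolics import Zero

from .chem import Formula, format_formula, parse_formula
from .errors import FormulaParseError, ModelIOError, ModelValidationError

logger = logging.getLogger(__name__)


class MetaboliteView:
    """Read-mostly view of one model metabolite.

    ``formula`` is parsed lazily: an invalid formula string surfaces as a
    warning (and ``None``) only when the parsed formula is first needed.
    """

    def __init__(self, met: cobra.Metabolite):
        self._met = met
        self._formula_parsed = False
        self._formula: Formula | None = None

    @property
    def id(self) -> str:
        return self._met.id

    @property
    def name(self) -> str:
        return self._met.name or ""

    @property
    def compartment(self) -> str:
        return self._met.compartment

    @property
    def formula_string(self) -> str | None:
        return self._met.formula or None

    @property
    def charge(self) -> float | None:
        return self._met.charge

    @property
    def formula(self) -> Formula | None:
        if not self._formula_parsed:
            self._formula_parsed = True
            raw = self._met.formula
            if raw:
                try:
                    self._formula = parse_formula(raw, charge=self._met.charge)
                except FormulaParseError as exc:
                    logger.warning(
                        "metabolite %s has unparseable formula %r: %s", self.id, raw, exc
                    )
                    self._formula = None
        return self._formula


class ReactionView:
    """Read-mostly view of one model reaction."""

    def __init__(self, rxn: cobra.Reaction):
        self._rxn = rxn

    @property
    def id(self) -> str:
        return self._rxn.id

    @property
    def name(self) -> str:
        return self._rxn.name or ""

    @property
    def stoichiometry(self) -> dict[str, float]:
        return {met.id: coeff for met, coeff in self._rxn.metabolites.items()}

    @property
    def lower_bound(self) -> float:
        return self._rxn.lower_bound

    @property
    def upper_bound(self) -> float:
        return self._rxn.upper_bound

    @property
    def bounds(self) -> tuple[float, float]:
        return self._rxn.bounds


class ModelHandle:
    """Wrapper around a :class:`cobra.Model` with ID-keyed views."""

    def __init__(self, model: cobra.Model):
        self.cobra_model = model

    # -- lookup -----------------------------------------------------------

    @property
    def metabolites(self) -> dict[str, MetaboliteView]:
        return {m.id: MetaboliteView(m) for m in self.cobra_model.metabolites}

    @property
    def reactions(self) -> dict[str, ReactionView]:
        return {r.id: ReactionView(r) for r in self.cobra_model.reactions}

    @property
    def compartments(self) -> dict[str, str]:
        return dict(self.cobra_model.compartments)

    def get_metabolite(self, met_id: str) -> MetaboliteView | None:
        if self.cobra_model.metabolites.has_id(met_id):
            return MetaboliteView(self.cobra_model.metabolites.get_by_id(met_id))
        return None

    def has_reaction(self, rxn_id: str) -> bool:
        return self.cobra_model.reactions.has_id(rxn_id)

    @property
    def objective(self) -> str | None:
        """ID of the (first) reaction with a nonzero objective coefficient."""
        from cobra.util.solver import linear_reaction_coefficients

        coeffs = linear_reaction_coefficients(self.cobra_model)
        for rxn, c in coeffs.items():
            if c != 0:
                return rxn.id
        return None

    def set_objective(self, rxn_id: str | None) -> None:
        if rxn_id is None:
            self.cobra_model.objective = Zero
        else:
            self.cobra_model.objective = self.cobra_model.reactions.get_by_id(rxn_id)

    # -- mutation (used by the builder) -----------------------------------

    def add_pseudo_metabolite(
        self,
        met_id: str,
        name: str,
        compartment: str,
        formula: Formula | None = None,
        charge: float | None = None,
    ) -> None:
        met = cobra.Metabolite(met_id, name=name, compartment=compartment)
        if formula is not None:
            met.formula = format_formula(formula)
        if charge is not None:
            met.charge = charge
        self.cobra_model.add_metabolites([met])

    def add_reaction(
        self,
        rxn_id: str,
        name: str,
        stoichiometry: dict[str, float],
        lower_bound: float = 0.0,
        upper_bound: float = 1000.0,
    ) -> None:
        rxn = cobra.Reaction(rxn_id, name=name)
        rxn.bounds = (lower_bound, upper_bound)
        self.cobra_model.add_reactions([rxn])
        rxn.add_metabolites(
            {self.cobra_model.metabolites.get_by_id(mid): c for mid, c in stoichiometry.items()}
        )

    def remove_reactions(self, rxn_ids: list[str]) -> None:
        rxns = [self.cobra_model.reactions.get_by_id(r) for r in rxn_ids]
        self.cobra_model.remove_reactions(rxns, remove_orphans=False)

    def remove_metabolites(self, met_ids: list[str]) -> None:
        mets = [self.cobra_model.metabolites.get_by_id(m) for m in met_ids]
        self.cobra_model.remove_metabolites(mets)

    def copy(self) -> "ModelHandle":
        return ModelHandle(self.cobra_model.copy())


def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in (".xml", ".sbml"):
        return "sbml"
    raise ModelIOError(
        f"cannot infer model format from {path.name!r}; pass format='sbml' or 'json'"
    )


def load_model(path: str | Path, format: str = "auto") -> ModelHandle:
    """Load a GEM from SBML or COBRA-JSON.

    The model must define at least one compartment; loading never mutates
    the file.  Metabolite formulas are NOT parsed here — bad formula
    strings only surface (as warnings) when a computation needs them.
    """
    path = Path(path)
    if not path.exists():
        raise ModelIOError(f"model file not found: {path}")
    fmt = _detect_format(path, format)
    try:
        if fmt == "json":
            model = cobra.io.load_json_model(str(path))
        elif fmt == "sbml":
            model = cobra.io.read_sbml_model(str(path))
        else:
            raise ModelIOError(f"unknown model format {fmt!r}")
    except ModelIOError:
        raise
    except Exception as exc:
        raise ModelIOError(f"failed to read {fmt.upper()} model from {path}: {exc}") from exc
    if not model.compartments:
        raise ModelValidationError(
            f"model {path.name!r} defines no compartment; a GEM must contain at "
            "least one compartment with an ID"
        )
    return ModelHandle(model)


def save_model(model: ModelHandle, path: str | Path, format: str = "auto") -> None:
    """Write the model; the written file re-loads to an identical handle
    (IDs, stoichiometry, bounds, formulas; charges exactly for JSON,
    rounded to integers for SBML/FBC)."""
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "sbml":
        fractional = [
            m.id
            for m in model.cobra_model.metabolites
            if m.charge is not None and not float(m.charge).is_integer()
        ]
        if fractional:
            logger.warning(
                "SBML/FBC stores integer charges; rounding non-integer charges "
                "of %d metabolite(s): %s",
                len(fractional),
                ", ".join(fractional[:10]),
            )
            model = model.copy()
            for mid in fractional:
                met = model.cobra_model.metabolites.get_by_id(mid)
                met.charge = int(round(met.charge))
    try:
        if fmt == "json":
            cobra.io.save_json_model(model.cobra_model, str(path))
        elif fmt == "sbml":
            cobra.io.write_sbml_model(model.cobra_model, str(path))
        else:
            raise ModelIOError(f"unknown model format {fmt!r}")
    except ModelIOError:
        raise
    except OSError as exc:
        raise ModelIOError(f"cannot write model to {path}: {exc}") from exc


def check_metabolites_exist(model: ModelHandle, ids: list[str]) -> list[str]:
    """Return exactly the IDs absent from the model, preserving input order
    and multiplicity.  Matching is exact and case-sensitive."""
    present = {m.id for m in model.cobra_model.metabolites}
    return [i for i in ids if i not in present]


def infer_availability(model: ModelHandle, met_ids: list[str]) -> tuple[bool, bool]:
    """Auto-detect whether formulas / charges are present for all of
    ``met_ids`` (the user availability flags default to this detection)."""
    formulas = True
    charges = True
    for mid in met_ids:
        met = model.get_metabolite(mid)
        if met is None:
            continue
        if not met.formula_string:
            formulas = False
        if met.charge is None or (isinstance(met.charge, float) and math.isnan(met.charge)):
            charges = False
    return formulas, charges
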