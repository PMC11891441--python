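"""Exception hierarchy shared by all bofkit modules.

Each error class maps to a distinct CLI exit code (see :mod:`bofkit.cli`)
so that scripted callers can branch on the failure category.
"""


class BofkitError(Exception):
    """Base class for all bofkit errors."""


class FormulaParseError(BofkitError):
    """A chemical formula string could not be tokenized."""

    def __init__(self, message: str, token: str | None = None, position: int | None = None):
        super().__init__(message)
        self.token = token
        self.position = position


class ChemistryError(BofkitError):
    """Molar-mass evaluation failed (element without a tabulated weight)."""


class ModelIOError(BofkitError):
    """A model file could not be read or written."""


class ModelValidationError(BofkitError):
    """A loaded model violates a structural requirement (e.g. no compartment)."""


class SchemaError(BofkitError):
    """A composition workbook does not follow the documented table layout."""


class SpecError(BofkitError):
    """Composition data failed semantic validation.

    ``failures`` carries every individual problem found so that a user can
    fix the whole workbook in one pass.
    """

    def __init__(self, failures: list[str]):
        self.failures = list(failures)
        super().__init__(
            "composition data failed validation:\n" + "\n".join(f"  - {f}" for f in self.failures)
        )


class ConversionError(BofkitError):
    """Unit conversion to mole fractions / mmol per gDW is impossible."""


class CollisionError(BofkitError):
    """A generated pseudo-entity ID already exists in the model."""


class NotFoundError(BofkitError):
    """No entity matches the requested tag or identifier."""


class EnvironmentError_(BofkitError):
    """A required runtime facility (LP solver) is unavailable."""


class ConfigError(BofkitError):
    """Invalid command-line / config-file input."""
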