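"""Typed exceptions shared across the package."""


class EaatKitError(Exception):
    """Base class for all package errors."""


class PDBParseError(EaatKitError, ValueError):
    """A PDB record could not be parsed; the message names the offending line."""


class TopologyError(EaatKitError, ValueError):
    """Inconsistent atom content between models of a multi-model file."""


class SelectionError(EaatKitError, KeyError):
    """An atom query matched nothing."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return self.args[0] if self.args else ""


class IntegrityError(EaatKitError, ValueError):
    """An atom query that must be unique matched more than one atom."""


class DegenerateFitError(EaatKitError, ValueError):
    """Superposition fit subset has fewer than 3 points or is collinear."""


class DomainError(EaatKitError, ValueError):
    """An input value is outside the mathematical domain of an operation."""
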