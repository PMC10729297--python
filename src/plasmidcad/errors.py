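"""Exception hierarchy for design parsing, compilation and liquid handling."""

from __future__ import annotations


class PlasmidCadError(Exception):
    """Base class for all package errors."""


class FormatError(PlasmidCadError):
    """A delimited-text table is malformed (e.g. a required column is missing)."""


class IntegrityError(PlasmidCadError):
    """Referential integrity is violated (dangling ids, collisions)."""

    def __init__(self, message: str, offenders: list[str] | None = None):
        super().__init__(message)
        self.offenders = offenders or []


class JunctionError(PlasmidCadError):
    """Adjacent fragments do not share the required homologous overlap."""

    def __init__(self, message: str, left: str = "", right: str = ""):
        super().__init__(message)
        self.pair = (left, right)


class AddressError(PlasmidCadError):
    """A well address is invalid for the plate geometry."""


class InsufficientVolumeError(PlasmidCadError):
    """A transfer would draw a source well below its dead volume."""

    def __init__(self, message: str, well: str = "", shortfall_ul: float = 0.0):
        super().__init__(message)
        self.well = well
        self.shortfall_ul = shortfall_ul


class CompileError(PlasmidCadError):
    """Instruction compilation failed (missing stocks, blocked reactions...)."""

    def __init__(self, message: str, blocked: list[str] | None = None):
        super().__init__(message)
        self.blocked = blocked or []


class VolumeOverflowError(PlasmidCadError):
    """A mix specification cannot fit in the requested total volume."""
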