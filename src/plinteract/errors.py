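"""Exception hierarchy for plinteract."""


class PlinteractError(Exception):
    """Base class for all package errors."""


class PDBParseError(PlinteractError):
    """A PDB line could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class SelectionError(PlinteractError):
    """A ligand selector matched zero or more than one residue."""


class TopologyError(PlinteractError):
    """Inconsistent chemistry, e.g. a hydrogen with no covalent heavy partner."""


class FrameError(PlinteractError):
    """A trajectory MODEL block is inconsistent with its topology."""


class EnergyTableError(PlinteractError):
    """A delimited energy table could not be parsed or is incomplete."""


class AlignmentError(PlinteractError):
    """Too few or degenerate (collinear) atoms for a rigid superposition."""


class GenerationError(PlinteractError):
    """Synthetic scene placement failed after bounded retries."""


class ParameterError(PlinteractError):
    """A generator parameter is outside its safe range (e.g. jitter too large)."""
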