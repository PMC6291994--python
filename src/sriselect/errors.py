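"""Exception hierarchy.

Errors are grouped into three families so that batch drivers (and the CLI)
can map them onto distinct exit codes: parse errors (malformed input files),
geometry errors (degenerate point configurations), and parameter errors
(invalid options or specs).
"""


class SriSelectError(Exception):
    """Base class for all package errors."""


class ParseError(SriSelectError):
    """Malformed input file (PDB record, CSV table, image)."""


class EmptyStructureError(ParseError):
    """No C-alpha atoms remain after filtering."""


class GeometryError(SriSelectError):
    """Degenerate point configuration."""


class DegenerateGeometryError(GeometryError):
    """A frame axis cannot be defined (coincident or collinear points)."""


class InsufficientPointsError(GeometryError):
    """Too few points for the requested operation."""


class ParameterError(SriSelectError):
    """Invalid option value or generator spec."""


class PairingError(ParameterError):
    """No residue pairs shared between two structures."""


class ImageTooSmallError(ParameterError):
    """Image degenerates to zero size after resizing."""


class DivergenceError(SriSelectError):
    """Network training produced a non-finite loss."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training loss became non-finite at epoch {epoch}")
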