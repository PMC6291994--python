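"""Reading and writing C-alpha point clouds in PDB format.

The whole pipeline works on the C-alpha trace of a structure: an ordered
list of (chain, residue number, insertion code, residue name, position)
records. Parsing is delegated to gemmi; a light pre-validation pass adds
line-numbered errors for malformed coordinate fields, which gemmi would
otherwise tolerate silently.

By default every chain of the first MODEL block is read; oligomeric
entries can be restricted with ``chain_filter``. For alternate locations
the first occurrence of an atom wins.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import gemmi
import numpy as np

from .errors import EmptyStructureError, ParseError

__all__ = [
    "ResidueId",
    "CalphaCloud",
    "read_calpha_cloud",
    "write_calpha_cloud",
    "residue_count",
]


class ResidueId(NamedTuple):
    """Identity of a residue: chain, number, insertion code, 3-letter name."""

    chain_id: str
    residue_number: int
    icode: str
    residue_name: str

    def key(self) -> tuple:
        """Identity used for pairing and ALTLOC deduplication (name excluded)."""
        return (self.chain_id, self.residue_number, self.icode)


@dataclass
class CalphaCloud:
    """Ordered C-alpha records of a structure.

    ``positions`` is an (n, 3) float array in Å, row i belonging to
    ``residues[i]``. Order is file order.
    """

    residues: list[ResidueId]
    positions: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.residues) != len(self.positions):
            raise ValueError("residues and positions length mismatch")
        if len(self.positions) and not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates in cloud")

    def __len__(self) -> int:
        return len(self.residues)

    def with_positions(self, positions: np.ndarray, source_label: Optional[str] = None) -> "CalphaCloud":
        """A copy of this cloud with new coordinates, identities preserved."""
        return CalphaCloud(
            residues=list(self.residues),
            positions=np.array(positions, dtype=float),
            source_label=self.source_label if source_label is None else source_label,
        )


def _validate_atom_lines(pdb_text: str) -> None:
    # gemmi is forgiving about garbage in the coordinate columns; reject it
    # here so the error can name the offending line.
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line.rstrip("\r")) < 54:
            raise ParseError(f"line {lineno}: ATOM record too short for coordinates")
        for lo, hi, label in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fieldtxt = line[lo:hi].strip()
            try:
                float(fieldtxt)
            except ValueError:
                raise ParseError(
                    f"line {lineno}: malformed {label} coordinate field {fieldtxt!r}"
                ) from None


def read_calpha_cloud(
    pdb_text: str,
    chain_filter: Optional[Iterable[str]] = None,
    model_index: int = 1,
    source_label: str = "",
) -> CalphaCloud:
    """Parse PDB-format text into a :class:`CalphaCloud`.

    Parameters
    ----------
    pdb_text:
        PDB-format text (LF or CRLF line endings).
    chain_filter:
        If given, only chains with these ids are kept.
    model_index:
        1-based ordinal of the MODEL block to read (default: first).
    source_label:
        Label stored on the returned cloud (e.g. a file name or PDB id).

    Only ATOM records with atom name CA are retained (HETATM CA, such as
    calcium ions, is excluded); one C-alpha per (chain, residue number,
    insertion code), the first ALTLOC occurrence winning.
    """
    _validate_atom_lines(pdb_text)
    try:
        structure = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # gemmi raises RuntimeError
        raise ParseError(f"PDB parse failure: {exc}") from exc
    if len(structure) == 0:
        raise EmptyStructureError("no MODEL block / no atoms in input")
    if not (1 <= model_index <= len(structure)):
        raise ParseError(
            f"model_index {model_index} out of range (file has {len(structure)} model(s))"
        )
    model = structure[model_index - 1]
    wanted = set(chain_filter) if chain_filter is not None else None

    residues: list[ResidueId] = []
    coords: list[tuple[float, float, float]] = []
    seen: set[tuple] = set()
    for chain in model:
        if wanted is not None and chain.name not in wanted:
            continue
        for res in chain:
            if res.het_flag != "A":  # skip HETATM records
                continue
            for atom in res:
                if atom.name != "CA":
                    continue
                rid = ResidueId(
                    chain_id=chain.name,
                    residue_number=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    residue_name=res.name,
                )
                if rid.key() in seen:  # first ALTLOC wins
                    continue
                seen.add(rid.key())
                residues.append(rid)
                coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
                break  # at most one CA per residue
    if not residues:
        raise EmptyStructureError(
            "no C-alpha atoms after chain/model filtering"
        )
    return CalphaCloud(residues=residues, positions=np.array(coords), source_label=source_label)


def write_calpha_cloud(cloud: CalphaCloud) -> str:
    """Serialize a cloud as PDB-format text (CA records only).

    Coordinates are written in the fixed 8.3 columns, so a round trip
    preserves positions to 1e-3 Å.
    """
    out = io.StringIO()
    for serial, (rid, pos) in enumerate(zip(cloud.residues, cloud.positions), start=1):
        out.write(
            "ATOM  {serial:>5d}  CA  {resname:>3s} {chain:1s}{resnum:>4d}{icode:1s}"
            "   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {elem:>2s}\n".format(
                serial=serial % 100000,
                resname=rid.residue_name[:3],
                chain=(rid.chain_id or "A")[:1],
                resnum=rid.residue_number,
                icode=rid.icode[:1] if rid.icode else " ",
                x=pos[0], y=pos[1], z=pos[2],
                occ=1.0, b=0.0, elem="C",
            )
        )
    out.write("END\n")
    return out.getvalue()


def residue_count(cloud: CalphaCloud) -> int:
    """Number of retained C-alpha records."""
    return len(cloud)
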