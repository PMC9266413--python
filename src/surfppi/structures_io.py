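"""Reading and writing atomic protein structures.

Parses PDB files into :class:`AtomCloud` objects — plain, validated containers
of atomic records — and encodes chemical elements over a fixed six-class
palette ``{C, N, O, S, H, other}``. Waters are always dropped; HETATM records
(ligands, ions, degrader molecules) are excluded by default and can be opted
in as "other" atoms. Alternate locations are resolved to the highest-occupancy
conformer (first-listed on ties). Hydrogens are kept when the deposition
contains them; none are ever added. Coordinates are Angstrom throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "ELEMENT_PALETTE",
    "Atom",
    "AtomCloud",
    "ProteinPair",
    "PDBParseError",
    "EmptySelectionError",
    "read_pdb",
    "write_pdb",
    "encode_elements",
]

#: Fixed element palette; index 5 is the catch-all "other" class.
ELEMENT_PALETTE: tuple[str, ...] = ("C", "N", "O", "S", "H", "other")

_PALETTE_INDEX = {e: i for i, e in enumerate(ELEMENT_PALETTE[:-1])}
_OTHER_CODE = len(ELEMENT_PALETTE) - 1


class PDBParseError(ValueError):
    """A PDB record could not be parsed; the message names the line number."""


class EmptySelectionError(ValueError):
    """Chain/record filtering left zero atoms."""


@dataclass(frozen=True)
class Atom:
    """One atomic record of a structure (position in Angstrom)."""

    element: str
    atom_name: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("Atom.element must be non-empty")
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name!r}")


def _element_code(element: str) -> int:
    return _PALETTE_INDEX.get(element.upper().strip(), _OTHER_CODE)


@dataclass
class AtomCloud:
    """An ordered set of atoms from one protein (or chain selection).

    Array views (``positions``, ``element_codes``) are derived once and
    cached; the ``atoms`` list is the source of truth.
    """

    atoms: list[Atom]
    _positions: np.ndarray | None = field(default=None, repr=False, compare=False)
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError("AtomCloud requires at least one atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) float64 coordinates in Angstrom."""
        if self._positions is None:
            self._positions = np.array([a.position for a in self.atoms], dtype=np.float64)
        return self._positions

    @property
    def element_codes(self) -> np.ndarray:
        """(N,) int indices into :data:`ELEMENT_PALETTE`."""
        if self._codes is None:
            self._codes = np.array([_element_code(a.element) for a in self.atoms], dtype=np.int64)
        return self._codes

    @property
    def residue_names(self) -> list[str]:
        return [a.residue_name for a in self.atoms]

    def translated(self, shift: Sequence[float]) -> "AtomCloud":
        """Return a copy rigidly translated by ``shift`` (Angstrom)."""
        s = np.asarray(shift, dtype=float)
        atoms = [
            Atom(a.element, a.atom_name, a.residue_name, a.residue_seq, a.chain_id,
                 tuple(np.asarray(a.position) + s))
            for a in self.atoms
        ]
        return AtomCloud(atoms)


@dataclass
class ProteinPair:
    """Two atom clouds considered as a candidate interacting pair."""

    a: AtomCloud
    b: AtomCloud
    id_a: str = "A"
    id_b: str = "B"


def _validate_coordinate_columns(path: Path) -> None:
    """Pre-scan ATOM/HETATM records so parse errors can name the line."""
    with open(path, "r", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"line {lineno}: truncated ATOM/HETATM record")
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBParseError(
                        f"line {lineno}: unparseable coordinate field {line[lo:hi]!r}"
                    ) from None


def _resolve_altlocs(records: list[tuple[str, float, Atom]]) -> list[Atom]:
    """Keep one conformer per (chain, resseq, resname, atom name).

    Highest occupancy wins; ties go to the first-listed record. Input order
    is preserved for the surviving atoms.
    """
    best: dict[tuple, tuple[int, float, Atom]] = {}
    order: list[tuple] = []
    for listed, (altloc, occ, atom) in enumerate(records):
        key = (atom.chain_id, atom.residue_seq, atom.residue_name, atom.atom_name)
        if key not in best:
            best[key] = (listed, occ, atom)
            order.append(key)
        elif occ > best[key][1]:
            best[key] = (best[key][0], occ, atom)  # keep original slot
    return [best[k][2] for k in order]


def read_pdb(
    path: str | Path,
    chains: Iterable[str] | None = None,
    include_hetatm: bool = False,
) -> AtomCloud:
    """Parse a PDB file into an :class:`AtomCloud`.

    Parameters
    ----------
    path
        PDB file with fixed-column ATOM/HETATM records.
    chains
        Author chain IDs to keep; ``None`` keeps all chains.
    include_hetatm
        When True, non-water HETATM records are kept (elements typically map
        to the "other" palette class). Waters are always excluded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")
    _validate_coordinate_columns(path)
    try:
        structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi is lenient
        raise PDBParseError(f"{path}: {exc}") from exc

    wanted = set(chains) if chains is not None else None
    records: list[tuple[str, float, Atom]] = []
    seen_chains: set[str] = set()
    if len(structure) == 0:
        raise EmptySelectionError(f"{path}: no models in file")
    model = structure[0]
    for chain in model:
        seen_chains.add(chain.name)
        if wanted is not None and chain.name not in wanted:
            continue
        for residue in chain:
            if residue.is_water():
                continue
            if residue.het_flag == "H" and not include_hetatm:
                continue
            for atom in residue:
                rec = Atom(
                    element=atom.element.name,
                    atom_name=atom.name,
                    residue_name=residue.name,
                    residue_seq=residue.seqid.num,
                    chain_id=chain.name,
                    position=(atom.pos.x, atom.pos.y, atom.pos.z),
                )
                records.append((atom.altloc, atom.occ, rec))
    atoms = _resolve_altlocs(records)
    if not atoms:
        detail = ""
        if wanted is not None and not (wanted & seen_chains):
            detail = f" (requested chains {sorted(wanted)}, file has {sorted(seen_chains)})"
        raise EmptySelectionError(f"{path}: no atoms after filtering{detail}")
    return AtomCloud(atoms)


def write_pdb(cloud: AtomCloud, path: str | Path) -> None:
    """Serialize an atom cloud as plain ATOM records (deterministic output).

    gemmi copies objects on ``add_*``, so residues are fully assembled before
    being attached to their chain.
    """
    structure = gemmi.Structure()
    model = gemmi.Model("1")
    chain_order: list[str] = []
    per_chain: dict[str, list[gemmi.Residue]] = {}
    current: dict[str, tuple] = {}
    for atom in cloud.atoms:
        cid = atom.chain_id
        key = (cid, atom.residue_seq, atom.residue_name)
        if cid not in per_chain:
            per_chain[cid] = []
            chain_order.append(cid)
            current[cid] = None
        if current[cid] != key:
            res = gemmi.Residue()
            res.name = atom.residue_name
            res.seqid = gemmi.SeqId(atom.residue_seq, " ")
            res.het_flag = "A"
            per_chain[cid].append(res)
            current[cid] = key
        ga = gemmi.Atom()
        ga.name = atom.atom_name
        ga.element = gemmi.Element(atom.element)
        ga.pos = gemmi.Position(*atom.position)
        ga.occ = 1.0
        ga.b_iso = 0.0
        per_chain[cid][-1].add_atom(ga)
    for cid in chain_order:
        chain = gemmi.Chain(cid)
        for res in per_chain[cid]:
            chain.add_residue(res)
        model.add_chain(chain)
    structure.add_model(model)
    with open(path, "w") as fh:
        fh.write(structure.make_pdb_string())


def encode_elements(cloud: AtomCloud) -> np.ndarray:
    """One-hot encode elements over ``{C, N, O, S, H, other}``.

    Returns an (N, 6) float array with exactly one 1 per row; elements outside
    the palette (e.g. Se, Zn) map to the trailing "other" class.
    """
    codes = cloud.element_codes
    onehot = np.zeros((cloud.n_atoms, len(ELEMENT_PALETTE)), dtype=np.float64)
    onehot[np.arange(cloud.n_atoms), codes] = 1.0
    return onehot
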