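"""Chain-level heavy-atom model of protein structures, with PDB input/output.

The in-memory model is deliberately small: a :class:`Chain` is an ordered list
of :class:`Residue` objects, each holding named heavy :class:`Atom` records.
Reading goes through Bio.PDB (first model only, one chain, ATOM records);
hydrogens, waters, HETATM groups and OXT are discarded, alternate locations
are resolved to a single conformer, and MSE is mapped to MET.  Writing emits
plain fixed-width ATOM records at standard PDB precision (3 decimals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np

log = logging.getLogger(__name__)

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU "
    "LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: nonstandard residues mapped onto a standard parent instead of being dropped
RESIDUE_NAME_MAP = {"MSE": "MET"}
#: atom renames that accompany a residue mapping (selenium -> sulfur)
_ATOM_NAME_MAP = {("MSE", "SE"): ("SD", "S")}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Atom:
    """A single heavy atom: PDB atom name, element and coordinates in Å."""

    name: str
    element: str
    coords: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.name!r}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: non-finite coordinates")
        if not self.name:
            raise ValueError("atom name must be non-empty")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coords.copy(),
                    self.altloc, self.occupancy)


@dataclass
class Residue:
    """One residue: 3-letter type, author sequence number, heavy atoms."""

    res_type: str
    seq_index: int
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def __contains__(self, name: str) -> bool:
        return self.atom(name) is not None

    def copy(self) -> "Residue":
        return Residue(self.res_type, self.seq_index,
                       [a.copy() for a in self.atoms])


@dataclass
class Chain:
    """An ordered protein chain.

    Residues are kept sorted by ``seq_index`` so that downstream sequence
    separation is computed on ordinal rank, immune to file ordering and
    numbering gaps.
    """

    chain_id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("chain must contain at least one residue")
        self.residues = sorted(self.residues, key=lambda r: r.seq_index)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])

    def coords(self) -> np.ndarray:
        """All atom coordinates as an (n_atoms, 3) array, in chain order."""
        return np.array([a.coords for r in self.residues for a in r.atoms])

    def with_coords(self, coords: np.ndarray) -> "Chain":
        """Copy of the chain with every atom coordinate replaced, in order."""
        coords = np.asarray(coords, dtype=float)
        out = self.copy()
        i = 0
        for res in out.residues:
            for atom in res.atoms:
                atom.coords = coords[i].copy()
                i += 1
        if i != len(coords):
            raise ValueError("coordinate array length mismatch")
        return out

    def transformed(self, rotation: Optional[np.ndarray] = None,
                    translation: Optional[np.ndarray] = None) -> "Chain":
        """Rigid-body transformed copy (rotation applied first)."""
        xyz = self.coords()
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, dtype=float)
        return self.with_coords(xyz)


def _resolve_altloc(entry) -> object:
    """Pick one conformer of a possibly disordered Bio.PDB atom.

    Highest occupancy wins; ties fall back to altloc code order.
    """
    if not entry.is_disordered():
        return entry
    children = sorted(
        entry.disordered_get_list(),
        key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
    )
    return children[0]


def read_structure(path, chain_id: Optional[str] = None) -> Chain:
    """Read one chain from a PDB file as a filtered heavy-atom :class:`Chain`.

    Parameters
    ----------
    path:
        PDB file to read (first MODEL only).
    chain_id:
        Chain identifier; when ``None`` the first chain is used.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        If the requested chain is missing or empty after filtering.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))

    structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    models = list(structure.get_models())
    if not models:
        raise ValueError(f"{path}: no model records")
    model = models[0]

    chains = {c.id: c for c in model}
    if not chains:
        raise ValueError(f"{path}: no chains")
    if chain_id is None:
        raw_chain = next(iter(chains.values()))
    elif chain_id in chains:
        raw_chain = chains[chain_id]
    else:
        raise ValueError(
            f"{path}: chain {chain_id!r} not found (have {sorted(chains)})")

    residues: list[Residue] = []
    for res in raw_chain:
        hetfield, resseq, _icode = res.id
        resname = res.get_resname().strip()
        if resname in RESIDUE_NAME_MAP:
            mapped = RESIDUE_NAME_MAP[resname]
        elif hetfield != " ":
            continue  # water / HETATM
        elif resname not in STANDARD_RESIDUES:
            log.warning("%s: dropping nonstandard residue %s %d",
                        path.name, resname, resseq)
            continue
        else:
            mapped = resname

        atoms: list[Atom] = []
        seen: set[str] = set()
        for entry in res:
            batom = _resolve_altloc(entry)
            name = batom.get_name().strip()
            element = (batom.element or "").strip().upper()
            if element in ("H", "D"):
                continue
            if name == "OXT":
                continue  # terminal oxygen is not part of any representation
            if (resname, name) in _ATOM_NAME_MAP:
                name, element = _ATOM_NAME_MAP[(resname, name)]
            if name in seen:
                continue
            seen.add(name)
            atoms.append(Atom(
                name=name,
                element=element or name[0],
                # PDB stores 3 decimals; rounding drops float32 parse noise
                coords=np.round(np.asarray(batom.get_coord(), dtype=float), 3),
                altloc=(batom.get_altloc() or "").strip(),
                occupancy=float(batom.get_occupancy() or 1.0),
            ))
        if atoms:
            residues.append(Residue(mapped, int(resseq), atoms))

    if not residues:
        raise ValueError(f"{path}: chain empty after filtering")
    return Chain(raw_chain.id or "A", residues)


def write_structure(chain: Chain, path) -> None:
    """Write a :class:`Chain` as a minimal single-chain PDB file."""
    if len(chain) == 0:
        raise ValueError("refusing to write an empty chain")
    cid = (chain.chain_id or "A")[0]
    lines = []
    serial = 1
    for res in chain:
        for atom in res.atoms:
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            x, y, z = atom.coords
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} {res.res_type:>3s} "
                f"{cid}{res.seq_index:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
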