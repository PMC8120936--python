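"""Projection of chains onto structural representations.

A representation selects which points of a chain take part in pairwise
scoring: single atoms (CA, CB, backbone, side chains, all heavy atoms),
unions of those, or MARTINI-style coarse-grained beads (one backbone bead
per residue plus up to four side-chain beads placed at centroids of fixed
atom groups).  Each selected point becomes a :class:`Site` carrying the
(residue type, site label) pair used as its statistical class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from itertools import combinations_with_replacement

import numpy as np

from .structure_io import BACKBONE_ATOMS, STANDARD_RESIDUES, Chain, Residue

log = logging.getLogger(__name__)

REPRESENTATIONS = (
    "CA", "CB", "CA_CB", "BACKBONE", "BACKBONE_CB",
    "SIDECHAINS", "ALL_ATOM", "BB", "SC", "BB_SC",
)
BEAD_REPRESENTATIONS = frozenset({"BB", "SC", "BB_SC"})
GLYCINE_POLICIES = ("substitute_ca", "exclude")
REFERENCE_MODES = ("all_atom_prior", "representation_prior")

#: canonical heavy-atom composition of the 20 standard residues (side chains;
#: every residue additionally has the N/CA/C/O backbone)
SIDECHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}


@dataclass(frozen=True)
class RepresentationSpec:
    """Which sites a chain is projected onto, plus glycine/reference policy."""

    name: str
    glycine_policy: str = "substitute_ca"
    reference_mode: str = "all_atom_prior"

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", self.name.upper())
        if self.name not in REPRESENTATIONS:
            raise ValueError(
                f"unknown representation {self.name!r}; "
                f"valid options: {', '.join(REPRESENTATIONS)}")
        if self.glycine_policy not in GLYCINE_POLICIES:
            raise ValueError(
                f"unknown glycine policy {self.glycine_policy!r}; "
                f"valid options: {', '.join(GLYCINE_POLICIES)}")
        if self.reference_mode not in REFERENCE_MODES:
            raise ValueError(
                f"unknown reference mode {self.reference_mode!r}; "
                f"valid options: {', '.join(REFERENCE_MODES)}")

    @property
    def is_bead(self) -> bool:
        return self.name in BEAD_REPRESENTATIONS

    def prior_spec(self) -> "RepresentationSpec":
        """Representation whose pooled pairs train the reference state."""
        if self.reference_mode == "representation_prior":
            return self
        prior = "BB_SC" if self.is_bead else "ALL_ATOM"
        return RepresentationSpec(prior, self.glycine_policy, self.reference_mode)


@dataclass(frozen=True)
class Site:
    """One scoring point produced by projection."""

    coords: np.ndarray
    res_type: str
    site_label: str
    seq_ordinal: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords",
                           np.asarray(self.coords, dtype=float))
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("site coordinates must be finite")


# PairKey: canonical unordered pair of (res_type, site_label) tuples.
PairKey = tuple[tuple[str, str], tuple[str, str]]


def canonical_pair_key(a: Site, b: Site) -> PairKey:
    """Order-independent statistical class of a site pair."""
    ta, tb = (a.res_type, a.site_label), (b.res_type, b.site_label)
    return (ta, tb) if ta <= tb else (tb, ta)


def pair_key_from_types(ta: tuple[str, str], tb: tuple[str, str]) -> PairKey:
    return (ta, tb) if ta <= tb else (tb, ta)


@lru_cache(maxsize=1)
def bead_table() -> dict[str, tuple[tuple[str, tuple[str, ...]], ...]]:
    """Residue -> ordered (bead label, atom group) pairs, from packaged data."""
    text = (resources.files("pairpot") / "data" / "martini_beads.tsv").read_text()
    table: dict[str, list[tuple[str, tuple[str, ...]]]] = {
        r: [] for r in STANDARD_RESIDUES}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        res, bead, atoms = line.split("\t")
        table[res].append((bead, tuple(atoms.split(","))))
    return {r: tuple(v) for r, v in table.items()}


_ATOM_ORDER = {name: i for i, name in enumerate(BACKBONE_ATOMS + ("CB",))}


def _selected_atoms(res_type: str, available: set[str],
                    spec: RepresentationSpec) -> list[tuple[str, str]]:
    """(site_label, atom_name) selections for one residue, deduplicated.

    ``available`` is the set of atom names to draw from — actual atoms when
    projecting, the canonical composition when enumerating classes.  Glycine
    under ``substitute_ca`` satisfies a CB selector with its CA; the dict
    keyed by label collapses the duplicate when CA is also selected directly.
    """
    name = spec.name
    wants_backbone = name in ("BACKBONE", "BACKBONE_CB", "ALL_ATOM")
    wants_ca = wants_backbone or name in ("CA", "CA_CB")
    wants_cb = name in ("CB", "CA_CB", "BACKBONE_CB")
    wants_sidechain = name in ("SIDECHAINS", "ALL_ATOM")

    selected: dict[str, str] = {}
    if wants_backbone:
        for a in BACKBONE_ATOMS:
            if a in available:
                selected[a] = a
    elif wants_ca:
        if "CA" in available:
            selected["CA"] = "CA"
    if wants_cb:
        if res_type == "GLY":
            if spec.glycine_policy == "substitute_ca" and "CA" in available:
                selected["CA"] = "CA"
        elif "CB" in available:
            selected["CB"] = "CB"
    if wants_sidechain:
        for a in sorted(available - set(BACKBONE_ATOMS)):
            selected[a] = a

    # stable order: backbone atoms first, then CB, then remaining names
    return sorted(selected.items(),
                  key=lambda kv: (_ATOM_ORDER.get(kv[0], len(_ATOM_ORDER)),
                                  kv[0]))


def project(chain: Chain, spec: RepresentationSpec) -> list[Site]:
    """Project a chain onto the sites of ``spec``, preserving residue order.

    Missing atoms are skipped silently (their absence is reported in the
    debug log); unknown residue types are skipped with a warning.
    """
    if spec.is_bead:
        return project_beads(chain, spec)
    sites: list[Site] = []
    n_missing = 0
    for ordinal, res in enumerate(chain):
        if res.res_type not in STANDARD_RESIDUES:
            log.warning("skipping unknown residue type %s", res.res_type)
            continue
        available = {a.name for a in res.atoms}
        expected = _selected_atoms(
            res.res_type,
            set(SIDECHAIN_ATOMS[res.res_type]) | set(BACKBONE_ATOMS),
            spec)
        n_missing += sum(1 for _, a in expected if a not in available)
        for label, atom_name in _selected_atoms(res.res_type, available, spec):
            atom = res.atom(atom_name)
            sites.append(Site(atom.coords, res.res_type, label, ordinal))
    if n_missing:
        log.debug("projection %s: %d expected atoms missing in chain %s",
                  spec.name, n_missing, chain.chain_id)
    return sites


def project_beads(chain: Chain, spec: RepresentationSpec) -> list[Site]:
    """MARTINI-style bead projection (BB / SC / BB_SC).

    The backbone bead sits at the centroid of the N/CA/C/O atoms present;
    each side-chain bead at the centroid of its mapped atom group.  Beads
    with no mapped atom present are skipped.
    """
    if not spec.is_bead:
        raise ValueError(f"{spec.name} is not a bead representation")
    table = bead_table()
    sites: list[Site] = []
    for ordinal, res in enumerate(chain):
        if res.res_type not in STANDARD_RESIDUES:
            log.warning("skipping unknown residue type %s", res.res_type)
            continue
        if spec.name in ("BB", "BB_SC"):
            coords = [res.atom(a).coords for a in BACKBONE_ATOMS
                      if res.atom(a) is not None]
            if coords:
                sites.append(Site(np.mean(coords, axis=0), res.res_type,
                                  "BB", ordinal))
        if spec.name in ("SC", "BB_SC"):
            for bead, group in table[res.res_type]:
                coords = [res.atom(a).coords for a in group
                          if res.atom(a) is not None]
                if coords:
                    sites.append(Site(np.mean(coords, axis=0), res.res_type,
                                      bead, ordinal))
    return sites


def single_site_types(spec: RepresentationSpec) -> set[tuple[str, str]]:
    """All (res_type, site_label) classes a spec can emit, over the 20 types."""
    types: set[tuple[str, str]] = set()
    for res in sorted(STANDARD_RESIDUES):
        if spec.is_bead:
            if spec.name in ("BB", "BB_SC"):
                types.add((res, "BB"))
            if spec.name in ("SC", "BB_SC"):
                for bead, _group in bead_table()[res]:
                    types.add((res, bead))
        else:
            available = set(SIDECHAIN_ATOMS[res]) | set(BACKBONE_ATOMS)
            for label, _atom in _selected_atoms(res, available, spec):
                types.add((res, label))
    return types


def enumerate_pair_classes(spec: RepresentationSpec) -> int:
    """Number of distinct pair classes under a spec.

    Counts unordered pairs with self-pairs included, by generating the full
    key set rather than by closed formula.
    """
    types = sorted(single_site_types(spec))
    keys = {pair_key_from_types(a, b)
            for a, b in combinations_with_replacement(types, 2)}
    return len(keys)
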