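"""Seeded synthetic protein-like structures and decoy ladders.

Chains are built from ideal peptide geometry (NeRF internal-coordinate
placement) with helix, strand or mixed backbone dihedrals; each residue
carries N/CA/C/O, a CB (except glycine) and — beyond alanine — one pseudo
side-chain atom extended along the CA->CB axis, so that side-chain and bead
representations have distinct content.  Decoys are Gaussian coordinate
perturbations of a native with TM-score ground truth attached.  Everything
is fully determined by its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .similarity import tm_score
from .structure_io import Atom, Chain, Residue

AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

# ideal backbone internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8

_PHI_PSI = {"helix": (-57.0, -47.0), "strand": (-120.0, 120.0)}

# Segment layout per fold: (segment dihedrals, segment lengths, alternating
# two-residue turns).  Turn dihedrals were chosen so that segments pack into
# compact, clash-free folds (helix bundle, strand meander, mixed sandwich)
# instead of extended rods — graded decoys then destroy genuine tertiary
# contacts rather than just local geometry.
_FOLD_LAYOUT: dict[str, tuple[tuple, tuple, tuple]] = {
    "helix": ((_PHI_PSI["helix"],), (12,),
              (((80.0, -100.0), (-60.0, -60.0)),
               ((80.0, -100.0), (-60.0, -60.0)))),
    "strand": ((_PHI_PSI["strand"],), (8,),
               (((60.0, 60.0), (60.0, 30.0)),
                ((80.0, -100.0), (-60.0, -30.0)))),
    "mixed": ((_PHI_PSI["helix"], _PHI_PSI["strand"]), (10, 8),
              (((80.0, -100.0), (-60.0, -60.0)),
               ((90.0, 0.0), (80.0, -100.0)))),
}

#: name and CB-extension distance (Å) of the single pseudo side-chain atom
#: placed beyond CB; chosen so the atom name maps into the bead table groups
_PSEUDO_SIDECHAIN: dict[str, tuple[str, float]] = {
    "ARG": ("CG", 4.1), "ASN": ("CG", 1.9), "ASP": ("CG", 1.9),
    "CYS": ("SG", 1.4), "GLN": ("CG", 2.6), "GLU": ("CG", 2.5),
    "HIS": ("CG", 2.4), "ILE": ("CG1", 1.8), "LEU": ("CG", 2.0),
    "LYS": ("CG", 3.4), "MET": ("CG", 2.9), "PHE": ("CG", 2.9),
    "PRO": ("CG", 1.3), "SER": ("OG", 1.0), "THR": ("OG1", 1.2),
    "TRP": ("CG", 3.2), "TYR": ("CG", 3.4), "VAL": ("CG1", 1.2),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic chain."""

    n_residues: int
    sequence: str = "random"   # residue-type string "ALA,GLY,..." or "random"
    fold: str = "mixed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError("n_residues must be >= 4")
        if self.fold not in ("helix", "strand", "mixed"):
            raise ValueError("fold must be helix, strand or mixed")


@dataclass(frozen=True)
class DecoyLadderSpec:
    """Parameters of a graded noise ladder around one native chain."""

    noise_sigmas: tuple[float, ...]
    n_decoys_per_sigma: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        sig = tuple(float(s) for s in self.noise_sigmas)
        object.__setattr__(self, "noise_sigmas", sig)
        if any(s <= 0 for s in sig) or list(sig) != sorted(set(sig)):
            raise ValueError("sigmas must be positive and strictly increasing")
        if self.n_decoys_per_sigma < 1:
            raise ValueError("n_decoys_per_sigma must be >= 1")


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float
                ) -> np.ndarray:
    """NeRF placement of atom D from reference atoms A-B-C."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _virtual_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    # standard virtual-CB construction from the backbone frame
    b = ca - n
    cdir = c - ca
    a = np.cross(b, cdir)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cdir + ca


def _dihedrals(fold: str, n_residues: int) -> list[tuple[float, float]]:
    segs, seglens, turns = _FOLD_LAYOUT[fold]
    out: list[tuple[float, float]] = []
    si = 0
    while len(out) < n_residues:
        out.extend([segs[si % len(segs)]] * seglens[si % len(seglens)])
        out.extend(turns[si % len(turns)])
        si += 1
    return out[:n_residues]


# residue pools for structure-aware random sequences; their union covers
# all 20 types (GLY/PRO enter through turns)
_HYDROPHOBIC = ("ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "CYS")
_POLAR = ("SER", "THR", "ASN", "GLN", "ASP", "GLU", "LYS", "ARG", "HIS", "TYR")
_TURN_POOL = ("GLY", "PRO", "ASN", "ASP", "SER", "THR")
#: probability that a buried position draws hydrophobic (exposed: polar)
_BURIAL_COUPLING = 0.95


def _random_sequence(dihedrals: list[tuple[float, float]],
                     ca_trace: np.ndarray,
                     rng: np.random.Generator) -> list[str]:
    """Seeded random sequence with native-like sequence-structure coupling.

    Buried positions (many CA neighbors) draw mostly from the hydrophobic
    pool, exposed ones from the polar pool, turn positions from a
    glycine/proline-rich pool — mirroring the composition bias that makes
    residue types informative about pair distances in real proteins.
    """
    n = len(ca_trace)
    d = np.linalg.norm(ca_trace[:, None] - ca_trace[None, :], axis=-1)
    sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    neighbors = ((d < 8.0) & (sep >= 3)).sum(axis=1)
    burial_cut = np.median(neighbors)
    regular = set(_PHI_PSI.values())
    seq = []
    for i in range(n):
        if tuple(dihedrals[i]) not in regular:
            pool = _TURN_POOL
        elif neighbors[i] >= burial_cut:
            pool = _HYDROPHOBIC if rng.random() < _BURIAL_COUPLING else _POLAR
        else:
            pool = _POLAR if rng.random() < _BURIAL_COUPLING else _HYDROPHOBIC
        seq.append(pool[rng.integers(0, len(pool))])
    return seq


def _parse_sequence(spec: FixtureSpec, rng: np.random.Generator) -> list[str]:
    tokens = spec.sequence.replace(",", " ").split()
    if len(tokens) == 1 and spec.n_residues > 1:
        tokens = tokens * spec.n_residues
    if len(tokens) != spec.n_residues:
        raise ValueError("sequence length does not match n_residues")
    bad = [t for t in tokens if t not in AMINO_ACIDS]
    if bad:
        raise ValueError(f"invalid residue codes: {bad}")
    return tokens


def make_chain(spec: FixtureSpec, jitter: float = 0.0,
               rng: Optional[np.random.Generator] = None) -> Chain:
    """Build an ideal-geometry chain for ``spec``.

    ``jitter`` adds seeded Gaussian displacement (Å sd) to every atom, used
    by :func:`make_training_set` to diversify otherwise identical folds.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    dihedrals = _dihedrals(spec.fold, spec.n_residues)

    # backbone first: sequence assignment may depend on the CA trace
    backbone: list[tuple[np.ndarray, ...]] = []
    prev_n = prev_ca = prev_c = None
    for i in range(spec.n_residues):
        phi, psi = dihedrals[i]
        if i == 0:
            n = np.zeros(3)
            ca = np.array([_B_N_CA, 0.0, 0.0])
            ang = math.radians(_A_N_CA_C)
            c = ca + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
        else:
            n = _place_atom(prev_n, prev_ca, prev_c,
                            _B_C_N, _A_CA_C_N, dihedrals[i - 1][1])
            ca = _place_atom(prev_ca, prev_c, n,
                             _B_N_CA, _A_C_N_CA, 180.0)
            c = _place_atom(prev_c, n, ca, _B_CA_C, _A_N_CA_C, phi)
        o = _place_atom(n, ca, c, _B_C_O, _A_CA_C_O, psi + 180.0)
        backbone.append((n, ca, c, o))
        prev_n, prev_ca, prev_c = n, ca, c

    if spec.sequence == "random":
        ca_trace = np.array([b[1] for b in backbone])
        sequence = _random_sequence(dihedrals, ca_trace, rng)
    else:
        sequence = _parse_sequence(spec, rng)

    residues: list[Residue] = []
    for i, res_type in enumerate(sequence):
        n, ca, c, o = backbone[i]
        atoms = [Atom("N", "N", n), Atom("CA", "C", ca),
                 Atom("C", "C", c), Atom("O", "O", o)]
        if res_type != "GLY":
            cb = _virtual_cb(n, ca, c)
            atoms.append(Atom("CB", "C", cb))
            if res_type in _PSEUDO_SIDECHAIN:
                name, dist = _PSEUDO_SIDECHAIN[res_type]
                axis = cb - ca
                axis = axis / np.linalg.norm(axis)
                atoms.append(Atom(name, name[0], cb + dist * axis))
        residues.append(Residue(res_type, i + 1, atoms))

    chain = Chain("A", residues)
    if jitter > 0.0:
        xyz = chain.coords()
        chain = chain.with_coords(xyz + rng.normal(0.0, jitter, xyz.shape))
    return chain


def perturb_chain(chain: Chain, sigma: float,
                  rng: np.random.Generator) -> Chain:
    """Chain copy with i.i.d. Gaussian noise added to every coordinate."""
    xyz = chain.coords()
    return chain.with_coords(xyz + rng.normal(0.0, sigma, xyz.shape))


class Decoy(NamedTuple):
    """One perturbed model with its ground-truth TM-score."""

    model_id: str
    sigma: float
    chain: Chain
    tm: float


def make_decoy_ladder(native: Chain, spec: DecoyLadderSpec) -> list[Decoy]:
    """Graded decoys of ``native``: per sigma, seeded Gaussian perturbations
    with TM-scores against the native attached."""
    rng = np.random.default_rng(spec.seed)
    decoys: list[Decoy] = []
    for sigma in spec.noise_sigmas:
        for k in range(spec.n_decoys_per_sigma):
            chain = perturb_chain(native, sigma, rng)
            tm = tm_score(chain, native)
            decoys.append(Decoy(f"s{sigma:g}_d{k}", sigma, chain, tm))
    return decoys


def make_training_set(n_chains: int, template: FixtureSpec,
                      seed: int = 0, jitter: float = 0.2) -> list[Chain]:
    """``n_chains`` chains with varied random sequences, folds cycling over
    helix/strand/mixed, and small geometric jitter around the ideal fold."""
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    rng = np.random.default_rng(seed)
    folds = ("helix", "strand", "mixed")
    chains = []
    for i in range(n_chains):
        spec = FixtureSpec(
            n_residues=template.n_residues,
            sequence=template.sequence,
            fold=folds[i % 3] if template.fold == "mixed" else template.fold,
            seed=seed + i,
        )
        chains.append(make_chain(spec, jitter=jitter, rng=rng))
    return chains
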