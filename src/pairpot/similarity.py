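"""Ground-truth structural similarity: Kabsch superposition, RMSD, TM-score
and TM-score quality categories."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .structure_io import Chain

log = logging.getLogger(__name__)


@dataclass
class Superposition:
    """Optimal rigid mapping of one point set onto another."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    degenerate: bool = False

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Least-squares optimal rigid superposition of ``a`` onto ``b``.

    Proper rotation enforced (determinant +1).  Raises on fewer than three
    points; collinear point sets are flagged ``degenerate``.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("point sets must have equal shapes")
    if a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")

    ca, cb = a.mean(axis=0), b.mean(axis=0)
    A, B = a - ca, b - cb
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T

    degenerate = bool(S[1] < 1e-8 * max(S[0], 1e-30))
    if degenerate:
        log.warning("kabsch: degenerate (collinear) point set")
    rmsd = float(np.sqrt(np.mean(np.sum((A @ R.T - B) ** 2, axis=1))))
    return Superposition(R, cb - R @ ca, rmsd, degenerate)


def _ca_map(chain: Chain) -> dict[int, np.ndarray]:
    out = {}
    for res in chain:
        atom = res.atom("CA")
        if atom is not None:
            out[res.seq_index] = atom.coords
    return out


def tm_d0(n_residues: int) -> float:
    """Length-dependent distance scale, floored at 0.5 Å for short chains."""
    if n_residues > 15:
        d0 = 1.24 * (n_residues - 15) ** (1.0 / 3.0) - 1.8
    else:
        d0 = 0.0
    return max(d0, 0.5)


def tm_score(model: Chain, native: Chain) -> float:
    """TM-score of ``model`` against ``native`` (normalized by native length).

    Residues are matched by shared ``seq_index``.  The superposition search
    seeds Kabsch fits from sliding fragments of length L, L/2 and L/4
    (minimum 4) and iteratively refines the included-residue set with a
    d0-based inclusion cutoff, keeping the best TM found.
    """
    ca_m, ca_n = _ca_map(model), _ca_map(native)
    shared = sorted(set(ca_m) & set(ca_n))
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared residues with CA atoms")
    xm = np.array([ca_m[i] for i in shared])
    xn = np.array([ca_n[i] for i in shared])

    L = len(shared)
    Ln = len(ca_n)
    d0 = tm_d0(Ln)

    best = 0.0
    lengths = sorted({L, max(4, L // 2), max(4, L // 4)}, reverse=True)
    for flen in lengths:
        if flen > L:
            continue
        for start in range(0, L - flen + 1, max(1, flen // 2)):
            window = np.arange(start, start + flen)
            sup = kabsch(xm[window], xn[window])
            included = window
            for _ in range(20):
                d = np.linalg.norm(sup.apply(xm) - xn, axis=1)
                d[d < 1e-6] = 0.0  # exactness guard for identical chains
                best = max(best, float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / Ln))
                cut = d0
                new = np.flatnonzero(d < cut)
                while len(new) < 3:
                    cut *= 1.5
                    new = np.flatnonzero(d < cut)
                if len(new) == len(included) and np.array_equal(new, included):
                    break
                sup = kabsch(xm[new], xn[new])
                included = new
    return min(best, 1.0)


class QualityCategory(str, Enum):
    """Model quality classes over TM-score intervals."""

    NEAR_NATIVE = "near_native"   # (0.8, 1.0]
    GOOD = "good"                 # (0.6, 0.8]
    MEDIUM = "medium"             # (0.4, 0.6]
    POOR = "poor"                 # [0.0, 0.4]


def quality_category(tm: float) -> QualityCategory:
    """Map a TM-score to its quality category.

    Boundary values fall into the lower category: 0.8 is ``good``, 0.6 is
    ``medium``, 0.4 is ``poor``.
    """
    if not 0.0 <= tm <= 1.0:
        raise ValueError(f"TM-score {tm} outside [0, 1]")
    if tm > 0.8:
        return QualityCategory.NEAR_NATIVE
    if tm > 0.6:
        return QualityCategory.GOOD
    if tm > 0.4:
        return QualityCategory.MEDIUM
    return QualityCategory.POOR
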