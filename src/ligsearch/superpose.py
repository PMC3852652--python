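"""Rigid-body superposition with iterative outlier trimming.

Hit structures are superposed onto the best-matching reference using the
main-chain atoms (N, CA, C, O) of residues made equivalent by the sequence
alignment.  A least-squares (Kabsch) fit is iterated: while the RMSD over
retained residue pairs is at or above the cutoff (default 12 Å), the worst
10% of pairs by per-residue deviation are removed (at least one, never
below three retained pairs).  This compensates for imperfections in the
sequence alignment.  The final transform carries the mobile structure's
ligand atoms into the reference frame.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .formats_io import Residue, Structure

logger = logging.getLogger(__name__)

MAIN_CHAIN_ATOMS = ("N", "CA", "C", "O")
DEFAULT_RMSD_CUTOFF = 12.0
REMOVAL_FRACTION = 0.10
MIN_PAIRS = 3


class SuperposeError(ValueError):
    pass


@dataclass
class Superposition:
    """A proper rotation + translation mapping mobile coords onto fixed ones."""

    rotation: np.ndarray           # 3x3, det = +1
    translation: np.ndarray        # 3-vector, Å
    rmsd: float                    # Å over the retained equivalences
    retained: list = field(default_factory=list)
    removed: list = field(default_factory=list)
    converged: bool = True
    n_iterations: int = 1
    rmsd_history: list = field(default_factory=list)

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise SuperposeError("rotation must be proper (det = +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        return coords @ self.rotation.T + self.translation


def kabsch(fixed: np.ndarray, mobile: np.ndarray) -> Superposition:
    """Least-squares optimal rigid superposition of ``mobile`` onto ``fixed``."""
    fixed = np.asarray(fixed, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if fixed.shape != mobile.shape or fixed.ndim != 2 or fixed.shape[1] != 3:
        raise SuperposeError("coordinate sets must both be N x 3")
    n = fixed.shape[0]
    if n < MIN_PAIRS:
        raise SuperposeError(f"at least {MIN_PAIRS} points required, got {n}")
    cf = fixed.mean(axis=0)
    cm = mobile.mean(axis=0)
    h = (mobile - cm).T @ (fixed - cf)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = cf - rotation @ cm
    diff = (mobile @ rotation.T + translation) - fixed
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return Superposition(rotation=rotation, translation=translation, rmsd=rmsd,
                         retained=list(range(n)))


def _main_chain_coords(pair: Tuple[Residue, Residue]):
    """Matched main-chain coordinates of an equivalent residue pair.

    Missing O atoms are tolerated (the fit uses the remaining three); pairs
    sharing fewer than three main-chain atoms are unusable.
    """
    ref_res, mob_res = pair
    fixed, mobile = [], []
    for name in MAIN_CHAIN_ATOMS:
        a = ref_res.atom(name)
        b = mob_res.atom(name)
        if a is not None and b is not None:
            fixed.append(a.coords)
            mobile.append(b.coords)
    if len(fixed) < 3:
        return None
    return np.array(fixed), np.array(mobile)


def iterative_superpose(reference: Structure, mobile: Structure,
                        equivalences: Sequence[Tuple[Residue, Residue]],
                        cutoff: float = DEFAULT_RMSD_CUTOFF,
                        removal_fraction: float = REMOVAL_FRACTION) -> Superposition:
    """Superpose ``mobile`` onto ``reference`` over equivalent residues.

    ``equivalences`` pairs (reference residue, mobile residue).  Pairs whose
    main-chain atoms are missing are skipped with a warning.  Iterates the
    Kabsch fit, trimming the worst ``removal_fraction`` of residue pairs per
    round, until the RMSD drops below ``cutoff``; reports ``converged=False``
    when fewer than three pairs remain instead.
    """
    if cutoff <= 0:
        raise SuperposeError("cutoff must be positive")
    usable: List[Tuple[Tuple[Residue, Residue], np.ndarray, np.ndarray]] = []
    for pair in equivalences:
        coords = _main_chain_coords(pair)
        if coords is None:
            logger.warning("equivalence %s/%s lacks main-chain atoms; skipped",
                           pair[0].key, pair[1].key)
            continue
        usable.append((pair, coords[0], coords[1]))
    if len(usable) < MIN_PAIRS:
        raise SuperposeError(
            f"need at least {MIN_PAIRS} usable equivalences, got {len(usable)}")

    removed: List[Tuple[Residue, Residue]] = []
    history: List[float] = []
    iteration = 0
    while True:
        iteration += 1
        fixed = np.concatenate([f for _, f, _ in usable])
        mob = np.concatenate([m for _, _, m in usable])
        fit = kabsch(fixed, mob)
        history.append(fit.rmsd)
        if fit.rmsd < cutoff:
            converged = True
            break
        if len(usable) <= MIN_PAIRS:
            converged = False
            break
        k = max(1, math.floor(removal_fraction * len(usable)))
        k = min(k, len(usable) - MIN_PAIRS)
        per_residue = [
            float(np.sqrt(((fit.apply(m) - f) ** 2).sum() / len(f)))
            for _, f, m in usable
        ]
        worst = sorted(range(len(usable)), key=lambda i: -per_residue[i])[:k]
        for i in sorted(worst, reverse=True):
            removed.append(usable[i][0])
            del usable[i]

    return Superposition(rotation=fit.rotation, translation=fit.translation,
                         rmsd=fit.rmsd, retained=[p for p, _, _ in usable],
                         removed=removed, converged=converged,
                         n_iterations=iteration, rmsd_history=history)


def transform_structure(structure: Structure, sup: Superposition) -> Structure:
    """Deep-copied structure with every atom carried through the transform."""
    out = copy.deepcopy(structure)
    for residues in out.chains.values():
        for res in residues:
            for atom in res.atoms:
                atom.coords = sup.apply(atom.coords)[0]
    for lig in out.ligands:
        for atom in lig.atoms:
            atom.coords = sup.apply(atom.coords)[0]
    return out
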