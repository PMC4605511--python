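"""Structural comparison of identical palindromes from different proteins.

Backbone atoms of one occurrence are superposed onto the other with the
Kabsch algorithm (least-squares optimal proper rotation; reflections are
rejected), and side-chain heavy atoms at equivalent positions are compared
after applying the backbone transform.  This operationalizes the question of
whether the same palindrome peptide sits in the same structural environment:
backbone RMSD quantifies conformational agreement, per-position side-chain
RMSD flags divergent rotamers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .palindrome_scan import PalindromeHit
from .struct_annotate import hit_residues
from .structure_io import StructureModel

__all__ = [
    "Superposition",
    "kabsch_superpose",
    "sidechain_divergence",
    "superpose_hits",
    "PositionDivergence",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Superposition:
    rotation: np.ndarray          # 3x3, det = +1
    translation: np.ndarray       # 3-vector: x_fit = R @ x + t
    rmsd: float                   # over the fitted atom set, Å
    fitted_atoms: list[str] = field(default_factory=list)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(coords_ref: np.ndarray, coords_mov: np.ndarray,
                     atom_names: Optional[Sequence[str]] = None
                     ) -> Superposition:
    """Optimal rigid superposition of ``coords_mov`` onto ``coords_ref``.

    Paired ordering, n >= 3.  Collinear (rank-deficient) input warns but a
    solution is still returned.
    """
    a = np.asarray(coords_ref, dtype=float)
    b = np.asarray(coords_mov, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must be matching (n, 3) arrays")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired atoms")
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    aa = a - ca
    bb = b - cb
    h = bb.T @ aa
    if np.linalg.matrix_rank(h) < 2:
        warnings.warn("degenerate (collinear) coordinates; superposition "
                      "is not unique")
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = ca - rot @ cb
    fitted = b @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - a) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=t, rmsd=rmsd,
                         fitted_atoms=list(atom_names or []))


def superpose_hits(model_a: StructureModel, hit_a: PalindromeHit,
                   model_b: StructureModel, hit_b: PalindromeHit,
                   atoms: Sequence[str] = BACKBONE_ATOMS) -> Superposition:
    """Backbone superposition of hit_b onto hit_a (identical sequences)."""
    if hit_a.sequence != hit_b.sequence:
        raise ValueError("hits must have identical sequences "
                         f"({hit_a.sequence!r} vs {hit_b.sequence!r})")
    res_a = hit_residues(model_a, hit_a)
    res_b = hit_residues(model_b, hit_b)
    pa, pb, names = [], [], []
    for ra, rb in zip(res_a, res_b):
        for name in atoms:
            aa, ab = ra.atom(name), rb.atom(name)
            if aa is not None and ab is not None:
                pa.append(aa.coords)
                pb.append(ab.coords)
                names.append(f"{ra.seq_number}:{name}")
    return kabsch_superpose(np.array(pa), np.array(pb), atom_names=names)


@dataclass
class PositionDivergence:
    position: int                  # 0-based within the palindrome
    residue_name: str
    rmsd: Optional[float]          # None when no comparable side-chain atoms
    n_atoms: int                   # atoms actually compared
    coverage: float                # compared / union of side-chain atoms
    divergent: bool


def sidechain_divergence(model_a: StructureModel, hit_a: PalindromeHit,
                         model_b: StructureModel, hit_b: PalindromeHit,
                         superposition: Optional[Superposition] = None,
                         threshold: float = 1.0) -> list[PositionDivergence]:
    """Per-position side-chain heavy-atom RMSD after backbone superposition.

    Atom sets are intersected by name when they differ (missing atoms);
    glycine positions carry ``rmsd=None`` and are never flagged.
    """
    sup = superposition or superpose_hits(model_a, hit_a, model_b, hit_b)
    res_a = hit_residues(model_a, hit_a)
    res_b = hit_residues(model_b, hit_b)
    out: list[PositionDivergence] = []
    backbone = set(BACKBONE_ATOMS)
    for pos, (ra, rb) in enumerate(zip(res_a, res_b)):
        sc_a = {a.name: a.coords for a in ra.atoms
                if a.name not in backbone and a.element.upper() != "H"}
        sc_b = {a.name: a.coords for a in rb.atoms
                if a.name not in backbone and a.element.upper() != "H"}
        common = sorted(set(sc_a) & set(sc_b))
        union = len(set(sc_a) | set(sc_b))
        if not common:
            out.append(PositionDivergence(position=pos, residue_name=ra.name3,
                                          rmsd=None, n_atoms=0,
                                          coverage=0.0 if union else 1.0,
                                          divergent=False))
            continue
        xa = np.array([sc_a[n] for n in common])
        xb = sup.apply(np.array([sc_b[n] for n in common]))
        rmsd = float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))
        out.append(PositionDivergence(position=pos, residue_name=ra.name3,
                                      rmsd=rmsd, n_atoms=len(common),
                                      coverage=len(common) / union,
                                      divergent=rmsd > threshold))
    return out
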