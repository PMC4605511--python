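"""Synthetic inputs: chains with planted palindromes, and small peptide
structures with ideal backbone geometry, written as valid PDB files.

These generators make every pipeline stage testable without downloads.  The
sequence generator draws background residues i.i.d. from configurable
frequencies (uniform over the 20 standard residues by default) and overwrites
planted palindromic windows at known positions, recording the ground truth.
The structure builder places backbone atoms (plus CB for non-glycine) by
sequential internal-coordinate construction with standard bond lengths
(N-CA 1.458, CA-C 1.525, C-N 1.329 Å), trans peptide bonds (omega = 180°) and
caller-chosen phi/psi — ideal alpha-helix (-57/-47) and beta-strand
(-139/135) presets included.  Side chains beyond CB are not generated; that
is sufficient for secondary-structure, SASA and contact tests, and real data
differ exactly there (full side chains, imperfect geometry, altlocs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import place_atom
from .palindrome_scan import (AA_ALPHABET, PalindromeHit, ScanConfig,
                              enumerate_palindromes, is_palindrome)
from .structure_io import (Atom, ChainSequence, Residue, StructureModel,
                           THREE_TO_ONE, write_pdb)

__all__ = [
    "PlantSpec",
    "GeometrySpec",
    "PlantedChain",
    "generate_sequence_with_palindromes",
    "build_ideal_peptide",
    "build_beta_hairpin",
    "write_dssp",
    "write_pdb",
    "CONFORMERS",
]

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Named backbone conformers: (phi, psi) in degrees.
CONFORMERS = {"helix": (-57.0, -47.0), "strand": (-139.0, 135.0)}

# Standard backbone internal coordinates (Engh & Huber values).
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_A_CA_C_O = 120.8
_OMEGA = 180.0


@dataclass
class PlantSpec:
    """Recipe for a background chain with planted palindromes."""

    background_length: int
    planted: list[tuple[str, int]] = field(default_factory=list)  # (seq, 0-based pos)
    residue_frequencies: Optional[Sequence[float]] = None  # over AA_ALPHABET
    seed: int = 0
    allow_overlap: bool = False
    chain_id: str = "A"
    pdb_id: str = "SYN1"

    def __post_init__(self) -> None:
        for seq, pos in self.planted:
            if not is_palindrome(seq):
                raise ValueError(f"planted sequence {seq!r} is not a palindrome")
            if pos < 0 or pos + len(seq) > self.background_length:
                raise ValueError(f"plant {seq!r}@{pos} does not fit in "
                                 f"{self.background_length} residues")
        if not self.allow_overlap:
            spans = sorted((pos, pos + len(s)) for s, pos in self.planted)
            for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValueError("planted windows overlap; set "
                                     "allow_overlap=True if intended")
        if self.residue_frequencies is not None:
            f = np.asarray(self.residue_frequencies, dtype=float)
            if f.shape != (20,) or not np.isclose(f.sum(), 1.0):
                raise ValueError("residue_frequencies must be 20 values summing to 1")


@dataclass
class PlantedChain:
    chain: ChainSequence
    truth: list[PalindromeHit]        # the planted windows, exact coordinates
    accidental: list[PalindromeHit]   # background palindromes found post hoc


def generate_sequence_with_palindromes(spec: PlantSpec) -> PlantedChain:
    """Draw a background sequence, overwrite the planted windows, and record
    ground truth.  Accidental background palindromes are permitted; a
    post-scan records them (windows not positionally identical to a plant)."""
    rng = np.random.default_rng(spec.seed)
    freqs = (np.full(20, 1 / 20) if spec.residue_frequencies is None
             else np.asarray(spec.residue_frequencies, dtype=float))
    letters = rng.choice(list(AA_ALPHABET), size=spec.background_length, p=freqs)
    seq = list(letters)
    for planted_seq, pos in spec.planted:
        seq[pos:pos + len(planted_seq)] = list(planted_seq)
    sequence = "".join(seq)
    chain = ChainSequence(
        chain_id=spec.chain_id, sequence=sequence,
        residue_index=[(i + 1, "") for i in range(len(sequence))],
        complete_mask=[True] * len(sequence), pdb_id=spec.pdb_id)
    truth = []
    for planted_seq, pos in spec.planted:
        truth.append(PalindromeHit(
            pdb_id=spec.pdb_id, chain_id=spec.chain_id, start_index=pos,
            sequence=planted_seq, start_pos=(pos + 1, ""),
            end_pos=(pos + len(planted_seq), "")))
    planted_keys = {(h.start_index, h.length) for h in truth}
    min_plant = min((len(s) for s, _ in spec.planted), default=5)
    cfg = ScanConfig(min_len=min(5, min_plant), max_len=None)
    accidental = [h for h in enumerate_palindromes(chain, cfg)
                  if (h.start_index, h.length) not in planted_keys]
    return PlantedChain(chain=chain, truth=truth, accidental=accidental)


@dataclass
class GeometrySpec:
    """Recipe for an ideal-geometry peptide."""

    sequence: str
    conformer: str = "helix"                      # key into CONFORMERS, or "custom"
    phi: Optional[Sequence[float]] = None         # per-residue, used when custom
    psi: Optional[Sequence[float]] = None
    chain_id: str = "A"
    pdb_id: str = "SYN2"

    def angles(self) -> tuple[np.ndarray, np.ndarray]:
        n = len(self.sequence)
        if self.conformer in CONFORMERS:
            phi0, psi0 = CONFORMERS[self.conformer]
            return np.full(n, phi0), np.full(n, psi0)
        if self.phi is None or self.psi is None:
            raise ValueError("custom conformer needs explicit phi and psi")
        phi = np.asarray(self.phi, dtype=float)
        psi = np.asarray(self.psi, dtype=float)
        if phi.shape != (n,) or psi.shape != (n,):
            raise ValueError("phi/psi must have one value per residue")
        return phi, psi


def _virtual_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    # L-configuration beta carbon from the backbone frame.
    b = ca - n
    cdir = c - ca
    a = np.cross(b, cdir)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cdir + ca


def build_ideal_peptide(spec: GeometrySpec,
                        het_atoms: Sequence[tuple[str, str, Sequence[float]]] = (),
                        offset: np.ndarray | None = None) -> StructureModel:
    """Build a peptide with exact phi/psi and standard covalent geometry.

    ``het_atoms`` appends decoy HETATM groups as (residue_name, element,
    coords) — e.g. ``("ZN", "Zn", (5, 0, 0))``.  Recomputing phi/psi from the
    output reproduces the spec within numerical precision.
    """
    seq = spec.sequence.upper()
    if len(seq) < 2:
        raise ValueError("need at least 2 residues")
    for letter in seq:
        if letter not in ONE_TO_THREE:
            raise ValueError(f"unsupported residue letter {letter!r}")
    phi, psi = spec.angles()

    n_coords: list[np.ndarray] = []
    ca_coords: list[np.ndarray] = []
    c_coords: list[np.ndarray] = []
    # Seed frame for residue 0.
    n_coords.append(np.array([0.0, 0.0, 0.0]))
    ca_coords.append(np.array([_B_N_CA, 0.0, 0.0]))
    c_coords.append(ca_coords[0] + _B_CA_C * np.array([np.cos(np.radians(_A_N_CA_C)) * -1,
                                                       np.sin(np.radians(_A_N_CA_C)), 0.0]))
    for i in range(1, len(seq)):
        n_next = place_atom(n_coords[i - 1], ca_coords[i - 1], c_coords[i - 1],
                            _B_C_N, _A_CA_C_N, psi[i - 1])
        ca_next = place_atom(ca_coords[i - 1], c_coords[i - 1], n_next,
                             _B_N_CA, _A_C_N_CA, _OMEGA)
        c_next = place_atom(c_coords[i - 1], n_next, ca_next,
                            _B_CA_C, _A_N_CA_C, phi[i])
        n_coords.append(n_next)
        ca_coords.append(ca_next)
        c_coords.append(c_next)

    shift = np.zeros(3) if offset is None else np.asarray(offset, dtype=float)
    residues: list[Residue] = []
    for i, letter in enumerate(seq):
        name3 = ONE_TO_THREE[letter]
        atoms = [Atom("N", "N", n_coords[i] + shift),
                 Atom("CA", "C", ca_coords[i] + shift)]
        atoms.append(Atom("C", "C", c_coords[i] + shift))
        # Carbonyl O: anti to the next N (psi + 180 about the CA-C bond).
        o_tor = psi[i] + 180.0
        o = place_atom(n_coords[i], ca_coords[i], c_coords[i],
                       _B_C_O, _A_CA_C_O, o_tor)
        atoms.append(Atom("O", "O", o + shift))
        if letter != "G":
            cb = _virtual_cb(n_coords[i], ca_coords[i], c_coords[i])
            atoms.append(Atom("CB", "C", cb + shift))
        complete = name3 in ("ALA", "GLY")  # backbone+CB covers ALA/GLY only
        residues.append(Residue(chain_id=spec.chain_id, seq_number=i + 1,
                                insertion_code="", name3=name3,
                                one_letter=letter, atoms=atoms,
                                is_complete=complete))
    het: list[Residue] = []
    for k, (name, element, coords) in enumerate(het_atoms):
        het.append(Residue(
            chain_id=spec.chain_id, seq_number=900 + k, insertion_code="",
            name3=name, one_letter="X",
            atoms=[Atom(name, element, np.asarray(coords, dtype=float),
                        is_hetero=True)],
            is_complete=False, is_water=(name == "HOH")))
    return StructureModel(pdb_id=spec.pdb_id,
                          chains={spec.chain_id: residues},
                          het_residues=het,
                          classification="DE NOVO PROTEIN")


def build_beta_hairpin(n_strand: int = 5, sequence: str | None = None,
                       pdb_id: str = "SYN3", chain_id: str = "A"
                       ) -> StructureModel:
    """An idealized two-stranded antiparallel beta-hairpin (single chain).

    Two ``n_strand``-residue strands joined by a two-residue turn whose
    dihedrals were refined once, offline, so that the canonical cross-strand
    hydrogen bonds (narrow pairs of the antiparallel register) all form with
    Kabsch-Sander energies well below the -0.5 kcal/mol threshold; the values
    are frozen here and the construction is deterministic.  Strand cores are
    assigned 'E' by hydrogen-bond-pattern assigners.
    """
    n = 2 * n_strand + 2
    seq = sequence or ("A" * n)
    if len(seq) != n:
        raise ValueError(f"sequence must have 2*n_strand+2 = {n} residues")
    phi = [_HAIRPIN_STRAND[0]] * n_strand + list(_HAIRPIN_TURN_PHI) + \
          [_HAIRPIN_STRAND[0]] * n_strand
    psi = [_HAIRPIN_STRAND[1]] * n_strand + list(_HAIRPIN_TURN_PSI) + \
          [_HAIRPIN_STRAND[1]] * n_strand
    return build_ideal_peptide(GeometrySpec(sequence=seq, conformer="custom",
                                            phi=phi, psi=psi,
                                            chain_id=chain_id, pdb_id=pdb_id))


# Hairpin internal coordinates: strand (phi, psi) and the two turn residues.
_HAIRPIN_STRAND = (-103.96, 101.15)
_HAIRPIN_TURN_PHI = (62.43, -116.83)
_HAIRPIN_TURN_PSI = (-90.53, 0.0)


def write_dssp(records: Sequence[tuple[str, int, str, str, str]], path) -> None:
    """Write a classic-format DSSP file from (chain, resnum, icode, aa, ss)
    records — a fixture generator for the DSSP reader (round-trip testing).

    Hydrogen-bond, accessibility and dihedral columns are zero-filled; the
    structure column holds the given code (use ' ' for coil rows).
    """
    lines = [
        "==== SECONDARY STRUCTURE DEFINITION BY THE PROGRAM DSSP "
        "(SYNTHETIC FIXTURE) ====",
        "REFERENCE  SYNTHETIC",
        f"  {len(records)}  1  0  0  0  TOTAL NUMBER OF RESIDUES",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
        "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    "
        "X-CA   Y-CA   Z-CA",
    ]
    for k, (chain_id, resnum, icode, aa, ss) in enumerate(records, start=1):
        row = [" "] * 120
        def put(start, text):
            row[start:start + len(text)] = list(text)
        put(0, f"{k:5d}")
        put(5, f"{resnum:5d}")
        put(10, (icode or " ")[:1])
        put(11, chain_id[:1])
        put(13, aa[:1])
        put(16, (ss or " ")[:1])
        put(34, "   0")          # ACC
        put(38, "      0")
        put(46, " 0.0")
        put(50, "     0")
        put(57, " 0.0")
        put(61, "     0")
        put(68, " 0.0")
        put(72, "     0")
        put(79, " 0.0")
        put(103, "   0.0")       # PHI
        put(109, "   0.0")       # PSI
        lines.append("".join(row).rstrip("\n"))
    from pathlib import Path as _Path
    _Path(path).write_text("\n".join(lines) + "\n")
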