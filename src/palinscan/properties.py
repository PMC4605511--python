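"""Sequence-level properties: hydropathy, position frequency matrices,
consensus sequences and logo-ready exports.

Hydropathy uses the Kyte–Doolittle scale; a peptide's value is the unweighted
mean of its residues, which is symmetric under sequence reversal (and hence
the same read in either direction — convenient for palindromes, where it is
a structural property of the window rather than of a reading direction).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "KYTE_DOOLITTLE",
    "PositionFrequencyMatrix",
    "average_hydrophobicity",
    "position_frequency_matrix",
    "consensus",
    "export_logo_groups",
    "write_fasta",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte & Doolittle residue hydropathy values (dimensionless).
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


def average_hydrophobicity(seq: str,
                           scale: Mapping[str, float] = KYTE_DOOLITTLE
                           ) -> float:
    """Mean per-residue hydropathy of a peptide.

    Raises on 'X' or any letter absent from the scale.
    """
    if not seq:
        raise ValueError("empty sequence")
    try:
        return float(np.mean([scale[a] for a in seq]))
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} has no hydropathy value") from exc


@dataclass
class PositionFrequencyMatrix:
    """L x 20 residue counts for a set of equal-length sequences."""

    counts: np.ndarray        # shape (L, 20), rows = positions
    n_sequences: int
    alphabet: str = AA_ORDER

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def column(self, i: int) -> dict[str, int]:
        return {a: int(c) for a, c in zip(self.alphabet, self.counts[i])
                if c > 0}

    def to_tsv(self, path) -> None:
        """Positions x residues table consumable by logo-rendering tools."""
        lines = ["pos\t" + "\t".join(self.alphabet)]
        for i, row in enumerate(self.counts, start=1):
            lines.append(f"{i}\t" + "\t".join(str(int(c)) for c in row))
        Path(path).write_text("\n".join(lines) + "\n")


def position_frequency_matrix(seqs: Sequence[str]) -> PositionFrequencyMatrix:
    """Count residues per position over equal-length sequences."""
    if not seqs:
        raise ValueError("no sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences have mixed lengths")
    index = {a: k for k, a in enumerate(AA_ORDER)}
    counts = np.zeros((L, len(AA_ORDER)), dtype=int)
    for s in seqs:
        for i, a in enumerate(s):
            try:
                counts[i, index[a]] += 1
            except KeyError:
                raise ValueError(f"nonstandard letter {a!r} in {s!r}") from None
    return PositionFrequencyMatrix(counts=counts, n_sequences=len(seqs))


def consensus(pfm: PositionFrequencyMatrix) -> str:
    """Per-column argmax residue; ties broken lexicographically
    (the alphabet is sorted, so the first maximum wins)."""
    if pfm.n_sequences < 1:
        raise ValueError("empty PFM")
    return "".join(pfm.alphabet[int(np.argmax(row))] for row in pfm.counts)


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    """Minimal FASTA writer with fixed-column wrap."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def export_logo_groups(hits, out_dir, prefix: str = "palins") -> dict[tuple[int, str], Path]:
    """Write one FASTA per (length, secondary-structure category) group.

    ``hits`` must carry ``.sequence`` and ``.ss_category``; ordering inside a
    file is deterministic (pdb_id, chain, start).  Empty groups emit no file.
    Returns the map group -> file path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    groups: dict[tuple[int, str], list] = {}
    for h in hits:
        groups.setdefault((h.length, h.ss_category), []).append(h)
    written: dict[tuple[int, str], Path] = {}
    for (length, category), members in sorted(groups.items()):
        members.sort(key=lambda h: (h.pdb_id, h.chain_id, h.start_index))
        path = out_dir / f"{prefix}_len{length}_{category}.fasta"
        write_fasta(
            ((f"{h.pdb_id}_{h.chain_id}_{h.start_index}", h.sequence)
             for h in members), path)
        written[(length, category)] = path
    return written
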