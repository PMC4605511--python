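"""Reading and writing protein structures.

PDB files are parsed with gemmi into a lightweight :class:`StructureModel`
holding polymer chains (author numbering and insertion codes preserved),
het groups, SITE records, the header classification and the resolution.
Chain sequences are derived from ATOM records — every residue in a sequence
has coordinates — with per-residue heavy-atom completeness flags, because all
downstream annotations are structural and windows over residues with missing
atoms are excluded from analysis.

Classic DSSP output files are read through Bio.PDB; a blank structure column
maps to ``'C'`` (coil) and residues absent from the DSSP file map to ``'-'``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np
from Bio.PDB.DSSP import make_dssp_dict

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "ChainSequence",
    "StructureParseError",
    "EmptyStructureError",
    "DsspFormatError",
    "read_structure",
    "chain_sequence",
    "read_dssp",
    "write_pdb",
    "THREE_TO_ONE",
    "EXPECTED_HEAVY_ATOMS",
]


class StructureParseError(ValueError):
    """The file could not be parsed as PDB."""


class EmptyStructureError(ValueError):
    """The file contains no ATOM records."""


class DsspFormatError(ValueError):
    """The file is not classic DSSP output."""


#: Standard residues; anything else (MSE, PTR, ...) maps to 'X'.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_BACKBONE = ("N", "CA", "C", "O")

#: Expected heavy atoms per standard residue (chemical component definitions,
#: hydrogens and terminal OXT ignored).
EXPECTED_HEAVY_ATOMS = {
    "ALA": _BACKBONE + ("CB",),
    "ARG": _BACKBONE + ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": _BACKBONE + ("CB", "CG", "OD1", "ND2"),
    "ASP": _BACKBONE + ("CB", "CG", "OD1", "OD2"),
    "CYS": _BACKBONE + ("CB", "SG"),
    "GLN": _BACKBONE + ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": _BACKBONE + ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": _BACKBONE,
    "HIS": _BACKBONE + ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": _BACKBONE + ("CB", "CG1", "CG2", "CD1"),
    "LEU": _BACKBONE + ("CB", "CG", "CD1", "CD2"),
    "LYS": _BACKBONE + ("CB", "CG", "CD", "CE", "NZ"),
    "MET": _BACKBONE + ("CB", "CG", "SD", "CE"),
    "PHE": _BACKBONE + ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": _BACKBONE + ("CB", "CG", "CD"),
    "SER": _BACKBONE + ("CB", "OG"),
    "THR": _BACKBONE + ("CB", "OG1", "CG2"),
    "TRP": _BACKBONE + ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3",
                        "CZ2", "CZ3", "CH2"),
    "TYR": _BACKBONE + ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": _BACKBONE + ("CB", "CG1", "CG2"),
}


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # (3,) in Å
    is_hetero: bool = False
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str  # '' when absent
    name3: str
    one_letter: str
    atoms: list[Atom] = field(default_factory=list)
    is_complete: bool = True
    is_water: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        sel = [a.coords for a in self.atoms
               if not (heavy_only and a.element.upper() == "H")]
        return np.array(sel) if sel else np.empty((0, 3))


@dataclass
class StructureModel:
    pdb_id: str
    chains: dict[str, list[Residue]]  # polymer residues in file order
    het_residues: list[Residue] = field(default_factory=list)
    site_records: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    classification: str = ""
    resolution: Optional[float] = None
    title: str = ""
    compound: str = ""

    def residue(self, chain_id: str, seq_number: int,
                insertion_code: str = "") -> Optional[Residue]:
        for res in self.chains.get(chain_id, []):
            if res.seq_number == seq_number and res.insertion_code == insertion_code:
                return res
        return None

    def dangling_site_residues(self) -> list[tuple[str, int, str]]:
        """SITE entries that resolve to no residue in chains or het groups."""
        known = {r.key for ress in self.chains.values() for r in ress}
        known |= {r.key for r in self.het_residues}
        return [ref for refs in self.site_records.values()
                for ref in refs if ref not in known]


@dataclass
class ChainSequence:
    chain_id: str
    sequence: str
    residue_index: list[tuple[int, str]]  # (author number, insertion code)
    complete_mask: list[bool]
    pdb_id: str = ""

    def __post_init__(self) -> None:
        if not (len(self.sequence) == len(self.residue_index) == len(self.complete_mask)):
            raise ValueError("sequence, residue_index and complete_mask "
                             "must have equal length")

    def __len__(self) -> int:
        return len(self.sequence)


def _pick_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate locations: highest occupancy, ties to altloc 'A'
    or the first conformer encountered."""
    by_name: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in res:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > prev.occ + 1e-9:
            by_name[atom.name] = atom
    return [by_name[n] for n in order]


def _convert_residue(res: gemmi.Residue, chain_id: str, is_het: bool) -> Residue:
    atoms = []
    for ga in _pick_altlocs(res):
        pos = ga.pos
        atoms.append(Atom(name=ga.name, element=ga.element.name,
                          coords=np.array([pos.x, pos.y, pos.z]),
                          is_hetero=is_het, occupancy=ga.occ))
    name3 = res.name.strip()
    one = THREE_TO_ONE.get(name3, "X")
    expected = EXPECTED_HEAVY_ATOMS.get(name3)
    present = {a.name for a in atoms}
    complete = expected is not None and all(n in present for n in expected)
    icode = res.seqid.icode.strip()
    return Residue(chain_id=chain_id, seq_number=res.seqid.num,
                   insertion_code=icode, name3=name3, one_letter=one,
                   atoms=atoms, is_complete=complete,
                   is_water=res.is_water())


def _parse_site_lines(path: Path) -> dict[str, list[tuple[str, int, str]]]:
    """Fixed-column parse of legacy SITE records (PDB v3.3 §9)."""
    sites: dict[str, list[tuple[str, int, str]]] = {}
    with open(path, "r", errors="replace") as fh:
        for line in fh:
            if not line.startswith("SITE "):
                continue
            name = line[11:14].strip()
            refs = sites.setdefault(name, [])
            for off in (18, 29, 40, 51):
                chunk = line[off:off + 10]
                if len(chunk.strip()) == 0:
                    continue
                res_name = line[off:off + 3].strip()
                chain_id = line[off + 4:off + 5].strip()
                num_str = line[off + 5:off + 9].strip()
                icode = line[off + 9:off + 10].strip()
                if not res_name or not num_str:
                    continue
                refs.append((chain_id, int(num_str), icode))
    return sites


def _parse_compound(path: Path) -> str:
    """First COMPND MOLECULE name, for 'protein description' columns."""
    with open(path, "r", errors="replace") as fh:
        for line in fh:
            if line.startswith("COMPND") and "MOLECULE:" in line:
                frag = line.split("MOLECULE:", 1)[1].strip()
                return frag.rstrip(";").strip()
    return ""


def read_structure(path, first_model_only: bool = True) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Polymer residues are grouped by chain in file order; alternate locations
    are resolved to the highest-occupancy conformer; waters are flagged among
    the het groups; only the first MODEL of multi-model files is kept.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no ATOM records")
    models = [st[0]] if first_model_only else list(st)

    chains: dict[str, list[Residue]] = {}
    het: list[Residue] = []
    n_atoms = 0
    for model in models:
        for gchain in model:
            for gres in gchain:
                # MSE and other modified residues carry the HETATM flag but
                # belong to the polymer; route on gemmi's entity typing.
                is_polymer = gres.entity_type == gemmi.EntityType.Polymer
                res = _convert_residue(gres, gchain.name, not is_polymer)
                n_atoms += len(res.atoms)
                if is_polymer:
                    chains.setdefault(gchain.name, []).append(res)
                else:
                    het.append(res)
    if n_atoms == 0:
        raise EmptyStructureError(f"{path}: no ATOM records")

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    info = dict(st.info)
    return StructureModel(
        pdb_id=(st.name or path.stem)[:4].upper(),
        chains=chains,
        het_residues=het,
        site_records=_parse_site_lines(path),
        classification=info.get("_struct_keywords.pdbx_keywords", "") or "",
        resolution=resolution,
        title=info.get("_struct.title", "") or "",
        compound=_parse_compound(path),
    )


def chain_sequence(model: StructureModel, chain_id: str) -> ChainSequence:
    """One-letter sequence of a chain, derived from ATOM-record residues.

    Nonstandard residues appear as ``'X'``; ``complete_mask`` mirrors each
    residue's heavy-atom completeness.
    """
    if chain_id not in model.chains:
        raise KeyError(
            f"chain {chain_id!r} not in {model.pdb_id}; "
            f"available: {sorted(model.chains)}")
    residues = model.chains[chain_id]
    return ChainSequence(
        chain_id=chain_id,
        sequence="".join(r.one_letter for r in residues),
        residue_index=[(r.seq_number, r.insertion_code) for r in residues],
        complete_mask=[r.is_complete for r in residues],
        pdb_id=model.pdb_id,
    )


def read_dssp(path) -> dict[tuple[str, int, str], str]:
    """Read a classic DSSP output file.

    Returns a map ``(chain_id, seq_number, insertion_code) -> code`` over the
    alphabet H/G/I/E/B/T/S/C.  A blank structure column is coil ``'C'``;
    chain-break ``'!'`` rows are skipped.  Residues absent from the returned
    map should be treated as ``'-'`` (no coordinates) by callers.
    """
    path = Path(path)
    text = path.read_text(errors="replace")
    if "  #  RESIDUE" not in text:
        raise DsspFormatError(f"{path}: missing DSSP residue header line")
    try:
        dssp_dict, _keys = make_dssp_dict(str(path))
    except Exception as exc:  # Bio raises bare Exception subclasses
        raise DsspFormatError(f"{path}: {exc}") from exc
    out: dict[tuple[str, int, str], str] = {}
    for (chain_id, res_id), values in dssp_dict.items():
        _het, num, icode = res_id
        ss = values[1]
        if ss in (" ", "-", ""):
            ss = "C"
        out[(chain_id, int(num), icode.strip())] = ss
    return out


def _format_atom_line(serial: int, atom: Atom, res: Residue, hetatm: bool) -> str:
    name = atom.name
    # PDB v3.3: atom names start in column 14 unless 4 chars or 2-char element
    if len(name) < 4 and len(atom.element) < 2:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    record = "HETATM" if hetatm else "ATOM  "
    x, y, z = atom.coords
    return (f"{record}{serial:>5d} {name_field} {res.name3:<3s} "
            f"{res.chain_id:>1s}{res.seq_number:>4d}{res.insertion_code or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}          "
            f"{atom.element.upper():>2s}\n")


def write_pdb(model: StructureModel, path) -> None:
    """Write a StructureModel as a PDB file (v3.3 ATOM record layout).

    Round-trips through :func:`read_structure` preserving atom counts,
    author numbering with insertion codes, and coordinates to 3 decimals.
    """
    if not model.chains and not model.het_residues:
        raise ValueError("refusing to write an empty structure")
    lines: list[str] = []
    if model.classification or model.pdb_id:
        lines.append(f"HEADER    {model.classification:<40s}{'':11s}{model.pdb_id:<4s}\n")
    if model.title:
        lines.append(f"TITLE     {model.title}\n")
    serial = 0
    for chain_id, residues in model.chains.items():
        last = None
        for res in residues:
            for atom in res.atoms:
                serial += 1
                lines.append(_format_atom_line(serial, atom, res, hetatm=False))
            last = res
        if last is not None:
            serial += 1
            lines.append(f"TER   {serial:>5d}      {last.name3:<3s} "
                         f"{last.chain_id:>1s}{last.seq_number:>4d}"
                         f"{last.insertion_code or ' ':1s}\n")
    for res in model.het_residues:
        for atom in res.atoms:
            serial += 1
            lines.append(_format_atom_line(serial, atom, res, hetatm=True))
    lines.append("END\n")
    Path(path).write_text("".join(lines))
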