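import numpy as np
import pytest

from palinscan.structure_io import Atom, Residue, StructureModel
from palinscan.synthetic_data import (GeometrySpec, build_beta_hairpin,
                                      build_ideal_peptide)


@pytest.fixture(scope="session")
def helix16():
    """Ideal poly-Ala alpha-helix, 16 residues."""
    return build_ideal_peptide(GeometrySpec(sequence="A" * 16,
                                            conformer="helix"))


@pytest.fixture(scope="session")
def hairpin():
    """Idealized two-stranded antiparallel beta-hairpin, 12 residues."""
    return build_beta_hairpin(n_strand=5)


@pytest.fixture()
def lone_carbon():
    """A single carbon atom: analytic SASA = 4*pi*(1.7+1.4)^2."""
    res = Residue("A", 1, "", "GLY", "G",
                  atoms=[Atom("CA", "C", np.zeros(3))], is_complete=False)
    return StructureModel(pdb_id="LONE", chains={"A": [res]})


def reference_dssp(model, tmp_path):
    """Secondary structure of every chain according to mdtraj's DSSP
    implementation (the independent reference), coil as 'C'."""
    import mdtraj as md

    from palinscan.structure_io import write_pdb

    path = tmp_path / "ref.pdb"
    write_pdb(model, path)
    codes = md.compute_dssp(md.load(str(path)), simplified=False)[0]
    out = {}
    k = 0
    for chain_id, residues in model.chains.items():
        out[chain_id] = "".join(codes[k:k + len(residues)]).replace(" ", "C")
        k += len(residues)
    return out
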