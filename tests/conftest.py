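"""Shared fixtures: reference parameter sets and tiny synthetic structures."""

from __future__ import annotations

import gemmi
import numpy as np
import pytest

from foldstab import ThermoParams
from foldstab.rad import StructureModel, VDW_RADII, DEFAULT_VDW


@pytest.fixture
def row70() -> ThermoParams:
    """Published parameters of the buried-core residue Leu70 of Yfh1."""
    return ThermoParams(dH_m=28.5, T_m=298.2, dCp=3.73)


def build_pdb(path, residues, hydrogens=False):
    """Write a small PDB file from [(resname, [(atom, element, xyz), ...])]."""
    st = gemmi.Structure()
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, (resname, atoms) in enumerate(residues, start=1):
        res = gemmi.Residue()
        res.name = resname
        res.seqid = gemmi.SeqId(i, " ")
        for name, element, xyz in atoms:
            if element == "H" and not hydrogens:
                continue
            a = gemmi.Atom()
            a.name = name
            a.element = gemmi.Element(element)
            a.pos = gemmi.Position(*xyz)
            res.add_atom(a)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
    return path


def tripeptide_residues(hydrogens=False):
    """Three alanine-like residues strung along x with plausible geometry."""
    out = []
    for i in range(3):
        x0 = 3.8 * i
        atoms = [
            ("N", "N", (x0, 0.0, 0.0)),
            ("CA", "C", (x0 + 1.2, 0.9, 0.3)),
            ("C", "C", (x0 + 2.5, 0.2, 0.1)),
            ("O", "O", (x0 + 2.6, -1.0, -0.2)),
            ("CB", "C", (x0 + 1.3, 1.9, 1.4)),
        ]
        if hydrogens:
            atoms.append(("H", "H", (x0 - 0.4, -0.8, 0.3)))
            atoms.append(("HA", "H", (x0 + 1.1, 1.5, -0.6)))
        out.append(("ALA", atoms))
    return out


@pytest.fixture
def tripeptide_pdb(tmp_path):
    return build_pdb(tmp_path / "tri.pdb", tripeptide_residues())


def make_model(coords, elements=None, atom_names=None, residue_numbers=None):
    """Bare StructureModel from coordinates (defaults: all N of residue 1)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    elements = np.array(elements if elements is not None else ["N"] * n)
    return StructureModel(
        elements=elements,
        residue_numbers=np.array(residue_numbers if residue_numbers is not None
                                 else [1] * n, dtype=int),
        residue_names=np.array(["GLY"] * n),
        atom_names=np.array(atom_names if atom_names is not None else ["N"] * n),
        coords=coords,
        radii=np.array([VDW_RADII.get(e, DEFAULT_VDW) for e in elements]),
    )
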