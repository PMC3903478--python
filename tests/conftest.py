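"""Shared fixtures: hand-written structure documents and model builders."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lyase_profile.structure_io import (
    AtomRecord,
    Chain,
    Residue,
    ResidueRef,
    StructureModel,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def _atom_line(serial, name, res_name, chain, res_num, x, y, z, element,
               alt="", occ=1.00, record="ATOM"):
    name_field = f" {name:<3}" if len(name) < 4 else name
    return (
        f"{record:<6}{serial:>5} {name_field}{alt or ' '}{res_name:>3} {chain}"
        f"{res_num:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2}  "
    )


@pytest.fixture
def two_chain_pdb() -> str:
    """Hand-written fixture: 2 chains × 3 residues × 4 atoms = 24 atoms."""
    lines = []
    serial = 1
    for chain in ("A", "B"):
        x0 = 0.0 if chain == "A" else 50.0
        for i, res in enumerate(("ASP", "GLU", "LYS"), start=1):
            for j, (name, element) in enumerate(
                (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"))
            ):
                lines.append(
                    _atom_line(serial, name, res, chain, i, x0 + 5.0 * i + j, 0.0, 0.0, element)
                )
                serial += 1
    return "\n".join(lines) + "\nEND\n"


@pytest.fixture
def assembly_pdb() -> str:
    """Monomer with a 4-operator assembly: identity + three rotations."""
    remark = [
        "REMARK 350 BIOMOLECULE: 1",
        "REMARK 350 APPLY THE FOLLOWING TO CHAINS: A",
    ]
    ops = [
        (np.eye(3), np.zeros(3)),
        (np.diag([-1.0, -1.0, 1.0]), np.array([30.0, 0.0, 0.0])),
        (np.diag([-1.0, 1.0, -1.0]), np.array([0.0, 30.0, 0.0])),
        (np.diag([1.0, -1.0, -1.0]), np.array([0.0, 0.0, 30.0])),
    ]
    for k, (rot, vec) in enumerate(ops, start=1):
        for r in range(3):
            remark.append(
                f"REMARK 350   BIOMT{r + 1} {k:>3} "
                f"{rot[r, 0]:9.6f} {rot[r, 1]:9.6f} {rot[r, 2]:9.6f} {vec[r]:14.5f}"
            )
    atoms = [
        _atom_line(1, "N", "ALA", "A", 1, 1.0, 2.0, 3.0, "N"),
        _atom_line(2, "CA", "ALA", "A", 1, 2.0, 2.0, 3.0, "C"),
        _atom_line(3, "CA", "GLY", "A", 2, 5.0, 2.0, 3.0, "C"),
    ]
    return "\n".join(remark + atoms) + "\nEND\n"


@pytest.fixture
def identity_assembly_pdb() -> str:
    remark = [
        "REMARK 350 BIOMOLECULE: 1",
        "REMARK 350 APPLY THE FOLLOWING TO CHAINS: A",
        "REMARK 350   BIOMT1   1  1.000000  0.000000  0.000000        0.00000",
        "REMARK 350   BIOMT2   1  0.000000  1.000000  0.000000        0.00000",
        "REMARK 350   BIOMT3   1  0.000000  0.000000  1.000000        0.00000",
    ]
    atoms = [
        _atom_line(1, "CA", "ALA", "A", 1, 1.0, 2.0, 3.0, "C"),
        _atom_line(2, "CA", "GLY", "A", 2, 5.0, 2.0, 3.0, "C"),
    ]
    return "\n".join(remark + atoms) + "\nEND\n"


@pytest.fixture
def waters_only_pdb() -> str:
    return (
        _atom_line(1, "O", "HOH", "A", 101, 1.0, 1.0, 1.0, "O", record="HETATM")
        + "\n"
        + _atom_line(2, "O", "HOH", "A", 102, 4.0, 4.0, 4.0, "O", record="HETATM")
        + "\nEND\n"
    )


@pytest.fixture
def altloc_pdb() -> str:
    lines = [
        _atom_line(1, "CA", "ASP", "A", 1, 0.0, 0.0, 0.0, "C"),
        _atom_line(2, "OD1", "ASP", "A", 1, 1.0, 0.0, 0.0, "O", alt="A", occ=0.60),
        _atom_line(3, "OD1", "ASP", "A", 1, 1.2, 0.0, 0.0, "O", alt="B", occ=0.40),
        _atom_line(4, "CA", "GLY", "A", 2, 5.0, 0.0, 0.0, "C"),
    ]
    return "\n".join(lines) + "\nEND\n"


def make_residue(chain_id, number, name, one_letter, atom_spec) -> Residue:
    """atom_spec: list of (atom_name, element, xyz)."""
    return Residue(
        ref=ResidueRef(chain_id=chain_id, residue_number=number, residue_name=name),
        one_letter=one_letter,
        atoms=[AtomRecord(name=n, element=e, position=np.asarray(p, dtype=float))
               for n, e, p in atom_spec],
    )


def make_model(residues_by_chain: dict[str, list[Residue]], structure_id="test") -> StructureModel:
    model = StructureModel(structure_id=structure_id)
    for chain_id, residues in residues_by_chain.items():
        model.chains.append(Chain(chain_id=chain_id, residues=list(residues)))
    return model


def asp_lys_model(distance: float, spread: float = 30.0) -> StructureModel:
    """Single Asp-Lys pair whose minimum O-N distance is exactly ``distance``."""
    asp = make_residue("A", 1, "ASP", "D", [
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("OD1", "O", (1.0, 0.0, 0.0)),
        ("OD2", "O", (0.0, 1.0, 0.0)),
    ])
    lys = make_residue("A", 2, "LYS", "K", [
        ("CA", "C", (1.0 + distance + 5.0, 0.0, 0.0)),
        ("NZ", "N", (1.0 + distance, 0.0, 0.0)),
    ])
    far = make_residue("A", 3, "ALA", "A", [("CA", "C", (spread, spread, spread))])
    return make_model({"A": [asp, lys, far]})
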