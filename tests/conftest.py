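"""Shared fixtures: tiny hand-built structures and cached heavy oracles."""

from __future__ import annotations

import numpy as np
import pytest

from trajnet.io import Atom, StructureModel, TrajectoryEnsemble
from trajnet.potentials import MuellerBrown, grid_minimax_saddle


def make_atom(
    name: str,
    chain: str = "A",
    resseq: int = 1,
    resname: str = "ALA",
    element: str | None = None,
    serial: int = 1,
    het: bool = False,
    icode: str = " ",
    occupancy: float = 1.0,
) -> Atom:
    if element is None:
        element = name[0]
    return Atom(serial, name, " ", resname, chain, resseq, icode,
                occupancy, 0.0, element, het)


def bead_model(positions, chain: str = "A", resname: str = "ALA",
               name: str = "CA", chains=None, resseqs=None) -> StructureModel:
    """One-bead-per-residue model at the given positions."""
    positions = np.asarray(positions, dtype=float)
    atoms = []
    for i in range(len(positions)):
        atoms.append(
            make_atom(
                name,
                chain=chains[i] if chains else chain,
                resseq=resseqs[i] if resseqs else i + 1,
                resname=resname,
                serial=i + 1,
            )
        )
    return StructureModel(atoms, positions)


def static_ensemble(model: StructureModel, n_frames: int) -> TrajectoryEnsemble:
    frames = np.broadcast_to(
        model.coords, (n_frames, model.n_atoms, 3)
    ).copy()
    return TrajectoryEnsemble(model, frames)


@pytest.fixture(scope="session")
def mueller_brown_saddle():
    """Brute-force minimax saddle of the Müller–Brown surface (2000² grid)."""
    pot = MuellerBrown()
    pos, energy = grid_minimax_saddle(
        pot, pot.MINIMUM_A, pot.MINIMUM_B, ((-1.8, 1.4), (-0.5, 2.2)), n=2000
    )
    return pos, energy


@pytest.fixture()
def two_triangle_edges():
    """Two triangles joined by one bridge: the hand-checkable GN fixture."""
    return [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]
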