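"""Shared fixtures: tiny alignments and toy structures, all built in memory."""

from __future__ import annotations

import numpy as np
import pytest

from spdca.alignment import Alignment, PairedAlignment
from spdca.dynamics import StructureFrame


def make_alignment(seqs: list[str], species: list[str] | None = None, name: str = "") -> Alignment:
    rows = np.array([list(s) for s in seqs], dtype="U1")
    species = species or [f"sp{i}" for i in range(len(seqs))]
    return Alignment(rows, species, name)


def make_paired(seqs: list[str], len_a: int, species: list[str] | None = None) -> PairedAlignment:
    rows = np.array([list(s) for s in seqs], dtype="U1")
    species = species or [f"sp{i}" for i in range(len(seqs))]
    return PairedAlignment(rows, species, len_a=len_a, len_b=len(seqs[0]) - len_a)


def make_frame(
    coords: np.ndarray,
    chains: list[str] | None = None,
    res_ids: list[int] | None = None,
    res_names: list[str] | None = None,
    atom_names: list[str] | None = None,
    elements: list[str] | None = None,
) -> StructureFrame:
    n = len(coords)
    return StructureFrame(
        chain_ids=np.array(chains or ["A"] * n),
        res_ids=np.array(res_ids or list(range(1, n + 1)), dtype=int),
        res_names=np.array(res_names or ["ALA"] * n),
        atom_names=np.array(atom_names or ["CA"] * n),
        elements=np.array(elements or ["C"] * n),
        coords=np.asarray(coords, dtype=float),
    )


def two_chain_frame(separation: float = 4.0, n_res: int = 3, atoms_per_res: int = 2) -> StructureFrame:
    """Two parallel chains of C atoms, ``separation`` Å apart along x."""
    chains, rids, names, xyz = [], [], [], []
    for c, ch in enumerate("AB"):
        for r in range(n_res):
            for a in range(atoms_per_res):
                chains.append(ch)
                rids.append(r + 1)
                names.append("CA" if a == 0 else "CB")
                xyz.append([c * separation, 3.0 * r, 1.2 * a])
    n = len(xyz)
    return StructureFrame(
        chain_ids=np.array(chains),
        res_ids=np.array(rids, dtype=int),
        res_names=np.array(["ALA"] * n),
        atom_names=np.array(names),
        elements=np.array(["C"] * n),
        coords=np.array(xyz, dtype=float),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
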