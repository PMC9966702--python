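"""Trajectory-analysis criteria for validating predicted interfaces.

Once a predicted interacting peptide pair has been simulated (e.g. with
a coarse-grained force field), the association is judged on supplied
coordinates by: the RMSD after optimal superposition (stability), the
radius of gyration (compactness), residue contact maps under the
"at least two heavy-atom pairs closer than 5 Å" rule, the per-frame
fraction of native contacts, and the screened Debye–Hückel electrostatic
energy

    V = K_elec Σ_{i<j} q_i q_j exp(−r_ij / l_D) / (ε_r r_ij),

with K_elec = (4πε0)⁻¹ = 332.24 kcal·mol⁻¹·e⁻²·Å, charges on one bead
per charged residue (Cβ, integer side-chain charges at pH 7, histidine
neutral), relative dielectric ε_r and Debye screening length l_D.  No
simulation is run here — the module is pure analysis of coordinates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.constants
import scipy.spatial

from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException


@dataclass
class StructureFrame:
    """Residue-indexed heavy/hydrogen atom coordinates for one frame."""

    chain_ids: np.ndarray    # (n_atoms,) str
    res_ids: np.ndarray      # (n_atoms,) int, 1-based author numbering
    res_names: np.ndarray    # (n_atoms,) str
    atom_names: np.ndarray   # (n_atoms,) str
    elements: np.ndarray     # (n_atoms,) str
    coords: np.ndarray       # (n_atoms, 3) Å
    is_heavy: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_hetero_skipped: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        if self.is_heavy is None:
            self.is_heavy = np.char.upper(self.elements.astype(str)) != "H"

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def select(self, predicate=None, heavy_only: bool = False) -> np.ndarray:
        """Boolean atom mask from an optional per-atom predicate."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if heavy_only:
            mask &= self.is_heavy
        if predicate is not None:
            extra = np.array(
                [
                    predicate(
                        {
                            "chain": self.chain_ids[k],
                            "res_id": int(self.res_ids[k]),
                            "res_name": self.res_names[k],
                            "atom_name": self.atom_names[k],
                            "element": self.elements[k],
                        }
                    )
                    for k in range(self.n_atoms)
                ],
                dtype=bool,
            )
            mask &= extra
        return mask

    def chain_mask(self, chain_id: str) -> np.ndarray:
        return self.chain_ids == chain_id


def read_frames(path: str | Path) -> list[StructureFrame]:
    """Parse a (possibly multi-MODEL) PDB file, one frame per MODEL.

    HETATM records (waters, ligands) are excluded and counted in
    ``n_hetero_skipped``; hydrogens are kept but flagged non-heavy by
    element.  Parsing is strict: malformed ATOM records raise with the
    parser's diagnostic (which includes the line number).
    """
    path = Path(path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise ValueError(f"{path}: unparseable PDB record: {exc}") from exc
    frames = []
    for model in structure:
        chains, resids, resnames, atnames, elements, coords = [], [], [], [], [], []
        n_het = 0
        for chain in model:
            for residue in chain:
                if residue.id[0] != " ":
                    n_het += len(residue)
                    continue
                for atom in residue:
                    chains.append(chain.id)
                    resids.append(residue.id[1])
                    resnames.append(residue.resname.strip())
                    atnames.append(atom.get_name())
                    elements.append(atom.element or "")
                    coords.append(atom.coord)
        if not coords:
            raise ValueError(f"{path}: MODEL with no ATOM records")
        frames.append(
            StructureFrame(
                chain_ids=np.array(chains),
                res_ids=np.array(resids, dtype=int),
                res_names=np.array(resnames),
                atom_names=np.array(atnames),
                elements=np.array(elements),
                coords=np.array(coords, dtype=float),
                n_hetero_skipped=n_het,
            )
        )
    if not frames:
        raise ValueError(f"{path}: no models found")
    return frames


def write_frames(frames: list[StructureFrame], path: str | Path) -> None:
    """Write frames as a multi-MODEL PDB (plain-text fixture helper)."""
    with open(path, "w") as fh:
        for m, fr in enumerate(frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for k in range(fr.n_atoms):
                name = fr.atom_names[k]
                pad = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    f"ATOM  {k + 1:5d} {pad:<4s} {fr.res_names[k]:<3s} "
                    f"{fr.chain_ids[k]}{int(fr.res_ids[k]):4d}    "
                    f"{fr.coords[k, 0]:8.3f}{fr.coords[k, 1]:8.3f}{fr.coords[k, 2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {fr.elements[k]:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Geometry


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rotation (SVD construction with reflection correction)."""
    H = mobile.T @ reference
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def kabsch_rmsd(
    mobile: StructureFrame,
    reference: StructureFrame,
    selection=None,
) -> float:
    """Minimal RMSD (Å) after optimal rigid superposition.

    Atoms correspond by order within the selection; both frames must
    select the same number of atoms (≥ 3 for a well-posed rotation).
    """
    mm = mobile.select(selection)
    rm = reference.select(selection)
    X = mobile.coords[mm]
    Y = reference.coords[rm]
    if X.shape != Y.shape:
        raise ValueError(f"selection sizes differ: {X.shape[0]} vs {Y.shape[0]}")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 atoms for superposition")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    R = kabsch_rotation(Xc, Yc)
    diff = Xc @ R.T - Yc
    return float(np.sqrt((diff ** 2).sum() / X.shape[0]))


def radius_of_gyration(
    frame: StructureFrame, selection=None, masses: np.ndarray | None = None
) -> float:
    """sqrt(Σ m_k |r_k − r_com|² / Σ m_k), unit masses by default (Å)."""
    mask = frame.select(selection)
    X = frame.coords[mask]
    if X.shape[0] == 0:
        raise ValueError("empty selection")
    m = np.ones(X.shape[0]) if masses is None else np.asarray(masses, dtype=float)[: X.shape[0]]
    com = (m[:, None] * X).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((X - com) ** 2).sum(axis=1)).sum() / m.sum()))


# ---------------------------------------------------------------------------
# Contacts


@dataclass
class ContactMap:
    """Boolean residue-residue contacts between two chains.

    contact(r_a, r_b) is true iff at least ``min_atom_pairs`` heavy-atom
    pairs (one atom from each residue) are separated by strictly less
    than ``cutoff`` Å.
    """

    matrix: np.ndarray           # (n_res_a, n_res_b) bool
    res_ids_a: np.ndarray
    res_ids_b: np.ndarray
    chain_a: str
    chain_b: str
    cutoff: float = 5.0
    min_atom_pairs: int = 2

    @property
    def n_contacts(self) -> int:
        return int(self.matrix.sum())


def residue_contact_map(
    frame: StructureFrame,
    chain_a: str,
    chain_b: str,
    cutoff: float = 5.0,
    min_atom_pairs: int = 2,
) -> ContactMap:
    """Inter-chain residue contact map under the heavy-atom pair-count rule."""
    ma = frame.chain_mask(chain_a) & frame.is_heavy
    mb = frame.chain_mask(chain_b) & frame.is_heavy
    if not ma.any():
        raise ValueError(f"chain {chain_a!r} absent or has no heavy atoms")
    if not mb.any():
        raise ValueError(f"chain {chain_b!r} absent or has no heavy atoms")
    res_a = np.unique(frame.res_ids[ma])
    res_b = np.unique(frame.res_ids[mb])
    ia = {r: k for k, r in enumerate(res_a)}
    ib = {r: k for k, r in enumerate(res_b)}
    d = scipy.spatial.distance.cdist(frame.coords[ma], frame.coords[mb])
    close = d < cutoff
    counts = np.zeros((res_a.size, res_b.size), dtype=int)
    ra = np.array([ia[r] for r in frame.res_ids[ma]])
    rb = np.array([ib[r] for r in frame.res_ids[mb]])
    np.add.at(counts, (ra[:, None].repeat(rb.size, 1), rb[None, :].repeat(ra.size, 0)), close)
    return ContactMap(
        matrix=counts >= min_atom_pairs,
        res_ids_a=res_a,
        res_ids_b=res_b,
        chain_a=chain_a,
        chain_b=chain_b,
        cutoff=cutoff,
        min_atom_pairs=min_atom_pairs,
    )


def native_contact_fraction(
    frames: list[StructureFrame], native: ContactMap
) -> np.ndarray:
    """Per-frame fraction of the native contacts present (same cutoff rule)."""
    n_native = native.n_contacts
    if n_native == 0:
        raise ValueError("native contact map is empty")
    out = np.empty(len(frames))
    for k, fr in enumerate(frames):
        cm = residue_contact_map(
            fr, native.chain_a, native.chain_b, native.cutoff, native.min_atom_pairs
        )
        # align residue index sets (frames may renumber nothing here, but be safe)
        common_a = np.intersect1d(native.res_ids_a, cm.res_ids_a)
        common_b = np.intersect1d(native.res_ids_b, cm.res_ids_b)
        na = np.searchsorted(native.res_ids_a, common_a)
        nb = np.searchsorted(native.res_ids_b, common_b)
        fa = np.searchsorted(cm.res_ids_a, common_a)
        fb = np.searchsorted(cm.res_ids_b, common_b)
        nat = native.matrix[np.ix_(na, nb)]
        now = cm.matrix[np.ix_(fa, fb)]
        present = int((nat & now).sum())
        out[k] = present / n_native
    return out


# ---------------------------------------------------------------------------
# Electrostatics


#: integer side-chain charges at pH 7 (histidine neutral)
DEFAULT_CHARGES = {"ASP": -1.0, "GLU": -1.0, "LYS": 1.0, "ARG": 1.0}

K_ELEC = 332.24  # kcal·mol⁻¹·e⁻²·Å, (4π ε0)⁻¹ in these units


def debye_length(temperature: float = 300.0, ionic_strength: float = 0.1,
                 eps_r: float = 80.0) -> float:
    """Debye screening length in Å from T (K) and ionic strength (mol/L).

    l_D = sqrt(ε_r ε0 k_B T / (2 N_A e² I)), with I converted to mol/m³.
    For water at 300 K and 0.1 M this gives ≈ 9.7 Å.
    """
    if temperature <= 0 or ionic_strength <= 0 or eps_r <= 0:
        raise ValueError("temperature, ionic strength and eps_r must be positive")
    c = scipy.constants
    I = ionic_strength * 1000.0  # mol/m³
    lam = math.sqrt(
        eps_r * c.epsilon_0 * c.k * temperature / (2 * c.N_A * c.e ** 2 * I)
    )
    return lam * 1e10


@dataclass
class ElectrostaticParams:
    """Parameters of the screened Debye–Hückel energy."""

    k_elec: float = K_ELEC
    eps_r: float = 80.0
    l_d: float = 10.0                       # Å
    charges: dict = field(default_factory=lambda: dict(DEFAULT_CHARGES))

    def __post_init__(self) -> None:
        if self.eps_r <= 0 or self.l_d <= 0:
            raise ValueError("eps_r and l_d must be positive")

    @classmethod
    def from_conditions(
        cls, temperature: float, ionic_strength: float, eps_r: float = 80.0, **kw
    ) -> "ElectrostaticParams":
        return cls(eps_r=eps_r, l_d=debye_length(temperature, ionic_strength, eps_r), **kw)


def _default_beads(frame: StructureFrame, charges: dict) -> np.ndarray:
    """One bead per charged residue: its Cβ atom (Cα for glycine)."""
    mask = np.zeros(frame.n_atoms, dtype=bool)
    key = np.char.add(np.char.add(frame.chain_ids.astype(str), ":"),
                      frame.res_ids.astype(str))
    for rk in np.unique(key):
        rmask = key == rk
        resname = frame.res_names[rmask][0]
        if resname not in charges:
            continue
        names = frame.atom_names[rmask]
        for want in ("CB", "CA"):
            hit = np.where(rmask)[0][names == want]
            if hit.size:
                mask[hit[0]] = True
                break
    return mask


def debye_huckel_energy(
    frame: StructureFrame,
    params: ElectrostaticParams | None = None,
    bead_selection: np.ndarray | None = None,
    bead_charges: np.ndarray | None = None,
    inter_chain_only: bool = False,
) -> float:
    """Screened electrostatic energy (kcal/mol) over charged-bead pairs.

    By default one bead per charged residue (Cβ position, integer charge
    at pH 7).  ``bead_selection``/``bead_charges`` override the defaults
    with an explicit atom mask and per-bead charges in elementary units.
    """
    params = params or ElectrostaticParams()
    if bead_selection is None:
        bead_selection = _default_beads(frame, params.charges)
        beads = np.where(bead_selection)[0]
        q = np.array([params.charges[frame.res_names[k]] for k in beads])
    else:
        bead_selection = np.asarray(bead_selection)
        if bead_selection.dtype == bool:
            beads = np.where(bead_selection)[0]
        else:
            beads = bead_selection.astype(int)
        if bead_charges is None:
            q = np.array(
                [params.charges.get(frame.res_names[k], 0.0) for k in beads]
            )
        else:
            q = np.asarray(bead_charges, dtype=float)
            if q.size != beads.size:
                raise ValueError("bead_charges does not match bead selection")
    if beads.size < 2 or not np.any(q):
        return 0.0
    X = frame.coords[beads]
    ii, jj = np.triu_indices(beads.size, k=1)
    if inter_chain_only:
        ch = frame.chain_ids[beads]
        keep = ch[ii] != ch[jj]
        ii, jj = ii[keep], jj[keep]
    if ii.size == 0:
        return 0.0
    r = np.linalg.norm(X[ii] - X[jj], axis=1)
    if np.any(r == 0.0):
        raise ValueError("coincident charged beads (r_ij = 0)")
    V = params.k_elec * (q[ii] * q[jj] / (params.eps_r * r)) * np.exp(-r / params.l_d)
    return float(V.sum())


# ---------------------------------------------------------------------------
# Per-trajectory summary


def trajectory_summary(
    frames: list[StructureFrame],
    reference: StructureFrame,
    chain_a: str,
    chain_b: str,
    cutoff: float = 5.0,
    min_atom_pairs: int = 2,
    electrostatics: ElectrostaticParams | None = None,
) -> pd.DataFrame:
    """Frame-by-frame RMSD, Rg, native-contact fraction and DH energy."""
    native = residue_contact_map(reference, chain_a, chain_b, cutoff, min_atom_pairs)
    if native.n_contacts == 0:
        warnings.warn("reference has no inter-chain contacts; native fraction is NaN",
                      stacklevel=2)
        qfrac = np.full(len(frames), np.nan)
    else:
        qfrac = native_contact_fraction(frames, native)
    rows = []
    for k, fr in enumerate(frames):
        rows.append(
            {
                "frame": k,
                "rmsd": kabsch_rmsd(fr, reference),
                "rg": radius_of_gyration(fr),
                "native_fraction": qfrac[k],
                "dh_energy": debye_huckel_energy(
                    fr, electrostatics, inter_chain_only=True
                ),
            }
        )
    return pd.DataFrame(rows)
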