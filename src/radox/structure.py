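"""Fragment-level structural descriptors from trajectory snapshots.

Re-implements the descriptor layer of an MD post-analysis: rigid Cα
superposition (Kabsch), backbone/side-chain RMSD per peptide fragment,
Shrake–Rupley solvent-accessible surface area with a hydrophobic/hydrophilic
split and its proportional solvation free-energy estimate, geometric
hydrogen-bond detection, and the fragment "occupancy" statistic — the sum
over hydrogen bonds attributed to a fragment of the percentage of frames in
which each bond exists (it can exceed 100%).

Coordinates are nanometres internally; RMSD is reported in Å to match the
field's tables. The simulation engine itself (force field, thermostat,
constraints) is out of scope: inputs are snapshots plus a per-atom metadata
sidecar carrying what a PDB cannot (vdW radius, partial charge, backbone
flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

#: default solvation surface-tension coefficient, kJ/mol/nm^2 (proportional
#: regression of reference Trp side-chain SASA/ΔG_solv pairs; see docs)
GAMMA_SOLV = -2.51

#: hydrophobicity split: |partial charge| below this is a hydrophobic atom
HYDROPHOBIC_CHARGE_CUTOFF = 0.2


@dataclass(frozen=True)
class AtomRecord:
    name: str
    element: str
    res_index: int  # 1-based
    res_name: str
    is_backbone: bool
    radius: float  # vdW radius, nm
    charge: float  # partial charge, e

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError(f"atom {self.name}: radius must be > 0")
        if (self.name in BACKBONE_NAMES) != self.is_backbone:
            raise ValueError(
                f"atom {self.name}: backbone flag inconsistent with atom name"
            )


@dataclass(frozen=True)
class FragmentSpec:
    """A named 1-based inclusive residue range."""

    name: str
    start: int
    end: int

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad fragment range {self.start}-{self.end}")

    def contains(self, res_index) -> bool:
        return (self.start <= np.asarray(res_index)) & (np.asarray(res_index) <= self.end)


class Trajectory:
    """Ordered snapshots over a fixed atom roster.

    ``coords`` has shape (n_frames, n_atoms, 3) in nm. Per-atom metadata is
    exposed as numpy arrays (``radii``, ``charges``, ``backbone``, ...).
    """

    def __init__(self, atoms: Sequence[AtomRecord], coords, dt_ps: float = 2.0):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if coords.shape[1] != len(atoms):
            raise ValueError("coordinate atom count does not match roster")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        self.atoms = tuple(atoms)
        self.coords = coords
        self.dt_ps = float(dt_ps)
        self.names = np.array([a.name for a in atoms])
        self.elements = np.array([a.element for a in atoms])
        self.res_index = np.array([a.res_index for a in atoms])
        self.res_names = np.array([a.res_name for a in atoms])
        self.backbone = np.array([a.is_backbone for a in atoms])
        self.radii = np.array([a.radius for a in atoms])
        self.charges = np.array([a.charge for a in atoms])
        self.heavy = self.elements != "H"

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def with_coords(self, coords) -> "Trajectory":
        return Trajectory(self.atoms, coords, self.dt_ps)


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def superpose(
    traj: Trajectory,
    reference_frame: int = 0,
    selection: Optional[np.ndarray] = None,
) -> Trajectory:
    """Rigid superposition of every frame onto the reference frame.

    Each frame receives the optimal rotation + translation (Kabsch) that
    minimizes the RMSD of the selected atoms (default: Cα) against the
    reference frame. The returned trajectory has the transform applied to
    all atoms.
    """
    if selection is None:
        selection = traj.names == "CA"
    selection = np.asarray(selection, dtype=bool)
    if selection.sum() < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    ref = traj.coords[reference_frame][selection]
    ref_centroid = ref.mean(axis=0)
    ref_c = ref - ref_centroid
    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        sel = traj.coords[f][selection]
        centroid = sel.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_c, sel - centroid)
        out[f] = rot.apply(traj.coords[f] - centroid) + ref_centroid
    return traj.with_coords(out)


def fragment_rmsd(
    traj: Trajectory,
    frag: FragmentSpec,
    part: str = "backbone",
    reference_frame: int = 0,
) -> float:
    """Mean-over-frames RMSD (Å) of a fragment's heavy atoms vs the reference.

    ``part`` selects backbone (N, Cα, C, O) or side-chain (all other heavy
    atoms). The trajectory is assumed already superposed; no fitting happens
    here. A fragment with no atoms of the requested part (e.g. a glycine-only
    fragment with part='side-chain') returns NaN.
    """
    in_frag = frag.contains(traj.res_index)
    if part == "backbone":
        mask = in_frag & traj.backbone & traj.heavy
    elif part in ("side-chain", "sidechain"):
        mask = in_frag & ~traj.backbone & traj.heavy
    else:
        raise ValueError(f"unknown part {part!r}")
    if not mask.any():
        return math.nan
    ref = traj.coords[reference_frame][mask]
    per_frame = [
        _rmsd(traj.coords[f][mask], ref) for f in range(traj.n_frames)
    ]
    return 10.0 * float(np.mean(per_frame))  # nm -> Å


# ---------------------------------------------------------------------------
# solvent accessibility


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    frame: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 0.14,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Shrake–Rupley per-atom solvent-accessible surface area (nm²).

    Each atom is expanded by the probe radius and sampled with a fixed
    quasi-uniform point set; points inside any neighbor's expanded sphere are
    occluded. The accessible fraction times the expanded-sphere area is the
    atom's SASA.
    """
    frame = np.asarray(frame, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if radii.shape[0] != frame.shape[0]:
        raise ValueError("one radius per atom required")
    if not np.all(np.isfinite(radii)) or np.any(radii <= 0):
        raise ValueError("missing or non-positive atom radius")
    if probe_radius < 0:
        raise ValueError("probe radius must be >= 0")
    if n_sphere_points < 100:
        raise ValueError("need at least 100 sphere points")
    expanded = radii + probe_radius
    unit = _sphere_points(n_sphere_points)
    tree = cKDTree(frame)
    r_max = expanded.max()
    areas = np.empty(len(frame))
    for i in range(len(frame)):
        pts = frame[i] + expanded[i] * unit
        neighbors = tree.query_ball_point(frame[i], expanded[i] + r_max)
        neighbors = [j for j in neighbors if j != i]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - frame[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        areas[i] = 4.0 * math.pi * expanded[i] ** 2 * accessible.mean()
    return areas


def sasa_split(areas: np.ndarray, charges: np.ndarray):
    """Split per-atom SASA into (hydrophobic, hydrophilic, total) nm².

    Atoms with |partial charge| strictly below 0.2 e count as hydrophobic;
    the boundary |q| = 0.2 is hydrophilic.
    """
    areas = np.asarray(areas, dtype=float)
    charges = np.asarray(charges, dtype=float)
    phob_mask = np.abs(charges) < HYDROPHOBIC_CHARGE_CUTOFF
    phob = float(areas[phob_mask].sum())
    phil = float(areas[~phob_mask].sum())
    return phob, phil, phob + phil


def dg_solv(total_sasa: float, gamma: float = GAMMA_SOLV) -> float:
    """Proportional solvation free-energy estimate: gamma × total SASA (kJ/mol)."""
    if not math.isfinite(gamma):
        raise ValueError("gamma must be finite")
    return gamma * total_sasa


def fit_gamma(total_sasa: Sequence[float], dg: Sequence[float]) -> float:
    """Proportional (through-origin) least-squares slope ΔG ≈ γ·SASA."""
    x = np.asarray(total_sasa, dtype=float)
    y = np.asarray(dg, dtype=float)
    return float((x @ y) / (x @ x))


# ---------------------------------------------------------------------------
# hydrogen bonds


@dataclass(frozen=True)
class HBond:
    donor: int  # heavy donor atom index
    hydrogen: int
    acceptor: int
    donor_res: int
    acceptor_res: int
    donor_sidechain: bool
    acceptor_sidechain: bool


@dataclass(frozen=True)
class HBondExistence:
    """Hydrogen bonds plus their per-frame boolean existence matrix."""

    bonds: tuple
    matrix: np.ndarray  # (n_bonds, n_frames) bool

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=bool)
        if m.ndim != 2 or m.shape[0] != len(self.bonds):
            raise ValueError("existence matrix shape inconsistent with bond list")
        object.__setattr__(self, "matrix", m)


def donor_hydrogen_pairs(
    frame: np.ndarray, traj: Trajectory, bond_cutoff: float = 0.125
) -> list:
    """Infer covalent donor–H pairs: each H bonds to the nearest N/O within cutoff."""
    h_idx = np.where(traj.elements == "H")[0]
    if h_idx.size == 0:
        raise ValueError(
            "no hydrogens in the atom roster; hydrogen-bond detection needs "
            "explicit H atoms (polar hydrogens at minimum)"
        )
    heavy_no = np.where((traj.elements == "N") | (traj.elements == "O"))[0]
    pairs = []
    for h in h_idx:
        d = np.linalg.norm(frame[heavy_no] - frame[h], axis=1)
        j = int(np.argmin(d))
        if d[j] <= bond_cutoff:
            pairs.append((int(heavy_no[j]), int(h)))
    return pairs


def detect_hbonds(
    frame: np.ndarray,
    traj: Trajectory,
    d_cut: float = 0.35,
    angle_cut: float = 30.0,
    dh_pairs: Optional[list] = None,
) -> set:
    """Geometric hydrogen bonds in one frame.

    A bond (donor D, hydrogen H, acceptor A) is present iff the D–A distance
    is ≤ ``d_cut`` (nm) and the H–D–A angle at the donor is ≤ ``angle_cut``
    (degrees). Donors are N/O with an attached hydrogen; acceptors are any
    other N/O. Returns a set of (donor, hydrogen, acceptor) index triples.
    """
    frame = np.asarray(frame, dtype=float)
    if dh_pairs is None:
        dh_pairs = donor_hydrogen_pairs(frame, traj)
    acceptors = np.where((traj.elements == "N") | (traj.elements == "O"))[0]
    present = set()
    cos_cut = math.cos(math.radians(angle_cut))
    for d_i, h_i in dh_pairs:
        da = frame[acceptors] - frame[d_i]
        dist = np.linalg.norm(da, axis=1)
        dh = frame[h_i] - frame[d_i]
        dh_norm = np.linalg.norm(dh)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = (da @ dh) / (dist * dh_norm)
        ok = (dist <= d_cut) & (dist > 0) & (cosang >= cos_cut)
        for a_i in acceptors[ok]:
            if a_i != d_i:
                present.add((d_i, h_i, int(a_i)))
    return present


def hbond_existence(
    traj: Trajectory, d_cut: float = 0.35, angle_cut: float = 30.0
) -> HBondExistence:
    """Scan the whole trajectory and build the bond × frame existence matrix.

    Donor–H covalent assignment is taken from frame 0 (topology is fixed).
    Bonds are ordered deterministically by (donor, hydrogen, acceptor).
    """
    dh_pairs = donor_hydrogen_pairs(traj.coords[0], traj)
    per_frame = [
        detect_hbonds(traj.coords[f], traj, d_cut, angle_cut, dh_pairs=dh_pairs)
        for f in range(traj.n_frames)
    ]
    all_bonds = sorted(set().union(*per_frame)) if per_frame else []
    matrix = np.zeros((len(all_bonds), traj.n_frames), dtype=bool)
    index = {b: i for i, b in enumerate(all_bonds)}
    for f, bonds in enumerate(per_frame):
        for b in bonds:
            matrix[index[b], f] = True
    records = tuple(
        HBond(
            donor=d, hydrogen=h, acceptor=a,
            donor_res=int(traj.res_index[d]),
            acceptor_res=int(traj.res_index[a]),
            donor_sidechain=not bool(traj.backbone[d]),
            acceptor_sidechain=not bool(traj.backbone[a]),
        )
        for d, h, a in all_bonds
    )
    return HBondExistence(bonds=records, matrix=matrix)


def occupancy(
    existence: HBondExistence, frag: FragmentSpec, scope: str = "total"
) -> float:
    """Fragment H-bond occupancy: sum over attributed bonds of percent presence.

    A bond is attributed to the fragment when either partner residue lies in
    the fragment's range (counted once even if both do). With
    ``scope='side-chain'`` the fragment-side partner must additionally be a
    side-chain atom. The result is a percent-sum and may exceed 100.
    """
    if existence.matrix.size == 0:
        return 0.0
    if scope not in ("total", "side-chain", "sidechain"):
        raise ValueError(f"unknown scope {scope!r}")
    total = 0.0
    n_frames = existence.matrix.shape[1]
    for bond, row in zip(existence.bonds, existence.matrix):
        partners = []
        if frag.start <= bond.donor_res <= frag.end:
            partners.append(bond.donor_sidechain)
        if frag.start <= bond.acceptor_res <= frag.end:
            partners.append(bond.acceptor_sidechain)
        if not partners:
            continue
        if scope != "total" and not any(partners):
            continue
        total += 100.0 * row.sum() / n_frames
    return total


# ---------------------------------------------------------------------------
# descriptor pipeline


def compute_descriptors(
    traj: Trajectory,
    fragments: Sequence[FragmentSpec],
    form: str,
    run: str,
    probe_radius: float = 0.14,
    n_sphere_points: int = 960,
    sasa_stride: int = 1,
    d_cut: float = 0.35,
    angle_cut: float = 30.0,
    gamma: float = GAMMA_SOLV,
    superpose_first: bool = True,
) -> pd.DataFrame:
    """Per-fragment descriptor table for one trajectory.

    Cα-superposes the trajectory (frame 0 reference), then computes per
    fragment: mean backbone and side-chain RMSD (Å), frame-averaged SASA
    split and total (nm², side-chain heavy atoms, every ``sasa_stride``-th
    frame), ΔG_solv (kJ/mol), and total / side-chain H-bond occupancy (%).
    Deterministic: identical inputs give an identical table.
    """
    if superpose_first:
        traj = superpose(traj)
    existence = hbond_existence(traj, d_cut=d_cut, angle_cut=angle_cut)
    sasa_frames = range(0, traj.n_frames, sasa_stride)
    per_frame_areas = [sasa(traj.coords[f], traj.radii, probe_radius, n_sphere_points)
                       for f in sasa_frames]
    rows = []
    for frag in fragments:
        mask = frag.contains(traj.res_index) & ~traj.backbone & traj.heavy
        phobs, phils = [], []
        for areas in per_frame_areas:
            ph, pl, _ = sasa_split(areas[mask], traj.charges[mask])
            phobs.append(ph)
            phils.append(pl)
        phob = float(np.mean(phobs))
        phil = float(np.mean(phils))
        total = phob + phil
        rows.append(
            dict(
                fragment=frag.name,
                form=form,
                run=run,
                rmsd_backbone_A=fragment_rmsd(traj, frag, "backbone"),
                rmsd_sidechain_A=fragment_rmsd(traj, frag, "side-chain"),
                sasa_hydrophobic_nm2=phob,
                sasa_hydrophilic_nm2=phil,
                sasa_total_nm2=total,
                dg_solv_kj_mol=dg_solv(total, gamma),
                occupancy_total=occupancy(existence, frag, "total"),
                occupancy_sidechain=occupancy(existence, frag, "side-chain"),
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exchange formats: multi-MODEL PDB + atom-attribute sidecar CSV

SIDECAR_COLUMNS = [
    "name", "element", "res_index", "res_name", "backbone", "radius_nm", "charge_e",
]


def write_trajectory(traj: Trajectory, pdb_path, sidecar_path) -> None:
    """Write snapshots as a multi-MODEL PDB plus an atom-attribute CSV sidecar."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = traj.n_atoms
    stack = struc.AtomArrayStack(traj.n_frames, n)
    stack.coord = traj.coords * 10.0  # nm -> Å
    stack.atom_name = traj.names
    stack.element = traj.elements
    stack.res_id = traj.res_index
    stack.res_name = traj.res_names
    stack.chain_id = np.full(n, "A")
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(pdb_path))
    pd.DataFrame(
        dict(
            name=traj.names, element=traj.elements, res_index=traj.res_index,
            res_name=traj.res_names, backbone=traj.backbone.astype(int),
            radius_nm=traj.radii, charge_e=traj.charges,
        )
    ).to_csv(sidecar_path, index=False)


def read_trajectory(pdb_path, sidecar_path, dt_ps: float = 2.0) -> Trajectory:
    """Read a multi-MODEL PDB and its sidecar back into a Trajectory."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(pdb_path))
    stack = pdb.get_structure()
    side = pd.read_csv(sidecar_path)
    missing = [c for c in SIDECAR_COLUMNS if c not in side.columns]
    if missing:
        raise ValueError(f"sidecar missing columns: {missing}")
    if len(side) != stack.array_length():
        raise ValueError("sidecar row count does not match PDB atom count")
    atoms = [
        AtomRecord(
            name=str(r["name"]), element=str(r["element"]),
            res_index=int(r["res_index"]), res_name=str(r["res_name"]),
            is_backbone=bool(r["backbone"]), radius=float(r["radius_nm"]),
            charge=float(r["charge_e"]),
        )
        for _, r in side.iterrows()
    ]
    coords = stack.coord / 10.0  # Å -> nm
    return Trajectory(atoms, coords, dt_ps=dt_ps)
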