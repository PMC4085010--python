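"""Synthetic inputs with the statistical structure the analysis assumes.

Everything here is a pure function of (spec, seed): dose-response series with
multiplicative lognormal noise around a known kinetic curve, toy helical
trajectories with controlled per-atom Gaussian fluctuation (optionally with
random rigid motions to exercise superposition, and with Bernoulli-switched
donor–H···acceptor probes to exercise hydrogen-bond statistics), and Bernoulli
existence matrices for the occupancy statistic. Ground-truth parameters are
returned alongside the data so recovery tests can close the loop.

Also provides the hen egg-white lysozyme fixture: the 129-residue mature
chain, the six SRM-monitored fragments, the detected-peptide set (eight
non-oxidized plus Met- and Trp-oxidized forms) and the validated Q1/Q3 ion
panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .kinetics import PAPER_DOSES, DecayFit, DoseSeries, FormDecayFit
from .peptides import CARBAMIDOMETHYL, OXIDATION, ProteinRecord, digest
from .structure import AtomRecord, FragmentSpec, HBond, HBondExistence, Trajectory

# ---------------------------------------------------------------------------
# lysozyme fixture

#: mature 129-residue hen egg-white lysozyme chain
LYSOZYME_SEQUENCE = (
    "KVFGRCELAAAMKRHGLDNYRGYSLGNWVCAAKFESNFNTQATNRNTDGSTDYGILQINSR"
    "WWCNDGRTPGSRNLCNIPCSALLSSDITASVNCAKKIVSDGNGMNAWVAWRNRCKGTDVQAWIRGCRL"
)

#: the six SRM-monitored fragments, 1-based inclusive ranges
LYSOZYME_FRAGMENTS = (
    ("CELAAAMK", 6, 13),
    ("HGLDNYR", 15, 21),
    ("GYSLGNWVCAAK", 22, 33),
    ("FESNFNTQATNR", 34, 45),
    ("WWCNDGR", 62, 68),
    ("GTDVQAWIR", 117, 125),
)

#: validated SRM ion panel, keyed by annotated peptide (``*`` = oxidation)
SRM_ION_PANEL = {
    "CELAAAMK": (("y", 5), ("y", 6), ("b", 2)),
    "HGLDNYR": (("y", 5), ("y", 6), ("b", 2)),
    "GYSLGNWVCAAK": (("y", 8), ("y", 10), ("b", 2)),
    "FESNFNTQATNR": (("y", 8), ("y", 10), ("b", 2)),
    "WWCNDGR": (("y", 2), ("y", 5), ("y", 6)),
    "GTDVQAWIR": (("y", 5), ("y", 7), ("b", 2)),
    "CELAAAM*K": (("y", 5), ("y", 6), ("b", 2)),
    "GTDVQAW*IR": (("y", 5), ("y", 6), ("b", 2)),
}

_CYS_POSITIONS = frozenset({6, 30, 64, 76, 80, 94, 115, 127})


def lysozyme_fixture():
    """The lysozyme ProteinRecord and the six monitored FragmentSpecs.

    Internal consistency is asserted at call time: the chain is 129 residues,
    every fragment range extracts its stated sequence, and all eight Cys sit
    at their documented positions.
    """
    protein = ProteinRecord(id="LYSC_CHICK", sequence=LYSOZYME_SEQUENCE)
    assert protein.length == 129
    frags = []
    for seq, start, end in LYSOZYME_FRAGMENTS:
        assert protein.sequence[start - 1 : end] == seq, seq
        frags.append(FragmentSpec(name=seq, start=start, end=end))
    assert {i + 1 for i, r in enumerate(protein.sequence) if r == "C"} == set(
        _CYS_POSITIONS
    )
    return protein, frags


def detected_peptides(protein: Optional[ProteinRecord] = None) -> list:
    """The ten detected tryptic peptides: eight non-oxidized (carbamidomethyl
    on every Cys) plus oxidized CELAAAM*K (Met12) and GTDVQAW*IR (Trp123).

    The two >12-residue peptides (NTDGSTDYGILQINSR, IVSDGNGMNAWVAWR) are in
    the list; the transition builder's length cutoff excludes them.
    """
    if protein is None:
        protein, _ = lysozyme_fixture()
    wanted = [
        "CELAAAMK", "HGLDNYR", "GYSLGNWVCAAK", "FESNFNTQATNR",
        "NTDGSTDYGILQINSR", "WWCNDGR", "IVSDGNGMNAWVAWR", "GTDVQAWIR",
    ]
    by_seq = {p.sequence: p for p in digest(protein, 0)}
    base = [by_seq[s].with_fixed_mod(CARBAMIDOMETHYL) for s in wanted]
    ox = [
        by_seq["CELAAAMK"].with_fixed_mod(CARBAMIDOMETHYL).with_mod(12, OXIDATION),
        by_seq["GTDVQAWIR"].with_fixed_mod(CARBAMIDOMETHYL).with_mod(123, OXIDATION),
    ]
    return base + ox


# ---------------------------------------------------------------------------
# dose-response generator


@dataclass(frozen=True)
class DoseResponseSpec:
    """One synthetic SRM dose-response experiment.

    The defaults are the study conditions: the ten-point dose ladder
    0–5000 Gy, three transitions per peptide, triplicate replicates, and 10%
    multiplicative noise (the reported replicate CVs were all below 20%).
    """

    params: object  # DecayFit or FormDecayFit (callable on dose)
    fragment: str = "synthetic"
    doses: tuple = PAPER_DOSES
    transitions: int = 3
    replicates: int = 3
    noise_cv: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ValueError("noise CV must be >= 0")
        if 0.0 not in self.doses:
            raise ValueError("dose ladder must include 0")


def gen_dose_response(spec: DoseResponseSpec):
    """Generate DoseSeries with multiplicative lognormal noise.

    The noise factor is lognormal with unit mean and coefficient of variation
    ``noise_cv`` (σ_log = sqrt(ln(1 + CV²))). Returns (series, truth) where
    truth records the generating parameters.
    """
    rng = np.random.default_rng(spec.seed)
    d = np.asarray(spec.doses, dtype=float)
    clean = np.asarray(spec.params(d), dtype=float)
    cv = spec.noise_cv / 100.0
    sigma = math.sqrt(math.log1p(cv * cv))
    series = []
    for rep in range(spec.replicates):
        for tr in range(spec.transitions):
            if cv > 0:
                noise = np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=d.size))
            else:
                noise = np.ones_like(d)
            series.append(
                DoseSeries(
                    fragment=spec.fragment,
                    transition=f"T{tr + 1}",
                    replicate=f"R{rep + 1}",
                    doses=tuple(d),
                    intensities=tuple(clean * noise),
                )
            )
    truth = dict(params=spec.params, noise_cv=spec.noise_cv, seed=spec.seed,
                 clean=tuple(clean))
    return series, truth


# ---------------------------------------------------------------------------
# trajectory generator

_RADII = {"N": 0.155, "O": 0.152, "C": 0.17, "H": 0.12, "S": 0.18}


def _helix_base(n_residues: int):
    """Idealized helical peptide: backbone N/H/CA/C/O plus CB/CG side chain."""
    atoms, coords = [], []
    radius, rise, twist = 0.23, 0.15, math.radians(100.0)
    offsets = {
        # local-frame offsets from CA, nm: (name, element, backbone, charge, xyz)
        "N": ("N", True, -0.42, (-0.145, 0.05, -0.04)),
        "H": ("H", False, 0.27, (-0.225, -0.02, -0.04)),
        "CA": ("C", True, 0.03, (0.0, 0.0, 0.0)),
        "C": ("C", True, 0.60, (0.15, 0.0, 0.04)),
        "O": ("O", True, -0.57, (0.17, 0.12, 0.04)),
        "CB": ("C", False, 0.05, (0.0, -0.12, 0.08)),
        "CG": ("C", False, -0.10, (0.05, -0.24, 0.13)),
    }
    for i in range(n_residues):
        ang = i * twist
        ca = np.array([radius * math.cos(ang), radius * math.sin(ang), i * rise])
        rot = np.array(
            [[math.cos(ang), -math.sin(ang), 0],
             [math.sin(ang), math.cos(ang), 0],
             [0, 0, 1.0]]
        )
        for name, (elem, bb, q, off) in offsets.items():
            # the CA record carries name "CA" so the backbone flag stays
            # consistent with BACKBONE_NAMES
            atom_name = name
            atoms.append(
                AtomRecord(
                    name=atom_name, element=elem, res_index=i + 1, res_name="ALA",
                    is_backbone=atom_name in ("N", "CA", "C", "O"),
                    radius=_RADII[elem], charge=q,
                )
            )
            coords.append(ca + rot @ np.asarray(off))
    return atoms, np.asarray(coords)


@dataclass(frozen=True)
class TrajectorySpec:
    """Toy trajectory: helix base + per-atom Gaussian fluctuation.

    ``sigma`` is the per-coordinate displacement (nm) applied independently
    to every atom of every frame after frame 0 (frame 0 is the exact base, so
    the expected all-atom RMSD against it is σ√3). ``rigid_motions`` applies
    an additional random rotation + translation to whole frames, which
    superposition must undo. ``hbond_probabilities`` appends isolated
    D–H···A probe triplets whose acceptor sits inside the geometric
    hydrogen-bond criterion in each frame independently with the given
    probability; ``hbond_residue`` attributes the probes to that residue.
    """

    n_residues: int = 10
    n_frames: int = 100
    sigma: float = 0.02
    rigid_motions: bool = False
    hbond_probabilities: tuple = ()
    hbond_residue: Optional[int] = None
    dt_ps: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0 or self.n_frames < 1:
            raise ValueError("sigma must be >= 0 and n_frames >= 1")
        if any(not 0 <= p <= 1 for p in self.hbond_probabilities):
            raise ValueError("H-bond probabilities must lie in [0, 1]")


def gen_trajectory(spec: TrajectorySpec):
    """Generate a toy Trajectory; returns (trajectory, truth).

    truth records the expected mean RMSD (σ√3, in Å) and, per H-bond probe,
    the realized presence fraction.
    """
    rng = np.random.default_rng(spec.seed)
    atoms, base = _helix_base(spec.n_residues)
    n_chain = len(atoms)
    probes = []
    probe_res = spec.hbond_residue or (spec.n_residues + 1)
    for j, p in enumerate(spec.hbond_probabilities):
        x0 = 10.0 + 2.0 * j  # far from the chain and from other probes
        for name, elem, bb, q, off in (
            ("ND", "N", False, -0.4, (0.0, 0.0, 0.0)),
            ("HD", "H", False, 0.3, (0.10, 0.0, 0.0)),
            ("OA", "O", False, -0.5, (0.28, 0.0, 0.0)),
        ):
            atoms.append(
                AtomRecord(name=name, element=elem, res_index=probe_res,
                           res_name="HBX", is_backbone=bb,
                           radius=_RADII[elem], charge=q)
            )
            probes.append(np.array([x0 + off[0], off[1], off[2]]))
    base = np.vstack([base, np.asarray(probes)]) if probes else base
    n_atoms = base.shape[0]

    frames = np.empty((spec.n_frames, n_atoms, 3))
    frames[0] = base
    presence = np.zeros((len(spec.hbond_probabilities), spec.n_frames), dtype=bool)
    presence[:, 0] = True  # frame 0 probes sit at the bonded geometry
    for f in range(1, spec.n_frames):
        fr = base.copy()
        if spec.sigma > 0:
            fr[:n_chain] += rng.normal(0.0, spec.sigma, size=(n_chain, 3))
        for j, p in enumerate(spec.hbond_probabilities):
            on = rng.random() < p
            presence[j, f] = on
            if not on:  # push the acceptor out of distance range
                fr[n_chain + 3 * j + 2, 0] += 0.4
        frames[f] = fr
    if spec.rigid_motions:
        from scipy.spatial.transform import Rotation

        for f in range(spec.n_frames):
            rot = Rotation.random(rng=rng)
            shift = rng.normal(0.0, 1.0, size=3)
            frames[f] = rot.apply(frames[f]) + shift

    traj = Trajectory(atoms, frames, dt_ps=spec.dt_ps)
    truth = dict(
        expected_rmsd_A=10.0 * spec.sigma * math.sqrt(3.0),
        n_chain_atoms=n_chain,
        probe_presence=presence,
        probe_occupancy=100.0 * presence.mean(axis=1),
    )
    return traj, truth


def gen_hbond_matrix(
    probabilities: Sequence[float],
    n_frames: int,
    seed: int = 0,
    residues: Optional[Sequence[int]] = None,
    sidechain: bool = True,
) -> HBondExistence:
    """Bernoulli existence matrix: bond i present in each frame with prob p_i.

    Expected fragment occupancy over the attributed bonds is 100 × Σ p_i.
    ``residues`` assigns each bond's partner residue (default: bond i sits on
    residue i+1, both partners inside).
    """
    probs = np.asarray(probabilities, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    matrix = rng.random((probs.size, n_frames)) < probs[:, None]
    if residues is None:
        residues = [i + 1 for i in range(probs.size)]
    bonds = tuple(
        HBond(
            donor=3 * i, hydrogen=3 * i + 1, acceptor=3 * i + 2,
            donor_res=int(residues[i]), acceptor_res=int(residues[i]),
            donor_sidechain=sidechain, acceptor_sidechain=sidechain,
        )
        for i in range(probs.size)
    )
    return HBondExistence(bonds=bonds, matrix=matrix)
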