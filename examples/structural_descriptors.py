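"""Compute fragment-level structural descriptors from a toy trajectory.

Generates a helical peptide trajectory with 0.03 nm per-atom fluctuation and
random rigid-body motion per frame, then runs the descriptor pipeline:
Cα superposition, backbone/side-chain RMSD, Shrake-Rupley SASA split by
atomic partial charge, ΔG_solv, and hydrogen-bond occupancy.
"""

from radox import structure as strc
from radox import synth

spec = synth.TrajectorySpec(
    n_residues=10, n_frames=40, sigma=0.03, rigid_motions=True,
    hbond_probabilities=(0.8, 0.4), seed=3,  # probes live on residue 11
)
traj, truth = synth.gen_trajectory(spec)
fragments = [
    strc.FragmentSpec("N-half", 1, 5),
    strc.FragmentSpec("C-half", 6, 10),
    strc.FragmentSpec("probes", 11, 11),
]
table = strc.compute_descriptors(traj, fragments, form="native", run="1",
                                 sasa_stride=4)
print(table.round(3).to_string(index=False))
print()
print(f"expected jitter RMSD (sigma*sqrt(3)): {truth['expected_rmsd_A']:.3f} A")
print(f"probe H-bond occupancy (ground truth): {truth['probe_occupancy'].sum():.1f} %")
# The chain fragments' RMSD sits near the expected jitter value once the
# rigid motions are removed by superposition; the probe fragment's occupancy
# sums the two Bernoulli bonds, a percent-sum that can exceed 100.
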