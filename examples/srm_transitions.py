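"""Design the lysozyme SRM panel: digestion, transitions, and coverage.

Digests the 129-residue hen egg-white lysozyme chain with trypsin in silico,
applies carbamidomethyl to every Cys (plus Met12/Trp123 oxidation for the two
oxidized forms), builds the Q1/Q3 transition table under the 12-residue
length cutoff, and reports sequence coverage.
"""

from radox import peptides as pep
from radox import synth

protein, _ = synth.lysozyme_fixture()
detected = synth.detected_peptides(protein)

rules = pep.TransitionRules(ion_selection=synth.SRM_ION_PANEL)
rows = pep.build_transitions(detected, rules)
table = pep.transitions_to_frame(rows)

print(table.to_string(index=False))
print()
print(f"followed peptides : {table['peptide'].nunique()} "
      f"(of {len(detected)} detected; >12-residue peptides are excluded)")
print(f"transitions       : {len(table)}")
print(f"sequence coverage : {pep.coverage(detected, protein)} % "
      "(union of detected residue positions over 129 residues)")
# Each row is one SRM transition: Q1 is the doubly protonated precursor m/z,
# Q3 the singly charged b/y fragment m/z used to quantify that peptide.
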