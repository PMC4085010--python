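"""Resistance ranking, structural group means, and the D50-t1 correlation.

Runs the report layer on the reference measurement tables: ranks the six
monitored lysozyme fragments by D50 in the native form, recomputes the
sensitive/resistant group statistics, the native-vs-reduced RMSD shift for
GTDVQAWIR, and the Spearman correlation between D50 and the fast half-dose.
"""

from radox import refdata, report

ranked = report.classify_resistance(refdata.RESISTANCE, form="native")
print(report.summary_text(ranked))
print()

sens = report.group_mean(refdata.RMSD, refdata.SENSITIVE_NATIVE, [1, 2],
                         "rmsd_sidechain_A", form="native")
resist = report.group_mean(refdata.RMSD, refdata.RESISTANT_NATIVE, [1, 2],
                           "rmsd_sidechain_A", form="native")
occ = report.group_mean(refdata.OCCUPANCY, refdata.RESISTANT_NATIVE, [1, 2],
                        "occupancy_sidechain", form="native")
print(f"side-chain RMSD, sensitive group : {report.truncate(sens, 2)} A")
print(f"side-chain RMSD, resistant group : {report.truncate(resist, 2)} A")
print(f"side-chain H-bond occupancy, resistant group: {report.truncate(occ):.0f} %")

native_bb, reduced_bb = report.form_delta(refdata.RMSD, "GTDVQAWIR",
                                          "rmsd_backbone_A")
print(f"GTDVQAWIR backbone RMSD native -> reduced: {native_bb:.2f} -> {reduced_bb:.2f} A")

kin = refdata.KINETICS[
    (refdata.KINETICS.form == "native")
    & ~refdata.KINETICS.fragment.str.contains("\\*", regex=True)
]
merged = kin.merge(refdata.RESISTANCE[refdata.RESISTANCE.form == "native"],
                   on=["fragment", "form"])
rho = report.rank_correlation(merged["t1_gy"], merged["d50_gy"])
print(f"Spearman rho, t1 vs D50 (native, 6 fragments): {rho:.3f}")
# Mobile, weakly hydrogen-bonded side chains mark the radiation-sensitive
# fragments; D50 and t1 rank the fragments almost identically.
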