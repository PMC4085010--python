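"""Reference lysozyme radiation-resistance measurements.

Published per-fragment measurements for native and reduced-alkylated
(misfolded) hen egg-white lysozyme: bi-exponential kinetic half-doses with
triplicate CVs, D50 / I_sat resistance summaries, two-run MD descriptor
tables (backbone and side-chain RMSD, hydrogen-bond occupancy) and the Trp
side-chain SASA / ΔG_solv table. They serve as fixtures for the report layer
(group statistics, rankings, correlations) and as regression anchors for the
descriptor arithmetic — the original raw MS data and trajectories are not
deposited, so these printed summaries are the ground truth available.
"""

from __future__ import annotations

import pandas as pd

FRAGMENTS = (
    "CELAAAMK", "GTDVQAWIR", "HGLDNYR", "GYSLGNWVCAAK", "FESNFNTQATNR", "WWCNDGR",
)

# fragment, form, t1 (Gy), t1 CV%, t2 (Gy), t2 CV% — n = 3
_KINETICS = [
    ("CELAAAMK", "native", 7.9, 9, 445.7, 10),
    ("CELAAAM*K", "native", 25.1, 18, 485.2, 17),
    ("GTDVQAWIR", "native", 58.9, 14, 338.9, 15),
    ("GTDVQAW*IR", "native", 82.4, 10, 675.2, 8),
    ("HGLDNYR", "native", 50.2, 4, 375.2, 6),
    ("GYSLGNWVCAAK", "native", 88.8, 13, 279.2, 14),
    ("FESNFNTQATNR", "native", 19.4, 7, 549.1, 9),
    ("WWCNDGR", "native", 75.4, 15, 654.2, 12),
    ("CELAAAMK", "reduced", 44.5, 19, 670.2, 12),
    ("CELAAAM*K", "reduced", 75.8, 9, 641.1, 6),
    ("GTDVQAWIR", "reduced", 21.1, 14, 570.3, 10),
    ("GTDVQAW*IR", "reduced", 38.9, 16, 651.6, 15),
    ("HGLDNYR", "reduced", 18.5, 17, 386.7, 19),
    ("GYSLGNWVCAAK", "reduced", 17.3, 6, 346.3, 4),
    ("FESNFNTQATNR", "reduced", 11.5, 6, 502.6, 9),
    ("WWCNDGR", "reduced", 33.8, 12, 678.6, 8),
]

KINETICS = pd.DataFrame(
    _KINETICS, columns=["fragment", "form", "t1_gy", "t1_cv", "t2_gy", "t2_cv"]
)

# fragment, form, D50 (Gy), CV%, I_sat (%), CV%
_RESISTANCE = [
    ("CELAAAMK", "native", 10, 12, 7.5, 7),
    ("GTDVQAWIR", "native", 385, 11, 28.6, 12),
    ("HGLDNYR", "native", 50, 7, 9.1, 8),
    ("GYSLGNWVCAAK", "native", 150, 8, 13.2, 7),
    ("FESNFNTQATNR", "native", 30, 12, 8.4, 10),
    ("WWCNDGR", "native", 510, 18, 32.6, 9),
    ("CELAAAMK", "reduced", 1241, 18, 42.0, 12),
    ("GTDVQAWIR", "reduced", 26, 9, 11.0, 11),
    ("HGLDNYR", "reduced", 100, 8, 12.5, 8),
    ("GYSLGNWVCAAK", "reduced", 298, 16, 32.1, 10),
    ("FESNFNTQATNR", "reduced", 10, 10, 7.1, 11),
    ("WWCNDGR", "reduced", 130, 8, 27.9, 12),
]

RESISTANCE = pd.DataFrame(
    _RESISTANCE, columns=["fragment", "form", "d50_gy", "d50_cv", "isat_pct", "isat_cv"]
)

# fragment, form, run, backbone RMSD (Å), side-chain RMSD (Å)
_RMSD = [
    ("CELAAAMK", "native", 1, 0.79, 1.25), ("CELAAAMK", "native", 2, 0.83, 1.22),
    ("CELAAAMK", "reduced", 1, 0.78, 1.37), ("CELAAAMK", "reduced", 2, 1.06, 1.47),
    ("GTDVQAWIR", "native", 1, 1.03, 1.65), ("GTDVQAWIR", "native", 2, 1.21, 1.56),
    ("GTDVQAWIR", "reduced", 1, 1.42, 1.94), ("GTDVQAWIR", "reduced", 2, 1.44, 1.90),
    ("HGLDNYR", "native", 1, 1.03, 1.94), ("HGLDNYR", "native", 2, 1.02, 2.01),
    ("HGLDNYR", "reduced", 1, 1.14, 1.98), ("HGLDNYR", "reduced", 2, 1.20, 2.02),
    ("GYSLGNWVCAAK", "native", 1, 0.66, 0.81), ("GYSLGNWVCAAK", "native", 2, 0.83, 1.11),
    ("GYSLGNWVCAAK", "reduced", 1, 0.94, 1.21), ("GYSLGNWVCAAK", "reduced", 2, 0.87, 1.15),
    ("FESNFNTQATNR", "native", 1, 0.77, 1.11), ("FESNFNTQATNR", "native", 2, 1.22, 2.64),
    ("FESNFNTQATNR", "reduced", 1, 0.93, 1.60), ("FESNFNTQATNR", "reduced", 2, 0.87, 1.73),
    ("WWCNDGR", "native", 1, 0.74, 1.30), ("WWCNDGR", "native", 2, 0.92, 1.53),
    ("WWCNDGR", "reduced", 1, 1.34, 2.63), ("WWCNDGR", "reduced", 2, 1.31, 2.24),
]

RMSD = pd.DataFrame(
    _RMSD, columns=["fragment", "form", "run", "rmsd_backbone_A", "rmsd_sidechain_A"]
)

# fragment, form, run, total occupancy (%), side-chain occupancy (%)
_OCCUPANCY = [
    ("CELAAAMK", "native", 1, 588, 120), ("CELAAAMK", "native", 2, 614, 114),
    ("CELAAAMK", "reduced", 1, 530, 98), ("CELAAAMK", "reduced", 2, 546, 106),
    ("GTDVQAWIR", "native", 1, 202, 14), ("GTDVQAWIR", "native", 2, 193, 7),
    ("GTDVQAWIR", "reduced", 1, 165, 3), ("GTDVQAWIR", "reduced", 2, 212, 1.6),
    ("HGLDNYR", "native", 1, 562, 88), ("HGLDNYR", "native", 2, 563, 74),
    ("HGLDNYR", "reduced", 1, 573, 93), ("HGLDNYR", "reduced", 2, 544, 55),
    ("GYSLGNWVCAAK", "native", 1, 758, 145), ("GYSLGNWVCAAK", "native", 2, 529, 124),
    ("GYSLGNWVCAAK", "reduced", 1, 590, 33), ("GYSLGNWVCAAK", "reduced", 2, 531, 33),
    ("FESNFNTQATNR", "native", 1, 640, 44), ("FESNFNTQATNR", "native", 2, 860, 75),
    ("FESNFNTQATNR", "reduced", 1, 1142, 122), ("FESNFNTQATNR", "reduced", 2, 923, 83),
    ("WWCNDGR", "native", 1, 833, 299), ("WWCNDGR", "native", 2, 891, 205),
    ("WWCNDGR", "reduced", 1, 777, 208), ("WWCNDGR", "reduced", 2, 847, 322),
]

OCCUPANCY = pd.DataFrame(
    _OCCUPANCY, columns=["fragment", "form", "run", "occupancy_total", "occupancy_sidechain"]
)

# Trp side-chain RMSD / SASA split / ΔG_solv, two runs per form
_TRP_SASA = [
    ("Trp62", "WWCNDGR", "native", 1, 1.26, 0.93, 0.13, 1.05, -2.65),
    ("Trp62", "WWCNDGR", "native", 2, 0.96, 0.97, 0.13, 1.10, -2.77),
    ("Trp62", "WWCNDGR", "reduced", 1, 1.07, 1.07, 0.12, 1.20, -3.00),
    ("Trp62", "WWCNDGR", "reduced", 2, 1.09, 1.09, 0.13, 1.22, -3.06),
    ("Trp63", "WWCNDGR", "native", 1, 0.64, 0.35, 0.09, 0.44, -1.11),
    ("Trp63", "WWCNDGR", "native", 2, 0.74, 0.30, 0.10, 0.40, -1.01),
    ("Trp63", "WWCNDGR", "reduced", 1, 1.41, 0.45, 0.11, 0.57, -1.42),
    ("Trp63", "WWCNDGR", "reduced", 2, 1.53, 0.38, 0.09, 0.47, -1.17),
    ("Trp123", "GTDVQAWIR", "native", 1, 1.06, 0.52, 0.13, 0.65, -1.64),
    ("Trp123", "GTDVQAWIR", "native", 2, 1.21, 0.47, 0.11, 0.58, -1.47),
    ("Trp123", "GTDVQAWIR", "reduced", 1, 1.40, 0.47, 0.13, 0.60, -1.52),
    ("Trp123", "GTDVQAWIR", "reduced", 2, 1.92, 0.58, 0.10, 0.68, -1.72),
]

TRP_SASA = pd.DataFrame(
    _TRP_SASA,
    columns=[
        "residue", "fragment", "form", "run",
        "rmsd_A", "sasa_hydrophobic_nm2", "sasa_hydrophilic_nm2",
        "sasa_total_nm2", "dg_solv_kj_mol",
    ],
)

#: resistance groups in the native form, by D50
SENSITIVE_NATIVE = ("CELAAAMK", "HGLDNYR", "FESNFNTQATNR")
RESISTANT_NATIVE = ("GTDVQAWIR", "WWCNDGR", "GYSLGNWVCAAK")
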