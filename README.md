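# radox

Peptide-level analysis of protein radiation-oxidation resistance, built
around the hen egg-white lysozyme gamma-irradiation system: targeted mass
spectrometry (SRM) assay design over tryptic peptides, bi-exponential
dose-kinetics fitting, and fragment-level structural descriptors from
molecular-dynamics-style trajectory snapshots, linked by a report layer that
correlates structure with resistance.

## Who it is for

Proteomics and structural-bioinformatics practitioners who quantify
region-specific oxidative damage: design Q1/Q3 transition lists for native
and oxidized tryptic peptides, turn peak-area-versus-dose tables into
half-life doses, and ask which structural features (side-chain mobility,
hydrogen bonding, solvent exposure) track the observed resistance.

## The models

**Mass layer.** Monoisotopic arithmetic with proton 1.007276 Da and water
18.010565 Da. Carbamidomethyl (+57.02146 Da on Cys), mono-oxidation
(+15.9949 Da on Met/Trp) and the diagnostic CH3SOH neutral loss
(−63.9983 Da from oxidized Met) are built in. Trypsin cleaves C-terminal to
K/R except before Pro; coordinates are 1-based inclusive.

**Kinetics.** Non-oxidized peptide intensity decays in two steps with an
eventual plateau, written so t1 and t2 are literally half-life doses (Gy):

    I(D) = A1·2^(−D/t1) + A2·2^(−D/t2) + C          (decay)
    I(D) = A·(2^(−D/t2) − 2^(−D/t1)),  t1 < t2      (oxidized form:
                                                     growth then decay)

Resistance summaries: D50, the smallest dose with I(D) = I(0)/2 (undefined
when the plateau C ≥ I(0)/2), and I_sat = 100·C/I(0), the surviving fraction
at saturating dose. Reproducibility is reported as CV = 100·sd/mean.

**Structure.** Kabsch Cα superposition; per-fragment backbone/side-chain
heavy-atom RMSD in Å; Shrake–Rupley SASA (probe 0.14 nm, 960 sphere points)
split into hydrophobic (|q| < 0.2 e) and hydrophilic atoms; ΔG_solv = γ·SASA
with γ = −2.51 kJ/mol/nm²; geometric hydrogen bonds (donor–acceptor
≤ 0.35 nm, H–D–A angle ≤ 30°); and fragment *occupancy* — the sum over
attributed H-bonds of the percentage of frames each bond exists (a
percent-sum, routinely above 100%).

## Worked example

`python examples/dose_kinetics.py` simulates the CELAAAMK dose-response
study (10-dose ladder 0–5000 Gy, 3 transitions × 3 replicates, 10%
multiplicative noise) and fits every series:

```
non-oxidized CELAAAMK (decay model), truth t1=7.9 t2=445.7 D50=19.4 Isat=10.0
fragment model parameter       mean    cv_pct  n  n_failed
CELAAAMK decay        t1   7.764577 47.454685  9         0
CELAAAMK decay        t2 433.942113 17.093229  9         0
CELAAAMK decay       D50  17.829928 41.532834  9         0
CELAAAMK decay      Isat   9.715481 12.579318  9         0
```

The `mean` column is the study-level estimate (average of the nine
per-series fits) and recovers the generating half-life doses; `cv_pct` is
the spread across single-series fits — the fast component, sampled by only
the 10 and 20 Gy points, is intrinsically the noisiest quantity.

The other examples print the full 24-row Q1/Q3 panel with 66.6% sequence
coverage (`srm_transitions.py`), descriptor tables against their analytic
expectations (`structural_descriptors.py`), and the resistance ranking with
group statistics — sensitive-group side-chain RMSD 1.69 Å vs resistant
1.32 Å, resistant-group side-chain H-bond occupancy 132%, Spearman
ρ(t1, D50) = 0.829 (`resistance_report.py`).

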