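# Methods

## Scope and data model

The package analyses region-specific radiation-oxidation resistance of a
protein through three coupled layers: (i) an SRM assay over its tryptic
peptides, (ii) dose-kinetics of peptide intensities over a gamma-irradiation
ladder, and (iii) structural descriptors of the same peptide regions
computed from trajectory snapshots. The lysozyme fixture (129-residue mature
chain, six monitored fragments, the validated ion panel) ships with the
package and is verified internally at construction time: every fragment
range must extract its stated sequence and all eight cysteines must sit at
their documented positions. Raw chromatograms, spectra and the original MD
trajectories are not inputs anywhere; the package starts from peak areas and
snapshot coordinates.

## Mass arithmetic

Monoisotopic residue masses come from pyteomics; proton = 1.007276 Da,
water = 18.010565 Da. A peptide's neutral mass is residues + water +
modification deltas. Precursor m/z = (M + z·p)/z. Fragment ions follow the
standard b/y conventions: y_i is the C-terminal i residues plus water, b_i
the N-terminal i residues, each plus z protons over z. Modifications are
positioned (1-based, in parent coordinates), so a fragment only carries the
deltas of modified residues it actually contains; this is what produces the
diagnostic +16 shift of y-ions spanning an oxidized Met and the −64
(CH3SOH, 63.9983 Da) neutral-loss satellites, which are only legal on
fragments containing an oxidized Met.

Carbamidomethyl (+57.02146 Da) is applied to every Cys when building
transitions for *both* protein forms: the monitored Cys-containing
precursors (e.g. the 447.21 Th doubly charged ion) are only obtainable with
the adduct, and the validated panel lists identical transitions for both
forms. Whether the native form was alkylated upstream is a sample-prep
question outside this package; the fixed-modification set is configurable
rather than guessed.

Trypsin digestion is implemented in-package (cleave after K/R, suppressed
before Pro, configurable missed cleavages) because downstream layers need
1-based inclusive coordinates for every product, which the generic cleavage
utilities in the surrounding libraries do not retain. Sequence coverage is
the size of the union of detected residue positions over the chain length;
the printed convention truncates (never rounds) at one decimal, so 86/129 is
reported as 66.6%.

The transition builder excludes peptides longer than 12 residues (long
sequences risk non-specific transitions) and emits a fixed number of
annotated transitions per retained peptide, with an explicit per-peptide ion
selection for the validated panel and a deterministic b2-plus-top-y fallback
otherwise.

## Kinetic models and fitting

Both kinetic forms are half-life parameterizations in base 2, so t1 and t2
are directly the doses at which a component halves:

* decay: `I(D) = A1·2^(−D/t1) + A2·2^(−D/t2) + C`, constraints
  A1, A2, C ≥ 0 and 0 < t1 < t2. I(0) = A1 + A2 + C; the plateau C realizes
  the saturating intensity I_sat = 100·C/I(0).
* growth-and-decay: `I(D) = A·(2^(−D/t2) − 2^(−D/t1))` with t1 < t2 and
  A > 0; zero at D = 0, maximal at `ln(k1/k2)/(k1 − k2)` with k = ln2/t
  (112.8 Gy for t1 = 25, t2 = 485).

These are the minimal forms consistent with every reported parameter
(t1, t2, D50, I_sat) and the described curve shapes.

Fitting is `scipy.optimize.least_squares` (trust-region reflective) over a
deterministic geometric grid of 20 (t1, t2) starts spanning the decades of
the dose ladder; time constants are optimized in log10 space with amplitude
non-negativity enforced by bounds, and the t1 ↔ t2 label swap is resolved
after every start. Residuals are scaled by the observed intensity by default
(`weighting="relative"`, floored at 0.1% of the series maximum): SRM peak
areas carry multiplicative noise, and unweighted residuals would let the
high-intensity low-dose points dominate. Plain least squares remains
available (`weighting="absolute"`).

Two degeneracies are handled explicitly. If the two time constants collapse
(t2 ≤ 1.001·t1) the amplitude split is unidentifiable, so the nested
single-exponential model is refit and reported with A2 = 0 (t2 then carries
no information and is set to 10·t1 by convention). All-zero series and
series with fewer than 6 dose points return flagged failure objects rather
than raising, so a batch over many fragments never halts on one bad series.

D50 is found by bisection of the fitted curve on [0, 10·t2] to 0.1 Gy, and
is undefined (None) when C ≥ I(0)/2 — a plateau above half the initial
intensity never crosses it. Replicate CV is 100 × sample sd (ddof = 1) /
mean, rejecting n < 2 or non-positive means.

Fragment-level summaries (`fit_fragment`) fit each transition × replicate
series separately, then average parameters across the fits and report the CV
across them, mirroring the triplicate-CV convention of SRM assays; a pooled
mode that sums transitions per replicate before fitting is provided because
the original protocol's choice between the two is not documented.

## Synthetic data

Generators are pure functions of (spec, seed) and always return ground truth
alongside the data.

*Dose-response*: intensities are the model curve times lognormal noise with
unit mean and requested CV (σ_log = √ln(1 + CV²)) — peak areas are positive
and errors are reported as CVs, which makes a multiplicative lognormal the
natural noise model. Defaults are the study conditions: the ten-dose ladder
{0, 10, 20, 50, 100, 200, 500, 1000, 2000, 5000} Gy, 3 transitions,
3 replicates, 10% noise (the reported replicate CVs were all below 20%).
When a plateau fraction is needed to complete a decay parameter set, the
reference I_sat supplies C and the remaining amplitude is split 2:1 between
fast and slow components, matching the 60/30/10 exemplar decomposition.

*Trajectories*: an idealized helical peptide (rise 0.15 nm, 100°/residue,
backbone N/H/CA/C/O plus CB/CG pseudo-side-chain with plausible radii and
partial charges). Frame 0 is the exact base geometry; later frames add
independent per-coordinate Gaussian displacement of σ nm, so the expected
RMSD against frame 0 is σ√3 (0.866 Å at σ = 0.05 nm). Optional random
rigid motions per frame exercise superposition; optional isolated
donor–H···acceptor probe triplets toggle in and out of the geometric H-bond
criterion with independent Bernoulli draws per frame, giving fragments with
known expected occupancy. What the toy does *not* emulate: solvent,
force-field energetics, correlated motions, realistic secondary-structure
H-bond networks. Passing descriptor tests therefore demonstrates the
*estimators* are correct (against analytic and brute-force oracles), not
that any particular protein would show particular descriptor values.

*Existence matrices*: independent Bernoulli per bond per frame with expected
fragment occupancy 100·Σp.

## Structural descriptors

Superposition is Kabsch (via scipy's rotation alignment) of each frame's Cα
selection onto frame 0, applied rigidly to all atoms. Fragment RMSD is the
per-frame heavy-atom RMSD against frame 0 averaged over frames, reported in
Å; "backbone" is N/Cα/C/O, "side-chain" everything else heavy (the upstream
convention for reference frame and hydrogen handling is not documented, so
frame 0 and heavy-atoms-only are fixed here and stated). A fragment with no
atoms of the requested class (glycine-only side chains) yields NaN.

SASA is Shrake–Rupley with a deterministic golden-spiral point set (default
960 points, probe 0.14 nm) over probe-expanded spheres, neighbor-pruned with
a k-d tree; per-atom radii come from the sidecar, never from a lookup table.
The hydrophobic/hydrophilic split is by |partial charge| < 0.2 e (boundary
value counts hydrophilic), mirroring the convention of the surface tool the
descriptor set originates from. ΔG_solv = γ·SASA; the default
γ = −2.51 kJ/mol/nm² is the through-origin regression slope of the twelve
reference Trp side-chain (SASA, ΔG_solv) pairs, and is configurable.

Hydrogen bonds use the classic geometric criterion: donor–acceptor distance
≤ 0.35 nm and H–donor–acceptor angle ≤ 30°, donors being N/O with a
covalently attached hydrogen (assigned once, from frame 0, as the nearest
N/O within 0.125 nm). Occupancy attributes a bond to a fragment when either
partner residue falls in the fragment range, counted once even when both do;
the side-chain scope additionally requires a fragment-side partner to be a
side-chain atom. The statistic is the sum over attributed bonds of
100 × frames-present / frames-total.

The descriptor pipeline (superpose → H-bond scan → per-frame SASA →
per-fragment table) is deterministic: identical inputs give byte-identical
tables. SASA may be strided across frames for cost control; the stride is
part of the configuration and hence of the determinism contract.

## Exchange formats

FASTA in via biopython; multi-MODEL PDB in/out via biotite (coordinates
stored in Å at PDB precision, converted to nm internally) with a CSV sidecar
carrying what PDB cannot: vdW radius (nm), partial charge (e), backbone
flag. Dose-response tables and transition lists are plain CSV; fit results
serialize to JSON with sorted keys.

## Report layer

Fragments are ranked by descending D50 (ties lexicographic; undefined D50
last, flagged). Class labels default to within-form D50 terciles because the
original grouping was narrative, without stated cutoffs; the sensitive and
resistant triples used for group statistics are exposed as constants. Group
means are plain arithmetic means over fragment × run cells, computed at full
precision; display truncates (RMSD 2 decimals, occupancy and D50 integer),
which is the convention under which the reference group statistics
(1.69/1.32 Å, 132%, 66.6%) reproduce exactly. Correlation between resistance
and kinetics is Spearman's ρ with average ranks on ties.

## Problem sizes used by the test suite

Noiseless kinetic recovery runs all eight native parameter sets on the
ten-dose ladder; the reproducibility check uses 200 seeded studies of
3 × 3 series each. RMSD oracle checks use a 10-residue, 500-frame toy
(70 chain atoms); SASA oracles use two-sphere systems at 240–3840 points;
H-bond/occupancy checks use up to 10 000-frame Bernoulli matrices and
400-frame probe trajectories. These sizes make every oracle's sampling error
comfortably smaller than the tolerance it is tested at while keeping the
whole suite in the minutes range.

## Known limitations

* The kinetic forms are phenomenological; mechanistic radiolysis chemistry
  (dose-rate effects, scavenger concentrations) is not modelled.
* t1 values below the first non-zero dose of the ladder are intrinsically
  poorly identified from single series — visible as large single-fit CVs —
  and only stabilize at the study level (averaging transitions and
  replicates).
* The occupancy statistic is a percent-sum and depends on the H-bond
  inventory; it is comparable across fragments within one configuration, not
  across different geometric criteria.
* Mono-oxidation only (+15.9949); higher oxidation states, carbonylation and
  backbone fragmentation are out of scope, as are spectrum/retention-time
  prediction and any simulation engine functionality.
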