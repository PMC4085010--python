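"""Tryptic peptides, mass modifications, and SRM transition design.

In-silico trypsin digestion with 1-based inclusive coordinates, monoisotopic
mass and m/z arithmetic for precursor and b/y fragment ions (including
methionine-sulfoxide +15.9949 and its characteristic CH3SOH neutral loss of
63.9983), construction of Q1/Q3 transition tables under a configurable
peptide-length cutoff, and sequence-coverage computation.

All masses are monoisotopic. Residue masses come from pyteomics; the proton
is 1.007276 Da and water 18.010565 Da.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from pyteomics import mass as _pmass

PROTON = 1.007276
WATER = 18.010565
CH3SOH = 63.9983  # neutral loss from oxidized Met side chain

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: monoisotopic residue masses (Da), 20 standard amino acids
RESIDUE_MASS: Mapping[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in STANDARD_RESIDUES
}


@dataclass(frozen=True)
class Modification:
    """A fixed or variable mass modification on specific residue types."""

    name: str
    targets: frozenset
    delta_mass: float

    def __post_init__(self):
        if not math.isfinite(self.delta_mass):
            raise ValueError(f"non-finite delta mass for {self.name}")
        object.__setattr__(self, "targets", frozenset(self.targets))


CARBAMIDOMETHYL = Modification("carbamidomethyl", frozenset("C"), 57.02146)
OXIDATION = Modification("oxidation", frozenset("MW"), 15.9949)


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self):
        bad = set(self.sequence) - STANDARD_RESIDUES
        if bad:
            raise ValueError(
                f"protein {self.id}: non-standard residue code(s) {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Peptide:
    """A tryptic fragment with 1-based inclusive coordinates in its parent.

    ``mods`` holds (position, Modification) pairs where position is the
    1-based coordinate in the *parent* protein sequence.
    """

    parent: str
    sequence: str
    start: int
    end: int
    mods: tuple = ()

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("peptide coordinates inconsistent with sequence length")
        bad = set(self.sequence) - STANDARD_RESIDUES
        if bad:
            raise ValueError(f"non-standard residue code(s) {sorted(bad)}")
        for pos, mod in self.mods:
            if not (self.start <= pos <= self.end):
                raise ValueError(f"mod position {pos} outside [{self.start},{self.end}]")
            res = self.sequence[pos - self.start]
            if res not in mod.targets:
                raise ValueError(f"{mod.name} does not target residue {res} at {pos}")

    def __len__(self) -> int:
        return len(self.sequence)

    def with_mod(self, position: int, mod: Modification) -> "Peptide":
        return replace(self, mods=tuple(self.mods) + ((position, mod),))

    def with_fixed_mod(self, mod: Modification) -> "Peptide":
        """Apply ``mod`` at every targeted residue (e.g. carbamidomethyl on all Cys)."""
        extra = tuple(
            (self.start + i, mod)
            for i, res in enumerate(self.sequence)
            if res in mod.targets
        )
        return replace(self, mods=tuple(self.mods) + extra)

    @property
    def annotated(self) -> str:
        """Sequence with variable (non-fixed) modified residues marked.

        Oxidized residues are followed by ``*`` (``CELAAAM*K``); other
        variable mods by ``[name]``. Carbamidomethyl is treated as fixed and
        not annotated, matching how SRM panels are usually written down.
        """
        marks = {}
        for pos, mod in self.mods:
            if mod.name == "carbamidomethyl":
                continue
            marks[pos - self.start] = "*" if mod.name == "oxidation" else f"[{mod.name}]"
        return "".join(res + marks.get(i, "") for i, res in enumerate(self.sequence))


def digest(protein: ProteinRecord, missed_cleavages: int = 0) -> list:
    """Tryptic digest: cleave C-terminal to K/R except before Pro.

    Returns peptides in N→C order with 1-based inclusive coordinates. With
    ``missed_cleavages = n`` every product spanning at most n internal
    cleavage sites is included (fully-cleaved products first, then 1-missed
    in order, etc.).
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    seq = protein.sequence
    # indices *after* which cleavage occurs (0-based)
    sites = [
        i
        for i in range(len(seq) - 1)
        if seq[i] in "KR" and seq[i + 1] != "P"
    ]
    bounds = [0] + [s + 1 for s in sites] + [len(seq)]
    segments = list(zip(bounds[:-1], bounds[1:]))
    out = []
    for mc in range(missed_cleavages + 1):
        for i in range(len(segments) - mc):
            a = segments[i][0]
            b = segments[i + mc][1]
            out.append(
                Peptide(parent=protein.id, sequence=seq[a:b], start=a + 1, end=b)
            )
    return out


def peptide_mass(p: Peptide) -> float:
    """Monoisotopic neutral mass: residues + water + modification deltas."""
    m = sum(RESIDUE_MASS[res] for res in p.sequence) + WATER
    m += sum(mod.delta_mass for _, mod in p.mods)
    return m


def precursor_mz(p: Peptide, z: int) -> float:
    if z < 1:
        raise ValueError("charge must be >= 1")
    return (peptide_mass(p) + z * PROTON) / z


def fragment_mz(
    p: Peptide,
    series: str,
    index: int,
    z: int = 1,
    neutral_loss: bool = False,
) -> float:
    """m/z of a b- or y-series fragment ion.

    y_i covers the i C-terminal residues (neutral = residues + water);
    b_i the i N-terminal residues (neutral = residues). ``neutral_loss``
    subtracts the CH3SOH mass and is only valid when the fragment contains
    an oxidized Met.
    """
    if z < 1:
        raise ValueError("charge must be >= 1")
    n = len(p)
    if not 1 <= index < n:
        raise ValueError(f"fragment index {index} out of range for length {n}")
    if series == "y":
        lo, hi = p.end - index + 1, p.end  # 1-based global positions covered
        neutral = sum(RESIDUE_MASS[r] for r in p.sequence[n - index:]) + WATER
    elif series == "b":
        lo, hi = p.start, p.start + index - 1
        neutral = sum(RESIDUE_MASS[r] for r in p.sequence[:index])
    else:
        raise ValueError(f"unknown ion series {series!r}")
    frag_mods = [(pos, mod) for pos, mod in p.mods if lo <= pos <= hi]
    neutral += sum(mod.delta_mass for _, mod in frag_mods)
    if neutral_loss:
        has_ox_met = any(
            mod.name == "oxidation" and p.sequence[pos - p.start] == "M"
            for pos, mod in frag_mods
        )
        if not has_ox_met:
            raise ValueError("neutral loss requires an oxidized Met inside the fragment")
        neutral -= CH3SOH
    return (neutral + z * PROTON) / z


@dataclass(frozen=True)
class TransitionRow:
    peptide: Peptide
    precursor_charge: int
    precursor_mz: float
    ion_label: str  # e.g. "y5", "b2", "y5-64"
    product_charge: int
    product_mz: float


IonSpec = tuple  # (series, index) or (series, index, neutral_loss)


def _default_ions(p: Peptide, k: int) -> list:
    """Fallback ion choice: b2 plus the longest y ions, k transitions total."""
    n = len(p)
    ions = [("y", n - 1 - j) for j in range(k - 1)]
    ions.append(("b", 2))
    return ions[:k]


@dataclass(frozen=True)
class TransitionRules:
    """SRM design rules: length cutoff, transition count, charges, ion choice.

    ``ion_selection`` maps an annotated peptide string (see
    :attr:`Peptide.annotated`) to an explicit ion list; peptides not in the
    mapping fall back to the default b2 + top-y rule.
    """

    max_length: int = 12
    transitions_per_peptide: int = 3
    precursor_charge: int = 2
    product_charge: int = 1
    ion_selection: Mapping[str, Sequence[IonSpec]] = field(default_factory=dict)

    def ions_for(self, p: Peptide) -> list:
        sel = self.ion_selection.get(p.annotated)
        if sel is None:
            sel = _default_ions(p, self.transitions_per_peptide)
        return list(sel)[: self.transitions_per_peptide]


def build_transitions(
    peptides: Iterable[Peptide], rules: TransitionRules = TransitionRules()
) -> list:
    """Build the SRM transition table.

    Peptides longer than ``rules.max_length`` are excluded (long sequences
    risk non-specific transitions); each retained peptide contributes
    ``transitions_per_peptide`` rows in a deterministic order.
    """
    rows = []
    for p in peptides:
        if len(p) > rules.max_length:
            continue
        q1 = precursor_mz(p, rules.precursor_charge)
        for spec in rules.ions_for(p):
            series, index = spec[0], spec[1]
            nl = bool(spec[2]) if len(spec) > 2 else False
            q3 = fragment_mz(p, series, index, rules.product_charge, neutral_loss=nl)
            label = f"{series}{index}" + ("-64" if nl else "")
            rows.append(
                TransitionRow(
                    peptide=p,
                    precursor_charge=rules.precursor_charge,
                    precursor_mz=q1,
                    ion_label=label,
                    product_charge=rules.product_charge,
                    product_mz=q3,
                )
            )
    return rows


def coverage(peptides: Iterable[Peptide], protein: ProteinRecord) -> float:
    """Sequence coverage in percent, truncated to one decimal.

    Overlapping and duplicate peptides count each residue once. Truncation
    (not rounding) matches the convention of reporting 86/129 as 66.6%.
    """
    covered = set()
    for p in peptides:
        if p.parent != protein.id:
            raise ValueError(f"peptide parent {p.parent!r} != protein {protein.id!r}")
        if p.start < 1 or p.end > protein.length:
            raise ValueError(f"peptide {p.sequence} outside protein bounds")
        covered.update(range(p.start, p.end + 1))
    pct = 100.0 * len(covered) / protein.length
    return math.trunc(pct * 10) / 10


def read_fasta(path) -> list:
    """Read a FASTA file into ProteinRecord objects (via biopython)."""
    return [
        ProteinRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def transitions_to_frame(rows: Iterable[TransitionRow]) -> pd.DataFrame:
    """Transition table as a DataFrame with the exchange-CSV schema."""
    recs = []
    for r in rows:
        p = r.peptide
        mods = ";".join(f"{pos}:{mod.name}" for pos, mod in p.mods)
        recs.append(
            dict(
                peptide=p.annotated,
                start=p.start,
                end=p.end,
                mods=mods,
                q1_mz=round(r.precursor_mz, 4),
                q1_charge=r.precursor_charge,
                q3_mz=round(r.product_mz, 4),
                q3_charge=r.product_charge,
                ion_label=r.ion_label,
            )
        )
    cols = [
        "peptide", "start", "end", "mods",
        "q1_mz", "q1_charge", "q3_mz", "q3_charge", "ion_label",
    ]
    return pd.DataFrame(recs, columns=cols)
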