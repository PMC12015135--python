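"""In-silico trypsin digestion and MS-detectability binning.

Trypsin cleaves C-terminal to lysine (K) or arginine (R) except when the
next residue is proline (P). Peptides of 8-15 residues (roughly 500-2000
Da) are the band mass spectrometers detect best; site-bearing peptides
falling outside it are one plausible reason a site is seen only in
targeted studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from pyteomics import mass as _pyteomics_mass

from .model import AMINO_ACIDS, LengthBin, PhosphoSite

PHOSPHO_MASS = 79.96633  # monoisotopic HPO3 addition per phosphosite

_VALID = set(AMINO_ACIDS)


@dataclass
class TrypticPeptide:
    kinase_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    sequence: str
    site_positions: list[int] = field(default_factory=list)
    length_bin: LengthBin = LengthBin.SHORT_LT8
    monoisotopic_mass: float = 0.0

    @property
    def length(self) -> int:
        return len(self.sequence)


def _check_residues(sequence: str) -> None:
    bad = sorted(set(sequence) - _VALID)
    if bad:
        raise ValueError(f"non-standard residue letters: {bad}")


def peptide_mass(sequence: str, n_phospho: int = 0) -> float:
    """Monoisotopic peptide mass in Daltons (residues + one water).

    ``n_phospho`` adds one phosphate mass per modified site; the default
    reports the unmodified peptide, the quantity the 500-2000 Da
    detectability band is usually quoted for.
    """
    if not sequence:
        raise ValueError("empty peptide")
    _check_residues(sequence)
    base = _pyteomics_mass.fast_mass(sequence, ion_type="M", charge=0)
    return base + n_phospho * PHOSPHO_MASS


def assign_length_bin(length: int) -> LengthBin:
    """8-15 residues is the MS-optimal bin; shorter/longer are flagged."""
    if length < 8:
        return LengthBin.SHORT_LT8
    if length <= 15:
        return LengthBin.OPT_8_15
    return LengthBin.LONG_GT15


def trypsin_digest(
    sequence: str,
    missed_cleavages: int = 0,
    kinase_id: str = "",
) -> list[TrypticPeptide]:
    """Digest a sequence with trypsin (cleave after K/R, not before P).

    With ``missed_cleavages = 0`` the peptides tile the sequence exactly;
    with ``m > 0`` every concatenation of up to ``m + 1`` adjacent
    fragments is additionally emitted.
    """
    if not sequence:
        raise ValueError("empty sequence")
    _check_residues(sequence)
    if not (0 <= missed_cleavages <= 2):
        raise ValueError("missed_cleavages must be 0..2")
    L = len(sequence)
    # boundaries[i] = start index (0-based) of fragment i; sentinel L at end
    boundaries = [0]
    for i in range(L - 1):
        if sequence[i] in "KR" and sequence[i + 1] != "P":
            boundaries.append(i + 1)
    boundaries.append(L)
    peptides: list[TrypticPeptide] = []
    n_frag = len(boundaries) - 1
    for i in range(n_frag):
        for m in range(missed_cleavages + 1):
            j = i + m + 1
            if j > n_frag:
                break
            start0, end0 = boundaries[i], boundaries[j]
            seq = sequence[start0:end0]
            peptides.append(
                TrypticPeptide(
                    kinase_id=kinase_id,
                    start=start0 + 1,
                    end=end0,
                    sequence=seq,
                    length_bin=assign_length_bin(len(seq)),
                    monoisotopic_mass=round(peptide_mass(seq), 4),
                )
            )
    return peptides


def map_sites_to_peptides(
    sites: Sequence[PhosphoSite],
    peptides: Sequence[TrypticPeptide],
) -> list[TrypticPeptide]:
    """Return the site-bearing peptides with ``site_positions`` filled.

    With zero missed cleavages the peptides tile the sequence, so each
    site lands in exactly one peptide.
    """
    if sites and peptides:
        kids = {s.kinase_id for s in sites} | {p.kinase_id for p in peptides}
        if len(kids) > 1:
            raise ValueError(f"sites and peptides span multiple kinases: {sorted(kids)}")
        max_end = max(p.end for p in peptides)
        for s in sites:
            if not (1 <= s.position <= max_end):
                raise ValueError(f"site position {s.position} outside digested sequence")
    out: list[TrypticPeptide] = []
    for pep in peptides:
        hits = sorted(s.position for s in sites if pep.start <= s.position <= pep.end)
        if hits:
            out.append(
                TrypticPeptide(
                    kinase_id=pep.kinase_id,
                    start=pep.start,
                    end=pep.end,
                    sequence=pep.sequence,
                    site_positions=hits,
                    length_bin=pep.length_bin,
                    monoisotopic_mass=pep.monoisotopic_mass,
                )
            )
    return out
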