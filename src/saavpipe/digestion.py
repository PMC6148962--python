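"""In-silico tryptic digestion with missed cleavages and length filtering.

Trypsin cleaves C-terminal of lysine (K) and arginine (R); the classic rule
suppresses cleavage when the following residue is proline.  Search-engine
dialects differ on that suppression ("Trypsin" vs "Trypsin/P"), so it is a
flag, default on.  Protein termini always count as cleavage boundaries.

Defaults mirror common shotgun-proteomics identification settings: at most
2 missed cleavages and a minimum identified peptide length of 7 residues.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_io import ProteinSeq
from .errors import ValidationError

DEFAULT_MAX_MISSED = 2
DEFAULT_MIN_LEN = 7


@dataclass(frozen=True)
class TrypticPeptide:
    """A tryptic fragment with its 1-based inclusive span in the parent."""

    sequence: str
    accession: str
    start: int
    end: int
    missed_cleavages: int

    @property
    def span_id(self) -> str:
        return f"{self.accession}_{self.start}_{self.end}"

    def __len__(self) -> int:
        return len(self.sequence)


def cleavage_boundaries(sequence: str, proline_rule: bool = True) -> list[int]:
    """0-based boundary offsets: 0, every cut point, and len(sequence).

    A cut point ``i`` means cleavage between residues ``i-1`` and ``i``
    (i.e. after a K/R at 0-based index ``i-1``).
    """
    bounds = [0]
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR":
            if proline_rule and sequence[i + 1] == "P":
                continue
            bounds.append(i + 1)
    bounds.append(len(sequence))
    return bounds


def digest(protein: ProteinSeq, max_missed: int = DEFAULT_MAX_MISSED,
           min_len: int = DEFAULT_MIN_LEN,
           proline_rule: bool = True) -> list[TrypticPeptide]:
    """Enumerate tryptic peptides with 0..max_missed retained internal sites.

    Returns peptides of length >= ``min_len`` ordered by (start, end).
    The 0-missed fragments partition the full sequence; each k-missed
    peptide is the join of k+1 consecutive fragments.
    """
    if max_missed < 0:
        raise ValidationError(f"max_missed must be >= 0, got {max_missed}")
    if min_len < 1:
        raise ValidationError(f"min_len must be >= 1, got {min_len}")
    seq = protein.sequence
    bounds = cleavage_boundaries(seq, proline_rule)
    n_frag = len(bounds) - 1
    peptides = []
    for j in range(n_frag):
        for k in range(min(max_missed, n_frag - 1 - j) + 1):
            lo, hi = bounds[j], bounds[j + k + 1]
            if hi - lo < min_len:
                continue
            peptides.append(TrypticPeptide(
                sequence=seq[lo:hi], accession=protein.accession,
                start=lo + 1, end=hi, missed_cleavages=k))
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def peptide_at(protein: ProteinSeq, position: int,
               max_missed: int = DEFAULT_MAX_MISSED,
               min_len: int = DEFAULT_MIN_LEN,
               proline_rule: bool = True) -> list[TrypticPeptide]:
    """Peptides from :func:`digest` whose span contains ``position``."""
    if not 1 <= position <= len(protein):
        raise ValidationError(
            f"position {position} outside 1..{len(protein)} "
            f"for {protein.accession}")
    return [p for p in digest(protein, max_missed, min_len, proline_rule)
            if p.start <= position <= p.end]
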