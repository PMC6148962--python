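"""Variant (SAAV) peptide database construction.

The generative model: apply each single-amino-acid substitution to its
parent protein, re-digest the *mutated* sequence, and keep the tryptic
peptides that cover the substituted residue.  Re-digesting (rather than
editing the wild-type peptide string) is essential because a substitution
that creates or destroys a K/R site changes the peptide spans; such
peptides are kept and flagged.  Candidates whose mutant sequence occurs
verbatim anywhere in the wild-type peptide universe carry no variant
evidence and are removed.

Each surviving record is identified by its span (``ACC_start_end``) plus
the substitution site (``D179N``), mirroring the usual reporting format
for SAAV tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .core_io import ProteinSeq, SaavEvent, write_fasta, make_protein
from .digestion import DEFAULT_MAX_MISSED, DEFAULT_MIN_LEN, digest
from .errors import ReferenceMismatchError, ValidationError

__all__ = [
    "SaavEvent", "VariantPeptide", "apply_event", "variant_peptides",
    "substitution_site", "filter_wildtype_collisions", "build_saav_fasta",
    "wild_peptide_universe", "fold_il",
]


@dataclass(frozen=True)
class VariantPeptide:
    """A mutant tryptic peptide carrying exactly one substitution.

    ``span_changed`` marks events that created/destroyed a cleavage site so
    that no wild-type peptide shares the mutant's span; ``wild_sequence``
    is then the shortest wild peptide covering the site instead.
    """

    mutant_sequence: str
    wild_sequence: str
    event: SaavEvent
    start: int
    end: int
    span_changed: bool = False

    def __post_init__(self):
        if not self.start <= self.event.position <= self.end:
            raise ValidationError(
                f"{self.span_id}: event position {self.event.position} "
                f"outside span")
        if not self.span_changed and self.mutant_sequence == self.wild_sequence:
            raise ValidationError(f"{self.span_id}: mutant equals wild")

    @property
    def span_id(self) -> str:
        return f"{self.event.accession}_{self.start}_{self.end}"


def apply_event(protein: ProteinSeq, event: SaavEvent) -> ProteinSeq:
    """Return the protein with the substitution applied.

    The residue at ``event.position`` must equal ``event.ref``; a mismatch
    signals stale annotation and raises :class:`ReferenceMismatchError`.
    """
    if event.accession != protein.accession:
        raise ValidationError(f"event targets {event.accession}, "
                              f"protein is {protein.accession}")
    pos = event.position
    if pos > len(protein):
        raise ReferenceMismatchError(
            f"{protein.accession}: position {pos} beyond length "
            f"{len(protein)}", [event])
    found = protein.sequence[pos - 1]
    if found != event.ref:
        raise ReferenceMismatchError(
            f"{protein.accession}: expected {event.ref} at {pos}, "
            f"sequence has {found}", [event])
    mutated = protein.sequence[:pos - 1] + event.alt + protein.sequence[pos:]
    return ProteinSeq(accession=protein.accession, sequence=mutated,
                      gene=protein.gene)


def variant_peptides(protein: ProteinSeq, event: SaavEvent,
                     max_missed: int = DEFAULT_MAX_MISSED,
                     min_len: int = DEFAULT_MIN_LEN,
                     proline_rule: bool = True) -> list[VariantPeptide]:
    """Digest the mutated protein and keep peptides covering the event.

    Each mutant peptide is paired with the wild-type peptide of identical
    span when one exists; otherwise (the substitution changed the cleavage
    pattern) the shortest covering wild peptide is attached and the record
    flagged ``span_changed``.
    """
    mutated = apply_event(protein, event)
    mut_peps = [p for p in digest(mutated, max_missed, min_len, proline_rule)
                if p.start <= event.position <= p.end]
    wild_by_span = {(p.start, p.end): p.sequence
                    for p in digest(protein, max_missed, min_len, proline_rule)}
    # unfiltered digest guarantees a covering wild peptide exists
    wild_covering = sorted(
        (p for p in digest(protein, max_missed, min_len=1,
                           proline_rule=proline_rule)
         if p.start <= event.position <= p.end),
        key=lambda p: (len(p), p.start))
    out = []
    for mp in mut_peps:
        wild = wild_by_span.get((mp.start, mp.end))
        if wild is not None and wild != mp.sequence:
            out.append(VariantPeptide(
                mutant_sequence=mp.sequence, wild_sequence=wild,
                event=event, start=mp.start, end=mp.end, span_changed=False))
        else:
            out.append(VariantPeptide(
                mutant_sequence=mp.sequence,
                wild_sequence=wild_covering[0].sequence if wild_covering else "",
                event=event, start=mp.start, end=mp.end, span_changed=True))
    return out


def substitution_site(wild: str, mutant: str, start: int) -> tuple[int, str, str]:
    """Locate the single differing residue between a wild/mutant peptide pair.

    ``start`` is the peptide's 1-based span start in the parent protein;
    the returned position is the protein coordinate of the substitution,
    with the wild and mutant letters there.  Exactly one difference is
    required.
    """
    if len(wild) != len(mutant):
        raise ValidationError(
            f"peptide lengths differ ({len(wild)} vs {len(mutant)})")
    diffs = [i for i, (w, m) in enumerate(zip(wild, mutant)) if w != m]
    if len(diffs) != 1:
        raise ValidationError(
            f"expected exactly one differing residue, found {len(diffs)}")
    i = diffs[0]
    return start + i, wild[i], mutant[i]


def fold_il(sequence: str) -> str:
    """Collapse isoleucine onto leucine (isobaric in MS spectra)."""
    return sequence.replace("I", "L")


def wild_peptide_universe(proteome: Iterable[ProteinSeq],
                          max_missed: int = DEFAULT_MAX_MISSED,
                          min_len: int = DEFAULT_MIN_LEN,
                          proline_rule: bool = True) -> set[str]:
    """All distinct wild-type tryptic peptide sequences of a proteome."""
    universe: set[str] = set()
    for protein in proteome:
        universe.update(p.sequence
                        for p in digest(protein, max_missed, min_len,
                                        proline_rule))
    return universe


def filter_wildtype_collisions(candidates: Sequence[VariantPeptide],
                               wild_universe: set[str],
                               il_fold: bool = False) -> list[VariantPeptide]:
    """Drop candidates whose mutant sequence occurs in the wild universe.

    With ``il_fold`` the comparison is done after mapping I onto L on both
    sides, since I/L are indistinguishable by mass.
    """
    if il_fold:
        folded = {fold_il(s) for s in wild_universe}
        return [c for c in candidates if fold_il(c.mutant_sequence) not in folded]
    return [c for c in candidates if c.mutant_sequence not in wild_universe]


def build_saav_fasta(proteome: Sequence[ProteinSeq],
                     events: Sequence[SaavEvent],
                     max_missed: int = DEFAULT_MAX_MISSED,
                     min_len: int = DEFAULT_MIN_LEN,
                     proline_rule: bool = True,
                     il_fold: bool = False,
                     fasta_path=None, index_path=None):
    """Build the variant-peptide database.

    Returns ``(records, index)``: one FASTA-ready record per surviving
    variant peptide with header ``ACC_start_end|XnY``, and a companion
    index table with sequence, span and aggregated sample/cohort
    provenance.  Records from the same event observed in several samples
    collapse to one database entry whose provenance lists every carrier.
    Reference mismatches across all events are aggregated into a single
    error report.

    When ``fasta_path``/``index_path`` are given the outputs are written
    (FASTA + TSV) in deterministic order.
    """
    by_acc = {p.accession: p for p in proteome}
    mismatches: list[tuple[SaavEvent, str]] = []
    candidates: list[VariantPeptide] = []
    for event in events:
        protein = by_acc.get(event.accession)
        if protein is None:
            mismatches.append((event, "accession not in proteome"))
            continue
        try:
            candidates.extend(variant_peptides(
                protein, event, max_missed, min_len, proline_rule))
        except ReferenceMismatchError as exc:
            mismatches.append((event, str(exc)))
    if mismatches:
        lines = "; ".join(f"{e.accession}:{e.site} ({why})"
                          for e, why in mismatches)
        raise ReferenceMismatchError(
            f"{len(mismatches)} event(s) failed reference check: {lines}",
            [e for e, _ in mismatches])

    universe = wild_peptide_universe(proteome, max_missed, min_len,
                                     proline_rule)
    surviving = filter_wildtype_collisions(candidates, universe, il_fold)

    # collapse (span, site, mutant) duplicates, aggregating provenance
    grouped: dict[tuple, dict] = {}
    for vp in surviving:
        key = (vp.span_id, vp.event.site, vp.mutant_sequence)
        entry = grouped.setdefault(key, {
            "span_id": vp.span_id, "site": vp.event.site,
            "accession": vp.event.accession, "start": vp.start,
            "end": vp.end, "mutant_peptide": vp.mutant_sequence,
            "wild_peptide": vp.wild_sequence,
            "span_changed": vp.span_changed,
            "samples": set(), "cohorts": set()})
        if vp.event.sample:
            entry["samples"].add(vp.event.sample)
        if vp.event.cohort:
            entry["cohorts"].add(vp.event.cohort)

    rows = sorted(grouped.values(),
                  key=lambda r: (r["accession"], r["start"], r["end"],
                                 r["site"]))
    index = pd.DataFrame(
        [{**r, "samples": ",".join(sorted(r["samples"])),
          "cohorts": ",".join(sorted(r["cohorts"]))} for r in rows],
        columns=["span_id", "site", "accession", "start", "end",
                 "mutant_peptide", "wild_peptide", "span_changed",
                 "samples", "cohorts"])
    records = [make_protein(f"{r['span_id']}|{r['site']}",
                            r["mutant_peptide"]) for r in rows]
    if fasta_path is not None:
        write_fasta(records, fasta_path)
    if index_path is not None:
        index.to_csv(index_path, sep="\t", index=False)
    return records, index
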