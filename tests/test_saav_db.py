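"""Variant peptide database construction: substitution application,
re-digestion, site arithmetic and wild-type collision filtering."""

import numpy as np
import pytest

from helpers import brute_force_digest, embed_peptide, random_protein
from saavpipe.core_io import ProteinSeq, SaavEvent
from saavpipe.digestion import digest
from saavpipe.errors import ReferenceMismatchError, ValidationError
from saavpipe.saav_db import (apply_event, build_saav_fasta,
                              filter_wildtype_collisions, fold_il,
                              substitution_site, variant_peptides,
                              wild_peptide_universe)


@pytest.fixture
def rab2a_like():
    """Parent protein carrying IQEGVFDIDNEANGIK as the tryptic span
    171-186, as in the published NM-specific table."""
    return embed_peptide("IQEGVFDIDNEANGIK", start=171, accession="P61019")


class TestApplyEvent:
    def test_single_residue_replaced(self, rab2a_like):
        ev = SaavEvent("P61019", 179, "D", "N")
        mut = apply_event(rab2a_like, ev)
        assert mut.sequence[178] == "N"
        assert len(mut) == len(rab2a_like)
        diffs = [i for i in range(len(mut))
                 if mut.sequence[i] != rab2a_like.sequence[i]]
        assert diffs == [178]

    def test_involution(self, rab2a_like):
        ev = SaavEvent("P61019", 179, "D", "N")
        back = SaavEvent("P61019", 179, "N", "D")
        assert apply_event(apply_event(rab2a_like, ev), back) == rab2a_like

    def test_reference_mismatch(self, rab2a_like):
        with pytest.raises(ReferenceMismatchError):
            apply_event(rab2a_like, SaavEvent("P61019", 179, "E", "N"))

    def test_position_beyond_length(self, rab2a_like):
        with pytest.raises(ReferenceMismatchError):
            apply_event(rab2a_like,
                        SaavEvent("P61019", 10_000, "D", "N"))


class TestVariantPeptides:
    def test_worked_example_span_and_sequences(self, rab2a_like):
        ev = SaavEvent("P61019", 179, "D", "N")
        vps = variant_peptides(rab2a_like, ev)
        exact = [v for v in vps if v.span_id == "P61019_171_186"]
        assert len(exact) == 1
        v = exact[0]
        assert v.wild_sequence == "IQEGVFDIDNEANGIK"
        assert v.mutant_sequence == "IQEGVFDINNEANGIK"
        assert not v.span_changed

    def test_site_destroying_substitution_repaired_spans(self):
        # K -> Q removes a cleavage site: the merged 0-missed mutant
        # peptide pairs with the wild 1-missed peptide of the same span,
        # while wider mutant peptides outrun the wild digest and are
        # flagged as span-changed.
        prot = embed_peptide("AAAEAAAKEEEEEEER", start=11, accession="ACC1")
        pos = 11 + 7  # the internal K
        ev = SaavEvent("ACC1", pos, "K", "Q")
        vps = variant_peptides(prot, ev)
        assert vps, "substituted peptide should still be covered"
        merged = [v for v in vps if v.mutant_sequence == "AAAEAAAQEEEEEEER"]
        assert merged and merged[0].wild_sequence == "AAAEAAAKEEEEEEER"
        assert any(v.span_changed for v in vps)

    def test_site_creating_substitution_flagged(self):
        # E -> K creates a cleavage site: the short mutant fragment's
        # span exists in no wild peptide, so the covering wild peptide is
        # attached and the record flagged.
        prot = embed_peptide("AAAEAAAAAEEEEEEK", start=11, accession="ACC3")
        pos = 11 + 3  # the E
        ev = SaavEvent("ACC3", pos, "E", "K")
        vps = variant_peptides(prot, ev)
        # peptides ending at the newly created K have spans absent from
        # the wild digest
        new_end = [v for v in vps if v.end == pos]
        assert new_end and all(v.span_changed for v in new_end)
        assert all(v.wild_sequence for v in new_end)

    def test_event_in_protein_without_cleavage_sites(self):
        prot = ProteinSeq("ACC2", "MAAAAAAA")
        vps = variant_peptides(prot, SaavEvent("ACC2", 1, "M", "V"))
        assert len(vps) == 1
        assert vps[0].mutant_sequence == "VAAAAAAA"
        assert (vps[0].start, vps[0].end) == (1, 8)

    def test_every_variant_peptide_covers_its_event(self):
        rng = np.random.default_rng(21)
        for i in range(20):
            prot = random_protein(rng, 80, accession=f"P{i}")
            pos = int(rng.integers(1, 81))
            ref = prot.sequence[pos - 1]
            alt = "W" if ref != "W" else "Y"
            for v in variant_peptides(prot, SaavEvent(f"P{i}", pos, ref, alt)):
                assert v.start <= pos <= v.end
                assert len(v.mutant_sequence) >= 7


class TestSubstitutionSite:
    @pytest.mark.parametrize("wild,mutant,start,expected", [
        ("IQEGVFDIDNEANGIK", "IQEGVFDINNEANGIK", 171, (179, "D", "N")),
        ("AGVIAHIEEER", "AGVITHIEEER", 765, (769, "A", "T")),
        ("NAIDDGCVVPGAGAVEVAMAEAIIK", "NAIDDGCVVPGAGAVEVAMAEAINK",
         400, (423, "I", "N")),
    ])
    def test_published_peptide_pairs(self, wild, mutant, start, expected):
        assert substitution_site(wild, mutant, start) == expected

    def test_zero_or_multiple_differences_rejected(self):
        with pytest.raises(ValidationError):
            substitution_site("PEPTIDEK", "PEPTIDEK", 1)
        with pytest.raises(ValidationError):
            substitution_site("PEPTIDEK", "PAPTADEK", 1)
        with pytest.raises(ValidationError):
            substitution_site("PEPTIDEK", "PEPTIDEKK", 1)

    def test_left_inverse_of_substitution(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            prot = random_protein(rng, 40)
            start = int(rng.integers(1, 20))
            wild = prot.sequence[start - 1:start + 11]
            off = int(rng.integers(len(wild)))
            alt = "W" if wild[off] != "W" else "Y"
            mutant = wild[:off] + alt + wild[off + 1:]
            pos, ref, got_alt = substitution_site(wild, mutant, start)
            assert pos == start + off
            assert ref == wild[off]
            assert got_alt == alt
            # applying (pos, ref, alt) to wild reproduces mutant
            rebuilt = wild[:pos - start] + got_alt + wild[pos - start + 1:]
            assert rebuilt == mutant


class TestCollisionFilter:
    def test_removal_matches_exhaustive_scan(self):
        rng = np.random.default_rng(17)
        proteome = [random_protein(rng, 100, accession=f"T{i}")
                    for i in range(20)]
        universe = wild_peptide_universe(proteome)
        # exhaustive recomputation by a different route
        exhaustive = set()
        for p in proteome:
            exhaustive.update(s for _, _, s, _ in
                              brute_force_digest(p.sequence, 2, 7))
        assert universe == exhaustive
        candidates = []
        for i in range(10):
            prot = proteome[i]
            pos = int(rng.integers(1, len(prot) + 1))
            ref = prot.sequence[pos - 1]
            alt = "H" if ref != "H" else "F"
            candidates.extend(variant_peptides(
                prot, SaavEvent(prot.accession, pos, ref, alt)))
        kept = filter_wildtype_collisions(candidates, universe)
        for c in candidates:
            if c.mutant_sequence in exhaustive:
                assert c not in kept
            else:
                assert c in kept

    def test_il_fold_removes_indistinguishable_candidate(self):
        prot = embed_peptide("IQEGVFDIDNEANGIK", start=171,
                             accession="P61019")
        ev = SaavEvent("P61019", 171, "I", "L")  # I->L: isobaric swap
        vps = variant_peptides(prot, ev)
        universe = wild_peptide_universe([prot])
        assert filter_wildtype_collisions(vps, universe, il_fold=True) == []
        survivors = filter_wildtype_collisions(vps, universe, il_fold=False)
        assert any(v.span_id == "P61019_171_186" for v in survivors)

    def test_fold_il_mapping(self):
        assert fold_il("ILLI") == "LLLL"


class TestBuildDatabase:
    def test_interior_event_produces_records_with_span_headers(self,
                                                               rab2a_like):
        ev = SaavEvent("P61019", 179, "D", "N", sample="s1", cohort="NM")
        records, index = build_saav_fasta([rab2a_like], [ev])
        assert len(records) >= 1
        assert any(r.accession == "P61019_171_186|D179N" for r in records)
        row = index[index["span_id"] == "P61019_171_186"].iloc[0]
        assert row["mutant_peptide"] == "IQEGVFDINNEANGIK"
        assert row["cohorts"] == "NM"

    def test_no_events_gives_empty_database(self, rab2a_like):
        records, index = build_saav_fasta([rab2a_like], [])
        assert records == []
        assert len(index) == 0

    def test_record_count_matches_independent_recount(self):
        rng = np.random.default_rng(31)
        proteome = [random_protein(rng, 120, accession=f"B{i}")
                    for i in range(10)]
        events = []
        for i in range(8):
            prot = proteome[int(rng.integers(len(proteome)))]
            pos = int(rng.integers(1, len(prot) + 1))
            ref = prot.sequence[pos - 1]
            alt = "W" if ref != "W" else "Y"
            events.append(SaavEvent(prot.accession, pos, ref, alt,
                                    sample=f"s{i}", cohort="MT"))
        records, index = build_saav_fasta(proteome, events)
        # independent recount: per-event variant peptides, collision scan,
        # dedup on (span, site, mutant)
        universe = wild_peptide_universe(proteome)
        by_acc = {p.accession: p for p in proteome}
        expected = set()
        for ev in events:
            for v in variant_peptides(by_acc[ev.accession], ev):
                if v.mutant_sequence not in universe:
                    expected.add((v.span_id, ev.site, v.mutant_sequence))
        assert len(records) == len(expected) == len(index)

    def test_reference_mismatches_aggregated(self, rab2a_like):
        bad = [SaavEvent("P61019", 179, "E", "N"),
               SaavEvent("MISSING", 5, "A", "V")]
        with pytest.raises(ReferenceMismatchError) as exc:
            build_saav_fasta([rab2a_like], bad)
        assert len(exc.value.mismatches) == 2

    def test_deterministic_output_order(self, rab2a_like):
        evs = [SaavEvent("P61019", 179, "D", "N", sample="s1", cohort="NM"),
               SaavEvent("P61019", 175, "V", "A", sample="s2", cohort="MT")]
        _, idx1 = build_saav_fasta([rab2a_like], evs)
        _, idx2 = build_saav_fasta([rab2a_like], list(reversed(evs)))
        assert idx1.equals(idx2)
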