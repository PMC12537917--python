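"""Hit-review rules: appended-position check, verdicts, ranking, rescreen."""

import dataclasses
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from signalstrap.align import smith_waterman
from signalstrap.bootstrap import build_query
from signalstrap.search import EmptyDatabaseError
from signalstrap.seqio import AA20, ProteinRecord, SignalPeptideAnnotation
from signalstrap.triage import (CandidateRecord, CoordinatingSet,
                                check_appended_alignment,
                                coordination_inventory, rank_candidates,
                                rescreen, triage_hit)

SP = "MKT" + "L" * 9 + "TASA"
QUERY = build_query(SP, "H", source_taxon="orgQ", query_id="q")


def _self_hit(scheme, subject_seq: str, subject_id: str = "s"):
    return smith_waterman(QUERY.query_sequence, subject_seq, scheme,
                          query_id="q", subject_id=subject_id)


def _hit_with(scheme, subject: ProteinRecord):
    hit = smith_waterman(QUERY.query_sequence, subject.sequence, scheme,
                         query_id="q", subject_id=subject.id)
    return dataclasses.replace(hit, evalue=1.0)


class TestAppendedAlignment:
    def test_identity_alignment_is_true(self, pam30):
        hit = _self_hit(pam30, QUERY.query_sequence)
        assert check_appended_alignment(hit, QUERY)

    def test_alignment_ending_before_position_is_false(self, pam30):
        hit = _self_hit(pam30, QUERY.sp_sequence)  # subject lacks the His
        assert hit.q_end < QUERY.appended_position
        assert not check_appended_alignment(hit, QUERY)

    def test_non_his_opposite_appended_is_false(self):
        # constructed gapless alignment covering the appended position with
        # tyrosine opposite the query's appended histidine
        from signalstrap.align import AlignmentHit
        q = QUERY.query_sequence
        hit = AlignmentHit(query_id="q", subject_id="s", score=50.0,
                           evalue=1.0, q_start=1, q_end=len(q),
                           s_start=1, s_end=len(q),
                           q_aln=q, s_aln=q[:-1] + "Y",
                           identity=(len(q) - 1) / len(q))
        assert not check_appended_alignment(hit, QUERY)

    def test_gap_opposite_appended_is_false(self):
        from signalstrap.align import AlignmentHit
        q = QUERY.query_sequence
        hit = AlignmentHit(query_id="q", subject_id="s", score=50.0,
                           evalue=1.0, q_start=1, q_end=len(q),
                           s_start=1, s_end=len(q) - 1,
                           q_aln=q, s_aln=q[:-1] + "-",
                           identity=(len(q) - 1) / len(q))
        assert not check_appended_alignment(hit, QUERY)


class TestTriageVerdicts:
    def _subject(self, mature: str, pid: str = "s") -> ProteinRecord:
        return ProteinRecord(id=pid, sequence=SP + mature, taxon="orgS")

    def _ann(self, pid: str = "s") -> SignalPeptideAnnotation:
        return SignalPeptideAnnotation(protein_id=pid, sp_end=len(SP),
                                       predictor="truth")

    def test_his1_glu2_accepted_by_default_rule_set(self, pam30):
        # mature starting HE: a worked-example family begins exactly this
        # way, so E/N/Q are excluded from the default position-2 rule set
        subject = self._subject("HETTAGGDGGHGG")
        cand = triage_hit(_hit_with(pam30, subject), QUERY, subject, self._ann())
        assert not cand.pos2_clash
        assert cand.verdict == "accepted"

    def test_his1_glu2_rejected_when_rule_set_includes_glu(self, pam30):
        subject = self._subject("HETTAGGDGGHGG")
        cand = triage_hit(_hit_with(pam30, subject), QUERY, subject,
                          self._ann(), pos2_rule=frozenset("HCDEMNQ"))
        assert cand.pos2_clash
        assert cand.verdict == "rejected_pos2"

    def test_accepted_candidate_inventory_positions(self, pam30):
        subject = self._subject("HGGGCGGDGGHGG")
        cand = triage_hit(_hit_with(pam30, subject), QUERY, subject, self._ann())
        assert cand.verdict == "accepted"
        assert cand.coordination_inventory == ((5, "C"), (8, "D"), (11, "H"))

    def test_no_his1_rejected(self, pam30):
        subject = self._subject("AHGGGGGGG")
        cand = triage_hit(_hit_with(pam30, subject), QUERY, subject, self._ann())
        assert cand.verdict == "rejected_no_his1"

    def test_no_annotation_rejected(self, pam30):
        subject = ProteinRecord(id="s", sequence="HHHH" + "G" * 30, taxon="orgS")
        hit = dataclasses.replace(
            smith_waterman(QUERY.query_sequence, subject.sequence, pam30,
                           query_id="q", subject_id="s"), evalue=1.0)
        cand = triage_hit(hit, QUERY, subject, None)
        assert cand.verdict == "rejected_no_annotation"

    def test_heuristic_fallback_rescues_missing_annotation(self, pam30):
        subject = self._subject("HGGGGGGGGGGGGGGGGGGGG")
        cand = triage_hit(_hit_with(pam30, subject), QUERY, subject, None,
                          allow_heuristic=True)
        assert cand.annotation is not None
        assert cand.annotation.predictor == "heuristic"
        assert cand.verdict == "accepted"

    def test_his1_without_alignment_support_is_review(self, pam30):
        # the subject's SP carries a 5-residue insertion before its His1, so
        # extending the SP-SP alignment to the His costs more than it gains;
        # His1 is real but lacks appended-position alignment evidence
        subject = ProteinRecord(id="s", sequence=SP + "PPPPP" + "HGGGG",
                                taxon="orgS")
        hit = smith_waterman(QUERY.query_sequence, subject.sequence, pam30,
                             query_id="q", subject_id="s")
        assert hit.q_end < QUERY.appended_position
        cand = triage_hit(
            dataclasses.replace(hit, evalue=1.0), QUERY, subject,
            SignalPeptideAnnotation(protein_id="s", sp_end=len(SP) + 5))
        assert cand.his1
        assert not cand.his_at_appended
        assert cand.verdict == "review"

    @given(mature=st.text(alphabet=AA20, min_size=1, max_size=30))
    def test_accepted_implies_his1_and_clean_pos2(self, mature, pam30):
        subject = self._subject(mature)
        cand = triage_hit(_hit_with(pam30, subject), QUERY, subject, self._ann())
        if cand.verdict == "accepted":
            assert cand.mature.position_one == "H"
            if len(cand.mature.residues) >= 2:
                assert cand.mature.residues[1] not in "HCDM"
        inv_positions = [p for p, _ in cand.coordination_inventory]
        assert all(p >= 3 for p in inv_positions)
        assert inv_positions == sorted(inv_positions)


class TestRanking:
    def _cand(self, verdict: str, n_inventory: int, evalue: float,
              pid: str, pam30) -> CandidateRecord:
        mature = "HG" + "H" * n_inventory + "G" * 5
        subject = ProteinRecord(id=pid, sequence=SP + mature, taxon="orgS")
        hit = dataclasses.replace(_hit_with(pam30, subject), evalue=evalue)
        ann = SignalPeptideAnnotation(protein_id=pid, sp_end=len(SP))
        cand = triage_hit(hit, QUERY, subject, ann)
        return dataclasses.replace(cand, verdict=verdict)

    def test_larger_inventory_first(self, pam30):
        a = self._cand("accepted", 4, 1.0, "a", pam30)
        b = self._cand("accepted", 1, 0.1, "b", pam30)
        assert [c.subject.id for c in rank_candidates([b, a])] == ["a", "b"]

    def test_accepted_before_review(self, pam30):
        a = self._cand("review", 2, 0.1, "a", pam30)
        b = self._cand("accepted", 2, 1.0, "b", pam30)
        assert [c.subject.id for c in rank_candidates([a, b])] == ["b", "a"]

    def test_empty_input(self):
        assert rank_candidates([]) == []


class TestRescreen:
    def test_family_members_recovered(self, pam30, small_dataset):
        fam = small_dataset.families[0]
        member = next(r for r in small_dataset.records
                      if r.id == fam.member_ids[0])
        ann = SignalPeptideAnnotation(protein_id=member.id,
                                      sp_end=len(fam.sp_sequence))
        query = build_query(fam.sp_sequence, "H", query_id="fam")
        hit = dataclasses.replace(
            smith_waterman(query.query_sequence, member.sequence, pam30,
                           query_id="fam", subject_id=member.id), evalue=1.0)
        cand = triage_hit(hit, query, member, ann)
        assert cand.verdict == "accepted"
        hits = rescreen(cand, small_dataset.records, pam30)
        hit_ids = {h.subject_id for h in hits}
        assert set(fam.member_ids) <= hit_ids
        keys = [(h.evalue, -h.score, h.subject_id) for h in hits]
        assert keys == sorted(keys)

    def test_only_accepted_candidates_rescreened(self, pam30):
        subject = ProteinRecord(id="s", sequence=SP + "AHGG", taxon="orgS")
        cand = triage_hit(_hit_with(pam30, subject), QUERY, subject,
                          SignalPeptideAnnotation(protein_id="s", sp_end=len(SP)))
        with pytest.raises(ValueError):
            rescreen(cand, [subject], pam30)

    def test_rescreen_with_empty_db_propagates_error(self, pam30):
        subject = ProteinRecord(id="s", sequence=SP + "HGGG", taxon="orgS")
        cand = triage_hit(_hit_with(pam30, subject), QUERY, subject,
                          SignalPeptideAnnotation(protein_id="s", sp_end=len(SP)))
        assert cand.verdict == "accepted"
        with pytest.raises(EmptyDatabaseError):
            rescreen(cand, [], pam30)


class TestInventory:
    def test_counts_only_positions_three_and_beyond(self):
        inv = coordination_inventory("HEHDG", CoordinatingSet())
        assert inv == ((3, "H"), (4, "D"))
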