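"""Hit review: turn alignment hits into ranked metalloprotein candidates.

The review rules mirror the manual procedure the search emulates:

* a subject is interesting when the residue aligned (without a gap) to the
  query's appended position is a histidine;
* the subject's own signal peptide is cleaved and histidine must be
  confirmed at mature position 1;
* a coordinating residue immediately after the N-terminal histidine
  (mature position 2) rejects the candidate — steric constraints make
  simultaneous coordination of positions 1 and 2 highly unlikely;
* additional coordinating residues further along the mature sequence raise
  a candidate's rank.

Note the position-2 rule set defaults to {H, C, D, M}, deliberately
narrower than the coordination-inventory set {H, C, D, E, M, N, Q}: the
worked-example DUF6702 query itself carries E at mature position 2, so a
rule set containing E/N/Q would contradict the method's own examples. Both
sets are independently configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .align import AlignmentHit
from .bootstrap import BootstrapQuery
from .scoring import ScoringScheme
from .search import SearchRun, search
from .seqio import (MatureSequence, ProteinRecord, SignalPeptideAnnotation,
                    cleave, heuristic_sp_call)

logger = logging.getLogger(__name__)

#: Residues counted as potential metal-coordinating side chains.
DEFAULT_COORDINATING = frozenset("HCDEMNQ")
#: Residues that trigger rejection when found at mature position 2.
DEFAULT_POS2_RULE = frozenset("HCDM")
#: Residues accepted as the chelating N-terminus (mature position 1).
DEFAULT_CHELATING = frozenset("H")

VERDICTS = ("accepted", "review", "rejected_no_his1", "rejected_pos2",
            "rejected_no_annotation")


@dataclass(frozen=True)
class CoordinatingSet:
    residues: frozenset[str] = DEFAULT_COORDINATING

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("coordinating set must be non-empty")

    def __contains__(self, residue: str) -> bool:
        return residue in self.residues


@dataclass(frozen=True)
class CandidateRecord:
    """A triaged subject with rule flags and a verdict."""

    subject: ProteinRecord
    hit: AlignmentHit
    annotation: Optional[SignalPeptideAnnotation]
    mature: Optional[MatureSequence]
    his_at_appended: bool
    his1: bool
    pos2_clash: bool
    coordination_inventory: tuple[tuple[int, str], ...]
    verdict: str

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")
        positions = [p for p, _ in self.coordination_inventory]
        if positions != sorted(set(positions)):
            raise ValueError("inventory positions must be strictly increasing")
        if self.verdict == "accepted" and not (self.his1 and not self.pos2_clash):
            raise ValueError("accepted candidate violates His1/position-2 rules")


def check_appended_alignment(hit: AlignmentHit, query: BootstrapQuery,
                             chelating: frozenset[str] = DEFAULT_CHELATING) -> bool:
    """True iff the query's appended position is inside the aligned interval,
    aligned to a residue (not a gap), and that subject residue is a chelator
    (H by default)."""
    pos = query.appended_position
    if not (hit.q_start <= pos <= hit.q_end):
        return False
    q_pos = hit.q_start - 1
    for a, b in zip(hit.q_aln, hit.s_aln):
        if a != "-":
            q_pos += 1
            if q_pos == pos:
                return b != "-" and b in chelating
    return False  # pragma: no cover - interval check makes this unreachable


def coordination_inventory(mature: str,
                           coord: CoordinatingSet) -> tuple[tuple[int, str], ...]:
    """Coordinating residues at mature positions >= 3 (1-based)."""
    return tuple((i, c) for i, c in enumerate(mature, start=1)
                 if i >= 3 and c in coord)


def triage_hit(hit: AlignmentHit, query: BootstrapQuery, subject: ProteinRecord,
               ann: Optional[SignalPeptideAnnotation],
               coord: CoordinatingSet = CoordinatingSet(),
               pos2_rule: frozenset[str] = DEFAULT_POS2_RULE,
               chelating: frozenset[str] = DEFAULT_CHELATING,
               allow_heuristic: bool = False) -> CandidateRecord:
    """Apply the hit-review rules to one subject.

    Without an annotation (and with the heuristic fallback disabled or
    unsuccessful) the verdict is ``rejected_no_annotation``. Otherwise the
    subject is cleaved; ``accepted`` requires a chelating mature position 1,
    no position-2 clash, and alignment support at the appended position —
    His1-positive subjects lacking that alignment support are flagged
    ``review`` for human judgement rather than dropped.
    """
    if subject.id != hit.subject_id:
        raise ValueError(f"subject {subject.id!r} does not match hit "
                         f"{hit.subject_id!r}")
    if ann is None and allow_heuristic and len(subject.sequence) >= 25:
        ann = heuristic_sp_call(subject)
        if ann is not None:
            logger.debug("annotation source for %s: heuristic", subject.id)
    his_at_appended = check_appended_alignment(hit, query, chelating)
    if ann is None:
        return CandidateRecord(subject=subject, hit=hit, annotation=None,
                               mature=None, his_at_appended=his_at_appended,
                               his1=False, pos2_clash=False,
                               coordination_inventory=(),
                               verdict="rejected_no_annotation")
    mature = cleave(subject, ann)
    his1 = mature.position_one in chelating
    pos2_clash = len(mature.residues) >= 2 and mature.residues[1] in pos2_rule
    inventory = coordination_inventory(mature.residues, coord)
    if not his1:
        verdict = "rejected_no_his1"
    elif pos2_clash:
        verdict = "rejected_pos2"
    elif not his_at_appended:
        verdict = "review"
    else:
        verdict = "accepted"
    return CandidateRecord(subject=subject, hit=hit, annotation=ann,
                           mature=mature, his_at_appended=his_at_appended,
                           his1=his1, pos2_clash=pos2_clash,
                           coordination_inventory=inventory, verdict=verdict)


_CLASS_ORDER = {"accepted": 0, "review": 1}


def rank_candidates(cands: Sequence[CandidateRecord]) -> list[CandidateRecord]:
    """Accepted first, then review, then rejections; within class by
    descending inventory size, ascending E-value, then id."""
    return sorted(cands, key=lambda c: (
        _CLASS_ORDER.get(c.verdict, 2),
        -len(c.coordination_inventory),
        c.hit.evalue,
        c.subject.id,
    ))


def rescreen(candidate: CandidateRecord, db: Sequence[ProteinRecord],
             scheme: ScoringScheme, evalue_cutoff: float = 1000.0,
             max_targets: int = 500,
             excluded_taxon: Optional[str] = None) -> list[AlignmentHit]:
    """Full-length re-search with an accepted candidate's complete sequence
    (signal peptide included) to gather its homologue set."""
    if candidate.verdict != "accepted":
        raise ValueError("only accepted candidates are rescreened")
    run = SearchRun(query_id=candidate.subject.id,
                    query_sequence=candidate.subject.sequence,
                    evalue_cutoff=evalue_cutoff, max_targets=max_targets,
                    excluded_taxon=excluded_taxon)
    return search(run, db, scheme)


def write_candidates_tsv(cands: Sequence[CandidateRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# id\tverdict\this1\tpos2_clash\this_at_appended\t"
                 "inventory\tevalue\n")
        for c in cands:
            inv = ";".join(f"{p}{r}" for p, r in c.coordination_inventory)
            fh.write(f"{c.subject.id}\t{c.verdict}\t{int(c.his1)}\t"
                     f"{int(c.pos2_clash)}\t{int(c.his_at_appended)}\t"
                     f"{inv}\t{c.hit.evalue:.3g}\n")
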