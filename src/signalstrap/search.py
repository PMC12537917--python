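"""Exhaustive short-query local search over a FASTA database.

Emulates the public-server blastp setup the signal-strapping procedure uses:
every database record (minus the query's own organism) is aligned with
Smith-Waterman under the short-sequence defaults (PAM30, gaps 9/1), hits are
assigned Karlin-Altschul E-values and kept under a deliberately permissive
cutoff (default 1000) because candidate selection happens downstream in
triage, not by significance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .align import AlignmentHit, smith_waterman
from .bootstrap import BootstrapQuery
from .scoring import ScoringScheme
from .seqio import ProteinRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchRun:
    """Parameters of one search: query, database size and cutoffs."""

    query_id: str
    query_sequence: str
    evalue_cutoff: float = 1000.0
    max_targets: int = 500
    excluded_taxon: Optional[str] = None
    db_size_letters: int = 0  # filled at search time

    @property
    def query_length(self) -> int:
        return len(self.query_sequence)


class EmptyDatabaseError(ValueError):
    """Search has no subject to scan (e.g. taxon exclusion emptied the db)."""


def _two_mer_set(seq: str) -> set[str]:
    return {seq[i:i + 2] for i in range(len(seq) - 1)}


def search(run: SearchRun, db: Sequence[ProteinRecord], scheme: ScoringScheme,
           prefilter: bool = False) -> list[AlignmentHit]:
    """Align the query against every non-excluded record; sort and truncate.

    Sort key: ascending E-value, then descending score, then subject id.
    With ``prefilter`` only subjects sharing an exact 2-mer with the query
    are scanned (results are a subset of the exhaustive scan).
    """
    if not db:
        raise EmptyDatabaseError("database is empty")
    subjects = []
    for rec in db:
        if run.excluded_taxon is not None:
            if rec.taxon is None:
                logger.debug("record %s has no taxon tag; never excluded", rec.id)
            elif rec.taxon == run.excluded_taxon:
                continue
        subjects.append(rec)
    if not subjects:
        raise EmptyDatabaseError(
            f"taxon exclusion {run.excluded_taxon!r} removed every record")
    n = sum(len(r) for r in subjects)
    run = dataclasses.replace(run, db_size_letters=n)
    m = run.query_length
    qmers = _two_mer_set(run.query_sequence) if prefilter else None
    hits: list[AlignmentHit] = []
    for rec in subjects:
        if qmers is not None and not (qmers & _two_mer_set(rec.sequence)):
            continue
        hit = smith_waterman(run.query_sequence, rec.sequence, scheme,
                             query_id=run.query_id, subject_id=rec.id)
        if hit is None:
            continue
        e = scheme.evalue(hit.score, m, n)
        if e <= run.evalue_cutoff:
            hits.append(dataclasses.replace(hit, evalue=e))
    hits.sort(key=lambda h: (h.evalue, -h.score, h.subject_id))
    return hits[: run.max_targets]


def search_query(query: BootstrapQuery, db: Sequence[ProteinRecord],
                 scheme: ScoringScheme, evalue_cutoff: float = 1000.0,
                 max_targets: int = 500, prefilter: bool = False) -> list[AlignmentHit]:
    """Convenience wrapper: search with a bootstrap query, excluding its
    source organism."""
    run = SearchRun(query_id=query.id, query_sequence=query.query_sequence,
                    evalue_cutoff=evalue_cutoff, max_targets=max_targets,
                    excluded_taxon=query.source_taxon)
    return search(run, db, scheme, prefilter=prefilter)


def _gap_opens(aln: str) -> int:
    opens, in_gap = 0, False
    for c in aln:
        if c == "-" and not in_gap:
            opens += 1
        in_gap = c == "-"
    return opens


def write_hits_tsv(hits: Sequence[AlignmentHit], scheme: ScoringScheme,
                   path: str | Path) -> None:
    """12-column tabular output (BLAST outfmt-6 convention, 1-based coords)."""
    with open(path, "w") as fh:
        fh.write("# qid\tsid\tpident\tlength\tmismatches\tgapopens\t"
                 "qstart\tqend\tsstart\tsend\tevalue\tbitscore\n")
        for h in hits:
            mismatches = sum(1 for a, b in zip(h.q_aln, h.s_aln)
                             if a != "-" and b != "-" and a != b)
            gapopens = _gap_opens(h.q_aln) + _gap_opens(h.s_aln)
            fh.write("\t".join([
                h.query_id, h.subject_id, f"{100.0 * h.identity:.2f}",
                str(h.length), str(mismatches), str(gapopens),
                str(h.q_start), str(h.q_end), str(h.s_start), str(h.s_end),
                f"{h.evalue:.3g}", f"{scheme.bit_score(h.score):.1f}",
            ]) + "\n")


def write_hits_json(hits: Sequence[AlignmentHit], path: str | Path) -> None:
    payload = [dataclasses.asdict(h) for h in hits]
    for row in payload:
        if isinstance(row["evalue"], float) and math.isnan(row["evalue"]):
            row["evalue"] = None
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")
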