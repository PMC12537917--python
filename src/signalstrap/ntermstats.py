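"""N-terminal residue frequencies: secreted vs cytosolic classes.

Secreted proteins contribute the residue revealed at mature position 1 after
signal-peptide cleavage; cytosolic proteins contribute position 2, the
residue adjacent to the initiator methionine (a proxy for the N-terminus
after Met excision — no aminopeptidase specificity model is applied, and
records not starting with M are skipped and counted). The enrichment ratio
f_sec(a) / f_cyt(a) quantifies how much more often residue ``a`` is exposed
at secreted N-termini; for histidine this ratio is the statistic motivating
the whole search strategy (chelating residues are several-fold enriched).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .seqio import AA20, ProteinRecord, SignalPeptideAnnotation, cleave

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NTermFrequencyTable:
    """Per-residue counts and class frequencies with enrichment ratios."""

    count_cyt: dict[str, int]
    count_sec: dict[str, int]
    n_cyt: int
    n_sec: int
    skipped_non_met: int = 0

    def f_cyt(self, residue: str) -> float:
        return self.count_cyt.get(residue, 0) / self.n_cyt

    def f_sec(self, residue: str) -> float:
        return self.count_sec.get(residue, 0) / self.n_sec

    def ratio(self, residue: str) -> Optional[float]:
        """f_sec / f_cyt; ``None`` (undefined) when f_cyt is zero."""
        fc = self.f_cyt(residue)
        if fc == 0.0:
            return None
        return self.f_sec(residue) / fc


def tabulate(secreted: Sequence[tuple[ProteinRecord, SignalPeptideAnnotation]],
             cytosolic: Sequence[ProteinRecord]) -> NTermFrequencyTable:
    """Count N-terminal-adjacent residues for both classes.

    ``secreted`` pairs each record with its signal-peptide annotation;
    ``cytosolic`` records must start with M and have length >= 2 (others are
    skipped with a warning counter).
    """
    if not secreted or not cytosolic:
        raise ValueError("both classes must be non-empty")
    count_sec: dict[str, int] = {}
    for record, ann in secreted:
        residue = cleave(record, ann).position_one
        count_sec[residue] = count_sec.get(residue, 0) + 1
    count_cyt: dict[str, int] = {}
    skipped = 0
    for record in cytosolic:
        if not record.sequence.startswith("M") or len(record.sequence) < 2:
            skipped += 1
            continue
        residue = record.sequence[1]
        count_cyt[residue] = count_cyt.get(residue, 0) + 1
    if skipped:
        logger.warning("skipped %d cytosolic records not starting with M", skipped)
    if not count_cyt:
        raise ValueError("no usable cytosolic records (none start with M)")
    return NTermFrequencyTable(
        count_cyt=count_cyt, count_sec=count_sec,
        n_cyt=sum(count_cyt.values()), n_sec=sum(count_sec.values()),
        skipped_non_met=skipped)


def enrichment_ratio(table: NTermFrequencyTable, residue: str) -> Optional[float]:
    """Secreted:cytosolic enrichment of ``residue`` (None when undefined)."""
    return table.ratio(residue)


def enrichment_from_frequencies(f_sec: float, f_cyt: float) -> Optional[float]:
    """Enrichment ratio directly from published per-class frequencies
    (both on the same scale, e.g. percent)."""
    if f_cyt == 0.0:
        return None
    return f_sec / f_cyt


def write_table_tsv(table: NTermFrequencyTable, path: str | Path) -> None:
    """TSV with one row per residue; frequencies in percent to one decimal
    (full precision retained in the count columns)."""
    with open(path, "w") as fh:
        fh.write("# residue\tcount_cyt\tcount_sec\tf_cyt_pct\tf_sec_pct\tratio\n")
        for a in AA20:
            r = table.ratio(a)
            fh.write(f"{a}\t{table.count_cyt.get(a, 0)}\t{table.count_sec.get(a, 0)}\t"
                     f"{100 * table.f_cyt(a):.1f}\t{100 * table.f_sec(a):.1f}\t"
                     f"{'NA' if r is None else f'{r:.2f}'}\n")
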