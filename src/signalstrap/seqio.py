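"""Sequence and signal-peptide annotation I/O, plus cleavage to mature sequences.

Coordinates are 1-based inclusive throughout the package, matching the
convention "position 1 of the mature protein". ``sp_end`` is the last residue
of the signal peptide, so cleavage occurs between ``sp_end`` and
``sp_end + 1`` (SignalP's "cleavage between k and k+1").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical one-letter order.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: Allowed sequence alphabet: the 20 standard residues plus the ambiguity code X.
ALPHABET = AA20 + "X"
_ALLOWED = frozenset(ALPHABET)

#: Residues whose hydrophobicity qualifies them for a signal-peptide h-region.
HYDROPHOBIC = frozenset("AILMFVW")


class SequenceError(ValueError):
    """Raised for malformed sequence or annotation input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One database or query protein.

    Parameters
    ----------
    id : str
        Unique identifier (first whitespace-delimited header token in FASTA).
    sequence : str
        Upper-case residue string over the 20-letter alphabet plus X.
    description : str
        Free text after the identifier.
    taxon : str, optional
        Organism label used for search-stage exclusion.
    """

    id: str
    sequence: str
    description: str = ""
    taxon: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("protein record requires a non-empty id")
        if not self.sequence:
            raise SequenceError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise SequenceError(
                f"{self.id}: illegal sequence character(s) {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SignalPeptideAnnotation:
    """Signal-peptide call for one protein.

    ``sp_end`` is the 1-based index of the LAST residue of the signal peptide.
    """

    protein_id: str
    sp_end: int
    predictor: str = "user"
    probability: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sp_end < 1:
            raise SequenceError(f"{self.protein_id}: sp_end must be >= 1")
        if self.probability is not None and not (0.0 <= self.probability <= 1.0):
            raise SequenceError(f"{self.protein_id}: probability outside [0, 1]")


@dataclass(frozen=True)
class MatureSequence:
    """The part of a protein left after signal-peptide cleavage."""

    protein_id: str
    residues: str

    @property
    def position_one(self) -> str:
        """Residue at mature position 1 (the new N-terminus)."""
        return self.residues[0]

    def __len__(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _parse_taxon(description: str) -> Optional[str]:
    # header convention: free text may carry a `taxon=...` key (spaces not
    # allowed inside the value); absent -> None
    for token in description.split():
        if token.startswith("taxon="):
            return token[len("taxon="):] or None
    return None


def _find_offending_line(path: Path, bad_chars: set[str]) -> int:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if bad_chars & set(line.strip().upper()):
                return lineno
    return -1


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Order is preserved, letters are upper-cased and a single terminal ``*``
    is stripped. Illegal characters raise :class:`SequenceError` naming the
    line number; duplicate ids are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        bad = set(seq) - _ALLOWED
        if bad:
            lineno = _find_offending_line(path, bad)
            raise SequenceError(
                f"{path}:{lineno}: illegal character(s) {sorted(bad)!r} "
                f"in record {entry.id!r}"
            )
        if entry.id in seen:
            raise SequenceError(f"{path}: duplicate record id {entry.id!r}")
        seen.add(entry.id)
        desc = entry.description
        if desc.startswith(entry.id):
            desc = desc[len(entry.id):].strip()
        records.append(
            ProteinRecord(
                id=entry.id,
                sequence=seq,
                description=desc,
                taxon=_parse_taxon(desc),
            )
        )
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA with canonicalised ``>id description`` headers."""
    with open(path, "w") as fh:
        for rec in records:
            desc = rec.description
            if rec.taxon and f"taxon={rec.taxon}" not in desc:
                desc = (desc + f" taxon={rec.taxon}").strip()
            header = f">{rec.id} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Signal-peptide annotations
# ---------------------------------------------------------------------------

def _dedupe(anns: list[SignalPeptideAnnotation]) -> list[SignalPeptideAnnotation]:
    """Keep the highest-probability annotation per protein id (warn on dupes)."""
    best: dict[str, SignalPeptideAnnotation] = {}
    for ann in anns:
        prev = best.get(ann.protein_id)
        if prev is None:
            best[ann.protein_id] = ann
            continue
        logger.warning("duplicate annotation for %s; keeping higher probability",
                       ann.protein_id)
        p_new = -1.0 if ann.probability is None else ann.probability
        p_old = -1.0 if prev.probability is None else prev.probability
        if p_new > p_old:
            best[ann.protein_id] = ann
    return list(best.values())


def read_sp_annotations(path: str | Path, dialect: str = "tsv") -> list[SignalPeptideAnnotation]:
    """Read signal-peptide annotations from a sidecar file.

    ``tsv``: three whitespace/tab-separated columns ``id  sp_end  probability``
    (probability optional; ``#`` comment lines skipped).
    ``gff3``: rows whose type column is ``signal_peptide``; coordinates are
    1-based inclusive and ``sp_end`` is the feature end. The score column, if
    numeric, is taken as the probability.
    """
    path = Path(path)
    if dialect not in ("tsv", "gff3"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    anns: list[SignalPeptideAnnotation] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if dialect == "tsv":
                    pid, sp_end = fields[0], int(fields[1])
                    prob = float(fields[2]) if len(fields) > 2 else None
                else:
                    if len(fields) < 8:
                        raise SequenceError(
                            f"{path}:{lineno}: GFF3 row has {len(fields)} columns")
                    if fields[2] != "signal_peptide":
                        continue
                    pid, sp_end = fields[0], int(fields[4])
                    prob = None if fields[5] in (".", "") else float(fields[5])
                anns.append(SignalPeptideAnnotation(
                    protein_id=pid, sp_end=sp_end,
                    predictor=dialect, probability=prob))
            except (ValueError, IndexError) as exc:
                raise SequenceError(f"{path}:{lineno}: {exc}") from exc
    return _dedupe(anns)


def write_sp_annotations(anns: list[SignalPeptideAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# id\tsp_end\tprobability (1-based inclusive sp_end)\n")
        for ann in anns:
            prob = "" if ann.probability is None else f"{ann.probability:.4f}"
            fh.write(f"{ann.protein_id}\t{ann.sp_end}\t{prob}\n")


# ---------------------------------------------------------------------------
# Cleavage
# ---------------------------------------------------------------------------

def cleave(record: ProteinRecord, ann: SignalPeptideAnnotation) -> MatureSequence:
    """Remove the signal peptide; mature residues are ``sequence[sp_end+1..]``.

    Raises :class:`SequenceError` if the annotation does not belong to the
    record or cleavage would leave an empty mature protein.
    """
    if ann.protein_id != record.id:
        raise SequenceError(
            f"annotation for {ann.protein_id!r} applied to record {record.id!r}")
    if ann.sp_end >= len(record.sequence):
        raise SequenceError(
            f"{record.id}: sp_end={ann.sp_end} >= length {len(record.sequence)}; "
            "cleavage leaves empty mature protein")
    return MatureSequence(protein_id=record.id,
                          residues=record.sequence[ann.sp_end:])


# ---------------------------------------------------------------------------
# Heuristic signal-peptide caller (fallback when no predictor output exists)
# ---------------------------------------------------------------------------

def heuristic_sp_call(record: ProteinRecord) -> Optional[SignalPeptideAnnotation]:
    """Crude tripartite signal-peptide detector.

    Requires >=1 K/R in the first 5 residues (n-region charge), a hydrophobic
    run of >=7 residues from {A,I,L,M,F,V,W} (h-region), and then an A-x-A
    motif whose second A — taken as ``sp_end`` — falls within residues 12-35.
    The motif must begin after at least 7 residues of the hydrophobic run.
    Returns ``None`` when no such pattern exists; this is a valid result.
    """
    seq = record.sequence
    if len(seq) < 25:
        raise SequenceError(f"{record.id}: sequence shorter than 25 residues")
    if not any(c in "KR" for c in seq[:5]):
        return None
    run_start = _first_hydrophobic_run(seq, min_len=7)
    if run_start is None:
        return None
    # first A-x-A whose second A is at position p in [12, 35]; the motif's
    # first A must sit at or beyond run_start + 7 (i.e. after the h-region core)
    for p in range(12, min(36, len(seq))):       # p is 1-based, mature must be non-empty
        first_a = p - 2                          # 1-based position of the first A
        if first_a < run_start + 7:
            continue
        if seq[first_a - 1] == "A" and seq[p - 1] == "A":
            return SignalPeptideAnnotation(
                protein_id=record.id, sp_end=p, predictor="heuristic")
    return None


def _first_hydrophobic_run(seq: str, min_len: int) -> Optional[int]:
    """1-based start of the first run of >= min_len hydrophobic residues."""
    run = 0
    for i, c in enumerate(seq):
        run = run + 1 if c in HYDROPHOBIC else 0
        if run == min_len:
            return i - min_len + 2
    return None
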