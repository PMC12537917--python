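"""Construction of signal-strapping queries.

A bootstrap query is a known signal peptide with one or two residues appended
at its C-terminus, the first of which is a chelator (histidine by default).
After cleavage in a real secreted protein the appended residue would sit at
mature position 1, so a short-query local search with the chimera retrieves
subjects whose residue aligned at that position is a candidate N-terminal
chelate.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

from .seqio import _ALLOWED, SequenceError

#: Chelating residues allowed as the first appended residue. Histidine is the
#: default; the approach generalises to other chelating N-termini such as
#: cysteine and aspartate.
DEFAULT_CHELATING = frozenset("H")
GENERALISED_CHELATING = frozenset("HCD")


@dataclass(frozen=True)
class BootstrapQuery:
    """A signal peptide plus manually appended chelating residue(s)."""

    id: str
    sp_sequence: str
    appended: str
    source_taxon: Optional[str] = None

    @property
    def query_sequence(self) -> str:
        return self.sp_sequence + self.appended

    @property
    def appended_position(self) -> int:
        """1-based index of the appended chelating residue in the query."""
        return len(self.sp_sequence) + 1

    def __len__(self) -> int:
        return len(self.query_sequence)


def build_query(sp: str, appended: str, source_taxon: Optional[str] = None,
                query_id: str = "query",
                chelating: frozenset[str] = DEFAULT_CHELATING) -> BootstrapQuery:
    """Append ``appended`` (H or HX) to the C-terminus of signal peptide ``sp``."""
    if not sp:
        raise SequenceError("empty signal peptide")
    if not appended:
        raise SequenceError("nothing appended")
    if len(appended) > 2:
        raise SequenceError("appended residues must be length 1-2 (H or HX)")
    if set(sp + appended) - _ALLOWED:
        raise SequenceError("illegal residue in query")
    if appended[0] not in chelating:
        raise SequenceError(
            f"first appended residue {appended[0]!r} is not in the chelating "
            f"set {sorted(chelating)}")
    return BootstrapQuery(id=query_id, sp_sequence=sp, appended=appended,
                          source_taxon=source_taxon)


def load_fixture_queries() -> list[BootstrapQuery]:
    """The four worked-example queries shipped with the package.

    Each entry pairs a real secreted-protein signal peptide with its manually
    appended residue(s) and the source organism to exclude during search:
    DUF4198 (GH5 SP + HG), DUF6702 (DUF4198 SP + HE), Ang-1 (SOD_Ni SP + H)
    and Ang-2 (GH16 SP + H).
    """
    queries: list[BootstrapQuery] = []
    text = (resources.files("signalstrap") / "data" / "bootstrap_queries.fasta").read_text()
    header, seq_lines = None, []
    entries = []
    for line in text.splitlines():
        if line.startswith(">"):
            if header is not None:
                entries.append((header, "".join(seq_lines)))
            header, seq_lines = line[1:], []
        elif line.strip():
            seq_lines.append(line.strip())
    if header is not None:
        entries.append((header, "".join(seq_lines)))
    for header, sp in entries:
        token = header.split()[0]
        qid, appended, taxon = token.split("|")
        taxon = taxon.replace("_", " ")
        queries.append(build_query(sp, appended, source_taxon=taxon, query_id=qid))
    return queries
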