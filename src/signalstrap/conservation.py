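"""Cleavage-anchored conservation statistics over a homologue set.

Every member is anchored at its own signal-peptide cleavage site, so mature
position 1 is exact for all members (the headline statistic — the fraction
of a family retaining an N-terminal histidine — needs no alignment) while
downstream positions are approximate because no multiple alignment is
performed. Pairwise percent identity uses a global affine-gap alignment
with gap columns included in the denominator.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .align import global_alignment
from .scoring import ScoringScheme
from .seqio import ProteinRecord, SignalPeptideAnnotation, cleave
from .triage import DEFAULT_CHELATING, CoordinatingSet


@dataclass(frozen=True)
class HomologueSet:
    """A family of (record, annotation) pairs; members without a usable
    annotation are dropped and counted at profiling time."""

    family_id: str
    members: tuple[tuple[ProteinRecord, SignalPeptideAnnotation | None], ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"{self.family_id}: homologue set is empty")


@dataclass(frozen=True)
class ConservationProfile:
    family_id: str
    n_used: int
    n_dropped: int
    his1_fraction: float
    position_counts: tuple[Counter, ...]          # index 0 = mature position 1
    coordinating_conservation: tuple[float, ...]  # same indexing

    def to_json(self) -> str:
        return json.dumps({
            "family_id": self.family_id,
            "n_used": self.n_used,
            "n_dropped": self.n_dropped,
            "his1_fraction": self.his1_fraction,
        }, indent=1)


def build_profile(homologues: HomologueSet,
                  coord: CoordinatingSet = CoordinatingSet(),
                  chelating: frozenset[str] = DEFAULT_CHELATING) -> ConservationProfile:
    """Tally residues per mature position across cleavage-anchored members.

    ``his1_fraction`` is the fraction of usable members whose mature
    position 1 is in the chelating set (default {H}).
    """
    matures: list[str] = []
    dropped = 0
    for record, ann in homologues.members:
        if ann is None or ann.sp_end >= len(record.sequence):
            dropped += 1
            continue
        matures.append(cleave(record, ann).residues)
    if not matures:
        raise ValueError(f"{homologues.family_id}: all members dropped")
    longest = max(len(m) for m in matures)
    counts = tuple(Counter(m[p] for m in matures if len(m) > p)
                   for p in range(longest))
    coord_cons = tuple(
        sum(c for r, c in counts[p].items() if r in coord) / sum(counts[p].values())
        for p in range(longest))
    his1 = sum(c for r, c in counts[0].items() if r in chelating) / len(matures)
    return ConservationProfile(
        family_id=homologues.family_id, n_used=len(matures), n_dropped=dropped,
        his1_fraction=his1, position_counts=counts,
        coordinating_conservation=coord_cons)


def profile_to_logo_counts(profile: ConservationProfile) -> list[dict]:
    """Per-position residue count rows suitable for sequence-logo rendering.

    Column sums at position p equal the number of members whose mature
    sequence reaches p, so sums are non-increasing with p.
    """
    return [{"position": p + 1, **dict(sorted(counter.items()))}
            for p, counter in enumerate(profile.position_counts)]


def write_logo_counts_tsv(profile: ConservationProfile, path: str | Path) -> None:
    residues = sorted({r for c in profile.position_counts for r in c})
    with open(path, "w") as fh:
        fh.write("# position (1-based mature coordinate)\t" + "\t".join(residues) + "\n")
        for p, counter in enumerate(profile.position_counts, start=1):
            fh.write(str(p) + "\t" + "\t".join(str(counter.get(r, 0))
                                               for r in residues) + "\n")


_IDENTITY_SCHEME: dict[str, ScoringScheme] = {}


def _identity_scheme() -> ScoringScheme:
    # BLOSUM62 with gaps 10/0.5: conventional global-alignment defaults
    if "scheme" not in _IDENTITY_SCHEME:
        _IDENTITY_SCHEME["scheme"] = ScoringScheme.create(
            "BLOSUM62", gap_open=10.0, gap_extend=0.5)
    return _IDENTITY_SCHEME["scheme"]


def pairwise_identity(a: ProteinRecord | str, b: ProteinRecord | str,
                      scheme: ScoringScheme | None = None) -> float:
    """Global percent identity: identical aligned pairs over all alignment
    columns, gap columns included in the denominator."""
    sa = a.sequence if isinstance(a, ProteinRecord) else a
    sb = b.sequence if isinstance(b, ProteinRecord) else b
    if sb < sa:
        # co-optimal alignments picked by the traceback tie-break can differ
        # in column count when the arguments swap; canonicalise the order so
        # pid(a, b) == pid(b, a) exactly
        sa, sb = sb, sa
    if scheme is None:
        scheme = _identity_scheme()
    a_aln, b_aln, _ = global_alignment(sa, sb, scheme)
    matches = sum(1 for x, y in zip(a_aln, b_aln) if x == y and x != "-")
    return 100.0 * matches / len(a_aln)
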