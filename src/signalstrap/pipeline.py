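"""End-to-end orchestration of a signal-strapping run.

One run executes: short-query search -> hit triage -> ranking -> full-length
rescreen of the top accepted candidates -> cleavage-anchored conservation
profiling of each rescreened homologue set. Every stage's parameters and
each protein's annotation source (user file > generator truth > heuristic)
are recorded in the run log; outputs land in a run directory with a
MANIFEST so aborted runs are detectable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .bootstrap import BootstrapQuery
from .conservation import (HomologueSet, build_profile, write_logo_counts_tsv)
from .scoring import ScoringScheme
from .search import search_query, write_hits_tsv
from .seqio import (ProteinRecord, SignalPeptideAnnotation, read_fasta,
                    read_sp_annotations, write_fasta)
from .triage import (CandidateRecord, CoordinatingSet, DEFAULT_CHELATING,
                     DEFAULT_POS2_RULE, rank_candidates, rescreen, triage_hit,
                     write_candidates_tsv)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of one run; round-trips losslessly through YAML."""

    db_fasta: Optional[str] = None
    annotations: Optional[str] = None
    annotation_dialect: str = "tsv"
    out_dir: str = "strap_run"
    matrix: str = "PAM30"
    gap_open: float = 9.0
    gap_extend: float = 1.0
    K: float = 0.13
    evalue_cutoff: float = 1000.0       # short-query search: permissive
    rescreen_evalue_cutoff: float = 1e-5  # full-length rescreen: stringent,
    # so the conservation profile is computed over likely family members
    # rather than every weak similarity
    max_targets: int = 500
    coordinating_set: str = "HCDEMNQ"
    pos2_rule_set: str = "HCDM"
    chelating_set: str = "H"
    allow_heuristic: bool = True
    max_rescreen: int = 3
    metal_cutoff: float = 2.8
    t_shaped_min_angle: float = 150.0
    facial_range: tuple[float, float] = (70.0, 110.0)
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["facial_range"] = list(self.facial_range)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "facial_range" in payload:
            payload["facial_range"] = tuple(payload["facial_range"])
        return cls(**payload)

    def scheme(self) -> ScoringScheme:
        return ScoringScheme.create(self.matrix, gap_open=self.gap_open,
                                    gap_extend=self.gap_extend, K=self.K)

    def validate_paths(self) -> None:
        for label, p in (("db_fasta", self.db_fasta),
                         ("annotations", self.annotations)):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label}: {p}")


@dataclass(frozen=True)
class StrapResult:
    query: BootstrapQuery
    hits: tuple
    candidates: tuple[CandidateRecord, ...]
    profiles: tuple
    run_dir: Optional[Path] = None

    @property
    def accepted(self) -> tuple[CandidateRecord, ...]:
        return tuple(c for c in self.candidates if c.verdict == "accepted")

    @property
    def review(self) -> tuple[CandidateRecord, ...]:
        return tuple(c for c in self.candidates if c.verdict == "review")


def execute(query: BootstrapQuery, db: Sequence[ProteinRecord],
            annotations: Sequence[SignalPeptideAnnotation],
            config: PipelineConfig) -> StrapResult:
    """Run search -> triage -> rank -> rescreen -> conservation in memory."""
    scheme = config.scheme()
    coord = CoordinatingSet(frozenset(config.coordinating_set))
    pos2 = frozenset(config.pos2_rule_set)
    chelating = frozenset(config.chelating_set)
    ann_map = {a.protein_id: a for a in annotations}
    db_map = {r.id: r for r in db}

    logger.info("search: query %s (%d aa), db %d records, E<=%g, max %d",
                query.id, len(query), len(db), config.evalue_cutoff,
                config.max_targets)
    hits = search_query(query, db, scheme, evalue_cutoff=config.evalue_cutoff,
                        max_targets=config.max_targets)
    candidates = []
    for hit in hits:
        subject = db_map[hit.subject_id]
        ann = ann_map.get(subject.id)
        source = "user/truth" if ann is not None else (
            "heuristic" if config.allow_heuristic else "none")
        logger.debug("annotation source for %s: %s", subject.id, source)
        cand = triage_hit(hit, query, subject, ann, coord=coord,
                          pos2_rule=pos2, chelating=chelating,
                          allow_heuristic=config.allow_heuristic)
        if cand.verdict.startswith("rejected"):
            logger.debug("rejected %s: %s", subject.id, cand.verdict)
        candidates.append(cand)
    ranked = rank_candidates(candidates)

    profiles = []
    for cand in [c for c in ranked if c.verdict == "accepted"][: config.max_rescreen]:
        try:
            homologue_hits = rescreen(
                cand, db, scheme,
                evalue_cutoff=config.rescreen_evalue_cutoff,
                max_targets=config.max_targets, excluded_taxon=None)
        except ValueError as exc:  # pragma: no cover - defensive
            logger.warning("rescreen failed for %s: %s", cand.subject.id, exc)
            continue
        members = tuple((db_map[h.subject_id], ann_map.get(h.subject_id))
                        for h in homologue_hits)
        if not members:
            continue
        homs = HomologueSet(family_id=cand.subject.id, members=members)
        try:
            profiles.append(build_profile(homs, coord=coord, chelating=chelating))
        except ValueError as exc:
            logger.warning("conservation profiling skipped for %s: %s",
                           cand.subject.id, exc)
    return StrapResult(query=query, hits=tuple(hits), candidates=tuple(ranked),
                       profiles=tuple(profiles))


def run_strap(config: PipelineConfig, query: BootstrapQuery) -> StrapResult:
    """File-based entry point: read inputs, execute, write the run directory."""
    config.validate_paths()
    if config.db_fasta is None:
        raise ValueError("config.db_fasta is required")
    db = read_fasta(config.db_fasta)
    annotations = (read_sp_annotations(config.annotations,
                                       config.annotation_dialect)
                   if config.annotations else [])
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = run_dir / "MANIFEST"
    manifest.write_text("status: INCOMPLETE\n")
    log_path = run_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("signalstrap")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(logging.DEBUG)
    try:
        logger.info("config: %s", json.dumps(dataclasses.asdict(config)))
        logger.info("coordinates are 1-based inclusive; sp_end is the last "
                    "SP residue")
        result = execute(query, db, annotations, config)
    except Exception as exc:
        manifest.write_text(f"status: ABORTED\nerror: {exc}\n")
        raise
    finally:
        root.removeHandler(handler)
        root.setLevel(old_level)
        handler.close()

    scheme = config.scheme()
    write_hits_tsv(result.hits, scheme, run_dir / "hits.tsv")
    write_candidates_tsv(result.candidates, run_dir / "candidates.tsv")
    review = [c for c in result.candidates if c.verdict == "review"]
    write_candidates_tsv(review, run_dir / "review.tsv")
    accepted_records = [
        ProteinRecord(id=c.subject.id, sequence=c.mature.residues,
                      description="mature after SP cleavage",
                      taxon=c.subject.taxon)
        for c in result.accepted]
    write_fasta(accepted_records, run_dir / "accepted_mature.fasta")
    for profile in result.profiles:
        stem = profile.family_id.replace("/", "_")
        (run_dir / f"conservation_{stem}.json").write_text(profile.to_json())
        write_logo_counts_tsv(profile, run_dir / f"logo_counts_{stem}.tsv")
    config.to_yaml(run_dir / "config.yaml")
    manifest.write_text(
        "status: COMPLETE\n"
        f"hits: {len(result.hits)}\n"
        f"accepted: {len(result.accepted)}\n"
        f"review: {len(review)}\n")
    return dataclasses.replace(result, run_dir=run_dir)
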