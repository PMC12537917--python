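"""Deterministic synthetic proteomes with planted metalloprotein families.

The generator provides ground truth for every pipeline stage. A synthetic
proteome contains three classes:

* **planted families** — secreted proteins sharing a family consensus: a
  tripartite signal peptide (charged n-region, hydrophobic h-region,
  c-region ending in an A-x-A cleavage motif) followed by a mature sequence
  carrying His at position 1, a partner His and one D/E planted downstream.
  Members apply an independent per-site substitution rate ``mu`` to the
  mature region (position 1 His mutates to a uniform non-H residue).
* **secreted decoys** — same SP architecture, background mature sequence
  with a non-His position 1.
* **cytosolic proteins** — initiator Met plus background residues, no SP.

The SP model is deliberately crude and pattern-based: it exists to exercise
cleavage-anchored statistics and the heuristic SP caller, not to model
biology faithfully. All randomness flows from a single numpy PCG64 seed, so
regeneration from (spec, seed) is byte-identical.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import smith_waterman
from .scoring import ScoringScheme, robinson_background
from .seqio import (AA20, HYDROPHOBIC, ProteinRecord, SignalPeptideAnnotation,
                    write_fasta, write_sp_annotations)

_POLAR = "STNQGPDE"  # c-region filler / n-region filler; excludes A so the
                     # terminal A-x-A motif is unambiguous
_HYDRO = "".join(sorted(HYDROPHOBIC))
# leucine-rich h-region composition (order matches _HYDRO = A F I L M V W);
# alanine kept rare so the c-region A-x-A cleavage motif stays distinctive
_HYDRO_P = np.array([0.08, 0.12, 0.14, 0.32, 0.10, 0.16, 0.08])


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic proteome."""

    n_proteins: int = 500
    frac_secreted: float = 0.5
    n_families: int = 2
    members_per_family: int = 10
    mu: float = 0.05                      # per-site substitution rate
    partner_his_range: tuple[int, int] = (10, 40)
    mature_length_range: tuple[int, int] = (80, 300)
    seed: int = 0

    def __post_init__(self) -> None:
        n_sec = int(round(self.n_proteins * self.frac_secreted))
        if self.n_families * self.members_per_family > n_sec:
            raise ValueError("planted family members exceed the secreted count")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mu must be in [0, 1]")
        if self.mature_length_range[0] < self.partner_his_range[1]:
            raise ValueError("mature sequences must cover the partner-His range")

    @property
    def n_secreted(self) -> int:
        return int(round(self.n_proteins * self.frac_secreted))

    @property
    def n_cytosolic(self) -> int:
        return self.n_proteins - self.n_secreted

    @property
    def n_decoys(self) -> int:
        return self.n_secreted - self.n_families * self.members_per_family


@dataclass(frozen=True)
class FamilyTruth:
    family_id: str
    sp_sequence: str
    consensus_mature: str
    member_ids: tuple[str, ...]
    partner_his_position: int
    acidic_position: int


@dataclass(frozen=True)
class SyntheticDataset:
    spec: SyntheticSpec
    records: tuple[ProteinRecord, ...]
    annotations: tuple[SignalPeptideAnnotation, ...]
    truth: pd.DataFrame
    families: tuple[FamilyTruth, ...]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit db.fasta, annotations.tsv and truth.tsv (deterministic bytes)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"fasta": outdir / "db.fasta",
                 "annotations": outdir / "annotations.tsv",
                 "truth": outdir / "truth.tsv"}
        write_fasta(list(self.records), paths["fasta"])
        write_sp_annotations(list(self.annotations), paths["annotations"])
        buf = io.StringIO()
        buf.write(f"# rng=numpy-PCG64 seed={self.spec.seed}\n")
        self.truth.to_csv(buf, sep="\t", index=False)
        paths["truth"].write_text(buf.getvalue())
        return paths


def _draw(rng: np.random.Generator, letters: str, k: int,
          p: Optional[np.ndarray] = None) -> str:
    idx = rng.choice(len(letters), size=k, p=p)
    return "".join(letters[i] for i in idx)


def _make_sp(rng: np.random.Generator) -> str:
    """Tripartite signal peptide: n (1-5 aa, >=1 K/R), h (7-15 hydrophobic),
    c (3-7 aa ending A-x-A)."""
    n_len = int(rng.integers(1, 6))
    if n_len == 1:
        n_region = "KR"[int(rng.integers(0, 2))]
    else:
        body = list("M" + _draw(rng, _POLAR, n_len - 1))
        kr_pos = int(rng.integers(1, n_len))
        body[kr_pos] = "KR"[int(rng.integers(0, 2))]
        n_region = "".join(body)
    h_region = _draw(rng, _HYDRO, int(rng.integers(7, 16)), p=_HYDRO_P)
    c_len = int(rng.integers(3, 8))
    c_region = _draw(rng, _POLAR, c_len - 3) + "A" + _POLAR[int(rng.integers(0, len(_POLAR)))] + "A"
    return n_region + h_region + c_region


def _mutate(rng: np.random.Generator, seq: str, mu: float,
            protect_non_coord_pos2: bool = False) -> str:
    """Independent per-site substitution to a uniform different residue."""
    out = list(seq)
    hits = rng.random(len(seq)) < mu
    for i in np.nonzero(hits)[0]:
        alternatives = AA20.replace(out[i], "")
        out[i] = alternatives[int(rng.integers(0, len(alternatives)))]
    return "".join(out)


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the proteome described by ``spec``; same seed, same bytes."""
    rng = np.random.default_rng(spec.seed)
    background = robinson_background()
    records: list[ProteinRecord] = []
    annotations: list[SignalPeptideAnnotation] = []
    truth_rows: list[dict] = []
    families: list[FamilyTruth] = []
    lo, hi = spec.mature_length_range
    p_lo, p_hi = spec.partner_his_range
    idx = 0

    def add(seq: str, klass: str, sp_end: int, his1: bool,
            coord_positions: Sequence[int], family: str = "") -> str:
        nonlocal idx
        pid = f"syn{idx:05d}"
        records.append(ProteinRecord(
            id=pid, sequence=seq, description=f"class={klass}",
            taxon=f"t{idx:05d}"))
        if sp_end:
            annotations.append(SignalPeptideAnnotation(
                protein_id=pid, sp_end=sp_end, predictor="truth",
                probability=1.0))
        truth_rows.append({
            "id": pid, "class": klass, "sp_end": sp_end,
            "his1_truth": int(his1),
            "coord_positions": ";".join(map(str, coord_positions)),
            "family": family})
        idx += 1
        return pid

    for k in range(spec.n_families):
        fam = f"fam{k}"
        sp = _make_sp(rng)
        mat_len = int(rng.integers(lo, hi + 1))
        partner = int(rng.integers(p_lo, p_hi + 1))
        acidic = partner
        while acidic == partner:
            acidic = int(rng.integers(p_lo, p_hi + 1))
        consensus = list(_draw(rng, AA20, mat_len, p=background))
        consensus[0] = "H"
        # keep consensus position 2 non-coordinating so triage rules act on
        # mutations, not on the construction itself
        while consensus[1] in "HCDEMNQ":
            consensus[1] = AA20[int(rng.integers(0, 20))]
        consensus[partner - 1] = "H"
        consensus[acidic - 1] = "DE"[int(rng.integers(0, 2))]
        consensus = "".join(consensus)
        member_ids = []
        for _ in range(spec.members_per_family):
            mature = _mutate(rng, consensus, spec.mu)
            pid = add(sp + mature, f"family:{fam}", len(sp),
                      mature[0] == "H", [partner, acidic], family=fam)
            member_ids.append(pid)
        families.append(FamilyTruth(
            family_id=fam, sp_sequence=sp, consensus_mature=consensus,
            member_ids=tuple(member_ids), partner_his_position=partner,
            acidic_position=acidic))

    non_h = AA20.replace("H", "")
    bg_non_h = np.array([background[AA20.index(a)] for a in non_h])
    bg_non_h /= bg_non_h.sum()
    for _ in range(spec.n_decoys):
        sp = _make_sp(rng)
        mat_len = int(rng.integers(lo, hi + 1))
        mature = (_draw(rng, non_h, 1, p=bg_non_h)
                  + _draw(rng, AA20, mat_len - 1, p=background))
        add(sp + mature, "secreted-decoy", len(sp), False, [])

    for _ in range(spec.n_cytosolic):
        length = int(rng.integers(lo, hi + 1))
        seq = "M" + _draw(rng, AA20, length - 1, p=background)
        add(seq, "cytosolic", 0, False, [])

    truth = pd.DataFrame(truth_rows,
                         columns=["id", "class", "sp_end", "his1_truth",
                                  "coord_positions", "family"])
    return SyntheticDataset(spec=spec, records=tuple(records),
                            annotations=tuple(annotations), truth=truth,
                            families=tuple(families))


# ---------------------------------------------------------------------------
# Empirical K calibration (check of the ungapped E-value approximation)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KCalibration:
    K_fit: float
    lambda_fit: float
    K_default: float

    @property
    def ratio(self) -> float:
        return self.K_fit / self.K_default


def fit_extreme_value(scores: np.ndarray, m: int, n: int,
                      K_default: float = 0.13) -> KCalibration:
    """Fit the Gumbel form of maximal local scores.

    For maxima of local alignment scores, ``P(S <= x) = exp(-K m n e^(-lambda x))``,
    a Gumbel with location ``ln(K m n) / lambda`` and scale ``1 / lambda``;
    the fit inverts those relations.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.std() == 0.0:
        raise ValueError("degenerate score distribution")
    loc, scale = stats.gumbel_r.fit(scores)
    lam = 1.0 / scale
    K = math.exp(lam * loc) / (m * n)
    return KCalibration(K_fit=K, lambda_fit=lam, K_default=K_default)


def calibrate_K(scheme: ScoringScheme, n_shuffles: int = 500,
                query_length: int = 21, subject_length: int = 200,
                seed: int = 0) -> KCalibration:
    """Estimate K by aligning a random query against shuffled background
    sequences and fitting the extreme-value form to the maximal scores."""
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    rng = np.random.default_rng(seed)
    background = robinson_background()
    query = _draw(rng, AA20, query_length, p=background)
    scores = np.empty(n_shuffles)
    for i in range(n_shuffles):
        subject = _draw(rng, AA20, subject_length, p=background)
        hit = smith_waterman(query, subject, scheme)
        scores[i] = 0.0 if hit is None else hit.score
    return fit_extreme_value(scores, query_length, subject_length,
                             K_default=scheme.K)
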