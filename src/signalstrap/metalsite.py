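"""Metal-site detection and N-terminal histidine-brace classification.

A metal site is a metal ion plus the protein/solvent N, O and S atoms
within a first-shell distance cutoff (default 2.8 A). The motif classes
distinguish how the mature protein's residue 1 engages the metal:

* ``canonical-histidine-brace`` — His1 donates both its free alpha-amino N
  and an imidazole N, completed by exactly one more His side-chain N (the
  LPMO-type site, e.g. His1 + a conserved second His).
* ``tri-His-brace`` — His1 (both N donors) plus two or more further His
  side chains (e.g. a His1/His28/His32 site).
* ``mono-His-brace`` — His1 is the only coordinating His, augmented by a
  non-His protein donor such as an Asn side-chain O, typically T-shaped.
* ``N-terminal-other`` — a non-His residue 1 donates its amine.
* ``non-brace`` — anything else.

Geometry is classified from donor-metal-donor angles among protein donors:
a near-linear trans pair (max angle >= 150 deg) is ``T-shaped``; three
mutually ~90 deg donors (all angles within [70, 110] deg) form a
``facial-cap``; exogenous ligands (waters, buffer ions) are inventoried but
never change the motif class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np

METALS = frozenset({"CU", "NI", "ZN", "CO", "FE", "MN", "MG", "CA"})
DONOR_ELEMENTS = frozenset({"N", "O", "S"})
WATER_NAMES = frozenset({"HOH", "WAT", "H2O"})
STANDARD_AA3 = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL"})
PROTEIN_DONOR_CLASSES = frozenset({
    "Nterm-amine", "His-sidechain-N", "protein-N", "protein-O", "protein-S"})

MOTIFS = ("canonical-histidine-brace", "mono-His-brace", "tri-His-brace",
          "N-terminal-other", "non-brace")
GEOMETRIES = ("T-shaped", "facial-cap", "other")


@dataclass(frozen=True)
class AtomRecord:
    chain: str
    residue_name: str
    residue_number: int
    atom_name: str
    element: str
    xyz: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.element != self.element.upper():
            raise ValueError("element symbols must be upper-case")
        if not all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")


@dataclass(frozen=True)
class MetalSite:
    metal: AtomRecord
    ligands: tuple[tuple[AtomRecord, float], ...]  # sorted by distance
    donor_classes: tuple[str, ...]
    motif: str = "non-brace"
    geometry: str = "other"

    @property
    def metal_element(self) -> str:
        return self.metal.element


class PDBParseError(ValueError):
    pass


def read_pdb(path: str | Path) -> list[AtomRecord]:
    """Read ATOM/HETATM records from a PDB file.

    Elements come from columns 77-78 with gemmi's atom-name fallback.
    Alternate locations: altloc 'A' or blank is kept; a residue modelled
    only as altloc 'B' (no 'A' present) is also kept.
    """
    path = Path(path)
    try:
        structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    atoms: list[AtomRecord] = []
    if len(structure) == 0:
        return atoms
    model = structure[0]
    for chain in model:
        for residue in chain:
            altlocs = {a.altloc for a in residue}
            keep = {"\0", "", "A"}
            if not (altlocs & keep):  # e.g. B-only residue: keep first altloc
                keep = {min(altlocs)}
            for atom in residue:
                if atom.altloc not in keep and atom.altloc != "\0":
                    continue
                atoms.append(AtomRecord(
                    chain=chain.name,
                    residue_name=residue.name.strip().upper(),
                    residue_number=residue.seqid.num,
                    atom_name=atom.name.strip().upper(),
                    element=atom.element.name.upper(),
                    xyz=(atom.pos.x, atom.pos.y, atom.pos.z)))
    return atoms


def _residue1_names(atoms: Sequence[AtomRecord]) -> dict[str, tuple[int, str]]:
    """Per chain: (lowest residue number among standard residues, its name)."""
    first: dict[str, tuple[int, str]] = {}
    for a in atoms:
        if a.residue_name not in STANDARD_AA3:
            continue
        cur = first.get(a.chain)
        if cur is None or a.residue_number < cur[0]:
            first[a.chain] = (a.residue_number, a.residue_name)
    return first


def _donor_class(atom: AtomRecord, residue1: dict[str, tuple[int, str]]) -> str:
    if atom.residue_name in WATER_NAMES:
        return "water-O" if atom.element == "O" else "hetero"
    if atom.residue_name not in STANDARD_AA3:
        return "hetero"
    first = residue1.get(atom.chain)
    if (first is not None and atom.residue_number == first[0]
            and atom.atom_name == "N"):
        return "Nterm-amine"
    if atom.residue_name == "HIS" and atom.atom_name in ("ND1", "NE2"):
        return "His-sidechain-N"
    if atom.element == "N":
        return "protein-N"
    if atom.element == "O":
        return "protein-O"
    if atom.element == "S":
        return "protein-S"
    return "hetero"  # pragma: no cover - donors are filtered to N/O/S


def find_metal_sites(atoms: Sequence[AtomRecord], cutoff: float = 2.8) -> list[MetalSite]:
    """One site per metal atom; ligands are N/O/S atoms within ``cutoff``
    (other metals excluded), sorted by distance."""
    residue1 = _residue1_names(atoms)
    metals = [a for a in atoms if a.element in METALS]
    sites: list[MetalSite] = []
    for metal in metals:
        mx = np.array(metal.xyz)
        ligands: list[tuple[AtomRecord, float]] = []
        for atom in atoms:
            if atom.element in METALS or atom.element not in DONOR_ELEMENTS:
                continue
            d = float(np.linalg.norm(np.array(atom.xyz) - mx))
            if d <= cutoff:
                ligands.append((atom, d))
        ligands.sort(key=lambda t: (t[1], t[0].chain, t[0].residue_number,
                                    t[0].atom_name))
        classes = tuple(_donor_class(a, residue1) for a, _ in ligands)
        site = MetalSite(metal=metal, ligands=tuple(ligands),
                         donor_classes=classes)
        site = classify(site, residue1)
        sites.append(site)
    return sites


def classify_motif(site: MetalSite,
                   residue1: Optional[dict[str, tuple[int, str]]] = None) -> str:
    """Histidine-brace motif label from the site's protein donors."""
    nterm = [(a, c) for (a, _), c in zip(site.ligands, site.donor_classes)
             if c == "Nterm-amine"]
    if not nterm:
        return "non-brace"
    nterm_atom = nterm[0][0]
    if residue1 is not None:
        first = residue1.get(nterm_atom.chain)
        if first is None:
            raise ValueError(
                f"residue 1 identity unknown for chain {nterm_atom.chain!r}")
        res1_name = first[1]
    else:
        res1_name = nterm_atom.residue_name
    if res1_name != "HIS":
        return "N-terminal-other"
    his1_side = any(
        c == "His-sidechain-N" and a.chain == nterm_atom.chain
        and a.residue_number == nterm_atom.residue_number
        for (a, _), c in zip(site.ligands, site.donor_classes))
    if not his1_side:
        return "non-brace"
    other_his = sum(
        1 for (a, _), c in zip(site.ligands, site.donor_classes)
        if c == "His-sidechain-N"
        and (a.chain, a.residue_number) != (nterm_atom.chain,
                                            nterm_atom.residue_number))
    if other_his == 1:
        return "canonical-histidine-brace"
    if other_his >= 2:
        return "tri-His-brace"
    other_protein = any(
        c in ("protein-N", "protein-O") and a.residue_name != "HIS"
        for (a, _), c in zip(site.ligands, site.donor_classes))
    return "mono-His-brace" if other_protein else "non-brace"


def classify_geometry(site: MetalSite, t_shaped_min_angle: float = 150.0,
                      facial_range: tuple[float, float] = (70.0, 110.0)) -> str:
    """Geometry label from donor-metal-donor angles among protein donors."""
    donors = [np.array(a.xyz) for (a, _), c in
              zip(site.ligands, site.donor_classes)
              if c in PROTEIN_DONOR_CLASSES]
    if len(donors) < 3:
        warnings.warn(f"metal site {site.metal.element} has "
                      f"{len(donors)} protein donors; geometry 'other'")
        return "other"
    centre = np.array(site.metal.xyz)
    angles = []
    for i in range(len(donors)):
        for j in range(i + 1, len(donors)):
            u = donors[i] - centre
            v = donors[j] - centre
            cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    if max(angles) >= t_shaped_min_angle:
        return "T-shaped"
    lo, hi = facial_range
    if all(lo <= a <= hi for a in angles):
        return "facial-cap"
    return "other"


def classify(site: MetalSite,
             residue1: Optional[dict[str, tuple[int, str]]] = None) -> MetalSite:
    """Return a copy of ``site`` with motif and geometry labels filled in."""
    import dataclasses
    return dataclasses.replace(
        site, motif=classify_motif(site, residue1),
        geometry=classify_geometry(site))


def site_report(sites: Sequence[MetalSite]) -> str:
    """JSON report: per site the metal, ligand inventory (distances to
    0.01 A), motif and geometry."""
    payload = []
    for s in sites:
        payload.append({
            "metal": s.metal.element,
            "chain": s.metal.chain,
            "ligands": [
                {"chain": a.chain, "residue": a.residue_name,
                 "number": a.residue_number, "atom": a.atom_name,
                 "distance": round(d, 2), "donor_class": c}
                for (a, d), c in zip(s.ligands, s.donor_classes)],
            "motif": s.motif,
            "geometry": s.geometry,
        })
    return json.dumps(payload, indent=1)
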