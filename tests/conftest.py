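"""Shared fixtures: scoring schemes, synthetic datasets, PDB text builders."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from signalstrap.scoring import ScoringScheme
from signalstrap.synthdata import SyntheticSpec, generate

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def pam30() -> ScoringScheme:
    return ScoringScheme.create("PAM30")


@pytest.fixture(scope="session")
def blosum62() -> ScoringScheme:
    return ScoringScheme.create("BLOSUM62")


@pytest.fixture(scope="session")
def small_dataset():
    """200 proteins, 2 planted families x 10 members, no mutations."""
    return generate(SyntheticSpec(n_proteins=200, frac_secreted=0.5,
                                  n_families=2, members_per_family=10,
                                  mu=0.0, seed=11))


def pdb_atom(serial: int, name: str, resname: str, chain: str, resnum: int,
             x: float, y: float, z: float, elem: str, het: bool = False,
             altloc: str = " ") -> str:
    """One fixed-column ATOM/HETATM line (synthetic structure fixtures)."""
    rec = "HETATM" if het else "ATOM  "
    nm = name if len(name) == 4 else f" {name:<3}"
    return (f"{rec}{serial:>5} {nm}{altloc}{resname:>3} {chain}{resnum:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {elem:>2}")


def write_pdb(path, lines) -> str:
    text = "\n".join(list(lines) + ["END"]) + "\n"
    path.write_text(text)
    return str(path)


def canonical_brace_lines():
    """Synthetic Cu site: His1 amine + His1 NE2 + His18 NE2, mutually ~90 deg."""
    return [
        pdb_atom(1, "CU", "CU", "A", 101, 0.0, 0.0, 0.0, "CU", het=True),
        pdb_atom(2, "N", "HIS", "A", 1, 2.0, 0.0, 0.0, "N"),
        pdb_atom(3, "NE2", "HIS", "A", 1, 0.0, 2.0, 0.0, "N"),
        pdb_atom(4, "CA", "HIS", "A", 1, 2.9, 1.2, 3.8, "C"),
        pdb_atom(5, "NE2", "HIS", "A", 18, 0.0, 0.0, 2.1, "N"),
        pdb_atom(6, "O", "HOH", "A", 201, 0.0, 0.0, -4.0, "O", het=True),
    ]


def mono_brace_t_shaped_lines():
    """Synthetic Cu site: His1 amine and NE2 trans (180 deg) + Asn O at 90."""
    return [
        pdb_atom(1, "CU", "CU", "A", 101, 0.0, 0.0, 0.0, "CU", het=True),
        pdb_atom(2, "N", "HIS", "A", 1, 2.0, 0.0, 0.0, "N"),
        pdb_atom(3, "NE2", "HIS", "A", 1, -2.0, 0.0, 0.0, "N"),
        pdb_atom(4, "OD1", "ASN", "A", 41, 0.0, 2.2, 0.0, "O"),
    ]


def tri_his_lines():
    """Synthetic site: His1 (amine + NE2) with His28 and His32 side chains."""
    return [
        pdb_atom(1, "NI", "NI", "A", 101, 0.0, 0.0, 0.0, "NI", het=True),
        pdb_atom(2, "N", "HIS", "A", 1, 2.0, 0.0, 0.0, "N"),
        pdb_atom(3, "ND1", "HIS", "A", 1, 0.0, 2.0, 0.0, "N"),
        pdb_atom(4, "NE2", "HIS", "A", 28, 0.0, 0.0, 2.1, "N"),
        pdb_atom(5, "NE2", "HIS", "A", 32, -2.1, 0.0, 0.0, "N"),
    ]
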