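"""Metal-site detection, histidine-brace motifs and coordination geometry."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from signalstrap.metalsite import (AtomRecord, classify_geometry,
                                   classify_motif, find_metal_sites, read_pdb)

from conftest import (canonical_brace_lines, mono_brace_t_shaped_lines,
                      pdb_atom, tri_his_lines, write_pdb)


def _site_from_lines(tmp_path, lines, cutoff=2.8):
    path = write_pdb(tmp_path / "site.pdb", lines)
    sites = find_metal_sites(read_pdb(path), cutoff=cutoff)
    assert len(sites) == 1
    return sites[0]


class TestReadPdb:
    def test_atom_and_hetatm_records_counted(self, tmp_path):
        path = write_pdb(tmp_path / "s.pdb", canonical_brace_lines())
        atoms = read_pdb(path)
        assert len(atoms) == 6
        assert sum(a.element == "CU" for a in atoms) == 1

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        assert read_pdb(p) == []

    def test_altloc_a_kept_b_dropped(self, tmp_path):
        lines = [
            pdb_atom(1, "N", "HIS", "A", 1, 0, 0, 0, "N", altloc="A"),
            pdb_atom(2, "N", "HIS", "A", 1, 9, 9, 9, "N", altloc="B"),
        ]
        atoms = read_pdb(write_pdb(tmp_path / "alt.pdb", lines))
        assert len(atoms) == 1
        assert atoms[0].xyz == (0.0, 0.0, 0.0)

    def test_altloc_b_only_residue_kept(self, tmp_path):
        lines = [pdb_atom(1, "N", "HIS", "A", 1, 1, 2, 3, "N", altloc="B")]
        atoms = read_pdb(write_pdb(tmp_path / "bonly.pdb", lines))
        assert len(atoms) == 1

    def test_lowercase_element_rejected_in_record(self):
        with pytest.raises(ValueError):
            AtomRecord(chain="A", residue_name="HIS", residue_number=1,
                       atom_name="N", element="cu", xyz=(0, 0, 0))


class TestFindSites:
    def test_cutoff_excludes_distant_water(self, tmp_path):
        site = _site_from_lines(tmp_path, canonical_brace_lines())
        assert len(site.ligands) == 3  # water at 4 A excluded
        dists = [d for _, d in site.ligands]
        assert dists == sorted(dists)
        assert all(d <= 2.8 for d in dists)

    def test_no_metal_no_sites(self, tmp_path):
        lines = [pdb_atom(1, "N", "HIS", "A", 1, 0, 0, 0, "N")]
        assert find_metal_sites(read_pdb(write_pdb(tmp_path / "n.pdb",
                                                   lines))) == []

    def test_two_metals_two_sites(self, tmp_path):
        lines = canonical_brace_lines() + [
            pdb_atom(7, "ZN", "ZN", "B", 300, 50.0, 50.0, 50.0, "ZN",
                     het=True)]
        path = write_pdb(tmp_path / "two.pdb", lines)
        sites = find_metal_sites(read_pdb(path))
        assert {s.metal_element for s in sites} == {"CU", "ZN"}


class TestMotifs:
    def test_canonical_histidine_brace(self, tmp_path):
        site = _site_from_lines(tmp_path, canonical_brace_lines())
        assert site.motif == "canonical-histidine-brace"
        assert "Nterm-amine" in site.donor_classes

    def test_tri_his_brace(self, tmp_path):
        site = _site_from_lines(tmp_path, tri_his_lines())
        assert site.motif == "tri-His-brace"

    def test_mono_his_brace(self, tmp_path):
        site = _site_from_lines(tmp_path, mono_brace_t_shaped_lines())
        assert site.motif == "mono-His-brace"

    def test_non_his_nterm_is_other(self, tmp_path):
        lines = [
            pdb_atom(1, "CU", "CU", "A", 101, 0, 0, 0, "CU", het=True),
            pdb_atom(2, "N", "ALA", "A", 1, 2.0, 0, 0, "N"),
            pdb_atom(3, "OD1", "ASN", "A", 41, 0, 2.2, 0, "O"),
        ]
        site = _site_from_lines(tmp_path, lines)
        assert site.motif == "N-terminal-other"

    def test_no_nterm_amine_is_non_brace(self, tmp_path):
        lines = [
            pdb_atom(1, "CU", "CU", "A", 101, 0, 0, 0, "CU", het=True),
            pdb_atom(2, "NE2", "HIS", "A", 18, 2.0, 0, 0, "N"),
            pdb_atom(3, "NE2", "HIS", "A", 30, 0, 2.0, 0, "N"),
        ]
        site = _site_from_lines(tmp_path, lines)
        assert site.motif == "non-brace"

    def test_exogenous_ligands_do_not_change_motif(self, tmp_path):
        lines = canonical_brace_lines() + [
            pdb_atom(7, "O", "HOH", "A", 202, 0.0, -2.2, 0.0, "O", het=True)]
        site = _site_from_lines(tmp_path, lines)
        assert site.motif == "canonical-histidine-brace"
        assert "water-O" in site.donor_classes

    def test_unknown_residue_one_identity_is_error(self, tmp_path):
        site = _site_from_lines(tmp_path, canonical_brace_lines())
        with pytest.raises(ValueError, match="residue 1"):
            classify_motif(site, residue1={})


class TestGeometry:
    def test_t_shaped_from_constructed_angles(self, tmp_path):
        site = _site_from_lines(tmp_path, mono_brace_t_shaped_lines())
        assert site.geometry == "T-shaped"

    def test_facial_cap_from_orthogonal_donors(self, tmp_path):
        site = _site_from_lines(tmp_path, canonical_brace_lines())
        assert site.geometry == "facial-cap"

    def test_fewer_than_three_donors_warns_other(self, tmp_path):
        lines = [
            pdb_atom(1, "CU", "CU", "A", 101, 0, 0, 0, "CU", het=True),
            pdb_atom(2, "N", "HIS", "A", 1, 2.0, 0, 0, "N"),
        ]
        with pytest.warns(UserWarning):
            site = _site_from_lines(tmp_path, lines)
        assert site.geometry == "other"

    @pytest.mark.parametrize("builder,expected", [
        (mono_brace_t_shaped_lines, "T-shaped"),
        (canonical_brace_lines, "facial-cap"),
    ])
    def test_rigid_transform_invariance(self, tmp_path, builder, expected):
        site = _site_from_lines(tmp_path, builder())
        rng = np.random.default_rng(2024)
        for _ in range(20):
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.normal(scale=20.0, size=3)
            moved = []
            for (atom, _d) in site.ligands:
                xyz = rot @ np.array(atom.xyz) + shift
                moved.append((AtomRecord(chain=atom.chain,
                                         residue_name=atom.residue_name,
                                         residue_number=atom.residue_number,
                                         atom_name=atom.atom_name,
                                         element=atom.element,
                                         xyz=tuple(xyz)), _d))
            metal_xyz = rot @ np.array(site.metal.xyz) + shift
            import dataclasses
            moved_site = dataclasses.replace(
                site,
                metal=dataclasses.replace(site.metal, xyz=tuple(metal_xyz)),
                ligands=tuple(moved))
            assert classify_geometry(moved_site) == expected
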