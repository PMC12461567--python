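"""Binding-pocket geometry: chromophore location and residue distances."""

import numpy as np
import pytest

from opsinspec.pocket import (
    ChromophoreFrame,
    locate_chromophore,
    read_structure,
    residue_pocket_distances,
    select_pocket_residues,
    synthetic_pocket_structure,
    write_pdb,
)


@pytest.fixture(scope="module")
def scripted_structure():
    return synthetic_pocket_structure(
        seed=3,
        residue_distances={
            10: ("ALA", "beta", 3.0),
            20: ("SER", "beta", 9.9),
            30: ("THR", "beta", 10.1),
            40: ("PHE", "rsb", 7.5),
        },
    )


class TestLocateChromophore:
    def test_ring_centroid_is_analytic_mean(self, scripted_structure):
        frame = locate_chromophore(scripted_structure)
        # hexagon vertices around the origin average to the origin
        np.testing.assert_allclose(frame.beta_ionone_centroid, 0.0, atol=1e-9)

    def test_schiff_base_lysine_autodetected_by_c15_proximity(self):
        st = synthetic_pocket_structure(seed=0)
        # add a decoy lysine far from C15
        import gemmi
        chain = st[0]["A"]
        decoy = gemmi.Residue()
        decoy.name = "LYS"
        decoy.seqid = gemmi.SeqId(500, " ")
        atom = gemmi.Atom()
        atom.name = "NZ"
        atom.element = gemmi.Element("N")
        atom.pos = gemmi.Position(50.0, 50.0, 50.0)
        decoy.add_atom(atom)
        chain.add_residue(decoy)
        frame = locate_chromophore(st)
        assert np.linalg.norm(frame.schiff_base_n - [14.6, 0.0, 0.0]) < 1e-9

    def test_missing_ligand_named_in_error(self, scripted_structure):
        with pytest.raises(ValueError, match="ZZZ"):
            locate_chromophore(scripted_structure, ligand_name="ZZZ")

    def test_frame_validates_degenerate_pose(self):
        with pytest.raises(ValueError, match="5 Å"):
            ChromophoreFrame(np.zeros(3), np.array([1.0, 0.0, 0.0]))


class TestDistances:
    def test_scripted_distances_recovered(self, scripted_structure):
        frame = locate_chromophore(scripted_structure)
        table = residue_pocket_distances(scripted_structure, frame)
        d = table.set_index("resnum")
        assert d.loc[10, "d_beta"] == pytest.approx(3.0, abs=1e-6)
        assert d.loc[20, "d_beta"] == pytest.approx(9.9, abs=1e-6)
        assert d.loc[30, "d_beta"] == pytest.approx(10.1, abs=1e-6)
        assert d.loc[40, "d_rsb"] == pytest.approx(7.5, abs=1e-6)

    def test_agrees_with_brute_force_pairwise_oracle(self, scripted_structure):
        frame = locate_chromophore(scripted_structure)
        table = residue_pocket_distances(scripted_structure, frame)
        backbone = {"N", "CA", "C", "O", "OXT"}
        for chain in scripted_structure[0]:
            for residue in chain:
                rows = table[(table.chain == chain.name)
                             & (table.resnum == residue.seqid.num)]
                if rows.empty:
                    continue
                dists_b, dists_r = [], []
                for atom in residue:
                    if atom.name in backbone:
                        continue
                    xyz = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    dists_b.append(np.linalg.norm(
                        xyz - frame.beta_ionone_centroid))
                    dists_r.append(np.linalg.norm(xyz - frame.schiff_base_n))
                assert rows.iloc[0]["d_beta"] == pytest.approx(
                    min(dists_b), abs=1e-9)
                assert rows.iloc[0]["d_rsb"] == pytest.approx(
                    min(dists_r), abs=1e-9)

    def test_isometry_invariance(self, scripted_structure, tmp_path):
        import gemmi
        frame = locate_chromophore(scripted_structure)
        base = residue_pocket_distances(scripted_structure, frame)

        # rigid-body rotate + translate every atom, then remeasure
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0],
                        [0, 0, 1.0]])
        shift = np.array([5.0, -3.0, 12.0])
        moved = synthetic_pocket_structure(
            seed=3,
            residue_distances={
                10: ("ALA", "beta", 3.0),
                20: ("SER", "beta", 9.9),
                30: ("THR", "beta", 10.1),
                40: ("PHE", "rsb", 7.5),
            },
        )
        for chain in moved[0]:
            for residue in chain:
                for atom in residue:
                    xyz = rot @ np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    xyz = xyz + shift
                    atom.pos = gemmi.Position(*xyz)
        frame2 = locate_chromophore(moved)
        table2 = residue_pocket_distances(moved, frame2)
        np.testing.assert_allclose(table2["d_beta"], base["d_beta"], atol=1e-9)
        np.testing.assert_allclose(table2["d_rsb"], base["d_rsb"], atol=1e-9)


class TestSelection:
    def test_cutoff_boundary_inclusive(self, scripted_structure):
        frame = locate_chromophore(scripted_structure)
        table = residue_pocket_distances(scripted_structure, frame)
        selected = select_pocket_residues(table, cutoff=10.0)
        nums = selected["resnum"].tolist()
        assert 20 in nums  # 9.9 Å: in
        assert 30 not in nums  # 10.1 Å: out
        assert nums == sorted(nums)

    def test_infinite_cutoff_selects_all_zero_none(self, scripted_structure):
        frame = locate_chromophore(scripted_structure)
        table = residue_pocket_distances(scripted_structure, frame)
        assert len(select_pocket_residues(table, cutoff=np.inf)) == len(table)
        # the Schiff-base lysine itself touches the RSB point at 0 Å
        at_zero = select_pocket_residues(table, cutoff=0.0)
        assert at_zero["resname"].tolist() == ["LYS"]


class TestSyntheticFixture:
    def test_pdb_roundtrip_preserves_geometry(self, scripted_structure,
                                              tmp_path):
        path = tmp_path / "pocket.pdb"
        write_pdb(scripted_structure, path)
        back = read_structure(path)
        frame = locate_chromophore(back)
        table = residue_pocket_distances(back, frame)
        d = table.set_index("resnum")
        # PDB coordinate fields carry 3 decimals
        assert d.loc[10, "d_beta"] == pytest.approx(3.0, abs=5e-3)
        assert d.loc[40, "d_rsb"] == pytest.approx(7.5, abs=5e-3)

    def test_distinct_seeds_same_topology_different_coordinates(self):
        kwargs = {"residue_distances": {10: ("ALA", "beta", 6.0)}}
        a = synthetic_pocket_structure(seed=1, **kwargs)
        b = synthetic_pocket_structure(seed=2, **kwargs)
        names_a = [(r.name, r.seqid.num) for c in a[0] for r in c]
        names_b = [(r.name, r.seqid.num) for c in b[0] for r in c]
        assert names_a == names_b
        cb_a = [at.pos.x for c in a[0] for r in c for at in r
                if r.seqid.num == 10 and at.name == "CB"]
        cb_b = [at.pos.x for c in b[0] for r in c for at in r
                if r.seqid.num == 10 and at.name == "CB"]
        assert cb_a != cb_b
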