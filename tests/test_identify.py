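"""The three identification algorithms against planted fixtures and oracles."""

from __future__ import annotations

import pytest

from conftest import exhaustive_crosslinks, report_key_set, truth_key_set
from modfinder import (
    BondConfig,
    ModificationCategory,
    ScanConfig,
    identify_all,
    identify_attachments,
    identify_crosslinks,
    identify_modified_residues,
    parse_structure,
)
from modfinder.fixtures import (
    FixtureSpec,
    Plant,
    composite_spec,
    make_fixture,
    perturb_fixture,
    random_spec,
    rotation_matrix,
)


def _scan(path, scan_config):
    return parse_structure(path), scan_config


class TestModifiedResidues:
    def test_phospho_chain(self, tmp_path, scan_config):
        spec = FixtureSpec(
            seed=0,
            entry_id="PHOS",
            chains=(("A", ("SER", "SEP", "GLY", "TPO")),),
            plants=(
                Plant("phosphoserine", (("A", 1),)),
                Plant("phosphothreonine", (("A", 3),)),
            ),
        )
        fx = make_fixture(spec, tmp_path)
        model = parse_structure(fx.pdb_path)
        mods = identify_modified_residues(model, scan_config)
        assert [(m.definition.internal_id, m.residues[0].polymer_index) for m in mods] == [
            ("phosphoserine", 1),
            ("phosphothreonine", 3),
        ]
        assert all(m.bonds == () for m in mods)

    def test_canonical_chain_yields_nothing(self, tmp_path, scan_config):
        spec = FixtureSpec(
            seed=0, entry_id="CANO",
            chains=(("A", ("ALA", "GLY", "SER", "LEU", "VAL")),),
        )
        fx = make_fixture(spec, tmp_path)
        model = parse_structure(fx.pdb_path)
        assert identify_modified_residues(model, scan_config) == []

    def test_nonpolymer_sep_not_reported(self, tmp_path, scan_config):
        """A nonstandard amino-acid code deposited as a free (non-polymer)
        group must not count as a modified residue."""
        pdb = tmp_path / "free.pdb"
        pdb.write_text(
            "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00 20.00           N\n"
            "ATOM      2  CA  GLY A   1       1.500   0.000   0.000  1.00 20.00           C\n"
            "ATOM      3  C   GLY A   1       2.300   1.200   0.000  1.00 20.00           C\n"
            "ATOM      4  O   GLY A   1       3.500   1.200   0.000  1.00 20.00           O\n"
            "TER\n"
            "HETATM    5  P   SEP B 201      50.000  50.000  50.000  1.00 20.00           P\n"
            "END\n"
        )
        model = parse_structure(pdb)
        assert [g.component_code for g in model.nonpolymer_groups] == ["SEP"]
        assert identify_modified_residues(model, scan_config) == []

    def test_n_terminal_restriction(self, tmp_path, scan_config):
        """PCA (pyroglutamate) is dictionary-restricted to the N terminus."""
        spec = FixtureSpec(
            seed=0, entry_id="PCA1",
            chains=(("A", ("PCA", "GLY", "ALA")), ("B", ("GLY", "PCA", "ALA"))),
        )
        fx = make_fixture(spec, tmp_path)
        model = parse_structure(fx.pdb_path)
        mods = identify_modified_residues(model, scan_config)
        assert [(m.residues[0].chain_id, m.residues[0].polymer_index) for m in mods] == [
            ("A", 0)
        ]


class TestAttachments:
    def test_glycosylation_bonded(self, tmp_path, scan_config):
        spec = FixtureSpec(
            seed=0, entry_id="NGLC",
            chains=(("A", ("GLY", "ASN", "GLY")),),
            plants=(Plant("n-glycosyl-asparagine", (("A", 1),), distance=1.43),),
        )
        fx = make_fixture(spec, tmp_path)
        model = parse_structure(fx.pdb_path)
        mods = identify_attachments(model, scan_config)
        assert len(mods) == 1
        (bond,) = mods[0].bonds
        assert {bond.atom_1.atom_name, bond.atom_2.atom_name} == {"ND2", "C1"}
        assert bond.distance == pytest.approx(1.43, abs=0.01)

    def test_glycan_too_far(self, tmp_path, scan_config):
        spec = FixtureSpec(
            seed=0, entry_id="FAR1",
            chains=(("A", ("GLY", "ASN", "GLY")),),
            plants=(Plant("n-glycosyl-asparagine", (("A", 1),), distance=3.2),),
        )
        # distance 3.2 is beyond any N+C threshold; plant it as a decoy-style
        # placement by building the fixture, then expect no identification
        fx = make_fixture(spec, tmp_path)
        model = parse_structure(fx.pdb_path)
        assert identify_attachments(model, scan_config) == []

    def test_zinc_tetra_coordination_one_record_per_residue(
        self, tmp_path, scan_config
    ):
        seq = ["ALA"] * 13
        seq[1], seq[4], seq[7], seq[10] = "HIS", "HIS", "CYS", "CYS"
        spec = FixtureSpec(
            seed=0, entry_id="ZNS1",
            chains=(("A", tuple(seq)),),
            plants=(
                Plant("zinc-histidine", (("A", 1),), group_label="zn"),
                Plant("zinc-histidine", (("A", 4),), group_label="zn"),
                Plant("zinc-cysteine", (("A", 7),), group_label="zn"),
                Plant("zinc-cysteine", (("A", 10),), group_label="zn"),
            ),
        )
        fx = make_fixture(spec, tmp_path)
        model = parse_structure(fx.pdb_path)
        mods = identify_attachments(model, scan_config)
        assert len(mods) == 4
        groups = {r.id_key for m in mods for r in m.residues if not r.is_polymer}
        assert len(groups) == 1  # one shared ZN ion
        assert report_key_set(
            identify_all(model, scan_config)
        ) >= truth_key_set(fx)


class TestCrosslinks:
    def test_single_disulfide(self, tmp_path, scan_config):
        spec = FixtureSpec(
            seed=0, entry_id="SS01",
            chains=(("A", ("CYS", "GLY", "GLY", "GLY", "CYS")),),
            plants=(Plant("disulfide", (("A", 0), ("A", 4)), distance=2.05),),
        )
        fx = make_fixture(spec, tmp_path)
        model = parse_structure(fx.pdb_path)
        mods = identify_crosslinks(model, scan_config)
        assert len(mods) == 1
        assert len(mods[0].residues) == 2 and len(mods[0].bonds) == 1
        assert mods[0].bonds[0].distance == pytest.approx(2.05, abs=0.01)

    def test_three_cysteine_chain_two_disulfides(self, scan_config):
        """SG distances A-B 2.05, B-C 2.05, A-C 3.9 -> exactly (A,B), (B,C)."""
        import numpy as np

        from modfinder.structure_io import AtomRecord, ResidueRecord, StructureModel

        def cys(seq, sg_x):
            return ResidueRecord(
                component_code="CYS", chain_id="A", seq_id=seq,
                polymer_index=seq - 1,
                atoms=[
                    AtomRecord(name="CA", element="C",
                               coords=np.array([sg_x, -3.0, 0.0])),
                    AtomRecord(name="SG", element="S",
                               coords=np.array([sg_x, 0.0, 0.0])),
                ],
            )

        # collinear SGs at x = 0, 2.05, 4.10: A-C distance 4.10 > 2.50
        model = StructureModel(
            entry_id="TRI", model_number=1,
            chains=[("A", [cys(1, 0.0), cys(2, 2.05), cys(3, 4.10)])],
            nonpolymer_groups=[], source_format="PDB",
        )
        mods = identify_crosslinks(model, scan_config)
        pairs = {tuple(sorted(k[1] for k in m.residue_keys)) for m in mods}
        assert pairs == {(1, 2), (2, 3)}

    def test_isopeptide(self, tmp_path, scan_config):
        spec = FixtureSpec(
            seed=0, entry_id="ISO1",
            chains=(("A", ("LYS", "GLY", "GLY", "GLY", "ASN")),),
            plants=(Plant("isopeptide-lys-asn", (("A", 0), ("A", 4)), distance=1.33),),
        )
        fx = make_fixture(spec, tmp_path)
        model = parse_structure(fx.pdb_path)
        mods = identify_crosslinks(model, scan_config)
        assert [m.definition.internal_id for m in mods] == ["isopeptide-lys-asn"]
        (bond,) = mods[0].bonds
        assert {bond.atom_1.atom_name, bond.atom_2.atom_name} == {"NZ", "CG"}

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_enumeration(self, seed, scan_config, tmp_path):
        """Backtracking matcher equals brute-force assignment enumeration."""
        fx = make_fixture(random_spec(seed), tmp_path / str(seed))
        model = parse_structure(fx.pdb_path)
        got = {
            (m.definition.internal_id, tuple(sorted(m.residue_keys)))
            for m in identify_crosslinks(model, scan_config)
        }
        expected = set()
        for d in scan_config.dictionary.by_category(ModificationCategory.CROSS_LINK):
            expected |= exhaustive_crosslinks(model, d, scan_config.bond_config)
        assert got == expected


class TestIdentifyAll:
    def test_composite_fixture_one_per_category(self, tmp_path, scan_config):
        fx = make_fixture(composite_spec(), tmp_path)
        model = parse_structure(fx.pdb_path)
        report = identify_all(model, scan_config)
        assert len(report.identifications) == 3
        assert {m.category for m in report.identifications} == set(ModificationCategory)
        assert report_key_set(report) == truth_key_set(fx)

    def test_empty_structure(self, tmp_path, scan_config):
        spec = FixtureSpec(seed=0, entry_id="MT01", chains=(("A", ("GLY", "ALA")),))
        fx = make_fixture(spec, tmp_path)
        report = identify_all(parse_structure(fx.pdb_path), scan_config)
        assert report.identifications == []

    def test_category_filter(self, tmp_path, dictionary):
        fx = make_fixture(composite_spec(), tmp_path)
        model = parse_structure(fx.pdb_path)
        cfg = ScanConfig(
            dictionary=dictionary,
            categories=frozenset({ModificationCategory.CROSS_LINK}),
        )
        report = identify_all(model, cfg)
        assert [m.definition.internal_id for m in report.identifications] == ["disulfide"]

    def test_no_double_counting(self, tmp_path, scan_config):
        for seed in range(10):
            fx = make_fixture(random_spec(seed), tmp_path / str(seed))
            report = identify_all(parse_structure(fx.pdb_path), scan_config)
            keys = [m.dedup_key for m in report.identifications]
            assert len(keys) == len(set(keys))

    def test_structural_invariants_of_records(self, tmp_path, scan_config):
        fx = make_fixture(composite_spec(), tmp_path)
        report = identify_all(parse_structure(fx.pdb_path), scan_config)
        for m in report.identifications:
            assert len(m.residues) == len(m.definition.components)
            for res, comp in zip(m.residues, m.definition.components):
                assert comp.matches_code(res.component_code)
            assert len(m.bonds) == len(m.definition.linkages)
            for bond, lk in zip(m.bonds, m.definition.linkages):
                names = {bond.atom_1.atom_name, bond.atom_2.atom_name}
                assert names <= set(lk.atoms_1) | set(lk.atoms_2)

    def test_tolerance_monotonicity_on_fixtures(self, tmp_path, dictionary):
        for seed in (3, 11):
            fx = make_fixture(random_spec(seed), tmp_path / str(seed))
            model = parse_structure(fx.pdb_path)
            previous = set()
            for tol in (0.0, 0.2, 0.4, 0.6):
                cfg = ScanConfig(
                    dictionary=dictionary, bond_config=BondConfig(tolerance=tol)
                )
                current = report_key_set(identify_all(model, cfg))
                assert previous <= current
                previous = current

    def test_permutation_and_rigid_motion_stability(self, tmp_path, scan_config):
        fx = make_fixture(composite_spec(decoys=1), tmp_path / "base")
        base = report_key_set(identify_all(parse_structure(fx.pdb_path), scan_config))
        p_pdb, _ = perturb_fixture(
            fx.pdb_path,
            tmp_path / "pert",
            rotation=rotation_matrix((0, 1, 0), 90.0),
            translation=(100.0, 100.0, 100.0),
            permutation_seed=13,
        )
        assert report_key_set(
            identify_all(parse_structure(p_pdb), scan_config)
        ) == base
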