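"""Structural filters: SASA against analytic and quadrature oracles,
exposure, polarity, pair geometry and salt-bridge detection."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oracles import brute_force_salt_bridges, sasa_quadrature
from ureakit.containers import CandidateResidue, StructureModel
from ureakit.structure import (
    cavity_exposed,
    find_salt_bridges,
    pair_facing,
    pathway_candidates,
    polar_filter,
    read_structure,
    sasa,
)
from ureakit.synthetic import gen_toy_structure


def _random_cluster(n_atoms: int, seed: int) -> StructureModel:
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-4.0, 4.0, size=(n_atoms, 3))
    elements = rng.choice(["C", "N", "O", "S"], size=n_atoms).tolist()
    return StructureModel(
        res_ids=list(range(1, n_atoms + 1)),
        res_names=["GLY"] * n_atoms,
        atom_names=["CA"] * n_atoms,
        elements=elements,
        coords=coords,
    )


class TestReadStructure:
    def test_round_trip_write_read(self, tmp_path):
        toy = gen_toy_structure("helix_bundle_with_cavity")
        path = tmp_path / "bundle.pdb"
        toy.model.to_pdb(path)
        assert read_structure(path) == toy.model

    def test_single_atom_pdb(self, tmp_path):
        path = tmp_path / "one.pdb"
        gen_toy_structure("single_sphere").model.to_pdb(path)
        assert len(read_structure(path)) == 1

    def test_hetatm_only_file_rejected(self, tmp_path):
        path = tmp_path / "het.pdb"
        path.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\n"
            "END\n"
        )
        with pytest.raises(ValueError, match="no ATOM"):
            read_structure(path)


class TestSASA:
    def test_isolated_sphere_matches_analytic_area(self):
        toy = gen_toy_structure("single_sphere")
        result = sasa(toy.model, probe_radius=2.0)
        exact = toy.truth["exact_sasa"][1]  # 4*pi*(1.7+2.0)^2 ~ 172 A^2
        assert result.per_atom[0] == pytest.approx(exact, rel=0.005)

    def test_disjoint_pair_is_additive(self):
        toy = gen_toy_structure("disjoint_pair")
        result = sasa(toy.model)
        single = toy.truth["exact_sasa"][1]
        assert result.per_atom == pytest.approx([single, single], rel=0.005)
        total = sum(result.per_residue_total.values())
        assert total == pytest.approx(2 * single, rel=0.005)

    def test_fully_enclosed_atom_has_zero_area(self):
        toy = gen_toy_structure("buried_atom")
        result = sasa(toy.model)
        assert result.per_atom[0] == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_cluster_agrees_with_quadrature_oracle(self, seed):
        model = _random_cluster(20, seed)
        mine = sasa(model, probe_radius=2.0, n_sphere_points=960).per_atom
        oracle = sasa_quadrature(model, probe_radius=2.0, n_theta=120)
        # 2% agreement on the total; per-atom at the point-set resolution
        assert mine.sum() == pytest.approx(oracle.sum(), rel=0.02)
        exposed = oracle > 5.0
        assert mine[exposed] == pytest.approx(oracle[exposed], rel=0.05, abs=1.0)

    def test_agrees_with_independent_library_implementation(self):
        # biotite's Shrake-Rupley as an external cross-check
        import biotite.structure as struc

        model = _random_cluster(15, seed=7)
        arr = struc.AtomArray(len(model))
        arr.coord = model.coords
        arr.res_id = model.res_ids
        arr.res_name = np.array(["GLY"] * len(model), dtype="U5")
        arr.atom_name = np.array(["CA"] * len(model), dtype="U6")
        arr.element = np.array([str(e) for e in model.elements], dtype="U2")
        arr.chain_id = np.full(len(model), "A", dtype="U4")
        arr.hetero = np.zeros(len(model), dtype=bool)
        theirs = struc.sasa(arr, probe_radius=2.0, point_number=1000, vdw_radii="Single")
        mine = sasa(model, probe_radius=2.0, n_sphere_points=1000).per_atom
        # radius tables differ slightly (biotite's single-atom set); compare loosely
        assert mine.sum() == pytest.approx(theirs.sum(), rel=0.05)

    def test_rotation_and_translation_invariance(self):
        model = _random_cluster(12, seed=3)
        base = sasa(model).per_atom
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = model.transformed(rot, np.array([10.0, -5.0, 3.0]))
        # the sampling point set is fixed in the lab frame, so invariance
        # holds to quadrature tolerance; totals agree more tightly
        assert sasa(moved).per_atom == pytest.approx(base, rel=0.06, abs=1.5)
        assert sasa(moved).per_atom.sum() == pytest.approx(base.sum(), rel=0.01)

    def test_isolated_atom_area_increases_with_probe(self):
        model = gen_toy_structure("single_sphere").model
        areas = [sasa(model, probe_radius=p).per_atom[0] for p in (0.0, 1.4, 2.0, 3.0)]
        assert np.all(np.diff(areas) > 0)

    def test_per_residue_sums_equal_atom_sums(self):
        toy = gen_toy_structure("helix_bundle_with_cavity")
        result = sasa(toy.model)
        for res_id in toy.model.residue_ids:
            mask = toy.model.res_ids == res_id
            assert result.per_residue_total[int(res_id)] == pytest.approx(
                result.per_atom[mask].sum()
            )

    def test_unknown_element_configurable(self):
        model = StructureModel([1], ["GLY"], ["CA"], ["X"], np.zeros((1, 3)))
        with pytest.raises(KeyError):
            sasa(model, on_unknown_element="fail")
        with pytest.warns(UserWarning, match="radius"):
            sasa(model, on_unknown_element="default")


class TestCavityExposure:
    def test_bundle_truth_lists_verified_by_sasa(self):
        toy = gen_toy_structure("helix_bundle_with_cavity")
        result = sasa(toy.model)
        for res in toy.truth["cavity_lining"] + toy.truth["surface"]:
            assert cavity_exposed(result, res, threshold=0.15), res
        for res in toy.truth["buried"]:
            assert not cavity_exposed(result, res, threshold=0.15)
            assert result.relative_sidechain[res] == pytest.approx(0.0, abs=1e-9)

    def test_buried_truth_confirmed_by_quadrature_oracle(self):
        toy = gen_toy_structure("helix_bundle_with_cavity")
        oracle = sasa_quadrature(toy.model, n_theta=60)
        buried = toy.truth["buried"][0]
        side = toy.model.atom_mask(buried, sidechain_only=True)
        assert oracle[side].sum() == pytest.approx(0.0, abs=1e-6)

    def test_zero_threshold_marks_everything_exposed(self):
        toy = gen_toy_structure("helix_bundle_with_cavity")
        result = sasa(toy.model)
        assert all(cavity_exposed(result, int(r), threshold=0.0) for r in toy.model.residue_ids)


class TestPolarFilter:
    def test_known_pathway_residues_all_polar(self):
        kept = polar_filter(["W82", "T133", "D286", "Y388"])
        assert kept == ["W82", "T133", "D286", "Y388"]

    def test_apolar_residues_dropped(self):
        assert polar_filter(["A", "L", "V"]) == []
        assert polar_filter(["ALA", "LEU", "VAL"]) == []

    def test_glycine_excluded_by_default(self):
        assert polar_filter(["G"]) == []

    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError):
            polar_filter(["XYZ123"])


class TestPathwayCandidates:
    def test_planted_conserved_exposed_polar_exactly_recovered(self):
        toy = gen_toy_structure("helix_bundle_with_cavity")
        result = sasa(toy.model)
        conserved = [
            CandidateResidue(int(r), toy.model.residue_name(int(r)), "family_conserved")
            for r in toy.truth["cavity_lining"] + toy.truth["buried"]
        ]
        out = pathway_candidates(toy.model, result, conserved)
        assert [c.ref_position for c in out.candidates] == sorted(toy.truth["polar_cavity"])

    def test_empty_conserved_set_gives_empty_result(self):
        toy = gen_toy_structure("helix_bundle_with_cavity")
        out = pathway_candidates(toy.model, sasa(toy.model), [])
        assert out.candidates == [] and out.unevaluable == []

    def test_position_outside_model_reported_unevaluable(self):
        toy = gen_toy_structure("helix_bundle_with_cavity")
        ghost = CandidateResidue(9999, "SER", "family_conserved")
        out = pathway_candidates(toy.model, sasa(toy.model), [ghost])
        assert out.candidates == [] and [c.ref_position for c in out.unevaluable] == [9999]

    def test_all_apolar_set_gives_empty(self):
        toy = gen_toy_structure("helix_bundle_with_cavity")
        result = sasa(toy.model)
        apolar = [
            CandidateResidue(int(r), "LEU", "family_conserved")
            for r in toy.truth["surface"][:3]
        ]
        assert pathway_candidates(toy.model, result, apolar).candidates == []


class TestPairFacing:
    def test_facing_pair_detected(self, facing_pair_model):
        res = pair_facing(facing_pair_model, 1, 2, distance_cutoff=8.0, angle_cutoff=60.0)
        assert res.facing
        assert res.centroid_distance == pytest.approx(6.0)

    def test_averted_pair_rejected(self, averted_pair_model):
        res = pair_facing(averted_pair_model, 1, 2)
        assert not res.facing
        assert res.angle_a == pytest.approx(180.0)

    def test_missing_sidechain_rejected(self):
        model = StructureModel([1, 2], ["GLY", "TYR"], ["CA", "CA"],
                               ["C", "C"], np.array([[0, 0, 0], [5, 0, 0.0]]))
        with pytest.raises(ValueError, match="sidechain"):
            pair_facing(model, 1, 2)

    def test_bundle_scan_matches_per_pair_evaluation(self):
        toy = gen_toy_structure("helix_bundle_with_cavity")
        with_side = [
            int(r) for r in toy.model.residue_ids
            if toy.model.atom_mask(int(r), sidechain_only=True).any()
        ]
        scan = {
            (a, b): pair_facing(toy.model, a, b).facing
            for a, b in itertools.combinations(with_side[:12], 2)
        }
        # symmetric under argument order
        for (a, b), flag in scan.items():
            assert pair_facing(toy.model, b, a).facing == flag


class TestSaltBridges:
    def test_planted_bridge_found_with_exact_distance(self):
        toy = gen_toy_structure("planted_salt_bridge")
        bridges = find_salt_bridges(toy.model, cutoff=4.0)
        assert len(bridges) == 1
        assert (bridges[0].basic_residue, bridges[0].acidic_residue) == toy.truth["bridge"]
        assert bridges[0].min_atom_distance == pytest.approx(3.0)

    def test_separated_pair_gives_no_bridge(self):
        toy = gen_toy_structure("planted_salt_bridge")
        coords = toy.model.coords.copy()
        coords[toy.model.atom_names == "OE1"] += [3.0, 0.0, 0.0]  # N-O now 6.0 A
        moved = StructureModel(
            toy.model.res_ids, toy.model.res_names, toy.model.atom_names,
            toy.model.elements, coords,
        )
        assert find_salt_bridges(moved, cutoff=4.0) == []

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_decoys_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_res = 12
        res_names, atom_names, res_ids, elements, coords = [], [], [], [], []
        for rid in range(1, n_res + 1):
            name = rng.choice(["ARG", "LYS", "HIS", "ASP", "GLU", "SER"])
            centre = rng.uniform(-8, 8, 3)
            atoms = {"ARG": ["NE", "NH1"], "LYS": ["NZ"], "HIS": ["ND1"],
                     "ASP": ["OD1", "OD2"], "GLU": ["OE1"], "SER": ["OG"]}[name]
            for a in ["CA"] + atoms:
                res_ids.append(rid)
                res_names.append(name)
                atom_names.append(a)
                elements.append(a[0])
                coords.append(centre + rng.uniform(-1.5, 1.5, 3))
        model = StructureModel(res_ids, res_names, atom_names, elements, np.array(coords))
        mine = {(b.basic_residue, b.acidic_residue) for b in find_salt_bridges(model)}
        assert mine == brute_force_salt_bridges(model)

    def test_symmetric_under_atom_permutation(self):
        toy = gen_toy_structure("planted_salt_bridge")
        perm = np.array([3, 1, 0, 2])
        shuffled = StructureModel(
            toy.model.res_ids[perm], toy.model.res_names[perm],
            toy.model.atom_names[perm], toy.model.elements[perm],
            toy.model.coords[perm],
        )
        a = find_salt_bridges(toy.model)
        b = find_salt_bridges(shuffled)
        assert [(x.basic_residue, x.acidic_residue) for x in a] == [
            (x.basic_residue, x.acidic_residue) for x in b
        ]
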