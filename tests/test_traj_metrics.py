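"""Coordinate-level metrics: PDB I/O, distances, DSSP, contacts, SASA."""

import math

import numpy as np
import pytest

from ubikin.synthetic_data import (
    SynthTrajSpec,
    build_antiparallel_sheet,
    build_ideal_helix,
    build_ideal_strand,
    synth_two_domain_ensemble,
)
from ubikin.traj_metrics import (
    Atom,
    EnsembleSet,
    SecondaryStructureSeries,
    Topology,
    Trajectory,
    assign_secondary_structure,
    contact_map,
    count_helical,
    pair_distance,
    read_multimodel_pdb,
    read_scalar_series,
    read_ss_series,
    residue_center_of_mass,
    salt_bridge_distance,
    sasa,
    write_multimodel_pdb,
)


def _random_rigid_transform(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.normal(scale=20.0, size=3)


class TestPdbIO:
    def test_round_trip_within_format_precision(self, helix_traj, tmp_path):
        path = tmp_path / "helix.pdb"
        write_multimodel_pdb(helix_traj, path)
        back = read_multimodel_pdb(path)
        assert np.abs(back.xyz - helix_traj.xyz).max() < 1e-3
        assert [a.name for a in back.topology.atoms] == \
               [a.name for a in helix_traj.topology.atoms]

    def test_three_models_give_three_frames(self, helix_traj, tmp_path):
        traj = Trajectory(helix_traj.topology,
                          np.repeat(helix_traj.xyz, 3, axis=0))
        path = tmp_path / "three.pdb"
        write_multimodel_pdb(traj, path)
        assert read_multimodel_pdb(path).n_frames == 3

    def test_inconsistent_model_rejected_naming_model(self, helix_traj, tmp_path):
        path = tmp_path / "bad.pdb"
        write_multimodel_pdb(
            Trajectory(helix_traj.topology, np.repeat(helix_traj.xyz, 2, axis=0)),
            path)
        lines = path.read_text().splitlines()
        # drop one ATOM line from the second model
        second_atom = [i for i, l in enumerate(lines)
                       if l.startswith("ATOM") and
                       any(lines[j].startswith("MODEL") and "2" in lines[j]
                           for j in range(max(0, i - 60), i))]
        del lines[second_atom[-1]]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="model 2"):
            read_multimodel_pdb(path)


class TestScalarSeries:
    def test_split_into_equal_blocks(self, tmp_path):
        path = tmp_path / "series.dat"
        path.write_text("#Frame value\n" + "".join(
            f"{i} {float(i)}\n" for i in range(320)))
        series = read_scalar_series(path, n_sims=32)
        assert len(series) == 32
        assert all(len(s.values) == 10 for s in series)
        assert series[0].values[0] == 0.0 and series[-1].values[-1] == 319.0

    def test_header_skipped_single_column(self, tmp_path):
        path = tmp_path / "one.dat"
        path.write_text("# comment\n1.5\n2.5\n")
        (s,) = read_scalar_series(path)
        np.testing.assert_array_equal(s.values, [1.5, 2.5])

    def test_indivisible_length_rejected(self, tmp_path):
        path = tmp_path / "bad.dat"
        path.write_text("".join(f"{i}\n" for i in range(10)))
        with pytest.raises(ValueError, match="not divisible"):
            read_scalar_series(path, n_sims=3)

    def test_ss_series_normalization(self, tmp_path):
        path = tmp_path / "ss.dat"
        path.write_text("HHSS0.\nHHTTCC\n")
        ss = read_ss_series(path)
        assert "".join(ss.codes[0]) == "HHCCCC"
        assert "".join(ss.codes[1]) == "HHTTCC"


class TestDistances:
    def test_three_four_five(self):
        top = Topology([Atom("CA", "C", 1, "GLY"), Atom("CA", "C", 2, "GLY")])
        frame = np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]])
        assert pair_distance(frame, top, (1, "CA"), (2, "CA")) == 5.0
        assert pair_distance(frame, top, (2, "CA"), (1, "CA")) == 5.0

    def test_missing_atom_named_in_error(self, helix_traj):
        with pytest.raises(KeyError, match="CB.*residue 3"):
            pair_distance(helix_traj.xyz[0], helix_traj.topology,
                          (3, "CB"), (4, "CA"))

    def test_against_direct_formula(self, helix_traj, rng):
        top = helix_traj.topology
        frame = helix_traj.xyz[0]
        for _ in range(20):
            r1, r2 = rng.integers(1, 13, size=2)
            a1 = rng.choice(["N", "CA", "C", "O"])
            a2 = rng.choice(["N", "CA", "C", "O"])
            d = pair_distance(frame, top, (int(r1), a1), (int(r2), a2))
            p, q = frame[top.index_of(int(r1), a1)], frame[top.index_of(int(r2), a2)]
            expected = math.sqrt(sum((pi - qi) ** 2 for pi, qi in zip(p, q)))
            assert d == pytest.approx(expected, abs=1e-9)

    def test_rigid_transform_invariance(self, helix_traj, rng):
        top = helix_traj.topology
        frame = helix_traj.xyz[0]
        rot, trans = _random_rigid_transform(rng)
        moved = frame @ rot.T + trans
        for sel in [((1, "N"), (12, "O")), ((3, "CA"), (7, "C"))]:
            assert pair_distance(moved, top, *sel) == pytest.approx(
                pair_distance(frame, top, *sel), abs=1e-6)


class TestSaltBridge:
    def _topology(self):
        return Topology([Atom("NZ", "N", 369, "LYS"),
                         Atom("OE1", "O", 386, "GLU"),
                         Atom("OE2", "O", 386, "GLU")])

    def test_minimum_of_two_oxygens_and_formed_flag(self):
        frame = np.array([[0, 0, 0], [2.8, 0, 0], [5.0, 0, 0]], dtype=float)
        d, formed = salt_bridge_distance(frame, self._topology())
        assert d == pytest.approx(2.8) and formed

    def test_not_formed_beyond_cutoff(self):
        frame = np.array([[0, 0, 0], [4.5, 0, 0], [5.0, 0, 0]], dtype=float)
        d, formed = salt_bridge_distance(frame, self._topology())
        assert d == pytest.approx(4.5) and not formed

    def test_invariant_under_oe_label_swap(self):
        frame = np.array([[0, 0, 0], [2.8, 0, 0], [5.0, 0, 0]], dtype=float)
        top_swapped = Topology([Atom("NZ", "N", 369, "LYS"),
                                Atom("OE2", "O", 386, "GLU"),
                                Atom("OE1", "O", 386, "GLU")])
        assert salt_bridge_distance(frame, self._topology()) == \
               salt_bridge_distance(frame, top_swapped)

    def test_missing_side_chain_rejected(self, helix_traj):
        with pytest.raises(KeyError):
            salt_bridge_distance(helix_traj.xyz[0], helix_traj.topology,
                                 lys_residue=1, glu_residue=2)


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_H(self, helix_traj):
        assert "".join(assign_secondary_structure(helix_traj).codes[0]) == \
               "CHHHHHHHHHHC"

    def test_extended_strand_has_no_H(self):
        codes = assign_secondary_structure(build_ideal_strand(12)).codes[0]
        assert not np.any(codes == "H")

    def test_antiparallel_strands_paired_region_is_E(self, sheet_traj):
        codes = assign_secondary_structure(sheet_traj).codes[0]
        assert (codes == "E").sum() >= 8

    def test_isolated_residue_is_coil(self):
        helix = build_ideal_helix(6)
        # take residue 1's four backbone atoms only
        idx = [helix.topology.index_of(1, n) for n in ("N", "CA", "C", "O")]
        top = Topology([helix.topology.atoms[i] for i in idx])
        traj = Trajectory(top, helix.xyz[:, idx])
        assert "".join(assign_secondary_structure(traj).codes[0]) == "C"

    @pytest.mark.parametrize("builder,name", [
        (lambda: build_ideal_helix(12), "helix"),
        (lambda: build_ideal_strand(12), "strand"),
        (lambda: build_antiparallel_sheet(8), "sheet"),
    ])
    def test_agreement_with_reference_dssp(self, builder, name, tmp_path):
        """>=95% per-residue agreement with mdtraj's DSSP on each fixture."""
        md = pytest.importorskip("mdtraj")
        traj = builder()
        path = tmp_path / f"{name}.pdb"
        write_multimodel_pdb(traj, path)
        ref = md.compute_dssp(md.load(str(path)), simplified=False)[0]
        ref = np.array(["C" if c in (" ", "S") else c for c in ref])
        mine = assign_secondary_structure(traj).codes[0]
        agreement = (mine == ref).mean()
        assert agreement >= 0.95, (name, "".join(mine), "".join(ref))

    def test_rigid_transform_invariance(self, helix_traj, rng):
        rot, trans = _random_rigid_transform(rng)
        moved = Trajectory(helix_traj.topology,
                           helix_traj.xyz[0] @ rot.T + trans)
        np.testing.assert_array_equal(
            assign_secondary_structure(moved).codes,
            assign_secondary_structure(helix_traj).codes)


class TestCountHelical:
    def _series(self, row):
        return SecondaryStructureSeries(list(range(380, 394)),
                                        np.array([list(row)]))

    def test_all_and_none(self):
        assert count_helical(self._series("H" * 14))[0] == 14
        assert count_helical(self._series("C" * 14))[0] == 0

    def test_threshold_boundary_ten(self):
        assert count_helical(self._series("H" * 10 + "T" * 4))[0] == 10

    def test_g_and_i_codes_excluded_by_default(self):
        counts = count_helical(self._series("H" * 8 + "G" * 3 + "I" * 3))
        assert counts[0] == 8
        wide = count_helical(self._series("H" * 8 + "G" * 3 + "I" * 3),
                             helix_codes={"H", "G", "I"})
        assert wide[0] == 14

    def test_range_outside_series_rejected(self):
        with pytest.raises(ValueError, match="range"):
            count_helical(self._series("H" * 14), residue_range=(1, 14))


class TestCenterOfMass:
    def test_single_atom_residue(self):
        top = Topology([Atom("CA", "C", 1, "GLY")])
        frame = np.array([[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(residue_center_of_mass(frame, top, 1),
                                   [1.0, 2.0, 3.0])

    def test_two_equal_mass_atoms_midpoint(self):
        top = Topology([Atom("C1", "C", 1, "LIG"), Atom("C2", "C", 1, "LIG")])
        frame = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        np.testing.assert_allclose(residue_center_of_mass(frame, top, 1),
                                   [1.0, 0.0, 0.0])

    def test_mass_weighting_against_hand_computation(self):
        top = Topology([Atom("N", "N", 1, "GLY"), Atom("CA", "C", 1, "GLY"),
                        Atom("O", "O", 1, "GLY")])
        frame = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        m = np.array([14.007, 12.011, 15.999])
        expected = (frame * m[:, None]).sum(0) / m.sum()
        np.testing.assert_allclose(residue_center_of_mass(frame, top, 1),
                                   expected, atol=1e-9)

    def test_unknown_element_rejected(self):
        top = Topology([Atom("XX", "XX", 1, "UNK")])
        with pytest.raises(ValueError, match="unknown element"):
            residue_center_of_mass(np.zeros((1, 3)), top, 1)


class TestContactMap:
    @pytest.fixture()
    def ensemble(self):
        return synth_two_domain_ensemble(
            SynthTrajSpec(n_sims=3, frames_per_sim=30, seed=5))

    def test_matches_brute_force_recount(self, ensemble):
        target, moiety = list(range(1, 7)), list(range(10, 16))
        cm = contact_map(ensemble, target, moiety, cutoff=10.0, stride_ps=1.0)
        counts = np.zeros((6, 6))
        total = 0
        for traj in ensemble.trajectories:
            for frame in traj.xyz:
                for i, r in enumerate(target):
                    for j, m in enumerate(moiety):
                        d = np.linalg.norm(
                            residue_center_of_mass(frame, traj.topology, r)
                            - residue_center_of_mass(frame, traj.topology, m))
                        counts[i, j] += d < 10.0
                total += 1
        np.testing.assert_array_equal(cm.values, counts / total)
        assert cm.n_snapshots == total

    def test_monotone_in_cutoff(self, ensemble):
        target, moiety = list(range(1, 7)), list(range(10, 16))
        prev = None
        for cutoff in (5.0, 10.0, 15.0, 25.0):
            cm = contact_map(ensemble, target, moiety, cutoff=cutoff,
                             stride_ps=1.0)
            if prev is not None:
                assert np.all(cm.values >= prev - 1e-12)
            prev = cm.values

    def test_permanent_and_never_contacts(self):
        top = Topology([Atom("CA", "C", 1, "GLY"), Atom("CA", "C", 2, "GLY"),
                        Atom("CA", "C", 3, "GLY")])
        xyz = np.zeros((4, 3, 3))
        xyz[:, 1, 0] = 5.0    # residue 2 always 5 A from residue 1
        xyz[:, 2, 0] = 50.0   # residue 3 never close
        ens = EnsembleSet("toy", [Trajectory(top, xyz)])
        cm = contact_map(ens, [1], [2, 3], cutoff=10.0, stride_ps=1.0)
        np.testing.assert_array_equal(cm.values, [[1.0, 0.0]])

    def test_stride_exceeding_trajectory_rejected(self, ensemble):
        with pytest.raises(ValueError, match="stride"):
            contact_map(ensemble, [1], [10], cutoff=10.0, stride_ps=1e6)


class TestSasa:
    def test_isolated_atom_closed_form(self):
        top = Topology([Atom("S", "S", 1, "CYS")])
        area = sasa(np.zeros((1, 3)), top, probe=1.4)
        exact = 4.0 * math.pi * (1.80 + 1.4) ** 2
        assert abs(area - exact) / exact < 0.005

    def test_buried_atom_is_near_zero(self, rng):
        atoms = [Atom("C0", "C", 1, "COR")]
        coords = [np.zeros(3)]
        # cage of carbons on a sphere of radius 2.5 A around the center
        for i in range(60):
            v = rng.normal(size=3)
            coords.append(2.5 * v / np.linalg.norm(v))
            atoms.append(Atom(f"C{i + 1}", "C", 2, "CAG"))
        top = Topology(atoms)
        buried = sasa(np.array(coords), top, selection=[0])
        assert buried < 1.0

    def test_quadrature_convergence_under_point_doubling(self, helix_traj):
        frame = helix_traj.xyz[0]
        a1 = sasa(frame, helix_traj.topology, n_sphere_points=960)
        a2 = sasa(frame, helix_traj.topology, n_sphere_points=1920)
        assert abs(a2 - a1) / a1 < 0.005

    def test_occluders_never_increase_area(self, helix_traj):
        frame = helix_traj.xyz[0]
        top = helix_traj.topology
        sel = top.residue_atom_indices(6)
        alone = sasa(frame, top, selection=sel, occluders=sel)
        occluded = sasa(frame, top, selection=sel)
        assert occluded <= alone

    def test_unknown_radius_rejected(self):
        top = Topology([Atom("FE", "FE", 1, "HEM")])
        with pytest.raises(ValueError, match="radius"):
            sasa(np.zeros((1, 3)), top)
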