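"""Helical construction, screw-axis recovery and buried surface area."""

import numpy as np
import pytest

from filaquant.helix import (
    HelicalParams,
    StructureModel,
    apply_helical_symmetry,
    buried_interface_area,
    dimers_per_turn,
    read_structure,
    recover_helical_params,
    screw_decompose,
    shrake_rupley_sasa,
    units_from_chain_groups,
    write_pdb,
    _rot_z,
)
from filaquant.simulate import make_toy_protomer


class TestConstruction:
    def test_single_unit_is_identity(self, protomer):
        fil = apply_helical_symmetry(protomer, HelicalParams(-108, 51), 1)
        np.testing.assert_allclose(fil.coords, protomer.coords)

    def test_closure_after_full_turn(self, protomer):
        # three applications of (-120, 50) complete a turn
        fil = apply_helical_symmetry(protomer, HelicalParams(-120, 50), 4)
        np.testing.assert_allclose(
            fil.select_unit(3).coords,
            fil.select_unit(0).coords + [0, 0, 150.0],
            atol=1e-9,
        )

    def test_d1_symmetry_doubles_atoms(self, protomer):
        fil = apply_helical_symmetry(protomer, HelicalParams(-108, 51, "D1"), 3)
        assert len(fil) == 6 * len(protomer)
        rec, _ = recover_helical_params(fil)
        assert rec.twist == pytest.approx(-108, abs=1e-6)
        assert rec.rise == pytest.approx(51, abs=1e-6)

    def test_chirality_mirror(self, protomer):
        left = apply_helical_symmetry(protomer, HelicalParams(-108, 51), 4)
        right = apply_helical_symmetry(
            StructureModel(protomer.coords * [-1, 1, 1]), HelicalParams(108, 51), 4
        )
        np.testing.assert_allclose(
            left.coords * [-1, 1, 1], right.coords, atol=1e-9
        )

    def test_param_validation(self):
        with pytest.raises(ValueError):
            HelicalParams(-181, 51)
        with pytest.raises(ValueError):
            HelicalParams(-108, -1)


class TestScrewDecompose:
    def test_identity(self, protomer):
        st = screw_decompose(protomer.coords, protomer.coords)
        assert st.angle_deg == pytest.approx(0.0, abs=1e-6)
        assert st.translation == pytest.approx(0.0, abs=1e-9)
        assert st.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_pure_translation(self, protomer):
        st = screw_decompose(protomer.coords, protomer.coords + [0, 0, 51.0])
        assert st.angle_deg == pytest.approx(0.0, abs=1e-6)
        assert st.translation == pytest.approx(51.0, abs=1e-9)

    def test_activated_state_parameters(self, protomer):
        b = protomer.coords @ _rot_z(-178.6).T + [0, 0, 46.7]
        st = screw_decompose(protomer.coords, b)
        assert st.angle_deg == pytest.approx(-178.6, abs=1e-6)
        assert st.translation == pytest.approx(46.7, abs=1e-6)

    def test_collinear_errors(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            screw_decompose(line, line + [0, 0, 1.0])


class TestRecovery:
    @pytest.mark.parametrize("twist,rise", [(-108.0, 51.0), (-178.6, 46.7)])
    def test_noiseless_round_trip(self, protomer, twist, rise):
        fil = apply_helical_symmetry(protomer, HelicalParams(twist, rise), 5)
        rec, transforms = recover_helical_params(fil)
        assert rec.twist == pytest.approx(twist, abs=1e-6)
        assert rec.rise == pytest.approx(rise, abs=1e-6)
        assert max(t.rmsd for t in transforms) < 1e-9

    def test_noise_robustness(self, protomer):
        rng = np.random.default_rng(7)
        fil = apply_helical_symmetry(protomer, HelicalParams(-108, 51), 5)
        for _ in range(20):
            noisy = StructureModel(
                fil.coords + rng.normal(0, 0.5, fil.coords.shape),
                fil.elements, fil.chains, fil.unit_index,
            )
            rec, _ = recover_helical_params(noisy)
            assert rec.twist == pytest.approx(-108, abs=0.5)
            assert rec.rise == pytest.approx(51, abs=0.5)

    def test_composition_over_unit_gaps(self, protomer):
        # pair (0, k) must recover k*twist wrapped to (-180, 180] and k*rise
        fil = apply_helical_symmetry(protomer, HelicalParams(-108, 51), 5)
        rec, _ = recover_helical_params(fil, pairs=[(0, 3)])
        wrapped = ((-108 * 3 + 180) % 360) - 180  # -324 -> 36
        assert rec.twist == pytest.approx(wrapped, abs=1e-6)
        assert rec.rise == pytest.approx(153, abs=1e-6)

    def test_mismatched_units_error(self, protomer):
        fil = apply_helical_symmetry(protomer, HelicalParams(-108, 51), 3)
        bad = StructureModel(
            np.vstack([fil.coords, [[0.0, 0.0, 0.0]]]),
            np.append(fil.elements, "C"),
            np.append(fil.chains, "X"),
            np.append(fil.unit_index, 2),
        )
        with pytest.raises(ValueError, match="atom"):
            recover_helical_params(bad)


class TestDimersPerTurn:
    @pytest.mark.parametrize(
        "twist,exact,nearest",
        [(-108.0, 3.3333, 3), (-178.6, 2.0157, 2), (-120.0, 3.0, 3)],
    )
    def test_values(self, twist, exact, nearest):
        units, n = dimers_per_turn(twist)
        assert units == pytest.approx(exact, abs=1e-3)
        assert n == nearest

    def test_zero_twist_errors(self):
        with pytest.raises(ValueError):
            dimers_per_turn(0.0)


def analytic_two_sphere_bsa(r1, r2, d, probe=1.4):
    """Closed-form buried area of two overlapping solvent-expanded spheres."""
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 0.0
    h1 = R1 - (d * d + R1 * R1 - R2 * R2) / (2 * d)
    h2 = R2 - (d * d + R2 * R2 - R1 * R1) / (2 * d)
    return 2 * np.pi * (R1 * h1 + R2 * h2)


class TestSASA:
    def test_isolated_atom_full_sphere(self):
        m = StructureModel(np.zeros((1, 3)), np.array(["C"]))
        assert shrake_rupley_sasa(m) == pytest.approx(
            4 * np.pi * (1.70 + 1.4) ** 2, rel=1e-12
        )

    def test_distant_atoms_bury_nothing(self):
        a = StructureModel(np.zeros((1, 3)))
        b = StructureModel(np.array([[0, 0, 100.0]]))
        assert buried_interface_area(a, b) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("d", [2.0, 3.0, 4.5])
    def test_two_sphere_analytic_oracle(self, d):
        a = StructureModel(np.zeros((1, 3)), np.array(["C"]))
        b = StructureModel(np.array([[0, 0, d]]), np.array(["N"]))
        exact = analytic_two_sphere_bsa(1.70, 1.55, d)
        assert buried_interface_area(a, b) == pytest.approx(exact, rel=0.02)

    def test_symmetry_and_additivity_bound(self, rng):
        for _ in range(5):
            a = StructureModel(rng.uniform(-3, 3, (4, 3)))
            b = StructureModel(rng.uniform(-3, 3, (4, 3)) + [2.0, 0, 0])
            ab = buried_interface_area(a, b)
            ba = buried_interface_area(b, a)
            assert ab == pytest.approx(ba, abs=1e-9)
            union = StructureModel(np.vstack([a.coords, b.coords]))
            assert shrake_rupley_sasa(union) <= (
                shrake_rupley_sasa(a) + shrake_rupley_sasa(b) + 1e-9
            )

    def test_empty_part_errors(self, protomer):
        with pytest.raises(ValueError):
            buried_interface_area(
                StructureModel(np.empty((0, 3))), protomer
            )


class TestStructureIO:
    def test_pdb_round_trip(self, tmp_path, protomer):
        fil = apply_helical_symmetry(protomer, HelicalParams(-108, 51), 2)
        path = tmp_path / "fil.pdb"
        write_pdb(fil, path)
        back = read_structure(path)
        assert len(back) == len(fil)
        # PDB format stores 3 decimals
        np.testing.assert_allclose(
            np.sort(back.coords, axis=0), np.sort(fil.coords, axis=0), atol=2e-3
        )

    def test_units_from_chain_groups(self, protomer):
        fil = apply_helical_symmetry(protomer, HelicalParams(-120, 50), 3)
        regrouped = units_from_chain_groups(
            StructureModel(fil.coords, fil.elements, fil.chains),
            [["A0"], ["A1"], ["A2"]],
        )
        rec, _ = recover_helical_params(regrouped)
        assert rec.twist == pytest.approx(-120, abs=1e-6)
        assert rec.rise == pytest.approx(50, abs=1e-6)


class TestToyProtomer:
    def test_distinct_distances_and_centred(self):
        p = make_toy_protomer(3, 5.0, seed=1)
        d = np.linalg.norm(p.coords[:, None] - p.coords[None, :], axis=-1)
        pair = np.sort(d[np.triu_indices(3, 1)])
        assert np.all(np.diff(pair) > 0)
        np.testing.assert_allclose(p.coords.mean(axis=0), 0.0, atol=1e-9)

    def test_seeding_contract(self):
        a = make_toy_protomer(50, 10.0, seed=2)
        b = make_toy_protomer(50, 10.0, seed=2)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_too_few_atoms(self):
        with pytest.raises(ValueError):
            make_toy_protomer(2, 5.0, seed=0)
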