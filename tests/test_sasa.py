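"""SASA quadrature, buried areas, and the desolvation surrogate."""

from __future__ import annotations

import math

import numpy as np
import pytest

from dockface import (DimerComplex, compute_sasa, delta_asa, per_residue_asa,
                      rigid_transform, solvation_delta_g, sphere_points)
from dockface.sasa import (RadiiTable, atom_delta_asa, default_radii,
                           default_solvation)
from dockface.structure import AtomRecord, coords_of


def _atom(serial, name, res, chain, seq, x, y, z, element=None):
    return AtomRecord(serial, name, element or name[0], "", res, chain,
                      seq, "", float(x), float(y), float(z))


class TestSpherePoints:
    def test_single_point_is_unit(self):
        p = sphere_points(1)
        assert p.shape == (1, 3)
        assert np.linalg.norm(p[0]) == pytest.approx(1.0, abs=1e-12)

    def test_all_norms_unit(self):
        p = sphere_points(960)
        np.testing.assert_allclose(np.linalg.norm(p, axis=1), 1.0,
                                   atol=1e-12)

    def test_near_uniform_coverage(self):
        # centroid of a uniform spherical point set is the origin
        assert np.linalg.norm(sphere_points(960).mean(axis=0)) < 0.02

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            sphere_points(0)


class TestComputeSasa:
    def test_isolated_atom_matches_analytic_sphere(self):
        atoms = [_atom(1, "CA", "ALA", "A", 1, 0, 0, 0)]
        radii = RadiiTable({}, {"C": 1.7})
        res = compute_sasa(atoms, radii, probe=1.4, n_points=4000)
        analytic = 4.0 * math.pi * 3.1 ** 2   # ~120.76 A^2
        assert res.total == pytest.approx(analytic, rel=5e-3)
        assert res.total == pytest.approx(120.76, rel=5e-3)

    def test_distant_atoms_are_additive(self):
        radii = RadiiTable({}, {"C": 1.7})
        one = compute_sasa([_atom(1, "CA", "ALA", "A", 1, 0, 0, 0)], radii)
        both = compute_sasa([_atom(1, "CA", "ALA", "A", 1, 0, 0, 0),
                             _atom(2, "CA", "ALA", "A", 2, 100, 0, 0)],
                            radii)
        assert both.total == pytest.approx(2 * one.total, abs=1e-9)

    def test_two_sphere_overlap_matches_spherical_caps(self):
        # analytic exposed area of two intersecting spheres R1, R2 at
        # centre distance d: each sphere loses the cap beyond the radical
        # plane at x_i = (d^2 + R_i^2 - R_j^2) / 2d from its own centre
        R1 = R2 = 1.7 + 1.4
        d = 3.0
        x1 = (d * d + R1 * R1 - R2 * R2) / (2 * d)
        analytic = 2 * (4 * math.pi * R1 ** 2
                        - 2 * math.pi * R1 * (R1 - x1))
        atoms = [_atom(1, "CA", "ALA", "A", 1, 0, 0, 0),
                 _atom(2, "CA", "ALA", "A", 2, d, 0, 0)]
        res = compute_sasa(atoms, RadiiTable({}, {"C": 1.7}),
                           n_points=2000)
        assert res.total == pytest.approx(analytic, rel=0.02)

    def test_total_is_sum_of_atom_areas(self, toy30):
        res = compute_sasa(toy30.atoms)
        assert res.total == pytest.approx(float(res.atom_area.sum()),
                                          abs=1e-6)

    def test_translation_invariance_exact(self, toy30):
        base = compute_sasa(toy30.atoms, n_points=240)
        moved = rigid_transform(toy30.atoms, np.eye(3),
                                np.array([11.0, -7.0, 3.0]))
        res = compute_sasa(moved, n_points=240)
        np.testing.assert_allclose(res.atom_area, base.atom_area,
                                   atol=1e-6)

    def test_rotation_invariance_within_quadrature_error(self, toy30):
        # the fixed space-frame point set makes rotation invariance hold
        # only to quadrature accuracy, not exactly
        base = compute_sasa(toy30.atoms, n_points=960)
        c, s = np.cos(0.7), np.sin(0.7)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        res = compute_sasa(rigid_transform(toy30.atoms, R, np.zeros(3)),
                           n_points=960)
        assert res.total == pytest.approx(base.total, rel=0.01)

    def test_convergence_with_point_count(self):
        atoms = [_atom(1, "CA", "ALA", "A", 1, 0, 0, 0)]
        radii = RadiiTable({}, {"C": 1.7})
        analytic = 4 * math.pi * 3.1 ** 2
        err = [abs(compute_sasa(atoms, radii, n_points=n).total - analytic)
               / analytic for n in (100, 4000)]
        assert err[1] < 5e-3 and err[1] <= err[0]


class TestPerResidue:
    def test_partition_of_total(self, toy30):
        res = compute_sasa(toy30.atoms, n_points=240)
        per = per_residue_asa(res)
        assert sum(per.values()) == pytest.approx(res.total, abs=1e-6)

    def test_matches_manual_regrouping(self):
        atoms = [_atom(1, "N", "GLY", "A", 1, 0, 0, 0),
                 _atom(2, "CA", "GLY", "A", 1, 1.46, 0, 0),
                 _atom(3, "C", "GLY", "A", 1, 2.98, 0, 0),
                 _atom(4, "N", "GLY", "A", 2, 4.3, 0.4, 0),
                 _atom(5, "CA", "GLY", "A", 2, 5.7, 0.4, 0),
                 _atom(6, "C", "GLY", "A", 2, 7.2, 0.4, 0),
                 _atom(7, "N", "GLY", "A", 3, 8.6, 0, 0),
                 _atom(8, "CA", "GLY", "A", 3, 10.0, 0, 0)]
        res = compute_sasa(atoms, n_points=960)
        manual = {}
        for a, area in zip(atoms, res.atom_area):
            manual[a.residue_key] = manual.get(a.residue_key, 0.0) + area
        per = per_residue_asa(res)
        assert set(per) == set(manual)
        for k in per:
            assert per[k] == pytest.approx(manual[k], abs=1e-9)


class TestDeltaAsa:
    def test_separated_chains_bury_nothing(self, toy30):
        far = DimerComplex(
            toy30.receptor,
            rigid_transform(toy30.ligand, np.eye(3),
                            np.array([200.0, 0, 0])))
        bsa = delta_asa(far, n_points=240)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in bsa.values())

    def test_bsa_nonnegative_everywhere(self, toy30):
        bsa = delta_asa(toy30, n_points=240)
        assert min(bsa.values()) >= 0.0
        assert max(bsa.values()) > 1.0  # the interface actually buries area

    def test_only_near_interface_residues_buried(self, toy30):
        from scipy.spatial import cKDTree
        bsa = delta_asa(toy30, n_points=240)
        rtree = cKDTree(coords_of(toy30.receptor))
        ltree = cKDTree(coords_of(toy30.ligand))
        for key, buried in bsa.items():
            if buried <= 0:
                continue
            own = [a for a in toy30.atoms if a.residue_key == key]
            other = ltree if key.chain_id == toy30.receptor_chain_id \
                else rtree
            dmin = min(other.query(a.coord)[0] for a in own)
            assert dmin < 15.0

    def test_matches_high_resolution_independent_sasa(self, toy30):
        # brute-force SASA re-coded without the package's neighbour logic
        def brute_sasa(atoms, n_points=4000, probe=1.4):
            radii = default_radii()
            xyz = coords_of(atoms)
            r = np.array([radii.radius(a) for a in atoms]) + probe
            i_pts = np.arange(n_points)
            z = 1 - 2 * (i_pts + 0.5) / n_points
            rho = np.sqrt(1 - z * z)
            th = math.pi * (3 - math.sqrt(5)) * i_pts
            unit = np.column_stack([rho * np.cos(th), rho * np.sin(th), z])
            out = np.empty(len(atoms))
            for i in range(len(atoms)):
                pts = xyz[i] + r[i] * unit
                exposed = np.ones(n_points, bool)
                for j in range(len(atoms)):
                    if j == i:
                        continue
                    exposed &= np.sum((pts - xyz[j]) ** 2, 1) >= r[j] ** 2
                out[i] = exposed.mean() * 4 * math.pi * r[i] ** 2
            return out

        sub_r = toy30.receptor[:40]
        sub_l = [a for a in toy30.ligand][:40]
        dimer = DimerComplex(sub_r, sub_l)
        mine, _, _, _ = atom_delta_asa(dimer, n_points=4000)
        ref = np.concatenate([brute_sasa(sub_r), brute_sasa(sub_l)]) \
            - brute_sasa(dimer.atoms)
        scale = max(ref.max(), 1.0)
        assert np.max(np.abs(mine - ref)) / scale < 0.03


class TestSolvationDeltaG:
    def test_zero_when_nothing_buried(self, toy30):
        far = DimerComplex(
            toy30.receptor,
            rigid_transform(toy30.ligand, np.eye(3),
                            np.array([300.0, 0, 0])))
        assert solvation_delta_g(far, n_points=240) == pytest.approx(0.0,
                                                                     abs=1e-9)

    def test_single_carbon_arithmetic(self, toy30):
        # one buried apolar carbon with dASA = 10 A^2 at sigma_C = 0.016
        delta = np.zeros(len(toy30.atoms))
        carbon = next(i for i, a in enumerate(toy30.atoms)
                      if a.atom_name == "CB")
        delta[carbon] = 10.0
        dg = solvation_delta_g(toy30, precomputed_delta=delta)
        assert dg == pytest.approx(-0.16, abs=1e-12)

    def test_matches_hand_summed_per_atom_table(self, toy30):
        from dockface.sasa import atom_solvation_class
        delta, _, _, _ = atom_delta_asa(toy30, n_points=240)
        sigma = default_solvation().sigma
        hand = -sum(sigma[atom_solvation_class(a)] * d
                    for a, d in zip(toy30.atoms, delta))
        assert solvation_delta_g(toy30, precomputed_delta=delta) == \
            pytest.approx(hand, abs=1e-9)

    def test_native_interface_is_stabilising(self, toy30):
        assert solvation_delta_g(toy30, n_points=240) < 0.0


class TestTables:
    def test_radii_in_plausible_range(self):
        t = default_radii()
        assert all(0.5 < r < 3.0 for r in t.by_element.values())
        with pytest.raises(ValueError):
            RadiiTable({}, {"C": 4.5})

    def test_carbon_sigma_positive_enforced(self):
        from dockface.sasa import SolvationParams
        with pytest.raises(ValueError):
            SolvationParams({"C": -0.01})
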