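"""Force-field terms, binding-energy flavors and the two-round minimizer."""
import copy
import warnings

import numpy as np
import pytest

from pepforge.energetics import (FLAVORS, EnergyBreakdown, System,
                                 TypedAtom, binding_energy, default_params,
                                 energy_breakdown, minimize_complex,
                                 movable_mask, nonbonded_energy,
                                 solvation_energy, type_residues)
from pepforge.structures import ComplexStructure, build_ideal_helix

from conftest import random_rotation, transform_complex


def _atom(tname, q, xyz):
    return TypedAtom(tname, q, np.asarray(xyz, float))


class TestNonbonded:
    def test_lj_minimum_depth(self):
        p = default_params()
        rmin = 2 * p.types["CT"].rmin_half
        e = nonbonded_energy([_atom("CT", 0, (0, 0, 0))],
                             [_atom("CT", 0, (rmin, 0, 0))], p)
        assert e.vdw == pytest.approx(-p.types["CT"].epsilon, abs=1e-9)
        assert e.coulomb == 0.0

    def test_screened_coulomb_at_3A(self):
        # k q1 q2 / (4 d^2) with the 4d distance-dependent dielectric
        e = nonbonded_energy([_atom("CT", 1.0, (0, 0, 0))],
                             [_atom("CT", -1.0, (3.0, 0, 0))])
        assert e.coulomb == pytest.approx(-332.0636 / 36.0, abs=1e-3)

    def test_distant_groups_negligible(self, separated_complex):
        p = default_params()
        rec = type_residues(separated_complex.receptor, p)
        pep = type_residues(separated_complex.peptide, p, capped=True)
        assert abs(nonbonded_energy(rec, pep, p).total) < 0.01

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(5)
        a = [_atom("CT", 0.3, rng.normal(size=3) * 3) for _ in range(4)]
        b = [_atom("O", -0.3, rng.normal(size=3) * 3 + 6) for _ in range(3)]
        assert nonbonded_energy(a, b).total \
            == pytest.approx(nonbonded_energy(b, a).total, abs=1e-9)

    def test_unparameterized_type_raises(self):
        with pytest.raises(KeyError):
            nonbonded_energy([_atom("ZZ", 0, (0, 0, 0))],
                             [_atom("CT", 0, (3, 0, 0))])


class TestBreakdown:
    def test_total_is_exact_component_sum(self):
        bd = EnergyBreakdown(vdw=1.25, coulomb=-3.5, solvation=0.75,
                             nonpolar_sasa=-0.25)
        assert bd.total == pytest.approx(1.25 - 3.5 + 0.75 - 0.25, abs=1e-12)

    def test_breakdown_matches_binding_energy(self, toy_hb2_sb1):
        for flavor in ("simple", "neutralized", "solvated"):
            assert energy_breakdown(toy_hb2_sb1, flavor).total \
                == pytest.approx(binding_energy(toy_hb2_sb1, flavor),
                                 abs=1e-6)


class TestSolvation:
    def test_isolated_atom_contributes_reference_energy(self):
        p = default_params()
        for t in ("CT", "O", "N3"):
            assert solvation_energy([_atom(t, 0, (0, 0, 0))], p) \
                == pytest.approx(p.types[t].dg_ref, abs=1e-12)

    def test_caged_atom_matches_direct_summation_oracle(self):
        p = default_params()
        center = _atom("O", 0, (0, 0, 0))
        cage = [_atom("CT", 0, c) for c in
                3.0 * np.array([[x, y, z] for x in (-1, 0, 1)
                                for y in (-1, 0, 1) for z in (-1, 0, 1)
                                if (x, y, z) != (0, 0, 0)], float)]
        got = solvation_energy([center] + cage, p)
        # independent direct pairwise summation of the Gaussian-exclusion
        # model, written without the vectorized machinery
        atoms = [center] + cage
        want = 0.0
        for i, ai in enumerate(atoms):
            ti = p.types[ai.type_name]
            s = ti.dg_ref
            for j, aj in enumerate(atoms):
                if i == j:
                    continue
                tj = p.types[aj.type_name]
                r = float(np.linalg.norm(ai.coords - aj.coords))
                x = (r - ti.rmin_half) / ti.lam
                s -= (ti.dg_ref / (2 * np.sqrt(np.pi) * ti.lam * r * r)
                      * np.exp(-x * x)) * tj.volume
            want += s
        assert got == pytest.approx(want, abs=1e-9)

    def test_rigid_motion_invariance(self, toy_hb2_sb1):
        p = default_params()
        atoms = type_residues(toy_hb2_sb1.receptor, p) \
            + type_residues(toy_hb2_sb1.peptide, p)
        e0 = solvation_energy(atoms, p)
        rng = np.random.default_rng(8)
        rot = random_rotation(rng)
        shift = rng.normal(size=3) * 20
        moved = [TypedAtom(a.type_name, a.charge, rot @ a.coords + shift)
                 for a in atoms]
        assert solvation_energy(moved, p) == pytest.approx(e0, abs=1e-8)


class TestBindingFlavors:
    def test_separated_components_score_zero(self, separated_complex):
        assert abs(binding_energy(separated_complex, "simple")) < 0.01

    def test_strain_penalty_is_non_negative(self, posed_complex,
                                            toy_hb2_sb1):
        for cs in (posed_complex, toy_hb2_sb1):
            assert binding_energy(cs, "strain") \
                >= binding_energy(cs, "simple") - 1e-9

    def test_neutralization_weakens_salt_bridge_complex(
            self, toy_saltbridge_only):
        simple = binding_energy(toy_saltbridge_only, "simple")
        neutral = binding_energy(toy_saltbridge_only, "neutralized")
        assert abs(neutral) < abs(simple)

    def test_rigid_motion_invariance(self, toy_hb2_sb1):
        rng = np.random.default_rng(2)
        moved = transform_complex(toy_hb2_sb1, random_rotation(rng),
                                  rng.normal(size=3) * 15)
        # the solvated flavor includes the sphere-point SASA term (rotation
        # invariant only to discretization accuracy) and the strain flavor
        # an iterative inner minimization (path-dependent stopping point)
        tols = {"simple": dict(abs=1e-5), "neutralized": dict(abs=1e-5),
                "strain": dict(abs=0.05), "solvated": dict(rel=0.01)}
        for flavor in FLAVORS:
            assert binding_energy(moved, flavor) == pytest.approx(
                binding_energy(toy_hb2_sb1, flavor), **tols[flavor])

    def test_unknown_flavor_rejected(self, toy_hb2_sb1):
        with pytest.raises(ValueError, match="unknown flavor"):
            binding_energy(toy_hb2_sb1, "exotic")


@pytest.fixture(scope="module")
def clashed_complex():
    """Close contact between two short helices: relaxation must help."""
    pep = build_ideal_helix("AWA", chain_id="B", capped=True)
    rec = build_ideal_helix("LFL", chain_id="A", capped=True)
    for r in rec:
        for a in r.atoms:
            a.coords = a.coords + np.array([0.0, 5.5, 0.0])
    return ComplexStructure(receptor=rec, peptide=pep, peptide_capped=True)


class TestMinimizer:
    def test_energy_non_increasing_per_round(self, clashed_complex):
        cs = copy.deepcopy(clashed_complex)
        energies = [System(cs).energy(System(cs).xyz)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for stage in ("round1", "round2"):
                cs = minimize_complex(cs, protocol=(stage,), max_iter=150)
                s = System(cs)
                energies.append(s.energy(s.xyz))
        assert energies[1] <= energies[0] + 1e-9
        assert energies[2] <= energies[1] + 1e-9

    def test_round1_freezes_backbone_and_distant_side_chains(
            self, clashed_complex):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = minimize_complex(clashed_complex, protocol=("round1",),
                                   max_iter=100)
        bb = ("N", "CA", "C", "O", "OXT")
        for before, after in zip(clashed_complex.receptor +
                                 clashed_complex.peptide,
                                 out.receptor + out.peptide):
            for a0, a1 in zip(before.atoms, after.atoms):
                if a0.name in bb:
                    assert np.allclose(a0.coords, a1.coords, atol=1e-9)
        # a receptor side chain > 4 A from the peptide must not move
        sys0 = System(clashed_complex)
        mask = movable_mask(sys0, "round1")
        pep_xyz = np.array([a.coords for r in clashed_complex.peptide
                            for a in r.atoms])
        for r in clashed_complex.receptor:
            side = [a for a in r.atoms if a.name not in bb]
            if not side:
                continue
            dmin = min(np.linalg.norm(pep_xyz - a.coords, axis=1).min()
                       for a in side)
            idxs = [sys0.key_to_idx[(a.chain_id, a.residue_index, a.name)]
                    for a in side]
            if dmin >= 4.0:
                assert not mask[idxs].any()

    def test_round2_fixes_entire_receptor(self, clashed_complex):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = minimize_complex(clashed_complex, protocol=("round2",),
                                   max_iter=100)
        for before, after in zip(clashed_complex.receptor, out.receptor):
            for a0, a1 in zip(before.atoms, after.atoms):
                assert np.allclose(a0.coords, a1.coords, atol=1e-9)

    def test_local_minimum_left_unchanged(self, separated_complex):
        """Once the peptide is relaxed to the gradient criterion the
        protocol is a no-op (with a distant receptor, round 1's movable
        set is a subset of round 2's, so one pass reaches a joint
        stationary point)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            relaxed = minimize_complex(separated_complex)
            again = minimize_complex(relaxed)
        s1, s2 = System(relaxed), System(again)
        assert abs(s2.energy(s2.xyz) - s1.energy(s1.xyz)) < 1e-6
        assert np.abs(s2.xyz - s1.xyz).max() < 1e-9
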