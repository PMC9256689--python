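"""Morse/LJ pair energies and CG cluster potentials."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from cgdamage.potential import (
    BondParams,
    alpha_from_force_constant,
    cluster_potential,
    enumerate_pairs,
    lj_energy,
    load_bond_params,
    morse_energy,
)

from conftest import TemplateAtom


@pytest.mark.parametrize(
    "k_e,d_e,expected",
    [
        (5e5, 3.61, 2.08),  # C-C
        (5e5, 3.73, 2.05),  # C-O
        (5e5, 1.50, 3.23),  # O-O
        (5e5, 3.47, 2.12),  # P-O
        (10e5, 5.64, 2.35),  # P=O
    ],
)
def test_alpha_reproduces_parameter_table(k_e, d_e, expected):
    """The Morse width recomputed from (k_e, D_e) matches the tabulated
    values to 3 significant figures."""
    alpha = alpha_from_force_constant(k_e, d_e)
    assert float(f"{alpha:.3g}") == pytest.approx(expected)


def test_alpha_scaling_law():
    """Doubling k_e scales alpha by sqrt(2)."""
    a1 = alpha_from_force_constant(5e5, 3.61)
    a2 = alpha_from_force_constant(10e5, 3.61)
    assert a2 == pytest.approx(math.sqrt(2) * a1, rel=1e-12)


@pytest.mark.parametrize("bad", [(0, 1.0), (-1.0, 1.0), (1.0, 0), (1.0, -2.0)])
def test_alpha_rejects_nonpositive(bad):
    with pytest.raises(ValueError):
        alpha_from_force_constant(*bad)


class TestMorse:
    def test_well_minimum_is_minus_de(self, bond_params):
        for p in bond_params.values():
            assert morse_energy(p.r_e, p) == pytest.approx(-p.d_e, rel=1e-12)

    @pytest.mark.parametrize(
        "r,pair,expected",
        [(1.480, "P-O", -2.9038), (1.482, "P=O", -5.6294), (1.598, "P-O", -3.4399)],
    )
    def test_reference_bond_energies(self, bond_params, r, pair, expected):
        assert morse_energy(r, bond_params[pair]) == pytest.approx(expected, abs=5e-4)

    def test_limits(self, bond_params):
        p = bond_params["C-C"]
        assert morse_energy(100.0, p) == pytest.approx(0.0, abs=1e-12)
        assert morse_energy(0.5 * p.r_e, p) > 0  # repulsive wall

    def test_rejects_nonpositive_distance(self, bond_params):
        with pytest.raises(ValueError):
            morse_energy(0.0, bond_params["C-C"])


class TestLennardJones:
    def test_zero_at_sigma(self, bond_params):
        for p in bond_params.values():
            assert lj_energy(p.sigma, p) == pytest.approx(0.0, abs=1e-12)

    def test_minimum_at_re(self, bond_params):
        """The LJ minimum sits at r_e = 2^(1/6) sigma with depth -D_e."""
        p = bond_params["O-O"]
        assert lj_energy(p.r_e, p) == pytest.approx(-p.d_e, rel=1e-12)
        res = minimize_scalar(lambda r: lj_energy(r, p), bounds=(0.8, 3.0), method="bounded")
        assert res.x == pytest.approx(p.r_e, abs=1e-6)

    @pytest.mark.parametrize(
        "r,expected", [(2.520, -0.1206), (2.506, -0.1246), (2.463, -0.1379)]
    )
    def test_reference_oo_energies(self, bond_params, r, expected):
        assert lj_energy(r, bond_params["O-O"]) == pytest.approx(expected, abs=2e-4)


class TestEnumeratePairs:
    def test_phosphate_pair_structure(self, template_atoms):
        atoms = [template_atoms[n] for n in ("P", "OP1", "OP2", "O5'")]
        bonded, nonbonded = enumerate_pairs(atoms)
        bset = {frozenset({a.name, b.name}) for a, b, _ in bonded}
        nset = {frozenset({a.name, b.name}) for a, b, _ in nonbonded}
        assert bset == {
            frozenset({"P", "OP1"}),
            frozenset({"P", "OP2"}),
            frozenset({"P", "O5'"}),
        }
        assert nset == {
            frozenset({"OP1", "OP2"}),
            frozenset({"OP1", "O5'"}),
            frozenset({"OP2", "O5'"}),
        }
        assert all(pt == "O-O" for _, _, pt in nonbonded)

    def test_single_atom_has_no_pairs(self, template_atoms):
        bonded, nonbonded = enumerate_pairs([template_atoms["P"]])
        assert bonded == [] and nonbonded == []

    def test_sugar_includes_phosphodiester_boundary_bonds(self, template_atoms):
        sugar = [template_atoms[n] for n in ("C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O3'")]
        bonded, _ = enumerate_pairs(sugar, boundary_atoms=[template_atoms["O5'"]])
        bset = {frozenset({a.name, b.name}) for a, b, _ in bonded}
        assert frozenset({"C3'", "O3'"}) in bset
        assert frozenset({"C5'", "O5'"}) in bset

    def test_unknown_atom_name_raises(self):
        with pytest.raises(ValueError, match="XX"):
            enumerate_pairs([TemplateAtom("P", [0, 0, 0]), TemplateAtom("XX", [1, 0, 0])])


class TestClusterPotential:
    def test_phosphate_worked_example(self, template_atoms, bond_params):
        """Phosphate cluster at the reference geometry: threshold 12.4 eV."""
        atoms = [template_atoms[n] for n in ("P", "OP1", "OP2", "O5'")]
        cp = cluster_potential(atoms, bond_params)
        assert cp.u_total == pytest.approx(-12.3562, abs=5e-4)
        assert round(cp.threshold, 1) == 12.4

    def test_empty_cluster(self, bond_params):
        cp = cluster_potential([], bond_params)
        assert cp.u_total == 0.0

    def test_matches_brute_force_double_loop(self, template_atoms, bond_params):
        """Cluster sum equals an independent O(N^2) evaluation that applies
        the Morse/LJ formulas directly."""
        from cgdamage.potential import BACKBONE_BONDS, ELEMENT_PAIR_TYPE

        names = ("C1'", "C2'", "C3'", "O3'")
        atoms = [template_atoms[n] for n in names]
        expected = 0.0
        for i in range(len(atoms)):
            for j in range(i + 1, len(atoms)):
                a, b = atoms[i], atoms[j]
                r = float(np.linalg.norm(a.position - b.position))
                key = frozenset({a.name, b.name})
                if key in BACKBONE_BONDS:
                    p = bond_params[BACKBONE_BONDS[key]]
                    al = math.sqrt(p.k_e * 1e-3 / (2 * p.d_e * 1.602176634e-19)) * 1e-10
                    x = math.exp(-al * (r - p.r_e))
                    expected += p.d_e * (x * x - 2 * x)
                else:
                    p = bond_params[ELEMENT_PAIR_TYPE[frozenset({a.element, b.element})]]
                    s = p.r_e / 2 ** (1 / 6)
                    expected += 4 * p.d_e * ((s / r) ** 12 - (s / r) ** 6)
        cp = cluster_potential(atoms, bond_params)
        assert cp.u_total == pytest.approx(expected, rel=1e-12)

    def test_missing_pair_type_raises(self, template_atoms):
        partial = {"C-C": BondParams("C-C", 1.54, 3.61)}
        atoms = [template_atoms[n] for n in ("C1'", "O4'")]
        with pytest.raises(KeyError, match="C-O"):
            cluster_potential(atoms, partial)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_motion_invariance(self, template_atoms, bond_params, seed):
        """U_total is unchanged by rotating + translating the cluster."""
        from scipy.spatial.transform import Rotation

        names = ("P", "OP1", "OP2", "O5'")
        atoms = [template_atoms[n] for n in names]
        ref = cluster_potential(atoms, bond_params).u_total
        rng = np.random.default_rng(seed)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(scale=20.0, size=3)
        moved = [
            TemplateAtom(n, rot @ template_atoms[n].position + shift) for n in names
        ]
        assert cluster_potential(moved, bond_params).u_total == pytest.approx(ref, abs=1e-9)

    def test_sugar_threshold_near_reference(self, template_atoms, bond_params):
        """Deoxyribose cluster (with both phosphodiester boundary bonds)
        lands within 10% of the 30.5 eV reference threshold."""
        sugar = [template_atoms[n] for n in ("C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O3'")]
        cp = cluster_potential(sugar, bond_params, boundary_atoms=[template_atoms["O5'"]])
        assert cp.threshold == pytest.approx(30.5, rel=0.10)
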