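"""Pair potentials and coarse-grained cluster threshold energies.

A coarse-grained (CG) bead replaces a covalently bonded atomic cluster
(e.g. the PO3 phosphate group of a nucleotide).  Its damage threshold is
taken as the magnitude of the cluster's total pair-potential energy

    U_total = sum_bonded U_Morse(r) + sum_nonbonded U_LJ(r)

where bonded pairs interact through a Morse well

    U_1(r) = D_e [ exp(-2 a (r - r_e)) - 2 exp(-a (r - r_e)) ],
    a = sqrt(k_e / (2 D_e)),

and non-bonded pairs through a 12-6 Lennard-Jones potential

    U_4(r) = 4 D_e [ (s/r)^12 - (s/r)^6 ],   s = r_e / 2^(1/6).

Three-body (angle) and four-body (torsion) terms are omitted; for the
backbone clusters considered here they contribute less than ~10% of the
total and the pairwise sum already brackets the threshold range used by
published track-structure damage models.

Bond parameters (r_e, D_e, bond order) ship as an editable CSV.  The Morse
width ``a`` is always recomputed from the bond-order force constant
(5/10/15 x 10^5 dyn/cm for single/double/triple bonds) rather than read
from a rounded table column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EV_TO_J = 1.602176634e-19
DYN_PER_CM_TO_N_PER_M = 1e-3

#: force constant of the well minimum by bond order, dyn/cm
FORCE_CONSTANT_DYN_CM = {"single": 5e5, "double": 10e5, "triple": 15e5}


def alpha_from_force_constant(k_e_dyn_cm: float, d_e_ev: float) -> float:
    """Morse width parameter ``a = sqrt(k_e / 2 D_e)`` in 1/Angstrom.

    Parameters
    ----------
    k_e_dyn_cm : force constant at the well minimum, dyn/cm.
    d_e_ev : well depth (dissociation energy), eV.
    """
    if k_e_dyn_cm <= 0 or d_e_ev <= 0:
        raise ValueError("k_e and D_e must be positive")
    k_si = k_e_dyn_cm * DYN_PER_CM_TO_N_PER_M  # N/m
    d_si = d_e_ev * EV_TO_J  # J
    alpha_per_m = math.sqrt(k_si / (2.0 * d_si))
    return alpha_per_m * 1e-10


@dataclass(frozen=True)
class BondParams:
    """One row of the pair-potential parameter table."""

    pair_type: str
    r_e: float  # equilibrium distance, Angstrom
    d_e: float  # well depth, eV
    bond_order: str = "single"

    @property
    def k_e(self) -> float:
        """Force constant, dyn/cm, set by the bond order."""
        return FORCE_CONSTANT_DYN_CM[self.bond_order]

    @property
    def alpha(self) -> float:
        """Morse width, 1/Angstrom, recomputed from k_e and D_e."""
        return alpha_from_force_constant(self.k_e, self.d_e)

    @property
    def sigma(self) -> float:
        """LJ zero-crossing distance, Angstrom."""
        return self.r_e / 2.0 ** (1.0 / 6.0)


def load_bond_params(path: str | Path | None = None) -> dict[str, BondParams]:
    """Load the bond-parameter table (shipped CSV by default)."""
    if path is None:
        src = resources.files("cgdamage.data").joinpath("bond_params.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    table = {}
    for row in df.itertuples(index=False):
        table[row.pair_type] = BondParams(
            pair_type=row.pair_type,
            r_e=float(row.r_e_angstrom),
            d_e=float(row.d_e_ev),
            bond_order=str(row.bond_order),
        )
    return table


def morse_energy(r: float, params: BondParams) -> float:
    """Morse pair energy U_1(r) in eV; U_1(r_e) = -D_e."""
    if r <= 0:
        raise ValueError("distance must be positive")
    a = params.alpha
    x = math.exp(-a * (r - params.r_e))
    return params.d_e * (x * x - 2.0 * x)


def lj_energy(r: float, params: BondParams) -> float:
    """Lennard-Jones 12-6 pair energy U_4(r) in eV; minimum -D_e at r_e."""
    if r <= 0:
        raise ValueError("distance must be positive")
    s6 = (params.sigma / r) ** 6
    return 4.0 * params.d_e * (s6 * s6 - s6)


# ---------------------------------------------------------------------------
# Nucleotide backbone connectivity
# ---------------------------------------------------------------------------

#: covalent bonds of the nucleotide backbone (heavy atoms), mapped to the
#: parameter-table row that describes each bond
BACKBONE_BONDS: dict[frozenset[str], str] = {
    frozenset({"P", "OP1"}): "P-O",
    frozenset({"P", "OP2"}): "P=O",
    frozenset({"P", "O5'"}): "P-O",
    frozenset({"C5'", "O5'"}): "C-O",
    frozenset({"C4'", "C5'"}): "C-C",
    frozenset({"C3'", "C4'"}): "C-C",
    frozenset({"C2'", "C3'"}): "C-C",
    frozenset({"C1'", "C2'"}): "C-C",
    frozenset({"C4'", "O4'"}): "C-O",
    frozenset({"C1'", "O4'"}): "C-O",
    frozenset({"C3'", "O3'"}): "C-O",
}

#: atom names the backbone bond graph knows about
KNOWN_BACKBONE_ATOMS = frozenset(n for pair in BACKBONE_BONDS for n in pair)

#: parameter-table row used for a *non-bonded* pair, by element pair
ELEMENT_PAIR_TYPE: dict[frozenset[str], str] = {
    frozenset({"C"}): "C-C",
    frozenset({"C", "O"}): "C-O",
    frozenset({"O"}): "O-O",
    frozenset({"O", "P"}): "P-O",
}


@dataclass(frozen=True)
class PairEnergy:
    atom_a: str
    atom_b: str
    kind: str  # "bonded" | "nonbonded"
    pair_type: str
    distance: float  # Angstrom
    energy: float  # eV


@dataclass
class ClusterPotential:
    pair_energies: list[PairEnergy] = field(default_factory=list)

    @property
    def u_total(self) -> float:
        return sum(p.energy for p in self.pair_energies)

    @property
    def threshold(self) -> float:
        return abs(self.u_total)


def _element_of(name: str) -> str:
    head = name.strip().rstrip("'")
    return head[0].upper()


def enumerate_pairs(
    atoms: Sequence,
    boundary_atoms: Sequence = (),
    bond_graph: dict[frozenset[str], str] = BACKBONE_BONDS,
) -> tuple[list[tuple], list[tuple]]:
    """List the (bonded, nonbonded) atom pairs of one CG cluster.

    ``atoms`` are the cluster members; ``boundary_atoms`` participate only
    through their covalent bond into the cluster (e.g. O5' contributes the
    C5'-O5' bond to the deoxyribose cluster but no LJ pairs).  Pairs are
    returned as ``(atom_a, atom_b, pair_type)``.  Atom objects need ``name``
    and ``element`` attributes.
    """
    for a in list(atoms) + list(boundary_atoms):
        if a.name not in KNOWN_BACKBONE_ATOMS:
            raise ValueError(f"atom {a.name!r} is not in the backbone bond graph")
    core = list(atoms)
    bonded: list[tuple] = []
    nonbonded: list[tuple] = []
    for i, a in enumerate(core):
        for b in core[i + 1 :]:
            key = frozenset({a.name, b.name})
            if key in bond_graph:
                bonded.append((a, b, bond_graph[key]))
            else:
                ekey = frozenset({a.element, b.element})
                if ekey not in ELEMENT_PAIR_TYPE:
                    raise KeyError(
                        f"no non-bonded parameters for element pair {sorted(ekey)}"
                    )
                nonbonded.append((a, b, ELEMENT_PAIR_TYPE[ekey]))
    for bnd in boundary_atoms:
        for a in core:
            key = frozenset({a.name, bnd.name})
            if key in bond_graph:
                bonded.append((a, bnd, bond_graph[key]))
    return bonded, nonbonded


def cluster_potential(
    atoms: Sequence,
    params_table: dict[str, BondParams],
    boundary_atoms: Sequence = (),
    bond_graph: dict[frozenset[str], str] = BACKBONE_BONDS,
) -> ClusterPotential:
    """Total pair-potential energy of a CG cluster.

    Sums the Morse energy over covalent bonds (including designated
    boundary bonds) and the LJ energy over every remaining atom pair
    inside the cluster, each at the observed inter-atomic distance.
    """
    bonded, nonbonded = enumerate_pairs(atoms, boundary_atoms, bond_graph)
    result = ClusterPotential()
    for a, b, ptype in bonded:
        if ptype not in params_table:
            raise KeyError(f"missing bond parameters for pair type {ptype!r}")
        r = float(np.linalg.norm(np.asarray(a.position) - np.asarray(b.position)))
        result.pair_energies.append(
            PairEnergy(a.name, b.name, "bonded", ptype, r, morse_energy(r, params_table[ptype]))
        )
    for a, b, ptype in nonbonded:
        if ptype not in params_table:
            raise KeyError(f"missing bond parameters for pair type {ptype!r}")
        r = float(np.linalg.norm(np.asarray(a.position) - np.asarray(b.position)))
        result.pair_energies.append(
            PairEnergy(a.name, b.name, "nonbonded", ptype, r, lj_energy(r, params_table[ptype]))
        )
    return result
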