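"""Coarse-grained bead construction from atomic DNA models.

Each nucleotide is reduced to three interaction sites: phosphate
(P, OP1, OP2, O5'), deoxyribose (C1'-C5', O4', O3') and base (the rest).
The bridging oxygens are split across the phosphodiester boundary: O5'
belongs to the phosphate cluster, O3' to the deoxyribose cluster, so no
atom is counted twice.  Bead radii come from the van der Waals union
volume of the cluster, r = (3V / 4 pi)^(1/3); thresholds from the
cluster pair potential (see :mod:`cgdamage.potential`).

The energy-scoring radius of a backbone bead is either its VDWR radius
or a fixed 3.4 A hydration-shell radius: the first ordered water layer
around duplex DNA sits within ~3.4 A of the backbone, and charge
transfer from that shell contributes to direct damage, so enlarging the
scoring sphere to 3.4 A is offered as the default mode.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .fixtures import Atom, DnaModel, PHOSPHATE_ATOMS, SUGAR_ATOMS
from .potential import BondParams, ClusterPotential, cluster_potential, load_bond_params

#: Bondi van der Waals radii, A
BONDI_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80}

HYDRATION_RADIUS = 3.4  # A

#: atom names recognized for generic purine/pyrimidine bases
_BASE_NAMES = {
    "N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9",
    "O2", "N2", "O4", "N4", "N6", "O6", "C7",
}
_PHOSPHATE_SET = set(PHOSPHATE_ATOMS)
_SUGAR_SET = set(SUGAR_ATOMS)


@dataclass
class MoietyPartition:
    nucleotide_index: int
    strand: int
    phosphate_atoms: list[Atom]
    sugar_atoms: list[Atom]
    base_atoms: list[Atom]
    has_phosphate: bool = True


@dataclass
class CGBead:
    moiety: str  # "phosphate" | "deoxyribose" | "base"
    center: np.ndarray  # (3,) A
    radius_vdwr: float  # A
    scoring_radius: float  # A
    threshold_energy: float | None  # eV; None for base beads
    nucleotide_index: int
    strand: int
    segment_id: int = 0


def partition_nucleotide(atoms: Sequence[Atom]) -> MoietyPartition:
    """Assign the atoms of one nucleotide to phosphate/sugar/base clusters."""
    keys = {(a.nucleotide_index, a.strand) for a in atoms}
    if len(keys) != 1:
        raise ValueError("atoms must share nucleotide_index and strand")
    idx, strand = next(iter(keys))
    ph, su, ba = [], [], []
    for a in atoms:
        if a.name in _PHOSPHATE_SET:
            ph.append(a)
            a.moiety = "phosphate"
        elif a.name in _SUGAR_SET:
            su.append(a)
            a.moiety = "deoxyribose"
        elif a.name in _BASE_NAMES:
            ba.append(a)
            a.moiety = "base"
        else:
            raise ValueError(f"unrecognized atom name {a.name!r}")
    has_p = any(a.name == "P" for a in ph)
    if not has_p:
        warnings.warn(
            f"nucleotide (strand {strand}, index {idx}) has no 5' phosphate",
            stacklevel=2,
        )
    missing_sugar = _SUGAR_SET - {a.name for a in su}
    if missing_sugar:
        warnings.warn(
            f"nucleotide (strand {strand}, index {idx}) is missing sugar atoms "
            f"{sorted(missing_sugar)}",
            stacklevel=2,
        )
    return MoietyPartition(idx, strand, ph, su, ba, has_phosphate=has_p)


# ---------------------------------------------------------------------------
# Union volumes
# ---------------------------------------------------------------------------


def union_volume(
    atoms: Sequence,
    vdw_radii: dict[str, float] = BONDI_RADII,
    method: str = "monte_carlo",
    samples: int = 200_000,
    spacing: float = 0.05,
    rng_seed: int = 0,
) -> float:
    """Volume (nm^3) of the union of van der Waals spheres of a cluster.

    ``monte_carlo`` rejection-samples the bounding box with the given
    seed; ``grid`` counts voxel centers at the given spacing (A).
    """
    atoms = list(atoms)
    if not atoms:
        raise ValueError("need at least one atom")
    centers = np.array([np.asarray(a.position, dtype=float) for a in atoms])
    radii = np.array([float(vdw_radii[a.element]) for a in atoms])
    if np.any(radii <= 0):
        raise ValueError("van der Waals radii must be positive")
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)
    if method == "monte_carlo":
        rng = np.random.default_rng(rng_seed)
        pts = rng.uniform(lo, hi, size=(int(samples), 3))
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        inside = (d2 <= radii[None, :] ** 2).any(axis=1)
        frac = inside.mean()
        vol_a3 = frac * float(np.prod(hi - lo))
    elif method == "grid":
        axes = [np.arange(lo[k] + spacing / 2, hi[k], spacing) for k in range(3)]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij", sparse=True)
        inside = np.zeros((len(axes[0]), len(axes[1]), len(axes[2])), dtype=bool)
        for c, r in zip(centers, radii):
            inside |= (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2 <= r * r
        vol_a3 = float(inside.sum()) * spacing**3
    else:
        raise ValueError(f"unknown method {method!r}")
    return vol_a3 / 1000.0  # A^3 -> nm^3


def two_sphere_union_volume(r1: float, r2: float, d: float) -> float:
    """Closed-form union volume (same units^3) of two spheres, lens-corrected."""
    v1 = 4.0 / 3.0 * math.pi * r1**3
    v2 = 4.0 / 3.0 * math.pi * r2**3
    if d >= r1 + r2:
        return v1 + v2
    if d <= abs(r1 - r2):
        return max(v1, v2)
    lens = (
        math.pi
        * (r1 + r2 - d) ** 2
        * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
        / (12.0 * d)
    )
    return v1 + v2 - lens


def radius_from_volume(v_nm3: float) -> float:
    """Bead radius (A) from a union volume (nm^3): r = (3V/4pi)^(1/3)."""
    if v_nm3 <= 0:
        raise ValueError("volume must be positive")
    r_nm = (3.0 * v_nm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    return r_nm * 10.0


# ---------------------------------------------------------------------------
# CG model construction
# ---------------------------------------------------------------------------


def _centroid(atoms: Sequence[Atom]) -> np.ndarray:
    return np.mean([a.position for a in atoms], axis=0)


def build_cg_model(
    model: DnaModel,
    scoring_radius_mode: str = "hydration",
    vdw_radii: dict[str, float] = BONDI_RADII,
    params_table: dict[str, BondParams] | None = None,
    union_volumes: dict[str, float] | None = None,
    include_c5_o5_bond: bool = True,
    volume_samples: int = 200_000,
    rng_seed: int = 0,
) -> list[CGBead]:
    """Build the three-bead-per-nucleotide CG model of a DNA molecule.

    Radii are derived from per-moiety union volumes, estimated once from
    the first complete nucleotide (the template repeats rigidly) unless
    ``union_volumes`` supplies them directly (nm^3 per moiety, e.g. the
    printed reference values).  Thresholds are computed per nucleotide
    from its own cluster geometry; base beads carry no threshold because
    only backbone (phosphodiester) bonds constitute a strand break site.
    """
    if scoring_radius_mode not in ("vdwr", "hydration"):
        raise ValueError(f"unknown scoring_radius_mode {scoring_radius_mode!r}")
    params = params_table or load_bond_params()
    radii_cache: dict[str, float] = {}
    if union_volumes:
        for moiety, vol in union_volumes.items():
            radii_cache[moiety] = radius_from_volume(vol)

    beads: list[CGBead] = []
    for (strand, idx), group in model.nucleotides():
        part = partition_nucleotide(group)
        clusters = {
            "phosphate": part.phosphate_atoms,
            "deoxyribose": part.sugar_atoms,
            "base": part.base_atoms,
        }
        o5 = [a for a in part.phosphate_atoms if a.name == "O5'"]
        for moiety, cluster in clusters.items():
            if not cluster:
                continue
            if moiety not in radii_cache:
                vol = union_volume(
                    cluster, vdw_radii, samples=volume_samples, rng_seed=rng_seed
                )
                radii_cache[moiety] = radius_from_volume(vol)
            r_vdwr = radii_cache[moiety]
            threshold = None
            if moiety == "phosphate" and part.has_phosphate:
                threshold = cluster_potential(cluster, params).threshold
            elif moiety == "deoxyribose":
                boundary = o5 if include_c5_o5_bond else []
                threshold = cluster_potential(
                    cluster, params, boundary_atoms=boundary
                ).threshold
            scoring = r_vdwr
            if scoring_radius_mode == "hydration" and moiety in (
                "phosphate",
                "deoxyribose",
            ):
                scoring = HYDRATION_RADIUS
            beads.append(
                CGBead(
                    moiety=moiety,
                    center=_centroid(cluster),
                    radius_vdwr=r_vdwr,
                    scoring_radius=scoring,
                    threshold_energy=threshold,
                    nucleotide_index=idx,
                    strand=strand,
                    segment_id=group[0].segment_id,
                )
            )
    return beads


# ---------------------------------------------------------------------------
# CG geometry text format
# ---------------------------------------------------------------------------

_CG_HEADER = "# cgdamage CG geometry format v1"
_CG_COLUMNS = (
    "# segment_id strand nucleotide_index moiety x_A y_A z_A "
    "radius_vdwr_A scoring_radius_A threshold_eV"
)


def write_cg(beads: Iterable[CGBead], path: str | Path) -> None:
    """Write beads to the plain-text CG geometry format (6-decimal fixed)."""
    with open(path, "w") as fh:
        fh.write(_CG_HEADER + "\n")
        fh.write(_CG_COLUMNS + "\n")
        for b in beads:
            thr = "nan" if b.threshold_energy is None else f"{b.threshold_energy:.6f}"
            fh.write(
                f"{b.segment_id} {b.strand} {b.nucleotide_index} {b.moiety} "
                f"{b.center[0]:.6f} {b.center[1]:.6f} {b.center[2]:.6f} "
                f"{b.radius_vdwr:.6f} {b.scoring_radius:.6f} {thr}\n"
            )


def read_cg(path: str | Path) -> list[CGBead]:
    """Read a CG geometry file written by :func:`write_cg`."""
    beads: list[CGBead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 10:
                raise ValueError(f"{path}:{lineno}: expected 10 fields, got {len(parts)}")
            seg, strand, idx, moiety = int(parts[0]), int(parts[1]), int(parts[2]), parts[3]
            x, y, z, rv, rs = map(float, parts[4:9])
            thr = float(parts[9])
            beads.append(
                CGBead(
                    moiety=moiety,
                    center=np.array([x, y, z]),
                    radius_vdwr=rv,
                    scoring_radius=rs,
                    threshold_energy=None if math.isnan(thr) else thr,
                    nucleotide_index=idx,
                    strand=strand,
                    segment_id=seg,
                )
            )
    return beads


# ---------------------------------------------------------------------------
# Flat array view used by the scoring stage
# ---------------------------------------------------------------------------

MOIETY_CODES = {"phosphate": 0, "deoxyribose": 1, "base": 2}


@dataclass
class BeadArray:
    """Column-oriented bead table (nm units) for vectorized scoring."""

    centers: np.ndarray  # (N, 3) nm
    scoring_radius: np.ndarray  # (N,) nm
    threshold: np.ndarray  # (N,) eV, nan where no threshold
    moiety: np.ndarray  # (N,) int8, see MOIETY_CODES
    segment_id: np.ndarray  # (N,) int32
    strand: np.ndarray  # (N,) int8
    nucleotide_index: np.ndarray  # (N,) int32

    def __len__(self) -> int:
        return len(self.centers)

    @classmethod
    def from_beads(cls, beads: Sequence[CGBead], angstrom_to_nm: bool = True) -> "BeadArray":
        scale = 0.1 if angstrom_to_nm else 1.0
        return cls(
            centers=np.array([b.center for b in beads], dtype=float) * scale,
            scoring_radius=np.array([b.scoring_radius for b in beads]) * scale,
            threshold=np.array(
                [math.nan if b.threshold_energy is None else b.threshold_energy for b in beads]
            ),
            moiety=np.array([MOIETY_CODES[b.moiety] for b in beads], dtype=np.int8),
            segment_id=np.array([b.segment_id for b in beads], dtype=np.int32),
            strand=np.array([b.strand for b in beads], dtype=np.int8),
            nucleotide_index=np.array([b.nucleotide_index for b in beads], dtype=np.int32),
        )

    @classmethod
    def concatenate(cls, arrays: Sequence["BeadArray"]) -> "BeadArray":
        return cls(
            centers=np.vstack([a.centers for a in arrays]),
            scoring_radius=np.concatenate([a.scoring_radius for a in arrays]),
            threshold=np.concatenate([a.threshold for a in arrays]),
            moiety=np.concatenate([a.moiety for a in arrays]),
            segment_id=np.concatenate([a.segment_id for a in arrays]),
            strand=np.concatenate([a.strand for a in arrays]),
            nucleotide_index=np.concatenate([a.nucleotide_index for a in arrays]),
        )
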