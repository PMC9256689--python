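"""Spherical water phantom populated with non-overlapping DNA segments.

Segment copies (CG bead models) are wrapped in a cuboid mother volume —
the axis-aligned bounding box of the bead scoring spheres plus a 1 nm
margin — and placed at uniform random positions and orientations inside
a water sphere.  Placements are rejection-sampled so that no two mother
volumes intersect (separating-axis test on the oriented boxes) and every
box lies fully inside the phantom.  Form mixing (e.g. 90% supercoiled /
10% relaxed, the morphology of dried plasmid preparations) uses exact
rounded counts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .cgbuild import BeadArray

WATER_DENSITY_G_CM3 = 1.0
MOTHER_VOLUME_MARGIN_NM = 1.0


@dataclass
class SegmentPlacement:
    segment_id: int
    translation: np.ndarray  # (3,) nm, global position of the box center
    rotation: np.ndarray  # (3,3) orthonormal
    form: str
    half_extents: np.ndarray  # (3,) nm, local box half sizes (margin included)
    local_center: np.ndarray  # (3,) nm, box center in the segment frame


@dataclass
class Phantom:
    radius_um: float
    placements: list[SegmentPlacement]
    bp_per_segment: int
    medium_density: float = WATER_DENSITY_G_CM3

    @property
    def radius_nm(self) -> float:
        return self.radius_um * 1e3

    @property
    def total_bp(self) -> int:
        return self.bp_per_segment * len(self.placements)

    @property
    def volume_nm3(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius_nm**3

    @property
    def mass_kg(self) -> float:
        return self.volume_nm3 * 1e-27 * self.medium_density * 1000.0


def bp_density(phantom: Phantom) -> float:
    """Base-pair density of the phantom, bp/nm^3."""
    if not phantom.placements:
        raise ValueError("phantom has no placements")
    return phantom.total_bp / phantom.volume_nm3


def _obb_separated(
    c1: np.ndarray, r1: np.ndarray, e1: np.ndarray,
    c2: np.ndarray, r2: np.ndarray, e2: np.ndarray,
) -> bool:
    """True when a separating axis exists (boxes do not intersect)."""
    rm = r1.T @ r2
    absr = np.abs(rm) + 1e-12
    t = r1.T @ (c2 - c1)
    for i in range(3):  # axes of box 1
        if abs(t[i]) > e1[i] + float(absr[i] @ e2):
            return True
    for j in range(3):  # axes of box 2
        if abs(float(rm[:, j] @ t)) > float(absr[:, j] @ e1) + e2[j]:
            return True
    for i in range(3):  # cross products
        for j in range(3):
            ra = e1[(i + 1) % 3] * absr[(i + 2) % 3, j] + e1[(i + 2) % 3] * absr[(i + 1) % 3, j]
            rb = e2[(j + 1) % 3] * absr[i, (j + 2) % 3] + e2[(j + 2) % 3] * absr[i, (j + 1) % 3]
            lhs = abs(
                t[(i + 2) % 3] * rm[(i + 1) % 3, j] - t[(i + 1) % 3] * rm[(i + 2) % 3, j]
            )
            if lhs > ra + rb:
                return True
    return False


def segment_box(beads: BeadArray, margin_nm: float = MOTHER_VOLUME_MARGIN_NM):
    """(local_center, half_extents) nm of the mother volume of a CG segment."""
    lo = (beads.centers - beads.scoring_radius[:, None]).min(axis=0) - margin_nm
    hi = (beads.centers + beads.scoring_radius[:, None]).max(axis=0) + margin_nm
    return (lo + hi) / 2.0, (hi - lo) / 2.0


def _exact_counts(n: int, fractions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder rounding of form fractions to exact counts."""
    raw = {f: n * frac for f, frac in fractions.items()}
    counts = {f: int(math.floor(v)) for f, v in raw.items()}
    rem = n - sum(counts.values())
    for f in sorted(raw, key=lambda f: raw[f] - counts[f], reverse=True)[:rem]:
        counts[f] += 1
    return counts


def place_segments(
    n_segments: int,
    phantom_radius_um: float,
    cg_models: Mapping[str, BeadArray],
    form_fractions: Mapping[str, float] | None = None,
    rng_seed: int = 0,
    max_attempts: int = 100,
    bp_per_segment: int | None = None,
) -> Phantom:
    """Place ``n_segments`` mother volumes uniformly in the phantom sphere.

    ``cg_models`` maps each form name to the BeadArray of one segment in
    its local frame (nm).  ``form_fractions`` defaults to the dried-plasmid
    mix {supercoiled: 0.9, relaxed: 0.1} when both forms are supplied,
    otherwise everything uses the single given form.  ``max_attempts`` is
    per segment; exceeding it raises with the achieved packing fraction.
    """
    if n_segments < 1:
        raise ValueError("need at least one segment")
    if form_fractions is None:
        if set(cg_models) >= {"supercoiled", "relaxed"}:
            form_fractions = {"supercoiled": 0.9, "relaxed": 0.1}
        else:
            only = next(iter(cg_models))
            form_fractions = {only: 1.0}
    missing = set(form_fractions) - set(cg_models)
    if missing:
        raise ValueError(f"no CG model for forms {sorted(missing)}")

    boxes = {f: segment_box(cg_models[f]) for f in form_fractions}
    radius_nm = phantom_radius_um * 1e3
    # feasibility pre-check by volume fraction
    counts = _exact_counts(n_segments, form_fractions)
    box_vol = sum(counts[f] * float(np.prod(2.0 * boxes[f][1])) for f in counts)
    sphere_vol = 4.0 / 3.0 * math.pi * radius_nm**3
    if box_vol > 0.3 * sphere_vol:
        raise ValueError(
            f"requested packing fraction {box_vol / sphere_vol:.2f} exceeds 0.3; "
            "phantom too small for the segment count"
        )

    rng = np.random.default_rng(rng_seed)
    forms = [f for f in sorted(counts) for _ in range(counts[f])]
    placements: list[SegmentPlacement] = []
    centers = np.empty((n_segments, 3))
    circum = np.empty(n_segments)
    for seg_id, form in enumerate(forms):
        local_center, half = boxes[form]
        box_circum = float(np.linalg.norm(half))
        max_center_r = radius_nm - box_circum
        if max_center_r <= 0:
            raise ValueError("segment mother volume larger than the phantom sphere")
        placed = False
        for _ in range(max_attempts):
            rot = Rotation.random(rng=rng).as_matrix()
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            r = max_center_r * rng.random() ** (1.0 / 3.0)
            center = r * direction
            ok = True
            if seg_id:
                prev = centers[:seg_id]
                near = np.flatnonzero(
                    np.linalg.norm(prev - center, axis=1) <= circum[:seg_id] + box_circum
                )
                for j in near:
                    pj = placements[j]
                    if not _obb_separated(
                        center, rot, half,
                        pj.translation, pj.rotation, pj.half_extents,
                    ):
                        ok = False
                        break
            if ok:
                centers[seg_id] = center
                circum[seg_id] = box_circum
                placements.append(
                    SegmentPlacement(
                        segment_id=seg_id,
                        translation=center,
                        rotation=rot,
                        form=form,
                        half_extents=half.copy(),
                        local_center=local_center.copy(),
                    )
                )
                placed = True
                break
        if not placed:
            achieved = sum(
                float(np.prod(2 * p.half_extents)) for p in placements
            ) / sphere_vol
            raise RuntimeError(
                f"could not place segment {seg_id} within {max_attempts} attempts "
                f"(achieved packing fraction {achieved:.3f})"
            )
    bp = bp_per_segment
    if bp is None:
        bp = len(next(iter(cg_models.values()))) // 6 * 2  # 3 beads per nucleotide
    return Phantom(
        radius_um=phantom_radius_um,
        placements=placements,
        bp_per_segment=bp,
    )


def flatten_beads(phantom: Phantom, cg_models: Mapping[str, BeadArray]) -> BeadArray:
    """Global bead table (nm) of every placed segment copy.

    Bead centers are transformed into the phantom frame; the placement
    rotation/translation apply to the segment's local origin (the box is
    centered at ``translation`` but beads rotate about the segment frame
    origin, offset by the rotated local box center).
    """
    parts = []
    for p in phantom.placements:
        local = cg_models[p.form]
        centers = (p.rotation @ local.centers.T).T + (
            p.translation - p.rotation @ p.local_center
        )
        parts.append(
            BeadArray(
                centers=centers,
                scoring_radius=local.scoring_radius.copy(),
                threshold=local.threshold.copy(),
                moiety=local.moiety.copy(),
                segment_id=np.full(len(local), p.segment_id, dtype=np.int32),
                strand=local.strand.copy(),
                nucleotide_index=local.nucleotide_index.copy(),
            )
        )
    return BeadArray.concatenate(parts)


def write_layout(phantom: Phantom, path: str | Path) -> None:
    """Write the placement layout TSV."""
    with open(path, "w") as fh:
        fh.write(f"# phantom radius_um={phantom.radius_um} bp_per_segment={phantom.bp_per_segment}\n")
        fh.write(
            "segment_id\tform\ttx\tty\ttz\t"
            + "\t".join(f"r{i}{j}" for i in range(1, 4) for j in range(1, 4))
            + "\n"
        )
        for p in phantom.placements:
            rot = "\t".join(f"{v:.9f}" for v in p.rotation.ravel())
            fh.write(
                f"{p.segment_id}\t{p.form}\t"
                f"{p.translation[0]:.6f}\t{p.translation[1]:.6f}\t{p.translation[2]:.6f}\t{rot}\n"
            )


def read_layout(path: str | Path, cg_models: Mapping[str, BeadArray]) -> Phantom:
    """Read a layout TSV back into a Phantom (boxes recomputed from models)."""
    placements = []
    radius_um = None
    bp = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("radius_um="):
                        radius_um = float(tok.split("=")[1])
                    elif tok.startswith("bp_per_segment="):
                        bp = int(tok.split("=")[1])
                continue
            if not line or line.startswith("segment_id"):
                continue
            parts = line.split("\t")
            seg_id, form = int(parts[0]), parts[1]
            t = np.array([float(x) for x in parts[2:5]])
            rot = np.array([float(x) for x in parts[5:14]]).reshape(3, 3)
            local_center, half = segment_box(cg_models[form])
            placements.append(
                SegmentPlacement(seg_id, t, rot, form, half, local_center)
            )
    if radius_um is None or bp is None:
        raise ValueError(f"{path}: missing phantom header line")
    return Phantom(radius_um=radius_um, placements=placements, bp_per_segment=bp)
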