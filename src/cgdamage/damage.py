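"""Strand-break detection, SSB/DSB cluster classification and yields.

A strand break occurs at a nucleotide when, within one radiation event,
the cumulative energy scored in its phosphate *or* its deoxyribose bead
strictly exceeds that bead's threshold ("one or both volumes").

Breaks of one event on one DNA molecule are then grouped into proximity
clusters (two breaks are linked when their base-pair separation is at
most ``max_separation``, 10 bp by default; modular distance on circular
molecules) and each cluster is reported once at its most complex class:

========  =======================================================
SSB       isolated single break
SSB+      >= 2 breaks on the same strand within the window
2SSB      SSB/SSB+ lesions on opposite strands separated by > 10 bp
DSB       exactly one opposite-strand break pair within the window
DSB+      a DSB plus at least one additional nearby break
DSB++     >= 2 disjoint opposite-strand pairs in one cluster
========  =======================================================

Because proximity links are at most 10 bp, a cluster containing both
strands necessarily contains an opposite-strand pair within 10 bp and is
DSB-class; single-strand clusters are SSB-class, and SSB-class clusters
on opposite strands (automatically > 10 bp apart) pair up as 2SSB.

The SSB yield counts SSB + SSB+ + 2 x 2SSB (a 2SSB is two separate
single-strand lesions; configurable); the DSB yield counts
DSB + DSB+ + DSB++.  Yields are reported per Gy per Gbp.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .cgbuild import BeadArray, MOIETY_CODES
from .tracks import ScoreTable

SSB_CLASSES = ("SSB", "SSB+", "2SSB")
DSB_CLASSES = ("DSB", "DSB+", "DSB++")
ALL_CLASSES = SSB_CLASSES + DSB_CLASSES

#: complexity ordering used by the "most complex break type" rule
COMPLEXITY_ORDER = {c: i for i, c in enumerate(ALL_CLASSES)}


@dataclass(frozen=True)
class BreakRecord:
    event_id: int
    segment_id: int
    strand: int
    nucleotide_index: int
    trigger: str  # "phosphate" | "deoxyribose" | "both"


@dataclass
class DamageTally:
    counts: Counter = field(default_factory=Counter)
    n_events_with_damage: int = 0

    def __add__(self, other: "DamageTally") -> "DamageTally":
        return DamageTally(
            counts=self.counts + other.counts,
            n_events_with_damage=self.n_events_with_damage + other.n_events_with_damage,
        )

    @property
    def total_breaks(self) -> int:
        """Break-site units: clusters weighted by their strand-lesion count."""
        return sum(self.counts[c] for c in ALL_CLASSES)


@dataclass
class YieldResult:
    ssb_yield: float  # per Gy per Gbp
    dsb_yield: float
    dose_gy: float
    total_bp: int
    nominal_let: float | None = None

    @property
    def ratio(self) -> float:
        if self.dsb_yield <= 0:
            raise ZeroDivisionError("DSB yield is zero; SSB/DSB ratio undefined")
        return self.ssb_yield / self.dsb_yield


def find_breaks(scores: ScoreTable, beads: BeadArray) -> list[BreakRecord]:
    """Strand breaks from per-(event, bead) scores vs bead thresholds.

    A nucleotide breaks in an event iff the energy in its phosphate or
    deoxyribose bead strictly exceeds the bead threshold.  Base beads
    absorb energy but never break.
    """
    if len(scores.energies) == 0:
        return []
    thr = beads.threshold[scores.bead_ids]
    over = scores.energies > thr  # nan thresholds (base beads) compare False
    if not over.any():
        return []
    b = scores.bead_ids[over]
    eids = scores.event_ids[over]
    moieties = beads.moiety[b]
    records: dict[tuple[int, int, int, int], set[str]] = {}
    code_to_name = {v: k for k, v in MOIETY_CODES.items()}
    for eid, bid, mo in zip(eids, b, moieties):
        key = (
            int(eid),
            int(beads.segment_id[bid]),
            int(beads.strand[bid]),
            int(beads.nucleotide_index[bid]),
        )
        records.setdefault(key, set()).add(code_to_name[int(mo)])
    out = []
    for (eid, seg, strand, idx), triggers in sorted(records.items()):
        trig = "both" if len(triggers) > 1 else next(iter(triggers))
        out.append(BreakRecord(eid, seg, strand, idx, trig))
    return out


def _bp_distance(i: int, j: int, topology: str, n_bp: int | None) -> int:
    d = abs(i - j)
    if topology == "circular":
        if n_bp is None:
            raise ValueError("circular topology requires n_bp")
        d = min(d, n_bp - d)
    elif topology != "linear":
        raise ValueError(f"unknown topology {topology!r}")
    return d


def _components(sites: list[tuple[int, int]], max_sep: int, topology: str, n_bp):
    """Connected components linking sites within max_sep bp (any strand)."""
    n = len(sites)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if _bp_distance(sites[i][1], sites[j][1], topology, n_bp) <= max_sep:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return list(comps.values())


def _has_two_disjoint_pairs(edges: list[tuple[int, int]]) -> bool:
    for (a1, b1), (a2, b2) in itertools.combinations(edges, 2):
        if {a1, b1}.isdisjoint({a2, b2}):
            return True
    return False


def classify_breaks(
    breaks: Sequence[BreakRecord] | Sequence[tuple[int, int]],
    max_separation: int = 10,
    topology: str = "circular",
    n_bp: int | None = None,
) -> Counter:
    """Classify the deduplicated breaks of one event on one molecule.

    ``breaks`` may be BreakRecords or bare ``(strand, nucleotide_index)``
    tuples.  Returns a Counter over the six subtype classes.
    """
    sites = []
    seen = set()
    for b in breaks:
        site = (b.strand, b.nucleotide_index) if isinstance(b, BreakRecord) else tuple(b)
        if site not in seen:
            seen.add(site)
            sites.append(site)
    counts: Counter = Counter({c: 0 for c in ALL_CLASSES})
    if not sites:
        return counts
    comps = _components(sites, max_separation, topology, n_bp)
    ssb_like: dict[int, list[tuple[str, int]]] = {0: [], 1: []}  # strand -> (class, min bp)
    for comp in comps:
        strands = {sites[i][0] for i in comp}
        if len(strands) > 1:
            edges = [
                (i, j)
                for i, j in itertools.combinations(comp, 2)
                if sites[i][0] != sites[j][0]
                and _bp_distance(sites[i][1], sites[j][1], topology, n_bp) <= max_separation
            ]
            if _has_two_disjoint_pairs(edges):
                counts["DSB++"] += 1
            elif len(comp) > 2:
                counts["DSB+"] += 1
            else:
                counts["DSB"] += 1
        else:
            cls = "SSB" if len(comp) == 1 else "SSB+"
            strand = next(iter(strands))
            ssb_like[strand].append((cls, min(sites[i][1] for i in comp)))
    # opposite-strand SSB-class lesions (> max_sep apart by construction)
    # pair up as 2SSB; the most complex lesions pair first ("most complex
    # break type selected"), so leftovers are the plainest clusters and
    # the outcome depends only on per-strand class counts
    for strand in (0, 1):
        ssb_like[strand].sort(key=lambda t: (-COMPLEXITY_ORDER[t[0]], t[1]))
    n_pairs = min(len(ssb_like[0]), len(ssb_like[1]))
    counts["2SSB"] += n_pairs
    for strand in (0, 1):
        for cls, _ in ssb_like[strand][n_pairs:]:
            counts[cls] += 1
    return counts


def tally_damage(
    breaks: Iterable[BreakRecord],
    max_separation: int = 10,
    topology: str = "circular",
    n_bp: int | None = None,
) -> DamageTally:
    """Aggregate subtype counts over all (event, molecule) break groups."""
    groups: dict[tuple[int, int], list[BreakRecord]] = {}
    for b in breaks:
        groups.setdefault((b.event_id, b.segment_id), []).append(b)
    tally = DamageTally()
    for group in groups.values():
        tally.counts += classify_breaks(group, max_separation, topology, n_bp)
        tally.n_events_with_damage += 1
    for c in ALL_CLASSES:
        tally.counts.setdefault(c, 0)
    return tally


def yields(
    tally: DamageTally,
    dose_gy: float,
    total_bp: int,
    nominal_let: float | None = None,
    two_ssb_units: int = 2,
) -> YieldResult:
    """SSB and DSB yields in Gy^-1 Gbp^-1 from a damage tally."""
    if dose_gy <= 0:
        raise ValueError("dose must be positive")
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    c = tally.counts
    ssb_units = c["SSB"] + c["SSB+"] + two_ssb_units * c["2SSB"]
    dsb_units = c["DSB"] + c["DSB+"] + c["DSB++"]
    gbp = total_bp * 1e-9
    return YieldResult(
        ssb_yield=ssb_units / (dose_gy * gbp),
        dsb_yield=dsb_units / (dose_gy * gbp),
        dose_gy=dose_gy,
        total_bp=total_bp,
        nominal_let=nominal_let,
    )


def mean_percentage_error(sim_values, exp_values) -> float:
    """Mean absolute relative deviation of simulation from experiment, %."""
    sim = np.asarray(sim_values, dtype=float)
    exp = np.asarray(exp_values, dtype=float)
    if sim.shape != exp.shape:
        raise ValueError("value arrays must have equal length")
    if np.any(exp == 0):
        raise ValueError("experimental values must be nonzero")
    return float(np.mean(np.abs((sim - exp) / exp)) * 100.0)
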