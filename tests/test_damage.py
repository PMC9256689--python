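"""Break detection, SSB/DSB cluster classification and yields.

The classification oracle used here is an independent implementation
built on networkx: proximity clusters via graph connected components,
the two-disjoint-pair question via maximum-cardinality matching.
"""

import itertools
from collections import Counter

import networkx as nx
import numpy as np
import pytest

from cgdamage.cgbuild import BeadArray
from cgdamage.damage import (
    ALL_CLASSES,
    BreakRecord,
    DamageTally,
    classify_breaks,
    find_breaks,
    mean_percentage_error,
    tally_damage,
    yields,
)
from cgdamage.tracks import ScoreTable


# ---------------------------------------------------------------------------
# Oracle
# ---------------------------------------------------------------------------


def oracle_classify(sites, max_sep, topology, n_bp):
    """Exhaustive reference classification of one break set."""

    def dist(a, b):
        d = abs(a[1] - b[1])
        return min(d, n_bp - d) if topology == "circular" else d

    g = nx.Graph()
    g.add_nodes_from(sites)
    for a, b in itertools.combinations(sites, 2):
        if dist(a, b) <= max_sep:
            g.add_edge(a, b)
    counts = Counter({c: 0 for c in ALL_CLASSES})
    ssb_like = {0: [], 1: []}
    for comp in nx.connected_components(g):
        comp = list(comp)
        strands = {s for s, _ in comp}
        if len(strands) == 2:
            cross = nx.Graph(
                (a, b)
                for a, b in itertools.combinations(comp, 2)
                if a[0] != b[0] and dist(a, b) <= max_sep
            )
            m = nx.algorithms.matching.max_weight_matching(cross, maxcardinality=True)
            if len(m) >= 2:
                counts["DSB++"] += 1
            elif len(comp) > 2:
                counts["DSB+"] += 1
            else:
                counts["DSB"] += 1
        else:
            cls = "SSB" if len(comp) == 1 else "SSB+"
            ssb_like[comp[0][0]].append((cls, min(b for _, b in comp)))
    complexity = {c: i for i, c in enumerate(ALL_CLASSES)}
    for s in (0, 1):
        ssb_like[s].sort(key=lambda t: (-complexity[t[0]], t[1]))
    n2 = min(len(ssb_like[0]), len(ssb_like[1]))
    counts["2SSB"] += n2
    for s in (0, 1):
        for cls, _ in ssb_like[s][n2:]:
            counts[cls] += 1
    return counts


def random_break_sets(n_sets, n_bp, seed, max_breaks=15):
    rng = np.random.default_rng(seed)
    for _ in range(n_sets):
        k = int(rng.integers(1, max_breaks + 1))
        sites = set()
        while len(sites) < k:
            sites.add((int(rng.integers(0, 2)), int(rng.integers(0, n_bp))))
        yield list(sites)


# ---------------------------------------------------------------------------
# find_breaks
# ---------------------------------------------------------------------------


def _bead_array_one_nucleotide():
    """Phosphate (thr 12.4), sugar (thr 30.5), base (no threshold)."""
    return BeadArray(
        centers=np.zeros((3, 3)),
        scoring_radius=np.full(3, 0.34),
        threshold=np.array([12.4, 30.5, np.nan]),
        moiety=np.array([0, 1, 2], dtype=np.int8),
        segment_id=np.zeros(3, dtype=np.int32),
        strand=np.zeros(3, dtype=np.int8),
        nucleotide_index=np.zeros(3, dtype=np.int32),
    )


def _table(rows):
    e, b, s = zip(*rows)
    return ScoreTable(
        event_ids=np.array(e, dtype=np.int64),
        bead_ids=np.array(b, dtype=np.int64),
        energies=np.array(s, dtype=float),
        unassigned_energy=0.0,
        total_energy=float(sum(s)),
    )


class TestFindBreaks:
    def test_score_above_threshold_breaks(self):
        beads = _bead_array_one_nucleotide()
        breaks = find_breaks(_table([(0, 0, 12.5)]), beads)
        assert len(breaks) == 1
        assert breaks[0].trigger == "phosphate"

    def test_strict_inequality(self):
        beads = _bead_array_one_nucleotide()
        assert find_breaks(_table([(0, 0, 12.4)]), beads) == []

    def test_sugar_trigger(self):
        beads = _bead_array_one_nucleotide()
        breaks = find_breaks(_table([(0, 0, 5.0), (0, 1, 31.0)]), beads)
        assert len(breaks) == 1
        assert breaks[0].trigger == "deoxyribose"

    def test_base_bead_never_breaks(self):
        beads = _bead_array_one_nucleotide()
        assert find_breaks(_table([(0, 2, 500.0)]), beads) == []

    def test_both_volumes_merge_to_one_break(self):
        beads = _bead_array_one_nucleotide()
        breaks = find_breaks(_table([(0, 0, 13.0), (0, 1, 31.0)]), beads)
        assert len(breaks) == 1
        assert breaks[0].trigger == "both"


# ---------------------------------------------------------------------------
# classify_breaks
# ---------------------------------------------------------------------------


class TestClassify:
    @pytest.mark.parametrize(
        "sites,expected",
        [
            ([(0, 100)], {"SSB": 1}),
            ([(0, 100), (1, 105)], {"DSB": 1}),
            ([(0, 100), (1, 111)], {"2SSB": 1}),
            ([(0, 100), (0, 105)], {"SSB+": 1}),
            ([(0, 100), (1, 105), (0, 108)], {"DSB+": 1}),
            ([(0, 100), (1, 105), (0, 112), (1, 118)], {"DSB++": 1}),
            ([(0, 100), (0, 130), (1, 160)], {"2SSB": 1, "SSB": 1}),
        ],
    )
    def test_canonical_patterns(self, sites, expected):
        counts = classify_breaks(sites, 10, "linear")
        assert {k: v for k, v in counts.items() if v} == expected

    def test_exactly_ten_bp_is_a_dsb(self):
        counts = classify_breaks([(0, 100), (1, 110)], 10, "linear")
        assert counts["DSB"] == 1
        counts = classify_breaks([(0, 100), (1, 111)], 10, "linear")
        assert counts["DSB"] == 0 and counts["2SSB"] == 1

    def test_circular_wraparound(self):
        counts = classify_breaks([(0, 1), (1, 434)], 10, "circular", n_bp=436)
        assert counts["DSB"] == 1

    def test_circular_requires_n_bp(self):
        with pytest.raises(ValueError):
            classify_breaks([(0, 1), (1, 5)], 10, "circular")

    def test_unknown_topology(self):
        with pytest.raises(ValueError):
            classify_breaks([(0, 1), (0, 5)], 10, "mobius")

    @pytest.mark.parametrize("topology", ["linear", "circular"])
    def test_matches_exhaustive_oracle(self, topology):
        """Greedy clustering equals the exhaustive matching oracle on
        random break sets."""
        n_bp = 436
        for sites in random_break_sets(300, n_bp, seed=13 if topology == "linear" else 14):
            got = classify_breaks(sites, 10, topology, n_bp=n_bp)
            exp = oracle_classify(sites, 10, topology, n_bp)
            assert got == exp, f"{topology}: {sorted(sites)}"

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        for sites in random_break_sets(50, 300, seed=6):
            perm = list(sites)
            rng.shuffle(perm)
            assert classify_breaks(sites, 10, "linear") == classify_breaks(
                perm, 10, "linear"
            )

    def test_circular_shift_invariance(self):
        n_bp = 436
        for sites in random_break_sets(50, n_bp, seed=7):
            shifted = [(s, (b + 123) % n_bp) for s, b in sites]
            assert classify_breaks(sites, 10, "circular", n_bp=n_bp) == classify_breaks(
                shifted, 10, "circular", n_bp=n_bp
            )

    def test_duplicates_deduplicated(self):
        counts = classify_breaks([(0, 100), (0, 100)], 10, "linear")
        assert counts["SSB"] == 1 and counts["SSB+"] == 0


# ---------------------------------------------------------------------------
# yields and error metric
# ---------------------------------------------------------------------------


class TestYields:
    def _tally(self, **kw):
        t = DamageTally()
        t.counts.update({c: 0 for c in ALL_CLASSES})
        t.counts.update(kw)
        return t

    def test_definition(self):
        t = self._tally(SSB=100, DSB=2)
        y = yields(t, dose_gy=1.0, total_bp=10**9)
        assert y.ssb_yield == pytest.approx(100.0)
        assert y.dsb_yield == pytest.approx(2.0)
        assert y.ratio == pytest.approx(50.0)

    def test_two_ssb_counts_twice_by_default(self):
        t = self._tally(**{"SSB": 1, "2SSB": 2})
        y = yields(t, 1.0, 10**9)
        assert y.ssb_yield == pytest.approx(5.0)
        y1 = yields(t, 1.0, 10**9, two_ssb_units=1)
        assert y1.ssb_yield == pytest.approx(3.0)

    def test_doubling_dose_halves_yields(self):
        t = self._tally(SSB=40, DSB=4)
        y1 = yields(t, 1.0, 10**9)
        y2 = yields(t, 2.0, 10**9)
        assert y2.ssb_yield == pytest.approx(y1.ssb_yield / 2)

    def test_zero_dose_raises(self):
        with pytest.raises(ValueError):
            yields(self._tally(SSB=1), 0.0, 10**9)

    def test_planted_scenario_end_to_end(self):
        """Hand-constructed breaks across two events and two molecules."""
        breaks = [
            BreakRecord(0, 0, 0, 50, "phosphate"),
            BreakRecord(0, 0, 1, 55, "phosphate"),  # DSB with the above
            BreakRecord(0, 1, 0, 10, "deoxyribose"),  # lone SSB
            BreakRecord(1, 0, 0, 50, "phosphate"),  # same site, new event: SSB
        ]
        tally = tally_damage(breaks, topology="circular", n_bp=436)
        assert tally.counts["DSB"] == 1
        assert tally.counts["SSB"] == 2
        assert tally.n_events_with_damage == 3  # (event, molecule) groups


class TestMeanPercentageError:
    def test_identical_arrays(self):
        assert mean_percentage_error([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_single_value(self):
        assert mean_percentage_error([1.1], [1.0]) == pytest.approx(10.0)

    def test_hand_evaluated(self):
        assert mean_percentage_error([2.0, 1.0], [1.0, 2.0]) == pytest.approx(75.0)

    def test_zero_experimental_value_raises(self):
        with pytest.raises(ValueError):
            mean_percentage_error([1.0], [0.0])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            mean_percentage_error([1.0], [1.0, 2.0])
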