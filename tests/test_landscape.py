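"""Landscape assembly, phylogeny-aware classification, sliding and parallel calls."""

import random

import pytest

from intronscape.core import (
    GeneModel,
    IntronClass,
    Phylogeny,
    ProjectedIntronPosition,
    ProteinAlignment,
)
from intronscape.families import IleFamily
from intronscape.landscape import (
    Category,
    Status,
    build_landscape,
    call_parallel_gains,
    classify_landscape,
    classify_position,
    detect_sliding_pairs,
    gain_frequency,
    position_distance,
    refine_boundaries,
    recover_events,
)

TREE = Phylogeny.from_newick("(((a,b),(c,d)),(e,f));")


def _row(present, absent=(), missing=()):
    row = {}
    for sp in present:
        row[sp] = Status.PRESENT
    for sp in absent:
        row[sp] = Status.ABSENT
    for sp in missing:
        row[sp] = Status.MISSING
    return row


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


class TestClassifyPosition:
    ALL = "abcdef"

    def test_present_in_all_is_conserved(self):
        assert classify_position(_row(self.ALL), TREE) is Category.CONSERVED

    def test_exactly_one_present(self):
        row = _row("a", absent="bcdef")
        assert classify_position(row, TREE) is Category.SINGLE_PRESENCE

    def test_clade_presence(self):
        row = _row("ab", absent="cdef")
        assert classify_position(row, TREE) is Category.SINGLE_PRESENCE_IN_CLADE

    def test_nine_of_ten_style_single_absence(self):
        row = _row("abcde", absent="f")
        assert classify_position(row, TREE) is Category.SINGLE_ABSENCE

    def test_non_clade_pair_is_polymorphic(self):
        row = _row("ae", absent="bcdf")
        assert (
            classify_position(row, TREE)
            is Category.PRESENCE_ABSENCE_POLYMORPHISM
        )

    def test_missing_excluded_from_denominator(self):
        # only a and b scored; both present -> conserved despite absences elsewhere
        row = _row("ab", missing="cdef")
        assert classify_position(row, TREE) is Category.CONSERVED

    def test_all_absent_rejected(self):
        with pytest.raises(ValueError):
            classify_position(_row("", absent=self.ALL), TREE)


def _random_topology(rng, leaves):
    """Random rooted binary tree as nested tuples (independent oracle form)."""
    nodes = list(leaves)
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        nodes.append((a, b))
    return nodes[0]


def _to_newick(node):
    if isinstance(node, str):
        return node
    return "(" + ",".join(_to_newick(c) for c in node) + ")"


def _oracle_clades(node, acc):
    """All leaf sets of subtrees, by direct recursion on the tuple form."""
    if isinstance(node, str):
        acc.append(frozenset({node}))
        return frozenset({node})
    ls = frozenset()
    for c in node:
        ls |= _oracle_clades(c, acc)
    acc.append(ls)
    return ls


def _oracle_classify(row, topology):
    scored = {sp for sp, st in row.items() if st is not Status.MISSING}
    present = {sp for sp in scored if row[sp] is Status.PRESENT}
    clades = []
    _oracle_clades(topology, clades)
    if present == scored:
        return Category.CONSERVED
    if len(present) == 1:
        return Category.SINGLE_PRESENCE
    if any((c & scored) == present for c in clades):
        return Category.SINGLE_PRESENCE_IN_CLADE
    if len(scored - present) == 1:
        return Category.SINGLE_ABSENCE
    return Category.PRESENCE_ABSENCE_POLYMORPHISM


class TestClassifyAgainstBruteForceOracle:
    @pytest.mark.parametrize("seed", range(4))
    def test_random_trees_and_rows(self, seed):
        rng = random.Random(seed)
        for _ in range(250):
            n = rng.randint(3, 12)
            leaves = [f"t{k}" for k in range(n)]
            topo = _random_topology(rng, leaves)
            tree = Phylogeny.from_newick(_to_newick(topo) + ";")
            row = {
                sp: rng.choice(
                    [Status.PRESENT, Status.ABSENT, Status.ABSENT, Status.MISSING]
                )
                for sp in leaves
            }
            if not any(st is Status.PRESENT for st in row.values()):
                row[leaves[0]] = Status.PRESENT
            assert classify_position(row, tree) == _oracle_classify(row, topo)


# ---------------------------------------------------------------------------
# sliding pairs
# ---------------------------------------------------------------------------


class TestSlidingPairs:
    def test_paper_distances_flagged(self):
        afos = [100, 101, 200, 208, 300, 303]
        positions = [ProjectedIntronPosition(a // 3, a % 3) for a in afos]
        pairs = detect_sliding_pairs(positions)
        dists = sorted(d for _, _, d in pairs)
        assert dists == [1, 3, 8]

    def test_distance_fifteen_not_flagged(self):
        positions = [ProjectedIntronPosition(0, 0), ProjectedIntronPosition(5, 0)]
        assert detect_sliding_pairs(positions) == []

    def test_distance_fourteen_flagged(self):
        positions = [ProjectedIntronPosition(0, 0), ProjectedIntronPosition(4, 2)]
        assert len(detect_sliding_pairs(positions)) == 1

    def test_matches_quadratic_scan(self):
        rng = random.Random(5)
        afos = rng.sample(range(0, 400), 40)
        positions = [ProjectedIntronPosition(a // 3, a % 3) for a in afos]
        got = {
            (a.alignment_frame_offset, b.alignment_frame_offset, d)
            for a, b, d in detect_sliding_pairs(positions)
        }
        expected = set()
        for i in range(len(positions)):
            for j in range(i + 1, len(positions)):
                d = position_distance(positions[i], positions[j])
                if 0 < d < 15:
                    x, y = sorted(
                        (positions[i].alignment_frame_offset,
                         positions[j].alignment_frame_offset)
                    )
                    expected.add((x, y, d))
        assert got == expected


# ---------------------------------------------------------------------------
# landscape assembly on hand-built gene models
# ---------------------------------------------------------------------------


def _gene(species, cds_parts, introns, gene_id="g"):
    """Assemble a '+' model from alternating exon/intron pieces."""
    seq = ""
    exons = []
    pos = 0
    for k, part in enumerate(cds_parts):
        exons.append((pos, pos + len(part)))
        seq += part
        pos += len(part)
        if k < len(introns):
            seq += introns[k]
            pos += len(introns[k])
    return GeneModel(gene_id, species, "+", tuple(exons), seq)


CDS = "ATG" + "GCT" * 20 + "TAA"  # 66 nt, stop-free interior


class TestBuildLandscape:
    TREE2 = Phylogeny.from_newick("((a,b),(c,d));")
    RSI = "GT" + "C" * 46 + "AG"

    def _alignment(self, species):
        prot = "M" + "A" * 20
        return ProteinAlignment({sp: prot for sp in species}, "t")

    def test_identical_structures_all_present(self):
        genes = {
            sp: _gene(sp, [CDS[:30], CDS[30:]], [self.RSI]) for sp in "abcd"
        }
        ls = build_landscape(genes, self._alignment("abcd"), self.TREE2)
        assert len(ls.positions) == 1
        assert all(
            ls.state(30, sp) is Status.PRESENT for sp in "abcd"
        )

    def test_private_intron_absent_elsewhere(self):
        genes = {"a": _gene("a", [CDS[:30], CDS[30:]], [self.RSI])}
        for sp in "bcd":
            genes[sp] = _gene(sp, [CDS], [])
        ls = build_landscape(genes, self._alignment("abcd"), self.TREE2)
        assert ls.state(30, "a") is Status.PRESENT
        assert all(ls.state(30, sp) is Status.ABSENT for sp in "bcd")

    def test_species_without_orthologue_is_missing(self):
        genes = {
            "a": _gene("a", [CDS[:30], CDS[30:]], [self.RSI]),
            "b": _gene("b", [CDS], []),
            "c": None,
            "d": _gene("d", [CDS], []),
        }
        ls = build_landscape(genes, self._alignment("abd"), self.TREE2)
        assert ls.state(30, "c") is Status.MISSING

    def test_internal_stop_flags_pseudogene(self):
        broken = CDS[:30] + "TAA" + CDS[33:]
        genes = {
            "a": _gene("a", [broken[:30], broken[30:]], [self.RSI]),
            "b": _gene("b", [CDS], []),
            "c": _gene("c", [CDS], []),
            "d": _gene("d", [CDS], []),
        }
        ls = build_landscape(genes, self._alignment("abcd"), self.TREE2)
        assert ls.pseudogene_flags["a"] is True
        assert ls.pseudogene_flags["b"] is False

    def test_species_order_invariance(self):
        genes = {
            sp: _gene(sp, [CDS[:30], CDS[30:]], [self.RSI]) for sp in "abcd"
        }
        ls1 = build_landscape(dict(genes), self._alignment("abcd"), self.TREE2)
        rev = dict(reversed(list(genes.items())))
        ls2 = build_landscape(rev, self._alignment("abcd"), self.TREE2)
        assert ls1.states == ls2.states
        assert [p.alignment_frame_offset for p in ls1.positions] == [
            p.alignment_frame_offset for p in ls2.positions
        ]

    def test_species_absent_from_tree_rejected(self):
        genes = {
            "a": _gene("a", [CDS], []),
            "z": _gene("z", [CDS], []),
        }
        with pytest.raises(ValueError, match="z"):
            build_landscape(genes, self._alignment("az"), self.TREE2)


# ---------------------------------------------------------------------------
# boundary refinement
# ---------------------------------------------------------------------------


class TestRefineBoundaries:
    def _setup(self, x_col):
        """Four carriers at column 10; species x's intron projected at x_col."""
        rows = {sp: "A" * 30 for sp in "abcde"}
        aln = ProteinAlignment(rows, "t")
        from intronscape.core import IntronInstance

        proj = {}
        for sp in "abcd":
            pos = ProjectedIntronPosition(10, 0, "t")
            proj[sp] = {30: (pos, IntronInstance("g", sp, 0, 30, "GTAAAG"))}
        pos = ProjectedIntronPosition(x_col, 0, "t")
        proj["e"] = {
            3 * x_col: (pos, IntronInstance("g", "e", 0, 3 * x_col, "GTAAAG"))
        }
        return proj, aln

    def test_no_nearby_position_unchanged(self):
        proj, aln = self._setup(20)
        out, log = refine_boundaries(proj, aln)
        assert set(out["e"]) == {60}
        assert log == []

    def test_snap_onto_shared_position_when_flanks_support(self):
        # species e's flank disagrees around its own column but matches at 10
        rows = {sp: "A" * 30 for sp in "abcd"}
        rows["e"] = "A" * 12 + "WYWYW" + "A" * 13  # noise right of column 11
        aln = ProteinAlignment(rows, "t")
        from intronscape.core import IntronInstance

        proj = {
            sp: {30: (ProjectedIntronPosition(10, 0, "t"),
                      IntronInstance("g", sp, 0, 30, "GTAAAG"))}
            for sp in "abcd"
        }
        proj["e"] = {33: (ProjectedIntronPosition(11, 0, "t"),
                          IntronInstance("g", "e", 0, 33, "GTAAAG"))}
        out, log = refine_boundaries(proj, aln)
        assert set(out["e"]) == {30}
        assert len(log) == 1 and log[0].to_afo == 30

    def test_equal_scores_leave_position_and_flag_tie(self):
        # two candidate positions at equal distance with identical flanks
        rows = {sp: "A" * 30 for sp in "abcde"}
        # noise at columns 6,7 and 15,16: both candidate windows (cols 9 and 13)
        # score equally and better than e's own column 11
        rows["e"] = "A" * 6 + "WW" + "A" * 7 + "WW" + "A" * 13
        aln = ProteinAlignment(rows, "t")
        from intronscape.core import IntronInstance

        proj = {}
        for sp, col in (("a", 9), ("b", 9), ("c", 13), ("d", 13)):
            proj[sp] = {3 * col: (ProjectedIntronPosition(col, 0, "t"),
                                  IntronInstance("g", sp, 0, 3 * col, "GTAAAG"))}
        proj["e"] = {33: (ProjectedIntronPosition(11, 0, "t"),
                          IntronInstance("g", "e", 0, 33, "GTAAAG"))}
        out, log = refine_boundaries(proj, aln, shift_window=2)
        assert set(out["e"]) == {33}
        assert any(entry.to_afo is None for entry in log)


# ---------------------------------------------------------------------------
# parallel gains and frequency
# ---------------------------------------------------------------------------


class TestParallelAndFrequency:
    def test_fixture_parallel_calls(self, fixture_collection, fixture_analysis):
        fx, res = fixture_collection, fixture_analysis
        got = []
        for gid, calls in res.calls.items():
            for c in calls:
                if c.parallel_gain and set(
                    res.landscapes[gid].classes_at(c.afo).values()
                ) == {IntronClass.ILE}:
                    partner, d = c.sliding_partners[0]
                    got.append((gid, c.afo, partner, d))
        assert sorted(got) == sorted(fx.expected_parallel)

    def test_rsi_only_sliding_pair_not_called(self, fixture_analysis):
        calls = fixture_analysis.calls["g004"]
        pair_afos = {c.afo for c in calls if c.sliding_partners}
        assert {90, 102, 900, 906} <= pair_afos
        assert not any(
            c.parallel_gain for c in calls if c.afo in {90, 102, 900, 906}
        )

    def test_frequency_of_three_in_thirteen_is_23(self, fixture_analysis):
        freq = fixture_analysis.summary["parallel_gain_frequency"]
        assert (freq["numerator"], freq["denominator"]) == (3, 13)
        assert freq["percent"] == 23

    def test_frequency_zero_and_undefined(self):
        from intronscape.landscape import PositionCall

        poly = [
            PositionCall(ProjectedIntronPosition(k, 0),
                         Category.PRESENCE_ABSENCE_POLYMORPHISM)
            for k in range(4)
        ]
        assert gain_frequency(poly).percent == 0
        sp = [PositionCall(ProjectedIntronPosition(0, 0), Category.SINGLE_PRESENCE)]
        assert gain_frequency(sp).percent is None


class TestEventRecoveryProperties:
    def test_no_losses_every_gain_is_clade_or_single_presence(self):
        from intronscape.fixtures import FIXTURE_TREE
        from intronscape.simulate import SimulationParams, simulate
        from intronscape import RunConfig, analyze

        params = SimulationParams(
            tree=FIXTURE_TREE, n_genes=6, cds_length=900, loss_rate=0.0,
            ile_families={"f": "GT" + "ACGTA" * 13 + "AG"}, seed=3,
            n_ancestral_introns=0,
        )
        sim = simulate(params)
        res = analyze(sim.gene_models, sim.alignments, sim.tree, (), RunConfig())
        gained = {(e.gene_id, e.cds_offset) for e in sim.events
                  if e.type.endswith("GAIN")}
        for gid, calls in res.calls.items():
            for c in calls:
                if (gid, c.afo) in gained:
                    assert c.category in (
                        Category.SINGLE_PRESENCE,
                        Category.SINGLE_PRESENCE_IN_CLADE,
                    )

    def test_recovered_clade_matches_gain_branch(self):
        from intronscape.fixtures import FIXTURE_TREE
        from intronscape.simulate import ForcedEvent, SimulationParams, simulate
        from intronscape import RunConfig, analyze

        params = SimulationParams(
            tree=FIXTURE_TREE, n_genes=1, cds_length=600,
            ile_gain_rate=0, rsi_gain_rate=0, loss_rate=0,
            n_ancestral_introns=0,
            forced_events=(ForcedEvent(("s05", "s08"), "RSI_GAIN", "g001", 300),),
            seed=0,
        )
        sim = simulate(params)
        res = analyze(sim.gene_models, sim.alignments, sim.tree, (), RunConfig())
        ls = res.landscapes["g001"]
        present = {sp for sp in ls.species if ls.state(300, sp) is Status.PRESENT}
        assert present == {"s05", "s06", "s07", "s08"}
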