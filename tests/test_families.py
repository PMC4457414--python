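"""ILE family clustering, consensus, assignment and classification."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intronscape.core import IntronClass, IntronInstance
from intronscape.families import (
    ClassifyParams,
    IleFamily,
    UsageError,
    assign_to_family,
    build_families,
    classify_intron,
    consensus,
    family_activity,
    pairwise_identity,
)

SEQ = st.text(alphabet="ACGT", min_size=8, max_size=40)


def _intron(seq, gene="g", ordinal=0):
    return IntronInstance(gene, "sp", ordinal, 30, seq)


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("GTAAGT", "GTAAGT") == 1.0

    def test_single_mismatch(self):
        assert pairwise_identity("GTAAGTACGA", "GTAAGTACGT") == pytest.approx(0.9)

    def test_no_shared_bases(self):
        assert pairwise_identity("AAAA", "TTTT") == 0.0

    def test_empty_rejected(self):
        with pytest.raises(UsageError):
            pairwise_identity("", "ACGT")

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(SEQ, SEQ)
    def test_symmetric_and_bounded(self, a, b):
        ab = pairwise_identity(a, b)
        assert 0.0 <= ab <= 1.0
        assert ab == pytest.approx(pairwise_identity(b, a))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(SEQ)
    def test_self_identity_is_one(self, a):
        assert pairwise_identity(a, a) == 1.0

    def test_iupac_code_matches_contained_base(self):
        assert pairwise_identity("ACGT", "ACGN", iupac=True) == 1.0
        assert pairwise_identity("ACGA", "ACGR", iupac=True) == 1.0  # R = A/G


class TestBuildFamilies:
    def test_identical_sequences_form_one_family(self):
        seqs = [(f"i{k}", "GT" + "ACGT" * 14 + "AG") for k in range(3)]
        (fam,) = build_families(seqs)
        assert fam.size == 3
        assert fam.max_pairwise_identity == 1.0
        assert fam.consensus == seqs[0][1]

    def test_two_distinct_groups_split(self):
        rng = random.Random(0)
        a = "GT" + "".join(rng.choice("ACGT") for _ in range(56)) + "AG"
        b = "GT" + "".join(rng.choice("ACGT") for _ in range(56)) + "AG"
        fams = build_families([("a1", a), ("a2", a), ("b1", b), ("b2", b)])
        assert sorted(f.size for f in fams) == [2, 2]
        member_sets = [set(m for m, _ in f.members) for f in fams]
        assert {"a1", "a2"} in member_sets and {"b1", "b2"} in member_sets

    def test_threshold_one_gives_singletons(self):
        fams = build_families(
            [("x", "GTAAACCCAG"), ("y", "GTAAACCCAC")], threshold=1.0
        )
        assert [f.size for f in fams] == [1, 1]

    def test_empty_input_rejected(self):
        with pytest.raises(UsageError):
            build_families([])

    def test_partition_property(self):
        rng = random.Random(3)
        seqs = [
            (f"s{k}", "GT" + "".join(rng.choice("ACGT") for _ in range(50)) + "AG")
            for k in range(12)
        ]
        fams = build_families(seqs)
        all_members = [m for f in fams for m, _ in f.members]
        assert sorted(all_members) == sorted(i for i, _ in seqs)

    def test_refinement_monotone_in_threshold(self):
        rng = random.Random(4)
        base = "GT" + "".join(rng.choice("ACGT") for _ in range(60)) + "AG"
        seqs = []
        for k in range(8):
            s = list(base)
            for _ in range(k):  # increasingly diverged copies
                s[rng.randrange(2, len(s) - 2)] = rng.choice("ACGT")
            seqs.append((f"v{k}", "".join(s)))
        for lo, hi in [(0.5, 0.8), (0.8, 0.95), (0.95, 1.0)]:
            coarse = build_families(seqs, threshold=lo)
            fine = build_families(seqs, threshold=hi)
            coarse_of = {m: f.name for f in coarse for m, _ in f.members}
            fine_groups = [set(m for m, _ in f.members) for f in fine]
            for grp in fine_groups:  # every fine cluster sits in one coarse cluster
                assert len({coarse_of[m] for m in grp}) == 1


class TestConsensus:
    def test_single_sequence_is_identity(self):
        assert consensus(["GTACGTAG"]) == "GTACGTAG"

    def test_majority_base_wins(self):
        assert consensus(["A", "A", "A", "C"]) == "A"

    def test_tie_becomes_iupac(self):
        assert consensus(["A", "A", "C", "C"]) == "M"

    def test_all_gap_column_dropped(self):
        assert consensus(["A-G", "A-G"]) == "AG"

    def test_unequal_lengths_rejected(self):
        with pytest.raises(UsageError):
            consensus(["AAA", "AA"])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(SEQ, st.integers(1, 5))
    def test_consensus_of_identical_copies(self, seq, k):
        assert consensus([seq] * k) == seq


class TestAssignment:
    FAMS = [
        IleFamily.from_consensus("cf01", "GTAAGT" + "ACGT" * 12 + "TTAG"),
        IleFamily.from_consensus("cf02", "GTGAGT" + "CCGA" * 12 + "CTAG"),
    ]

    def test_exact_consensus_match(self):
        hit = assign_to_family("q", self.FAMS[0].consensus, self.FAMS)
        assert hit.family_name == "cf01"
        assert hit.identity_to_consensus == 1.0

    def test_ambiguity_code_counts_as_match(self):
        fams = [IleFamily.from_consensus("f", "GTAAGTAAACCCGGGTTTAG".replace("C", "N"))]
        hit = assign_to_family("q", "GTAAGTAAACCCGGGTTTAG", fams, min_identity=0.9)
        assert hit.family_name == "f"
        assert hit.identity_to_consensus == 1.0

    def test_below_min_identity_returns_none(self):
        hit = assign_to_family("q", "GT" + "TTTTAAAA" * 7 + "AG", self.FAMS,
                               min_identity=0.9)
        assert hit.family_name is None


class TestClassifyAndActivity:
    FAMS = [IleFamily.from_consensus("cf01", "GTAAGT" + "ACGT" * 15 + "TTAG")]

    def test_family_hit_is_ile(self):
        intron = _intron(self.FAMS[0].consensus)
        assert classify_intron(intron, self.FAMS) is IntronClass.ILE

    def test_short_orphan_is_rsi(self):
        rng = random.Random(9)
        intron = _intron("GT" + "".join(rng.choice("ACGT") for _ in range(48)) + "AG")
        assert classify_intron(intron, self.FAMS) is IntronClass.RSI

    def test_long_orphan_is_degenerate_candidate(self):
        rng = random.Random(10)
        intron = _intron("GT" + "".join(rng.choice("ACGT") for _ in range(81)) + "AG")
        assert classify_intron(intron, self.FAMS) is IntronClass.DEGENERATE_ILE_CANDIDATE

    def test_odd_length_orphan_unclassified(self):
        intron = _intron("GTAAGCCTTAG")  # 11 bp: below the RSI range
        assert classify_intron(intron, self.FAMS) is IntronClass.UNCLASSIFIED

    def test_activity(self):
        fam = IleFamily("f", [("a", "x"), ("b", "x")], "x",
                        max_pairwise_identity=1.0, mean_pairwise_identity=1.0)
        assert family_activity(fam) == "ACTIVE"
        fam.max_pairwise_identity = 0.85
        assert family_activity(fam) == "DEGENERATE"
        singleton = IleFamily("s", [("a", "x")], "x")
        assert family_activity(singleton) is None
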