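"""Introner-like element (ILE) families.

An ILE family is a cluster of near-identical intron sequences that have
multiplied through a genome.  Families are built by single-linkage
clustering of pairwise sequence identity (>80% by default, the conventional
threshold for introner detection in fungi), summarised by an IUPAC consensus
sequence, and used to classify introns: a landscape intron that matches a
family consensus is an ILE (a recent gain), a short non-matching intron is a
regular spliceosomal intron (RSI; typically 50–55 bp in these fungi), and a
long non-matching intron is a candidate degenerated ILE.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from statistics import mean
from typing import Iterable, Optional, Sequence

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.IUPACData import ambiguous_dna_values

from .core import IntronClass, IntronInstance

IUPAC_ALPHABET = "ACGTRYSWKMBDHVN"

#: IUPAC code → set of bases it covers.
IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}
#: frozenset of bases → smallest IUPAC code covering them.
SET_TO_IUPAC: dict[frozenset[str], str] = {
    frozenset(bases): code
    for code, bases in ambiguous_dna_values.items()
    if code in IUPAC_ALPHABET
}


class UsageError(ValueError):
    pass


# ---------------------------------------------------------------------------
# pairwise identity
# ---------------------------------------------------------------------------


def _make_aligner(iupac: bool) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if iupac:
        m = substitution_matrices.Array(IUPAC_ALPHABET, dims=2)
        for a in IUPAC_ALPHABET:
            for b in IUPAC_ALPHABET:
                if IUPAC_SETS[a] & IUPAC_SETS[b]:
                    m[a, b] = 1.0
        aligner.substitution_matrix = m
    else:
        aligner.match_score = 1.0
        aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    aligner.end_gap_score = 0.0  # end-gap-free: trimmed ends are not penalised
    return aligner


_ALIGNER = _make_aligner(iupac=False)
_IUPAC_ALIGNER = _make_aligner(iupac=True)


def _bases_match(a: str, b: str) -> bool:
    """IUPAC-aware base comparison: codes match when their sets intersect."""
    sa = IUPAC_SETS.get(a.upper())
    sb = IUPAC_SETS.get(b.upper())
    if sa is None or sb is None:
        return a.upper() == b.upper()
    return bool(sa & sb)


def _alignment_identity(
    row_a: str, row_b: str, min_len: int, min_overlap_frac: float
) -> float:
    """Identity over the end-trimmed span of one pairwise alignment.

    The span runs from the first to the last column where both rows are
    non-gap; internal gap columns count in the denominator.  When
    ``min_overlap_frac`` > 0 the denominator is floored at that fraction of
    the shorter input, so a tiny chance overlap cannot masquerade as high
    identity.
    """
    both = [i for i, (x, y) in enumerate(zip(row_a, row_b)) if x != "-" and y != "-"]
    if not both:
        denom = 0
        matches = 0
    else:
        lo, hi = both[0], both[-1] + 1
        denom = hi - lo
        matches = sum(
            1
            for x, y in zip(row_a[lo:hi], row_b[lo:hi])
            if x != "-" and y != "-" and _bases_match(x, y)
        )
    floor = int(round(min_overlap_frac * min_len))
    denom = max(denom, floor)
    return matches / denom if denom else 0.0


def pairwise_identity(
    a: str, b: str, *, iupac: bool = False, min_overlap_frac: float = 0.0
) -> float:
    """Fraction of identical positions in an end-gap-free global alignment.

    Scoring is match=1 / mismatch=0 / gap=-1 with free end gaps; the identity
    denominator is the end-trimmed alignment length including internal gaps.
    Symmetric; in [0, 1].
    """
    if not a or not b:
        raise UsageError("pairwise_identity requires non-empty sequences")
    a, b = a.upper(), b.upper()
    if b < a:  # canonical order makes the tie-break exactly symmetric
        a, b = b, a
    aligner = _IUPAC_ALIGNER if iupac else _ALIGNER
    aln = aligner.align(a, b)[0]
    return _alignment_identity(aln[0], aln[1], min(len(a), len(b)), min_overlap_frac)


# ---------------------------------------------------------------------------
# family construction
# ---------------------------------------------------------------------------


@dataclass
class IleFamily:
    """A named cluster of near-identical intron sequences."""

    name: str
    members: list[tuple[str, str]]
    consensus: str
    max_pairwise_identity: Optional[float] = None
    mean_pairwise_identity: Optional[float] = None

    @property
    def size(self) -> int:
        return len(self.members)

    @classmethod
    def from_consensus(cls, name: str, consensus: str) -> "IleFamily":
        """A family known only by its consensus (e.g. from a prior survey)."""
        return cls(name=name, members=[(name, consensus)], consensus=consensus)


@dataclass
class FamilyAssignment:
    query_id: str
    family_name: Optional[str]
    identity_to_consensus: float


def align_members(seqs: Sequence[str]) -> list[str]:
    """Return the member sequences aligned to equal length.

    Equal-length inputs (substitution-only divergence, the common case for
    active ILE copies) are used as-is; otherwise the alignment is delegated
    to ``mafft``.
    """
    if len({len(s) for s in seqs}) == 1:
        return [s.upper() for s in seqs]
    mafft = shutil.which("mafft")
    if mafft is None:
        raise UsageError(
            "members have unequal lengths and mafft is not on PATH"
        )
    with tempfile.TemporaryDirectory() as tmp:
        fa = Path(tmp) / "in.fa"
        fa.write_text(
            "".join(f">m{i}\n{s}\n" for i, s in enumerate(seqs))
        )
        out = subprocess.run(
            [mafft, "--quiet", "--retree", "2", str(fa)],
            capture_output=True,
            text=True,
            check=True,
        ).stdout
    aligned: dict[str, str] = {}
    name = None
    for line in out.splitlines():
        if line.startswith(">"):
            name = line[1:].strip()
            aligned[name] = ""
        elif name is not None:
            aligned[name] += line.strip()
    return [aligned[f"m{i}"].upper() for i in range(len(seqs))]


def consensus(aligned: Sequence[str]) -> str:
    """IUPAC consensus of aligned member sequences.

    Per column: the majority base when one base reaches ≥50% (of non-gap
    characters) with no tie, otherwise the smallest IUPAC code covering all
    bases at frequency ≥25% (or all observed bases when none reaches 25%).
    All-gap columns are dropped.
    """
    if not aligned:
        raise UsageError("consensus of zero sequences")
    if len({len(s) for s in aligned}) != 1:
        raise UsageError("consensus requires equal-length aligned members")
    out = []
    for col in zip(*[s.upper() for s in aligned]):
        bases = [c for c in col if c != "-"]
        if not bases:
            continue
        counts: dict[str, int] = {}
        for c in bases:
            counts[c] = counts.get(c, 0) + 1
        n = len(bases)
        top = max(counts.values())
        leaders = [c for c, k in counts.items() if k == top]
        if top / n >= 0.5 and len(leaders) == 1:
            out.append(leaders[0])
            continue
        covered = frozenset(c for c, k in counts.items() if k / n >= 0.25)
        if not covered:
            covered = frozenset(counts)
        out.append(SET_TO_IUPAC.get(covered, "N"))
    return "".join(out)


def build_families(
    seqs: Sequence[tuple[str, str]] | dict,
    threshold: float = 0.80,
    *,
    min_overlap_frac: float = 0.5,
    name_prefix: str = "fam",
) -> list[IleFamily]:
    """Single-linkage clustering of sequences under identity > ``threshold``.

    ``seqs`` is a sequence of ``(id, sequence)`` pairs (or a mapping).
    Families are ordered by size (descending), then by lexicographically
    smallest member id; members within a family are sorted by id.  The
    inequality is strict, matching the conventional ">80% identity" rule.
    """
    if isinstance(seqs, dict):
        seqs = list(seqs.items())
    if not seqs:
        raise UsageError("build_families requires at least one sequence")
    ids = [i for i, _ in seqs]
    if len(set(ids)) != len(ids):
        raise UsageError("duplicate sequence ids")
    g = nx.Graph()
    g.add_nodes_from(ids)
    ident: dict[frozenset, float] = {}
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            idv = pairwise_identity(
                seqs[i][1], seqs[j][1], min_overlap_frac=min_overlap_frac
            )
            ident[frozenset({ids[i], ids[j]})] = idv
            if idv > threshold:
                g.add_edge(ids[i], ids[j])
    by_id = dict(seqs)
    clusters = sorted(
        (sorted(comp) for comp in nx.connected_components(g)),
        key=lambda members: (-len(members), members[0]),
    )
    families = []
    for rank, members in enumerate(clusters, start=1):
        pair_ids = [
            ident[frozenset({a, b})]
            for k, a in enumerate(members)
            for b in members[k + 1:]
        ]
        aligned = align_members([by_id[m] for m in members])
        families.append(
            IleFamily(
                name=f"{name_prefix}{rank:02d}",
                members=[(m, by_id[m]) for m in members],
                consensus=consensus(aligned),
                max_pairwise_identity=max(pair_ids) if pair_ids else None,
                mean_pairwise_identity=mean(pair_ids) if pair_ids else None,
            )
        )
    return families


def assign_to_family(
    query_id: str,
    query_seq: str,
    families: Sequence[IleFamily],
    min_identity: float = 0.70,
    *,
    min_overlap_frac: float = 0.6,
) -> FamilyAssignment:
    """Assign a query to the best-matching family consensus.

    Matching is IUPAC-aware (a base matches any code containing it).  Ties
    break deterministically on family order.  ``family_name`` is None when
    the best identity falls below ``min_identity``.
    """
    if not families:
        raise UsageError("assign_to_family requires at least one family")
    best_name, best_identity = None, -1.0
    for fam in families:
        idv = pairwise_identity(
            query_seq, fam.consensus, iupac=True, min_overlap_frac=min_overlap_frac
        )
        if idv > best_identity:
            best_name, best_identity = fam.name, idv
    if best_identity < min_identity:
        return FamilyAssignment(query_id, None, max(best_identity, 0.0))
    return FamilyAssignment(query_id, best_name, best_identity)


# ---------------------------------------------------------------------------
# classification and activity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassifyParams:
    """Thresholds for intron classification.

    ``rsi_range`` brackets the regular spliceosomal intron lengths typical of
    these fungi (50–55 bp, bracketed generously); introns at or above
    ``long_intron_threshold`` that match no family are candidate degenerated
    ILEs (known cases are 81 and 87 bp).
    """

    min_identity: float = 0.70
    rsi_range: tuple[int, int] = (40, 60)
    long_intron_threshold: int = 70
    min_overlap_frac: float = 0.6


def classify_intron(
    intron: IntronInstance,
    families: Sequence[IleFamily],
    params: ClassifyParams = ClassifyParams(),
) -> IntronClass:
    """ILE / RSI / degenerate-ILE-candidate / unclassified for one intron."""
    if families:
        hit = assign_to_family(
            f"{intron.gene_id}:{intron.ordinal}",
            intron.sequence,
            families,
            min_identity=params.min_identity,
            min_overlap_frac=params.min_overlap_frac,
        )
        if hit.family_name is not None:
            return IntronClass.ILE
    if intron.length >= params.long_intron_threshold:
        return IntronClass.DEGENERATE_ILE_CANDIDATE
    lo, hi = params.rsi_range
    if lo <= intron.length <= hi:
        return IntronClass.RSI
    return IntronClass.UNCLASSIFIED


def family_activity(
    family: IleFamily, activity_threshold: float = 0.98
) -> Optional[str]:
    """ACTIVE when the family's best pair is ≥98% identical, else DEGENERATE.

    A family still multiplying leaves near-identical recent copies; returns
    ``None`` (undetermined) for singleton families.
    """
    if family.size < 2 or family.max_pairwise_identity is None:
        return None
    return (
        "ACTIVE"
        if family.max_pairwise_identity >= activity_threshold
        else "DEGENERATE"
    )
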