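"""Domain types and coordinate arithmetic for gene structures and introns.

Conventions used throughout the package:

* Genomic intervals are 0-based, half-open ``(start, end)``.
* A gene's exons are stored in **transcript** order (5'→3' along the mRNA);
  for a '-' strand gene the first exon therefore has the largest genomic
  coordinates.
* ``cds_offset`` of an intron is the number of coding nucleotides 5' of the
  intron, so the intron phase is simply ``cds_offset % 3``.
* An intron position projected onto a protein alignment is a
  ``(column, phase)`` pair; the scalar ``alignment_frame_offset``
  (``3 * column + phase``) uniquely identifies a position within one
  alignment and makes nucleotide-scale distances between positions a plain
  absolute difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
from Bio.Seq import Seq

MIN_INTRON_LEN = 4

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class StructuralError(ValueError):
    """A gene model violates its structural invariants."""


class ProjectionError(ValueError):
    """An intron cannot be projected onto the given alignment row."""


class IntronClass(str, Enum):
    ILE = "ILE"
    RSI = "RSI"
    DEGENERATE_ILE_CANDIDATE = "DEGENERATE_ILE_CANDIDATE"
    UNCLASSIFIED = "UNCLASSIFIED"


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return str(Seq(seq).reverse_complement())


def translate(cds: str) -> str:
    return str(Seq(cds).translate())


@dataclass(frozen=True)
class GeneModel:
    """One species' gene as ordered exons on a genomic sequence.

    ``exons`` are genomic intervals in transcript orientation.  The model is
    validated on construction: exons must be non-empty, pairwise disjoint,
    sorted 5'→3' along the transcript, and every inter-exon gap (intron)
    must be at least :data:`MIN_INTRON_LEN` nucleotides long.
    """

    gene_id: str
    species: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    genomic_seq: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise StructuralError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise StructuralError(f"{self.gene_id}: gene model has no exons")
        n = len(self.genomic_seq)
        for s, e in self.exons:
            if not (0 <= s < e <= n):
                raise StructuralError(
                    f"{self.gene_id}: exon ({s},{e}) outside genomic sequence"
                )
        ivals = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if e1 > s2:
                raise StructuralError(f"{self.gene_id}: overlapping exons")
        expect = ivals if self.strand == "+" else ivals[::-1]
        if tuple(expect) != self.exons:
            raise StructuralError(
                f"{self.gene_id}: exons not sorted in transcript orientation"
            )
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 - e1 < MIN_INTRON_LEN:
                raise StructuralError(
                    f"{self.gene_id}: intron between ({s1},{e1}) and ({s2},{e2}) "
                    f"shorter than {MIN_INTRON_LEN} nt"
                )

    # -- derived sequence views ------------------------------------------

    def exon_sequences(self) -> list[str]:
        """Exon sequences in transcript orientation (strand-corrected)."""
        out = []
        for s, e in self.exons:
            sub = self.genomic_seq[s:e]
            out.append(sub if self.strand == "+" else revcomp(sub))
        return out

    def cds(self) -> str:
        """Spliced coding sequence in reading orientation."""
        return "".join(self.exon_sequences())

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_partial(self) -> bool:
        """True when the spliced CDS length is not a multiple of 3."""
        return self.cds_length % 3 != 0

    def protein(self) -> str:
        """Translated CDS, trailing stop stripped."""
        aa = translate(self.cds()[: self.cds_length - self.cds_length % 3])
        return aa[:-1] if aa.endswith("*") else aa

    def has_internal_stop(self) -> bool:
        """Pseudogene signal: an in-frame stop before the final codon."""
        return "*" in self.protein()


@dataclass
class IntronInstance:
    """A single intron of one gene: its coding-frame position and sequence."""

    gene_id: str
    species: str
    ordinal: int
    cds_offset: int
    sequence: str
    intron_class: IntronClass = IntronClass.UNCLASSIFIED

    def __post_init__(self) -> None:
        if self.cds_offset < 0:
            raise StructuralError(f"{self.gene_id}: negative cds_offset")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def donor(self) -> str:
        return self.sequence[:2]

    @property
    def acceptor(self) -> str:
        return self.sequence[-2:]

    @property
    def is_canonical(self) -> bool:
        return self.donor == "GT" and self.acceptor == "AG"

    @property
    def phase(self) -> int:
        return self.cds_offset % 3


def extract_introns(gene: GeneModel) -> list[IntronInstance]:
    """One :class:`IntronInstance` per inter-exon gap, in transcript order.

    ``cds_offset`` is the cumulative exon length 5' of the gap; intron
    sequences are strand-corrected into transcript orientation.
    """
    introns: list[IntronInstance] = []
    offset = 0
    total = gene.cds_length
    for i in range(len(gene.exons) - 1):
        offset += gene.exons[i][1] - gene.exons[i][0]
        if gene.strand == "+":
            gap = (gene.exons[i][1], gene.exons[i + 1][0])
            seq = gene.genomic_seq[gap[0]: gap[1]]
        else:
            gap = (gene.exons[i + 1][1], gene.exons[i][0])
            seq = revcomp(gene.genomic_seq[gap[0]: gap[1]])
        if offset >= total:  # cannot happen for a validated model
            raise StructuralError(f"{gene.gene_id}: intron after CDS end")
        introns.append(
            IntronInstance(
                gene_id=gene.gene_id,
                species=gene.species,
                ordinal=i,
                cds_offset=offset,
                sequence=seq,
            )
        )
    return introns


@dataclass(frozen=True)
class ProjectedIntronPosition:
    """An intron position in protein-alignment coordinates.

    ``column`` is the 0-based alignment column of the codon containing the
    intron (phase 1/2) or immediately following it (phase 0).
    """

    column: int
    phase: int
    alignment_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.phase not in (0, 1, 2):
            raise ValueError("phase must be 0, 1 or 2")
        if self.column < 0:
            raise ValueError("column must be non-negative")

    @property
    def alignment_frame_offset(self) -> int:
        return 3 * self.column + self.phase


class ProteinAlignment:
    """A protein multiple alignment: species → equal-length gapped rows."""

    def __init__(self, rows: Mapping[str, str], alignment_id: str = "aln"):
        rows = dict(rows)
        if not rows:
            raise ValueError("alignment has no rows")
        lengths = {len(r) for r in rows.values()}
        if len(lengths) != 1:
            raise ValueError("alignment rows have unequal lengths")
        self.rows = rows
        self.alignment_id = alignment_id
        self.length = lengths.pop()

    def __contains__(self, species: str) -> bool:
        return species in self.rows

    def row(self, species: str) -> str:
        return self.rows[species]

    @property
    def species(self) -> list[str]:
        return sorted(self.rows)


def project_position(
    intron: IntronInstance | int,
    row: str,
    alignment_id: Optional[str] = None,
) -> ProjectedIntronPosition:
    """Map an intron (or a raw ``cds_offset``) onto a gapped protein row.

    The column is that of the ``cds_offset // 3``-th non-gap residue of the
    row; the phase is ``cds_offset % 3``.  Raises :class:`ProjectionError`
    when the offset lies beyond the row's coding capacity.
    """
    cds_offset = intron if isinstance(intron, int) else intron.cds_offset
    if cds_offset < 0:
        raise ProjectionError("negative cds_offset")
    residue_index = cds_offset // 3
    phase = cds_offset % 3
    seen = 0
    for col, ch in enumerate(row):
        if ch != "-":
            if seen == residue_index:
                return ProjectedIntronPosition(col, phase, alignment_id)
            seen += 1
    # phase-0 intron immediately before a residue that is the (seen)-th:
    raise ProjectionError(
        f"cds_offset {cds_offset} beyond row capacity ({seen} residues)"
    )


def unproject_position(pos: ProjectedIntronPosition, row: str) -> int:
    """Inverse of :func:`project_position` for the same row."""
    if pos.column >= len(row):
        raise ProjectionError("column beyond alignment length")
    if row[pos.column] == "-":
        raise ProjectionError("position column is a gap in this row")
    residues_before = sum(1 for ch in row[: pos.column] if ch != "-")
    return 3 * residues_before + pos.phase


def position_distance(a: ProjectedIntronPosition, b: ProjectedIntronPosition) -> int:
    """Nucleotide distance between two positions of one alignment."""
    if (
        a.alignment_id is not None
        and b.alignment_id is not None
        and a.alignment_id != b.alignment_id
    ):
        raise ValueError(
            f"positions from different alignments: {a.alignment_id!r} vs "
            f"{b.alignment_id!r}"
        )
    return abs(a.alignment_frame_offset - b.alignment_frame_offset)


class Phylogeny:
    """A rooted species tree with leaf names equal to species names.

    Thin wrapper over :mod:`dendropy` adding the clade/leaf-set queries the
    landscape classification needs.  Internal nodes are labelled
    deterministically by their sorted leaf set joined with ``+``.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._leafsets: dict[int, frozenset[str]] = {}
        labels = []
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                name = nd.taxon.label.replace(" ", "_") if nd.taxon else nd.label
                if not name:
                    raise ValueError("tree has an unnamed leaf")
                ls = frozenset({name})
            else:
                ls = frozenset().union(
                    *(self._leafsets[id(c)] for c in nd.child_nodes())
                )
            self._leafsets[id(nd)] = ls
            labels.append(ls)
        leaves = [l for l in labels if len(l) == 1]
        names = [next(iter(l)) for l in leaves]
        if len(set(names)) != len(names):
            raise ValueError("leaf names are not unique")
        self.leaves: tuple[str, ...] = tuple(sorted(names))

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        return cls(tree)

    # -- queries ----------------------------------------------------------

    def node_label(self, node) -> str:
        return "+".join(sorted(self._leafsets[id(node)]))

    def leafset(self, node) -> frozenset[str]:
        return self._leafsets[id(node)]

    def clade_leafsets(self) -> list[frozenset[str]]:
        """Leaf sets of every node (leaves included), root first."""
        return [self._leafsets[id(nd)] for nd in self.tree.preorder_node_iter()]

    def is_monophyletic(
        self, species: Iterable[str], restrict_to: Optional[Iterable[str]] = None
    ) -> bool:
        """Does some node's leaf set (∩ ``restrict_to``) equal ``species``?

        ``restrict_to`` lists the species actually scored; leaves outside it
        (e.g. species with no orthologue) are ignored when testing monophyly.
        """
        target = frozenset(species)
        restrict = frozenset(restrict_to) if restrict_to is not None else None
        if not target:
            return False
        for ls in self._leafsets.values():
            eff = ls if restrict is None else ls & restrict
            if eff == target:
                return True
        return False

    def mrca_leafset(self, species: Iterable[str]) -> frozenset[str]:
        """Leaf set of the most recent common ancestor of ``species``."""
        target = frozenset(species)
        if not target:
            raise ValueError("mrca of an empty species set")
        unknown = target - set(self.leaves)
        if unknown:
            raise ValueError(f"species not in tree: {sorted(unknown)}")
        best: Optional[frozenset[str]] = None
        for ls in self._leafsets.values():
            if target <= ls and (best is None or len(ls) < len(best)):
                best = ls
        assert best is not None
        return best

    def mrca_node(self, species: Iterable[str]):
        target = frozenset(species)
        best = None
        for nd in self.tree.preorder_node_iter():
            ls = self._leafsets[id(nd)]
            if target <= ls and (best is None or len(ls) < len(self._leafsets[id(best)])):
                best = nd
        if best is None:
            raise ValueError("species not found in tree")
        return best

    def preorder_edges(self):
        """Yield ``(parent_node, child_node, branch_length)`` preorder."""
        for nd in self.tree.preorder_node_iter():
            for child in nd.child_nodes():
                yield nd, child, child.edge.length
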