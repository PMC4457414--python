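"""Forward simulation of orthologous gene families with intron dynamics.

Genes evolve along a rooted, branch-length-scaled phylogeny.  Each gene
starts as a stop-free random CDS at the root (optionally with ancestral
introns) and accumulates, along every branch:

* nucleotide substitutions in exons (stop-avoiding) and intron interiors
  (the terminal GT/AG dinucleotides are kept intact so every simulated
  intron stays canonical);
* ILE gains — a mutated copy of a family consensus inserted at a uniform
  random coding position;
* RSI gains — a fresh random 45–60 bp GT…AG intron;
* losses — precise excision of one existing intron.

Event counts are Poisson with mean rate × branch length (branch lengths are
expected substitutions per site; event rates are per gene per unit branch
length).  Every event is logged with the branch, gene, coding offset and
resulting intron length; replaying the log from the root reproduces each
leaf's gene *structure* exactly (sequences additionally carry the neutral
substitutions, which are not events).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core import (
    GeneModel,
    Phylogeny,
    ProteinAlignment,
    STOP_CODONS,
    revcomp,
)

BASES = "ACGT"


@dataclass(frozen=True)
class ForcedEvent:
    """A deterministic event placed on a specific branch.

    ``clade`` is a tuple of leaf names whose MRCA's parent branch carries the
    event, or the string ``"root"`` for a state present in the root ancestor.
    """

    clade: tuple[str, ...] | str
    type: str  # ILE_GAIN | RSI_GAIN | LOSS
    gene_id: str
    cds_offset: int
    family: Optional[str] = None


@dataclass(frozen=True)
class TrueEvent:
    branch: str  # label of the child node of the branch (or "root")
    gene_id: str
    type: str
    cds_offset: int
    family: Optional[str]
    length: int


@dataclass
class SimulationParams:
    """Simulation conditions.

    Rates are per gene per unit branch length except ``subst_rate``
    (per site per unit branch length) and ``ile_copy_mutation`` (per-site
    substitution probability applied once to each new ILE copy).
    """

    tree: str | Phylogeny
    n_genes: int = 20
    cds_length: int = 1500
    subst_rate: float = 0.02
    ile_gain_rate: float = 0.15
    rsi_gain_rate: float = 0.25
    loss_rate: float = 0.1
    ile_families: Mapping[str, str] = field(default_factory=dict)
    ile_copy_mutation: float = 0.01
    n_ancestral_introns: int = 2
    rsi_length_range: tuple[int, int] = (45, 60)
    forced_events: Sequence[ForcedEvent] = ()
    seed: int = 0
    flank_length: int = 20
    alternate_strands: bool = True

    def __post_init__(self) -> None:
        for r in (self.subst_rate, self.ile_gain_rate, self.rsi_gain_rate,
                  self.loss_rate, self.ile_copy_mutation):
            if r < 0:
                raise ValueError("rates must be non-negative")
        if self.cds_length % 3:
            raise ValueError("cds_length must be a multiple of 3")


@dataclass
class _Intron:
    sequence: str
    family: Optional[str] = None  # family name for ILE copies, None for RSIs


@dataclass
class _GeneState:
    cds: str
    introns: dict[int, _Intron] = field(default_factory=dict)

    def copy(self) -> "_GeneState":
        return _GeneState(
            self.cds, {k: _Intron(v.sequence, v.family) for k, v in self.introns.items()}
        )


@dataclass
class SimulationResult:
    params: SimulationParams
    tree: Phylogeny
    gene_models: dict[str, dict[str, GeneModel]]  # species -> gene_id -> model
    events: list[TrueEvent]
    alignments: dict[str, ProteinAlignment]  # gene_id -> protein alignment
    root_structures: dict[str, dict[int, int]]  # gene_id -> offset -> length

    @property
    def species(self) -> list[str]:
        return sorted(self.gene_models)

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.alignments)


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """ATG + random internal non-stop codons + TAA."""
    n_codons = length // 3
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list(BASES), size=3))
        if c not in STOP_CODONS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _mutate_cds(rng: np.random.Generator, cds: str, p: float) -> str:
    """Per-site substitutions that never introduce an in-frame stop."""
    if p <= 0:
        return cds
    arr = list(cds)
    hits = np.flatnonzero(rng.random(len(arr)) < min(p, 0.75))
    for i in hits:
        if i >= len(arr) - 3:  # keep the terminal stop codon intact
            continue
        old = arr[i]
        new = BASES[rng.integers(4)]
        if new == old:
            continue
        arr[i] = new
        codon_start = 3 * (i // 3)
        codon = "".join(arr[codon_start: codon_start + 3])
        if codon in STOP_CODONS and codon_start + 3 < len(arr):
            arr[i] = old  # stop-avoidance: skip this substitution
    return "".join(arr)


def _mutate_intron(rng: np.random.Generator, seq: str, p: float) -> str:
    """Interior substitutions; the GT…AG boundary dinucleotides are kept."""
    if p <= 0 or len(seq) <= 4:
        return seq
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < min(p, 0.75))
    for i in hits:
        if i < 2 or i >= len(arr) - 2:
            continue
        arr[i] = BASES[rng.integers(4)]
    return "".join(arr)


def _random_intron(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    interior = "".join(rng.choice(list(BASES), size=length - 4))
    return "GT" + interior + "AG"


def _insertion_offset(
    rng: np.random.Generator, cds_len: int, taken: Iterable[int]
) -> Optional[int]:
    """Uniform coding position avoiding the start/stop codons and collisions."""
    taken = set(taken)
    for _ in range(50):
        off = int(rng.integers(3, cds_len - 3))
        if off not in taken:
            return off
    return None


def simulate(params: SimulationParams) -> SimulationResult:
    """Run the forward simulation; identical params give identical output."""
    tree = (
        params.tree
        if isinstance(params.tree, Phylogeny)
        else Phylogeny.from_newick(params.tree)
    )
    rng = np.random.default_rng(params.seed)
    gene_ids = [f"g{k + 1:03d}" for k in range(params.n_genes)]
    families = dict(params.ile_families)

    # forced events grouped by branch label ("root" or child-node label)
    forced_by_branch: dict[str, list[ForcedEvent]] = {}
    for ev in params.forced_events:
        if ev.clade == "root":
            label = "root"
        else:
            label = tree.node_label(tree.mrca_node(ev.clade))
        forced_by_branch.setdefault(label, []).append(ev)

    events: list[TrueEvent] = []

    def log(branch: str, gene: str, type_: str, off: int,
            family: Optional[str], length: int) -> None:
        events.append(TrueEvent(branch, gene, type_, off, family, length))

    def apply_forced(state: dict[str, _GeneState], ev: ForcedEvent,
                     branch_label: str) -> None:
        g = state[ev.gene_id]
        if ev.type == "LOSS":
            if ev.cds_offset not in g.introns:
                raise ValueError(
                    f"forced LOSS at {ev.gene_id}:{ev.cds_offset}: no intron there"
                )
            length = len(g.introns.pop(ev.cds_offset).sequence)
            log(branch_label, ev.gene_id, "LOSS", ev.cds_offset, None, length)
            return
        if ev.cds_offset in g.introns:
            raise ValueError(
                f"forced gain at occupied offset {ev.gene_id}:{ev.cds_offset}"
            )
        if ev.type == "ILE_GAIN":
            seed_seq = families[ev.family]
            seq = _mutate_intron(rng, seed_seq, params.ile_copy_mutation)
            g.introns[ev.cds_offset] = _Intron(seq, ev.family)
            log(branch_label, ev.gene_id, "ILE_GAIN", ev.cds_offset, ev.family,
                len(seq))
        elif ev.type == "RSI_GAIN":
            seq = _random_intron(rng, *params.rsi_length_range)
            g.introns[ev.cds_offset] = _Intron(seq, None)
            log(branch_label, ev.gene_id, "RSI_GAIN", ev.cds_offset, None,
                len(seq))
        else:
            raise ValueError(f"unknown forced event type {ev.type!r}")

    # root state
    root_state: dict[str, _GeneState] = {}
    for gid in gene_ids:
        g = _GeneState(_random_cds(rng, params.cds_length))
        for _ in range(params.n_ancestral_introns):
            off = _insertion_offset(rng, len(g.cds), g.introns)
            if off is not None:
                g.introns[off] = _Intron(
                    _random_intron(rng, *params.rsi_length_range)
                )
        root_state[gid] = g
    for ev in forced_by_branch.get("root", []):
        apply_forced(root_state, ev, "root")

    root_structures = {
        gid: {off: len(i.sequence) for off, i in g.introns.items()}
        for gid, g in root_state.items()
    }

    # traversal
    leaf_states: dict[str, dict[str, _GeneState]] = {}
    node_state = {id(tree.tree.seed_node): root_state}
    for parent, child, blen in tree.preorder_edges():
        if blen is None:
            raise ValueError("tree branches must carry lengths")
        state = {gid: g.copy() for gid, g in node_state[id(parent)].items()}
        child_label = tree.node_label(child)
        p_sub = params.subst_rate * blen
        for gid in gene_ids:
            g = state[gid]
            # stochastic events
            n_ile = rng.poisson(params.ile_gain_rate * blen) if families else 0
            n_rsi = rng.poisson(params.rsi_gain_rate * blen)
            n_loss = rng.poisson(params.loss_rate * blen)
            for _ in range(n_ile):
                off = _insertion_offset(rng, len(g.cds), g.introns)
                if off is None:
                    continue
                fam = sorted(families)[rng.integers(len(families))]
                seq = _mutate_intron(rng, families[fam], params.ile_copy_mutation)
                g.introns[off] = _Intron(seq, fam)
                log(child_label, gid, "ILE_GAIN", off, fam, len(seq))
            for _ in range(n_rsi):
                off = _insertion_offset(rng, len(g.cds), g.introns)
                if off is None:
                    continue
                seq = _random_intron(rng, *params.rsi_length_range)
                g.introns[off] = _Intron(seq, None)
                log(child_label, gid, "RSI_GAIN", off, None, len(seq))
            for _ in range(n_loss):
                if not g.introns:
                    break
                offs = sorted(g.introns)
                off = offs[rng.integers(len(offs))]
                length = len(g.introns.pop(off).sequence)
                log(child_label, gid, "LOSS", off, None, length)
            # substitutions
            g.cds = _mutate_cds(rng, g.cds, p_sub)
            for off in sorted(g.introns):
                intr = g.introns[off]
                intr.sequence = _mutate_intron(rng, intr.sequence, p_sub)
        for ev in forced_by_branch.get(child_label, []):
            apply_forced(state, ev, child_label)
        if child.is_leaf():
            leaf_states[child_label] = state
        else:
            node_state[id(child)] = state

    # emission
    gene_models: dict[str, dict[str, GeneModel]] = {}
    for sp in sorted(leaf_states):
        gene_models[sp] = {}
        for k, gid in enumerate(gene_ids):
            g = leaf_states[sp][gid]
            strand = "-" if params.alternate_strands and k % 2 else "+"
            flank5 = "".join(rng.choice(list(BASES), size=params.flank_length))
            flank3 = "".join(rng.choice(list(BASES), size=params.flank_length))
            gene_models[sp][gid] = _emit_gene(
                gid, sp, g, strand, flank5, flank3
            )

    alignments = {}
    for gid in gene_ids:
        rows = {
            sp: gene_models[sp][gid].protein() for sp in sorted(leaf_states)
        }
        lengths = {len(r) for r in rows.values()}
        if len(lengths) != 1:  # cannot happen: substitutions are length-neutral
            raise AssertionError("unequal protein lengths")
        alignments[gid] = ProteinAlignment(rows, alignment_id=gid)

    return SimulationResult(
        params=params,
        tree=tree,
        gene_models=gene_models,
        events=events,
        alignments=alignments,
        root_structures=root_structures,
    )


def _emit_gene(
    gene_id: str,
    species: str,
    g: _GeneState,
    strand: str,
    flank5: str,
    flank3: str,
) -> GeneModel:
    """Interleave CDS and introns into a genomic contig and exon intervals."""
    pieces = []
    exon_ivals = []  # sense-strand coordinates
    pos = len(flank5)
    pieces.append(flank5)
    prev = 0
    for off in sorted(g.introns):
        exon = g.cds[prev:off]
        pieces.append(exon)
        exon_ivals.append((pos, pos + len(exon)))
        pos += len(exon)
        intron = g.introns[off].sequence
        pieces.append(intron)
        pos += len(intron)
        prev = off
    last = g.cds[prev:]
    pieces.append(last)
    exon_ivals.append((pos, pos + len(last)))
    pos += len(last)
    pieces.append(flank3)
    sense = "".join(pieces)
    if strand == "+":
        return GeneModel(gene_id, species, "+", tuple(exon_ivals), sense)
    n = len(sense)
    minus_ivals = tuple((n - e, n - s) for s, e in exon_ivals)
    return GeneModel(gene_id, species, "-", minus_ivals, revcomp(sense))


def replay_events(
    root_structures: Mapping[str, Mapping[int, int]],
    events: Sequence[TrueEvent],
    tree: Phylogeny,
) -> dict[str, dict[str, dict[int, int]]]:
    """Replay the event log: species → gene → {cds_offset: intron length}.

    Independent of the simulator's internals: walks the tree, applying the
    logged events of each branch to the inherited structure.
    """
    root = {g: dict(s) for g, s in root_structures.items()}
    by_branch: dict[str, list[TrueEvent]] = {}
    for ev in events:
        by_branch.setdefault(ev.branch, []).append(ev)
    # root-branch events are already reflected in root_structures

    out: dict[str, dict[str, dict[int, int]]] = {}
    node_state = {id(tree.tree.seed_node): root}
    for parent, child, _ in tree.preorder_edges():
        state = {g: dict(s) for g, s in node_state[id(parent)].items()}
        label = tree.node_label(child)
        for ev in by_branch.get(label, []):
            if ev.type == "LOSS":
                state[ev.gene_id].pop(ev.cds_offset)
            else:
                state[ev.gene_id][ev.cds_offset] = ev.length
        if child.is_leaf():
            out[label] = state
        else:
            node_state[id(child)] = state
    return out


def structures_from_models(
    gene_models: Mapping[str, Mapping[str, GeneModel]],
) -> dict[str, dict[str, dict[int, int]]]:
    """Leaf gene structures (offset → intron length) read off the models."""
    from .core import extract_introns

    out: dict[str, dict[str, dict[int, int]]] = {}
    for sp, genes in gene_models.items():
        out[sp] = {}
        for gid, model in genes.items():
            out[sp][gid] = {
                i.cds_offset: i.length for i in extract_introns(model)
            }
    return out
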