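"""Positions × species intron landscapes and phylogeny-aware position calls.

For one orthologue set, every intron of every species is projected onto the
shared protein alignment; identical (column, phase) cells merge into one
position.  Each position is then read against the species tree:

* ``CONSERVED`` — present in every scored species;
* ``SINGLE_PRESENCE`` — present in exactly one species (a unique gain);
* ``SINGLE_PRESENCE_IN_CLADE`` — the present species form exactly one
  monophyletic clade of ≥2 leaves (one gain on an internal branch);
* ``SINGLE_ABSENCE`` — absent in exactly one species (one loss);
* ``PRESENCE_ABSENCE_POLYMORPHISM`` — any other pattern.

Species without an orthologue (or whose alignment row is gapped at the
position) contribute ``MISSING`` and are excluded from the classification
denominator: absence of evidence is not intron loss.

Pairs of positions closer than 15 nt in the alignment frame are "sliding"
candidates — classically read as one intron that shifted.  When one side of
such a pair carries only family-assigned ILEs (necessarily recent gains) and
the other carries regular spliceosomal introns in species outside the ILE
carrier's clade, sliding is excluded and the pair is called a parallel
intron gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .core import (
    GeneModel,
    IntronClass,
    IntronInstance,
    Phylogeny,
    ProjectedIntronPosition,
    ProteinAlignment,
    extract_introns,
    position_distance,
    project_position,
)
from .families import ClassifyParams, IleFamily, classify_intron

logger = logging.getLogger(__name__)

SLIDING_WINDOW_NT = 15


class Status(str, Enum):
    PRESENT = "PRESENT"
    ABSENT = "ABSENT"
    MISSING = "MISSING"


class Category(str, Enum):
    CONSERVED = "CONSERVED"
    SINGLE_PRESENCE = "SINGLE_PRESENCE"
    SINGLE_PRESENCE_IN_CLADE = "SINGLE_PRESENCE_IN_CLADE"
    PRESENCE_ABSENCE_POLYMORPHISM = "PRESENCE_ABSENCE_POLYMORPHISM"
    SINGLE_ABSENCE = "SINGLE_ABSENCE"


@dataclass
class SnapLogEntry:
    species: str
    gene_id: str
    from_afo: int
    to_afo: Optional[int]
    reason: str


@dataclass
class Landscape:
    """The landscape matrix of one orthologue set."""

    gene_id: str
    species: tuple[str, ...]
    positions: list[ProjectedIntronPosition]
    states: dict[tuple[int, str], Status]
    introns: dict[tuple[int, str], IntronInstance]
    pseudogene_flags: dict[str, bool]
    alignment_id: str
    snap_log: list[SnapLogEntry] = field(default_factory=list)

    def state(self, afo: int, species: str) -> Status:
        return self.states[(afo, species)]

    def states_row(self, afo: int) -> dict[str, Status]:
        return {sp: self.states[(afo, sp)] for sp in self.species}

    def classes_at(self, afo: int) -> dict[str, IntronClass]:
        return {
            sp: self.introns[(afo, sp)].intron_class
            for sp in self.species
            if (afo, sp) in self.introns
        }


@dataclass
class PositionCall:
    position: ProjectedIntronPosition
    category: Category
    sliding_partners: list[tuple[int, int]] = field(default_factory=list)
    parallel_gain: bool = False
    possible_parallel: bool = False
    ambiguous_coincident: bool = False
    evidence: str = ""

    @property
    def afo(self) -> int:
        return self.position.alignment_frame_offset


# ---------------------------------------------------------------------------
# boundary refinement
# ---------------------------------------------------------------------------


def _flank_identity(
    alignment: ProteinAlignment,
    species: str,
    carriers: Sequence[str],
    column: int,
    flank: int,
) -> float:
    """Mean cross-species identity of the residues flanking a junction column."""
    row = alignment.row(species)
    lo = max(0, column - flank)
    hi = min(alignment.length, column + flank)
    scores = []
    for other in carriers:
        orow = alignment.row(other)
        pairs = [
            (row[i], orow[i])
            for i in range(lo, hi)
            if row[i] != "-" and orow[i] != "-"
        ]
        if pairs:
            scores.append(sum(1 for a, b in pairs if a == b) / len(pairs))
    return sum(scores) / len(scores) if scores else 0.0


def refine_boundaries(
    projected: Mapping[str, dict[int, tuple[ProjectedIntronPosition, IntronInstance]]],
    alignment: ProteinAlignment,
    shift_window: int = 1,
    flank: int = 5,
) -> tuple[dict[str, dict[int, tuple[ProjectedIntronPosition, IntronInstance]]], list[SnapLogEntry]]:
    """Snap near-miss positions onto shared positions when flanks support it.

    This automates the manual curation step of correcting misaligned
    exon–intron–exon boundaries: a position within ``shift_window`` codons of
    a position held by ≥2 *other* species is snapped onto it when the
    cross-species flank identity around the junction is strictly higher
    there.  Ties between equally scoring candidates leave the position
    unchanged and flag it ambiguous.  Every decision is logged.
    """
    # census of positions per afo
    carriers: dict[int, set[str]] = {}
    for sp, by_afo in projected.items():
        for afo in by_afo:
            carriers.setdefault(afo, set()).add(sp)

    out: dict[str, dict[int, tuple[ProjectedIntronPosition, IntronInstance]]] = {}
    log: list[SnapLogEntry] = []
    for sp, by_afo in projected.items():
        out[sp] = {}
        for afo, (pos, intron) in sorted(by_afo.items()):
            candidates = []
            for cand_afo, cand_sp in carriers.items():
                others = cand_sp - {sp}
                if cand_afo == afo or len(others) < 2:
                    continue
                if abs(cand_afo // 3 - pos.column) > shift_window:
                    continue
                score = _flank_identity(
                    alignment, sp, sorted(others), cand_afo // 3, flank
                )
                base = _flank_identity(
                    alignment, sp, sorted(others), pos.column, flank
                )
                if score > base:
                    candidates.append((score, cand_afo))
            new_pos = pos
            if candidates:
                candidates.sort(key=lambda t: (-t[0], t[1]))
                best_score = candidates[0][0]
                tied = [c for c in candidates if c[0] == best_score]
                if len(tied) > 1:
                    log.append(
                        SnapLogEntry(sp, intron.gene_id, afo, None, "ambiguous tie")
                    )
                else:
                    target = tied[0][1]
                    new_pos = ProjectedIntronPosition(
                        target // 3, target % 3, pos.alignment_id
                    )
                    log.append(
                        SnapLogEntry(
                            sp, intron.gene_id, afo, target,
                            f"flank identity {best_score:.3f} improved",
                        )
                    )
                    logger.debug(
                        "snap %s %s: %d -> %d", sp, intron.gene_id, afo, target
                    )
            out[sp][new_pos.alignment_frame_offset] = (new_pos, intron)
    return out, log


# ---------------------------------------------------------------------------
# landscape construction
# ---------------------------------------------------------------------------


def build_landscape(
    genes: Mapping[str, Optional[GeneModel]],
    alignment: ProteinAlignment,
    tree: Phylogeny,
    families: Sequence[IleFamily] = (),
    classify_params: ClassifyParams = ClassifyParams(),
    *,
    gene_id: str = "gene",
    refine: bool = True,
    shift_window: int = 1,
) -> Landscape:
    """Assemble the positions × species matrix for one orthologue set.

    ``genes`` maps species → gene model (None for a species with no
    orthologue, which contributes a MISSING column entry).  Every species
    with a model must have a row in ``alignment`` and a leaf in ``tree``.
    """
    species = tuple(sorted(genes))
    if len([sp for sp in species if genes[sp] is not None]) < 2:
        raise ValueError("landscape requires at least two species with orthologues")
    missing_from_tree = [sp for sp in species if sp not in set(tree.leaves)]
    if missing_from_tree:
        raise ValueError(f"species absent from tree: {missing_from_tree}")

    projected: dict[str, dict[int, tuple[ProjectedIntronPosition, IntronInstance]]] = {}
    pseudo: dict[str, bool] = {}
    for sp in species:
        gene = genes[sp]
        if gene is None:
            continue
        if sp not in alignment:
            raise ValueError(f"species {sp} has no alignment row")
        pseudo[sp] = gene.has_internal_stop()
        row = alignment.row(sp)
        projected[sp] = {}
        for intron in extract_introns(gene):
            if families or intron.intron_class is IntronClass.UNCLASSIFIED:
                intron.intron_class = classify_intron(
                    intron, families, classify_params
                )
            pos = project_position(intron, row, alignment.alignment_id)
            projected[sp][pos.alignment_frame_offset] = (pos, intron)

    snap_log: list[SnapLogEntry] = []
    if refine:
        projected, snap_log = refine_boundaries(
            projected, alignment, shift_window=shift_window
        )

    afos = sorted({afo for by_afo in projected.values() for afo in by_afo})
    positions = [
        ProjectedIntronPosition(afo // 3, afo % 3, alignment.alignment_id)
        for afo in afos
    ]
    states: dict[tuple[int, str], Status] = {}
    introns: dict[tuple[int, str], IntronInstance] = {}
    for afo, pos in zip(afos, positions):
        for sp in species:
            gene = genes[sp]
            if gene is None:
                states[(afo, sp)] = Status.MISSING
                continue
            if sp in projected and afo in projected[sp]:
                states[(afo, sp)] = Status.PRESENT
                introns[(afo, sp)] = projected[sp][afo][1]
            elif alignment.row(sp)[pos.column] == "-":
                # no aligned residue here: the model is partial at this column
                states[(afo, sp)] = Status.MISSING
            else:
                states[(afo, sp)] = Status.ABSENT

    return Landscape(
        gene_id=gene_id,
        species=species,
        positions=positions,
        states=states,
        introns=introns,
        pseudogene_flags=pseudo,
        alignment_id=alignment.alignment_id,
        snap_log=snap_log,
    )


# ---------------------------------------------------------------------------
# classification against the phylogeny
# ---------------------------------------------------------------------------


def classify_position(
    states_row: Mapping[str, Status], tree: Phylogeny
) -> Category:
    """Category of one position from its presence/absence row and the tree.

    MISSING species are excluded from the denominator.  Precedence:
    conserved → single presence → single clade presence → single absence →
    polymorphism.
    """
    scored = {sp for sp, st in states_row.items() if st is not Status.MISSING}
    present = {sp for sp in scored if states_row[sp] is Status.PRESENT}
    if not present:
        raise ValueError("position with no PRESENT species")
    if present == scored:
        return Category.CONSERVED
    if len(present) == 1:
        return Category.SINGLE_PRESENCE
    if tree.is_monophyletic(present, restrict_to=scored):
        return Category.SINGLE_PRESENCE_IN_CLADE
    if len(scored - present) == 1:
        return Category.SINGLE_ABSENCE
    return Category.PRESENCE_ABSENCE_POLYMORPHISM


def classify_landscape(ls: Landscape, tree: Phylogeny) -> list[PositionCall]:
    calls = []
    for pos in ls.positions:
        afo = pos.alignment_frame_offset
        row = ls.states_row(afo)
        if all(st is Status.MISSING for st in row.values()):
            logger.warning("position %d all-MISSING: dropped", afo)
            continue
        calls.append(PositionCall(pos, classify_position(row, tree)))
    return calls


def detect_sliding_pairs(
    positions: Sequence[ProjectedIntronPosition],
    window_nt: int = SLIDING_WINDOW_NT,
) -> list[tuple[ProjectedIntronPosition, ProjectedIntronPosition, int]]:
    """All unordered position pairs strictly closer than ``window_nt``.

    Distance 0 means the same position and is never a pair.
    """
    out = []
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            d = position_distance(positions[i], positions[j])
            if 0 < d < window_nt:
                a, b = sorted(
                    (positions[i], positions[j]),
                    key=lambda p: p.alignment_frame_offset,
                )
                out.append((a, b, d))
    out.sort(key=lambda t: (t[0].alignment_frame_offset, t[1].alignment_frame_offset))
    return out


def call_parallel_gains(
    ls: Landscape,
    calls: list[PositionCall],
    sliding_pairs: Sequence[
        tuple[ProjectedIntronPosition, ProjectedIntronPosition, int]
    ],
    tree: Phylogeny,
) -> list[PositionCall]:
    """Mark parallel intron gains among sliding pairs; annotate the rest.

    A pair is a parallel gain when one position carries only family-assigned
    ILEs and its partner carries RSIs in species outside the minimal clade
    of the ILE carriers — the ILE is then a fresh, independent insertion
    next to an older regular intron, not a slid copy of it.  Partners
    carrying only long degenerate-ILE candidates outside the clade give a
    lower-confidence POSSIBLE_PARALLEL.  An ILE occupying the *same*
    position as an RSI elsewhere is flagged AMBIGUOUS_COINCIDENT instead of
    being auto-called.
    """
    by_afo = {c.afo: c for c in calls}
    for a, b, d in sliding_pairs:
        ca, cb = by_afo.get(a.alignment_frame_offset), by_afo.get(
            b.alignment_frame_offset
        )
        if ca is None or cb is None:
            continue
        ca.sliding_partners.append((b.alignment_frame_offset, d))
        cb.sliding_partners.append((a.alignment_frame_offset, d))
        for ile_call, partner_call in ((ca, cb), (cb, ca)):
            ile_classes = ls.classes_at(ile_call.afo)
            if not ile_classes or set(ile_classes.values()) != {IntronClass.ILE}:
                continue
            carrier_clade = tree.mrca_leafset(ile_classes)
            partner_classes = ls.classes_at(partner_call.afo)
            outside = {
                sp: cl for sp, cl in partner_classes.items()
                if sp not in carrier_clade
            }
            if IntronClass.RSI in outside.values():
                ile_call.parallel_gain = True
                partner_call.parallel_gain = True
                ev = (
                    f"ILE at {ile_call.afo} ({'/'.join(sorted(ile_classes))}) vs "
                    f"RSI at {partner_call.afo} "
                    f"({'/'.join(sorted(sp for sp, cl in outside.items() if cl is IntronClass.RSI))}), "
                    f"{d} nt apart"
                )
                ile_call.evidence = (ile_call.evidence + "; " + ev).strip("; ")
                partner_call.evidence = (partner_call.evidence + "; " + ev).strip("; ")
            elif IntronClass.DEGENERATE_ILE_CANDIDATE in outside.values():
                ile_call.possible_parallel = True
                partner_call.possible_parallel = True
                ev = (
                    f"ILE at {ile_call.afo} vs degenerate-ILE candidate at "
                    f"{partner_call.afo}, {d} nt apart"
                )
                ile_call.evidence = (ile_call.evidence + "; " + ev).strip("; ")
    # coincident ILE/RSI at one position
    for call in calls:
        classes = set(ls.classes_at(call.afo).values())
        if IntronClass.ILE in classes and IntronClass.RSI in classes:
            call.ambiguous_coincident = True
            call.evidence = (
                call.evidence + "; ILE and RSI coincide at this position"
            ).strip("; ")
    return calls


@dataclass(frozen=True)
class GainFrequency:
    percent: Optional[int]
    numerator: int
    denominator: int


def gain_frequency(
    calls: Sequence[PositionCall], ls: Optional[Landscape] = None
) -> GainFrequency:
    """Parallel-gain frequency: ILE-side parallel positions per polymorphic position.

    Numerator: parallel-gain positions whose PRESENT cells are all
    family-assigned ILEs (the newly gained side of each pair).  Denominator:
    positions classified PRESENCE_ABSENCE_POLYMORPHISM.  Reported as a
    percentage rounded to the nearest integer, with both counts; undefined
    (``percent is None``) when the denominator is zero.
    """
    def is_ile_side(c: PositionCall) -> bool:
        if ls is None:
            return c.parallel_gain and c.category in (
                Category.SINGLE_PRESENCE,
                Category.SINGLE_PRESENCE_IN_CLADE,
            )
        classes = set(ls.classes_at(c.afo).values())
        return c.parallel_gain and classes == {IntronClass.ILE}

    num = sum(1 for c in calls if is_ile_side(c))
    den = sum(
        1 for c in calls if c.category is Category.PRESENCE_ABSENCE_POLYMORPHISM
    )
    if den == 0:
        return GainFrequency(None, num, 0)
    return GainFrequency(round(100 * num / den), num, den)


# ---------------------------------------------------------------------------
# parsimony event recovery (for simulation ground-truth comparison)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InferredEvent:
    gene_id: str
    afo: int
    type: str  # GAIN or LOSS


def recover_events(ls: Landscape, tree: Phylogeny) -> list[InferredEvent]:
    """Single-gain parsimony reconstruction of gains and losses per position.

    Each position is gained once on the branch above the MRCA of its present
    species (no gain is called when that MRCA is the tree root — the intron
    is then read as ancestral) and lost on the root branch of every maximal
    fully-absent clade inside the MRCA clade.
    """
    events: list[InferredEvent] = []
    all_leaves = frozenset(tree.leaves)
    for pos in ls.positions:
        afo = pos.alignment_frame_offset
        row = ls.states_row(afo)
        present = {sp for sp, st in row.items() if st is Status.PRESENT}
        scored = {sp for sp, st in row.items() if st is not Status.MISSING}
        if not present:
            continue
        mrca = tree.mrca_leafset(present)
        if mrca != all_leaves:
            events.append(InferredEvent(ls.gene_id, afo, "GAIN"))
        # maximal absent clades within the mrca clade
        node = tree.mrca_node(present)
        stack = [node]
        losses = 0
        while stack:
            nd = stack.pop()
            ls_nd = tree.leafset(nd) & scored
            if not ls_nd:
                continue
            if ls_nd.isdisjoint(present):
                losses += 1
                continue
            stack.extend(nd.child_nodes())
        if losses:
            events.append(InferredEvent(ls.gene_id, afo, "LOSS"))
    return events


# ---------------------------------------------------------------------------
# summaries and rendering
# ---------------------------------------------------------------------------


def summarize(
    landscapes: Sequence[Landscape],
    calls_per_gene: Mapping[str, Sequence[PositionCall]],
) -> dict:
    """Aggregate category / sliding / parallel counts over orthologue sets."""
    all_calls = [c for calls in calls_per_gene.values() for c in calls]
    counts = {cat.value: 0 for cat in Category}
    for c in all_calls:
        counts[c.category.value] += 1
    sliding = sum(len(c.sliding_partners) for c in all_calls) // 2
    ls_by_gene = {l.gene_id: l for l in landscapes}
    parallel_pairs = 0
    for gene, calls in calls_per_gene.items():
        seen = set()
        for c in calls:
            if not c.parallel_gain:
                continue
            for partner, _ in c.sliding_partners:
                key = frozenset({c.afo, partner})
                pc = next((x for x in calls if x.afo == partner), None)
                if pc is not None and pc.parallel_gain and key not in seen:
                    seen.add(key)
        parallel_pairs += len(seen)
    freq_num = freq_den = 0
    for gene, calls in calls_per_gene.items():
        gf = gain_frequency(list(calls), ls_by_gene.get(gene))
        freq_num += gf.numerator
        freq_den += gf.denominator
    percent = round(100 * freq_num / freq_den) if freq_den else None
    n_sp = counts[Category.SINGLE_PRESENCE.value]
    n_spc = counts[Category.SINGLE_PRESENCE_IN_CLADE.value]
    return {
        "n_positions": len(all_calls),
        "categories": counts,
        "n_single_presence": n_sp,
        "n_single_presence_incl_clades": n_sp + n_spc,
        "n_polymorphic": counts[Category.PRESENCE_ABSENCE_POLYMORPHISM.value],
        "n_single_absence": counts[Category.SINGLE_ABSENCE.value],
        "n_sliding_pairs": sliding,
        "n_parallel_gain_pairs": parallel_pairs,
        "parallel_gain_frequency": {
            "percent": percent,
            "numerator": freq_num,
            "denominator": freq_den,
        },
        "pseudogenes": sorted(
            {
                sp
                for l in landscapes
                for sp, flag in l.pseudogene_flags.items()
                if flag
            }
        ),
    }


def render_grid(ls: Landscape, calls: Sequence[PositionCall]) -> str:
    """Text rendering of the presence/absence grid (one row per species)."""
    glyph = {Status.PRESENT: "#", Status.ABSENT: ".", Status.MISSING: " "}
    afos = [p.alignment_frame_offset for p in ls.positions]
    width = max((len(str(a)) for a in afos), default=1)
    lines = [
        f"{ls.gene_id}: positions "
        + " ".join(str(a).rjust(width) for a in afos)
    ]
    for sp in ls.species:
        cells = " ".join(
            glyph[ls.states[(a, sp)]].rjust(width) for a in afos
        )
        flag = " *" if ls.pseudogene_flags.get(sp) else ""
        lines.append(f"{sp:>12} {cells}{flag}")
    cats = {c.afo: c.category.value[:4] for c in calls}
    lines.append(
        " " * 13 + " ".join(cats.get(a, "").rjust(width)[:width] for a in afos)
    )
    return "\n".join(lines)
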