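# Methods

This note documents the models, conventions and numerical choices behind
`intronscape`, and what the bundled synthetic data do and do not establish.

## Coordinates and projection

Genomic intervals are 0-based half-open; exons are stored in transcript
orientation, and all intron arithmetic happens in transcript orientation
(genomic orientation exists only at the GFF3/FASTA boundary). An intron's
`cds_offset` counts coding nucleotides 5' of it, so its phase is
`cds_offset mod 3` with no off-by-one cases. Projection maps the intron to
the protein-alignment column of residue `⌊cds_offset/3⌋`: a phase-0 intron
is assigned to the column of the *next* codon, phase-1/2 introns to the
split codon, which makes the alignment-frame offset `3·column + phase`
strictly increasing along a gene and unique per position. Projection and
un-projection are exact inverses for any gap placement (property-tested).

Distances between positions are computed in the alignment frame — gaps
count through columns, not through either species' ungapped sequence. This
is the only frame in which cross-species distances are defined; output
records carry the alignment id so positions from different alignments
cannot be compared silently.

## Pairwise identity and family clustering

Identity comes from an end-gap-free global alignment (match +1, mismatch 0,
gap −1); the denominator is the end-trimmed alignment length including
internal gaps, so trimmed amplicon ends are not penalised. Inputs are
canonically ordered before alignment so identity is exactly symmetric.
Because an end-gap-free alignment of two short sequences can score high
identity over a tiny chance overlap, clustering and consensus assignment
floor the denominator at a fraction of the shorter sequence
(`min_overlap_frac`, default 0.5 for clustering and 0.6 for assignment);
without the floor, unrelated ~50-bp introns occasionally exceed 70%
"identity" over a 10–15 nt overlap.

Families are single-linkage components of the graph whose edges are
identity strictly greater than the threshold (default 0.80) — the
conventional connectivity reading of "more than 80% pairwise identity".
Raising the threshold can only refine the partition (tested). Family order
is deterministic: size descending, then smallest member id.

The consensus rule is: per column (all-gap columns dropped, frequencies
over non-gap characters), the majority base when one base reaches ≥50%
without a tie, otherwise the smallest IUPAC code covering all bases at
frequency ≥25% (all observed bases when none reaches 25%). Classification
of a landscape intron is performed against *provided* family consensi (a
prior survey), not against families built from the landscape introns
themselves: orthologous introns inherited across species are near-identical
without being genomic multiplications, and would masquerade as families.

Classification thresholds: family hit at ≥0.70 identity → ILE; otherwise
length ≥70 bp → degenerate-ILE candidate (known degenerated cases are 81
and 87 bp); otherwise length within 40–60 bp → RSI (typical fungal RSIs are
50–55 bp); otherwise unclassified. Activity: a family is ACTIVE when its
best pair is ≥0.98 identical, DEGENERATE below, undetermined for
singletons. All thresholds are config-exposed (`RunConfig`); only the 0.80
clustering and ~0.98 activity values are anchored in the introner
literature.

## Primers and in-silico PCR

Primer sites are gap-free alignment windows (default 18 nt, ≥15 enforced)
with at most `max_variable` (default 4) variable columns, ranked by fewest
variable columns, then longest invariant 3' tail. Variable columns become
IUPAC codes; degeneracy is the product of code sizes and is multiplicative
across windows. A pair takes the best-ranked window as forward primer and
the best-ranked non-overlapping downstream window (rightmost among ties, to
cover most of the element) reverse-complemented as reverse primer. Because
the codes cover every observed member base, each member is amplified by its
own family's pair with zero mismatches (tested self-consistency).

The in-silico PCR reports every locus where the forward primer matches the
sense strand and the reverse primer matches the antisense strand downstream
within `max_amplicon` (default 1000 bp — large enough for two ILE copies
145–626 bp apart plus flanks), with IUPAC-aware mismatch counting up to
`max_mismatch` and an exact 3'-terminal 3-nt anchor, standard PCR practice.
No melting-temperature or secondary-structure modelling is attempted. At
zero mismatches the implementation is equivalent to a naive sliding-window
enumeration (oracle-tested on random 5-kb templates).

## Landscape classification

Cells are PRESENT, ABSENT or MISSING; a species contributes MISSING when it
lacks an orthologue or its alignment row is gapped at the position's column
— absence of evidence is not intron loss, so MISSING species leave the
classification denominator. Categories are assigned with an explicit
precedence (present-in-all → single presence → single clade presence →
single absence → polymorphism); the categories themselves do not overlap
except that a clade-presence with exactly one absentee would otherwise be
ambiguous, and single absence is tested *after* monophyly so that a clean
two-leaf clade is read as one gain, not as multiple losses. Monophyly is
tested on leaf sets intersected with the scored species. The implementation
is checked against a brute-force clade-enumeration oracle on random trees.

A spliced CDS with an internal in-frame stop flags the species' orthologue
as a likely pseudogene; the flag is carried in the landscape and reports.

Boundary refinement replaces manual alignment curation: a position within
`shift_window` codons (default 1) of a position held by ≥2 other species is
snapped onto it when the cross-species flank identity (±5 alignment
columns, computed on the protein rows, which are column-consistent with the
codon alignment) is strictly higher at the target; equal-scoring candidates
leave the position unchanged and flag it ambiguous. Every snap and tie is
logged; `refine=False` disables the step.

## Sliding and parallel gains

Position pairs with alignment-frame distance strictly less than 15 nt
(distance 0 is the same position) are sliding candidates — the classical
window for "intron sliding". A pair is promoted to a parallel-gain call
when one side carries only family-assigned ILEs and the partner carries
RSIs in species outside the minimal clade of the ILE carriers: an ILE is a
demonstrably recent insertion, so it cannot be the slid remnant of the
older intron next door. Partners carrying only long degenerate-ILE
candidates outside the clade yield a lower-confidence POSSIBLE_PARALLEL;
an ILE occupying the *same* offset as an RSI elsewhere is reported as
AMBIGUOUS_COINCIDENT and never auto-called. The parallel-gain frequency is
the number of ILE-side parallel positions over the number of
presence–absence polymorphic positions, as a rounded percentage with both
counts reported so alternative denominators remain auditable.

## The simulator and the bundled benchmark

The simulator draws Poisson event counts per branch (rates per gene per
unit branch length; branch lengths are expected substitutions per site) and
applies: ILE gains (a family consensus copy, each site mutated with
probability `ile_copy_mutation`, inserted at a uniform coding position — no
proto-splice-site bias; a bias hook is deliberately absent by default), RSI
gains (random 45–60 bp GT…AG), and losses (precise excision only).
Substitutions hit exons with stop-avoidance (a substitution creating an
in-frame stop is skipped; the terminal stop codon is immutable) and intron
interiors, with the terminal GT/AG dinucleotides fully protected so every
simulated intron stays canonical — the invariant "all introns are GT…AG"
takes precedence over merely reducing the boundary rate. Genes alternate
between '+' and '−' contigs to exercise strand handling. Identical
parameters give byte-identical output, and replaying the event log from the
root reproduces every leaf's gene structure exactly (both tested).

Because substitutions are length-neutral and events never shift coding
offsets, the per-gene protein rows are equal-length and the alignment is
the identity alignment; real orthologue sets additionally contain indels,
alignment error and missing data, which the simulator does not emulate —
passing tests therefore establish the correctness of the coordinate
arithmetic, classification logic and calling rules, not robustness to
alignment noise (the refinement step addresses small boundary misplacements
only).

The benchmark (`make_parallel_gain_fixture`) places all events as forced
events with stochastic rates zero, so the expected category of each of its
39 positions is known by construction for any seed: 16 single presences
(8 ILEs: two per gene in one of two focal species, pairs ~300 bp apart),
9 clade-level single presences, 13 polymorphic positions, 1 single absence,
6 sliding pairs of which 3 pit an ILE against a distant-clade RSI at 1, 8
and 3 nt. Neutral background: substitution rate 0.05/site/unit on a tree of
total length ≈1, ILE copy mutation 0.01, CDS length 1800 nt. These values
were fixed once as a realistic regime for recently invaded genomes.

## Event recovery

`recover_events` reconstructs per-position events by single-gain parsimony:
one gain on the branch above the MRCA of the present species — unless that
MRCA is the root, in which case the intron is read as ancestral and no gain
is called — plus one loss per maximal fully-absent clade inside the MRCA
clade. An ancestral intron lost along an entire root-child clade is
indistinguishable from a clade-level gain under this rule (no outgroup
exists inside the dataset); at the recovery study's rates (20 genes,
1200 nt CDS, gain rates 0.15 + 0.25, loss 0.10, 2 ancestral introns per
gene, 20 replicate seeds) this and the rarer gain-then-total-loss overlap
cost a few percent, leaving precision and recall ≈0.95–0.96.

## Known limitations

* No probabilistic ancestral-state reconstruction (Dollo/ML); calls are
  parsimony narratives, as in the analysis the package automates.
* No orthologue detection, gene prediction or alignment computation:
  curated orthologue sets, gene models and alignments are inputs.
* The simulator is haploid and population-free; polymorphism within a
  species is out of scope.
* Real ILE length distributions per family are not modelled; family seeds
  default to the 60–90 bp range and are configurable.
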