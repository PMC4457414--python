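"""Degenerate primer derivation from ILE family alignments and in-silico PCR.

Primer candidates are gap-free conserved stretches of the family member
alignment with at most a small number of variable columns (four, following
standard degenerate-primer practice for shared ILE families); variable
columns are encoded as IUPAC ambiguity codes.  The in-silico PCR emulates
amplification of family members from genomic templates: a product is
reported wherever the forward primer matches the sense strand and the
reverse primer matches the antisense strand downstream, with a hard
3'-anchor (the 3'-terminal three bases must match exactly) as in real PCR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .core import revcomp
from .families import IUPAC_SETS, IleFamily, UsageError, align_members


def expand_degeneracy(primer: str) -> int:
    """Number of distinct concrete oligos an IUPAC primer encodes."""
    d = 1
    for c in primer.upper():
        d *= len(IUPAC_SETS.get(c, {c}))
    return d


def n_variable_positions(primer: str) -> int:
    return sum(1 for c in primer.upper() if c not in "ACGT")


@dataclass(frozen=True)
class ConservedWindow:
    """A gap-free alignment window usable as a primer site."""

    start: int  # alignment column, inclusive
    end: int    # alignment column, exclusive
    n_variable: int
    tail_conserved: int  # run of invariant columns at the 3' (right) edge

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair; both given 5'→3' as synthesised.

    The reverse primer anneals to the sense strand, i.e. its reverse
    complement appears on the sense strand at the 3' end of the product.
    """

    name: str
    forward: str
    reverse: str
    target_families: tuple[str, ...] = ()

    @property
    def degeneracy(self) -> int:
        return expand_degeneracy(self.forward) * expand_degeneracy(self.reverse)

    @property
    def n_variable_positions(self) -> int:
        return n_variable_positions(self.forward) + n_variable_positions(
            self.reverse
        )


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    start: int
    end: int
    fwd_mismatches: int
    rev_mismatches: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _column_profile(aligned: Sequence[str]) -> list[frozenset[str]]:
    return [frozenset(c.upper() for c in col) for col in zip(*aligned)]


def find_conserved_stretches(
    aligned: Sequence[str], window_len: int = 20, max_variable: int = 4
) -> list[ConservedWindow]:
    """All gap-free windows with ≤ ``max_variable`` variable columns.

    Ranked by (fewest variable columns, longest invariant 3' tail, leftmost).
    """
    if window_len < 15:
        raise UsageError("primer windows shorter than 15 nt are not useful")
    if not aligned:
        raise UsageError("no aligned members")
    cols = _column_profile(aligned)
    if window_len > len(cols):
        raise UsageError("window_len exceeds alignment length")
    has_gap = ["-" in c for c in cols]
    variable = [len(c - {"-"}) > 1 for c in cols]
    windows = []
    for s in range(len(cols) - window_len + 1):
        e = s + window_len
        if any(has_gap[s:e]):
            continue
        nv = sum(variable[s:e])
        if nv > max_variable:
            continue
        tail = 0
        for i in range(e - 1, s - 1, -1):
            if variable[i]:
                break
            tail += 1
        windows.append(ConservedWindow(s, e, nv, tail))
    windows.sort(key=lambda w: (w.n_variable, -w.tail_conserved, w.start))
    return windows


def make_degenerate_primer(aligned: Sequence[str], start: int, end: int) -> str:
    """IUPAC primer for alignment columns [start, end) (must be gap-free)."""
    from .families import SET_TO_IUPAC

    cols = _column_profile(aligned)[start:end]
    out = []
    for c in cols:
        if "-" in c:
            raise UsageError("primer window contains a gap column")
        out.append(SET_TO_IUPAC.get(frozenset(c), "N") if len(c) > 1 else next(iter(c)))
    return "".join(out)


def design_primer_pair(
    family: IleFamily,
    *,
    primer_len: int = 18,
    max_variable: int = 4,
    name: Optional[str] = None,
) -> PrimerPair:
    """Best forward/reverse pair from a family's member alignment.

    The forward primer is the best-ranked window; the reverse primer is the
    best-ranked non-overlapping window downstream of it, reverse-complemented
    into synthesis orientation.  Every family member is amplified by its own
    pair with zero mismatches, because the IUPAC codes cover all observed
    member bases.
    """
    aligned = align_members([s for _, s in family.members])
    windows = find_conserved_stretches(aligned, primer_len, max_variable)
    for fwd_w in windows:
        downstream = [w for w in windows if w.start >= fwd_w.end]
        if not downstream:
            continue
        rev_w = downstream[0]
        # prefer the rightmost among equally ranked downstream windows so the
        # product covers most of the element
        best_key = (rev_w.n_variable, -rev_w.tail_conserved)
        rev_w = max(
            (w for w in downstream if (w.n_variable, -w.tail_conserved) == best_key),
            key=lambda w: w.end,
        )
        fwd = make_degenerate_primer(aligned, fwd_w.start, fwd_w.end)
        rev_sense = make_degenerate_primer(aligned, rev_w.start, rev_w.end)
        return PrimerPair(
            name=name or f"{family.name}_pair",
            forward=fwd,
            reverse=revcomp(rev_sense),
            target_families=(family.name,),
        )
    raise UsageError(
        f"no non-overlapping primer windows of length {primer_len} in family "
        f"{family.name}"
    )


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------


def _mismatches(primer: str, window: str, max_mismatch: int) -> Optional[int]:
    """IUPAC-aware mismatch count, or None when above ``max_mismatch``."""
    mm = 0
    for p, t in zip(primer, window):
        ps = IUPAC_SETS.get(p)
        ts = IUPAC_SETS.get(t)
        if ps is None or ts is None or not (ps & ts):
            mm += 1
            if mm > max_mismatch:
                return None
    return mm


def _primer_sites(
    sense_primer: str, template: str, max_mismatch: int, anchor: str
) -> list[tuple[int, int]]:
    """All (start, mismatches) matches of a sense-oriented primer.

    ``anchor`` is 'right' when the primer 3' end is the window's right edge
    (forward primer) and 'left' when it is the left edge (a reverse primer
    represented by its reverse complement on the sense strand); the anchored
    three bases must match exactly.
    """
    k = len(sense_primer)
    sense_primer = sense_primer.upper()
    template = template.upper()
    sites = []
    anchor_slice = slice(k - 3, k) if anchor == "right" else slice(0, 3)
    for s in range(len(template) - k + 1):
        window = template[s: s + k]
        if _mismatches(
            sense_primer[anchor_slice], window[anchor_slice], 0
        ) is None:
            continue
        mm = _mismatches(sense_primer, window, max_mismatch)
        if mm is not None:
            sites.append((s, mm))
    return sites


def insilico_pcr(
    template: str,
    pair: PrimerPair,
    max_mismatch: int = 0,
    max_amplicon: int = 1000,
    template_id: str = "template",
) -> list[Amplicon]:
    """Predict PCR products of ``pair`` on a sense-strand template.

    Returns every locus where the forward primer matches the sense strand
    and the reverse primer matches the antisense strand downstream within
    ``max_amplicon``, each site with ≤ ``max_mismatch`` IUPAC-aware
    mismatches and an exact 3'-terminal 3-nt match.  Sorted by start.
    """
    if len(pair.forward) < 15 or len(pair.reverse) < 15:
        raise UsageError("primers must be at least 15 nt")
    fwd_sites = _primer_sites(pair.forward, template, max_mismatch, "right")
    rev_rc = revcomp(pair.reverse)
    rev_sites = _primer_sites(rev_rc, template, max_mismatch, "left")
    out = []
    flen, rlen = len(pair.forward), len(rev_rc)
    for fs, fmm in fwd_sites:
        for rs, rmm in rev_sites:
            if rs < fs + flen:
                continue
            end = rs + rlen
            if end - fs > max_amplicon:
                continue
            out.append(Amplicon(template_id, fs, end, fmm, rmm))
    out.sort(key=lambda a: (a.start, a.end))
    return out


def insilico_pcr_both_strands(
    template: str,
    pair: PrimerPair,
    max_mismatch: int = 0,
    max_amplicon: int = 1000,
    template_id: str = "template",
) -> list[Amplicon]:
    """PCR products on either orientation of a double-stranded template.

    Amplicons found on the reverse strand are reported in the coordinates of
    the given (sense) string.
    """
    fwd = insilico_pcr(template, pair, max_mismatch, max_amplicon, template_id)
    n = len(template)
    rev = [
        Amplicon(template_id, n - a.end, n - a.start, a.fwd_mismatches, a.rev_mismatches)
        for a in insilico_pcr(revcomp(template), pair, max_mismatch, max_amplicon, template_id)
    ]
    out = sorted(set(fwd) | set(rev), key=lambda a: (a.start, a.end))
    return out
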