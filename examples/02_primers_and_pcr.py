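"""Design a degenerate primer pair for an ILE family and amplify in silico.

Derives primers from the conserved stretches of a family alignment (at most
four variable positions, encoded as IUPAC codes) and predicts the PCR
products on a genomic template carrying two copies of the family — the
situation that reveals genes with multiple recent insertions: the pair
amplifies each copy *and* the fragment spanning both.
"""

import random

from intronscape import build_families, design_primer_pair, insilico_pcr

rng = random.Random(1)


def mutate(seq, n):
    s = list(seq)
    for _ in range(n):
        s[rng.randrange(2, len(s) - 2)] = rng.choice("ACGT")
    return "".join(s)


seed = "GT" + "".join(rng.choice("ACGT") for _ in range(68)) + "AG"
copies = [(f"c{k}", mutate(seed, 2)) for k in range(5)]
(family,) = build_families(copies)

pair = design_primer_pair(family, primer_len=18, max_variable=4)
print(f"forward  5'-{pair.forward}-3'")
print(f"reverse  5'-{pair.reverse}-3'")
print(f"degeneracy {pair.degeneracy}, variable positions {pair.n_variable_positions}")

# template: exon — ILE copy — 300 bp exon — ILE copy — exon
exon = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
template = exon(150) + mutate(seed, 1) + exon(300) + mutate(seed, 1) + exon(150)

print("\namplicons (start, end, length):")
for amp in insilico_pcr(template, pair, max_mismatch=1, max_amplicon=1000):
    print(f"  {amp.start:4d} {amp.end:4d}  {amp.length:4d} bp")
# The two short products are the individual copies; the long one spans the
# exonic sequence between the two insertions (the "two-ILE fragment").
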