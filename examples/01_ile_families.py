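"""Cluster intron sequences into ILE families and assess their activity.

Builds a small set of intron copies (two multiplying families plus one
diverged orphan), clusters them at the conventional >80% identity
threshold, and prints each family's consensus and activity call.
"""

import random

from intronscape import build_families, classify_intron, family_activity
from intronscape.core import IntronInstance

rng = random.Random(0)


def mutate(seq, n):
    s = list(seq)
    for _ in range(n):
        s[rng.randrange(2, len(s) - 2)] = rng.choice("ACGT")
    return "".join(s)


seed_a = "GT" + "".join(rng.choice("ACGT") for _ in range(68)) + "AG"
seed_b = "GT" + "".join(rng.choice("ACGT") for _ in range(56)) + "AG"
copies = (
    [(f"a{k}", mutate(seed_a, 1)) for k in range(4)]      # active: ~99% identical
    + [(f"b{k}", mutate(seed_b, 6)) for k in range(3)]    # degenerating copies
    + [("orphan", "GT" + "".join(rng.choice("ACGT") for _ in range(48)) + "AG")]
)

families = build_families(copies, threshold=0.80)
for fam in families:
    act = family_activity(fam) or "UNDETERMINED"
    print(
        f"{fam.name}: {fam.size} members, max identity "
        f"{fam.max_pairwise_identity if fam.max_pairwise_identity else '-'}"
        f" -> {act}"
    )
    print(f"   consensus {fam.consensus}")

# classify a fresh intron against the recovered families
intron = IntronInstance("gene1", "spX", 0, 123, mutate(seed_a, 1))
print("new 72-bp intron classified as:", classify_intron(intron, families).value)

# A family whose best pair is >=98% identical is still multiplying (ACTIVE);
# lower identity means the copies have started to degenerate.
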