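"""The full landscape analysis on the bundled parallel-gain benchmark.

Builds the synthetic ten-species, four-gene orthologue collection, runs the
pipeline (classification of every intron position against the phylogeny,
sliding-pair detection, parallel-gain calling) and prints the grid for one
gene plus the aggregate summary.
"""

import json

from intronscape import RunConfig, analyze, make_parallel_gain_fixture
from intronscape.families import IleFamily
from intronscape.landscape import render_grid

fx = make_parallel_gain_fixture(seed=1)
families = [
    IleFamily.from_consensus(name, seq)
    for name, seq in sorted(fx.family_seeds.items())
]
res = analyze(
    fx.result.gene_models, fx.result.alignments, fx.result.tree,
    families, RunConfig(seed=1),
)

print(render_grid(res.landscapes["g001"], res.calls["g001"]))
print()
for gid, calls in sorted(res.calls.items()):
    for c in calls:
        if c.parallel_gain:
            print(f"parallel gain {gid} afo={c.afo}: {c.evidence}")
print()
print(json.dumps(res.summary, indent=2, sort_keys=True))
# '#' = intron present, '.' = absent.  The three ILE positions sit 1, 8 and
# 3 nt from regular introns carried by distant clades: three parallel gains
# among 13 polymorphic positions, a 23% parallel-gain frequency.
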