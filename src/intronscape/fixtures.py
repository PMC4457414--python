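"""Synthetic benchmark fixture for the parallel-gain analysis.

``make_parallel_gain_fixture`` builds — entirely in silico — a ten-species
orthologue collection of four genes whose intron landscape reproduces the
published configuration this package is designed to analyse:

* 39 intron positions in total;
* 16 single-presence positions (8 of them ILE insertions, two per gene in
  one of two focal species), 25 when clade-level single presences are
  included;
* 13 presence–absence polymorphic positions;
* 1 single absence;
* 6 sliding candidates (position pairs < 15 nt apart), three of which pit a
  freshly gained ILE against a regular spliceosomal intron conserved in a
  distant clade at alignment-frame distances of exactly 1, 8 and 3 nt —
  the three parallel intron gains;
* in each of the four genes the two ILEs sit a few hundred bp apart, so a
  single family primer pair amplifies a two-ILE fragment (four fragments in
  all).

All intron gains and losses are placed as forced events on specific
branches; stochastic gain/loss rates are zero, so the expected category of
every position is known by construction for any seed (the seed only varies
the neutral sequence background and the ILE copy mutations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import Phylogeny
from .simulate import ForcedEvent, SimulationParams, SimulationResult, simulate

FIXTURE_TREE = (
    "((((s01:0.05,s02:0.05):0.05,(s03:0.05,s04:0.05):0.05):0.05,"
    "((s05:0.05,s06:0.05):0.05,(s07:0.05,s08:0.05):0.05):0.05):0.05,"
    "(s09:0.1,s10:0.1):0.1);"
)

# clade shorthands: MRCA of the named leaves carries the event
_S01 = ("s01",)
_S02 = ("s02",)
_C12 = ("s01", "s02")
_C34 = ("s03", "s04")
_C56 = ("s05", "s06")
_C78 = ("s07", "s08")
_C1234 = ("s01", "s04")
_C5678 = ("s05", "s08")
_C18 = ("s01", "s08")
_C910 = ("s09", "s10")


def _events(include_iles: bool) -> list[ForcedEvent]:
    ile = ForcedEvent
    ev: list[ForcedEvent] = []

    def gain(clade, gene, off, family=None):
        ev.append(
            ForcedEvent(clade, "ILE_GAIN" if family else "RSI_GAIN", gene, off, family)
        )

    def loss(clade, gene, off):
        ev.append(ForcedEvent(clade, "LOSS", gene, off))

    # --- g001 (focal s01, family famA) ---------------------------------
    if include_iles:
        gain(_S01, "g001", 301, "famA")       # parallel partner at d=1
        gain(_S01, "g001", 600, "famA")
    gain(_C56, "g001", 300)                   # RSI conserved in distant clade
    gain(("s07",), "g001", 900)
    gain(("s09",), "g001", 1200)
    gain(_C34, "g001", 60)
    gain(_C18, "g001", 1500); loss(("s04",), "g001", 1500)   # polymorphic
    gain(_C12, "g001", 990); gain(_C78, "g001", 990)          # polymorphic

    # --- g002 (focal s01, family famA) ---------------------------------
    if include_iles:
        gain(_S01, "g002", 421, "famA")       # parallel partner at d=8
        gain(_S01, "g002", 720, "famA")
    gain(_C78, "g002", 429)
    gain(("s03",), "g002", 60)
    gain(("s10",), "g002", 1000)
    gain(_C910, "g002", 1255); gain(_C34, "g002", 1264)       # RSI sliding d=9
    gain(_C18, "g002", 1500); loss(("s06",), "g002", 1500)
    gain(_C1234, "g002", 150); loss(("s02",), "g002", 150)

    # --- g003 (focal s02, family famB) ---------------------------------
    if include_iles:
        gain(_S02, "g003", 241, "famB")       # parallel partner at d=3
        gain(_S02, "g003", 540, "famB")
    gain(_C56, "g003", 244)
    gain(("s05",), "g003", 60)
    gain(("s08",), "g003", 900)
    gain("root", "g003", 1200); loss(("s07",), "g003", 1200)  # single absence
    gain(_C5678, "g003", 1500); loss(("s06",), "g003", 1500)
    gain(_C18, "g003", 1020); loss(("s03",), "g003", 1020)
    gain(_C12, "g003", 1740); gain(_C910, "g003", 1740)
    gain(_C1234, "g003", 840); loss(("s01",), "g003", 840)

    # --- g004 (focal s02, family famB) ---------------------------------
    if include_iles:
        gain(_S02, "g004", 360, "famB")
        gain(_S02, "g004", 660, "famB")
    gain(_C78, "g004", 90); gain(_C34, "g004", 102)           # RSI sliding d=12
    gain(_C910, "g004", 1500)
    gain(_C18, "g004", 900); loss(("s04",), "g004", 900)      # sliding d=6 …
    gain(_C1234, "g004", 906); loss(("s02",), "g004", 906)    # … both polymorphic
    gain(_C12, "g004", 1200); gain(_C56, "g004", 1200)
    gain(_C18, "g004", 450); loss(("s07",), "g004", 450)
    gain(_C1234, "g004", 1740); loss(("s03",), "g004", 1740)
    gain(("s06",), "g004", 1050)
    gain(("s09",), "g004", 550)
    return ev


#: expected classification per (gene, alignment_frame_offset)
EXPECTED_CATEGORIES: dict[tuple[str, int], str] = {}
for _g, _offs in {
    "g001": {
        301: "SINGLE_PRESENCE", 600: "SINGLE_PRESENCE",
        900: "SINGLE_PRESENCE", 1200: "SINGLE_PRESENCE",
        300: "SINGLE_PRESENCE_IN_CLADE", 60: "SINGLE_PRESENCE_IN_CLADE",
        1500: "PRESENCE_ABSENCE_POLYMORPHISM",
        990: "PRESENCE_ABSENCE_POLYMORPHISM",
    },
    "g002": {
        421: "SINGLE_PRESENCE", 720: "SINGLE_PRESENCE",
        60: "SINGLE_PRESENCE", 1000: "SINGLE_PRESENCE",
        429: "SINGLE_PRESENCE_IN_CLADE", 1255: "SINGLE_PRESENCE_IN_CLADE",
        1264: "SINGLE_PRESENCE_IN_CLADE",
        1500: "PRESENCE_ABSENCE_POLYMORPHISM",
        150: "PRESENCE_ABSENCE_POLYMORPHISM",
    },
    "g003": {
        241: "SINGLE_PRESENCE", 540: "SINGLE_PRESENCE",
        60: "SINGLE_PRESENCE", 900: "SINGLE_PRESENCE",
        244: "SINGLE_PRESENCE_IN_CLADE",
        1200: "SINGLE_ABSENCE",
        1500: "PRESENCE_ABSENCE_POLYMORPHISM",
        1020: "PRESENCE_ABSENCE_POLYMORPHISM",
        1740: "PRESENCE_ABSENCE_POLYMORPHISM",
        840: "PRESENCE_ABSENCE_POLYMORPHISM",
    },
    "g004": {
        360: "SINGLE_PRESENCE", 660: "SINGLE_PRESENCE",
        1050: "SINGLE_PRESENCE", 550: "SINGLE_PRESENCE",
        90: "SINGLE_PRESENCE_IN_CLADE", 102: "SINGLE_PRESENCE_IN_CLADE",
        1500: "SINGLE_PRESENCE_IN_CLADE",
        900: "PRESENCE_ABSENCE_POLYMORPHISM",
        906: "PRESENCE_ABSENCE_POLYMORPHISM",
        1200: "PRESENCE_ABSENCE_POLYMORPHISM",
        450: "PRESENCE_ABSENCE_POLYMORPHISM",
        1740: "PRESENCE_ABSENCE_POLYMORPHISM",
    },
}.items():
    for _o, _c in _offs.items():
        EXPECTED_CATEGORIES[(_g, _o)] = _c

#: parallel-gain pairs (gene, ILE-side afo, RSI-side afo, distance)
EXPECTED_PARALLEL = [
    ("g001", 301, 300, 1),
    ("g002", 421, 429, 8),
    ("g003", 241, 244, 3),
]


def _family_seeds(seed: int) -> dict[str, str]:
    """Two ILE family consensus seeds (GT…AG, 66 and 72 bp)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x11E]))
    out = {}
    for name, length in (("famA", 72), ("famB", 66)):
        interior = "".join(rng.choice(list("ACGT"), size=length - 4))
        out[name] = "GT" + interior + "AG"
    return out


@dataclass
class Fixture:
    params: SimulationParams
    result: SimulationResult
    family_seeds: dict[str, str]
    expected_categories: dict[tuple[str, int], str] = field(
        default_factory=lambda: dict(EXPECTED_CATEGORIES)
    )
    expected_parallel: list[tuple[str, int, int, int]] = field(
        default_factory=lambda: list(EXPECTED_PARALLEL)
    )
    focal_genes: dict[str, str] = field(
        default_factory=lambda: {
            "g001": "s01", "g002": "s01", "g003": "s02", "g004": "s02"
        }
    )

    @property
    def tree(self) -> Phylogeny:
        return self.result.tree


def make_parallel_gain_fixture(
    seed: int = 0, include_iles: bool = True
) -> Fixture:
    """Build the benchmark orthologue collection (see module docstring)."""
    seeds = _family_seeds(seed)
    params = SimulationParams(
        tree=FIXTURE_TREE,
        n_genes=4,
        cds_length=1800,
        subst_rate=0.05,
        ile_gain_rate=0.0,
        rsi_gain_rate=0.0,
        loss_rate=0.0,
        ile_families=seeds,
        ile_copy_mutation=0.01,
        n_ancestral_introns=0,
        forced_events=tuple(_events(include_iles)),
        seed=seed,
    )
    result = simulate(params)
    fx = Fixture(params=params, result=result, family_seeds=seeds)
    if not include_iles:
        ile_offsets = {
            ("g001", 301), ("g001", 600), ("g002", 421), ("g002", 720),
            ("g003", 241), ("g003", 540), ("g004", 360), ("g004", 660),
        }
        fx.expected_categories = {
            k: v for k, v in EXPECTED_CATEGORIES.items() if k not in ile_offsets
        }
        fx.expected_parallel = []
    return fx
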