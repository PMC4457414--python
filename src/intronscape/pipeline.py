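"""End-to-end analysis: families → classification → landscapes → calls.

The pipeline consumes an orthologue collection (per-species gene models, a
protein alignment per gene, a species tree, and a set of known ILE family
consensus sequences), builds one landscape per gene, classifies every
position against the phylogeny, detects sliding pairs, calls parallel
gains, and reports aggregate counts with the parallel-gain frequency.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from .config import RunConfig
from .core import (
    GeneModel,
    IntronClass,
    Phylogeny,
    ProteinAlignment,
    extract_introns,
    revcomp,
)
from .families import (
    ClassifyParams,
    IleFamily,
    assign_to_family,
)
from .landscape import (
    Landscape,
    PositionCall,
    build_landscape,
    call_parallel_gains,
    classify_landscape,
    detect_sliding_pairs,
    summarize,
)
from .primers import Amplicon, design_primer_pair, insilico_pcr
from .simulate import SimulationResult
from . import io as iomod

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    landscapes: dict[str, Landscape]
    calls: dict[str, list[PositionCall]]
    summary: dict
    families: list[IleFamily]


def classify_params_from(config: RunConfig) -> ClassifyParams:
    return ClassifyParams(
        min_identity=config.assignment_min_identity,
        rsi_range=config.rsi_range,
        long_intron_threshold=config.long_intron_threshold,
        min_overlap_frac=config.min_overlap_frac,
    )


def analyze(
    gene_models: Mapping[str, Mapping[str, GeneModel]],
    alignments: Mapping[str, ProteinAlignment],
    tree: Phylogeny,
    families: Sequence[IleFamily] = (),
    config: RunConfig = RunConfig(),
) -> PipelineResult:
    """Run landscapes + calls for every gene of an orthologue collection.

    ``gene_models`` maps species → gene_id → model; a species may lack a
    gene (treated as MISSING in that gene's landscape).
    """
    if not gene_models:
        raise PipelineError("landscape", "empty orthologue set")
    cp = classify_params_from(config)
    landscapes: dict[str, Landscape] = {}
    calls: dict[str, list[PositionCall]] = {}
    species = sorted(gene_models)
    for gid in sorted(alignments):
        genes = {sp: gene_models.get(sp, {}).get(gid) for sp in species}
        ls = build_landscape(
            genes,
            alignments[gid],
            tree,
            families,
            cp,
            gene_id=gid,
            refine=config.refine,
            shift_window=config.shift_window,
        )
        gene_calls = classify_landscape(ls, tree)
        pairs = detect_sliding_pairs(ls.positions, config.sliding_window_nt)
        call_parallel_gains(ls, gene_calls, pairs, tree)
        landscapes[gid] = ls
        calls[gid] = gene_calls
    return PipelineResult(
        landscapes=landscapes,
        calls=calls,
        summary=summarize(list(landscapes.values()), calls),
        families=list(families),
    )


# ---------------------------------------------------------------------------
# two-ILE fragment survey (family primers on genomic templates)
# ---------------------------------------------------------------------------


def as_plus_strand(model: GeneModel) -> GeneModel:
    """Equivalent gene model with the contig in transcript orientation."""
    if model.strand == "+":
        return model
    n = len(model.genomic_seq)
    ivals = tuple(sorted((n - e, n - s) for s, e in model.exons))
    return GeneModel(
        model.gene_id, model.species, "+", ivals, revcomp(model.genomic_seq)
    )


def _intron_sense_intervals(model: GeneModel) -> list[tuple[int, int]]:
    plus = as_plus_strand(model)
    ivals = sorted(plus.exons)
    return [(e1, s2) for (_, e1), (s2, _) in zip(ivals, ivals[1:])]


@dataclass
class TwoIleFragment:
    species: str
    gene_id: str
    family: str
    amplicon: Amplicon
    n_iles_spanned: int


def survey_two_ile_fragments(
    gene_models: Mapping[str, Mapping[str, GeneModel]],
    families: Sequence[IleFamily],
    config: RunConfig = RunConfig(),
) -> list[TwoIleFragment]:
    """Amplify every genomic template with family primers; keep two-ILE products.

    Emulates the discovery of genes with recent multiple ILE insertions: a
    single family primer pair anneals inside each of two nearby copies and
    the product spans the exonic sequence between them.  Primer pairs are
    designed from the observed ILE copies of each family; only amplicons
    spanning at least two ILE insertions are reported.
    """
    cp = classify_params_from(config)
    # classify introns, collect ILE members per family and ILE intervals
    members: dict[str, list[tuple[str, str]]] = {}
    ile_intervals: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for sp in sorted(gene_models):
        for gid in sorted(gene_models[sp]):
            model = as_plus_strand(gene_models[sp][gid])
            intervals = _intron_sense_intervals(model)
            for intron, ival in zip(extract_introns(model), intervals):
                hit = assign_to_family(
                    f"{sp}:{gid}:{intron.ordinal}",
                    intron.sequence,
                    families,
                    min_identity=cp.min_identity,
                    min_overlap_frac=cp.min_overlap_frac,
                ) if families else None
                if hit is not None and hit.family_name is not None:
                    members.setdefault(hit.family_name, []).append(
                        (hit.query_id, intron.sequence)
                    )
                    ile_intervals.setdefault((sp, gid), []).append(ival)
    fragments: list[TwoIleFragment] = []
    for fam_name in sorted(members):
        fam = IleFamily(
            name=fam_name,
            members=sorted(members[fam_name]),
            consensus="",
        )
        pair = design_primer_pair(
            fam, primer_len=config.primer_len, max_variable=config.max_variable
        )
        for (sp, gid), iles in sorted(ile_intervals.items()):
            template = as_plus_strand(gene_models[sp][gid]).genomic_seq
            for amp in insilico_pcr(
                template,
                pair,
                max_mismatch=config.max_mismatch,
                max_amplicon=config.max_amplicon,
                template_id=f"{sp}:{gid}",
            ):
                # primers anneal inside the copies, so count overlapped ILEs
                spanned = sum(
                    1 for s, e in iles if amp.start < e and s < amp.end
                )
                if spanned >= 2:
                    fragments.append(
                        TwoIleFragment(sp, gid, fam_name, amp, spanned)
                    )
    return fragments


# ---------------------------------------------------------------------------
# simulation directory round-trip
# ---------------------------------------------------------------------------


def write_simulation(result: SimulationResult, outdir) -> None:
    """Emit genomes, annotations, alignments, tree, families and event log."""
    out = Path(str(outdir))
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(exist_ok=True)
    (out / "alignments").mkdir(exist_ok=True)
    for sp in result.species:
        iomod.write_gene_models(
            out / "annotations" / f"{sp}.gff3",
            out / "genomes" / f"{sp}.fasta",
            result.gene_models[sp],
        )
    for gid, aln in result.alignments.items():
        iomod.write_fasta(out / "alignments" / f"{gid}.fasta", aln.rows)
    newick = result.tree.tree.as_string(schema="newick").strip()
    (out / "tree.nwk").write_text(newick + "\n")
    iomod.write_fasta(out / "ile_families.fasta", dict(result.params.ile_families))
    iomod.write_tsv(
        out / "events.tsv",
        ["branch", "gene_id", "type", "cds_offset", "family", "length"],
        [
            (e.branch, e.gene_id, e.type, e.cds_offset, e.family or "", e.length)
            for e in result.events
        ],
        header_lines=[f"# intronscape simulation seed={result.params.seed}"],
    )
    params = {
        "n_genes": result.params.n_genes,
        "cds_length": result.params.cds_length,
        "subst_rate": result.params.subst_rate,
        "ile_gain_rate": result.params.ile_gain_rate,
        "rsi_gain_rate": result.params.rsi_gain_rate,
        "loss_rate": result.params.loss_rate,
        "ile_copy_mutation": result.params.ile_copy_mutation,
        "seed": result.params.seed,
    }
    (out / "params.yaml").write_text(yaml.safe_dump(params, sort_keys=True))


def load_collection(indir):
    """Load an orthologue collection directory (the simulator's layout)."""
    root = Path(str(indir))
    if not root.is_dir():
        raise PipelineError("load", f"input directory {root} does not exist")
    tree = iomod.read_tree(root / "tree.nwk")
    gene_models: dict[str, dict[str, GeneModel]] = {}
    for fa in sorted((root / "genomes").glob("*.fasta")):
        sp = fa.stem
        gff = root / "annotations" / f"{sp}.gff3"
        gene_models[sp] = iomod.read_gene_models(gff, fa, sp)
    alignments = {
        p.stem: iomod.read_alignment(p, p.stem)
        for p in sorted((root / "alignments").glob("*.fasta"))
    }
    fam_fa = root / "ile_families.fasta"
    families = (
        [
            IleFamily.from_consensus(name, seq)
            for name, seq in sorted(iomod.read_fasta(fam_fa).items())
        ]
        if fam_fa.exists()
        else []
    )
    if not gene_models or not alignments:
        raise PipelineError("load", f"no orthologue data under {root}")
    return gene_models, alignments, tree, families


def run_pipeline(indir, outdir, config: RunConfig = RunConfig()) -> dict:
    """File-level entry point: read a collection, write landscape reports.

    Outputs (all carrying a version/config-hash/seed header):
    ``landscape_<gene>.tsv``, ``calls.tsv``, ``summary.json``.  Partial
    outputs are removed when a stage fails.
    """
    out = Path(str(outdir))
    out.mkdir(parents=True, exist_ok=True)
    try:
        gene_models, alignments, tree, families = load_collection(indir)
        result = analyze(gene_models, alignments, tree, families, config)
    except PipelineError:
        shutil.rmtree(out, ignore_errors=True)
        raise
    except Exception as exc:  # pragma: no cover - defensive
        shutil.rmtree(out, ignore_errors=True)
        raise PipelineError("analyze", str(exc)) from exc
    header = iomod.report_header(config.to_dict(), config.seed)
    for gid, ls in result.landscapes.items():
        rows = []
        for pos in ls.positions:
            afo = pos.alignment_frame_offset
            cells = []
            for sp in ls.species:
                st = ls.state(afo, sp)
                cls = (
                    ls.introns[(afo, sp)].intron_class.value
                    if (afo, sp) in ls.introns
                    else ""
                )
                cells.append(f"{st.value[0]}{':' + cls if cls else ''}")
            call = next(c for c in result.calls[gid] if c.afo == afo)
            rows.append(
                [gid, pos.column, pos.phase, afo, call.category.value,
                 ";".join(f"{p}@{d}" for p, d in call.sliding_partners),
                 int(call.parallel_gain), *cells]
            )
        iomod.write_tsv(
            out / f"landscape_{gid}.tsv",
            ["gene", "column", "phase", "afo", "category", "sliding_partners",
             "parallel_gain", *ls.species],
            rows,
            header_lines=header,
        )
    call_rows = []
    for gid in sorted(result.calls):
        for c in result.calls[gid]:
            call_rows.append(
                [gid, c.afo, c.category.value,
                 ";".join(f"{p}@{d}" for p, d in c.sliding_partners),
                 int(c.parallel_gain), int(c.possible_parallel),
                 int(c.ambiguous_coincident), c.evidence]
            )
    iomod.write_tsv(
        out / "calls.tsv",
        ["gene", "afo", "category", "sliding_partners", "parallel_gain",
         "possible_parallel", "ambiguous_coincident", "evidence"],
        call_rows,
        header_lines=header,
    )
    iomod.write_json(
        out / "summary.json",
        result.summary,
        header={
            "version": header[0].split()[-1],
            "config_hash": iomod.config_hash(config.to_dict()),
            "seed": config.seed,
        },
    )
    return result.summary
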