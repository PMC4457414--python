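"""File formats: FASTA, aligned FASTA, GFF3, newick, TSV/JSON reports.

Readers lean on Biopython (FASTA) and gffutils (GFF3); writers emit plain
text with a reproducibility header (tool version, config hash, seed).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .core import GeneModel, Phylogeny, ProteinAlignment


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, seqs: Mapping[str, str] | Iterable[tuple[str, str]]) -> None:
    items = seqs.items() if isinstance(seqs, Mapping) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(records, str(path), "fasta")


def read_alignment(path, alignment_id: Optional[str] = None) -> ProteinAlignment:
    rows = read_fasta(path)
    return ProteinAlignment(rows, alignment_id or Path(str(path)).stem)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gene_models(gff3_path, fasta_path, species: str) -> dict[str, GeneModel]:
    """Gene models from a GFF3 (exon features grouped by Parent) + genome FASTA."""
    genome = read_fasta(fasta_path)
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        from_string=False,
        merge_strategy="create_unique",
        keep_order=True,
    )
    by_gene: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        parents = feat.attributes.get("Parent") or feat.attributes.get("ID")
        if not parents:
            raise ValueError(f"exon without Parent in {gff3_path}")
        gene_id = parents[0]
        rec = by_gene.setdefault(
            gene_id, {"seqid": feat.seqid, "strand": feat.strand, "exons": []}
        )
        # GFF3 is 1-based inclusive
        rec["exons"].append((feat.start - 1, feat.end))
    models = {}
    for gene_id, rec in by_gene.items():
        seq = genome[rec["seqid"]]
        ivals = sorted(rec["exons"])
        if rec["strand"] == "-":
            ivals = ivals[::-1]
        models[gene_id] = GeneModel(
            gene_id, species, rec["strand"], tuple(ivals), seq
        )
    return models


def write_gene_models(gff3_path, fasta_path, models: Mapping[str, GeneModel]) -> None:
    """One contig per gene: genomic FASTA plus exon features in GFF3."""
    write_fasta(fasta_path, {m.gene_id: m.genomic_seq for m in models.values()})
    lines = ["##gff-version 3"]
    for gid in sorted(models):
        m = models[gid]
        ivals = sorted(m.exons)
        lines.append(
            "\t".join(
                [gid, "intronscape", "gene", str(ivals[0][0] + 1),
                 str(ivals[-1][1]), ".", m.strand, ".", f"ID={gid}"]
            )
        )
        for k, (s, e) in enumerate(ivals, 1):
            lines.append(
                "\t".join(
                    [gid, "intronscape", "exon", str(s + 1), str(e), ".",
                     m.strand, ".", f"ID={gid}.exon{k};Parent={gid}"]
                )
            )
    Path(str(gff3_path)).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def read_tree(path) -> Phylogeny:
    return Phylogeny.from_file(path)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def config_hash(config: Mapping) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def report_header(config: Mapping, seed: Optional[int]) -> list[str]:
    return [
        f"# intronscape {__version__}",
        f"# config_hash={config_hash(config)}",
        f"# seed={seed}",
    ]


def write_tsv(
    path,
    columns: Sequence[str],
    rows: Iterable[Sequence],
    header_lines: Sequence[str] = (),
) -> None:
    lines = list(header_lines)
    lines.append("\t".join(columns))
    for row in rows:
        lines.append("\t".join("" if v is None else str(v) for v in row))
    Path(str(path)).write_text("\n".join(lines) + "\n")


def write_json(path, payload, header: Optional[Mapping] = None) -> None:
    doc = dict(payload)
    if header:
        doc = {"_meta": dict(header), **doc}
    Path(str(path)).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
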