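"""Readers and writers for the plain-text formats the pipeline touches.

GTF and RepeatMasker ``.out`` are 1-based inclusive on disk and converted to
the package's 0-based half-open convention on read (and back on write); BED is
already half-open.  Writers emit deterministic ordering (chrom, start, id) so
that equal inputs give byte-identical files.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import (
    Gene,
    GeneAnnotation,
    GenomicInterval,
    TEAnnotation,
    TranscriptModel,
)


class ParseError(ValueError):
    pass


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon features from a GTF into transcripts.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Exons are grouped by ``transcript_id`` and sorted; a malformed line raises
    :class:`ParseError` naming the line number, an exon without a
    ``transcript_id`` raises a record-level error.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinates") from exc
            attributes = _parse_gtf_attributes(attrs)
            tid = attributes.get("transcript_id")
            if not tid:
                raise ParseError(f"{path}:{lineno}: exon without transcript_id")
            gid = attributes.get("gene_id", tid)
            exons.setdefault(tid, [])
            if tid not in gene_of:
                order.append(tid)
                gene_of[tid] = gid
            try:
                exons[tid].append(GenomicInterval(chrom, s - 1, e, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return [TranscriptModel(tid, gene_of[tid], exons[tid]) for tid in order]


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    ordered = sorted(transcripts, key=lambda t: (t.chrom, t.span.start, t.transcript_id))
    with open(path, "w") as fh:
        for t in ordered:
            for exon in t.exons:
                fh.write(
                    f"{exon.chrom}\ttelncrna\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f'{exon.strand}\t.\tgene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";\n'
                )


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA → ``{id: uppercased sequence}``; id is the first whitespace token."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"{path}: duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sorted(sequences.items())
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_gff3_genes(path: str | Path) -> GeneAnnotation:
    """Read gene and exon features from a GFF3 into a :class:`GeneAnnotation`.

    Exons are attached to their gene via the ``Parent``/``ID`` attributes
    (transcript-level features are followed one level up when present).
    """
    spans: dict[str, GenomicInterval] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    parent_of: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            attributes = dict(
                kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
            )
            try:
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if feature == "gene":
                gid = attributes.get("ID")
                if not gid:
                    raise ParseError(f"{path}:{lineno}: gene without ID")
                spans[gid] = iv
                order.append(gid)
            elif feature in {"mRNA", "transcript"}:
                tid, parent = attributes.get("ID"), attributes.get("Parent")
                if tid and parent:
                    parent_of[tid] = parent
            elif feature == "exon":
                parent = attributes.get("Parent")
                if not parent:
                    raise ParseError(f"{path}:{lineno}: exon without Parent")
                gid = parent_of.get(parent, parent)
                exons.setdefault(gid, []).append(iv)
    genes = []
    for gid in order:
        ex = sorted(exons.get(gid, []), key=lambda e: (e.start, e.end))
        genes.append(Gene(gid, spans[gid], ex))
    return GeneAnnotation(genes)


def write_gff3_genes(ann: GeneAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(ann.genes, key=lambda g: (g.span.chrom, g.span.start, g.gene_id)):
            s = g.span
            fh.write(
                f"{s.chrom}\ttelncrna\tgene\t{s.start + 1}\t{s.end}\t.\t{s.strand}\t.\tID={g.gene_id}\n"
            )
            for i, exon in enumerate(g.exons, start=1):
                fh.write(
                    f"{exon.chrom}\ttelncrna\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{exon.strand}\t.\tID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def read_te_annotation(path: str | Path, dialect: str = "bed") -> TEAnnotation:
    """Read a TE annotation in BED4 or RepeatMasker ``.out`` dialect.

    BED is 0-based half-open with the superfamily in column 4; ``.out`` is a
    whitespace table, 1-based inclusive, with query coordinates in columns
    5-7 and the repeat class/family in column 11.  Header lines of ``.out``
    files are skipped; any other non-numeric coordinate row is rejected.
    """
    records: list[tuple[GenomicInterval, str]] = []
    if dialect == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ParseError(f"{path}:{lineno}: BED4 needs >= 4 columns")
                chrom, start, end, fam = fields[:4]
                try:
                    iv = GenomicInterval(chrom, int(start), int(end))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
                records.append((iv, fam))
    elif dialect == "repeatmasker_out":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                fields = line.split()
                if not fields:
                    continue
                # the two banner lines start with 'SW'/'score' and 'bit'/'div'
                if not fields[0].replace(".", "").isdigit():
                    continue
                if len(fields) < 11:
                    raise ParseError(f"{path}:{lineno}: truncated .out row")
                chrom, begin, end, fam = fields[4], fields[5], fields[6], fields[10]
                try:
                    iv = GenomicInterval(chrom, int(begin) - 1, int(end))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric coordinates") from exc
                records.append((iv, fam))
    else:
        raise ValueError(f"unknown TE annotation dialect {dialect!r}")
    return TEAnnotation(records)


def write_te_bed(te: TEAnnotation, path: str | Path) -> None:
    ordered = sorted(te.records, key=lambda r: (r[0].chrom, r[0].start, r[0].end, r[1]))
    with open(path, "w") as fh:
        for iv, fam in ordered:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{fam}\n")
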