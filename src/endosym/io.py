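"""Readers and writers for every on-disk format the pipeline touches.

Formats: FASTA (contigs, reads), GFF3 (annotations), Newick (trees),
tab-separated hit tables (BLAST outfmt-6 plus three appended columns:
subject kingdom, ``;``-joined subject lineage, query length), and 2-column
depth tables (contig id, mean depth).

All intervals are converted between 1-based inclusive (disk) and 0-based
half-open (memory) here and nowhere else.
"""

from __future__ import annotations

import logging
import re
import urllib.parse
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .config import Config
from .model import AnnotationSet, Association, Contig, GeneRecord, HitRecord, HitTable

logger = logging.getLogger(__name__)

_NON_ACGTN = re.compile(r"[^ACGTN]")

HIT_TABLE_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "skingdom", "slineage", "qlen",
]


def header_lines(config: Optional[Config] = None, **extra: object) -> list[str]:
    """Standard ``#`` comment header recording version and config hash."""
    from . import __version__

    lines = [f"# endosym v{__version__}"]
    if config is not None:
        lines.append(f"# config_hash={config.hash()}")
    for key, value in extra.items():
        lines.append(f"# {key}={value}")
    return lines


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_fasta(path: str | Path) -> list[Contig]:
    """Read a FASTA file into contigs.

    Sequences are uppercased; characters outside {A,C,G,T,N} are replaced by
    N (a warning reports the count).  Record order is preserved.
    """
    path = Path(path)
    contigs: list[Contig] = []
    seen: set[str] = set()
    n_replaced = 0
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            cid = title.split()[0] if title.split() else ""
            if cid in seen:
                raise ValueError(f"{path}: duplicate contig id {cid!r}")
            seen.add(cid)
            seq = seq.upper()
            cleaned = _NON_ACGTN.sub("N", seq)
            n_replaced += sum(a != b for a, b in zip(seq, cleaned)) if cleaned != seq else 0
            contigs.append(Contig(id=cid, seq=cleaned))
    if n_replaced:
        logger.warning("%s: replaced %d non-ACGTN characters with N", path, n_replaced)
    if not contigs:
        raise ValueError(f"{path}: no records")
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as handle:
        for contig in contigs:
            handle.write(f">{contig.id}\n")
            for i in range(0, len(contig.seq), width):
                handle.write(contig.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Depth tables
# ---------------------------------------------------------------------------

def parse_depth_table(path: str | Path) -> dict[str, float]:
    """Read a 2-column TSV of contig id -> mean mapped depth."""
    depths: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns")
        depth = float(fields[1])
        if depth < 0:
            raise ValueError(f"{path}:{lineno}: negative depth")
        depths[fields[0]] = depth
    return depths


def write_depth_table(depths: dict[str, float], path: str | Path) -> None:
    with open(path, "w") as handle:
        for cid, depth in depths.items():
            handle.write(f"{cid}\t{depth:.6g}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

# type-column mapping, disk -> memory (documented contract)
_GFF_TYPE_TO_CLASS = {
    "CDS": "CDS",
    "pseudogene": "pseudogene",
    "repeat_region": "repeat",
    "prophage": "phage",
    "phage": "phage",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
}
_CLASS_TO_GFF_TYPE = {
    "CDS": "CDS",
    "pseudogene": "pseudogene",
    "repeat": "repeat_region",
    "phage": "prophage",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
}


def _parse_gff_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in field.split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        key, _, value = part.partition("=")
        attrs[key] = urllib.parse.unquote(value)
    return attrs


def parse_gff(path: str | Path,
              contigs: Optional[Sequence[Contig] | dict[str, int]] = None,
              genome_id: Optional[str] = None) -> AnnotationSet:
    """Read a GFF3 file into an :class:`AnnotationSet`.

    ``contigs`` supplies contig lengths, either as parsed contigs or as an
    id -> length mapping; when omitted, lengths are taken from
    ``##sequence-region`` pragmas.  Coordinates are converted from 1-based
    inclusive to 0-based half-open.  A feature with a ``pseudogene=`` or
    ``pseudo=`` attribute is classed as pseudogene regardless of its type
    column.
    """
    path = Path(path)
    if contigs is None:
        lengths = {}
        for raw in path.read_text().splitlines():
            if raw.startswith("##sequence-region"):
                parts = raw.split()
                if len(parts) >= 4:
                    lengths[parts[1]] = int(parts[3])
        if not lengths:
            raise ValueError(
                f"{path}: no contig lengths given and no ##sequence-region pragmas"
            )
    elif isinstance(contigs, dict):
        lengths = dict(contigs)
    else:
        lengths = {c.id: len(c) for c in contigs}
    records: list[GeneRecord] = []
    counter = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 tab-separated columns")
        seqid, _source, ftype, start1, end1, _score, strand, _phase, attr_field = fields
        if ftype not in _GFF_TYPE_TO_CLASS:
            continue  # tolerate region/gene/mRNA scaffolding lines
        if seqid not in lengths:
            raise ValueError(f"{path}:{lineno}: unknown contig {seqid!r}")
        attrs = _parse_gff_attributes(attr_field)
        feature_class = _GFF_TYPE_TO_CLASS[ftype]
        if "pseudogene" in attrs or attrs.get("pseudo") == "true":
            feature_class = "pseudogene"
        if attrs.get("prophage") == "true" or attrs.get("phage") == "true":
            feature_class = "phage"
        start = int(start1) - 1
        end = int(end1)
        if end > lengths[seqid]:
            raise ValueError(
                f"{path}:{lineno}: feature extends past end of contig {seqid!r}"
            )
        counter += 1
        gene_id = attrs.get("ID", f"feature_{counter:05d}")
        protein_length = None
        if feature_class == "CDS":
            if "protein_length" in attrs:
                protein_length = int(attrs["protein_length"])
            else:
                protein_length = max(1, (end - start) // 3 - 1)
        records.append(
            GeneRecord(
                gene_id=gene_id,
                contig_id=seqid,
                start=start,
                end=end,
                strand=strand if strand in "+-" else "+",
                feature_class=feature_class,
                product=attrs.get("product", "hypothetical protein"),
                protein_length=protein_length,
            )
        )
    return AnnotationSet(
        genome_id=genome_id or path.stem,
        records=records,
        genome_length=sum(lengths.values()),
        contig_lengths=lengths,
    )


def write_gff(annotation: AnnotationSet, path: str | Path) -> None:
    """Write an annotation back out as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for cid, length in annotation.contig_lengths.items():
            handle.write(f"##sequence-region {cid} 1 {length}\n")
        for rec in annotation.records:
            attrs = [f"ID={rec.gene_id}",
                     f"product={urllib.parse.quote(rec.product, safe=' ')}"]
            if rec.protein_length is not None:
                attrs.append(f"protein_length={rec.protein_length}")
            handle.write(
                "\t".join(
                    [
                        rec.contig_id,
                        "endosym",
                        _CLASS_TO_GFF_TYPE[rec.feature_class],
                        str(rec.start + 1),
                        str(rec.end),
                        ".",
                        rec.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------

def parse_hit_table(path: str | Path) -> HitTable:
    """Read a tab-separated hit table (outfmt-6 + kingdom, lineage, qlen).

    Query coverage is computed as ``aln_len / qlen``, capped at 1.
    """
    hits: list[HitRecord] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) != len(HIT_TABLE_COLUMNS):
            raise ValueError(
                f"{path}:{lineno}: expected {len(HIT_TABLE_COLUMNS)} columns, "
                f"got {len(fields)}"
            )
        try:
            evalue = float(fields[10])
            aln_len = int(fields[3])
            qlen = int(fields[14])
            pident = float(fields[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
        if evalue < 0:
            raise ValueError(f"{path}:{lineno}: negative evalue")
        hits.append(
            HitRecord(
                query_id=fields[0],
                subject_id=fields[1],
                subject_kingdom=fields[12],
                subject_lineage=[x for x in fields[13].split(";") if x],
                evalue=evalue,
                qcov=min(1.0, aln_len / qlen),
                pct_identity=pident,
                aln_len=aln_len,
            )
        )
    return HitTable(hits)


def write_hit_table(table: HitTable, path: str | Path) -> None:
    """Write a hit table in the same 15-column dialect ``parse_hit_table`` reads.

    Alignment coordinates not carried by :class:`HitRecord` are emitted as
    a 1..aln_len span; qlen is reconstructed from qcov so the round trip is
    exact for tables produced by this package.
    """
    with open(path, "w") as handle:
        for hit in table.all_hits():
            qlen = max(hit.aln_len, round(hit.aln_len / hit.qcov)) if hit.qcov > 0 else hit.aln_len
            handle.write(
                "\t".join(
                    [
                        hit.query_id,
                        hit.subject_id,
                        f"{hit.pct_identity:.3f}",
                        str(hit.aln_len),
                        "0",
                        "0",
                        "1",
                        str(hit.aln_len),
                        "1",
                        str(hit.aln_len),
                        f"{hit.evalue:.3g}",
                        "0.0",
                        hit.subject_kingdom,
                        ";".join(hit.subject_lineage),
                        str(qlen),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def parse_newick(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree; support values are kept as internal node labels."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"{path}: Newick parse error: {exc}") from exc
    return tree


def parse_newick_string(newick: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ValueError(f"Newick parse error: {exc}") from exc
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


# ---------------------------------------------------------------------------
# Associations
# ---------------------------------------------------------------------------

def parse_association(path: str | Path) -> Association:
    """Read a 2-column TSV of (host leaf name, symbiont leaf name)."""
    pairs: list[tuple[str, str]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns")
        pairs.append((fields[0], fields[1]))
    return Association(pairs)


def write_association(assoc: Association, path: str | Path) -> None:
    with open(path, "w") as handle:
        for host, symbiont in assoc.pairs:
            handle.write(f"{host}\t{symbiont}\n")
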