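"""Sequence and table I/O: FASTA, GFF3 intervals, expression matrices, edge export.

All sequences are held internally as upper-case RNA (``U``); DNA is accepted on
input and normalized on request.  Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

log = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line/row."""


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


def normalize_rna(seq: str) -> str:
    """Upper-case, strip whitespace, and convert T to U."""
    return "".join(seq.split()).upper().replace("T", "U")


def revcomp_rna(seq: str) -> str:
    """Reverse complement of an RNA string (A<->U, C<->G)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FastaRecord:
    id: str
    sequence: str


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA; merged records carry colon-joined sorted ids."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"miRNA {self.id!r}: empty sequence")
        if self.sequence != self.sequence.upper():
            raise ValidationError(f"miRNA {self.id!r}: sequence must be upper-case")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValidationError(
                f"miRNA {self.id!r}: non-RNA characters {sorted(bad)}"
            )
        if not 18 <= len(self.sequence) <= 26:
            raise ValidationError(
                f"miRNA {self.id!r}: length {len(self.sequence)} outside 18-26"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Transcript:
    id: str
    sequence: str
    biotype: str = "lincRNA"  # lincRNA | mRNA

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValidationError(f"transcript {self.id!r}: empty sequence")
        if self.biotype not in ("lincRNA", "mRNA"):
            raise ValidationError(
                f"transcript {self.id!r}: biotype {self.biotype!r} not in "
                "{'lincRNA', 'mRNA'}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"interval {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"bad strand {self.strand!r}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strand-agnostic >=1 bp overlap under 1-based inclusive coordinates."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


class ExpressionMatrix:
    """Genes x samples matrix of non-negative FPKM-like values."""

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if (df.values < 0).any():
            raise ValidationError("expression values must be >= 0")
        self.values = df.astype(float)
        self.genes = [str(g) for g in df.index]
        self.samples = [str(s) for s in df.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, gene: str):
        return self.values.loc[gene].to_numpy()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, to_rna: bool = True) -> list[FastaRecord]:
    """Read a FASTA file into records, preserving order.

    Parameters
    ----------
    path : str or path-like
    to_rna : bool
        When true (default) sequences are upper-cased and T->U normalized.

    Raises
    ------
    ParseError
        On an empty file, a first line that is not a header, an empty header,
        an empty sequence, or a duplicate record id (the message names the
        line number or duplicate id).
    """
    records: list[FastaRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_lineno = 0
    chunks: list[str] = []

    def flush() -> None:
        if cur_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(
                f"{path}: record {cur_id!r} (line {cur_lineno}) has no sequence"
            )
        seq = normalize_rna(seq) if to_rna else "".join(seq.split())
        records.append(FastaRecord(cur_id, seq))

    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                chunks = []
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"{path}: empty FASTA header at line {lineno}")
                cur_id = header.split()[0]
                cur_lineno = lineno
                if cur_id in seen:
                    raise ParseError(
                        f"{path}: duplicate record id {cur_id!r} at line {lineno}"
                    )
                seen.add(cur_id)
            else:
                if cur_id is None:
                    raise ParseError(
                        f"{path}: expected FASTA header at line {lineno}, "
                        f"got {line[:30]!r}"
                    )
                chunks.append(line)
    flush()
    if not records:
        raise ParseError(f"{path}: empty FASTA file")
    return records


def write_fasta(records: Iterable, path, width: int = 70) -> None:
    """Write records (anything with .id and .sequence) as FASTA."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_transcripts(path, biotype: str = "lincRNA") -> list[Transcript]:
    """Read a transcript FASTA, assigning every record the given biotype."""
    return [Transcript(r.id, r.sequence, biotype) for r in read_fasta(path)]


# ---------------------------------------------------------------------------
# miRNA loading
# ---------------------------------------------------------------------------

def merge_identical_mirnas(mirnas: Sequence[MatureMiRNA]) -> list[MatureMiRNA]:
    """Merge records sharing a sequence; merged id = sorted ids joined by ':'.

    Idempotent: already-merged ids are split on ':' before re-sorting, so
    merging a merged set changes nothing.
    """
    by_seq: dict[str, list[str]] = {}
    order: list[str] = []
    for m in mirnas:
        if m.sequence not in by_seq:
            by_seq[m.sequence] = []
            order.append(m.sequence)
        by_seq[m.sequence].extend(m.id.split(":"))
    return [
        MatureMiRNA(":".join(sorted(set(by_seq[s]))), s) for s in order
    ]


def load_and_merge_mirnas(path, species_prefix: str) -> list[MatureMiRNA]:
    """Load a miRBase-style mature FASTA, keep one species, merge duplicates.

    Only ids starting with ``species_prefix`` are retained; records with
    identical mature sequences are merged into a single record whose id is the
    sorted original ids joined by ':'.  Pre/post-merge counts are logged.
    """
    recs = [r for r in read_fasta(path) if r.id.startswith(species_prefix)]
    if not recs:
        raise ValidationError(
            f"{path}: no records with species prefix {species_prefix!r}"
        )
    mirnas = [MatureMiRNA(r.id, r.sequence) for r in recs]
    merged = merge_identical_mirnas(mirnas)
    log.info(
        "loaded %d %s* mature miRNAs, %d unique sequences after merging",
        len(mirnas), species_prefix, len(merged),
    )
    return merged


def count_species_records(path, species_prefix: str) -> int:
    """Number of mature records with the species prefix, before merging."""
    return sum(1 for r in read_fasta(path) if r.id.startswith(species_prefix))


# ---------------------------------------------------------------------------
# Intergenic filter
# ---------------------------------------------------------------------------

def filter_intergenic_lincrnas(
    lincs: Sequence[tuple[Transcript, GenomicInterval]],
    genes: Sequence[GenomicInterval],
    hairpins: Sequence[GenomicInterval] = (),
) -> list[Transcript]:
    """Drop lincRNAs overlapping (>=1 bp, strand-agnostic) a gene or hairpin.

    Survivors are returned in input order.  Uses a per-chromosome sorted
    interval sweep; behavior equals the all-pairs overlap scan.
    """
    blockers: dict[str, list[tuple[int, int]]] = {}
    for iv in list(genes) + list(hairpins):
        blockers.setdefault(iv.chrom, []).append((iv.start, iv.end))
    # merge per chromosome so the sweep is a single sorted pass
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, spans in blockers.items():
        spans.sort()
        out: list[tuple[int, int]] = []
        for s, e in spans:
            if out and s <= out[-1][1] + 1:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[chrom] = out

    import bisect

    survivors: list[Transcript] = []
    for tx, iv in lincs:
        spans = merged.get(iv.chrom, [])
        idx = bisect.bisect_left(spans, (iv.start, iv.start))
        hit = (idx > 0 and spans[idx - 1][1] >= iv.start) or (
            idx < len(spans) and spans[idx][0] <= iv.end
        )
        if not hit:
            survivors.append(tx)
    return survivors


# ---------------------------------------------------------------------------
# GFF3 intervals (only seqid/type/start/end/strand are consumed)
# ---------------------------------------------------------------------------

def read_gff3_intervals(path, feature_types: set[str] | None = None) -> list[GenomicInterval]:
    """Read intervals from a GFF3 file, optionally restricted to feature types."""
    out: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ParseError(f"{path}: line {lineno}: expected >=8 GFF3 columns")
            seqid, _src, ftype, start, end, _score, strand = fields[:7]
            if feature_types is not None and ftype not in feature_types:
                continue
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad coordinates") from exc
            out.append(GenomicInterval(seqid, s, e, strand if strand in "+-." else "."))
    return out


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a TSV (first column gene id, header row of sample ids).

    Raises ParseError with a row number for ragged rows or non-numeric cells.
    """
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        ncol = len(header)
        rows: list[list[str]] = []
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != ncol:
                raise ParseError(
                    f"{path}: row {lineno}: {len(fields)} fields, expected {ncol}"
                )
            rows.append(fields)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    df = pd.DataFrame([r[1:] for r in rows], index=[r[0] for r in rows],
                      columns=header[1:])
    try:
        df = df.astype(float)
    except ValueError:
        for i, r in enumerate(rows):
            for cell in r[1:]:
                try:
                    float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}: row {i + 2}: non-numeric cell {cell!r}"
                    ) from None
        raise
    return ExpressionMatrix(df)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values
    with open(path, "w") as handle:
        handle.write("gene\t" + "\t".join(matrix.samples) + "\n")
        for gene in matrix.genes:
            vals = "\t".join(format(v, "g") for v in df.loc[gene])
            handle.write(f"{gene}\t{vals}\n")


# ---------------------------------------------------------------------------
# Network edge export
# ---------------------------------------------------------------------------

def export_network_edges(network, path, dialect: str = "SIF") -> str:
    """Export edges one per line plus a node-attribute side file.

    ``dialect`` is ``SIF`` ("source interaction target") or ``TSV`` (header +
    three columns).  Returns the node-attribute file path.
    """
    if dialect not in ("SIF", "TSV"):
        raise ValidationError(f"unknown edge dialect {dialect!r}")
    path = os.fspath(path)
    with open(path, "w") as handle:
        if dialect == "TSV":
            handle.write("source\tinteraction\ttarget\n")
        for mirna, partner, role in sorted(network.edges):
            if dialect == "SIF":
                handle.write(f"{mirna} {role} {partner}\n")
            else:
                handle.write(f"{mirna}\t{role}\t{partner}\n")
    attr_path = path + ".nodes.tsv"
    with open(attr_path, "w") as handle:
        handle.write("node\tkind\troles\n")
        for node in sorted(network.nodes):
            info = network.nodes[node]
            roles = ",".join(sorted(info.roles))
            handle.write(f"{node}\t{info.kind}\t{roles}\n")
    return attr_path
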