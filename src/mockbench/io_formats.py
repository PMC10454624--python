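"""Readers and writers for the standard formats the pipeline exchanges.

All genomic intervals are 0-based half-open internally.  SAM input (1-based)
is converted exactly once, at ingestion.  Taxonomic labels keep their
original spelling for reporting but are compared after normalization
(whitespace-collapsed, case-folded).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam

RANKS = ("phylum", "family", "genus", "species")

_OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def normalize_label(label: str | None) -> str:
    """Normalize a taxonomic label for comparison.

    Trims, collapses internal whitespace, and case-folds.  ``None`` and
    placeholder strings ("", "NA", "-") normalize to the empty string,
    meaning "not classified at this rank".
    """
    if label is None:
        return ""
    text = re.sub(r"\s+", " ", str(label).strip())
    if text in ("", "NA", "na", "-", "."):
        return ""
    return text.casefold()


@dataclass(frozen=True)
class TaxonomicLineage:
    """Ranked labels from phylum to species; empty string = unclassified."""

    phylum: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def label(self, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank: {rank!r}")
        return getattr(self, rank)

    def normalized(self, rank: str) -> str:
        return normalize_label(self.label(rank))

    def matches(self, other: "TaxonomicLineage", rank: str) -> bool:
        a, b = self.normalized(rank), other.normalized(rank)
        return bool(a) and a == b


@dataclass(frozen=True)
class SsuGene:
    """One annotated 16S rRNA gene copy (0-based half-open interval)."""

    gene_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.gene_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """A genome's length and its annotated 16S gene copies."""

    genome_id: str
    length_bp: int
    ssu_genes: list[SsuGene] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError("genome length must be positive")
        seen: set[str] = set()
        for g in self.ssu_genes:
            if g.end > self.length_bp:
                raise ValueError(
                    f"gene {g.gene_id} [{g.start},{g.end}) exceeds genome "
                    f"length {self.length_bp}"
                )
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene id {g.gene_id!r}")
            seen.add(g.gene_id)


@dataclass
class AlignmentRecord:
    """One parsed SAM alignment in 0-based half-open reference coordinates.

    ``aligned_blocks`` are the maximal reference intervals covered by
    M/=/X/D CIGAR operations (deletions bridge blocks: reference-space
    pileup semantics).  Insertions and clips consume no reference.
    """

    read_id: str
    mate: str  # {"fwd", "rev", "single"}
    mapped: bool
    primary: bool
    genome_id: str | None = None
    ref_span: tuple[int, int] | None = None
    aligned_blocks: list[tuple[int, int]] = field(default_factory=list)

    @property
    def aligned_ref_bases(self) -> int:
        return sum(e - s for s, e in self.aligned_blocks)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(identifier, sequence), ...]``.

    Order is preserved.  Sequences are upper-cased.  Malformed headers,
    empty records, and characters outside {A,C,G,T,N} raise
    :class:`FormatError` naming the offending line.
    """
    records: list[tuple[str, str]] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}: empty record {header!r} at line {header_line}")
        records.append((header, seq))
        header, chunks = None, []

    line_no = 0
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush(line_no)
                name = line[1:].split()[0] if line[1:].strip() else ""
                if not name:
                    raise FormatError(f"{path}: malformed header at line {line_no}")
                header, header_line = name, line_no
            else:
                if header is None:
                    raise FormatError(
                        f"{path}: sequence before any header at line {line_no}"
                    )
                seq = line.strip().upper()
                if not set(seq) <= set("ACGTN"):
                    bad = sorted(set(seq) - set("ACGTN"))
                    raise FormatError(
                        f"{path}: invalid characters {bad} at line {line_no}"
                    )
                chunks.append(seq)
        flush(line_no)
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]],
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[tuple[str, SsuGene]]:
    """Read a 3–6 column BED file of 16S gene intervals.

    Returns ``[(genome_id, SsuGene), ...]`` in file order.  Coordinates are
    0-based half-open as in the BED standard; the strand column defaults to
    "+" when absent.
    """
    out: list[tuple[str, SsuGene]] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}: fewer than 3 columns at line {line_no}")
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-integer coordinate at line {line_no}"
                ) from exc
            if start >= end or start < 0:
                raise FormatError(
                    f"{path}: invalid interval [{start}, {end}) at line {line_no}"
                )
            name = cols[3] if len(cols) > 3 and cols[3] != "." else f"{chrom}:{start}-{end}"
            strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "+"
            out.append((chrom, SsuGene(name, start, end, strand)))
    return out


def write_bed(path: str | Path, intervals: Iterable[tuple[str, SsuGene]]) -> None:
    with open(path, "w") as fh:
        for genome_id, g in intervals:
            fh.write(f"{genome_id}\t{g.start}\t{g.end}\t{g.gene_id}\t.\t{g.strand}\n")


def annotations_from_bed(
    path: str | Path, genome_lengths: dict[str, int]
) -> dict[str, GenomeAnnotation]:
    """Assemble per-genome annotations from a BED file and known lengths."""
    genes: dict[str, list[SsuGene]] = {gid: [] for gid in genome_lengths}
    for genome_id, gene in read_bed(path):
        if genome_id not in genome_lengths:
            raise FormatError(f"BED references unknown genome {genome_id!r}")
        genes[genome_id].append(gene)
    return {
        gid: GenomeAnnotation(gid, genome_lengths[gid], genes[gid])
        for gid in genome_lengths
    }


# ---------------------------------------------------------------------------
# SAM


def _blocks_from_cigar(cigartuples: Sequence[tuple[int, int]],
                       start: int) -> list[tuple[int, int]]:
    # pysam op codes: 0=M 1=I 2=D 3=N 4=S 5=H 6=P 7== 8=X
    blocks: list[tuple[int, int]] = []
    pos = start
    open_start: int | None = None
    for op, length in cigartuples:
        if op in (0, 2, 7, 8):  # M, D, =, X consume reference and count as covered
            if open_start is None:
                open_start = pos
            pos += length
        elif op == 3:  # N: reference skip breaks the block
            if open_start is not None:
                blocks.append((open_start, pos))
                open_start = None
            pos += length
        elif op in (1, 4, 5, 6):  # I, S, H, P: no reference consumption
            continue
        else:
            raise FormatError(f"unknown CIGAR opcode {op}")
    if open_start is not None:
        blocks.append((open_start, pos))
    return blocks


def _record_from_pysam(seg: pysam.AlignedSegment,
                       lengths: dict[str, int]) -> AlignmentRecord:
    if seg.is_paired:
        mate = "rev" if seg.is_read2 else "fwd"
    else:
        mate = "single"
    if seg.is_unmapped:
        return AlignmentRecord(seg.query_name, mate, mapped=False,
                               primary=not (seg.is_secondary or seg.is_supplementary))
    genome_id = seg.reference_name
    if genome_id not in lengths:
        raise FormatError(f"alignment references absent genome {genome_id!r}")
    blocks = _blocks_from_cigar(seg.cigartuples or [], seg.reference_start)
    span = (blocks[0][0], blocks[-1][1]) if blocks else None
    if span is not None and span[1] > lengths[genome_id]:
        raise FormatError(
            f"alignment of {seg.query_name} exceeds length of {genome_id}"
        )
    return AlignmentRecord(
        read_id=seg.query_name,
        mate=mate,
        mapped=True,
        primary=not (seg.is_secondary or seg.is_supplementary),
        genome_id=genome_id,
        ref_span=span,
        aligned_blocks=blocks,
    )


def read_sam(path: str | Path) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a SAM file (text; header required).

    pysam does the heavy lifting; 1-based SAM positions become 0-based
    half-open intervals here and nowhere else.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        lengths = dict(zip(fh.references, fh.lengths))
        for seg in fh:
            yield _record_from_pysam(seg, lengths)


# ---------------------------------------------------------------------------
# TSV tables


def read_mock_metadata(path: str | Path) -> pd.DataFrame:
    """Read the mock composition table.

    Required columns: species, phylum, family, genus, genome_length_bp,
    ssu_copies.  Returns the validated DataFrame.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"species", "phylum", "family", "genus",
                "genome_length_bp", "ssu_copies"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df["species"].duplicated().any():
        dup = df.loc[df["species"].duplicated(), "species"].tolist()
        raise FormatError(f"{path}: duplicate species {dup}")
    if (df["genome_length_bp"] < 1).any() or (df["ssu_copies"] < 1).any():
        raise FormatError(f"{path}: genome_length_bp and ssu_copies must be >= 1")
    return df


def lineages_from_metadata(df: pd.DataFrame) -> dict[str, TaxonomicLineage]:
    """Map species label -> lineage from a mock metadata table."""
    return {
        row["species"]: TaxonomicLineage(
            phylum=str(row["phylum"]), family=str(row["family"]),
            genus=str(row["genus"]), species=str(row["species"]),
        )
        for _, row in df.iterrows()
    }


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a features × samples count table (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate sample names")
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative counts")
    return df


def write_feature_table(path: str | Path, table: pd.DataFrame,
                        index_label: str = "feature_id") -> None:
    table.to_csv(path, sep="\t", index_label=index_label)


def read_taxonomy_calls(path: str | Path) -> pd.DataFrame:
    """Read per-ASV taxonomy calls (asv_id, rank columns, optional confidence)."""
    df = pd.read_csv(path, sep="\t", dtype={"asv_id": str}, keep_default_na=False)
    if "asv_id" not in df.columns:
        raise FormatError(f"{path}: missing asv_id column")
    if "confidence" in df.columns:
        conf = pd.to_numeric(df["confidence"].replace("", "nan"), errors="coerce")
        if ((conf < 0) | (conf > 1)).any():
            raise FormatError(f"{path}: confidence outside [0, 1]")
        df["confidence"] = conf
    return df


def read_blast_outfmt6(path: str | Path) -> pd.DataFrame:
    """Read a BLAST outfmt-6 tabular hit file (standard 12 columns)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=_OUTFMT6_COLUMNS,
                     dtype={"qseqid": str, "sseqid": str})
    if df.empty:
        return df
    if ((df["pident"] < 0) | (df["pident"] > 100)).any():
        raise FormatError(f"{path}: pident outside [0, 100]")
    return df
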