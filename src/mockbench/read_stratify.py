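"""Stratify aligned reads against annotated 16S genes; per-gene coverage.

Reads (or read pairs) mapped to the mock reference genomes are sorted into
four categories:

* ``on_target``   — the primary alignment(s) overlap an annotated 16S gene;
  for pairs, both mates must land on the same gene or on byte-identical
  copies of it within the same genome.
* ``ambiguous``   — pairs touching 16S regions that fail the same-gene /
  identical-copy rule (including one mate on-gene, the other elsewhere).
* ``off_target``  — mapped, but no mate overlaps any 16S gene.
* ``unmapped``    — no mate has a primary mapped alignment.

Only primary alignments participate; secondary and supplementary records
are ignored everywhere.  Genomes frequently carry several rRNA operons
whose 16S sequences are literally identical, which is why concordance is
judged at the level of identical-copy groups rather than individual gene
ids.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_formats import AlignmentRecord, GenomeAnnotation, SsuGene

CATEGORIES = ("on_target", "ambiguous", "off_target", "unmapped")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PairClassification:
    """Verdict for one read or read pair."""

    category: str
    assigned_gene: str | None = None  # gene id or identical-copy group id
    species: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.assigned_gene is not None and self.category != "on_target":
            raise ValueError("assigned_gene only valid for on_target")


@dataclass
class CoverageProfile:
    """Per-position read depth over one 16S gene."""

    gene_id: str
    depth: np.ndarray

    @property
    def total_bases(self) -> int:
        return int(self.depth.sum())


def identical_copy_groups(genome_sequence: str,
                          ssu_genes: Iterable[SsuGene]) -> dict[str, str]:
    """Partition a genome's 16S copies into byte-identical groups.

    Minus-strand copies are reverse-complemented before comparison, so two
    copies on opposite strands with the same gene sequence group together.
    Returns ``gene_id -> group_id`` where the group id is the
    lexicographically smallest member joined with its peers by "|".
    """
    genome_sequence = genome_sequence.upper()
    by_seq: dict[str, list[str]] = defaultdict(list)
    for g in ssu_genes:
        if g.end > len(genome_sequence):
            raise ValueError(
                f"gene {g.gene_id} [{g.start},{g.end}) outside genome of "
                f"length {len(genome_sequence)}"
            )
        seq = genome_sequence[g.start:g.end]
        if g.strand == "-":
            seq = reverse_complement(seq)
        by_seq[seq].append(g.gene_id)
    mapping: dict[str, str] = {}
    for members in by_seq.values():
        group_id = "|".join(sorted(members))
        for gene_id in members:
            mapping[gene_id] = group_id
    return mapping


def overlaps_ssu(record: AlignmentRecord, annotation: GenomeAnnotation,
                 min_overlap_bp: int = 1) -> str | None:
    """Gene whose interval overlaps the record's aligned blocks by
    >= ``min_overlap_bp`` reference bases, or None.

    Overlap is summed over aligned blocks (deletions included, insertions
    and clips not).  If several genes qualify, the one with the largest
    overlap wins (ties: leftmost gene).
    """
    if not record.mapped or not record.primary:
        raise ValueError("record must be a mapped primary alignment")
    best: tuple[int, int, str] | None = None  # (-overlap, start, gene_id)
    for gene in annotation.ssu_genes:
        overlap = 0
        for s, e in record.aligned_blocks:
            overlap += max(0, min(e, gene.end) - max(s, gene.start))
        if overlap >= min_overlap_bp:
            key = (-overlap, gene.start, gene.gene_id)
            if best is None or key < best:
                best = key
    return best[2] if best else None


def _is_usable(rec: AlignmentRecord | None) -> bool:
    return rec is not None and rec.mapped and rec.primary


def classify_pair(fwd: AlignmentRecord | None, rev: AlignmentRecord | None,
                  annotations: Mapping[str, GenomeAnnotation],
                  copy_groups: Mapping[str, Mapping[str, str]],
                  min_overlap_bp: int = 1,
                  species_of: Mapping[str, str] | None = None,
                  ) -> PairClassification:
    """Classify a read pair from the primary alignments of its two mates.

    ``copy_groups`` maps genome_id -> (gene_id -> identical-copy group id).
    A pair is on-target only when both mates overlap 16S genes belonging to
    the same identical-copy group of the same genome; pairs touching 16S
    regions in any other configuration are ambiguous.
    """
    if (fwd is not None and rev is not None
            and fwd.read_id != rev.read_id):
        raise ValueError(
            f"mate read ids differ: {fwd.read_id!r} vs {rev.read_id!r}"
        )
    mates = [m for m in (fwd, rev) if _is_usable(m)]
    if not mates:
        return PairClassification("unmapped")

    hits: list[tuple[str, str] | None] = []  # (genome_id, gene_id) per usable mate
    for m in mates:
        gene = overlaps_ssu(m, annotations[m.genome_id], min_overlap_bp)
        hits.append((m.genome_id, gene) if gene is not None else None)

    n_on = sum(h is not None for h in hits)
    if n_on == 0:
        return PairClassification("off_target")
    if n_on < 2 or len(mates) < 2:
        # one mate on a 16S gene, the other off-target/unmapped: the pair
        # touches a target region but is not concordant
        return PairClassification("ambiguous")

    (g1, gene1), (g2, gene2) = hits  # type: ignore[misc]
    if g1 == g2:
        grp1 = copy_groups[g1].get(gene1, gene1)
        grp2 = copy_groups[g2].get(gene2, gene2)
        if grp1 == grp2:
            species = species_of.get(g1, g1) if species_of else g1
            return PairClassification("on_target", assigned_gene=grp1,
                                      species=species)
    return PairClassification("ambiguous")


def classify_single(rec: AlignmentRecord | None,
                    annotations: Mapping[str, GenomeAnnotation],
                    min_overlap_bp: int = 1,
                    species_of: Mapping[str, str] | None = None,
                    ) -> PairClassification:
    """Classify a single (e.g. full-length) read from its primary alignment."""
    if not _is_usable(rec):
        return PairClassification("unmapped")
    assert rec is not None
    gene = overlaps_ssu(rec, annotations[rec.genome_id], min_overlap_bp)
    if gene is None:
        return PairClassification("off_target")
    species = species_of.get(rec.genome_id, rec.genome_id) if species_of \
        else rec.genome_id
    return PairClassification("on_target", assigned_gene=gene, species=species)


@dataclass
class StratificationReport:
    """Category counts/percentages and on-target species abundances."""

    counts: dict[str, int]
    total: int
    species_counts: dict[str, int] = field(default_factory=dict)
    classifications: dict[str, PairClassification] = field(default_factory=dict)

    @property
    def percentages(self) -> dict[str, float]:
        if self.total == 0:
            return {c: 0.0 for c in CATEGORIES}
        return {c: 100.0 * self.counts[c] / self.total for c in CATEGORIES}

    @property
    def species_ra(self) -> dict[str, float]:
        on = sum(self.species_counts.values())
        if on == 0:
            return {}
        return {sp: n / on for sp, n in sorted(self.species_counts.items())}

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame({
            "category": list(CATEGORIES),
            "count": [self.counts[c] for c in CATEGORIES],
            "percent": [pct[c] for c in CATEGORIES],
        })


def stratify(alignments: Iterable[AlignmentRecord],
             annotations: Mapping[str, GenomeAnnotation],
             copy_groups: Mapping[str, Mapping[str, str]] | None = None,
             paired: bool = True,
             min_overlap_bp: int = 1,
             species_of: Mapping[str, str] | None = None,
             ) -> StratificationReport:
    """Classify every read (pair) in an alignment stream.

    Counts are per pair when ``paired`` (a pair with no mapped mate counts
    once as unmapped), per read otherwise.  Secondary and supplementary
    alignments are dropped before grouping and can never influence the
    outcome.  Species relative abundances are computed over on-target
    reads only.
    """
    if copy_groups is None:
        copy_groups = {}
    copy_groups = defaultdict(dict, copy_groups)

    by_read: dict[str, dict[str, AlignmentRecord]] = defaultdict(dict)
    order: list[str] = []
    for rec in alignments:
        if not rec.primary:
            continue
        if rec.mapped and rec.genome_id not in annotations:
            raise ValueError(f"unannotated genome {rec.genome_id!r}")
        if rec.read_id not in by_read:
            order.append(rec.read_id)
        by_read[rec.read_id][rec.mate] = rec

    counts = {c: 0 for c in CATEGORIES}
    species_counts: dict[str, int] = defaultdict(int)
    classifications: dict[str, PairClassification] = {}
    for read_id in order:
        mates = by_read[read_id]
        if paired:
            cls = classify_pair(mates.get("fwd"), mates.get("rev"),
                                annotations, copy_groups, min_overlap_bp,
                                species_of)
        else:
            rec = mates.get("single") or mates.get("fwd") or mates.get("rev")
            cls = classify_single(rec, annotations, min_overlap_bp, species_of)
        counts[cls.category] += 1
        if cls.category == "on_target" and cls.species is not None:
            species_counts[cls.species] += 1
        classifications[read_id] = cls

    return StratificationReport(
        counts=counts, total=len(order),
        species_counts=dict(species_counts),
        classifications=classifications,
    )


def gene_coverage(alignments: Iterable[AlignmentRecord],
                  genome_id: str, gene: SsuGene) -> CoverageProfile:
    """Per-position depth over one gene from primary alignments.

    ``depth[p]`` counts the primary-alignment blocks covering reference
    position ``gene.start + p``; deletion-spanned positions count as
    covered (reference-space pileup semantics).
    """
    length = len(gene)
    diff = np.zeros(length + 1, dtype=np.int64)
    for rec in alignments:
        if not (rec.mapped and rec.primary and rec.genome_id == genome_id):
            continue
        for s, e in rec.aligned_blocks:
            lo = max(s, gene.start) - gene.start
            hi = min(e, gene.end) - gene.start
            if lo < hi:
                diff[lo] += 1
                diff[hi] -= 1
    return CoverageProfile(gene.gene_id, np.cumsum(diff[:-1]))
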