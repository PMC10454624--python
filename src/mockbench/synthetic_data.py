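"""Ground-truth simulator for the whole benchmarking pipeline.

Emulates the structure of a 20-strain even-genomic-mass mock community:
each species gets a random genome with several 16S gene copies implanted
(a configurable fraction byte-identical, the rest mutated at >= 1 site),
all species' 16S genes descending from one shared ancestral sequence so
that inter-species similarity is controllable.  From that bundle it
simulates:

* short paired-end and full-length reads with truth alignments (SAM), so
  stratification can be tested without running an aligner;
* ASVs with sequence noise, read counts, and taxonomic calls with per-rank
  error (confidences higher for correct calls on average);
* multi-sample count tables with group structure for diversity testing.

Genome lengths default to a scaled-down range (tens to hundreds of kb
rather than Mb) that preserves the relative genome-size and copy-number
variability driving the expectation model while keeping desk-scale runs
fast.  Every output is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd
import pysam

from .io_formats import (
    AlignmentRecord,
    GenomeAnnotation,
    SsuGene,
    TaxonomicLineage,
    write_bed,
    write_fasta,
)
from .mock_model import ExpectedProfile, MockSpecies, expected_profile
from .read_stratify import identical_copy_groups, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the simulator, with study-shaped defaults."""

    n_species: int = 20
    genome_length_range: tuple[int, int] = (80_000, 340_000)
    ssu_copies_range: tuple[int, int] = (1, 10)
    identical_copy_fraction: float = 0.5
    gene_length: int = 1550
    divergence: float = 0.05            # substitutions/site between species 16S genes
    read_length: int = 250              # per mate, short PE mode
    insert_range: tuple[int, int] = (350, 550)
    long_read_range: tuple[int, int] = (1000, 1600)
    n_reads: int = 10_000
    read_error: float = 0.001           # substitutions/site on read sequences
    off_target_fraction: float = 0.01
    unmapped_fraction: float = 0.0
    n_asvs: int | None = None           # default: one ASV per 16S gene copy
    asv_noise: float = 0.005            # substitutions/site on ASV sequences
    call_error: float = 0.1             # per-rank probability of a wrong/blank call
    call_blank_fraction: float = 0.5    # share of call errors that are blanks
    n_samples: int = 6                  # per group, count-table simulation
    n_groups: int = 2
    depth: int = 10_000
    dirichlet_concentration: float = 50.0
    group_separation: float = 0.0       # log-scale spread of group means
    concentration_ng_per_ul: float = 2.6
    volume_ul: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("identical_copy_fraction", "off_target_fraction",
                     "unmapped_fraction", "asv_noise", "call_error",
                     "call_blank_fraction", "divergence", "read_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("genome_length_range", "ssu_copies_range",
                     "insert_range", "long_read_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"invalid range {name}={lo, hi}")
        if self.off_target_fraction + self.unmapped_fraction > 1.0:
            raise ValueError("off_target + unmapped fractions exceed 1")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator,
            min_subs: int = 0) -> str:
    n = max(min_subs, rng.binomial(len(seq), rate)) if rate > 0 else min_subs
    n = min(n, len(seq))
    if n == 0:
        return seq
    positions = rng.choice(len(seq), size=n, replace=False)
    out = bytearray(seq, "ascii")
    for p in positions:
        old = chr(out[p])
        choices = [b for b in "ACGT" if b != old]
        out[p] = ord(choices[rng.integers(0, len(choices))])
    return out.decode()


def _make_lineages(n_species: int, rng: np.random.Generator
                   ) -> list[TaxonomicLineage]:
    """Synthetic lineages: a few phyla, families of 1-2 genera, and two
    genera carrying two species each (congeneric pairs, as real mocks do)."""
    n_pairs = 2 if n_species >= 4 else 0
    n_genera = n_species - n_pairs
    genus_of_species: list[int] = list(range(n_genera))
    for p in range(n_pairs):
        genus_of_species.append(p)  # second species of the first genera
    lineages = []
    for i, g in enumerate(genus_of_species):
        genus = f"Genus{g + 1:02d}"
        family = f"Family{g // 2 + 1:02d}"
        phylum = f"Phylum{g % 5 + 1}"
        sp_idx = genus_of_species[:i + 1].count(g)
        lineages.append(TaxonomicLineage(
            phylum=phylum, family=family, genus=genus,
            species=f"{genus} sp{sp_idx}",
        ))
    return lineages


@dataclass
class TruthBundle:
    """Everything the simulator knows about the mock it generated."""

    config: SimConfig
    species: list[MockSpecies]
    genomes: dict[str, str]
    annotations: dict[str, GenomeAnnotation]
    gene_sequences: dict[tuple[str, str], str]  # (genome, gene) -> 5'->3' seq
    genome_to_species: dict[str, str]

    @property
    def copy_groups(self) -> dict[str, dict[str, str]]:
        return {
            gid: identical_copy_groups(self.genomes[gid],
                                       self.annotations[gid].ssu_genes)
            for gid in self.genomes
        }

    @property
    def expected(self) -> ExpectedProfile:
        return expected_profile(self.species,
                                self.config.concentration_ng_per_ul,
                                self.config.volume_ul)

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "species": s.name,
            "phylum": s.lineage.phylum,
            "family": s.lineage.family,
            "genus": s.lineage.genus,
            "genome_length_bp": s.genome_length_bp,
            "ssu_copies": s.ssu_copies,
        } for s in self.species])

    def truth_lineages(self) -> dict[str, TaxonomicLineage]:
        """genome_id -> known lineage (the ASV-evaluation truth map)."""
        by_name = {s.name: s.lineage for s in self.species}
        return {gid: by_name[sp] for gid, sp in self.genome_to_species.items()}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "genomes.fasta", sorted(self.genomes.items()))
        intervals = [(gid, g) for gid in sorted(self.annotations)
                     for g in self.annotations[gid].ssu_genes]
        write_bed(outdir / "ssu.bed", intervals)
        self.metadata().to_csv(outdir / "mock_metadata.tsv", sep="\t",
                               index=False)
        pd.DataFrame([{
            "genome_id": gid,
            "phylum": lin.phylum, "family": lin.family,
            "genus": lin.genus, "species": lin.species,
        } for gid, lin in sorted(self.truth_lineages().items())]).to_csv(
            outdir / "truth_lineages.tsv", sep="\t", index=False)


def simulate_mock(config: SimConfig) -> TruthBundle:
    """Generate mock genomes with annotated, partly identical 16S copies."""
    rng = np.random.default_rng(config.seed)
    ancestor = _random_seq(rng, config.gene_length)
    lineages = _make_lineages(config.n_species, rng)

    species: list[MockSpecies] = []
    genomes: dict[str, str] = {}
    annotations: dict[str, GenomeAnnotation] = {}
    gene_sequences: dict[tuple[str, str], str] = {}
    genome_to_species: dict[str, str] = {}
    seen_genes: set[str] = set()

    for i, lineage in enumerate(lineages):
        genome_id = f"genome{i + 1:02d}"
        length = int(rng.integers(config.genome_length_range[0],
                                  config.genome_length_range[1] + 1))
        copies = int(rng.integers(config.ssu_copies_range[0],
                                  config.ssu_copies_range[1] + 1))
        if length < copies * (config.gene_length + 200) + 200:
            raise ValueError(
                f"genome of {length} bp too short for {copies} gene copies")

        # species 16S gene: descended from the shared ancestor, unique
        for _ in range(100):
            base_gene = _mutate(ancestor, config.divergence, rng, min_subs=1)
            if base_gene not in seen_genes:
                break
        else:
            raise RuntimeError("could not generate a distinct species gene")
        seen_genes.add(base_gene)

        n_identical = int(round(config.identical_copy_fraction * copies))
        copy_seqs = [base_gene] * n_identical
        variants = {base_gene}
        for _ in range(copies - n_identical):
            for _ in range(100):
                var = _mutate(base_gene, 0.0, rng, min_subs=1)
                if var not in variants:
                    break
            variants.add(var)
            copy_seqs.append(var)
        rng.shuffle(copy_seqs)

        # non-overlapping placements with a small margin
        placements: list[int] = []
        pad = 100
        for _ in range(copies):
            for _ in range(1000):
                start = int(rng.integers(pad, length - config.gene_length - pad))
                if all(abs(start - s) >= config.gene_length + pad
                       for s in placements):
                    placements.append(start)
                    break
            else:
                raise RuntimeError("could not place gene copies")
        placements.sort()

        genome = bytearray(_random_seq(rng, length), "ascii")
        genes: list[SsuGene] = []
        for j, start in enumerate(placements):
            seq = copy_seqs[j]
            strand = "+" if rng.random() < 0.5 else "-"
            implant = seq if strand == "+" else reverse_complement(seq)
            genome[start:start + config.gene_length] = implant.encode()
            gene = SsuGene(f"{genome_id}_ssu{j + 1}", start,
                           start + config.gene_length, strand)
            genes.append(gene)
            gene_sequences[(genome_id, gene.gene_id)] = seq

        species.append(MockSpecies(lineage.species, lineage, length, copies))
        genomes[genome_id] = genome.decode()
        annotations[genome_id] = GenomeAnnotation(genome_id, length, genes)
        genome_to_species[genome_id] = lineage.species

    return TruthBundle(config, species, genomes, annotations,
                       gene_sequences, genome_to_species)


# ---------------------------------------------------------------------------
# Reads


@dataclass
class SimRead:
    """One simulated alignment (or unmapped read) plus its truth."""

    read_id: str
    mate: str                      # fwd / rev / single
    genome_id: str | None
    start: int | None              # 0-based leftmost reference position
    length: int
    sequence: str
    reverse: bool
    category: str                  # on_target / off_target / unmapped
    species: str | None
    gene_id: str | None


@dataclass
class ReadSet:
    reads: list[SimRead]
    paired: bool
    genome_lengths: dict[str, int]

    def truth(self) -> pd.DataFrame:
        """Per read (pair) truth categories, one row per template."""
        rows = {}
        for r in self.reads:
            rows.setdefault(r.read_id, {
                "read_id": r.read_id, "category": r.category,
                "species": r.species, "gene_id": r.gene_id,
            })
        return pd.DataFrame(list(rows.values()))

    def alignment_records(self) -> Iterator[AlignmentRecord]:
        """Truth alignments as in-memory records (bypassing SAM round-trip)."""
        for r in self.reads:
            if r.category == "unmapped" or r.genome_id is None:
                yield AlignmentRecord(r.read_id, r.mate, mapped=False,
                                      primary=True)
            else:
                span = (r.start, r.start + r.length)
                yield AlignmentRecord(r.read_id, r.mate, mapped=True,
                                      primary=True, genome_id=r.genome_id,
                                      ref_span=span, aligned_blocks=[span])

    def write_sam(self, path: str | Path) -> None:
        names = sorted(self.genome_lengths)
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": n, "LN": self.genome_lengths[n]} for n in names],
        }
        ref_index = {n: i for i, n in enumerate(names)}
        with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
            by_template: dict[str, list[SimRead]] = {}
            for r in self.reads:
                by_template.setdefault(r.read_id, []).append(r)
            for reads in by_template.values():
                for r in reads:
                    a = pysam.AlignedSegment(fh.header)
                    a.query_name = r.read_id
                    a.query_sequence = r.sequence
                    flag = 0
                    if self.paired:
                        flag |= 0x1
                        flag |= 0x40 if r.mate == "fwd" else 0x80
                        other = next((o for o in reads if o is not r), None)
                        other_mapped = (other is not None
                                        and other.category != "unmapped")
                        if other_mapped and r.category != "unmapped":
                            flag |= 0x2
                        if other_mapped and other.reverse:
                            flag |= 0x20
                        if not other_mapped:
                            flag |= 0x8
                    if r.category == "unmapped" or r.genome_id is None:
                        flag |= 0x4
                        a.flag = flag
                        a.reference_id = -1
                        a.reference_start = -1
                        a.mapping_quality = 0
                    else:
                        if r.reverse:
                            flag |= 0x10
                        a.flag = flag
                        a.reference_id = ref_index[r.genome_id]
                        a.reference_start = r.start
                        a.mapping_quality = 60
                        a.cigarstring = f"{r.length}M"
                    fh.write(a)

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                suffix = {"fwd": "/1", "rev": "/2", "single": ""}[r.mate]
                fh.write(f"@{r.read_id}{suffix}\n{r.sequence}\n+\n"
                         + "I" * len(r.sequence) + "\n")


def _read_seq(genome: str, start: int, length: int, reverse: bool,
              error: float, rng: np.random.Generator) -> str:
    seq = genome[start:start + length]
    if reverse:
        seq = reverse_complement(seq)
    return _mutate(seq, error, rng) if error > 0 else seq


def _intergenic_start(annotation: GenomeAnnotation, span: int,
                      rng: np.random.Generator) -> int | None:
    for _ in range(200):
        start = int(rng.integers(0, annotation.length_bp - span))
        if all(min(start + span, g.end) <= max(start, g.start)
               for g in annotation.ssu_genes):
            return start
    return None


def simulate_reads(bundle: TruthBundle,
                   mode: Literal["short_pe", "long"] = "short_pe",
                   config: SimConfig | None = None,
                   seed: int | None = None) -> ReadSet:
    """Simulate reads with truth alignments.

    On-target templates are drawn from 16S genes with species probabilities
    equal to the bundle's expected profile (copy choice uniform within a
    species); ``off_target_fraction`` of templates come from intergenic
    loci and ``unmapped_fraction`` are random sequence.  Short PE mode
    emits proper fwd/rev mate pairs from a fragment inside the gene; long
    mode emits single full-length reads whose lengths fall in
    ``long_read_range`` (clipped to the gene length).
    """
    config = config or bundle.config
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    paired = mode == "short_pe"

    profile = bundle.expected
    species_names = profile.names
    probs = profile.expected_ra
    genome_of = {sp: gid for gid, sp in bundle.genome_to_species.items()}
    genome_ids = sorted(bundle.genomes)

    reads: list[SimRead] = []
    categories = rng.choice(
        ["on_target", "off_target", "unmapped"],
        size=config.n_reads,
        p=[1 - config.off_target_fraction - config.unmapped_fraction,
           config.off_target_fraction, config.unmapped_fraction],
    )
    species_draw = rng.choice(len(species_names), size=config.n_reads, p=probs)

    for i in range(config.n_reads):
        read_id = f"read{i + 1:07d}"
        category = str(categories[i])

        if category == "unmapped":
            n_mates = 2 if paired else 1
            for m in range(n_mates):
                mate = ("fwd", "rev")[m] if paired else "single"
                reads.append(SimRead(
                    read_id, mate, None, None, config.read_length,
                    _random_seq(rng, config.read_length), bool(m), category,
                    None, None))
            continue

        if category == "on_target":
            sp = species_names[species_draw[i]]
            gid = genome_of[sp]
            ann = bundle.annotations[gid]
            gene = ann.ssu_genes[rng.integers(0, len(ann.ssu_genes))]
            lo, hi, gene_id = gene.start, gene.end, gene.gene_id
        else:
            gid = genome_ids[rng.integers(0, len(genome_ids))]
            sp, gene_id = None, None
            ann = bundle.annotations[gid]

        genome = bundle.genomes[gid]
        if paired:
            max_ins = (hi - lo) if category == "on_target" else config.insert_range[1]
            ins_lo = min(config.insert_range[0], max_ins)
            ins_hi = min(config.insert_range[1], max_ins)
            insert = int(rng.integers(ins_lo, ins_hi + 1))
            insert = max(insert, config.read_length)
            if category == "on_target":
                frag = lo + int(rng.integers(0, hi - lo - insert + 1))
            else:
                start = _intergenic_start(ann, insert, rng)
                if start is None:  # genome too gene-dense; fall back to unmapped
                    continue
                frag = start
            r1 = (frag, config.read_length, False, "fwd")
            r2 = (frag + insert - config.read_length, config.read_length,
                  True, "rev")
            for start, length, rev, mate in (r1, r2):
                reads.append(SimRead(
                    read_id, mate, gid, start, length,
                    _read_seq(genome, start, length, rev, config.read_error,
                              rng),
                    rev, category, sp, gene_id))
        else:
            if category == "on_target":
                span = hi - lo
                rl_lo = min(config.long_read_range[0], span)
                rl_hi = min(config.long_read_range[1], span)
                length = int(rng.integers(rl_lo, rl_hi + 1))
                start = lo + int(rng.integers(0, span - length + 1))
            else:
                length = int(rng.integers(*config.long_read_range))
                start = _intergenic_start(ann, length, rng)
                if start is None:
                    continue
            rev = bool(rng.random() < 0.5)
            reads.append(SimRead(
                read_id, "single", gid, start, length,
                _read_seq(genome, start, length, rev, config.read_error, rng),
                rev, category, sp, gene_id))

    lengths = {gid: bundle.annotations[gid].length_bp for gid in bundle.genomes}
    return ReadSet(reads, paired, lengths)


# ---------------------------------------------------------------------------
# ASVs


@dataclass
class SimAsvs:
    asvs: list  # list[AsvRecord]; typed loosely to avoid an import cycle
    truth: pd.DataFrame  # asv_id, genome_id, gene_id, species + per-rank correctness


def _wrong_label(true_label: str, pool: list[str],
                 rng: np.random.Generator) -> str | None:
    others = sorted({p for p in pool if p and p != true_label})
    if not others:
        return None
    return others[rng.integers(0, len(others))]


def simulate_asvs(bundle: TruthBundle, config: SimConfig | None = None,
                  seed: int | None = None) -> SimAsvs:
    """Simulate ASVs with sequence noise and error-prone taxonomic calls.

    One ASV per 16S gene copy by default, or ``config.n_asvs`` ASVs drawn
    uniformly over gene copies.  Per rank, the call equals the truth with
    probability 1 - call_error; otherwise it is blank (with probability
    ``call_blank_fraction``) or a wrong label drawn from the other species.
    Read counts are log-normal; confidences are Beta-distributed with a
    higher mean for species-correct calls.
    """
    from .asv_eval import AsvRecord  # local import: asv_eval imports nothing from here

    config = config or bundle.config
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    ranks = ("phylum", "family", "genus", "species")
    label_pools = {r: [s.lineage.label(r) for s in bundle.species]
                   for r in ranks}
    lineage_of = {s.name: s.lineage for s in bundle.species}

    gene_keys = sorted(bundle.gene_sequences)
    if config.n_asvs is None:
        chosen = list(gene_keys)
    else:
        idx = rng.integers(0, len(gene_keys), size=config.n_asvs)
        chosen = [gene_keys[i] for i in idx]

    asvs: list[AsvRecord] = []
    truth_rows = []
    for i, (genome_id, gene_id) in enumerate(chosen):
        asv_id = f"asv{i + 1:05d}"
        seq = _mutate(bundle.gene_sequences[(genome_id, gene_id)],
                      config.asv_noise, rng)
        sp = bundle.genome_to_species[genome_id]
        true_lineage = lineage_of[sp]

        call_labels: dict[str, str] = {}
        correct: dict[str, bool] = {}
        for rank in ranks:
            true_label = true_lineage.label(rank)
            if rng.random() >= config.call_error:
                call_labels[rank] = true_label
                correct[rank] = True
            else:
                correct[rank] = False
                if rng.random() < config.call_blank_fraction:
                    call_labels[rank] = ""
                else:
                    wrong = _wrong_label(true_label, label_pools[rank], rng)
                    call_labels[rank] = wrong if wrong is not None else ""

        confidence = float(rng.beta(8, 2) if correct["species"]
                           else rng.beta(2, 5))
        read_count = float(1 + int(rng.lognormal(3.0, 1.0)))
        asvs.append(AsvRecord(
            asv_id=asv_id, sequence=seq, read_count=read_count,
            call=TaxonomicLineage(**call_labels), confidence=confidence,
        ))
        truth_rows.append({
            "asv_id": asv_id, "genome_id": genome_id, "gene_id": gene_id,
            "species": sp,
            **{f"correct_{r}": correct[r] for r in ranks},
        })
    return SimAsvs(asvs, pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# Count tables


def simulate_counts(bundle: TruthBundle, config: SimConfig | None = None,
                    seed: int | None = None):
    """Simulate a species-level count table with group structure.

    Group mean compositions start from the bundle's expected profile;
    ``group_separation`` scales log-normal perturbations that push the
    groups apart (0 = identical distributions, the PERMANOVA null).
    Samples are Dirichlet-multinomial around their group mean.  Returns
    (FeatureTable, sample -> group mapping).
    """
    from .diversity import FeatureTable

    config = config or bundle.config
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    base = bundle.expected.expected_ra
    n_feat = len(base)

    columns: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    for g in range(config.n_groups):
        group = f"group{g + 1}"
        if config.group_separation > 0:
            shift = rng.normal(0.0, config.group_separation, size=n_feat)
            mean = base * np.exp(shift)
            mean = mean / mean.sum()
        else:
            mean = base
        alpha = config.dirichlet_concentration * mean
        for j in range(config.n_samples):
            sample = f"{group}_s{j + 1}"
            comp = rng.dirichlet(alpha)
            columns[sample] = rng.multinomial(config.depth, comp)
            groups[sample] = group

    counts = pd.DataFrame(columns, index=[s.name for s in bundle.species])
    lineages = {s.name: s.lineage for s in bundle.species}
    return FeatureTable(counts, lineages), groups
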