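"""Expected 16S rDNA copies and relative abundances for an even-mass mock.

An even-genomic-mass mock community pools the same DNA mass of each member
species.  Because genomes differ in length, the same mass corresponds to a
different number of genome copies per species, and because genomes differ
in per-genome 16S gene copy number, the expected number of amplifiable 16S
templates differs again.  The chain is:

    GMW_i  = L_i × 607.4                 genome molecular weight [g/mol]
    nGM_i  = GMW_i / N_A × 10^9          single-genome mass [ng]
    m      = c × V / n                   per-species DNA mass [ng]
    GCN_i  = m / nGM_i                   genome copies in the pool
    E_i    = GCN_i × k_i                 expected 16S copies (k_i = copies/genome)

with L_i the genome length in bp, 607.4 g/mol the average mass of a dsDNA
base pair, N_A Avogadro's number, c the mix concentration [ng/µL], V its
volume [µL] and n the number of species.  Expected relative abundances are
the E_i normalized to sum to one; all mass terms cancel, so they reduce to
k_i / L_i renormalized — but the intermediate quantities are reported
because they are meaningful bench-side numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import TaxonomicLineage

#: Average mass of one double-stranded DNA base pair [g/mol].
BP_WEIGHT = 607.4
#: Avogadro's number [1/mol].
AVOGADRO = 6.022e23


@dataclass(frozen=True)
class MockSpecies:
    """One member of the mock: label, lineage, genome size, 16S copy count."""

    name: str
    lineage: TaxonomicLineage
    genome_length_bp: int
    ssu_copies: int

    def __post_init__(self) -> None:
        if self.genome_length_bp < 1:
            raise ValueError(f"{self.name}: genome_length_bp must be >= 1")
        if self.ssu_copies < 1:
            raise ValueError(f"{self.name}: ssu_copies must be >= 1")


def genome_molecular_weight(length_bp: float) -> float:
    """Genome molecular weight [g/mol] from its length in base pairs."""
    if length_bp < 0:
        raise ValueError("genome length must be nonnegative")
    return length_bp * BP_WEIGHT


def genome_mass_ng(gmw: float) -> float:
    """Mass of a single genome copy [ng] from its molecular weight [g/mol]."""
    if gmw < 0:
        raise ValueError("molecular weight must be nonnegative")
    return gmw / AVOGADRO * 1e9


def per_species_mass(concentration: float, volume: float,
                     n_species: int) -> float:
    """DNA mass [ng] contributed by each species of an even-mass mix.

    ``concentration`` [ng/µL] × ``volume`` [µL] is the total DNA mass of the
    mix, split evenly over ``n_species`` members.
    """
    if concentration <= 0 or volume <= 0:
        raise ValueError("concentration and volume must be positive")
    if n_species <= 0:
        raise ValueError("n_species must be positive")
    return concentration * volume / n_species


def genome_copy_number(mock_mass: float, ngm: float) -> float:
    """Number of genome copies in ``mock_mass`` ng of DNA.

    Real-valued by design: only ratios of copy numbers matter downstream and
    rounding would bias them.
    """
    if ngm <= 0:
        raise ValueError("single-genome mass must be positive")
    return mock_mass / ngm


@dataclass
class ExpectedProfile:
    """Per-species expected 16S copies and relative abundances.

    Arrays are aligned with ``species``.  ``expected_ra`` sums to 1.
    """

    species: list[MockSpecies]
    gmw: np.ndarray          # g/mol
    ngm: np.ndarray          # ng
    gcn: np.ndarray          # genome copies (real-valued)
    expected_copies: np.ndarray
    expected_ra: np.ndarray

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.species]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "species": self.names,
            "gmw_g_per_mol": self.gmw,
            "ngm_ng": self.ngm,
            "gcn": self.gcn,
            "expected_16s_copies": self.expected_copies,
            "expected_ra": self.expected_ra,
        })

    def ra_by_name(self) -> dict[str, float]:
        return dict(zip(self.names, self.expected_ra))

    def collapse(self, rank: str) -> pd.Series:
        """Aggregate expected relative abundances to a taxonomic rank.

        Species sharing a label at ``rank`` (e.g. two congeneric species)
        have their expected abundances summed, which is the expectation of
        the sum of their 16S copy pools.
        """
        labels = [s.lineage.label(rank) or s.name for s in self.species]
        return (
            pd.Series(self.expected_ra, index=labels)
            .groupby(level=0).sum().sort_index()
        )


def expected_profile(species: list[MockSpecies], concentration: float = 2.6,
                     volume: float = 50.0) -> ExpectedProfile:
    """Chain the even-mass model over a species list.

    Defaults reflect a 20-species even mix supplied at 2.6 ng/µL in 50 µL.
    Relative abundances are invariant to ``concentration`` and ``volume``
    (they cancel in the normalization); the absolute copy counts are not.
    """
    if not species:
        raise ValueError("species list is empty")
    names = [s.name for s in species]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate species names: {dupes}")

    lengths = np.array([s.genome_length_bp for s in species], dtype=float)
    copies = np.array([s.ssu_copies for s in species], dtype=float)

    gmw = np.array([genome_molecular_weight(l) for l in lengths])
    ngm = np.array([genome_mass_ng(w) for w in gmw])
    mass = per_species_mass(concentration, volume, len(species))
    gcn = np.array([genome_copy_number(mass, m) for m in ngm])
    expected = gcn * copies
    ra = expected / expected.sum()
    return ExpectedProfile(list(species), gmw, ngm, gcn, expected, ra)


def species_from_metadata(df: pd.DataFrame) -> list[MockSpecies]:
    """Build MockSpecies records from a mock metadata table (see io_formats)."""
    out = []
    for _, row in df.iterrows():
        lineage = TaxonomicLineage(
            phylum=str(row["phylum"]), family=str(row["family"]),
            genus=str(row["genus"]), species=str(row["species"]),
        )
        out.append(MockSpecies(
            name=str(row["species"]), lineage=lineage,
            genome_length_bp=int(row["genome_length_bp"]),
            ssu_copies=int(row["ssu_copies"]),
        ))
    return out
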