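"""Polarize cohort SNPs against an archaic genome and an outgroup.

A cohort SNP enters the archaic set iff the archaic genotype is homozygous
for one of its two alleles (that allele is *derived*, regardless of whether
it is VCF REF or ALT) and the outgroup carries the other allele (*ancestral*).
Heterozygous or missing archaic genotypes, and outgroup alleles matching
neither cohort allele, exclude the site; exclusions are counted.  The
resulting haplotype matrix is recoded so 1 = derived everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional

import numpy as np

from .dataio import HaplotypeSource, VariantRecord

__all__ = ["ArchaicSNP", "HaplotypeMatrix", "call_archaic_set", "classify_cpg"]

BASES = frozenset("ACGT")


@dataclass
class ArchaicSNP:
    """A polarized biallelic site.

    ``f_a`` is the exact derived-allele frequency over the 2N cohort
    haplotypes; ``role`` is filled by the block partitioning (block,
    singleton, omitted; monomorphic sites stay 'monomorphic').
    """

    chrom: str
    pos: int
    ancestral_allele: str
    derived_allele: str
    f_a: Fraction
    cpg_flag: Optional[bool] = None
    role: str = "unassigned"

    def __post_init__(self):
        if self.ancestral_allele == self.derived_allele:
            raise ValueError("ancestral and derived alleles must differ")

    @property
    def maf(self) -> Fraction:
        return min(self.f_a, 1 - self.f_a)

    @property
    def is_polymorphic(self) -> bool:
        return 0 < self.f_a < 1

    @property
    def strong_weak_pair(self) -> bool:
        """True iff one allele is G/C and the other A/T."""
        strong = {"G", "C"}
        return (self.ancestral_allele in strong) != (self.derived_allele in strong)


@dataclass
class HaplotypeMatrix:
    """Phased cohort over the archaic SNP set: haplotypes × sites, 1 = derived."""

    snps: list[ArchaicSNP]
    matrix: np.ndarray  # shape (2N, n_sites), int8
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.ascontiguousarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.snps):
            raise ValueError("matrix shape does not match SNP list")
        if self.sample_ids and self.matrix.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("row count must be 2 × sample count")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def column_frequency(self, j: int) -> Fraction:
        return Fraction(int(self.matrix[:, j].sum()), self.n_haplotypes)

    def check_frequencies(self) -> bool:
        """Stored f_a must equal the column mean at every site."""
        return all(self.column_frequency(j) == snp.f_a
                   for j, snp in enumerate(self.snps))

    def positions(self, chrom: Optional[str] = None) -> np.ndarray:
        return np.asarray([s.pos for s in self.snps
                           if chrom is None or s.chrom == chrom], dtype=np.int64)


def call_archaic_set(
    cohort_variants: HaplotypeSource | Iterable[VariantRecord],
    archaic_genotypes: Mapping[tuple[str, int], tuple[str, str]],
    outgroup_alleles: Mapping[tuple[str, int], str],
    sample_ids: Optional[list[str]] = None,
) -> tuple[HaplotypeMatrix, dict[str, int]]:
    """Build the archaic SNP set and derived-coded haplotype matrix.

    ``archaic_genotypes`` maps (chrom, pos) to the archaic diploid genotype
    (two single-base strings); ``outgroup_alleles`` maps (chrom, pos) to the
    outgroup base.  Returns the matrix together with exclusion counts whose
    sum plus retained sites equals the input site count.
    """
    if isinstance(cohort_variants, HaplotypeSource):
        sample_ids = sample_ids or cohort_variants.sample_ids
        records: Iterable[VariantRecord] = cohort_variants.records
    else:
        records = list(cohort_variants)
    counts = {
        "retained": 0,
        "archaic_missing": 0,
        "archaic_heterozygous": 0,
        "archaic_allele_mismatch": 0,
        "outgroup_missing": 0,
        "outgroup_allele_mismatch": 0,
    }
    snps: list[ArchaicSNP] = []
    columns: list[np.ndarray] = []
    for rec in records:
        key = (rec.chrom, rec.pos)
        arch = archaic_genotypes.get(key)
        if arch is None:
            counts["archaic_missing"] += 1
            continue
        a1, a2 = arch
        if a1 != a2:
            counts["archaic_heterozygous"] += 1
            continue
        if a1 == rec.ref_allele:
            derived, ancestral_candidate = rec.ref_allele, rec.alt_allele
            derived_is_alt = False
        elif a1 == rec.alt_allele:
            derived, ancestral_candidate = rec.alt_allele, rec.ref_allele
            derived_is_alt = True
        else:
            counts["archaic_allele_mismatch"] += 1
            continue
        out = outgroup_alleles.get(key)
        if out is None:
            counts["outgroup_missing"] += 1
            continue
        if out != ancestral_candidate:
            counts["outgroup_allele_mismatch"] += 1
            continue
        col = rec.genotypes if derived_is_alt else 1 - rec.genotypes
        col = col.astype(np.int8)
        counts["retained"] += 1
        snps.append(ArchaicSNP(
            chrom=rec.chrom, pos=rec.pos,
            ancestral_allele=ancestral_candidate, derived_allele=derived,
            f_a=Fraction(int(col.sum()), col.shape[0])))
        columns.append(col)
    n_hap = columns[0].shape[0] if columns else (
        2 * len(sample_ids) if sample_ids else 0)
    matrix = (np.stack(columns, axis=1) if columns
              else np.empty((n_hap, 0), dtype=np.int8))
    return HaplotypeMatrix(snps=snps, matrix=matrix,
                           sample_ids=sample_ids or []), counts


def classify_cpg(snp: ArchaicSNP, reference_sequence) -> bool:
    """True iff either allele forms a CpG dinucleotide with a flanking ref base.

    The allele-or-context rule: allele C followed by reference G, or allele G
    preceded by reference C — capturing both CpG-destroying and CpG-creating
    alleles.  ``reference_sequence`` is indexable per chromosome (pyfaidx
    Fasta or a plain dict of strings).  A missing flank at a chromosome edge
    classifies as non-CpG with a warning.
    """
    seq = reference_sequence[snp.chrom]
    p0 = snp.pos - 1  # 0-based
    try:
        nxt = str(seq[p0 + 1]).upper() if p0 + 1 < len(seq) else None
    except IndexError:
        nxt = None
    prev = str(seq[p0 - 1]).upper() if p0 >= 1 else None
    if nxt is None or prev is None:
        warnings.warn(f"{snp.chrom}:{snp.pos}: flank beyond chromosome edge; "
                      "classified non-CpG")
    for allele in (snp.ancestral_allele, snp.derived_allele):
        if allele == "C" and nxt == "G":
            return True
        if allele == "G" and prev == "C":
            return True
    return False
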