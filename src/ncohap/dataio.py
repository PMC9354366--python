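"""I/O for the pipeline's external formats and tabular outputs; no science here.

Coordinate conventions follow the format standards: VCF positions are
1-based, BED intervals 0-based half-open.  A SNP at 1-based position p
overlaps interval (s, e) iff s ≤ p−1 < e.  Overlapping intervals within one
track are merged on load, because overlap is called per track as a binary
any-tissue union.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SOURCE_CLASSES = {
    "histone_mark", "dnase", "5mC", "5hmC", "dmc1", "cgi", "chrom_state", "other",
}

SNP_TABLE_COLUMNS = [
    "chrom", "pos", "ancestral", "derived", "f_a", "role", "block_id",
    "f_hap", "r2_a_hap", "Dprime_a_hap", "nco_rate", "delta_f_a_hap", "cpg_flag",
]


@dataclass
class VariantRecord:
    """One biallelic phased SNV: 1-based position, per-haplotype 0/1 over REF/ALT."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotypes: np.ndarray  # shape (2N,), int8, 0 = REF allele, 1 = ALT allele

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be ≥ 1, got {self.pos}")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError("VariantRecord holds single-base SNVs only")


@dataclass
class HaplotypeSource:
    """Chromosome-ordered stream of phased biallelic SNVs plus skip accounting."""

    records: list[VariantRecord]
    sample_ids: list[str]
    skip_counts: dict[str, int]

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


class IntervalTrack:
    """Named set of merged, sorted 0-based half-open intervals per chromosome."""

    def __init__(self, name: str, intervals: Iterable[tuple[str, int, int]],
                 source_class: str = "other"):
        if source_class not in SOURCE_CLASSES:
            raise ValueError(f"unknown source_class {source_class!r}")
        self.name = name
        self.source_class = source_class
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"interval start ≥ end: {chrom}:{start}-{end}")
            by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            starts, ends = _merge_intervals(ivs)
            self._starts[chrom] = starts
            self._ends[chrom] = ends

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays for one chromosome (empty arrays if absent)."""
        empty = np.empty(0, dtype=np.int64)
        return self._starts.get(chrom, empty), self._ends.get(chrom, empty)

    def to_list(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in self.chroms:
            s, e = self.intervals(chrom)
            out.extend((chrom, int(a), int(b)) for a, b in zip(s, e))
        return out

    def total_bp(self) -> int:
        return sum(e - s for _, s, e in self.to_list())

    def __len__(self) -> int:
        return sum(len(v) for v in self._starts.values())

    def contains(self, chrom: str, positions) -> np.ndarray:
        """Boolean overlap for an array of *1-based* SNP positions."""
        pos0 = np.asarray(positions, dtype=np.int64) - 1
        starts, ends = self.intervals(chrom)
        if len(starts) == 0:
            return np.zeros(pos0.shape, dtype=bool)
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(pos0.shape, dtype=bool)
        hit[ok] = pos0[ok] < ends[idx[ok]]
        return hit


def _merge_intervals(ivs: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    ivs = sorted(ivs)
    starts: list[int] = []
    ends: list[int] = []
    for s, e in ivs:
        if starts and s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


@dataclass
class GeneModel:
    """One gene: transcript-union span and exon/CDS/UTR structure, 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str
    transcript_intervals: list[tuple[int, int]]
    exon_intervals: list[tuple[int, int]]
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)
    utr5_intervals: list[tuple[int, int]] = field(default_factory=list)
    utr3_intervals: list[tuple[int, int]] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (min(s for s, _ in self.transcript_intervals),
                max(e for _, e in self.transcript_intervals))


def read_phased_vcf(path: str, sample_subset: Optional[Sequence[str]] = None
                    ) -> HaplotypeSource:
    """Read phased biallelic SNVs from a VCF.

    Multi-allelic sites, indels, and sites with any unphased or missing
    genotype are skipped (counted in ``skip_counts``); a requested sample
    missing from the header is fatal.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    if sample_subset is not None:
        missing = set(sample_subset) - set(vcf.samples)
        if missing:
            raise KeyError(f"samples not in VCF: {sorted(missing)}")
        vcf.close()
        vcf = VCF(path, samples=list(sample_subset))
    samples = list(vcf.samples)
    skips = {"multi_allelic": 0, "indel": 0, "unphased": 0, "missing": 0}
    records: list[VariantRecord] = []
    for v in vcf:
        if len(v.ALT) != 1:
            skips["multi_allelic"] += 1
            continue
        if not v.is_snp:
            skips["indel"] += 1
            continue
        gts = v.genotypes  # [[a, b, phased], ...]
        alleles = np.empty(2 * len(gts), dtype=np.int8)
        ok = True
        for k, g in enumerate(gts):
            if len(g) != 3:  # haploid or odd ploidy
                skips["missing"] += 1
                ok = False
                break
            a, b, phased = g
            if a < 0 or b < 0:
                skips["missing"] += 1
                ok = False
                break
            if not phased and a != b:
                skips["unphased"] += 1
                warnings.warn(
                    f"unphased heterozygote at {v.CHROM}:{v.POS}; site skipped")
                ok = False
                break
            alleles[2 * k] = a
            alleles[2 * k + 1] = b
        if not ok:
            continue
        records.append(VariantRecord(
            chrom=v.CHROM, pos=v.POS, ref_allele=v.REF,
            alt_allele=v.ALT[0], genotypes=alleles))
    vcf.close()
    records.sort(key=lambda r: (r.chrom, r.pos))
    return HaplotypeSource(records=records, sample_ids=samples, skip_counts=skips)


def read_bed(path: str, name: str, source_class: str = "other") -> IntervalTrack:
    """Read a BED3+ file into a merged IntervalTrack; start ≥ end is fatal."""
    import pyranges as pr

    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start ≥ end ({start} ≥ {end})")
            rows.append((chrom, start, end))
    if not rows:
        return IntervalTrack(name, [], source_class)
    df = pd.DataFrame(rows, columns=["Chromosome", "Start", "End"])
    merged = pr.PyRanges(df).merge().df
    return IntervalTrack(
        name,
        list(zip(merged["Chromosome"].astype(str), merged["Start"], merged["End"])),
        source_class,
    )


def read_state_bed(path: str) -> dict[str, IntervalTrack]:
    """Read a chromatin-state BED (state label in column 4) → one track per state."""
    by_state: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: state BED needs 4 columns")
            chrom, start, end, state = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start ≥ end")
            by_state.setdefault(state, []).append((chrom, start, end))
    return {state: IntervalTrack(state, ivs, "chrom_state")
            for state, ivs in by_state.items()}


def read_gene_models(path_gff3: str) -> list[GeneModel]:
    """Parse GFF3 gene/mRNA/exon/CDS features into GeneModels.

    UTRs are taken from explicit five_prime_UTR/three_prime_UTR features when
    present, otherwise derived as exon minus CDS on the correct strand.  A CDS
    outside every exon is fatal.
    """
    import gffutils

    db = gffutils.create_db(path_gff3, ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        exons, cdss, utr5, utr3, txs = [], [], [], [], []
        for feat in db.children(g.id):
            iv = (feat.start - 1, feat.end)  # GFF3 is 1-based inclusive
            if feat.featuretype in ("mRNA", "transcript"):
                txs.append(iv)
            elif feat.featuretype == "exon":
                exons.append(iv)
            elif feat.featuretype == "CDS":
                cdss.append(iv)
            elif feat.featuretype == "five_prime_UTR":
                utr5.append(iv)
            elif feat.featuretype == "three_prime_UTR":
                utr3.append(iv)
        if not txs:
            txs = [(g.start - 1, g.end)]
        if not exons:
            exons = list(txs)
        exons = _merge_list(exons)
        cdss = _merge_list(cdss)
        for cs, ce in cdss:
            if not any(es <= cs and ce <= ee for es, ee in exons):
                raise ValueError(f"gene {g.id}: CDS ({cs},{ce}) outside every exon")
        if cdss and not (utr5 or utr3):
            utr5, utr3 = _derive_utrs(exons, cdss, g.strand)
        genes.append(GeneModel(
            gene_id=g.id, chrom=g.seqid, strand=g.strand,
            transcript_intervals=_merge_list(txs), exon_intervals=exons,
            cds_intervals=cdss, utr5_intervals=_merge_list(utr5),
            utr3_intervals=_merge_list(utr3)))
    return genes


def _merge_list(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    s, e = _merge_intervals(list(ivs))
    return list(zip(s.tolist(), e.tolist()))


def _derive_utrs(exons, cdss, strand):
    """Exonic minus coding; the low-coordinate side is 5' on +, 3' on −."""
    cds_lo = min(s for s, _ in cdss)
    cds_hi = max(e for _, e in cdss)
    low, high = [], []
    for es, ee in exons:
        if es < cds_lo:
            low.append((es, min(ee, cds_lo)))
        if ee > cds_hi:
            high.append((max(es, cds_hi), ee))
    if strand == "-":
        return high, low
    return low, high


def read_archaic_table(path: str) -> dict[tuple[str, int], tuple[str, str]]:
    """Archaic genotype TSV (chrom, pos, allele1, allele2) → site mapping."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {(r.chrom, int(r.pos)): (str(r.allele1), str(r.allele2))
            for r in df.itertuples()}


def read_outgroup_table(path: str) -> dict[tuple[str, int], str]:
    """Outgroup allele TSV (chrom, pos, allele) → site mapping."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {(r.chrom, int(r.pos)): str(r.allele) for r in df.itertuples()}


def write_snp_table(df: pd.DataFrame, path: str) -> None:
    """Write the per-SNP table as TSV (UTF-8, header, '.' for missing).

    The frame must carry :data:`SNP_TABLE_COLUMNS`; any extra columns (one
    binary overlap column per loaded track, subregion labels, …) are written
    after them in their existing order.
    """
    missing = [c for c in SNP_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"snp table missing columns: {missing}")
    extra = [c for c in df.columns if c not in SNP_TABLE_COLUMNS]
    out = df[SNP_TABLE_COLUMNS + extra]
    out.to_csv(path, sep="\t", index=False, na_rep=".")


def read_snp_table(path: str) -> pd.DataFrame:
    """Read back a table written by :func:`write_snp_table` (round-trip safe)."""
    df = pd.read_csv(path, sep="\t", na_values=["."], keep_default_na=False,
                     dtype={"chrom": str}, float_precision="round_trip")
    for col in ("cpg_flag",):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False}).astype("boolean")
    return df
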