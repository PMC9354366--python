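"""Model-style front end: fit the linkage-block analysis to a phased cohort.

:class:`ArchaicNCOModel` holds the polarized haplotype matrix and the
analysis settings; :meth:`ArchaicNCOModel.fit` partitions the archaic SNPs
into linkage blocks and returns an :class:`ArchaicNCOResults` carrying the
per-SNP estimates (r²_{a,hap}, D'_{a,hap}, NCO rate, Δf), the block table,
diagnostics, and downstream analyses (GC bias, haplotype composition,
annotation overlays) as methods.

    >>> model = ArchaicNCOModel.from_simulation(sim)      # or .from_files(...)
    >>> res = model.fit()
    >>> print(res.summary())
    >>> res.gc_bias()
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import annotation_profiles as ap
from .archaic_snps import HaplotypeMatrix, call_archaic_set, classify_cpg
from .dataio import (IntervalTrack, SNP_TABLE_COLUMNS, read_archaic_table,
                     read_outgroup_table, read_phased_vcf)
from .gc_bias import (classify_transmission, gc_bias_estimate,
                      select_single_event_snps)
from .linkage_blocks import (DEFAULT_WINDOW_BP, HaplotypeComposition,
                             LinkageBlock, block_summary, haplotype_composition,
                             partition_blocks)

__all__ = ["ArchaicNCOModel", "ArchaicNCOResults"]


class ArchaicNCOModel:
    """Linkage-block NCO-rate analysis of a polarized phased cohort.

    Parameters
    ----------
    haplotypes
        Derived-coded haplotype matrix over the archaic SNP set.
    window_bp
        Maximum bp separation for perfect-linkage pairs and for
        singleton-to-core candidacy (default 200,000).
    min_core_size
        Minimum number of perfectly linked SNPs forming a core (default 2).
    """

    def __init__(self, haplotypes: HaplotypeMatrix,
                 window_bp: int = DEFAULT_WINDOW_BP,
                 min_core_size: int = 2,
                 exclusion_counts: Optional[dict] = None):
        self.haplotypes = haplotypes
        self.window_bp = int(window_bp)
        self.min_core_size = int(min_core_size)
        self.exclusion_counts = exclusion_counts or {}

    @classmethod
    def from_files(cls, cohort_vcf: str, archaic_table: str,
                   outgroup_table: str, reference=None,
                   sample_subset: Optional[Sequence[str]] = None,
                   window_bp: int = DEFAULT_WINDOW_BP,
                   min_core_size: int = 2) -> "ArchaicNCOModel":
        """Build the model from a phased VCF plus archaic/outgroup TSV tables.

        ``reference`` (pyfaidx Fasta or chrom→sequence mapping) enables CpG
        classification; without it cpg_flag stays unset.
        """
        source = read_phased_vcf(cohort_vcf, sample_subset)
        matrix, counts = call_archaic_set(
            source, read_archaic_table(archaic_table),
            read_outgroup_table(outgroup_table))
        counts.update({f"vcf_skip_{k}": v for k, v in source.skip_counts.items()})
        if matrix.n_sites == 0:
            raise ValueError("empty archaic SNP set")
        if reference is not None:
            for snp in matrix.snps:
                snp.cpg_flag = classify_cpg(snp, reference)
        return cls(matrix, window_bp=window_bp, min_core_size=min_core_size,
                   exclusion_counts=counts)

    @classmethod
    def from_simulation(cls, sim, window_bp: int = DEFAULT_WINDOW_BP,
                        min_core_size: int = 2) -> "ArchaicNCOModel":
        """Model over a :class:`~ncohap.synthetic_data.SimResult` (in memory)."""
        return cls(sim.haplotypes, window_bp=window_bp,
                   min_core_size=min_core_size)

    def fit(self) -> "ArchaicNCOResults":
        blocks, omitted = partition_blocks(
            self.haplotypes, window_bp=self.window_bp,
            min_core_size=self.min_core_size)
        return ArchaicNCOResults(model=self, blocks=blocks, omitted=omitted)


@dataclass
class ArchaicNCOResults:
    """Fitted linkage-block partition with per-SNP LD estimates."""

    model: ArchaicNCOModel
    blocks: list[LinkageBlock]
    omitted: list[int]
    _snp_table: Optional[pd.DataFrame] = field(default=None, repr=False)

    @property
    def haplotypes(self) -> HaplotypeMatrix:
        return self.model.haplotypes

    @property
    def assignments(self):
        return [a for b in self.blocks for a in b.singletons]

    @property
    def block_summary(self) -> dict:
        return block_summary(self.blocks, n_omitted=len(self.omitted))

    @property
    def snp_table(self) -> pd.DataFrame:
        """Per-SNP table (the deposited-artifact shape); floats from exact values."""
        if self._snp_table is None:
            m = self.haplotypes
            n = m.n_sites
            cols: dict = {c: [None] * n for c in SNP_TABLE_COLUMNS}
            for j, snp in enumerate(m.snps):
                cols["chrom"][j] = snp.chrom
                cols["pos"][j] = snp.pos
                cols["ancestral"][j] = snp.ancestral_allele
                cols["derived"][j] = snp.derived_allele
                cols["f_a"][j] = float(snp.f_a)
                cols["role"][j] = snp.role
                cols["cpg_flag"][j] = snp.cpg_flag
            for b in self.blocks:
                for j in b.core.member_indices:
                    cols["block_id"][j] = b.block_id
                    cols["f_hap"][j] = float(b.core.f_hap)
                for a in b.singletons:
                    j = a.snp_index
                    cols["block_id"][j] = a.block_id
                    cols["f_hap"][j] = float(b.core.f_hap)
                    cols["r2_a_hap"][j] = float(a.ld.r2)
                    cols["Dprime_a_hap"][j] = float(a.ld.d_prime)
                    cols["nco_rate"][j] = float(a.ld.nco_rate)
                    if a.delta_f.defined:
                        cols["delta_f_a_hap"][j] = float(a.delta_f.delta)
            df = pd.DataFrame(cols)
            df["pos"] = df["pos"].astype(np.int64)
            df["block_id"] = df["block_id"].astype("Int64")
            for c in ("f_a", "f_hap", "r2_a_hap", "Dprime_a_hap", "nco_rate",
                      "delta_f_a_hap"):
                df[c] = df[c].astype(float)
            self._snp_table = df
        return self._snp_table

    def nco_rates(self, include_block_snps: bool = True) -> np.ndarray:
        """Per-SNP NCO rate vector: singletons carry 1 − D'², block SNPs 0
        (perfect linkage), others NaN."""
        df = self.snp_table
        rates = df["nco_rate"].to_numpy(dtype=float, copy=True)
        if include_block_snps:
            rates[(df["role"] == "block").to_numpy()] = 0.0
        return rates

    def composition(self, block_id: int) -> HaplotypeComposition:
        return haplotype_composition(self.haplotypes, self.blocks[block_id])

    def gc_bias(self, maf_min=Fraction(1, 5), stratify_by_cpg: bool = True):
        """Transmission events at single-NCO-event SNPs and the GC bias.

        Returns (events, estimate): the per-stratum estimate is
        #GC / (#GC + #AT) with counts; see :mod:`ncohap.gc_bias`.
        """
        snps = self.haplotypes.snps
        eligible = select_single_event_snps(self.assignments, snps,
                                            maf_min=maf_min)
        events = []
        for a in eligible:
            ev = classify_transmission(snps[a.snp_index], a.delta_f,
                                       snp_index=a.snp_index)
            if ev is not None:
                events.append(ev)
        return events, gc_bias_estimate(events, stratify_by_cpg=stratify_by_cpg)

    def annotate(self, tracks: Mapping[str, IntervalTrack]) -> pd.DataFrame:
        """Add one binary overlap column per track to the SNP table (in place)."""
        df = self.snp_table
        for name, track in tracks.items():
            df[f"overlap_{name}"] = ap.overlap_any(df["chrom"], df["pos"], track)
        return df

    def block_table(self) -> pd.DataFrame:
        rows = []
        for b in self.blocks:
            rows.append({
                "block_id": b.block_id, "chrom": b.core.chrom,
                "span_start": b.core.span[0], "span_end": b.core.span[1],
                "n_core": b.core.n_members, "n_singletons": len(b.singletons),
                "f_hap": float(b.core.f_hap)})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        s = self.block_summary
        m = self.haplotypes
        lines = [
            "Archaic NCO linkage-block analysis",
            "=" * 50,
            f"{'Haplotypes (2N)':35s}{m.n_haplotypes:>15,}",
            f"{'Archaic SNPs':35s}{m.n_sites:>15,}",
            f"{'Linkage blocks':35s}{s['n_blocks']:>15,}",
            f"{'Block SNPs':35s}{s['n_block_snps']:>15,}",
            f"{'Singleton SNPs':35s}{s['n_singletons']:>15,}",
            f"{'Omitted singletons':35s}{s['n_omitted']:>15,}",
            "-" * 50,
            f"{'Mean block SNPs / block':35s}{s['mean_block_snps_per_block']:>15.2f}",
            f"{'Mean singletons / block':35s}{s['mean_singletons_per_block']:>15.2f}",
            f"{'Mean total SNPs / block':35s}{s['mean_total_snps_per_block']:>15.2f}",
            f"{'Singleton share (%)':35s}{s['singleton_percent']:>15.2f}",
            f"{'Mean core span (bp)':35s}{s['mean_span_bp']:>15.1f}",
            "=" * 50,
            f"window_bp={self.model.window_bp}, "
            f"min_core_size={self.model.min_core_size}",
        ]
        return "\n".join(lines)
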