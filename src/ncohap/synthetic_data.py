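"""Synthetic phased cohorts with known gene-conversion ground truth.

The generator embodies the two-founder idealisation of the analysis: every
haplotype starts as a copy of either the fully *derived* (archaic) or the
fully *ancestral* founder haplotype, and is then rearranged by

* hotspot-localised crossovers, which fragment the region into independently
  refounded segments (this is what breaks the archaic haplotype into
  discrete linkage blocks), and
* non-crossover gene conversion: per haplotype, each SNP site initiates an
  event with hazard λ × multiplier(annotation at the site); the event copies
  a geometric ~1 kb tract from the opposite founder class, except that at
  heterozygous strong/weak (G/C vs A/T) sites the strong allele is
  transmitted with probability ``gc_transmission_bias``.

Every event is recorded in :class:`SimTruth`, so any derived↔ancestral
discordance against the founder assignment is attributable, and per-class
event densities can be compared against their analytic expectation.
Identical (seed, config) pairs reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from typing import Optional

import numpy as np

from .archaic_snps import ArchaicSNP, HaplotypeMatrix, classify_cpg
from .dataio import GeneModel, IntervalTrack

__all__ = [
    "SimConfig", "Landscape", "ConversionEvent", "SimTruth", "SimResult",
    "generate_annotation_landscape", "simulate_cohort", "simulate",
    "expected_truth_summary",
]

STATE_MNEMONICS = [
    "TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh", "ZNF/Rpts",
    "Het", "TssBiv", "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Simulation parameters; defaults mirror the studied cohort geometry.

    ``base_conversion_rate`` (λ) is the per-SNP-site, per-haplotype
    initiation probability; ``rate_multipliers`` maps landscape track names
    (e.g. "exon", "cgi", "hotspot", or custom class tiles) to hazard
    multipliers, composed multiplicatively where tracks overlap.
    """

    seed: int = 0
    n_samples: int = 99                    # 198 haplotypes
    region_length_bp: int = 1_000_000
    n_archaic_snps: int = 1000
    founder_derived_freq: float = 0.5
    base_conversion_rate: float = 0.0      # λ per site per haplotype
    rate_multipliers: dict = field(default_factory=dict)
    tract_length_mean_bp: float = 1000.0
    gc_transmission_bias: float = 0.68
    n_crossovers: int = 0
    drift_generations: int = 0
    chrom: str = "chr1"
    # landscape composition
    gc_background: float = 0.40
    gc_cgi: float = 0.65
    n_genes: int = 3
    n_cgi: int = 5
    cgi_length_bp: int = 1500
    n_hotspots: int = 4
    hotspot_halfwidth_bp: int = 1000
    n_mark_intervals: int = 30
    mark_interval_bp: int = 2000
    n_state_tiles: int = 60
    prob_ref_is_ancestral: float = 0.7
    custom_class_tiles: tuple = ()         # names of disjoint tiling classes
    max_events_per_site_hap: int = 10

    def __post_init__(self):
        if not 0 < self.founder_derived_freq < 1:
            raise ValueError("founder_derived_freq must be in (0, 1)")
        if not 0 <= self.gc_transmission_bias <= 1:
            raise ValueError("gc_transmission_bias must be in [0, 1]")
        if self.base_conversion_rate < 0:
            raise ValueError("rates must be ≥ 0")
        if any(m <= 0 for m in self.rate_multipliers.values()):
            raise ValueError("multipliers must be > 0")


@dataclass
class Landscape:
    """Reference sequence plus annotation geometry for one region."""

    chrom: str
    length: int
    reference: str
    tracks: dict[str, IntervalTrack]
    genes: list[GeneModel]
    states: dict[str, IntervalTrack]

    def reference_mapping(self) -> dict[str, str]:
        return {self.chrom: self.reference}

    def write_fasta(self, path: str, width: int = 80) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.chrom}\n")
            for i in range(0, self.length, width):
                fh.write(self.reference[i:i + width] + "\n")

    def write_gff3(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                lo, hi = g.span
                fh.write(f"{g.chrom}\tncohap\tgene\t{lo+1}\t{hi}\t.\t"
                         f"{g.strand}\t.\tID={g.gene_id}\n")
                tid = f"{g.gene_id}.t1"
                fh.write(f"{g.chrom}\tncohap\tmRNA\t{lo+1}\t{hi}\t.\t"
                         f"{g.strand}\t.\tID={tid};Parent={g.gene_id}\n")
                for kind, ivs in (("exon", g.exon_intervals),
                                  ("CDS", g.cds_intervals),
                                  ("five_prime_UTR", g.utr5_intervals),
                                  ("three_prime_UTR", g.utr3_intervals)):
                    for k, (s, e) in enumerate(ivs):
                        fh.write(f"{g.chrom}\tncohap\t{kind}\t{s+1}\t{e}\t.\t"
                                 f"{g.strand}\t.\tID={tid}.{kind}{k};Parent={tid}\n")

    def write_tracks_bed(self, outdir) -> dict[str, str]:
        import os
        paths = {}
        for name, track in self.tracks.items():
            safe = name.replace("/", "_")
            p = os.path.join(outdir, f"track_{safe}.bed")
            with open(p, "w") as fh:
                for chrom, s, e in track.to_list():
                    fh.write(f"{chrom}\t{s}\t{e}\n")
            paths[name] = p
        return paths

    def write_states_bed(self, path: str) -> None:
        rows = []
        for state, track in self.states.items():
            rows.extend((chrom, s, e, state) for chrom, s, e in track.to_list())
        rows.sort()
        with open(path, "w") as fh:
            for chrom, s, e, state in rows:
                fh.write(f"{chrom}\t{s}\t{e}\t{state}\n")


@dataclass
class ConversionEvent:
    """One gene-conversion event: tract, covered sites, per-site outcome.

    ``changes`` holds (site_index, old_value, new_value, transmitted_class)
    for sites where the heteroduplex was resolved; transmitted_class is
    'GC'/'AT' for strong/weak sites, None otherwise.
    """

    haplotype: int
    tract_start: int
    tract_end: int
    seed_site: int                 # site index whose hazard initiated the event
    site_indices: list[int]
    donor_class: int
    changes: list[tuple[int, int, int, Optional[str]]]


@dataclass
class SimTruth:
    events: list[ConversionEvent]
    founder: np.ndarray                 # (2N, n_segments) founder class
    segment_bounds: list[int]           # breakpoint positions (0-based)
    crossover_positions: list[int]
    site_conversion_counts: np.ndarray  # per site, events covering it
    pre_drift_matrix: Optional[np.ndarray] = None
    drift_maps: list = field(default_factory=list)

    def to_json(self, path: str) -> None:
        payload = {
            "segment_bounds": list(map(int, self.segment_bounds)),
            "crossover_positions": list(map(int, self.crossover_positions)),
            "site_conversion_counts": self.site_conversion_counts.tolist(),
            "founder": self.founder.tolist(),
            "drift_maps": [list(map(int, m)) for m in self.drift_maps],
            "events": [
                {"haplotype": e.haplotype, "tract_start": e.tract_start,
                 "tract_end": e.tract_end, "seed_site": int(e.seed_site),
                 "site_indices": e.site_indices,
                 "donor_class": e.donor_class,
                 "changes": [[int(a), int(b), int(c), d] for a, b, c, d in e.changes]}
                for e in self.events],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class SimResult:
    config: SimConfig
    landscape: Landscape
    haplotypes: HaplotypeMatrix
    truth: SimTruth
    ref_is_ancestral: np.ndarray  # per site: VCF REF allele is the ancestral one

    def archaic_genotypes(self) -> dict[tuple[str, int], tuple[str, str]]:
        """Archaic table: homozygous derived at every site."""
        return {(s.chrom, s.pos): (s.derived_allele, s.derived_allele)
                for s in self.haplotypes.snps}

    def outgroup_alleles(self) -> dict[tuple[str, int], str]:
        return {(s.chrom, s.pos): s.ancestral_allele
                for s in self.haplotypes.snps}

    def write_vcf(self, path: str) -> None:
        m = self.haplotypes
        chrom = self.landscape.chrom
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(f"##contig=<ID={chrom},length={self.landscape.length}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(m.sample_ids) + "\n")
            for j, snp in enumerate(m.snps):
                if self.ref_is_ancestral[j]:
                    ref, alt = snp.ancestral_allele, snp.derived_allele
                    col = m.matrix[:, j]          # 1=derived=ALT
                else:
                    ref, alt = snp.derived_allele, snp.ancestral_allele
                    col = 1 - m.matrix[:, j]      # derived is REF
                gts = "\t".join(f"{col[2*k]}|{col[2*k+1]}"
                                for k in range(len(m.sample_ids)))
                fh.write(f"{chrom}\t{snp.pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                         f"{gts}\n")

    def write_archaic_table(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tallele1\tallele2\n")
            for s in self.haplotypes.snps:
                fh.write(f"{s.chrom}\t{s.pos}\t{s.derived_allele}\t"
                         f"{s.derived_allele}\n")

    def write_outgroup_table(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tallele\n")
            for s in self.haplotypes.snps:
                fh.write(f"{s.chrom}\t{s.pos}\t{s.ancestral_allele}\n")

    def to_files(self, outdir: str) -> dict[str, str]:
        import os
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "vcf": os.path.join(outdir, "cohort.vcf"),
            "fasta": os.path.join(outdir, "reference.fa"),
            "gff3": os.path.join(outdir, "genes.gff3"),
            "archaic": os.path.join(outdir, "archaic.tsv"),
            "outgroup": os.path.join(outdir, "outgroup.tsv"),
            "states": os.path.join(outdir, "states.bed"),
            "truth": os.path.join(outdir, "truth.json"),
        }
        self.write_vcf(paths["vcf"])
        self.landscape.write_fasta(paths["fasta"])
        self.landscape.write_gff3(paths["gff3"])
        self.write_archaic_table(paths["archaic"])
        self.write_outgroup_table(paths["outgroup"])
        self.landscape.write_states_bed(paths["states"])
        self.truth.to_json(paths["truth"])
        paths.update(self.landscape.write_tracks_bed(outdir))
        return paths


def _random_intervals(rng, length: int, n: int, iv_len: int,
                      forbidden: Optional[list[tuple[int, int]]] = None
                      ) -> list[tuple[int, int]]:
    """n non-overlapping intervals of ~iv_len avoiding the forbidden list."""
    out: list[tuple[int, int]] = []
    taken = list(forbidden or [])
    tries = 0
    while len(out) < n and tries < 200 * max(n, 1):
        tries += 1
        s = int(rng.integers(0, max(1, length - iv_len)))
        e = min(length, s + iv_len)
        if any(s < te and ts < e for ts, te in taken):
            continue
        out.append((s, e))
        taken.append((s, e))
    out.sort()
    return out


def _sample_sequence(rng, length: int, gc: float) -> np.ndarray:
    p = np.asarray([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def generate_annotation_landscape(config: SimConfig,
                                  rng: Optional[np.random.Generator] = None
                                  ) -> Landscape:
    """Reference FASTA-able sequence, gene models, tracks and a 15-state map.

    CpG-island segments are sampled at elevated GC; everything else at the
    background GC.  Genes carry exons, a CDS and both UTRs.  Custom class
    tiles (when configured) tile the region with disjoint, cycling tracks —
    the handle used by rate-landscape recovery experiments.
    """
    if config.region_length_bp < 10_000:
        raise ValueError("region_length_bp must be ≥ 10 kb")
    rng = rng or np.random.default_rng(config.seed)
    L = config.region_length_bp
    chrom = config.chrom

    cgi = _random_intervals(rng, L, config.n_cgi, config.cgi_length_bp)
    seq = np.empty(L, dtype="S1")
    cursor = 0
    for s, e in cgi + [(L, L)]:
        if s > cursor:
            seq[cursor:s] = _sample_sequence(rng, s - cursor, config.gc_background)
        if e > s:
            seq[s:e] = _sample_sequence(rng, e - s, config.gc_cgi)
        cursor = max(cursor, e)
    reference = seq.tobytes().decode("ascii")

    genes: list[GeneModel] = []
    gene_len = max(5000, L // max(3 * config.n_genes, 1))
    gene_spans = _random_intervals(rng, L, config.n_genes, gene_len)
    for gi, (gs, ge) in enumerate(gene_spans):
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(2, 6))
        edges = np.sort(rng.choice(np.arange(gs + 50, ge - 50), size=2 * n_ex,
                                   replace=False))
        exons = [(int(edges[2 * k]), int(edges[2 * k + 1])) for k in range(n_ex)]
        exons = [(s, e) for s, e in exons if e > s]
        # CDS spans the middle of the exon chain; UTRs derived from the rest
        first_s, first_e = exons[0]
        last_s, last_e = exons[-1]
        cds_lo = min(first_e - 1, first_s + max(1, (first_e - first_s) // 2))
        cds_hi = max(last_s + 1, last_e - max(1, (last_e - last_s) // 2))
        cdss = [(max(s, cds_lo), min(e, cds_hi)) for s, e in exons
                if min(e, cds_hi) > max(s, cds_lo)]
        low = [(first_s, cds_lo)] if cds_lo > first_s else []
        high = [(cds_hi, last_e)] if last_e > cds_hi else []
        utr5, utr3 = (high, low) if strand == "-" else (low, high)
        genes.append(GeneModel(
            gene_id=f"gene{gi + 1}", chrom=chrom, strand=strand,
            transcript_intervals=[(gs, ge)], exon_intervals=exons,
            cds_intervals=cdss, utr5_intervals=utr5, utr3_intervals=utr3))

    tracks: dict[str, IntervalTrack] = {
        "cgi": IntervalTrack("cgi", [(chrom, s, e) for s, e in cgi], "cgi"),
    }
    hotspot_centers = sorted(int(rng.integers(config.hotspot_halfwidth_bp,
                                              L - config.hotspot_halfwidth_bp))
                             for _ in range(config.n_hotspots))
    tracks["hotspot"] = IntervalTrack(
        "hotspot",
        [(chrom, c - config.hotspot_halfwidth_bp, c + config.hotspot_halfwidth_bp)
         for c in hotspot_centers], "dmc1")
    for mark in ("H3K4me3", "H3K27me3"):
        ivs = _random_intervals(rng, L, config.n_mark_intervals,
                                config.mark_interval_bp)
        tracks[mark] = IntervalTrack(mark, [(chrom, s, e) for s, e in ivs],
                                     "histone_mark")
    exon_iv = [(chrom, s, e) for g in genes for s, e in g.exon_intervals]
    tracks["exon"] = IntervalTrack("exon", exon_iv, "other")
    utr_iv = [(chrom, s, e) for g in genes
              for s, e in g.utr5_intervals + g.utr3_intervals]
    tracks["utr"] = IntervalTrack("utr", utr_iv, "other")
    intron_iv = []
    for g in genes:
        lo, hi = g.span
        cursor = lo
        for es, ee in g.exon_intervals:
            if es > cursor:
                intron_iv.append((chrom, cursor, es))
            cursor = max(cursor, ee)
        if hi > cursor:
            intron_iv.append((chrom, cursor, hi))
    tracks["intron"] = IntervalTrack("intron", intron_iv, "other")

    if config.custom_class_tiles:
        names = list(config.custom_class_tiles)
        tile = max(1, L // max(config.n_state_tiles, len(names)))
        per_class: dict[str, list] = {n: [] for n in names}
        for k, s in enumerate(range(0, L, tile)):
            per_class[names[k % len(names)]].append((chrom, s, min(L, s + tile)))
        for n in names:
            tracks[n] = IntervalTrack(n, per_class[n], "other")

    tile = max(1, L // config.n_state_tiles)
    state_ivs: dict[str, list] = {s: [] for s in STATE_MNEMONICS}
    for s in range(0, L, tile):
        state = STATE_MNEMONICS[int(rng.integers(0, len(STATE_MNEMONICS)))]
        state_ivs[state].append((chrom, s, min(L, s + tile)))
    states = {s: IntervalTrack(s, ivs, "chrom_state")
              for s, ivs in state_ivs.items() if ivs}

    return Landscape(chrom=chrom, length=L, reference=reference,
                     tracks=tracks, genes=genes, states=states)


def _sample_positions(rng, length: int, n: int) -> np.ndarray:
    """n distinct positions in [1, length−2] (flanks exist for CpG calls)."""
    if n > length - 2:
        raise ValueError("more SNPs than available positions")
    seen: np.ndarray = np.empty(0, dtype=np.int64)
    while len(seen) < n:
        draw = rng.integers(1, length - 1, size=int(1.2 * (n - len(seen))) + 8)
        seen = np.unique(np.concatenate([seen, draw]))
    return np.sort(rng.choice(seen, size=n, replace=False))


def simulate_cohort(config: SimConfig, landscape: Landscape,
                    rng: Optional[np.random.Generator] = None) -> SimResult:
    """Phased cohort + archaic/outgroup tables + ground truth for one region."""
    rng = rng or np.random.default_rng(config.seed + 1)
    n_hap = 2 * config.n_samples
    S = config.n_archaic_snps
    chrom = landscape.chrom
    strong = frozenset("GC")

    pos0 = _sample_positions(rng, landscape.length, S)   # 0-based
    ref_bases = np.asarray([landscape.reference[p] for p in pos0], dtype="U1")
    ref_is_anc = rng.random(S) < config.prob_ref_is_ancestral
    other = np.empty(S, dtype="U1")
    for j in range(S):
        choices = [b for b in "ACGT" if b != ref_bases[j]]
        other[j] = choices[int(rng.integers(0, 3))]
    ancestral = np.where(ref_is_anc, ref_bases, other)
    derived = np.where(ref_is_anc, other, ref_bases)

    # crossover breakpoints at hotspot centres → independently refounded segments
    hs_starts, hs_ends = landscape.tracks["hotspot"].intervals(chrom)
    centers = ((hs_starts + hs_ends) // 2).tolist()
    n_co = min(config.n_crossovers, len(centers))
    if config.n_crossovers > len(centers):
        warnings.warn("n_crossovers exceeds hotspot count; using one per hotspot")
    co_positions = sorted(int(c) for c in
                          rng.choice(centers, size=n_co, replace=False)) if n_co else []
    bounds = [0] + co_positions + [landscape.length]
    n_seg = len(bounds) - 1
    seg_of_site = np.searchsorted(np.asarray(bounds[1:-1]), pos0, side="right")

    founder = (rng.random((n_hap, n_seg)) < config.founder_derived_freq
               ).astype(np.int8)
    matrix = founder[:, seg_of_site].copy()

    # per-site hazard = λ × product of multipliers for overlapping tracks
    mult = np.ones(S)
    pos1 = pos0 + 1
    for name, m in config.rate_multipliers.items():
        track = landscape.tracks.get(name)
        if track is None:
            raise KeyError(f"rate multiplier refers to unknown track {name!r}")
        hit = track.contains(chrom, pos1)
        mult[hit] *= m
    hazard = np.clip(config.base_conversion_rate * mult, 0.0, 0.95)

    is_sw = np.asarray([(a in strong) != (d in strong)
                        for a, d in zip(ancestral, derived)])
    der_is_strong = np.asarray([d in strong for d in derived])

    events: list[ConversionEvent] = []
    cover = np.zeros(S, dtype=np.int64)
    cover_per_hap_site_max = 0
    mean_T = max(1.0, config.tract_length_mean_bp)
    for h in range(n_hap):
        if hazard.max() == 0:
            break
        hits = np.flatnonzero(rng.random(S) < hazard)
        if len(hits) == 0:
            continue
        hap_cover = np.zeros(S, dtype=np.int16)
        for s_idx in hits:
            T = int(rng.geometric(1.0 / mean_T))
            offset = int(rng.integers(0, T))
            t_start = int(pos0[s_idx]) - offset
            t_end = t_start + T
            lo = int(np.searchsorted(pos0, t_start, side="left"))
            hi = int(np.searchsorted(pos0, t_end, side="left"))
            sites = list(range(lo, hi))
            seg = int(seg_of_site[s_idx])
            donor = int(1 - founder[h, seg])
            changes = []
            for t in sites:
                hap_cover[t] += 1
                donor_t = int(1 - founder[h, seg_of_site[t]])
                cur = int(matrix[h, t])
                if cur == donor_t:
                    continue  # duplex homozygous, nothing to resolve
                if is_sw[t]:
                    take_strong = rng.random() < config.gc_transmission_bias
                    new = int(der_is_strong[t] == take_strong)
                    cls = "GC" if take_strong else "AT"
                else:
                    new, cls = donor_t, None
                if new != cur:
                    matrix[h, t] = new
                changes.append((t, cur, int(matrix[h, t]), cls))
            cover[sites] += 1
            events.append(ConversionEvent(
                haplotype=h, tract_start=t_start, tract_end=t_end,
                seed_site=int(s_idx), site_indices=sites, donor_class=donor,
                changes=changes))
        cover_per_hap_site_max = max(cover_per_hap_site_max,
                                     int(hap_cover.max()) if len(hits) else 0)
    if cover_per_hap_site_max > config.max_events_per_site_hap:
        warnings.warn(
            f"a site was covered {cover_per_hap_site_max}× on one haplotype; "
            "the model leaves the single-event regime")

    pre_drift = None
    drift_maps = []
    if config.drift_generations > 0:
        pre_drift = matrix.copy()
        for _ in range(config.drift_generations):
            idx = rng.integers(0, n_hap, n_hap)
            drift_maps.append(idx.copy())
            matrix = matrix[idx]
            founder = founder[idx]

    snps = []
    ref_map = landscape.reference_mapping()
    for j in range(S):
        snp = ArchaicSNP(
            chrom=chrom, pos=int(pos0[j]) + 1,
            ancestral_allele=str(ancestral[j]), derived_allele=str(derived[j]),
            f_a=Fraction(int(matrix[:, j].sum()), n_hap))
        snp.cpg_flag = classify_cpg(snp, ref_map)
        snps.append(snp)
    hap = HaplotypeMatrix(
        snps=snps, matrix=matrix,
        sample_ids=[f"S{i + 1:03d}" for i in range(config.n_samples)])
    truth = SimTruth(
        events=events, founder=founder, segment_bounds=bounds,
        crossover_positions=co_positions, site_conversion_counts=cover,
        pre_drift_matrix=pre_drift, drift_maps=drift_maps)
    return SimResult(config=config, landscape=landscape, haplotypes=hap,
                     truth=truth, ref_is_ancestral=ref_is_anc)


def simulate(config: SimConfig) -> SimResult:
    """Landscape + cohort in one call, all randomness derived from config.seed."""
    landscape = generate_annotation_landscape(
        config, np.random.default_rng(config.seed))
    return simulate_cohort(config, landscape,
                           np.random.default_rng(config.seed + 1))


def expected_truth_summary(result: SimResult) -> "pd.DataFrame":
    """Analytic expected initiation counts per annotation class vs realized.

    Expectation per class = λ × multiplier × (SNP sites in class) × 2N,
    where a site's class is the multiplier-track combination covering it
    ('background' when none applies).
    """
    import pandas as pd

    config, landscape = result.config, result.landscape
    S = len(result.haplotypes.snps)
    pos1 = np.asarray([s.pos for s in result.haplotypes.snps])
    n_hap = result.haplotypes.n_haplotypes
    mult = np.ones(S)
    class_label = np.full(S, "background", dtype=object)
    for name, m in sorted(config.rate_multipliers.items()):
        hit = landscape.tracks[name].contains(landscape.chrom, pos1)
        mult[hit] *= m
        class_label[hit] = np.where(class_label[hit] == "background", name,
                                    class_label[hit] + "+" + name)
    init_counts = np.zeros(S, dtype=np.int64)
    for e in result.truth.events:
        init_counts[e.seed_site] += 1
    rows = []
    lam = config.base_conversion_rate
    for cls in pd.unique(class_label):
        m = class_label == cls
        rows.append({
            "annotation_class": cls,
            "n_sites": int(m.sum()),
            "mean_multiplier": float(mult[m].mean()),
            "expected_initiations": float(lam * (mult[m] * n_hap).sum()),
            "realized_initiations": int(init_counts[m].sum()),
        })
    return pd.DataFrame(rows)
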