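"""End-to-end orchestration: inputs → blocks → LD/NCO → GC bias → profiles.

Everything here is a thin composition of the library modules behind a
:class:`RunConfig`; the heavy lifting lives in :mod:`ncohap.model`.  Each
stage writes its documented TSV so runs can be resumed or stages swapped
from the command line, and a manifest JSON records configuration and the
filter-count ledger (no SNP is lost unaccounted).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from . import annotation_profiles as ap
from .dataio import (read_bed, read_gene_models, read_state_bed,
                     write_snp_table)
from .model import ArchaicNCOModel

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis"]


@dataclass
class RunConfig:
    """Paths and constants for a full run; defaults follow the study design
    (200 kb linkage window, maf > 0.2 for the GC bias, 200 bp GC window)."""

    cohort_vcf: str = ""
    archaic_table: str = ""
    outgroup_table: str = ""
    reference_fasta: Optional[str] = None
    gene_models_gff3: Optional[str] = None
    track_beds: dict = field(default_factory=dict)      # name -> path
    state_beds: dict = field(default_factory=dict)      # epigenome id -> path
    sample_subset: Optional[Sequence[str]] = None
    window_bp: int = 200_000
    maf_min: float = 0.2
    gc_window_bp: int = 200
    min_core_size: int = 2
    n_rate_bins: int = 10
    hotspot_track: str = "hotspot"   # track excluded from mark-delta tests
    output_dir: str = "ncohap_out"
    seed: int = 0


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_full_analysis(cfg: RunConfig) -> dict:
    """Execute every stage and write the result bundle to ``cfg.output_dir``.

    Returns the manifest dict.  Annotation stages are skipped with a warning
    when their inputs are absent; earlier outputs remain intact.
    """
    os.makedirs(cfg.output_dir, exist_ok=True)
    manifest: dict = {"version": __version__, "config": asdict(cfg),
                      "config_hash": _config_hash(cfg), "counts": {}}

    reference = None
    if cfg.reference_fasta:
        from pyfaidx import Fasta
        reference = Fasta(cfg.reference_fasta)

    model = ArchaicNCOModel.from_files(
        cfg.cohort_vcf, cfg.archaic_table, cfg.outgroup_table,
        reference=reference, sample_subset=cfg.sample_subset,
        window_bp=cfg.window_bp, min_core_size=cfg.min_core_size)
    manifest["counts"]["polarization"] = model.exclusion_counts
    results = model.fit()
    manifest["counts"]["blocks"] = results.block_summary

    tracks = {name: read_bed(path, name) for name, path in cfg.track_beds.items()}
    if tracks:
        results.annotate(tracks)
    df = results.snp_table

    genes = None
    if cfg.gene_models_gff3:
        genes = read_gene_models(cfg.gene_models_gff3)
        df["subregion"] = ap.genic_subregion_assign(df["chrom"], df["pos"], genes)
        df["subregion_coarse"] = ap.coarse_subregion(df["subregion"])
    if reference is not None:
        df["gc_content"] = [
            ap.gc_content_window(reference, c, p, cfg.gc_window_bp)
            for c, p in zip(df["chrom"], df["pos"])]

    snp_path = os.path.join(cfg.output_dir, "snp_table.tsv")
    write_snp_table(df, snp_path)
    results.block_table().to_csv(
        os.path.join(cfg.output_dir, "block_table.tsv"), sep="\t", index=False)

    events, bias = results.gc_bias(maf_min=cfg.maf_min)
    manifest["counts"]["gc_bias_events"] = len(events)
    pd.DataFrame([
        {"stratum": k, **v} for k, v in bias.items()
    ]).to_csv(os.path.join(cfg.output_dir, "gc_bias.tsv"), sep="\t", index=False)

    rates = results.nco_rates()
    if tracks and genes is not None:
        exclude = None
        if cfg.hotspot_track in tracks:
            exclude = df[f"overlap_{cfg.hotspot_track}"].to_numpy()
        deltas = []
        for name in tracks:
            if name == cfg.hotspot_track:
                continue
            deltas.append(ap.subregion_mark_delta(
                rates, df[f"overlap_{name}"], df["subregion_coarse"],
                exclude_mask=exclude, mark_name=name))
        if deltas:
            pd.concat(deltas, ignore_index=True).to_csv(
                os.path.join(cfg.output_dir, "mark_delta.tsv"),
                sep="\t", index=False)
    elif cfg.track_beds or cfg.gene_models_gff3:
        logger.warning("mark-delta stage skipped: needs both tracks and genes")

    if cfg.state_beds:
        labels = {}
        for epi, path in cfg.state_beds.items():
            labels[epi] = ap.assign_states(df["chrom"], df["pos"],
                                           read_state_bed(path))
        mark_cols = {n: df[f"overlap_{n}"] for n in tracks}
        table, corr = ap.state_region_summary(rates, labels, mark_cols)
        table.to_csv(os.path.join(cfg.output_dir, "state_summary.tsv"),
                     sep="\t", index=False)
        manifest["state_spearman"] = {k: list(v) for k, v in corr.items()}

    manifest["outputs"] = sorted(os.listdir(cfg.output_dir))
    with open(os.path.join(cfg.output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
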