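"""NCO-rate vs annotation analyses.

Overlap flags, boundary-distance and GC-content profiles, genic sub-region
stratification with Mann-Whitney tests, overlap fold-change regressions and
chromatin-state summaries.  All operations take plain arrays / DataFrames
(typically columns of the per-SNP table) plus :class:`~ncohap.dataio.
IntervalTrack` / :class:`~ncohap.dataio.GeneModel` objects, and are
permutation-invariant in SNP order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import GeneModel, IntervalTrack

__all__ = [
    "FINE_SUBREGIONS", "COARSE_SUBREGIONS", "coarse_subregion",
    "overlap_any", "signed_distance", "gc_content_window",
    "genic_subregion_assign", "binned_mean_profile", "subregion_mark_delta",
    "overlap_foldchange_slope", "assign_states", "state_region_summary",
]

FINE_SUBREGIONS = [
    "intergenic_gt50kb_up", "intergenic_5to50kb_up", "intergenic_0to5kb_up",
    "UTR5", "exonic", "splice_site", "intronic", "UTR3",
    "intergenic_0to5kb_down", "intergenic_5to50kb_down", "intergenic_gt50kb_down",
]

# 7-way grouping; splice sites are intronic positions, so they merge into
# intronic here (the coarse scheme has no splice category).
_COARSE_MAP = {
    "intergenic_gt50kb_up": "intergenic",
    "intergenic_5to50kb_up": "intergenic",
    "intergenic_0to5kb_up": "upstream_lt5kb",
    "UTR5": "UTR5",
    "exonic": "exonic",
    "splice_site": "intronic",
    "intronic": "intronic",
    "UTR3": "UTR3",
    "intergenic_0to5kb_down": "downstream_lt5kb",
    "intergenic_5to50kb_down": "intergenic",
    "intergenic_gt50kb_down": "intergenic",
}
COARSE_SUBREGIONS = ["intergenic", "upstream_lt5kb", "UTR5", "intronic",
                     "exonic", "UTR3", "downstream_lt5kb"]

SPLICE_FLANK_BP = 2


def coarse_subregion(fine_labels: Sequence[str]) -> np.ndarray:
    return np.asarray([_COARSE_MAP[l] for l in fine_labels], dtype=object)


def overlap_any(chroms: Sequence[str], positions: Sequence[int],
                track: IntervalTrack) -> np.ndarray:
    """Binary overlap per SNP (1-based positions) with a merged track."""
    chroms = np.asarray(chroms, dtype=object)
    positions = np.asarray(positions, dtype=np.int64)
    out = np.zeros(len(positions), dtype=bool)
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        out[mask] = track.contains(str(chrom), positions[mask])
    return out


def signed_distance(chroms: Sequence[str], positions: Sequence[int],
                    track: IntervalTrack) -> pd.DataFrame:
    """Distance of each SNP to the nearest interval / interval boundary.

    Columns: ``distance`` (0 inside an interval, else bp gap to the nearest
    interval), ``boundary_distance`` (bp to the nearest interval edge, also
    for inside positions — used by profiles that split inside vs outside),
    ``inside``.  Chromosomes without intervals yield NaN distances.
    """
    chroms = np.asarray(chroms, dtype=object)
    pos0 = np.asarray(positions, dtype=np.int64) - 1
    n = len(pos0)
    dist = np.full(n, np.nan)
    bdist = np.full(n, np.nan)
    inside = np.zeros(n, dtype=bool)
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        starts, ends = track.intervals(str(chrom))
        if len(starts) == 0:
            continue
        p = pos0[mask]
        idx = np.searchsorted(starts, p, side="right") - 1
        prev_ok = idx >= 0
        ins = np.zeros(len(p), dtype=bool)
        ins[prev_ok] = p[prev_ok] < ends[idx[prev_ok]]
        # gap to previous interval end / next interval start (outside points)
        gap_prev = np.full(len(p), np.inf)
        gap_prev[prev_ok] = p[prev_ok] - (ends[idx[prev_ok]] - 1)
        nxt = np.searchsorted(starts, p, side="right")
        next_ok = nxt < len(starts)
        gap_next = np.full(len(p), np.inf)
        gap_next[next_ok] = starts[nxt[next_ok]] - p[next_ok]
        d_out = np.minimum(gap_prev, gap_next)
        # boundary distance for inside points: to either edge of own interval
        b = np.where(ins,
                     np.minimum(p - starts[np.clip(idx, 0, None)],
                                ends[np.clip(idx, 0, None)] - 1 - p),
                     d_out)
        dist[mask] = np.where(ins, 0.0, d_out)
        bdist[mask] = b
        inside[mask] = ins
    return pd.DataFrame({"distance": dist, "boundary_distance": bdist,
                         "inside": inside})


def gc_content_window(reference, chrom: str, pos: int, window_bp: int = 200
                      ) -> Optional[float]:
    """G+C fraction of the window_bp window centred on the SNP (100 bp flanks).

    N bases are excluded from the denominator; the window is truncated at
    chromosome ends.  An all-N window is undefined (None).
    """
    seq = reference[chrom]
    half = window_bp // 2
    p0 = pos - 1
    lo = max(0, p0 - half)
    hi = min(len(seq), p0 + window_bp - half)
    window = str(seq[lo:hi]).upper()
    valid = sum(1 for b in window if b in "ACGT")
    if valid == 0:
        return None
    gc = sum(1 for b in window if b in "GC")
    return gc / valid


def _interval_arrays(intervals: Sequence[tuple[int, int]]):
    if not intervals:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    ivs = sorted(intervals)
    return (np.asarray([s for s, _ in ivs], dtype=np.int64),
            np.asarray([e for _, e in ivs], dtype=np.int64))


def _member(p: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    if len(starts) == 0:
        return np.zeros(len(p), dtype=bool)
    idx = np.searchsorted(starts, p, side="right") - 1
    ok = idx >= 0
    out = np.zeros(len(p), dtype=bool)
    out[ok] = p[ok] < ends[idx[ok]]
    return out


def genic_subregion_assign(chroms: Sequence[str], positions: Sequence[int],
                           gene_models: Sequence[GeneModel]) -> np.ndarray:
    """Fine 11-way sub-region label per SNP.

    Inside a gene body the priority is splice_site > UTR5 > UTR3 > exonic >
    intronic, where splice sites are intronic positions within 2 bp of an
    exon boundary.  Outside, the SNP is binned by distance to the nearest
    gene body (0–5 kb, 5–50 kb, >50 kb) on the up- or downstream side as
    seen from that gene's strand.  A chromosome without genes yields the
    far-upstream intergenic label.
    """
    chroms = np.asarray(chroms, dtype=object)
    pos0 = np.asarray(positions, dtype=np.int64) - 1
    labels = np.full(len(pos0), "intergenic_gt50kb_up", dtype=object)

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)

    for chrom in np.unique(chroms):
        mask = chroms == chrom
        p = pos0[mask]
        genes = by_chrom.get(str(chrom), [])
        if not genes:
            continue
        exon_iv, utr5_iv, utr3_iv, body_iv, splice_iv = [], [], [], [], []
        for g in genes:
            lo, hi = g.span
            body_iv.append((lo, hi))
            exon_iv.extend(g.exon_intervals)
            utr5_iv.extend(g.utr5_intervals)
            utr3_iv.extend(g.utr3_intervals)
            for es, ee in g.exon_intervals:
                splice_iv.append((max(lo, es - SPLICE_FLANK_BP), es))
                splice_iv.append((ee, min(hi, ee + SPLICE_FLANK_BP)))
        in_exon = _member(p, *_interval_arrays(exon_iv))
        in_body = _member(p, *_interval_arrays(body_iv))
        in_splice = _member(p, *_interval_arrays([iv for iv in splice_iv
                                                  if iv[0] < iv[1]]))
        in_utr5 = _member(p, *_interval_arrays(utr5_iv))
        in_utr3 = _member(p, *_interval_arrays(utr3_iv))

        lab = np.full(len(p), "", dtype=object)
        lab[in_body] = "intronic"
        lab[in_body & in_exon] = "exonic"
        lab[in_body & in_utr3] = "UTR3"
        lab[in_body & in_utr5] = "UTR5"
        lab[in_body & in_splice & ~in_exon] = "splice_site"

        # intergenic: nearest gene body and its strand
        out = ~in_body
        if out.any():
            order = sorted(range(len(genes)), key=lambda i: genes[i].span[0])
            starts = np.asarray([genes[i].span[0] for i in order])
            ends = np.asarray([genes[i].span[1] for i in order])
            strands = [genes[i].strand for i in order]
            cummax_end = np.maximum.accumulate(ends)
            argmax_end = np.zeros(len(ends), dtype=int)
            for i in range(1, len(ends)):
                argmax_end[i] = i if ends[i] >= cummax_end[i - 1] else argmax_end[i - 1]
            po = p[out]
            nxt = np.searchsorted(starts, po, side="right")
            lab_out = np.empty(len(po), dtype=object)
            for k in range(len(po)):
                i = nxt[k]
                d_next = starts[i] - po[k] if i < len(starts) else np.inf
                d_prev = (po[k] - (cummax_end[i - 1] - 1)) if i > 0 else np.inf
                if d_prev <= d_next:
                    gi, left_side = argmax_end[i - 1], False
                    dist = d_prev
                else:
                    gi, left_side = i, True
                    dist = d_next
                upstream = (strands[gi] == "+") == left_side
                if dist <= 5000:
                    binlab = "0to5kb"
                elif dist <= 50000:
                    binlab = "5to50kb"
                else:
                    binlab = "gt50kb"
                lab_out[k] = (f"intergenic_{binlab}_up" if upstream
                              else f"intergenic_{binlab}_down")
            lab[out] = lab_out
        labels[mask] = lab
    return labels


@dataclass
class BinnedProfile:
    """Per-bin mean and count; weighted bin means recombine to the global mean."""

    table: pd.DataFrame  # columns bin_left, bin_right, count, mean

    @property
    def global_mean(self) -> float:
        t = self.table[self.table["count"] > 0]
        return float((t["count"] * t["mean"]).sum() / t["count"].sum())


def binned_mean_profile(values: Sequence[float], by: Sequence[float],
                        bin_edges: Sequence[float]) -> BinnedProfile:
    """Mean of ``values`` per bin of ``by``; bins are (a, b] with the lowest
    edge included.  Empty bins are reported with count 0, mean NaN."""
    values = np.asarray(values, dtype=float)
    by = np.asarray(by, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    if np.nanmin(by) < edges[0] or np.nanmax(by) > edges[-1]:
        raise ValueError("bin_spec does not cover the data range")
    cats = pd.cut(by, bins=edges, include_lowest=True)
    df = pd.DataFrame({"v": values, "bin": cats})
    grouped = df.groupby("bin", observed=False)["v"]
    table = pd.DataFrame({
        "bin_left": edges[:-1], "bin_right": edges[1:],
        "count": grouped.count().to_numpy(),
        "mean": grouped.mean().to_numpy(),
    })
    return BinnedProfile(table=table)


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided U test: exact for small tie-free samples, else normal approx
    with tie correction (scipy's asymptotic method)."""
    combined = np.concatenate([x, y])
    small = max(len(x), len(y)) <= 50
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def subregion_mark_delta(
    rates: Sequence[float],
    on_mask: Sequence[bool],
    subregion_labels: Sequence[str],
    exclude_mask: Optional[Sequence[bool]] = None,
    mark_name: str = "mark",
) -> pd.DataFrame:
    """Δ(mean NCO rate) on vs off a mark, per sub-region, with Mann-Whitney p.

    ``exclude_mask`` removes SNPs first (e.g. DMC1-hotspot overlaps, which
    would contaminate the NCO signal with crossover machinery).  Cells where
    either stratum is empty are untestable (delta/U/p NaN).
    """
    rates = np.asarray(rates, dtype=float)
    on = np.asarray(on_mask, dtype=bool)
    labels = np.asarray(subregion_labels, dtype=object)
    keep = ~np.asarray(exclude_mask, dtype=bool) if exclude_mask is not None \
        else np.ones(len(rates), dtype=bool)
    keep &= ~np.isnan(rates)
    rows = []
    for sub in pd.unique(labels[keep]):
        m = keep & (labels == sub)
        x = rates[m & on]
        y = rates[m & ~on]
        row = {"mark": mark_name, "subregion": sub,
               "n_on": len(x), "n_off": len(y),
               "mean_on": float(np.mean(x)) if len(x) else np.nan,
               "mean_off": float(np.mean(y)) if len(y) else np.nan,
               "delta": np.nan, "U": np.nan, "p_value": np.nan,
               "testable": bool(len(x) and len(y))}
        if row["testable"]:
            row["delta"] = row["mean_on"] - row["mean_off"]
            row["U"], row["p_value"] = _mannwhitney(x, y)
        rows.append(row)
    return pd.DataFrame(rows)


def overlap_foldchange_slope(
    rates: Sequence[float], overlap_mask: Sequence[bool], n_bins: int = 10
) -> tuple[pd.DataFrame, float, float]:
    """Fold change of track overlap across NCO-rate bins, with an OLS line.

    Singletons are binned by NCO rate into ``n_bins`` equal-width bins over
    [0, 1]; each bin's fold change is its overlap frequency divided by the
    overall overlap frequency.  Returns (per-bin table, slope m, r²) from an
    ordinary least-squares regression of fold change on bin mean rate.
    """
    rates = np.asarray(rates, dtype=float)
    overlap = np.asarray(overlap_mask, dtype=bool)
    ok = ~np.isnan(rates)
    rates, overlap = rates[ok], overlap[ok]
    overall = overlap.mean() if len(overlap) else 0.0
    if overall == 0:
        raise ValueError("overall overlap frequency is 0; fold change undefined")
    edges = np.linspace(0, 1, n_bins + 1)
    cats = pd.cut(rates, bins=edges, include_lowest=True)
    df = pd.DataFrame({"rate": rates, "ov": overlap, "bin": cats})
    g = df.groupby("bin", observed=False)
    table = pd.DataFrame({
        "bin_left": edges[:-1], "bin_right": edges[1:],
        "count": g["ov"].count().to_numpy(),
        "mean_rate": g["rate"].mean().to_numpy(),
        "overlap_freq": g["ov"].mean().to_numpy(),
    })
    table["fold_change"] = table["overlap_freq"] / overall
    nz = table[table["count"] > 0]
    if len(nz) < 3:
        raise ValueError("need ≥3 non-empty bins for a regression")
    fit = stats.linregress(nz["mean_rate"], nz["fold_change"])
    return table, float(fit.slope), float(fit.rvalue ** 2)


def assign_states(chroms: Sequence[str], positions: Sequence[int],
                  state_tracks: Mapping[str, IntervalTrack]) -> np.ndarray:
    """Chromatin-state label per SNP from one epigenome's per-state tracks.

    States are expected to partition the genome; positions covered by no
    state get the empty label and are dropped from summaries.
    """
    labels = np.full(len(positions), "", dtype=object)
    for state, track in state_tracks.items():
        hit = overlap_any(chroms, positions, track)
        labels[hit & (labels == "")] = state
    return labels


def state_region_summary(
    rates: Sequence[float],
    state_labels: Mapping[str, Sequence[str]],
    mark_overlaps: Mapping[str, Sequence[bool]],
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Per (epigenome, state): mean NCO rate and per-mark overlap frequency.

    ``state_labels`` maps epigenome id → per-SNP state label array;
    ``mark_overlaps`` maps mark name → per-SNP boolean overlap.  Returns the
    cell table and, per mark, the Spearman (rho, p) between mean rate and
    mark frequency across all (epigenome × state) cells.  States with no
    SNPs in an epigenome are dropped.
    """
    rates = np.asarray(rates, dtype=float)
    marks = {m: np.asarray(v, dtype=bool) for m, v in mark_overlaps.items()}
    rows = []
    for epi, labels in state_labels.items():
        labels = np.asarray(labels, dtype=object)
        for state in pd.unique(labels):
            if state == "":
                continue
            m = (labels == state) & ~np.isnan(rates)
            if not m.any():
                continue
            row = {"epigenome_id": epi, "state": state, "n_snps": int(m.sum()),
                   "mean_nco_rate": float(rates[m].mean())}
            for name, ov in marks.items():
                row[f"freq_{name}"] = float(ov[m].mean())
            rows.append(row)
    table = pd.DataFrame(rows)
    correlations: dict[str, tuple[float, float]] = {}
    for name in marks:
        col = table[f"freq_{name}"]
        if col.nunique() <= 1:
            correlations[name] = (float("nan"), float("nan"))
        else:
            rho, p = stats.spearmanr(table["mean_nco_rate"], col)
            correlations[name] = (float(rho), float(p))
    return table, correlations
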