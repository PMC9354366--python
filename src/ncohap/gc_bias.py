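"""GC-biased transmission at single-NCO-event SNPs.

The single-event signature is exact D'²_{a,hap} = 1 with exact r²_{a,hap} < 1:
only three of the four allele/core combinations exist in the cohort, the
configuration produced by one conversion event.  Among such singletons with a
strong/weak allele pair (one of G/C vs one of A/T) and maf above a drift
floor (default 0.2), the sign of Δf_{a,hap} tells which allele the event
transmitted: Δf > 0 means the derived allele expanded into the ancestral
haplotype, Δf < 0 means it was replaced by the ancestral allele.  The GC
bias is the fraction of events that transmitted the strong allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

from .archaic_snps import ArchaicSNP
from .ld_stats import DeltaF
from .linkage_blocks import SingletonAssignment

__all__ = [
    "TransmissionEvent", "select_single_event_snps", "classify_transmission",
    "gc_bias_estimate",
]

STRONG = frozenset("GC")
WEAK = frozenset("AT")


@dataclass(frozen=True)
class TransmissionEvent:
    snp_index: int
    strong_allele: str
    weak_allele: str
    delta_f_sign: int          # +1 or −1
    transmitted_class: str     # "GC" or "AT"
    cpg: Optional[bool] = None


def select_single_event_snps(
    assignments: Sequence[SingletonAssignment],
    snps: Sequence[ArchaicSNP],
    maf_min: Fraction | float = Fraction(1, 5),
) -> list[SingletonAssignment]:
    """Keep singletons with exact D'² = 1, exact r² < 1, maf > maf_min,
    and a strong/weak (G/C vs A/T) allele pair."""
    maf_min = Fraction(maf_min).limit_denominator(10**9)
    keep = []
    for a in assignments:
        if not a.ld.defined or a.ld.d_prime is None:
            continue
        if a.ld.d_prime ** 2 != 1 or a.ld.r2 >= 1:
            continue
        snp = snps[a.snp_index]
        if snp.maf <= maf_min:
            continue
        if not snp.strong_weak_pair:
            continue
        keep.append(a)
    return keep


def classify_transmission(
    snp: ArchaicSNP, delta_f: DeltaF, snp_index: int = -1
) -> Optional[TransmissionEvent]:
    """Which allele class the event transmitted; None when Δf is 0/undefined.

    Transmitted allele = derived if Δf > 0 (expansion into the ancestral
    haplotype) else ancestral (replacement of the derived allele).
    """
    if not delta_f.defined or delta_f.delta == 0:
        return None
    if snp.derived_allele in STRONG:
        strong, weak = snp.derived_allele, snp.ancestral_allele
    else:
        strong, weak = snp.ancestral_allele, snp.derived_allele
    if strong not in STRONG or weak not in WEAK:
        raise ValueError(f"not a strong/weak pair: {snp.ancestral_allele}/"
                         f"{snp.derived_allele}")
    sign = 1 if delta_f.delta > 0 else -1
    transmitted = snp.derived_allele if sign > 0 else snp.ancestral_allele
    return TransmissionEvent(
        snp_index=snp_index, strong_allele=strong, weak_allele=weak,
        delta_f_sign=sign,
        transmitted_class="GC" if transmitted in STRONG else "AT",
        cpg=snp.cpg_flag)


def gc_bias_estimate(
    events: Sequence[TransmissionEvent], stratify_by_cpg: bool = True
) -> dict[str, dict]:
    """Bias = #GC / (#GC + #AT) per stratum, with counts.

    Strata are 'non_cpg'/'cpg' when stratifying (events with unknown CpG
    status land in 'unknown'), plus an 'all' row.  An empty stratum reports
    bias None, never 0.
    """
    def tally(evs):
        n_gc = sum(1 for e in evs if e.transmitted_class == "GC")
        n_at = sum(1 for e in evs if e.transmitted_class == "AT")
        total = n_gc + n_at
        return {"n_GC": n_gc, "n_AT": n_at,
                "bias": n_gc / total if total else None}

    out = {"all": tally(events)}
    if stratify_by_cpg:
        out["non_cpg"] = tally([e for e in events if e.cpg is False])
        out["cpg"] = tally([e for e in events if e.cpg is True])
        unknown = [e for e in events if e.cpg is None]
        if unknown:
            out["unknown"] = tally(unknown)
    return out
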