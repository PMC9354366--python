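"""Exact derived-allele-oriented linkage-disequilibrium statistics.

All count-derived quantities (joint probabilities, D, D_max, D', r² and the
NCO rate 1 − D'²) are kept as :class:`fractions.Fraction` over the haplotype
count 2N.  Block membership and the single-event filter of the GC-bias
analysis are defined by *exact* equalities (r² = 1, D'² = 1), which float
arithmetic cannot certify; rational arithmetic makes them integer identities.

Only the correlation coefficient ``r`` itself is irrational (it carries a
square root) and is returned as a float; its square and sign are exact.

Conventions
-----------
* Haplotype columns are 0/1 vectors over the 2N phased haplotypes of the
  cohort, with 1 = derived allele (or "carries the full core haplotype").
* ``D = P11 − f1·f2`` where ``P11`` is the fraction of haplotypes carrying
  the derived allele (or core) at both columns.
* ``D_max`` follows the piecewise normalisation
  ``D < 0: max{−f1·f2, −(1−f1)(1−f2)}``,
  ``D > 0: min{f1(1−f2), (1−f1)·f2}``,
  so ``D' = D / D_max ≥ 0`` in both branches (for D < 0 both numerator and
  denominator are negative).  ``D = 0`` maps to ``D' = 0`` by convention.
* A monomorphic margin leaves r, D' and the NCO rate undefined; undefined
  values are represented as ``None`` and propagate (never silently 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "LDPair",
    "DeltaF",
    "joint_frequencies",
    "lewontin_D",
    "correlation_r",
    "d_prime",
    "nco_rate",
    "ld_pair_from_counts",
    "ld_pair",
    "normalized_delta_f",
]

FractionLike = Union[Fraction, int]


@dataclass(frozen=True)
class LDPair:
    """Full LD statistic bundle for one allele-vs-allele (or allele-vs-core) pair.

    ``r`` is a float (irrational in general); every other statistic is an
    exact Fraction, or ``None`` when a monomorphic margin leaves it undefined.
    """

    p_joint: Fraction
    f1: Fraction
    f2: Fraction
    D: Fraction
    r: Optional[float]
    r2: Optional[Fraction]
    d_max: Optional[Fraction]
    d_prime: Optional[Fraction]
    nco_rate: Optional[Fraction]

    @property
    def defined(self) -> bool:
        return self.r2 is not None

    @property
    def r_sign(self) -> Optional[int]:
        """Sign of r (equals sign of D); None when r is undefined."""
        if self.r2 is None:
            return None
        return (self.D > 0) - (self.D < 0)


@dataclass(frozen=True)
class DeltaF:
    """Phasing-aware normalized frequency Δf of a derived allele vs its core.

    With positive r the derived allele rides the core haplotype and
    ``delta = f_a − f_hap``; with negative r it rides the complementary
    (ancestral) haplotype and ``delta = (1 − f_a) − f_hap``.  ``r = 0``
    leaves the phase ambiguous: ``delta`` is None and the SNP is excluded
    from Δf-based analyses.
    """

    f_a: Fraction
    f_hap: Fraction
    r_sign: int
    delta: Optional[Fraction]

    @property
    def defined(self) -> bool:
        return self.delta is not None


def _as_fraction(x, name: str) -> Fraction:
    f = Fraction(x)
    if not 0 <= f <= 1:
        raise ValueError(f"{name} must lie in [0, 1], got {x}")
    return f


def joint_frequencies(
    matrix: np.ndarray, col_i: int, col_j: int
) -> tuple[Fraction, Fraction, Fraction]:
    """Exact (P_joint, f1, f2) for two 0/1 columns of a haplotype matrix.

    P_joint is the fraction of haplotypes with the derived allele at both
    columns, as a Fraction over the number of haplotype rows.
    """
    a = np.asarray(matrix)[:, col_i]
    b = np.asarray(matrix)[:, col_j]
    if a.shape != b.shape:
        raise ValueError("column length mismatch")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    n11 = int(np.count_nonzero((a == 1) & (b == 1)))
    n1 = int(np.count_nonzero(a == 1))
    n2 = int(np.count_nonzero(b == 1))
    return Fraction(n11, n), Fraction(n1, n), Fraction(n2, n)


def lewontin_D(p_joint: FractionLike, f1: FractionLike, f2: FractionLike) -> Fraction:
    """D = P_joint − f1·f2."""
    p = _as_fraction(p_joint, "p_joint")
    x = _as_fraction(f1, "f1")
    y = _as_fraction(f2, "f2")
    return p - x * y


def correlation_r(
    D: FractionLike, f1: FractionLike, f2: FractionLike
) -> tuple[Optional[float], Optional[Fraction]]:
    """(r, r²): r as float, r² as exact Fraction; (None, None) if a margin is fixed."""
    d = Fraction(D)
    x = _as_fraction(f1, "f1")
    y = _as_fraction(f2, "f2")
    den = x * (1 - x) * y * (1 - y)
    if den == 0:
        return None, None
    r2 = d * d / den
    sign = 1 if d > 0 else (-1 if d < 0 else 0)
    return sign * math.sqrt(r2), r2


def d_prime(
    D: FractionLike, f1: FractionLike, f2: FractionLike
) -> tuple[Optional[Fraction], Optional[Fraction]]:
    """(D_max, D') under the piecewise normalisation; D = 0 → D' = 0.

    Returns (None, None) when a margin is monomorphic (D' undefined).
    """
    d = Fraction(D)
    x = _as_fraction(f1, "f1")
    y = _as_fraction(f2, "f2")
    if x in (0, 1) or y in (0, 1):
        return None, None
    if d == 0:
        return None, Fraction(0)
    if d < 0:
        dmax = max(-(x * y), -((1 - x) * (1 - y)))
    else:
        dmax = min(x * (1 - y), (1 - x) * y)
    return dmax, d / dmax


def nco_rate(dp: Optional[FractionLike]) -> Optional[Fraction]:
    """NCO rate = 1 − D'²; undefined input propagates."""
    if dp is None:
        return None
    f = Fraction(dp)
    if abs(f) > 1:
        raise ValueError(f"|D'| must be ≤ 1, got {f}")
    return 1 - f * f


def ld_pair_from_counts(n11: int, n1: int, n2: int, n: int) -> LDPair:
    """Assemble the full statistic bundle from the four haplotype-class counts.

    ``n11``: haplotypes derived at both sites; ``n1``/``n2``: derived at each
    site; ``n``: total haplotypes (2N).
    """
    if not (0 <= n11 <= min(n1, n2) and n1 <= n and n2 <= n and n >= 2):
        raise ValueError(f"inconsistent counts n11={n11} n1={n1} n2={n2} n={n}")
    if n11 < n1 + n2 - n:
        raise ValueError("counts imply a negative haplotype class")
    p = Fraction(n11, n)
    f1 = Fraction(n1, n)
    f2 = Fraction(n2, n)
    D = lewontin_D(p, f1, f2)
    r, r2 = correlation_r(D, f1, f2)
    dmax, dp = d_prime(D, f1, f2)
    return LDPair(
        p_joint=p, f1=f1, f2=f2, D=D, r=r, r2=r2,
        d_max=dmax, d_prime=dp, nco_rate=nco_rate(dp),
    )


def ld_pair(a: Sequence[int] | np.ndarray, b: Sequence[int] | np.ndarray) -> LDPair:
    """LD bundle for two 0/1 haplotype columns (e.g. SNP vs core indicator)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("column length mismatch")
    n = int(a.shape[0])
    n11 = int(np.count_nonzero((a == 1) & (b == 1)))
    return ld_pair_from_counts(n11, int(np.count_nonzero(a == 1)),
                               int(np.count_nonzero(b == 1)), n)


def normalized_delta_f(
    f_a: FractionLike, f_hap: FractionLike, r_sign: int
) -> DeltaF:
    """Δf_{a,hap} under the phasing rule keyed on the sign of r_{a,hap}."""
    fa = _as_fraction(f_a, "f_a")
    fh = _as_fraction(f_hap, "f_hap")
    if r_sign > 0:
        delta: Optional[Fraction] = fa - fh
    elif r_sign < 0:
        delta = (1 - fa) - fh
    else:
        delta = None
    return DeltaF(f_a=fa, f_hap=fh, r_sign=(r_sign > 0) - (r_sign < 0), delta=delta)
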