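"""Map expansion: expected density of recombination breakpoints.

If R(r) is the probability that a two-locus haplotype is recombinant, the
map expansion is dR/dr at r = 0 — the factor by which the density of
visible breakpoints on a random chromosome exceeds that of one meiosis.

Closed forms:

* AIL autosome:        s/2            (X: 2/3 of that, s/3)
* HS autosome:         M_1 = 3,  M_s = (7s+17)/8   (X: 2/3 of that)
* DO autosome:         M_s = (7/8)(s-1) + M_1(alpha), with M_1(alpha) the
  alpha-weighted map expansion of the transmitted pre-CC gamete, computed
  numerically from the exact chain  (X: 2/3 of that)
* unbalanced AIL X:    recurrence M'_{s+1} = M'_s + (4/3)(q_s - q_{s-1} q_{s-2}),
  M'_1 = 0, M'_2 = 2/3.  M'_s is the *overall* X map expansion
  (2/3 female + 1/3 male), which follows by differentiating the
  haplotype recurrences directly.

An earlier treatment of HS had assumed (7/8)(s+2); the corrected value
(7/8)(s-1) + 3 exceeds it by 3/8 for every s: in the first three
generations with recombination all individuals are fully heterozygous and
every crossover is visible, whereas in the s - 1 outcross generations a
crossover is visible only with probability 7/8.
"""

from __future__ import annotations

import math
from typing import Callable

from .core import AlphaDistribution, Balance, Chromosome, Design, check_s
from .ail import unbalanced_allele_freq
from .precc import precc_autosome_q

__all__ = [
    "map_expansion_closed",
    "map_expansion_unbalancedX",
    "map_expansion_numeric",
    "hs_map_expansion_legacy",
    "do_m1",
]

#: Fraction of autosomal map expansion seen on the X (balanced designs).
X_FACTOR = 2.0 / 3.0


def map_expansion_numeric(recombinant_fn: Callable[[float], float], h: float = 1e-6) -> float:
    """Numerical dR/dr at r = 0 by forward differences with one Richardson
    refinement (steps h and h/2).  R is defined only for r >= 0, so forward
    differencing is required; R(0) is evaluated rather than assumed zero.
    """
    if h <= 0:
        raise ValueError("step h must be positive")
    r0 = float(recombinant_fn(0.0))
    d1 = (float(recombinant_fn(h)) - r0) / h
    d2 = (float(recombinant_fn(h / 2.0)) - r0) / (h / 2.0)
    est = 2.0 * d2 - d1
    if not math.isfinite(est):
        raise ValueError("recombinant function returned non-finite values")
    return est


def do_m1(alpha: AlphaDistribution, h: float = 1e-6) -> float:
    """First-generation DO map expansion M_1(alpha) = -8 d/dr sum_k alpha_k
    q_{k+1} at r = 0, computed numerically from the pre-CC chain."""

    def neg8p1(r: float) -> float:
        return 1.0 - 8.0 * sum(a * precc_autosome_q(k + 1, r) for k, a in alpha.items())

    return map_expansion_numeric(neg8p1, h=h)


def map_expansion_closed(
    design: Design | str,
    chromosome: Chromosome | str,
    s: int,
    alpha: AlphaDistribution | None = None,
    balance: Balance | str = Balance.BALANCED,
) -> float:
    """Closed-form map expansion for a design/chromosome/generation."""
    design, chromosome, balance = Design(design), Chromosome(chromosome), Balance(balance)
    s = check_s(s)
    if balance is Balance.UNBALANCED:
        if design is Design.AIL2 and chromosome is Chromosome.X:
            raise ValueError(
                "no closed form for the unbalanced AIL X; use map_expansion_unbalancedX"
            )
        raise ValueError("unbalanced crosses are only defined for the AIL X chromosome")
    if design is Design.AIL2:
        # s/2 (and s/3 on X) hold from s = 2; an F1 chromosome has passed
        # through no meiosis, so the map expansion at s = 1 is 0.
        auto = 0.0 if s == 1 else s / 2.0
    elif design is Design.HS8:
        auto = (7.0 * s + 17.0) / 8.0
    else:
        if alpha is None:
            raise ValueError("the DO requires a progenitor-generation distribution alpha")
        auto = 7.0 / 8.0 * (s - 1) + do_m1(alpha)
    return auto if chromosome is Chromosome.AUTOSOME else X_FACTOR * auto


def hs_map_expansion_legacy(s: int) -> float:
    """The superseded HS autosome map expansion (7/8)(s+2), kept for
    comparison with the corrected (7/8)(s-1) + 3."""
    return 7.0 / 8.0 * (check_s(s) + 2)


def map_expansion_unbalancedX(s: int) -> float:
    """Overall map expansion M'_s on the unbalanced AIL X.

    M'_1 = 0 (all F1 X's are intact founder chromosomes), M'_2 = 2/3, and
    M'_{s+1} = M'_s + (4/3)(q_s - q_{s-1} q_{s-2}) with q the female
    A-allele frequency (q_{-1} = 0).  The per-generation increment tends to
    (4/3)(2/3 - 4/9) = 8/27, smaller than the balanced 1/3 because reduced
    heterozygosity (allele frequencies 2/3 vs 1/3) hides crossovers.
    """
    s = check_s(s)
    m = 0.0  # M'_1
    q = unbalanced_allele_freq
    for t in range(1, s):
        m += (4.0 / 3.0) * (q(t) - q(t - 1) * q(t - 2))
    return m
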