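"""Two-locus haplotype probabilities for heterogeneous stock and the DO.

Both populations carry eight founder genomes.  HS is founded directly from
the eight-way cross (equivalently, the DO with all progenitors at pre-CC
generation k = 1); the DO is founded from pre-CC mice spread over
generations k with weights alpha_k.  Generation s = 1 denotes the first
outcross generation, i.e. the offspring of the progenitors, so every s = 1
haplotype has passed through one outcross meiosis.  Subsequent generations
follow linear recurrences with stationary point 1/64 (uniform over the 64
ordered founder-haplotype pairs):

* autosome:  p_{s+1} = (1-r) p_s + r/64,            p_1 = sum_k alpha_k q_{k+1}
* X:         m_{s+1} = (1-r) f_s + r/64
             f_{s+1} = m_s/2 + (1-r) f_s/2 + r/128

The X initialisation is computed from the exact pre-CC chain: a first
outcross male's X is the gamete of a pre-CC dam (whose two X's carry
founder alleles of a single funnel, so the usual r/64 recombinant term
does not apply to that first meiosis), and a first outcross female adds
the pre-CC sire's X transmitted intact.  With this initialisation the
population's X map expansion is exactly 2/3 of the autosomal one at every
generation (see ``docs/methods.md`` for why this differs from transcribing
the progenitor-generation formulas).

By the complete balance of cross orders, the 8 intact haplotypes are
equally likely, as are the 56 recombinant ones, so the full table is
determined by the AA frequency alone.
"""

from __future__ import annotations

from .core import (
    FEMALE_X_WEIGHT,
    AlphaDistribution,
    HaplotypeFreqTable,
    Sex,
    check_r,
    check_s,
)
from .ail import _check_method, _x_recurrence, x_pair_closed_form
from .precc import (
    precc_autosome_q,
    precc_x_progenitor_freqs,
    precc_x_transmitted_AA,
)

__all__ = [
    "do_p1",
    "do_autosome_AA",
    "do_autosome_table",
    "do_recombinant",
    "do_x_init",
    "do_x_AA",
    "do_x_table",
    "do_x_recombinant",
    "hs_alpha",
]


def hs_alpha() -> AlphaDistribution:
    """The progenitor distribution making the DO formulas specialise to HS."""
    return AlphaDistribution.point_mass(1)


def _check_alpha(alpha: AlphaDistribution) -> AlphaDistribution:
    if not isinstance(alpha, AlphaDistribution):
        alpha = AlphaDistribution(alpha)
    return alpha


def do_p1(alpha: AlphaDistribution, r: float) -> float:
    """Autosomal AA frequency at the first outcross generation,
    p_1 = sum_k alpha_k q_{k+1}."""
    alpha = _check_alpha(alpha)
    r = check_r(r)
    return sum(a * precc_autosome_q(k + 1, r) for k, a in alpha.items())


def do_autosome_AA(
    s: int, r: float, alpha: AlphaDistribution, method: str = "recurrence"
) -> float:
    """Frequency p_s of the AA haplotype on a DO/HS autosome.

    Closed form: p_s = 1/64 + (1-r)^(s-1) (p_1 - 1/64).
    """
    s, r = check_s(s), check_r(r)
    _check_method(method)
    p = do_p1(alpha, r)
    if method == "closed_form":
        return 1.0 / 64.0 + (1.0 - r) ** (s - 1) * (p - 1.0 / 64.0)
    for _ in range(s - 1):
        p = (1.0 - r) * p + r / 64.0
    return p


def do_autosome_table(s: int, r: float, alpha: AlphaDistribution) -> HaplotypeFreqTable:
    """8x8 joint table: diagonal p_s, each of the 56 recombinant haplotypes
    (1 - 8 p_s)/56."""
    return HaplotypeFreqTable.balanced(8, do_autosome_AA(s, r, alpha))


def do_recombinant(s: int, r: float, alpha: AlphaDistribution) -> float:
    """Probability 1 - 8 p_s that an autosomal haplotype is recombinant."""
    return 1.0 - 8.0 * do_autosome_AA(s, r, alpha)


# ---------------------------------------------------------------------------
# X chromosome
# ---------------------------------------------------------------------------


def do_x_init(alpha: AlphaDistribution, r: float) -> tuple[float, float]:
    """(m_1, f_1): AA frequencies on the X at the first outcross generation.

    m_1 is the alpha-weighted probability that the gamete transmitted by a
    pre-CC dam is AA; f_1 averages that maternal gamete with the pre-CC
    sire's X (transmitted intact to daughters).  Computed exactly from the
    pre-CC X chain.
    """
    alpha = _check_alpha(alpha)
    r = check_r(r)
    m1 = 0.0
    f1 = 0.0
    for k, a in alpha.items():
        g = precc_x_transmitted_AA(k, r)
        m_prog, _f_prog = precc_x_progenitor_freqs(k, r)
        m1 += a * g
        f1 += a * 0.5 * (g + m_prog)
    return m1, f1


def do_x_AA(
    s: int, r: float, alpha: AlphaDistribution, sex: Sex | str, method: str = "recurrence"
) -> float:
    """Frequency m_s (males) or f_s (females) of the AA haplotype on the
    DO/HS X chromosome."""
    s, r = check_s(s), check_r(r)
    sex = Sex(sex)
    if sex is Sex.OVERALL:
        raise ValueError("per-sex AA frequency requested: sex must be male or female")
    _check_method(method)
    m1, f1 = do_x_init(alpha, r)
    const = (r / 64.0, r / 128.0)
    if method == "closed_form" and s >= 2:
        m, f = x_pair_closed_form(m1, f1, const, r, s, s_anchor=1)
    else:
        m, f = _x_recurrence(m1, f1, const, r, s - 1)
    return m if sex is Sex.MALE else f


def do_x_table(s: int, r: float, alpha: AlphaDistribution, sex: Sex | str) -> HaplotypeFreqTable:
    sex = Sex(sex)
    if sex is Sex.OVERALL:
        e = (1.0 - FEMALE_X_WEIGHT) * do_x_table(s, r, alpha, Sex.MALE).entries + \
            FEMALE_X_WEIGHT * do_x_table(s, r, alpha, Sex.FEMALE).entries
        return HaplotypeFreqTable(e, sex=sex)
    return HaplotypeFreqTable.balanced(8, do_x_AA(s, r, alpha, sex), sex=sex)


def do_x_recombinant(s: int, r: float, alpha: AlphaDistribution, sex: Sex | str) -> float:
    """Recombinant-haplotype frequency on the DO/HS X.

    Per sex this is 1 - 8 m_s or 1 - 8 f_s (eight-fold founder symmetry);
    ``overall`` weights females by 2/3.
    """
    sex = Sex(sex)
    if sex is Sex.OVERALL:
        male = do_x_recombinant(s, r, alpha, Sex.MALE)
        female = do_x_recombinant(s, r, alpha, Sex.FEMALE)
        return (1.0 - FEMALE_X_WEIGHT) * male + FEMALE_X_WEIGHT * female
    return 1.0 - 8.0 * do_x_AA(s, r, alpha, sex)
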