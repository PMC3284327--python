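"""Exact infinite-population propagation of full haplotype tables.

An independent implementation path from the scalar recurrences: instead of
tracking single probabilities (p_s, m_s, f_s), the full joint table over
ordered founder pairs is propagated one generation at a time.

With an effectively infinite number of mating pairs, the two haplotypes of
an individual are independent, so the gamete distribution from a parent
with chromosome tables T1, T2 (left/maternal and right/paternal copies) is

    G(a, b) = (1-r) (T1 + T2)/2 (a, b)
            + (r/2) [u1(a) v2(b) + u2(a) v1(b)]

where u, v are the locus-1 and locus-2 marginals.  On the autosome both
parents transmit the same way; on the X the male transmits his single X
intact to daughters and nothing to sons, so three tables are tracked:
female-maternal X, female-paternal X, and male X.

The scalar modules must agree with this propagator to near machine
precision on every entry; that cross-check is the package's main defence
against transcription errors in the closed forms.
"""

from __future__ import annotations

import numpy as np

from .core import (
    AlphaDistribution,
    Balance,
    Chromosome,
    Design,
    HaplotypeFreqTable,
    Sex,
    validate_params,
)
from .dohs import do_p1
from .precc import precc_x_progenitor_freqs, precc_x_transmitted_AA

__all__ = ["propagate_exact"]


def _gamete_table(t1: np.ndarray, t2: np.ndarray, r: float) -> np.ndarray:
    u1, v1 = t1.sum(axis=1), t1.sum(axis=0)
    u2, v2 = t2.sum(axis=1), t2.sum(axis=0)
    return (1.0 - r) * 0.5 * (t1 + t2) + 0.5 * r * (np.outer(u1, v2) + np.outer(u2, v1))


def _balanced_table(n: int, diag: float) -> np.ndarray:
    off = (1.0 - n * diag) / (n * (n - 1))
    t = np.full((n, n), off)
    np.fill_diagonal(t, diag)
    return t


def _init_autosome(
    design: Design, alpha: AlphaDistribution | None, r: float, s: int
) -> tuple[np.ndarray, int]:
    """Initial autosome table and the generation it describes.

    For AIL the factorised gamete recursion is valid only from F2 onward
    (an F1's haplotypes are the perfectly correlated AA and BB), so the
    exact F2 gamete table anchors the propagation; DO/HS progenitor lines
    are independent, so s = 1 is a valid anchor there.
    """
    if design is Design.AIL2:
        if s == 1:
            return np.diag([0.5, 0.5]), 1  # F1: intact AA and BB haplotypes
        f2 = np.array([[(1.0 - r) / 2.0, r / 2.0], [r / 2.0, (1.0 - r) / 2.0]])
        return f2, 2
    return _balanced_table(8, do_p1(alpha, r)), 1


def _init_x(
    design: Design, balance: Balance, alpha: AlphaDistribution | None, r: float, s: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """(female-maternal, female-paternal, male) X tables and their anchor
    generation.

    The balanced AIL X anchors at s = 2 (F1 females carry the correlated
    AA/BB pair, so the factorised cross term is wrong for the first
    meiosis); the unbalanced case is exact from s = 1 because the F1 X
    tables are degenerate (every female is exactly (AA, BB)), making the
    factorisation trivially exact.
    """
    if design is Design.AIL2:
        if balance is Balance.UNBALANCED:
            aa = np.array([[1.0, 0.0], [0.0, 0.0]])
            bb = np.array([[0.0, 0.0], [0.0, 1.0]])
            return aa, bb, aa.copy(), 1  # daughters (X_A, X_B); sons hemizygous A
        half = np.diag([0.5, 0.5])
        if s == 1:
            return half, half.copy(), half.copy(), 1
        g2 = np.array([[(1.0 - r) / 2.0, r / 2.0], [r / 2.0, (1.0 - r) / 2.0]])
        return g2, half, g2.copy(), 2
    # DO/HS: maternal X and the male X are the alpha-weighted transmitted
    # gamete of a pre-CC dam; the paternal X is a pre-CC sire's X intact.
    # Off-diagonal mass is uniform by the complete balance of cross orders.
    g = sum(a * precc_x_transmitted_AA(k, r) for k, a in alpha.items())
    m_prog = sum(a * precc_x_progenitor_freqs(k, r)[0] for k, a in alpha.items())
    fmat = _balanced_table(8, g)
    fpat = _balanced_table(8, m_prog)
    return fmat, fpat, fmat.copy(), 1


def propagate_exact(
    design: Design | str,
    chromosome: Chromosome | str,
    s: int,
    r: float,
    balance: Balance | str = Balance.BALANCED,
    alpha: AlphaDistribution | None = None,
) -> dict[Sex, HaplotypeFreqTable] | HaplotypeFreqTable:
    """Exact per-sex haplotype tables at generation s by full-table
    recursion.

    Returns a single table for the autosome, or ``{Sex.MALE: ...,
    Sex.FEMALE: ...}`` for the X (the female table averages her two X's).
    """
    design, chromosome, s, r, balance, alpha = validate_params(
        design, chromosome, s, r, balance, alpha
    )
    if chromosome is Chromosome.AUTOSOME:
        t, s0 = _init_autosome(design, alpha, r, s)
        for _ in range(s - s0):
            t = _gamete_table(t, t, r)
        return HaplotypeFreqTable(t)
    fmat, fpat, male, s0 = _init_x(design, balance, alpha, r, s)
    for _ in range(s - s0):
        g = _gamete_table(fmat, fpat, r)
        fmat, fpat, male = g, male, g.copy()
    return {
        Sex.MALE: HaplotypeFreqTable(male, sex=Sex.MALE),
        Sex.FEMALE: HaplotypeFreqTable(0.5 * (fmat + fpat), sex=Sex.FEMALE),
    }
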