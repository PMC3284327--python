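"""Founder-allele transition matrices for genotype-reconstruction HMMs.

A hidden Markov model over founder ancestry needs, for each adjacent marker
interval, the conditional probability that a chromosome carries founder j
at the right locus given founder i at the left locus.  These are the
two-locus joint haplotype probabilities divided by the left-locus founder
frequencies, plus the left-locus frequencies themselves as the initial
state distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

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
from . import ail, dohs

__all__ = ["TransitionMatrix", "haplotype_table", "transition_matrix", "transition_matrices"]


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic founder transition matrix plus the matching
    left-locus founder distribution.

    The two are emitted together because for the unbalanced AIL X they are
    sex specific and must not be mixed across sexes downstream.
    """

    entries: np.ndarray
    locus1_dist: np.ndarray
    sex: Sex | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=float)
        d = np.asarray(self.locus1_dist, dtype=float)
        if e.min() < -1e-12:
            raise ValueError("negative transition probability")
        if np.abs(e.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError("transition-matrix rows must sum to 1")
        if abs(d.sum() - 1.0) > 1e-12:
            raise ValueError("locus-1 founder distribution must sum to 1")
        object.__setattr__(self, "entries", e)
        object.__setattr__(self, "locus1_dist", d)

    @property
    def n_founders(self) -> int:
        return self.entries.shape[0]


def haplotype_table(
    design: Design | str,
    chromosome: Chromosome | str,
    s: int,
    r: float,
    sex: Sex | str | None = None,
    balance: Balance | str = Balance.BALANCED,
    alpha: AlphaDistribution | None = None,
) -> HaplotypeFreqTable:
    """Dispatch to the appropriate design's joint two-locus table."""
    design, chromosome, s, r, balance, alpha = validate_params(
        design, chromosome, s, r, balance, alpha
    )
    if chromosome is Chromosome.X:
        if sex is None:
            raise ValueError("sex is required for X-chromosome tables")
        sex = Sex(sex)
    if design is Design.AIL2:
        if chromosome is Chromosome.AUTOSOME:
            return ail.ail_autosome_table(s, r)
        if balance is Balance.UNBALANCED:
            return ail.ail_unbalancedX_table(s, r, sex)
        return ail.ail_balancedX_table(s, r, sex)
    if chromosome is Chromosome.AUTOSOME:
        return dohs.do_autosome_table(s, r, alpha)
    return dohs.do_x_table(s, r, alpha, sex)


def transition_matrix(
    design: Design | str,
    chromosome: Chromosome | str,
    s: int,
    r: float,
    sex: Sex | str | None = None,
    balance: Balance | str = Balance.BALANCED,
    alpha: AlphaDistribution | None = None,
) -> TransitionMatrix:
    """P(founder at locus 2 | founder at locus 1) for one marker interval.

    At r = 0 this is the identity; for balanced designs it is symmetric and
    doubly stochastic.  Left-locus founder frequencies are strictly
    positive in every supported design at s >= 1, so the quotient is always
    defined.
    """
    table = haplotype_table(design, chromosome, s, r, sex, balance, alpha)
    marg = table.locus1_marginals
    assert marg.min() > 0.0, "zero founder frequency cannot occur for s >= 1"
    return TransitionMatrix(table.entries / marg[:, None], marg, sex=table.sex)


def transition_matrices(
    design: Design | str,
    chromosome: Chromosome | str,
    s: int,
    r_values: Sequence[float],
    sex: Sex | str | None = None,
    balance: Balance | str = Balance.BALANCED,
    alpha: AlphaDistribution | None = None,
) -> list[TransitionMatrix]:
    """One transition matrix per marker interval, given the vector of
    interval recombination fractions (the HMM use case)."""
    return [
        transition_matrix(design, chromosome, s, r, sex, balance, alpha) for r in r_values
    ]
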