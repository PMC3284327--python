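"""Shared domain types, parameter validation and design enumerations.

The quantities handled throughout the package are two-locus founder-haplotype
probabilities in multiparent mouse populations: two-way advanced intercross
lines (AIL), eight-way heterogeneous stock (HS) and the diversity outcross
(DO).  Everything is parameterised by the meiotic recombination fraction
``r`` between the two loci and the generation number ``s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np

__all__ = [
    "Design",
    "Chromosome",
    "Balance",
    "Sex",
    "AlphaDistribution",
    "HaplotypeFreqTable",
    "ClosedFormCoefficients",
    "closed_form_coefficients",
    "check_r",
    "check_s",
    "validate_params",
    "example_alpha",
    "FEMALE_X_WEIGHT",
]

#: Weight of the female compartment in "overall" X-linked quantities.
#: Two-thirds of the X chromosomes in a population reside in females.
FEMALE_X_WEIGHT = 2.0 / 3.0


class Design(str, Enum):
    """Breeding design: two-way AIL, eight-way HS, or the DO."""

    AIL2 = "ail2"
    HS8 = "hs"
    DO8 = "do"

    @property
    def n_founders(self) -> int:
        return 2 if self is Design.AIL2 else 8


class Chromosome(str, Enum):
    AUTOSOME = "A"
    X = "X"


class Balance(str, Enum):
    """Cross balance for the AIL X chromosome.

    ``BALANCED`` means the F1 generation contains both reciprocal crosses
    (A x B and B x A) in equal proportion, so F1 males are equally likely to
    be hemizygous A or B.  ``UNBALANCED`` means all F1s derive from
    female A x male B, so all F1 males are hemizygous A.
    """

    BALANCED = "balanced"
    UNBALANCED = "unbalanced"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    #: 1/3 male + 2/3 female mixture of X-linked quantities.
    OVERALL = "overall"


def check_r(r: float) -> float:
    """Validate a meiotic recombination fraction, r in [0, 1/2]."""
    r = float(r)
    if not math.isfinite(r) or not (0.0 <= r <= 0.5):
        raise ValueError(f"r out of range: recombination fraction must lie in [0, 0.5], got {r}")
    return r


def check_s(s: int, minimum: int = 1, name: str = "s") -> int:
    s = int(s)
    if s < minimum:
        raise ValueError(f"{name} must be >= {minimum}, got {s}")
    return s


@dataclass(frozen=True)
class AlphaDistribution:
    """Distribution of pre-CC progenitor generations for the DO.

    ``weights[k]`` is the proportion of DO progenitors that were pre-CC mice
    at sib-mating generation G2:F_k.  HS is the special case of a point mass
    at k = 1.
    """

    weights: Mapping[int, float]
    _tol: float = field(default=1e-12, repr=False, compare=False)

    def __post_init__(self) -> None:
        w = {int(k): float(v) for k, v in self.weights.items()}
        if not w:
            raise ValueError("alpha distribution must have at least one weight")
        for k, v in w.items():
            if k < 1:
                raise ValueError(f"pre-CC generation k must be >= 1, got {k}")
            if v < 0:
                raise ValueError(f"alpha weights must be non-negative, got alpha_{k} = {v}")
        total = sum(w.values())
        if abs(total - 1.0) > self._tol:
            raise ValueError(f"alpha weights must sum to 1 (got {total})")
        object.__setattr__(self, "weights", dict(sorted(w.items())))

    @classmethod
    def point_mass(cls, k: int) -> "AlphaDistribution":
        return cls({int(k): 1.0})

    @classmethod
    def from_dict(cls, d: Mapping, tol: float = 1e-6) -> "AlphaDistribution":
        """Build from a possibly unnormalised mapping (e.g. parsed JSON).

        The weights must sum to 1 within ``tol``; they are then renormalised
        exactly.
        """
        w = {int(k): float(v) for k, v in d.items()}
        total = sum(w.values())
        if abs(total - 1.0) > tol:
            raise ValueError(f"alpha weights must sum to 1 within {tol} (got {total})")
        return cls({k: v / total for k, v in w.items()})

    def items(self):
        return self.weights.items()

    @property
    def is_hs(self) -> bool:
        return self.weights == {1: 1.0}

    @property
    def max_k(self) -> int:
        return max(self.weights)


def example_alpha() -> AlphaDistribution:
    """An illustrative DO progenitor-generation distribution.

    Uniform over k = 4..8 (mean 6), loosely emulating the spread of pre-CC
    generations among actual DO progenitors.  This is a documented example
    only, not a published distribution; real analyses should supply their
    own weights.
    """
    return AlphaDistribution({k: 0.2 for k in range(4, 9)})


@dataclass(frozen=True)
class ClosedFormCoefficients:
    """Eigen-quantities of the two-generation X-chromosome recurrence.

    The homogeneous part of the male/female X recurrence is the 2x2 matrix
    [[0, 1-r], [1/2, (1-r)/2]], whose eigenvalues are w = (1-r+z)/4 and
    y = (1-r-z)/4 with z = sqrt((1-r)(9-r)).  They satisfy w + y = (1-r)/2
    and w*y = -(1-r)/2.
    """

    z: float
    w: float
    y: float


def closed_form_coefficients(r: float) -> ClosedFormCoefficients:
    r = check_r(r)
    z = math.sqrt((1.0 - r) * (9.0 - r))
    return ClosedFormCoefficients(z=z, w=(1.0 - r + z) / 4.0, y=(1.0 - r - z) / 4.0)


@dataclass(frozen=True)
class HaplotypeFreqTable:
    """Joint distribution over ordered two-locus founder-haplotype pairs.

    ``entries[i, j]`` is the probability that a random chromosome carries
    founder allele ``i`` at locus 1 and ``j`` at locus 2.  For X-linked
    tables ``sex`` records which compartment the table describes.
    """

    entries: np.ndarray
    sex: Sex | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=float)
        if e.ndim != 2 or e.shape[0] != e.shape[1] or e.shape[0] not in (2, 8):
            raise ValueError(f"entries must be a 2x2 or 8x8 matrix, got shape {e.shape}")
        if e.min() < -1e-12:
            raise ValueError(f"negative haplotype probability: {e.min()}")
        total = float(e.sum())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"haplotype probabilities must sum to 1 (got {total})")
        object.__setattr__(self, "entries", np.clip(e, 0.0, None))

    @property
    def n_founders(self) -> int:
        return self.entries.shape[0]

    @property
    def locus1_marginals(self) -> np.ndarray:
        return self.entries.sum(axis=1)

    @property
    def locus2_marginals(self) -> np.ndarray:
        return self.entries.sum(axis=0)

    @property
    def recombinant_mass(self) -> float:
        """Probability that the haplotype is recombinant (off-diagonal mass)."""
        return float(1.0 - np.trace(self.entries))

    @classmethod
    def balanced(cls, n_founders: int, diag: float, sex: Sex | None = None) -> "HaplotypeFreqTable":
        """Exchangeable-founder table: all diagonal entries equal ``diag``,
        all off-diagonal entries equal and sharing the remaining mass."""
        n = int(n_founders)
        off_mass = 1.0 - n * diag
        n_off = n * (n - 1)
        e = np.full((n, n), off_mass / n_off)
        np.fill_diagonal(e, diag)
        return cls(e, sex=sex)


def validate_params(
    design: Design,
    chromosome: Chromosome,
    s: int,
    r: float,
    balance: Balance = Balance.BALANCED,
    alpha: AlphaDistribution | None = None,
) -> tuple[Design, Chromosome, int, float, Balance, AlphaDistribution | None]:
    """Validate a full parameter bundle, returning it unchanged.

    Raises ``ValueError`` naming the violated invariant.
    """
    design = Design(design)
    chromosome = Chromosome(chromosome)
    balance = Balance(balance)
    s = check_s(s)
    r = check_r(r)
    if balance is Balance.UNBALANCED and not (
        design is Design.AIL2 and chromosome is Chromosome.X
    ):
        raise ValueError("unbalanced crosses are only defined for the AIL X chromosome")
    if design is Design.DO8:
        if alpha is None:
            raise ValueError("the DO requires a progenitor-generation distribution alpha")
    elif design is Design.HS8:
        if alpha is None:
            alpha = AlphaDistribution.point_mass(1)
        elif not alpha.is_hs:
            raise ValueError("HS is the DO with alpha concentrated at k = 1")
    elif alpha is not None:
        raise ValueError("alpha is only meaningful for HS/DO designs")
    return design, chromosome, s, r, balance, alpha
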