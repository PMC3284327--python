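"""Two-locus haplotype probabilities for two-way advanced intercross lines.

An AIL starts from two inbred strains A and B; the F1 hybrids are then
randomly mated for many generations.  With an effectively infinite number
of mating pairs, no sex difference in recombination, and no selection or
mutation, the frequency of the intact ``AA`` two-locus haplotype follows
simple linear recurrences:

* autosome:      p_{s+1} = (1-r) p_s + r/4,    p_1 = 1/2
* balanced X:    m_{s+1} = (1-r) f_s + r/4
                 f_{s+1} = m_s/2 + (1-r) f_s/2 + r/8,    m_1 = f_1 = 1/2
* unbalanced X:  as the balanced case, but the r-terms carry the product of
  the sex-specific A-allele frequencies q_{s-1} q_{s-2} because all F1
  males are hemizygous A and allele frequencies differ by sex and
  generation.

The recurrences are the reference implementation; closed forms (obtained by
diagonalising the two-generation recurrence) are a cross-checked fast path.
"""

from __future__ import annotations

import numpy as np

from .core import (
    FEMALE_X_WEIGHT,
    HaplotypeFreqTable,
    Sex,
    check_r,
    check_s,
    closed_form_coefficients,
)

__all__ = [
    "ail_autosome_AA",
    "ail_autosome_recombinant",
    "ail_autosome_table",
    "ail_balancedX_AA",
    "ail_balancedX_recombinant",
    "ail_balancedX_table",
    "unbalanced_allele_freq",
    "ail_unbalancedX_AA",
    "ail_unbalancedX_recombinant",
    "ail_unbalancedX_table",
    "x_pair_closed_form",
]


def _check_method(method: str) -> str:
    if method not in ("recurrence", "closed_form"):
        raise ValueError(f"method must be 'recurrence' or 'closed_form', got {method!r}")
    return method


def ail_autosome_AA(s: int, r: float, method: str = "recurrence") -> float:
    """Frequency p_s of the AA haplotype on an AIL autosome at F_s.

    The closed form p_s = [1 + (1-2r)(1-r)^(s-2)]/4 holds for s >= 2; at
    s = 1 the F1 value 1/2 is returned by either method.

    The recurrence p_{s+1} = (1-r) p_s + r/4 applies from s = 2 onward: its
    r/4 term assumes the transmitting parent's two haplotypes carry
    independent alleles, which is false for F1 hybrids (AA paired with BB),
    so the first meiosis gives p_2 = (1-r)/2 exactly — equivalently the F2
    recombinant fraction equals r.
    """
    s, r = check_s(s), check_r(r)
    _check_method(method)
    if s == 1:
        return 0.5
    if method == "closed_form":
        return 0.25 * (1.0 + (1.0 - 2.0 * r) * (1.0 - r) ** (s - 2))
    p = (1.0 - r) / 2.0  # p_2: a recombinant F1 gamete is never AA
    for _ in range(s - 2):
        p = (1.0 - r) * p + r * 0.25
    return p


def ail_autosome_recombinant(s: int, r: float) -> float:
    """Frequency 1 - 2 p_s of recombinant haplotypes at F_s."""
    return 1.0 - 2.0 * ail_autosome_AA(s, r)


def ail_autosome_table(s: int, r: float) -> HaplotypeFreqTable:
    """2x2 joint haplotype table (AA, AB / BA, BB) on the autosome."""
    return HaplotypeFreqTable.balanced(2, ail_autosome_AA(s, r))


# ---------------------------------------------------------------------------
# X chromosome: shared two-generation linear recurrence machinery
# ---------------------------------------------------------------------------

def _x_recurrence_matrix(r: float) -> np.ndarray:
    return np.array([[0.0, 1.0 - r], [0.5, (1.0 - r) / 2.0]])


def x_pair_closed_form(
    m_a: float,
    f_a: float,
    const: tuple[float, float],
    r: float,
    s: int,
    s_anchor: int = 1,
) -> tuple[float, float]:
    """Closed form for the coupled male/female X recurrence.

    Solves x_{s+1} = T x_s + c for x = (m, f), T = [[0, 1-r],
    [1/2, (1-r)/2]] and constant term ``c``, anchored at
    x_{s_anchor} = (m_a, f_a), by eigendecomposition of T.  The eigenvalues
    are w and y of :func:`closed_form_coefficients`; the solution is
    x_s = x* + A w^(s - s_anchor) + B y^(s - s_anchor) with vector
    coefficients fixed by the anchor.  (The printed closed forms in the
    source derivations are typographically unreliable; re-deriving them
    this way reproduces the recurrence to machine precision.)
    """
    if r == 0.0:
        # T has eigenvalue 1 at r = 0 (no unique fixed point); the exact
        # trajectory is the plain iteration, which costs O(s) only here.
        return _x_recurrence(m_a, f_a, const, r, s - s_anchor)
    cfc = closed_form_coefficients(r)
    T = _x_recurrence_matrix(r)
    c = np.asarray(const, dtype=float)
    xa = np.array([m_a, f_a], dtype=float)
    # fixed point x* = (I - T)^-1 c
    xstar = np.linalg.solve(np.eye(2) - T, c)
    d1 = xa - xstar
    d2 = T @ d1
    w, y = cfc.w, cfc.y
    det = y - w
    A = (y * d1 - d2) / det
    B = (d2 - w * d1) / det
    n = s - s_anchor
    xs = xstar + A * w**n + B * y**n
    return float(xs[0]), float(xs[1])


def _x_recurrence(
    m_a: float, f_a: float, const: tuple[float, float], r: float, n_steps: int
) -> tuple[float, float]:
    m, f = m_a, f_a
    cm, cf = const
    for _ in range(n_steps):
        m, f = (1.0 - r) * f + cm, 0.5 * m + 0.5 * (1.0 - r) * f + cf
    return m, f


def ail_balancedX_AA(s: int, r: float, sex: Sex | str, method: str = "recurrence") -> float:
    """Frequency m_s (males) or f_s (females) of the AA haplotype on the
    X chromosome in a balanced AIL (both reciprocal F1 crosses present).

    As on the autosome, the coupled recurrence applies from s = 2; the
    first meiosis is anchored exactly at m_2 = (1-r)/2 (an F2 male's X is
    a gamete of an F1 female, whose X's are the intact AA and BB) and
    f_2 = (2-r)/4 (average of that gamete and the father's intact X).
    """
    s, r = check_s(s), check_r(r)
    sex = Sex(sex)
    if sex is Sex.OVERALL:
        raise ValueError("per-sex AA frequency requested: sex must be male or female")
    _check_method(method)
    if s == 1:
        return 0.5
    const = (r / 4.0, r / 8.0)
    m2, f2 = (1.0 - r) / 2.0, (2.0 - r) / 4.0
    if method == "closed_form":
        m, f = x_pair_closed_form(m2, f2, const, r, s, s_anchor=2)
    else:
        m, f = _x_recurrence(m2, f2, const, r, s - 2)
    return m if sex is Sex.MALE else f


def ail_balancedX_recombinant(s: int, r: float, sex: Sex | str) -> float:
    """Recombinant-haplotype frequency on the balanced AIL X.

    Per sex this is 1 - 2 m_s or 1 - 2 f_s; ``overall`` weights females
    by 2/3 because two-thirds of X chromosomes reside in females.
    """
    sex = Sex(sex)
    if sex is Sex.OVERALL:
        male = 1.0 - 2.0 * ail_balancedX_AA(s, r, Sex.MALE)
        female = 1.0 - 2.0 * ail_balancedX_AA(s, r, Sex.FEMALE)
        return (1.0 - FEMALE_X_WEIGHT) * male + FEMALE_X_WEIGHT * female
    return 1.0 - 2.0 * ail_balancedX_AA(s, r, sex)


def ail_balancedX_table(s: int, r: float, sex: Sex | str) -> HaplotypeFreqTable:
    sex = Sex(sex)
    if sex is Sex.OVERALL:
        e = (1.0 - FEMALE_X_WEIGHT) * ail_balancedX_table(s, r, Sex.MALE).entries + \
            FEMALE_X_WEIGHT * ail_balancedX_table(s, r, Sex.FEMALE).entries
        return HaplotypeFreqTable(e, sex=sex)
    return HaplotypeFreqTable.balanced(2, ail_balancedX_AA(s, r, sex), sex=sex)


# ---------------------------------------------------------------------------
# Unbalanced AIL X (all F1 from female A x male B)
# ---------------------------------------------------------------------------

def unbalanced_allele_freq(s: int, method: str = "closed_form") -> float:
    """Frequency q_s of the A allele in females at F_s of an unbalanced AIL.

    Males at F_s carry frequency q_{s-1}.  The recurrence is
    q_{s+1} = q_s/2 + q_{s-1}/2 with q_0 = 1, q_1 = 1/2; the closed form is
    q_s = 2/3 + (1/3)(-1/2)^s for s >= 0.  The pre-cross boundary value
    q_{-1} = 0 encodes that the F1 female's paternal X carries no A allele.
    """
    s = check_s(s, minimum=-1)
    _check_method(method)
    if s == -1:
        return 0.0
    if method == "closed_form":
        return 2.0 / 3.0 + (1.0 / 3.0) * (-0.5) ** s
    qprev, q = 1.0, 0.5  # q_0, q_1
    if s == 0:
        return 1.0
    for _ in range(s - 1):
        qprev, q = q, 0.5 * q + 0.5 * qprev
    return q


def ail_unbalancedX_AA(s: int, r: float, sex: Sex | str) -> float:
    """Frequency m'_s (males) or f'_s (females) of the AA haplotype on the
    unbalanced AIL X.  No closed form exists; the recurrence is exact."""
    s, r = check_s(s), check_r(r)
    sex = Sex(sex)
    if sex is Sex.OVERALL:
        raise ValueError("per-sex AA frequency requested: sex must be male or female")
    m, f = 1.0, 0.5  # m'_1, f'_1: all F1 males hemizygous A
    q = unbalanced_allele_freq
    for t in range(1, s):
        # A recombinant gamete from an F_t female joins one allele from her
        # mother's side (A with freq q_{t-1}) and one from her father's
        # (q_{t-2}); at t=1 the paternal X carries no A, hence q_{-1} = 0.
        cross = q(t - 1) * q(t - 2)
        m, f = (1.0 - r) * f + r * cross, 0.5 * m + 0.5 * (1.0 - r) * f + 0.5 * r * cross
    return m if sex is Sex.MALE else f


def ail_unbalancedX_table(s: int, r: float, sex: Sex | str) -> HaplotypeFreqTable:
    """Full 2x2 table on the unbalanced AIL X.

    Both loci share the A-allele frequency q_s in females and q_{s-1} in
    males, so AB = BA = q - AA and BB = 1 - 2q + AA.
    """
    sex = Sex(sex)
    if sex is Sex.OVERALL:
        e = (1.0 - FEMALE_X_WEIGHT) * ail_unbalancedX_table(s, r, Sex.MALE).entries + \
            FEMALE_X_WEIGHT * ail_unbalancedX_table(s, r, Sex.FEMALE).entries
        return HaplotypeFreqTable(e, sex=sex)
    aa = ail_unbalancedX_AA(s, r, sex)
    qa = unbalanced_allele_freq(s if sex is Sex.FEMALE else s - 1)
    ab = qa - aa
    e = np.array([[aa, ab], [ab, 1.0 - 2.0 * qa + aa]])
    return HaplotypeFreqTable(e, sex=sex)


def ail_unbalancedX_recombinant(s: int, r: float, sex: Sex | str) -> float:
    """Recombinant-haplotype frequency on the unbalanced AIL X.

    Unlike the balanced case the A and B labels are not exchangeable, so the
    recombinant mass is 2(q - AA) rather than 1 - 2 AA.
    """
    sex = Sex(sex)
    if sex is Sex.OVERALL:
        male = ail_unbalancedX_recombinant(s, r, Sex.MALE)
        female = ail_unbalancedX_recombinant(s, r, Sex.FEMALE)
        return (1.0 - FEMALE_X_WEIGHT) * male + FEMALE_X_WEIGHT * female
    return ail_unbalancedX_table(s, r, sex).recombinant_mass
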