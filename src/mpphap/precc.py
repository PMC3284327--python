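"""Exact two-locus haplotype frequencies for pre-CC progenitors.

The Collaborative Cross (CC) combines eight inbred founders through a
funnel of two-way, four-way and eight-way crosses, followed by repeated
sibling mating.  "Pre-CC" mice are individuals at intermediate sib-mating
generations G2:F_k (G2:F1 = offspring of the eight-way cross; each further
generation is one round of sib mating).  The DO was founded from such mice,
so their two-locus haplotype frequencies initialise the DO recurrences.

Everything here is computed from first principles by exact propagation of
a lumped Markov chain over sib-pair two-locus genotype configurations:

* autosome: the state is the unordered pair of sib diplotypes, lumped by
  founder-label permutation (all eight founders are exchangeable on the
  autosome under the balanced funnel), individual order and within-
  individual chromosome order.  The lumping is exact because meiosis and
  mating are equivariant under all three symmetries.
* X chromosome: the state is (female maternal X, female paternal X, male X)
  over the five founder roles that an X can descend from in an eight-way
  funnel (the two maternally mixing founders, the intact grand-paternal
  founder, and the two founders feeding the eight-way sire's X).  The
  four-way chain uses the three-role analogue.

Meiosis is the standard two-locus gamete model: each parental haplotype is
transmitted intact with probability (1-r)/2, and each of the two
recombinant combinations arises with probability r/2.

Founder-label balance ("the order of the crosses was random") means the
frequency of the ``AA`` haplotype for any specific founder A equals the
frequency of carrying the *same* founder allele at both loci, divided by 8.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .core import check_r, check_s

__all__ = [
    "precc_autosome_q",
    "precc_x_freqs",
    "precc_x_progenitor_freqs",
    "precc_x_transmitted_AA",
]

Hap = tuple[int, int]
Ind = tuple[Hap, Hap]

# ---------------------------------------------------------------------------
# meiosis and chain steps
# ---------------------------------------------------------------------------


def _gamete_choices(ind: Ind) -> list[tuple[Hap, int]]:
    """The four equally-structured meiotic outcomes of a diplotype.

    Returns (haplotype, n_recombinations); the outcome probability is
    (1-r)/2 when n_rec = 0 and r/2 when n_rec = 1.  Duplicates are kept so
    that every outcome has a pure (1-r)^a r^b probability monomial.
    """
    h1, h2 = ind
    return [(h1, 0), (h2, 0), ((h1[0], h2[1]), 1), ((h2[0], h1[1]), 1)]


def _relabel(flat: tuple[int, ...]) -> tuple[int, ...]:
    mapping: dict[int, int] = {}
    out = []
    for l in flat:
        if l not in mapping:
            mapping[l] = len(mapping)
        out.append(mapping[l])
    return tuple(out)


def _canon_auto(state: tuple[Ind, Ind]) -> tuple[int, ...]:
    """Canonical form of a sib-pair autosome state.

    Minimum over the 8 structural symmetries (swap individuals, swap the
    two chromosomes within each individual) of the first-occurrence
    relabelled flat tuple.  Exact lumping: all are true symmetries of the
    sib-mating dynamics and of the same-label statistic.
    """
    (a, b), (c, d) = state
    best = None
    for i1, i2 in (((a, b), (c, d)), ((c, d), (a, b))):
        for p in (i1, (i1[1], i1[0])):
            for q in (i2, (i2[1], i2[0])):
                flat = _relabel(p[0] + p[1] + q[0] + q[1])
                if best is None or flat < best:
                    best = flat
    return best


def _unflatten_auto(flat: tuple[int, ...]) -> tuple[Ind, Ind]:
    h = [(flat[i], flat[i + 1]) for i in range(0, 8, 2)]
    return ((h[0], h[1]), (h[2], h[3]))


_AUTO_ROWS: dict[tuple[int, ...], dict[tuple[int, ...], np.ndarray]] = {}


def _auto_row(flat: tuple[int, ...]) -> dict[tuple[int, ...], np.ndarray]:
    """Transition row of the autosome sib chain.

    Maps next canonical state -> counts indexed by total number of
    recombinant gametes a in 0..4; the transition probability is
    sum_a counts[a] (1-r)^(4-a) r^a / 16.
    """
    row = _AUTO_ROWS.get(flat)
    if row is not None:
        return row
    mother, father = _unflatten_auto(flat)
    row = {}
    for gm1, a1 in _gamete_choices(mother):
        for gp1, a2 in _gamete_choices(father):
            for gm2, a3 in _gamete_choices(mother):
                for gp2, a4 in _gamete_choices(father):
                    nxt = _canon_auto(((gm1, gp1), (gm2, gp2)))
                    cnt = row.get(nxt)
                    if cnt is None:
                        cnt = row[nxt] = np.zeros(5)
                    cnt[a1 + a2 + a3 + a4] += 1.0
    _AUTO_ROWS[flat] = row
    return row


def _step_auto(dist: dict[tuple[int, ...], float], r: float) -> dict[tuple[int, ...], float]:
    w = np.array([(1.0 - r) ** (4 - a) * r**a / 16.0 for a in range(5)])
    new: dict[tuple[int, ...], float] = {}
    for state, p in dist.items():
        for nxt, cnt in _auto_row(state).items():
            new[nxt] = new.get(nxt, 0.0) + p * float(cnt @ w)
    return new


# X chain: state = (female maternal X, female paternal X, male X); no
# relabelling (specific roles are tracked), states stay few hundred.
XState = tuple[Hap, Hap, Hap]

_X_ROWS: dict[XState, dict[XState, np.ndarray]] = {}


def _x_row(state: XState) -> dict[XState, np.ndarray]:
    row = _X_ROWS.get(state)
    if row is not None:
        return row
    fxm, fxp, mx = state
    row = {}
    for g1, a1 in _gamete_choices((fxm, fxp)):
        for g2, a2 in _gamete_choices((fxm, fxp)):
            # daughter = (maternal gamete, father's X intact); son = gamete
            nxt = (g1, mx, g2)
            cnt = row.get(nxt)
            if cnt is None:
                cnt = row[nxt] = np.zeros(3)
            cnt[a1 + a2] += 1.0
    _X_ROWS[state] = row
    return row


def _step_x(dist: dict[XState, float], r: float) -> dict[XState, float]:
    w = np.array([(1.0 - r) ** (2 - a) * r**a / 4.0 for a in range(3)])
    new: dict[XState, float] = {}
    for state, p in dist.items():
        for nxt, cnt in _x_row(state).items():
            new[nxt] = new.get(nxt, 0.0) + p * float(cnt @ w)
    return new


# ---------------------------------------------------------------------------
# initial distributions
# ---------------------------------------------------------------------------


def _init_auto(r: float) -> dict[tuple[int, ...], float]:
    """Mating pair founding the eight-way sib line ("G2:F0").

    Dam = four-way hybrid of founders 0..3 (diplotype = one gamete from the
    0x1 F1, one from the 2x3 F1); sire = four-way hybrid of founders 4..7.
    One chain step then yields the G2:F1 sib pair, with the sibs correlated
    through their shared parents.
    """
    two_way = [((0, 0), (1, 1)), ((2, 2), (3, 3)), ((4, 4), (5, 5)), ((6, 6), (7, 7))]
    wg = [(1.0 - r) / 2.0, r / 2.0]
    dist: dict[tuple[int, ...], float] = {}
    for g1, a1 in _gamete_choices(two_way[0]):
        for g2, a2 in _gamete_choices(two_way[1]):
            for g3, a3 in _gamete_choices(two_way[2]):
                for g4, a4 in _gamete_choices(two_way[3]):
                    st = _canon_auto(((g1, g2), (g3, g4)))
                    p = wg[a1] * wg[a2] * wg[a3] * wg[a4]
                    dist[st] = dist.get(st, 0.0) + p
    return dist


# X founder roles: 0, 1 = the two founders mixing on the maternal side
# (the dam of the four-way was their F1 daughter); 2 = the founder whose X
# passes intact through the four-way sire; 3, 4 = the founders feeding the
# eight-way sire's X.
def _init_x_8way(r: float) -> dict[XState, float]:
    """Mating pair founding the eight-way sib line, X chromosome.

    Dam = four-way female with X pair (gamete of roles 0/1, intact role 2);
    sire = eight-way-funnel male whose X is a gamete of roles 3/4.
    """
    wg = [(1.0 - r) / 2.0, r / 2.0]
    dist: dict[XState, float] = {}
    for g, a1 in _gamete_choices((((0, 0)), (1, 1))):
        for t, a2 in _gamete_choices(((3, 3), (4, 4))):
            st = (g, (2, 2), t)
            p = wg[a1] * wg[a2]
            dist[st] = dist.get(st, 0.0) + p
    return dist


def _init_x_4way() -> dict[XState, float]:
    """Mating pair founding a four-way sib line, X chromosome.

    Dam = two-way F1 female with intact X's of roles 0 and 1; sire = male
    carrying the intact X of role 2 (his dam was inbred).
    """
    return {((0, 0), (1, 1), (2, 2)): 1.0}


@lru_cache(maxsize=4096)
def _auto_dist(k: int, r: float) -> dict[tuple[int, ...], float]:
    if k == 0:
        return _init_auto(r)
    dist = _auto_dist(k - 1, r)
    return _step_auto(dist, r)


@lru_cache(maxsize=4096)
def _x_dist(which: str, k: int, r: float) -> dict[XState, float]:
    if k == 0:
        return _init_x_8way(r) if which == "8way" else _init_x_4way()
    return _step_x(_x_dist(which, k - 1, r), r)


# ---------------------------------------------------------------------------
# public quantities
# ---------------------------------------------------------------------------


def _same(h: Hap) -> bool:
    return h[0] == h[1]


@lru_cache(maxsize=100_000)
def precc_autosome_q(k: int, r: float) -> float:
    """Frequency q_k of the AA haplotype on the autosome at G2:F_k.

    A pre-CC progenitor at G2:F_k transmits the AA haplotype with frequency
    q_{k+1}.  At r = 0, q_k = 1/8 for every k (intact founder haplotypes).
    """
    k, r = check_s(k, name="k"), check_r(r)
    dist = _auto_dist(k, r)
    acc = 0.0
    for flat, p in dist.items():
        same = sum(flat[i] == flat[i + 1] for i in range(0, 8, 2))
        acc += p * same / 4.0
    return acc / 8.0


def _x_female_role_freqs(dist: dict[XState, float]) -> np.ndarray:
    """freq[role] of the (role, role) haplotype on a random female X."""
    freqs = np.zeros(5)
    for (fxm, fxp, _mx), p in dist.items():
        for h in (fxm, fxp):
            if _same(h):
                freqs[h[0]] += 0.5 * p
    return freqs


@lru_cache(maxsize=100_000)
def precc_x_freqs(k: int, r: float) -> tuple[float, float]:
    """(hAA, hCC) on the female X in four-way sib mating, as consumed for
    pre-CC progenitors at G2:F_k.

    hAA is the frequency of the intact haplotype of either maternally
    mixing founder (they are symmetric); hCC that of the founder whose X
    entered intact through the four-way sire.  k = 1 corresponds to the
    four-way cross offspring: hAA = (1-r)/4, hCC = 1/2.
    """
    k, r = check_s(k, name="k"), check_r(r)
    dist = _x_dist("4way", k, r)
    freqs = _x_female_role_freqs(dist)
    haa = 0.5 * (freqs[0] + freqs[1])
    hcc = freqs[2]
    return haa, hcc


@lru_cache(maxsize=100_000)
def precc_x_progenitor_freqs(k: int, r: float) -> tuple[float, float]:
    """(male, female) frequencies of the AA haplotype on the X *in* pre-CC
    progenitors at G2:F_k of the eight-way funnel, for a specific founder A
    under complete balance of cross orders.

    At k = 1 these equal (2 - 3r + r^2)/16 and (4 - 5r + r^2)/32.
    """
    k, r = check_s(k, name="k"), check_r(r)
    dist = _x_dist("8way", k, r)
    m = 0.0
    f = 0.0
    for (fxm, fxp, mx), p in dist.items():
        if _same(mx):
            m += p
        f += 0.5 * p * (_same(fxm) + _same(fxp))
    return m / 8.0, f / 8.0


@lru_cache(maxsize=100_000)
def precc_x_transmitted_AA(k: int, r: float) -> float:
    """Probability that the X gamete transmitted by a pre-CC female at
    G2:F_k carries the AA haplotype (specific founder A, balanced).

    This is the chance that a DO male at the first outcross generation is
    hemizygous AA when his dam was at G2:F_k.  Note the within-funnel
    recombinant term: the dam's two X's carry founder alleles from the same
    funnel, so a recombinant gamete is AA only when both X's happen to
    carry the same founder at the complementary loci (it is *not* the
    random-mating cross term r/64).
    """
    k, r = check_s(k, name="k"), check_r(r)
    dist = _x_dist("8way", k, r)
    acc = 0.0
    for (fxm, fxp, _mx), p in dist.items():
        same_nr = 0.5 * (_same(fxm) + _same(fxp))
        same_rec = 0.5 * ((fxm[0] == fxp[1]) + (fxp[0] == fxm[1]))
        acc += p * ((1.0 - r) * same_nr + r * same_rec)
    return acc / 8.0
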