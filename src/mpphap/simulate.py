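"""Forward Monte-Carlo simulation of the breeding designs.

An independent brute-force check on every analytic result: populations are
simulated gamete by gamete under the generative assumptions of the theory
(large random-mating populations, no sex difference in recombination, no
selection or mutation, random funnel orders), and two-locus haplotype
tables are estimated by counting.

Meiosis follows the standard two-locus gamete model: the locus-1 allele is
drawn from a uniformly chosen parental chromosome and the locus-2 allele
comes from the same chromosome with probability 1-r, otherwise from the
homologue.

Estimates are pooled over several independent replicate populations, and
standard errors come from the spread of the replicate means.  Within one
finite population, chromosomes share genetic drift, so the plain binomial
standard error understates the sampling variance of frequency estimates
once several generations have elapsed; replicate populations are mutually
independent, making the replicate-based standard error properly
calibrated.  (Finite population size also introduces an O(s/N) inbreeding
bias, far below the standard error at the default sizes.)
"""

from __future__ import annotations

from dataclasses import dataclass

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

__all__ = ["SimResult", "simulate_freqs"]


@dataclass(frozen=True)
class SimResult:
    """Estimated haplotype tables pooled over replicate populations.

    ``tables`` maps sex (or ``None`` for the autosome) to the pooled
    :class:`HaplotypeFreqTable`; ``replicate_entries`` holds the
    per-replicate tables (R, n_founders, n_founders); ``n`` the total
    number of chromosomes counted per sex.
    """

    tables: dict[Sex | None, HaplotypeFreqTable]
    replicate_entries: dict[Sex | None, np.ndarray]
    n: dict[Sex | None, int]
    seed: int

    def table(self, sex: Sex | None = None) -> HaplotypeFreqTable:
        return self.tables[sex]

    @property
    def n_replicates(self) -> int:
        return next(iter(self.replicate_entries.values())).shape[0]

    def diag_mean(self, sex: Sex | None = None) -> float:
        """Balanced estimate of the intact-haplotype (AA) frequency."""
        t = self.tables[sex]
        return float(np.trace(t.entries)) / t.n_founders

    def recombinant(self, sex: Sex | None = None) -> float:
        return self.tables[sex].recombinant_mass

    def _se_of(self, per_replicate: np.ndarray) -> float:
        r = len(per_replicate)
        return float(np.std(per_replicate, ddof=1) / np.sqrt(r))

    def se_diag_mean(self, sex: Sex | None = None) -> float:
        e = self.replicate_entries[sex]
        return self._se_of(np.trace(e, axis1=1, axis2=2) / e.shape[1])

    def se_recombinant(self, sex: Sex | None = None) -> float:
        e = self.replicate_entries[sex]
        return self._se_of(1.0 - np.trace(e, axis1=1, axis2=2))

    def se_entry(self, i: int, j: int, sex: Sex | None = None) -> float:
        return self._se_of(self.replicate_entries[sex][:, i, j])


def _meiosis(h1: np.ndarray, h2: np.ndarray, rng: np.random.Generator, r: float) -> np.ndarray:
    n = h1.shape[0]
    c1 = rng.integers(0, 2, n)
    c2 = c1 ^ (rng.random(n) < r)
    stacked = np.stack([h1, h2], axis=1)
    idx = np.arange(n)
    g = np.empty((n, 2), dtype=h1.dtype)
    g[:, 0] = stacked[idx, c1, 0]
    g[:, 1] = stacked[idx, c2, 1]
    return g


def _count_table(haps: np.ndarray, n_founders: int) -> tuple[np.ndarray, int]:
    flat = haps.reshape(-1, 2)
    idx = flat[:, 0].astype(np.int64) * n_founders + flat[:, 1]
    counts = np.bincount(idx, minlength=n_founders * n_founders).astype(float)
    return counts.reshape(n_founders, n_founders) / len(flat), len(flat)


# ---------------------------------------------------------------------------
# AIL
# ---------------------------------------------------------------------------


def _sim_ail_autosome(s, r, n_gametes, rng):
    n = max(n_gametes // 2, 2)
    pop = np.zeros((n, 2, 2), dtype=np.int8)
    pop[:, 1, :] = 1  # F1: haplotypes AA and BB
    for _ in range(s - 1):
        mothers = rng.integers(0, n, n)
        fathers = rng.integers(0, n, n)
        new = np.empty_like(pop)
        new[:, 0] = _meiosis(pop[mothers, 0], pop[mothers, 1], rng, r)
        new[:, 1] = _meiosis(pop[fathers, 0], pop[fathers, 1], rng, r)
        pop = new
    t, cnt = _count_table(pop, 2)
    return {None: t}, {None: cnt}


def _sim_ail_x(s, r, balance, n_gametes, rng):
    n = max(n_gametes // 3, 2)
    f_xm = np.zeros((n, 2), dtype=np.int8)  # F1 females: (X_A, X_B)
    f_xp = np.ones((n, 2), dtype=np.int8)
    if balance is Balance.UNBALANCED:
        m_x = np.zeros((n, 2), dtype=np.int8)  # all F1 males hemizygous A
    else:
        lab = rng.integers(0, 2, n).astype(np.int8)
        m_x = np.stack([lab, lab], axis=1)
    for _ in range(s - 1):
        mi = rng.integers(0, n, n)
        fi = rng.integers(0, n, n)
        fi2 = rng.integers(0, n, n)
        f_xm, f_xp, m_x = (
            _meiosis(f_xm[fi], f_xp[fi], rng, r),
            m_x[mi],
            _meiosis(f_xm[fi2], f_xp[fi2], rng, r),
        )
    tf, nf = _count_table(np.concatenate([f_xm, f_xp]), 2)
    tm, nm = _count_table(m_x, 2)
    return {Sex.FEMALE: tf, Sex.MALE: tm}, {Sex.FEMALE: nf, Sex.MALE: nm}


# ---------------------------------------------------------------------------
# pre-CC funnels and DO/HS
# ---------------------------------------------------------------------------


def _sim_precc(ks: np.ndarray, r: float, rng: np.random.Generator):
    """Simulate independent eight-way funnels plus sib mating.

    ``ks[i]`` is the target generation G2:F_k for line i.  Returns the
    autosomal diplotypes of the line's final female and male
    (shape (L, 2, 2)) and their X's (female (L, 2, 2), male (L, 2)),
    labelled by funnel role 0..7.
    """
    L = len(ks)

    def const(hap):
        return np.tile(np.array(hap, dtype=np.int8), (L, 1))

    # autosome: dam = four-way hybrid of founders 0..3, sire of 4..7
    dam = np.stack(
        [_meiosis(const((0, 0)), const((1, 1)), rng, r),
         _meiosis(const((2, 2)), const((3, 3)), rng, r)], axis=1)
    sire = np.stack(
        [_meiosis(const((4, 4)), const((5, 5)), rng, r),
         _meiosis(const((6, 6)), const((7, 7)), rng, r)], axis=1)
    # X: dam's X pair = (gamete of founders 0/1, intact founder 2);
    # sire's X = gamete of founders 4/5 (his dam was the 4x5 F1 female)
    dam_x = np.stack([_meiosis(const((0, 0)), const((1, 1)), rng, r), const((2, 2))], axis=1)
    sire_x = _meiosis(const((4, 4)), const((5, 5)), rng, r)

    kmax = int(ks.max())
    out_f = np.empty_like(dam)
    out_m = np.empty_like(sire)
    out_fx = np.empty_like(dam_x)
    out_mx = np.empty_like(sire_x)
    for j in range(1, kmax + 1):
        new_f = np.stack(
            [_meiosis(dam[:, 0], dam[:, 1], rng, r),
             _meiosis(sire[:, 0], sire[:, 1], rng, r)], axis=1)
        new_m = np.stack(
            [_meiosis(dam[:, 0], dam[:, 1], rng, r),
             _meiosis(sire[:, 0], sire[:, 1], rng, r)], axis=1)
        new_fx = np.stack(
            [_meiosis(dam_x[:, 0], dam_x[:, 1], rng, r), sire_x], axis=1)
        new_mx = _meiosis(dam_x[:, 0], dam_x[:, 1], rng, r)
        dam, sire, dam_x, sire_x = new_f, new_m, new_fx, new_mx
        done = ks == j
        if done.any():
            out_f[done] = dam[done]
            out_m[done] = sire[done]
            out_fx[done] = dam_x[done]
            out_mx[done] = sire_x[done]
    return out_f, out_m, out_fx, out_mx


def _apply_perm(haps: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Relabel funnel roles by each line's random founder permutation."""
    line = np.arange(haps.shape[0])
    shape = haps.shape
    flat = haps.reshape(shape[0], -1)
    out = perms[line[:, None], flat]
    return out.reshape(shape).astype(np.int8)


def _sim_do(chromosome, s, r, alpha, n_gametes, rng):
    n = max(n_gametes // (2 if chromosome is Chromosome.AUTOSOME else 3), 2)
    ks_list = np.array(sorted(alpha.weights), dtype=int)
    probs = np.array([alpha.weights[k] for k in ks_list])

    def progenitors(count):
        ks = ks_list[rng.choice(len(ks_list), count, p=probs)]
        pf, pm, pfx, pmx = _sim_precc(ks, r, rng)
        perms = np.argsort(rng.random((count, 8)), axis=1).astype(np.int8)
        return (_apply_perm(pf, perms), _apply_perm(pm, perms),
                _apply_perm(pfx, perms), _apply_perm(pmx, perms))

    if chromosome is Chromosome.AUTOSOME:
        dam_f, _, _, _ = progenitors(n)
        _, sire_m, _, _ = progenitors(n)
        pop = np.empty((n, 2, 2), dtype=np.int8)
        pop[:, 0] = _meiosis(dam_f[:, 0], dam_f[:, 1], rng, r)
        pop[:, 1] = _meiosis(sire_m[:, 0], sire_m[:, 1], rng, r)
        for _ in range(s - 1):
            mothers = rng.integers(0, n, n)
            fathers = rng.integers(0, n, n)
            new = np.empty_like(pop)
            new[:, 0] = _meiosis(pop[mothers, 0], pop[mothers, 1], rng, r)
            new[:, 1] = _meiosis(pop[fathers, 0], pop[fathers, 1], rng, r)
            pop = new
        t, cnt = _count_table(pop, 8)
        return {None: t}, {None: cnt}

    # X: females need a dam line and a sire line; males a dam line only.
    _, _, dam_fx, _ = progenitors(n)
    _, _, _, sire_mx = progenitors(n)
    f_xm = _meiosis(dam_fx[:, 0], dam_fx[:, 1], rng, r)
    f_xp = sire_mx
    _, _, dam_fx2, _ = progenitors(n)
    m_x = _meiosis(dam_fx2[:, 0], dam_fx2[:, 1], rng, r)
    for _ in range(s - 1):
        mi = rng.integers(0, n, n)
        fi = rng.integers(0, n, n)
        fi2 = rng.integers(0, n, n)
        f_xm, f_xp, m_x = (
            _meiosis(f_xm[fi], f_xp[fi], rng, r),
            m_x[mi],
            _meiosis(f_xm[fi2], f_xp[fi2], rng, r),
        )
    tf, nf = _count_table(np.concatenate([f_xm, f_xp]), 8)
    tm, nm = _count_table(m_x, 8)
    return {Sex.FEMALE: tf, Sex.MALE: tm}, {Sex.FEMALE: nf, Sex.MALE: nm}


def simulate_freqs(
    design: Design | str,
    chromosome: Chromosome | str,
    s: int,
    r: float,
    balance: Balance | str = Balance.BALANCED,
    alpha: AlphaDistribution | None = None,
    n_gametes: int = 200_000,
    n_replicates: int = 16,
    seed: int = 0,
) -> SimResult:
    """Estimate two-locus haplotype tables by forward simulation.

    ``n_gametes`` chromosomes are counted in total, split over
    ``n_replicates`` independent replicate populations; standard errors
    come from the replicate spread.  Reproducible given ``seed``: each
    replicate draws its stream from a spawned
    :class:`numpy.random.SeedSequence`, so results do not depend on
    evaluation order elsewhere.
    """
    design, chromosome, s, r, balance, alpha = validate_params(
        design, chromosome, s, r, balance, alpha
    )
    if n_gametes < 1000:
        raise ValueError("n_gametes must be at least 1000")
    if n_replicates < 2 or n_gametes // n_replicates < 500:
        raise ValueError("need at least 2 replicates of at least 500 gametes each")
    per_rep = n_gametes // n_replicates
    streams = np.random.SeedSequence(int(seed)).spawn(n_replicates)
    rep_tables: dict[Sex | None, list[np.ndarray]] = {}
    counts: dict[Sex | None, int] = {}
    for ss in streams:
        rng = np.random.default_rng(ss)
        if design is Design.AIL2:
            if chromosome is Chromosome.AUTOSOME:
                raw, cnt = _sim_ail_autosome(s, r, per_rep, rng)
            else:
                raw, cnt = _sim_ail_x(s, r, balance, per_rep, rng)
        else:
            raw, cnt = _sim_do(chromosome, s, r, alpha, per_rep, rng)
        for sex, t in raw.items():
            rep_tables.setdefault(sex, []).append(t)
            counts[sex] = counts.get(sex, 0) + cnt[sex]
    replicate_entries = {sex: np.stack(ts) for sex, ts in rep_tables.items()}
    tables = {
        sex: HaplotypeFreqTable(e.mean(axis=0) / e.mean(axis=0).sum(), sex=sex)
        for sex, e in replicate_entries.items()
    }
    return SimResult(
        tables=tables,
        replicate_entries=replicate_entries,
        n=counts,
        seed=int(seed),
    )
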