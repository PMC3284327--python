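"""DO and HS haplotype probabilities, autosome and X."""

import numpy as np
import pytest

from mpphap import (
    AlphaDistribution,
    Sex,
    do_autosome_AA,
    do_autosome_table,
    do_p1,
    do_recombinant,
    do_x_AA,
    do_x_init,
    do_x_recombinant,
    do_x_table,
    haplotype_table,
    map_expansion_closed,
    map_expansion_numeric,
    precc_autosome_q,
)

R_GRID = [0.0, 0.01, 0.05, 0.1, 0.2, 0.35, 0.5]


class TestAutosome:
    def test_p1_no_recombination(self, do_alpha):
        assert do_autosome_AA(1, 0.0, do_alpha) == pytest.approx(0.125, abs=1e-12)

    def test_hs_p1_is_q2(self, hs):
        for r in R_GRID:
            assert do_p1(hs, r) == pytest.approx(precc_autosome_q(2, r), abs=1e-15)

    def test_hs_s10_recombinant_rounds_to_0103(self, hs):
        assert round(do_recombinant(10, 0.01, hs), 3) == 0.103

    def test_stationary_limit(self, skewed_alpha):
        assert do_autosome_AA(2000, 0.25, skewed_alpha) == pytest.approx(
            1.0 / 64.0, abs=1e-12
        )

    def test_closed_form_matches_recurrence(self, hs, do_alpha):
        for alpha in (hs, do_alpha):
            for s in range(1, 41):
                for r in R_GRID:
                    assert do_autosome_AA(s, r, alpha, "closed_form") == pytest.approx(
                        do_autosome_AA(s, r, alpha, "recurrence"), abs=1e-14
                    )

    def test_table_uniform_off_diagonal(self, hs):
        t = do_autosome_table(10, 0.01, hs)
        p10 = do_autosome_AA(10, 0.01, hs)
        assert np.allclose(np.diag(t.entries), p10, atol=1e-15)
        off = t.entries[~np.eye(8, dtype=bool)]
        assert np.allclose(off, (1 - 8 * p10) / 56, atol=1e-15)
        t0 = do_autosome_table(1, 0.0, hs)
        assert np.allclose(t0.entries, np.eye(8) / 8, atol=1e-15)

    def test_recombinant_monotone(self, do_alpha):
        vals = [do_recombinant(s, 0.05, do_alpha) for s in range(1, 15)]
        assert all(b >= a - 1e-13 for a, b in zip(vals, vals[1:]))
        vals = [do_recombinant(5, r, do_alpha) for r in R_GRID]
        assert all(b >= a - 1e-13 for a, b in zip(vals, vals[1:]))
        assert do_recombinant(3, 0.0, do_alpha) == pytest.approx(0.0, abs=1e-15)


class TestX:
    def test_init_no_recombination(self, hs, do_alpha):
        for alpha in (hs, do_alpha):
            m1, f1 = do_x_init(alpha, 0.0)
            assert m1 == pytest.approx(0.125, abs=1e-12)
            assert f1 == pytest.approx(0.125, abs=1e-12)

    @pytest.mark.parametrize("r", [0.05, 0.1, 0.3])
    def test_hs_init_first_principles_values(self, hs, r):
        """First outcross generation: m_1 = (1-r)^2 (4-r)/32 (gamete of a
        G2:F1 dam) and f_1 = (1-r)(8-7r+r^2)/64 (that gamete averaged with
        the sire's intact X).  Verified independently by forward
        simulation; see docs/methods.md for the relation to the
        progenitor-generation forms."""
        m1, f1 = do_x_init(hs, r)
        assert m1 == pytest.approx((1 - r) ** 2 * (4 - r) / 32, abs=1e-13)
        assert f1 == pytest.approx((1 - r) * (8 - 7 * r + r**2) / 64, abs=1e-13)

    def test_s1_female_equals_init(self, do_alpha):
        m1, f1 = do_x_init(do_alpha, 0.1)
        assert do_x_AA(1, 0.1, do_alpha, Sex.FEMALE) == pytest.approx(f1, abs=1e-15)
        assert do_x_AA(1, 0.1, do_alpha, Sex.MALE) == pytest.approx(m1, abs=1e-15)

    def test_one_recurrence_step(self, hs):
        r = 0.1
        m1, f1 = do_x_init(hs, r)
        assert do_x_AA(2, r, hs, Sex.MALE) == pytest.approx(
            (1 - r) * f1 + r / 64, abs=1e-15
        )
        assert do_x_AA(2, r, hs, Sex.FEMALE) == pytest.approx(
            m1 / 2 + (1 - r) * f1 / 2 + r / 128, abs=1e-15
        )

    def test_stationary_fixed_point(self, do_alpha):
        """The fixed point of the X recurrence is m = f = 1/64 for every
        r > 0."""
        for r in (0.05, 0.2, 0.5):
            for sex in (Sex.MALE, Sex.FEMALE):
                assert do_x_AA(1500, r, do_alpha, sex) == pytest.approx(
                    1.0 / 64.0, abs=1e-10
                )
            m = f = 1.0 / 64.0
            assert (1 - r) * f + r / 64 == pytest.approx(m, abs=1e-15)
            assert m / 2 + (1 - r) * f / 2 + r / 128 == pytest.approx(f, abs=1e-15)

    def test_closed_form_matches_recurrence(self, hs, do_alpha):
        for alpha in (hs, do_alpha):
            for s in range(1, 41):
                for r in R_GRID:
                    for sex in (Sex.MALE, Sex.FEMALE):
                        assert do_x_AA(s, r, alpha, sex, "closed_form") == pytest.approx(
                            do_x_AA(s, r, alpha, sex, "recurrence"), abs=1e-12
                        )

    def test_recombinant_eightfold_symmetry_and_overall(self, do_alpha):
        s, r = 4, 0.15
        male = do_x_recombinant(s, r, do_alpha, Sex.MALE)
        assert male == pytest.approx(1 - 8 * do_x_AA(s, r, do_alpha, Sex.MALE), abs=1e-15)
        assert male == pytest.approx(
            do_x_table(s, r, do_alpha, Sex.MALE).recombinant_mass, abs=1e-12
        )
        overall = do_x_recombinant(s, r, do_alpha, Sex.OVERALL)
        female = do_x_recombinant(s, r, do_alpha, Sex.FEMALE)
        assert overall == pytest.approx(male / 3 + 2 * female / 3, abs=1e-15)

    @pytest.mark.parametrize("s", [1, 5, 10])
    def test_x_map_expansion_is_two_thirds_of_autosome(self, hs, s):
        """The overall X map expansion equals 2/3 of the autosomal HS value
        (7s+17)/8 at every generation."""
        num = map_expansion_numeric(lambda r: do_x_recombinant(s, r, hs, Sex.OVERALL))
        assert num == pytest.approx(2.0 / 3.0 * (7 * s + 17) / 8, abs=1e-4)


class TestHsDoIdentity:
    """HS must be identical to the DO with alpha concentrated at k = 1
    through the public dispatch API, at machine precision."""

    def test_tables_identical(self):
        point = AlphaDistribution.point_mass(1)
        for s, r in ((1, 0.0), (3, 0.1), (10, 0.01)):
            a = haplotype_table("hs", "A", s, r)
            b = haplotype_table("do", "A", s, r, alpha=point)
            assert np.array_equal(a.entries, b.entries)
            for sex in (Sex.MALE, Sex.FEMALE):
                ax = haplotype_table("hs", "X", s, r, sex=sex)
                bx = haplotype_table("do", "X", s, r, sex=sex, alpha=point)
                assert np.array_equal(ax.entries, bx.entries)

    def test_map_expansion_identical(self):
        point = AlphaDistribution.point_mass(1)
        for s in (1, 5, 10):
            hs_val = map_expansion_closed("hs", "A", s)
            do_val = map_expansion_closed("do", "A", s, alpha=point)
            assert do_val == pytest.approx(hs_val, abs=1e-4)
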