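"""Two-way AIL haplotype probabilities: autosome, balanced X, unbalanced X."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpphap import (
    Sex,
    ail_autosome_AA,
    ail_autosome_recombinant,
    ail_balancedX_AA,
    ail_balancedX_recombinant,
    ail_balancedX_table,
    ail_unbalancedX_AA,
    ail_unbalancedX_recombinant,
    ail_unbalancedX_table,
    unbalanced_allele_freq,
)

R_GRID = np.arange(0.0, 0.51, 0.01).tolist()


class TestAutosome:
    @pytest.mark.parametrize(
        "s,r,expected",
        [
            (5, 0.0, 0.5),  # no recombination preserves parental haplotypes
            (1, 0.3, 0.5),
            (2, 0.1, 0.45),  # one meiosis from the F1: p_2 = (1-r)/2
            # eleven iterations of the recurrence, cross-checked against the
            # closed form [1 + (1-2r)(1-r)^10]/4
            (12, 0.01, 0.4715736083771571),
        ],
    )
    def test_AA_values(self, s, r, expected):
        assert ail_autosome_AA(s, r) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("r", R_GRID)
    def test_f2_recombinant_fraction_equals_r(self, r):
        """An F2 gamete is one meiosis from the F1, so the recombinant
        fraction at s = 2 is exactly r."""
        assert ail_autosome_recombinant(2, r) == pytest.approx(r, abs=1e-15)

    def test_recombinant_limits(self):
        assert ail_autosome_recombinant(12, 0.0) == 0.0
        assert ail_autosome_recombinant(500, 0.25) == pytest.approx(0.5, abs=1e-12)

    def test_closed_form_matches_recurrence_on_grid(self):
        for s in range(2, 51):
            for r in R_GRID:
                assert ail_autosome_AA(s, r, "closed_form") == pytest.approx(
                    ail_autosome_AA(s, r, "recurrence"), abs=1e-12
                )

    @settings(derandomize=True, max_examples=60)
    @given(
        s=st.integers(min_value=1, max_value=60),
        r=st.floats(min_value=0.0, max_value=0.5),
    )
    def test_bounds_and_monotonicity(self, s, r):
        p = ail_autosome_AA(s, r)
        assert 0.25 - 1e-12 <= p <= 0.5 + 1e-12
        assert ail_autosome_recombinant(s + 1, r) >= ail_autosome_recombinant(s, r) - 1e-12


class TestBalancedX:
    def test_no_recombination(self):
        assert ail_balancedX_AA(3, 0.0, Sex.FEMALE) == pytest.approx(0.5, abs=1e-15)

    @pytest.mark.parametrize("r", [0.0, 0.1, 0.3, 0.5])
    def test_first_meiosis_anchor(self, r):
        """m_2 = (1-r)/2: an F2 male's X is a gamete of an F1 female whose
        X's are the intact AA and BB, so a recombinant gamete is never AA.
        f_2 = (2-r)/4 adds the father's intact X."""
        assert ail_balancedX_AA(2, r, Sex.MALE) == pytest.approx((1 - r) / 2, abs=1e-15)
        assert ail_balancedX_AA(2, r, Sex.FEMALE) == pytest.approx((2 - r) / 4, abs=1e-15)

    def test_recombinant_overall_weighting(self):
        s, r = 7, 0.12
        male = ail_balancedX_recombinant(s, r, Sex.MALE)
        female = ail_balancedX_recombinant(s, r, Sex.FEMALE)
        overall = ail_balancedX_recombinant(s, r, Sex.OVERALL)
        assert overall == pytest.approx(male / 3 + 2 * female / 3, abs=1e-15)
        assert ail_balancedX_recombinant(s, 0.0, Sex.OVERALL) == 0.0

    def test_closed_form_matches_recurrence_on_grid(self):
        for s in range(2, 51):
            for r in R_GRID:
                for sex in (Sex.MALE, Sex.FEMALE):
                    assert ail_balancedX_AA(s, r, sex, "closed_form") == pytest.approx(
                        ail_balancedX_AA(s, r, sex, "recurrence"), abs=1e-12
                    )

    @pytest.mark.parametrize("sex", [Sex.MALE, Sex.FEMALE])
    def test_limit_one_quarter(self, sex):
        assert ail_balancedX_AA(1000, 0.1, sex) == pytest.approx(0.25, abs=1e-10)

    def test_table_label_exchange_symmetry(self):
        t = ail_balancedX_table(6, 0.2, Sex.FEMALE)
        e = t.entries
        assert e[0, 0] == pytest.approx(e[1, 1], abs=1e-15)
        assert e[0, 1] == pytest.approx(e[1, 0], abs=1e-15)


class TestUnbalancedX:
    @pytest.mark.parametrize(
        "s,expected", [(-1, 0.0), (0, 1.0), (1, 0.5), (2, 0.75), (40, 2.0 / 3.0)]
    )
    def test_allele_freq_values(self, s, expected):
        assert unbalanced_allele_freq(s) == pytest.approx(expected, abs=1e-9)

    def test_allele_freq_closed_equals_recurrence(self):
        for s in range(0, 60):
            assert unbalanced_allele_freq(s, "closed_form") == pytest.approx(
                unbalanced_allele_freq(s, "recurrence"), abs=1e-14
            )

    def test_f1_males_hemizygous_A(self):
        assert ail_unbalancedX_AA(1, 0.3, Sex.MALE) == 1.0

    @pytest.mark.parametrize("r", [0.0, 0.2, 0.5])
    def test_first_meiosis_exact(self, r):
        """m'_2 = (1-r)/2: the F1 female's haplotypes are AA and BB, so her
        non-recombinant AA gamete has probability (1-r)/2 and recombinant
        gametes are never AA (q_{-1} = 0)."""
        assert ail_unbalancedX_AA(2, r, Sex.MALE) == pytest.approx((1 - r) / 2, abs=1e-15)

    @pytest.mark.parametrize("sex", [Sex.MALE, Sex.FEMALE])
    def test_limit_four_ninths(self, sex):
        assert ail_unbalancedX_AA(1000, 0.1, sex) == pytest.approx(4.0 / 9.0, abs=1e-10)

    def test_tables(self):
        t = ail_unbalancedX_table(1, 0.37, Sex.FEMALE)
        assert np.allclose(t.entries, [[0.5, 0.0], [0.0, 0.5]], atol=1e-15)
        t = ail_unbalancedX_table(1, 0.37, Sex.MALE)
        assert np.allclose(t.entries, [[1.0, 0.0], [0.0, 0.0]], atol=1e-15)
        t = ail_unbalancedX_table(2, 0.2, Sex.MALE)
        assert np.allclose(t.entries, [[0.4, 0.1], [0.1, 0.4]], atol=1e-15)

    @settings(derandomize=True, max_examples=60)
    @given(
        s=st.integers(min_value=1, max_value=40),
        r=st.floats(min_value=0.0, max_value=0.5),
        sex=st.sampled_from([Sex.MALE, Sex.FEMALE]),
    )
    def test_table_marginals_equal_allele_freqs(self, s, r, sex):
        """Row and column marginals of every table equal the sex-specific
        A/B allele frequencies (q_s in females, q_{s-1} in males)."""
        t = ail_unbalancedX_table(s, r, sex)
        q = unbalanced_allele_freq(s if sex is Sex.FEMALE else s - 1)
        assert np.allclose(t.locus1_marginals, [q, 1 - q], atol=1e-12)
        assert np.allclose(t.locus2_marginals, [q, 1 - q], atol=1e-12)

    def test_overall_recombinant_weighting(self):
        s, r = 9, 0.23
        overall = ail_unbalancedX_recombinant(s, r, Sex.OVERALL)
        expected = (
            ail_unbalancedX_recombinant(s, r, Sex.MALE) / 3
            + 2 * ail_unbalancedX_recombinant(s, r, Sex.FEMALE) / 3
        )
        assert overall == pytest.approx(expected, abs=1e-15)
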