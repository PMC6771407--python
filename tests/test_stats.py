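"""Exact 2x2 tests against independent oracles, Bonferroni families and
fold elevations."""

from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from hacscreen.simulate import simulate_mn_counts
from hacscreen.stats import (
    ContingencyTable,
    bonferroni_family,
    compare_foci_fractions,
    fisher_exact,
    fold_elevation,
    mn_test_report,
)


def oracle_two_sided(a, b, c, d):
    """Brute-force minimum-likelihood two-sided p by enumerating every
    table with the observed margins, using only integer combinatorics."""
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    denom = comb(n, col1)
    probs = {}
    for k in range(max(0, col1 - row2), min(row1, col1) + 1):
        probs[k] = comb(row1, k) * comb(row2, col1 - k) / denom
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))


class TestFisherExact:
    def test_balanced_table_p_one(self):
        assert fisher_exact(ContingencyTable(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_worked_example(self):
        # full enumeration of margins (4, 4 | 4, 4) gives 0.4857...
        p = fisher_exact(ContingencyTable(3, 1, 1, 3))
        assert p == pytest.approx(oracle_two_sided(3, 1, 1, 3), abs=1e-12)
        assert p == pytest.approx(0.485714285714, abs=1e-9)

    def test_extreme_table(self):
        p = fisher_exact(ContingencyTable(0, 10, 10, 0))
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)
        assert p < 2e-4

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 30, 4)
            if a + b == 0 or c + d == 0:
                continue
            ours = fisher_exact(ContingencyTable(int(a), int(b), int(c), int(d)))
            ref = scipy.stats.fisher_exact([[a, b], [c, d]]).pvalue
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_one_sided_is_upper_tail(self):
        table = ContingencyTable(8, 2, 2, 8)
        ref = scipy.stats.fisher_exact([[8, 2], [2, 8]], alternative="greater")
        assert fisher_exact(table, "one_sided") == pytest.approx(
            ref.pvalue, rel=1e-9
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    def test_invariant_under_simultaneous_row_and_column_swap(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        p1 = fisher_exact(ContingencyTable(a, b, c, d))
        p2 = fisher_exact(ContingencyTable(d, c, b, a))
        assert p1 == pytest.approx(p2, rel=1e-9, abs=1e-12)

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 5, 5)


class TestBonferroni:
    def test_family_of_one_is_identity(self):
        (res,) = bonferroni_family([0.04], alpha=0.05)
        assert res.adjusted_alpha == pytest.approx(0.05)
        assert res.significant

    def test_family_of_45_matches_printed_level(self):
        results = bonferroni_family([0.001] * 45, alpha=0.05)
        assert results[0].adjusted_alpha == pytest.approx(0.05 / 45, abs=1e-9)
        assert results[0].adjusted_alpha == pytest.approx(0.00111, abs=1e-5)
        assert all(r.significant for r in results)  # 0.001 < 0.00111

    def test_significance_non_increasing_as_family_grows(self):
        """A fixed set of p-values can only lose significance as padding
        comparisons enlarge the family."""
        core = [0.001, 0.01, 0.03, 0.2]
        prev = None
        for m_extra in (0, 4, 16, 60):
            family = core + [0.99] * m_extra
            sig = {
                i for i, r in enumerate(bonferroni_family(family, 0.05)[:4])
                if r.significant
            }
            if prev is not None:
                assert sig <= prev
            prev = sig

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_family([])

    def test_null_calibration(self):
        """Under equal binomial rates the familywise false-positive rate at
        the adjusted level stays at or below alpha (+3 SE)."""
        rng = np.random.default_rng(7)
        alpha, m, n_fam = 0.05, 5, 2000
        n_false = 0
        for i in range(n_fam):
            p_values = []
            for j in range(m):
                a = int(rng.binomial(200, 0.05))
                c = int(rng.binomial(200, 0.05))
                p_values.append(
                    fisher_exact(ContingencyTable(a, 200 - a, c, 200 - c))
                )
            results = bonferroni_family(p_values, alpha=alpha)
            n_false += any(r.significant for r in results)
        rate = n_false / n_fam
        se = np.sqrt(alpha * (1 - alpha) / n_fam)
        assert rate <= alpha + 3 * se


class TestFoldElevation:
    def test_equal_rates_fold_one(self):
        assert fold_elevation(0.05, 0.05) == pytest.approx(1.0)

    def test_nineteen_fold(self):
        assert fold_elevation(0.19, 0.01) == pytest.approx(19.0)

    def test_table_form(self):
        t = ContingencyTable(19, 81, 1, 99)
        assert fold_elevation(t) == pytest.approx(19.0)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError, match="absolute rates"):
            fold_elevation(0.19, 0.0)


class TestFociComparison:
    def test_elevated_fraction_significant(self):
        # 20% focus-positive vs <3% in control, 100 cells each
        res = compare_foci_fractions((20, 80), (3, 97))
        assert res.p_value < 0.05 and res.significant
        assert res.fold_elevation == pytest.approx(20 / 3, rel=1e-9)

    def test_identical_tables_p_one(self):
        res = compare_foci_fractions((10, 90), (10, 90))
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_equal_rates_at_mitosis_sample_size_not_significant(self):
        # ~150 mitotic events per condition with equal abnormality rates
        res = compare_foci_fractions((15, 135), (15, 135))
        assert not res.significant


class TestMnReport:
    def test_family_report(self):
        counts = pd.DataFrame(
            {
                "condition": ["control", "PINK1", "BUB1B"],
                "n_scored": [1000, 1000, 1000],
                "n_mni_cells": [10, 120, 300],
                "n_npb_cells": [10, 190, 80],
            }
        )
        report = mn_test_report(counts, "control", alpha=0.05)
        assert len(report) == 4  # 2 conditions x 2 endpoints
        assert (report["m"] == 4).all()
        assert np.allclose(report["adjusted_alpha"], 0.0125)
        pink_npb = report.query(
            "condition == 'PINK1' and endpoint == 'n_npb_cells'"
        ).iloc[0]
        assert pink_npb["fold_elevation"] == pytest.approx(19.0)
        assert pink_npb["significant"]

    def test_simulated_fold_recovered(self):
        with_ev, without = simulate_mn_counts(4000, 0.01, 19, seed=0)
        ctrl_with, ctrl_without = simulate_mn_counts(4000, 0.01, 1, seed=1)
        fold = fold_elevation(
            with_ev / 4000, ctrl_with / 4000
        )
        assert fold == pytest.approx(19.0, rel=0.35)  # binomial noise at n=4000
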