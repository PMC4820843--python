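"""Dual differential-expression statistic and its component tests.

The exact tests are checked against independent brute-force enumeration:
the Wilcoxon p against all C(n1+n2, n1) group assignments of the pooled
sample, and the Fisher p against the full hypergeometric distribution over
same-margin tables computed from binomial coefficients.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hscbias import (
    CountsMatrix,
    ExpressionMatrix,
    bh_adjust,
    detection_calls,
    differential_expression,
    fisher_combine,
    fisher_exact_2x2,
    significance_threshold,
    wilcoxon_level_test,
)


def brute_wilcoxon_p(x, y):
    """Two-sided rank-sum p by enumerating every group assignment."""
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1
    n1 = len(x)
    obs = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2
    stats = [
        sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), n1)
    ]
    extreme = sum(abs(s - mean) >= abs(obs - mean) - 1e-9 for s in stats)
    return extreme / len(stats)


def brute_fisher_p(a, b, c, d):
    """Two-sided Fisher p from the full hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    p_obs = math.comb(r1, a) * math.comb(r2, c) / denom
    total = 0.0
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = math.comb(r1, aa) * math.comb(r2, c1 - aa) / denom
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


class TestWilcoxon:
    def test_exact_nonoverlapping(self):
        # x entirely below y: only 2 of the 20 assignments are as extreme
        assert wilcoxon_level_test([1, 2, 3], [4, 5, 6]) == pytest.approx(2 / 20)

    def test_identical_samples_p_one(self):
        assert wilcoxon_level_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    @pytest.mark.parametrize("n1,n2", [(2, 3), (4, 4), (5, 3), (8, 8), (1, 6)])
    def test_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            assert wilcoxon_level_test(x, y) == pytest.approx(
                brute_wilcoxon_p(x, y), abs=1e-10
            )

    def test_exact_and_asymptotic_agree(self):
        """Normal approximation close to enumeration for n=8/8 samples.

        Measured over tie-free 8/8 draws: mean gap ~0.016, worst case
        ~0.043 (largest in the small-p tail); the bounds assert that
        envelope."""
        import scipy.stats

        rng = np.random.default_rng(42)
        gaps = []
        for _ in range(10):
            x, y = rng.normal(size=8), rng.normal(0.5, 1, size=8)
            exact = brute_wilcoxon_p(x, y)
            asym = scipy.stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=False
            ).pvalue
            gaps.append(abs(asym - exact))
        assert max(gaps) < 0.05
        assert np.mean(gaps) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_level_test([], [1.0])


class TestFisherExact:
    def test_degenerate_margins(self):
        assert fisher_exact_2x2(0, 5, 0, 5) == 1.0
        assert fisher_exact_2x2(0, 0, 0, 0) == 1.0

    def test_perfect_separation(self):
        assert fisher_exact_2x2(5, 0, 0, 5) == pytest.approx(2 / math.comb(10, 5))

    def test_small_table_oracle(self):
        assert fisher_exact_2x2(3, 2, 1, 4) == pytest.approx(
            brute_fisher_p(3, 2, 1, 4), rel=1e-7
        )

    def test_all_tables_up_to_margin_eight(self):
        """Exhaustive agreement with enumeration for every table with row sums <= 8."""
        for r1 in range(9):
            for r2 in range(9):
                if r1 + r2 == 0:
                    continue
                for a in range(r1 + 1):
                    for c in range(r2 + 1):
                        got = fisher_exact_2x2(a, r1 - a, c, r2 - c)
                        want = brute_fisher_p(a, r1 - a, c, r2 - c)
                        assert got == pytest.approx(want, rel=1e-7, abs=1e-12)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fisher_exact_2x2(-1, 2, 3, 4)


class TestFisherCombine:
    def test_ones_combine_to_one(self):
        assert fisher_combine(1.0, 1.0) == 1.0

    def test_closed_form(self):
        x = -2 * (math.log(0.05) + math.log(0.05))
        want = math.exp(-x / 2) * (1 + x / 2)
        assert fisher_combine(0.05, 0.05) == pytest.approx(want, abs=1e-15)
        assert fisher_combine(0.05, 0.05) == pytest.approx(0.017479, abs=5e-7)

    def test_combining_with_one_gives_p_times_one_minus_log(self):
        for p in (0.01, 0.3, 0.9):
            assert fisher_combine(p, 1.0) == pytest.approx(p * (1 - math.log(p)), rel=1e-12)
        assert fisher_combine(0.01, 1.0) == pytest.approx(0.0561, abs=5e-5)

    def test_matches_scipy(self):
        import scipy.stats

        for pl, pf in [(0.03, 0.2), (0.5, 0.5), (1e-10, 0.9)]:
            ref = scipy.stats.combine_pvalues([pl, pf], method="fisher")[1]
            assert fisher_combine(pl, pf) == pytest.approx(ref, rel=1e-9)

    def test_zero_clamped(self):
        assert 0.0 < fisher_combine(0.0, 0.5) < 1e-250

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            fisher_combine(1.5, 0.5)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_stepwise_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(13)
        p = rng.uniform(size=200)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), ref, rtol=1e-12)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_permutation_equivariance(self, ps):
        p = np.array(ps)
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), atol=1e-12)


class TestDetectionCalls:
    def test_zero_gene_zero_frequency(self, tiny_counts):
        from hscbias import cpm_normalize

        cpm = cpm_normalize(tiny_counts)
        det = detection_calls(cpm)
        assert det[0].tolist() == [False, True, True, True]

    def test_higher_threshold_is_subset(self, tiny_counts):
        from hscbias import cpm_normalize

        cpm = cpm_normalize(tiny_counts)
        low, high = detection_calls(cpm, 0.0), detection_calls(cpm, 100_000.0)
        assert np.all(low | ~high)


@pytest.fixture(scope="module")
def simulated():
    from hscbias import SimulationConfig, simulate_counts

    cfg = SimulationConfig(
        seed=11, n_genes=300, n_program_genes=30, n_cells_per_group=40,
        freq_effect=0.4, level_effect=4.0,
    )
    return simulate_counts(cfg)


class TestDifferentialExpression:
    def test_label_swap_symmetry(self, simulated):
        cm, _ = simulated
        fwd = differential_expression(cm, group_a="young", group_b="old")
        rev = differential_expression(cm, group_a="old", group_b="young")
        for a, b in zip(fwd, rev):
            assert a.p_level == pytest.approx(b.p_level, rel=1e-9)
            assert a.p_freq == pytest.approx(b.p_freq, rel=1e-9)
            assert a.fold_regulation == pytest.approx(-b.fold_regulation, rel=1e-9)

    def test_program_genes_recovered(self, simulated):
        cm, truth = simulated
        records = differential_expression(cm)
        sig = {r.gene_id for r in records if r.significant}
        program = set(truth[truth.is_program].gene_id)
        assert len(program & sig) / len(program) >= 0.9

    def test_rare_gene_level_p_is_one(self):
        counts = np.zeros((2, 8), dtype=int)
        counts[0, :3] = 5  # detected only in group a: no level comparison
        counts[1] = 10
        cm = CountsMatrix(
            ["rare", "house"], [f"c{i}" for i in range(8)], counts,
            {f"c{i}": ("a" if i < 4 else "b") for i in range(8)},
        )
        rec = differential_expression(cm)[0]
        assert rec.p_level == 1.0
        assert rec.p_freq < 1.0

    def test_alpha_rule(self):
        assert significance_threshold(100) == 0.05
        assert significance_threshold(101) == 0.005
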