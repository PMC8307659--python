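"""Per-CpG statistics: chi-squared oracle, BH oracle, classification, global shift."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from dmrkit import diff
from dmrkit import simulate as sim

from conftest import make_methylome


def pearson_chi2_oracle(a, b, c, d):
    """Brute-force Pearson statistic: sum (obs-exp)^2/exp over the 2x2 table."""
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if n == 0 or (rows == 0).any() or (cols == 0).any():
        return 0.0
    chi2 = 0.0
    for i in range(2):
        for j in range(2):
            exp = rows[i] * cols[j] / n
            chi2 += (table[i, j] - exp) ** 2 / exp
    return chi2


def bh_oracle(p):
    """Independent step-up: q_(i) = min_{j>=i} p_(j) * m / j, input order, capped."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestChiSquare:
    def test_hand_worked_table(self):
        chi2, p, delta = diff.chi_square_site((10, 0), (0, 10))
        assert chi2 == pytest.approx(20.0, abs=1e-12)
        assert delta == pytest.approx(-1.0)

    def test_identical_proportions(self):
        chi2, p, delta = diff.chi_square_site((5, 5), (5, 5))
        assert (chi2, p, delta) == (0.0, 1.0, 0.0)

    def test_swap_symmetry(self, rng):
        for _ in range(50):
            a = tuple(int(x) for x in rng.integers(0, 30, 2))
            b = tuple(int(x) for x in rng.integers(0, 30, 2))
            if sum(a) == 0 or sum(b) == 0:
                continue
            f = diff.chi_square_site(a, b)
            r = diff.chi_square_site(b, a)
            assert f[0] == pytest.approx(r[0], abs=1e-12)
            assert f[1] == pytest.approx(r[1], abs=1e-12)
            assert f[2] == pytest.approx(-r[2], abs=1e-12)

    def test_degenerate_marginal_flagged_p1(self):
        chi2, p, delta = diff.chi_square_site((7, 0), (3, 0))  # all methylated
        assert (chi2, p, delta) == (0.0, 1.0, 0.0)

    def test_agrees_with_scipy_on_nondegenerate_tables(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) + 1 for x in rng.integers(0, 25, 4))
            chi2, p, _ = diff.chi_square_site((a, b), (c, d))
            ref = sps.chi2_contingency([[a, b], [c, d]], correction=False)
            assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            diff.chi_square_site((0, 0), (1, 1))


class TestAdjustBH:
    def test_worked_example(self):
        q = diff.adjust_bh([0.001, 0.01, 0.02, 0.8])
        assert q == pytest.approx([0.004, 0.02, 0.02666667, 0.8], abs=1e-6)

    def test_ties_all_equal(self):
        q = diff.adjust_bh([0.05] * 10)
        assert q == pytest.approx([0.05] * 10)

    def test_empty(self):
        assert diff.adjust_bh([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diff.adjust_bh([0.5, 1.5])

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_matches_step_up_oracle(self, pvals):
        assert diff.adjust_bh(pvals) == pytest.approx(bh_oracle(pvals), abs=1e-12)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.random(500)
        q = diff.adjust_bh(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestFilterAndClassify:
    def test_filter_per_replicate_rule(self):
        assert diff.filter_coverage([5, 6, 4, 9], min_cov=4) is True
        assert diff.filter_coverage([5, 3, 8, 8], min_cov=4) is False
        assert diff.filter_coverage([0, 0, 0, 0], min_cov=0) is True

    @pytest.mark.parametrize(
        "q,delta,expect",
        [
            (0.15, 0.12, "hyper"),
            (0.15, 0.10, "not_significant"),  # strict inequality on delta
            (0.25, 0.5, "not_significant"),  # FDR gate
            (0.15, -0.12, "hypo"),
            (0.2, 0.5, "not_significant"),  # strict inequality on q
        ],
    )
    def test_threshold_semantics(self, q, delta, expect):
        df = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [0], "delta": [delta], "q": [q], "state": ["not_significant"]}
        )
        out = diff.classify_sites(df)
        assert out["state"].iloc[0] == expect

    def test_state_partition_sums(self, small_sim):
        ref, a, b, _ = small_sim
        sites = diff.test_methylomes(a, b, exclude_chroms=[ref.spikein_chrom])
        counts = sites["state"].value_counts()
        assert counts.sum() == len(sites)
        assert set(counts.index) <= {"hyper", "hypo", "not_significant", "filtered"}

    def test_filtered_iff_coverage_rule_fails(self, small_sim):
        ref, a, b, _ = small_sim
        sites = diff.test_methylomes(a, b, min_cov=4, exclude_chroms=[ref.spikein_chrom])
        merged = None
        for i, m in enumerate(a + b):
            cov = m.sites.assign(**{f"c{i}": m.sites["n_meth"] + m.sites["n_unmeth"]})[
                ["chrom", "pos", f"c{i}"]
            ]
            merged = cov if merged is None else merged.merge(cov, on=["chrom", "pos"], how="outer")
        merged = merged[merged["chrom"] != ref.spikein_chrom].fillna(0).sort_values(["chrom", "pos"])
        ok = (merged.drop(columns=["chrom", "pos"]).to_numpy() >= 4).all(axis=1)
        assert np.array_equal(sites["state"].to_numpy() == "filtered", ~ok)


class TestGlobalShift:
    def test_identical_conditions_flagged_degenerate(self):
        rows = [("chr1", p * 100, 5, 5) for p in range(200)]
        a = [make_methylome(rows)]
        b = [make_methylome(rows, sample_id="t", condition="KO")]
        res = diff.global_methylation_shift(a, b, bin_size=1000)
        assert res.mean_a == res.mean_b
        assert res.degenerate and np.isnan(res.p)

    def test_swap_negates_difference(self, small_sim):
        ref, a, b, _ = small_sim
        f = diff.global_methylation_shift(a, b, bin_size=20_000, exclude_chroms=[ref.spikein_chrom])
        r = diff.global_methylation_shift(b, a, bin_size=20_000, exclude_chroms=[ref.spikein_chrom])
        assert f.mean_difference == pytest.approx(-r.mean_difference, abs=1e-12)
        assert f.p == pytest.approx(r.p, rel=1e-9)

    def test_recovers_simulated_shift(self):
        cfg = sim.SimConfig(global_shift=0.02, n_hyper_dmr=0, n_hypo_dmr=0, seed=21)
        ref = sim.simulate_reference(cfg)
        a, b, _ = sim.simulate_methylomes(ref, cfg)
        res = diff.global_methylation_shift(a, b, bin_size=100_000, exclude_chroms=[ref.spikein_chrom])
        assert res.n_bins == 100
        assert res.mean_difference == pytest.approx(0.02, abs=0.005)
        assert res.p < 0.01

    def test_too_few_bins_rejected(self):
        rows = [("chr1", p, 5, 5) for p in range(10)]
        with pytest.raises(ValueError, match="bin_size"):
            diff.global_methylation_shift([make_methylome(rows)], [make_methylome(rows)], bin_size=10**9)


class TestHexbin:
    def test_identical_conditions_mass_on_diagonal(self):
        rows = [("chr1", p * 10, p % 11, 11 - p % 11) for p in range(100)]
        a, b = [make_methylome(rows)], [make_methylome(rows)]
        h = diff.methylation_hexbin(a, b, n_bins=10, min_cov=4)
        off_diag = h.sum() - np.trace(h)
        assert off_diag == 0

    def test_total_equals_paired_testable(self, small_sim):
        ref, a, b, _ = small_sim
        h = diff.methylation_hexbin(a, b, n_bins=50, min_cov=4, exclude_chroms=[ref.spikein_chrom])
        sites = diff.test_methylomes(a, b, min_cov=4, exclude_chroms=[ref.spikein_chrom])
        assert h.sum() == (sites["state"] != "filtered").sum()

    def test_hyper_shift_puts_mass_above_diagonal(self):
        cfg = sim.SimConfig(global_shift=0.05, n_hyper_dmr=0, n_hypo_dmr=0, chrom_length=1_000_000, seed=2)
        ref = sim.simulate_reference(cfg)
        a, b, _ = sim.simulate_methylomes(ref, cfg)
        h = diff.methylation_hexbin(a, b, exclude_chroms=[ref.spikein_chrom])
        above = np.triu(h, 1).sum()  # level_b bin > level_a bin
        below = np.tril(h, -1).sum()
        assert above > below
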