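"""PMR statistics, background estimation, binomial degree posteriors and
windowed parent-offspring vs sibling discrimination."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import logsumexp
from scipy.stats import binom

from paleokin.datatypes import ALT, MISSING, REF, PseudoHaploidMatrix, SNPPanel
from paleokin.kinship import (
    PARENT_OFFSPRING,
    SIBLING,
    UNRELATED,
    BackgroundRate,
    PairwiseStats,
    WindowSeries,
    classify_degree,
    classify_po_vs_sibling,
    estimate_background,
    expected_pmr,
    pairwise_mismatch,
    relatedness_table,
    windowed_pmr,
)


def matrix_from(calls, ids=None):
    calls = np.asarray(calls, dtype=np.int8)
    ids = ids or [f"I{k}" for k in range(calls.shape[0])]
    return PseudoHaploidMatrix(ids, calls)


def uniform_panel(n_sites, n_chrom=1, morgans=1.0):
    """Sites evenly spaced on each chromosome's genetic map."""
    per = n_sites // n_chrom
    chrom = np.concatenate([np.full(per, str(c + 1), dtype=object) for c in range(n_chrom)])
    pos = np.tile(np.arange(1, per + 1) * 1000, n_chrom)
    gpos = np.tile(np.linspace(0, morgans, per, endpoint=False), n_chrom)
    return SNPPanel(chrom=chrom, pos=pos, gpos=gpos,
                    ref=np.full(n_chrom * per, "A", dtype=object),
                    alt=np.full(n_chrom * per, "G", dtype=object))


class TestPairwiseMismatch:
    def test_identical_vectors(self):
        m = matrix_from([[REF, ALT, REF], [REF, ALT, REF]])
        s = pairwise_mismatch(m, "I0", "I1", min_overlap=1)
        assert (s.n, s.k, s.pmr) == (3, 0, 0.0)

    def test_complementary_vectors(self):
        calls = np.zeros((2, 100), dtype=np.int8)
        calls[1] = ALT
        s = pairwise_mismatch(matrix_from(calls), "I0", "I1", min_overlap=10)
        assert s.pmr == 1.0 and s.k == 100

    def test_matches_naive_double_loop(self, rng):
        """Vectorized counts equal a direct per-site loop on a noisy fixture."""
        calls = rng.choice(np.array([REF, ALT], dtype=np.int8), size=(2, 1000))
        miss = rng.random((2, 1000)) < 0.1
        calls[miss] = MISSING
        m = matrix_from(calls)
        s = pairwise_mismatch(m, "I0", "I1", min_overlap=1)
        n = k = 0
        for site in range(1000):
            a, b = calls[0, site], calls[1, site]
            if a != MISSING and b != MISSING:
                n += 1
                k += a != b
        assert (s.n, s.k) == (n, k)

    def test_symmetry(self):
        calls = np.array([[REF, ALT, MISSING, REF], [ALT, ALT, REF, MISSING]], dtype=np.int8)
        m = matrix_from(calls)
        assert pairwise_mismatch(m, "I0", "I1", 1) == pairwise_mismatch(m, "I1", "I0", 1)

    def test_low_overlap_flagged(self):
        m = matrix_from([[REF] * 10, [REF] * 10])
        s = pairwise_mismatch(m, "I0", "I1", min_overlap=100)
        assert "LOW_OVERLAP" in s.flags

    def test_unknown_id(self):
        with pytest.raises(KeyError):
            pairwise_mismatch(matrix_from([[REF], [REF]]), "I0", "nope")


def stats_with_pmr(pmrs, n=10_000):
    return [
        PairwiseStats(f"A{i}", f"B{i}", n, round(p * n)) for i, p in enumerate(pmrs)
    ]


class TestEstimateBackground:
    def test_constant_pmr_recovered_exactly(self):
        bg = estimate_background(stats_with_pmr([0.25] * 10))
        assert bg.p0 == 0.25

    def test_close_kin_pair_does_not_shift_estimate(self):
        """One parent-offspring pair among 20 unrelated leaves p0 unchanged."""
        base = [0.24 + 0.001 * (i % 5) for i in range(20)]
        with_po = base + [0.18]
        assert estimate_background(stats_with_pmr(with_po)).p0 == pytest.approx(
            estimate_background(stats_with_pmr(base)).p0, abs=1e-3
        )

    def test_recovers_simulated_unrelated_rate(self, rng):
        truth = 0.24
        n = 20_000
        ks = rng.binomial(n, truth, size=50)
        stats = [PairwiseStats(f"A{i}", f"B{i}", n, int(k)) for i, k in enumerate(ks)]
        bg = estimate_background(stats)
        se = math.sqrt(truth * (1 - truth) / n)
        assert abs(bg.p0 - truth) < 3 * se

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match=">= 3"):
            estimate_background(stats_with_pmr([0.2, 0.25]))

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            BackgroundRate(p0=0.0, n_pairs_used=5, iterations=1)


class TestExpectedPmr:
    def test_class_rates(self):
        p0 = 0.28
        assert expected_pmr(0, p0) == pytest.approx(0.5 * p0)
        assert expected_pmr(1, p0) == pytest.approx(0.75 * p0)
        assert expected_pmr(2, p0) == pytest.approx(0.875 * p0)
        assert expected_pmr(UNRELATED, p0) == p0

    def test_strictly_increasing_toward_background(self):
        p0 = 0.3
        rates = [expected_pmr(d, p0) for d in range(8)]
        assert all(a < b for a, b in zip(rates, rates[1:]))
        assert rates[-1] < p0

    def test_monte_carlo_draw_oracle(self, rng):
        """Two pseudo-haploid draws from one diploid mismatch at half the
        unrelated rate; parent-offspring at three quarters (simulated from
        first principles, no package code)."""
        n = 200_000
        f = rng.uniform(0.05, 0.95, n)
        mother = rng.random((2, n)) < f
        father = rng.random((2, n)) < f
        child = np.stack([
            np.where(rng.random(n) < 0.5, mother[0], mother[1]),
            np.where(rng.random(n) < 0.5, father[0], father[1]),
        ])

        def draw(dip):
            pick = rng.random(n) < 0.5
            return np.where(pick, dip[0], dip[1])

        p0_hat = (draw(mother) != draw(father)).mean()
        dup = (draw(mother) != draw(mother)).mean()
        po = (draw(mother) != draw(child)).mean()
        se = 3 * math.sqrt(0.25 / n)
        assert abs(dup - expected_pmr(0, p0_hat)) < 3 * se
        assert abs(po - expected_pmr(1, p0_hat)) < 3 * se

    def test_invalid_p0(self):
        with pytest.raises(ValueError):
            expected_pmr(1, 1.5)


class TestClassifyDegree:
    def test_zero_overlap_gives_uniform_posterior(self):
        post = classify_degree(PairwiseStats("a", "b", 0, 0), p0=0.25)
        assert all(p == pytest.approx(0.25) for p in post.probabilities.values())

    @pytest.mark.parametrize(
        "k,expected", [(18_750, 1), (25_000, UNRELATED), (12_500, 0), (21_875, 2)]
    )
    def test_matches_direct_pmf_evaluation(self, k, expected):
        """Chosen class maximizes the binomial pmf at the class rates."""
        n, p0 = 100_000, 0.25
        post = classify_degree(PairwiseStats("a", "b", n, k), p0=p0)
        rates = {0: 0.5 * p0, 1: 0.75 * p0, 2: 0.875 * p0, UNRELATED: p0}
        logl = {c: binom.logpmf(k, n, r) for c, r in rates.items()}
        norm = logsumexp(list(logl.values()))
        assert post.chosen == expected
        assert post.probabilities[expected] > 0.99
        for c in rates:
            assert post.probabilities[c] == pytest.approx(math.exp(logl[c] - norm), abs=1e-9)

    @given(st.integers(min_value=1, max_value=5000), st.integers(min_value=0, max_value=5000))
    def test_posterior_normalized(self, n, k):
        if k > n:
            n, k = k, n
        post = classify_degree(PairwiseStats("a", "b", n, k), p0=0.25)
        assert sum(post.probabilities.values()) == pytest.approx(1.0, abs=1e-9)

    def test_posterior_concentrates_with_n(self):
        """Holding k/n at the degree-1 rate, posterior mass on class 1
        grows to 1 with n."""
        p0 = 0.25
        rate = 0.75 * p0
        masses = [
            classify_degree(
                PairwiseStats("a", "b", n, round(rate * n)), p0=p0
            ).probabilities[1]
            for n in (500, 5_000, 50_000)
        ]
        assert masses[0] < masses[1] < masses[2]
        assert masses[2] > 0.999

    def test_tie_breaks_toward_distant_class(self):
        """With no data beyond the prior, ties resolve conservatively."""
        post = classify_degree(PairwiseStats("a", "b", 0, 0), p0=0.25)
        assert post.chosen == UNRELATED


class TestWindowedPmr:
    def test_window_count_arithmetic(self):
        """A 1-Morgan chromosome tiles into five 20-cM windows."""
        m = matrix_from(np.full((2, 1000), REF, dtype=np.int8))
        series = windowed_pmr(m, "I0", "I1", uniform_panel(1000), window_cm=20, min_sites=10)
        assert len(series.table) == 5
        assert series.table["usable"].all()

    def test_window_counts_conserve_pair_totals(self, rng):
        calls = rng.choice(np.array([REF, ALT, MISSING], dtype=np.int8), size=(2, 3000))
        m = matrix_from(calls)
        panel = uniform_panel(3000, n_chrom=3)
        series = windowed_pmr(m, "I0", "I1", panel, window_cm=20, min_sites=1)
        s = pairwise_mismatch(m, "I0", "I1", min_overlap=1)
        assert series.table["k"].sum() == s.k
        assert series.table["n"].sum() == s.n

    def test_no_usable_windows_raises(self):
        calls = np.full((2, 100), MISSING, dtype=np.int8)
        calls[:, 0] = REF
        with pytest.raises(ValueError, match="usable"):
            windowed_pmr(matrix_from(calls), "I0", "I1", uniform_panel(100))


def series_from_rates(rates, n_per_window=2_000):
    rows = [
        {"chrom": "1", "g_start": 0.2 * i, "g_end": 0.2 * (i + 1),
         "n": n_per_window, "k": round(r * n_per_window),
         "pmr": r, "usable": True}
        for i, r in enumerate(rates)
    ]
    return WindowSeries("a", "b", pd.DataFrame(rows))


class TestPoVsSibling:
    P0 = 0.25

    def test_flat_profile_called_parent_offspring(self):
        """All windows at 0.75 p0: the single-rate model wins (the sibling
        mixture pays its prior spread), matching direct pmf computation."""
        series = series_from_rates([0.75 * self.P0] * 20)
        call, log_bf = classify_po_vs_sibling(series, self.P0)
        assert call == PARENT_OFFSPRING and log_bf > 0
        # oracle: direct mixture computation for one window
        n = 2000
        k = round(0.75 * self.P0 * n)
        lpo = binom.logpmf(k, n, 0.75 * self.P0)
        lsib = logsumexp([
            math.log(0.25) + binom.logpmf(k, n, self.P0),
            math.log(0.5) + binom.logpmf(k, n, 0.75 * self.P0),
            math.log(0.25) + binom.logpmf(k, n, 0.5 * self.P0),
        ])
        assert log_bf == pytest.approx(20 * (lpo - lsib))

    def test_trimodal_profile_called_sibling(self):
        """Windows split 1/4 : 1/2 : 1/4 across the IBD-state rates."""
        rates = ([self.P0] * 5 + [0.75 * self.P0] * 10 + [0.5 * self.P0] * 5)
        call, log_bf = classify_po_vs_sibling(series_from_rates(rates), self.P0)
        assert call == SIBLING and log_bf < 0

    def test_too_few_windows_indeterminate(self):
        series = series_from_rates([0.75 * self.P0] * 5)
        call, _ = classify_po_vs_sibling(series, self.P0)
        assert call == "INDETERMINATE"


class TestRelatednessTable:
    def test_two_individuals_one_row(self, rng):
        calls = rng.choice(np.array([REF, ALT], dtype=np.int8), size=(2, 6000))
        m = matrix_from(calls)
        table = relatedness_table(
            m, background=BackgroundRate(p0=0.25, n_pairs_used=10, iterations=1),
            min_overlap=1000,
        )
        assert len(table) == 1

    def test_deterministic(self, small_dataset):
        t1 = relatedness_table(small_dataset.matrix, small_dataset.panel)
        t2 = relatedness_table(small_dataset.matrix, small_dataset.panel)
        pd.testing.assert_frame_equal(t1, t2)

    def test_duplicate_sampling_normalized_half(self, rng):
        """Two error-free pseudo-haploid samplings of one diploid sit at
        normalized PMR 1/2."""
        from paleokin.simulate import SimulationConfig, drop_genes, make_panel, sample_pseudohaploid
        from paleokin.simulate.pedigree import PedNode, TruePedigree
        from paleokin.datatypes import ADULT, XX, XY

        cfg = SimulationConfig(seed=5, n_snps=44_000, error_rate=0.0)
        panel = make_panel(cfg, rng)
        ped = TruePedigree()
        for i in range(8):
            ped.add(PedNode(f"U{i}", XY, 1, True, ADULT, 0, mt_hg="m", y_hg="y"))
        dip = drop_genes(ped, panel, cfg, rng)
        m1 = sample_pseudohaploid(dip, cfg, rng)
        m2 = sample_pseudohaploid(dip, cfg, rng, ids=["U0"])
        combined = PseudoHaploidMatrix(
            m1.ids + ["U0dup"], np.vstack([m1.calls, m2.calls])
        )
        from itertools import combinations
        from paleokin.kinship import pairwise_mismatch as pm

        unrelated = [pm(combined, a, b) for a, b in combinations([f"U{i}" for i in range(8)], 2)]
        bg = estimate_background(unrelated)
        dup = pm(combined, "U0", "U0dup")
        norm = dup.pmr / bg.p0
        se = dup.se / bg.p0
        assert abs(norm - 0.5) < 3 * se
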