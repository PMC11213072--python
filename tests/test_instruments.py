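"""Instrument construction: clumping vs a brute-force oracle, score
orientation invariance, partial-F arithmetic and the liability-scale
transformation."""

import math

import numpy as np
import pandas as pd
import pytest
from oracles import greedy_clump_oracle
from scipy.stats import norm

from mrdoc.instruments import (
    GenotypeMatrix,
    LDMatrix,
    MqtlSummaryStats,
    greedy_clump,
    incremental_strength,
    liability_scale_r2,
    residualize_standardize,
    weighted_allelic_score,
)
from mrdoc.synthetic_data import simulate_genotype_fixture


def _random_fixture(rng, n_snps):
    pos = np.sort(rng.integers(0, 2_000_000, n_snps))
    stats = MqtlSummaryStats(
        pd.DataFrame(
            {
                "snp_id": [f"rs{i}" for i in range(n_snps)],
                "position": pos,
                "effect_allele": "A",
                "other_allele": "G",
                "beta": rng.normal(size=n_snps),
                "pvalue": 10 ** rng.uniform(-12, 0, n_snps),
            }
        )
    )
    A = rng.normal(size=(n_snps, n_snps))
    corr = np.corrcoef(A @ A.T)
    ld = LDMatrix([f"rs{i}" for i in range(n_snps)], corr**2)
    return stats, ld


def test_clump_single_significant_snp():
    rng = np.random.default_rng(0)
    stats, ld = _random_fixture(rng, 5)
    stats.table["pvalue"] = [1e-8, 0.5, 0.9, 0.2, 0.7]
    sel = greedy_clump(stats, ld, p_threshold=5e-8, r2_threshold=0.1)
    assert sel == ["rs0"]
    stats.table["pvalue"] = [0.5] * 5
    assert greedy_clump(stats, ld, p_threshold=5e-8) == []


def test_clump_matches_bruteforce_oracle():
    rng = np.random.default_rng(1)
    for trial in range(200):
        n = int(rng.integers(2, 30))
        stats, ld = _random_fixture(rng, n)
        p_thr = 10 ** rng.uniform(-8, 0)
        r2_thr = rng.uniform(0.05, 0.9)
        cpg = int(rng.integers(0, 2_000_000))
        window = int(rng.integers(50_000, 1_500_000))
        got = greedy_clump(stats, ld, p_thr, r2_thr, window, cpg)
        want = greedy_clump_oracle(stats.table, ld.lookup, p_thr, r2_thr, window, cpg)
        assert got == want
        # no two selected SNPs in high LD
        for i, a in enumerate(got):
            for b in got[i + 1 :]:
                assert ld.lookup(a, b) < r2_thr


def test_clump_missing_snp_errors():
    rng = np.random.default_rng(2)
    stats, ld = _random_fixture(rng, 4)
    ld_small = LDMatrix(ld.snp_ids[:3], ld.r2[:3, :3])
    with pytest.raises(KeyError, match="rs3"):
        greedy_clump(stats, ld_small, p_threshold=1.0)


def test_clump_recovers_one_snp_per_block():
    geno, ld, stats = simulate_genotype_fixture(
        n_individuals=2000, n_snps=50, ld_block_size=5, within_block_r=0.8,
        maf_range=(0.2, 0.4), seed=12, causal_per_block=1, causal_beta=0.5,
    )
    sel = greedy_clump(stats, ld, p_threshold=5e-8, r2_threshold=0.1)
    per_block = {}
    for s in sel:
        b = (int(s[2:]) - 1) // 5
        per_block[b] = per_block.get(b, 0) + 1
    assert all(v <= 1 for v in per_block.values())


def test_weighted_score_simple_and_orientation_invariance():
    doses = pd.DataFrame({"rs1": [0.0, 1.0, 2.0]})
    stats = MqtlSummaryStats(
        pd.DataFrame(
            {
                "snp_id": ["rs1"], "position": [100], "effect_allele": ["A"],
                "other_allele": ["G"], "beta": [0.5], "pvalue": [1e-9],
            }
        )
    )
    geno = GenotypeMatrix(doses, {"rs1": "A"}, {"rs1": "G"})
    np.testing.assert_allclose(
        weighted_allelic_score(geno, stats, ["rs1"]), [0.0, 0.5, 1.0]
    )
    # flip alleles and negate the effect: identical after centering
    flipped = MqtlSummaryStats(
        stats.table.assign(effect_allele="G", other_allele="A", beta=-0.5)
    )
    s1 = weighted_allelic_score(geno, stats, ["rs1"])
    s2 = weighted_allelic_score(geno, flipped, ["rs1"])
    np.testing.assert_allclose(s1 - s1.mean(), s2 - s2.mean(), atol=1e-12)
    # inconsistent alleles must raise
    bad = MqtlSummaryStats(stats.table.assign(effect_allele="T", other_allele="C"))
    with pytest.raises(ValueError, match="orientation"):
        weighted_allelic_score(geno, bad, ["rs1"])


def test_weighted_score_matches_hand_computed_sum():
    geno, ld, stats = simulate_genotype_fixture(
        n_individuals=500, n_snps=9, ld_block_size=3, within_block_r=0.0,
        maf_range=(0.3, 0.5), seed=3, causal_beta=0.4,
    )
    selected = ["rs000001", "rs000004", "rs000007"]
    score = weighted_allelic_score(geno, stats, selected)
    t = stats.table.set_index("snp_id")
    hand = np.zeros(500)
    for s in selected:
        b = float(t.loc[s, "beta"])
        d = geno.dosages[s].to_numpy()
        hand += abs(b) * (d if b > 0 else 2 - d)
    np.testing.assert_allclose(score, hand, atol=1e-12)


def test_incremental_strength_null_and_analytic_share(rng):
    n = 10_000
    score = rng.normal(size=n)
    null_out = rng.normal(size=n)
    res = incremental_strength(score, null_out)
    assert res.incremental_r2 < 1e-3
    assert res.f_statistic < 4
    assert not res.relevant
    # outcome = 0.3*score + N(0,1): R2 = 0.09/1.09
    out = 0.3 * score + rng.normal(size=n)
    res = incremental_strength(score, out)
    assert res.incremental_r2 == pytest.approx(0.09 / 1.09, abs=0.01)
    assert res.relevant


def test_partial_f_matches_textbook_anova():
    # 20-row dataset, explicit ANOVA decomposition via statsmodels
    import statsmodels.api as sm

    rng = np.random.default_rng(9)
    n = 20
    cov = rng.normal(size=n)
    score = rng.normal(size=n)
    y = 0.5 * cov + 0.4 * score + rng.normal(size=n)
    res = incremental_strength(score, y, cov)
    full = sm.OLS(y, sm.add_constant(np.column_stack([cov, score]))).fit()
    red = sm.OLS(y, sm.add_constant(cov)).fit()
    f_anova = (red.ssr - full.ssr) / 1 / (full.ssr / (n - 3))
    assert res.f_statistic == pytest.approx(f_anova, rel=1e-10)
    assert res.incremental_r2 == pytest.approx(full.rsquared - red.rsquared, abs=1e-12)


def test_incremental_strength_collinear_errors():
    x = np.arange(10.0)
    with pytest.raises(ValueError, match="collinear"):
        incremental_strength(x, np.random.default_rng(0).normal(size=10), x)


def test_liability_r2_closed_form_at_k_equals_p(rng):
    n = 20_000
    score = rng.normal(size=n)
    liab = math.sqrt(0.05) * score + math.sqrt(0.95) * rng.normal(size=n)
    K = 0.26
    y = (liab > norm.ppf(1 - K)).astype(float)
    r2, meta = liability_scale_r2(y, score, population_prevalence=K)
    # closed form: R2_liab = R2_obs * K(1-K) / phi(t)^2 when P ~= K
    t = norm.ppf(1 - K)
    by_hand = meta["r2_observed"] * K * (1 - K) / norm.pdf(t) ** 2
    assert r2 == pytest.approx(by_hand, rel=0.02)
    # generative truth: score explains 5% of liability variance
    assert r2 == pytest.approx(0.05, abs=0.01)
    assert meta["transformation"] == "lee_ascertainment_adjusted"


def test_liability_r2_null_and_errors(rng):
    y = (rng.uniform(size=5000) < 0.3).astype(float)
    r2, _ = liability_scale_r2(y, rng.normal(size=5000), population_prevalence=0.3)
    assert abs(r2) < 0.01
    with pytest.raises(ValueError, match="cases and controls"):
        liability_scale_r2(np.ones(100), rng.normal(size=100), population_prevalence=0.3)


def test_residualize_standardize_properties(rng):
    n = 500
    cov = rng.normal(size=(n, 3))
    y = cov @ [0.5, -1.0, 0.2] + rng.normal(size=n)
    res = residualize_standardize(y, cov)
    assert abs(res.mean()) < 1e-12
    assert abs(res.std(ddof=1) - 1) < 1e-12
    # orthogonal to every covariate column
    assert np.max(np.abs(cov.T @ res)) / n < 1e-8
    # intercept-only = z-score
    z = residualize_standardize(y)
    np.testing.assert_allclose(z, (y - y.mean()) / y.std(ddof=1), atol=1e-12)
    with pytest.raises(ValueError, match="zero"):
        residualize_standardize(np.ones(50))


def test_f_statistic_monotone_in_incremental_r2():
    # at fixed n and k, F increases with the incremental R2
    rng = np.random.default_rng(17)
    n = 2000
    score = rng.normal(size=n)
    noise = rng.normal(size=n)
    fs = []
    for b in (0.1, 0.2, 0.3, 0.5):
        res = incremental_strength(score, b * score + noise)
        fs.append(res.f_statistic)
    assert fs == sorted(fs)
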