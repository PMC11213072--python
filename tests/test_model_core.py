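"""Model-core checks: implied moments, likelihood oracle equivalence,
starting values, fitting invariances and Wald inference."""

import math
from dataclasses import replace

import numpy as np
import pytest
from oracles import quadrature_pair_loglik, random_admissible_params, random_record
from scipy.stats import multivariate_normal

from mrdoc.model_core import (
    FitOptions,
    FitResult,
    InadmissibleParameters,
    MRDoCSpec,
    ParameterVector,
    cohort_loglik,
    fit_mrdoc,
    implied_covariance,
    pair_loglik,
    solve_e_x,
    starting_values,
    wald_statistics,
)
from mrdoc.synthetic_data import SyntheticScenario, simulate_cohort

SPECS = [
    MRDoCSpec("doc1_pleiotropy", "binary_exposure"),
    MRDoCSpec("doc1_re", "continuous_exposure"),
    MRDoCSpec("doc2", "bidirectional"),
]


def test_spec_validation():
    with pytest.raises(ValueError):
        MRDoCSpec("doc2", "binary_exposure")
    with pytest.raises(ValueError):
        MRDoCSpec("doc1_re", "bidirectional")
    with pytest.raises(ValueError):
        MRDoCSpec("doc3", "binary_exposure")


def test_implied_covariance_null_paths():
    # all paths and correlations zero: DNAm cross-twin covariance is a_y^2
    # scaled by the zygosity coefficient; smoking-DNAm covariances vanish
    half = math.sqrt(0.5)
    p = ParameterVector(a_y=half, e_y=half, a_x=0.6, e_x=0.8, b1=0.0, r_a=0.0)
    spec = MRDoCSpec("doc1_pleiotropy", "binary_exposure")
    for zyg, expect in (("MZ", 0.5), ("DZ", 0.25)):
        ms = implied_covariance(spec, p, zyg)
        i = {n: j for j, n in enumerate(ms.order)}
        assert ms.covariance[i["dnam1"], i["dnam2"]] == pytest.approx(expect, abs=1e-12)
        assert ms.covariance[i["smk1"], i["dnam1"]] == pytest.approx(0.0, abs=1e-12)
        assert ms.covariance[i["smk1"], i["dnam2"]] == pytest.approx(0.0, abs=1e-12)


def test_implied_covariance_doc2_iv_covariance_direct():
    p = ParameterVector(c_iv=0.17, e_x=0.8)
    ms = implied_covariance(MRDoCSpec("doc2", "bidirectional"), p, "MZ")
    i = {n: j for j, n in enumerate(ms.order)}
    assert ms.covariance[i["prs1"], i["mqtl1"]] == pytest.approx(0.17, abs=1e-15)


def test_implied_covariance_rejects_inadmissible():
    p = ParameterVector(r_a=1.2, e_x=0.8)
    with pytest.raises(InadmissibleParameters):
        implied_covariance(MRDoCSpec("doc1_re", "binary_exposure"), p, "MZ")
    with pytest.raises(ValueError):
        implied_covariance(MRDoCSpec("doc1_re", "binary_exposure"), ParameterVector(), "XX")


def test_solve_e_x_restores_unit_liability_variance():
    rng = np.random.default_rng(2)
    spec = MRDoCSpec("doc2", "bidirectional")
    for _ in range(20):
        p = random_admissible_params(rng, spec)
        ms = implied_covariance(spec, p, "DZ")
        assert ms.covariance[0, 0] == pytest.approx(1.0, abs=1e-10)


@pytest.mark.parametrize("spec", SPECS, ids=lambda s: s.variant)
def test_pair_loglik_matches_quadrature(spec):
    rng = np.random.default_rng(99)
    worst = 0.0
    for trial in range(25):
        p = random_admissible_params(rng, spec)
        rec = random_record(rng, spec, zygosity=["MZ", "DZ", "singleton"][trial % 3])
        got = pair_loglik(p, rec, spec, "cg00000001")
        want = quadrature_pair_loglik(p, rec, spec, "cg00000001")
        worst = max(worst, abs(got - want))
    assert worst < 1e-6


def test_pair_loglik_independence_case():
    # smoking independent of everything, threshold at the median: each twin's
    # binary contribution is log(1/2), jointly log(1/4)
    p = ParameterVector(b1=0.0, b2=0.0, r_a=0.0, r_e=0.0, tau=0.0, a_x=0.0)
    spec = MRDoCSpec("doc1_pleiotropy", "binary_exposure")
    p.e_x = solve_e_x(spec, p)
    rng = np.random.default_rng(0)
    rec = random_record(rng, spec, zygosity="DZ", missing_rate=0.0)
    rec.smoking = np.array([1.0, 1.0])
    rec.age = np.zeros(2)
    rec.sex = np.zeros(2)
    full = pair_loglik(p, rec, spec, "cg00000001")
    cont_only = _continuous_block_logdens(p, rec, spec)
    assert full - cont_only == pytest.approx(math.log(0.25), abs=1e-10)


def _continuous_block_logdens(p, rec, spec, cpg="cg00000001"):
    ms = implied_covariance(spec, p, "DZ" if rec.zygosity == "DZ" else "MZ")
    i = {n: j for j, n in enumerate(ms.order)}
    iv = spec.iv_names[0]
    vals = {"prs": rec.prs, "mqtl": rec.mqtl_score[cpg]}[iv]
    names = ["dnam1", f"{iv}1", "dnam2", f"{iv}2"]
    vec = np.array([rec.dnam[cpg][0], vals[0], rec.dnam[cpg][1], vals[1]])
    if rec.zygosity != "DZ":
        names = ["dnam1", f"{iv}1", "dnam2"]
        vec = vec[:3]
    sel = [i[n] for n in names]
    cov = ms.covariance[np.ix_(sel, sel)]
    return float(multivariate_normal(np.zeros(len(sel)), cov).logpdf(vec))


@pytest.mark.parametrize("zygosity", ["MZ", "DZ"])
def test_pair_loglik_normalizes_over_smoking_patterns(zygosity):
    """Summing the pair likelihood over the four binary patterns must
    recover the continuous-block density exactly."""
    rng = np.random.default_rng(7)
    spec = MRDoCSpec("doc1_pleiotropy", "binary_exposure")
    for _ in range(10):
        p = random_admissible_params(rng, spec)
        rec = random_record(rng, spec, zygosity=zygosity, missing_rate=0.0)
        total = 0.0
        for s1 in (0.0, 1.0):
            for s2 in (0.0, 1.0):
                rec.smoking = np.array([s1, s2])
                total += math.exp(pair_loglik(p, rec, spec, "cg00000001"))
        want = math.exp(_continuous_block_logdens(p, rec, spec))
        assert total == pytest.approx(want, abs=1e-10 * max(1.0, want))


def test_starting_values(default_cohort):
    spec = MRDoCSpec("doc2", "bidirectional")
    p = starting_values(default_cohort, spec)
    # causal paths start at exactly zero by convention
    assert p.g1 == 0.0 and p.g2 == 0.0
    # threshold from the observed proportion
    prev = float(np.nanmean(default_cohort.data["smoking"]))
    from scipy.stats import norm

    assert p.tau == pytest.approx(norm.ppf(1 - prev), abs=1e-9)
    # instrument-on-phenotype start near the generative value 0.25
    assert p.b3 == pytest.approx(0.25, abs=0.1)


def test_starting_values_degenerate_cohort_errors(default_cohort):
    bad = default_cohort.data.copy()
    bad["smoking"] = 1.0
    from mrdoc.synthetic_data import TwinCohort

    with pytest.raises(ValueError, match="degenerate"):
        starting_values(TwinCohort(bad, default_cohort.cpg_ids), MRDoCSpec())


def test_fit_doc2_recovers_generative_truth(default_cohort):
    fit = fit_mrdoc(default_cohort, MRDoCSpec("doc2", "bidirectional"))
    assert fit.converged
    assert fit.estimates.g1 == pytest.approx(0.2, abs=0.15)
    assert fit.estimates.b3 == pytest.approx(0.25, abs=0.08)
    assert fit.standard_errors["g1"] > 0
    # MLE beats the generative parameters on the same data
    sc = default_cohort.scenario
    truth = ParameterVector(
        g1=sc.g1, g2=sc.g2, b1=sc.b1, b3=sc.b3, a_x=sc.a_x, e_x=sc.e_x,
        a_y=sc.a_y, e_y=sc.e_y, r_a=sc.r_a, tau=sc.threshold,
        beta_age=sc.beta_age, beta_sex=sc.beta_sex, c_iv=sc.iv_covariance,
    )
    ll_truth = cohort_loglik(default_cohort, MRDoCSpec("doc2", "bidirectional"), truth)
    assert fit.loglik >= ll_truth - 1e-6


def test_fit_is_invariant_to_record_order(default_cohort):
    spec = MRDoCSpec("doc1_pleiotropy", "binary_exposure")
    fit1 = fit_mrdoc(default_cohort, spec, options=FitOptions(compute_se=False))
    from mrdoc.synthetic_data import TwinCohort

    shuffled = default_cohort.data.sample(frac=1.0, random_state=1)
    coh2 = TwinCohort(shuffled, default_cohort.cpg_ids, scenario=default_cohort.scenario)
    fit2 = fit_mrdoc(coh2, spec, options=FitOptions(compute_se=False))
    for name in fit1.free_names:
        assert getattr(fit1.estimates, name) == pytest.approx(
            getattr(fit2.estimates, name), abs=1e-8
        )


def test_nesting_doc1_variants_share_likelihood_surface(default_cohort):
    """doc1_pleiotropy with b2 pinned to 0 and doc1_re with rE pinned to 0
    are the same model and must reach the same maximum."""
    fa = fit_mrdoc(
        default_cohort,
        MRDoCSpec("doc1_pleiotropy", "binary_exposure", extra_fixed=("b2",)),
        options=FitOptions(compute_se=False),
    )
    fb = fit_mrdoc(
        default_cohort,
        MRDoCSpec("doc1_re", "binary_exposure", extra_fixed=("r_e",)),
        options=FitOptions(compute_se=False),
    )
    assert abs(fa.loglik - fb.loglik) < 1e-6


def test_wald_statistics():
    fit = FitResult(
        spec=MRDoCSpec(), cpg_id="cg1", estimates=ParameterVector(g1=1.96),
        free_names=("g1",), standard_errors={"g1": 1.0}, vcov=None,
        loglik=0.0, convergence_status={"converged": True}, n_pairs_used={},
    )
    z, p = wald_statistics(fit, "g1")
    assert z == pytest.approx(1.96) and p == pytest.approx(0.05, abs=1e-3)
    fit.estimates.g1 = 0.0
    z, p = wald_statistics(fit, "g1")
    assert z == 0.0 and p == pytest.approx(1.0)
    fit.standard_errors["g1"] = 0.0
    with pytest.raises(ZeroDivisionError):
        wald_statistics(fit, "g1")
    fit.convergence_status["converged"] = False
    with pytest.raises(ValueError):
        wald_statistics(fit, "g1")


def test_doc1_re_recovers_environmental_confounding():
    sc = SyntheticScenario(
        n_mz_pairs=3000, n_dz_pairs=1800, n_singletons=0,
        g1=0.0, r_e=0.3, r_a=0.2, b2=0.0, seed=33,
    )
    coh = simulate_cohort(sc)
    fit = fit_mrdoc(coh, MRDoCSpec("doc1_re", "binary_exposure"))
    assert fit.converged
    assert fit.estimates.r_e == pytest.approx(0.3, abs=0.12)
    assert fit.estimates.g1 == pytest.approx(0.0, abs=0.08)
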