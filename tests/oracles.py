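"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they validate: the pair likelihood
oracle integrates the latent liabilities by 2-D Gauss-Legendre quadrature
of the joint normal density; the clumping oracle is a direct transcription
of the greedy rule over explicit candidate lists; the BH oracle applies the
step-up definition literally.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.stats import multivariate_normal

from mrdoc.model_core import implied_covariance


def quadrature_pair_loglik(params, record, spec, cpg_id, n_nodes: int = 80) -> float:
    """Joint log-likelihood of a twin record by direct numerical integration
    over the latent smoking liabilities."""
    zyg = "DZ" if record.zygosity == "DZ" else "MZ"
    ms = implied_covariance(spec, params, zyg)
    full = ms.covariance
    k = len(spec.iv_names)
    iv_map = {"prs": record.prs, "mqtl": record.mqtl_score.get(cpg_id)}
    nt = 1 if record.is_singleton else 2

    cont_idx, cont_vals, lat_idx, thresholds, smk_obs = [], [], [], [], []
    for t in range(nt):
        off = t * (2 + k)
        lat_idx.append(off)
        thresholds.append(
            params.tau - params.beta_age * record.age[t] - params.beta_sex * record.sex[t]
        )
        smk_obs.append(record.smoking[t])
        if spec.observed_liability:
            raise NotImplementedError("oracle covers the threshold model")
        cont_idx.append(off + 1)
        cont_vals.append(record.dnam[cpg_id][t])
        for j, iv in enumerate(spec.iv_names):
            cont_idx.append(off + 2 + j)
            cont_vals.append(iv_map[iv][t])
    cont_vals = np.asarray(cont_vals, dtype=float)
    if zyg == "MZ" and nt == 2:
        # identical instrument values across MZ co-twins: drop the duplicates
        drop = {(2 + k) + 2 + j for j in range(k)}
        keep = [i for i, ci in enumerate(cont_idx) if ci not in drop]
        cont_idx = [cont_idx[i] for i in keep]
        cont_vals = cont_vals[keep]

    scc = full[np.ix_(cont_idx, cont_idx)]
    log_dens = multivariate_normal(np.zeros(len(cont_idx)), scc).logpdf(cont_vals)
    sxc = full[np.ix_(lat_idx, cont_idx)]
    W = sxc @ np.linalg.inv(scc)
    mu = W @ cont_vals
    scond = full[np.ix_(lat_idx, lat_idx)] - W @ sxc.T

    nodes, weights = leggauss(n_nodes)

    def interval(i):
        s = smk_obs[i]
        if np.isnan(s):
            return None
        half = 12.0 * math.sqrt(scond[i, i])
        return (thresholds[i], thresholds[i] + half) if s > 0.5 else (
            thresholds[i] - half,
            thresholds[i],
        )

    regions = [interval(i) for i in range(len(lat_idx))]
    live = [i for i, r in enumerate(regions) if r is not None]
    if not live:
        prob = 1.0
    elif len(live) == 1:
        i = live[0]
        a, b = regions[i]
        xs = 0.5 * (b - a) * nodes + 0.5 * (a + b)
        v = scond[i, i]
        prob = (
            0.5
            * (b - a)
            * float(np.sum(weights * np.exp(-0.5 * (xs - mu[i]) ** 2 / v)))
            / math.sqrt(2 * math.pi * v)
        )
    else:
        (a1, b1), (a2, b2) = regions[0], regions[1]
        x1 = 0.5 * (b1 - a1) * nodes + 0.5 * (a1 + b1)
        x2 = 0.5 * (b2 - a2) * nodes + 0.5 * (a2 + b2)
        X1, X2 = np.meshgrid(x1, x2, indexing="ij")
        pts = np.column_stack([X1.ravel() - mu[0], X2.ravel() - mu[1]])
        sinv = np.linalg.inv(scond)
        qf = np.einsum("ij,jk,ik->i", pts, sinv, pts)
        pdf = np.exp(-0.5 * qf) / (2 * math.pi * math.sqrt(np.linalg.det(scond)))
        w2 = np.outer(weights, weights).ravel()
        prob = 0.25 * (b1 - a1) * (b2 - a2) * float(np.sum(w2 * pdf))
    return float(log_dens + math.log(max(prob, 1e-300)))


def random_admissible_params(rng, spec):
    """A random parameter draw satisfying the spec's constraints."""
    from mrdoc.model_core import InadmissibleParameters, ParameterVector, solve_e_x

    while True:
        p = ParameterVector(
            g1=rng.uniform(-0.3, 0.3),
            g2=rng.uniform(-0.3, 0.3),
            b1=rng.uniform(-0.4, 0.4),
            b2=rng.uniform(-0.2, 0.2) if spec.variant == "doc1_pleiotropy" else 0.0,
            b3=rng.uniform(-0.4, 0.4) if spec.variant == "doc2" else 0.0,
            a_x=rng.uniform(0.2, 0.7),
            a_y=rng.uniform(0.3, 0.8),
            e_y=rng.uniform(0.4, 0.9),
            r_a=rng.uniform(-0.6, 0.6),
            r_e=rng.uniform(-0.5, 0.5) if spec.variant == "doc1_re" else 0.0,
            tau=rng.uniform(-0.5, 1.0),
            beta_age=rng.uniform(-0.2, 0.2),
            beta_sex=rng.uniform(-0.2, 0.2),
            v_prs=rng.uniform(0.8, 1.2),
            v_mqtl=rng.uniform(0.8, 1.2),
            c_iv=rng.uniform(-0.2, 0.2) if spec.variant == "doc2" else 0.0,
        )
        if spec.direction == "binary_exposure":
            p.g2 = 0.0
        if spec.direction == "continuous_exposure":
            p.g1 = 0.0
        try:
            p.e_x = solve_e_x(spec, p)
        except InadmissibleParameters:
            continue
        return p


def random_record(rng, spec, cpg_id="cg00000001", zygosity=None, missing_rate=0.2):
    """A random twin record consistent with the spec's instrument set."""
    from mrdoc.synthetic_data import TwinPairRecord

    zyg = zygosity or rng.choice(["MZ", "DZ", "singleton"])
    share = zyg != "DZ"
    smk = rng.integers(0, 2, size=2).astype(float)
    if zyg != "singleton" and rng.uniform() < missing_rate:
        smk[rng.integers(0, 2)] = np.nan
    return TwinPairRecord(
        family_id=1,
        zygosity=zyg,
        smoking=smk if zyg != "singleton" else np.array([smk[0], np.nan]),
        prs=np.repeat(rng.normal(), 2) if share else rng.normal(size=2),
        age=rng.normal(size=2) * 0.5,
        sex=rng.integers(0, 2, 2).astype(float),
        dnam={cpg_id: rng.normal(size=2)},
        mqtl_score={cpg_id: np.repeat(rng.normal(), 2) if share else rng.normal(size=2)},
    )


def greedy_clump_oracle(stats_table, r2_lookup, p_threshold, r2_threshold, cis_window, cpg_pos):
    """Literal transcription of the clumping rule for small fixtures."""
    cands = []
    for _, row in stats_table.iterrows():
        if row["pvalue"] > p_threshold:
            continue
        if cpg_pos is not None and abs(row["position"] - cpg_pos) > cis_window:
            continue
        cands.append((row["pvalue"], row["position"], row["snp_id"]))
    cands.sort()
    selected = []
    while cands:
        top = cands.pop(0)
        selected.append(top[2])
        cands = [c for c in cands if r2_lookup(top[2], c[2]) < r2_threshold]
    return selected


def bh_oracle(pvals):
    """Step-up BH by the literal definition: q_i = min over j with
    p_(j) >= p_i of min(1, m * p_(j) / rank_j)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        q[i] = min(
            min(1.0, m * p[j] / ranks[j]) for j in range(m) if ranks[j] >= ranks[i]
        )
    return q
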