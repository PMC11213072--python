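"""MR-DoC structural equation models for twin pairs.

Three model variants estimate causal effects between a binary smoking
phenotype (modelled as a thresholded normal liability) and a continuous
DNAm variable, using polygenic instrument scores alongside the cross-twin
cross-trait covariance information of MZ and DZ pairs:

* ``doc1_pleiotropy`` — unidirectional, one instrument, a free horizontal
  pleiotropy path from the instrument to the outcome, rE fixed at 0;
* ``doc1_re`` — unidirectional, one instrument, no pleiotropy path, free
  unique-environmental confounding rE;
* ``doc2`` — bidirectional, both instruments with a free covariance
  between them, both causal paths free.

Each phenotype's residual variance decomposes into additive-genetic (A)
and unique-environmental (E) factors (an AE model); rA/rE are the
cross-trait correlations of those factors and represent confounding.
The likelihood is full-information: complete pairs contribute a Gaussian
density for the continuous block times a bivariate-normal rectangle
probability for the smoking pattern conditional on it; pairs with one
missing smoking status marginalize that dimension, and singletons
contribute their one-twin marginal.  The liability scale is identified by
constraining its total structural variance to 1 (the residual E loading is
solved from the remaining parameters); age and sex shift the liability
mean only (DNAm is residualized for them upstream).  Internally, age is
z-scored and sex centred within the cohort, so ``beta_age`` is per SD of
age.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

from ._bvn import bivariate_normal_orthant, bvn_cdf

__all__ = [
    "MRDoCSpec",
    "ParameterVector",
    "MomentSet",
    "FitResult",
    "FitOptions",
    "implied_covariance",
    "bivariate_normal_orthant",
    "pair_loglik",
    "cohort_loglik",
    "starting_values",
    "fit_mrdoc",
    "wald_statistics",
]

VARIANTS = ("doc1_pleiotropy", "doc1_re", "doc2")
DIRECTIONS = ("binary_exposure", "continuous_exposure", "bidirectional")

_LOG2PI = math.log(2.0 * math.pi)
_TINY_P = 1e-300


@dataclass(frozen=True)
class MRDoCSpec:
    """Which MR-DoC variant to fit, in which causal direction.

    ``binary_exposure`` is Smoking -> DNAm with the smoking PRS as the
    instrument; ``continuous_exposure`` is DNAm -> Smoking with the mQTL
    allelic score; ``bidirectional`` (doc2 only) carries both.
    ``dz_iv_cross_corr`` is the DZ cross-twin correlation of the instrument
    scores: 0.5 under random mating, or the string ``"free"`` to estimate it.
    ``observed_liability`` replaces the threshold model by a directly
    observed continuous exposure (the asymptotic IV limit of the model).
    """

    variant: str = "doc1_pleiotropy"
    direction: str = "binary_exposure"
    dz_iv_cross_corr: float | str = 0.5
    free_re_doc2: bool = False
    observed_liability: bool = False
    extra_fixed: tuple[str, ...] = ()  # parameters to pin at 0 (e.g. nesting checks)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if (self.variant == "doc2") != (self.direction == "bidirectional"):
            raise ValueError("doc2 is bidirectional; doc1 variants are unidirectional")

    @property
    def iv_names(self) -> tuple[str, ...]:
        if self.direction == "binary_exposure":
            return ("prs",)
        if self.direction == "continuous_exposure":
            return ("mqtl",)
        return ("prs", "mqtl")

    def free_parameters(self) -> tuple[str, ...]:
        names: list[str] = []
        if self.direction in ("binary_exposure", "bidirectional"):
            names.append("g1")
        if self.direction in ("continuous_exposure", "bidirectional"):
            names.append("g2")
        names.append("b1")
        if self.variant == "doc1_pleiotropy":
            names.append("b2")
        if self.variant == "doc2":
            names += ["b3", "c_iv"]
        names += ["a_x", "a_y", "e_y"]
        if self.observed_liability:
            names.append("e_x")
        names.append("r_a")
        if self.variant == "doc1_re" or (self.variant == "doc2" and self.free_re_doc2):
            names.append("r_e")
        if not self.observed_liability:
            names.append("tau")
        names += ["beta_age", "beta_sex"]
        if "prs" in self.iv_names:
            names.append("v_prs")
        if "mqtl" in self.iv_names:
            names.append("v_mqtl")
        if self.dz_iv_cross_corr == "free":
            names.append("dz_iv_cross_corr")
        return tuple(n for n in names if n not in self.extra_fixed)


@dataclass
class ParameterVector:
    """Natural-scale parameters of an MR-DoC model.

    ``b1`` is instrument -> exposure, ``b2`` the horizontal-pleiotropy path
    instrument -> outcome, ``b3`` the second instrument's path to its own
    phenotype (doc2).  Parameters not used by a given spec are ignored.
    """

    g1: float = 0.0
    g2: float = 0.0
    b1: float = 0.0
    b2: float = 0.0
    b3: float = 0.0
    a_x: float = 0.6
    e_x: float = 0.8
    a_y: float = 0.7
    e_y: float = 0.7
    r_a: float = 0.0
    r_e: float = 0.0
    tau: float = 0.0
    beta_age: float = 0.0
    beta_sex: float = 0.0
    v_prs: float = 1.0
    v_mqtl: float = 1.0
    c_iv: float = 0.0
    dz_iv_cross_corr: float = 0.5

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class MomentSet:
    """Model-implied moments for one zygosity group.

    Variable order is [smk1, dnam1, iv(s)1, smk2, dnam2, iv(s)2]; means are
    zero for the continuous variables while the liability mean per
    individual is beta_age*zage + beta_sex*csex.
    """

    order: tuple[str, ...]
    covariance: np.ndarray
    zygosity: str
    tau: float
    beta_age: float
    beta_sex: float

    @property
    def mean_base(self) -> np.ndarray:
        return np.zeros(len(self.order))


class InadmissibleParameters(ValueError):
    pass


def _structural_paths(spec: MRDoCSpec, p: ParameterVector):
    """(prs->liab, prs->dnam, mqtl->dnam, mqtl->liab) for the spec."""
    if spec.direction == "binary_exposure":
        return p.b1, p.b2, 0.0, 0.0
    if spec.direction == "continuous_exposure":
        return 0.0, 0.0, p.b1, p.b2
    return p.b1, p.b2, p.b3, 0.0


def _check_admissible(spec: MRDoCSpec, p: ParameterVector) -> None:
    if abs(p.r_a) > 1 or abs(p.r_e) > 1 or abs(p.dz_iv_cross_corr) > 1:
        raise InadmissibleParameters("correlation outside [-1, 1]")
    if p.e_x <= 0 or p.e_y <= 0:
        raise InadmissibleParameters("unique-environment loadings must be positive")
    if p.v_prs <= 0 or p.v_mqtl <= 0:
        raise InadmissibleParameters("instrument variances must be positive")
    if abs(p.g1 * p.g2) >= 1:
        raise InadmissibleParameters("unstable simultaneous system: |g1*g2| >= 1")
    if len(spec.iv_names) == 2 and p.c_iv**2 > p.v_prs * p.v_mqtl:
        raise InadmissibleParameters("instrument covariance exceeds variance bound")


def _assemble_sigma(spec: MRDoCSpec, p: ParameterVector, zygosity: str) -> np.ndarray:
    """Full implied covariance over [smk1, dnam1, ivs1, smk2, dnam2, ivs2]."""
    _check_admissible(spec, p)
    ivs = spec.iv_names
    k = len(ivs)
    pl, pd_, md, ml = _structural_paths(spec, p)
    q = 4 + k  # exogenous: A_x, E_x, A_y, E_y, iv(s)
    lam = np.zeros((2, q))
    lam[0, 0], lam[0, 1] = p.a_x, p.e_x
    lam[1, 2], lam[1, 3] = p.a_y, p.e_y
    for j, iv in enumerate(ivs):
        lam[0, 4 + j] = pl if iv == "prs" else ml
        lam[1, 4 + j] = pd_ if iv == "prs" else md
    det = 1.0 - p.g1 * p.g2
    M = np.array([[1.0, p.g2], [p.g1, 1.0]]) / det
    G = np.zeros((2 + k, q))
    G[:2] = M @ lam
    for j in range(k):
        G[2 + j, 4 + j] = 1.0

    if k == 1:
        v = p.v_prs if ivs[0] == "prs" else p.v_mqtl
        szz = np.array([[v]])
    else:
        szz = np.array([[p.v_prs, p.c_iv], [p.c_iv, p.v_mqtl]])

    def exo_cov(kappa_a: float, kappa_e: float, kappa_z: float) -> np.ndarray:
        S = np.zeros((q, q))
        S[0, 0] = S[2, 2] = kappa_a
        S[0, 2] = S[2, 0] = kappa_a * p.r_a
        S[1, 1] = S[3, 3] = kappa_e
        S[1, 3] = S[3, 1] = kappa_e * p.r_e
        S[4:, 4:] = kappa_z * szz
        return S

    kappa_a = 1.0 if zygosity == "MZ" else 0.5
    kappa_z = 1.0 if zygosity == "MZ" else float(p.dz_iv_cross_corr)
    s_within = exo_cov(1.0, 1.0, 1.0)
    s_cross = exo_cov(kappa_a, 0.0, kappa_z)
    sig_w = G @ s_within @ G.T
    sig_c = G @ s_cross @ G.T
    d = 2 + k
    full = np.empty((2 * d, 2 * d))
    full[:d, :d] = sig_w
    full[d:, d:] = sig_w
    full[:d, d:] = sig_c
    full[d:, :d] = sig_c.T
    return full


def implied_covariance(spec: MRDoCSpec, params: ParameterVector, zygosity: str) -> MomentSet:
    """Model-implied covariance matrix for MZ or DZ twin pairs.

    Cross-twin A-mediated covariances carry coefficient 1 (MZ) or 0.5 (DZ);
    instrument cross-twin covariances carry 1 (MZ) or ``dz_iv_cross_corr``
    (DZ); the simultaneous g1/g2 system is resolved by its exact reduced
    form.
    """
    if zygosity not in ("MZ", "DZ"):
        raise ValueError("zygosity must be 'MZ' or 'DZ'")
    cov = _assemble_sigma(spec, params, zygosity)
    names = []
    for t in (1, 2):
        names += [f"smk{t}", f"dnam{t}"] + [f"{iv}{t}" for iv in spec.iv_names]
    return MomentSet(
        order=tuple(names),
        covariance=cov,
        zygosity=zygosity,
        tau=params.tau,
        beta_age=params.beta_age,
        beta_sex=params.beta_sex,
    )


def solve_e_x(spec: MRDoCSpec, p: ParameterVector) -> float:
    """Residual liability E loading that makes the structural liability
    variance exactly 1 (probit identification).

    Raises :class:`InadmissibleParameters` when no positive solution exists.
    """
    pl, pd_, md, ml = _structural_paths(spec, p)
    ivs = spec.iv_names
    v1 = p.v_prs if "prs" in ivs else 0.0
    v2 = p.v_mqtl if "mqtl" in ivs else 0.0
    c12 = p.c_iv if len(ivs) == 2 else 0.0
    P = pl**2 * v1 + ml**2 * v2 + 2 * pl * ml * c12 + p.a_x**2
    Q = pl * pd_ * v1 + ml * md * v2 + (pl * md + ml * pd_) * c12 + p.a_x * p.a_y * p.r_a
    R = pd_**2 * v1 + md**2 * v2 + 2 * pd_ * md * c12 + p.a_y**2 + p.e_y**2
    D = (1.0 - p.g1 * p.g2) ** 2
    b = p.g2 * p.r_e * p.e_y
    c_term = P + 2 * p.g2 * Q + p.g2**2 * R - D
    disc = b * b - c_term
    if disc <= 0:
        raise InadmissibleParameters(
            "no positive residual E loading satisfies unit liability variance"
        )
    e_x = -b + math.sqrt(disc)
    if e_x <= 1e-6:
        raise InadmissibleParameters("residual E loading collapsed to zero")
    return e_x


# --------------------------------------------------------------------------
# Prepared data and vectorized likelihood


def _full_order_indices(k: int):
    """Index helpers into the [smk1, dnam1, z1.., smk2, dnam2, z2..] order."""
    smk = (0, 2 + k)
    dnam = (1, 3 + k)
    z1 = list(range(2, 2 + k))
    z2 = list(range(4 + k, 4 + 2 * k))
    return smk, dnam, z1, z2


class _Group:
    """Pre-extracted arrays for one homogeneous likelihood group."""

    def __init__(self, kind, zygosity, cont, cont_idx, lat_idx, smk, zage, csex, smk_cols=()):
        self.kind = kind  # "pair" | "single"
        self.zygosity = zygosity
        self.cont = cont  # (n, d_c)
        self.cont_idx = np.asarray(cont_idx, dtype=int)
        self.lat_idx = np.asarray(lat_idx, dtype=int)
        self.smk = smk  # (n, 2) or (n, 1), float with NaN
        self.zage = zage
        self.csex = csex
        self.smk_cols = smk_cols  # positions of observed-liability columns in cont
        self.n = len(cont)
        self.cc_ix = np.ix_(self.cont_idx, self.cont_idx)
        self.xc_ix = np.ix_(self.lat_idx, self.cont_idx)
        self.xx_ix = np.ix_(self.lat_idx, self.lat_idx)
        self.cont_T = np.ascontiguousarray(cont.T)
        m = smk.shape[1]
        obs = ~np.isnan(smk)
        if m == 2:
            self.idx_both = np.flatnonzero(obs[:, 0] & obs[:, 1])
            self.idx_only1 = np.flatnonzero(obs[:, 0] & ~obs[:, 1])
            self.idx_only2 = np.flatnonzero(~obs[:, 0] & obs[:, 1])
            s = smk
            self.sign1 = 1.0 - 2.0 * s[self.idx_both, 0]
            self.sign2 = 1.0 - 2.0 * s[self.idx_both, 1]
            self.sign_o1 = 1.0 - 2.0 * s[self.idx_only1, 0]
            self.sign_o2 = 1.0 - 2.0 * s[self.idx_only2, 1]
        else:
            self.idx_obs = np.flatnonzero(obs[:, 0])
            self.sign_s = 1.0 - 2.0 * smk[self.idx_obs, 0]


class _Likelihood:
    """Vectorized FIML log-likelihood over a prepared twin cohort."""

    def __init__(self, cohort, spec: MRDoCSpec, cpg_id: str, standardize_covariates: bool = True):
        from .synthetic_data import dnam_col, mqtl_col

        self.spec = spec
        self.cpg_id = cpg_id
        # canonical order: estimates must not depend on record order
        df = cohort.data.sort_values(["zygosity", "family_id", "twin_order"]).reset_index(
            drop=True
        )
        k = len(spec.iv_names)
        self.k = k
        age = df["age"].to_numpy(dtype=float)
        sex = df["sex"].to_numpy(dtype=float)
        if standardize_covariates and len(df) > 1:
            self.age_mean = float(age.mean())
            self.age_sd = float(age.std(ddof=1)) or 1.0
            self.sex_mean = float(sex.mean())
        else:
            self.age_mean, self.age_sd, self.sex_mean = 0.0, 1.0, 0.0

        cols = {"dnam": dnam_col(cpg_id)}
        iv_col = {"prs": "prs", "mqtl": mqtl_col(cpg_id)}
        for iv in spec.iv_names:
            if iv_col[iv] not in df.columns:
                raise KeyError(f"cohort lacks instrument column {iv_col[iv]!r}")

        work = df.copy()
        work["_zage"] = (age - self.age_mean) / self.age_sd
        work["_csex"] = sex - self.sex_mean

        self.groups: list[_Group] = []
        self.n_pairs_used = {"MZ": 0, "DZ": 0, "singleton": 0}
        singles = [work[work["zygosity"] == "singleton"]]
        for zyg in ("MZ", "DZ"):
            sub = work[work["zygosity"] == zyg].sort_values(["family_id", "twin_order"])
            sizes = sub.groupby("family_id").size()
            lone = sizes[sizes != 2].index
            if len(lone):
                singles.append(sub[sub["family_id"].isin(lone)])
                sub = sub[~sub["family_id"].isin(lone)]
            if not len(sub):
                continue
            n = len(sub) // 2
            self.n_pairs_used[zyg] = n

            def wide(col, s=sub, n=n):
                return s[col].to_numpy(dtype=float).reshape(n, 2)

            dnam = wide(cols["dnam"])
            zvals = {iv: wide(iv_col[iv]) for iv in spec.iv_names}
            smk = wide("smoking")
            zage, csex = wide("_zage"), wide("_csex")
            smk_idx, dnam_idx, z1, z2 = _full_order_indices(k)
            if spec.observed_liability:
                if zyg == "MZ":
                    cont = np.column_stack(
                        [smk[:, 0], dnam[:, 0], smk[:, 1], dnam[:, 1]]
                        + [zvals[iv].mean(axis=1) for iv in spec.iv_names]
                    )
                    cont_idx = [smk_idx[0], dnam_idx[0], smk_idx[1], dnam_idx[1]] + z1
                    smk_cols = (0, 2)
                else:
                    cont = np.column_stack(
                        [smk[:, 0], dnam[:, 0]]
                        + [zvals[iv][:, 0] for iv in spec.iv_names]
                        + [smk[:, 1], dnam[:, 1]]
                        + [zvals[iv][:, 1] for iv in spec.iv_names]
                    )
                    cont_idx = [smk_idx[0], dnam_idx[0], *z1, smk_idx[1], dnam_idx[1], *z2]
                    smk_cols = (0, 2 + k)
                if np.isnan(cont).any():
                    raise ValueError("observed-liability model requires complete data")
                grp = _Group("pair", zyg, cont, cont_idx, [], np.full((n, 2), np.nan), zage, csex, smk_cols)
            else:
                if zyg == "MZ":
                    cont = np.column_stack(
                        [dnam[:, 0], dnam[:, 1]]
                        + [zvals[iv].mean(axis=1) for iv in spec.iv_names]
                    )
                    cont_idx = [dnam_idx[0], dnam_idx[1]] + z1
                else:
                    cont = np.column_stack(
                        [dnam[:, 0]]
                        + [zvals[iv][:, 0] for iv in spec.iv_names]
                        + [dnam[:, 1]]
                        + [zvals[iv][:, 1] for iv in spec.iv_names]
                    )
                    cont_idx = [dnam_idx[0], *z1, dnam_idx[1], *z2]
                grp = _Group("pair", zyg, cont, cont_idx, list(smk_idx), smk, zage, csex)
            self.groups.append(grp)

        sing = singles[0] if len(singles) == 1 else pd.concat(singles, ignore_index=True)
        if len(sing):
            self.n_pairs_used["singleton"] = len(sing)
            dnam = sing[cols["dnam"]].to_numpy(dtype=float)[:, None]
            zvals = [sing[iv_col[iv]].to_numpy(dtype=float)[:, None] for iv in spec.iv_names]
            smk = sing["smoking"].to_numpy(dtype=float)[:, None]
            zage = sing["_zage"].to_numpy(dtype=float)[:, None]
            csex = sing["_csex"].to_numpy(dtype=float)[:, None]
            if spec.observed_liability:
                cont = np.column_stack([smk, dnam] + zvals)
                grp = _Group(
                    "single", "MZ", cont, list(range(2 + k)), [],
                    np.full((len(sing), 1), np.nan), zage, csex, smk_cols=(0,),
                )
            else:
                cont = np.column_stack([dnam] + zvals)
                grp = _Group("single", "MZ", cont, list(range(1, 2 + k)), [0], smk, zage, csex)
            self.groups.append(grp)
        if self.n_pairs_used["MZ"] == 0 or self.n_pairs_used["DZ"] == 0:
            warnings.warn("cohort lacks one zygosity group; A/E decomposition weakly identified")

    # -- evaluation ---------------------------------------------------------

    def loglik(self, p: ParameterVector) -> float:
        sig = {
            "MZ": _assemble_sigma(self.spec, p, "MZ"),
            "DZ": _assemble_sigma(self.spec, p, "DZ"),
        }
        total = 0.0
        for g in self.groups:
            total += self._group_loglik(g, sig[g.zygosity], p)
        return float(total)

    def _group_loglik(self, g: _Group, sigma: np.ndarray, p: ParameterVector) -> float:
        d_full = sigma.shape[0]
        if g.kind == "single":
            sigma = sigma[: d_full // 2, : d_full // 2]
        scc = sigma[g.cc_ix]
        cont_T = g.cont_T
        if g.smk_cols:  # observed liability: subtract its covariate mean
            cont_T = cont_T.copy()
            for pos, t in zip(g.smk_cols, range(g.zage.shape[1])):
                cont_T[pos] -= p.beta_age * g.zage[:, t] + p.beta_sex * g.csex[:, t]
        try:
            cho = cho_factor(scc, lower=True, check_finite=False)
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise InadmissibleParameters(f"continuous block not PD: {exc}") from None
        logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        sol = cho_solve(cho, cont_T, check_finite=False)
        quad = float(np.sum(cont_T * sol))
        d_c = len(g.cont_idx)
        ll = -0.5 * (g.n * d_c * _LOG2PI + g.n * logdet + quad)
        if len(g.lat_idx) == 0:
            return ll
        sxc = sigma[g.xc_ix]
        W = cho_solve(cho, sxc.T, check_finite=False).T
        scond = sigma[g.xx_ix] - W @ sxc.T
        mu = cont_T.T @ W.T
        if g.kind == "single" or g.smk.shape[1] == 1:
            var = scond[0, 0]
            if var <= 0:
                raise InadmissibleParameters("non-PSD conditional liability variance")
            sd = math.sqrt(var)
            t_thr = p.tau - p.beta_age * g.zage[:, 0] - p.beta_sex * g.csex[:, 0]
            lo = (t_thr - mu[:, 0]) / sd
            pr = ndtr(g.sign_s * lo[g.idx_obs])
            return ll + float(np.sum(np.log(np.clip(pr, _TINY_P, 1.0))))
        v1, v2 = scond[0, 0], scond[1, 1]
        if v1 <= 0 or v2 <= 0:
            raise InadmissibleParameters(
                "non-PSD conditional liability covariance (check r_a/r_e/loadings)"
            )
        sd1, sd2 = math.sqrt(v1), math.sqrt(v2)
        rho = scond[0, 1] / (sd1 * sd2)
        rho = float(np.clip(rho, -1.0, 1.0))
        t1 = p.tau - p.beta_age * g.zage[:, 0] - p.beta_sex * g.csex[:, 0]
        t2 = p.tau - p.beta_age * g.zage[:, 1] - p.beta_sex * g.csex[:, 1]
        l1 = (t1 - mu[:, 0]) / sd1
        l2 = (t2 - mu[:, 1]) / sd2
        out = 0.0
        if len(g.idx_both):
            c1 = g.sign1 * l1[g.idx_both]
            c2 = g.sign2 * l2[g.idx_both]
            same = g.sign1 * g.sign2 > 0
            pr = np.empty(len(c1))
            if same.any():
                pr[same] = bvn_cdf(c1[same], c2[same], rho)
            if (~same).any():
                pr[~same] = bvn_cdf(c1[~same], c2[~same], -rho)
            out += float(np.sum(np.log(np.clip(pr, _TINY_P, 1.0))))
        if len(g.idx_only1):
            pr = ndtr(g.sign_o1 * l1[g.idx_only1])
            out += float(np.sum(np.log(np.clip(pr, _TINY_P, 1.0))))
        if len(g.idx_only2):
            pr = ndtr(g.sign_o2 * l2[g.idx_only2])
            out += float(np.sum(np.log(np.clip(pr, _TINY_P, 1.0))))
        return ll + out


def _record_cohort(record, cpg_id: str):
    """Wrap one TwinPairRecord as a minimal cohort (no covariate rescaling:
    the record's age/sex are taken as already on the analysis scale)."""
    from .synthetic_data import TwinCohort, dnam_col, mqtl_col

    n_tw = 1 if record.is_singleton else 2
    rows = {
        "family_id": [record.family_id] * n_tw,
        "zygosity": [record.zygosity] * n_tw,
        "twin_order": list(range(1, n_tw + 1)),
        "smoking": record.smoking[:n_tw],
        "age": record.age[:n_tw],
        "sex": record.sex[:n_tw],
        "prs": record.prs[:n_tw],
        dnam_col(cpg_id): record.dnam[cpg_id][:n_tw],
    }
    if cpg_id in record.mqtl_score:
        rows[mqtl_col(cpg_id)] = record.mqtl_score[cpg_id][:n_tw]
    return TwinCohort(pd.DataFrame(rows), [cpg_id])


def pair_loglik(params: ParameterVector, record, spec: MRDoCSpec, cpg_id: str | None = None) -> float:
    """FIML log-likelihood contribution of a single twin pair or singleton.

    The record's age and sex values are used as-is (no within-cohort
    standardization is possible for one record), so supply them on the same
    scale the liability model assumes.
    """
    if cpg_id is None:
        cpg_id = next(iter(record.dnam))
    obs = ~np.isnan(record.dnam[cpg_id][: 1 if record.is_singleton else 2])
    if not obs.any():
        raise ValueError("record has no observed data for the requested CpG")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lik = _Likelihood(
            _record_cohort(record, cpg_id), spec, cpg_id, standardize_covariates=False
        )
    return lik.loglik(params)


def cohort_loglik(cohort, spec: MRDoCSpec, params: ParameterVector, cpg_id: str | None = None) -> float:
    """Total FIML log-likelihood of a cohort at fixed parameters."""
    if cpg_id is None:
        cpg_id = cohort.cpg_ids[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lik = _Likelihood(cohort, spec, cpg_id)
    return lik.loglik(params)


# --------------------------------------------------------------------------
# Fitting


_LOG_PARAMS = ("v_prs", "v_mqtl", "e_y", "e_x")
_TANH_PARAMS = ("r_a", "r_e", "dz_iv_cross_corr")


def _theta_to_params(theta, free_names, template: ParameterVector, spec: MRDoCSpec):
    p = replace(template)
    pending_c = None
    for name, val in zip(free_names, theta):
        if name in _LOG_PARAMS:
            setattr(p, name, math.exp(min(val, 50.0)))
        elif name in _TANH_PARAMS:
            setattr(p, name, math.tanh(val))
        elif name == "c_iv":
            pending_c = val
        else:
            setattr(p, name, val)
    if pending_c is not None:
        p.c_iv = math.tanh(pending_c) * math.sqrt(p.v_prs * p.v_mqtl)
    if abs(p.g1 * p.g2) >= 0.999:
        raise InadmissibleParameters("causal loop near instability")
    if not spec.observed_liability:
        p.e_x = solve_e_x(spec, p)
    return p


def _params_to_theta(p: ParameterVector, free_names) -> np.ndarray:
    out = []
    for name in free_names:
        v = getattr(p, name)
        if name in _LOG_PARAMS:
            out.append(math.log(max(v, 1e-6)))
        elif name in _TANH_PARAMS:
            out.append(math.atanh(float(np.clip(v, -0.99, 0.99))))
        elif name == "c_iv":
            r = v / math.sqrt(max(p.v_prs * p.v_mqtl, 1e-12))
            out.append(math.atanh(float(np.clip(r, -0.99, 0.99))))
        else:
            out.append(v)
    return np.array(out, dtype=float)


@dataclass
class FitOptions:
    maxiter: int = 1000
    gtol: float = 1e-6
    ftol: float = 1e-11
    max_restarts: int = 3
    seed: int = 0
    compute_se: bool = True
    hessian_step: float = 1e-4


@dataclass
class FitResult:
    """MLE, standard errors and Wald inference for one CpG x model."""

    spec: MRDoCSpec
    cpg_id: str
    estimates: ParameterVector
    free_names: tuple[str, ...]
    standard_errors: dict[str, float]
    vcov: np.ndarray | None
    loglik: float
    convergence_status: dict
    n_pairs_used: dict[str, int]

    @property
    def converged(self) -> bool:
        return bool(self.convergence_status.get("converged", False))

    def wald(self, name: str):
        return wald_statistics(self, name)


def starting_values(cohort, spec: MRDoCSpec, cpg_id: str | None = None) -> ParameterVector:
    """Data-driven starting values.

    The threshold starts at the probit of the observed smoking proportion;
    instrument paths at single-variable probit/linear regression slopes;
    variance loadings follow Falconer-style cross-twin correlation
    arithmetic; causal paths start at exactly 0.
    """
    from .synthetic_data import dnam_col, mqtl_col

    if cpg_id is None:
        cpg_id = cohort.cpg_ids[0]
    df = cohort.data.sort_values(["zygosity", "family_id", "twin_order"]).reset_index(drop=True)
    if not len(df):
        raise ValueError("empty cohort")
    smk = df["smoking"].to_numpy(dtype=float)
    obs = smk[~np.isnan(smk)]
    if spec.observed_liability:
        tau0 = 0.0
    else:
        prev = float(obs.mean()) if len(obs) else math.nan
        if not len(obs) or prev in (0.0, 1.0):
            raise ValueError("degenerate cohort: smoking proportion is 0 or 1")
        tau0 = float(ndtri(1.0 - prev))
    y = df[dnam_col(cpg_id)].to_numpy(dtype=float)

    def cross_twin_corr(col):
        out = {}
        for zyg in ("MZ", "DZ"):
            sub = df[df["zygosity"] == zyg].sort_values(["family_id", "twin_order"])
            sizes = sub.groupby("family_id").size()
            sub = sub[sub["family_id"].isin(sizes[sizes == 2].index)]
            v = sub[col].to_numpy(dtype=float).reshape(-1, 2)
            v = v[~np.isnan(v).any(axis=1)]
            out[zyg] = float(np.corrcoef(v[:, 0], v[:, 1])[0, 1]) if len(v) > 2 else np.nan
        return out

    ry = cross_twin_corr(dnam_col(cpg_id))
    a2y = 2.0 * ((ry["MZ"] or 0) - (ry["DZ"] or 0)) if not any(np.isnan(list(ry.values()))) else 0.4
    a2y = float(np.clip(np.nan_to_num(a2y, nan=0.4), 0.05, 0.85))
    e2y = float(np.clip(1.0 - np.nan_to_num(ry["MZ"], nan=0.5), 0.05, 0.9))
    rs = cross_twin_corr("smoking")
    if spec.observed_liability:
        a2x = 2.0 * np.nan_to_num(rs["MZ"] - rs["DZ"], nan=0.2)
    else:
        t = ndtri(1.0 - prev)
        infl = prev * (1.0 - prev) / (math.exp(-0.5 * t * t) / math.sqrt(2 * math.pi)) ** 2
        a2x = 2.0 * np.nan_to_num(rs["MZ"] - rs["DZ"], nan=0.2) * infl
    a2x = float(np.clip(a2x, 0.05, 0.7))

    p = ParameterVector(tau=tau0, a_y=math.sqrt(a2y), e_y=math.sqrt(e2y), a_x=math.sqrt(a2x))
    mq = mqtl_col(cpg_id)

    def ols_slope(xcol):
        x = df[xcol].to_numpy(dtype=float)
        return float(np.cov(x, y)[0, 1] / x.var(ddof=1))

    def probit_slope(xcol):
        x = df[xcol].to_numpy(dtype=float)
        m = ~np.isnan(smk)
        if spec.observed_liability:  # exposure observed directly: linear slope
            return float(np.cov(x[m], smk[m])[0, 1] / x[m].var(ddof=1))
        try:
            import statsmodels.api as sm

            fitted = sm.Probit(smk[m], sm.add_constant(x[m])).fit(disp=0, maxiter=50)
            return float(fitted.params[1])
        except Exception:
            return 0.1

    if spec.direction == "binary_exposure":
        p.b1 = probit_slope("prs")
        p.v_prs = float(df["prs"].var(ddof=1))
    elif spec.direction == "continuous_exposure":
        p.b1 = ols_slope(mq)
        p.v_mqtl = float(df[mq].var(ddof=1))
    else:
        p.b1 = probit_slope("prs")
        p.b3 = ols_slope(mq)
        p.v_prs = float(df["prs"].var(ddof=1))
        p.v_mqtl = float(df[mq].var(ddof=1))
        p.c_iv = float(np.cov(df["prs"], df[mq])[0, 1])
    if spec.dz_iv_cross_corr != "free":
        p.dz_iv_cross_corr = float(spec.dz_iv_cross_corr)
    if spec.observed_liability:
        m = ~np.isnan(smk)
        resid_var = float(np.var(smk[m])) - p.b1**2 * float(np.var(df["prs"][m]))
        resid_var = max(resid_var, 0.1)
        p.a_x = math.sqrt(max(resid_var * a2x, 0.02))
        p.e_x = math.sqrt(max(resid_var - p.a_x**2, 0.02))
    else:
        cap = 0.95 * (1.0 - p.a_x**2)
        if p.b1**2 > cap and spec.direction != "continuous_exposure":
            p.b1 = math.copysign(math.sqrt(cap), p.b1)
        try:
            p.e_x = solve_e_x(spec, p)
        except InadmissibleParameters:
            p.a_x, p.b1 = 0.5, 0.1
            p.e_x = solve_e_x(spec, p)
    return p


def _fixed_template(spec: MRDoCSpec, start: ParameterVector) -> ParameterVector:
    """Template holding every fixed parameter at its fixed value."""
    p = replace(start)
    free = set(spec.free_parameters())
    if "g1" not in free:
        p.g1 = 0.0
    if "g2" not in free:
        p.g2 = 0.0
    if "b2" not in free:
        p.b2 = 0.0
    if "b3" not in free:
        p.b3 = 0.0
    if "c_iv" not in free:
        p.c_iv = 0.0
    if "r_e" not in free:
        p.r_e = 0.0
    if "beta_age" not in free:
        p.beta_age = 0.0
    if "beta_sex" not in free:
        p.beta_sex = 0.0
    if spec.dz_iv_cross_corr != "free":
        p.dz_iv_cross_corr = float(spec.dz_iv_cross_corr)
    for name in spec.extra_fixed:
        setattr(p, name, 0.0)
    return p


def fit_mrdoc(cohort, spec: MRDoCSpec, cpg_id: str | None = None, options: FitOptions | None = None) -> FitResult:
    """Maximum-likelihood fit of an MR-DoC model to a twin cohort.

    Optimization runs in an unconstrained reparameterization (variances and
    E loadings on the log scale, correlations through tanh, the liability
    identification constraint enforced by construction) with quasi-Newton
    iterations and up to ``max_restarts`` jittered restarts on
    non-convergence.  Standard errors come from the central-difference
    Hessian on the unconstrained scale, delta-mapped to the natural scale.
    Non-convergence flags the result instead of raising.
    """
    opts = options or FitOptions()
    if cpg_id is None:
        cpg_id = cohort.cpg_ids[0]
    lik = _Likelihood(cohort, spec, cpg_id)
    free_names = spec.free_parameters()
    start = starting_values(cohort, spec, cpg_id)
    template = _fixed_template(spec, start)
    theta0 = _params_to_theta(template, free_names)

    def objective(theta):
        try:
            p = _theta_to_params(theta, free_names, template, spec)
            ll = lik.loglik(p)
        except (InadmissibleParameters, np.linalg.LinAlgError):
            return 1e10
        if not np.isfinite(ll):
            return 1e10
        return -ll

    rng = np.random.default_rng(opts.seed)
    best = None
    n_restarts = 0
    theta_try = theta0.copy()
    for attempt in range(opts.max_restarts + 1):
        res = minimize(
            objective,
            theta_try,
            method="L-BFGS-B",
            options={"maxiter": opts.maxiter, "ftol": opts.ftol, "gtol": opts.gtol},
        )
        ok = res.success and np.isfinite(res.fun) and res.fun < 1e9
        if best is None or res.fun < best.fun:
            best = res
        if ok:
            break
        n_restarts = attempt + 1
        theta_try = theta0 + rng.normal(scale=0.25, size=len(theta0))
    res = best
    theta_hat = res.x
    converged = bool(res.success and np.isfinite(res.fun) and res.fun < 1e9)
    try:
        p_hat = _theta_to_params(theta_hat, free_names, template, spec)
    except InadmissibleParameters:
        p_hat = template
        converged = False
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else math.nan

    boundary = [
        n for n in free_names
        if n in _TANH_PARAMS and abs(getattr(p_hat, n)) > 0.999
    ]
    se: dict[str, float] = {}
    vcov_nat = None
    hess_cond = math.nan
    if converged and opts.compute_se:
        H = _numerical_hessian(objective, theta_hat, opts.hessian_step)
        try:
            hess_cond = float(np.linalg.cond(H))
            vcov_u = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            vcov_u = np.linalg.pinv(H)
        J = _transform_jacobian(theta_hat, free_names, template, spec)
        vcov_nat = J @ vcov_u @ J.T
        diag = np.clip(np.diag(vcov_nat), 0.0, None)
        se = {n: float(math.sqrt(v)) for n, v in zip(free_names, diag)}
    status = {
        "converged": converged,
        "message": str(res.message),
        "grad_norm": grad_norm,
        "hessian_condition": hess_cond,
        "n_restarts": n_restarts,
        "boundary_parameters": boundary,
        "n_function_evals": int(res.nfev),
    }
    return FitResult(
        spec=spec,
        cpg_id=cpg_id,
        estimates=p_hat,
        free_names=free_names,
        standard_errors=se,
        vcov=vcov_nat,
        loglik=float(-res.fun),
        convergence_status=status,
        n_pairs_used=dict(lik.n_pairs_used),
    )


def _numerical_hessian(f, x, step):
    n = len(x)
    H = np.empty((n, n))
    h = step * np.maximum(1.0, np.abs(x))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                H[i, i] = (f(xp) - 2 * f0 + f(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[[i, j]] += [h[i], h[j]]
                xpm[i] += h[i]
                xpm[j] -= h[j]
                xmp[i] -= h[i]
                xmp[j] += h[j]
                xmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h[i] * h[j])
    return H


def _transform_jacobian(theta, free_names, template, spec, step=1e-6):
    """d(natural free parameters)/d(theta), by central differences."""
    n = len(theta)
    J = np.empty((n, n))

    def natural(th):
        p = _theta_to_params(th, free_names, template, spec)
        return np.array([getattr(p, nm) for nm in free_names])

    for i in range(n):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += step
        tm[i] -= step
        J[:, i] = (natural(tp) - natural(tm)) / (2 * step)
    return J


def wald_statistics(fit: FitResult, param_name: str) -> tuple[float, float]:
    """Wald z and two-sided p for one free parameter of a converged fit."""
    if not fit.converged:
        raise ValueError("fit did not converge; Wald inference unavailable")
    if param_name not in fit.free_names:
        raise ValueError(f"{param_name!r} is not a free parameter of this fit")
    se = fit.standard_errors.get(param_name)
    if se is None:
        raise ValueError("standard errors were not computed for this fit")
    if se == 0:
        raise ZeroDivisionError(f"standard error of {param_name!r} is zero")
    est = getattr(fit.estimates, param_name)
    z = est / se
    p = 2.0 * float(ndtr(-abs(z)))
    return float(z), p
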