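"""Synthetic twin cohorts with the covariance structure MR-DoC models assume.

The generator mirrors the study design it is meant to exercise: MZ and DZ
twin pairs plus singletons; a binary smoking status arising from a normal
liability crossing a threshold; one or more standardized continuous DNAm
variables; polygenic instrument scores with cross-twin correlation 1 in MZ
and 0.5 (random mating) in DZ pairs; latent additive-genetic (A) and unique
environmental (E) factors with cross-trait correlations rA and rE providing
confounding; causal paths in both directions solved as a simultaneous
linear system; and age/sex effects shifting the liability mean.

Default cohort sizes, smoking prevalence, instrument strengths and the
age/sex composition reproduce the target study design: 706 MZ pairs, 412 DZ
pairs, 341 singletons; current-smoking prevalence 528/2020 among the
current-vs-never contrast; PRS explaining 5.07% of liability variance; mQTL
scores explaining 9.04% of DNAm variance on average; ages 18-79; 67% female.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq, fsolve
from scipy.special import ndtri
from scipy.stats import norm

from ._bvn import bivariate_normal_orthant
from .instruments import GenotypeMatrix, LDMatrix, MqtlSummaryStats

__all__ = [
    "SyntheticScenario",
    "TwinCohort",
    "TwinPairRecord",
    "simulate_cohort",
    "simulate_screen_cohort",
    "simulate_genotype_fixture",
    "dnam_col",
    "mqtl_col",
]

# Study design constants (cohort composition and instrument strength).
_N_NEVER, _N_FORMER, _N_CURRENT = 1492, 549, 528
_CURRENT_PREVALENCE = _N_CURRENT / (_N_CURRENT + _N_NEVER)
_PRS_LIABILITY_R2 = 0.0507
_MQTL_DNAM_R2 = 0.0904
_LIABILITY_A_SHARE = 0.44  # residual A share; total genetic ~0.49 incl. PRS


def dnam_col(cpg_id: str) -> str:
    return f"dnam_{cpg_id}"


def mqtl_col(cpg_id: str) -> str:
    return f"mqtl_{cpg_id}"


@dataclass(frozen=True)
class SyntheticScenario:
    """Generative parameters of a simulated twin cohort (one CpG).

    Paths are on the standardized-liability / standardized-DNAm scale:
    ``g1`` liability->DNAm, ``g2`` DNAm->liability, ``b1`` PRS->liability,
    ``b2`` pleiotropy PRS->DNAm, ``b3`` mQTL-score->DNAm.  ``a_*``/``e_*``
    are square-root A/E loadings, ``r_a``/``r_e`` the cross-trait factor
    correlations.  ``tau=None`` calibrates the threshold to the study's
    current-smoking prevalence.  Covariate effects apply to within-cohort
    z-scored age and centred sex so that they shift the liability mean
    without changing its structural variance.
    """

    n_mz_pairs: int = 706
    n_dz_pairs: int = 412
    n_singletons: int = 341
    g1: float = 0.0
    g2: float = 0.0
    b1: float = math.sqrt(_PRS_LIABILITY_R2)
    b2: float = 0.0
    b3: float = math.sqrt(_MQTL_DNAM_R2)
    a_x: float = math.sqrt(_LIABILITY_A_SHARE)
    e_x: float = math.sqrt(1.0 - _PRS_LIABILITY_R2 - _LIABILITY_A_SHARE)
    a_y: float = math.sqrt((1.0 - _MQTL_DNAM_R2) / 2.0)
    e_y: float = math.sqrt((1.0 - _MQTL_DNAM_R2) / 2.0)
    r_a: float = 0.3
    r_e: float = 0.0
    tau: float | None = None
    beta_age: float = -0.1
    beta_sex: float = -0.1
    age_range: tuple[float, float] = (18.0, 79.0)
    sex_fraction: float = 0.67
    iv_covariance: float = 0.0
    dz_iv_cross_corr: float = 0.5
    seed: int = 2026

    def __post_init__(self) -> None:
        if min(self.n_mz_pairs, self.n_dz_pairs, self.n_singletons) < 0:
            raise ValueError("cohort counts must be non-negative")
        if abs(self.r_a) > 1 or abs(self.r_e) > 1:
            raise ValueError("|r_a| and |r_e| must not exceed 1")
        if min(self.a_x, self.e_x, self.a_y, self.e_y) < 0:
            raise ValueError("A/E loadings must be non-negative")
        if self.e_x <= 0 or self.e_y <= 0:
            raise ValueError("unique-environment loadings must be positive")
        if abs(self.g1 * self.g2) >= 1:
            raise ValueError("unstable simultaneous system: |g1*g2| must be < 1")
        if not 0 <= self.sex_fraction <= 1:
            raise ValueError("sex_fraction must lie in [0, 1]")
        if abs(self.dz_iv_cross_corr) > 1 or abs(self.iv_covariance) > 1:
            raise ValueError("instrument correlations must lie in [-1, 1]")

    @property
    def threshold(self) -> float:
        if self.tau is not None:
            return self.tau
        return float(ndtri(1.0 - _CURRENT_PREVALENCE))

    def calibrated(self) -> "SyntheticScenario":
        """Rescale the A/E loadings so the implied liability and DNAm
        variances are exactly 1 under the causal and instrument paths.

        With non-zero g1/g2 the reduced-form variances exceed the sum of the
        exogenous shares; solving a 2x2 system for scale factors on the
        (a_x, e_x) and (a_y, e_y) pairs restores unit variance, so fitted
        path estimates are directly comparable to the generative values.
        """
        g1, g2, c = self.g1, self.g2, self.iv_covariance
        det2 = (1.0 - g1 * g2) ** 2
        hx = self.a_x**2 + self.e_x**2
        hy = self.a_y**2 + self.e_y**2
        cross0 = self.a_x * self.a_y * self.r_a + self.e_x * self.e_y * self.r_e
        bx = self.b1**2  # exogenous variance entering the liability equation
        by = self.b3**2 + self.b2**2 + 2 * self.b2 * self.b3 * c
        bxy = self.b1 * self.b2 + self.b1 * self.b3 * c

        def eqs(s):
            sx, sy = s
            vux = bx + sx**2 * hx
            vuy = by + sy**2 * hy
            cxy = bxy + sx * sy * cross0
            vx = (vux + 2 * g2 * cxy + g2**2 * vuy) / det2
            vy = (g1**2 * vux + 2 * g1 * cxy + vuy) / det2
            return [vx - 1.0, vy - 1.0]

        sx, sy = fsolve(eqs, [1.0, 1.0], full_output=False)
        if sx <= 0 or sy <= 0 or max(abs(np.array(eqs([sx, sy])))) > 1e-8:
            raise ValueError("could not calibrate loadings to unit variance")
        return replace(
            self,
            a_x=self.a_x * sx,
            e_x=self.e_x * sx,
            a_y=self.a_y * sy,
            e_y=self.e_y * sy,
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass
class TwinPairRecord:
    """One twin pair's (or singleton's) observed data.

    Arrays have length 2; a singleton carries NaN in the second slot.
    """

    family_id: int
    zygosity: str  # MZ | DZ | singleton
    smoking: np.ndarray
    prs: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    dnam: dict[str, np.ndarray]
    mqtl_score: dict[str, np.ndarray]

    @property
    def is_singleton(self) -> bool:
        return self.zygosity == "singleton"


@dataclass
class TwinCohort:
    """A twin cohort as a tidy one-row-per-individual table.

    Columns: family_id, zygosity, twin_order, smoking (0/1/NaN), age, sex,
    prs, then ``dnam_<cpg>`` and ``mqtl_<cpg>`` per CpG.
    """

    data: pd.DataFrame
    cpg_ids: list[str]
    contrast: str = "current_vs_never"
    scenario: SyntheticScenario | None = None

    def __post_init__(self) -> None:
        bad = set(self.data["zygosity"]) - {"MZ", "DZ", "singleton"}
        if bad:
            raise ValueError(f"unknown zygosity labels: {sorted(bad)}")

    @property
    def n_individuals(self) -> int:
        return len(self.data)

    def records(self):
        """Iterate over pairs/singletons as TwinPairRecord objects."""
        for fam, grp in self.data.groupby("family_id", sort=True):
            grp = grp.sort_values("twin_order")
            zyg = grp["zygosity"].iloc[0]

            def two(col, g=grp):
                v = g[col].to_numpy(dtype=float)
                return v if len(v) == 2 else np.array([v[0], np.nan])

            yield TwinPairRecord(
                family_id=int(fam),
                zygosity=zyg,
                smoking=two("smoking"),
                prs=two("prs"),
                age=two("age"),
                sex=two("sex"),
                dnam={c: two(dnam_col(c)) for c in self.cpg_ids},
                mqtl_score={
                    c: two(mqtl_col(c)) for c in self.cpg_ids if mqtl_col(c) in self.data
                },
            )

    def standardize(self) -> "TwinCohort":
        """Z-score the DNAm, mQTL-score and PRS columns within cohort."""
        df = self.data.copy()
        cols = ["prs"] + [dnam_col(c) for c in self.cpg_ids]
        cols += [mqtl_col(c) for c in self.cpg_ids if mqtl_col(c) in df]
        for col in cols:
            v = df[col].to_numpy(dtype=float)
            df[col] = (v - v.mean()) / v.std(ddof=1)
        return TwinCohort(df, list(self.cpg_ids), self.contrast, self.scenario)

    def write_tsv(self, path, sidecar: bool = True) -> None:
        self.data.to_csv(path, sep="\t", index=False)
        if sidecar:
            meta = {
                "cpg_ids": self.cpg_ids,
                "contrast": self.contrast,
                "scenario": dataclasses.asdict(self.scenario) if self.scenario else None,
            }
            with open(f"{path}.json", "w") as fh:
                json.dump(meta, fh, indent=2)

    @classmethod
    def read_tsv(cls, path) -> "TwinCohort":
        df = pd.read_csv(path, sep="\t")
        cpgs = [c[len("dnam_") :] for c in df.columns if c.startswith("dnam_")]
        contrast = "current_vs_never"
        scenario = None
        try:
            with open(f"{path}.json") as fh:
                meta = json.load(fh)
            contrast = meta.get("contrast", contrast)
            if meta.get("scenario"):
                sc = meta["scenario"]
                sc["age_range"] = tuple(sc["age_range"])
                scenario = SyntheticScenario(**sc)
        except FileNotFoundError:
            pass
        return cls(df, cpgs, contrast, scenario)


def _familial_normal(rng, n_pairs, within_cov, kappa):
    """Draw (n_pairs, 2, d) with within-person covariance ``within_cov`` and
    cross-twin covariance ``kappa * within_cov`` via shared/unique factors."""
    d = within_cov.shape[0]
    L = np.linalg.cholesky(within_cov + 1e-12 * np.eye(d))
    shared = rng.standard_normal((n_pairs, d)) @ L.T
    out = np.empty((n_pairs, 2, d))
    sk, su = math.sqrt(kappa), math.sqrt(1.0 - kappa)
    for t in range(2):
        unique = rng.standard_normal((n_pairs, d)) @ L.T
        out[:, t, :] = sk * shared + su * unique
    return out


def _simulate_group(rng, n_pairs, scen: SyntheticScenario, kappa_a: float, kappa_z: float):
    """Latent draws and structural solve for one zygosity group.

    Returns per-twin arrays of shape (n_pairs, 2): liability x (without the
    covariate mean shift), DNAm y, PRS, mQTL score.
    """
    ae_cov_x = np.array([[1.0, scen.r_a], [scen.r_a, 1.0]])
    # A factors (A_x, A_y) share kappa_a across twins; E factors are unshared
    A = _familial_normal(rng, n_pairs, ae_cov_x, kappa_a)
    ecov = np.array([[1.0, scen.r_e], [scen.r_e, 1.0]])
    E = _familial_normal(rng, n_pairs, ecov, 0.0)
    zcov = np.array([[1.0, scen.iv_covariance], [scen.iv_covariance, 1.0]])
    Z = _familial_normal(rng, n_pairs, zcov, kappa_z)
    prs, mqtl = Z[:, :, 0], Z[:, :, 1]
    u_x = scen.b1 * prs + scen.a_x * A[:, :, 0] + scen.e_x * E[:, :, 0]
    u_y = (
        scen.b3 * mqtl
        + scen.b2 * prs
        + scen.a_y * A[:, :, 1]
        + scen.e_y * E[:, :, 1]
    )
    det = 1.0 - scen.g1 * scen.g2
    x = (u_x + scen.g2 * u_y) / det
    y = (scen.g1 * u_x + u_y) / det
    return x, y, prs, mqtl


def _draw_age_sex(rng, n_pairs, scen, zygosity):
    """Co-twins share their age at blood draw; MZ co-twins share sex."""
    age = np.repeat(rng.uniform(*scen.age_range, size=(n_pairs, 1)), 2, axis=1)
    if zygosity == "DZ":
        sex = (rng.uniform(size=(n_pairs, 2)) < scen.sex_fraction).astype(float)
    else:
        sex = np.repeat(
            (rng.uniform(size=(n_pairs, 1)) < scen.sex_fraction).astype(float), 2, axis=1
        )
    return age, sex


def simulate_cohort(
    scenario: SyntheticScenario,
    cpg_id: str = "cg00000001",
    standardize: bool = False,
    binary_smoking: bool = True,
) -> TwinCohort:
    """Simulate a twin cohort with one DNAm variable under ``scenario``.

    Singletons are generated as MZ pairs with the co-twin dropped, which
    preserves the marginal distribution.  ``standardize=True`` additionally
    z-scores the continuous columns (the analysis-ready convention); the
    default keeps the exact model scale so sample moments can be compared
    with the implied covariance algebra.  ``binary_smoking=False`` writes
    the continuous liability itself into the smoking column (the
    non-thresholded limit of the model).
    """
    scen = scenario
    rng = np.random.default_rng(scen.seed)
    groups = []
    fam0 = 0
    for zyg, n_pairs, ka, kz, keep2 in [
        ("MZ", scen.n_mz_pairs, 1.0, 1.0, True),
        ("DZ", scen.n_dz_pairs, 0.5, scen.dz_iv_cross_corr, True),
        ("singleton", scen.n_singletons, 1.0, 1.0, False),
    ]:
        if n_pairs == 0:
            continue
        x, y, prs, mqtl = _simulate_group(rng, n_pairs, scen, ka, kz)
        age, sex = _draw_age_sex(rng, n_pairs, scen, zyg)
        n_twins = 2 if keep2 else 1
        fam = np.repeat(np.arange(fam0, fam0 + n_pairs), n_twins)
        fam0 += n_pairs
        order = np.tile(np.arange(1, n_twins + 1), n_pairs)
        sl = slice(None) if keep2 else slice(0, 1)
        groups.append(
            pd.DataFrame(
                {
                    "family_id": fam,
                    "zygosity": zyg,
                    "twin_order": order,
                    "_x": x[:, sl].ravel(),
                    dnam_col(cpg_id): y[:, sl].ravel(),
                    "prs": prs[:, sl].ravel(),
                    mqtl_col(cpg_id): mqtl[:, sl].ravel(),
                    "age": age[:, sl].ravel(),
                    "sex": sex[:, sl].ravel(),
                }
            )
        )
    df = pd.concat(groups, ignore_index=True)
    zage = (df["age"] - df["age"].mean()) / df["age"].std(ddof=1)
    csex = df["sex"] - df["sex"].mean()
    shift = scen.beta_age * zage + scen.beta_sex * csex
    if binary_smoking:
        df["smoking"] = (df["_x"] + shift > scen.threshold).astype(float)
    else:
        df["smoking"] = df["_x"] + shift
    df = df.drop(columns="_x")
    cols = ["family_id", "zygosity", "twin_order", "smoking", "age", "sex", "prs"]
    df = df[cols + [dnam_col(cpg_id), mqtl_col(cpg_id)]]
    cohort = TwinCohort(df, [cpg_id], scenario=scen)
    return cohort.standardize() if standardize else cohort


def simulate_screen_cohort(
    scenario: SyntheticScenario,
    cpg_effects: dict[str, dict],
    standardize: bool = True,
) -> TwinCohort:
    """Simulate a cohort with many CpGs sharing one smoking phenotype.

    ``cpg_effects`` maps each CpG id to per-CpG overrides of the scenario
    (typically g1, b3, r_a).  Reverse causation (g2) must be 0 for every
    CpG: a shared liability cannot simultaneously receive feedback from
    many methylation variables.  Each CpG's A/E loadings are rescaled so
    its implied DNAm variance is exactly 1, keeping the stated paths on
    the standardized scale.
    """
    rng = np.random.default_rng(scenario.seed)
    base = replace(scenario, g2=0.0)
    frames = []
    fam0 = 0
    spec_groups = [
        ("MZ", base.n_mz_pairs, 1.0, 1.0, True),
        ("DZ", base.n_dz_pairs, 0.5, base.dz_iv_cross_corr, True),
        ("singleton", base.n_singletons, 1.0, 1.0, False),
    ]
    cpgs = list(cpg_effects)
    for zyg, n_pairs, ka, kz, keep2 in spec_groups:
        if n_pairs == 0:
            continue
        # shared liability side: PRS and the liability's A/E factors
        a_liab = _familial_normal(rng, n_pairs, np.eye(1), ka)[:, :, 0]
        e_liab = rng.standard_normal((n_pairs, 2))
        prs = _familial_normal(rng, n_pairs, np.eye(1), kz)[:, :, 0]
        x = base.b1 * prs + base.a_x * a_liab + base.e_x * e_liab
        n_twins = 2 if keep2 else 1
        sl = slice(None) if keep2 else slice(0, 1)
        fam = np.repeat(np.arange(fam0, fam0 + n_pairs), n_twins)
        fam0 += n_pairs
        cols = {
            "family_id": fam,
            "zygosity": zyg,
            "twin_order": np.tile(np.arange(1, n_twins + 1), n_pairs),
            "_x": x[:, sl].ravel(),
            "prs": prs[:, sl].ravel(),
        }
        for cpg in cpgs:
            sc = replace(base, **cpg_effects[cpg])
            if sc.g2 != 0.0:
                raise ValueError("simulate_screen_cohort requires g2 = 0 per CpG")
            # per-CpG genetic factor correlated r_a with the liability's A
            a_extra = _familial_normal(rng, n_pairs, np.eye(1), ka)[:, :, 0]
            a_cpg = sc.r_a * a_liab + math.sqrt(max(1 - sc.r_a**2, 0.0)) * a_extra
            e_extra = rng.standard_normal((n_pairs, 2))
            e_cpg = sc.r_e * e_liab + math.sqrt(max(1 - sc.r_e**2, 0.0)) * e_extra
            mqtl = _familial_normal(rng, n_pairs, np.eye(1), kz)[:, :, 0]
            s_y = _unit_dnam_scale(sc)
            y = (
                sc.g1 * x
                + sc.b3 * mqtl
                + sc.b2 * prs
                + s_y * sc.a_y * a_cpg
                + s_y * sc.e_y * e_cpg
            )
            cols[dnam_col(cpg)] = y[:, sl].ravel()
            cols[mqtl_col(cpg)] = mqtl[:, sl].ravel()
        age, sex = _draw_age_sex(rng, n_pairs, base, zyg)
        cols["age"] = age[:, sl].ravel()
        cols["sex"] = sex[:, sl].ravel()
        frames.append(pd.DataFrame(cols))
    df = pd.concat(frames, ignore_index=True)
    zage = (df["age"] - df["age"].mean()) / df["age"].std(ddof=1)
    csex = df["sex"] - df["sex"].mean()
    df["smoking"] = (
        df["_x"] + base.beta_age * zage + base.beta_sex * csex > base.threshold
    ).astype(float)
    df = df.drop(columns="_x")
    front = ["family_id", "zygosity", "twin_order", "smoking", "age", "sex", "prs"]
    df = df[front + [c for c in df.columns if c not in front]]
    cohort = TwinCohort(df, cpgs, scenario=scenario)
    return cohort.standardize() if standardize else cohort


def _unit_dnam_scale(sc: SyntheticScenario) -> float:
    """Scale on (a_y, e_y) giving Var(DNAm) = 1 in the shared-liability
    (g2 = 0) generator: solves s^2*h + 2*g1*c*s + (g1^2 + b3^2 + b2^2
    + 2*g1*b1*b2) - 1 = 0 with c the A/E covariance between the liability
    and the CpG's residual factors."""
    h = sc.a_y**2 + sc.e_y**2
    cross = sc.a_y * sc.a_x * sc.r_a + sc.e_y * sc.e_x * sc.r_e
    const = sc.g1**2 + sc.b3**2 + sc.b2**2 + 2 * sc.g1 * sc.b1 * sc.b2 - 1.0
    b = sc.g1 * cross
    disc = b * b - h * const
    if disc <= 0:
        raise ValueError("cannot scale DNAm loadings to unit variance")
    s = (-b + math.sqrt(disc)) / h
    if s <= 0:
        raise ValueError("cannot scale DNAm loadings to unit variance")
    return s


def _latent_r_for_dosage_r(target_r: float, maf: float) -> float:
    """Invert the Gaussian-copula attenuation so the *dosage* correlation of
    two SNPs hits ``target_r`` (solved at the block-mean MAF)."""
    if abs(target_r) < 1e-12:
        return 0.0
    t = ndtri(1.0 - maf)

    def gap(r_lat):
        p11 = float(bivariate_normal_orthant(t, t, r_lat))
        return (p11 - maf * maf) / (maf * (1.0 - maf)) - target_r

    return brentq(gap, -0.999, 0.999, xtol=1e-10)


def simulate_genotype_fixture(
    n_individuals: int,
    n_snps: int,
    ld_block_size: int,
    within_block_r: float = 0.0,
    maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
    causal_per_block: int = 1,
    causal_beta: float = 0.3,
    cpg_position: int | None = None,
) -> tuple[GenotypeMatrix, LDMatrix, MqtlSummaryStats]:
    """Genotype dosages in LD blocks, with matching LD matrix and marginal
    cis-mQTL summary statistics for a simulated DNAm phenotype.

    Each block is equicorrelated; one (or ``causal_per_block``) SNP per block
    carries a true effect ``causal_beta`` on the phenotype, and per-SNP
    effect sizes / p-values come from marginal regressions on the simulated
    data, as in a single-SNP association scan.
    """
    if n_snps % ld_block_size != 0:
        raise ValueError("ld_block_size must divide n_snps")
    if not 0 < maf_range[0] <= maf_range[1] <= 0.5:
        raise ValueError("MAFs must lie in (0, 0.5]")
    if abs(within_block_r) >= 1:
        raise ValueError("|within_block_r| must be < 1")
    rng = np.random.default_rng(seed)
    n_blocks = n_snps // ld_block_size
    mafs = rng.uniform(maf_range[0], maf_range[1], size=n_snps)
    doses = np.empty((n_individuals, n_snps))
    for b in range(n_blocks):
        cols = slice(b * ld_block_size, (b + 1) * ld_block_size)
        block_maf = min(float(np.mean(mafs[cols])), 0.5 - 1e-9)
        r_lat = _latent_r_for_dosage_r(within_block_r, block_maf)
        C = np.full((ld_block_size, ld_block_size), r_lat)
        np.fill_diagonal(C, 1.0)
        L = np.linalg.cholesky(C + 1e-10 * np.eye(ld_block_size))
        thr = ndtri(mafs[cols])
        block = np.zeros((n_individuals, ld_block_size))
        for _hap in range(2):
            lat = rng.standard_normal((n_individuals, ld_block_size)) @ L.T
            block += (lat < thr).astype(float)
        doses[:, cols] = block
    snp_ids = [f"rs{i + 1:06d}" for i in range(n_snps)]
    positions = 10_000 + 5_000 * np.arange(n_snps)
    causal = np.zeros(n_snps, dtype=bool)
    for b in range(n_blocks):
        causal[b * ld_block_size : b * ld_block_size + causal_per_block] = True
    pheno = doses[:, causal] @ np.full(causal.sum(), causal_beta)
    pheno = pheno + rng.standard_normal(n_individuals)
    betas = np.empty(n_snps)
    pvals = np.empty(n_snps)
    for j in range(n_snps):
        g = doses[:, j]
        vg = g.var()
        if vg == 0:
            betas[j], pvals[j] = 0.0, 1.0
            continue
        slope = np.cov(g, pheno)[0, 1] / g.var(ddof=1)
        resid = pheno - pheno.mean() - slope * (g - g.mean())
        se = math.sqrt(resid @ resid / (n_individuals - 2) / (g.var(ddof=1) * (n_individuals - 1)))
        z = slope / se
        pvals[j] = max(2 * norm.sf(abs(z)), 1e-300)
        betas[j] = slope
    stats = MqtlSummaryStats(
        pd.DataFrame(
            {
                "snp_id": snp_ids,
                "position": positions,
                "effect_allele": "A",
                "other_allele": "G",
                "beta": betas,
                "pvalue": pvals,
            }
        )
    )
    geno = GenotypeMatrix(
        pd.DataFrame(doses, columns=snp_ids),
        effect_alleles={s: "A" for s in snp_ids},
        other_alleles={s: "G" for s in snp_ids},
    )
    ld = LDMatrix.from_genotypes(geno)
    return geno, ld, stats
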