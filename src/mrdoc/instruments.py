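"""Instrumental-variable construction and evaluation for mQTL allelic scores.

Candidate cis-mQTLs are reduced to an approximately independent set by greedy
LD clumping with p-value thresholding, combined into a weighted sum of
DNAm-increasing alleles, and evaluated for instrument relevance with the
incremental-R2 partial F statistic (the conventional F > 10 rule) and, for
binary outcomes, the liability-scale transformation of the observed R2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "MqtlSummaryStats",
    "LDMatrix",
    "GenotypeMatrix",
    "InstrumentStrength",
    "greedy_clump",
    "weighted_allelic_score",
    "incremental_strength",
    "liability_scale_r2",
    "residualize_standardize",
]


@dataclass
class MqtlSummaryStats:
    """Per-SNP cis-mQTL association summary statistics.

    ``table`` columns: snp_id, position (bp), effect_allele, other_allele,
    beta (DNAm SD per effect allele), pvalue.
    """

    table: pd.DataFrame

    REQUIRED = ("snp_id", "position", "effect_allele", "other_allele", "beta", "pvalue")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        t = self.table
        if ((t["pvalue"] <= 0) | (t["pvalue"] > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        if (t["position"] < 0).any():
            raise ValueError("base-pair positions must be non-negative")
        if (t["effect_allele"] == t["other_allele"]).any():
            raise ValueError("effect and other allele must differ")

    @classmethod
    def read_tsv(cls, path) -> "MqtlSummaryStats":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class LDMatrix:
    """Pairwise r-squared between SNPs."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snp_ids)
        if self.r2.shape != (n, n):
            raise ValueError("LD matrix shape does not match SNP ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-10):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if (self.r2 < -1e-12).any() or (self.r2 > 1 + 1e-12).any():
            raise ValueError("r2 values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._index[a], self._index[b]])
        except KeyError as exc:
            raise KeyError(f"SNP {exc.args[0]!r} missing from LD matrix") from None

    @classmethod
    def from_genotypes(cls, geno: "GenotypeMatrix") -> "LDMatrix":
        corr = np.corrcoef(geno.dosages.to_numpy(dtype=float), rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        return cls(list(geno.dosages.columns), corr**2)

    @classmethod
    def read_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def write_tsv(self, path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(path, sep="\t")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosages with the allele each column counts."""

    dosages: pd.DataFrame
    effect_alleles: dict[str, str] = field(default_factory=dict)
    other_alleles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        if (vals < -1e-9).any() or (vals > 2 + 1e-9).any():
            raise ValueError("dosages must lie in [0, 2]")

    @classmethod
    def read_tsv(cls, path, effect_alleles=None, other_alleles=None) -> "GenotypeMatrix":
        return cls(pd.read_csv(path, sep="\t"), effect_alleles or {}, other_alleles or {})

    def write_tsv(self, path) -> None:
        self.dosages.to_csv(path, sep="\t", index=False)


@dataclass
class InstrumentStrength:
    incremental_r2: float
    f_statistic: float
    n: int
    k_covariates: int

    @property
    def relevant(self) -> bool:
        """Conventional weak-instrument rule: partial F above 10."""
        return self.f_statistic > 10.0


def greedy_clump(
    stats: MqtlSummaryStats,
    ld: LDMatrix,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.1,
    cis_window_bp: int = 1_000_000,
    cpg_position: int | None = None,
) -> list[str]:
    """Greedy LD clumping with p-value thresholding.

    Only SNPs with p <= ``p_threshold`` and (if ``cpg_position`` given) within
    ``cis_window_bp`` of the CpG are considered.  The smallest-p remaining SNP
    is selected and every remaining SNP with r2 >= ``r2_threshold`` to it is
    discarded; ties on p break on smaller position, then SNP id.
    """
    if not (0 < p_threshold <= 1) or not (0 < r2_threshold <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    t = stats.table
    for snp in t["snp_id"]:
        if snp not in ld._index:
            raise KeyError(f"SNP {snp!r} missing from LD matrix")
    mask = t["pvalue"] <= p_threshold
    if cpg_position is not None:
        mask &= (t["position"] - cpg_position).abs() <= cis_window_bp
    cand = t.loc[mask, ["snp_id", "position", "pvalue"]]
    cand = cand.sort_values(["pvalue", "position", "snp_id"], kind="mergesort")
    remaining = list(cand["snp_id"])
    selected: list[str] = []
    while remaining:
        top = remaining.pop(0)
        selected.append(top)
        remaining = [s for s in remaining if ld.lookup(top, s) < r2_threshold]
    return selected


def weighted_allelic_score(
    genotypes: GenotypeMatrix,
    stats: MqtlSummaryStats,
    selected: list[str],
) -> np.ndarray:
    """Weighted sum of DNAm-increasing alleles over the selected SNPs.

    SNPs with negative effect sizes are re-oriented (allele flip, dosage
    2 - d) so every term counts the DNAm-increasing allele with a positive
    weight.
    """
    t = stats.table.set_index("snp_id")
    missing = [s for s in selected if s not in genotypes.dosages.columns]
    if missing:
        raise KeyError(f"selected SNPs absent from genotypes: {missing}")
    score = np.zeros(len(genotypes.dosages), dtype=float)
    for snp in selected:
        beta = float(t.loc[snp, "beta"])
        stats_ea = t.loc[snp, "effect_allele"]
        stats_oa = t.loc[snp, "other_allele"]
        dose = genotypes.dosages[snp].to_numpy(dtype=float)
        geno_ea = genotypes.effect_alleles.get(snp, stats_ea)
        geno_oa = genotypes.other_alleles.get(snp, stats_oa)
        if geno_ea == stats_ea and geno_oa == stats_oa:
            pass
        elif geno_ea == stats_oa and geno_oa == stats_ea:
            dose = 2.0 - dose
        else:
            raise ValueError(
                f"allele orientation mismatch for {snp}: genotypes carry "
                f"{geno_ea}/{geno_oa}, summary statistics {stats_ea}/{stats_oa}"
            )
        if beta < 0:  # count the DNAm-increasing allele
            beta, dose = -beta, 2.0 - dose
        score += beta * dose
    return score


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("outcome has zero variance")
    return 1.0 - float(np.sum(resid**2)) / tss


def _design(n: int, covariates) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValueError("covariates must have one row per observation")
    return np.column_stack([np.ones(n), C])


def incremental_strength(score, outcome, covariates=None) -> InstrumentStrength:
    """Incremental R2 of the score beyond covariates, with the partial F.

    F = dR2 * (n - k - 2) / (1 - R2_full), with k the number of covariates;
    the denominator degrees of freedom count the intercept, the covariates and
    the score.
    """
    y = np.asarray(outcome, dtype=float)
    s = np.asarray(score, dtype=float)
    n = len(y)
    X0 = _design(n, covariates)
    k = X0.shape[1] - 1
    if n <= k + 2:
        raise ValueError("too few observations for the requested covariates")
    X1 = np.column_stack([X0, s])
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise ValueError("score is collinear with the covariates")
    r2_red = _ols_r2(y, X0)
    r2_full = _ols_r2(y, X1)
    dr2 = max(r2_full - r2_red, 0.0)
    f = dr2 * (n - k - 2) / max(1.0 - r2_full, 1e-300)
    return InstrumentStrength(incremental_r2=dr2, f_statistic=f, n=n, k_covariates=k)


def liability_scale_r2(
    binary_outcome,
    score,
    covariates=None,
    population_prevalence: float = None,
) -> tuple[float, dict]:
    """Observed-scale incremental R2 transformed to the liability scale.

    Uses the ascertainment-adjusted threshold-model transformation with
    population prevalence K and sample case fraction P; with P = K it reduces
    to R2_liab = R2_obs * K(1-K) / phi(t)^2.  Returns (r2_liability, metadata).
    """
    y = np.asarray(binary_outcome, dtype=float)
    s = np.asarray(score, dtype=float)
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    mask = ~np.isnan(y)
    y, s = y[mask], s[mask]
    if C is not None:
        C = C[mask]
    P = float(y.mean())
    if P in (0.0, 1.0):
        raise ValueError("binary outcome must contain both cases and controls")
    K = P if population_prevalence is None else float(population_prevalence)
    if not 0 < K < 1:
        raise ValueError("population prevalence must lie in (0, 1)")
    obs = incremental_strength(s, y, C)
    r2_obs = obs.incremental_r2
    t = norm.ppf(1.0 - K)
    z = norm.pdf(t)
    m = z / K
    c_factor = (K * (1 - K) / z**2) * (K * (1 - K) / (P * (1 - P)))
    theta = m * (P - K) / (1 - K) * (m * (P - K) / (1 - K) - t)
    r2_liab = c_factor * r2_obs / (1 + c_factor * theta * r2_obs)
    meta = {
        "transformation": "lee_ascertainment_adjusted",
        "r2_observed": r2_obs,
        "K": K,
        "P": P,
        "threshold": t,
        "f_statistic": obs.f_statistic,
        "n": obs.n,
    }
    return float(r2_liab), meta


def residualize_standardize(values, covariates=None) -> np.ndarray:
    """OLS residuals of ``values`` on covariates, z-scored (ddof=1).

    With no covariates (or an intercept only) this is plain z-scoring.
    """
    y = np.asarray(values, dtype=float)
    n = len(y)
    X = _design(n, covariates)
    if n <= X.shape[1]:
        raise ValueError("too few observations to residualize")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sd = resid.std(ddof=1)
    if sd == 0 or np.ptp(y) == 0:
        raise ValueError("input has zero residual variance")
    return (resid - resid.mean()) / sd
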