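"""Epigenome-scale causal screen across CpGs.

For every CpG the three MR-DoC models are fitted in each causal direction
(the bidirectional model once, supplying both directions), with the
DNAm -> Smoking and bidirectional fits restricted to CpGs whose mQTL
allelic score passes the instrument-relevance rule (partial F above a
threshold, conventionally 10).  Per model and direction, p-values are
corrected across CpGs by Benjamini-Hochberg FDR; genomic inflation of the
causal test statistics is summarized by the median-chi-square lambda or a
normal-mixture null-component lambda; and evidence is triangulated across
the three models into robust / consistent-nominal / inconsistent
categories.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .instruments import incremental_strength
from .model_core import FitOptions, MRDoCSpec, fit_mrdoc, wald_statistics
from .synthetic_data import TwinCohort, dnam_col, mqtl_col

__all__ = [
    "MODELS",
    "DIRECTIONS",
    "ModelEstimate",
    "ScreenRow",
    "InflationResult",
    "run_screen",
    "bh_fdr",
    "inflation_lambda",
    "triangulate",
    "intersection_counts",
    "serialize_results",
    "load_results",
]

logger = logging.getLogger("mrdoc.screen")

MODELS = ("doc2", "doc1_pleiotropy", "doc1_re")
DIRECTIONS = ("smoking_to_dnam", "dnam_to_smoking")
CATEGORIES = ("robust", "consistent_nominal", "inconsistent", "not_tested")

# median of the chi-square distribution with 1 degree of freedom
CHI2_1_MEDIAN = 0.4549364231195728


@dataclass
class ModelEstimate:
    """One model's causal estimate for one CpG and direction."""

    estimate: float = math.nan
    se: float = math.nan
    z: float = math.nan
    p: float = math.nan
    q: float = math.nan
    converged: bool = False


@dataclass
class ScreenRow:
    cpg_id: str
    direction: str
    models: dict[str, ModelEstimate]
    instrument_f: float = math.nan
    triangulation_category: str = "not_tested"


@dataclass
class InflationResult:
    lambda_value: float
    method: str
    bias: float | None
    n_tests: int


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN entries are propagated."""
    p = np.asarray(pvalues, dtype=float)
    mask = ~np.isnan(p)
    if mask.any() and ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    ps = p[mask]
    m = ps.size
    if m == 0:
        return q
    order = np.argsort(ps, kind="mergesort")
    scaled = ps[order] * m / (np.arange(m) + 1.0)
    qs = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(qs, 0.0, 1.0)
    q[mask] = out
    return q


def _median_lambda(z: np.ndarray) -> float:
    return float(np.median(z**2) / CHI2_1_MEDIAN)


def _em_mixture(z: np.ndarray, n_tails: int, max_iter: int = 500, tol: float = 1e-8):
    """Deterministic EM for a normal mixture with a dominant null component
    and ``n_tails`` (0 or 2) sign-constrained tail components."""
    n = z.size
    s0 = float(1.4826 * np.median(np.abs(z - np.median(z))))
    s0 = s0 or float(z.std())
    if n_tails == 0:
        mu = float(z.mean())
        var = float(z.var())
        ll = float(np.sum(-0.5 * (np.log(2 * np.pi * var) + (z - mu) ** 2 / var)))
        return ll, 2, (mu, math.sqrt(var))
    k = 3
    mu = np.array([0.0, -3.0 * s0, 3.0 * s0])
    sig = np.array([s0, s0, s0])
    pi = np.array([0.9, 0.05, 0.05])
    alpha = np.array([8.0, 1.5, 1.5])  # Dirichlet pseudo-counts keep the null dominant
    ll_old = -np.inf
    ll = ll_old
    for _ in range(max_iter):
        logpdf = (
            -0.5 * np.log(2 * np.pi)
            - np.log(sig)[None, :]
            - 0.5 * ((z[:, None] - mu[None, :]) / sig[None, :]) ** 2
            + np.log(pi)[None, :]
        )
        mx = logpdf.max(axis=1, keepdims=True)
        w = np.exp(logpdf - mx)
        tot = w.sum(axis=1, keepdims=True)
        ll = float(np.sum(mx.ravel() + np.log(tot.ravel())))
        r = w / tot
        nk = r.sum(axis=0)
        pi = (nk + alpha - 1.0) / (n + alpha.sum() - k)
        pi = np.clip(pi, 1e-8, None)
        pi = pi / pi.sum()
        mu = (r * z[:, None]).sum(axis=0) / np.maximum(nk, 1e-8)
        # sign constraints: tail means flank the null mean
        mu[1] = min(mu[1], mu[0] - 1e-3)
        mu[2] = max(mu[2], mu[0] + 1e-3)
        var = (r * (z[:, None] - mu[None, :]) ** 2).sum(axis=0) / np.maximum(nk, 1e-8)
        sig = np.sqrt(np.clip(var, 1e-6, None))
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            break
        ll_old = ll
    return ll, 3 * k - 1, (float(mu[0]), float(sig[0]))


def inflation_lambda(zscores, method: str = "median_chi2") -> InflationResult:
    """Genomic inflation factor of a vector of causal-test z-scores.

    ``median_chi2``: lambda = median(z^2) / median of chi-square(1).
    ``bayesian_mixture``: a normal-mixture decomposition with a dominant
    null component fitted by deterministic EM; lambda is the squared SD of
    the null component and ``bias`` its mean.  The null-plus-tails mixture
    is compared with a single-component fit by BIC, so that data without
    genuine tail effects are not over-decomposed.
    """
    z = np.asarray(zscores, dtype=float)
    z = z[~np.isnan(z)]
    if method == "median_chi2":
        if z.size < 100:
            raise ValueError("median_chi2 requires at least 100 z-scores")
        return InflationResult(_median_lambda(z), "median_chi2", None, int(z.size))
    if method != "bayesian_mixture":
        raise ValueError(f"unknown method {method!r}")
    if z.size < 1000:
        raise ValueError("bayesian_mixture requires at least 1000 z-scores")
    ll1, k1, (mu1, s1) = _em_mixture(z, n_tails=0)
    ll3, k3, (mu3, s3) = _em_mixture(z, n_tails=2)
    bic1 = -2 * ll1 + k1 * math.log(z.size)
    bic3 = -2 * ll3 + k3 * math.log(z.size)
    mu0, sd0 = (mu1, s1) if bic1 <= bic3 else (mu3, s3)
    return InflationResult(float(sd0**2), "bayesian_mixture", float(mu0), int(z.size))


def triangulate(row: ScreenRow, fdr_alpha: float = 0.05, nominal_alpha: float = 0.05) -> str:
    """Triangulation category from the three models' estimates.

    ``robust``: FDR q < alpha in all three models with a consistent sign;
    ``consistent_nominal``: nominally significant (p < alpha) in all three
    with a consistent sign; otherwise ``inconsistent``.  Any missing or
    non-converged fit yields ``not_tested``.
    """
    ests = [row.models.get(m) for m in MODELS]
    if any(e is None or not e.converged or math.isnan(e.p) for e in ests):
        return "not_tested"
    signs = {math.copysign(1.0, e.estimate) for e in ests}
    same_sign = len(signs) == 1
    if same_sign and all(e.q < fdr_alpha for e in ests):
        return "robust"
    if same_sign and all(e.p < nominal_alpha for e in ests):
        return "consistent_nominal"
    return "inconsistent"


def intersection_counts(rows: list[ScreenRow], alpha: float = 0.05) -> dict[str, int]:
    """Counts of CpGs significant (q < alpha) in each exact model subset.

    Keys are '+'-joined model names for exclusive subsets, plus
    ``at_least_one``, ``at_least_two`` and ``all_three`` rollups.
    """
    directions = {r.direction for r in rows}
    if len(directions) > 1:
        raise ValueError("intersection counts require rows from a single direction")
    subset_keys = []
    for size in (1, 2, 3):
        from itertools import combinations

        for combo in combinations(MODELS, size):
            subset_keys.append("+".join(combo))
    counts = {k: 0 for k in subset_keys}
    counts.update({"at_least_one": 0, "at_least_two": 0, "all_three": 0})
    for row in rows:
        sig = tuple(
            m
            for m in MODELS
            if (e := row.models.get(m)) is not None
            and e.converged
            and not math.isnan(e.q)
            and e.q < alpha
        )
        if not sig:
            continue
        counts["+".join(sig)] += 1
        counts["at_least_one"] += 1
        if len(sig) >= 2:
            counts["at_least_two"] += 1
        if len(sig) == 3:
            counts["all_three"] += 1
    return counts


def _fit_estimate(cohort, spec, cpg, param, options) -> ModelEstimate:
    fit = fit_mrdoc(cohort, spec, cpg, options)
    est = ModelEstimate(converged=fit.converged)
    if fit.converged:
        est.estimate = float(getattr(fit.estimates, param))
        se = fit.standard_errors.get(param, math.nan)
        est.se = float(se)
        if se and se > 0:
            z, p = wald_statistics(fit, param)
            est.z, est.p = z, p
        else:
            est.converged = False
    return est


def run_screen(
    cohort: TwinCohort,
    cpg_ids: list[str] | None = None,
    directions: tuple[str, ...] = DIRECTIONS,
    f_threshold: float = 10.0,
    fdr_alpha: float = 0.05,
    nominal_alpha: float = 0.05,
    seed: int = 0,
    fit_options: FitOptions | None = None,
) -> list[ScreenRow]:
    """Fit the three MR-DoC models per CpG and triangulate the evidence.

    Smoking -> DNAm MR-DoC1 fits run for every requested CpG; the
    DNAm -> Smoking and bidirectional fits run only where the mQTL allelic
    score has partial F above ``f_threshold``.  Returns one row per CpG and
    direction, with FDR q-values per model computed across CpGs.
    """
    cpgs = list(cpg_ids) if cpg_ids is not None else list(cohort.cpg_ids)
    if not cpgs:
        raise ValueError("empty CpG list")
    unknown = [c for c in cpgs if c not in cohort.cpg_ids]
    if unknown:
        raise KeyError(f"CpGs absent from cohort: {unknown}")
    rows: dict[tuple[str, str], ScreenRow] = {}
    for i, cpg in enumerate(cpgs):
        base = fit_options or FitOptions()
        opts = dataclasses.replace(base, seed=seed + i)
        score = cohort.data[mqtl_col(cpg)].to_numpy(dtype=float)
        outcome = cohort.data[dnam_col(cpg)].to_numpy(dtype=float)
        f_stat = incremental_strength(score, outcome).f_statistic
        strong = f_stat > f_threshold
        per_dir: dict[str, dict[str, ModelEstimate]] = {d: {} for d in DIRECTIONS}
        if strong:
            spec2 = MRDoCSpec(variant="doc2", direction="bidirectional")
            fit2 = fit_mrdoc(cohort, spec2, cpg, opts)
            for d, param in (("smoking_to_dnam", "g1"), ("dnam_to_smoking", "g2")):
                est = ModelEstimate(converged=fit2.converged)
                if fit2.converged:
                    est.estimate = float(getattr(fit2.estimates, param))
                    se = fit2.standard_errors.get(param, math.nan)
                    est.se = float(se)
                    if se and se > 0:
                        est.z, est.p = wald_statistics(fit2, param)
                    else:
                        est.converged = False
                per_dir[d]["doc2"] = est
        if "smoking_to_dnam" in directions:
            for variant in ("doc1_pleiotropy", "doc1_re"):
                spec = MRDoCSpec(variant=variant, direction="binary_exposure")
                per_dir["smoking_to_dnam"][variant] = _fit_estimate(
                    cohort, spec, cpg, "g1", opts
                )
        if "dnam_to_smoking" in directions and strong:
            for variant in ("doc1_pleiotropy", "doc1_re"):
                spec = MRDoCSpec(variant=variant, direction="continuous_exposure")
                per_dir["dnam_to_smoking"][variant] = _fit_estimate(
                    cohort, spec, cpg, "g2", opts
                )
        for d in directions:
            rows[(cpg, d)] = ScreenRow(
                cpg_id=cpg, direction=d, models=per_dir[d], instrument_f=float(f_stat)
            )
        logger.info(
            "screen %s (%d/%d): F=%.2f%s", cpg, i + 1, len(cpgs), f_stat,
            "" if strong else " (below threshold; reverse/bidirectional skipped)",
        )
    # FDR per model per direction across CpGs
    for d in directions:
        dir_rows = [rows[(c, d)] for c in cpgs if (c, d) in rows]
        for model in MODELS:
            ps = np.array(
                [
                    r.models[model].p
                    if model in r.models and r.models[model].converged
                    else np.nan
                    for r in dir_rows
                ]
            )
            qs = bh_fdr(ps)
            for r, q in zip(dir_rows, qs):
                if model in r.models:
                    r.models[model].q = float(q) if not np.isnan(q) else math.nan
        for r in dir_rows:
            r.triangulation_category = triangulate(r, fdr_alpha, nominal_alpha)
    n_nonconv = sum(
        1 for r in rows.values() for e in r.models.values() if not e.converged
    )
    if n_nonconv:
        logger.info("screen: %d non-converged fits excluded from FDR", n_nonconv)
    return [rows[(c, d)] for c in cpgs for d in directions if (c, d) in rows]


# --------------------------------------------------------------------------
# Serialization

_FIELDS = ("estimate", "se", "z", "p", "q", "converged")


def serialize_results(rows: list[ScreenRow], path, metadata: dict | None = None) -> None:
    """Write screen rows to TSV (floats at 17 significant digits) plus a JSON
    run-metadata sidecar."""
    recs = []
    for r in rows:
        rec: dict = {
            "cpg_id": r.cpg_id,
            "direction": r.direction,
            "instrument_f": r.instrument_f,
            "triangulation_category": r.triangulation_category,
        }
        for m in MODELS:
            e = r.models.get(m)
            for fname in _FIELDS:
                key = f"{m}_{fname}"
                if e is None:
                    rec[key] = ""
                elif fname == "converged":
                    rec[key] = int(e.converged)
                else:
                    rec[key] = getattr(e, fname)
        recs.append(rec)
    cols = ["cpg_id", "direction", "instrument_f", "triangulation_category"] + [
        f"{m}_{f}" for m in MODELS for f in _FIELDS
    ]
    df = pd.DataFrame(recs, columns=cols)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    meta = {"n_rows": len(rows), "models": list(MODELS)}
    if metadata:
        meta.update(metadata)
    with open(f"{path}.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


def load_results(path) -> list[ScreenRow]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    rows = []
    for _, rec in df.iterrows():
        models = {}
        for m in MODELS:
            if pd.isna(rec[f"{m}_converged"]) or rec[f"{m}_converged"] == "":
                continue
            models[m] = ModelEstimate(
                estimate=float(rec[f"{m}_estimate"]),
                se=float(rec[f"{m}_se"]),
                z=float(rec[f"{m}_z"]),
                p=float(rec[f"{m}_p"]),
                q=float(rec[f"{m}_q"]),
                converged=bool(int(rec[f"{m}_converged"])),
            )
        rows.append(
            ScreenRow(
                cpg_id=str(rec["cpg_id"]),
                direction=str(rec["direction"]),
                models=models,
                instrument_f=float(rec["instrument_f"]),
                triangulation_category=str(rec["triangulation_category"]),
            )
        )
    return rows
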