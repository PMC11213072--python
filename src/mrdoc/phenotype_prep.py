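"""Analysis-ready phenotype preparation.

DNAm beta-values are residualized per CpG on age, sex, measured white blood
cell percentages (neutrophils, monocytes, eosinophils) and the technical
covariates array row and bisulfite sample plate, then standardized to mean
0, SD 1.  Lymphocyte percentage (collinear with neutrophils) and basophil
percentage (near-zero variance) are never accepted as covariates.  Smoking
status is encoded for a chosen binary contrast; the excluded category maps
to missing, never to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DnamMatrix", "SmokingEncoding", "residualize_dnam", "encode_smoking"]

NUMERIC_COVARIATES = ("age", "sex", "neutrophil_pct", "monocyte_pct", "eosinophil_pct")
CATEGORICAL_COVARIATES = ("array_row", "sample_plate")
_FORBIDDEN = ("lymphocyte", "basophil")

SMOKING_CATEGORIES = ("never", "former", "current")
CONTRASTS = ("current_vs_never", "former_vs_never")


@dataclass
class DnamMatrix:
    """Individuals x CpGs methylation values with a covariate table.

    On input, values are normalized beta-values in [0, 1] (or already
    residualized values); on output of :func:`residualize_dnam` every column
    has mean 0 and SD 1.
    """

    values: pd.DataFrame
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    residualized: bool = False

    def __post_init__(self) -> None:
        for col in self.covariates.columns:
            low = str(col).lower()
            if any(f in low for f in _FORBIDDEN):
                raise ValueError(
                    f"covariate {col!r} is not accepted (lymphocyte % is collinear "
                    "with neutrophil %; basophil % has near-zero variance)"
                )
        if len(self.covariates) and len(self.covariates) != len(self.values):
            raise ValueError("covariate table length does not match values")


@dataclass
class SmokingEncoding:
    """A binary smoking contrast: 1 = contrast category, 0 = never,
    missing = the excluded category."""

    contrast: str
    encoded: pd.Series
    counts: dict[str, int]


def _design_matrix(cov: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(cov))]
    names = ["intercept"]
    for c in cov.columns:
        if c in CATEGORICAL_COVARIATES or cov[c].dtype == object:
            dummies = pd.get_dummies(cov[c].astype("category"), prefix=c, drop_first=True)
            for dc in dummies.columns:
                cols.append(dummies[dc].to_numpy(dtype=float))
                names.append(dc)
        else:
            cols.append(cov[c].to_numpy(dtype=float))
            names.append(str(c))
    X = np.column_stack(cols)
    return X, names


def _check_collinear(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via the QR diagonal
        _, R = np.linalg.qr(X)
        bad = [names[i] for i in range(X.shape[1]) if abs(R[i, i]) < 1e-8 * max(1, abs(R[0, 0]))]
        raise ValueError(f"collinear covariates: {bad or names}")


def residualize_dnam(matrix: DnamMatrix) -> DnamMatrix:
    """Per-CpG OLS residualization on the covariate table, then z-scoring.

    With an empty (or constant-only) covariate table this reduces to plain
    z-scoring.  Rows with missing covariates are excluded listwise with a
    recorded count; the model stage, not residualization, handles missing
    outcome data.
    """
    cov = matrix.covariates
    vals = matrix.values
    if len(cov.columns):
        complete = ~cov.isna().any(axis=1)
        n_dropped = int((~complete).sum())
        cov = cov.loc[complete]
        vals = vals.loc[complete]
    else:
        n_dropped = 0
        cov = pd.DataFrame(index=vals.index)
    X, names = _design_matrix(cov)
    _check_collinear(X, names)
    Y = vals.to_numpy(dtype=float)
    if np.any(np.nanstd(Y, axis=0) == 0):
        bad = [c for c, s in zip(vals.columns, np.nanstd(Y, axis=0)) if s == 0]
        raise ValueError(f"zero-variance CpG columns: {bad}")
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    resid = resid - resid.mean(axis=0)
    resid = resid / resid.std(axis=0, ddof=1)
    out = pd.DataFrame(resid, index=vals.index, columns=vals.columns)
    result = DnamMatrix(out, cov.copy(), residualized=True)
    result.n_excluded = n_dropped  # type: ignore[attr-defined]
    return result


def encode_smoking(status_column, contrast: str) -> SmokingEncoding:
    """Encode raw smoking status for one binary contrast.

    ``current_vs_never``: current -> 1, never -> 0, former -> missing;
    ``former_vs_never``: former -> 1, never -> 0, current -> missing.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")
    s = pd.Series(status_column).astype(object)
    known = set(SMOKING_CATEGORIES)
    bad = {v for v in s.dropna().unique() if v not in known}
    if bad:
        raise ValueError(f"unknown smoking categories: {sorted(map(str, bad))}")
    one = "current" if contrast == "current_vs_never" else "former"
    drop = "former" if contrast == "current_vs_never" else "current"
    mapping = {"never": 0.0, one: 1.0, drop: np.nan}
    enc = s.map(lambda v: mapping.get(v, np.nan)).astype(float)
    counts = {
        "cases": int((enc == 1).sum()),
        "controls": int((enc == 0).sum()),
        "missing": int(enc.isna().sum()),
    }
    return SmokingEncoding(contrast=contrast, encoded=enc, counts=counts)
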