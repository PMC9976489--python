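"""Per-CpG association engines for age and all-cause mortality.

The chronological-age EWAS follows the outcome orientation in which age is
the dependent variable and the (standardized) CpG M-value — optionally with
its square — is the predictor of interest, adjusting for fixed-effect
covariates (sex, batch/set, smoking, pack years, cell proportions, DNAm
principal components).  Age is centred by its mean and CpG / CpG^2 M-value
columns are scaled to mean zero and variance one before fitting.

For speed at many CpGs the covariates are projected out once
(Frisch-Waugh-Lovell): age and all CpG columns are residualized on the
covariate design via a QR-based annihilator, after which every per-CpG fit
is a one- or two-variable regression.  The equivalence with the full design
is asserted in the test suite.

The mortality EWAS fits one Cox proportional-hazards model per CpG
(Newton-Raphson on the Breslow partial likelihood) and reports the hazard
ratio per standard deviation of the M-value.

Epigenome-wide significance defaults to p < 3.6e-8, the array-wide
multiple-testing threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._cox import cox_fit
from .errors import ValidationError
from .io import MethylationMatrix, smoking_design

GENOME_WIDE_P = 3.6e-8


@dataclass
class CovariateSpec:
    """Which phenotype columns enter the EWAS design, in a fixed order."""

    sex: bool = True
    batch: bool = True
    set: bool = False
    smoking_status: bool = True
    pack_years: bool = True
    cell_proportions: tuple = ()
    n_dnam_pcs: int = 0

    def build_design(self, pheno: pd.DataFrame, pcs: pd.DataFrame | None = None) -> pd.DataFrame:
        cols = {}
        if self.sex:
            cols["sex"] = pheno["sex"].astype(float)
        if self.pack_years:
            cols["pack_years"] = pheno["pack_years"].astype(float)
        parts = [pd.DataFrame(cols, index=pheno.index)]
        if self.batch:
            parts.append(pd.get_dummies(pheno["batch"], prefix="batch", drop_first=True, dtype=float))
        if self.set:
            parts.append(pd.get_dummies(pheno["set"], prefix="set", drop_first=True, dtype=float))
        if self.smoking_status:
            parts.append(smoking_design(pheno["smoking_status"]))
        if self.cell_proportions:
            # proportions sum to one; drop the last column to keep full rank
            keep = list(self.cell_proportions)[:-1]
            parts.append(pheno[keep].astype(float))
        if self.n_dnam_pcs:
            if pcs is None:
                raise ValidationError("CovariateSpec requests DNAm PCs but none were supplied")
            parts.append(pcs.iloc[:, : self.n_dnam_pcs])
        design = pd.concat(parts, axis=1)
        if len(design.columns):
            rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(design)), design.to_numpy()]))
            if rank < design.shape[1] + 1:
                raise ValidationError("covariate design is rank deficient")
        return design


NO_COVARIATES = CovariateSpec(sex=False, batch=False, smoking_status=False, pack_years=False)


# ---------------------------------------------------------------------------
# DNAm principal components
# ---------------------------------------------------------------------------

def compute_dnam_pcs(matrix: MethylationMatrix, k: int, n_top_cpgs: int = 20000) -> pd.DataFrame:
    """Top-k DNAm principal-component scores (left singular directions
    scaled by singular values) of the standardized M-value matrix.

    Computed on up to ``n_top_cpgs`` most variable CpGs to bound memory.
    """
    mvals = matrix.to_mvalues().data
    n, p = mvals.shape
    if k >= min(n, p):
        raise ValidationError(f"k={k} must be < min(n_samples, n_cpgs)={min(n, p)}")
    if p > n_top_cpgs:
        variances = mvals.var(axis=0)
        keep = variances.sort_values(ascending=False).index[:n_top_cpgs]
        mvals = mvals[keep]
    arr = mvals.to_numpy()
    sds = arr.std(axis=0, ddof=1)
    ok = sds > 0
    arr = (arr[:, ok] - arr[:, ok].mean(axis=0)) / sds[ok]
    U, S, _ = np.linalg.svd(arr, full_matrices=False)
    scores = U[:, :k] * S[:k]
    return pd.DataFrame(scores, index=mvals.index, columns=[f"PC{i+1}" for i in range(k)])


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _standardize(arr: np.ndarray):
    """Column z-scores (n-1 sd); zero-variance columns flagged as NaN."""
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mean) / sd
    z[:, sd == 0] = np.nan
    return z, sd


def _annihilate(Z: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residualize the columns of Z on [1, C] via a QR-based projector."""
    Q, _ = np.linalg.qr(C)
    return Z - Q @ (Q.T @ Z)


def _covariate_matrix(pheno, covariates, pcs):
    covariates = covariates if covariates is not None else NO_COVARIATES
    design = covariates.build_design(pheno, pcs)
    C = np.column_stack([np.ones(len(pheno))] + ([design.to_numpy(dtype=float)] if design.shape[1] else []))
    return C, design


# ---------------------------------------------------------------------------
# chronological-age EWAS
# ---------------------------------------------------------------------------

def linear_age_ewas(
    matrix: MethylationMatrix,
    pheno: pd.DataFrame,
    covariates: CovariateSpec | None = None,
    pcs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """OLS of centred age on each standardized CpG M-value plus covariates.

    Returns one row per CpG: ``beta_linear``, ``se_linear``, ``p_linear``
    (two-sided t), plus ``rss``, ``df`` and ``n_used`` for nested F-tests.
    CpGs with zero variance or collinear with the covariates are flagged
    with missing results rather than raising.
    """
    pheno = pheno.loc[matrix.sample_ids]
    y = pheno["age"].to_numpy(dtype=float)
    y = y - y.mean()
    M = matrix.to_mvalues().values
    Z, sd = _standardize(M)
    C, _ = _covariate_matrix(pheno, covariates, pcs)
    n, q = C.shape
    if n <= q + 1:
        raise ValidationError(f"n={n} too small for {q} covariate columns plus a CpG")
    Zt = _annihilate(np.nan_to_num(Z), C)
    yt = _annihilate(y[:, None], C)[:, 0]
    sxx = np.einsum("ij,ij->j", Zt, Zt)
    sxy = Zt.T @ yt
    tss = float(yt @ yt)
    df = n - q - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = sxy / sxx
        rss = tss - beta * sxy
        sigma2 = rss / df
        se = np.sqrt(sigma2 / sxx)
        tval = beta / se
    p = 2.0 * stats.t.sf(np.abs(tval), df)
    # standardized columns have raw SS = n-1; residual SS near zero means
    # the CpG is (numerically) collinear with the covariates
    bad = (sd == 0) | (sxx <= (n - 1) * 1e-10) | ~np.isfinite(beta)
    out = pd.DataFrame(
        {
            "beta_linear": np.where(bad, np.nan, beta),
            "se_linear": np.where(bad, np.nan, se),
            "p_linear": np.where(bad, np.nan, p),
            "rss": np.where(bad, np.nan, rss),
            "df": df,
            "n_used": n,
        },
        index=pd.Index(matrix.cpg_ids, name="cpg"),
    )
    return out


def quadratic_age_ewas(
    matrix: MethylationMatrix,
    pheno: pd.DataFrame,
    covariates: CovariateSpec | None = None,
    pcs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Joint OLS of centred age on standardized CpG and CpG^2 M-values.

    Both the linear and squared M-value columns are scaled to mean zero and
    unit variance before fitting.  Reports both coefficients with SEs and
    two-sided t p-values (`beta_quadratic` etc. refer to the squared term).
    """
    pheno = pheno.loc[matrix.sample_ids]
    y = pheno["age"].to_numpy(dtype=float)
    y = y - y.mean()
    M = matrix.to_mvalues().values
    Z1, sd1 = _standardize(M)
    Z2, sd2 = _standardize(M ** 2)
    C, _ = _covariate_matrix(pheno, covariates, pcs)
    n, q = C.shape
    if n <= q + 2:
        raise ValidationError(f"n={n} too small for {q} covariate columns plus two CpG terms")
    Z1t = _annihilate(np.nan_to_num(Z1), C)
    Z2t = _annihilate(np.nan_to_num(Z2), C)
    yt = _annihilate(y[:, None], C)[:, 0]
    a11 = np.einsum("ij,ij->j", Z1t, Z1t)
    a22 = np.einsum("ij,ij->j", Z2t, Z2t)
    a12 = np.einsum("ij,ij->j", Z1t, Z2t)
    b1 = Z1t.T @ yt
    b2 = Z2t.T @ yt
    det = a11 * a22 - a12 ** 2
    tss = float(yt @ yt)
    df = n - q - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        c1 = (a22 * b1 - a12 * b2) / det
        c2 = (a11 * b2 - a12 * b1) / det
        rss = tss - (c1 * b1 + c2 * b2)
        sigma2 = rss / df
        se1 = np.sqrt(sigma2 * a22 / det)
        se2 = np.sqrt(sigma2 * a11 / det)
        p1 = 2.0 * stats.t.sf(np.abs(c1 / se1), df)
        p2 = 2.0 * stats.t.sf(np.abs(c2 / se2), df)
    bad = (sd1 == 0) | (sd2 == 0) | (det <= (a11 * a22) * 1e-10) | ~np.isfinite(det)
    out = pd.DataFrame(
        {
            "beta_linear": np.where(bad, np.nan, c1),
            "se_linear": np.where(bad, np.nan, se1),
            "p_linear": np.where(bad, np.nan, p1),
            "beta_quadratic": np.where(bad, np.nan, c2),
            "se_quadratic": np.where(bad, np.nan, se2),
            "p_quadratic": np.where(bad, np.nan, p2),
            "rss": np.where(bad, np.nan, rss),
            "df": df,
            "n_used": n,
        },
        index=pd.Index(matrix.cpg_ids, name="cpg"),
    )
    return out


def nested_f_test(fit_linear: pd.DataFrame, fit_quadratic: pd.DataFrame) -> pd.DataFrame:
    """F-test comparing the linear model with the linear+quadratic model.

    F = ((RSS1 - RSS2) / 1) / (RSS2 / df2) with p from F(1, df2); both fits
    must come from the same samples and covariates.
    """
    if not fit_linear.index.equals(fit_quadratic.index):
        raise ValidationError("nested F-test requires identical CpG sets")
    if not (fit_linear["n_used"] == fit_quadratic["n_used"]).all():
        raise ValidationError("nested F-test requires identical sample sets")
    rss1 = fit_linear["rss"].to_numpy()
    rss2 = fit_quadratic["rss"].to_numpy()
    df2 = fit_quadratic["df"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.maximum(rss1 - rss2, 0.0) / (rss2 / df2)
    p = stats.f.sf(f, 1, df2)
    return pd.DataFrame({"f_stat": f, "p_f": p}, index=fit_linear.index)


# ---------------------------------------------------------------------------
# mortality EWAS
# ---------------------------------------------------------------------------

def cox_mortality_ewas(
    matrix: MethylationMatrix,
    pheno: pd.DataFrame,
    covariates: CovariateSpec | None = None,
    pcs: pd.DataFrame | None = None,
    max_iter: int = 50,
) -> pd.DataFrame:
    """Per-CpG Cox PH model of time to all-cause mortality.

    Each standardized CpG M-value enters as the predictor of interest on
    top of the covariates; reports the hazard ratio per SD, the SE of the
    log hazard ratio and the Wald p-value.  Constant CpGs are flagged
    degenerate (HR 1, p 1); non-convergent fits are flagged.
    """
    pheno = pheno.loc[matrix.sample_ids]
    tte = pheno["tte"].to_numpy(dtype=float)
    event = pheno["event"].to_numpy(dtype=int)
    if event.sum() < 1:
        raise ValidationError("mortality EWAS requires at least one event")
    M = matrix.to_mvalues().values
    Z, sd = _standardize(M)
    C, _ = _covariate_matrix(pheno, covariates, pcs)
    Ccov = C[:, 1:]  # Cox has no intercept

    rows = []
    for j, cpg in enumerate(matrix.cpg_ids):
        if sd[j] == 0:
            rows.append((1.0, np.nan, 1.0, False, True))
            continue
        X = np.column_stack([Z[:, j], Ccov]) if Ccov.shape[1] else Z[:, [j]]
        fit = cox_fit(X, tte, event, max_iter=max_iter)
        loghr, se = fit.coef[0], fit.se[0]
        p = 2.0 * stats.norm.sf(abs(loghr / se)) if se > 0 else np.nan
        rows.append((np.exp(loghr), se, p, fit.converged, False))
    out = pd.DataFrame(
        rows,
        columns=["hr", "se_loghr", "p_cox", "converged", "degenerate"],
        index=pd.Index(matrix.cpg_ids, name="cpg"),
    )
    out["n_used"] = len(pheno)
    return out


def apply_significance(ewas: pd.DataFrame, p_column: str = "p_linear",
                       threshold: float = GENOME_WIDE_P) -> pd.DataFrame:
    """Rows with p < threshold, sorted by ascending p (NaNs dropped)."""
    if p_column not in ewas.columns:
        raise ValidationError(f"no column {p_column!r} in EWAS table")
    keep = ewas[ewas[p_column] < threshold].copy()
    return keep.sort_values(p_column, kind="mergesort")
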