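"""Performance metrics, survival association, meta-analysis, PH diagnostics
and the leave-one-cohort-out (LOCO) harness.

A note on MAE: throughout this package MAE is the MEDIAN absolute error
(the convention of the clock-benchmarking literature), not the mean; the
mean absolute error is reported separately as ``mean_abs_error``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._cox import CoxFit, cox_fit, schoenfeld_residuals
from .errors import ValidationError


# ---------------------------------------------------------------------------
# regression metrics
# ---------------------------------------------------------------------------

@dataclass
class RegressionMetrics:
    r: float
    rmse: float
    mae: float            # MEDIAN absolute error
    mean_abs_error: float
    n: int

    def as_dict(self):
        return {"r": self.r, "rmse": self.rmse, "mae": self.mae,
                "mean_abs_error": self.mean_abs_error, "n": self.n}


def regression_metrics(pred, truth) -> RegressionMetrics:
    """Pearson r, RMSE and median absolute error of predictions."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValidationError("pred and truth must be equal-length 1-D vectors")
    if len(pred) < 3:
        raise ValidationError("need at least 3 samples")
    if not (np.isfinite(pred).all() and np.isfinite(truth).all()):
        raise ValidationError("non-finite values in pred or truth")
    err = pred - truth
    if pred.std() == 0 or truth.std() == 0:
        r = np.nan  # correlation undefined for a constant vector
    else:
        r = float(np.corrcoef(pred, truth)[0, 1])
    return RegressionMetrics(
        r=r,
        rmse=float(np.sqrt(np.mean(err ** 2))),
        mae=float(np.median(np.abs(err))),
        mean_abs_error=float(np.mean(np.abs(err))),
        n=len(pred),
    )


# ---------------------------------------------------------------------------
# Harrell's C
# ---------------------------------------------------------------------------

def harrells_c(score, tte, event) -> float:
    """Concordance index for a risk score against censored survival times.

    A pair is comparable when the earlier time is an event; it is concordant
    when the sample with the earlier time has the higher score, and score
    ties count one half.
    """
    score = np.asarray(score, dtype=float)
    tte = np.asarray(tte, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(score)
    if not (len(tte) == len(event) == n):
        raise ValidationError("score, tte and event must have equal length")
    conc = 0.0
    comp = 0
    # i ranges over events; pairs (i, j) with t_i < t_j, or t_i == t_j and
    # j censored, are comparable
    for i in np.flatnonzero(event == 1):
        cmp_mask = (tte[i] < tte) | ((tte[i] == tte) & (event == 0))
        cmp_mask[i] = False
        m = int(cmp_mask.sum())
        if m == 0:
            continue
        comp += m
        s = score[cmp_mask]
        conc += float((score[i] > s).sum()) + 0.5 * float((score[i] == s).sum())
    if comp == 0:
        raise ValidationError("no comparable pairs")
    return conc / comp


# ---------------------------------------------------------------------------
# survival association and meta-analysis
# ---------------------------------------------------------------------------

@dataclass
class SurvivalAssociation:
    hr_per_sd: float
    ci95: tuple
    p: float
    loghr: float
    se_loghr: float
    n: int
    n_events: int
    covariates: tuple = ()
    converged: bool = True


def cox_association(accel, tte, event, age, sex,
                    extra: pd.DataFrame | None = None) -> SurvivalAssociation:
    """Cox PH association of an age-acceleration score with mortality.

    The score is z-scored within the dataset (so the hazard ratio is per
    SD) and modelled with age and sex as covariates; Wald CI and p-value.
    ``extra`` allows further joint covariates (e.g. a competing clock).
    """
    accel = np.asarray(accel, dtype=float)
    sd = accel.std(ddof=1)
    if sd == 0:
        raise ValidationError("acceleration score has zero variance")
    z = (accel - accel.mean()) / sd
    cols = [z, np.asarray(age, float), np.asarray(sex, float)]
    names = ["accel", "age", "sex"]
    if extra is not None:
        for c in extra.columns:
            cols.append(extra[c].to_numpy(dtype=float))
            names.append(str(c))
    X = np.column_stack(cols)
    fit = cox_fit(X, tte, event)
    loghr, se = fit.coef[0], fit.se[0]
    zcrit = stats.norm.isf(0.025)
    return SurvivalAssociation(
        hr_per_sd=float(np.exp(loghr)),
        ci95=(float(np.exp(loghr - zcrit * se)), float(np.exp(loghr + zcrit * se))),
        p=float(2.0 * stats.norm.sf(abs(loghr / se))),
        loghr=float(loghr),
        se_loghr=float(se),
        n=fit.n,
        n_events=fit.n_events,
        covariates=tuple(names[1:]),
        converged=fit.converged,
    )


@dataclass
class MetaResult:
    loghr: float
    se: float
    hr: float
    ci95: tuple
    p: float
    per_study: list = field(default_factory=list)


def fixed_effects_meta(per_study) -> MetaResult:
    """Inverse-variance-weighted fixed-effects pooling of log hazard ratios."""
    studies = list(per_study)
    if not studies:
        raise ValidationError("no studies to pool")
    thetas = np.array([s.loghr for s in studies])
    ses = np.array([s.se_loghr for s in studies])
    if np.any(ses <= 0) or not np.isfinite(ses).all():
        raise ValidationError("all study SEs must be positive and finite")
    w = 1.0 / ses ** 2
    pooled = float((w * thetas).sum() / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    zcrit = stats.norm.isf(0.025)
    return MetaResult(
        loghr=pooled, se=se, hr=float(np.exp(pooled)),
        ci95=(float(np.exp(pooled - zcrit * se)), float(np.exp(pooled + zcrit * se))),
        p=float(2.0 * stats.norm.sf(abs(pooled / se))),
        per_study=studies,
    )


def forest_table(per_study: dict) -> pd.DataFrame:
    """Forest-plot-ready table: study, HR, CI bounds, p."""
    rows = [
        {"study": name, "hr": s.hr_per_sd, "low": s.ci95[0], "high": s.ci95[1], "p": s.p}
        for name, s in per_study.items()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# proportional-hazards diagnostics
# ---------------------------------------------------------------------------

def _km_transform(times, tte, event):
    """Left-continuous Kaplan-Meier transform g(t) = 1 - S(t-) at event times."""
    tte = np.asarray(tte, float)
    event = np.asarray(event, int)
    uniq = np.unique(tte[event == 1])
    surv = 1.0
    g = {}
    at_risk_time = np.sort(tte)
    for t in uniq:
        g[t] = 1.0 - surv  # value just before the drop at t
        n_risk = int((tte >= t).sum())
        d = int(((tte == t) & (event == 1)).sum())
        surv *= (1.0 - d / n_risk) if n_risk > 0 else 1.0
    return np.array([g[t] for t in times])


def schoenfeld_test(fit: CoxFit, X, tte, event, transform: str = "km") -> pd.DataFrame:
    """Grambsch-Therneau test of the proportional-hazards assumption.

    Scaled Schoenfeld residuals are regressed (as a score test) on a
    transform of event time — the Kaplan-Meier transform by default,
    ``identity`` or ``rank`` by option.  Returns per-variable chi-square
    statistics and p-values plus a GLOBAL row.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    event = np.asarray(event, int)
    if event.sum() < 3:
        raise ValidationError("Schoenfeld test needs at least 3 events")
    S, times = schoenfeld_residuals(X, tte, event, fit.coef)
    d, p = S.shape
    if transform == "km":
        g = _km_transform(times, tte, event)
    elif transform == "identity":
        g = times.astype(float)
    elif transform == "rank":
        g = stats.rankdata(times)
    else:
        raise ValidationError(f"unknown time transform {transform!r}")
    w = g - g.mean()
    ssw = float(w @ w)
    if ssw == 0:
        raise ValidationError("degenerate time transform (all event times equal)")
    u = S.T @ w                      # p-vector
    V = fit.cov                      # inverse information at the optimum
    rows = []
    cu = V @ u
    for j in range(p):
        chi = d * cu[j] ** 2 / (V[j, j] * ssw)
        rows.append({"variable": f"x{j}", "chisq": float(chi), "df": 1,
                     "p": float(stats.chi2.sf(chi, 1))})
    chi_g = float(d * (u @ cu) / ssw)
    rows.append({"variable": "GLOBAL", "chisq": chi_g, "df": p,
                 "p": float(stats.chi2.sf(chi_g, p))})
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# leave-one-cohort-out harness
# ---------------------------------------------------------------------------

def loco_harness(cohorts: dict, train_fn, predict_fn, truth_key: str = "age",
                 anchor_cohort: str | None = None):
    """Leave-one-cohort-out evaluation.

    ``cohorts`` maps cohort name -> (data, phenotypes); for each held-out
    cohort (never the anchor, which always stays in training), ``train_fn``
    is called on the remaining cohorts and ``predict_fn(model, data)`` on
    the held-out one.  Returns ``(per_cohort_metrics, combined_metrics,
    provenance)`` where provenance proves the held-out cohort never entered
    training and combined metrics pool all held-out predictions.
    """
    names = list(cohorts)
    if len(names) < 2:
        raise ValidationError("LOCO needs at least two cohorts")
    if anchor_cohort is not None and anchor_cohort not in cohorts:
        raise ValidationError(f"anchor cohort {anchor_cohort!r} not among cohorts")
    held_out = [n for n in names if n != anchor_cohort]
    per_cohort = {}
    provenance = []
    all_pred, all_truth = [], []
    for test_name in held_out:
        train = {n: cohorts[n] for n in names if n != test_name}
        assert test_name not in train
        try:
            model = train_fn(train)
        except Exception as exc:
            raise RuntimeError(f"LOCO round holding out {test_name!r} failed: {exc}") from exc
        data, pheno = cohorts[test_name]
        pred = np.asarray(predict_fn(model, data), dtype=float)
        truth = pheno[truth_key].to_numpy(dtype=float)
        per_cohort[test_name] = regression_metrics(pred, truth)
        provenance.append({
            "held_out": test_name,
            "trained_on": sorted(train),
            "n_test": len(truth),
        })
        all_pred.append(pred)
        all_truth.append(truth)
    combined = regression_metrics(np.concatenate(all_pred), np.concatenate(all_truth))
    return per_cohort, combined, provenance
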