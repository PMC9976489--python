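"""Chronological-age (cAge) and biological-age (bAge) clock construction.

cAge: an elastic-net clock over EWAS-preselected CpG beta values (linear
and squared terms), trained twice — on age and on log(age).  At prediction
time the age-trained model is applied first; whenever its output is 20
years or younger the prediction is replaced by the exponentiated output of
the log(age) model (young ages follow a log-shaped methylation trajectory,
so the log model is better calibrated there).

bAge: a penalized Cox model over protein EpiScores (methylation surrogates
of plasma protein levels), a smoking score, chronological age and sex.
Every input feature is z-scored within the scoring dataset, and the fitted
linear predictor is itself z-scored within the dataset, making bAge a
cohort-relative score; its residual after regressing on chronological age
("bAgeAccel") measures accelerated epigenetic ageing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ValidationError
from .io import MethylationMatrix, WeightTable, write_weight_table, read_weight_table
from .net import (CoxElasticNet, GaussianElasticNet, build_feature_matrix,
                  make_folds)

#: hybrid rule: predictions at or below this many years are re-estimated
#: with the log(age) model (inclusive threshold)
LOG_MODEL_THRESHOLD = 20.0


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class ClockModel:
    """Serializable clock: weight table + outcome transform + metadata."""

    weights: WeightTable
    outcome_transform: str = "identity"  # or "log"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.outcome_transform not in ("identity", "log"):
            raise ValidationError(f"unknown outcome transform {self.outcome_transform!r}")

    def linear_predictor(self, matrix: MethylationMatrix) -> pd.Series:
        """Intercept + sum of weights over (beta or beta^2) features."""
        if matrix.scale != "beta":
            raise ValidationError("clock features are defined on the beta-value scale")
        ent = self.weights.entries
        missing = sorted(set(ent["feature"]) - set(matrix.data.columns))
        if missing:
            raise ValidationError(
                f"{len(missing)} model CpGs missing from matrix: {missing[:10]}"
            )
        vals = matrix.data[ent["feature"].tolist()].to_numpy()
        sq = (ent["transform"] == "squared").to_numpy()
        vals = np.where(sq[None, :], vals ** 2, vals)
        lp = vals @ ent["weight"].to_numpy() + self.weights.intercept
        return pd.Series(lp, index=matrix.data.index, name="prediction")

    def save(self, path):
        meta = dict(self.weights.metadata)
        meta.update({str(k): str(v) for k, v in self.metadata.items()})
        meta["outcome_transform"] = self.outcome_transform
        wt = WeightTable(self.weights.name, self.weights.intercept,
                         self.weights.entries, meta)
        write_weight_table(wt, path)

    @classmethod
    def load(cls, path) -> "ClockModel":
        wt = read_weight_table(path)
        transform = wt.metadata.get("outcome_transform", "identity")
        return cls(weights=wt, outcome_transform=transform, metadata=dict(wt.metadata))


@dataclass
class EpiScoreModel:
    """A protein EpiScore: beta-scale weight table for one protein."""

    protein: str
    weights: WeightTable

    def __post_init__(self):
        if (self.weights.entries["weight"] == 0).all():
            raise ValidationError(f"EpiScore {self.protein!r} has no nonzero weight")


@dataclass
class BAgeModel:
    """Cox-selected weights over standardized bAge input features.

    The standardization contract: every input feature is z-scored within
    the scoring dataset, and the resulting linear predictor is z-scored
    within the dataset before reporting.
    """

    features: list
    weights: np.ndarray  # per-SD Cox weights, aligned with ``features``
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.features) != len(self.weights):
            raise ValidationError("feature list and weight vector lengths differ")
        if not np.isfinite(self.weights).all():
            raise ValidationError("non-finite bAge weights")
        if not np.any(self.weights != 0):
            raise ValidationError("bAge model has no nonzero weight")

    def save(self, path):
        entries = pd.DataFrame({
            "feature": self.features,
            "transform": "linear",
            "weight": self.weights,
        })
        meta = {str(k): str(v) for k, v in self.metadata.items()}
        meta["standardization"] = "features z-scored within scoring dataset; output z-scored"
        wt = WeightTable("bAge", 0.0, entries, meta)
        write_weight_table(wt, path)

    @classmethod
    def load(cls, path) -> "BAgeModel":
        wt = read_weight_table(path)
        return cls(features=wt.entries["feature"].tolist(),
                   weights=wt.entries["weight"].to_numpy(),
                   metadata=dict(wt.metadata))


# ---------------------------------------------------------------------------
# sklearn-style estimators
# ---------------------------------------------------------------------------

class CAgeClock(BaseEstimator, RegressorMixin):
    """Hybrid chronological-age clock estimator.

    ``fit(X, y)`` takes a beta-scale feature design (columns as produced by
    :func:`methclock.net.build_feature_matrix`) and ages in years; it fits
    one elastic net on age and one on log(age) over the same features.
    ``predict`` applies the hybrid rule: the age model's output, replaced
    by exp(log-model output) whenever it is <= ``threshold`` years.
    """

    def __init__(self, alpha=0.5, lambda_grid=None, n_lambda=100,
                 lambda_min_ratio=1e-3, cv=10, threshold=LOG_MODEL_THRESHOLD,
                 tol=1e-7, random_state=0):
        self.alpha = alpha
        self.lambda_grid = lambda_grid
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.threshold = threshold
        self.tol = tol
        self.random_state = random_state

    def _net(self):
        return GaussianElasticNet(
            alpha=self.alpha, lambda_grid=self.lambda_grid,
            n_lambda=self.n_lambda, lambda_min_ratio=self.lambda_min_ratio,
            cv=self.cv, tol=self.tol, random_state=self.random_state)

    def fit(self, X, y, folds=None):
        y = np.asarray(y, dtype=float)
        if np.any(y <= 0):
            raise ValidationError("ages must be positive (log(age) model)")
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names_in_ = [f"f{j}" for j in range(X.shape[1])]
        self.net_age_ = self._net().fit(X, y, folds=folds)
        self.net_logage_ = self._net().fit(X, np.log(y), folds=folds)
        return self

    def predict(self, X, return_branch=False):
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names_in_].to_numpy(dtype=float)
        pred = self.net_age_.predict(X)
        log_branch = pred <= self.threshold
        if log_branch.any():
            pred = np.where(log_branch, np.exp(self.net_logage_.predict(X)), pred)
        if return_branch:
            return pred, np.where(log_branch, "log", "age")
        return pred

    def to_clock_models(self, extra_metadata=None):
        """Export the two fitted nets as serializable :class:`ClockModel`\\ s."""
        out = []
        for net, transform in ((self.net_age_, "identity"), (self.net_logage_, "log")):
            rows = []
            for name, w in zip(self.feature_names_in_, net.coef_):
                if w == 0.0:
                    continue
                if name.endswith("^2"):
                    rows.append((name[:-2], "squared", w))
                else:
                    rows.append((name, "linear", w))
            entries = pd.DataFrame(rows, columns=["feature", "transform", "weight"])
            meta = {
                "alpha": self.alpha,
                "lambda_selected": net.lambda_selected_,
                "n_features": len(entries),
                "outcome_transform": transform,
            }
            meta.update(extra_metadata or {})
            name = "cAge" if transform == "identity" else "cAge_log"
            out.append(ClockModel(WeightTable(name, float(net.intercept_), entries),
                                  outcome_transform=transform, metadata=meta))
        return tuple(out)


class BAgeClock(BaseEstimator):
    """Biological-age estimator: Cox elastic net over standardized features.

    ``fit(X, time, event)`` z-scores every column of X within the training
    dataset and fits a penalized Cox model with Harrell's C shrinkage
    selection; ``predict(X)`` applies the standardization contract (z-score
    features within the scoring dataset, z-score the linear predictor).
    """

    def __init__(self, alpha=0.5, lambda_grid=None, n_lambda=100,
                 lambda_min_ratio=1e-2, cv=10, tol=1e-6, random_state=0):
        self.alpha = alpha
        self.lambda_grid = lambda_grid
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, time, event, folds=None):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = list(X.columns)
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            self.feature_names_in_ = [f"f{j}" for j in range(arr.shape[1])]
        sds = arr.std(axis=0, ddof=1)
        if np.any(sds == 0):
            bad = [self.feature_names_in_[j] for j in np.flatnonzero(sds == 0)]
            raise ValidationError(f"zero-variance bAge features: {bad[:10]}")
        Z = (arr - arr.mean(axis=0)) / sds
        net = CoxElasticNet(alpha=self.alpha, lambda_grid=self.lambda_grid,
                            n_lambda=self.n_lambda,
                            lambda_min_ratio=self.lambda_min_ratio, cv=self.cv,
                            tol=self.tol, random_state=self.random_state)
        net.fit(Z, np.asarray(time, float), np.asarray(event, int), folds=folds)
        self.net_ = net
        self.coef_ = net.coef_  # per-SD weights (features entered z-scored)
        self.lambda_selected_ = net.lambda_selected_
        return self

    def model_(self) -> BAgeModel:
        keep = np.flatnonzero(self.coef_ != 0)
        return BAgeModel(
            features=[self.feature_names_in_[j] for j in keep],
            weights=self.coef_[keep],
            metadata={"alpha": self.alpha, "lambda_selected": self.lambda_selected_},
        )

    def predict(self, X):
        model = self.model_()
        X = pd.DataFrame(X, columns=self.feature_names_in_) if not isinstance(X, pd.DataFrame) else X
        return compute_bage(X, model).to_numpy()


# ---------------------------------------------------------------------------
# functional operations
# ---------------------------------------------------------------------------

def train_cage(cohorts, features: pd.DataFrame, alpha: float = 0.5,
               k_folds: int = 25, seed: int = 0, folds=None, **net_kwargs):
    """Train the hybrid cAge clock on pooled cohorts.

    ``cohorts`` maps cohort name -> (MethylationMatrix, phenotype frame);
    ``features`` comes from :func:`methclock.net.preselect_features`.
    Returns ``(ClockModel_age, ClockModel_logage)``.
    """
    designs, ages, groups = [], [], []
    for name, (meth, pheno) in cohorts.items():
        designs.append(build_feature_matrix(meth, features))
        a = pheno.loc[meth.sample_ids, "age"].to_numpy(dtype=float)
        if np.any(a <= 0):
            raise ValidationError(f"cohort {name!r} has non-positive ages")
        ages.append(a)
        groups.extend(pheno.loc[meth.sample_ids, "batch"].astype(str))
    X = pd.concat(designs, axis=0)
    y = np.concatenate(ages)
    if folds is None:
        folds = make_folds(X.index, k_folds, group_labels=groups, seed=seed).to_numpy()
    clock = CAgeClock(alpha=alpha, random_state=seed, **net_kwargs)
    clock.fit(X, y, folds=folds)
    meta = {"cohorts": ",".join(sorted(cohorts)), "n_samples": len(y)}
    model_age, model_log = clock.to_clock_models(meta)
    return model_age, model_log


def predict_cage(matrix: MethylationMatrix, model_age: ClockModel,
                 model_logage: ClockModel,
                 threshold: float = LOG_MODEL_THRESHOLD) -> pd.DataFrame:
    """Hybrid cAge prediction with branch bookkeeping.

    The age model's output is returned unless it is ``threshold`` years or
    younger, in which case the exponentiated log-model output replaces it.
    """
    if model_logage.outcome_transform != "log":
        raise ValidationError("second model must be the log(age) model")
    pred = model_age.linear_predictor(matrix)
    branch = np.where(pred <= threshold, "log", "age")
    if (pred <= threshold).any():
        log_pred = np.exp(model_logage.linear_predictor(matrix))
        pred = pd.Series(np.where(pred <= threshold, log_pred, pred),
                         index=pred.index, name="prediction")
    return pd.DataFrame({"prediction": pred, "branch": branch}, index=pred.index)


def project_episcores(matrix: MethylationMatrix, panel) -> pd.DataFrame:
    """Project an EpiScore panel: score = intercept + sum(w * beta).

    ``panel`` is a mapping protein -> WeightTable (or EpiScoreModel).  No
    scaling happens at this stage.  Missing CpGs are a hard error.
    """
    if matrix.scale != "beta":
        raise ValidationError("EpiScores are defined on the beta-value scale")
    out = {}
    for name, model in panel.items():
        wt = model.weights if isinstance(model, EpiScoreModel) else model
        missing = sorted(set(wt.entries["feature"]) - set(matrix.data.columns))
        if missing:
            raise ValidationError(
                f"EpiScore {name!r}: {len(missing)} CpGs missing: {missing[:10]}"
            )
        vals = matrix.data[wt.entries["feature"].tolist()].to_numpy()
        out[name] = vals @ wt.entries["weight"].to_numpy() + wt.intercept
    return pd.DataFrame(out, index=matrix.data.index)


def train_bage(features_table: pd.DataFrame, tte, event, alpha: float = 0.5,
               k_folds: int = 20, group_labels=None, seed: int = 0,
               folds=None, **net_kwargs) -> BAgeModel:
    """Train the bAge Cox elastic net on a standardized feature table.

    ``features_table`` columns are chronological age, sex, a smoking score
    and protein EpiScores; each is z-scored within the training dataset
    before fitting.  Folds keep technical-batch groups together.
    """
    if folds is None:
        folds = make_folds(features_table.index, k_folds,
                           group_labels=group_labels, seed=seed).to_numpy()
    clock = BAgeClock(alpha=alpha, random_state=seed, **net_kwargs)
    clock.fit(features_table, tte, event, folds=folds)
    return clock.model_()


def compute_bage(features_table: pd.DataFrame, model: BAgeModel) -> pd.Series:
    """bAge linear predictor under the standardization contract.

    Features are z-scored within this dataset, combined with the model
    weights, and the result is z-scored within the dataset (mean 0, sd 1).
    """
    missing = [f for f in model.features if f not in features_table.columns]
    if missing:
        raise ValidationError(f"bAge features missing from table: {missing[:10]}")
    arr = features_table[model.features].to_numpy(dtype=float)
    sds = arr.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [model.features[j] for j in np.flatnonzero(sds == 0)]
        raise ValidationError(f"zero-variance bAge features in scoring dataset: {bad}")
    Z = (arr - arr.mean(axis=0)) / sds
    lp = Z @ model.weights
    sd = lp.std(ddof=1)
    if sd == 0:
        raise ValidationError("bAge linear predictor has zero variance")
    return pd.Series((lp - lp.mean()) / sd, index=features_table.index, name="bage")


def compute_age_accel(predictions, age) -> np.ndarray:
    """Residual of a clock prediction regressed on chronological age.

    Simple least squares; the residuals are orthogonal to age and to the
    constant, so positive values mean "older than calendar age".
    """
    pred = np.asarray(predictions, dtype=float)
    age = np.asarray(age, dtype=float)
    if len(pred) != len(age) or len(pred) < 3:
        raise ValidationError("need >= 3 paired predictions and ages")
    if age.std() == 0:
        raise ValidationError("age is constant; acceleration undefined")
    A = np.column_stack([np.ones_like(age), age])
    coef, *_ = np.linalg.lstsq(A, pred, rcond=None)
    return pred - A @ coef
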