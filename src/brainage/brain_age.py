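"""Brain-age prediction and the relative-brain-age statistic.

The predictor is an L1-penalized (lasso) linear regression of
chronological age (CA) on standardized morphometric features, with the
penalty weight chosen by internal cross-validation.  Because noisy
predictors attenuate the fitted slope (regression dilution), the naive
delta PBA - CA is negatively correlated with CA; relative brain age
removes this by subtracting the expected PBA at a subject's age,

    RBA = PBA - E[PBA | CA],

where E[PBA | CA] (EPBA) is an ordinary least-squares line of PBA on CA
fitted on the training set.  RBA is uncorrelated with CA by construction
and positive RBA means the brain appears older than age-matched peers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold


@dataclass
class BrainAgeModel:
    """Fitted lasso age predictor (affine in standardized features)."""

    intercept: float
    coefficients: pd.Series          # per-feature weights, sparse in practice
    lambda_: float                   # selected L1 penalty weight
    cv_folds: int
    feature_means: pd.Series
    feature_scales: pd.Series
    training_mae: float

    @property
    def feature_names(self) -> list[str]:
        return list(self.coefficients.index)

    @property
    def n_nonzero(self) -> int:
        return int((self.coefficients != 0).sum())

    def to_json(self, path) -> None:
        obj = {
            "intercept": self.intercept,
            "lambda": self.lambda_,
            "cv_folds": self.cv_folds,
            "training_mae": self.training_mae,
            "features": self.feature_names,
            "coefficients": self.coefficients.tolist(),
            "feature_means": self.feature_means.tolist(),
            "feature_scales": self.feature_scales.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "BrainAgeModel":
        with open(path) as fh:
            obj = json.load(fh)
        idx = pd.Index(obj["features"])
        return cls(
            intercept=obj["intercept"],
            coefficients=pd.Series(obj["coefficients"], index=idx),
            lambda_=obj["lambda"],
            cv_folds=obj["cv_folds"],
            feature_means=pd.Series(obj["feature_means"], index=idx),
            feature_scales=pd.Series(obj["feature_scales"], index=idx),
            training_mae=obj["training_mae"],
        )


@dataclass
class EpbaModel:
    """OLS line of PBA on CA: EPBA(ca) = alpha + beta * ca."""

    alpha: float
    beta: float

    def predict(self, ca) -> np.ndarray:
        return self.alpha + self.beta * np.asarray(ca, dtype=float)


def split_cohort(subject_ids, training_fraction: float, seed: int):
    """Random split into training and evaluation sets.

    The training set takes ``ceil(fraction * n)`` subjects; the split is
    disjoint, exhaustive and reproducible for a fixed seed.
    """
    ids = list(subject_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 subjects to split")
    if not 0.0 < training_fraction < 1.0:
        raise ValueError("training_fraction must be in (0, 1)")
    n_train = math.ceil(training_fraction * n)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = [ids[i] for i in sorted(perm[:n_train])]
    evaluation = [ids[i] for i in sorted(perm[n_train:])]
    return train, evaluation


def _check_features(features: pd.DataFrame) -> None:
    bad = features.columns[~np.isfinite(features.to_numpy()).all(axis=0)]
    if len(bad):
        raise ValueError(f"non-finite values in feature(s): {list(bad[:5])}")


def fit_brain_age_model(
    features: pd.DataFrame,
    ca,
    cv_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    lambda_rule: str = "min",
) -> BrainAgeModel:
    """Fit the lasso age predictor.

    All features enter the model (no pre-selection); they are
    standardized to zero mean / unit variance before penalization, and
    the penalty weight is chosen by ``cv_folds``-fold cross-validation
    over a geometric grid.  ``lambda_rule='min'`` takes the CV-error
    minimizer (least shrinkage, best for unbiased downstream effect
    estimation); ``'1se'`` takes the sparsest penalty within one
    standard error of the minimum (much higher support-selection
    precision, slightly more attenuation).
    """
    ca = np.asarray(ca, dtype=float)
    if len(features) != len(ca):
        raise ValueError("features and ca must have equal length")
    if len(features) < 10 * cv_folds:
        raise ValueError(
            f"need >= {10 * cv_folds} subjects for {cv_folds}-fold CV"
        )
    _check_features(features)
    if np.ptp(ca) == 0:
        raise ValueError("chronological age is constant; cannot fit")

    X = features.to_numpy(dtype=float)
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales[scales == 0] = 1.0            # constant feature: keep, weight 0
    Xs = (X - means) / scales

    if lambda_rule not in ("min", "1se"):
        raise ValueError("lambda_rule must be 'min' or '1se'")
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    fit = LassoCV(alphas=n_lambdas, cv=cv, max_iter=50_000).fit(Xs, ca)
    lam = float(fit.alpha_)
    intercept, coefs = float(fit.intercept_), fit.coef_
    if lambda_rule == "1se":
        mse = fit.mse_path_.mean(axis=1)
        se = fit.mse_path_.std(axis=1) / np.sqrt(cv_folds)
        ceiling = mse.min() + se[int(mse.argmin())]
        lam = float(fit.alphas_[int(np.flatnonzero(mse <= ceiling).min())])
        refit = Lasso(alpha=lam, max_iter=50_000).fit(Xs, ca)
        intercept, coefs = float(refit.intercept_), refit.coef_

    coef = pd.Series(coefs, index=features.columns)
    model = BrainAgeModel(
        intercept=intercept,
        coefficients=coef,
        lambda_=lam,
        cv_folds=cv_folds,
        feature_means=pd.Series(means, index=features.columns),
        feature_scales=pd.Series(scales, index=features.columns),
        training_mae=float("nan"),
    )
    model.training_mae = mae(predict_brain_age(model, features), ca)
    return model


def predict_brain_age(model: BrainAgeModel, features: pd.DataFrame) -> np.ndarray:
    """Predicted brain age (PBA), in years."""
    missing = [c for c in model.feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing[:5]}")
    X = features[model.feature_names].to_numpy(dtype=float)
    _check_features(features[model.feature_names])
    Xs = (X - model.feature_means.to_numpy()) / model.feature_scales.to_numpy()
    return model.intercept + Xs @ model.coefficients.to_numpy()


def fit_epba(pba_train, ca_train) -> EpbaModel:
    """OLS of training-set PBA on CA: the expected PBA at each age."""
    pba = np.asarray(pba_train, dtype=float)
    ca = np.asarray(ca_train, dtype=float)
    if len(pba) != len(ca):
        raise ValueError("pba and ca must have equal length")
    if len(pba) < 3:
        raise ValueError("need at least 3 training subjects to fit EPBA")
    beta, alpha = np.polyfit(ca, pba, 1)
    return EpbaModel(alpha=float(alpha), beta=float(beta))


def compute_rba(pba, ca, epba_model: EpbaModel) -> np.ndarray:
    """Relative brain age: RBA = PBA - EPBA(CA), in years."""
    pba = np.asarray(pba, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if len(pba) != len(ca):
        raise ValueError("pba and ca must have equal length")
    return pba - epba_model.predict(ca)


def mae(pba, ca) -> float:
    """Mean absolute error between predicted and chronological age."""
    pba = np.asarray(pba, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if pba.size == 0:
        raise ValueError("empty input")
    if pba.shape != ca.shape:
        raise ValueError("pba and ca must have equal length")
    return float(np.mean(np.abs(pba - ca)))


def brain_age_table(subject_id, ca, pba, epba_model: EpbaModel) -> pd.DataFrame:
    """Per-subject CA/PBA/EPBA/RBA table (rba = pba - epba exactly)."""
    epba = epba_model.predict(ca)
    return pd.DataFrame(
        {
            "subject_id": list(subject_id),
            "ca": np.asarray(ca, dtype=float),
            "pba": np.asarray(pba, dtype=float),
            "epba": epba,
            "rba": np.asarray(pba, dtype=float) - epba,
        }
    )
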