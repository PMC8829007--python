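"""ROC analysis of per-sample predictors and nested-model comparison."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .exceptions import ParameterError

logger = logging.getLogger(__name__)


@dataclass
class RocReport:
    name: str
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "thresholds": self.thresholds.tolist(),
            "sensitivities": self.sensitivities.tolist(),
            "specificities": self.specificities.tolist(),
            "auc": self.auc,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


def roc_auc(score, label, name: str = "predictor") -> RocReport:
    """ROC curve and AUC for a continuous predictor of a binary label.

    The AUC is computed from the rank (Mann-Whitney U) statistic with
    average-rank tie handling, so it equals the proportion of concordant
    pairs plus half the ties.
    """
    score = np.asarray(score, dtype=float)
    label = np.asarray(label)
    if score.shape != label.shape:
        raise ParameterError("score and label must align")
    classes = np.unique(label)
    if len(classes) != 2:
        raise ParameterError(f"label must be binary with both classes present, got {classes}")
    y = (label == classes.max()).astype(int)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    ranks = rankdata(score)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    auc = float(u / (n_pos * n_neg))
    fpr, tpr, thr = roc_curve(y, score)
    return RocReport(
        name=name,
        thresholds=thr,
        sensitivities=tpr,
        specificities=1.0 - fpr,
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def _fit_logistic(x: np.ndarray, y: np.ndarray):
    """ML logistic fit; ridge fallback on separation/non-convergence."""
    design = sm.add_constant(x, has_constant="add")
    model = sm.Logit(y, design)
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=200)
        if np.any(~np.isfinite(res.params)) or np.any(np.abs(res.params) > 1e6):
            raise ValueError("diverged")
        return res.params, float(res.llf)
    except Exception:
        logger.warning("logistic fit failed to converge; ridge fallback (alpha=1e-4)")
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1e4, max_iter=5000)
        clf.fit(x, y)
        params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
        return params, float(model.loglike(params))


def combine_predictors(scores, label) -> np.ndarray:
    """Unpenalized logistic combination of predictors; returns the
    per-sample linear predictor."""
    x = np.column_stack([np.asarray(s, dtype=float) for s in scores])
    if x.shape[1] < 2:
        raise ParameterError("need >= 2 predictors to combine")
    label = np.asarray(label)
    y = (label == np.unique(label).max()).astype(int)
    if len(np.unique(y)) != 2:
        raise ParameterError("label must be binary")
    params, _ = _fit_logistic(x, y)
    return sm.add_constant(x, has_constant="add") @ params


def compare_nested_lrt(base_predictors, extended_predictors, label):
    """Likelihood-ratio test between nested logistic models.

    ``base_predictors`` must be a subset of ``extended_predictors``
    (compared by array identity of columns).  Returns (chi2, df, p).
    """
    base = [np.asarray(s, dtype=float) for s in base_predictors]
    ext = [np.asarray(s, dtype=float) for s in extended_predictors]
    for b in base:
        if not any(b.shape == e.shape and np.array_equal(b, e) for e in ext):
            raise ParameterError("base predictors must be a subset of extended predictors")
    label = np.asarray(label)
    y = (label == np.unique(label).max()).astype(int)
    if len(np.unique(y)) != 2:
        raise ParameterError("label must be binary")
    _, ll_base = _fit_logistic(np.column_stack(base), y)
    _, ll_ext = _fit_logistic(np.column_stack(ext), y)
    df = len(ext) - len(base)
    chi2 = max(0.0, 2.0 * (ll_ext - ll_base))
    if df == 0:
        return chi2, 0, 1.0
    return chi2, df, float(stats.chi2.sf(chi2, df))
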