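"""Finite Gaussian-mixture subtype discovery with BIC model selection.

A small EM implementation is used rather than an off-the-shelf mixture so
that all four covariance families (including the equal-spherical one), the
per-iteration log-likelihood trace, and the "larger is better" BIC
convention (2*loglik - p*ln n) are available and testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus
from sklearn.manifold import TSNE

from .exceptions import FitError, ParameterError

logger = logging.getLogger(__name__)

COVARIANCE_MODELS = ("spherical-equal", "spherical-varying", "diagonal", "full")

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class GaussianMixtureFit:
    """A converged mixture fit for one (k, covariance_model) pair."""

    k: int
    covariance_model: str
    weights: np.ndarray          # (k,)
    means: np.ndarray            # (k, d)
    covariances: np.ndarray      # family-dependent shape
    loglik: float
    loglik_trace: list[float]
    n_iter: int
    converged: bool
    seed: int

    @property
    def d(self) -> int:
        return self.means.shape[1]

    def n_params(self) -> int:
        k, d = self.k, self.d
        base = (k - 1) + k * d
        if self.covariance_model == "spherical-equal":
            return base + 1
        if self.covariance_model == "spherical-varying":
            return base + k
        if self.covariance_model == "diagonal":
            return base + k * d
        return base + k * d * (d + 1) // 2

    def bic(self, n: int) -> float:
        """mclust sign convention: larger is better."""
        return 2.0 * self.loglik - self.n_params() * np.log(n)

    def log_resp(self, x: np.ndarray) -> np.ndarray:
        lp = _log_prob(x, self.means, self.covariances, self.covariance_model)
        lp = lp + np.log(self.weights)[None, :]
        return lp - logsumexp(lp, axis=1, keepdims=True)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return np.exp(self.log_resp(x))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.log_resp(x), axis=1)


@dataclass
class SubtypeModel:
    """Selected mixture plus the full BIC trace and subtype assignments."""

    k: int
    covariance_model: str
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    bic: float
    bic_trace: dict[str, float]          # "k=6,model=diagonal" -> BIC
    assignment: np.ndarray               # subtype labels, 1..k by descending size
    responsibilities: np.ndarray         # samples x k, columns in label order
    loglik: float
    seed: int
    sample_ids: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "covariance_model": self.covariance_model,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": np.asarray(self.covariances).tolist(),
            "bic": self.bic,
            "bic_trace": self.bic_trace,
            "assignment": {s: int(a) for s, a in zip(self.sample_ids, self.assignment)},
            "loglik": self.loglik,
            "seed": self.seed,
            "feature_ids": self.feature_ids,
        }


def _log_prob(x: np.ndarray, means: np.ndarray, covs: np.ndarray, model: str) -> np.ndarray:
    """Per-sample per-component Gaussian log density, (n, k)."""
    n, d = x.shape
    k = means.shape[0]
    out = np.empty((n, k))
    if model == "spherical-equal":
        var = float(covs)
        for j in range(k):
            sq = np.sum((x - means[j]) ** 2, axis=1)
            out[:, j] = -0.5 * (d * (_LOG2PI + np.log(var)) + sq / var)
    elif model == "spherical-varying":
        for j in range(k):
            var = covs[j]
            sq = np.sum((x - means[j]) ** 2, axis=1)
            out[:, j] = -0.5 * (d * (_LOG2PI + np.log(var)) + sq / var)
    elif model == "diagonal":
        for j in range(k):
            var = covs[j]
            sq = np.sum((x - means[j]) ** 2 / var, axis=1)
            out[:, j] = -0.5 * (d * _LOG2PI + np.sum(np.log(var)) + sq)
    elif model == "full":
        for j in range(k):
            chol = np.linalg.cholesky(covs[j])
            z = np.linalg.solve(chol, (x - means[j]).T).T
            logdet = 2.0 * np.sum(np.log(np.diag(chol)))
            out[:, j] = -0.5 * (d * _LOG2PI + logdet + np.sum(z**2, axis=1))
    else:
        raise ParameterError(f"unknown covariance model {model!r}")
    return out


def _m_step(x: np.ndarray, resp: np.ndarray, model: str, reg: float = 1e-6):
    n, d = x.shape
    nk = resp.sum(axis=0)
    weights = nk / n
    means = (resp.T @ x) / nk[:, None]
    if model == "spherical-equal":
        total = 0.0
        for j in range(means.shape[0]):
            total += np.sum(resp[:, j] * np.sum((x - means[j]) ** 2, axis=1))
        covs = np.asarray(total / (n * d) + reg)
    elif model == "spherical-varying":
        covs = np.empty(means.shape[0])
        for j in range(means.shape[0]):
            covs[j] = np.sum(resp[:, j] * np.sum((x - means[j]) ** 2, axis=1)) / (nk[j] * d) + reg
    elif model == "diagonal":
        covs = np.empty((means.shape[0], d))
        for j in range(means.shape[0]):
            covs[j] = (resp[:, j, None] * (x - means[j]) ** 2).sum(axis=0) / nk[j] + reg
    else:  # full
        covs = np.empty((means.shape[0], d, d))
        for j in range(means.shape[0]):
            diff = x - means[j]
            covs[j] = (resp[:, j, None] * diff).T @ diff / nk[j] + reg * np.eye(d)
    return weights, means, covs


def _init_params(x: np.ndarray, k: int, model: str, rng: np.random.Generator):
    centers, _ = kmeans_plusplus(x, k, random_state=int(rng.integers(2**31)))
    # hard assignment to nearest center seeds the responsibilities
    d2 = np.sum((x[:, None, :] - centers[None, :, :]) ** 2, axis=2)
    labels = np.argmin(d2, axis=1)
    resp = np.zeros((x.shape[0], k))
    resp[np.arange(x.shape[0]), labels] = 1.0
    resp = resp + 1e-10
    resp /= resp.sum(axis=1, keepdims=True)
    return _m_step(x, resp, model)


def fit_gmm(
    x: np.ndarray,
    k: int,
    covariance_model: str = "diagonal",
    n_init: int = 10,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> GaussianMixtureFit:
    """EM fit of a k-component Gaussian mixture; best of ``n_init`` starts.

    The log-likelihood is non-decreasing across iterations; an empty
    component triggers re-initialization (up to 5 times) before failing.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ParameterError("x must be samples x features")
    n, d = x.shape
    if covariance_model not in COVARIANCE_MODELS:
        raise ParameterError(f"covariance_model must be one of {COVARIANCE_MODELS}")
    if k < 1:
        raise ParameterError("k must be >= 1")
    if n <= k:
        raise ParameterError(f"need more samples ({n}) than components ({k})")

    rng = np.random.default_rng(seed)
    best: GaussianMixtureFit | None = None
    for init in range(max(1, n_init)):
        fit = None
        for attempt in range(5):
            try:
                fit = _em_once(x, k, covariance_model, rng, max_iter, tol)
                break
            except _EmptyComponent:
                continue
        if fit is None:
            continue
        if best is None or fit.loglik > best.loglik:
            best = fit
    if best is None:
        raise FitError(f"all EM initializations collapsed for k={k}, {covariance_model}")
    best.seed = seed
    return best


class _EmptyComponent(Exception):
    pass


def _em_once(x, k, model, rng, max_iter, tol) -> GaussianMixtureFit:
    n, d = x.shape
    weights, means, covs = _init_params(x, k, model, rng)
    trace: list[float] = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lp = _log_prob(x, means, covs, model) + np.log(weights)[None, :]
        norm = logsumexp(lp, axis=1)
        loglik = float(norm.sum())
        trace.append(loglik)
        resp = np.exp(lp - norm[:, None])
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-8):
            raise _EmptyComponent
        weights, means, covs = _m_step(x, resp, model)
        if np.isfinite(prev) and abs(loglik - prev) <= tol * max(abs(prev), 1.0):
            converged = True
            break
        prev = loglik
    return GaussianMixtureFit(k, model, weights, means, covs,
                              trace[-1], trace, it, converged, seed=0)


def select_model_bic(
    scores: np.ndarray,
    k_range: range | list[int] = range(2, 29),
    models: list[str] | tuple[str, ...] = COVARIANCE_MODELS,
    n_init: int = 10,
    seed: int = 0,
    sample_ids: list[str] | None = None,
    feature_ids: list[str] | None = None,
) -> SubtypeModel:
    """Fit every (k, model) pair and return the BIC maximizer.

    BIC uses the "larger is better" convention ``2*loglik - p*ln(n)``.
    The winning fit's labels are renumbered by descending cluster size.
    """
    x = np.asarray(scores, dtype=float)
    n = x.shape[0]
    ks = list(k_range)
    if not ks or min(ks) < 1:
        raise ParameterError("k_range must contain positive integers")
    trace: dict[str, float] = {}
    best_fit: GaussianMixtureFit | None = None
    best_bic = -np.inf
    failures: list[str] = []
    ss = np.random.SeedSequence(seed)
    child_seeds = iter(ss.generate_state(len(ks) * len(models) * 2))
    for k in ks:
        for model in models:
            key = f"k={k},model={model}"
            sub_seed = int(next(child_seeds)) % (2**31)
            try:
                fit = fit_gmm(x, k, model, n_init=n_init, seed=sub_seed)
            except (FitError, ParameterError) as exc:
                failures.append(f"{key}: {exc}")
                continue
            bic = fit.bic(n)
            trace[key] = float(bic)
            if bic > best_bic:
                best_bic, best_fit = bic, fit
    if best_fit is None:
        raise FitError("all (k, model) fits failed: " + "; ".join(failures))

    resp = best_fit.predict_proba(x)
    raw = np.argmax(resp, axis=1)
    order = np.argsort([-np.sum(raw == j) for j in range(best_fit.k)], kind="stable")
    relabel = np.empty(best_fit.k, dtype=int)
    relabel[order] = np.arange(1, best_fit.k + 1)
    assignment = relabel[raw]
    return SubtypeModel(
        k=best_fit.k,
        covariance_model=best_fit.covariance_model,
        weights=best_fit.weights[order],
        means=best_fit.means[order],
        covariances=np.asarray(best_fit.covariances)[order]
        if best_fit.covariance_model != "spherical-equal"
        else best_fit.covariances,
        bic=float(best_bic),
        bic_trace=trace,
        assignment=assignment,
        responsibilities=resp[:, order],
        loglik=best_fit.loglik,
        seed=seed,
        sample_ids=list(sample_ids) if sample_ids is not None else [],
        feature_ids=list(feature_ids) if feature_ids is not None else [],
    )


def assign_subtypes(model: SubtypeModel, scores: np.ndarray) -> np.ndarray:
    """Posterior-argmax subtype labels (1..k) for new samples."""
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2 or x.shape[1] != model.means.shape[1]:
        raise ParameterError(
            f"scores must be samples x {model.means.shape[1]}, got {x.shape}"
        )
    lp = _log_prob(x, model.means, np.asarray(model.covariances), model.covariance_model)
    lp = lp + np.log(model.weights)[None, :]
    return np.argmax(lp, axis=1) + 1


def embed_2d(scores: np.ndarray, seed: int = 0, perplexity: float | None = None) -> np.ndarray:
    """Seed-fixed 2-D stochastic-neighbor embedding for reporting only."""
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ParameterError("embedding needs samples x d with d >= 2")
    if perplexity is None:
        perplexity = min(30.0, max(2.0, (x.shape[0] - 1) / 4))
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    return tsne.fit_transform(x)
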