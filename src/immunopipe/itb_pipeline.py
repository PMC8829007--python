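"""Prognostic-score construction and survival stratification.

Pipeline: subtype-marker panel -> (optional classifier validation) ->
per-gene univariate Cox -> PCA on the z-scored panel -> per-sample score
summing PC1 contributions of hazard-increasing genes minus those of
hazard-decreasing genes -> survival-based cutpoint -> high/low groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test, multivariate_logrank_test
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .exceptions import FitError, ParameterError
from .signature_scoring import zscore_rows

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# results


@dataclass
class CoxResult:
    gene: str
    coefficient: float
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    n_events: int
    converged: bool = True

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class ClassifierReport:
    algorithm: str
    subtype: object
    selected_features: list[str]
    fold_aucs: list[float]
    cv_auc: float
    test_auc: float
    seed: int

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["subtype"] = str(self.subtype)
        return d


@dataclass
class ITBResult:
    gene_panel: list[str]
    pc1_loadings: dict[str, float]
    positive_genes: list[str]
    negative_genes: list[str]
    score: pd.Series
    cutpoint: float | None = None
    group: pd.Series | None = None
    logrank_p: float | None = None
    hr_high_vs_low: float | None = None
    hr_ci: tuple[float, float] | None = None
    cox_results: list[CoxResult] = field(default_factory=list)
    pca_mode: str = "pooled"

    def to_dict(self) -> dict:
        return {
            "gene_panel": self.gene_panel,
            "pc1_loadings": self.pc1_loadings,
            "positive_genes": self.positive_genes,
            "negative_genes": self.negative_genes,
            "score": {s: float(v) for s, v in self.score.items()},
            "cutpoint": self.cutpoint,
            "group": {s: v for s, v in self.group.items()} if self.group is not None else None,
            "logrank_p": self.logrank_p,
            "hr_high_vs_low": self.hr_high_vs_low,
            "hr_ci": list(self.hr_ci) if self.hr_ci is not None else None,
            "cox_results": [c.to_dict() for c in self.cox_results],
            "pca_mode": self.pca_mode,
        }


# ---------------------------------------------------------------------------
# cohort splitting and feature selection


def split_cohort(sample_ids, labels, train_fraction: float = 0.7, seed: int = 0):
    """Stratified, seed-reproducible train/test split of sample ids."""
    if not 0 < train_fraction < 1:
        raise ParameterError(f"train_fraction must be in (0, 1), got {train_fraction}")
    sample_ids = np.asarray(sample_ids)
    labels = np.asarray(labels)
    if sample_ids.shape[0] != labels.shape[0]:
        raise ParameterError("sample_ids and labels must align")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ParameterError("every subtype needs >= 2 samples for a stratified split")
    train, test = train_test_split(
        sample_ids, train_size=train_fraction, stratify=labels, random_state=seed
    )
    return list(train), list(test)


def lasso_select(
    expr_train: pd.DataFrame,
    labels,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> list[str]:
    """L1-penalized logistic feature selection with the 1-SE rule.

    ``expr_train`` is genes x samples; ``labels`` binary.  Lambda is
    chosen by cross-validated deviance: the largest lambda within one
    standard error of the minimum.  Returns genes with nonzero
    coefficients (possibly empty, with a warning).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ParameterError(f"labels must be binary, got {len(classes)} classes")
    if expr_train.shape[1] < 10:
        raise ParameterError("need >= 10 training samples")
    x = expr_train.to_numpy(dtype=float).T
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd[sd == 0] = 1.0
    x = (x - mu) / sd
    y = (labels == classes[1]).astype(int)
    if lambda_grid is None:
        lambda_grid = np.logspace(-3, 1, 20)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(x, y))
    dev = np.zeros((len(lambda_grid), cv_folds))
    for i, lam in enumerate(lambda_grid):
        for f, (tr, va) in enumerate(folds):
            clf = LogisticRegression(
                l1_ratio=1.0, C=1.0 / (lam * len(tr)), solver="liblinear", max_iter=2000
            )
            clf.fit(x[tr], y[tr])
            p = np.clip(clf.predict_proba(x[va])[:, 1], 1e-12, 1 - 1e-12)
            dev[i, f] = -2.0 * np.mean(y[va] * np.log(p) + (1 - y[va]) * np.log(1 - p))
    mean_dev = dev.mean(axis=1)
    se_dev = dev.std(axis=1, ddof=1) / np.sqrt(cv_folds)
    i_min = int(np.argmin(mean_dev))
    threshold = mean_dev[i_min] + se_dev[i_min]
    # grid is descending, so the first index within threshold is the
    # largest (most parsimonious) lambda
    i_1se = int(np.flatnonzero(mean_dev <= threshold)[0])
    lam = lambda_grid[i_1se]
    clf = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (lam * len(y)), solver="liblinear", max_iter=2000
    )
    clf.fit(x, y)
    selected = list(expr_train.index[np.abs(clf.coef_.ravel()) > 1e-10])
    if not selected:
        logger.warning("LASSO selected no features at lambda=%.4g", lam)
    return selected


def _make_classifier(algorithm: str, seed: int):
    if algorithm == "logistic":
        return LogisticRegression(max_iter=2000)
    if algorithm == "svm":
        return SVC(kernel="linear", random_state=seed)
    if algorithm == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    raise ParameterError(f"unknown algorithm {algorithm!r}")


def _decision_scores(clf, x: np.ndarray) -> np.ndarray:
    if hasattr(clf, "decision_function"):
        return clf.decision_function(x)
    return clf.predict_proba(x)[:, 1]


def compare_classifiers(
    expr_train: pd.DataFrame,
    labels,
    expr_test: pd.DataFrame | None = None,
    test_labels=None,
    algorithms: tuple[str, ...] = ("logistic", "svm", "random_forest"),
    folds: int = 5,
    seed: int = 0,
    target=None,
) -> list[ClassifierReport]:
    """Fivefold CV comparison of classifiers on one-vs-rest subtype targets.

    LASSO selection runs inside every fold on the 4/5 training part; the
    winner per subtype is the algorithm with the highest mean CV AUC and
    is refit on the full training set for the held-out test AUC.
    """
    from .evaluation import roc_auc

    labels = np.asarray(labels)
    subtypes = [target] if target is not None else list(np.unique(labels))
    reports: list[ClassifierReport] = []
    for st in subtypes:
        y = (labels == st).astype(int)
        if y.sum() < folds or (1 - y).sum() < folds:
            logger.warning("subtype %r too small for %d-fold CV; skipped", st, folds)
            continue
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        fold_splits = list(skf.split(expr_train.columns, y))
        full_sel = lasso_select(expr_train, y, cv_folds=3, seed=seed)
        if not full_sel:
            full_sel = list(expr_train.index)
        for algorithm in algorithms:
            fold_aucs = []
            for tr, va in fold_splits:
                sel = lasso_select(expr_train.iloc[:, tr], y[tr], cv_folds=3, seed=seed)
                if not sel:
                    sel = list(expr_train.index)
                xtr = expr_train.loc[sel].to_numpy().T[tr]
                xva = expr_train.loc[sel].to_numpy().T[va]
                clf = _make_classifier(algorithm, seed)
                clf.fit(xtr, y[tr])
                fold_aucs.append(roc_auc(_decision_scores(clf, xva), y[va]).auc)
            test_auc = float("nan")
            if expr_test is not None and test_labels is not None:
                y_test = (np.asarray(test_labels) == st).astype(int)
                clf = _make_classifier(algorithm, seed)
                clf.fit(expr_train.loc[full_sel].to_numpy().T, y)
                test_auc = roc_auc(
                    _decision_scores(clf, expr_test.loc[full_sel].to_numpy().T), y_test
                ).auc
            reports.append(
                ClassifierReport(
                    algorithm=algorithm,
                    subtype=st,
                    selected_features=full_sel,
                    fold_aucs=[float(a) for a in fold_aucs],
                    cv_auc=float(np.mean(fold_aucs)),
                    test_auc=float(test_auc),
                    seed=seed,
                )
            )
    return reports


# ---------------------------------------------------------------------------
# Cox screening and the score


def univariate_cox(
    gene_expr,
    survival: pd.DataFrame,
    gene: str = "gene",
    min_events: int = 10,
) -> CoxResult:
    """Univariate Cox proportional-hazards fit (Efron ties, Wald CI).

    Non-convergence (monotone likelihood) returns a flagged result with
    infinite confidence bounds rather than raising.
    """
    x = np.asarray(gene_expr, dtype=float)
    n_events = int(survival["event"].sum())
    if n_events < min_events:
        raise ParameterError(f"need >= {min_events} events, got {n_events}")
    df = pd.DataFrame(
        {"time": survival["time"].to_numpy(), "event": survival["event"].to_numpy(), "x": x}
    )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, ValueError) as exc:
        logger.warning("Cox fit for %s did not converge: %s", gene, exc)
        return CoxResult(gene, 0.0, 1.0, 0.0, float("inf"), 1.0, n_events, converged=False)
    row = cph.summary.loc["x"]
    return CoxResult(
        gene=gene,
        coefficient=float(row["coef"]),
        hr=float(row["exp(coef)"]),
        ci_low=float(np.exp(row["coef lower 95%"])),
        ci_high=float(np.exp(row["coef upper 95%"])),
        p_value=float(row["p"]),
        n_events=n_events,
        converged=True,
    )


def _pc1_loadings(z: np.ndarray) -> np.ndarray:
    """First principal loading vector of a genes x samples z-scored block."""
    u, _, _ = np.linalg.svd(z, full_matrices=False)
    return u[:, 0]


def compute_itbscore(
    expr: pd.DataFrame,
    cox: list[CoxResult],
    pca_mode: str = "pooled",
) -> ITBResult:
    """Cox-sign-partitioned PC1 score for every sample.

    The panel expression is z-scored per gene and decomposed by PCA; each
    gene's per-sample contribution is loading * z-expression, and the
    score sums contributions of genes with positive Cox coefficients and
    subtracts those with negative coefficients.  The loading vector is
    oriented so that (sum of positive-gene loadings - sum of
    negative-gene loadings) >= 0.  ``pca_mode="split"`` runs one PCA per
    sign partition instead of a pooled one.
    """
    if pca_mode not in ("pooled", "split"):
        raise ParameterError(f"pca_mode must be 'pooled' or 'split', got {pca_mode!r}")
    by_gene = {c.gene: c for c in cox}
    panel = [g for g in expr.index if g in by_gene]
    if len(panel) < 2:
        raise ParameterError(f"need >= 2 panel genes with Cox results, got {len(panel)}")
    usable = [g for g in panel
              if by_gene[g].converged and np.isfinite(by_gene[g].coefficient)
              and by_gene[g].coefficient != 0.0]
    dropped = sorted(set(panel) - set(usable))
    if dropped:
        logger.info("excluding %d genes with zero/non-finite Cox coefficients", len(dropped))
    if len(usable) < 2:
        raise ParameterError("fewer than 2 panel genes with usable Cox coefficients")
    pos = [g for g in usable if by_gene[g].coefficient > 0]
    neg = [g for g in usable if by_gene[g].coefficient < 0]
    if not pos or not neg:
        logger.info("all Cox coefficients share one sign; score is a single signed sum")

    z = zscore_rows(expr.loc[usable])
    zv = z.to_numpy()
    sign = np.array([1.0 if g in pos else -1.0 for g in usable])

    if pca_mode == "pooled":
        loadings = _pc1_loadings(zv)
        orient = np.sum(loadings * sign)
        if abs(orient) < 1e-10:  # signed sum ties: fall back to plain sum
            orient = loadings.sum()
        if abs(orient) < 1e-10:
            orient = loadings[np.flatnonzero(np.abs(loadings) > 1e-10)[0]]
        if orient < 0:
            loadings = -loadings
    else:
        loadings = np.zeros(len(usable))
        for part in (pos, neg):
            if not part:
                continue
            idx = [usable.index(g) for g in part]
            if len(idx) == 1:
                loadings[idx[0]] = 1.0
                continue
            sub = _pc1_loadings(zv[idx])
            if sub.sum() < 0:
                sub = -sub
            for i, j in enumerate(idx):
                loadings[j] = sub[i]

    contributions = loadings[:, None] * zv
    score = (sign[:, None] * contributions).sum(axis=0)
    return ITBResult(
        gene_panel=list(usable),
        pc1_loadings={g: float(l) for g, l in zip(usable, loadings)},
        positive_genes=pos,
        negative_genes=neg,
        score=pd.Series(score, index=expr.columns, name="itbscore"),
        cox_results=[by_gene[g] for g in usable],
        pca_mode=pca_mode,
    )


# ---------------------------------------------------------------------------
# survival stratification


def _logrank_z(high: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Standardized two-group log-rank statistic (group = ``high``)."""
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], high[order].astype(float)
    n = len(t)
    at_risk_total = np.arange(n, 0, -1, dtype=float)
    # walk distinct event times
    obs = exp = var = 0.0
    i = 0
    n1 = g.sum()
    ntot = float(n)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = e[i:j].sum()
        if d > 0:
            d1 = (e[i:j] * g[i:j]).sum()
            obs += d1
            exp += d * n1 / ntot
            if ntot > 1:
                var += d * (n1 / ntot) * (1 - n1 / ntot) * (ntot - d) / (ntot - 1)
        n1 -= g[i:j].sum()
        ntot -= j - i
        i = j
    if var <= 0:
        return float("nan")
    return float((obs - exp) / np.sqrt(var))


def optimal_cutpoint(
    score,
    survival: pd.DataFrame,
    minprop: float = 0.1,
) -> tuple[float, pd.Series]:
    """Maximally selected rank-statistic cutpoint.

    Every candidate split leaving at least ``minprop`` of samples on each
    side is scored by the absolute standardized log-rank statistic; the
    maximizer wins, ties going to the smaller cutpoint.  Returns the
    cutpoint and a high/low label per sample (high: score > cutpoint).
    """
    score = pd.Series(score) if not isinstance(score, pd.Series) else score
    n = len(score)
    if n < 20:
        raise ParameterError(f"need >= 20 samples, got {n}")
    n_events = int(survival["event"].sum())
    if n_events < 5:
        raise ParameterError(f"need >= 5 events, got {n_events}")
    time = survival["time"].to_numpy(dtype=float)
    event = survival["event"].to_numpy(dtype=int)
    vals = np.sort(np.unique(score.to_numpy()))
    if len(vals) < 2:
        raise ParameterError("score is constant; no candidate cutpoints")
    mids = (vals[:-1] + vals[1:]) / 2.0
    svals = score.to_numpy()
    best_z, best_cut = -np.inf, None
    for cut in mids:
        high = svals > cut
        k = high.sum()
        if k < minprop * n or (n - k) < minprop * n:
            continue
        z = abs(_logrank_z(high, time, event))
        if np.isfinite(z) and z > best_z + 1e-12:
            best_z, best_cut = z, float(cut)
    if best_cut is None:
        raise ParameterError("no valid cutpoint candidate (degenerate survival or minprop)")
    groups = pd.Series(
        np.where(svals > best_cut, "high", "low"), index=score.index, name="group"
    )
    return best_cut, groups


def km_logrank(groups, survival: pd.DataFrame):
    """Kaplan-Meier curves per group plus the log-rank test.

    Returns ``(curves, chi2, p)`` where ``curves`` maps group label to a
    survival-function DataFrame.
    """
    groups = pd.Series(groups) if not isinstance(groups, pd.Series) else groups
    labels = groups.to_numpy()
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ParameterError("log-rank needs >= 2 groups")
    time = survival["time"].to_numpy(dtype=float)
    event = survival["event"].to_numpy(dtype=int)
    curves = {}
    for g in uniq:
        mask = labels == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask], label=str(g))
        curves[g] = kmf.survival_function_
    if len(uniq) == 2:
        res = logrank_test(
            time[labels == uniq[0]], time[labels == uniq[1]],
            event_observed_A=event[labels == uniq[0]],
            event_observed_B=event[labels == uniq[1]],
        )
    else:
        res = multivariate_logrank_test(time, labels, event)
    return curves, float(res.test_statistic), float(res.p_value)


def cox_on_score(score, survival: pd.DataFrame, covariates: pd.DataFrame | None = None) -> CoxResult:
    """Cox model of survival on a continuous score (optionally adjusted)."""
    df = pd.DataFrame(
        {"time": survival["time"].to_numpy(), "event": survival["event"].to_numpy(),
         "score": np.asarray(score, dtype=float)}
    )
    if covariates is not None:
        for col in covariates.columns:
            df[col] = covariates[col].to_numpy()
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    row = cph.summary.loc["score"]
    return CoxResult(
        gene="score",
        coefficient=float(row["coef"]),
        hr=float(row["exp(coef)"]),
        ci_low=float(np.exp(row["coef lower 95%"])),
        ci_high=float(np.exp(row["coef upper 95%"])),
        p_value=float(row["p"]),
        n_events=int(df["event"].sum()),
    )


def run_itb(
    expr: pd.DataFrame,
    panel: list[str],
    survival: pd.DataFrame,
    pca_mode: str = "pooled",
    minprop: float = 0.1,
    min_events: int = 10,
) -> ITBResult:
    """Panel -> per-gene Cox -> score -> cutpoint -> stratified survival."""
    panel = [g for g in panel if g in expr.index]
    if len(panel) < 2:
        raise ParameterError("panel must contain >= 2 genes present in expression")
    cox_results = []
    for g in panel:
        cox_results.append(
            univariate_cox(expr.loc[g].to_numpy(), survival, gene=g, min_events=min_events)
        )
    result = compute_itbscore(expr.loc[panel], cox_results, pca_mode=pca_mode)
    cut, groups = optimal_cutpoint(result.score, survival, minprop=minprop)
    result.cutpoint = cut
    result.group = groups
    _, chi2, p = km_logrank(groups, survival)
    result.logrank_p = p
    hi = (groups == "high").astype(float)
    try:
        hr_res = cox_on_score(hi, survival)
        result.hr_high_vs_low = hr_res.hr
        result.hr_ci = (hr_res.ci_low, hr_res.ci_high)
    except (ConvergenceError, FitError):  # pragma: no cover - degenerate strata
        logger.warning("high-vs-low Cox did not converge")
    return result
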