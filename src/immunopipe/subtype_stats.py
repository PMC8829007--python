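"""Group-comparison statistics, FDR control, and subtype marker calling."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ParameterError

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    groups: tuple
    q_value: float | None = None
    effect: float | None = None

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "q_value": self.q_value,
            "groups": list(self.groups),
            "effect": self.effect,
        }


def _split_groups(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape[0] != labels.shape[0]:
        raise ParameterError("values and labels must be sample-aligned")
    uniq = np.unique(labels)
    groups = [values[labels == g] for g in uniq]
    for g, arr in zip(uniq, groups):
        if arr.size == 0:
            raise ParameterError(f"group {g!r} is empty")
    return uniq, groups


def kruskal_wallis(values, labels) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected) across k >= 2 groups."""
    uniq, groups = _split_groups(values, labels)
    if len(uniq) < 2:
        raise ParameterError("need >= 2 groups")
    if np.ptp(np.concatenate(groups)) == 0:
        # all observations identical: H is 0 by convention, not NaN
        return TestResult(0.0, 1.0, tuple(uniq))
    stat, p = stats.kruskal(*groups)
    return TestResult(float(stat), float(p), tuple(uniq))


def wilcoxon_one_vs_rest(values, labels, target) -> TestResult:
    """Two-sided Wilcoxon rank-sum of one group against all others.

    Exact enumeration for small untied samples, normal approximation with
    tie and continuity correction otherwise (scipy's ``method="auto"``).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    mask = labels == target
    a, b = values[mask], values[~mask]
    if a.size < 2 or b.size < 2:
        raise ParameterError("each side needs >= 2 samples")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    effect = float(np.mean(a) - np.mean(b))
    return TestResult(float(stat), float(p), (target, "rest"), effect=effect)


def t_test(values, labels) -> TestResult:
    """Two-sided Student's t-test for a binary grouping."""
    uniq, groups = _split_groups(values, labels)
    if len(uniq) != 2:
        raise ParameterError(f"t-test needs exactly 2 groups, got {len(uniq)}")
    if min(g.size for g in groups) < 2:
        raise ParameterError("each group needs >= 2 samples")
    stat, p = stats.ttest_ind(groups[0], groups[1])
    return TestResult(float(stat), float(p), tuple(uniq),
                      effect=float(np.mean(groups[0]) - np.mean(groups[1])))


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher exact test of a 2x2 contingency table."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ParameterError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ParameterError("table must hold nonnegative integers")
    arr = np.round(arr).astype(int)
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return TestResult(float(odds), float(p), ("row1", "row2"))


def correlation(x, y, method: str = "spearman") -> TestResult:
    """Spearman or Pearson correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ParameterError("x and y must be equal-length with >= 3 values")
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ParameterError("zero-variance input for Pearson correlation")
        r, p = stats.pearsonr(x, y)
    else:
        raise ParameterError(f"unknown correlation method {method!r}")
    return TestResult(float(r), float(p), ("x", "y"), effect=float(r))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def subtype_marker_genes(
    expr: pd.DataFrame,
    labels,
    fdr_max: float = 0.05,
    lfc_min: float = 1.0,
    joint_correction: bool = True,
) -> dict:
    """Subtype-specific genes by one-vs-rest rank-sum tests.

    For each gene and subtype a two-sided Wilcoxon one-vs-rest p-value and
    the mean log2 difference are computed; BH correction runs jointly over
    the genes x subtypes grid (or per subtype if ``joint_correction`` is
    off).  A gene is a marker of a subtype when q < ``fdr_max`` and
    |mean difference| >= ``lfc_min``.

    Returns a dict with per-subtype marker lists, the union panel, and the
    full statistics table.
    """
    labels = np.asarray(labels)
    if expr.shape[1] != labels.shape[0]:
        raise ParameterError("expression and labels must be sample-aligned")
    subtypes = np.unique(labels)
    if len(subtypes) < 2:
        raise ParameterError("need >= 2 subtypes")
    x = expr.to_numpy(dtype=float)

    rows = []
    pmat = np.empty((expr.shape[0], len(subtypes)))
    dmat = np.empty_like(pmat)
    for j, st in enumerate(subtypes):
        mask = labels == st
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ParameterError(f"subtype {st!r} needs >= 2 samples on each side")
        a, b = x[:, mask], x[:, ~mask]
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", axis=1)
        pmat[:, j] = res.pvalue
        dmat[:, j] = a.mean(axis=1) - b.mean(axis=1)

    if joint_correction:
        qmat = bh_adjust(pmat.ravel()).reshape(pmat.shape)
    else:
        qmat = np.column_stack([bh_adjust(pmat[:, j]) for j in range(pmat.shape[1])])

    per_subtype: dict = {}
    for j, st in enumerate(subtypes):
        hits = np.flatnonzero((qmat[:, j] < fdr_max) & (np.abs(dmat[:, j]) >= lfc_min))
        per_subtype[st] = list(expr.index[hits])
        for i in hits:
            rows.append((expr.index[i], st, pmat[i, j], qmat[i, j], dmat[i, j]))

    panel = sorted({g for genes in per_subtype.values() for g in genes})
    if not panel:
        logger.warning("no gene passed fdr<%g and |lfc|>=%g", fdr_max, lfc_min)
    table = pd.DataFrame(
        {"gene": expr.index.repeat(len(subtypes)),
         "subtype": np.tile(subtypes, expr.shape[0]),
         "p_value": pmat.ravel(),
         "q_value": qmat.ravel(),
         "log2_diff": dmat.ravel()}
    )
    return {"per_subtype": per_subtype, "panel": panel, "table": table}
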