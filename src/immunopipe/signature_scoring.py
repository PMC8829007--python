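"""Per-sample gene-set enrichment scores.

The score for a set in a sample integrates the difference between the
rank-weighted cumulative distribution of in-set genes and the uniform
cumulative distribution of out-of-set genes, walking the genes of that
sample in descending expression order.  Ties take average ranks, so the
score is invariant to any strictly increasing transform of one sample's
expression values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import ParameterError

logger = logging.getLogger(__name__)


def ssgsea_score(
    expr: pd.DataFrame,
    sets: dict[str, list[str]],
    alpha: float = 0.25,
    normalize: bool = False,
    min_genes: int = 2,
) -> pd.DataFrame:
    """Score each gene set in each sample.

    Parameters
    ----------
    expr
        Genes x samples expression matrix.
    sets
        Mapping from signature name to gene list.  Genes absent from
        ``expr`` are dropped; sets overlapping ``expr`` in fewer than
        ``min_genes`` genes are skipped with a warning.
    alpha
        Rank-weighting exponent (>= 0).
    normalize
        If True, divide all scores by the global (max - min) score range.

    Returns
    -------
    Signatures x samples score DataFrame.
    """
    if alpha < 0:
        raise ParameterError(f"alpha must be >= 0, got {alpha}")
    if not sets:
        raise ParameterError("empty gene-set collection")
    gene_index = {g: i for i, g in enumerate(expr.index)}
    n_genes, n_samples = expr.shape

    memberships: dict[str, np.ndarray] = {}
    for name, genes in sets.items():
        idx = np.array(sorted({gene_index[g] for g in genes if g in gene_index}), dtype=int)
        if len(idx) < len(set(genes)):
            logger.info("set %r: %d/%d genes present in expression matrix",
                        name, len(idx), len(set(genes)))
        if len(idx) < min_genes:
            logger.warning("set %r overlaps expression in %d < %d genes; skipped",
                           name, len(idx), min_genes)
            continue
        memberships[name] = idx
    if not memberships:
        raise ParameterError("no gene set overlaps the expression matrix")

    values = expr.to_numpy(dtype=float)
    # average ranks, 1 = lowest expression; weight of a gene is rank^alpha
    ranks = rankdata(values, axis=0)
    scores = np.empty((len(memberships), n_samples), dtype=float)
    for j in range(n_samples):
        # walk genes in descending expression; stable order for determinism
        order = np.argsort(-values[:, j], kind="stable")
        rank_w = ranks[order, j] ** alpha
        for i, (name, idx) in enumerate(memberships.items()):
            in_set = np.zeros(n_genes, dtype=bool)
            in_set[idx] = True
            in_set = in_set[order]
            n_out = n_genes - in_set.sum()
            if n_out == 0:
                # degenerate complement: both distributions coincide
                scores[i, j] = 0.0
                continue
            w = np.where(in_set, rank_w, 0.0)
            p_in = np.cumsum(w) / w.sum()
            p_out = np.cumsum(~in_set) / n_out
            scores[i, j] = np.sum(p_in - p_out)

    out = pd.DataFrame(scores, index=list(memberships.keys()), columns=expr.columns)
    if normalize:
        rng = float(out.to_numpy().max() - out.to_numpy().min())
        if rng > 0:
            out = out / rng
    return out


def zscore_rows(matrix: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Standardize each row to mean 0, variance 1.

    Raises
    ------
    ParameterError
        Naming the offending row if any row has zero variance.
    """
    arr = matrix.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=ddof, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if len(zero):
        raise ParameterError(f"zero-variance row(s): {list(matrix.index[zero])[:5]}")
    return pd.DataFrame((arr - mu) / sd, index=matrix.index, columns=matrix.columns)
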