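"""Signed topological-overlap network over signature scores.

Signatures are nodes; the signed adjacency ((1 + spearman)/2)^power feeds
a topological overlap matrix, which is clustered by average linkage.  The
tree is cut at the height (over all inter-merge gaps) maximizing Newman
modularity of the induced partition on the adjacency graph; clusters below
the minimum size are left unassigned (label 0).  Each retained module is
represented by its most intramodularly connected member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .exceptions import ParameterError

logger = logging.getLogger(__name__)


@dataclass
class SignatureNetwork:
    """Correlation/adjacency/TOM triple over a set of signatures."""

    signature_ids: list[str]
    correlation: np.ndarray
    adjacency: np.ndarray
    tom: np.ndarray
    power: float
    signed: bool = True

    def to_dict(self) -> dict:
        return {
            "signature_ids": self.signature_ids,
            "correlation": self.correlation.tolist(),
            "adjacency": self.adjacency.tolist(),
            "tom": self.tom.tolist(),
            "power": self.power,
            "signed": self.signed,
        }


@dataclass
class ModuleSet:
    """Module assignment (0 = unassigned) with per-module representatives."""

    signature_ids: list[str]
    assignment: dict[str, int]
    module_sizes: dict[int, int]
    eigen_signature: dict[int, str]
    connectivity: dict[str, float]
    cut_height: float = field(default=float("nan"))

    def to_dict(self) -> dict:
        return {
            "signature_ids": self.signature_ids,
            "assignment": self.assignment,
            "module_sizes": {str(k): v for k, v in self.module_sizes.items()},
            "eigen_signature": {str(k): v for k, v in self.eigen_signature.items()},
            "connectivity": self.connectivity,
            "cut_height": self.cut_height,
        }


def build_network(scores: pd.DataFrame, power: float = 20.0, signed: bool = True) -> SignatureNetwork:
    """Build the signed-TOM network from a signatures x samples score matrix.

    adjacency ``a_ij = ((1 + cor_ij)/2)^power`` (signed) or
    ``|cor_ij|^power`` (unsigned); TOM follows the standard formula
    ``(sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``.
    """
    s, n = scores.shape
    if s < 3:
        raise ParameterError(f"need >= 3 signatures, got {s}")
    if n < 3:
        raise ParameterError(f"need >= 3 samples, got {n}")
    if power < 1:
        raise ParameterError(f"power must be >= 1, got {power}")
    arr = scores.to_numpy(dtype=float)
    constant = np.flatnonzero(np.ptp(arr, axis=1) == 0)
    if len(constant):
        raise ParameterError(
            f"constant signature row(s), Spearman undefined: {list(scores.index[constant])[:5]}"
        )
    cor = spearmanr(arr, axis=1).statistic
    cor = np.atleast_2d(np.asarray(cor, dtype=float))
    np.fill_diagonal(cor, 1.0)
    if signed:
        adj = ((1.0 + cor) / 2.0) ** power
    else:
        adj = np.abs(cor) ** power
    np.fill_diagonal(adj, 1.0)
    tom = _tom_from_adjacency(adj)
    return SignatureNetwork(list(scores.index), cor, adj, tom, power, signed)


def _tom_from_adjacency(adj: np.ndarray) -> np.ndarray:
    """Topological overlap with unit diagonal, vectorized."""
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # sum_u a_iu a_uj, u running over all nodes (diag zeroed)
    kmin = np.minimum.outer(k, k)
    tom = (shared + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(net: SignatureNetwork, min_module_size: int = 3) -> ModuleSet:
    """Cut the average-linkage TOM dendrogram at the modularity-optimal height.

    Candidate cut heights are the midpoints between consecutive distinct
    merge heights; the partition maximizing Newman modularity on the
    adjacency graph wins.  Clusters smaller than ``min_module_size`` end up
    unassigned (module 0).
    """
    ids = net.signature_ids
    s = len(ids)
    if min_module_size > s:
        raise ParameterError(f"min_module_size {min_module_size} exceeds {s} signatures")
    diss = 1.0 - net.tom
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    tree = linkage(squareform(diss, checks=False), method="average")
    heights = np.unique(tree[:, 2])
    if len(heights) > 1:
        candidates = (heights[:-1] + heights[1:]) / 2.0
    else:
        candidates = np.array([heights[0] / 2.0])

    adj = net.adjacency.copy()
    np.fill_diagonal(adj, 0.0)
    best_q, best_labels, best_h = -np.inf, None, float("nan")
    for h in candidates:
        labels = fcluster(tree, t=h, criterion="distance")
        if labels.max() == 1:
            continue
        q = _modularity(adj, labels)
        if q > best_q + 1e-12:
            best_q, best_labels, best_h = q, labels, float(h)
    if best_labels is None:  # every cut yields a single cluster
        best_labels = np.ones(s, dtype=int)
        best_h = float(candidates[-1])

    # renumber retained modules by descending size; undersized ones -> 0
    sizes = pd.Series(best_labels).value_counts()
    retained = [lab for lab, sz in sizes.items() if sz >= min_module_size]
    if not retained:
        raise ParameterError(f"no module of size >= {min_module_size}")
    retained.sort(key=lambda lab: (-sizes[lab], lab))
    relabel = {old: new for new, old in enumerate(retained, start=1)}
    assignment = {
        ids[i]: relabel.get(int(best_labels[i]), 0) for i in range(s)
    }

    connectivity: dict[str, float] = {}
    eigen: dict[int, str] = {}
    module_sizes: dict[int, int] = {}
    for mod in sorted(set(assignment.values()) - {0}):
        members = [i for i, sid in enumerate(ids) if assignment[sid] == mod]
        module_sizes[mod] = len(members)
        sub = net.adjacency[np.ix_(members, members)].copy()
        np.fill_diagonal(sub, 0.0)
        kwithin = sub.sum(axis=1)
        for i, m in enumerate(members):
            connectivity[ids[m]] = float(kwithin[i])
        kmax = kwithin.max()
        tied = sorted(ids[members[i]] for i in np.flatnonzero(kwithin >= kmax - 1e-12))
        if len(tied) > 1:
            logger.info("module %d: connectivity tie among %s; choosing %r", mod, tied, tied[0])
        eigen[mod] = tied[0]
    for sid in ids:
        connectivity.setdefault(sid, 0.0)
    return ModuleSet(ids, assignment, module_sizes, eigen, connectivity, best_h)


def _modularity(adj: np.ndarray, labels: np.ndarray) -> float:
    """Weighted Newman modularity of a partition (adjacency diag must be 0)."""
    two_m = adj.sum()
    if two_m == 0:
        return 0.0
    k = adj.sum(axis=1)
    q = 0.0
    for lab in np.unique(labels):
        mask = labels == lab
        q += adj[np.ix_(mask, mask)].sum() / two_m - (k[mask].sum() / two_m) ** 2
    return q


def select_eigen_signatures(modules: ModuleSet) -> list[str]:
    """One representative per module, ordered by descending module size."""
    if not modules.eigen_signature:
        raise ParameterError("module set contains no modules")
    order = sorted(modules.module_sizes, key=lambda m: (-modules.module_sizes[m], m))
    return [modules.eigen_signature[m] for m in order]


def prediction_strength(
    scores: pd.DataFrame,
    k: int,
    n_splits: int = 5,
    seed: int = 0,
    covariance_model: str = "diagonal",
) -> float:
    """Tibshirani-Walther prediction strength of a k-cluster structure.

    ``scores`` is signatures x samples; samples are split in half, both
    halves clustered with the same Gaussian-mixture procedure used for
    subtype discovery, test samples are classified by the training-half
    model, and the strength is the minimum over test clusters of the
    fraction of co-clustered pairs preserved, averaged over splits.
    """
    from .subtype_clustering import fit_gmm  # local import avoids a cycle

    n = scores.shape[1]
    if k < 2:
        raise ParameterError("k must be >= 2")
    if n < 2 * k:
        raise ParameterError(f"{n} samples too few for k={k} half-splits")
    x = scores.to_numpy(dtype=float).T  # samples x d
    rng = np.random.default_rng(seed)
    strengths = []
    for split in range(n_splits):
        perm = rng.permutation(n)
        half = n // 2
        train, test = perm[:half], perm[half:]
        m_train = fit_gmm(x[train], k, covariance_model, n_init=3,
                          seed=int(rng.integers(2**31)))
        m_test = fit_gmm(x[test], k, covariance_model, n_init=3,
                         seed=int(rng.integers(2**31)))
        own = m_test.predict(x[test])
        crossed = m_train.predict(x[test])
        strengths.append(_pair_preservation(own, crossed))
    return float(np.mean(strengths))


def _pair_preservation(own: np.ndarray, crossed: np.ndarray) -> float:
    """min over own-clusters of the co-assignment rate of their pairs."""
    worst = 1.0
    for lab in np.unique(own):
        idx = np.flatnonzero(own == lab)
        if len(idx) < 2:
            continue
        sub = crossed[idx]
        same = (sub[:, None] == sub[None, :])
        n_pairs = len(idx) * (len(idx) - 1)
        preserved = (same.sum() - len(idx)) / n_pairs
        worst = min(worst, float(preserved))
    return worst


def flag_nonrobust_representatives(
    scores: pd.DataFrame,
    k: int,
    threshold: float = 0.8,
    n_splits: int = 5,
    seed: int = 0,
) -> list[str]:
    """Representatives whose removal lifts prediction strength above the
    threshold while alone they fall below it.

    Returns the flagged signature ids (candidates for exclusion).
    """
    flagged = []
    for sid in scores.index:
        rest = scores.drop(index=sid)
        if rest.shape[0] < 1:
            continue
        ps_without = prediction_strength(rest, k, n_splits=n_splits, seed=seed)
        ps_alone = prediction_strength(scores.loc[[sid]], k, n_splits=n_splits, seed=seed)
        if ps_without > threshold and ps_alone < threshold:
            flagged.append(sid)
    return flagged
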