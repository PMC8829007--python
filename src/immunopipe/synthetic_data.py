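"""Synthetic cohorts with known subtype, module, prognosis and mutational
signature structure, so every downstream stage has a recoverable truth.

Construction
------------
Signatures are assigned round-robin to modules.  Each module carries one
latent factor per sample plus a subtype-dependent centroid; genes of a
signature mix the module factor (weight sqrt(module_correlation)) with a
signature-private factor, so downstream signature scores correlate within
modules at roughly the requested level.  A dedicated prognostic factor
(the planted per-sample score) additionally loads positively on every
signature gene, making it the dominant axis of the signature-gene block;
survival times are exponential (optionally Weibull)
with log-hazard proportional to it, and censoring is administrative and
independent.  Mutation catalogs are multinomial draws from planted
96-context signatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .io_formats import (
    CONTEXT_LABELS,
    write_catalog,
    write_expression,
    write_gmt,
    write_survival,
)

logger = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    n_samples: int = 300
    n_genes: int = 2000
    n_signatures: int = 30
    n_modules: int = 5
    k_subtypes: int = 3
    subtype_separation: float = 3.0
    module_correlation: float = 0.8
    survival_beta: float = 0.7
    censor_rate: float = 0.3
    n_signature_genes: int = 20
    noise_sd: float = 1.0
    seed: int = 0
    prognostic_weight: float = 1.5
    subtype_proportions: list[float] | None = None
    weibull_shape: float = 1.0          # 1.0 = exponential baseline hazard
    n_mut_signatures: int = 4
    mutations_per_sample: int = 500

    def validate(self) -> None:
        if self.k_subtypes < 2:
            raise ParameterError("k_subtypes must be >= 2")
        if self.n_modules > self.n_signatures:
            raise ParameterError("n_modules must be <= n_signatures")
        if self.n_signature_genes * self.n_signatures > self.n_genes:
            raise ParameterError(
                "n_signature_genes * n_signatures must be <= n_genes"
            )
        if not 0 <= self.censor_rate < 1:
            raise ParameterError("censor_rate must lie in [0, 1)")
        if not 0 <= self.module_correlation < 1:
            raise ParameterError("module_correlation must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.weibull_shape <= 0:
            raise ParameterError("weibull_shape must be > 0")
        if self.subtype_proportions is not None:
            p = np.asarray(self.subtype_proportions, dtype=float)
            if len(p) != self.k_subtypes or np.any(p <= 0) or not np.isclose(p.sum(), 1.0):
                raise ParameterError(
                    "subtype_proportions must be k_subtypes positive values summing to 1"
                )

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, (list, tuple)) else v)
                for k, v in self.__dict__.items()}


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame
    gene_sets: dict[str, list[str]]
    true_subtype: np.ndarray
    true_score: np.ndarray
    survival: pd.DataFrame
    catalog: pd.DataFrame
    true_nmf_signatures: np.ndarray
    true_exposures: np.ndarray
    config: SyntheticConfig = field(repr=False, default=None)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.columns)

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write every component under ``outdir``; returns name -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": outdir / "expression.tsv",
            "gene_sets": outdir / "gene_sets.gmt",
            "survival": outdir / "survival.tsv",
            "catalog": outdir / "catalog.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_expression(self.expression, paths["expression"])
        write_gmt(self.gene_sets, paths["gene_sets"])
        write_survival(self.survival, paths["survival"])
        write_catalog(self.catalog, paths["catalog"])
        truth = pd.DataFrame(
            {"true_subtype": self.true_subtype, "true_score": self.true_score},
            index=self.expression.columns,
        )
        truth.to_csv(paths["truth"], sep="\t", index_label="sample_id")
        return {k: str(v) for k, v in paths.items()}


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a full cohort; identical config (incl. seed) is bit-identical."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, k, m = config.n_samples, config.k_subtypes, config.n_modules
    s = config.n_signatures

    # subtype labels 1..k, balanced unless proportions given
    if config.subtype_proportions is None:
        base = np.tile(np.arange(1, k + 1), n // k + 1)[:n]
    else:
        counts = np.floor(np.asarray(config.subtype_proportions) * n).astype(int)
        while counts.sum() < n:
            counts[np.argmax(config.subtype_proportions)] += 1
        base = np.repeat(np.arange(1, k + 1), counts)
    labels = base[rng.permutation(n)]

    # per-module subtype centroids and latent factors
    centroids = config.subtype_separation * rng.standard_normal((k, m))
    z = rng.standard_normal((n, m))

    # planted prognostic factor, independent of subtype; loads positively
    # on every signature gene so the hazard genes form one well-correlated
    # block dominating the panel's first principal axis
    true_score = rng.standard_normal(n)
    w = config.prognostic_weight

    # expression: signature gene blocks + unstructured background
    module_of_sig = np.arange(s) % m             # 0-based module index
    sig_private = rng.standard_normal((n, s))
    c = config.module_correlation
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    sample_ids = [f"S{i:04d}" for i in range(n)]
    expr = rng.standard_normal((config.n_genes, n))  # background + gene noise
    gene_sets: dict[str, list[str]] = {}
    g = 0
    for j in range(s):
        mod = module_of_sig[j]
        signal = (centroids[labels - 1, mod]
                  + np.sqrt(c) * z[:, mod]
                  + w * true_score
                  + np.sqrt(1.0 - c) * sig_private[:, j])
        block = slice(g, g + config.n_signature_genes)
        expr[block] = signal[None, :] + config.noise_sd * rng.standard_normal(
            (config.n_signature_genes, n)
        )
        gene_sets[f"SIG{j:03d}"] = gene_ids[block]
        g += config.n_signature_genes
    expression = pd.DataFrame(expr, index=gene_ids, columns=sample_ids)

    # survival: Weibull(shape) baseline (shape 1 = exponential),
    # log-hazard = survival_beta * true_score
    base_rate = np.log(2.0) / 50.0
    u = rng.uniform(size=n)
    hazard = base_rate * np.exp(config.survival_beta * true_score)
    t_event = (-np.log(u) / hazard) ** (1.0 / config.weibull_shape)
    if config.censor_rate > 0:
        c_max = _censor_window(t_event, config.censor_rate)
        t_cens = rng.uniform(0.0, c_max, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)

    # mutation catalog from planted sparse signatures
    r = config.n_mut_signatures
    signatures = _sparse_signatures(r, rng)
    exposures = rng.dirichlet(np.full(r, 0.5), size=n).T  # r x samples
    catalog = generate_mutation_catalog(
        signatures, exposures, config.mutations_per_sample,
        seed=int(rng.integers(2**31)), sample_ids=sample_ids,
    )

    survival = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "subtype": labels,
            "tmb": catalog.sum(axis=0).to_numpy(),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SyntheticCohort(
        expression, gene_sets, labels, true_score, survival, catalog,
        signatures, exposures, config,
    )


def _censor_window(t_event: np.ndarray, censor_rate: float) -> float:
    """Width of the uniform censoring window hitting censor_rate in expectation.

    With C ~ U(0, w), P(censored_i) = min(t_i / w, 1); bisect on w.
    """
    def expected(w):
        return float(np.mean(np.minimum(t_event / w, 1.0)))

    lo, hi = 1e-9, float(t_event.max()) * 2
    while expected(hi) > censor_rate:
        hi *= 2
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected(mid) > censor_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _sparse_signatures(r: int, rng: np.random.Generator) -> np.ndarray:
    """r signatures with disjoint context supports, unit column sums."""
    signatures = np.zeros((96, r))
    support = np.array_split(rng.permutation(96), r)
    for j in range(r):
        w = rng.gamma(0.5, size=len(support[j]))
        signatures[support[j], j] = w / w.sum()
    return signatures


def generate_mutation_catalog(
    signatures: np.ndarray,
    exposures: np.ndarray,
    total_mutations: int | np.ndarray,
    seed: int = 0,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Multinomial 96-context counts from a signature/exposure mixture.

    ``signatures`` is 96 x r with unit column sums; ``exposures`` is
    r x samples, nonnegative.  Column totals equal the requested totals
    exactly (all-zero exposure columns give all-zero counts).
    """
    signatures = np.asarray(signatures, dtype=float)
    exposures = np.asarray(exposures, dtype=float)
    if signatures.ndim != 2 or signatures.shape[0] != 96:
        raise ParameterError("signatures must be 96 x r")
    if np.any(signatures < 0) or np.any(exposures < 0):
        raise ParameterError("signatures and exposures must be nonnegative")
    if not np.allclose(signatures.sum(axis=0), 1.0):
        raise ParameterError("signature columns must sum to 1")
    if exposures.ndim != 2 or exposures.shape[0] != signatures.shape[1]:
        raise ParameterError("exposures must be r x samples")
    n = exposures.shape[1]
    totals = np.broadcast_to(np.asarray(total_mutations, dtype=int), (n,))
    rng = np.random.default_rng(seed)
    counts = np.zeros((96, n), dtype=int)
    mix = signatures @ exposures                 # 96 x samples
    for j in range(n):
        colsum = mix[:, j].sum()
        if colsum == 0:
            continue
        counts[:, j] = rng.multinomial(totals[j], mix[:, j] / colsum)
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n)]
    return pd.DataFrame(counts, index=list(CONTEXT_LABELS), columns=sample_ids)
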