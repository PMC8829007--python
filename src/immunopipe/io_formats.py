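"""Readers and writers for the on-disk formats the pipeline touches.

Canonical dialects: tab-separated tables (UTF-8, '.' decimal), GMT gene
sets, JSON for fitted models.  Expression matrices are genes x samples
DataFrames; survival tables are indexed by sample id; mutation catalogs
are 96-context x samples count DataFrames in the fixed COSMIC row order.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .exceptions import FormatError

logger = logging.getLogger(__name__)

_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")

#: The 96 trinucleotide contexts in COSMIC convention: substitution-major
#: (C>A, C>G, C>T, T>A, T>C, T>G), 16 flanking combinations each, 5' base
#: varying slowest.
CONTEXT_LABELS: tuple[str, ...] = tuple(
    f"{p5}[{sub}]{p3}" for sub in _SUBSTITUTIONS for p5 in _BASES for p3 in _BASES
)


def read_expression(
    path: str | Path,
    missing_policy: str = "median",
    max_missing: float = 0.2,
) -> pd.DataFrame:
    """Load a genes x samples expression TSV.

    The first column holds gene ids, the header row sample ids.  Duplicate
    gene rows are collapsed by mean.  Genes missing in more than
    ``max_missing`` of samples are dropped; remaining missing values are
    imputed per ``missing_policy`` (``"median"`` or ``"mean"``, gene-wise).

    Raises
    ------
    FormatError
        On malformed headers, non-numeric cells (with row/column location),
        duplicate sample ids, or an empty matrix.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        dupes = sorted({s for s in header if header.count(s) > 1})
        raise FormatError(f"{path}: duplicate sample ids {dupes}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error surface
        raise FormatError(f"{path}: cannot parse TSV: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty expression matrix")

    values = df.apply(pd.to_numeric, errors="coerce")
    # cells that were text rather than genuinely missing
    bad = values.isna() & df.notna()
    if bad.any().any():
        gene = bad.any(axis=1).idxmax()
        col = bad.loc[gene].idxmax()
        raise FormatError(
            f"{path}: non-numeric value {df.loc[gene, col]!r} at gene {gene!r}, sample {col!r}"
        )

    if values.index.duplicated().any():
        n_dup = int(values.index.duplicated().sum())
        logger.warning("%s: collapsing %d duplicate gene rows by mean", path, n_dup)
        values = values.groupby(level=0, sort=False).mean()

    missing_frac = values.isna().mean(axis=1)
    dropped = missing_frac[missing_frac > max_missing]
    if len(dropped):
        logger.warning("%s: dropping %d genes with >%.0f%% missing", path, len(dropped), 100 * max_missing)
        values = values.loc[missing_frac <= max_missing]
    if values.shape[0] == 0:
        raise FormatError(f"{path}: no genes left after missingness filter")

    if values.isna().any().any():
        if missing_policy == "median":
            fill = values.median(axis=1)
        elif missing_policy == "mean":
            fill = values.mean(axis=1)
        else:
            raise FormatError(f"unknown missing_policy {missing_policy!r}")
        values = values.T.fillna(fill).T
    if not np.isfinite(values.to_numpy()).all():
        raise FormatError(f"{path}: non-finite values after imputation")
    return values


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into an ordered name -> gene-list mapping.

    Each line is ``name TAB description TAB gene TAB gene ...``.  Duplicate
    set names and empty gene lists are rejected; duplicate genes within a
    set are dropped with a warning.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected name, description and >=1 gene")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                logger.warning("%s:%d: set %r contains duplicate genes; dropped", path, lineno, name)
            sets[name] = unique
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_survival(path: str | Path) -> pd.DataFrame:
    """Load a clinical/survival TSV with columns sample_id, time, event.

    Extra columns (covariates such as subtype or TMB) are carried through.
    Returns a DataFrame indexed by sample_id.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    time = pd.to_numeric(df["time"], errors="coerce")
    if time.isna().any() or (time < 0).any():
        raise FormatError(f"{path}: time must be nonnegative numeric")
    event = pd.to_numeric(df["event"], errors="coerce")
    if event.isna().any() or not event.isin([0, 1]).all():
        raise FormatError(f"{path}: event must be 0 or 1")
    df = df.copy()
    df["time"] = time.astype(float)
    df["event"] = event.astype(int)
    return df.set_index("sample_id")


def write_survival(surv: pd.DataFrame, path: str | Path) -> None:
    surv.to_csv(path, sep="\t", index_label="sample_id")


def read_catalog(path: str | Path) -> pd.DataFrame:
    """Load a 96-context x samples mutation-count TSV.

    Rows must be exactly the 96 COSMIC context labels; rows may appear in
    any order and are canonicalized.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != 96:
        raise FormatError(f"{path}: expected 96 contexts, found {df.shape[0]}")
    unknown = set(df.index) - set(CONTEXT_LABELS)
    if unknown:
        raise FormatError(f"{path}: unknown context labels {sorted(unknown)[:5]}")
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate context labels")
    counts = df.apply(pd.to_numeric, errors="coerce")
    if counts.isna().any().any():
        raise FormatError(f"{path}: non-numeric counts")
    if (counts.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative counts")
    return counts.loc[list(CONTEXT_LABELS)]


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    catalog.loc[list(CONTEXT_LABELS)].to_csv(path, sep="\t", index_label="context")


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index_label="signature_id")


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate signature ids")
    return df.apply(pd.to_numeric)


def write_model(obj: Any, path: str | Path) -> None:
    """Serialize a model/result object to JSON.

    Objects exposing ``to_dict`` are converted through it; plain dicts are
    written as-is.  Keys are sorted so identical objects serialize to
    identical bytes.
    """
    payload = obj.to_dict() if hasattr(obj, "to_dict") else obj
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_model(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def align_samples(
    expr: pd.DataFrame,
    survival: pd.DataFrame | None = None,
    catalog: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.DataFrame | None]:
    """Intersect tables on sample id, expression column order winning.

    Dropped samples are reported at WARNING level.
    """
    keep = list(expr.columns)
    for other, what in ((survival, "survival"), (catalog, "catalog")):
        if other is None:
            continue
        ids = set(other.index) if what == "survival" else set(other.columns)
        lost = [s for s in keep if s not in ids]
        if lost:
            logger.warning("dropping %d samples absent from %s table", len(lost), what)
        keep = [s for s in keep if s in ids]
    if not keep:
        raise FormatError("no samples shared across tables")
    expr_out = expr[keep]
    surv_out = survival.loc[keep] if survival is not None else None
    cat_out = catalog[keep] if catalog is not None else None
    return expr_out, surv_out, cat_out
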