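"""Single-sample gene-signature scoring primitives.

Three flavours of signature scores feed the reference models:

* mean of per-gene z-scored expression (optionally stratified, e.g. by
  histology) — a plain average signature;
* a competitive mean-rank enrichment statistic — the standardized
  Mann–Whitney mean rank of the set genes among all genes of a patient;
* a weighted Kolmogorov–Smirnov random-walk enrichment score — a
  single-sample GSEA-style statistic reported as the difference between the
  maximum positive and maximum negative deviation of the walk.

Gene identifiers are matched by exact string comparison after upper-casing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .trial_data import GeneSet

logger = logging.getLogger(__name__)


class SignatureError(ValueError):
    pass


@dataclass
class SignatureScore:
    signature_name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        bad = [p for p, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise SignatureError(f"non-finite signature values for patients {bad}")

    def series(self) -> pd.Series:
        return pd.Series(self.values, name=self.signature_name)


def _match_genes(expression: pd.DataFrame, geneset: GeneSet) -> list:
    wanted = {g.upper() for g in geneset.genes}
    idx_upper = expression.index.astype(str).str.upper()
    present = expression.index[idx_upper.isin(wanted)]
    n_absent = len(wanted) - len(set(idx_upper[idx_upper.isin(wanted)]))
    if n_absent:
        logger.warning("gene set %r: %d gene(s) absent from the matrix",
                       geneset.name, n_absent)
    return list(present)


def zscore_genes(expression: pd.DataFrame,
                 strata: pd.Series | dict | None = None) -> pd.DataFrame:
    """Z-score each gene row to mean 0, unit sample sd (ddof=1).

    With ``strata`` (patient -> group label), scaling is performed
    independently within each patient stratum.  Zero-variance genes map to
    all-zero rows.  Every stratum must hold at least two patients.
    """
    if strata is None:
        groups = {None: list(expression.columns)}
    else:
        strata = pd.Series(strata)
        groups = {lev: idx.tolist() for lev, idx in strata.groupby(strata).groups.items()}
    out = expression.astype(float).copy()
    for level, cols in groups.items():
        if len(cols) < 2:
            raise SignatureError(f"stratum {level!r} has fewer than 2 patients")
        block = expression[cols].to_numpy(dtype=float)
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (block - mu) / sd
        z[np.broadcast_to(sd == 0, z.shape)] = 0.0
        out[cols] = z
    return out


def signature_mean_score(scaled_expression: pd.DataFrame,
                         geneset: GeneSet) -> SignatureScore:
    """Per-patient arithmetic mean of the scaled expression of the set genes."""
    rows = _match_genes(scaled_expression, geneset)
    if not rows:
        raise SignatureError(f"no gene of set {geneset.name!r} present in the matrix")
    means = scaled_expression.loc[rows].mean(axis=0)
    return SignatureScore(geneset.name, means.to_dict())


def rank_enrichment_score(expression: pd.DataFrame,
                          geneset: GeneSet) -> SignatureScore:
    """Standardized Mann–Whitney mean-rank of the set genes, per patient.

    With G genes in total and m set genes, genes are ranked ascending by
    expression (mid-ranks for ties) and the score is

        (mean rank of set genes - (G+1)/2) / sqrt((G+1)(G-m) / (12 m)),

    i.e. the competitive mean-rank statistic, symmetric around 0 when
    expression values are exchangeable.
    """
    rows = _match_genes(expression, geneset)
    G = expression.shape[0]
    m = len(rows)
    if m == 0:
        raise SignatureError(f"no gene of set {geneset.name!r} present in the matrix")
    if m == G:
        raise SignatureError("gene set covers the whole matrix; complement is empty")
    in_set = expression.index.isin(rows)
    ranks = np.apply_along_axis(rankdata, 0, expression.to_numpy(dtype=float))
    mean_rank = ranks[in_set].mean(axis=0)
    sd = np.sqrt((G + 1) * (G - m) / (12.0 * m))
    values = (mean_rank - (G + 1) / 2.0) / sd
    return SignatureScore(geneset.name, dict(zip(expression.columns, values)))


def walk_enrichment_score(expression: pd.DataFrame, geneset: GeneSet,
                          weight_exponent: float = 1.0) -> SignatureScore:
    """Single-sample weighted KS random-walk enrichment score.

    Per patient, genes are ordered by decreasing expression; the walk steps
    up by ``rank^weight_exponent`` (normalized) at set genes, where rank is
    the ascending mid-rank of the gene's expression, and down by a constant
    1/(G-m) outside the set.  The score is the maximum positive deviation of
    the walk minus the magnitude of its maximum negative deviation (the
    "difference" convention).
    """
    rows = _match_genes(expression, geneset)
    G = expression.shape[0]
    m = len(rows)
    if m == 0:
        raise SignatureError(f"no gene of set {geneset.name!r} present in the matrix")
    in_set = expression.index.isin(rows)
    X = expression.to_numpy(dtype=float)
    values = {}
    for j, patient in enumerate(expression.columns):
        x = X[:, j]
        ranks = rankdata(x)
        order = np.argsort(-x, kind="stable")
        member = in_set[order]
        w = np.abs(ranks[order]) ** weight_exponent
        steps = np.where(member, w, 0.0)
        total_w = steps.sum()
        steps = steps / total_w
        if G > m:
            steps = steps - np.where(member, 0.0, 1.0 / (G - m))
        walk = np.cumsum(steps)
        max_pos = max(walk.max(), 0.0)
        max_neg = max(-walk.min(), 0.0)
        values[patient] = max_pos - max_neg
    return SignatureScore(geneset.name, values)


def quantile_threshold(values, q: float) -> float:
    """Empirical q-quantile (linear interpolation, type-7) of non-missing values.

    Cohort cut points (tertiles, medians, 67th percentiles) all flow through
    here so every model shares one quantile definition.
    """
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if arr.size == 0:
        raise SignatureError("all values missing; no quantile defined")
    if arr.size < 3:
        raise SignatureError("need at least 3 non-missing values for a cohort quantile")
    return float(np.quantile(arr, q, method="linear"))
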