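"""Single-sample gene-set enrichment (ssGSEA) scoring.

The score for one sample and one gene set is the integrated difference of
two walk statistics over the genes ordered from highest to lowest
expression rank: a rank-weighted ECDF over set members,

    P_in(i)  = sum_{set genes among first i} rank^alpha
             / sum_{all set genes} rank^alpha,

and the unweighted ECDF over non-members,

    P_out(i) = #{non-set genes among first i} / (N - |set|),

with  ES = sum_{i=1..N} (P_in(i) - P_out(i)).

Ranks are 1..N with the highest expression at rank N, ties averaged; the
walk order breaks rank ties lexicographically by gene identifier so the
statistic is deterministic. Because only ranks enter, the score is
invariant under any strictly increasing per-sample transform of
expression. With ``normalize=True`` every score in a scoring run is
divided by the global (max - min) of the unnormalized score table, the
cross-sample range normalization of the published ssGSEA formulation.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .io import GeneSet, GeneSetCollection

logger = logging.getLogger("autoscore")


@dataclass
class SsgseaParams:
    """Parameters of the ssGSEA statistic.

    alpha
        Rank-weight exponent (>= 0); 0.25 is the published default.
    normalize
        Divide all scores in a run by the global score range.
    tie_method
        Rank-tie rule; only ``"average"`` is supported.
    """

    alpha: float = 0.25
    normalize: bool = True
    tie_method: str = "average"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.tie_method != "average":
            raise ValueError(f"unsupported tie_method {self.tie_method!r}")


def rank_transform(values: pd.Series) -> pd.Series:
    """Average ranks of one sample's expression, highest value = rank N."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need >= 2 genes to rank")
    if not np.isfinite(arr).all():
        raise ValueError("non-finite expression values cannot be ranked")
    return pd.Series(rankdata(arr, method="average"), index=values.index)


def enrichment_score(ranks: pd.Series, gene_set: GeneSet, params: SsgseaParams | None = None) -> float:
    """ssGSEA enrichment score of one sample for one gene set.

    ``ranks`` is the output of :func:`rank_transform`. Set genes absent
    from the ranked universe are dropped (logged); an empty effective set
    or a set covering the whole universe is an error.
    """
    params = params or SsgseaParams()
    universe = ranks.index
    member = universe.isin(gene_set.genes)
    n_dropped = len(gene_set) - int(member.sum())
    if n_dropped:
        logger.info("gene set %r: %d genes absent from matrix", gene_set.name, n_dropped)
    m = int(member.sum())
    n = len(universe)
    if m == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the matrix")
    if m == n:
        raise ValueError(f"gene set {gene_set.name!r} covers every gene; P_out undefined")
    r = np.asarray(ranks, dtype=float)
    # walk order: decreasing rank, ties broken by gene id (lexicographic)
    order = np.lexsort((np.asarray(universe), -r))
    memb = np.asarray(member)[order]
    rw = np.where(memb, r[order] ** params.alpha, 0.0)
    p_in = np.cumsum(rw) / rw.sum()
    p_out = np.cumsum(~memb) / (n - m)
    return float(np.sum(p_in - p_out))


def score_matrix(
    matrix: pd.DataFrame,
    sets: GeneSetCollection | GeneSet,
    params: SsgseaParams | None = None,
) -> pd.DataFrame:
    """Score every sample (column) of a feature x sample matrix against
    every gene set; returns a set x sample table.

    With ``params.normalize`` the whole table is divided by its global
    unnormalized range (max - min); a degenerate zero range leaves scores
    unnormalized with a warning.
    """
    params = params or SsgseaParams()
    if isinstance(sets, GeneSet):
        sets = GeneSetCollection([sets])
    values = matrix.to_numpy(dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 features to score")
    if not np.isfinite(values).all():
        raise ValueError("matrix contains non-finite values")

    # pre-sort rows lexicographically by gene id so that a stable argsort on
    # -rank yields the deterministic tie-break for free
    gene_order = np.argsort(matrix.index.to_numpy())
    genes = matrix.index.to_numpy()[gene_order]
    values = values[gene_order]
    n, n_samples = values.shape

    ranks = np.apply_along_axis(lambda c: rankdata(c, method="average"), 0, values)
    walk = np.argsort(-ranks, axis=0, kind="stable")
    ranks_w = np.take_along_axis(ranks, walk, axis=0)

    rows = []
    kept = []
    for gs in sets:
        member = np.isin(genes, np.asarray(gs.genes))
        m = int(member.sum())
        if m == 0:
            logger.warning("gene set %r: empty intersection with matrix, skipped", gs.name)
            continue
        if m == n:
            raise ValueError(f"gene set {gs.name!r} covers every gene; P_out undefined")
        if m < len(gs):
            logger.info("gene set %r: %d genes absent from matrix", gs.name, len(gs) - m)
        memb_w = member[walk]  # membership in walk order, per sample
        rw = np.where(memb_w, ranks_w**params.alpha, 0.0)
        p_in = np.cumsum(rw, axis=0) / rw.sum(axis=0)
        p_out = np.cumsum(~memb_w, axis=0) / (n - m)
        rows.append((p_in - p_out).sum(axis=0))
        kept.append(gs.name)
    if not rows:
        raise ValueError("every gene set has an empty intersection with the matrix")
    scores = pd.DataFrame(np.vstack(rows), index=kept, columns=matrix.columns)
    if params.normalize:
        rng = float(scores.to_numpy().max() - scores.to_numpy().min())
        if rng > 0:
            scores = scores / rng
        else:
            logger.warning("score range is zero; normalization skipped")
    return scores


class SsgseaScorer(BaseEstimator, TransformerMixin):
    """Transformer computing per-sample gene-set enrichment scores.

    Follows the sklearn convention (rows = samples), transposing
    internally to the feature-major layout the scoring core uses.

    Parameters
    ----------
    gene_sets : GeneSetCollection or GeneSet
        Sets to score.
    alpha : float, default 0.25
        Rank-weight exponent.
    normalize : bool, default True
        Divide scores by the global range of the run.
    """

    def __init__(self, gene_sets=None, alpha: float = 0.25, normalize: bool = True):
        self.gene_sets = gene_sets
        self.alpha = alpha
        self.normalize = normalize

    def fit(self, X: pd.DataFrame, y=None) -> "SsgseaScorer":
        if self.gene_sets is None:
            raise ValueError("gene_sets must be provided")
        self._params = SsgseaParams(alpha=self.alpha, normalize=self.normalize)
        sets = self.gene_sets
        if isinstance(sets, GeneSet):
            sets = GeneSetCollection([sets])
        self.set_names_ = list(sets.names)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Score samples (rows of X, genes as columns) -> sample x set table."""
        if not hasattr(self, "set_names_"):
            raise ValueError("SsgseaScorer is not fitted")
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame with gene-symbol columns")
        return score_matrix(X.T, self.gene_sets, self._params).T
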