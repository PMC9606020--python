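"""Weights-aware differential feature calling between score-high and
score-low groups, with permutation stabilization and BH FDR.

Continuous layers are compared with a Welch-type t statistic computed on
matching-weighted means and variances, using Kish effective sample sizes
ess = (sum w)^2 / sum w^2 in place of raw counts; binary layers use a
two-proportion z statistic on weighted proportions, falling back to the
exact two-sided hypergeometric test for sparse unweighted tables. The
weighting keeps the propensity balance first-class; a label-permutation
layer (default 100 permutations, weights traveling with their samples)
guards the closed-form approximations against random noise.

Effects follow the sign-magnitude fold-change convention: the ratio of
weighted linear-scale group means reported as +r when high >= low and
-(low/high) otherwise, so a halving is -2.0, not 0.5. Difference layers
(protein, methylation) report the weighted mean difference, binary layers
the weighted proportion difference.

A feature is called significant only when all three criteria hold: the
layer's effect threshold, BH FDR below the layer's bound, and permutation
p at or below perm_alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

logger = logging.getLogger("autoscore")


@dataclass(frozen=True)
class LayerSpec:
    """Per-layer effect kind and significance thresholds."""

    layer: str
    effect_kind: str  # fold_change | difference | proportion
    effect_threshold: float = 0.0
    fdr_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.effect_kind not in ("fold_change", "difference", "proportion"):
            raise ValueError(f"unknown effect_kind {self.effect_kind!r}")
        if self.effect_threshold < 0 or not (0 < self.fdr_threshold <= 1):
            raise ValueError("thresholds out of domain")


#: default per-layer significance criteria
LAYER_SPECS: dict[str, LayerSpec] = {
    "mRNA": LayerSpec("mRNA", "fold_change", 2.0),
    "miRNA": LayerSpec("miRNA", "fold_change", 1.5),
    "protein": LayerSpec("protein", "difference", 0.2),
    "methylation": LayerSpec("methylation", "difference", 0.2),
    "mutation": LayerSpec("mutation", "proportion", 0.0),
    "SCNA": LayerSpec("SCNA", "proportion", 0.0),
}


def _as_masks(group: pd.Series | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g = np.asarray(group)
    hi, lo = g == "high", g == "low"
    if hi.sum() == 0 or lo.sum() == 0:
        raise ValueError("both high and low groups must be non-empty")
    return hi, lo


def _group_stats(X: np.ndarray, mask: np.ndarray, w: np.ndarray):
    """Weighted mean/variance/ess per feature row over samples in ``mask``."""
    wg = w[mask]
    sw = wg.sum()
    if sw <= 0:
        raise ValueError("total weight is zero in a group")
    Xg = X[:, mask]
    mean = Xg @ wg / sw
    denom = sw - (wg**2).sum() / sw
    if denom > 0:
        var = ((Xg - mean[:, None]) ** 2) @ wg / denom
    else:
        var = np.zeros_like(mean)
    ess = sw**2 / (wg**2).sum()
    return mean, var, ess


def weighted_group_stats(values, group, weights=None):
    """(mean_high, mean_low, var_high, var_low, ess_high, ess_low) for one feature."""
    x = np.asarray(values, dtype=float)[None, :]
    hi, lo = _as_masks(group)
    w = np.ones(x.shape[1]) if weights is None else np.asarray(weights, dtype=float)
    mh, vh, eh = _group_stats(x, hi, w)
    ml, vl, el = _group_stats(x, lo, w)
    return float(mh[0]), float(ml[0]), float(vh[0]), float(vl[0]), float(eh), float(el)


def sign_magnitude_fc(mean_high: np.ndarray, mean_low: np.ndarray) -> np.ndarray:
    """Fold change of group means in sign-magnitude form (+r up, -r down)."""
    mh, ml = np.asarray(mean_high, dtype=float), np.asarray(mean_low, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        up = np.where(ml != 0, mh / ml, np.inf)
        down = np.where(mh != 0, -ml / mh, -np.inf)
    eq = np.isclose(mh, ml)
    fc = np.where(mh >= ml, up, down)
    return np.where(eq, 1.0, fc)


def _welch_from_stats(mh, ml, vh, vl, eh, el):
    """Welch t statistic and p using effective sample sizes."""
    se2 = vh / eh + vl / el
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se2 > 0, (mh - ml) / np.sqrt(se2), 0.0)
        df = np.where(
            se2 > 0,
            se2**2 / ((vh / eh) ** 2 / max(eh - 1, 1e-12) + (vl / el) ** 2 / max(el - 1, 1e-12)),
            1.0,
        )
    diff = ~np.isclose(mh, ml)
    p = np.where(se2 > 0, 2 * stats.t.sf(np.abs(t), np.maximum(df, 1e-12)), np.where(diff, 0.0, 1.0))
    return t, p


def _continuous_stats(X: np.ndarray, hi, lo, w, spec: LayerSpec):
    mh, vh, eh = _group_stats(X, hi, w)
    ml, vl, el = _group_stats(X, lo, w)
    t, p = _welch_from_stats(mh, ml, vh, vl, eh, el)
    if spec.effect_kind == "fold_change":
        effect = sign_magnitude_fc(mh, ml)
        if not np.isfinite(effect).all():
            logger.warning("%s: %d features with zero denominator mean (effect = signed inf)",
                           spec.layer, int((~np.isfinite(effect)).sum()))
    else:
        effect = mh - ml
    return effect, t, p


def _binary_stats(X: np.ndarray, hi, lo, w):
    ph, _, eh = _group_stats(X, hi, w)
    pl, _, el = _group_stats(X, lo, w)
    effect = ph - pl
    pbar = (ph * eh + pl * el) / (eh + el)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(pbar * (1 - pbar) * (1 / eh + 1 / el))
        z = np.where(se > 0, effect / se, 0.0)
    p = np.where(se > 0, 2 * stats.norm.sf(np.abs(z)), 1.0)
    return effect, z, p


def exact_binary_p(k_high: int, n_high: int, k_low: int, n_low: int) -> float:
    """Two-sided conditional (hypergeometric) p for a 2x2 table.

    Sums P(X = j) over the support for every j with pmf not exceeding the
    observed pmf (the standard two-sided Fisher rule).
    """
    n = n_high + n_low
    k = k_high + k_low
    rv = stats.hypergeom(n, k, n_high)
    support = np.arange(max(0, k - n_low), min(k, n_high) + 1)
    pmf = rv.pmf(support)
    obs = rv.pmf(k_high)
    return float(min(1.0, pmf[pmf <= obs * (1 + 1e-7)].sum()))


def continuous_feature_test(values, group, weights=None, spec: LayerSpec | None = None) -> dict:
    """Effect and p for one continuous feature (no permutation p)."""
    spec = spec or LAYER_SPECS["mRNA"]
    x = np.asarray(values, dtype=float)[None, :]
    hi, lo = _as_masks(group)
    w = np.ones(x.shape[1]) if weights is None else np.asarray(weights, dtype=float)
    effect, t, p = _continuous_stats(x, hi, lo, w, spec)
    return {"effect": float(effect[0]), "stat": float(t[0]), "p_value": float(p[0])}


def binary_feature_test(values, group, weights=None) -> dict:
    """Effect and p for one binary 0/1 feature (no permutation p).

    Substitutes the exact conditional test when weights are uniform and
    any expected cell of the unweighted 2x2 table is below 5. A feature
    constant across all samples is uninformative: effect 0, p 1.
    """
    x = np.asarray(values, dtype=float)
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("binary feature must contain only 0/1")
    hi, lo = _as_masks(group)
    w = np.ones(x.size) if weights is None else np.asarray(weights, dtype=float)
    if x[hi | lo].min() == x[hi | lo].max():
        return {"effect": 0.0, "stat": 0.0, "p_value": 1.0, "uninformative": True}
    effect, z, p = _binary_stats(x[None, :], hi, lo, w)
    out = {"effect": float(effect[0]), "stat": float(z[0]), "p_value": float(p[0])}
    uniform = np.allclose(w, w[0])
    if uniform:
        kh, nh = int(x[hi].sum()), int(hi.sum())
        kl, nl = int(x[lo].sum()), int(lo.sum())
        n, k = nh + nl, kh + kl
        expected = np.array([[k * nh, k * nl], [(n - k) * nh, (n - k) * nl]]) / n
        if expected.min() < 5:
            out["p_value"] = exact_binary_p(kh, nh, kl, nl)
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def _stat_matrix(X: np.ndarray, hi, lo, w, spec: LayerSpec) -> np.ndarray:
    if spec.effect_kind == "proportion":
        _, z, _ = _binary_stats(X, hi, lo, w)
        return z
    _, t, _ = _continuous_stats(X, hi, lo, w, spec)
    return t


def permutation_stability(
    matrix: pd.DataFrame,
    group: pd.Series,
    weights: pd.Series | None = None,
    spec: LayerSpec | None = None,
    n_perm: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Empirical permutation p per feature.

    Group labels are shuffled across samples (weights stay attached to
    their samples); the test statistic is recomputed per permutation and
    perm_p = (1 + #{|T_perm| >= |T_obs|}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    spec = spec or LAYER_SPECS["mRNA"]
    X = matrix.to_numpy(dtype=float)
    g = np.asarray(group.reindex(matrix.columns))
    w = np.ones(X.shape[1]) if weights is None else weights.reindex(matrix.columns).to_numpy(dtype=float)
    hi, lo = _as_masks(g)
    t_obs = np.abs(np.nan_to_num(_stat_matrix(X, hi, lo, w, spec)))
    rng = np.random.default_rng(seed)
    exceed = np.zeros(X.shape[0])
    for _ in range(n_perm):
        gp = rng.permutation(g)
        hp, lp = gp == "high", gp == "low"
        t_perm = np.abs(np.nan_to_num(_stat_matrix(X, hp, lp, w, spec)))
        exceed += t_perm >= t_obs
    return pd.Series((1.0 + exceed) / (n_perm + 1.0), index=matrix.index)


def analyze_layer(
    matrix: pd.DataFrame,
    group: pd.Series,
    weights: pd.Series | None = None,
    spec: LayerSpec | None = None,
    n_perm: int = 100,
    perm_alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Full differential table for one omics layer.

    Returns columns: effect, p_value, fdr, perm_p, significant.
    """
    spec = spec or LAYER_SPECS["mRNA"]
    X = matrix.to_numpy(dtype=float)
    g = np.asarray(group.reindex(matrix.columns))
    w = np.ones(X.shape[1]) if weights is None else weights.reindex(matrix.columns).to_numpy(dtype=float)
    hi, lo = _as_masks(g)
    if spec.effect_kind == "proportion":
        if not np.isin(X, (0.0, 1.0)).all():
            raise ValueError(f"layer {spec.layer!r} must be binary 0/1")
        effect, _, p = _binary_stats(X, hi, lo, w)
        constant = X[:, hi | lo].min(axis=1) == X[:, hi | lo].max(axis=1)
        effect = np.where(constant, 0.0, effect)
        p = np.where(constant, 1.0, p)
        if np.allclose(w, w[0]):
            # exact conditional test for sparse tables
            kh = X[:, hi].sum(axis=1)
            kl = X[:, lo].sum(axis=1)
            nh, nl = int(hi.sum()), int(lo.sum())
            n = nh + nl
            k = kh + kl
            expected_min = np.minimum.reduce(
                [k * nh / n, k * nl / n, (n - k) * nh / n, (n - k) * nl / n]
            )
            for i in np.nonzero((expected_min < 5) & ~constant)[0]:
                p[i] = exact_binary_p(int(kh[i]), nh, int(kl[i]), nl)
    else:
        effect, _, p = _continuous_stats(X, hi, lo, w, spec)
    fdr = bh_fdr(np.clip(p, 0.0, 1.0))
    perm_p = permutation_stability(matrix, group, weights, spec, n_perm=n_perm, seed=seed)
    res = pd.DataFrame(
        {"effect": effect, "p_value": p, "fdr": fdr, "perm_p": perm_p.to_numpy()},
        index=matrix.index,
    )
    res.index.name = "feature"
    return call_significant_features(res, spec, perm_alpha=perm_alpha)


def call_significant_features(
    results: pd.DataFrame, spec: LayerSpec, perm_alpha: float = 0.05
) -> pd.DataFrame:
    """Apply the full per-layer criterion and set the ``significant`` flag.

    significant <=> |effect| passes the layer threshold AND fdr below the
    layer bound AND perm_p <= perm_alpha.
    """
    res = results.copy()
    if spec.effect_kind == "proportion":
        effect_ok = res["effect"].abs() > spec.effect_threshold if spec.effect_threshold > 0 else True
    else:
        effect_ok = res["effect"].abs() > spec.effect_threshold
    res["significant"] = effect_ok & (res["fdr"] < spec.fdr_threshold) & (res["perm_p"] <= perm_alpha)
    return res


def summarize_counts(per_cancer: dict[str, dict[str, pd.DataFrame]]) -> pd.DataFrame:
    """Cancer x layer table of significant-feature counts and percentages."""
    rows = []
    for cancer, layers in per_cancer.items():
        for layer, res in layers.items():
            n_sig = int(res["significant"].sum())
            n_tot = int(len(res))
            rows.append(
                {
                    "cancer": cancer,
                    "layer": layer,
                    "n_significant": n_sig,
                    "n_tested": n_tot,
                    "pct_significant": 100.0 * n_sig / n_tot if n_tot else 0.0,
                }
            )
    return pd.DataFrame(rows)


def pathway_protein_score(
    protein_matrix: pd.DataFrame,
    pathways: dict[str, list[tuple[str, int]]],
    group: pd.Series,
    weights: pd.Series | None = None,
) -> pd.DataFrame:
    """Signed-member pathway scores from protein data, compared by group.

    Each pathway is a list of (protein, sign) members (+1 activating,
    -1 inhibitory); the per-sample score is
    (sum of + members - sum of - members) / n_members. Group differences
    use the weighted continuous test, BH-adjusted across pathways.
    """
    spec = LayerSpec("pathway", "difference", 0.0)
    rows, names = [], []
    for name, members in pathways.items():
        present = [(gene, sign) for gene, sign in members if gene in protein_matrix.index]
        if not present:
            raise ValueError(f"pathway {name!r}: no members found in protein matrix")
        signs = pd.Series({g: s for g, s in present})
        sub = protein_matrix.loc[signs.index]
        score = (sub.mul(signs, axis=0)).sum(axis=0) / len(present)
        rows.append(continuous_feature_test(score, group.reindex(score.index), weights, spec))
        names.append(name)
    out = pd.DataFrame(rows, index=pd.Index(names, name="pathway"))
    out = out.rename(columns={"effect": "score_diff"})
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    return out.drop(columns=["stat"])


class DifferentialFeatureCaller(BaseEstimator):
    """Estimator calling autophagy-associated features for one omics layer.

    Parameters
    ----------
    layer : str, default "mRNA"
        One of mRNA, miRNA, protein, methylation, mutation, SCNA; sets the
        effect kind and default threshold.
    effect_threshold, fdr_threshold : float or None
        Override the layer defaults.
    n_perm : int, default 100
        Label permutations for the stability p.
    perm_alpha : float, default 0.05
    seed : int, default 0

    Attributes
    ----------
    results_ : DataFrame (feature x [effect, p_value, fdr, perm_p, significant])
    significant_ : Index of called features
    """

    def __init__(
        self,
        layer: str = "mRNA",
        effect_threshold: float | None = None,
        fdr_threshold: float | None = None,
        n_perm: int = 100,
        perm_alpha: float = 0.05,
        seed: int = 0,
    ):
        self.layer = layer
        self.effect_threshold = effect_threshold
        self.fdr_threshold = fdr_threshold
        self.n_perm = n_perm
        self.perm_alpha = perm_alpha
        self.seed = seed

    def _spec(self) -> LayerSpec:
        if self.layer not in LAYER_SPECS:
            raise ValueError(f"unknown layer {self.layer!r}")
        spec = LAYER_SPECS[self.layer]
        if self.effect_threshold is not None:
            spec = replace(spec, effect_threshold=self.effect_threshold)
        if self.fdr_threshold is not None:
            spec = replace(spec, fdr_threshold=self.fdr_threshold)
        return spec

    def fit(self, X: pd.DataFrame, y, sample_weight=None) -> "DifferentialFeatureCaller":
        """X: samples x features DataFrame; y: high/low labels per sample."""
        y = pd.Series(np.asarray(y), index=X.index)
        w = None
        if sample_weight is not None:
            w = pd.Series(np.asarray(sample_weight, dtype=float), index=X.index)
        self.results_ = analyze_layer(
            X.T, y, w, self._spec(),
            n_perm=self.n_perm, perm_alpha=self.perm_alpha, seed=self.seed,
        )
        self.significant_ = self.results_.index[self.results_["significant"]]
        return self
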