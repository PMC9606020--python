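"""Correlation-based drug-response association and sensitivity labeling.

Two analyses share one machinery:

* gene expression vs drug AUC across cancer cell lines (|Rs| > 0.3,
  FDR < 0.05, BH per drug across genes), and
* autophagy score vs imputed drug response across tumor samples within a
  cancer type (|Rs| > 0.2, FDR < 0.05, BH across drugs within cancer).

Under the GDSC convention a higher AUC means more viable cells, i.e. more
resistant; a negative Spearman correlation between expression (or score)
and AUC therefore labels the pair drug-sensitive, a positive one
drug-resistant.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

logger = logging.getLogger("autoscore")

MIN_PAIRED_N = 10


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ties and t-approximation p.

    Pairs with a missing value in either vector are dropped
    (pairwise-complete); fewer than 4 complete pairs or a zero-variance
    ranked vector yields (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        logger.warning("spearman: only %d complete pairs (< 4)", n)
        return float("nan"), float("nan")
    rx, ry = rankdata(x), rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        logger.warning("spearman: zero variance in a ranked vector")
        return float("nan"), float("nan")
    rs = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    rs = max(-1.0, min(1.0, rs))
    if abs(rs) == 1.0:
        return rs, 0.0
    t = rs * np.sqrt((n - 2) / (1 - rs**2))
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return rs, p


def _label(rs: float, fdr: float, rs_min: float, fdr_max: float) -> str:
    if np.isnan(rs) or np.isnan(fdr) or abs(rs) <= rs_min or fdr >= fdr_max:
        return "none"
    return "resistant" if rs > 0 else "sensitive"


def gene_drug_associations(
    expr: pd.DataFrame,
    auc: pd.DataFrame,
    rs_min: float = 0.3,
    fdr_max: float = 0.05,
    min_n: int = MIN_PAIRED_N,
) -> pd.DataFrame:
    """Gene x drug Spearman associations across cell lines.

    ``expr`` is gene x cell-line, ``auc`` drug x cell-line. Pairs with
    fewer than ``min_n`` shared cell lines after missing-data removal are
    skipped with a log entry. BH is applied per drug across genes.
    """
    shared = expr.columns.intersection(auc.columns)
    rows = []
    for drug in auc.index:
        a = auc.loc[drug, shared].to_numpy(dtype=float)
        for gene in expr.index:
            x = expr.loc[gene, shared].to_numpy(dtype=float)
            n_ok = int((np.isfinite(x) & np.isfinite(a)).sum())
            if n_ok < min_n:
                logger.info("skipping (%s, %s): %d shared cell lines", gene, drug, n_ok)
                continue
            rs, p = spearman(x, a)
            rows.append({"unit": gene, "drug": drug, "rs": rs, "p_value": p, "n": n_ok})
    out = pd.DataFrame(rows)
    if out.empty:
        return out.reindex(columns=["unit", "drug", "rs", "p_value", "n", "fdr", "label"])
    out["fdr"] = np.nan
    for drug, idx in out.groupby("drug").groups.items():
        out.loc[idx, "fdr"] = bh_safe(out.loc[idx, "p_value"])
    out["label"] = [
        _label(r, f, rs_min, fdr_max) for r, f in zip(out["rs"], out["fdr"])
    ]
    return out


def score_drug_associations(
    scores: Mapping[str, pd.Series] | pd.Series,
    imputed: pd.DataFrame,
    rs_min: float = 0.2,
    fdr_max: float = 0.05,
    min_n: int = MIN_PAIRED_N,
) -> pd.DataFrame:
    """Autophagy score vs imputed drug response, per cancer.

    ``scores`` maps cancer type -> per-sample score vector (a bare Series
    is treated as a single unnamed cancer); ``imputed`` is drug x sample.
    BH is applied across drugs within each cancer.
    """
    if isinstance(scores, pd.Series):
        scores = {"": scores}
    rows = []
    for cancer, sv in scores.items():
        shared = sv.index.intersection(imputed.columns)
        for drug in imputed.index:
            y = imputed.loc[drug, shared].to_numpy(dtype=float)
            x = sv.loc[shared].to_numpy(dtype=float)
            n_ok = int((np.isfinite(x) & np.isfinite(y)).sum())
            if n_ok < min_n:
                logger.info("cancer %s: drug %s skipped (%d paired samples)", cancer, drug, n_ok)
                continue
            rs, p = spearman(x, y)
            rows.append(
                {"cancer": cancer, "unit": "autophagy_score", "drug": drug,
                 "rs": rs, "p_value": p, "n": n_ok}
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out.reindex(columns=["cancer", "unit", "drug", "rs", "p_value", "n", "fdr", "label"])
    out["fdr"] = np.nan
    for cancer, idx in out.groupby("cancer").groups.items():
        out.loc[idx, "fdr"] = bh_safe(out.loc[idx, "p_value"])
    out["label"] = [
        _label(r, f, rs_min, fdr_max) for r, f in zip(out["rs"], out["fdr"])
    ]
    return out


def bh_safe(p: pd.Series) -> np.ndarray:
    """BH over a p vector that may contain NaN (NaN entries stay NaN)."""
    from .diff import bh_fdr

    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = np.isfinite(arr)
    if ok.any():
        out[ok] = bh_fdr(arr[ok])
    return out


def annotate_actionable(
    associations: pd.DataFrame,
    drug_targets: pd.DataFrame,
    cag_list: Iterable[str],
) -> pd.DataFrame:
    """Flag each association with its drug's targets and CAG membership.

    ``drug_targets`` has columns (drug, target); a drug absent from the
    annotation is flagged unannotated. ``targets_cag`` is True when any
    target gene is in the clinically-actionable-gene list.
    """
    cags = set(cag_list)
    targets_of: dict[str, list[str]] = {
        str(d): sorted(set(sub["target"]))
        for d, sub in drug_targets.groupby("drug")
    }
    out = associations.copy()
    out["targets"] = [",".join(targets_of.get(str(d), [])) for d in out["drug"]]
    out["annotated"] = [str(d) in targets_of for d in out["drug"]]
    out["targets_cag"] = [
        any(t in cags for t in targets_of.get(str(d), [])) for d in out["drug"]
    ]
    return out
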