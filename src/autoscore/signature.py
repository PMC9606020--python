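"""Candidate gene-list validation and consensus signature derivation.

A candidate autophagy gene list is validated on a labeled dataset by
scoring every sample with ssGSEA and comparing score distributions of the
known autophagy-high and autophagy-low groups with a two-sided Welch
t-test; the list passes when p < alpha_v AND the high-group mean score
exceeds the low-group mean (the direction constraint keeps an inverted
list from validating). Lists passing in at least ``min_datasets`` of the
labeled datasets are retained, and the consensus signature is their exact
set intersection.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce

import pandas as pd
from scipy import stats

from .io import GeneSet, GeneSetCollection
from .ssgsea import SsgseaParams, score_matrix

HIGH, LOW = "autophagy_high", "autophagy_low"


@dataclass
class LabeledDataset:
    """An expression matrix with known per-sample autophagy status."""

    name: str
    matrix: pd.DataFrame  # feature x sample
    labels: pd.Series  # sample -> autophagy_high / autophagy_low

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - {HIGH, LOW}
        if bad:
            raise ValueError(f"dataset {self.name!r}: unknown labels {sorted(bad)}")
        if not {HIGH, LOW} <= set(self.labels.unique()):
            raise ValueError(f"dataset {self.name!r}: both labels must be present")
        missing = self.labels.index.difference(self.matrix.columns)
        if len(missing):
            raise ValueError(f"dataset {self.name!r}: labeled samples missing from matrix: {list(missing)[:5]}")


@dataclass(frozen=True)
class ValidationOutcome:
    list_name: str
    dataset_name: str
    p_value: float
    direction_ok: bool
    passed: bool


def evaluate_gene_list(
    gene_list: GeneSet,
    dataset: LabeledDataset,
    alpha_v: float = 0.05,
    params: SsgseaParams | None = None,
) -> ValidationOutcome:
    """Validate one candidate list on one labeled dataset.

    Scores all labeled samples in a single ssGSEA run, then applies a
    two-sided Welch t-test of high vs low scores; passes iff p < alpha_v
    and mean(high) > mean(low).
    """
    labeled = dataset.labels.index
    scores = score_matrix(dataset.matrix[labeled], gene_list, params).iloc[0]
    high = scores[dataset.labels == HIGH]
    low = scores[dataset.labels == LOW]
    if len(high) < 2 or len(low) < 2:
        raise ValueError(f"dataset {dataset.name!r}: need >= 2 samples per group")
    if high.var() == 0 and low.var() == 0:
        # identical constant scores: no evidence either way
        p = 1.0
    else:
        p = float(stats.ttest_ind(high, low, equal_var=False).pvalue)
    direction_ok = bool(high.mean() > low.mean())
    return ValidationOutcome(
        list_name=gene_list.name,
        dataset_name=dataset.name,
        p_value=p,
        direction_ok=direction_ok,
        passed=bool(p < alpha_v and direction_ok),
    )


def validate_gene_lists(
    lists: GeneSetCollection,
    datasets: list[LabeledDataset],
    alpha_v: float = 0.05,
    params: SsgseaParams | None = None,
) -> pd.DataFrame:
    """All (list, dataset) validation outcomes as a tidy table."""
    rows = [
        evaluate_gene_list(gs, ds, alpha_v=alpha_v, params=params)
        for gs in lists
        for ds in datasets
    ]
    return pd.DataFrame([vars(o) for o in rows])


def select_consistent_lists(outcomes: pd.DataFrame, min_datasets: int = 4) -> list[str]:
    """Names of lists passing in at least ``min_datasets`` datasets.

    ``outcomes`` must cover every (list, dataset) pair; a missing pair is
    an error rather than an implicit fail.
    """
    lists = outcomes["list_name"].unique()
    datasets = outcomes["dataset_name"].unique()
    counts = outcomes.groupby(["list_name", "dataset_name"]).size()
    for ln in lists:
        for dn in datasets:
            if (ln, dn) not in counts.index:
                raise ValueError(f"missing validation outcome for list {ln!r} on dataset {dn!r}")
    passes = outcomes.groupby("list_name")["passed"].sum()
    return [ln for ln in lists if passes[ln] >= min_datasets]


def derive_consensus_signature(retained: GeneSetCollection, name: str = "consensus") -> GeneSet:
    """Exact intersection of all retained lists, ordered lexicographically."""
    if len(retained) == 0:
        raise ValueError("no retained lists to intersect")
    core = reduce(lambda a, b: a & b, (set(s.genes) for s in retained))
    if not core:
        sizes = {s.name: len(s) for s in retained}
        raise ValueError(f"empty intersection of retained lists (sizes: {sizes})")
    return GeneSet(name=name, description="consensus signature", genes=tuple(sorted(core)))
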