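"""Readers and writers for the tabular formats the pipeline exchanges.

Canonical dialect: UTF-8 TSV, ``NA`` as the single missing-value token.
Expression matrices are feature-major (rows = features, columns = samples),
matching the per-sample scoring access pattern. Gene identifiers are matched
case-sensitively as symbols; no alias resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger("autoscore")

NA_TOKEN = "NA"

#: layers whose matrices are binary presence/absence indicators
BINARY_LAYERS = frozenset({"mutation", "SCNA"})
#: layers carrying continuous measurements
CONTINUOUS_LAYERS = frozenset({"mRNA", "miRNA", "protein", "methylation"})


class ParseError(ValueError):
    """A file violated its format contract; message carries the position."""


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered list of unique gene symbols."""

    name: str
    description: str = ""
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate genes")
        if any(not g for g in self.genes):
            raise ValueError(f"gene set {self.name!r} contains empty gene ids")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass
class GeneSetCollection:
    """An ordered collection of gene sets with unique names (GMT contents)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene set names: {dupes}")

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def _dedup_preserving_order(items: Iterable[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for it in items:
        seen.setdefault(it, None)
    return tuple(seen)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name, description, member genes per line).

    Duplicate genes within a set are deduplicated preserving first
    occurrence; a duplicate set name or a line with fewer than three
    fields is a :class:`ParseError` naming the line.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    names_seen: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            if name in names_seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            names_seen.add(name)
            genes = _dedup_preserving_order(g for g in fields[2:] if g)
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(name=name, description=description, genes=genes))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join((s.name, s.description, *s.genes)) + "\n")


def read_matrix(path: str | Path, layer: str = "mRNA") -> pd.DataFrame:
    """Read a feature x sample TSV matrix for one omics layer.

    Binary layers (mutation, SCNA) must contain only {0, 1}; any other
    value is rejected with its row/column address. Continuous layers allow
    ``NA`` entries (parsed as NaN).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate feature ids {dupes[:5]}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate sample ids {dupes[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at "
            f"feature {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    numeric = numeric.astype(float)
    if layer in BINARY_LAYERS:
        values = numeric.to_numpy()
        ok = np.isin(values, (0.0, 1.0)) | np.isnan(values)
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ParseError(
                f"{path}: missing value in binary layer at "
                f"feature {numeric.index[r]!r}, sample {numeric.columns[c]!r}"
            )
        if not ok.all():
            r, c = np.argwhere(~ok)[0]
            raise ParseError(
                f"{path}: binary layer {layer!r} contains {values[r, c]!r} at "
                f"feature {numeric.index[r]!r}, sample {numeric.columns[c]!r}; expected 0/1"
            )
    return numeric


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a feature x sample matrix as TSV with stable float formatting."""
    matrix.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format="%.10g")


def read_pairs(path: str | Path) -> pd.DataFrame:
    """Read a two-column regulator->target TSV; deduplicate directed pairs.

    Self-loops are kept but logged, since the reference databases contain
    autoregulatory entries.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (regulator, target)")
    df = df.iloc[:, :2]
    df.columns = ["regulator", "target"]
    before = len(df)
    df = df.drop_duplicates(ignore_index=True)
    if len(df) < before:
        logger.info("read_pairs(%s): dropped %d duplicate pairs", path, before - len(df))
    loops = int((df["regulator"] == df["target"]).sum())
    if loops:
        logger.warning("read_pairs(%s): %d self-loop pairs kept", path, loops)
    return df


def write_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read a per-sample covariate table (first column = sample_id)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate sample ids {dupes[:5]}")
    missing = df.isna().sum()
    for cov, n in missing[missing > 0].items():
        logger.warning("read_sample_table(%s): covariate %r missing in %d samples", path, cov, n)
    return df


def write_sample_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Generic TSV table (no index column)."""
    return pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN, float_format="%.10g")
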