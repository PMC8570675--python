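"""Count matrix construction and library-size normalization.

Normalization divides each sample's counts by a library-size factor S_j,
the median across reference rows of the ratio between that sample's
count and a pseudo-reference count, where the pseudo-reference for a row
is the geometric mean of its counts across all samples. Rows containing
any zero are excluded from factor computation (the geometric mean would
vanish); a +0.5 pseudocount mode is available instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import AnnotationResult
from .seqio import write_table

COUNTED_CLASSES = ("known_mature", "novel_arm_candidate")


@dataclass
class CountMatrix:
    counts: pd.DataFrame     # rows: miRNA / candidate ids, columns: samples

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate row ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.counts.shape[1] < 1:
            raise ValueError("at least one sample required")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    @property
    def m(self) -> int:
        return self.counts.shape[1]

    def write(self, path: str | Path) -> None:
        write_table(self.counts, path, index_label="id")


@dataclass
class LibrarySizeFactors:
    factors: pd.Series            # S_j per sample, all > 0
    reference_rows: list[str]

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("library size factors must be positive")

    def write(self, path: str | Path) -> None:
        df = self.factors.rename("S_j").to_frame()
        write_table(df, path, index_label="sample")


def build_count_matrix(annotations: AnnotationResult,
                       accepted_novel: set[str] | None = None) -> CountMatrix:
    """Aggregate unique-sequence counts into per-miRNA rows.

    Known matures always count; novel candidates count only when their id
    is in ``accepted_novel`` (None accepts all candidates).
    """
    rows = annotations.rows
    counts = annotations.counts
    keep = rows["class"].isin(COUNTED_CLASSES)
    if accepted_novel is not None:
        keep &= (rows["class"] == "known_mature") | rows["assigned_id"].isin(
            accepted_novel)
    sub = counts.loc[keep]
    ids = rows.loc[keep, "assigned_id"]
    if sub.empty:
        return CountMatrix(pd.DataFrame(
            columns=counts.columns, index=pd.Index([], name="id"), dtype=int))
    agg = sub.groupby(ids).sum()
    agg.index.name = "id"
    return CountMatrix(agg.sort_index().astype(int))


def library_size_factors(matrix: CountMatrix,
                         pseudocount: float = 0.0) -> LibrarySizeFactors:
    """Median-of-ratios factors against a geometric-mean pseudo-reference.

    With ``pseudocount`` 0 only rows positive in every sample enter the
    median; a positive pseudocount is added to every count first, letting
    all rows contribute.
    """
    c = matrix.counts.astype(float) + pseudocount
    positive = (c > 0).all(axis=1)
    ref = c.loc[positive]
    if ref.empty:
        raise ValueError(
            "no row has positive counts in every sample; filter rows or "
            "pass pseudocount > 0")
    # geometric mean in log space for stability; median on the ratio scale
    # (even cardinality = mean of the two central ratios)
    log_gm = np.log(ref.values).mean(axis=1)
    ratios = ref.values / np.exp(log_gm)[:, None]
    s = np.median(ratios, axis=0)
    return LibrarySizeFactors(
        pd.Series(s, index=matrix.counts.columns, name="S_j"),
        list(ref.index))


def normalize(matrix: CountMatrix,
              factors: LibrarySizeFactors) -> pd.DataFrame:
    """Divide each sample's counts by its factor; zeros stay zero."""
    if list(matrix.counts.columns) != list(factors.factors.index):
        raise ValueError("sample ids of matrix and factors differ")
    return matrix.counts.astype(float).div(factors.factors, axis=1)
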