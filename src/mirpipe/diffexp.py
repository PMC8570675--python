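"""Differential-expression screening.

Normalized values are compared between groups with Welch's t-test (two
groups) or one-way ANOVA (three or more); aggregated raw counts can be
screened with a chi-square 2x2 test (no continuity correction) or
Fisher's exact test against the remaining library counts. Calls use raw
p-values and a fold-change gate, with no multiple-testing adjustment —
the screening design deliberately avoids FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import write_table

LOG2FC_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class GroupDesign:
    groups: Mapping[str, str]       # sample id -> group label

    def samples_of(self, label: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == label]

    @property
    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups.values():
            seen.setdefault(g)
        return list(seen)


def log2_fold_change(mean_a: float, mean_b: float,
                     eps: float = LOG2FC_PSEUDOCOUNT) -> float:
    """log2 of (second group / first group) mean, guarded by eps."""
    return float(np.log2((mean_b + eps) / (mean_a + eps)))


def _welch_row(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 1.0, True
        return 0.0, True          # disjoint constants: formally certain
    _, p = stats.ttest_ind(a, b, equal_var=False)
    return float(p), False


def compare_two_groups(values: pd.DataFrame, design: GroupDesign,
                       test: str = "t",
                       group_pair: tuple[str, str] | None = None,
                       eps: float = LOG2FC_PSEUDOCOUNT) -> pd.DataFrame:
    """Per-row two-group comparison.

    ``test`` is one of ``t`` (Welch, on normalized values), ``chi2_2x2``
    or ``fisher`` (on per-group aggregated counts vs the rest of the
    library, no continuity correction). Fold change is second group over
    first.
    """
    labels = list(group_pair) if group_pair else design.labels
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    ga = [s for s in values.columns if design.groups.get(s) == labels[0]]
    gb = [s for s in values.columns if design.groups.get(s) == labels[1]]
    if test == "t" and (len(ga) < 2 or len(gb) < 2):
        raise ValueError("t-test needs at least 2 samples per group")

    out = []
    if test in ("chi2_2x2", "fisher"):
        tot_a = float(values[ga].values.sum())
        tot_b = float(values[gb].values.sum())
    for rid, row in values.iterrows():
        a = row[ga].to_numpy(dtype=float)
        b = row[gb].to_numpy(dtype=float)
        mean_a, mean_b = float(a.mean()), float(b.mean())
        lfc = log2_fold_change(mean_a, mean_b, eps)
        degenerate = False
        if test == "t":
            p, degenerate = _welch_row(a, b)
        elif test in ("chi2_2x2", "fisher"):
            ca, cb = a.sum(), b.sum()
            table = np.array([[ca, tot_a - ca], [cb, tot_b - cb]])
            if test == "fisher":
                _, p = stats.fisher_exact(table)
            else:
                stat, p, _, _ = stats.chi2_contingency(table,
                                                       correction=False)
        else:
            raise ValueError(f"unknown test {test!r}")
        out.append({"mean_" + labels[0]: mean_a, "mean_" + labels[1]: mean_b,
                    "log2fc": lfc, "test": test, "p": float(p),
                    "degenerate": degenerate, "id": rid})
    df = pd.DataFrame(out).set_index("id")
    return df


def chi2_2x2(table: np.ndarray | list[list[float]]) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction."""
    stat, p, _, _ = stats.chi2_contingency(np.asarray(table, dtype=float),
                                           correction=False)
    return float(stat), float(p)


def compare_k_groups(values: pd.DataFrame, design: GroupDesign,
                     eps: float = LOG2FC_PSEUDOCOUNT) -> pd.DataFrame:
    """One-way ANOVA per row with all pairwise log2 fold changes.

    Delegates to Welch's t through :func:`compare_two_groups` when only
    two groups are present.
    """
    labels = design.labels
    if len(labels) == 2:
        return compare_two_groups(values, design, test="t", eps=eps)
    cols = {g: [s for s in values.columns if design.groups.get(s) == g]
            for g in labels}
    for g, ss in cols.items():
        if len(ss) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    out = []
    for rid, row in values.iterrows():
        arrays = [row[cols[g]].to_numpy(dtype=float) for g in labels]
        if all(np.var(a) == 0 for a in arrays) and len(
                {float(a.mean()) for a in arrays}) == 1:
            f, p = 0.0, 1.0
        else:
            f, p = stats.f_oneway(*arrays)
        rec = {"id": rid, "test": "anova", "p": float(p), "F": float(f)}
        for g, arr in zip(labels, arrays):
            rec[f"mean_{g}"] = float(arr.mean())
        for i, g1 in enumerate(labels):
            for g2 in labels[i + 1:]:
                rec[f"log2fc_{g2}_vs_{g1}"] = log2_fold_change(
                    rec[f"mean_{g1}"], rec[f"mean_{g2}"], eps)
        out.append(rec)
    return pd.DataFrame(out).set_index("id")


def call_de(results: pd.DataFrame, alpha: float = 0.05,
            lfc_min: float = 1.0,
            lfc_col: str = "log2fc") -> pd.DataFrame:
    """Flag rows with |log2FC| >= lfc_min and raw p < alpha.

    Adds ``de`` (bool), ``direction`` (up/down/none) and ``neg_log10_p``
    volcano columns; no multiple-testing adjustment is applied.
    """
    df = results.copy()
    lfc = df[lfc_col].astype(float)
    df["de"] = (lfc.abs() >= lfc_min) & (df["p"] < alpha)
    df["direction"] = np.where(~df["de"], "none",
                               np.where(lfc > 0, "up", "down"))
    with np.errstate(divide="ignore"):
        df["neg_log10_p"] = -np.log10(df["p"].astype(float))
    return df


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    write_table(df, path, index_label="id")
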