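"""OTU tables and alpha diversity for the microbial side of the pairing.

Counts come from marker-gene (16S/ITS) OTU clustering upstream; here
they are converted to relative abundance and summarized per sample by
the classic alpha-diversity suite: observed OTUs, bias-corrected Chao1
richness, Shannon (nats), Gini-Simpson, Pielou evenness and (when a
phylogeny is supplied) Faith's phylogenetic diversity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import (
    DuplicateIdError,
    EmptySampleError,
    TreeCoverageError,
    ValidationError,
)

__all__ = [
    "OTUTable",
    "AlphaDiversity",
    "relative_abundance",
    "alpha_diversity",
    "alpha_diversity_table",
    "faith_pd",
    "top_n_features",
]


@dataclass
class OTUTable:
    """OTU x sample integer count matrix with optional taxonomy and tree.

    ``counts`` is indexed by OTU id with one column per sample.  When
    present, ``taxonomy`` and ``tree`` must cover every OTU id.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None
    tree: TreeNode | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate otu_id values: {dups}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise DuplicateIdError(f"duplicate sample ids: {dups}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("OTU counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("OTU counts must be non-negative")
        if self.taxonomy is not None:
            missing = self.counts.index.difference(self.taxonomy.index)
            if len(missing):
                raise ValidationError(f"taxonomy missing for OTUs: {missing.tolist()[:5]}")
        if self.tree is not None:
            tips = {t.name for t in self.tree.tips()}
            missing_t = set(self.counts.index) - tips
            if missing_t:
                raise TreeCoverageError(f"tree missing OTUs: {sorted(missing_t)[:5]}")

    @property
    def otu_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()


def relative_abundance(table: OTUTable) -> pd.DataFrame:
    """Per-sample proportions; every column sums to 1.

    A sample with zero total counts is an error naming the sample.
    """
    totals = table.counts.sum(axis=0)
    empty = totals.index[totals == 0].tolist()
    if empty:
        raise EmptySampleError(f"sample(s) with zero total counts: {empty}")
    return table.counts / totals


@dataclass(frozen=True)
class AlphaDiversity:
    """Alpha-diversity suite for one sample (shannon in nats; simpson is
    Gini-Simpson ``1 - sum(p^2)`` unless dominance was requested)."""

    observed_otus: int
    chao1: float
    shannon: float
    simpson: float
    pielou: float
    faith_pd: float | None = None


def faith_pd(tree: TreeNode, observed_ids: Sequence[str]) -> float:
    """Faith's PD: total branch length of the subtree spanning the
    observed OTUs and the root."""
    tips = {t.name: t for t in tree.tips()}
    missing = set(observed_ids) - tips.keys()
    if missing:
        raise TreeCoverageError(f"tree missing observed OTUs: {sorted(missing)[:5]}")
    visited: set[int] = set()
    total = 0.0
    for oid in observed_ids:
        node = tips[oid]
        while node is not None and id(node) not in visited:
            visited.add(id(node))
            if node.length is not None:
                total += node.length
            node = node.parent
    return total


def alpha_diversity(
    counts: Sequence[int] | np.ndarray,
    tree: TreeNode | None = None,
    otu_ids: Sequence[str] | None = None,
    dominance: bool = False,
) -> AlphaDiversity:
    """Alpha diversity of one sample's integer count vector.

    * observed = number of OTUs with count > 0
    * Chao1 (bias-corrected) = S_obs + F1(F1-1) / (2(F2+1)), F1/F2 the
      singleton/doubleton counts
    * Shannon = -sum(p ln p) over p > 0, natural log
    * Simpson = 1 - sum(p^2) (Gini-Simpson; ``dominance=True`` reports
      sum(p^2) instead for mothur-style comparability)
    * Pielou = Shannon / ln(observed) for observed >= 2, else NaN
    * Faith's PD only when a tree (and matching ``otu_ids``) is given.
    """
    x = np.asarray(counts)
    if x.ndim != 1:
        raise ValidationError("counts must be a 1-D vector")
    if not np.issubdtype(x.dtype, np.integer):
        if not np.allclose(x, np.round(x)):
            raise ValidationError("counts must be integers")
        x = np.round(x).astype(np.int64)
    if (x < 0).any():
        raise ValidationError("counts must be non-negative")
    if x.sum() == 0:
        raise EmptySampleError("sample has zero total counts")

    observed = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    chao1 = observed + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    p = x[x > 0] / x.sum()
    shannon = float(-(p * np.log(p)).sum())
    sum_p2 = float((p**2).sum())
    simpson = sum_p2 if dominance else 1.0 - sum_p2
    pielou = shannon / np.log(observed) if observed >= 2 else float("nan")

    pd_value = None
    if tree is not None:
        if otu_ids is None:
            raise ValidationError("otu_ids are required to compute Faith's PD")
        observed_ids = [oid for oid, cnt in zip(otu_ids, x) if cnt > 0]
        pd_value = faith_pd(tree, observed_ids)
    return AlphaDiversity(
        observed_otus=observed,
        chao1=chao1,
        shannon=shannon,
        simpson=simpson,
        pielou=pielou,
        faith_pd=pd_value,
    )


def alpha_diversity_table(table: OTUTable, dominance: bool = False) -> pd.DataFrame:
    """Alpha-diversity suite for every sample of an OTU table."""
    rows = {}
    for sample in table.sample_ids:
        a = alpha_diversity(
            table.counts[sample].to_numpy(),
            tree=table.tree,
            otu_ids=table.otu_ids if table.tree is not None else None,
            dominance=dominance,
        )
        rows[sample] = {
            "observed_otus": a.observed_otus,
            "chao1": a.chao1,
            "shannon": a.shannon,
            "simpson": a.simpson,
            "pielou": a.pielou,
            "faith_pd": a.faith_pd if a.faith_pd is not None else np.nan,
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")


def top_n_features(matrix: pd.DataFrame, n: int) -> pd.DataFrame:
    """The ``n`` features (rows) with the largest mean relative abundance
    across samples; ties broken by feature label ascending.

    If fewer than ``n`` features exist all are kept, with a warning.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if len(matrix) <= n:
        if len(matrix) < n:
            warnings.warn(
                f"requested top {n} features but only {len(matrix)} available; keeping all",
                stacklevel=2,
            )
        order = matrix.mean(axis=1).sort_values(ascending=False, kind="stable")
        return matrix.loc[order.index]
    means = matrix.mean(axis=1)
    ranked = (
        means.to_frame("mean")
        .assign(label=means.index.astype(str))
        .sort_values(["mean", "label"], ascending=[False, True], kind="stable")
    )
    return matrix.loc[ranked.index[:n]]
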