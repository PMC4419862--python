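"""Rank genes and virtual clusters by induction indexes.

Single genes ranked by m, t, a or m*a often fail to put the true
biosynthesis genes near the top: replicate noise scatters individual
values.  Averaging an index over a window of consecutive genes
suppresses that noise, because a co-regulated cluster contributes
several same-signed values to one window while background windows
average toward zero.  This module produces both rank tables.

Ranks are competition ranks, descending by value: the best item is
rank 1 and ties share the minimum rank (values [3, 3, 1] rank
[1, 1, 3]).  Genes with an unavailable or flagged index rank last.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from middascan.errors import InputError
from middascan.expression_stats import InductionProfile
from middascan.genome_model import GeneOrder, enumerate_virtual_clusters

__all__ = ["RankTable", "rank_genes", "rank_virtual_clusters"]


@dataclass
class RankTable:
    """Ranked items (genes or windows) for one index.

    ``table`` has columns item, value, rank; sorted by rank then item
    id for a stable display order.  ``direction`` records whether
    ranking was by signed value or by magnitude.
    """

    index: str
    table: pd.DataFrame
    direction: str = "signed_descending"

    def rank_of(self, item: str) -> int:
        row = self.table.loc[self.table["item"] == item, "rank"]
        if row.empty:
            raise InputError(f"item not in rank table: {item}")
        return int(row.iloc[0])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _competition_ranks(values: np.ndarray, absolute: bool) -> np.ndarray:
    """Descending competition ranks; non-finite values rank last."""
    keyed = np.abs(values) if absolute else values.astype(float)
    keyed = np.where(np.isfinite(keyed), keyed, -np.inf)
    return rankdata(-keyed, method="min").astype(int)


def _build_table(index: str, items: list[str], values: np.ndarray, absolute: bool) -> RankTable:
    ranks = _competition_ranks(values, absolute)
    table = pd.DataFrame({"item": items, "value": values, "rank": ranks})
    table = table.sort_values(["rank", "item"], kind="stable").reset_index(drop=True)
    return RankTable(
        index=index,
        table=table,
        direction="absolute_descending" if absolute else "signed_descending",
    )


def rank_genes(
    profile: InductionProfile, index: str, absolute: bool = False
) -> RankTable:
    """Competition-rank all genes by one index, best (largest) first.

    ``absolute=True`` ranks by magnitude instead of signed value.
    Genes flagged undefined for m, or with an infinite t, are ranked
    last regardless of their stored value.
    """
    values = np.array(profile.index_values(index), dtype=float)
    bad = profile.undefined.copy()
    if index == "t" and profile.t_infinite is not None:
        bad |= profile.t_infinite
    values = np.where(bad, -np.inf, values)
    return _build_table(index, list(profile.gene_ids), values, absolute)


def rank_virtual_clusters(
    profile: InductionProfile,
    order: GeneOrder,
    ncl: int,
    index: str,
    absolute: bool = False,
) -> RankTable:
    """Rank all windows of ``ncl`` consecutive genes by the window mean
    of one index.

    Window items are labelled ``contig:first_gene..last_gene``.  With
    ncl = 1 this reduces to :func:`rank_genes` (up to item labels).
    """
    values = np.array(profile.index_values(index), dtype=float)
    bad = profile.undefined.copy()
    if index == "t" and profile.t_infinite is not None:
        bad |= profile.t_infinite
    values = np.where(bad, np.nan, values)
    pos = {g: k for k, g in enumerate(profile.gene_ids)}
    missing = [g for g in order.gene_ids() if g not in pos]
    if missing:
        raise InputError(f"profile lacks annotated gene {missing[0]}")
    windows = enumerate_virtual_clusters(order, ncl)
    items: list[str] = []
    means = np.empty(len(windows))
    for w, vc in enumerate(windows):
        vals = values[[pos[g] for g in vc.gene_ids]]
        means[w] = np.nan if np.isnan(vals).any() else vals.mean()
        items.append(f"{vc.contig}:{vc.gene_ids[0]}..{vc.gene_ids[-1]}")
    means = np.where(np.isnan(means), -np.inf, means)
    return _build_table(index, items, means, absolute)
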