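"""Context grouping, context-specific RE calling, and genome category builders.

An RE of context i is *context-specific* when no RE of any other context
overlaps it beyond a base-ratio threshold.  The rule is two-tier: against
contexts of a different group the overlap ratio (overlapping bases divided by
the length of the candidate RE) must not exceed 0.50; against contexts of the
same group the bar is relaxed to 0.60, so that lineage-shared REs (e.g. among
several brain tissues) are not all discarded.  Both thresholds are strict
(ratio must be strictly greater to count as overlapped).

Five category methods are supported:

``specific``  specificity-filtered network REs (the package's own categories)
``are``       all REs of each context's network
``aap``       all accessible peaks of each context
``sap``       the specificity rule applied to accessible peaks
``seg``       +/-100 kb windows around the top 10% specifically expressed genes
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from regherit.io import GenomicInterval, merge_intervals
from regherit.regnet import RegulatoryNetwork

logger = logging.getLogger(__name__)

CROSS_GROUP_RATIO = 0.50
WITHIN_GROUP_RATIO = 0.60
SEG_TOP_FRACTION = 0.10
SEG_WINDOW_BP = 100_000

CATEGORY_METHODS = ("specific", "are", "aap", "sap", "seg")


@dataclass
class ContextAtlas:
    """A set of per-context regulatory networks with a grouping of contexts."""

    networks: list[RegulatoryNetwork]
    group_of: dict[str, int]

    def __post_init__(self):
        ids = [nw.context_id for nw in self.networks]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate context ids in atlas")
        missing = set(ids) - set(self.group_of)
        if missing:
            raise ValueError(f"contexts without a group: {sorted(missing)}")

    @property
    def context_ids(self) -> list[str]:
        return [nw.context_id for nw in self.networks]

    @property
    def n_groups(self) -> int:
        return len(set(self.group_of.values()))

    def network(self, context_id: str) -> RegulatoryNetwork:
        for nw in self.networks:
            if nw.context_id == context_id:
                return nw
        raise KeyError(f"unknown context: {context_id}")

    def re_sets(self) -> dict[str, list[GenomicInterval]]:
        return {nw.context_id: [nw.re_intervals[r] for r in sorted(nw.res)]
                for nw in self.networks}


@dataclass
class RegulatoryCategory:
    """A genome category: merged region set plus the source REs it came from."""

    context_id: str
    method: str
    regions: list[GenomicInterval]
    source_re_ids: list[str]

    @property
    def total_bp(self) -> int:
        return sum(iv.length for iv in self.regions)


def cluster_contexts(
    networks: Sequence[RegulatoryNetwork], n_groups: int = 36
) -> dict[str, int]:
    """Group contexts by average-linkage clustering of their TRS vectors.

    Each context is vectorized over the union of (tf, tg) pairs (absent pairs
    count 0); distance is 1 - Pearson correlation; the average-linkage tree is
    cut into ``n_groups`` flat labels (1-based).
    """
    if len(networks) < 2:
        raise ValueError("need at least 2 contexts to cluster")
    if n_groups > len(networks):
        raise ValueError(f"n_groups={n_groups} exceeds {len(networks)} contexts")
    frames = []
    for nw in networks:
        e = nw.trs_edges
        s = pd.Series(e["trs"].to_numpy(float),
                      index=pd.MultiIndex.from_arrays([e["tf"], e["tg"]]),
                      name=nw.context_id)
        frames.append(s[~s.index.duplicated()])
    mat = pd.concat(frames, axis=1).fillna(0.0).to_numpy(float).T
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(mat)
    dist = 1.0 - np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=n_groups, criterion="maxclust")
    return {nw.context_id: int(g) for nw, g in zip(networks, labels)}


def _trees(
    interval_sets: Mapping[str, Sequence[GenomicInterval]]
) -> dict[str, dict[str, IntervalTree]]:
    out: dict[str, dict[str, IntervalTree]] = {}
    for ctx, ivs in interval_sets.items():
        per_chrom: dict[str, IntervalTree] = {}
        for iv in ivs:
            per_chrom.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        out[ctx] = per_chrom
    return out


def _is_overlapped(iv: GenomicInterval,
                   trees: dict[str, IntervalTree],
                   ratio: float) -> bool:
    tree = trees.get(iv.chrom)
    if tree is None:
        return False
    for hit in tree.overlap(iv.start, iv.end):
        ov = min(iv.end, hit.end) - max(iv.start, hit.begin)
        if ov / iv.length > ratio:
            return True
    return False


def specific_intervals(
    interval_sets: Mapping[str, Sequence[GenomicInterval]],
    group_of: Mapping[str, int],
    focal: str,
    cross_group_ratio: float = CROSS_GROUP_RATIO,
    within_group_ratio: float = WITHIN_GROUP_RATIO,
) -> list[GenomicInterval]:
    """Return the intervals of ``focal`` not overlapped by any other context.

    The overlap-base ratio uses the candidate (query) interval's length as
    denominator, so specificity is a property of the query RE.
    """
    if focal not in interval_sets:
        raise KeyError(f"unknown context: {focal}")
    trees = _trees({c: ivs for c, ivs in interval_sets.items() if c != focal})
    retained = []
    for iv in interval_sets[focal]:
        ok = True
        for other, other_trees in trees.items():
            ratio = (within_group_ratio if group_of[other] == group_of[focal]
                     else cross_group_ratio)
            if _is_overlapped(iv, other_trees, ratio):
                ok = False
                break
        if ok:
            retained.append(iv)
    return retained


def call_specific_res(
    atlas: ContextAtlas,
    context_id: str,
    cross_group_ratio: float = CROSS_GROUP_RATIO,
    within_group_ratio: float = WITHIN_GROUP_RATIO,
) -> RegulatoryCategory:
    """Call the context-specific REs of one context's network (method ``specific``)."""
    retained = specific_intervals(
        atlas.re_sets(), atlas.group_of, context_id,
        cross_group_ratio, within_group_ratio)
    return RegulatoryCategory(
        context_id=context_id,
        method="specific",
        regions=merge_intervals(retained),
        source_re_ids=[iv.id for iv in retained],
    )


def build_categories(
    atlas: ContextAtlas,
    method: str,
    peaks: Mapping[str, Sequence[GenomicInterval]] | None = None,
    expression: pd.DataFrame | None = None,
    gene_intervals: Mapping[str, GenomicInterval] | None = None,
) -> list[RegulatoryCategory]:
    """Build one genome category per context with the chosen method.

    ``peaks`` (per-context accessible-peak intervals) is required for
    aap/sap; ``expression`` (gene x context) and ``gene_intervals`` are
    required for seg.
    """
    if method not in CATEGORY_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {CATEGORY_METHODS}")
    if method == "specific":
        return [call_specific_res(atlas, c) for c in atlas.context_ids]
    if method == "are":
        out = []
        for nw in atlas.networks:
            ivs = [nw.re_intervals[r] for r in sorted(nw.res)]
            out.append(RegulatoryCategory(nw.context_id, "are",
                                          merge_intervals(ivs),
                                          [iv.id for iv in ivs]))
        return out
    if method in ("aap", "sap"):
        if peaks is None:
            raise ValueError(f"method {method!r} requires per-context peaks")
        if method == "aap":
            return [RegulatoryCategory(c, "aap", merge_intervals(peaks[c]),
                                       [iv.id for iv in peaks[c]])
                    for c in atlas.context_ids]
        out = []
        for c in atlas.context_ids:
            retained = specific_intervals(peaks, atlas.group_of, c)
            out.append(RegulatoryCategory(c, "sap", merge_intervals(retained),
                                          [iv.id for iv in retained]))
        return out
    # seg
    if expression is None or gene_intervals is None:
        raise ValueError("method 'seg' requires expression and gene_intervals")
    return _seg_categories(atlas.context_ids, expression, gene_intervals)


def seg_t_statistics(expression: pd.DataFrame) -> pd.DataFrame:
    """Per gene and context: (value - mean of other contexts) / sd of others.

    One sample per context (no replicates); genes x contexts in, same shape out.
    """
    x = expression.to_numpy(float)
    n = x.shape[1]
    if n < 3:
        raise ValueError("seg t-statistics need >= 3 contexts")
    tot = x.sum(axis=1, keepdims=True)
    mean_others = (tot - x) / (n - 1)
    sq = (x ** 2).sum(axis=1, keepdims=True)
    var_others = (sq - x ** 2) / (n - 1) - mean_others ** 2
    var_others = np.clip(var_others * (n - 1) / (n - 2), 0.0, None)  # ddof=1
    sd = np.sqrt(var_others)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (x - mean_others) / sd
    return pd.DataFrame(t, index=expression.index, columns=expression.columns)


def _seg_categories(context_ids, expression, gene_intervals):
    t = seg_t_statistics(expression)
    n_top = int(np.ceil(SEG_TOP_FRACTION * expression.shape[0]))
    out = []
    for c in context_ids:
        top = t[c].sort_values(ascending=False).index[:n_top]
        regions = []
        for gene in top:
            iv = gene_intervals.get(gene)
            if iv is None:
                logger.warning("seg: no interval for gene %s; skipped", gene)
                continue
            regions.append(GenomicInterval(
                iv.chrom, max(0, iv.start - SEG_WINDOW_BP),
                iv.end + SEG_WINDOW_BP, gene))
        out.append(RegulatoryCategory(c, "seg", merge_intervals(regions),
                                      list(top)))
    return out


def build_group_categories(
    atlas: ContextAtlas,
    interval_sets: Mapping[str, Sequence[GenomicInterval]] | None = None,
) -> list[RegulatoryCategory]:
    """Pool member-context REs per group and keep the group-specific ones.

    A pooled RE is group-specific when no RE of any *other* group overlaps it
    by more than the cross-group ratio (0.50).  Returns one category per
    group, with ``context_id`` set to ``group<g>``.
    """
    if interval_sets is None:
        interval_sets = atlas.re_sets()
    pooled: dict[int, list[GenomicInterval]] = {}
    for ctx, ivs in interval_sets.items():
        pooled.setdefault(atlas.group_of[ctx], []).extend(ivs)
    group_trees = {g: _trees({"pool": ivs})["pool"] for g, ivs in pooled.items()}
    out = []
    for g in sorted(pooled):
        retained = []
        for iv in pooled[g]:
            if any(_is_overlapped(iv, group_trees[h], CROSS_GROUP_RATIO)
                   for h in pooled if h != g):
                continue
            retained.append(iv)
        out.append(RegulatoryCategory(f"group{g}", "specific",
                                      merge_intervals(retained),
                                      [iv.id for iv in retained]))
    return out


def categories_manifest(categories: Sequence[RegulatoryCategory]) -> pd.DataFrame:
    """Summary table (context, method, n_regions, total_bp) for a category set."""
    return pd.DataFrame([
        {"context": c.context_id, "method": c.method,
         "n_regions": len(c.regions), "total_bp": c.total_bp}
        for c in categories
    ])
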