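"""Hypergeometric trait enrichment of hierarchy communities.

For each (community, trait gene-set) pair, over-representation is tested
with the upper-tail hypergeometric law on the 2x2 table drawn from a
fixed gene universe, p-values are corrected across the whole
community x trait family with the Benjamini-Hochberg step-up, and odds
ratios (with optional Haldane-Anscombe 0.5 correction for zero cells)
feed the trait-by-community heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ParameterError

__all__ = [
    "TraitGeneSet",
    "hypergeom_test",
    "odds_ratio",
    "bh_fdr",
    "enrich_communities",
    "enrich_hierarchy",
    "annotate_communities",
    "or_heatmap",
]


@dataclass
class TraitGeneSet:
    trait_name: str
    genes: frozenset
    source: str = ""


def _check_counts(overlap, community_size, trait_size, universe_size):
    if not (0 <= overlap <= min(community_size, trait_size)):
        raise ParameterError(
            f"overlap {overlap} inconsistent with sizes "
            f"({community_size}, {trait_size})")
    if community_size > universe_size or trait_size > universe_size:
        raise ParameterError("set sizes exceed universe size")
    if universe_size <= 0:
        raise ParameterError("empty universe")
    # the 2x2 table must have a nonnegative remainder cell
    if universe_size - community_size - trait_size + overlap < 0:
        raise ParameterError("counts imply a negative remainder cell")


def hypergeom_test(overlap: int, community_size: int, trait_size: int,
                   universe_size: int) -> float:
    """Upper-tail P(X >= overlap) for X ~ Hypergeom(N, K=trait, n=community)."""
    _check_counts(overlap, community_size, trait_size, universe_size)
    return float(hypergeom.sf(overlap - 1, universe_size, trait_size, community_size))


def odds_ratio(overlap: int, community_size: int, trait_size: int,
               universe_size: int, haldane: bool = True) -> float:
    """Odds ratio of the 2x2 community-membership x trait-membership table.

    With ``haldane=True`` (default), 0.5 is added to every cell whenever
    any cell is zero, keeping the ratio finite.
    """
    _check_counts(overlap, community_size, trait_size, universe_size)
    a = overlap
    b = community_size - overlap
    c = trait_size - overlap
    d = universe_size - community_size - trait_size + overlap
    if haldane and 0 in (a, b, c, d):
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    if b * c == 0:
        return float("inf")
    return (a * d) / (b * c)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    In p-sorted order, q_(i) = min_{j >= i} min(1, p_(j) * m / j), mapped
    back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def enrich_communities(communities, trait_sets, universe,
                       fdr_level: float = 0.05, haldane: bool = True) -> pd.DataFrame:
    """Long-format enrichment table over all (community, trait) pairs.

    ``communities`` maps community_id -> gene set; trait sets are
    intersected with the universe before testing; the FDR family is the
    full community x trait grid of this call.
    """
    universe = frozenset(universe)
    if not universe:
        raise ParameterError("empty universe")
    rows = []
    for cid in communities:
        cgenes = frozenset(communities[cid]) & universe
        for ts in trait_sets:
            tgenes = frozenset(ts.genes) & universe
            a = len(cgenes & tgenes)
            p = hypergeom_test(a, len(cgenes), len(tgenes), len(universe)) \
                if cgenes and tgenes else 1.0
            orr = odds_ratio(a, len(cgenes), len(tgenes), len(universe), haldane) \
                if cgenes and tgenes else np.nan
            rows.append({
                "community_id": cid,
                "trait": ts.trait_name,
                "overlap": a,
                "community_size": len(cgenes),
                "trait_size": len(tgenes),
                "universe_size": len(universe),
                "odds_ratio": orr,
                "p_value": p,
            })
    table = pd.DataFrame(rows)
    if len(table):
        table["q_value"] = bh_fdr(table["p_value"].to_numpy())
        table["significant"] = table["q_value"] < fdr_level
    return table


def enrich_hierarchy(hierarchy, trait_sets, universe,
                     fdr_level: float = 0.05, haldane: bool = True,
                     include_root: bool = False) -> pd.DataFrame:
    """Enrichment of every hierarchy community (synthetic root excluded
    by default) against the trait gene-sets."""
    comm = {
        c.community_id: c.genes for c in hierarchy.nodes
        if include_root or c.community_id != hierarchy.root
        or c.annotation != "synthetic root"
    }
    if not comm:  # hierarchy collapsed to a single (root) community
        comm = {c.community_id: c.genes for c in hierarchy.nodes}
    return enrich_communities(comm, trait_sets, universe, fdr_level, haldane)


def annotate_communities(hierarchy, term_sets, universe,
                         fdr_level: float = 0.05) -> dict[str, str]:
    """Label each community with its top enriched annotation term.

    The top term is the one with the smallest q-value (ties broken by
    larger overlap, then term name); communities with no significant
    term stay unlabeled.  A manual-override annotation already present
    on a community is preserved.
    """
    table = enrich_hierarchy(hierarchy, term_sets, universe, fdr_level)
    labels: dict[str, str] = {}
    for cid, sub in table.groupby("community_id"):
        sig = sub[sub["significant"]]
        if not len(sig):
            continue
        best = sig.sort_values(
            ["q_value", "overlap", "trait"], ascending=[True, False, True]).iloc[0]
        labels[cid] = str(best["trait"])
    for c in hierarchy.nodes:
        if c.community_id in labels and not c.annotation:
            c.annotation = labels[c.community_id]
    return labels


def or_heatmap(table: pd.DataFrame, ax=None, log2: bool = True):
    """Community x trait odds-ratio heatmap (significant cells outlined)."""
    import matplotlib.pyplot as plt

    wide = table.pivot(index="community_id", columns="trait", values="odds_ratio")
    vals = np.log2(wide.to_numpy(dtype=float)) if log2 else wide.to_numpy(dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.6 * wide.shape[1], 1 + 0.4 * wide.shape[0]))
    lim = np.nanmax(np.abs(vals)) if np.isfinite(vals).any() else 1.0
    im = ax.imshow(vals, cmap="RdBu_r", vmin=-lim, vmax=lim, aspect="auto")
    ax.set_xticks(range(wide.shape[1]), wide.columns, rotation=45, ha="right")
    ax.set_yticks(range(wide.shape[0]), wide.index)
    sig = table.pivot(index="community_id", columns="trait", values="significant")
    for i in range(wide.shape[0]):
        for j in range(wide.shape[1]):
            if bool(sig.iloc[i, j]):
                ax.text(j, i, "*", ha="center", va="center")
    ax.figure.colorbar(im, ax=ax, label="log2 odds ratio" if log2 else "odds ratio")
    return ax
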