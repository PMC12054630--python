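"""Anchor-gene correlation screen, cross-species transport, and stress validation.

The discovery route: rank every gene by its Spearman correlation with the
anchor across the selected cells, take the top K, transport the list through
an explicit homolog table into the second species' namespace, intersect with
that species' own top K, and validate the surviving candidates with a
stressed-vs-control rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import NormalizedMatrix, subset_cells, validate_cell_meta


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone-adjusted, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _spearman_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-tailed P from the large-sample t approximation with n-2 df."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0
    return p


def anchor_correlation(
    norm: NormalizedMatrix,
    cells: Sequence[str],
    anchor: str,
    min_cells: int = 50,
    min_frac_expressing: float = 0.01,
) -> pd.DataFrame:
    """Spearman correlation of every gene with the anchor over selected cells.

    Ties get average ranks. Genes with zero variance are recorded with
    undefined (NaN) rho; those plus genes expressed in fewer than
    ``min_frac_expressing`` of cells, plus the anchor itself, are marked
    ineligible and excluded from the 1-based descending-rho ranking.
    Rank ties are broken lexicographically on gene label; the returned table
    is ordered by rank then gene label (ineligible genes last).
    """
    cells = list(cells)
    if len(cells) < min_cells:
        raise ValueError(f"need at least {min_cells} cells, got {len(cells)}")
    col_of = {b: j for j, b in enumerate(norm.barcodes)}
    missing = [b for b in cells if b not in col_of]
    if missing:
        raise KeyError(f"barcode {missing[0]!r} not present in matrix")
    cols = np.array([col_of[b] for b in cells])
    ai = norm.gene_index(anchor)

    x = np.asarray(norm.x[:, cols].todense())
    anchor_vals = x[ai]
    if not np.any(anchor_vals > 0):
        raise ValueError(f"anchor gene {anchor!r} has zero expression in all selected cells")

    n = len(cells)
    frac_expr = (x > 0).mean(axis=1)
    variable = x.std(axis=1) > 0

    ranks = stats.rankdata(x, axis=1)
    r = ranks - ranks.mean(axis=1, keepdims=True)
    anchor_r = r[ai]
    denom = np.sqrt((r**2).sum(axis=1) * (anchor_r**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (r @ anchor_r) / denom
    rho[~variable] = np.nan

    genes = np.array(norm.genes)
    eligible = variable & (frac_expr >= min_frac_expressing)
    eligible[ai] = False

    tbl = pd.DataFrame(
        {
            "gene": genes,
            "rho": rho,
            "p_two_tailed": _spearman_p(rho, n),
            "n_cells": n,
            "frac_expressing": frac_expr,
            "eligible": eligible,
        }
    )
    elig = tbl[tbl["eligible"]].sort_values(
        ["rho", "gene"], ascending=[False, True], kind="stable"
    )
    tbl["rank"] = pd.Series(
        np.arange(1, len(elig) + 1, dtype=float), index=elig.index
    )
    tbl = pd.concat(
        [
            tbl.loc[elig.index],
            tbl[~tbl["eligible"]].sort_values("gene", kind="stable"),
        ]
    ).reset_index(drop=True)
    return tbl


def top_k(table: pd.DataFrame, k: int = 50) -> list[str]:
    """The k highest-rho eligible genes (all if fewer); anchor never included.

    Boundary ties are broken by gene label ascending, so the selection is
    byte-deterministic.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    elig = table[table["eligible"]]
    if len(elig) == 0:
        raise ValueError("no eligible genes in correlation table")
    ordered = elig.sort_values(["rho", "gene"], ascending=[False, True], kind="stable")
    return list(ordered["gene"].head(k))


def map_homologs(
    genes: Sequence[str], table: pd.DataFrame, a_to_b: bool = True
) -> tuple[set[str], int, list[str]]:
    """Transport a gene list across the homolog map (many-to-many expansion).

    Returns (partner set in the target namespace, number of input genes with
    at least one partner, input genes without a partner in input order).
    """
    src, dst = ("gene_a", "gene_b") if a_to_b else ("gene_b", "gene_a")
    partners: dict[str, list[str]] = {}
    for s, d in zip(table[src], table[dst]):
        partners.setdefault(s, []).append(d)
    mapped: set[str] = set()
    unmapped: list[str] = []
    n_mappable = 0
    for g in genes:
        hits = partners.get(g)
        if hits:
            mapped.update(hits)
            n_mappable += 1
        else:
            unmapped.append(g)
    return mapped, n_mappable, unmapped


def conserved_intersection(
    mapped_a_in_b: Iterable[str],
    top_b: Sequence[str],
    rank_a_by_b: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Genes in both the transported A list and species-B's own top list.

    Ordered by species-B rank. ``rank_a_by_b`` optionally supplies, per
    B-space label, the originating species-A rank for the report.
    """
    mapped = set(mapped_a_in_b)
    rows = []
    for b_rank, gene in enumerate(top_b, start=1):
        if gene in mapped:
            rows.append(
                {
                    "gene": gene,
                    "rank_b": b_rank,
                    "rank_a": (rank_a_by_b or {}).get(gene),
                }
            )
    return pd.DataFrame(rows, columns=["gene", "rank_b", "rank_a"])


def exact_ranksum_p(group1: Sequence[float], group2: Sequence[float]) -> float:
    """Two-sided exact rank-sum p by full enumeration of group assignments.

    Statistic: sum of (tie-averaged) pooled ranks in group 1. p is the
    fraction of the C(n1+n2, n1) assignments whose statistic deviates from
    its null mean at least as much as observed.
    """
    from itertools import combinations

    g1 = list(map(float, group1))
    g2 = list(map(float, group2))
    pooled = np.array(g1 + g2)
    ranks = stats.rankdata(pooled)
    n1, n = len(g1), len(pooled)
    w_obs = ranks[:n1].sum()
    mean_w = n1 * (n + 1) / 2.0
    dev_obs = abs(w_obs - mean_w)
    count = 0
    total = comb(n, n1)
    for combo in combinations(range(n), n1):
        w = ranks[list(combo)].sum()
        if abs(w - mean_w) >= dev_obs - 1e-12:
            count += 1
    return count / total


def _ranksum_p(group1: np.ndarray, group2: np.ndarray, exact_max: int = 7) -> float:
    if len(group1) <= exact_max and len(group2) <= exact_max:
        return exact_ranksum_p(group1, group2)
    # normal approximation with tie correction, no continuity correction
    res = stats.mannwhitneyu(
        group1, group2, alternative="two-sided", method="asymptotic",
        use_continuity=False,
    )
    return float(res.pvalue)


@dataclass
class StressDeParams:
    cell_type: str = "CM"
    pseudocount: float = 1e-9
    exact_max_group: int = 7
    min_group: int = 3


def stress_de(
    norm: NormalizedMatrix,
    meta: pd.DataFrame,
    genes: Sequence[str],
    params: StressDeParams | None = None,
) -> pd.DataFrame:
    """Stressed-vs-control differential expression for a candidate gene list.

    Two-sided Wilcoxon rank-sum on normalized values within the target cell
    type (exact enumeration when both groups are small, normal approximation
    with tie correction otherwise), log2 fold change of group means with a
    small pseudocount, and BH adjustment across exactly the supplied list.
    """
    params = params or StressDeParams()
    validate_cell_meta(meta)
    stressed_bc = subset_cells(meta, params.cell_type, condition="stressed")
    control_bc = subset_cells(meta, params.cell_type, condition="control")
    if len(stressed_bc) < params.min_group or len(control_bc) < params.min_group:
        raise ValueError(
            f"need >= {params.min_group} cells per condition in {params.cell_type}; "
            f"got {len(control_bc)} control, {len(stressed_bc)} stressed"
        )
    col_of = {b: j for j, b in enumerate(norm.barcodes)}
    s_cols = [col_of[b] for b in stressed_bc]
    c_cols = [col_of[b] for b in control_bc]

    rows = []
    for gene in genes:
        gi = norm.gene_index(gene)
        vec = np.asarray(norm.x[gi].todense()).ravel()
        sv, cv = vec[s_cols], vec[c_cols]
        pc = params.pseudocount
        lfc = float(np.log2((sv.mean() + pc) / (cv.mean() + pc)))
        p = _ranksum_p(sv, cv, exact_max=params.exact_max_group)
        rows.append({"gene": gene, "log2fc": lfc, "p": p})
    tbl = pd.DataFrame(rows)
    tbl["q"] = bh_adjust(tbl["p"].to_numpy())
    return tbl


def discover_conserved(
    corr_a: pd.DataFrame,
    corr_b: pd.DataFrame,
    homologs: pd.DataFrame,
    k: int = 50,
) -> pd.DataFrame:
    """Full Fig-style pipeline step: top-K in A, transport, intersect with top-K in B."""
    top_a = top_k(corr_a, k)
    top_b = top_k(corr_b, k)
    mapped, _, _ = map_homologs(top_a, homologs, a_to_b=True)
    rank_a = {}
    partners: dict[str, list[str]] = {}
    for a, b in zip(homologs["gene_a"], homologs["gene_b"]):
        partners.setdefault(a, []).append(b)
    for a_rank, g in enumerate(top_a, start=1):
        for b in partners.get(g, []):
            rank_a.setdefault(b, a_rank)
    return conserved_intersection(mapped, top_b, rank_a_by_b=rank_a)
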