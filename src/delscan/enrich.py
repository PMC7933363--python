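"""Hypergeometric over-representation of gene sets with BH-FDR control.

Given a query gene list (here, the deletion gene catalog), each annotated
gene set is tested one-sidedly for over-representation against a background
of protein-coding genes with the hypergeometric tail P(X >= k); p-values are
adjusted with the Benjamini-Hochberg step-up within each database, and
significance is declared on adjusted q < alpha (default 0.05).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import GeneSet

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "hypergeom_sf", "bh_adjust", "enrich", "enrich_databases"]


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    database: str
    k: int  # query genes in the set
    K: int  # set size within background
    n: int  # query size within background
    N: int  # background size
    p_value: float
    q_value: float
    significant: bool


def hypergeom_sf(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the background size, K the number of marked genes, n the draw size
    and k the observed number of marked genes in the draw. Computed via the
    log-space survival function; k = 0 returns 1.0 exactly and k beyond
    min(K, n) returns 0.0.
    """
    if not (0 <= K <= N and 0 <= n <= N and k >= 0):
        raise ValueError(f"invalid hypergeometric parameters k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    if k > min(K, n):
        return 0.0
    # scipy's sf(k) is P(X > k); shift by one for the inclusive tail
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return [float(q) for q in stats.false_discovery_control(p, method="bh")]


def enrich(
    query_genes: Iterable[str],
    gene_sets: Mapping[str, GeneSet],
    background: Iterable[str],
    alpha: float = 0.05,
    database: str = "",
) -> list[EnrichmentResult]:
    """Test every gene set of one database for over-representation.

    Query genes outside the background are dropped with a warning; gene sets
    are intersected with the background and sets that become empty are not
    tested. Results are sorted by (q, p, set name).
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background gene set")
    query = set(query_genes)
    outside = query - bg
    if outside:
        logger.warning(
            "%d query genes outside background dropped (e.g. %s)",
            len(outside),
            sorted(outside)[:3],
        )
    query &= bg
    N, n = len(bg), len(query)

    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name].genes) & bg
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        rows.append((name, k, K))
    p_values = [hypergeom_sf(k, K, n, N) for _, k, K in rows]
    q_values = bh_adjust(p_values)
    results = [
        EnrichmentResult(
            set_name=name,
            database=database,
            k=k,
            K=K,
            n=n,
            N=N,
            p_value=p,
            q_value=q,
            significant=q < alpha,
        )
        for (name, k, K), p, q in zip(rows, p_values, q_values)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.set_name))
    return results


def enrich_databases(
    query_genes: Iterable[str],
    databases: Mapping[str, Mapping[str, GeneSet]],
    background: Iterable[str],
    alpha: float = 0.05,
    pooled: bool = False,
) -> list[EnrichmentResult]:
    """Run :func:`enrich` per database, adjusting within each by default.

    With ``pooled=True`` the BH adjustment runs once across all databases.
    """
    if not pooled:
        out: list[EnrichmentResult] = []
        for db in sorted(databases):
            out.extend(enrich(query_genes, databases[db], background, alpha, db))
        return out
    merged: dict[str, GeneSet] = {}
    db_of: dict[str, str] = {}
    for db in sorted(databases):
        for name, gs in databases[db].items():
            key = f"{db}::{name}"
            merged[key] = GeneSet(key, gs.description, gs.genes)
            db_of[key] = db
    results = enrich(query_genes, merged, background, alpha, "pooled")
    return [
        EnrichmentResult(
            r.set_name.split("::", 1)[1],
            db_of[r.set_name],
            r.k, r.K, r.n, r.N, r.p_value, r.q_value, r.significant,
        )
        for r in results
    ]
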