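"""Score-matrix clustering and hypergeometric term enrichment.

Gene groups come from agglomerative hierarchical clustering (Euclidean
distance, Ward linkage) of the genes x tumor-types score matrix; each
group is then tested for over-representation of annotation terms with
the hypergeometric upper tail and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .io import ValidationError

logger = logging.getLogger("surfscore")

__all__ = [
    "cluster_genes",
    "hypergeom_tail",
    "bh_adjust",
    "enrich",
]


def cluster_genes(s_matrix: pd.DataFrame, n_clusters: int = 3) -> pd.Series:
    """Cut a Ward-linkage tree of the gene x tumor-type score matrix.

    Missing scores are imputed as 0 (logged).  Returns a Series mapping
    gene -> cluster label in 1..n_clusters.
    """
    if n_clusters > len(s_matrix):
        raise ValidationError(
            f"cluster_genes: n_clusters={n_clusters} > n_genes={len(s_matrix)}"
        )
    if n_clusters < 1:
        raise ValidationError("cluster_genes: n_clusters must be >= 1")
    X = s_matrix.to_numpy(dtype=float)
    n_missing = int(np.isnan(X).sum())
    if n_missing:
        logger.info("cluster_genes: imputing %d missing scores as 0", n_missing)
        X = np.nan_to_num(X, nan=0.0)
    if len(s_matrix) == 1:
        return pd.Series([1], index=s_matrix.index, name="cluster")
    Z = linkage(X, method="ward")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=s_matrix.index, name="cluster")


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k].

    X counts annotated genes in a size-n draw from a universe of N genes
    of which K carry the term.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"hypergeom_tail: invalid (N={N}, K={K}, n={n})")
    if not (0 <= k <= min(n, K)):
        raise ValidationError(f"hypergeom_tail: k={k} outside [0, min(n, K)]")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    adj_(i) = min(1, cummin_{j >= i} m * p_(j) / j) mapped back to the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust: expected a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValidationError("bh_adjust: p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def enrich(
    query_genes: Iterable[str],
    term_map: Mapping[str, set[str]],
    universe: Iterable[str],
    cutoff: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric term enrichment of a query set against a universe.

    Every query gene must belong to the universe.  Terms are restricted
    to their universe members; terms with no universe member are
    skipped.  Returns one row per tested term with columns (term_id, k,
    n, K, N, gene_ratio, p, p_adj, kept) sorted by ascending p; ``kept``
    flags p_adj < cutoff.
    """
    query = set(query_genes)
    universe = set(universe)
    offenders = sorted(query - universe)
    if offenders:
        raise ValidationError(f"enrich: query genes outside universe: {offenders}")
    N, n = len(universe), len(query)
    rows = []
    for term in sorted(term_map):
        members = term_map[term] & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        p = hypergeom_tail(N, K, n, k)
        rows.append((term, k, n, K, N, (k / n if n else 0.0), p))
    df = pd.DataFrame(
        rows, columns=["term_id", "k", "n", "K", "N", "gene_ratio", "p"]
    )
    if df.empty:
        df["p_adj"] = pd.Series(dtype=float)
        df["kept"] = pd.Series(dtype=bool)
        return df
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    df["kept"] = df["p_adj"] < cutoff
    return df.sort_values(["p", "term_id"], ignore_index=True)
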