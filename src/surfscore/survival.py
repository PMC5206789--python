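"""Kaplan-Meier estimation, log-rank testing, and signature search.

All statistics here are implemented from first principles (no survival
library), because these primitives are the measurement instrument of the
whole pipeline and must be verifiable against independent oracles.

Kaplan-Meier product-limit estimator
    Shat(t) = prod_{t_j <= t} (1 - d_j / n_j)
    over distinct event times t_j with d_j events and n_j subjects at
    risk (subjects censored exactly at t_j remain at risk for t_j:
    events precede censoring at ties).

Two-group log-rank test
    O1 = sum_j d1j                       observed events in group 1
    E1 = sum_j n1j * d_j / n_j           expected under the null
    V  = sum_j d_j (n1j/n_j)(n2j/n_j)(n_j - d_j)/(n_j - 1)
         (strata with n_j == 1 are skipped)
    chi2 = (O1 - E1)^2 / V,  p = upper tail of chi-square, 1 df.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .alteration import AlterationMatrix
from .enrichment import bh_adjust
from .io import ValidationError

logger = logging.getLogger("surfscore")

__all__ = [
    "KMCurve",
    "LogRankResult",
    "ScreenResult",
    "km_estimate",
    "logrank_test",
    "gene_screen",
    "combination_search",
]


@dataclass
class KMCurve:
    """Product-limit estimate at the distinct event times."""

    times: np.ndarray  # distinct event times, ascending
    n_risk: np.ndarray  # subjects at risk just before each event time
    n_event: np.ndarray  # events at each event time
    survival: np.ndarray  # Shat at each event time

    def at(self, t: float) -> float:
        """Step-function value of Shat at time ``t`` (Shat(0) = 1)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self, n_total: int | None = None) -> pd.DataFrame:
        """Curve as a table, with a leading t=0 row when the cohort size is known."""
        df = pd.DataFrame(
            {
                "time": self.times,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
                "survival": self.survival,
            }
        )
        if n_total is not None:
            head = pd.DataFrame(
                {"time": [0.0], "n_risk": [n_total], "n_event": [0], "survival": [1.0]}
            )
            df = pd.concat([head, df], ignore_index=True)
        return df


@dataclass
class LogRankResult:
    observed: float  # O1
    expected: float  # E1
    variance: float  # V
    chi2: float
    p: float


def _as_time_event(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    if t.size == 0:
        raise ValidationError("survival: empty input")
    if t.shape != e.shape:
        raise ValidationError("survival: times and events differ in length")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValidationError("survival: times must be finite and >= 0")
    return t, e


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimate from follow-up times and event flags."""
    t, e = _as_time_event(times, events)
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order].astype(int)
    n = ts.size
    change = np.ones(n, dtype=bool)
    change[1:] = ts[1:] != ts[:-1]
    starts = np.flatnonzero(change)
    d = np.add.reduceat(es, starts)
    n_risk = n - starts
    keep = d > 0
    d, n_risk, tj = d[keep], n_risk[keep], ts[starts][keep]
    surv = np.cumprod(1.0 - d / n_risk)
    return KMCurve(times=tj, n_risk=n_risk, n_event=d, survival=surv)


@dataclass
class _Cohort:
    """Pre-sorted cohort enabling O(n) log-rank for many group masks."""

    order: np.ndarray  # sort permutation of the input
    times: np.ndarray  # sorted times
    events: np.ndarray  # 0/1 ints, sorted order
    starts: np.ndarray  # start index of each distinct time
    d: np.ndarray  # total events at each distinct time
    n_risk: np.ndarray  # total at risk at each distinct time


def _prepare(times: np.ndarray, events: np.ndarray) -> _Cohort:
    order = np.argsort(times, kind="stable")
    ts = times[order]
    es = events[order].astype(np.int64)
    n = ts.size
    change = np.ones(n, dtype=bool)
    change[1:] = ts[1:] != ts[:-1]
    starts = np.flatnonzero(change)
    d = np.add.reduceat(es, starts)
    return _Cohort(order=order, times=ts, events=es, starts=starts, d=d, n_risk=n - starts)


def _logrank_sorted(cohort: _Cohort, g_sorted: np.ndarray) -> LogRankResult:
    """Log-rank statistic for a 0/1 group vector already in sorted order."""
    total_g = int(g_sorted.sum())
    cum = np.concatenate(([0], np.cumsum(g_sorted)))
    n1 = total_g - cum[cohort.starts]  # group-1 at risk at each distinct time
    d1 = np.add.reduceat(cohort.events * g_sorted, cohort.starts)

    ev = cohort.d > 0
    d, n, n1e, d1e = cohort.d[ev], cohort.n_risk[ev], n1[ev], d1[ev]
    o1 = float(d1e.sum())
    e1 = float((n1e * d / n).sum())
    big = n > 1
    frac1 = n1e[big] / n[big]
    v = float(
        (d[big] * frac1 * (1.0 - frac1) * (n[big] - d[big]) / (n[big] - 1.0)).sum()
    )
    if v <= 0:
        if d.sum() == 0:
            warnings.warn("logrank: zero events in both groups; p = 1", stacklevel=3)
        chi2 = 0.0
        p = 1.0
    else:
        chi2 = (o1 - e1) ** 2 / v
        p = float(stats.chi2.sf(chi2, df=1))
        p = max(p, np.finfo(float).tiny)
    return LogRankResult(observed=o1, expected=e1, variance=v, chi2=chi2, p=p)


def logrank_test(groups, times, events) -> LogRankResult:
    """Two-group log-rank test.

    ``groups`` is a boolean (or 0/1) vector marking membership in group
    1; both groups must be nonempty.  Swapping the labels leaves the
    statistic and p-value unchanged.
    """
    t, e = _as_time_event(times, events)
    g = np.asarray(groups).astype(bool)
    if g.shape != t.shape:
        raise ValidationError("logrank_test: groups and times differ in length")
    if g.all() or not g.any():
        raise ValidationError("logrank_test: both groups must be nonempty")
    cohort = _prepare(t, e)
    return _logrank_sorted(cohort, g[cohort.order].astype(np.int64))


@dataclass
class ScreenResult:
    """Outcome of the per-gene survival screen."""

    table: pd.DataFrame  # gene_id, n_altered, chi2, p, p_adj, kept, reason
    selected: list[str]  # up to top_k kept genes, ascending p


def _align(matrix: AlterationMatrix, clinical: pd.DataFrame):
    clin = clinical[clinical["sample_id"].isin(matrix.samples)]
    if len(clin) < len(clinical):
        logger.info(
            "survival: dropping %d clinical samples absent from the alteration matrix",
            len(clinical) - len(clin),
        )
    samples = clin["sample_id"].tolist()
    times = clin["os_time_days"].to_numpy(dtype=float)
    events = clin["os_event"].to_numpy(dtype=int)
    alt = matrix.values[samples].to_numpy()
    return samples, times, events, alt


def gene_screen(
    genes: list[str],
    matrix: AlterationMatrix,
    clinical: pd.DataFrame,
    alpha: float = 0.05,
    top_k: int = 20,
) -> ScreenResult:
    """Per-gene altered-vs-unaltered log-rank screen.

    Genes with a degenerate split (all or no samples altered) are
    skipped with a logged reason.  Raw p-values drive selection (BH
    values are reported alongside); genes with identical altered-sample
    sets are redundant and collapse to the lexicographically first
    symbol.  Up to ``top_k`` genes with p < alpha are returned, ordered
    by ascending p with lexicographic tie-breaks.
    """
    genes = sorted(set(genes))
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        raise ValidationError(f"gene_screen: genes not in alteration matrix: {missing}")
    samples, times, events, alt_full = _align(matrix, clinical)
    if not samples:
        raise ValidationError("gene_screen: no samples shared with the clinical table")
    cohort = _prepare(times, np.asarray(events))
    gene_rows = {g: i for i, g in enumerate(matrix.genes)}

    rows = []
    masks: dict[str, bytes] = {}
    for gene in genes:
        mask = alt_full[gene_rows[gene]]
        n_alt = int(mask.sum())
        if n_alt == 0 or n_alt == len(samples):
            logger.info("gene_screen: skipping %s (degenerate split, %d altered)", gene, n_alt)
            rows.append((gene, n_alt, np.nan, np.nan, False, "degenerate_split"))
            continue
        res = _logrank_sorted(cohort, mask[cohort.order].astype(np.int64))
        masks[gene] = mask.tobytes()
        rows.append((gene, n_alt, res.chi2, res.p, True, ""))

    table = pd.DataFrame(
        rows, columns=["gene_id", "n_altered", "chi2", "p", "tested", "reason"]
    )
    tested = table["tested"].to_numpy()
    p_adj = np.full(len(table), np.nan)
    if tested.any():
        p_adj[tested] = bh_adjust(table.loc[tested, "p"].to_numpy())
    table["p_adj"] = p_adj

    # redundancy: identical altered-sample sets -> keep first symbol
    first_of_mask: dict[bytes, str] = {}
    for gene in table.loc[tested, "gene_id"]:
        first_of_mask.setdefault(masks[gene], gene)

    kept, reasons = [], []
    for gene, is_tested, p, reason in zip(
        table["gene_id"], tested, table["p"], table["reason"]
    ):
        if not is_tested:
            kept.append(False)
            reasons.append(reason)
        elif not (p < alpha):
            kept.append(False)
            reasons.append("p_above_alpha")
        elif first_of_mask[masks[gene]] != gene:
            kept.append(False)
            reasons.append(f"redundant_with:{first_of_mask[masks[gene]]}")
        else:
            kept.append(True)
            reasons.append("")
    table["kept"] = kept
    table["reason"] = reasons

    selected = (
        table[table["kept"]]
        .sort_values(["p", "gene_id"], ignore_index=True)
        .head(top_k)["gene_id"]
        .tolist()
    )
    table = table[
        ["gene_id", "n_altered", "chi2", "p", "p_adj", "kept", "reason"]
    ]
    return ScreenResult(table=table, selected=selected)


def combination_search(
    screened_genes: list[str],
    matrix: AlterationMatrix,
    clinical: pd.DataFrame,
    k: int = 3,
) -> pd.DataFrame:
    """Exhaustive log-rank over every k-subset of the screened genes.

    A sample counts as altered for a subset when any member gene is
    altered (OR semantics).  Evaluates exactly C(n, k) subsets and
    returns them ranked by ascending p with lexicographic tie-breaks;
    subsets with a degenerate altered/unaltered split get chi2 = 0 and
    p = 1.
    """
    genes = sorted(set(screened_genes))
    if len(genes) < k:
        raise ValidationError(
            f"combination_search: need >= {k} genes, got {len(genes)}"
        )
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        raise ValidationError(f"combination_search: genes not in matrix: {missing}")
    samples, times, events, alt_full = _align(matrix, clinical)
    cohort = _prepare(times, np.asarray(events))
    gene_rows = {g: i for i, g in enumerate(matrix.genes)}
    # gene x sample bool matrix, pre-permuted into cohort sort order
    alt_sorted = alt_full[[gene_rows[g] for g in genes]][:, cohort.order]

    rows = []
    for combo in combinations(range(len(genes)), k):
        g = alt_sorted[combo[0]].copy()
        for idx in combo[1:]:
            g |= alt_sorted[idx]
        n_alt = int(g.sum())
        if n_alt == 0 or n_alt == g.size:
            chi2, p = 0.0, 1.0
        else:
            res = _logrank_sorted(cohort, g.astype(np.int64))
            chi2, p = res.chi2, res.p
        rows.append(tuple(genes[i] for i in combo) + (n_alt, chi2, p))

    cols = [f"gene{i + 1}" for i in range(k)] + ["n_altered", "chi2", "p"]
    df = pd.DataFrame(rows, columns=cols)
    df = df.sort_values(["p"] + cols[:k], ignore_index=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
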