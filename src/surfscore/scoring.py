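"""Integrative per-gene, per-tumor-type cancer scoring.

Each (gene, sample) pair contributes a three-level evidence value:

* oncogene-like signals: high-level amplification (copy-number call +2)
  or over-expression (z above the high cutoff);
* suppressor-like signals: deep deletion (-2), under-expression (z below
  the low cutoff), or at least one deleterious mutation
  (nonsense / frameshift / splice-site);
* evidence ``e = sign(#oncogene_signals - #suppressor_signals)``.

The gene's score over a cohort of N samples is

    S = 100 * sum_i e(g, i) / N,

a percent-like net alteration frequency bounded in [-100, 100]; positive
scores indicate oncogene-like alteration patterns, negative scores
suppressor-like ones.  Scores are standardized to z-scores against the
distribution of all scored genes within one tumor type, and genes are
called at a z threshold (inclusive at the main threshold by default).

All signal definitions and cutoffs live in :class:`ScoringConfig` so the
evidence formula can be swapped without touching callers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DELETERIOUS_CLASSES, Omics, ValidationError

logger = logging.getLogger("surfscore")

__all__ = [
    "ScoringConfig",
    "per_sample_evidence",
    "evidence_matrix",
    "s_score",
    "s_score_table",
    "standardize",
    "classify_cancer_genes",
    "score_tumor_type",
    "pan_cancer_union",
]


@dataclass(frozen=True)
class ScoringConfig:
    """Signal definitions feeding the evidence value."""

    cna_amplified: int = 2
    cna_deleted: int = -2
    expr_high: float = 2.0
    expr_low: float = -2.0
    deleterious_classes: frozenset[str] = frozenset(DELETERIOUS_CLASSES)
    #: when true, missense mutations count as an oncogene-like signal
    missense_oncogenic: bool = False


def _deleterious_mask(
    mutations: pd.DataFrame | None,
    genes: list[str],
    samples: list[str],
    classes: frozenset[str],
) -> pd.DataFrame:
    """Boolean gene x sample matrix: has >=1 mutation of the given classes."""
    out = pd.DataFrame(False, index=genes, columns=samples)
    if mutations is None or mutations.empty:
        return out
    hit = mutations[mutations["variant_class"].isin(classes)]
    hit = hit[hit["gene_id"].isin(out.index) & hit["sample_id"].isin(out.columns)]
    for gene, sample in zip(hit["gene_id"], hit["sample_id"]):
        out.at[gene, sample] = True
    return out


def _layer(
    matrix: pd.DataFrame | None, genes: list[str], samples: list[str], fill: float
) -> pd.DataFrame:
    """Align a gene x sample layer onto (genes, samples), filling gaps."""
    if matrix is None:
        return pd.DataFrame(fill, index=genes, columns=samples)
    missing = [g for g in genes if g not in matrix.index]
    if missing:
        logger.info("scoring: %d genes missing from a matrix layer (no signal)", len(missing))
    return matrix.reindex(index=genes, columns=samples).fillna(fill)


def evidence_matrix(
    genes: list[str], omics: Omics, cfg: ScoringConfig = ScoringConfig()
) -> pd.DataFrame:
    """Vectorized evidence values for all (gene, sample) pairs.

    Returns an int8 gene x sample DataFrame with values in {-1, 0, +1}.
    """
    samples = list(omics.samples)
    cna = _layer(omics.cna, genes, samples, 0).to_numpy()
    expr = _layer(omics.expr, genes, samples, 0.0).to_numpy()
    delmut = _deleterious_mask(
        omics.mutations, genes, samples, cfg.deleterious_classes
    ).to_numpy()

    onc = (cna == cfg.cna_amplified).astype(int) + (expr > cfg.expr_high).astype(int)
    if cfg.missense_oncogenic:
        missense = _deleterious_mask(
            omics.mutations, genes, samples, frozenset({"missense"})
        ).to_numpy()
        onc += missense.astype(int)
    sup = (
        (cna == cfg.cna_deleted).astype(int)
        + (expr < cfg.expr_low).astype(int)
        + delmut.astype(int)
    )
    e = np.sign(onc - sup).astype(np.int8)
    return pd.DataFrame(e, index=genes, columns=samples)


def per_sample_evidence(
    gene: str, sample: str, omics: Omics, cfg: ScoringConfig = ScoringConfig()
) -> int:
    """Evidence value for a single (gene, sample) pair; in {-1, 0, +1}."""
    if sample not in omics.samples:
        raise ValidationError(f"sample {sample!r} not in the reconciled sample set")
    onc = 0
    sup = 0
    if omics.cna is not None and gene in omics.cna.index:
        v = int(omics.cna.at[gene, sample])
        onc += v == cfg.cna_amplified
        sup += v == cfg.cna_deleted
    if omics.expr is not None and gene in omics.expr.index:
        z = float(omics.expr.at[gene, sample])
        onc += z > cfg.expr_high
        sup += z < cfg.expr_low
    if omics.mutations is not None and not omics.mutations.empty:
        m = omics.mutations
        classes = set(
            m.loc[(m["gene_id"] == gene) & (m["sample_id"] == sample), "variant_class"]
        )
        sup += bool(classes & cfg.deleterious_classes)
        if cfg.missense_oncogenic:
            onc += "missense" in classes
    return int(np.sign(onc - sup))


def s_score(evidence: pd.Series | np.ndarray) -> float:
    """Score one gene from its per-sample evidence vector.

    ``S = 100 * sum(e) / N``; errors on an empty cohort.
    """
    e = np.asarray(evidence)
    if e.size == 0:
        raise ValidationError("s_score: empty cohort")
    return 100.0 * float(e.sum()) / e.size


def s_score_table(
    genes: list[str], omics: Omics, cfg: ScoringConfig = ScoringConfig()
) -> pd.Series:
    """S-scores for all genes over the cohort (index = gene)."""
    if not omics.samples:
        raise ValidationError("s_score_table: no samples after reconciliation")
    ev = evidence_matrix(genes, omics, cfg)
    return 100.0 * ev.sum(axis=1) / ev.shape[1]


def standardize(scores: pd.Series) -> pd.Series:
    """Standardize S-scores to z-scores within one tumor type.

    Uses the sample standard deviation (n-1 denominator); requires at
    least two genes and nonzero variance.
    """
    if len(scores) < 2:
        raise ValidationError("standardize: need >= 2 genes")
    sd = float(scores.std(ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise ValidationError("standardize: zero variance in S-scores")
    return (scores - scores.mean()) / sd


def classify_cancer_genes(
    z: pd.Series, threshold: float, inclusive: bool = True
) -> pd.Series:
    """Call each gene oncogene / suppressor / none at a z threshold.

    ``inclusive`` controls whether the boundary |z| == threshold is
    called (the main-threshold convention); the relaxed threshold is
    conventionally strict.
    """
    if threshold <= 0:
        raise ValidationError("classify_cancer_genes: threshold must be > 0")
    zv = z.to_numpy(dtype=float)
    if inclusive:
        onc, sup = zv >= threshold, zv <= -threshold
    else:
        onc, sup = zv > threshold, zv < -threshold
    out = np.where(onc, "oncogene", np.where(sup, "suppressor", "none"))
    return pd.Series(out, index=z.index, name="class")


def score_tumor_type(
    genes: list[str],
    omics: Omics,
    tumor_type: str,
    cfg: ScoringConfig = ScoringConfig(),
    threshold: float = 3.0,
    inclusive: bool = True,
) -> pd.DataFrame:
    """Full scoring pass for one tumor type.

    Returns a DataFrame (gene_id, tumor_type, S, z, class) sorted by
    gene.
    """
    s = s_score_table(genes, omics, cfg)
    z = standardize(s)
    cls = classify_cancer_genes(z, threshold, inclusive)
    return pd.DataFrame(
        {
            "gene_id": s.index,
            "tumor_type": tumor_type,
            "S": s.to_numpy(),
            "z": z.to_numpy(),
            "class": cls.to_numpy(),
        }
    ).sort_values("gene_id", ignore_index=True)


def pan_cancer_union(tables: dict[str, pd.DataFrame]) -> list[str]:
    """Genes classified as a cancer gene in at least one tumor type."""
    union: set[str] = set()
    for df in tables.values():
        union |= set(df.loc[df["class"] != "none", "gene_id"])
    return sorted(union)
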