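"""Sample-level altered/unaltered classification for survival analysis.

A sample is *altered* for a gene when any of five disjuncts holds:
extreme expression in either direction, high-level copy-number change in
either direction, or a deleterious mutation.  Shallow copy-number calls
(+/-1) never trigger under the default config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DELETERIOUS_CLASSES, Omics, ValidationError
from .scoring import _deleterious_mask, _layer

logger = logging.getLogger("surfscore")

__all__ = [
    "AlterationConfig",
    "AlterationMatrix",
    "REASONS",
    "is_altered",
    "build_alteration_matrix",
    "signature_altered",
    "signature_vector",
]

REASONS = ("expr_up", "expr_down", "amplified", "deleted", "deleterious_mutation")


@dataclass(frozen=True)
class AlterationConfig:
    expr_high: float = 2.0
    expr_low: float = -2.0
    #: GISTIC-style high-level calls only by default
    include_shallow: bool = False
    deleterious_classes: frozenset[str] = frozenset(DELETERIOUS_CLASSES)

    @property
    def amplified_values(self) -> frozenset[int]:
        return frozenset({1, 2}) if self.include_shallow else frozenset({2})

    @property
    def deleted_values(self) -> frozenset[int]:
        return frozenset({-1, -2}) if self.include_shallow else frozenset({-2})


@dataclass
class AlterationMatrix:
    """Boolean gene x sample alteration calls plus per-reason layers."""

    values: pd.DataFrame  # bool, gene x sample
    layers: dict[str, pd.DataFrame]  # reason -> bool gene x sample

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def reasons_for(self, gene: str, sample: str) -> frozenset[str]:
        return frozenset(
            r for r, layer in self.layers.items() if bool(layer.at[gene, sample])
        )

    def altered_counts(self) -> pd.Series:
        """Per-gene number of altered samples."""
        return self.values.sum(axis=1)

    def reasons_frame(self) -> pd.DataFrame:
        """Comma-joined reason codes per cell (empty string = unaltered)."""
        parts = []
        for r in REASONS:
            layer = self.layers[r]
            parts.append(layer.to_numpy())
        arr = np.stack(parts, axis=-1)
        out = np.empty(self.values.shape, dtype=object)
        for i in range(arr.shape[0]):
            for j in range(arr.shape[1]):
                out[i, j] = ",".join(r for r, on in zip(REASONS, arr[i, j]) if on)
        return pd.DataFrame(out, index=self.values.index, columns=self.values.columns)


def is_altered(
    gene: str, sample: str, omics: Omics, cfg: AlterationConfig = AlterationConfig()
) -> tuple[bool, frozenset[str]]:
    """Classify one (gene, sample) pair; returns (altered, reasons)."""
    if sample not in omics.samples:
        raise ValidationError(f"sample {sample!r} not in the reconciled sample set")
    reasons = set()
    if omics.expr is not None and gene in omics.expr.index:
        z = float(omics.expr.at[gene, sample])
        if z > cfg.expr_high:
            reasons.add("expr_up")
        if z < cfg.expr_low:
            reasons.add("expr_down")
    if omics.cna is not None and gene in omics.cna.index:
        v = int(omics.cna.at[gene, sample])
        if v in cfg.amplified_values:
            reasons.add("amplified")
        if v in cfg.deleted_values:
            reasons.add("deleted")
    if omics.mutations is not None and not omics.mutations.empty:
        m = omics.mutations
        classes = set(
            m.loc[(m["gene_id"] == gene) & (m["sample_id"] == sample), "variant_class"]
        )
        if classes & cfg.deleterious_classes:
            reasons.add("deleterious_mutation")
    return bool(reasons), frozenset(reasons)


def build_alteration_matrix(
    genes: list[str], omics: Omics, cfg: AlterationConfig = AlterationConfig()
) -> AlterationMatrix:
    """Vectorized alteration calls for a gene list over the cohort."""
    samples = list(omics.samples)
    if not samples:
        raise ValidationError("build_alteration_matrix: no samples")
    expr = _layer(omics.expr, genes, samples, 0.0).to_numpy()
    cna = _layer(omics.cna, genes, samples, 0).to_numpy()
    delmut = _deleterious_mask(
        omics.mutations, genes, samples, cfg.deleterious_classes
    ).to_numpy()

    amp = np.isin(cna, list(cfg.amplified_values))
    dele = np.isin(cna, list(cfg.deleted_values))
    layers = {
        "expr_up": expr > cfg.expr_high,
        "expr_down": expr < cfg.expr_low,
        "amplified": amp,
        "deleted": dele,
        "deleterious_mutation": delmut,
    }
    values = np.zeros(expr.shape, dtype=bool)
    for layer in layers.values():
        values |= layer
    return AlterationMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        layers={
            r: pd.DataFrame(v, index=genes, columns=samples) for r, v in layers.items()
        },
    )


def signature_vector(gene_set: list[str], matrix: AlterationMatrix) -> pd.Series:
    """Per-sample OR over the gene set's alteration rows."""
    missing = [g for g in gene_set if g not in matrix.values.index]
    if missing:
        raise ValidationError(f"signature genes not in alteration matrix: {missing}")
    if not gene_set:
        raise ValidationError("signature_vector: empty gene set")
    return matrix.values.loc[list(gene_set)].any(axis=0)


def signature_altered(gene_set: list[str], sample: str, matrix: AlterationMatrix) -> bool:
    """True iff at least one gene in the set is altered in the sample."""
    return bool(signature_vector(gene_set, matrix)[sample])
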