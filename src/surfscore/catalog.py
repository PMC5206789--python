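"""Cell-surface gene catalog: membership rules and benchmark metrics.

A protein isoform is a *surface candidate* when it carries at least one
transmembrane (TM) helix that cannot be explained away as a signal
peptide.  A gene enters the catalog when at least one of its isoforms is
a candidate and its annotated subcellular compartments are not
*exclusively* internal.

Rule order per isoform (first match wins):

R1  zero TM segments                      -> ``no_tm``
R2  exactly one TM segment ending within the first 50 residues
    (configurable window/anchor)          -> ``secreted``
R3  signal peptide predicted, exactly one TM segment, and that segment
    lies within the signal peptide
    (segment end <= cleavage position)    -> ``secreted``
otherwise                                 -> ``pass`` (surface candidate)

Gene-level rule:

R4  if any isoform passed: the gene is ``internal_compartment`` when its
    compartment set is nonempty and entirely contained in the exclusion
    vocabulary, else ``surfaceome``.  If no isoform passed, the gene
    verdict is the most permissive isoform verdict
    (``secreted`` > ``no_tm``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import ProteinRecord, SignalPeptideCall, ValidationError

__all__ = [
    "DEFAULT_EXCLUSION_VOCABULARY",
    "CatalogConfig",
    "MembershipDecision",
    "CatalogResult",
    "classify_isoform",
    "is_exclusively_internal",
    "classify_gene",
    "build_catalog",
    "family_coverage",
    "set_overlap",
]

#: Compartments whose *exclusive* annotation excludes a gene from the
#: catalog.  ("liposome" is kept verbatim from the source vocabulary.)
DEFAULT_EXCLUSION_VOCABULARY = frozenset(
    {
        "lysosome",
        "endoplasmic reticulum",
        "mitochondria",
        "cytoskeleton",
        "endosome",
        "liposome",
        "nucleolus",
        "nucleus",
        "ribosome",
    }
)

VERDICTS = ("surfaceome", "secreted", "internal_compartment", "no_tm")


@dataclass(frozen=True)
class CatalogConfig:
    """Tunable parameters of the membership rules."""

    #: window (in residues) of rule R2
    r2_window: int = 50
    #: which segment coordinate R2 compares against the window: "end"
    #: (strict reading, default) or "start"
    r2_anchor: str = "end"
    exclusion_vocabulary: frozenset[str] = DEFAULT_EXCLUSION_VOCABULARY

    def __post_init__(self) -> None:
        if self.r2_anchor not in {"end", "start"}:
            raise ValueError(f"r2_anchor must be 'end' or 'start', got {self.r2_anchor!r}")
        if self.r2_window < 1:
            raise ValueError("r2_window must be >= 1")


@dataclass
class MembershipDecision:
    """Gene-level verdict with the rule trace that produced it."""

    gene_id: str
    verdict: str
    reason_trace: list[str]
    isoform_verdicts: dict[str, str] = field(default_factory=dict)


@dataclass
class CatalogResult:
    """Full catalog: the surfaceome set plus per-gene decision records."""

    decisions: dict[str, MembershipDecision]
    surfaceome: set[str]
    counts: dict[str, int]


def classify_isoform(
    protein: ProteinRecord,
    segments: Sequence[tuple[int, int]],
    sp: SignalPeptideCall | None = None,
    cfg: CatalogConfig = CatalogConfig(),
) -> tuple[str, list[str]]:
    """Apply R1-R3 to one isoform.

    Returns ``(verdict, trace)`` with verdict in {"no_tm", "secreted",
    "pass"} and a nonempty trace of the rules evaluated.
    """
    for start, end in segments:
        if not (1 <= start <= end <= protein.length):
            raise ValidationError(
                f"{protein.protein_id}: TM segment ({start},{end}) outside "
                f"1..{protein.length}"
            )
    if not segments:
        return "no_tm", ["R1"]
    if len(segments) == 1:
        start, end = segments[0]
        anchor = end if cfg.r2_anchor == "end" else start
        if anchor <= cfg.r2_window:
            return "secreted", ["R2"]
        if sp is not None and sp.positive and end <= sp.cleavage_pos:
            return "secreted", ["R3"]
    return "pass", ["pass"]


def is_exclusively_internal(
    compartments: Iterable[str], vocabulary: Iterable[str] = DEFAULT_EXCLUSION_VOCABULARY
) -> bool:
    """True iff the compartment set is nonempty and entirely internal."""
    comp = set(compartments)
    return bool(comp) and comp <= set(vocabulary)


def classify_gene(
    gene_id: str,
    isoform_verdicts: Mapping[str, str],
    compartments: Iterable[str] = (),
    exclusion_vocabulary: Iterable[str] = DEFAULT_EXCLUSION_VOCABULARY,
) -> MembershipDecision:
    """Aggregate isoform verdicts and apply the compartment rule R4."""
    if not isoform_verdicts:
        raise ValidationError(f"gene {gene_id!r}: no isoform verdicts")
    bad = set(isoform_verdicts.values()) - {"no_tm", "secreted", "pass"}
    if bad:
        raise ValidationError(f"gene {gene_id!r}: unknown isoform verdicts {bad}")

    verdicts = set(isoform_verdicts.values())
    if "pass" in verdicts:
        if is_exclusively_internal(compartments, exclusion_vocabulary):
            return MembershipDecision(
                gene_id, "internal_compartment", ["R4"], dict(isoform_verdicts)
            )
        return MembershipDecision(
            gene_id, "surfaceome", ["R4:not_exclusive"], dict(isoform_verdicts)
        )
    if "secreted" in verdicts:
        return MembershipDecision(gene_id, "secreted", ["R2/R3"], dict(isoform_verdicts))
    return MembershipDecision(gene_id, "no_tm", ["R1"], dict(isoform_verdicts))


def build_catalog(
    proteins: Sequence[ProteinRecord],
    tm_segments: Mapping[str, Sequence[tuple[int, int]]],
    signalp: Mapping[str, SignalPeptideCall] | Sequence[SignalPeptideCall] | None = None,
    compartments: Mapping[str, set[str]] | None = None,
    cfg: CatalogConfig = CatalogConfig(),
    genes: Sequence[str] | None = None,
) -> CatalogResult:
    """Classify every gene and assemble the surfaceome catalog.

    ``genes``, when given, fixes the gene universe; a listed gene with
    no isoform is an error.  Otherwise the universe is the set of genes
    seen in ``proteins``.
    """
    if signalp is None:
        sp_map: dict[str, SignalPeptideCall] = {}
    elif isinstance(signalp, Mapping):
        sp_map = dict(signalp)
    else:
        sp_map = {c.protein_id: c for c in signalp}
    compartments = compartments or {}

    by_gene: dict[str, list[ProteinRecord]] = {}
    for p in proteins:
        by_gene.setdefault(p.gene_id, []).append(p)

    universe = list(genes) if genes is not None else sorted(by_gene)
    decisions: dict[str, MembershipDecision] = {}
    for gene in universe:
        isoforms = by_gene.get(gene, [])
        if not isoforms:
            raise ValidationError(f"gene {gene!r}: zero isoforms")
        verdicts = {}
        for p in isoforms:
            v, _trace = classify_isoform(
                p, tm_segments.get(p.protein_id, []), sp_map.get(p.protein_id), cfg
            )
            verdicts[p.protein_id] = v
        decisions[gene] = classify_gene(
            gene, verdicts, compartments.get(gene, set()), cfg.exclusion_vocabulary
        )

    counts = {v: 0 for v in VERDICTS}
    for d in decisions.values():
        counts[d.verdict] += 1
    surfaceome = {g for g, d in decisions.items() if d.verdict == "surfaceome"}
    return CatalogResult(decisions=decisions, surfaceome=surfaceome, counts=counts)


def family_coverage(catalog: Iterable[str], family: Iterable[str]) -> float:
    """Fraction of a gene family represented in the catalog."""
    family = set(family)
    if not family:
        raise ValidationError("family_coverage: empty family")
    return len(family & set(catalog)) / len(family)


def set_overlap(
    catalog: Iterable[str], external: Iterable[str]
) -> tuple[int, float, float]:
    """Overlap of the catalog with an external gene set.

    Returns ``(|intersection|, |inter|/|external|, |inter|/|catalog|)``.
    """
    catalog, external = set(catalog), set(external)
    if not catalog or not external:
        raise ValidationError("set_overlap: both sets must be nonempty")
    inter = len(catalog & external)
    return inter, inter / len(external), inter / len(catalog)
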