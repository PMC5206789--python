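"""Readers and writers for every external file the pipeline touches.

All tabular formats are plain TSV with fixed, documented headers; every
parser validates its input strictly and raises :class:`ValidationError`
rather than silently coercing bad values.  Coordinates are 1-based
inclusive residue positions throughout (the convention of the upstream
transmembrane-helix predictor whose output is consumed here).

Formats
-------
protein FASTA
    Header ``>proteinID|geneID`` (separator/regex configurable).
TM segment table
    Either a simplified 3-column TSV ``protein_id  start  end`` or the
    long per-helix output of a TMHMM-style predictor (lines whose
    topology field is ``TMhelix``; other topology lines are skipped).
signal-peptide table
    3-column TSV ``protein_id  YES|NO  cleavage_pos`` (cleavage position
    is the last residue of the signal peptide, empty unless YES).
compartment table
    2-column TSV ``gene_id  compartment``, one row per annotation.
MAF (minimal)
    Tab-separated with at least ``Hugo_Symbol``, ``Tumor_Sample_Barcode``
    and ``Variant_Classification``; classes are normalized to a closed
    vocabulary (unknown classes fall back to ``other`` with a warning).
gene x sample matrices
    TSV with an index column named ``gene_id`` and one column per sample;
    copy-number matrices must hold integers in {-2,-1,0,1,2}.
clinical table
    TSV ``sample_id  os_time_days  os_event``.
term map
    TSV ``term_id  term_name  gene_id``, one row per (term, gene) pair.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("surfscore")

__all__ = [
    "ValidationError",
    "ProteinRecord",
    "SignalPeptideCall",
    "Omics",
    "VARIANT_CLASSES",
    "DELETERIOUS_CLASSES",
    "MAF_CLASS_MAP",
    "parse_fasta",
    "parse_tm_segments",
    "parse_signalp",
    "parse_compartments",
    "parse_maf",
    "parse_matrix",
    "parse_clinical",
    "parse_term_map",
    "parse_gene_list",
    "write_fasta",
    "write_tm_segments",
    "write_signalp",
    "write_compartments",
    "write_maf",
    "write_matrix",
    "write_clinical",
    "write_term_map",
    "reconcile_samples",
]


class ValidationError(ValueError):
    """Raised when an input file or value violates its contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """One protein isoform: identifiers, length, optional sequence."""

    protein_id: str
    gene_id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError(
                f"protein {self.protein_id!r}: length must be >= 1, got {self.length}"
            )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValidationError(
                f"protein {self.protein_id!r}: sequence length "
                f"{len(self.sequence)} != declared length {self.length}"
            )


@dataclass(frozen=True)
class SignalPeptideCall:
    """Signal-peptide prediction for one protein.

    ``cleavage_pos`` is the 1-based index of the last residue of the
    signal peptide and must be present iff ``positive`` is true.
    """

    protein_id: str
    positive: bool
    cleavage_pos: int | None = None

    def __post_init__(self) -> None:
        if self.positive and self.cleavage_pos is None:
            raise ValidationError(
                f"protein {self.protein_id!r}: positive signal-peptide call "
                "requires a cleavage position"
            )
        if not self.positive and self.cleavage_pos is not None:
            raise ValidationError(
                f"protein {self.protein_id!r}: cleavage position given "
                "without a positive signal-peptide call"
            )
        if self.cleavage_pos is not None and self.cleavage_pos < 1:
            raise ValidationError(
                f"protein {self.protein_id!r}: cleavage position must be >= 1"
            )


#: Closed vocabulary of normalized variant classes.
VARIANT_CLASSES = frozenset(
    {"nonsense", "frameshift", "splice_site", "missense", "silent", "other"}
)

#: Variant classes treated as deleterious downstream.
DELETERIOUS_CLASSES = frozenset({"nonsense", "frameshift", "splice_site"})

#: Mapping from MAF ``Variant_Classification`` values to the closed
#: vocabulary.  Normalized class names map to themselves so written
#: tables round-trip.
MAF_CLASS_MAP: dict[str, str] = {
    "Nonsense_Mutation": "nonsense",
    "Frame_Shift_Del": "frameshift",
    "Frame_Shift_Ins": "frameshift",
    "Splice_Site": "splice_site",
    "Missense_Mutation": "missense",
    "Silent": "silent",
    **{c: c for c in VARIANT_CLASSES},
}


@dataclass
class Omics:
    """Bundle of the per-tumor-type omics layers used for scoring.

    Any layer may be ``None``; consumers treat a missing layer as
    contributing no signal.
    """

    mutations: pd.DataFrame | None = None  # sample_id, gene_id, variant_class
    cna: pd.DataFrame | None = None  # gene x sample, int in {-2..2}
    expr: pd.DataFrame | None = None  # gene x sample, float z-scores
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.samples:
            self.samples = _common_samples(self.mutations, self.cna, self.expr)


def _common_samples(
    mutations: pd.DataFrame | None,
    cna: pd.DataFrame | None,
    expr: pd.DataFrame | None,
) -> list[str]:
    sets = []
    if cna is not None:
        sets.append(list(cna.columns))
    if expr is not None:
        sets.append(list(expr.columns))
    if not sets and mutations is not None:
        sets.append(list(pd.unique(mutations["sample_id"])))
    if not sets:
        return []
    common = set(sets[0])
    for s in sets[1:]:
        common &= set(s)
    # keep the order of the first table for determinism
    return [s for s in sets[0] if s in common]


# ---------------------------------------------------------------------------
# Parsers
# ---------------------------------------------------------------------------

_DEFAULT_HEADER_RE = re.compile(r"^(?P<protein_id>[^|\s]+)\|(?P<gene_id>\S+)")


def parse_fasta(path: str | Path, header_regex: str | None = None) -> list[ProteinRecord]:
    """Parse a protein FASTA into :class:`ProteinRecord` objects.

    Headers must match ``proteinID|geneID`` (or ``header_regex`` with
    named groups ``protein_id`` and ``gene_id``).  Empty sequences and
    duplicate protein IDs are hard errors.
    """
    pattern = re.compile(header_regex) if header_regex else _DEFAULT_HEADER_RE
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        m = pattern.match(entry.description)
        if m is None:
            raise ValidationError(
                f"{path}: malformed FASTA header {entry.description!r} "
                f"(expected pattern {pattern.pattern!r})"
            )
        seq = str(entry.seq)
        if not seq:
            raise ValidationError(
                f"{path}: empty sequence for header {entry.description!r}"
            )
        pid = m.group("protein_id")
        if pid in seen:
            raise ValidationError(f"{path}: duplicate protein_id {pid!r}")
        seen.add(pid)
        records.append(
            ProteinRecord(
                protein_id=pid,
                gene_id=m.group("gene_id"),
                length=len(seq),
                sequence=seq,
            )
        )
    return records


def _validate_segments(
    protein_id: str,
    segments: list[tuple[int, int]],
    length: int | None,
) -> list[tuple[int, int]]:
    segments = sorted(segments)
    prev_end = 0
    for start, end in segments:
        if start < 1:
            raise ValidationError(f"{protein_id}: segment start {start} < 1")
        if start > end:
            raise ValidationError(
                f"{protein_id}: segment start {start} > end {end}"
            )
        if start <= prev_end:
            raise ValidationError(
                f"{protein_id}: overlapping TM segments at start {start}"
            )
        if length is not None and end > length:
            raise ValidationError(
                f"{protein_id}: segment end {end} exceeds protein length {length}"
            )
        prev_end = end
    return segments


def parse_tm_segments(
    path: str | Path,
    proteins: Sequence[ProteinRecord] | None = None,
) -> dict[str, list[tuple[int, int]]]:
    """Parse TM helix segments into ``{protein_id: [(start, end), ...]}``.

    Accepts either the simplified 3-column TSV or TMHMM-style long
    format (only lines whose topology field is ``TMhelix`` are read;
    ``inside``/``outside`` lines are skipped).  When ``proteins`` is
    given, every protein gets an entry (possibly empty) and segment
    coordinates are checked against the protein length.
    """
    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) >= 4 and "TMhelix" in fields:
                idx = fields.index("TMhelix")
                if idx + 2 >= len(fields):
                    raise ValidationError(
                        f"{path}:{lineno}: truncated TMhelix line"
                    )
                pid, s, e = fields[0], fields[idx + 1], fields[idx + 2]
            elif len(fields) >= 4:
                # long-format line with another topology label
                continue
            elif len(fields) == 3:
                if fields[1] == "start":  # header row of the simple dialect
                    continue
                pid, s, e = fields
            else:
                raise ValidationError(
                    f"{path}:{lineno}: expected 3 columns or a TMhelix line, "
                    f"got {line!r}"
                )
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: non-integer coordinate in {line!r}"
                ) from exc
            raw.setdefault(pid, []).append((start, end))

    lengths = {p.protein_id: p.length for p in proteins} if proteins else {}
    table: dict[str, list[tuple[int, int]]] = {}
    for pid, segs in raw.items():
        table[pid] = _validate_segments(pid, segs, lengths.get(pid))
    if proteins is not None:
        for p in proteins:
            table.setdefault(p.protein_id, [])
    return table


def parse_signalp(path: str | Path) -> list[SignalPeptideCall]:
    """Parse the 3-column signal-peptide summary TSV."""
    calls: list[SignalPeptideCall] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[:2] == ["protein_id", "signal_peptide"]:
                continue
            if len(fields) < 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected >=2 columns, got {line!r}"
                )
            pid, flag = fields[0], fields[1].strip().upper()
            if flag not in {"YES", "NO"}:
                raise ValidationError(
                    f"{path}:{lineno}: signal-peptide flag must be YES/NO, "
                    f"got {fields[1]!r}"
                )
            if pid in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate protein_id {pid!r}")
            seen.add(pid)
            cleav = fields[2].strip() if len(fields) > 2 else ""
            pos = int(cleav) if cleav else None
            try:
                calls.append(
                    SignalPeptideCall(pid, positive=(flag == "YES"), cleavage_pos=pos)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return calls


def parse_compartments(
    path: str | Path, vocabulary: Iterable[str] | None = None
) -> dict[str, set[str]]:
    """Parse the gene -> compartment annotation TSV into a dict of sets.

    Labels are lower-cased; when ``vocabulary`` is given, labels outside
    it are rejected.
    """
    vocab = {v.lower() for v in vocabulary} if vocabulary is not None else None
    table: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[:2] == ["gene_id", "compartment"]:
                continue
            if len(fields) < 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected 2 columns, got {line!r}"
                )
            gene, label = fields[0], fields[1].strip().lower()
            if not label:
                raise ValidationError(f"{path}:{lineno}: empty compartment label")
            if vocab is not None and label not in vocab:
                raise ValidationError(
                    f"{path}:{lineno}: compartment {label!r} not in vocabulary"
                )
            table.setdefault(gene, set()).add(label)
    return table


def parse_maf(path: str | Path) -> pd.DataFrame:
    """Parse a minimal MAF into columns (sample_id, gene_id, variant_class).

    ``Variant_Classification`` values are normalized through
    :data:`MAF_CLASS_MAP`; unknown classes map to ``other`` and emit a
    warning (the only permitted coercion).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: MAF missing columns {sorted(missing)}")

    classes = df["Variant_Classification"]
    unknown = sorted(set(classes) - set(MAF_CLASS_MAP))
    if unknown:
        warnings.warn(
            f"{path}: unknown variant classes mapped to 'other': {unknown}",
            stacklevel=2,
        )
        logger.warning("%s: unknown variant classes mapped to 'other': %s", path, unknown)
    out = pd.DataFrame(
        {
            "sample_id": df["Tumor_Sample_Barcode"],
            "gene_id": df["Hugo_Symbol"],
            "variant_class": classes.map(lambda c: MAF_CLASS_MAP.get(c, "other")),
        }
    )
    return out.reset_index(drop=True)


def parse_matrix(path: str | Path, kind: str) -> pd.DataFrame:
    """Parse a gene x sample matrix TSV.

    ``kind`` is ``"cna"`` (integers in {-2..2}) or ``"expr"`` (floats).
    """
    if kind not in {"cna", "expr"}:
        raise ValueError(f"kind must be 'cna' or 'expr', got {kind!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    df.columns = [str(c) for c in df.columns]
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene rows {dups}")
    if kind == "cna":
        values = df.to_numpy()
        if not np.all(np.isfinite(values)) or not np.all(values == np.round(values)):
            raise ValidationError(f"{path}: CNA matrix must hold integers")
        bad = set(np.unique(values)) - {-2.0, -1.0, 0.0, 1.0, 2.0}
        if bad:
            raise ValidationError(
                f"{path}: CNA values outside {{-2..2}}: {sorted(bad)}"
            )
        return df.astype(np.int64)
    if not np.all(np.isfinite(df.to_numpy())):
        raise ValidationError(f"{path}: expression matrix holds non-finite values")
    return df.astype(float)


def parse_clinical(path: str | Path) -> pd.DataFrame:
    """Parse the clinical TSV (sample_id, os_time_days, os_event)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "os_time_days", "os_event"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: clinical table missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample_id in clinical table")
    times = df["os_time_days"].to_numpy(dtype=float)
    if not np.all(np.isfinite(times)) or np.any(times < 0):
        raise ValidationError(f"{path}: os_time_days must be finite and >= 0")
    events = df["os_event"].to_numpy()
    if not set(np.unique(events)) <= {0, 1}:
        raise ValidationError(f"{path}: os_event must be 0 or 1")
    out = df[["sample_id", "os_time_days", "os_event"]].copy()
    out["os_time_days"] = out["os_time_days"].astype(float)
    out["os_event"] = out["os_event"].astype(int)
    return out.reset_index(drop=True)


def parse_term_map(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Parse the term map TSV into ``(term -> gene set, term -> name)``."""
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "term_id":
                continue
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: expected 3 columns, got {line!r}"
                )
            term, name, gene = fields[0], fields[1], fields[2]
            terms.setdefault(term, set()).add(gene)
            names.setdefault(term, name)
    return terms, names


def parse_gene_list(path: str | Path) -> set[str]:
    """Parse a one-gene-per-line list (e.g. a family membership file)."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.add(g)
    return genes


# ---------------------------------------------------------------------------
# Writers (each is the exact inverse of its parser)
# ---------------------------------------------------------------------------


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.sequence is None:
                raise ValidationError(
                    f"cannot write protein {rec.protein_id!r} without a sequence"
                )
            fh.write(f">{rec.protein_id}|{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def write_tm_segments(
    table: Mapping[str, Sequence[tuple[int, int]]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tstart\tend\n")
        for pid in sorted(table):
            for start, end in table[pid]:
                fh.write(f"{pid}\t{start}\t{end}\n")


def write_signalp(calls: Sequence[SignalPeptideCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tsignal_peptide\tcleavage_pos\n")
        for call in sorted(calls, key=lambda c: c.protein_id):
            flag = "YES" if call.positive else "NO"
            pos = str(call.cleavage_pos) if call.cleavage_pos is not None else ""
            fh.write(f"{call.protein_id}\t{flag}\t{pos}\n")


def write_compartments(table: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcompartment\n")
        for gene in sorted(table):
            for label in sorted(table[gene]):
                fh.write(f"{gene}\t{label}\n")


def write_maf(mutations: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "Hugo_Symbol": mutations["gene_id"],
            "Tumor_Sample_Barcode": mutations["sample_id"],
            "Variant_Classification": mutations["variant_class"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical[["sample_id", "os_time_days", "os_event"]].to_csv(
        path, sep="\t", index=False
    )


def write_term_map(
    terms: Mapping[str, set[str]], names: Mapping[str, str], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("term_id\tterm_name\tgene_id\n")
        for term in sorted(terms):
            for gene in sorted(terms[term]):
                fh.write(f"{term}\t{names.get(term, term)}\t{gene}\n")


# ---------------------------------------------------------------------------
# Sample reconciliation
# ---------------------------------------------------------------------------


def reconcile_samples(omics: Omics, clinical: pd.DataFrame | None = None) -> list[str]:
    """Intersect the sample sets of all provided tables.

    Returns the common samples in the order of the first matrix layer;
    dropped samples are logged.
    """
    common = list(omics.samples)
    if clinical is not None:
        clin = set(clinical["sample_id"])
        dropped = [s for s in common if s not in clin]
        if dropped:
            logger.info(
                "reconcile_samples: dropping %d samples absent from clinical table",
                len(dropped),
            )
        common = [s for s in common if s in clin]
    return common
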