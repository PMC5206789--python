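"""Synthetic input generators with known ground truth.

Every generator is fully deterministic given its seed (a single
``numpy.random.default_rng`` stream consumed in a fixed order) and
returns its truth labels alongside the data, so each downstream stage
can be tested for exact or statistical recovery without any downloads.

Generators
----------
``gen_annotation_bundle``
    protein FASTA + TM segments + signal-peptide calls + compartment
    annotations, stratified so every catalog rule fires by construction.
``gen_cohort``
    MAF + copy-number matrix + expression z matrix with planted
    oncogene/suppressor alteration frequencies over a background rate.
``gen_survival``
    clinical table with exponential survival, a proportional-hazard
    effect for signature-altered samples, and independent exponential
    censoring tuned to the requested censoring rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alteration import AlterationConfig, build_alteration_matrix, signature_vector
from .io import (
    Omics,
    ProteinRecord,
    SignalPeptideCall,
    write_clinical,
    write_compartments,
    write_fasta,
    write_maf,
    write_matrix,
    write_signalp,
    write_term_map,
    write_tm_segments,
)

__all__ = [
    "STRATA",
    "AnnotationBundle",
    "Cohort",
    "stratum_counts",
    "gen_annotation_bundle",
    "gen_cohort",
    "gen_survival",
    "gen_survival_cohort",
    "gen_full_preset",
]

#: Catalog strata, in generation order.
STRATA = ("no_tm", "secreted_tm", "signal_peptide", "multi_tm", "internal")

_STRATUM_VERDICT = {
    "no_tm": "no_tm",
    "secreted_tm": "secreted",
    "signal_peptide": "secreted",
    "multi_tm": "surfaceome",
    "internal": "internal_compartment",
}

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

_SURFACE_LABELS = ("plasma membrane", "extracellular region", "cell junction")
_INTERNAL_LABELS = (
    "lysosome",
    "endoplasmic reticulum",
    "mitochondria",
    "cytoskeleton",
    "endosome",
    "liposome",
    "nucleolus",
    "nucleus",
    "ribosome",
)


def stratum_counts(n: int, proportions: tuple[float, ...]) -> list[int]:
    """Deterministic largest-remainder apportionment of n over strata."""
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    raw = [p * n for p in proportions]
    counts = [int(np.floor(r)) for r in raw]
    short = n - sum(counts)
    # hand leftovers to the largest fractional parts; index breaks ties
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return counts


@dataclass
class AnnotationBundle:
    proteins: list[ProteinRecord]
    tm_segments: dict[str, list[tuple[int, int]]]
    signalp: dict[str, SignalPeptideCall]
    compartments: dict[str, set[str]]
    truth: pd.DataFrame  # gene_id, stratum, verdict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "proteins.fasta",
            "tm": outdir / "tm_segments.tsv",
            "signalp": outdir / "signalp.tsv",
            "go": outdir / "compartments.tsv",
            "truth": outdir / "catalog_truth.tsv",
        }
        write_fasta(self.proteins, paths["fasta"])
        write_tm_segments(self.tm_segments, paths["tm"])
        write_signalp(list(self.signalp.values()), paths["signalp"])
        write_compartments(self.compartments, paths["go"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def _multi_tm_segments(
    rng: np.random.Generator, allow_single: bool
) -> tuple[list[tuple[int, int]], int]:
    """Segments that pass R1-R3: either >=2 helices, or one past residue 50."""
    k = int(rng.integers(1 if allow_single else 2, 6))
    segments = []
    pos = int(rng.integers(55, 80)) if k == 1 else int(rng.integers(5, 30))
    for _ in range(k):
        length = int(rng.integers(18, 26))
        segments.append((pos, pos + length - 1))
        pos = pos + length + int(rng.integers(5, 16))
    protein_len = segments[-1][1] + int(rng.integers(20, 60))
    return segments, protein_len


def gen_annotation_bundle(
    n_genes: int = 100,
    proportions: tuple[float, float, float, float, float] = (0.2, 0.2, 0.1, 0.4, 0.1),
    seed: int = 0,
) -> AnnotationBundle:
    """Generate one annotation bundle with planted catalog verdicts.

    Strata (in ``proportions`` order): no TM domain; single TM inside the
    first 50 residues; single TM covered by a predicted signal peptide;
    true multi-TM (or single late-TM) surface protein; surface-like TM
    geometry but exclusively internal compartment annotation.
    """
    rng = np.random.default_rng(seed)
    counts = stratum_counts(n_genes, proportions)

    proteins: list[ProteinRecord] = []
    tm: dict[str, list[tuple[int, int]]] = {}
    sp: dict[str, SignalPeptideCall] = {}
    comp: dict[str, set[str]] = {}
    truth_rows = []

    idx = 0
    for stratum, count in zip(STRATA, counts):
        for _ in range(count):
            idx += 1
            gene = f"G{idx:05d}"
            pid = f"P{idx:05d}"
            if stratum == "no_tm":
                length = int(rng.integers(150, 400))
                tm[pid] = []
                sp[pid] = SignalPeptideCall(pid, positive=False)
                # compartments are irrelevant to the verdict here
                if rng.random() < 0.5:
                    comp[gene] = {str(rng.choice(_SURFACE_LABELS))}
            elif stratum == "secreted_tm":
                start = int(rng.integers(5, 26))
                end = start + int(rng.integers(15, 25))
                end = min(end, 50)
                length = end + int(rng.integers(150, 300))
                tm[pid] = [(start, end)]
                sp[pid] = SignalPeptideCall(pid, positive=False)
            elif stratum == "signal_peptide":
                # TM past residue 50 (R2 silent) but inside the signal peptide
                cleavage = int(rng.integers(75, 96))
                end = cleavage - int(rng.integers(0, 4))
                start = end - 18
                length = end + int(rng.integers(150, 300))
                tm[pid] = [(start, end)]
                sp[pid] = SignalPeptideCall(pid, positive=True, cleavage_pos=cleavage)
            elif stratum == "multi_tm":
                segments, length = _multi_tm_segments(rng, allow_single=True)
                tm[pid] = segments
                sp[pid] = SignalPeptideCall(pid, positive=False)
                u = rng.random()
                if u < 0.4:
                    comp[gene] = {str(rng.choice(_SURFACE_LABELS))}
                elif u < 0.6:
                    # mixed annotation: one internal label does not exclude
                    comp[gene] = {
                        str(rng.choice(_INTERNAL_LABELS)),
                        str(rng.choice(_SURFACE_LABELS)),
                    }
            else:  # internal
                segments, length = _multi_tm_segments(rng, allow_single=False)
                tm[pid] = segments
                sp[pid] = SignalPeptideCall(pid, positive=False)
                n_labels = int(rng.integers(1, 4))
                labels = rng.choice(_INTERNAL_LABELS, size=n_labels, replace=False)
                comp[gene] = {str(v) for v in labels}
            proteins.append(
                ProteinRecord(pid, gene, length, _random_sequence(rng, length))
            )
            truth_rows.append((gene, stratum, _STRATUM_VERDICT[stratum]))

    truth = pd.DataFrame(truth_rows, columns=["gene_id", "stratum", "verdict"])
    return AnnotationBundle(proteins, tm, sp, comp, truth)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    mutations: pd.DataFrame
    cna: pd.DataFrame
    expr: pd.DataFrame
    truth: pd.DataFrame  # gene_id, role, planted_freq

    @property
    def omics(self) -> Omics:
        return Omics(mutations=self.mutations, cna=self.cna, expr=self.expr)

    def write(self, outdir: str | Path, prefix: str = "") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "maf": outdir / f"{prefix}mutations.maf",
            "cna": outdir / f"{prefix}cna.tsv",
            "expr": outdir / f"{prefix}expr.tsv",
            "truth": outdir / f"{prefix}cohort_truth.tsv",
        }
        write_maf(self.mutations, paths["maf"])
        write_matrix(self.cna, paths["cna"])
        write_matrix(self.expr, paths["expr"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _truncated_normal(rng: np.random.Generator, shape, bound: float = 2.0) -> np.ndarray:
    """Standard normal draws resampled into (-bound, bound)."""
    x = rng.normal(size=shape)
    bad = np.abs(x) >= bound
    while bad.any():
        x[bad] = rng.normal(size=int(bad.sum()))
        bad = np.abs(x) >= bound
    return x


_DELETERIOUS = ("nonsense", "frameshift", "splice_site")


def gen_cohort(
    n_genes: int = 2000,
    n_samples: int = 500,
    background_rate: float = 0.01,
    planted: dict[str, tuple[str, float]] | None = None,
    gene_ids: list[str] | None = None,
    sample_prefix: str = "S",
    shallow_rate: float = 0.02,
    passenger_rate: float = 0.005,
    seed: int = 0,
) -> Cohort:
    """Generate one tumor cohort with planted alteration frequencies.

    ``planted`` maps a gene to ``(role, frequency)`` with role
    ``"oncogene"`` or ``"suppressor"``.  Null genes draw each alteration
    channel (amplification, deletion, over-/under-expression,
    deleterious mutation) independently at ``background_rate``.  Planted
    genes are altered in a Bernoulli(frequency) sample subset, each
    altered sample through one channel drawn uniformly from the
    role-consistent channels; planted genes receive no background.
    Shallow +/-1 copy-number noise and passenger missense/silent
    mutations are sprinkled on top and must not register as alterations.
    """
    rng = np.random.default_rng(seed)
    genes = list(gene_ids) if gene_ids is not None else [
        f"G{i:05d}" for i in range(1, n_genes + 1)
    ]
    if len(genes) != n_genes:
        n_genes = len(genes)
    samples = [f"{sample_prefix}{i:04d}" for i in range(1, n_samples + 1)]
    planted = planted or {}
    unknown = sorted(set(planted) - set(genes))
    if unknown:
        raise ValueError(f"gen_cohort: planted genes not in gene list: {unknown}")

    shape = (n_genes, n_samples)
    amp = rng.random(shape) < background_rate
    dele = rng.random(shape) < background_rate
    up = rng.random(shape) < background_rate
    dn = rng.random(shape) < background_rate
    mut = rng.random(shape) < background_rate

    gene_index = {g: i for i, g in enumerate(genes)}
    for gene in sorted(planted):
        role, freq = planted[gene]
        i = gene_index[gene]
        amp[i] = dele[i] = up[i] = dn[i] = mut[i] = False
        hit = rng.random(n_samples) < freq
        if role == "suppressor":
            channel = rng.integers(0, 3, size=n_samples)
            dele[i] = hit & (channel == 0)
            dn[i] = hit & (channel == 1)
            mut[i] = hit & (channel == 2)
        elif role == "oncogene":
            channel = rng.integers(0, 2, size=n_samples)
            amp[i] = hit & (channel == 0)
            up[i] = hit & (channel == 1)
        else:
            raise ValueError(f"gen_cohort: unknown role {role!r} for {gene}")

    # expression: background inside (-2, 2), altered cells pushed past 2.5
    expr = _truncated_normal(rng, shape)
    expr[up] = 2.5 + np.abs(rng.normal(0.0, 0.5, size=int(up.sum())))
    expr[dn] = -(2.5 + np.abs(rng.normal(0.0, 0.5, size=int(dn.sum()))))
    expr = np.round(expr, 4)

    cna = np.zeros(shape, dtype=np.int64)
    cna[amp] = 2
    cna[dele] = -2
    neutral = cna == 0
    shallow = neutral & (rng.random(shape) < shallow_rate)
    signs = np.where(rng.random(shape) < 0.5, 1, -1)
    cna[shallow] = signs[shallow]

    rows = []
    passenger = rng.random(shape) < passenger_rate
    for i, gene in enumerate(genes):
        for j in np.flatnonzero(mut[i]):
            cls = _DELETERIOUS[int(rng.integers(0, 3))]
            rows.append((samples[j], gene, cls))
        for j in np.flatnonzero(passenger[i]):
            cls = "missense" if rng.random() < 0.7 else "silent"
            rows.append((samples[j], gene, cls))
    mutations = pd.DataFrame(rows, columns=["sample_id", "gene_id", "variant_class"])

    roles = {g: planted.get(g, ("null", 0.0)) for g in genes}
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "role": [roles[g][0] for g in genes],
            "planted_freq": [roles[g][1] for g in genes],
        }
    )
    return Cohort(
        mutations=mutations,
        cna=pd.DataFrame(cna, index=genes, columns=samples),
        expr=pd.DataFrame(expr, index=genes, columns=samples),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Survival generation
# ---------------------------------------------------------------------------


def gen_survival(
    sample_ids: list[str],
    altered: np.ndarray,
    hazard_ratio: float = 3.0,
    baseline_hazard: float = 1e-3,
    censoring_rate: float = 0.3,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Exponential survival with a proportional hazard on altered samples.

    Event times are Exponential(baseline * HR) for signature-altered
    samples and Exponential(baseline) otherwise; censoring times are
    Exponential(lambda_c) with lambda_c = c/(1-c) * mean(rate), which
    hits the requested censoring rate ``c`` in expectation (exactly for
    a homogeneous cohort, approximately otherwise).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    altered = np.asarray(altered, dtype=bool)
    if altered.shape != (len(sample_ids),):
        raise ValueError("gen_survival: altered flags must match sample_ids")
    if not (0.0 <= censoring_rate < 1.0):
        raise ValueError("gen_survival: censoring_rate must be in [0, 1)")
    if hazard_ratio <= 0 or baseline_hazard <= 0:
        raise ValueError("gen_survival: hazard_ratio and baseline_hazard must be > 0")

    rates = baseline_hazard * np.where(altered, hazard_ratio, 1.0)
    event_t = rng.exponential(1.0 / rates)
    if censoring_rate > 0:
        lam_c = censoring_rate / (1.0 - censoring_rate) * float(rates.mean())
        censor_t = rng.exponential(1.0 / lam_c, size=len(sample_ids))
    else:
        censor_t = np.full(len(sample_ids), np.inf)
    os_time = np.round(np.minimum(event_t, censor_t), 4)
    os_event = (event_t <= censor_t).astype(int)
    return pd.DataFrame(
        {"sample_id": sample_ids, "os_time_days": os_time, "os_event": os_event}
    )


def gen_survival_cohort(
    n_null: int = 17,
    n_signature: int = 3,
    n_samples: int = 500,
    altered_freq: float = 0.10,
    hazard_ratio: float = 3.0,
    baseline_hazard: float = 1e-3,
    censoring_rate: float = 0.3,
    seed: int = 0,
) -> tuple[Cohort, pd.DataFrame, list[str]]:
    """Cohort + clinical table with a planted k-gene survival signature.

    All genes (signature and null) are altered at ``altered_freq``; only
    samples altered for at least one signature gene carry the hazard
    effect.  Returns ``(cohort, clinical, signature_genes)``.
    """
    rng = np.random.default_rng(seed)
    n_genes = n_null + n_signature
    genes = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    sig_idx = rng.choice(n_genes, size=n_signature, replace=False)
    signature = sorted(genes[i] for i in sig_idx)
    planted = {}
    for g in genes:
        role = "suppressor" if (g in signature or rng.random() < 0.5) else "oncogene"
        planted[g] = (role, altered_freq)
    cohort = gen_cohort(
        n_genes=n_genes,
        n_samples=n_samples,
        background_rate=0.0,
        planted=planted,
        seed=int(rng.integers(2**31)),
    )
    matrix = build_alteration_matrix(genes, cohort.omics, AlterationConfig())
    altered = signature_vector(signature, matrix).to_numpy()
    clinical = gen_survival(
        matrix.samples,
        altered,
        hazard_ratio=hazard_ratio,
        baseline_hazard=baseline_hazard,
        censoring_rate=censoring_rate,
        rng=rng,
    )
    return cohort, clinical, signature


# ---------------------------------------------------------------------------
# Full preset (everything the pipeline consumes, plus a run config)
# ---------------------------------------------------------------------------


def gen_full_preset(
    outdir: str | Path,
    seed: int = 0,
    n_genes: int = 300,
    n_samples: int = 300,
    n_tumor_types: int = 3,
) -> dict:
    """Write a complete synthetic input set plus a pipeline run config.

    The first tumor type carries the planted 3-gene survival signature;
    the remaining tumor types share the planted oncogenes/suppressors so
    the score matrix has cluster structure.  Returns a manifest dict
    with all paths and the planted truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root_rng = np.random.default_rng(seed)

    bundle = gen_annotation_bundle(n_genes=n_genes, seed=int(root_rng.integers(2**31)))
    bundle_paths = bundle.write(outdir)
    surface = sorted(bundle.truth.loc[bundle.truth["verdict"] == "surfaceome", "gene_id"])
    if len(surface) < 30:
        raise ValueError("gen_full_preset: too few surface genes; increase n_genes")

    pick = root_rng.choice(len(surface), size=11, replace=False)
    signature = sorted(surface[i] for i in pick[:3])
    planted_sup = [surface[i] for i in pick[3:7]]
    planted_onc = [surface[i] for i in pick[7:11]]
    planted = {g: ("suppressor", 0.15) for g in signature}
    planted.update({g: ("suppressor", 0.15) for g in planted_sup})
    planted.update({g: ("oncogene", 0.15) for g in planted_onc})

    tumor_types = [f"TT{i + 1}" for i in range(n_tumor_types)]
    tumors = {}
    clinical_path = None
    for ti, tt in enumerate(tumor_types):
        cohort = gen_cohort(
            n_genes=len(surface),
            n_samples=n_samples if ti == 0 else max(100, n_samples // 2),
            background_rate=0.01,
            planted=planted,
            gene_ids=surface,
            sample_prefix=f"{tt}_",
            seed=int(root_rng.integers(2**31)),
        )
        paths = cohort.write(outdir, prefix=f"{tt.lower()}_")
        tumors[tt] = {
            "maf": str(paths["maf"]),
            "cna": str(paths["cna"]),
            "expr": str(paths["expr"]),
        }
        if ti == 0:
            matrix = build_alteration_matrix(surface, cohort.omics, AlterationConfig())
            altered = signature_vector(signature, matrix).to_numpy()
            clinical = gen_survival(
                matrix.samples,
                altered,
                hazard_ratio=3.0,
                censoring_rate=0.3,
                rng=root_rng,
            )
            clinical_path = outdir / f"{tt.lower()}_clinical.tsv"
            write_clinical(clinical, clinical_path)
            tumors[tt]["clinical"] = str(clinical_path)

    # annotation terms over the surface genes, one per planted role group
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    n_random_terms = 6
    for i in range(n_random_terms):
        size = int(root_rng.integers(10, 30))
        members = root_rng.choice(surface, size=min(size, len(surface)), replace=False)
        term = f"T{i + 1:03d}"
        terms[term] = {str(g) for g in members}
        names[term] = f"random term {i + 1}"
    terms["T900"] = set(planted_sup) | set(signature)
    names["T900"] = "planted suppressor program"
    terms["T901"] = set(planted_onc)
    names["T901"] = "planted oncogene program"
    terms_path = outdir / "terms.tsv"
    write_term_map(terms, names, terms_path)

    truth = {
        "signature": signature,
        "planted_suppressors": sorted(planted_sup),
        "planted_oncogenes": sorted(planted_onc),
    }
    manifest = {
        "fasta": str(bundle_paths["fasta"]),
        "tm": str(bundle_paths["tm"]),
        "signalp": str(bundle_paths["signalp"]),
        "go": str(bundle_paths["go"]),
        "terms": str(terms_path),
        "tumors": tumors,
        "survival_tumor": tumor_types[0],
        "truth": truth,
    }

    config = {
        "inputs": {
            "fasta": manifest["fasta"],
            "tm": manifest["tm"],
            "signalp": manifest["signalp"],
            "go": manifest["go"],
            "terms": manifest["terms"],
            "tumors": tumors,
        },
        "survival_tumor": tumor_types[0],
        "thresholds": {
            "z_main": 3.0,
            "z_relaxed": 2.0,
            "alpha": 0.05,
            "top_k": 20,
            "k": 3,
            "enrich_cutoff": 0.01,
            "n_clusters": 3,
        },
        "out_dir": str(outdir / "results"),
        "seed": seed,
    }
    import yaml

    config_path = outdir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    manifest["config"] = str(config_path)

    truth_path = outdir / "pipeline_truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("kind\tgene_id\n")
        for g in signature:
            fh.write(f"signature\t{g}\n")
        for g in sorted(planted_sup):
            fh.write(f"suppressor\t{g}\n")
        for g in sorted(planted_onc):
            fh.write(f"oncogene\t{g}\n")
    manifest["truth_path"] = str(truth_path)
    return manifest
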