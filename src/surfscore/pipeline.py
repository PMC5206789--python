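"""End-to-end orchestration: catalog -> scoring -> survival -> enrichment.

A single YAML config drives the run; every stage writes its TSV outputs
under the configured directory and the run ends with a machine-readable
``report.json``.  All outputs are deterministic given the inputs and
seed (no timestamps in any artifact).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .alteration import AlterationConfig, build_alteration_matrix
from .catalog import CatalogConfig, build_catalog
from .enrichment import cluster_genes, enrich
from .io import (
    Omics,
    ValidationError,
    parse_clinical,
    parse_compartments,
    parse_fasta,
    parse_maf,
    parse_matrix,
    parse_signalp,
    parse_term_map,
    parse_tm_segments,
    reconcile_samples,
)
from .scoring import ScoringConfig, classify_cancer_genes, pan_cancer_union, score_tumor_type
from .survival import combination_search, gene_screen, km_estimate

logger = logging.getLogger("surfscore")

__all__ = ["RunConfig", "load_config", "run_pipeline"]


@dataclass
class RunConfig:
    fasta: Path
    tm: Path
    signalp: Path
    go: Path
    tumors: dict[str, dict[str, Path]]
    out_dir: Path
    terms: Path | None = None
    survival_tumor: str | None = None
    z_main: float = 3.0
    z_relaxed: float = 2.0
    alpha: float = 0.05
    top_k: int = 20
    k: int = 3
    enrich_cutoff: float = 0.01
    n_clusters: int = 3
    seed: int = 0
    raw: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("z_main", "z_relaxed", "alpha", "enrich_cutoff"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"config: {name} must be > 0")
        if self.top_k < 1 or self.k < 1 or self.n_clusters < 1:
            raise ValidationError("config: top_k, k and n_clusters must be >= 1")
        paths = [self.fasta, self.tm, self.signalp, self.go]
        if self.terms is not None:
            paths.append(self.terms)
        for tt, layers in self.tumors.items():
            for key, p in layers.items():
                paths.append(Path(p))
        for p in paths:
            if not Path(p).exists():
                raise ValidationError(f"config: input file not found: {p}")
        if self.survival_tumor is not None:
            if self.survival_tumor not in self.tumors:
                raise ValidationError(
                    f"config: survival_tumor {self.survival_tumor!r} not in tumors"
                )
            if "clinical" not in self.tumors[self.survival_tumor]:
                raise ValidationError(
                    f"config: tumor {self.survival_tumor!r} lacks a clinical table"
                )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        inputs = raw["inputs"]
        thresholds = raw.get("thresholds", {})
        tumors = {
            tt: {k: Path(v) for k, v in layers.items()}
            for tt, layers in inputs["tumors"].items()
        }
        cfg = RunConfig(
            fasta=Path(inputs["fasta"]),
            tm=Path(inputs["tm"]),
            signalp=Path(inputs["signalp"]),
            go=Path(inputs["go"]),
            terms=Path(inputs["terms"]) if inputs.get("terms") else None,
            tumors=tumors,
            survival_tumor=raw.get("survival_tumor"),
            out_dir=Path(raw["out_dir"]),
            z_main=float(thresholds.get("z_main", 3.0)),
            z_relaxed=float(thresholds.get("z_relaxed", 2.0)),
            alpha=float(thresholds.get("alpha", 0.05)),
            top_k=int(thresholds.get("top_k", 20)),
            k=int(thresholds.get("k", 3)),
            enrich_cutoff=float(thresholds.get("enrich_cutoff", 0.01)),
            n_clusters=int(thresholds.get("n_clusters", 3)),
            seed=int(raw.get("seed", 0)),
            raw=raw,
        )
    except KeyError as exc:
        raise ValidationError(f"config: missing required key {exc}") from exc
    return cfg


def _config_hash(cfg: RunConfig) -> str:
    def normalize(obj):
        if isinstance(obj, dict):
            return {k: normalize(v) for k, v in sorted(obj.items())}
        if isinstance(obj, list):
            return [normalize(v) for v in obj]
        if isinstance(obj, str) and ("/" in obj or "\\" in obj):
            return Path(obj).name  # directory placement must not affect the hash
        return obj

    blob = json.dumps(normalize(cfg.raw), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_omics(layers: dict[str, Path]) -> tuple[Omics, pd.DataFrame | None]:
    mutations = parse_maf(layers["maf"]) if "maf" in layers else None
    cna = parse_matrix(layers["cna"], "cna") if "cna" in layers else None
    expr = parse_matrix(layers["expr"], "expr") if "expr" in layers else None
    clinical = parse_clinical(layers["clinical"]) if "clinical" in layers else None
    omics = Omics(mutations=mutations, cna=cna, expr=expr)
    return omics, clinical


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and return the report dict (also written to disk)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "stages": {},
    }

    # --- stage 1: surfaceome catalog -------------------------------------
    stage = "catalog"
    try:
        proteins = parse_fasta(cfg.fasta)
        tm = parse_tm_segments(cfg.tm, proteins)
        signalp = {c.protein_id: c for c in parse_signalp(cfg.signalp)}
        compartments = parse_compartments(cfg.go)
        result = build_catalog(proteins, tm, signalp, compartments, CatalogConfig())
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    catalog_genes = sorted(result.surfaceome)
    rows = [
        (g, d.verdict, ";".join(d.reason_trace))
        for g, d in sorted(result.decisions.items())
    ]
    pd.DataFrame(rows, columns=["gene_id", "verdict", "reasons"]).to_csv(
        out / "catalog.tsv", sep="\t", index=False
    )
    report["stages"][stage] = {
        "n_genes": len(result.decisions),
        "counts": result.counts,
        "catalog_size": len(catalog_genes),
    }
    logger.info("catalog: %d/%d genes", len(catalog_genes), len(result.decisions))

    # --- stage 2: per-tumor scoring --------------------------------------
    stage = "scoring"
    tables: dict[str, pd.DataFrame] = {}
    omics_by_tumor: dict[str, Omics] = {}
    clinical_by_tumor: dict[str, pd.DataFrame] = {}
    try:
        for tt in sorted(cfg.tumors):
            omics, clinical = _load_omics(cfg.tumors[tt])
            if clinical is not None:
                omics.samples = reconcile_samples(omics, clinical)
                clinical = clinical[clinical["sample_id"].isin(omics.samples)]
                clinical_by_tumor[tt] = clinical.reset_index(drop=True)
            omics_by_tumor[tt] = omics
            table = score_tumor_type(
                catalog_genes, omics, tt, ScoringConfig(), cfg.z_main, inclusive=True
            )
            table.to_csv(out / f"scores_{tt}.tsv", sep="\t", index=False)
            tables[tt] = table
    except (ValidationError, RuntimeError) as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    s_matrix = pd.DataFrame(
        {tt: df.set_index("gene_id")["S"] for tt, df in tables.items()}
    )
    s_matrix.index.name = "gene_id"
    s_matrix.to_csv(out / "s_matrix.tsv", sep="\t")
    union = pan_cancer_union(tables)
    report["stages"][stage] = {
        "tumor_types": sorted(tables),
        "cancer_genes_per_tumor": {
            tt: int((df["class"] != "none").sum()) for tt, df in tables.items()
        },
        "union_size": len(union),
    }

    # --- stage 3: clustering + enrichment --------------------------------
    stage = "enrichment"
    if union and len(union) >= cfg.n_clusters:
        sub = s_matrix.loc[union]
        clusters = cluster_genes(sub, n_clusters=cfg.n_clusters)
        clusters.rename_axis("gene_id").reset_index().to_csv(
            out / "clusters.tsv", sep="\t", index=False
        )
        enrichment_rows = []
        if cfg.terms is not None:
            term_map, _names = parse_term_map(cfg.terms)
            annotated = set().union(*term_map.values()) if term_map else set()
            universe = sorted(set(catalog_genes) & annotated)
            for label in sorted(clusters.unique()):
                query = sorted(
                    set(clusters.index[clusters == label]) & set(universe)
                )
                if not query:
                    continue
                res = enrich(query, term_map, universe, cutoff=cfg.enrich_cutoff)
                res.insert(0, "cluster", label)
                enrichment_rows.append(res)
        if enrichment_rows:
            enr = pd.concat(enrichment_rows, ignore_index=True)
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            n_kept = int(enr["kept"].sum())
        else:
            n_kept = 0
        report["stages"][stage] = {
            "n_clusters": int(clusters.nunique()),
            "cluster_sizes": {
                str(c): int((clusters == c).sum()) for c in sorted(clusters.unique())
            },
            "enriched_terms": n_kept,
        }
    else:
        report["stages"][stage] = {"skipped": "too few cancer genes to cluster"}

    # --- stage 4: survival screen + signature search ---------------------
    stage = "survival"
    if cfg.survival_tumor is not None:
        tt = cfg.survival_tumor
        omics = omics_by_tumor[tt]
        clinical = clinical_by_tumor[tt]
        z = tables[tt].set_index("gene_id")["z"]
        relaxed = classify_cancer_genes(z, cfg.z_relaxed, inclusive=False)
        candidates = sorted(relaxed.index[relaxed != "none"])
        report["stages"][stage] = {"candidates": len(candidates)}
        if len(candidates) >= cfg.k:
            matrix = build_alteration_matrix(candidates, omics, AlterationConfig())
            screen = gene_screen(
                candidates, matrix, clinical, alpha=cfg.alpha, top_k=cfg.top_k
            )
            screen.table.to_csv(out / "screen.tsv", sep="\t", index=False)
            report["stages"][stage]["screened"] = len(screen.selected)
            if len(screen.selected) >= cfg.k:
                combos = combination_search(screen.selected, matrix, clinical, k=cfg.k)
                combos.to_csv(out / "combinations.tsv", sep="\t", index=False)
                top = combos.iloc[0]
                top_genes = [top[f"gene{i + 1}"] for i in range(cfg.k)]
                sig = matrix.values.loc[top_genes].any(axis=0)
                clin = clinical.set_index("sample_id").loc[matrix.samples]
                for label, mask in (("altered", sig), ("unaltered", ~sig)):
                    subset = clin[mask.to_numpy()]
                    if len(subset):
                        curve = km_estimate(
                            subset["os_time_days"].to_numpy(),
                            subset["os_event"].to_numpy(),
                        )
                        curve.to_frame(n_total=len(subset)).to_csv(
                            out / f"km_top_signature_{label}.tsv", sep="\t", index=False
                        )
                report["stages"][stage]["top_signature"] = {
                    "genes": top_genes,
                    "n_altered": int(top["n_altered"]),
                    "chi2": float(top["chi2"]),
                    "p": float(top["p"]),
                    "n_combinations": len(combos),
                }
            else:
                report["stages"][stage]["top_signature"] = None
        else:
            report["stages"][stage]["skipped"] = "too few candidates"
    else:
        report["stages"][stage] = {"skipped": "no survival tumor configured"}

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
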