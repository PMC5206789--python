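# surfscore

A pipeline for characterizing cell-surface genes in tumor cohorts:

1. **Catalog** — classify genes as surfaceome / secreted / internal /
   no-TM from transmembrane-helix predictions, signal-peptide calls and
   subcellular-compartment annotations, with benchmark metrics
   (family coverage, external-set overlap).
2. **Scoring** — integrate mutation, copy-number and expression
   evidence into a per-gene, per-tumor-type S-score (percent-like net
   alteration frequency, sign = oncogene/suppressor role), standardize
   to z-scores and call cancer genes at a z threshold.
3. **Alteration model** — classify each (gene, sample) as
   altered/unaltered (extreme expression, high-level copy-number change
   or deleterious mutation), with per-call reason codes.
4. **Survival signatures** — Kaplan–Meier estimation and the two-group
   log-rank test implemented from first principles, a per-gene survival
   screen, and an exhaustive k-gene signature search with OR semantics.
5. **Enrichment** — Ward-linkage clustering of the gene × tumor-type
   score matrix and hypergeometric term enrichment with BH adjustment.
6. **Simulation** — generators for every input format with planted
   ground truth (catalog strata, alteration frequencies, a hazard
   effect on a planted gene signature), so the whole pipeline is
   testable offline.

## CLI

Every stage is a subcommand of `surfscore`; `simulate` writes synthetic
inputs plus a ready-to-run config:

```sh
surfscore simulate --preset full --seed 1 --out demo
surfscore run --config demo/config.yaml        # full pipeline -> demo/results/
surfscore catalog --fasta F --tm T --signalp S --go G --out DIR
surfscore score   --maf M --cna C --expr E --tumor-type BRCA --threshold 3 --out scores.tsv
surfscore alter   --genes LIST --maf M --cna C --expr E --out DIR
surfscore survive --genes LIST --maf M --cna C --expr E --clinical CLIN \
                  --alpha 0.05 --top 20 --k 3 --out DIR
surfscore enrich  --query Q --terms TERMS --out enrichment.tsv
```

Exit codes: 0 success, 2 validation error, 1 runtime error.

All file formats are plain TSV/FASTA with documented headers; see the
module docstring of `surfscore.io` for the dialects (TMHMM-style long
format is accepted for TM segments, minimal MAF for mutations,
GISTIC-style −2..+2 matrices for copy number).

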