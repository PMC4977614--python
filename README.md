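# varprio

Pedigree-aware prioritization of germline variants from disease families.

Starting from a pre-annotated multi-sample VCF, a 6-column PED pedigree and
a per-member status sidecar, `varprio` applies a filter cascade and reports
ranked candidate predisposition variants together with a per-stage,
per-region-class survivor funnel:

1. **Technical QC** — variant quality > 20, carrier coverage > 5x, strand
   bias for SNVs (≥ 1 alt read on each strand, pooled over carriers),
   upstream caller FILTER status for indels.
2. **Rarity** — MAF < 0.1 % in every population resource with data
   (1000 Genomes, non-TCGA ExAC, optional in-house controls); missing
   frequency counts as rare.
3. **Relatedness QC** (advisory) — pairwise rare-variant sharing (Jaccard)
   compared against pedigree-expected kinship to catch sample swaps; warns
   by default, aborts with `--strict-relatedness`.
4. **Segregation** — dominant-model compatibility with five-level member
   statuses (definite case, possible phenocopy, non-carrier control,
   possible-carrier control, uninformative) under configurable numeric
   tolerances.
5. **Score gate** — scaled deleteriousness (CADD-style) score > 10, with
   tier annotation (> 10 / > 20 / > 30).
6. **Conservation** — GERP > 2.0 and/or PhastCons > 0.3 as a flag (default)
   or a gate (configurable).
7. **Branch evaluation** — coding: ≥ 3-of-4 predictor consensus vote plus a
   separately logged gene-intolerance sub-stage; 3'UTR: miRNA-target
   promotion (mirSVR < −0.1); 5'UTR/intergenic/intronic: regulatory-evidence
   ranking from RegulomeDB-style categories and HaploReg-style flags.

All thresholds are strict inequalities by default and configurable. A
gene-drop simulator (`varprio.simulate`) generates complete synthetic
cohorts — multi-generation pedigrees, one injected dominant causal variant
with incomplete penetrance and phenocopies, gene-dropped decoys, and
annotation scores — so the entire cascade is testable without external
data.

## CLI

```bash
# write a commented config template with all default thresholds
varprio init-config config.yaml

# generate a synthetic cohort (VCF + PED + status sidecar + truth)
varprio simulate --out-dir sim/ --seed 1 --n-decoys 80

# run the full cascade
varprio run --vcf sim/cohort.vcf --ped sim/cohort.ped \
            --statuses sim/cohort.statuses.tsv --out-dir out/

# relatedness QC only
varprio check-relatedness --vcf sim/cohort.vcf --ped sim/cohort.ped \
                          --statuses sim/cohort.statuses.tsv

# re-summarize a funnel report
varprio funnel out/funnel.json
```

`run` writes `candidates.tsv` (one row per surviving variant with all
annotations, flags and per-stage verdicts), `funnel.json` (machine-readable
stage counts) and `relatedness.tsv`. Outputs are deterministic:
re-running on identical inputs is byte-identical.

## Library

```python
from varprio import PipelineConfig, SimulationSpec, run_pipeline, simulate_cohort

cohort = simulate_cohort(SimulationSpec(seed=1, causal_penetrance=1.0))
result = run_pipeline(cohort.pairs, cohort.pedigree, PipelineConfig())
assert cohort.causal_key in result.candidate_keys()
```

Annotation transport is configurable via a key map (INFO keys for
site-level scores, FORMAT keys for per-sample read evidence); a TSV
annotation sidecar keyed by `chrom:pos:ref:alt` can be merged on top.
Multi-allelic sites are decomposed per alt allele. Missing annotations stay
missing — each gate documents its own missing-value rule.

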