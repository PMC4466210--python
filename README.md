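# mitonuclear

A reusable pipeline for studying mitonuclear expression coordination in
cloned piglets, rebuilt end to end as tested Python:

- **lineage** — maternal-breed determination from ND1 SNP-panel genotypes:
  discriminating-position discovery, panel-match scoring with an UNRESOLVED
  tie rule, private-variant flagging, codon-effect classification under the
  vertebrate mitochondrial genetic code, and a strict 25% heteroplasmy
  detectability rule.
- **array_processing** — two-channel microarray processing: local background
  subtraction with a floor, 70%-pixel present calls, per-slide lowess
  normalization of M on A, dye-swap combination, and the three-clause
  informative-probe filter (presence > 90% of arrays, raw intensity > 100,
  ratio SD < 1.4).
- **coordination** — pairwise-complete Pearson correlation of samples,
  average-linkage hierarchical clustering on 1 − r with deterministic
  tie-breaking, within-treatment coherence (mean pairwise r), 2-cut
  treatment-separation purity, and the nuclear-mito vs mtDNA purity
  contrast.
- **diffexpr** — Welch t-tests with Benjamini–Hochberg adjustment, the
  fold-change ≥ 1.5 AND adjusted p ≤ 0.05 DE rule (inclusive boundaries),
  genome-of-origin partitioning, and Fisher's exact gene-set enrichment
  over GMT gene sets.
- **qpcr** — comparative-CT (2^−ΔΔCt) relative quantification with an
  internal-control gene and calibrator sample, F-test-then-one-sided-t group
  comparison, and microarray directionality concordance.
- **synthetic_data** — a seeded generator for every input: breed reference
  sequences whose panel substitutions are synonymous by construction, the
  22-animal cohort with optional heteroplasmy, a latent expression model
  with a tunable coordination parameter, 44 dye-swap slides with planted
  intensity-dependent dye bias, and Ct panels consistent with the latent
  expression.
- **cli_pipeline** — one-command orchestration with a YAML config, stage
  manifests, and a deterministic `report.json`.

## CLI

```bash
# full synthetic run
cat > run.yaml <<EOF
outdir: run
seed: 7
simulation:
  n_probes: 2000
  n_nuclear_mito: 200
  n_mtdna: 32
EOF
mitonuclear run --config run.yaml

# individual stages
mitonuclear simulate --outdir sim --seed 7
mitonuclear lineage --fasta sim/animals.fasta --panel sim/panel.tsv \
    --design sim/design.tsv --out lin
mitonuclear normalize --slides sim/slides --annotation sim/annotation.tsv \
    --design sim/design.tsv --span 0.3 --out norm
mitonuclear cluster --matrix norm/expression_matrix.tsv \
    --annotation sim/annotation.tsv --design sim/design.tsv \
    --subsets global,nuclear_mito,mtdna --out clu
mitonuclear de --matrix norm/expression_matrix.tsv \
    --annotation sim/annotation.tsv --design sim/design.tsv --out de
mitonuclear enrich --de de/de_results.tsv --gmt sim/gene_sets.gmt \
    --annotation sim/annotation.tsv --out enr
mitonuclear qpcr --ct sim/qpcr.tsv --control-gene TBB2 --calibrator REF \
    --out q
```

`mitonuclear run` writes, under `outdir`: per-group expression matrices and
probe flags, per-subset cluster JSONs and a coherence table, DE result
tables, enrichment results, qPCR relative-expression/test/concordance
tables, `report.json` (byte-identical across runs with the same seed), and
`manifest.json` with SHA-256 digests of every output.

## Layout

```
src/mitonuclear/
  datasets.py          # packaged panel / animal-call / platform-count inputs
  lineage.py           # breed assignment, codon effects, heteroplasmy
  array_processing.py  # slides -> normalized, filtered expression matrix
  coordination.py      # clustering, coherence, separation purity
  diffexpr.py          # Welch + BH DE calls, Fisher enrichment
  qpcr.py              # comparative CT, group tests, concordance
  synthetic_data.py    # seeded generator for all inputs
  pipeline.py, cli.py  # orchestration and command line
tests/                 # unit + property tests, oracles, acceptance suite
scripts/acceptance.py  # acceptance report
```
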