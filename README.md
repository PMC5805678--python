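# methylscape

Methylome landscape, clock-age, subtype and variant-filter analyses for
epidermal Infinium-style methylation array cohorts, exercisable end to end on
synthetic data.

The package implements, as a reusable and tested pipeline:

- **Probe filtering** — detection p-value, sex-chromosome, SNP and
  self-hybridization exclusion rules with per-rule reporting
  (`methylscape.filtering`).
- **Moderated differential methylation** — per-probe linear group models
  with empirical-Bayes variance shrinkage (closed-form moment/digamma prior
  estimation), moderated t/F statistics and Benjamini–Hochberg correction
  (`methylscape.differential`).
- **Landscape statistics** — CpG island / shore / shelf / open-sea shifts
  and hyper/hypo fractions, lamina-associated-domain (LAD) shifts, and the
  non-CpG (CH-context) analysis (`methylscape.landscape`).
- **Methylation age** — a pluggable linear clock with the piecewise
  log-linear age transform and chronological-vs-predicted age gaps
  (`methylscape.meth_age`). Clock coefficients are never bundled; supply any
  clock in the documented TSV format.
- **Two-subclass calling** — keratin-gene and enhancer-aggregated profiles,
  PCA, hierarchical clustering with reference anchors, EpSC-like vs
  keratinocyte-like subclass assignment with a silhouette guard against
  forcing structure onto null data, delta-vs-healthy maps, and
  hypermethylated-gene selection (`methylscape.subtyping`).
- **Whole-exome artifact filter** — the integer confidence score (start at
  10, deduct per artifact category, strict < 8 exclusion) and the
  population-frequency exclusion cascade (`methylscape.variant_filter`).
- **Synthetic data** — manifests with region sets (LADs, two enhancer sets
  with controlled overlap, gained/lost enhancer regions), cohorts with
  planted group effects and two latent subclasses, reference methylomes, an
  invertible synthetic clock, and annotated variant tables
  (`methylscape.synthetic`). Latent truth lives only on the sample sheet and
  is never consumed by any analysis operation.

All I/O is plain text: TSV matrices/tables, BED3/BED4 region sets, a small
TSV clock format, YAML pipeline configs (`methylscape.io`).

## CLI

A single `methylscape` entry point with one subcommand per stage:

```bash
# end-to-end synthetic run
cat > config.yaml <<EOF
seed: 1
alpha: 0.05
synthetic:
  n_probes: 20000
  seed: 1
  n_clock_probes: 50
  n_variants: 200
EOF
methylscape pipeline run config.yaml --out out/

# individual stages on files
methylscape pipeline synth config.yaml --out inputs/
methylscape filter --beta inputs/beta.tsv --manifest inputs/manifest.tsv --out filtered.tsv
methylscape diff --beta inputs/beta.tsv --samplesheet inputs/samplesheet.tsv \
    --contrast healthy:AK --out diff.tsv
methylscape landscape --beta inputs/beta.tsv --manifest inputs/manifest.tsv \
    --samplesheet inputs/samplesheet.tsv --lads inputs/regions_LAD.bed --out landscape/
methylscape age --beta inputs/beta.tsv --clock inputs/clock.tsv \
    --samplesheet inputs/samplesheet.tsv --out age.tsv
methylscape subtype --beta inputs/beta.tsv --manifest inputs/manifest.tsv \
    --samplesheet inputs/samplesheet.tsv --mode keratin --out subtype/
methylscape varfilter --variants inputs/variants.tsv --out retained.tsv
```

The pipeline writes a `run_manifest.json` (config hash, seed, version,
output list); identical config + seed reproduces every output byte for byte.

## Conventions

- Beta values live in [0, 1]; missing values are `NA` on disk, NaN in memory.
- Manifest positions are 1-based; region sets are 0-based half-open BED. A
  probe at 1-based position p belongs to (start, end) iff start < p <= end.
- Chromosome names are normalized to the `chr` dialect on load; mixed
  dialects in one input are an error, never silently repaired.
- Delta-beta is always mean(comparison) − mean(reference); age gap is always
  predicted − chronological (negative = younger-looking methylome).
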