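# guanodiet

Dietary metabarcoding analysis toolkit for pooled fecal (guano) samples:
from amplicon reads or MOTU read-count tables to trophic-niche statistics,
with a fully ground-truthed synthetic data generator.

## What it does

- **read_pipeline** — paired-read merging (≥10 bp overlap, ≤8% mismatch),
  per-read quality filtering (≥90% of bases above Q30), dereplication,
  length (≥149 bp) and global minimum-count (≥5 reads) filters, a
  per-sample 0.1‰ relative-abundance filter, greedy 1-mismatch centroid
  clustering into MOTUs, and exclusion of non-target MOTUs (reference
  matches below 40% similarity, configured non-prey taxa, anything seen in
  blank controls).
- **datasets** — the four diet treatments: occurrence, wPOO
  (inverse-richness weighted occurrence), RRA (relative read abundance),
  no-rare-items (dataset singletons removed), and family-level collapse;
  plus community-vs-small-replicate regime comparison and a taxonomy
  composition summary.
- **niche** — Levins and Shannon-Wiener niche breadth, seasonal
  aggregation, a Shapiro → F/Levene → Student/Welch test cascade, colony ×
  season pooling, and Morisita-Horn / Pianka overlap matrices.
- **richness** — incidence-based Chao2, exact sample-based rarefaction,
  extrapolation, and the minimal sampling effort to reach a target
  fraction of the estimated asymptote.
- **ordination** — similarity→distance conversion, classical PCoA (Gower
  double centering; negative eigenvalues reported, optional Cailliez
  correction), and between/within group-separation ratios.
- **synthetic** — a generator emulating the full study design (5 colonies,
  one highland; 11 biweekly dates over 3 seasons; 15–20-pellet community
  samples and 3-pellet replicates; lognormal amplification bias; sub-
  threshold error sequences; blank-borne contaminants) with complete
  ground truth for recovery testing.

## CLI

All stages are subcommands of one entry point:

```sh
guanodiet simulate --seed 1 --outdir sim/
guanodiet exclude --table sim/motu_table.tsv --taxonomy sim/taxonomy.tsv \
    --metadata sim/metadata.tsv --out clean.tsv --report-out report.tsv
guanodiet build-datasets --table clean.tsv --taxonomy sim/taxonomy.tsv --outdir sets/
guanodiet overlap --table clean.tsv --metadata sim/metadata.tsv --out overlap.tsv
guanodiet ordinate --similarity overlap.tsv --out pcoa.tsv
guanodiet richness --occurrence sets/diet_occurrence.tsv --out rich.json
guanodiet run-all --seed 1 --outdir full_run/   # the whole chain + manifest
```

`filter-reads` and `cluster` cover the sequence-level stages from FASTQ
(gzip transparent). Runs are deterministic given `--seed`; `run-all`
writes every intermediate artifact plus a manifest with a config hash.

## Formats

TSV everywhere (samples as rows, first column `sample_id`), FASTA for
centroids, JSON for summaries and ground truth, YAML for configuration;
floats are serialized at 10 significant digits with Unix newlines.
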