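# mutaccum

Mutation-accumulation analysis for cohorts of isogenic whole-genome samples:

* **synthetic** — generate reference genomes and isogenic cohorts with
  implanted sample-private SNVs/indels (controllable triplet spectrum,
  deletion contexts including microhomology), shared germline heterozygous
  sites, and noisy per-position allele-count tables (negative-binomial
  coverage, small per-base error).
* **calling** — unique-mutation calling by simultaneous comparison of all
  samples at each position: a variant is accepted when exactly one sample
  shows it (alt fraction ≥ 0.2, depth ≥ 5), every other sample is clean
  (reference fraction ≥ 0.93), and a Fisher exact-test quality score
  against the noisiest other sample is ≥ 2 (−log10 p). Indels up to 50 bp.
* **spectra** — 96-triplet mutation spectra (pyrimidine-centred convention),
  normalization by genome triplet occurrence, rainfall/intermutation
  distances and the clustered fraction.
* **signatures** — cross-genome triplet-frequency adjustment, Pearson
  correlation against a 30-signature catalogue, baseline subtraction, and
  NCG>NTG (CpG) overrepresentation. A synthetic demo catalogue is bundled.
* **indels** — deletion context classification (repeat / microhomology
  k = 1–5 / other), length histograms, KS and exact R×C category tests.
* **stats** — pooled-variance and paired t-tests (from raw samples or
  summary statistics), two-sample KS (permutation-exact for tiny samples),
  Fisher's exact test (2×2 and enumerated R×C). No multiplicity adjustment.
* **reporting** — cohort summaries (per-genotype mean ± s.d. counts), fold
  changes vs a baseline genotype, and an end-to-end pipeline that writes
  TSV/VCF/JSON outputs.

## CLI

```sh
mutaccum simulate --genome-spec genome.yaml --cohort-spec cohort.yaml --out sim/ --seed 1
mutaccum call --counts sim/counts.tsv --out called/
mutaccum spectrum --calls called/calls.tsv --ref sim/reference.fa --sample s1 --out spec/
mutaccum signatures --spectrum spec/spectrum_counts.tsv --source-freqs freqs.tsv --out sig/
mutaccum indels --calls called/calls.tsv --ref sim/reference.fa --out ind/
mutaccum stats --summary groups.tsv --out ttests.tsv
mutaccum run --config pipeline.yaml --out run/ --seed 1
```

`mutaccum run` drives the whole pipeline from a YAML config; with a
`simulate:` section it generates the cohort first, otherwise it reads a
count table plus a sample-metadata TSV (`sample`, `genotype`, `treatment`).
Example config:

```yaml
seed: 5
baseline_genotype: WT
genome: {chromosome_lengths: [1000000], gc_content: 0.42}
simulate:
  samples: [[wt1, WT], [wt2, WT], [m1, MUT]]
  snv_burden: 100
  deletion_burden: 10
  deletion_mix: [0.2, 0.5, 0.3]
  noise: {mean_coverage: 25, per_base_error: 0.002}
```

## File formats

Plain text throughout: FASTA references, TSV count tables
(`sample chrom pos ref_base A C G T ins del depth`, with `ins`/`del`
holding `seq:count` / `len:seq:count` tokens), TSV truth sets and call
tables, minimal VCF v4.2 per sample, TSV spectra (96 `A[C>T]G`-style
classes), and a JSON run report. Coordinates in files are 1-based; indels
are anchored on the base before the event.

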