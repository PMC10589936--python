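# nanoplex-qc

QC toolkit for multiplexed Oxford Nanopore sequencing runs, built for
microbial-genomics groups comparing library preparation strategies
(ligation, tagmentation, PCR barcoding) or auditing a multiplexed run before
assembly. Given a run's per-read metadata, its read-vs-reference alignments
and a tandem-repeat report, the package answers: how much of the output is
usable, how much barcode leakage crossed samples, and how much of the
sequence is artifactual tandem repeat — at the flow-cell, per-channel and
per-barcode level.

## What it computes

Each read carries two independent labels: the barcode the demultiplexer
called (or `unclassified`) and the genome its best alignment hits (or none).
Crossing them partitions the run:

- **mapped / unmapped** — the read does / does not align to the curated
  reference set; unmapped reads proxy sequencing noise;
- **correct** — the barcode's sample matches the mapped genome;
- **leaked** — barcode and mapped genome disagree (index hopping /
  sample-to-read misassignment); the leakage rate among classified reads is
  the run's cross-contamination estimate;
- **unclassified** — no barcode called; the unclassified fraction is the
  demultiplexing loss.

One alignment defines a read's taxonomy: the best primary alignment by PAF
residue matches m, with identity `100·m/b` (b = alignment block length) and
query coverage `100·(q_end − q_start)/L` (L = read length). A stringent
sorting filter keeps mapped reads with `L ≥ 5000`, identity ≥ 95% and
coverage ≥ 80% for reassembly use.

Tandem-repeat reports (TRF `.dat`) are merged per read — overlapping
intervals are unioned, total tandem length computed — and tandem bases are
binned by distance from each read end (default 500 bp bins over the first
15 kbp per side), exposing the edge-located tandem artifacts characteristic
of nanopore reads. Per-channel totals over the flow cell's 512 channels are
summarised as mean ± population SD over active channels to gauge run
homogeneity.

A synthetic-run generator produces FASTQ, sequencing summary, PAF, TRF-style
dat and a ground-truth table with configurable unclassified rate (default
20%), leakage rate (default 1.5%), per-strategy noise and length/quality
models, Dirichlet-multinomial channel overdispersion and edge-planted tandem
artifacts — so the whole pipeline runs and is testable with no data
downloads.

## Worked example

```python
from nanoplex_qc import (build_synthesis, classified_summary, default_config,
                         library_summary, percent, simulate_run)

config = default_config(model="LIG", n_reads=5000, seed=42)
run = simulate_run(config)
rows = build_synthesis(run.summary, run.alignments, config.barcode_map)
cls = classified_summary(rows)
print(f"leaked: {cls.leaked_reads} ({percent(cls.leaked_reads, cls.all_reads)}%)")
```

Running `python examples/simulate_and_classify.py` (the same computation,
fuller report) prints:

```
simulated 5000 reads, 21.8 Mbp total
mapped:         4667  (93.3%)
unmapped:        333  (6.7%)
unclassified:   1024  (20.5%)
of 3976 classified reads:
  correct:   3658  (92.0%)
  leaked:      57  (1.4%)
  unmapped:   261  (6.6%)
```

The 6.7% unmapped and 1.4% leaked estimates recover the ligation-like
model's configured noise (7%) and leakage (1.5%) rates; the 20.5%
unclassified fraction recovers the configured demultiplexing loss (20%).
The other scripts in `examples/` demonstrate tandem merging and edge
profiling, per-channel homogeneity, and the planted printed-table fixtures.

## Command line

```sh
nanoplex-qc simulate --model PCR --n-reads 20000 --seed 1 --out run/
nanoplex-qc classify --summary run/sequencing_summary.txt --paf run/alignments.paf \
    --barcode-map run/barcode_map.tsv --trf-dat run/tandems.dat --out synthesis.tsv
nanoplex-qc report --synthesis synthesis.tsv --out report/
nanoplex-qc run --config pipeline.yaml --seed 1   # all stages from a config
```

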