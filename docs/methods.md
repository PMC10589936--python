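# Methods

## Read categorisation model

The unit of analysis is one sequenced read with two independent labels: the
demultiplexer's barcode call (a barcode label or the `unclassified`
sentinel) and the mapping call (the genome of its best alignment, or none).
The cross of the two gives five exclusive categories — CORRECT, LEAKED,
UNMAPPED, UNCLASSIFIED_MAPPED, UNCLASSIFIED_UNMAPPED — satisfying two
partition identities used as invariants throughout:
`correct + leaked + unmapped = classified` and
`classified + unclassified = all reads`, in both read counts and cumulative
base pairs. Mapped/unmapped is likewise an exact partition, equivalent to
splitting an alignment file on the unmapped flag.

One alignment defines a read's taxonomy. Among a read's alignments, primary
ones are preferred over secondary; then the maximum of PAF residue matches
wins; remaining ties break by higher identity, then lexicographically
smallest target. This is a total order, so classification is invariant under
permutation of the alignment file — checked by test. Reads mapping almost
equally well to two near-identical genomes are resolved by the same
deterministic order; `ambiguous_reads(margin)` surfaces reads whose top two
targets differ by fewer matched bases than the margin (default 0: empty
report), rather than changing the call.

Identity is `100·matched_bases/block_length` — the alignment-block (BLAST-
like) denominator. An alternative denominator (full read length) would
conflate partial alignment with error rate; query coverage
`100·(q_end − q_start)/read_length` reports that separately. The stringent
sorting filter keeps mapped reads with length ≥ 5000 bp, identity ≥ 95% and
coverage ≥ 80%; thresholds are inclusive (≥), matching the command-line flag
semantics of the filtering tools this mirrors, although prose descriptions
often say "greater than".

Leakage is estimated among classified reads only: an unclassified read's
barcode is unknown, so its leakage status is unobservable. The recovery
tests accordingly compare `leaked/(correct + leaked)` — a binomial estimate
of the per-read leakage probability among classified, mappable reads —
against the generator's configured rate.

## Coordinates and formats

All internal intervals are 0-based half-open. PAF query coordinates already
are; TRF `.dat` rows (1-based inclusive) are shifted on ingest, so a
normalised interval's length equals the report's inclusive length. The
sequencing summary is the read universe: an alignment whose read id is
absent from the summary is a hard validation error, while a summary read
with no alignment is legitimately unmapped. A missing `passes_filtering`
column is recomputed as mean Qscore ≥ 7 (the standard pass/fail threshold);
when the column is present the file's flag wins, because the basecaller's
own classification is the operative record. Unknown summary columns are
carried through as opaque strings and re-emitted on write.

## Tandem merging and edge profiling

Repeat finders report one row per (period, span) candidate, so one artifact
yields several overlapping rows. Merging unions strictly overlapping
intervals (`next.start < current.end`); abutting intervals stay separate —
total tandem length, the quantity that matters downstream, is invariant to
that choice, and the exact behaviour of historical parsers on touching
intervals is not documented. A read "has tandem content" when its merged
total is positive.

The edge profile counts tandem *bases* (not interval midpoints) per
distance-from-end bin, default 500 bp bins over a 15 kbp window per side:
base counting is unambiguous for intervals spanning several bins, and the
500 bp default resolves accumulation within the first 500–2500 bp of read
ends where nanopore tandem artifacts concentrate. The 5' and 3' panels are
independent views: on a read shorter than twice the window a base may count
on both sides, bounding the total binned mass by twice the tandem mass
(equality only when every tandem base lies inside both windows).

The naive detector finds maximal runs of `s[i] == s[i−p]` per period p
(positions with N never match), reporting runs with ≥ 2 unit copies above a
minimum span; every reported interval is verifiably a perfect repeat. It
exists so tests and examples need no external repeat-finder binary and it
deliberately omits alignment-scored, mismatch-tolerant detection; the
production path ingests TRF reports.

## Summary statistics

Flow-cell tables report reads in M (10⁶) and lengths in Gbp (10⁹),
rounded half-up to 2 decimals; percentages are computed from full-precision
counts and rounded half-up once, to 1 decimal in human tables and 4 decimals
in machine outputs. Per-channel means and SDs are taken over *active*
channels (≥ 1 read): silent channels are indistinguishable from dead pores,
and including them would understate per-channel output on partially used
flow cells. The SD is the population SD (ddof = 0) by default with the
sample SD exposed via `ddof=1`; with ~500 active channels the difference is
negligible, and neither convention is canonical for this report.

## Synthetic-run generator

The generator emulates the statistical structure of a multiplexed MinION
run; its defaults are the study conditions the analysis targets:

- **Unclassified rate 0.20** and **leakage rate 0.015** — the typical ~20%
  demultiplexing loss and <1.5% leakage of barcoded runs.
- **Noise rate per strategy** — LIG-like 0.07, TAG-like 0.13, PCR-like 0.75:
  the observed unmapped fractions of the three strategies (roughly 7%, 13%
  and more than 75%).
- **Length models** — log-normal bodies: LIG-like median 2500 bp, σ = 1.1
  (defined abundance peak at 2.5 kbp, heavy upper tail); TAG-like median
  2800 bp, σ = 1.25 (broad, no defined peak); PCR-like median 900 bp,
  σ = 0.9 hard-capped at 30 kbp, the processivity ceiling of a long-range
  polymerase. Noise reads draw shorter log-normals (unmapped reads are
  mostly sub-kbp). These are shape-matched approximations, not fits — only
  means, maxima and narrative shape are published — and every parameter is
  config-overridable.
- **Quality** — per-read mean Qscore ~ Normal(11, 1.5) clipped to [1, 30];
  noise reads run 2 points lower for LIG/TAG-like models and equal for
  PCR-like, where amplification artifacts sequence cleanly through pores.
- **Channels** — a symmetric Dirichlet over 512 channels (concentration 30 /
  10 / 3 for LIG / TAG / PCR-like) then multinomial assignment: one
  overdispersion knob reproducing the homogeneous-to-erratic ordering of
  per-channel output across strategies.
- **Tandem artifacts** — with per-strategy probability (0.19 / 0.28 / 0.63,
  the observed tandem-bearing read fractions) an exact repeat (period
  5–200 bp, ≥ 3 copies, ≤ 2000 bp) overwrites a stretch within 2500 bp of a
  uniformly chosen read end, and is recorded in the truth table and the
  `.dat` output.

Draw order per run is fixed (vectorised channel/noise/origin/length/
leakage/unclassified/tandem/Qscore draws, then a per-read loop for sequence
start, identity, coverage and tandem geometry) from a single seeded
generator, so one seed yields byte-identical files. Leakage is drawn before
unclassified masking: a leaked read can end unclassified and thus
undetectable, as in real runs, which is why recovery conditions on
classified reads. Simulated alignments are ground-truth-derived (target =
origin genome; identity ~ clipped Normal per strategy: 0.903 / 0.913 /
0.843 mean, matching observed mapped-read identities; coverage ~ clipped
Normal(0.97, 0.02)); no aligner runs, so alignment is error-free by
construction — the perfect-information limit in which classification must
recover every truth label exactly, and does (tested).

What the generator does **not** model: per-base error profiles and
homopolymer errors, signal-level behaviour, duplex reads, chimeras, barcode
cross-talk structure beyond uniform leakage, temporal pore decay. Passing
recovery tests therefore shows the *estimators* are correct on data with the
assumed statistical structure, not that real runs satisfy those assumptions.

## Planted table fixtures

Run-scale statistics derive from ~15 M reads and are not recomputable at
desk scale from raw data, so published table rows are reproduced via planted
fixtures: collections of synthesis rows whose category counts and cumulative
lengths equal the printed cells at 1:10,000 scale (cells are printed to
2 decimals in M/Gbp, so scaled counts are exact integers). Applying the
summary operations and rescaling reproduces the cells under the rounding
contract; ratio statistics recomputed from printed (rounded) cells can
differ from the publication's full-precision ratios by the propagated
rounding half-width, which the tests compute rather than guess. One
published row is internally inconsistent by one rounding unit (its
mapped + unmapped read and Gbp cells sum 0.01 below the printed totals);
the fixtures follow the partition cells and tolerate the unit offset.

## Problem sizes and numerical choices

Simulation-based tests and the acceptance script use 20,000-read runs per
library model — large enough that 3-binomial-SE recovery bands are a few
tenths of a percentage point, small enough to simulate in seconds — with
genome length 200 kb × 12 replicons (genome length only bounds read length
and does not enter any reported statistic). Merging sorts by (start, end)
with stable ties; empty inputs yield zero-valued summaries rather than
errors except where a mean is undefined (`length_quality_stats` requires
≥ 1 row); division-by-zero percentages report 0. Read lengths are floored
at 100 bp so planted tandems (minimum 15 bp) always fit.

## Known limitations

- Identity uses the alignment-block denominator; tools differ here, and
  comparisons against identities computed with other denominators need care.
- The leakage estimator cannot see leakage among unclassified reads by
  construction; reported leakage is a lower bound on total misassignment.
- The naive tandem detector finds perfect repeats only; real artifact
  detection should use a dedicated repeat finder and feed its report in.
- `plant_table_fixture` distributes lengths near-uniformly within a
  category, so fixtures reproduce totals and ratios, not length
  distributions.
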