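# Methods

This note records the models, rules and numerical conventions implemented
in `ighvkit`, the design choices made where the design was genuinely open,
and what the synthetic-data tests do and do not demonstrate.

## Data model and coordinates

A germline V allele is a named V-REGION with optional upstream segments
(5′UTR, L-PART1, L-PART2) that concatenate 5′→3′ into the full upstream
sequence, L-PART2 abutting the V-REGION start. V-REGION coordinates are
1-based over the IMGT-gapped string: gap (`.`) positions consume
coordinates, so the substitution labels the package emits (`G207T`,
`C210A`, …) follow the IMGT unique numbering. Ungapped references are
treated as already aligned to coordinate 1. Inferred reads are ungapped;
we standardise on gapped coordinates throughout and map them to read
offsets by counting non-gap reference positions. Upstream coordinates are
negative and right-anchored: −1 is the base immediately 5′ of the
V-REGION.

Mutation counting runs over gapped coordinates 1..312 by default — the
region germline-inference tools actually cover — skipping N and gap
positions and stopping at the read's end. Reads truncated short of a
position are treated as carrying no information there, equivalent to an N.

## Quality filters

Samples with strictly fewer than 2000 reads are excluded (a sample at
exactly 2000 is kept); the depth is the row count of the input table.
Analysis reads require V-REGION length strictly greater than 200 nt, at
most 3 mutations, and — for usage and upstream analyses — a single label
in `v_call` *after* duplicated-gene collapsing. Because the depth filter
counts rows of whatever table it is given, it commutes with the read
filters only when sample depths sit away from the threshold; the pipeline
applies it first, on the full table.

## False-positive filter

The mismatch frequency of a candidate (allele *a*, position *p*, base
change *x*→*y*) in carrier *i* is the fraction of *i*'s reads assigned to
*a* in the original (pre-realignment) annotation whose base at *p* is not
the germline *x*, among reads that cover *p* with a called base. Reads
with N at *p* are excluded from numerator and denominator alike (the
sources are silent on this; excluding them avoids biasing the fraction
with missing data). A carrier with an empty denominator raises an error
rather than returning 0 — the two situations mean different things.

Verdicts, in decreasing precedence:

1. `fp_blacklist` — the substitution pattern is on the configurable
   blacklist (default A152G, T154G, A85C) and pattern exclusion is
   enabled. The blacklist is configuration, not hard-coded biology: the
   patterns are dataset-specific artifacts, A→C being the dominant
   Illumina MiSeq substitution error.
2. `fp_batch_artifact` — every carrier lies outside the main batch and
   every carrier frequency equals 1.0.
3. `fp_low_frequency` — frequency < 0.35 in **all** carriers; one carrier
   at or above the threshold rescues the candidate.
4. `retained`.

The bundled positional detector (per sample and allele with ≥50 assigned
reads among ≤1-mutation reads, modal non-germline base at ≥0.2 of covering
reads) is plumbing so the filter can be exercised end-to-end; it is not a
reimplementation of any published inference algorithm, and real candidate
lists can be supplied as TSV instead.

## Usage and duplicated-gene collapsing

Collapse rules match on the *set* of labels in `v_call`, so annotator
ordering is irrelevant. The built-in rules merge
`{IGHV3-23*01, IGHV3-23D*01}`→`IGHV3-23*01D`,
`{IGHV1-69*01, IGHV1-69D*01}`→`IGHV1-69*01D`,
`{IGHV2-70*04, IGHV2-70D*04}`→`IGHV2-70*04D`,
`{IGHV3-30-5*01, IGHV3-30*18}`→`IGHV3-30X*doub` and that set plus
`IGHV3-30*01`→`IGHV3-30X*trip`; `CollapseMap.for_database` additionally
derives a rule for every identical-V-REGION group in a given reference.
Merged labels map to their own pseudo-gene (`IGHV3-23(D)`, `IGHV3-30X`) in
gene usage — the naming is explicit and configurable. Usage fractions are
computed over the analysis-filtered reads of each individual (the
denominator choice is exposed through what is passed in); allele fractions
sum to 1 per sample and gene fractions are an exact coarsening.

## Upstream inference

Per gene, ragged 5′ ends are conceptually N-padded to the longest read;
scanning from the anchor toward 5′, the first position where the N
fraction reaches 0.95 and everything 5′ of it are removed, then the
artificial Ns are dropped. The scan direction is chosen because, with
right-anchored padding, the N fraction is non-decreasing toward 5′, making
"the first position" well defined. Per allele, lengths with frequency
strictly above 0.1 are frequent; shorter reads are removed, longer ones
5′-trimmed to the longest frequent length. Per allele and individual,
reads are single-linkage clustered at identity ≥ 0.999 (matching non-N
positions over compared positions, right-anchored overlap) — at realistic
lengths a single mismatch breaks a link, so this is exact-match grouping
ignoring Ns; an all-N read has no comparable positions and forms a
singleton. A separate read-length coverage parameter is not reproduced:
after trimming, lengths are near-uniform and the criterion is vacuous — an
intentional simplification. Consensus calls the modal base where it
reaches 0.6 of non-N bases (non-strict, giving deterministic boundary
behaviour; two bases cannot tie at ≥0.6, and ties below threshold give N).
Cluster frequency is members over the individual's surviving reads for
that allele; clusters with <10 members or frequency <0.1 are removed (both
bounds inclusive on the keep side: 10 members at 0.1 survives). Clusters
whose consensus contains an N at a position where members genuinely
disagree (two or more distinct called bases) are split there — 5′-most
such position first, reads with N forming their own part — consensuses are
rebuilt, the cluster filters re-applied, and the process recurses.
Finally, per allele, all individuals' consensuses are 5′-trimmed to the
shortest, deduplicated within each individual, and identical sequences
across individuals become one record; variant indices are assigned by
descending carrier count, ties broken lexicographically, and the variant
suffix (`_1`, `_2`, …) appears only when an allele has more than one
record.

Open choices resolved here: the 95%-N trim pools all alleles of a gene
(the later steps are per allele), and the length-frequency denominator is
per allele. Both are flagged as conventions, not facts about the
underlying biology.

## Disambiguation

A candidate's upstream consensus is compared right-anchored against each
competing gene's records over the common support, N positions skipped; a
gene's distance is the minimum over its records. The unique minimiser is
assigned when the runner-up is at least `min_margin` (default 1) mismatches
worse; otherwise the call is `ambiguous` — with identical records for both
genes the output is always `ambiguous`, never a coin flip. The sources
give no quantitative margin rule ("matched better"), so the margin is an
explicit knob. On reassignment the candidate is renamed against the new
gene's closest allele; the record keeps both labels, which describe the
same sequence.

## Synthetic cohorts

The generator emulates a naïve-repertoire AIRR-seq experiment at the level
this package analyses it. Per individual: a diploid genotype per gene from
configurable allele frequencies (the per-gene remainder to 1 is deletion
mass); planted novel alleles make carriers heterozygous (closest reference
on one haplotype, novel on the other); one upstream haplotype per allele
drawn from configurable variants. Per read: a gene uniformly among present
genes, a copy at 50:50 by default (an imbalance parameter exists — the
0.35 threshold implicitly tolerates imbalance down to roughly 35:65); the
captured 5′UTR length follows, with probability 0.95, a discrete
triangular law rising over the last 8 lengths up to the full UTR (library
prep leaves only slight length variation) and is otherwise uniformly short
— the extreme-length tail the length-frequency filter exists to remove;
0–3 V-REGION point mutations per read (default P = 0.6/0.25/0.1/0.05);
sequencing errors at a uniform per-base rate, optionally with a threefold
A→C excess at A sites. `v_call` is filled deterministically with the
closest reference allele(s) by Hamming distance, ties joined with `", "` —
reads from planted novel alleles are therefore assigned to the closest
reference allele and duplicated identical genes produce multi-label calls,
exactly the situations the filters and collapse rules exist for. A single
integer seed determines everything; identical configurations are
byte-identical.

The bundled reference (`default_reference`) is synthetic: eight genes with
315 nt V-REGIONs, 45 nt L-PART1, 10 nt L-PART2 and family-specific UTR
lengths (20–64 nt), including one duplicated pair with identical V-REGIONs
but distinct 5′UTRs and one paralog pair differing at two V positions with
fully distinct upstreams. It reproduces the *structure* of the human IGHV
locus's awkward cases, not its sequences.

What the simulations do not emulate: UMI structure, paired-end assembly,
quality scores, clonal expansion, somatic hypermutation beyond 3
substitutions, indels, chimeric reads, or realistic allele-frequency
spectra. Passing parameter-recovery tests therefore shows the rules are
implemented faithfully and are identifiable under the stated noise models
— not that real repertoires satisfy those models.

## Benchmark conditions and problem sizes

The packaged benchmarks fix the study conditions used by the tests and by
`scripts/acceptance.py`:

* *Filter sensitivity/specificity*: 20 individuals at depth 2000, error
  rate 0.005 with threefold A→C bias, two planted heterozygous novel
  alleles at population frequency 0.5 with balanced expression.
* *Upstream recovery*: 6 individuals at depth 800, zero noise, two alleles
  carrying a second mid-UTR upstream haplotype at frequency 0.5. Depth is
  set so every carrier comfortably clears the 10-read cluster minimum
  after length filtering (roughly 3× the minimum per allele copy).
* *Disambiguation*: 4 individuals at depth 500 (same ≥3× headroom per
  allele copy), every individual a heterozygous carrier of the
  between-paralog candidate; a variant of the scenario gives both genes
  identical upstreams to verify the `ambiguous` outcome.

The test suite runs 50 seeds of the filter and disambiguation benchmarks
and 50 of upstream recovery; the acceptance script uses 25 seeds per
benchmark and reports the problem size next to every number it writes.

## Degenerate inputs and numerical conventions

Zero-denominator mismatch frequencies raise; alleles whose upstream
lengths are all infrequent are skipped with a warning at the pipeline
level (and raise at the operation level); empty upstream reads are
dropped; an empty germline database or a novel-allele spec referencing an
absent allele is a configuration error. All fraction comparisons follow
the strictness conventions above ("above 0.1" strict for lengths, "below
0.1"/"<10" strict for cluster removal, "≥0.6" non-strict for consensus,
"<2000" strict for depth, ">200" strict for V length, "<0.35 in all
carriers" strict). Equality checks against 1.0 in the batch rule use a
1e-12 tolerance.

## Known limitations

The candidate detector is intentionally naive (positional, no haplotype
model) and should not be used as an inference method on real data. The
annotation-confusion model (global nearest neighbour) ignores alignment
heuristics of real annotators. Upstream inference is always conditioned on
the V annotation and cannot discover upstream variants of alleles missing
from the reference. Introns are outside cDNA data and therefore outside
the package's evidence; disambiguation rests on upstream sequence alone.
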