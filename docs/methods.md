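# Methods

This note documents the models, parameter choices, numerical
conventions and known limitations of `endosift`.  It is written for a
reader who wants to know *why* the pipeline behaves as it does, and
what passing its tests does and does not demonstrate about real data.

## Coordinate and format conventions

All internal coordinates are 0-based, half-open.  The only 1-based
surfaces are VCF records, the wet-lab exclusion TSV and qPCR tables;
conversion happens at the format boundary and nowhere else.
Multiallelic VCF records are decomposed before filtering, and each
alternative allele is evaluated independently.  Alignments are consumed
through a reference-projected view (`ReadSet`): each query base maps to
one reference coordinate, insertions are dropped from the projection
(they consume no reference) and deletions are padded, matching pileup
semantics.  Duplicate marking is assumed to have happened upstream;
secondary and supplementary alignments are dropped at load time.

## Candidate calling and the support filter

The built-in caller is a frequency caller: at each pileup column, every
non-reference base whose per-sample observation fraction reaches
`min_fraction` (default **F = 0.03**) in at least one sample becomes a
candidate SNP.  It emits substitutions only; indel candidates enter via
external VCF ingestion and are carried through the depth-based stages
but skipped by the allele-anomaly battery (allele assignment at an
indel would require realignment, which is out of scope).  The caller
does not replicate the internals of haplotype-aware callers (population
priors, allele-balance aggregation); it stands behind the same module
surface so that external VCFs and simulated data follow one path.

The support filter retains a candidate when, within **at least one
tissue**, total depth is **strictly over 200** and the alternative
allele has **at least 10** reads.  The strict/non-strict readings
follow the wording of the thresholds ("over", "at least").  Whether the
depth clause should hold in one tissue or all is genuinely ambiguous;
`any_tissue` is the default (a real within-host variant may be absent
from a tissue) and `all_tissues` is a configuration switch.

## Uninfected-line window screen

A 300-bp window starting 150 bp before each candidate is searched for
reads from symbiont-free host lines aligned against the symbiont
reference; **≥ 2** such reads exclude the candidate.  Reads are pooled
across all uninfected samples (a per-sample mode exists), overlap of a
single aligned base counts, and the mapping-quality floor defaults
to 0 — each choice is the most conservative toward exclusion, matching
the pipeline's overall stance that a discarded true variant is cheaper
than a validated artifact.  Windows wrap on circular references and are
truncated at the edges of linear ones.

## Alignment-anomaly battery

Reads covering a candidate SNP (base quality ≥ 13 where qualities are
available; the floor is a common Phred cutoff and the only quality
filter in the battery) are split by carried allele.  Three features are
compared between the groups with two-sided Fisher exact tests:

* **clipped** — reads with any soft/hard clip, as a 2×2 read-count table;
* **proper_pair** — reads with the proper-pair flag, likewise (the
  counting unit is reads, not pairs: each read carries the flag, and
  mates may fall in different allele groups);
* **mismatch** — mismatching versus matching aligned bases, pooled per
  group, with the focal site excluded (alt-carrying reads have one
  mismatch subtracted).  Fisher requires counts, and base totals are
  the natural count rendition of a per-read mismatch load; a per-read
  binarisation (≥ 1 mismatch vs none) is available as `mismatch_mode =
  "read"`.

The Fisher p-value sums hypergeometric probabilities (computed in log
space via `gammaln`) of all tables no more probable than the observed
one; ties are detected with a relative tolerance of 1e-11, far below
the spacing of distinct hypergeometric probabilities at the table sizes
involved and far above the ~1e-14 accuracy of the log-gamma route.  A
zero margin leaves a single possible table, so p = 1.  The test suite
checks agreement with exact rational enumeration over every table with
total ≤ 40.

FDR correction (Benjamini–Hochberg, via statsmodels) is applied once
over the pooled candidates × features family (`global`), since the
validation is one correction pass over one candidate set; a
`per_candidate` scope is available.  A candidate is excluded when any
adjusted p is strictly below α = 0.05.  Candidates whose site is
uncovered or whose allele groups cannot both be populated are
**retained with an `untestable` flag** rather than silently dropped:
retention is conservative against silent loss, and the flag forces the
manual review that closes the pipeline.

Because Fisher p-values are discrete and conservative, the realised
exclusion rate of unbiased variants sits far below the nominal α; the
acceptance check bounds it at 6%.

## Coverage profiles

Window coverage is the mean per-base depth of called bases over
adjacent, non-overlapping windows (5 kb by default), normalised by the
median over windows.  Deleted reference columns contribute span but no
base, mirroring pileup depth.  The trailing partial window of a genome
not divisible by the window size is kept as its own shorter window —
the statistic is per-base, so no bias results.  The median of an even
number of windows is the mean of the two central values.  Window base
sums are kept as exact integers, so the conservation identity (sum of
window sums = total aligned bases) is exact.  Depth review around
surviving candidates uses 100-bp windows over ±500 bp, and a series is
flagged anomalous when any window departs from the series median by a
fold factor (default 2.0; the underlying decision is visual in
practice, so the threshold is configurable).

## Gene-conversion detection

Homologous pairs come from a catalog (emitted by the generator, or any
BED-pairs TSV) or from `find_pairs`, a seeded self-comparison: exact
16-mers shared by two genome positions seed candidate offsets, each
offset's gap-free mismatch track is grown greedily into maximal tracts
with identity ≥ `min_identity` (default 0.95) and length ≥ `min_tract`
(default 100 bp), and overlapping boundary alternatives are collapsed
to the interval with the sharpest boundary contrast (inside identity
minus flanking identity).  Gap-free comparison is justified by the
≥ 80% identity regime of interest.  The reported tract can extend a few
bases beyond a planted near-identical core when the flanking homology
permits, which may add one or two extra positionwise differences to the
diagnostic list; the generator's catalog is therefore preferred for
detection when available.

Detection evaluates, per sample, pair and direction, three criteria:
acceptor tract depth / flank depth ≤ **0.5**, donor tract depth / flank
depth ≥ **1.5**, and donor-allele fraction ≥ **0.9** at the acceptor's
diagnostic sites among reads still anchored there.  All three are
required for a `conversion` verdict; partial evidence (e.g., a deletion
produces the drop without the rise or the allele switch) is recorded on
a `none` verdict.  Tract and flank statistics are means of per-base
depth over the exact intervals — per-base resolution is finer than the
half-tract window the drop/rise structure requires, and avoids window
phasing artifacts on a ~100-bp tract.  Flanks span 2 kb on each side,
excluding other catalogued homologous regions.  The three thresholds
are calibrated on the simulator, where a paired-end retention fraction
of 0.2 produces acceptor/donor ratios near 0.2/1.8; the published
description of the phenomenon is qualitative ("very sharp drop",
matching rise).

`unpaired_remap_check` rescores acceptor-tract reads against both
copies, restricted to tract positions (the copies are identical there
apart from the diagnostic sites, so diagnostics decide the placement;
positions outside the tract are neutral, emulating soft clipping).
Reads covering no diagnostic site are ties, reported as unresolved.
With base errors at 1e-3, a read whose only covered diagnostic site is
hit by an error can tie or flip, so the expected reassigned fraction
among resolved reads is bounded below by roughly 1 − 3·(error rate),
not exactly 1; the acceptance check uses 0.99.

Generic structural-variant calling (discordant pairs, split reads) is
deliberately not reimplemented; external SV caller VCFs can be ingested
for annotation.

## Synthetic data generator

The generator emulates the study conditions the pipeline targets, at
desk scale (1/16 of the real genome):

* **Genome**: random circular 100 kb sequence carrying two homologous
  copies, 800 bp long, 8 kb apart (scaled from ~80 kb), at 92% overall
  identity, whose final 104-bp tract differs at exactly 5 diagnostic
  sites.  Outside the tract, the copy-to-copy differences are spread
  quasi-uniformly (even spacing with ±¼-spacing jitter) — the
  uniform-divergence model of an anciently duplicated paralog — so the
  tract is the only segment whose local identity rises above the
  copy-wide level.
* **Nuclear inserts**: three 2-kb symbiont fragments mutated at 3%
  divergence (per-site Bernoulli; the realised substitution count is
  recorded in the truth table), each embedded between 5-kb random host
  flanks as its own host contig.
* **Samples**: tissues `haemolymph`, `nerve_chain`, `ovaries` at
  533.7×, 769.8× and 723.9× symbiont coverage — the coverages of the
  motivating experiment — with paired 150-bp reads, fragment length
  Normal(350, 50) truncated at the read length, and uniform base errors
  at 1e-3.  Tissue libraries additionally contain host reads at 30×
  over the host contigs (total-DNA extraction carries host material);
  two uninfected samples at 15× each contain host reads only.
* **Mapping emulation**: reads are emitted as directly-constructed
  alignments, so the pipeline is testable with no aligner installed
  (SAM and FASTQ renditions exist for interoperability).  A host read
  is placed on the symbiont reference iff it overlaps the embedded
  insert by ≥ 50 bp (a typical seed-anchor requirement); overhangs into
  host background are soft-clipped and a read whose mate fails to map
  loses the proper-pair flag.  This reproduces the clipped, improper,
  mismatch-rich signature of insert-derived reads.
* **Planted events**: true SNPs at per-tissue frequencies (default: one
  SNP at 0.466/0.584/0.239, the frequency profile of the motivating
  experiment's validated variant), realised per read as a Bernoulli
  draw; artifact variants whose alternative reads receive soft clips
  with probability 0.5 and Poisson(3) extra mismatches; and optionally
  a gene conversion, realised both in the template (donor alleles over
  the acceptor tract) and in the mapping (a read covering ≥ 1
  diagnostic site is re-placed at the donor with probability 0.8,
  the remainder representing paired-end rescue).  A baseline 2% of all
  reads carry a random 5–30-bp soft clip, so the clip feature's
  reference group is non-degenerate.
* **Placement rules**: planted variants and artifacts are kept ≥ 500 bp
  from insert intervals and homolog copies and ≥ 400 bp from each
  other, so each planted event tests exactly one mechanism.
* **Determinism**: all randomness derives from the design seed through
  fixed named streams; identical designs give byte-identical FASTQ,
  SAM and truth-table output.  The truth table round-trips through TSV
  losslessly.

What the generator does **not** model: sequencing-technology error
profiles (quality ramps, context-dependent errors), PCR duplicates,
indel errors, GC-coverage bias, mapping ambiguity beyond the anchor
rule, and host genome structure beyond isolated insert contigs.
Passing the planted-truth tests therefore shows that the stages
implement their contracts and have the intended power against the
modelled artifact mechanisms — not that real libraries are free of
artifact classes outside the model.

## Problem sizes in the checks

The reproduction script and the acceptance tests use the generator's
default conditions: 20 seeds for the window-screen recovery (full
three-tissue datasets), 20 seeds × 50 unbiased variants plus 3
clip-biased artifacts for the battery's error control, 20 converted and
20 unconverted single-sample 500× runs for the conversion detector,
the full enumeration of 2×2 tables with total ≤ 40 for the Fisher
reference, 1,000 random vectors for the BH reference, and a 10-kb
genome for the brute-force coverage oracle.  These sizes make every
check exact or tightly bounded while keeping a complete run in the
minutes range.

## Known limitations

* The naive caller has no indel support and no local realignment.
* `find_pairs` does not search across the origin of circular genomes
  and reports gap-free tracts only.
* The anomaly battery pools reads across tissue samples; a per-tissue
  battery would need a further FDR-scope decision the pipeline does not
  take.
* The conversion detector assumes the acceptor and donor tracts are
  catalogued; it does not scan for unannotated homology at detection
  time (use `find_pairs` first).
* Retention percentages are reported both rounded and truncated because
  published funnel percentages do not state which convention they use.
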