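# Methods

## Data model and selection

The atomic unit is the *occurrence*: one report of a taxon in one sample of
one literature reference, assigned to a stage bin.  An entry may stand for
one specimen or many; it is always counted once.  Samples are identified
only within their reference (`reference_id` + `sample_id` is the key).
Stage labels must resolve to exactly one bin of the configured scale; three
sentinels exist outside the scale — `pre-interval` and `post-interval`
records are kept solely to extend taxon ranges to the scale's edges, and
`unresolved` records (dating too coarse for a single bin) are removed at
the first filter step.  Records that could be duplicated into several
candidate bins are not: multi-bin dating maps to `unresolved`, which keeps
per-bin counts reproducible.

Open-nomenclature parsing is positional.  Qualifiers before the genus word
("?Lepidopteris martinsii", "cf. Voltzia") mark a tentative generic
assignment and exclude the record from genus-level and species-level
analyses; qualifiers at the epithet slot ("Lepidopteris sp.",
"Voltzia cf. heterophylla") exclude it only from species-level analyses.
The recognized tokens are sp, spp, cf, aff, ?, ex gr; any other
provisional marker is folded into a single open-nomenclature category and
treated like sp.  Reworked and possibly-reworked *sporomorph* records are
dropped at every rank; macrofossils carry the flag but are kept by default,
since reworking assessments for them are rarely reported.

Synonymy, whole-plant merging of organ genera, and genus→family assignment
are user-supplied two-column tables, not code: taxonomic opinion is data.
Maps must be pre-resolved (no a→b, b→c chains).  Every transformation logs
how many rows it removed; the provenance deltas always reconcile with the
row counts, so data loss is never silent.

## Ranges and indices

A taxon's range is the closed bin interval between its first and last
in-interval occurrence; within it the taxon is present even where
unsampled (a Lazarus taxon), and pre-/post-interval occurrences extend
presence to the scale's outer bins.  Per bin, present taxa split into four
exclusive types by boundary crossing (single-bin / bottom-only / top-only /
through), with extensions counting as crossing the outermost boundaries.
From the four counts:

* total (range-through) diversity = their sum; SIB diversity counts only
  sampled presence; Lazarus count = total − SIB;
* normalized diversity = `n_through + 0.5·(n_bottom + n_top + w_single·n_single)`.
  The half-weight reading for taxa that both originate and go extinct in
  the bin is genuinely ambiguous; `w_single = 1` (such a taxon contributes
  two half-events, weight 0.5 in total) is the default and `w_single = 0`
  is exposed;
* originations = top-only, extinctions = bottom-only — single-bin taxa are
  excluded from turnover — and rates divide these counts by the bin
  duration in Myr.  Durations come from the stage scale; the default scale
  uses ICS 2018/08 ages, making the Induan (0.702 Myr) four- to
  seven-fold shorter than its neighbours.

Edge bins deserve a caveat: without out-of-interval extensions, every
taxon reaching the final bin counts as "going extinct" there and every
taxon in the first bin as "originating".  Interpretation (and the tests)
therefore focus on interior bins.

The extinction *fraction* of a bin divides extinctions by total
(range-through) diversity by default; SIB is available as an alternative
denominator, since printed percentages in the literature rarely state
which was used.

The species-diversity floor (`species_diversity_variants`) addresses bins
where genus diversity exceeds named-species diversity: logically each
genus present in a bin must carry at least one species, so the
`min-one-per-genus` variant adds one species for every genus (sampled or
ranging through) contributing no named species to that bin.

## Coverage and subsampling

Good's coverage of a selection is `u = 1 − n1/N` (n1 = taxa with exactly
one occurrence, N = total occurrences).  An "occurrence" for coverage
counting is a taxon's incidence in one sample, merged within a reference
when `merge_repeats` is on — both in the subsampler and in the per-bin
`coverage_u` column, which are thereby consistent.

The subsampling unit is the reference.  Per trial: shuffle the bin's
references; for each drawn reference take up to `sample_quota` (default 5)
of its samples uniformly without replacement; add the (merged) occurrences;
recompute `u`; record the current distinct-taxon count at every *upward
crossing* of the quorum.  Trials (default 500) are pooled before
summarizing into the median and the 2.5th/97.5th percentiles (linear
interpolation between order statistics, the numpy default — R's default
`quantile` type differs slightly).

The crossing rule is the one deliberate interpretive choice in this
module.  Recording at every draw at or above the quorum makes the pooled
median grow with the total size of a bin's literature (measured on
constant-richness data: medians 22 vs 50 for 10 vs 50 references), which
defeats the purpose of coverage standardization; recording at crossings
ties the estimate to the selection size at which coverage first attains
the quorum, and recovers equal medians for equally rich bins regardless
of effort (measured: 38% SIB contrast vs ~1% median contrast).  Coverage
can genuinely dip below the quorum when a singleton-rich reference
arrives, so one trial can still record several values.  No dominant-taxon
exclusion or three-timer correction is applied.  A trial that never
attains the quorum records nothing; a bin where no trial does (e.g. a
single-reference bin, where every merged occurrence is a singleton and
`u` is pinned to 0) yields a flagged no-estimate row rather than a number.

Randomness: one master seed; per-bin and per-trial substreams are derived
through `SeedSequence`, so results are independent of the order in which
bins are computed and identical seeds give byte-identical exports.

## Trend statistics

Spearman's r_s is computed from average ranks (scipy).  The two-sided
p-value is exact — full enumeration of the n! rank permutations — for
tie-free series with n ≤ 9, which covers the six-bin series this package
exists for; with ties or longer series it falls back to the
t-approximation, and the result records which method was used.  Exact
small-n p-values are chunky by nature (multiples of 1/n!), and published
values computed with other approximations may differ; r_s itself does not.
Flags: strong if |r_s| > 0.6, significant if p < 0.05, always recomputed
from the stored values.  σ-scaling subtracts the mean and divides by the
sample (n−1) standard deviation; constant series are an error, not a NaN.

## The synthetic record

The generator separates biology from preservation so that each analysis
stage can be tested against known truth.

*Biology*: discrete-time birth–death over the stage bins.  Each taxon
enters with the initial cohort (probability `origination_probs[0]`) or at
a later bin, terminates with the per-bin extinction probability, and draws
one relative abundance weight — lognormal(0, 1) by default, because
coverage-based methods are only informative when frequency distributions
are heterogeneous.  Origination and extinction are bin-boundary events,
matching the binned analysis rather than continuous time.

*Preservation*: per bin, a configured number of references; samples per
reference and occurrences per sample follow small count distributions
(fixed, geometric ≥ 1, or shifted Poisson ≥ 1); each occurrence draws a
taxon from the bin's extant pool proportionally to abundance.  Emitted
tables use the standard input dialect, so they flow through the reader,
filters and indices unchanged.  What this does *not* emulate: facies and
taphonomic structure, spatial provinciality, taxonomic inconsistency
between workers, or correlated sampling across bins.  Passing tests
demonstrate that the *statistical* machinery behaves correctly under the
stated sampling model, not that any real dataset is unbiased.

Scenario presets encode the three artifact narratives.
`uniform-richness-uneven-sampling`: 60 taxa in every bin, references
varying 5× (50/25/10/15/30/50), geometric(2) samples, Poisson(3)+1
occurrences — sampling-driven diversity for the SQS recovery experiment.
`sudden-extinction`: 60 taxa, half terminating at the second stage
boundary, uniform sampling — a true pulse the indices must localize.
`induan-gap`: 250 taxa in every bin, 10 references per stage but one in
the short bin, fixed 3 samples per reference, Poisson(6)+1 occurrences.
The gap preset's intensity was set by a detection-probability power
calculation: a taxon with per-bin detection d contributes
`d²(1−d)³·(1−d_gap)` to the expected apparent-extinction count in the bin
before the gap (it must be seen in both earlier bins and missed
afterwards), which is maximized near d ≈ 0.4; 250 taxa at ≈210
occurrences per bin put the expected count near 4.6, so the smearing
demonstration is reliable rather than anecdotal, and a fixed
samples-per-reference count keeps per-bin effort from overdispersing it.

## Sizes and tolerances

Replicate experiments use 20 replicates and 100 subsampling trials
(defaults elsewhere remain 500); six bins, 60–250 taxa.  Scaled-series
checks use 1e−12 on moments; exact integer quantities (classification
counts, coverage numerators) are compared exactly.  Known limitations:
no abundance-weighted or extrapolating richness estimators, no
phylogenetic or spatial structure, edge-bin turnover is uninterpretable
without out-of-interval data, and exact reproduction of historical
p-values computed with other software's tie-handling is out of reach by
design.
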