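# floradiv

Stage-binned diversity analysis for fossil occurrence data, built for the
kind of question the Permian–Triassic land-plant record poses: when a
diversity curve drops across a boundary, is that biology or is it the
literature?  The package turns long-format occurrence tables (one row per
taxon report per sample per reference) into per-stage diversity and
turnover indices, standardizes richness for uneven sampling with
coverage-based (shareholder quorum) subsampling, and quantifies
sampling-bias symptoms — all backed by a synthetic fossil-record generator
with known truth, so every claim the chain makes can be tested against a
record where the answer is known.

## What it computes

For taxa binned into an ordered stage scale (default: Wuchiapingian →
Ladinian, ICS 2018/08 ages), each taxon's range runs from its first to its
last occurrence, with presence inferred in unsampled interior bins
(Lazarus taxa) and optional extension by out-of-interval records.  Within a
bin every present taxon is one of four types — confined to the bin,
bottom-boundary crosser (going extinct), top-boundary crosser
(originating), or ranging through — and from these counts follow:

* **sampled-in-bin (SIB)** richness and **total (range-through)** richness;
* **normalized diversity** `n_through + ½(n_bottom + n_top + w·n_single)`,
  an estimate of mean standing diversity;
* origination/extinction/turnover counts (single-bin taxa excluded) and
  their per-Myr rates;
* Lazarus counts and proportions, entries per stage, and Good's coverage
  `u = 1 − n1/N` per bin.

**SQS by reference** draws references without replacement, adds up to five
samples per reference (a taxon repeated within one reference counts once),
recomputes `u` after every draw, and records the distinct-taxon count at
each upward crossing of the quorum (default 0.4); the pooled counts over
500 trials give a median and 95% interval of richness at equal coverage.
**Trend diagnostics** are Spearman rank correlations (exact permutation
p-values at these series lengths) and mean-centred, σ-scaled overlays.

## Worked example

A constant-richness flora (250 genera, every bin) sampled by 10 references
per stage — except the short Induan, which gets one:

```python
import floradiv as fd

history, records = fd.simulate_scenario("induan-gap", seed=1)
filtered = fd.apply_selection_filters(records, "genus")
ranges = fd.build_taxon_ranges(filtered, "genus")
table = fd.compute_stage_table(filtered, ranges)
print(table[["sib", "total", "lazarus_proportion", "extinction_rate", "coverage_u"]].round(3))
```

```
               sib  total  lazarus_proportion  extinction_rate  coverage_u
stage
Wuchiapingian   97     97               0.000            0.000       0.651
Changhsingian   96    124               0.226            0.894       0.663
Induan          16    121               0.868            0.000       0.000
Olenekian      122    157               0.223            4.000       0.635
Anisian         99    135               0.267            7.308       0.702
Ladinian       103    103               0.000           17.400       0.685
```

True richness is flat at 250 and true extinction is zero everywhere, yet
the under-sampled Induan collapses to 16 sampled genera with 87% Lazarus
taxa, and apparent extinctions appear in the Changhsingian — the
Signor–Lipps effect manufactured on demand.  (The Induan's single
reference also defeats coverage estimation: with every merged occurrence a
singleton, `u` stays at 0 and SQS correctly reports *no estimate* rather
than a number.)

The numbered drivers under `analysis/` run the full study:
`01_simulate_scenarios.py` writes the three scenario datasets,
`02_diversity_tables.py` their stage tables, `03_sqs_recovery.py` the
20-replicate subsampling experiment (raw SIB contrast 38% between the
best- and worst-sampled bins vs 1.3% for SQS medians, intervals
overlapping in 20/20), and `04_bias_diagnostics.py` the effort
correlations (mean r_s = 0.94 under constant true richness) and the
Signor–Lipps tally.  There is also a CLI: `floradiv simulate --preset
induan-gap --seed 1 --out DIR` and `floradiv run --occurrences FILE --rank
genus --seed 1 --out DIR`.

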