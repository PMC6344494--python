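"""Per-stage diversity, turnover and bias-diagnostic indices.

All indices derive from the four boundary-crossing classes of
:mod:`floradiv.ranges`:

* sampled-in-bin (SIB) diversity — taxa actually reported from the bin;
* total (range-through) diversity — the sum of the four classes;
* normalized diversity — an estimate of mean standing diversity:
  through-rangers count fully, taxa that originate or go extinct within the
  bin count half, and single-bin taxa (which do both) count ``w_single``
  halves (default ``w_single = 1``, i.e. weight 0.5);
* origination = top-only crossers, extinction = bottom-only crossers
  (single-bin taxa are excluded from turnover), with per-Myr rates obtained
  by dividing by the bin duration;
* Lazarus count = total − SIB: taxa inferred present but unreported;
* Good's coverage u = 1 − n1/N of the bin's occurrences, where a taxon's
  occurrence count is the number of distinct references reporting it
  (repeat reports within one reference are merged, matching the
  subsampling module's counting).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import UndefinedResultError
from .ranges import FourTypeCounts, TaxonRange, classify_stage_taxa
from .records import OccurrenceRecordSet
from .sqs import goods_coverage

__all__ = [
    "bin_coverage",
    "compute_stage_table",
    "extinction_fraction",
    "normalized_diversity",
    "species_diversity_variants",
]


def normalized_diversity(counts: FourTypeCounts, w_single: float = 1.0) -> float:
    """Mean-standing-diversity estimate from the four-type counts."""
    return counts.n_through + 0.5 * (
        counts.n_bottom_only + counts.n_top_only + w_single * counts.n_single
    )


def bin_coverage(records: OccurrenceRecordSet, stage_name: str) -> float:
    """Good's u for one bin; NaN for an empty bin."""
    df = records.in_interval
    sub = df[df["stage"] == stage_name]
    if sub.empty:
        return float("nan")
    taxon = (sub["genus_name"] + " " + sub["species_epithet"]).str.strip()
    merged = sub.assign(_t=taxon).groupby(["reference_id", "_t"]).size()
    counts = merged.groupby(level="_t").size()  # references per taxon
    state = goods_coverage(counts.to_dict())
    return state.u


def compute_stage_table(
    records: OccurrenceRecordSet,
    ranges: dict[str, TaxonRange],
    w_single: float = 1.0,
) -> pd.DataFrame:
    """Full per-stage diversity table (one row per bin, oldest first).

    Columns: sib, total, normalized, lazarus_count, lazarus_proportion,
    n_single / n_bottom_only / n_top_only / n_through, originations,
    extinctions, turnover, the per-Myr rates, n_entries and coverage_u.
    """
    scale = records.stage_scale
    n_bins = len(scale)
    range_list = list(ranges.values())
    entries = records.in_interval["stage"].value_counts()

    rows = []
    for b, sbin in enumerate(scale):
        four = classify_stage_taxa(range_list, b, n_bins)
        sib = sum(r.sampled[b] for r in range_list)
        total = four.total
        lazarus = total - sib
        originations = four.n_top_only
        extinctions = four.n_bottom_only
        turnover = originations + extinctions
        rows.append(
            {
                "stage": sbin.name,
                "duration_myr": sbin.duration,
                "sib": sib,
                "total": total,
                "normalized": normalized_diversity(four, w_single),
                "lazarus_count": lazarus,
                "lazarus_proportion": lazarus / total if total else 0.0,
                "n_single": four.n_single,
                "n_bottom_only": four.n_bottom_only,
                "n_top_only": four.n_top_only,
                "n_through": four.n_through,
                "originations": originations,
                "extinctions": extinctions,
                "turnover": turnover,
                "origination_rate": originations / sbin.duration,
                "extinction_rate": extinctions / sbin.duration,
                "turnover_rate": turnover / sbin.duration,
                "n_entries": int(entries.get(sbin.name, 0)),
                "coverage_u": bin_coverage(records, sbin.name),
            }
        )
    table = pd.DataFrame(rows).set_index("stage")
    assert (table["sib"] <= table["total"]).all()
    assert (table["lazarus_count"] >= 0).all()
    return table


def extinction_fraction(
    table: pd.DataFrame, stage_name: str, denominator: str = "total"
) -> float:
    """Percentage of the bin's standing taxa that go extinct in it.

    ``denominator`` is ``"total"`` (range-through diversity, the default) or
    ``"sib"``.  Returned unrounded, on the 0–100 scale.
    """
    row = table.loc[stage_name]
    denom = row[denominator]
    if denom == 0:
        raise UndefinedResultError(
            f"extinction fraction undefined: {denominator}={0} in {stage_name}"
        )
    return 100.0 * row["extinctions"] / denom


def species_diversity_variants(
    ranges_species: dict[str, TaxonRange],
    ranges_genus: dict[str, TaxonRange],
    n_bins: int,
) -> pd.DataFrame:
    """Named-only vs at-least-one-species-per-genus species diversity.

    Species totals undercount whenever a genus is present in a bin (sampled
    or ranging through) without any named species recorded there; logically
    at least one species of that genus must have existed.  The second
    variant adds one species for every such genus.
    """
    named = np.zeros(n_bins, dtype=int)
    genus_named = {}  # genus -> boolean presence-by-named-species vector
    for taxon, r in ranges_species.items():
        genus = taxon.split()[0]
        lo, hi = r.presence_bounds()
        vec = genus_named.setdefault(genus, np.zeros(n_bins, dtype=bool))
        vec[lo : hi + 1] = True
        named[lo : hi + 1] += 1

    extra = np.zeros(n_bins, dtype=int)
    for genus, r in ranges_genus.items():
        lo, hi = r.presence_bounds()
        covered = genus_named.get(genus, np.zeros(n_bins, dtype=bool))
        for b in range(lo, hi + 1):
            if not covered[b]:
                extra[b] += 1

    return pd.DataFrame(
        {"named_only": named, "min_one_per_genus": named + extra},
        index=pd.RangeIndex(n_bins, name="bin"),
    )
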