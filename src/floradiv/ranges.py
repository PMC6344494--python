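"""Taxon stratigraphic ranges and boundary-crosser classification.

A taxon's range is the contiguous stretch of stage bins between its first
and last sampled occurrence; inside that stretch it is *inferred present*
even in bins where it was never reported (Lazarus bins).  Occurrences that
pre- or post-date the studied interval do not get bins of their own but can
extend a range to the scale's outer edge.

Within any one bin a present taxon falls into exactly one of four classes
depending on which bin boundaries its range crosses:

* single       — confined to the bin (crosses neither boundary)
* bottom-only  — enters from below and ends here (goes extinct)
* top-only     — first appears here and continues (originates)
* through      — crosses both boundaries

These four counts are the basis of every diversity and turnover index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .records import OccurrenceRecordSet
from .stages import POST_INTERVAL, PRE_INTERVAL, SENTINELS


@dataclass(frozen=True)
class TaxonRange:
    """Sampled and inferred presence of one taxon over the stage bins."""

    taxon: str
    first_bin: int
    last_bin: int
    sampled: tuple[bool, ...]          # reported-in-bin flags, one per bin
    extended_before: bool = False      # pre-interval occurrence exists
    extended_after: bool = False       # post-interval occurrence exists

    def __post_init__(self) -> None:
        if self.first_bin > self.last_bin:
            raise ValueError("first_bin > last_bin")

    @property
    def n_bins(self) -> int:
        return len(self.sampled)

    def presence_bounds(self, extend: bool = True) -> tuple[int, int]:
        """Inclusive (lo, hi) bin span of inferred presence."""
        lo = 0 if (extend and self.extended_before) else self.first_bin
        hi = self.n_bins - 1 if (extend and self.extended_after) else self.last_bin
        return lo, hi

    def present(self, b: int, extend: bool = True) -> bool:
        lo, hi = self.presence_bounds(extend)
        return lo <= b <= hi

    def crosses_bottom(self, b: int, extend: bool = True) -> bool:
        """Range crosses the older boundary of bin ``b``.

        A pre-interval extension counts as crossing the scale's outermost
        bottom boundary.
        """
        lo, hi = self.presence_bounds(extend)
        if not (lo <= b <= hi):
            return False
        return b > lo or (b == 0 and extend and self.extended_before)

    def crosses_top(self, b: int, extend: bool = True) -> bool:
        lo, hi = self.presence_bounds(extend)
        if not (lo <= b <= hi):
            return False
        return b < hi or (b == self.n_bins - 1 and extend and self.extended_after)


@dataclass(frozen=True)
class FourTypeCounts:
    """Per-bin counts of the four boundary-crossing classes."""

    n_single: int
    n_bottom_only: int
    n_top_only: int
    n_through: int

    @property
    def total(self) -> int:
        """Range-through (total) diversity of the bin."""
        return self.n_single + self.n_bottom_only + self.n_top_only + self.n_through


def _taxon_labels(df: pd.DataFrame, rank_level: str) -> pd.Series:
    if rank_level == "species":
        labels = (df["genus_name"] + " " + df["species_epithet"]).str.strip()
        labels[df["species_epithet"] == ""] = ""
    elif rank_level == "genus":
        labels = df["genus_name"]
    elif rank_level == "family":
        labels = df["family"]
    else:
        raise ConfigError(f"unknown rank_level {rank_level!r}")
    return labels


def build_taxon_ranges(
    records: OccurrenceRecordSet,
    rank_level: str,
    extend: bool = True,
) -> dict[str, TaxonRange]:
    """Build one :class:`TaxonRange` per taxon at the requested rank.

    Records that cannot be named at the rank (no epithet at species level,
    no family at family level) are dropped.  Taxa known only from outside
    the studied interval yield no range at all — they are never present in
    any bin.  ``extend=False`` ignores pre-/post-interval occurrences
    entirely.
    """
    scale = records.stage_scale
    n_bins = len(scale)
    df = records.df
    labels = _taxon_labels(df, rank_level)
    usable = labels != ""

    ranges: dict[str, TaxonRange] = {}
    for taxon, sub in df[usable].groupby(labels[usable], sort=True):
        stages = sub["stage"]
        in_bins = sorted(scale.index(s) for s in stages[~stages.isin(SENTINELS)])
        before = extend and (stages == PRE_INTERVAL).any()
        after = extend and (stages == POST_INTERVAL).any()
        if not in_bins:
            continue  # sentinel-only taxon: never present in the interval
        sampled = np.zeros(n_bins, dtype=bool)
        sampled[in_bins] = True
        ranges[taxon] = TaxonRange(
            taxon=taxon,
            first_bin=in_bins[0],
            last_bin=in_bins[-1],
            sampled=tuple(sampled.tolist()),
            extended_before=bool(before),
            extended_after=bool(after),
        )
    return ranges


def classify_stage_taxa(ranges, b: int, n_bins: int | None = None) -> FourTypeCounts:
    """Count the four boundary-crossing classes among taxa present in bin ``b``.

    ``ranges`` is any iterable of :class:`TaxonRange` (or the dict returned
    by :func:`build_taxon_ranges`, in which case its values are used).
    """
    if isinstance(ranges, dict):
        ranges = list(ranges.values())
    else:
        ranges = list(ranges)
    if n_bins is None:
        if not ranges:
            raise ConfigError("cannot infer the number of bins from an empty range set")
        n_bins = ranges[0].n_bins
    if not (0 <= b < n_bins):
        raise ConfigError(f"bin {b} outside the {n_bins}-bin scale")

    single = bottom = top = through = 0
    for r in ranges:
        if not r.present(b):
            continue
        cb, ct = r.crosses_bottom(b), r.crosses_top(b)
        if cb and ct:
            through += 1
        elif cb:
            bottom += 1
        elif ct:
            top += 1
        else:
            single += 1
    return FourTypeCounts(
        n_single=single, n_bottom_only=bottom, n_top_only=top, n_through=through
    )
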