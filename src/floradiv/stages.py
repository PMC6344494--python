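"""Chronostratigraphic stage scales.

A :class:`StageScale` is the ordered list of time bins every other module
bins occurrences into.  Bins are ordered oldest to youngest, adjacent bins
share a boundary age, and each bin carries a duration in Myr used to
normalize turnover counts into rates.

Occurrence tables may additionally carry three sentinel "stages" that are
not bins of the scale: ``pre-interval`` and ``post-interval`` (records older
or younger than the studied interval, retained only to extend taxon ranges)
and ``unresolved`` (dating too coarse to place the record in a single bin).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PRE_INTERVAL = "pre-interval"
POST_INTERVAL = "post-interval"
UNRESOLVED = "unresolved"
SENTINELS = frozenset({PRE_INTERVAL, POST_INTERVAL, UNRESOLVED})


@dataclass(frozen=True)
class StageBin:
    """One chronostratigraphic bin with numeric boundary ages in Ma."""

    name: str
    base_age: float  # older boundary, Ma
    top_age: float   # younger boundary, Ma

    @property
    def duration(self) -> float:
        """Bin duration in Myr."""
        return self.base_age - self.top_age


@dataclass(frozen=True)
class StageScale:
    """Ordered (oldest -> youngest) sequence of stage bins."""

    bins: tuple[StageBin, ...]

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValueError("StageScale needs at least one bin")
        for b in self.bins:
            if not b.duration > 0:
                raise ValueError(f"bin {b.name!r} has non-positive duration")
        for older, younger in zip(self.bins, self.bins[1:]):
            if not np.isclose(older.top_age, younger.base_age):
                raise ValueError(
                    f"bins {older.name!r} and {younger.name!r} do not share a boundary age"
                )
        names = [b.name for b in self.bins]
        if len(set(names)) != len(names):
            raise ValueError("duplicate bin names")

    def __len__(self) -> int:
        return len(self.bins)

    def __iter__(self):
        return iter(self.bins)

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bins]

    @property
    def durations(self) -> np.ndarray:
        return np.array([b.duration for b in self.bins])

    def index(self, name: str) -> int:
        """Bin index of a stage name; raises ``KeyError`` for sentinels."""
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"{name!r} is not a bin of this stage scale") from None

    def is_valid_stage(self, label: str) -> bool:
        """True for bin names and the three sentinel labels."""
        return label in SENTINELS or label in self.names


def default_scale() -> StageScale:
    """Wuchiapingian–Ladinian scale with ICS (2018/08) boundary ages.

    The Induan is the conspicuously short bin (~0.7 Myr) against 2.2–5.2 Myr
    for the other five stages, which is what makes per-Myr rate normalization
    and the under-sampling diagnostics in this interval interesting.
    """
    ages = [
        ("Wuchiapingian", 259.1, 254.14),
        ("Changhsingian", 254.14, 251.902),
        ("Induan", 251.902, 251.2),
        ("Olenekian", 251.2, 247.2),
        ("Anisian", 247.2, 242.0),
        ("Ladinian", 242.0, 237.0),
    ]
    return StageScale(tuple(StageBin(n, b, t) for n, b, t in ages))
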