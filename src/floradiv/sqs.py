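"""Shareholder quorum subsampling (SQS) by reference.

Richness counts from unevenly sampled bins are not comparable; SQS compares
them at equal *coverage* instead of equal sample size.  Coverage of a
selection of occurrences is estimated with Good's u,

    u = 1 − n1 / N,

where n1 is the number of taxa with exactly one occurrence in the selection
and N the total number of occurrences.  The subsampling unit here is the
literature reference: within one bin, references are drawn randomly without
replacement, up to ``sample_quota`` samples of the drawn reference are added
to the selection, and (with ``merge_repeats``) a taxon reported in several
samples of that one reference counts as a single occurrence, so references
that repeat a short list of taxa cannot inflate coverage.  Coverage is
recomputed after every reference draw, and each time it reaches or
overtakes the quorum — i.e. at every upward crossing, since a draw rich in
new singletons can push the estimate back below the quorum — the current
distinct-taxon count is recorded.  The whole walk through the references is
repeated ``trials`` times; the pooled recorded counts yield the median and
its 2.5th/97.5th percentile bounds.  Recording at crossings rather than at
every draw above the quorum is what makes the estimate coverage-
standardized: the recorded richness reflects the selection size at which
coverage first attains the quorum, not how much further the bin's
literature happens to extend.

Defaults follow the standard configuration for stage-binned plant data:
quorum 0.4, 500 trials, sample quota 5, merge repeats on.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .stages import SENTINELS

__all__ = [
    "CoverageState",
    "SQSConfig",
    "goods_coverage",
    "sqs_by_reference",
    "sqs_per_stage",
    "summarize_trials",
]


@dataclass(frozen=True)
class CoverageState:
    """Occurrence totals and estimated coverage of a selection."""

    N: int
    n1: int

    @property
    def u(self) -> float:
        """Good's coverage estimate; NaN for an empty selection."""
        if self.N == 0:
            return float("nan")
        return 1.0 - self.n1 / self.N


def goods_coverage(selection) -> CoverageState:
    """Coverage of a multiset of taxon occurrences.

    ``selection`` is an iterable of taxon labels (one element per
    occurrence) or a mapping taxon -> occurrence count.
    """
    counts = selection if isinstance(selection, dict) else Counter(selection)
    n = int(sum(counts.values()))
    n1 = sum(1 for c in counts.values() if c == 1)
    return CoverageState(N=n, n1=n1)


@dataclass(frozen=True)
class SQSConfig:
    quorum: float = 0.4
    trials: int = 500
    sample_quota: int = 5
    merge_repeats: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.quorum < 1:
            raise ConfigError("quorum must be in (0, 1)")
        if self.trials < 1 or self.sample_quota < 1:
            raise ConfigError("trials and sample_quota must be positive")


def _bin_structure(df: pd.DataFrame) -> dict[str, dict[str, list[str]]]:
    """reference_id -> sample_id -> list of distinct taxon labels."""
    taxon = (df["genus_name"] + " " + df["species_epithet"]).str.strip()
    struct: dict[str, dict[str, list[str]]] = {}
    for (ref, samp), sub in df.assign(_t=taxon).groupby(
        ["reference_id", "sample_id"], sort=True
    ):
        struct.setdefault(ref, {})[samp] = sorted(set(sub["_t"]))
    return struct


def _run_trial(
    refs: list[str],
    struct: dict[str, dict[str, list[str]]],
    config: SQSConfig,
    rng: np.random.Generator,
) -> list[int]:
    """One randomized walk through the references; recorded richness values."""
    order = rng.permutation(len(refs))
    counts: Counter = Counter()
    n_total = 0
    n_single = 0
    recorded: list[int] = []
    above = False  # was coverage at/above quorum after the previous draw?
    for i in order:
        samples = struct[refs[i]]
        names = sorted(samples)
        if len(names) > config.sample_quota:
            chosen = [names[j] for j in rng.choice(len(names), config.sample_quota, replace=False)]
        else:
            chosen = names
        if config.merge_repeats:
            increments = Counter(set().union(*(samples[s] for s in chosen)))
        else:
            increments = Counter(t for s in chosen for t in samples[s])
        for taxon, inc in increments.items():
            old = counts[taxon]
            counts[taxon] = old + inc
            n_total += inc
            if old == 0 and inc == 1:
                n_single += 1
            elif old == 1:
                n_single -= 1
            elif old == 0 and inc > 1:
                pass  # arrives already as a multi-occurrence taxon
        now_above = n_total > 0 and (1.0 - n_single / n_total) >= config.quorum
        if now_above and not above:
            recorded.append(len(counts))
        above = now_above
    return recorded


def sqs_by_reference(bin_df: pd.DataFrame, config: SQSConfig) -> tuple[list[int], int]:
    """All recorded richness counts for one bin, pooled over trials.

    ``bin_df`` holds the occurrence rows of a single bin.  Returns the
    pooled recorded counts and the number of trials in which coverage never
    reached the quorum.  A fixed ``config.seed`` makes the result
    reproducible; per-trial substreams are derived from it so trials are
    independent of execution order.
    """
    struct = _bin_structure(bin_df)
    refs = sorted(struct)
    if not refs:
        return [], config.trials
    pooled: list[int] = []
    n_failed = 0
    for trial in range(config.trials):
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([config.seed, trial])))
        rec = _run_trial(refs, struct, config, rng)
        if rec:
            pooled.extend(rec)
        else:
            n_failed += 1
    return pooled, n_failed


def summarize_trials(recorded, n_failed_trials: int = 0) -> dict:
    """Median and 95% interval (2.5th/97.5th percentiles, linear
    interpolation between order statistics) of the pooled recorded counts.

    An empty pool yields a no-estimate row (NaNs), not an exception.
    """
    arr = np.asarray(list(recorded), dtype=float)
    if arr.size == 0:
        return {
            "median_richness": float("nan"),
            "ci_lower": float("nan"),
            "ci_upper": float("nan"),
            "n_recorded": 0,
            "n_failed_trials": n_failed_trials,
        }
    lo, med, hi = np.percentile(arr, [2.5, 50, 97.5], method="linear")
    return {
        "median_richness": float(med),
        "ci_lower": float(lo),
        "ci_upper": float(hi),
        "n_recorded": int(arr.size),
        "n_failed_trials": n_failed_trials,
    }


def sqs_per_stage(records, config: SQSConfig) -> pd.DataFrame:
    """SQS summary per bin of a filtered record set.

    Each bin gets its own deterministic seed substream derived from
    ``config.seed`` and the bin index, so bins can be computed in any order
    (or one at a time) with identical results.
    """
    scale = records.stage_scale
    df = records.df[~records.df["stage"].isin(SENTINELS)]
    rows = []
    for b, sbin in enumerate(scale):
        sub = df[df["stage"] == sbin.name]
        bin_seed = int(np.random.SeedSequence([config.seed, b]).generate_state(1)[0] % (2**31))
        bin_cfg = SQSConfig(
            quorum=config.quorum,
            trials=config.trials,
            sample_quota=config.sample_quota,
            merge_repeats=config.merge_repeats,
            seed=bin_seed,
        )
        pooled, n_failed = sqs_by_reference(sub, bin_cfg)
        row = {"stage": sbin.name, "quorum": config.quorum}
        row.update(summarize_trials(pooled, n_failed))
        rows.append(row)
    return pd.DataFrame(rows).set_index("stage")
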