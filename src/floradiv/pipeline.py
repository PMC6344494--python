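"""End-to-end analysis orchestration.

One :class:`AnalysisConfig` drives the whole chain — read, normalize,
filter, ranges, per-stage indices, SQS, effort correlations — for every
requested rank level and group slice, deterministically under a master
seed.  :func:`export_bundle` writes each table as delimited text plus a run
manifest (config, seed, package version, input hashes) so a result can be
traced back to its exact inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .diversity import compute_stage_table
from .errors import ConfigError, UndefinedResultError
from .ranges import build_taxon_ranges
from .records import (
    OccurrenceRecordSet,
    apply_selection_filters,
    normalize_taxonomy,
    read_occurrence_table,
)
from .sqs import SQSConfig, sqs_per_stage
from .stages import StageBin, StageScale, default_scale
from .trends import entries_per_stage, spearman

logger = logging.getLogger(__name__)


def load_stage_scale(path) -> StageScale:
    """Stage scale from a CSV/TSV with columns name, base_age, top_age."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    try:
        bins = tuple(
            StageBin(str(r[cols["name"]]), float(r[cols["base_age"]]), float(r[cols["top_age"]]))
            for _, r in df.iterrows()
        )
    except KeyError as e:
        raise ConfigError(f"stage scale file lacks column {e}") from None
    return StageScale(bins)


@dataclass
class AnalysisConfig:
    occurrences: str
    stage_scale: str | None = None
    synonymy: str | None = None
    families: str | None = None
    ranks: tuple[str, ...] = ("genus",)
    group_by: str | None = None          # e.g. "fossil_class" or "higher_group"
    schema: dict = field(default_factory=dict)
    drop_reworked_sporomorphs: bool = True
    drop_reworked_macrofossils: bool = False
    w_single: float = 1.0
    sqs_quorum: float = 0.4
    sqs_trials: int = 500
    sqs_sample_quota: int = 5
    sqs_merge_repeats: bool = True
    run_sqs: bool = True
    seed: int = 0

    def validate(self) -> None:
        for rank in self.ranks:
            if rank not in ("species", "genus", "family"):
                raise ConfigError(f"invalid rank {rank!r} in field 'ranks'")
        if not Path(self.occurrences).exists():
            raise ConfigError(f"field 'occurrences': no such file {self.occurrences!r}")
        for name in ("stage_scale", "synonymy", "families"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"field {name!r}: no such file {p!r}")


@dataclass
class ResultBundle:
    diversity: dict[tuple[str, str], pd.DataFrame]   # (rank, group) -> stage table
    sqs: dict[tuple[str, str], pd.DataFrame]
    correlations: pd.DataFrame
    provenance: dict[str, str]
    config: dict
    seed: int


def _slices(records: OccurrenceRecordSet, group_by: str | None):
    yield "all", records
    if group_by:
        for value in sorted(records.df[group_by].unique()):
            sub = records.df[records.df[group_by] == value]
            yield value, OccurrenceRecordSet(
                df=sub.reset_index(drop=True),
                stage_scale=records.stage_scale,
                provenance=records.provenance + ((f"slice[{group_by}={value}]", 0),),
            )


def run_analysis(config: AnalysisConfig, records: OccurrenceRecordSet | None = None) -> ResultBundle:
    """Run the full chain; pass ``records`` to skip re-reading the table."""
    config.validate()
    if records is None:
        scale = load_stage_scale(config.stage_scale) if config.stage_scale else None
        records = read_occurrence_table(config.occurrences, config.schema, scale)
    records = normalize_taxonomy(records, config.synonymy, config.families)

    if "family" in config.ranks and (records.df["family"] == "").all():
        raise ConfigError(
            "field 'ranks': family rank requested but no family column or map supplies families"
        )

    sqs_cfg = SQSConfig(
        quorum=config.sqs_quorum,
        trials=config.sqs_trials,
        sample_quota=config.sqs_sample_quota,
        merge_repeats=config.sqs_merge_repeats,
        seed=config.seed,
    )

    diversity: dict[tuple[str, str], pd.DataFrame] = {}
    sqs_tables: dict[tuple[str, str], pd.DataFrame] = {}
    corr_rows = []
    provenance: dict[str, str] = {}

    for rank in config.ranks:
        filtered = apply_selection_filters(
            records,
            rank,
            drop_reworked_sporomorphs=config.drop_reworked_sporomorphs,
            drop_reworked_macrofossils=config.drop_reworked_macrofossils,
        )
        for group, sl in _slices(filtered, config.group_by):
            key = (rank, group)
            if sl.in_interval.empty:
                logger.warning("slice %s is empty after filtering; skipped", key)
                continue
            ranges = build_taxon_ranges(sl, rank)
            table = compute_stage_table(sl, ranges, w_single=config.w_single)
            diversity[key] = table
            provenance[f"{rank}/{group}"] = sl.provenance_text()
            if config.run_sqs:
                sqs_tables[key] = sqs_per_stage(sl, sqs_cfg)
            effort = entries_per_stage(sl)
            try:
                res = spearman(effort.to_numpy(), table["sib"].to_numpy())
                corr_rows.append(
                    {
                        "pair": f"n_entries~sib[{rank}/{group}]",
                        "r_s": res.r_s,
                        "p": res.p,
                        "n": res.n,
                        "strong": res.strong,
                        "significant": res.significant,
                    }
                )
            except UndefinedResultError:
                logger.warning("constant series in slice %s; correlation skipped", key)

    return ResultBundle(
        diversity=diversity,
        sqs=sqs_tables,
        correlations=pd.DataFrame(corr_rows),
        provenance=provenance,
        config=asdict(config),
        seed=config.seed,
    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def export_bundle(bundle: ResultBundle, out_dir, force: bool = False) -> list[Path]:
    """Write every table plus a run manifest; refuses to overwrite unless forced."""
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{out} already holds results; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)

    written: list[Path] = []
    try:
        for (rank, group), table in sorted(bundle.diversity.items()):
            p = out / f"diversity_{rank}_{group}.tsv"
            table.to_csv(p, sep="\t")
            written.append(p)
        for (rank, group), table in sorted(bundle.sqs.items()):
            p = out / f"sqs_{rank}_{group}.tsv"
            table.to_csv(p, sep="\t")
            written.append(p)
        if not bundle.correlations.empty:
            p = out / "correlations.tsv"
            bundle.correlations.to_csv(p, sep="\t", index=False)
            written.append(p)
        p = out / "provenance.txt"
        p.write_text(
            "".join(f"# {k}\n{v}" for k, v in sorted(bundle.provenance.items())),
            encoding="utf-8",
        )
        written.append(p)

        inputs = {}
        for key in ("occurrences", "stage_scale", "synonymy", "families"):
            path = bundle.config.get(key)
            if path and Path(path).exists():
                inputs[key] = _sha256(path)
        manifest = {
            "package": "floradiv",
            "version": __version__,
            "seed": bundle.seed,
            "config": bundle.config,
            "input_sha256": inputs,
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str), encoding="utf-8")
        written.append(manifest_path)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return written
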