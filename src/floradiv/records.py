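"""Occurrence tables: reading, validation, taxonomic normalization, filtering.

The atomic data unit is the *occurrence*: one reported presence of a taxon in
one sample of one literature reference, assigned to a stage bin.  Occurrences
live in a :class:`OccurrenceRecordSet`, a thin wrapper around a pandas
DataFrame with a fixed column vocabulary plus a provenance log that records
how many rows each transformation removed, so no data loss is ever silent.

Taxon-name strings are parsed into a genus, an optional species epithet, and
open-nomenclature qualifiers ("sp.", "spp.", "cf.", "aff.", "?", "ex gr."
and any other provisional marker).  Qualifier *position* matters downstream:
a qualifier before the genus ("?Lepidopteris martinsii", "cf. Voltzia sp.")
marks a tentative generic assignment and excludes the record from genus-level
counts, while a qualifier at the epithet ("Lepidopteris sp.") only excludes
it from species-level counts.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import ConfigError, SchemaError, ValidationError
from .stages import SENTINELS, UNRESOLVED, StageScale, default_scale

logger = logging.getLogger(__name__)

#: canonical column order of the in-memory table
COLUMNS = [
    "record_id",
    "genus_name",
    "species_epithet",
    "qualifiers",
    "qualifier_position",
    "rank",
    "higher_group",
    "fossil_class",
    "stage",
    "reference_id",
    "sample_id",
    "reworked",
    "family",
]

#: open-nomenclature tokens and their canonical qualifier names
_QUALIFIER_TOKENS = {
    "sp": "sp",
    "spp": "spp",
    "cf": "cf",
    "aff": "aff",
    "?": "question",
    "ex gr": "ex_gr",
}
#: provisional markers not in the core vocabulary, folded into one bucket
_OTHER_OPEN_TOKENS = {"indet", "gen", "vel", "et", "sensu", "cfr", "sp1", "sp2"}

_GENUS_RE = re.compile(r"^[A-Z][\w-]*$")


def _norm_token(tok: str) -> str:
    return tok.rstrip(".").lower()


def parse_taxon_name(text: str) -> dict:
    """Parse a taxon-name string into its structured parts.

    Returns a dict with keys ``genus_name``, ``species_epithet``,
    ``qualifiers`` (space-joined canonical tokens), ``qualifier_position``
    and ``rank``.  Qualifiers appearing before the genus word are
    genus-level; qualifiers at or after the epithet slot are species-level.
    """
    text = (text or "").strip()
    genus = ""
    epithet = ""
    genus_quals: list[str] = []
    species_quals: list[str] = []

    tokens = text.replace("?", " ? ").split()
    # rejoin "ex gr" style two-token qualifiers
    merged: list[str] = []
    i = 0
    while i < len(tokens):
        if _norm_token(tokens[i]) == "ex" and i + 1 < len(tokens) and _norm_token(tokens[i + 1]) == "gr":
            merged.append("ex gr")
            i += 2
        else:
            merged.append(tokens[i])
            i += 1

    seen_genus = False
    for tok in merged:
        key = _norm_token(tok) if tok != "?" else "?"
        if key in _QUALIFIER_TOKENS:
            qual = _QUALIFIER_TOKENS[key]
            (species_quals if seen_genus else genus_quals).append(qual)
        elif not seen_genus and _GENUS_RE.match(tok.rstrip(".")):
            genus = tok.rstrip(".")
            seen_genus = True
        elif seen_genus and not epithet and tok.islower() and key not in _OTHER_OPEN_TOKENS:
            epithet = tok
        else:
            # unknown provisional marker ("indet.", "gen. nov." leftovers...)
            (species_quals if seen_genus else genus_quals).append("other-open-nomenclature")

    if genus_quals:
        position = "genus-level"
    elif species_quals:
        position = "species-level"
    else:
        position = "none"

    rank = "species" if epithet else ("genus" if genus else "family-only")
    quals = sorted(set(genus_quals + species_quals))
    return {
        "genus_name": genus,
        "species_epithet": epithet,
        "qualifiers": " ".join(quals),
        "qualifier_position": position,
        "rank": rank,
    }


@dataclass(frozen=True)
class OccurrenceRecordSet:
    """An occurrence table, its stage scale, and its transformation history.

    Instances are treated as immutable: every transformation returns a new
    record set with one more provenance entry ``(step_name, rows_removed)``.
    The provenance deltas always sum to (initial − current) row count.
    """

    df: pd.DataFrame
    stage_scale: StageScale
    provenance: tuple[tuple[str, int], ...] = ()

    def __len__(self) -> int:
        return len(self.df)

    def _step(self, name: str, new_df: pd.DataFrame) -> "OccurrenceRecordSet":
        removed = len(self.df) - len(new_df)
        if removed:
            logger.warning("%s removed %d of %d records", name, removed, len(self.df))
        return replace(
            self,
            df=new_df.reset_index(drop=True),
            provenance=self.provenance + ((name, removed),),
        )

    @property
    def in_interval(self) -> pd.DataFrame:
        """Rows assigned to a bin of the stage scale (sentinels excluded)."""
        return self.df[~self.df["stage"].isin(SENTINELS)]

    def provenance_text(self) -> str:
        lines = [f"{name}\t{removed}" for name, removed in self.provenance]
        return "\n".join(lines) + ("\n" if lines else "")

    def write_table(self, path, sep: str = "\t") -> None:
        self.df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# reading


def _sniff_sep(path) -> str:
    with open(path, "r", encoding="utf-8-sig") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_occurrence_table(
    path,
    schema_config: dict[str, str] | None = None,
    stage_scale: StageScale | None = None,
) -> OccurrenceRecordSet:
    """Read a delimited occurrence table into a validated record set.

    ``schema_config`` maps logical field names (the canonical column names,
    plus ``taxon`` for a combined name column) to the file's column headers;
    matching is case-insensitive and unmapped logical fields fall back to a
    same-named column.  Taxon strings are parsed into genus / epithet /
    qualifiers unless pre-parsed columns are supplied.
    """
    scale = stage_scale or default_scale()
    schema_config = dict(schema_config or {})
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8-sig")

    lower_cols = {c.strip().lower(): c for c in raw.columns}

    def col(logical: str) -> str | None:
        target = schema_config.get(logical, logical)
        return lower_cols.get(target.strip().lower())

    has_taxon = col("taxon") is not None
    has_genus = col("genus_name") is not None or col("genus") is not None
    if not has_taxon and not has_genus:
        raise SchemaError("missing required column: taxon (or genus_name)")
    for logical in ("stage", "reference_id", "sample_id", "fossil_class"):
        if col(logical) is None:
            raise SchemaError(f"missing required column: {logical}")

    n = len(raw)
    out = pd.DataFrame(index=range(n))

    if has_taxon:
        parsed = pd.DataFrame([parse_taxon_name(t) for t in raw[col("taxon")]])
    else:
        gcol = col("genus_name") or col("genus")
        scol = col("species_epithet") or col("species")
        joined = raw[gcol].str.strip()
        if scol is not None:
            joined = (joined + " " + raw[scol].str.strip()).str.strip()
        parsed = pd.DataFrame([parse_taxon_name(t) for t in joined])
    for c in ("genus_name", "species_epithet", "qualifiers", "qualifier_position"):
        # pre-parsed columns in the file win over the parser
        src = col(c)
        out[c] = raw[src].str.strip() if src is not None else parsed[c]

    rank_col = col("rank")
    out["rank"] = raw[rank_col].str.strip().str.lower() if rank_col else parsed["rank"]
    # epithet-free records can never be species-rank
    out.loc[out["species_epithet"] == "", "rank"] = out.loc[
        out["species_epithet"] == "", "rank"
    ].replace("species", "genus")

    for logical, default in (
        ("higher_group", "unknown"),
        ("reworked", "no"),
        ("family", ""),
    ):
        src = col(logical) or (col("group") if logical == "higher_group" else None)
        out[logical] = raw[src].str.strip() if src is not None else default

    out["fossil_class"] = raw[col("fossil_class")].str.strip().str.lower()
    out["stage"] = raw[col("stage")].str.strip()
    out["reference_id"] = raw[col("reference_id")].str.strip()
    out["sample_id"] = raw[col("sample_id")].str.strip()

    id_col = col("record_id")
    out["record_id"] = (
        raw[id_col].str.strip() if id_col is not None else [f"r{i}" for i in range(n)]
    )

    dupes = out["record_id"][out["record_id"].duplicated()]
    if not dupes.empty:
        raise ValidationError(f"duplicate record_id values: {sorted(set(dupes))[:10]}")

    bad = out.index[~out["stage"].map(scale.is_valid_stage)]
    if len(bad):
        labels = sorted(set(out.loc[bad, "stage"]))
        raise ValidationError(
            f"unknown stage labels {labels} in rows {list(bad[:20])} "
            f"(valid: {scale.names} + {sorted(SENTINELS)})"
        )

    out = out[COLUMNS]
    return OccurrenceRecordSet(df=out, stage_scale=scale, provenance=(("read", 0),))


# ---------------------------------------------------------------------------
# taxonomic normalization


def _as_mapping(table, what: str) -> dict[str, str]:
    if table is None:
        return {}
    if isinstance(table, dict):
        mapping = {str(k).strip(): str(v).strip() for k, v in table.items()}
    else:
        df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table, dtype=str)
        if df.shape[1] < 2:
            raise ConfigError(f"{what} table needs two columns (from,to)")
        mapping = {
            str(k).strip(): str(v).strip()
            for k, v in zip(df.iloc[:, 0], df.iloc[:, 1])
        }
    return mapping


def normalize_taxonomy(
    records: OccurrenceRecordSet,
    synonymy_map=None,
    family_map=None,
) -> OccurrenceRecordSet:
    """Apply accepted-name and genus->family mapping tables.

    Synonymy keys containing a space are full species names ("Genus epithet")
    and rewrite both name parts; single-word keys rewrite the genus (this is
    also how organ genera are merged under a whole-plant genus).  Maps must be
    pre-resolved: a mapping whose target is itself a key is rejected.
    Unmapped names pass through unchanged; families are filled only where the
    family field is empty.
    """
    syn = _as_mapping(synonymy_map, "synonymy")
    fam = _as_mapping(family_map, "family")

    chained = [k for k, v in syn.items() if v in syn and syn[v] != v]
    if chained:
        raise ConfigError(
            f"synonymy map is chained or cyclic for keys {sorted(chained)[:5]}; "
            "resolve it to accepted names first"
        )

    df = records.df.copy()
    genus_syn = {k: v for k, v in syn.items() if " " not in k}
    species_syn = {k: v for k, v in syn.items() if " " in k}

    if genus_syn:
        df["genus_name"] = df["genus_name"].map(lambda g: genus_syn.get(g, g))
    if species_syn:
        full = (df["genus_name"] + " " + df["species_epithet"]).str.strip()
        hits = full.map(species_syn).dropna()
        for idx, accepted in hits.items():
            parts = accepted.split(None, 1)
            df.loc[idx, "genus_name"] = parts[0]
            df.loc[idx, "species_epithet"] = parts[1] if len(parts) > 1 else ""

    if fam:
        empty = df["family"] == ""
        df.loc[empty, "family"] = df.loc[empty, "genus_name"].map(fam).fillna("")
    unmapped = df[(df["family"] == "") & (df["genus_name"] != "")]["genus_name"]
    if fam and not unmapped.empty:
        logger.warning(
            "%d genera remain without a family and will be dropped from "
            "family-level counts: %s",
            unmapped.nunique(),
            sorted(unmapped.unique())[:10],
        )

    return records._step("normalize_taxonomy", df)


# ---------------------------------------------------------------------------
# selection filters


def apply_selection_filters(
    records: OccurrenceRecordSet,
    rank_level: str,
    *,
    drop_unresolved: bool = True,
    drop_reworked_sporomorphs: bool = True,
    drop_reworked_macrofossils: bool = False,
) -> OccurrenceRecordSet:
    """Apply the rank-dependent selection filters, in order, with logging.

    1. records with ``stage = unresolved`` (dating too coarse for one bin);
       pre-/post-interval records are kept — they only extend ranges;
    2. reworked or possibly-reworked sporomorph records (macrofossils carry
       the flag but are not filtered by default);
    3. rank ``species``: any open-nomenclature qualifier excludes the record;
    4. rank ``genus``: only genus-level qualifiers (tentative generic
       assignment) exclude it — "Lepidopteris sp." stays, "?Lepidopteris
       martinsii" goes.
    """
    if rank_level not in ("species", "genus", "family"):
        raise ConfigError(f"unknown rank_level {rank_level!r}")
    out = records
    df = out.df

    if drop_unresolved:
        out = out._step(f"drop_unresolved[{rank_level}]", df[df["stage"] != UNRESOLVED])
        df = out.df

    reworked = df["reworked"].isin(["reworked", "possibly-reworked"])
    drop = pd.Series(False, index=df.index)
    if drop_reworked_sporomorphs:
        drop |= reworked & (df["fossil_class"] == "sporomorph")
    if drop_reworked_macrofossils:
        drop |= reworked & (df["fossil_class"] == "macrofossil")
    out = out._step(f"drop_reworked[{rank_level}]", df[~drop])
    df = out.df

    if rank_level == "species":
        keep = df["qualifiers"] == ""
        out = out._step("drop_open_nomenclature[species]", df[keep])
    elif rank_level == "genus":
        keep = df["qualifier_position"] != "genus-level"
        out = out._step("drop_tentative_genus[genus]", df[keep])
    return out
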