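"""Reading, name parsing, taxonomy normalization, and selection filters."""

import textwrap

import pytest

from floradiv.errors import ConfigError, SchemaError, ValidationError
from floradiv.ranges import build_taxon_ranges
from floradiv.records import (
    apply_selection_filters,
    normalize_taxonomy,
    parse_taxon_name,
    read_occurrence_table,
)
from floradiv.stages import default_scale


@pytest.mark.parametrize(
    "text,genus,epithet,quals,position",
    [
        ("Lepidopteris martinsii", "Lepidopteris", "martinsii", "", "none"),
        ("Lepidopteris sp.", "Lepidopteris", "", "sp", "species-level"),
        ("Lepidopteris spp.", "Lepidopteris", "", "spp", "species-level"),
        ("?Lepidopteris martinsii", "Lepidopteris", "martinsii", "question", "genus-level"),
        ("cf. Voltzia", "Voltzia", "", "cf", "genus-level"),
        ("Voltzia cf. heterophylla", "Voltzia", "heterophylla", "cf", "species-level"),
        ("Voltzia aff. walchiaeformis", "Voltzia", "walchiaeformis", "aff", "species-level"),
        ("Peltaspermum ex gr. martinsii", "Peltaspermum", "martinsii", "ex_gr", "species-level"),
        ("Pecopteris indet.", "Pecopteris", "", "other-open-nomenclature", "species-level"),
        ("Pleuromeia sternbergii?", "Pleuromeia", "sternbergii", "question", "species-level"),
    ],
)
def test_name_parsing(text, genus, epithet, quals, position):
    parsed = parse_taxon_name(text)
    assert parsed["genus_name"] == genus
    assert parsed["species_epithet"] == epithet
    assert parsed["qualifiers"] == quals
    assert parsed["qualifier_position"] == position


def test_epithet_free_records_are_not_species_rank():
    assert parse_taxon_name("Lepidopteris sp.")["rank"] == "genus"
    assert parse_taxon_name("Voltzia heterophylla")["rank"] == "species"


def _write(tmp_path, body, name="occ.csv"):
    p = tmp_path / name
    p.write_text(textwrap.dedent(body), encoding="utf-8")
    return p


GOOD_CSV = """\
    taxon,stage,reference_id,sample_id,fossil_class
    Lepidopteris martinsii,Induan,refA,s1,macrofossil
    Lepidopteris sp.,Anisian,refA,s2,macrofossil
    Voltzia heterophylla,Anisian,refB,s1,macrofossil
    """


def test_read_toy_table(tmp_path):
    rs = read_occurrence_table(_write(tmp_path, GOOD_CSV))
    assert len(rs) == 3
    assert rs.provenance == (("read", 0),)
    row = rs.df.iloc[1]
    assert row["genus_name"] == "Lepidopteris"
    assert row["species_epithet"] == ""
    assert row["qualifiers"] == "sp"
    assert row["qualifier_position"] == "species-level"


def test_read_tsv_and_case_insensitive_headers(tmp_path):
    body = "Taxon\tSTAGE\tReference_id\tsample_id\tfossil_class\nVoltzia sp.\tLadinian\tr1\ts1\tmacrofossil\n"
    p = tmp_path / "occ.tsv"
    p.write_text(body, encoding="utf-8")
    rs = read_occurrence_table(p)
    assert len(rs) == 1
    assert rs.df.iloc[0]["stage"] == "Ladinian"


def test_unknown_stage_label_rejected(tmp_path):
    p = _write(
        tmp_path,
        """\
        taxon,stage,reference_id,sample_id,fossil_class
        Voltzia sp.,Cretaceous,r1,s1,macrofossil
        """,
    )
    with pytest.raises(ValidationError, match="Cretaceous"):
        read_occurrence_table(p)


def test_sentinel_stage_labels_accepted(tmp_path):
    p = _write(
        tmp_path,
        """\
        taxon,stage,reference_id,sample_id,fossil_class
        Voltzia sp.,pre-interval,r1,s1,macrofossil
        Voltzia sp.,unresolved,r1,s2,macrofossil
        """,
    )
    assert len(read_occurrence_table(p)) == 2


def test_missing_required_column_named_in_error(tmp_path):
    p = _write(
        tmp_path,
        """\
        taxon,reference_id,sample_id,fossil_class
        Voltzia sp.,r1,s1,macrofossil
        """,
    )
    with pytest.raises(SchemaError, match="stage"):
        read_occurrence_table(p)


def test_duplicate_record_id_rejected(tmp_path):
    p = _write(
        tmp_path,
        """\
        record_id,taxon,stage,reference_id,sample_id,fossil_class
        r1,Voltzia sp.,Induan,r1,s1,macrofossil
        r1,Voltzia sp.,Anisian,r1,s2,macrofossil
        """,
    )
    with pytest.raises(ValidationError, match="duplicate"):
        read_occurrence_table(p)


def test_schema_config_maps_columns(tmp_path):
    p = _write(
        tmp_path,
        """\
        name,bin,ref,samp,kind
        Voltzia heterophylla,Anisian,r1,s1,macrofossil
        """,
    )
    rs = read_occurrence_table(
        p,
        schema_config={
            "taxon": "name",
            "stage": "bin",
            "reference_id": "ref",
            "sample_id": "samp",
            "fossil_class": "kind",
        },
    )
    assert rs.df.iloc[0]["genus_name"] == "Voltzia"


# --- taxonomy normalization -------------------------------------------------


def test_empty_maps_are_identity(recset_factory):
    rs = recset_factory([{"genus_name": "Voltzia", "stage": "Anisian"}])
    out = normalize_taxonomy(rs)
    assert out.df.equals(rs.df)
    assert out.provenance[-1] == ("normalize_taxonomy", 0)


def test_synonymy_reduces_genus_diversity_by_one(recset_factory):
    rs = recset_factory(
        [
            {"genus_name": "GenusA", "stage": "Induan"},
            {"genus_name": "GenusB", "stage": "Induan", "sample_id": "s2"},
        ]
    )
    before = len(build_taxon_ranges(rs, "genus"))
    after = len(build_taxon_ranges(normalize_taxonomy(rs, {"GenusA": "GenusB"}), "genus"))
    assert before - after == 1


def test_species_level_synonymy_rewrites_both_parts(recset_factory):
    rs = recset_factory(
        [{"genus_name": "GenusA", "species_epithet": "oldus", "stage": "Induan"}]
    )
    out = normalize_taxonomy(rs, {"GenusA oldus": "GenusB novus"})
    assert out.df.iloc[0]["genus_name"] == "GenusB"
    assert out.df.iloc[0]["species_epithet"] == "novus"


def test_chained_synonymy_rejected(recset_factory):
    rs = recset_factory([{"genus_name": "A", "stage": "Induan"}])
    with pytest.raises(ConfigError, match="chained|cyclic"):
        normalize_taxonomy(rs, {"A": "B", "B": "C"})


def test_family_map_fills_only_empty_and_unmapped_pass_through(recset_factory):
    rs = recset_factory(
        [
            {"genus_name": "GenusA", "stage": "Induan"},
            {"genus_name": "GenusB", "stage": "Induan", "family": "Keptaceae"},
            {"genus_name": "GenusC", "stage": "Induan"},
        ]
    )
    out = normalize_taxonomy(rs, family_map={"GenusA": "Mappedaceae", "GenusB": "Wrongaceae"})
    assert out.df.iloc[0]["family"] == "Mappedaceae"
    assert out.df.iloc[1]["family"] == "Keptaceae"
    assert out.df.iloc[2]["family"] == ""
    # the family-less genus contributes nothing at family level
    assert set(build_taxon_ranges(out, "family")) == {"Mappedaceae", "Keptaceae"}


# --- selection filters -------------------------------------------------------


def _filter_rows(recset_factory, rows, rank):
    rs = recset_factory(rows)
    return apply_selection_filters(rs, rank)


def test_open_nomenclature_excluded_at_species_kept_at_genus(recset_factory):
    rows = [
        {
            "genus_name": "Lepidopteris",
            "stage": "Induan",
            "qualifiers": "sp",
            "qualifier_position": "species-level",
        }
    ]
    assert len(_filter_rows(recset_factory, rows, "species")) == 0
    assert len(_filter_rows(recset_factory, rows, "genus")) == 1


def test_tentative_genus_excluded_at_both_ranks(recset_factory):
    rows = [
        {
            "genus_name": "Lepidopteris",
            "species_epithet": "martinsii",
            "stage": "Induan",
            "qualifiers": "question",
            "qualifier_position": "genus-level",
        }
    ]
    assert len(_filter_rows(recset_factory, rows, "species")) == 0
    assert len(_filter_rows(recset_factory, rows, "genus")) == 0


@pytest.mark.parametrize("rank", ["species", "genus", "family"])
def test_reworked_sporomorphs_excluded_everywhere(recset_factory, rank):
    rows = [
        {
            "genus_name": "Lundbladispora",
            "stage": "Induan",
            "fossil_class": "sporomorph",
            "reworked": "possibly-reworked",
        }
    ]
    assert len(_filter_rows(recset_factory, rows, rank)) == 0


def test_reworked_macrofossils_kept_by_default(recset_factory):
    rows = [{"genus_name": "Voltzia", "stage": "Induan", "reworked": "reworked"}]
    assert len(_filter_rows(recset_factory, rows, "genus")) == 1


def test_unresolved_dropped_sentinels_kept(recset_factory):
    rows = [
        {"genus_name": "Voltzia", "stage": "unresolved"},
        {"genus_name": "Voltzia", "stage": "pre-interval", "sample_id": "s2"},
        {"genus_name": "Voltzia", "stage": "post-interval", "sample_id": "s3"},
    ]
    out = _filter_rows(recset_factory, rows, "genus")
    assert set(out.df["stage"]) == {"pre-interval", "post-interval"}


def test_filtering_is_idempotent_and_counts_reconcile(recset_factory):
    rows = [
        {"genus_name": "Voltzia", "stage": "unresolved"},
        {"genus_name": "Voltzia", "stage": "Induan", "sample_id": "s2"},
        {
            "genus_name": "Densoisporites",
            "stage": "Olenekian",
            "fossil_class": "sporomorph",
            "reworked": "reworked",
            "sample_id": "s3",
        },
        {
            "genus_name": "Lepidopteris",
            "stage": "Induan",
            "qualifiers": "question",
            "qualifier_position": "genus-level",
            "sample_id": "s4",
        },
    ]
    rs = recset_factory(rows)
    once = apply_selection_filters(rs, "genus")
    twice = apply_selection_filters(once, "genus")
    assert once.df.equals(twice.df)
    removed = sum(n for _, n in once.provenance)
    assert len(rs) - len(once) == removed
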