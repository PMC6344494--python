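import pandas as pd
import pytest

from floradiv.records import COLUMNS, OccurrenceRecordSet
from floradiv.stages import default_scale

_DEFAULTS = {
    "species_epithet": "",
    "qualifiers": "",
    "qualifier_position": "none",
    "rank": "genus",
    "higher_group": "unknown",
    "fossil_class": "macrofossil",
    "reference_id": "ref1",
    "sample_id": "s1",
    "reworked": "no",
    "family": "",
}


def make_recset(rows, scale=None):
    """Build a record set from minimal row dicts (genus_name + stage required)."""
    scale = scale or default_scale()
    full = []
    for i, row in enumerate(rows):
        r = dict(_DEFAULTS, record_id=f"r{i}", **row)
        if r["species_epithet"]:
            r.setdefault("rank", "species")
        full.append(r)
    df = pd.DataFrame(full, columns=COLUMNS).astype(str)
    return OccurrenceRecordSet(df=df, stage_scale=scale, provenance=(("read", 0),))


@pytest.fixture
def scale():
    return default_scale()


@pytest.fixture
def recset_factory():
    return make_recset
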