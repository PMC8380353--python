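from __future__ import annotations

from datetime import date

import pytest

from hipbench import Bearing, Gender, ProcedureRecord


def make_record(
    pid: str = "p1",
    gender: Gender | None = Gender.female,
    stem: str = "StemA",
    cup: str = "CupA",
    bearing: Bearing = Bearing.MP,
    primary: date = date(2010, 1, 1),
    revision: date | None = None,
    death: date | None = None,
) -> ProcedureRecord:
    return ProcedureRecord(
        procedure_id=pid,
        gender=gender,
        stem_brand=stem,
        cup_brand=cup,
        bearing=bearing,
        primary_date=primary,
        revision_date=revision,
        death_date=death,
    )


@pytest.fixture
def three_row_csv(tmp_path):
    """Tiny registry: one plain record, one revised, one dead."""
    path = tmp_path / "registry.csv"
    path.write_text(
        "procedure_id,gender,stem_brand,cup_brand,bearing,primary_date,"
        "revision_date,death_date\n"
        "p1,female,StemA,CupA,MP,2010-01-01,,\n"
        "p2,male,StemA,CupA,CP,2011-02-03,2014-02-03,\n"
        "p3,female,StemB,CupB,CC,2012-05-06,,2018-05-06\n"
    )
    return path
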