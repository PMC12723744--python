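"""Shared fixtures: one handcrafted mini-campaign exercising every status
transition, plus a larger generated campaign for oracle-equivalence tests."""

from datetime import date

import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("repro", derandomize=True, deadline=None)
hyp_settings.load_profile("repro")

from clonecoord.core_model import (
    AssemblyRecord,
    ConstructRecord,
    DsDNARecord,
    ExperimentRecord,
    Instance,
    MiniprepRecord,
    OligoRecord,
    SequencingRecord,
    Settings,
    TransformationRecord,
)
from clonecoord.synthetic_fixtures import SimParams, generate_instance


def d(iso: str) -> date:
    return date.fromisoformat(iso)


@pytest.fixture
def mini_campaign() -> Instance:
    """Four constructs at different stages.

    c1: complete (a1 transformed twice, m1 sequence-verified); a second
        attempt a3 still ready to assemble.
    c2: single attempt a2 stalled because part d3's PCR failed.
    c3: queued, no assemblies yet.
    c4: assembly a4 done, awaiting transformation.
    """
    inst = Instance(settings=Settings())
    inst.oligos = [OligoRecord("o1"), OligoRecord("o2")]
    inst.dsdna = [
        DsDNARecord("d1", source="pcr", primer_ids=["o1", "o2"], length_kb=2.0,
                    conc_ng_ul=50.0, gel_code="single_band_expected_size",
                    purification_date=d("2024-02-20")),
        DsDNARecord("d2", source="pcr", primer_ids=["o1", "o2"], length_kb=1.0),
        DsDNARecord("d3", source="pcr", primer_ids=["o1", "o2"], length_kb=3.0,
                    gel_code="smear"),
        DsDNARecord("d4", source="external", length_kb=4.0, conc_ng_ul=30.0),
        DsDNARecord("d5", source="external", length_kb=2.5),
        DsDNARecord("d6", source="pcr", primer_ids=["o1", "o2"], length_kb=1.5,
                    conc_ng_ul=40.0, purification_date=d("2024-02-25")),
    ]
    inst.registry = [
        ConstructRecord("c1", name="pA", priority=True, queued_date=d("2024-02-01")),
        ConstructRecord("c2", name="pB", queued_date=d("2024-02-02")),
        ConstructRecord("c3", name="pC", queued_date=d("2024-02-03")),
        ConstructRecord("c4", name="pD", queued_date=d("2024-02-04")),
    ]
    inst.assemblies = [
        AssemblyRecord("a1", type="USER", part_ids=["d1", "d4"], construct_id="c1",
                       date=d("2024-03-01"), condition="USERStandard v1"),
        AssemblyRecord("a2", type="USER", part_ids=["d1", "d3"], construct_id="c2"),
        AssemblyRecord("a3", type="GoldenGate", part_ids=["d1", "d6"],
                       construct_id="c1"),
        AssemblyRecord("a4", type="USER", part_ids=["d6"], construct_id="c4",
                       date=d("2024-03-05")),
    ]
    inst.transformations = [
        TransformationRecord("t1", assembly_id="a1", date=d("2024-03-02"),
                             colony_category="10-50", procedure="standard"),
        TransformationRecord("t2", assembly_id="a1", date=d("2024-03-04"),
                             colony_category="51-100", procedure="standard"),
    ]
    inst.minipreps = [
        MiniprepRecord("m1", assembly_id="a1", transformation_id="t2",
                       inoculation_date=d("2024-03-05"),
                       miniprep_date=d("2024-03-06"),
                       gel_code="single_band_expected_size", conc_ng_ul=120.0),
        MiniprepRecord("m2", assembly_id="a1", inoculation_date=d("2024-03-03"),
                       miniprep_date=d("2024-03-04"),
                       gel_code="supercoiled_plus_relaxed", conc_ng_ul=90.0),
        MiniprepRecord("m3", assembly_id="a1", inoculation_date=d("2024-03-05"),
                       miniprep_date=d("2024-03-06"), conc_ng_ul=80.0),
    ]
    inst.sequencing = [
        SequencingRecord("s1", miniprep_id="m1", submission_date=d("2024-03-08"),
                         interpretation="all_parts_verified"),
    ]
    inst.experiments = [
        ExperimentRecord("e1", construct_ids=["c1"]),
        ExperimentRecord("e2", construct_ids=["c2", "c4"]),
    ]
    return inst


@pytest.fixture(scope="session")
def generated_campaign() -> Instance:
    return generate_instance(SimParams(n_constructs=40, seed=7))
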