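"""Synthetic cloning-campaign generator.

Builds statistically structured, referentially consistent instances so the
status engine, tracker, dashboard, and analytics are all testable without
any external data.  The generator walks each registered construct through
the real pipeline -- parts, assembly attempts, transformation after a
sampled storage delay, colony scoring, miniprep picks, gel reads, and
sequencing -- drawing failures from configured rates: PCRs fail at
``pcr_fail``, transformations plate empty at ``assembly_fail``, and each
picked clone is independently correct with probability ``hit_rate``.

Gel reads are faithful to clone correctness (a correct clone shows a clean
single band, an incorrect one a failing pattern) except for an
``gel_ambiguity`` fraction of lanes that are not run; sequencing of a
gel-failed clone draws its defect interpretation from a configurable
mixture.  The generator is a test instrument, not a calibrated simulator
of cloning biology.

All draws come from one seeded generator, so instances are reproducible
bit-for-bit given the same parameters.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional

import numpy as np

from .core_model import (
    AssemblyRecord,
    AssemblyType,
    ConstructRecord,
    DsDNARecord,
    DsDNASource,
    GelCode,
    Instance,
    MiniprepRecord,
    OligoRecord,
    SeqInterpretation,
    SequencingRecord,
    Settings,
    TransformationRecord,
    TransformationProcedure,
    ExperimentRecord,
)

__all__ = ["SimParams", "generate_instance", "inject_corruption"]


@dataclass
class SimParams:
    """Study conditions for one synthetic campaign.

    Rates and distributions default to a realistically messy mid-size
    campaign: a 47% per-clone hit rate with 4 clones picked per
    transformation, ~10% PCR failures, ~15% of transformations plating no
    colonies, storage delays concentrated at 0-2 days with a long tail,
    and defect reads dominated by primer-dimer insertion and surviving
    template.
    """

    n_constructs: int = 25
    parts_per_construct: dict[int, float] = field(
        default_factory=lambda: {1: 0.25, 2: 0.40, 3: 0.25, 4: 0.10}
    )
    pcr_fail: float = 0.10
    assembly_fail: float = 0.15
    hit_rate: float = 0.47
    minipreps_per_transformation: int = 4
    colony_categories_given_success: dict[str, float] = field(
        default_factory=lambda: {
            "1-9": 0.15, "10-50": 0.30, "51-100": 0.20, "101-500": 0.25, ">500": 0.10,
        }
    )
    defect_mixture: dict[str, float] = field(
        default_factory=lambda: {
            SeqInterpretation.PRIMER_DIMER_IN_PLACE_OF_PART.value: 0.40,
            SeqInterpretation.TEMPLATE_SURVIVING.value: 0.25,
            SeqInterpretation.POINT_MUTATIONS.value: 0.20,
            SeqInterpretation.MIXED_CLONE.value: 0.15,
        }
    )
    storage_delay_days: dict[int, float] = field(
        default_factory=lambda: {
            0: 0.40, 1: 0.20, 2: 0.15, 3: 0.08, 5: 0.07, 8: 0.05, 20: 0.04, 60: 0.01,
        }
    )
    gel_ambiguity: float = 0.05
    part_sharing: float = 0.15
    assembly_type_mix: dict[str, float] = field(
        default_factory=lambda: {
            AssemblyType.USER.value: 0.65,
            AssemblyType.GOLDEN_GATE.value: 0.25,
            AssemblyType.GIBSON.value: 0.08,
            AssemblyType.LIGATION.value: 0.02,
        }
    )
    seq_followup_incorrect: float = 0.5  # chance a gel-failed clone is sequenced anyway
    queued_only_fraction: float = 0.05  # constructs registered but not yet attempted
    priority_fraction: float = 0.10
    max_attempts: int = 3
    start_date: date = date(2024, 1, 8)
    seed: int = 0

    def validate(self) -> None:
        for name in ("pcr_fail", "assembly_fail", "hit_rate", "gel_ambiguity",
                     "part_sharing", "seq_followup_incorrect",
                     "queued_only_fraction", "priority_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [0, 1], got {v}")
        for name in ("parts_per_construct", "colony_categories_given_success",
                     "defect_mixture", "storage_delay_days", "assembly_type_mix"):
            dist = getattr(self, name)
            if not dist or abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a distribution summing to 1")
        if self.n_constructs < 0:
            raise ValueError("n_constructs must be >= 0")
        if self.minipreps_per_transformation < 1:
            raise ValueError("minipreps_per_transformation must be >= 1")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")


_CONDITION_BY_TYPE = {
    AssemblyType.USER.value: "USERStandard v1",
    AssemblyType.GOLDEN_GATE.value: "GGATE60",
    AssemblyType.GIBSON.value: "GibsonStandard v1",
    AssemblyType.LIGATION.value: "LigationStandard v1",
}

_FAIL_GELS = (GelCode.WRONG_SIZE.value, GelCode.MULTIPLE_BANDS.value,
              GelCode.BAND_ABSENT.value)


def _choice(rng: np.random.Generator, dist: dict) -> object:
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


class _Campaign:
    """Mutable build state while generating one instance."""

    def __init__(self, params: SimParams):
        self.instance = Instance(settings=Settings())
        self.params = params

    def new_id(self, table: str, prefix: str) -> str:
        return f"{prefix}{self.instance.next_serial(table)}"

    def add_oligo(self, day: date) -> OligoRecord:
        rec = OligoRecord(id=self.new_id("oligos", "o"), order_date=day)
        self.instance.oligos.append(rec)
        return rec

    def add_part(self, rng: np.random.Generator, day: date, failed: bool) -> DsDNARecord:
        primers = [self.add_oligo(day - timedelta(days=5)).id for _ in range(2)]
        length = float(np.round(rng.uniform(0.5, 6.0), 2))
        rec = DsDNARecord(
            id=self.new_id("dsdna", "d"),
            source=DsDNASource.PCR.value,
            primer_ids=primers,
            length_kb=length,
        )
        if failed:
            rec.gel_code = str(_choice(rng, {GelCode.SMEAR.value: 0.5,
                                             GelCode.BAND_ABSENT.value: 0.5}))
        else:
            rec.purification_date = day
            rec.conc_ng_ul = float(np.round(np.clip(rng.normal(55.0, 15.0), 10.0, 150.0), 1))
            if rng.random() < 0.5:
                rec.gel_code = GelCode.SINGLE_BAND_EXPECTED_SIZE.value
        self.instance.dsdna.append(rec)
        return rec


def generate_instance(params: Optional[SimParams] = None) -> Instance:
    """Generate one synthetic campaign instance; deterministic given seed.

    The result always passes :func:`~clonecoord.core_model.validate_instance`
    and keeps dates self-consistent (assembly <= transformation <=
    inoculation <= miniprep <= sequencing).
    """
    params = params or SimParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    camp = _Campaign(params)
    inst = camp.instance

    shared_backbone: Optional[DsDNARecord] = None
    k = params.minipreps_per_transformation

    for ci in range(params.n_constructs):
        queue_day = params.start_date + timedelta(days=int(ci * 2 + rng.integers(0, 3)))
        construct = ConstructRecord(
            id=camp.new_id("registry", "c"),
            name=f"pSYN{ci + 1:03d}",
            project=f"project-{1 + ci % 3}",
            priority=bool(rng.random() < params.priority_fraction),
            queued_date=queue_day,
        )
        inst.registry.append(construct)

        if rng.random() < params.queued_only_fraction:
            continue  # registered, awaiting its first attempt

        # build the parts once; failed PCRs are logged and replaced
        n_parts = int(_choice(rng, params.parts_per_construct))
        part_ids: list[str] = []
        prep_day = queue_day + timedelta(days=3)
        for pi in range(n_parts):
            if shared_backbone is not None and rng.random() < params.part_sharing:
                part_ids.append(shared_backbone.id)
                continue
            if rng.random() < params.pcr_fail:
                failed = camp.add_part(rng, prep_day, failed=True)
                construct.troubleshooting.append(
                    (prep_day.isoformat(), f"PCR for {failed.id} failed; re-queued")
                )
                prep_day += timedelta(days=2)
            part = camp.add_part(rng, prep_day, failed=False)
            part_ids.append(part.id)
            if shared_backbone is None and pi == 0:
                shared_backbone = part

        asm_type = str(_choice(rng, params.assembly_type_mix))
        day = prep_day + timedelta(days=1)
        done = False
        for attempt in range(params.max_attempts):
            asm = AssemblyRecord(
                id=camp.new_id("assemblies", "a"),
                type=asm_type,
                part_ids=list(part_ids),
                construct_id=construct.id,
                date=day,
                condition=_CONDITION_BY_TYPE[asm_type],
                volume_ul=10.0,
            )
            inst.assemblies.append(asm)

            delay = int(_choice(rng, params.storage_delay_days))
            t_day = day + timedelta(days=delay)
            plated_empty = rng.random() < params.assembly_fail
            trans = TransformationRecord(
                id=camp.new_id("transformations", "t"),
                assembly_id=asm.id,
                date=t_day,
                cell_batch=f"batch-{1 + int(rng.integers(0, 3))}",
                procedure=TransformationProcedure.STANDARD.value,
                colony_category="0" if plated_empty else str(
                    _choice(rng, params.colony_categories_given_success)
                ),
            )
            inst.transformations.append(trans)

            if plated_empty:
                construct.troubleshooting.append(
                    (t_day.isoformat(), f"{asm.id} gave no colonies; retrying")
                )
                day = t_day + timedelta(days=2)
                continue

            correct_flags = rng.random(k) < params.hit_rate
            first_correct_mid: Optional[str] = None
            defect_mid: Optional[str] = None
            for mi in range(k):
                m = MiniprepRecord(
                    id=camp.new_id("minipreps", "m"),
                    assembly_id=asm.id,
                    transformation_id=trans.id if rng.random() < 0.5 else None,
                    inoculation_date=t_day + timedelta(days=1),
                    miniprep_date=t_day + timedelta(days=2),
                    conc_ng_ul=float(np.round(rng.uniform(40.0, 300.0), 1)),
                )
                if rng.random() < params.gel_ambiguity:
                    m.gel_code = GelCode.NOT_RUN.value
                elif correct_flags[mi]:
                    m.gel_code = (
                        GelCode.SINGLE_BAND_EXPECTED_SIZE.value
                        if rng.random() < 0.7
                        else GelCode.SUPERCOILED_PLUS_RELAXED.value
                    )
                else:
                    m.gel_code = str(_FAIL_GELS[int(rng.integers(0, len(_FAIL_GELS)))])
                inst.minipreps.append(m)
                if (correct_flags[mi] and first_correct_mid is None
                        and m.gel_code != GelCode.NOT_RUN.value):
                    first_correct_mid = m.id
                if (not correct_flags[mi] and defect_mid is None
                        and m.gel_code != GelCode.NOT_RUN.value):
                    defect_mid = m.id

            seq_day = t_day + timedelta(days=4)
            if first_correct_mid is not None:
                inst.sequencing.append(
                    SequencingRecord(
                        id=camp.new_id("sequencing", "s"),
                        miniprep_id=first_correct_mid,
                        submission_date=seq_day,
                        interpretation=SeqInterpretation.ALL_PARTS_VERIFIED.value,
                    )
                )
                done = True
            if defect_mid is not None and rng.random() < params.seq_followup_incorrect:
                inst.sequencing.append(
                    SequencingRecord(
                        id=camp.new_id("sequencing", "s"),
                        miniprep_id=defect_mid,
                        submission_date=seq_day,
                        interpretation=str(_choice(rng, params.defect_mixture)),
                    )
                )
            if done:
                break
            construct.troubleshooting.append(
                (seq_day.isoformat(), f"no correct clone from {asm.id}; new attempt")
            )
            day = seq_day + timedelta(days=3)

    # group completed-ish constructs into a few experiments
    if inst.registry:
        cids = [c.id for c in inst.registry]
        for start in range(0, len(cids), 5):
            group = cids[start:start + 5]
            inst.experiments.append(
                ExperimentRecord(
                    id=camp.new_id("experiments", "e"),
                    construct_ids=group,
                    conditions=f"growth assay panel {start // 5 + 1}",
                )
            )
    return inst


# ---------------------------------------------------------------------------
# Corruption injection
# ---------------------------------------------------------------------------

_CORRUPTIONS = ("dangling_ref", "duplicate_id", "bad_enum", "bad_date")


def inject_corruption(
    instance: Instance, kind: str, seed: int = 0
) -> tuple[Instance, tuple[str, str, str]]:
    """Return a deep copy of ``instance`` with exactly one record corrupted.

    ``kind`` is one of dangling_ref, duplicate_id, bad_enum, bad_date.  The
    corruption location is returned as (table, row id, field) and is
    guaranteed to be reported by ``validate_instance``.
    """
    if kind not in _CORRUPTIONS:
        raise ValueError(f"unknown corruption kind {kind!r}")
    inst = copy.deepcopy(instance)
    rng = np.random.default_rng(seed)

    def pick(table: str):
        records = inst.table(table)
        if not records:
            raise ValueError(f"cannot corrupt empty table {table!r}")
        return records[int(rng.integers(0, len(records)))]

    if kind == "dangling_ref":
        candidates = [t for t in ("minipreps", "transformations", "sequencing")
                      if inst.table(t)]
        if not candidates:
            raise ValueError("no referencing records to corrupt")
        table = candidates[int(rng.integers(0, len(candidates)))]
        rec = pick(table)
        fld = {"minipreps": "assembly_id", "transformations": "assembly_id",
               "sequencing": "miniprep_id"}[table]
        setattr(rec, fld, {"minipreps": "a999999", "transformations": "a999999",
                           "sequencing": "m999999"}[table])
        return inst, (table, rec.id, fld)

    if kind == "duplicate_id":
        candidates = [t for t in ("dsdna", "minipreps", "oligos", "assemblies")
                      if len(inst.table(t)) >= 1]
        if not candidates:
            raise ValueError("no table with records to duplicate")
        table = candidates[int(rng.integers(0, len(candidates)))]
        rec = pick(table)
        clone = copy.deepcopy(rec)
        inst.table(table).append(clone)
        return inst, (table, rec.id, "id")

    if kind == "bad_enum":
        candidates = [t for t in ("minipreps", "dsdna", "sequencing", "assemblies")
                      if inst.table(t)]
        if not candidates:
            raise ValueError("no records with enum fields to corrupt")
        table = candidates[int(rng.integers(0, len(candidates)))]
        rec = pick(table)
        fld = {"minipreps": "gel_code", "dsdna": "gel_code",
               "sequencing": "interpretation", "assemblies": "type"}[table]
        setattr(rec, fld, "definitely_not_a_code")
        return inst, (table, rec.id, fld)

    # bad_date
    candidates = [t for t in ("assemblies", "transformations", "minipreps",
                              "sequencing", "registry") if inst.table(t)]
    if not candidates:
        raise ValueError("no dated records to corrupt")
    table = candidates[int(rng.integers(0, len(candidates)))]
    rec = pick(table)
    fld = {"assemblies": "date", "transformations": "date",
           "minipreps": "inoculation_date", "sequencing": "submission_date",
           "registry": "queued_date"}[table]
    setattr(rec, fld, "2024-13-45")
    return inst, (table, rec.id, fld)
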