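"""Domain model for a cloning campaign: typed records, sample IDs, storage
arithmetic, and instance load/save/validate.

A campaign ("instance") is a directory of delimited-text tables, one per
record type, plus a settings file.  Every physical sample carries a compact
identifier -- a one-letter type prefix followed by a serial number ("a20",
"d1286") -- that doubles as its storage address: serials map bijectively
onto tube positions in 96-slot plates filled column-major in 8-tube strips.

Record fields that are enumerations or dates are kept as loosely typed
values at load time (an unparseable date survives as its raw string) so
that :func:`validate_instance` can report malformed data instead of the
loader crashing on it.  Downstream modules assume a validated instance.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Optional, Union

import yaml

__all__ = [
    "SampleIDError",
    "SchemaError",
    "SampleID",
    "PlateLayout",
    "StorageLocation",
    "GelCode",
    "SeqInterpretation",
    "AssemblyType",
    "DsDNASource",
    "TransformationProcedure",
    "ColonyCategory",
    "Settings",
    "OligoRecord",
    "DsDNARecord",
    "AssemblyRecord",
    "TransformationRecord",
    "MiniprepRecord",
    "SequencingRecord",
    "ConstructRecord",
    "ExperimentRecord",
    "AlertRecord",
    "Issue",
    "Instance",
    "parse_sample_id",
    "format_sample_id",
    "id_to_row_index",
    "id_to_storage_location",
    "storage_location_to_serial",
    "serial_of",
    "validate_instance",
    "load_instance",
    "save_instance",
]

SAMPLE_PREFIXES = ("o", "d", "a", "g", "m")

# table-local prefixes for records that are not stored physical samples
TABLE_PREFIXES = {
    "oligos": "o",
    "dsdna": "d",
    "assemblies": "a",
    "transformations": "t",
    "minipreps": "m",
    "sequencing": "s",
    "registry": "c",
    "experiments": "e",
}


class SampleIDError(ValueError):
    """Raised when a sample identifier cannot be parsed."""


class SchemaError(ValueError):
    """Raised when an instance directory is missing a table or column."""


# ---------------------------------------------------------------------------
# Sample identifiers and storage arithmetic
# ---------------------------------------------------------------------------

_ID_RE = re.compile(r"^([a-z])([0-9]+)$")


@dataclass(frozen=True, order=True)
class SampleID:
    """A typed sample identifier: one-letter prefix plus positive serial.

    Prefixes: ``o`` oligo, ``d`` dsDNA fragment, ``a`` assembly mixture,
    ``g`` glycerol/strain stock, ``m`` miniprep.
    """

    prefix: str
    serial: int

    def __str__(self) -> str:
        return f"{self.prefix}{self.serial}"


def parse_sample_id(text: str, prefixes: tuple[str, ...] = SAMPLE_PREFIXES) -> SampleID:
    """Parse ``"a20"`` into ``SampleID("a", 20)``.

    Raises :class:`SampleIDError` naming the offending text for an unknown
    prefix, a non-numeric serial, a zero-padded serial, or serial < 1.
    """
    if not text:
        raise SampleIDError("empty sample id")
    m = _ID_RE.match(text)
    if not m:
        raise SampleIDError(f"malformed sample id: {text!r}")
    prefix, digits = m.group(1), m.group(2)
    if prefix not in prefixes:
        raise SampleIDError(f"unknown sample-type prefix in {text!r}")
    if digits != str(int(digits)):
        raise SampleIDError(f"zero-padded serial in {text!r}")
    serial = int(digits)
    if serial < 1:
        raise SampleIDError(f"serial must be >= 1 in {text!r}")
    return SampleID(prefix, serial)


def format_sample_id(sid: SampleID) -> str:
    return str(sid)


def serial_of(id_text: str) -> int:
    """Serial number of any prefixed record id (``"t42"`` -> 42)."""
    m = _ID_RE.match(id_text)
    if not m:
        raise SampleIDError(f"malformed id: {id_text!r}")
    return int(m.group(2))


def id_to_row_index(sid: Union[SampleID, str], num_header_rows: int) -> int:
    """Row index of a sample in its table: serial plus the header-row count.

    Mirrors the serial-keyed layout in which a sample's row is fully
    determined by its serial, so lookups are O(1) index arithmetic.
    """
    if num_header_rows < 0:
        raise ValueError("num_header_rows must be >= 0")
    if isinstance(sid, str):
        sid = parse_sample_id(sid)
    return sid.serial + num_header_rows


@dataclass(frozen=True)
class PlateLayout:
    """Physical storage layout: 8-tube strips (columns) in 12-column plates."""

    positions_per_column: int = 8
    columns_per_plate: int = 12

    @property
    def slots_per_plate(self) -> int:
        return self.positions_per_column * self.columns_per_plate


@dataclass(frozen=True)
class StorageLocation:
    plate: int
    column: int
    position: int


def id_to_storage_location(
    sid: Union[SampleID, str, int], layout: PlateLayout = PlateLayout()
) -> StorageLocation:
    """Storage slot for a serial: strips fill position-first, then column,
    then plate (column-major).  Serial 1 is plate 1, column 1, position 1.
    """
    if isinstance(sid, str):
        sid = parse_sample_id(sid)
    serial = sid.serial if isinstance(sid, SampleID) else int(sid)
    if serial < 1:
        raise ValueError("serial must be >= 1")
    s0 = serial - 1
    plate, rem = divmod(s0, layout.slots_per_plate)
    column, position = divmod(rem, layout.positions_per_column)
    return StorageLocation(plate + 1, column + 1, position + 1)


def storage_location_to_serial(
    loc: StorageLocation, layout: PlateLayout = PlateLayout()
) -> int:
    """Inverse of :func:`id_to_storage_location`."""
    if not (1 <= loc.column <= layout.columns_per_plate):
        raise ValueError(f"column out of range: {loc.column}")
    if not (1 <= loc.position <= layout.positions_per_column):
        raise ValueError(f"position out of range: {loc.position}")
    if loc.plate < 1:
        raise ValueError(f"plate out of range: {loc.plate}")
    return (
        (loc.plate - 1) * layout.slots_per_plate
        + (loc.column - 1) * layout.positions_per_column
        + loc.position
    )


# ---------------------------------------------------------------------------
# Closed enumerations
# ---------------------------------------------------------------------------


class GelCode(str, Enum):
    """Coded interpretation of one agarose-gel lane."""

    SINGLE_BAND_EXPECTED_SIZE = "single_band_expected_size"
    SUPERCOILED_PLUS_RELAXED = "supercoiled_plus_relaxed"
    BAND_ABSENT = "band_absent"
    SMEAR = "smear"
    WRONG_SIZE = "wrong_size"
    MULTIPLE_BANDS = "multiple_bands"
    NOT_RUN = "not_run"


class SeqInterpretation(str, Enum):
    """Closed set of sequencing-alignment interpretation categories."""

    ALL_PARTS_VERIFIED = "all_parts_verified"
    SOME_PARTS_VERIFIED = "some_parts_verified"
    PRIMER_DIMER_IN_PLACE_OF_PART = "primer_dimer_in_place_of_part"
    PRIMER_DIMER_IN_ADDITION = "primer_dimer_in_addition"
    MIXUP_MATCHES_OTHER_MAP = "mixup_matches_other_map"
    MIXUP_PART_FROM_UNLISTED_SOURCE = "mixup_part_from_unlisted_source"
    MIXED_CLONE = "mixed_clone"
    PARTS_MISSING = "parts_missing"
    EVIDENCE_OF_MISASSEMBLY = "evidence_of_misassembly"
    POINT_MUTATIONS = "point_mutations"
    SMALL_INDEL = "small_indel"
    LARGE_INDEL = "large_indel"
    TRANSPOSABLE_ELEMENT = "transposable_element"
    TEMPLATE_SURVIVING = "template_surviving"
    PCR_AMPLIFIED_UNDESIRED = "pcr_amplified_undesired"
    POOR_READ_QUALITY = "poor_read_quality"
    OTHER = "other"


#: Interpretations that do NOT count as a detected defect: verification of
#: some/all parts, or a failed read carrying no information.
NON_DEFECT_INTERPRETATIONS = frozenset(
    {
        SeqInterpretation.ALL_PARTS_VERIFIED.value,
        SeqInterpretation.SOME_PARTS_VERIFIED.value,
        SeqInterpretation.POOR_READ_QUALITY.value,
    }
)


class AssemblyType(str, Enum):
    USER = "USER"
    GIBSON = "Gibson"
    GOLDEN_GATE = "GoldenGate"
    LIGATION = "Ligation"


class DsDNASource(str, Enum):
    PCR = "pcr"
    DIGEST = "digest"
    ANNEALED_OLIGOS = "annealed_oligos"
    EXTERNAL = "external"


class TransformationProcedure(str, Enum):
    STANDARD = "standard"
    MAXIMUM_CARE = "maximum_care"


_GEL_VALUES = frozenset(c.value for c in GelCode)
_SEQ_VALUES = frozenset(c.value for c in SeqInterpretation)
_ASM_VALUES = frozenset(c.value for c in AssemblyType)
_SRC_VALUES = frozenset(c.value for c in DsDNASource)
_PROC_VALUES = frozenset(c.value for c in TransformationProcedure)


# ---------------------------------------------------------------------------
# Settings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColonyCategory:
    """One colony-count bucket; ``hi=None`` means unbounded above."""

    label: str
    lo: int
    hi: Optional[int]

    def contains(self, count: int) -> bool:
        return count >= self.lo and (self.hi is None or count <= self.hi)


#: Quasi-logarithmic colony-count buckets with a boundary at 100 colonies,
#: the threshold separating low- from high-yield transformations downstream.
DEFAULT_COLONY_CATEGORIES = (
    ColonyCategory("0", 0, 0),
    ColonyCategory("1-9", 1, 9),
    ColonyCategory("10-50", 10, 50),
    ColonyCategory("51-100", 51, 100),
    ColonyCategory("101-500", 101, 500),
    ColonyCategory(">500", 501, None),
)

#: gel code -> quality class used both by the status engine and analytics
DEFAULT_GEL_QUALITY_FLAGS = {
    GelCode.SINGLE_BAND_EXPECTED_SIZE.value: "likely_correct",
    GelCode.SUPERCOILED_PLUS_RELAXED.value: "likely_correct",
    GelCode.BAND_ABSENT.value: "likely_incorrect",
    GelCode.SMEAR.value: "likely_incorrect",
    GelCode.WRONG_SIZE.value: "likely_incorrect",
    GelCode.MULTIPLE_BANDS.value: "likely_incorrect",
    GelCode.NOT_RUN.value: "ambiguous",
}

TASK_NAMES = (
    "purify",
    "quantify",
    "gel",
    "assemble",
    "transform",
    "miniprep",
    "sequence",
)


@dataclass
class Settings:
    """Per-instance configuration: table layout, QC requirements, task
    thresholds, and the coded-value dictionaries.

    ``batch_threshold`` and ``staleness_days`` hold per-task overrides; a
    task not present falls back to the ``default_*`` scalar.
    """

    num_header_rows: int = 2
    default_batch_threshold: int = 8
    default_staleness_days: int = 14
    batch_threshold: dict[str, int] = field(default_factory=dict)
    staleness_days: dict[str, int] = field(default_factory=dict)
    require_dsdna_gel: bool = False
    require_miniprep_gel: bool = True
    require_analytical_pcr: bool = False
    sequencing_mandated: bool = True
    gel_quality_flags: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_GEL_QUALITY_FLAGS)
    )
    colony_categories: list[ColonyCategory] = field(
        default_factory=lambda: list(DEFAULT_COLONY_CATEGORIES)
    )

    def batch_threshold_for(self, task: str) -> int:
        return self.batch_threshold.get(task, self.default_batch_threshold)

    def staleness_days_for(self, task: str) -> int:
        return self.staleness_days.get(task, self.default_staleness_days)

    def colony_category(self, label: str) -> Optional[ColonyCategory]:
        for cat in self.colony_categories:
            if cat.label == label:
                return cat
        return None

    def colony_labels(self) -> list[str]:
        return [c.label for c in self.colony_categories]

    def validate(self) -> list[str]:
        """Check the colony-category invariants: ordered, disjoint, covering
        0..infinity, with a bucket boundary at exactly 100."""
        problems: list[str] = []
        if self.num_header_rows < 0:
            problems.append("num_header_rows must be >= 0")
        cats = self.colony_categories
        if not cats:
            return problems + ["colony_categories must not be empty"]
        if cats[0].lo != 0:
            problems.append("colony categories must start at 0")
        if cats[-1].hi is not None:
            problems.append("last colony category must be unbounded")
        for prev, nxt in zip(cats, cats[1:]):
            if prev.hi is None or nxt.lo != prev.hi + 1:
                problems.append(
                    f"colony categories {prev.label!r} and {nxt.label!r} are "
                    "not contiguous"
                )
        if not any(c.hi == 100 for c in cats):
            problems.append("colony categories must include a boundary at 100")
        for code in self.gel_quality_flags:
            if code not in _GEL_VALUES:
                problems.append(f"gel_quality_flags has unknown gel code {code!r}")
        return problems

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "num_header_rows": self.num_header_rows,
            "default_batch_threshold": self.default_batch_threshold,
            "default_staleness_days": self.default_staleness_days,
            "batch_threshold": dict(self.batch_threshold),
            "staleness_days": dict(self.staleness_days),
            "require_dsdna_gel": self.require_dsdna_gel,
            "require_miniprep_gel": self.require_miniprep_gel,
            "require_analytical_pcr": self.require_analytical_pcr,
            "sequencing_mandated": self.sequencing_mandated,
            "gel_quality_flags": dict(self.gel_quality_flags),
            "colony_categories": [
                {"label": c.label, "lo": c.lo, "hi": c.hi}
                for c in self.colony_categories
            ],
        }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "Settings":
        kwargs = dict(data)
        cats = kwargs.pop("colony_categories", None)
        settings = cls(**kwargs)
        if cats is not None:
            settings.colony_categories = [
                ColonyCategory(c["label"], int(c["lo"]),
                               None if c["hi"] is None else int(c["hi"]))
                for c in cats
            ]
        return settings


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

# Column specs: (csv column, attribute, kind). Kinds drive generic CSV
# (de)serialization; "date" tolerates malformed input by keeping the raw
# string so validate_instance can report it.


@dataclass
class OligoRecord:
    id: str
    sequence: Optional[str] = None
    order_date: Any = None
    stock_volume_ul: Optional[float] = None
    stock_conc_uM: Optional[float] = None
    voided: bool = False
    extra: dict[str, str] = field(default_factory=dict)

    _columns = [
        ("id", "id", "str"),
        ("sequence", "sequence", "str"),
        ("order_date", "order_date", "date"),
        ("stock_volume_ul", "stock_volume_ul", "float"),
        ("stock_conc_uM", "stock_conc_uM", "float"),
        ("voided", "voided", "bool"),
    ]


@dataclass
class DsDNARecord:
    id: str
    source: Optional[str] = None  # DsDNASource value
    template_id: Optional[str] = None
    primer_ids: list[str] = field(default_factory=list)
    length_kb: Optional[float] = None
    conc_ng_ul: Optional[float] = None
    gel_code: Optional[str] = None
    purification_date: Any = None
    volume_low: bool = False
    certify_queued: bool = False
    voided: bool = False
    extra: dict[str, str] = field(default_factory=dict)

    _columns = [
        ("id", "id", "str"),
        ("source", "source", "str"),
        ("template_id", "template_id", "str"),
        ("primer_ids", "primer_ids", "idlist"),
        ("length_kb", "length_kb", "float"),
        ("conc_ng_ul", "conc_ng_ul", "float"),
        ("gel_code", "gel_code", "str"),
        ("purification_date", "purification_date", "date"),
        ("volume_low", "volume_low", "bool"),
        ("certify_queued", "certify_queued", "bool"),
        ("voided", "voided", "bool"),
    ]


@dataclass
class AssemblyRecord:
    id: str
    type: Optional[str] = None  # AssemblyType value
    part_ids: list[str] = field(default_factory=list)
    construct_id: Optional[str] = None
    date: Any = None
    condition: Optional[str] = None
    volume_ul: Optional[float] = None
    voided: bool = False
    extra: dict[str, str] = field(default_factory=dict)

    _columns = [
        ("id", "id", "str"),
        ("type", "type", "str"),
        ("part_ids", "part_ids", "idlist"),
        ("construct_id", "construct_id", "str"),
        ("date", "date", "date"),
        ("condition", "condition", "str"),
        ("volume_ul", "volume_ul", "float"),
        ("voided", "voided", "bool"),
    ]


@dataclass
class TransformationRecord:
    id: str
    assembly_id: Optional[str] = None
    date: Any = None
    cell_batch: Optional[str] = None
    procedure: Optional[str] = None  # TransformationProcedure value
    colony_category: Optional[str] = None  # label from Settings.colony_categories
    voided: bool = False
    extra: dict[str, str] = field(default_factory=dict)

    _columns = [
        ("id", "id", "str"),
        ("assembly_id", "assembly_id", "str"),
        ("date", "date", "date"),
        ("cell_batch", "cell_batch", "str"),
        ("procedure", "procedure", "str"),
        ("colony_category", "colony_category", "str"),
        ("voided", "voided", "bool"),
    ]


@dataclass
class MiniprepRecord:
    id: str
    assembly_id: Optional[str] = None
    transformation_id: Optional[str] = None  # explicit source, when recorded
    inoculation_date: Any = None
    miniprep_date: Any = None
    gel_code: Optional[str] = None
    conc_ng_ul: Optional[float] = None
    voided: bool = False
    extra: dict[str, str] = field(default_factory=dict)

    _columns = [
        ("id", "id", "str"),
        ("assembly_id", "assembly_id", "str"),
        ("transformation_id", "transformation_id", "str"),
        ("inoculation_date", "inoculation_date", "date"),
        ("miniprep_date", "miniprep_date", "date"),
        ("gel_code", "gel_code", "str"),
        ("conc_ng_ul", "conc_ng_ul", "float"),
        ("voided", "voided", "bool"),
    ]


@dataclass
class SequencingRecord:
    id: str
    miniprep_id: Optional[str] = None
    submission_date: Any = None
    interpretation: Optional[str] = None  # SeqInterpretation value
    voided: bool = False
    extra: dict[str, str] = field(default_factory=dict)

    _columns = [
        ("id", "id", "str"),
        ("miniprep_id", "miniprep_id", "str"),
        ("submission_date", "submission_date", "date"),
        ("interpretation", "interpretation", "str"),
        ("voided", "voided", "bool"),
    ]

    @property
    def serial(self) -> int:
        return serial_of(self.id)


@dataclass
class ConstructRecord:
    id: str
    name: Optional[str] = None
    description: Optional[str] = None
    assembly_plan: Optional[str] = None
    project: Optional[str] = None
    priority: bool = False
    queued_date: Any = None
    troubleshooting: list[tuple[str, str]] = field(default_factory=list)
    voided: bool = False
    extra: dict[str, str] = field(default_factory=dict)

    _columns = [
        ("id", "id", "str"),
        ("name", "name", "str"),
        ("description", "description", "str"),
        ("assembly_plan", "assembly_plan", "str"),
        ("project", "project", "str"),
        ("priority", "priority", "bool"),
        ("queued_date", "queued_date", "date"),
        ("troubleshooting", "troubleshooting", "json"),
        ("voided", "voided", "bool"),
    ]


@dataclass
class ExperimentRecord:
    id: str
    construct_ids: list[str] = field(default_factory=list)
    conditions: Optional[str] = None
    voided: bool = False
    extra: dict[str, str] = field(default_factory=dict)

    _columns = [
        ("id", "id", "str"),
        ("construct_ids", "construct_ids", "idlist"),
        ("conditions", "conditions", "str"),
        ("voided", "voided", "bool"),
    ]


@dataclass
class AlertRecord:
    """One entry in the append-only alert event log (replaces email delivery)."""

    experiment_id: str
    kind: str  # "experiment_ready" | "construct_stalled"
    construct_id: Optional[str] = None
    date: Any = None
    state_hash: Optional[str] = None
    extra: dict[str, str] = field(default_factory=dict)

    _columns = [
        ("experiment_id", "experiment_id", "str"),
        ("kind", "kind", "str"),
        ("construct_id", "construct_id", "str"),
        ("date", "date", "date"),
        ("state_hash", "state_hash", "str"),
    ]


TABLE_SPECS: dict[str, tuple[type, str]] = {
    "oligos": (OligoRecord, "oligos.csv"),
    "dsdna": (DsDNARecord, "dsdna.csv"),
    "assemblies": (AssemblyRecord, "assemblies.csv"),
    "transformations": (TransformationRecord, "transformations.csv"),
    "minipreps": (MiniprepRecord, "minipreps.csv"),
    "sequencing": (SequencingRecord, "sequencing.csv"),
    "registry": (ConstructRecord, "registry.csv"),
    "experiments": (ExperimentRecord, "experiments.csv"),
}

SETTINGS_FILE = "settings.yaml"
ALERTS_FILE = "alerts.csv"


# ---------------------------------------------------------------------------
# Instance
# ---------------------------------------------------------------------------


@dataclass
class Instance:
    """The full relational record set of one cloning campaign."""

    settings: Settings = field(default_factory=Settings)
    oligos: list[OligoRecord] = field(default_factory=list)
    dsdna: list[DsDNARecord] = field(default_factory=list)
    assemblies: list[AssemblyRecord] = field(default_factory=list)
    transformations: list[TransformationRecord] = field(default_factory=list)
    minipreps: list[MiniprepRecord] = field(default_factory=list)
    sequencing: list[SequencingRecord] = field(default_factory=list)
    registry: list[ConstructRecord] = field(default_factory=list)
    experiments: list[ExperimentRecord] = field(default_factory=list)
    alerts: list[AlertRecord] = field(default_factory=list)

    def table(self, name: str) -> list:
        return getattr(self, name)

    def index(self, name: str) -> dict[str, Any]:
        """id -> record map for one table (last record wins on duplicates)."""
        return {rec.id: rec for rec in self.table(name)}

    def get(self, name: str, rec_id: str):
        for rec in self.table(name):
            if rec.id == rec_id:
                return rec
        raise KeyError(f"{rec_id!r} not found in table {name!r}")

    def has(self, name: str, rec_id: str) -> bool:
        return any(rec.id == rec_id for rec in self.table(name))

    def next_serial(self, name: str) -> int:
        serials = [serial_of(rec.id) for rec in self.table(name)]
        return (max(serials) + 1) if serials else 1

    def validate(self) -> list["Issue"]:
        return validate_instance(self)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Issue:
    """One validation finding, naming table, row id, field, and rule."""

    table: str
    row_id: str
    field: str
    rule: str
    message: str

    def __str__(self) -> str:
        return f"{self.table}[{self.row_id}].{self.field}: {self.rule} -- {self.message}"


def _check_date(issues: list[Issue], table: str, rid: str, fname: str, value: Any) -> None:
    if value is None or isinstance(value, date):
        return
    issues.append(
        Issue(table, rid, fname, "malformed_date", f"unparseable date {value!r}")
    )


def _check_enum(
    issues: list[Issue], table: str, rid: str, fname: str, value: Any,
    allowed: frozenset, optional: bool = True,
) -> None:
    if value is None and optional:
        return
    if value not in allowed:
        issues.append(
            Issue(table, rid, fname, "bad_enum", f"value {value!r} not in closed set")
        )


def _check_ref(
    issues: list[Issue], table: str, rid: str, fname: str, value: Optional[str],
    target_ids: set[str], target_table: str,
) -> None:
    if value is None:
        return
    if value not in target_ids:
        issues.append(
            Issue(
                table, rid, fname, "dangling_ref",
                f"{value!r} does not resolve in table {target_table!r}",
            )
        )


def validate_instance(instance: Instance) -> list[Issue]:
    """Check every type invariant and all referential integrity rules.

    Returns an empty list iff the instance is fully consistent.  Each issue
    names the table, the offending row id, the field, and the rule violated.
    """
    issues: list[Issue] = []

    for problem in instance.settings.validate():
        issues.append(Issue("settings", "-", "-", "bad_settings", problem))

    # id well-formedness + per-table serial uniqueness
    for tname in TABLE_SPECS:
        expected_prefix = TABLE_PREFIXES[tname]
        seen: set[str] = set()
        for rec in instance.table(tname):
            try:
                sid = parse_sample_id(rec.id, prefixes=(expected_prefix,))
            except SampleIDError as exc:
                issues.append(Issue(tname, rec.id, "id", "bad_id", str(exc)))
                continue
            if str(sid) in seen:
                issues.append(
                    Issue(tname, rec.id, "id", "duplicate_id",
                          f"serial {sid.serial} reused within prefix {sid.prefix!r}")
                )
            seen.add(str(sid))

    ids = {tname: {rec.id for rec in instance.table(tname)} for tname in TABLE_SPECS}
    colony_labels = set(instance.settings.colony_labels())

    for rec in instance.oligos:
        _check_date(issues, "oligos", rec.id, "order_date", rec.order_date)

    for rec in instance.dsdna:
        _check_enum(issues, "dsdna", rec.id, "source", rec.source, _SRC_VALUES)
        _check_enum(issues, "dsdna", rec.id, "gel_code", rec.gel_code, _GEL_VALUES)
        _check_date(issues, "dsdna", rec.id, "purification_date", rec.purification_date)
        # a PCR template may itself be a miniprep, a dsDNA fragment, or external
        if rec.template_id is not None:
            tmpl_ok = rec.template_id in ids["minipreps"] or rec.template_id in ids["dsdna"]
            if not tmpl_ok:
                issues.append(
                    Issue("dsdna", rec.id, "template_id", "dangling_ref",
                          f"{rec.template_id!r} resolves in neither minipreps nor dsdna")
                )
        for pid in rec.primer_ids:
            _check_ref(issues, "dsdna", rec.id, "primer_ids", pid, ids["oligos"], "oligos")
        if rec.length_kb is not None and rec.length_kb <= 0:
            issues.append(Issue("dsdna", rec.id, "length_kb", "bad_value",
                                f"length must be > 0, got {rec.length_kb}"))

    for rec in instance.assemblies:
        _check_enum(issues, "assemblies", rec.id, "type", rec.type, _ASM_VALUES)
        _check_date(issues, "assemblies", rec.id, "date", rec.date)
        if not rec.part_ids:
            issues.append(Issue("assemblies", rec.id, "part_ids", "empty_parts",
                                "assembly has zero parts"))
        for pid in rec.part_ids:
            _check_ref(issues, "assemblies", rec.id, "part_ids", pid, ids["dsdna"], "dsdna")
        _check_ref(issues, "assemblies", rec.id, "construct_id", rec.construct_id,
                   ids["registry"], "registry")

    for rec in instance.transformations:
        _check_date(issues, "transformations", rec.id, "date", rec.date)
        _check_enum(issues, "transformations", rec.id, "procedure", rec.procedure,
                    _PROC_VALUES)
        _check_ref(issues, "transformations", rec.id, "assembly_id", rec.assembly_id,
                   ids["assemblies"], "assemblies")
        if rec.colony_category is not None and rec.colony_category not in colony_labels:
            issues.append(
                Issue("transformations", rec.id, "colony_category", "bad_enum",
                      f"{rec.colony_category!r} is not a configured colony category")
            )

    for rec in instance.minipreps:
        _check_date(issues, "minipreps", rec.id, "inoculation_date", rec.inoculation_date)
        _check_date(issues, "minipreps", rec.id, "miniprep_date", rec.miniprep_date)
        _check_enum(issues, "minipreps", rec.id, "gel_code", rec.gel_code, _GEL_VALUES)
        _check_ref(issues, "minipreps", rec.id, "assembly_id", rec.assembly_id,
                   ids["assemblies"], "assemblies")
        _check_ref(issues, "minipreps", rec.id, "transformation_id",
                   rec.transformation_id, ids["transformations"], "transformations")

    for rec in instance.sequencing:
        _check_date(issues, "sequencing", rec.id, "submission_date", rec.submission_date)
        _check_enum(issues, "sequencing", rec.id, "interpretation", rec.interpretation,
                    _SEQ_VALUES)
        _check_ref(issues, "sequencing", rec.id, "miniprep_id", rec.miniprep_id,
                   ids["minipreps"], "minipreps")

    for rec in instance.registry:
        _check_date(issues, "registry", rec.id, "queued_date", rec.queued_date)

    for rec in instance.experiments:
        for cid in rec.construct_ids:
            _check_ref(issues, "experiments", rec.id, "construct_ids", cid,
                       ids["registry"], "registry")

    return issues


# ---------------------------------------------------------------------------
# CSV (de)serialization
# ---------------------------------------------------------------------------


def _to_cell(value: Any, kind: str) -> str:
    if value is None:
        return ""
    if kind == "date":
        return value.isoformat() if isinstance(value, date) else str(value)
    if kind == "bool":
        return "true" if value else "false"
    if kind == "idlist":
        return ";".join(value)
    if kind == "json":
        return json.dumps(value) if value else ""
    if kind == "float":
        # integral floats print without trailing .0 noise
        f = float(value)
        return str(int(f)) if f == int(f) else repr(f)
    return str(value)


def _from_cell(cell: str, kind: str) -> Any:
    if cell == "":
        return [] if kind == "idlist" else ([] if kind == "json" else None)
    if kind == "date":
        try:
            return date.fromisoformat(cell)
        except ValueError:
            return cell  # kept raw; validate_instance flags it
    if kind == "bool":
        return cell.strip().lower() in ("true", "1", "yes")
    if kind == "idlist":
        return [p for p in cell.split(";") if p]
    if kind == "json":
        loaded = json.loads(cell)
        return [tuple(entry) for entry in loaded] if isinstance(loaded, list) else loaded
    if kind == "float":
        return float(cell)
    if kind == "int":
        return int(cell)
    return cell


def _record_to_row(rec: Any, columns: list[str]) -> list[str]:
    spec = {col: (attr, kind) for col, attr, kind in type(rec)._columns}
    row = []
    for col in columns:
        if col in spec:
            attr, kind = spec[col]
            row.append(_to_cell(getattr(rec, attr), kind))
        else:
            row.append(rec.extra.get(col, ""))
    return row


def _record_from_row(cls: type, header: list[str], row: list[str]) -> Any:
    spec = {col: (attr, kind) for col, attr, kind in cls._columns}
    kwargs: dict[str, Any] = {}
    extra: dict[str, str] = {}
    for col, cell in zip(header, row):
        if col in spec:
            attr, kind = spec[col]
            value = _from_cell(cell, kind)
            if value is not None or kind in ("idlist", "json"):
                kwargs[attr] = value
        elif cell != "":
            extra[col] = cell
    rec = cls(**kwargs)
    rec.extra = extra
    return rec


def _table_columns(cls: type, records: Iterable[Any]) -> list[str]:
    cols = [col for col, _, _ in cls._columns]
    extra_cols: list[str] = []
    for rec in records:
        for key in rec.extra:
            if key not in extra_cols:
                extra_cols.append(key)
    return cols + sorted(extra_cols)


def load_instance(path: Union[str, Path]) -> Instance:
    """Load an instance directory (one CSV per table + ``settings.yaml``).

    Raises :class:`SchemaError` naming any missing table file or missing
    required column.  Malformed enum/date cells load as raw values and are
    reported by :func:`validate_instance`, not here.
    """
    root = Path(path)
    if not root.is_dir():
        raise SchemaError(f"instance path is not a directory: {root}")

    settings_path = root / SETTINGS_FILE
    if settings_path.exists():
        with open(settings_path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        settings = Settings.from_dict(data)
    else:
        settings = Settings()

    instance = Instance(settings=settings)
    for tname, (cls, filename) in TABLE_SPECS.items():
        fpath = root / filename
        if not fpath.exists():
            raise SchemaError(f"missing required table file: {filename}")
        with open(fpath, "r", encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                raise SchemaError(f"table {filename} has no header row") from None
            required = {col for col, _, _ in cls._columns}
            missing = required - set(header)
            if missing:
                raise SchemaError(
                    f"table {filename} missing required column(s): "
                    + ", ".join(sorted(missing))
                )
            records = [_record_from_row(cls, header, row) for row in reader if row]
        setattr(instance, tname, records)

    alerts_path = root / ALERTS_FILE
    if alerts_path.exists():
        with open(alerts_path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header:
                instance.alerts = [
                    _record_from_row(AlertRecord, header, row) for row in reader if row
                ]
    return instance


def save_instance(instance: Instance, path: Union[str, Path]) -> None:
    """Write the instance as canonical CSVs; load∘save is the identity on
    canonicalized instances and unknown extra columns are preserved."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)

    with open(root / SETTINGS_FILE, "w", encoding="utf-8") as fh:
        yaml.safe_dump(instance.settings.to_dict(), fh, sort_keys=True)

    for tname, (cls, filename) in TABLE_SPECS.items():
        records = instance.table(tname)
        columns = _table_columns(cls, records)
        with open(root / filename, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(columns)
            for rec in records:
                writer.writerow(_record_to_row(rec, columns))

    if instance.alerts:
        columns = _table_columns(AlertRecord, instance.alerts)
        with open(root / ALERTS_FILE, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(columns)
            for rec in instance.alerts:
                writer.writerow(_record_to_row(rec, columns))
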