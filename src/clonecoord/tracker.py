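"""Construct Tracker: per-construct build histories and campaign totals.

A construct's history is the complete join of everything logged while
building it, organized by assembly attempt: the parts consumed (with
cross-construct evidence for each), the transformations and their colony
counts, the minipreps with their QC outcomes, and every sequencing read.
Dated troubleshooting notes from the registry ride along so that whoever
picks the construct up next sees what was already tried.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Any, Optional

from .core_model import Instance, Settings, serial_of
from .status_engine import (
    COMPLETE,
    IN_PROGRESS,
    NEEDS_INTERVENTION,
    EvidenceSummary,
    Status,
    assembly_status,
    construct_status,
    dsdna_status,
    miniprep_status,
    part_evidence,
)

__all__ = [
    "PartReport",
    "MiniprepReport",
    "AttemptReport",
    "ConstructHistory",
    "construct_history",
    "count_attempts",
    "filter_constructs",
    "tracker_dashboard",
]


@dataclass
class PartReport:
    part_id: str
    status: Status
    evidence: EvidenceSummary


@dataclass
class MiniprepReport:
    miniprep_id: str
    status: Status
    gel_code: Optional[str]
    interpretations: list[str] = field(default_factory=list)


@dataclass
class AttemptReport:
    """Everything logged for one assembly attempt."""

    assembly_id: str
    assembly_type: Optional[str]
    date: Optional[date]
    status: Status
    parts: list[PartReport] = field(default_factory=list)
    transformations: list[tuple[str, Optional[str]]] = field(default_factory=list)
    minipreps: list[MiniprepReport] = field(default_factory=list)


@dataclass
class ConstructHistory:
    construct_id: str
    name: Optional[str]
    status: str
    attempts: list[AttemptReport] = field(default_factory=list)
    troubleshooting: list[tuple[str, str]] = field(default_factory=list)
    summary: str = ""


def _attempt_sort_key(asm) -> tuple:
    # assembly date first, serial breaks ties (and orders undated attempts)
    d = asm.date if isinstance(asm.date, date) else date.max
    return (d, serial_of(asm.id))


def construct_history(construct_id: str, instance: Instance,
                      settings: Optional[Settings] = None) -> ConstructHistory:
    """Full dated history of one construct, organized by assembly attempt."""
    settings = settings or instance.settings
    rec = instance.get("registry", construct_id)  # KeyError for unknown construct
    status = construct_status(construct_id, instance, settings)

    assemblies = sorted(
        (a for a in instance.assemblies if a.construct_id == construct_id),
        key=_attempt_sort_key,
    )

    attempts: list[AttemptReport] = []
    last_event: Optional[date] = None
    for asm in assemblies:
        report = AttemptReport(
            assembly_id=asm.id,
            assembly_type=asm.type,
            date=asm.date if isinstance(asm.date, date) else None,
            status=assembly_status(asm.id, instance, settings),
        )
        for pid in asm.part_ids:
            report.parts.append(
                PartReport(pid, dsdna_status(pid, instance, settings),
                           part_evidence(pid, instance, exclude_assembly=asm.id))
            )
        for t in instance.transformations:
            if t.assembly_id == asm.id:
                report.transformations.append((t.id, t.colony_category))
                if isinstance(t.date, date):
                    last_event = max(last_event or t.date, t.date)
        for m in instance.minipreps:
            if m.assembly_id == asm.id:
                reads = sorted(
                    (s for s in instance.sequencing if s.miniprep_id == m.id),
                    key=lambda s: serial_of(s.id),
                )
                report.minipreps.append(
                    MiniprepReport(
                        m.id,
                        miniprep_status(m.id, instance, settings),
                        m.gel_code,
                        [s.interpretation for s in reads if s.interpretation],
                    )
                )
                for s in reads:
                    if isinstance(s.submission_date, date):
                        last_event = max(last_event or s.submission_date,
                                         s.submission_date)
        if report.date:
            last_event = max(last_event or report.date, report.date)
        attempts.append(report)

    if not attempts:
        summary = "queued"
    else:
        summary = f"{status}; {len(attempts)} attempt(s)"
        if last_event:
            summary += f"; last event {last_event.isoformat()}"

    return ConstructHistory(
        construct_id=construct_id,
        name=rec.name,
        status=status,
        attempts=attempts,
        troubleshooting=list(rec.troubleshooting),
        summary=summary,
    )


def count_attempts(construct_id: str, instance: Instance) -> int:
    """Number of assembly attempts logged for a construct -- a proxy for how
    much troubleshooting it has needed."""
    instance.get("registry", construct_id)
    return sum(1 for a in instance.assemblies if a.construct_id == construct_id)


_FILTER_KEYS = {"status", "assembly_type", "project", "min_attempts", "priority"}


def filter_constructs(
    instance: Instance,
    filters: Optional[dict[str, Any]] = None,
    settings: Optional[Settings] = None,
) -> list[dict[str, Any]]:
    """Filtered construct listing, one row per registered construct.

    Filters combine conjunctively over ``status`` (construct state),
    ``assembly_type`` (any attempt of that type), ``project``,
    ``min_attempts``, and ``priority``.  Rows are ordered by construct
    serial.  Unknown filter keys raise ``KeyError``.
    """
    filters = filters or {}
    settings = settings or instance.settings
    unknown = set(filters) - _FILTER_KEYS
    if unknown:
        raise KeyError(f"unknown filter key(s): {sorted(unknown)}")

    rows = []
    for rec in sorted(instance.registry, key=lambda c: serial_of(c.id)):
        status = construct_status(rec.id, instance, settings)
        attempts = count_attempts(rec.id, instance)
        types = {a.type for a in instance.assemblies
                 if a.construct_id == rec.id and a.type}
        row = {
            "construct_id": rec.id,
            "name": rec.name,
            "project": rec.project,
            "priority": rec.priority,
            "status": status,
            "attempts": attempts,
            "assembly_types": sorted(types),
        }
        if "status" in filters and status != filters["status"]:
            continue
        if "assembly_type" in filters and filters["assembly_type"] not in types:
            continue
        if "project" in filters and rec.project != filters["project"]:
            continue
        if "min_attempts" in filters and attempts < filters["min_attempts"]:
            continue
        if "priority" in filters and rec.priority != bool(filters["priority"]):
            continue
        rows.append(row)
    return rows


def tracker_dashboard(
    instance: Instance, settings: Optional[Settings] = None
) -> dict[str, Any]:
    """Campaign totals: constructs per overall state, plus how many
    constructs are waiting on each ready task.  State totals always sum to
    the registry size."""
    settings = settings or instance.settings
    totals = {IN_PROGRESS: 0, NEEDS_INTERVENTION: 0, COMPLETE: 0}
    ready_tasks: dict[str, int] = {}

    from .dashboard import collect_statuses, _constructs_of_sample

    statuses = collect_statuses(instance, settings)
    construct_tasks: dict[str, set[str]] = {}
    for (table, rec_id), st in statuses.items():
        if st.state != "ready" or st.task is None:
            continue
        for cid in _constructs_of_sample(table, rec_id, instance):
            construct_tasks.setdefault(st.task, set()).add(cid)

    for rec in instance.registry:
        totals[construct_status(rec.id, instance, settings)] += 1
    for task, cids in sorted(construct_tasks.items()):
        ready_tasks[task] = len(cids)

    return {"totals": totals, "ready_task_construct_counts": ready_tasks,
            "n_constructs": len(instance.registry)}
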