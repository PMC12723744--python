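"""Prioritized task list and experiment evaluation.

The dashboard turns derived sample statuses into a to-do list, one row per
pipeline operation, with a three-layer highlighting scheme: *batch* when
enough samples have accumulated to make the operation efficient, *priority*
when flagged constructs are waiting on it, and *stale* when the operation
has not been performed for too long.

Experiments bind a set of constructs to planned test conditions; evaluating
one emits events into an append-only alert log (the file-backed replacement
for email delivery) when the experiment becomes ready or a member construct
stalls.  Events are deduplicated on a state hash so re-evaluation of an
unchanged campaign is a no-op.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from datetime import date
from typing import Optional

from .core_model import AlertRecord, Instance, Settings, TASK_NAMES, serial_of
from .status_engine import (
    COMPLETE,
    NEEDS_INTERVENTION,
    Status,
    assembly_status,
    construct_status,
    dsdna_status,
    miniprep_status,
)

__all__ = [
    "TaskSummary",
    "AlertEvent",
    "collect_statuses",
    "build_task_list",
    "prioritize_tasks",
    "evaluate_experiment",
]

AlertEvent = AlertRecord

EXPERIMENT_READY = "experiment_ready"
CONSTRUCT_STALLED = "construct_stalled"


@dataclass
class TaskSummary:
    """One dashboard row: an operation and how much of it is waiting."""

    task_name: str
    ready_count: int = 0
    priority_count: int = 0
    last_done: Optional[date] = None
    highlights: set[str] = field(default_factory=set)
    ready_ids: list[str] = field(default_factory=list)


def _priority_construct_ids(instance: Instance) -> set[str]:
    return {c.id for c in instance.registry if c.priority and not c.voided}


def _constructs_of_sample(table: str, rec_id: str, instance: Instance) -> set[str]:
    """Construct ids a sample contributes to, via the relational joins."""
    if table == "assemblies":
        asm = instance.get("assemblies", rec_id)
        return {asm.construct_id} if asm.construct_id else set()
    if table == "dsdna":
        out = set()
        for asm in instance.assemblies:
            if rec_id in asm.part_ids and asm.construct_id:
                out.add(asm.construct_id)
        return out
    if table == "minipreps":
        m = instance.get("minipreps", rec_id)
        if m.assembly_id:
            return _constructs_of_sample("assemblies", m.assembly_id, instance)
        return set()
    return set()


def collect_statuses(
    instance: Instance, settings: Optional[Settings] = None
) -> dict[tuple[str, str], Status]:
    """Derived status of every live sample, keyed by (table, id)."""
    settings = settings or instance.settings
    out: dict[tuple[str, str], Status] = {}
    for rec in instance.dsdna:
        out[("dsdna", rec.id)] = dsdna_status(rec.id, instance, settings)
    for rec in instance.assemblies:
        if rec.part_ids:
            out[("assemblies", rec.id)] = assembly_status(rec.id, instance, settings)
    for rec in instance.minipreps:
        out[("minipreps", rec.id)] = miniprep_status(rec.id, instance, settings)
    return out


def _last_done_dates(instance: Instance) -> dict[str, date]:
    """Most recent logged completion date per task type."""
    out: dict[str, date] = {}

    def note(task: str, d) -> None:
        if isinstance(d, date) and (task not in out or d > out[task]):
            out[task] = d

    for rec in instance.dsdna:
        note("purify", rec.purification_date)
    for rec in instance.assemblies:
        note("assemble", rec.date)
    for rec in instance.transformations:
        note("transform", rec.date)
    for rec in instance.minipreps:
        note("miniprep", rec.miniprep_date)
    for rec in instance.sequencing:
        note("sequence", rec.submission_date)
    return out


def build_task_list(
    instance: Instance, settings: Optional[Settings] = None
) -> list[TaskSummary]:
    """One summary per task type, in pipeline order, counting ready samples
    and those belonging to priority-flagged constructs."""
    settings = settings or instance.settings
    statuses = collect_statuses(instance, settings)
    priority_ids = _priority_construct_ids(instance)
    last_done = _last_done_dates(instance)

    summaries = {name: TaskSummary(name, last_done=last_done.get(name))
                 for name in TASK_NAMES}
    for (table, rec_id), status in sorted(statuses.items()):
        if status.state != "ready" or status.task not in summaries:
            continue
        summary = summaries[status.task]
        summary.ready_count += 1
        summary.ready_ids.append(rec_id)
        if _constructs_of_sample(table, rec_id, instance) & priority_ids:
            summary.priority_count += 1
    return [summaries[name] for name in TASK_NAMES]


def prioritize_tasks(
    tasks: list[TaskSummary], settings: Settings, today: date
) -> list[TaskSummary]:
    """Apply the highlight rules in place and return the task list.

    batch: ready count strictly exceeds the per-task batch threshold.
    stale: the task was last done at least ``staleness_days`` ago, or never
    logged while samples are waiting.  priority: any ready sample belongs to
    a priority-flagged construct.
    """
    for task in tasks:
        task.highlights = set()
        if task.ready_count > settings.batch_threshold_for(task.task_name):
            task.highlights.add("batch")
        if task.priority_count > 0:
            task.highlights.add("priority")
        window = settings.staleness_days_for(task.task_name)
        if task.last_done is None:
            if task.ready_count > 0:
                task.highlights.add("stale")
        elif (today - task.last_done).days >= window:
            task.highlights.add("stale")
    return tasks


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------


def _state_hash(exp_id: str, construct_states: dict[str, str]) -> str:
    payload = exp_id + "|" + "|".join(
        f"{cid}={state}" for cid, state in sorted(construct_states.items())
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def evaluate_experiment(
    exp_id: str,
    instance: Instance,
    settings: Optional[Settings] = None,
    today: Optional[date] = None,
) -> tuple[str, list[AlertEvent]]:
    """Evaluate an experiment's readiness and emit alert events.

    Returns the experiment status (``ready``, ``stalled``, or ``waiting``)
    and the list of *new* events, which are also appended to
    ``instance.alerts``.  An ``experiment_ready`` event fires only when
    every member construct is complete; a ``construct_stalled`` event fires
    per member needing intervention.  Events are deduplicated against the
    alert log by (experiment, kind, construct, state hash), so re-evaluating
    an unchanged instance emits nothing.
    """
    settings = settings or instance.settings
    exp = instance.get("experiments", exp_id)
    if not exp.construct_ids:
        raise ValueError(f"experiment {exp_id} has an empty construct set")
    today = today or date.today()

    states = {cid: construct_status(cid, instance, settings) for cid in exp.construct_ids}
    shash = _state_hash(exp_id, states)
    seen = {(a.experiment_id, a.kind, a.construct_id, a.state_hash)
            for a in instance.alerts}

    new_events: list[AlertEvent] = []

    def emit(kind: str, construct_id: Optional[str]) -> None:
        key = (exp_id, kind, construct_id, shash)
        if key in seen:
            return
        event = AlertEvent(exp_id, kind, construct_id, today, shash)
        instance.alerts.append(event)
        new_events.append(event)

    if all(state == COMPLETE for state in states.values()):
        emit(EXPERIMENT_READY, None)
        return "ready", new_events

    stalled = [cid for cid, state in states.items() if state == NEEDS_INTERVENTION]
    for cid in sorted(stalled, key=serial_of):
        emit(CONSTRUCT_STALLED, cid)
    return ("stalled" if stalled else "waiting"), new_events
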