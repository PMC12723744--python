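"""Campaign analytics: outcome classification and binned frequency tables.

These procedures squeeze quantitative cloning insight out of routinely
logged data with no dedicated experiments:

* each miniprep is matched to the transformation it most plausibly came
  from (explicit reference wins; otherwise the largest-serial
  transformation of its assembly dated on or before inoculation);
* gel lanes give a provisional correct/incorrect/ambiguous call per
  miniprep, which sequencing then confirms, refutes, or overrides;
* per assembly, the reconciled calls roll up into an outcome class
  (all / some / none correct) and an *empirical hit rate* -- the share of
  checked clones that appear correct;
* storage-time tables bin assemblies by days elapsed between assembly and
  transformation into decile-derived bins and cross-tabulate colony-count
  categories plus eventual verification;
* sequencing-outcome tables cross-tabulate read interpretation categories
  against colony counts, sorted by their propensity for low-colony plates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    Instance,
    MiniprepRecord,
    SeqInterpretation,
    Settings,
    NON_DEFECT_INTERPRETATIONS,
    serial_of,
)
from .status_engine import latest_read, verified_minipreps_of_assembly

__all__ = [
    "LIKELY_CORRECT",
    "LIKELY_INCORRECT",
    "AMBIGUOUS",
    "FrequencyTable",
    "DecileBins",
    "match_miniprep_to_transformation",
    "classify_gel",
    "reconcile_sequencing",
    "assembly_outcome",
    "empirical_hit_rate",
    "mean_empirical_hit_rate",
    "storage_time_table",
    "sequencing_outcome_table",
    "prob_correct_clone",
    "operations_timeline",
]

LIKELY_CORRECT = "likely_correct"
LIKELY_INCORRECT = "likely_incorrect"
AMBIGUOUS = "ambiguous"

ALL_CORRECT = "all_correct"
SOME_CORRECT = "some_correct"
ALL_INCORRECT = "all_incorrect"
UNCLASSIFIED = "unclassified"


# ---------------------------------------------------------------------------
# Transformation matching
# ---------------------------------------------------------------------------


def match_miniprep_to_transformation(m_id: str, instance: Instance) -> Optional[str]:
    """Transformation a miniprep most plausibly derives from.

    An explicitly referenced source transformation wins outright.
    Otherwise, among the miniprep's assembly's transformations dated on or
    before the inoculation date, the one with the largest serial number is
    chosen.  Returns ``None`` (unmatched) when no transformation qualifies.
    """
    m = instance.get("minipreps", m_id)
    if m.transformation_id is not None:
        return m.transformation_id
    if m.assembly_id is None or not isinstance(m.inoculation_date, date):
        return None
    candidates = [
        t for t in instance.transformations
        if t.assembly_id == m.assembly_id
        and not t.voided
        and isinstance(t.date, date)
        and t.date <= m.inoculation_date
    ]
    if not candidates:
        return None
    return max(candidates, key=lambda t: serial_of(t.id)).id


# ---------------------------------------------------------------------------
# Gel + sequencing fusion
# ---------------------------------------------------------------------------


def classify_gel(gel_code: Optional[str], settings: Settings) -> str:
    """Provisional per-miniprep class from the gel lane alone.

    A single band at the expected size (or the supercoiled + relaxed pair of
    an intact plasmid) reads as likely correct; an absent band, smear, wrong
    size, or extra bands as likely incorrect; anything else is ambiguous.
    """
    if gel_code is None:
        return AMBIGUOUS
    return settings.gel_quality_flags.get(gel_code, AMBIGUOUS)


def reconcile_sequencing(
    minipreps: Sequence[MiniprepRecord],
    instance: Instance,
    settings: Optional[Settings] = None,
) -> dict[str, str]:
    """Final per-miniprep classes for one assembly's miniprep set.

    Per miniprep the largest-serial read governs.  A fully verifying read
    makes that miniprep correct without touching the others' gel-based
    classes.  A read showing a defect (anything other than some/all parts
    verified or a failed read) makes that miniprep incorrect; if the gel
    had called it likely correct, that gel call is refuted, and the
    gel-based likely-correct calls of the set's other members are demoted
    to incorrect as well.  A read of some-parts-verified or too-poor
    quality leaves the gel-based class in place.
    """
    settings = settings or instance.settings
    classes: dict[str, str] = {}
    gel_based: set[str] = set()  # members whose class rests on the gel alone
    gel_refuted = False

    for m in minipreps:
        gel_class = classify_gel(m.gel_code, settings)
        read = latest_read(m.id, instance)
        interp = read.interpretation if read is not None else None
        if interp == SeqInterpretation.ALL_PARTS_VERIFIED:
            classes[m.id] = LIKELY_CORRECT
        elif interp is not None and interp not in NON_DEFECT_INTERPRETATIONS:
            classes[m.id] = LIKELY_INCORRECT
            if gel_class == LIKELY_CORRECT:
                gel_refuted = True  # gel said correct, sequencing disagreed
        else:
            classes[m.id] = gel_class
            gel_based.add(m.id)

    if gel_refuted:
        for mid in gel_based:
            if classes[mid] == LIKELY_CORRECT:
                classes[mid] = LIKELY_INCORRECT
    return classes


def _assembly_minipreps(a_id: str, instance: Instance) -> list[MiniprepRecord]:
    return [m for m in instance.minipreps if m.assembly_id == a_id and not m.voided]


def assembly_outcome(
    a_id: str, instance: Instance, settings: Optional[Settings] = None
) -> str:
    """Roll one assembly's reconciled miniprep classes up to an outcome.

    ``all_correct`` / ``some_correct`` / ``all_incorrect`` where decidable;
    an ambiguous member blocks the all-or-nothing calls, yielding
    ``unclassified`` unless both a correct and an incorrect member pin the
    outcome to ``some_correct``.
    """
    settings = settings or instance.settings
    members = _assembly_minipreps(a_id, instance)
    if not members:
        raise ValueError(f"assembly {a_id} has no minipreps to classify")
    classes = list(reconcile_sequencing(members, instance, settings).values())
    n_corr = classes.count(LIKELY_CORRECT)
    n_inc = classes.count(LIKELY_INCORRECT)
    n_amb = classes.count(AMBIGUOUS)
    if n_amb:
        return SOME_CORRECT if (n_corr and n_inc) else UNCLASSIFIED
    if n_corr == len(classes):
        return ALL_CORRECT
    if n_inc == len(classes):
        return ALL_INCORRECT
    return SOME_CORRECT


def empirical_hit_rate(
    a_id: str, instance: Instance, settings: Optional[Settings] = None
) -> Optional[float]:
    """Share of an assembly's checked clones that appear correct (percent).

    max(number presumed correct, number sequence-verified) over the total
    miniprep count, as a percentage.  Undefined (``None``) when any
    member's gel data is ambiguous or absent: the denominator would then be
    untrustworthy.
    """
    settings = settings or instance.settings
    members = _assembly_minipreps(a_id, instance)
    if not members:
        return None
    if any(classify_gel(m.gel_code, settings) == AMBIGUOUS for m in members):
        return None
    classes = reconcile_sequencing(members, instance, settings)
    n_presumed = sum(1 for c in classes.values() if c == LIKELY_CORRECT)
    n_verified = len(verified_minipreps_of_assembly(a_id, instance))
    return 100.0 * max(n_presumed, n_verified) / len(members)


def mean_empirical_hit_rate(
    instance: Instance, settings: Optional[Settings] = None
) -> tuple[Optional[float], int]:
    """Mean hit rate over assemblies where it is defined, with that count."""
    settings = settings or instance.settings
    rates = []
    for asm in instance.assemblies:
        if asm.voided or not _assembly_minipreps(asm.id, instance):
            continue
        rate = empirical_hit_rate(asm.id, instance, settings)
        if rate is not None:
            rates.append(rate)
    if not rates:
        return None, 0
    return float(np.mean(rates)), len(rates)


# ---------------------------------------------------------------------------
# Frequency tables and decile bins
# ---------------------------------------------------------------------------


@dataclass
class FrequencyTable:
    """Binned stacked-count table: rows are bins or categories, columns are
    colony-count categories."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray  # shape (rows, cols), nonnegative ints
    row_n: list[int] = field(default_factory=list)
    row_percent: list[Optional[float]] = field(default_factory=list)
    row_percent_name: Optional[str] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if not self.row_n:
            self.row_n = [int(s) for s in self.counts.sum(axis=1)]

    def normalized(self) -> np.ndarray:
        """Row-normalized proportions; all-zero rows stay zero."""
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(totals > 0, self.counts / totals, 0.0)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.row_labels, columns=self.col_labels)
        df["n"] = self.row_n
        if self.row_percent:
            df[self.row_percent_name or "percent"] = self.row_percent
        return df


@dataclass
class DecileBins:
    """Integer day bins derived from decile cutoffs.

    ``cutoffs`` are the deduplicated inner-decile upper bounds; values above
    the last cutoff fall into an overflow bin labeled ``"<cutoff+1>+"``,
    which is emitted only when occupied.
    """

    cutoffs: list[int]
    labels: list[str]
    has_overflow: bool

    def bin_of(self, value: int) -> int:
        for i, cut in enumerate(self.cutoffs):
            if value <= cut:
                return i
        return len(self.cutoffs)  # overflow


def compute_decile_bins(values: Sequence[int]) -> tuple[DecileBins, list[int]]:
    """Decile-derived bins plus the bin index of each input value.

    Cutoffs are the 10%..90% percentiles (linear interpolation) floored to
    whole days -- durations are day-quantized, so flooring changes no counts
    -- and deduplicated.  Bin *i* covers (cutoff[i-1], cutoff[i]]; the first
    covers 0..cutoff[0]; values above cutoff[-1] form the "+"-labeled
    overflow bin.
    """
    if not values:
        raise ValueError("no values to bin")
    arr = np.asarray(values)
    raw = np.percentile(arr, np.arange(10, 100, 10), method="linear")
    cutoffs: list[int] = []
    for c in np.floor(raw).astype(int):
        if not cutoffs or c > cutoffs[-1]:
            cutoffs.append(int(c))

    labels = []
    lo = 0
    for cut in cutoffs:
        labels.append(str(cut) if cut == lo else f"{lo}-{cut}")
        lo = cut + 1
    overflow_label = f"{cutoffs[-1] + 1}+"
    has_overflow = bool((arr > cutoffs[-1]).any())
    if has_overflow:
        labels.append(overflow_label)

    bins = DecileBins(cutoffs, labels, has_overflow)
    assignments = [bins.bin_of(int(v)) for v in values]
    return bins, assignments


def _most_recent_transformation(a_id: str, instance: Instance):
    cands = [t for t in instance.transformations
             if t.assembly_id == a_id and not t.voided and isinstance(t.date, date)]
    if not cands:
        return None
    # ties on date broken by serial, consistent with the matching heuristic
    return max(cands, key=lambda t: (t.date, serial_of(t.id)))


def storage_time_table(
    instance: Instance,
    assembly_type: Optional[str] = None,
    settings: Optional[Settings] = None,
) -> tuple[Optional[DecileBins], Optional[FrequencyTable]]:
    """Transformation outcome vs. assembly storage time.

    For each (optionally type-filtered) assembly with dates on record,
    elapsed days = most recent transformation date minus assembly date.
    Rows are decile-derived day bins; columns are colony-count categories;
    the per-row percentage is the share of binned assemblies that
    eventually yielded a sequence-verified clone.  Returns ``(None, None)``
    when no assembly qualifies.
    """
    settings = settings or instance.settings
    elapsed: list[int] = []
    cats: list[Optional[str]] = []
    verified: list[bool] = []
    for asm in instance.assemblies:
        if asm.voided or not isinstance(asm.date, date):
            continue
        if assembly_type is not None and asm.type != assembly_type:
            continue
        t = _most_recent_transformation(asm.id, instance)
        if t is None:
            continue
        elapsed.append((t.date - asm.date).days)
        cats.append(t.colony_category)
        verified.append(bool(verified_minipreps_of_assembly(asm.id, instance)))

    if not elapsed:
        return None, None

    bins, assignment = compute_decile_bins(elapsed)
    col_labels = settings.colony_labels()
    col_index = {label: i for i, label in enumerate(col_labels)}
    counts = np.zeros((len(bins.labels), len(col_labels)), dtype=int)
    bin_total = np.zeros(len(bins.labels), dtype=int)
    bin_verified = np.zeros(len(bins.labels), dtype=int)
    for b, cat, ok in zip(assignment, cats, verified):
        bin_total[b] += 1
        if ok:
            bin_verified[b] += 1
        if cat in col_index:
            counts[b, col_index[cat]] += 1

    percent = [
        (100.0 * v / t) if t else None for v, t in zip(bin_verified, bin_total)
    ]
    table = FrequencyTable(
        row_labels=list(bins.labels),
        col_labels=col_labels,
        counts=counts,
        row_n=[int(t) for t in bin_total],
        row_percent=percent,
        row_percent_name="percent_verified",
    )
    return bins, table


def sequencing_outcome_table(
    instance: Instance,
    assembly_type: Optional[str] = None,
    procedure: Optional[str] = None,
    min_observations: int = 10,
    settings: Optional[Settings] = None,
) -> FrequencyTable:
    """Read interpretation categories vs. colony counts.

    Every sequencing submission traceable miniprep -> assembly (optionally
    filtered by assembly type and transformation procedure) contributes one
    observation in the colony category of its matched transformation.
    Interpretation rows with fewer than ``min_observations`` observations
    are suppressed; the remaining rows are sorted by decreasing fraction of
    observations with <=100 colonies, and an "All" row unions the displayed
    categories.
    """
    settings = settings or instance.settings
    asm_by_id = instance.index("assemblies")
    mini_by_id = instance.index("minipreps")
    trans_by_id = instance.index("transformations")

    col_labels = settings.colony_labels()
    col_index = {label: i for i, label in enumerate(col_labels)}
    low_cols = {
        i for i, c in enumerate(settings.colony_categories)
        if c.hi is not None and c.hi <= 100
    }

    per_interp: dict[str, np.ndarray] = {}
    for read in instance.sequencing:
        if read.voided or read.interpretation is None or read.miniprep_id is None:
            continue
        m = mini_by_id.get(read.miniprep_id)
        if m is None or m.assembly_id is None:
            continue
        asm = asm_by_id.get(m.assembly_id)
        if asm is None:
            continue
        if assembly_type is not None and asm.type != assembly_type:
            continue
        t_id = match_miniprep_to_transformation(m.id, instance)
        if t_id is None:
            continue
        t = trans_by_id.get(t_id)
        if t is None or t.colony_category not in col_index:
            continue
        if procedure is not None and t.procedure != procedure:
            continue
        row = per_interp.setdefault(
            read.interpretation, np.zeros(len(col_labels), dtype=int)
        )
        row[col_index[t.colony_category]] += 1

    kept = {
        interp: row for interp, row in per_interp.items()
        if int(row.sum()) >= min_observations
    }

    def frac_low(row: np.ndarray) -> float:
        total = row.sum()
        return float(sum(row[i] for i in low_cols) / total) if total else 0.0

    ordered = sorted(kept.items(), key=lambda kv: (-frac_low(kv[1]), kv[0]))
    rows = [row for _, row in ordered]
    labels = [interp for interp, _ in ordered]
    if rows:
        all_row = np.sum(rows, axis=0)
        labels = ["All"] + labels
        rows = [all_row] + rows
        counts = np.vstack(rows)
    else:
        counts = np.zeros((0, len(col_labels)), dtype=int)
    return FrequencyTable(row_labels=labels, col_labels=col_labels, counts=counts)


# ---------------------------------------------------------------------------
# Colony-checking probability
# ---------------------------------------------------------------------------


def prob_correct_clone(hit_rate_percent: float, k_checked: int) -> int:
    """Chance (percent, nearest integer) of finding at least one correct
    clone when checking ``k_checked`` independent clones at a given hit
    rate: 100 * (1 - (1 - h/100)^k)."""
    if not 0 <= hit_rate_percent <= 100:
        raise ValueError("hit rate must be within [0, 100]")
    if k_checked < 1:
        raise ValueError("k_checked must be >= 1")
    p = 1.0 - (1.0 - hit_rate_percent / 100.0) ** k_checked
    return int(round(100.0 * p))


# ---------------------------------------------------------------------------
# Operations timeline
# ---------------------------------------------------------------------------

_TASK_DATE_FIELDS = {
    "purify": ("dsdna", "purification_date"),
    "assemble": ("assemblies", "date"),
    "transform": ("transformations", "date"),
    "inoculate": ("minipreps", "inoculation_date"),
    "miniprep": ("minipreps", "miniprep_date"),
    "sequence": ("sequencing", "submission_date"),
}


def operations_timeline(
    instance: Instance,
    task_names: Sequence[str],
    settings: Optional[Settings] = None,
) -> dict[str, Any]:
    """Cumulative completed-operation counts over time for up to 5 tasks,
    plus the in-progress construct count by date and the days-to-completion
    of each completed construct.

    A construct counts as in progress from its queue date until the
    submission date of its first fully verifying read.
    """
    if len(task_names) > 5:
        raise ValueError("at most 5 tasks may be plotted")
    unknown = [t for t in task_names if t not in _TASK_DATE_FIELDS]
    if unknown:
        raise ValueError(f"unknown task name(s): {unknown}")
    settings = settings or instance.settings

    event_dates: dict[str, list[date]] = {}
    for task in task_names:
        table, attr = _TASK_DATE_FIELDS[task]
        event_dates[task] = sorted(
            getattr(rec, attr) for rec in instance.table(table)
            if isinstance(getattr(rec, attr), date) and not rec.voided
        )

    # construct completion date: first verifying read across its assemblies
    completion: dict[str, Optional[date]] = {}
    queue_date: dict[str, Optional[date]] = {}
    mini_by_id = instance.index("minipreps")
    asm_construct = {a.id: a.construct_id for a in instance.assemblies}
    for c in instance.registry:
        queue_date[c.id] = c.queued_date if isinstance(c.queued_date, date) else None
        completion[c.id] = None
    for read in sorted(
        instance.sequencing,
        key=lambda s: (s.submission_date if isinstance(s.submission_date, date)
                       else date.max, serial_of(s.id)),
    ):
        if read.interpretation != SeqInterpretation.ALL_PARTS_VERIFIED:
            continue
        if not isinstance(read.submission_date, date) or read.miniprep_id is None:
            continue
        m = mini_by_id.get(read.miniprep_id)
        cid = asm_construct.get(m.assembly_id) if m and m.assembly_id else None
        if cid is not None and completion.get(cid) is None:
            completion[cid] = read.submission_date

    all_dates = sorted(
        set(d for ds in event_dates.values() for d in ds)
        | {d for d in queue_date.values() if d}
        | {d for d in completion.values() if d}
    )

    cumulative = {
        task: [sum(1 for d in ds if d <= cutoff) for cutoff in all_dates]
        for task, ds in event_dates.items()
    }
    in_progress = [
        sum(
            1 for cid in queue_date
            if queue_date[cid] is not None and queue_date[cid] <= cutoff
            and (completion[cid] is None or completion[cid] > cutoff)
        )
        for cutoff in all_dates
    ]
    days_to_completion = {
        cid: (completion[cid] - queue_date[cid]).days
        for cid in completion
        if completion[cid] is not None and queue_date[cid] is not None
    }
    return {
        "dates": all_dates,
        "cumulative": cumulative,
        "in_progress_constructs": in_progress,
        "days_to_completion": days_to_completion,
    }
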