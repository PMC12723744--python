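"""Status derivation for samples and constructs.

Every status is recomputed from logged data on demand -- nothing is stored
-- so the task list always reflects the current state of the campaign.  A
deliberately small, deterministic state table covers the attested
transitions: a fragment whose gel shows a failure stalls, an assembly
becomes ready once all its parts are available, a construct is complete
once any of its assemblies is linked (assembly -> transformation ->
miniprep -> sequencing) to a fully verified read.

Cross-construct evidence: a part shared between constructs accumulates
verification and colony-count evidence from the *other* assemblies using
it, which is surfaced alongside direct QC in the construct tracker.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .core_model import (
    DsDNASource,
    Instance,
    MiniprepRecord,
    SeqInterpretation,
    Settings,
    NON_DEFECT_INTERPRETATIONS,
    serial_of,
)

__all__ = [
    "Status",
    "EvidenceSummary",
    "dsdna_status",
    "assembly_status",
    "miniprep_status",
    "construct_status",
    "part_evidence",
    "latest_read",
    "verified_minipreps_of_assembly",
]

#: construct-level states
IN_PROGRESS = "in_progress"
NEEDS_INTERVENTION = "needs_intervention"
COMPLETE = "complete"


@dataclass(frozen=True)
class Status:
    """Derived state of one sample record.

    ``state`` is one of ``queued``, ``ready``, ``in_progress``, ``stalled``,
    ``complete``; ``task`` names the pending operation when ready and
    ``reason`` carries a machine-readable code when stalled.  ``verified``
    marks records linked to a fully sequence-verified clone.
    """

    state: str
    task: Optional[str] = None
    reason: Optional[str] = None
    verified: bool = False
    evidence: Optional["EvidenceSummary"] = None

    @property
    def label(self) -> str:
        if self.state == "ready" and self.task:
            return f"ready:{self.task}"
        if self.state == "stalled" and self.reason:
            return f"stalled:{self.reason}"
        return self.state

    @property
    def available(self) -> bool:
        """A part is available for assembly once its own pipeline is done."""
        return self.state == "complete"


@dataclass(frozen=True)
class EvidenceSummary:
    """Outcome evidence for a part gathered from other assemblies using it."""

    n_constructs_sharing_part: int = 0
    n_verified_elsewhere: int = 0
    n_transformed_elsewhere_with_colonies: int = 0


def _ready(task: str) -> Status:
    return Status("ready", task=task)


def _stalled(reason: str) -> Status:
    return Status("stalled", reason=reason)


def _gel_class(gel_code: Optional[str], settings: Settings) -> Optional[str]:
    if gel_code is None:
        return None
    return settings.gel_quality_flags.get(gel_code)


def latest_read(m_id: str, instance: Instance):
    """The governing sequencing record for a miniprep: largest serial."""
    reads = [s for s in instance.sequencing if s.miniprep_id == m_id and not s.voided]
    if not reads:
        return None
    return max(reads, key=lambda s: serial_of(s.id))


def verified_minipreps_of_assembly(a_id: str, instance: Instance) -> list[MiniprepRecord]:
    """Minipreps of an assembly whose governing read fully verifies them."""
    out = []
    for m in instance.minipreps:
        if m.voided or m.assembly_id != a_id:
            continue
        read = latest_read(m.id, instance)
        if read is not None and read.interpretation == SeqInterpretation.ALL_PARTS_VERIFIED:
            out.append(m)
    return out


# ---------------------------------------------------------------------------
# dsDNA
# ---------------------------------------------------------------------------


def dsdna_status(d_id: str, instance: Instance, settings: Optional[Settings] = None) -> Status:
    """Status of a dsDNA fragment.

    PCR-derived fragments walk purify -> (gel if required) -> quantify ->
    complete, and stall immediately on a failing gel class.  External
    fragments only need a concentration.
    """
    settings = settings or instance.settings
    rec = instance.get("dsdna", d_id)
    if rec.voided:
        return _stalled("voided")

    # a failing gel stalls the fragment regardless of stage
    if _gel_class(rec.gel_code, settings) == "likely_incorrect":
        return _stalled("pcr_failed")

    if rec.source == DsDNASource.EXTERNAL:
        if rec.conc_ng_ul is None:
            return _ready("quantify")
        return Status("complete")

    # pcr / digest / annealed_oligos all pass through purification
    if rec.template_id is not None and not (
        instance.has("minipreps", rec.template_id) or instance.has("dsdna", rec.template_id)
    ):
        raise KeyError(f"dsDNA {d_id}: dangling template ref {rec.template_id!r}")
    for pid in rec.primer_ids:
        if not instance.has("oligos", pid):
            raise KeyError(f"dsDNA {d_id}: dangling primer ref {pid!r}")

    if rec.purification_date is None:
        return _ready("purify")
    if settings.require_dsdna_gel and rec.gel_code is None:
        return _ready("gel")
    if rec.conc_ng_ul is None:
        return _ready("quantify")
    return Status("complete")


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def assembly_status(a_id: str, instance: Instance, settings: Optional[Settings] = None) -> Status:
    """Status of an assembly reaction.

    Ready to assemble once every part is available; stalled the moment any
    part stalls; ready to transform once assembled; verified (and complete)
    once a linked miniprep is fully sequence-verified.
    """
    settings = settings or instance.settings
    rec = instance.get("assemblies", a_id)
    if not rec.part_ids:
        raise ValueError(f"assembly {a_id} has zero parts")
    if rec.voided:
        return _stalled("voided")

    part_statuses = [dsdna_status(pid, instance, settings) for pid in rec.part_ids]
    if any(s.state == "stalled" for s in part_statuses):
        return _stalled("part_failed")

    if rec.date is None:
        if all(s.available for s in part_statuses):
            return _ready("assemble")
        return Status("in_progress")  # parts still being built

    transformations = [
        t for t in instance.transformations if t.assembly_id == a_id and not t.voided
    ]
    if not transformations:
        return _ready("transform")

    if verified_minipreps_of_assembly(a_id, instance):
        return Status("complete", verified=True)

    # transformed but not yet verified: stalled if the latest plate was empty
    latest = max(transformations, key=lambda t: (t.date or rec.date, serial_of(t.id)))
    cat = settings.colony_category(latest.colony_category) if latest.colony_category else None
    if cat is not None and cat.lo == 0 and cat.hi == 0:
        return _stalled("no_colonies")

    # if clones were picked and every one of them stalled on QC, checking
    # more colonies (or re-queueing) is a manual decision
    members = [m for m in instance.minipreps if m.assembly_id == a_id and not m.voided]
    if members:
        member_statuses = [miniprep_status(m.id, instance, settings) for m in members]
        if all(s.state == "stalled" for s in member_statuses):
            return _stalled("screening_exhausted")
    return Status("in_progress")


# ---------------------------------------------------------------------------
# Miniprep
# ---------------------------------------------------------------------------


def miniprep_status(m_id: str, instance: Instance, settings: Optional[Settings] = None) -> Status:
    """Status of a miniprep: gel QC (if required), then sequencing, with the
    latest-serial read governing the outcome."""
    settings = settings or instance.settings
    rec = instance.get("minipreps", m_id)
    if rec.voided:
        return _stalled("voided")

    read = latest_read(m_id, instance)
    if read is not None and read.interpretation is not None:
        interp = read.interpretation
        if interp == SeqInterpretation.ALL_PARTS_VERIFIED:
            return Status("complete", verified=True)
        if interp not in NON_DEFECT_INTERPRETATIONS:
            return _stalled(interp)
        # some_parts_verified / poor_read_quality: more sequencing needed
        return _ready("sequence")

    if settings.require_miniprep_gel and rec.gel_code is None:
        return _ready("gel")
    if _gel_class(rec.gel_code, settings) == "likely_incorrect":
        return _stalled("gel_failed")
    if settings.sequencing_mandated:
        return _ready("sequence")
    return Status("complete")


# ---------------------------------------------------------------------------
# Construct
# ---------------------------------------------------------------------------


def construct_status(
    construct_id: str, instance: Instance, settings: Optional[Settings] = None
) -> str:
    """Overall build state of a registered construct.

    ``complete`` iff any linked assembly is verified; ``needs_intervention``
    iff no pipeline step is ready or in flight for it (every attempt stalled
    or exhausted); otherwise ``in_progress``.
    """
    settings = settings or instance.settings
    rec = instance.get("registry", construct_id)
    if rec.voided:
        return NEEDS_INTERVENTION

    assemblies = [a for a in instance.assemblies if a.construct_id == construct_id]
    if not assemblies:
        return IN_PROGRESS  # freshly queued; awaiting first assembly attempt

    statuses = [assembly_status(a.id, instance, settings) for a in assemblies]
    if any(s.verified for s in statuses):
        return COMPLETE

    if any(st.state in ("ready", "in_progress") for st in statuses):
        return IN_PROGRESS
    # every assembly attempt stalled; the construct still counts as in
    # progress if any derived miniprep remains workable (gel/sequence pending)
    for asm in assemblies:
        for m in instance.minipreps:
            if m.assembly_id == asm.id and not m.voided:
                mst = miniprep_status(m.id, instance, settings)
                if mst.state in ("ready", "in_progress"):
                    return IN_PROGRESS
    return NEEDS_INTERVENTION


# ---------------------------------------------------------------------------
# Cross-construct part evidence
# ---------------------------------------------------------------------------


def part_evidence(
    d_id: str, instance: Instance, exclude_assembly: Optional[str] = None
) -> EvidenceSummary:
    """Evidence about a part from the other assemblies that consumed it.

    Counts assemblies (excluding ``exclude_assembly``) including the part,
    how many of those are sequence-verified, and how many produced at least
    one transformation with a nonzero colony-count category.
    """
    settings = instance.settings
    sharing = 0
    verified = 0
    with_colonies = 0
    for asm in instance.assemblies:
        if asm.voided or asm.id == exclude_assembly or d_id not in asm.part_ids:
            continue
        sharing += 1
        if verified_minipreps_of_assembly(asm.id, instance):
            verified += 1
        for t in instance.transformations:
            if t.voided or t.assembly_id != asm.id or t.colony_category is None:
                continue
            cat = settings.colony_category(t.colony_category)
            if cat is not None and not (cat.lo == 0 and cat.hi == 0):
                with_colonies += 1
                break
    return EvidenceSummary(sharing, verified, with_colonies)
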