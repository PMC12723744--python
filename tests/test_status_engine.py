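"""Status derivation: the deterministic state table, cross-construct
evidence, and the global invariants over generated campaigns."""

import copy

import pytest

from clonecoord.core_model import SequencingRecord, serial_of
from clonecoord.status_engine import (
    COMPLETE,
    IN_PROGRESS,
    NEEDS_INTERVENTION,
    assembly_status,
    construct_status,
    dsdna_status,
    miniprep_status,
    part_evidence,
)
from clonecoord.synthetic_fixtures import SimParams, generate_instance


class TestDsDNAStatus:
    def test_pcr_failing_gel_stalls(self, mini_campaign):
        st = dsdna_status("d3", mini_campaign)
        assert st.label == "stalled:pcr_failed"

    def test_unpurified_pcr_is_ready_to_purify(self, mini_campaign):
        assert dsdna_status("d2", mini_campaign).label == "ready:purify"

    def test_purified_clean_gel_is_available(self, mini_campaign):
        st = dsdna_status("d1", mini_campaign)
        assert st.state == "complete" and st.available

    def test_external_with_concentration_is_available(self, mini_campaign):
        assert dsdna_status("d4", mini_campaign).available

    def test_external_without_concentration_awaits_quantification(self, mini_campaign):
        assert dsdna_status("d5", mini_campaign).label == "ready:quantify"

    def test_gel_requirement_gates_completion(self, mini_campaign):
        mini_campaign.settings.require_dsdna_gel = True
        assert dsdna_status("d6", mini_campaign).label == "ready:gel"

    def test_dangling_primer_raises(self, mini_campaign):
        mini_campaign.dsdna[1].primer_ids = ["o99"]
        with pytest.raises(KeyError, match="o99"):
            dsdna_status("d2", mini_campaign)


class TestAssemblyStatus:
    def test_all_parts_available_and_undated_is_ready(self, mini_campaign):
        assert assembly_status("a3", mini_campaign).label == "ready:assemble"

    def test_stalled_part_stalls_assembly(self, mini_campaign):
        assert assembly_status("a2", mini_campaign).label == "stalled:part_failed"

    def test_assembled_untransformed_is_ready_to_transform(self, mini_campaign):
        assert assembly_status("a4", mini_campaign).label == "ready:transform"

    def test_verified_via_linked_miniprep(self, mini_campaign):
        st = assembly_status("a1", mini_campaign)
        assert st.state == "complete" and st.verified

    def test_zero_parts_raises(self, mini_campaign):
        mini_campaign.assemblies[0].part_ids = []
        with pytest.raises(ValueError, match="zero parts"):
            assembly_status("a1", mini_campaign)

    def test_empty_plate_stalls(self, mini_campaign):
        mini_campaign.sequencing = []
        mini_campaign.minipreps = []
        for t in mini_campaign.transformations:
            t.colony_category = "0"
        assert assembly_status("a1", mini_campaign).label == "stalled:no_colonies"


class TestMiniprepStatus:
    def test_gel_required_first(self, mini_campaign):
        assert miniprep_status("m3", mini_campaign).label == "ready:gel"

    def test_clean_gel_then_sequencing_mandated(self, mini_campaign):
        assert miniprep_status("m2", mini_campaign).label == "ready:sequence"

    def test_verified_read_completes(self, mini_campaign):
        st = miniprep_status("m1", mini_campaign)
        assert st.state == "complete" and st.verified

    def test_defect_read_stalls_with_interpretation(self, mini_campaign):
        mini_campaign.sequencing[0].interpretation = "template_surviving"
        assert miniprep_status("m1", mini_campaign).label == "stalled:template_surviving"

    def test_largest_serial_read_governs(self, mini_campaign):
        # an earlier defect read is superseded by a later verifying read
        mini_campaign.sequencing[0].interpretation = "poor_read_quality"
        mini_campaign.sequencing.append(
            SequencingRecord("s2", miniprep_id="m1",
                             interpretation="all_parts_verified")
        )
        assert miniprep_status("m1", mini_campaign).verified


class TestConstructStatus:
    def test_mini_campaign_partition(self, mini_campaign):
        assert construct_status("c1", mini_campaign) == COMPLETE
        assert construct_status("c2", mini_campaign) == NEEDS_INTERVENTION
        assert construct_status("c3", mini_campaign) == IN_PROGRESS
        assert construct_status("c4", mini_campaign) == IN_PROGRESS

    def test_every_generated_construct_is_classifiable(self, generated_campaign):
        states = {c.id: construct_status(c.id, generated_campaign)
                  for c in generated_campaign.registry}
        assert set(states.values()) <= {IN_PROGRESS, NEEDS_INTERVENTION, COMPLETE}
        assert len(states) == len(generated_campaign.registry)


class TestPartEvidence:
    def test_worked_example(self, mini_campaign):
        # d1 sits in a1 (verified, colonies), a2 (stalled), a3 (unattempted);
        # from a2's point of view the other two provide the evidence
        ev = part_evidence("d1", mini_campaign, exclude_assembly="a2")
        assert ev.n_constructs_sharing_part == 2
        assert ev.n_verified_elsewhere == 1
        assert ev.n_transformed_elsewhere_with_colonies == 1

    def test_single_use_part(self, mini_campaign):
        ev = part_evidence("d4", mini_campaign, exclude_assembly=None)
        assert ev.n_constructs_sharing_part == 1
        assert ev.n_verified_elsewhere == 1

    def test_unused_part_is_all_zero(self, mini_campaign):
        ev = part_evidence("d5", mini_campaign)
        assert (ev.n_constructs_sharing_part, ev.n_verified_elsewhere,
                ev.n_transformed_elsewhere_with_colonies) == (0, 0, 0)

    def test_verified_bounded_by_sharing(self, generated_campaign):
        for rec in generated_campaign.dsdna:
            ev = part_evidence(rec.id, generated_campaign)
            assert ev.n_verified_elsewhere <= ev.n_constructs_sharing_part

    def test_oracle_equivalence(self, generated_campaign):
        """part_evidence matches an independent nested-loop scan of the
        assembly/transformation/miniprep/sequencing joins."""
        inst = generated_campaign

        def brute(d_id, exclude):
            sharing = verified = colonies = 0
            for asm in inst.assemblies:
                if asm.voided or asm.id == exclude or d_id not in asm.part_ids:
                    continue
                sharing += 1
                ok = False
                for m in inst.minipreps:
                    if m.voided or m.assembly_id != asm.id:
                        continue
                    reads = [s for s in inst.sequencing
                             if s.miniprep_id == m.id and not s.voided]
                    if reads:
                        best = max(reads, key=lambda s: serial_of(s.id))
                        if best.interpretation == "all_parts_verified":
                            ok = True
                if ok:
                    verified += 1
                if any(
                    t.assembly_id == asm.id and not t.voided
                    and t.colony_category not in (None, "0")
                    for t in inst.transformations
                ):
                    colonies += 1
            return sharing, verified, colonies

        focal = inst.assemblies[0].id if inst.assemblies else None
        for rec in inst.dsdna:
            ev = part_evidence(rec.id, inst, exclude_assembly=focal)
            assert brute(rec.id, focal) == (
                ev.n_constructs_sharing_part,
                ev.n_verified_elsewhere,
                ev.n_transformed_elsewhere_with_colonies,
            ), rec.id


class TestInvariants:
    def test_monotone_evidence(self):
        """Adding a fully verifying read never demotes any complete status."""
        inst = generate_instance(SimParams(n_constructs=20, seed=11))
        before = {}
        for asm in inst.assemblies:
            before[("a", asm.id)] = assembly_status(asm.id, inst)
        for c in inst.registry:
            before[("c", c.id)] = construct_status(c.id, inst)

        target = next(m for m in inst.minipreps)
        inst.sequencing.append(
            SequencingRecord(f"s{inst.next_serial('sequencing')}",
                             miniprep_id=target.id,
                             interpretation="all_parts_verified")
        )
        for asm in inst.assemblies:
            after = assembly_status(asm.id, inst)
            if before[("a", asm.id)].state == "complete":
                assert after.state == "complete"
        for c in inst.registry:
            if before[("c", c.id)] == COMPLETE:
                assert construct_status(c.id, inst) == COMPLETE
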