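"""Deletion-gap recovery, joint inference, parental reconstruction, and
cohort statistics."""

import math

import numpy as np
import pytest

import tndecay as td
from tndecay.excision import (PLACEMENT_AMBIGUOUS, ReconstructionError,
                              align_to_parent, find_deletion_joint)


def _analyze(child, parent, **kw):
    gaps, warnings = align_to_parent(child, parent, **kw)
    events = [find_deletion_joint(parent, child, g) for g in gaps]
    return events, warnings


class TestAlignToParent:
    def test_identical_sequences_zero_gaps(self):
        seq = td.make_backbone(2000, 0.5, 40)
        gaps, warnings = align_to_parent(seq, seq)
        assert gaps == [] and warnings == []

    def test_single_gap_exact_round_trip(self, composite_demo):
        parent, truth = composite_demo["parent"], composite_demo["truth"]
        child, pu, ctruth = td.excise_is(parent, truth, "downstream",
                                         joint_len=2, deletion_len=1070,
                                         seed=20)
        gaps, warnings = align_to_parent(child, pu)
        assert len(gaps) == 1 and warnings == []
        assert gaps[0].length == 1070
        assert gaps[0].exact
        # hard invariant: collapsing the gap reproduces the child exactly
        assert pu[: gaps[0].start] + pu[gaps[0].end :] == child

    def test_two_sequential_excisions_two_gaps(self):
        cfg = td.CohortConfig(n_intact=0, n_single_up=0, n_single_down=0,
                              n_no_is=1)
        rec = td.simulate_cohort(cfg, seed=23).records[0]
        gaps, warnings = align_to_parent(rec.seq, rec.parent_seq)
        assert len(gaps) == 2
        assert "multi_event" in warnings
        collapsed = rec.parent_seq
        for g in sorted(gaps, key=lambda g: -g.start):
            collapsed = collapsed[: g.start] + collapsed[g.end :]
        assert collapsed == rec.seq

    def test_parent_shorter_rejected(self):
        with pytest.raises(ValueError):
            align_to_parent("ACGTACGT" * 10, "ACGTACGT")


class TestFindDeletionJoint:
    def test_published_tt_joint_geometry(self):
        # two TT copies; the deletion removes everything between them plus
        # one copy, and the surviving junction carries a single TT
        A, B, C = "CAGGATCCGA", "GGCATCATGC", "ACCGATTCAG"
        parent = A + "TT" + B + "TT" + C
        child = A + "TT" + C
        assert parent[len(A) - 1] != B[-1]  # construction: joint is maximal
        assert B[0] != C[0]
        events, _ = _analyze(child, parent, min_gap=5)
        assert len(events) == 1
        ev = events[0]
        assert ev.joint_seq == "TT" and ev.joint_len == 2
        assert ev.deletion_len == len(B) + 2
        assert ev.placement == PLACEMENT_AMBIGUOUS
        assert ev.equivalence_class_size == 3
        assert ev.collapse(parent) == child

    def test_published_aaga_joint_geometry(self):
        A, B, C = "CTGGCACCTG", "TCGATGGCAC", "GTCCATGCTA"
        parent = A + "AAGA" + B + "AAGA" + C
        child = A + "AAGA" + C
        assert A[-1] != B[-1] and B[0] != C[0]
        events, _ = _analyze(child, parent, min_gap=5)
        ev = events[0]
        assert ev.joint_seq == "AAGA" and ev.joint_len == 4
        assert ev.deletion_len == len(B) + 4
        assert ev.collapse(parent) == child

    @pytest.mark.parametrize("side", ["downstream", "upstream"])
    def test_planted_joints_recovered_exactly(self, composite_demo, side):
        # exhaustive over the published 1-4 bp joint range
        parent, truth = composite_demo["parent"], composite_demo["truth"]
        for j in (1, 2, 3, 4):
            for d in (1064, 1070, 1074):
                child, pu, ctruth = td.excise_is(
                    parent, truth, side, joint_len=j, deletion_len=d,
                    seed=1000 * j + d)
                events, warnings = _analyze(child, pu)
                assert len(events) == 1 and warnings == []
                ev = events[0]
                planted = ctruth.events[-1]
                assert ev.deletion_len == planted["deletion_len"]
                assert ev.joint_len == planted["joint_len"]
                assert ev.joint_seq == planted["joint_seq"]
                # placement equivalence: planted window is reachable from the
                # leftmost reported window by sliding right <= joint_len steps
                u_p, e_p = planted["removed_interval"]
                u_i, e_i = ev.removed_interval
                assert 0 <= u_p - u_i <= ev.joint_len
                assert ev.collapse(pu) == child

    def test_leftmost_determinism(self, composite_demo):
        parent, truth = composite_demo["parent"], composite_demo["truth"]
        child, pu, _ = td.excise_is(parent, truth, "downstream", joint_len=3,
                                    deletion_len=1071, seed=30)
        first, _ = _analyze(child, pu)
        for _ in range(3):
            again, _ = _analyze(child, pu)
            assert again == first

    def test_retained_flank_reporting(self, composite_demo):
        parent, truth = composite_demo["parent"], composite_demo["truth"]
        child, pu, _ = td.excise_is(parent, truth, "downstream", joint_len=2,
                                    deletion_len=1070, seed=31)
        events, _ = _analyze(child, pu)
        ev = events[0]
        junction = ev.removed_interval[0]
        assert ev.retained_up == child[junction - 20 : junction]
        assert ev.retained_down == child[junction : junction + 20]


class TestReconstructParent:
    def _bounds(self, seq, catalog, cargo):
        from tndecay.pipeline import _structure_bounds

        ann = td.annotate_locus(seq, catalog, cargo)
        return _structure_bounds(ann, "ISApl1-like")

    def _unit(self, rec, catalog, cargo):
        ins = rec.truth.events[0]
        unit_len = 2 * catalog["ISApl1-like"].length + cargo.length + 4
        s = ins["pos"] + ins["tsd_len"]
        return rec.parent_seq[s : s + unit_len]

    def test_round_trip_recovers_exact_parent(self, catalog, cargo):
        rec = td.irr_retaining_variant(seed=8)
        bounds = self._bounds(rec.seq, catalog, cargo)
        assert bounds is not None
        parent, meta = td.reconstruct_parent(
            rec.seq, rec.empty_site_seq, self._unit(rec, catalog, cargo),
            bounds=bounds)
        assert meta["hypothetical"] is True
        assert meta["tsd_len"] == 2
        assert parent == rec.parent_seq

    def test_two_path_consistency(self, catalog, cargo):
        # events inferred against the truth parent and against the
        # empty-site reconstruction must be identical
        rec = td.irr_retaining_variant(seed=9)
        bounds = self._bounds(rec.seq, catalog, cargo)
        recon, _meta = td.reconstruct_parent(
            rec.seq, rec.empty_site_seq, self._unit(rec, catalog, cargo),
            bounds=bounds)
        ev_truth, _ = _analyze(rec.seq, rec.parent_seq)
        ev_recon, _ = _analyze(rec.seq, recon)
        assert [(e.removed_interval, e.joint_seq) for e in ev_truth] == [
            (e.removed_interval, e.joint_seq) for e in ev_recon]

    def test_ragged_junction_with_catalog_tsd_len(self, catalog, cargo):
        # a fully-excised downstream side leaves no right boundary; the
        # characteristic 2-bp TSD supplied from the catalog still allows
        # exact reconstruction
        cfg = td.CohortConfig(n_intact=0, n_single_up=1, n_single_down=0,
                              n_no_is=0)
        rec = td.simulate_cohort(cfg, seed=26).records[0]
        ann = td.annotate_locus(rec.seq, catalog, cargo)
        up = [h for h in ann.is_hits if h.complete][0]
        bounds = (up.start, max(h.end for h in ann.cargo_hits))
        parent, meta = td.reconstruct_parent(
            rec.seq, rec.empty_site_seq, self._unit(rec, catalog, cargo),
            bounds=bounds, tsd_len=2)
        assert parent == rec.parent_seq

    def test_no_tsd_evidence_warns(self, catalog, cargo, small_element):
        rng = np.random.default_rng(27)
        backbone = td.make_backbone(800, 0.5, rng)
        pos = td.choose_clean_site(backbone, rng, 0, 250, 500)
        product, _ = td.insert_with_tsd(backbone, small_element, pos,
                                        tsd_override=0)
        parent, meta = td.reconstruct_parent(
            product, backbone, small_element.seq,
            bounds=(pos, pos + small_element.length))
        assert meta["tsd_len"] == 0
        assert "no_tsd_evidence" in meta["warnings"]
        assert parent == product  # placing the element back reproduces it

    def test_unmappable_flank_raises(self, catalog, cargo):
        rec = td.irr_retaining_variant(seed=10)
        bounds = self._bounds(rec.seq, catalog, cargo)
        unrelated = td.make_backbone(5000, 0.5, 999)
        with pytest.raises(ReconstructionError):
            td.reconstruct_parent(rec.seq, unrelated,
                                  self._unit(rec, catalog, cargo),
                                  bounds=bounds)


class TestCohortStats:
    def _event(self, d, j):
        return td.DeletionEvent(
            record_id="r", parent_id="p", removed_interval=(0, d),
            deletion_len=d, joint_seq="A" * j, joint_len=j,
            retained_up="", retained_down="", placement="unique")

    def test_constant_cohort(self):
        events = [self._event(1070, 2) for _ in range(6)]
        stats = td.cohort_deletion_stats(events)
        assert stats.mean_deletion == 1070 and stats.sd_deletion == 0.0
        assert stats.min_deletion == stats.max_deletion == 1070

    def test_uniform_span_min_max(self):
        events = [self._event(d, 1) for d in range(1064, 1075)]
        stats = td.cohort_deletion_stats(events)
        assert (stats.min_deletion, stats.max_deletion) == (1064, 1074)

    def test_hand_computed_mean_and_sd(self):
        # hand arithmetic: mean = 5346/5 = 1069.2; squared deviations
        # 27.04 + 4.84 + 0.64 + 3.24 + 23.04 = 58.8; sample var = 14.7
        events = [self._event(d, 1) for d in (1064, 1067, 1070, 1071, 1074)]
        stats = td.cohort_deletion_stats(events)
        assert stats.mean_deletion == pytest.approx(1069.2, abs=1e-9)
        assert stats.sd_deletion == pytest.approx(math.sqrt(14.7), abs=1e-9)
        assert stats.sd_convention == "sample (n-1)"

    def test_joint_histogram_and_classes(self):
        events = [self._event(1070, j) for j in (1, 2, 2, 4)]
        stats = td.cohort_deletion_stats(events, calls=["NO_IS", "NO_IS",
                                                        "SINGLE_UPSTREAM"])
        assert stats.joint_len_histogram == {1: 1, 2: 2, 4: 1}
        assert stats.class_counts == {"NO_IS": 2, "SINGLE_UPSTREAM": 1}
        assert sum(stats.joint_len_histogram.values()) == stats.n

    def test_empty_event_list(self):
        stats = td.cohort_deletion_stats([])
        assert stats.n == 0 and stats.mean_deletion is None
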