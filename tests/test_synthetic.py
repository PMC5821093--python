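"""Generator contracts: length conservation, TSD geometry, joint planting,
cohort determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import tndecay as td
from tndecay.synthetic import CLASS_INTACT, CLASS_NO_IS, CLASS_SINGLE_UP


class TestMakeBackbone:
    def test_length_and_seed_determinism(self):
        assert len(td.make_backbone(5000, 0.5, 42)) == 5000
        assert td.make_backbone(100, 0.5, 1) == td.make_backbone(100, 0.5, 1)

    def test_gc_within_binomial_bound(self):
        # binomial oracle: n=10,000 draws at p=0.3 -> sd = sqrt(n p (1-p))
        n, p = 10_000, 0.3
        seq = td.make_backbone(n, p, 7)
        gc = seq.count("G") + seq.count("C")
        assert abs(gc - n * p) <= 3 * math.sqrt(n * p * (1 - p))

    @pytest.mark.parametrize("length,gc", [(50, 0.5), (1000, 0.0), (1000, 1.0)])
    def test_input_errors(self, length, gc):
        with pytest.raises(ValueError):
            td.make_backbone(length, gc, 0)


class TestInsertWithTsd:
    @pytest.mark.parametrize("name", ["ISApl1-like", "Tn3-like", "ISKpn6-like",
                                      "IS1A-like", "IS1294-like"])
    def test_duplication_geometry(self, catalog, name):
        element = catalog[name]
        backbone = td.make_backbone(2000, 0.5, 3)
        pos = 800
        product, tsd = td.insert_with_tsd(backbone, element, pos)
        t = element.tsd_len
        assert len(product) == len(backbone) + element.length + t
        assert tsd == backbone[pos : pos + t]
        # direct repeat flanks the element on both sides
        s, e = pos + t, pos + t + element.length
        assert product[s - t : s] == product[e : e + t] == tsd
        assert product[s:e] == element.seq
        # backbone outside the insertion point unchanged
        assert product[:pos] == backbone[:pos]
        assert product[e:] == backbone[pos:]

    def test_rolling_circle_no_duplication(self, catalog):
        element = catalog["IS1294-like"]
        backbone = td.make_backbone(1000, 0.5, 5)
        product, tsd = td.insert_with_tsd(backbone, element, 400)
        assert tsd == ""
        assert len(product) == len(backbone) + element.length

    def test_exact_removal_is_inverse(self, catalog):
        element = catalog["ISApl1-like"]
        backbone = td.make_backbone(1000, 0.5, 11)
        pos, t = 300, element.tsd_len
        product, _ = td.insert_with_tsd(backbone, element, pos)
        # removing the element plus one TSD copy restores the backbone
        restored = product[:pos] + product[pos + t + element.length :]
        assert restored == backbone

    def test_position_out_of_range(self, catalog):
        backbone = td.make_backbone(500, 0.5, 1)
        with pytest.raises(ValueError):
            td.insert_with_tsd(backbone, catalog["ISApl1-like"], 501)

    @given(pos=st.integers(0, 398), seed=st.integers(0, 10_000))
    def test_length_conservation_property(self, small_element, pos, seed):
        backbone = td.make_backbone(400, 0.5, seed)
        product, tsd = td.insert_with_tsd(backbone, small_element, pos)
        assert len(product) == 400 + small_element.length + small_element.tsd_len
        assert len(tsd) == small_element.tsd_len


class TestFormComposite:
    def test_layout_and_length(self, composite_demo, catalog, cargo):
        isapl1 = catalog["ISApl1-like"]
        parent, truth = composite_demo["parent"], composite_demo["truth"]
        backbone = composite_demo["backbone"]
        expected = (len(backbone) + 2 * isapl1.length + cargo.length + 4
                    + isapl1.tsd_len)
        assert len(parent) == expected
        cs, ce = truth.coords["cargo"]
        # inside-end dinucleotides: ancestral AT upstream / CG downstream
        assert parent[cs - 2 : cs] == "AT"
        assert parent[ce : ce + 2] == "CG"
        us, ue = truth.coords["up_is"]
        ds, de = truth.coords["down_is"]
        assert parent[us:ue] == parent[ds:de] == isapl1.seq
        ts, te = truth.coords["tsd_left"]
        rs, re = truth.coords["tsd_right"]
        assert parent[ts:te] == parent[rs:re]

    def test_site_out_of_range(self, catalog, cargo):
        backbone = td.make_backbone(500, 0.5, 1)
        with pytest.raises(ValueError):
            td.form_composite(backbone, cargo, catalog["ISApl1-like"], 1000)


class TestExciseIs:
    @pytest.mark.parametrize("joint_len", [1, 2, 3, 4])
    def test_length_oracle_over_joints(self, composite_demo, joint_len):
        parent, truth = composite_demo["parent"], composite_demo["truth"]
        d = 1066 + joint_len
        child, parent_used, ctruth = td.excise_is(
            parent, truth, "downstream", joint_len=joint_len,
            deletion_len=d, seed=1)
        assert len(parent_used) - len(child) == d
        assert ctruth.events[-1]["deletion_len"] == d
        assert ctruth.class_label == CLASS_SINGLE_UP

    def test_joint_present_twice_in_parent_once_in_child(self, composite_demo):
        parent, truth = composite_demo["parent"], composite_demo["truth"]
        child, parent_used, ctruth = td.excise_is(
            parent, truth, "downstream", joint_len=3, deletion_len=1070,
            seed=2)
        ev = ctruth.events[-1]
        u, e0 = ev["removed_interval"]
        joint = ev["joint_seq"]
        assert len(joint) == 3
        # two copies in the parent: immediately left of each boundary
        assert parent_used[u - 3 : u] == joint
        assert parent_used[e0 - 3 : e0] == joint
        # exactly one copy survives at the child junction
        assert child == parent_used[:u] + parent_used[e0:]
        window = child[u - 12 : u + 12]
        assert window.count(joint) >= 1

    def test_remnant_retains_irr(self, composite_demo, catalog):
        isapl1 = catalog["ISApl1-like"]
        parent, truth = composite_demo["parent"], composite_demo["truth"]
        child, _pu, ctruth = td.excise_is(
            parent, truth, "downstream", joint_len=7, deletion_len=1030,
            remnant_len=42, seed=3)
        rs, re = ctruth.coords["down_remnant"]
        assert re - rs == 42
        assert child[rs:re] == isapl1.seq[-42:]
        assert child[rs:re].endswith(isapl1.irr_seq)

    def test_upstream_then_no_is(self, composite_demo):
        parent, truth = composite_demo["parent"], composite_demo["truth"]
        mid, pu, mtruth = td.excise_is(parent, truth, "downstream",
                                       joint_len=2, seed=4)
        child, _pu2, ctruth = td.excise_is(mid, mtruth, "upstream",
                                           joint_len=2, seed=5)
        assert ctruth.class_label == CLASS_NO_IS
        # excising an already-removed side is a state error
        with pytest.raises(LookupError):
            td.excise_is(child, ctruth, "upstream", seed=6)

    def test_engineered_positions_logged(self, composite_demo):
        parent, truth = composite_demo["parent"], composite_demo["truth"]
        _child, parent_used, ctruth = td.excise_is(
            parent, truth, "downstream", joint_len=4, deletion_len=1070,
            seed=7)
        diffs = [i for i, (a, b) in enumerate(zip(parent, parent_used))
                 if a != b]
        assert set(diffs) == set(ctruth.events[-1]["engineered_positions"])
        assert len(diffs) <= 4 + 2  # joint plus at most two maximality pins


class TestSimulateCohort:
    def test_counts_and_labels(self):
        cfg = td.CohortConfig(n_intact=5, n_single_up=5, n_single_down=1,
                              n_no_is=5)
        cohort = td.simulate_cohort(cfg, seed=1)
        assert len(cohort.records) == 16
        labels = [r.truth.class_label for r in cohort.records]
        assert labels.count("INTACT_COMPOSITE") == 5
        assert labels.count("SINGLE_UPSTREAM") == 5
        assert labels.count("SINGLE_DOWNSTREAM") == 1
        assert labels.count("NO_IS") == 5

    def test_deletion_lengths_in_published_range(self):
        cfg = td.CohortConfig(n_intact=0, n_single_up=8, n_single_down=0,
                              n_no_is=4)
        cohort = td.simulate_cohort(cfg, seed=2)
        lengths = [
            ev["deletion_len"]
            for r in cohort.records
            for ev in r.truth.events
            if ev["kind"] == "excision"
        ]
        assert lengths and all(1064 <= d <= 1074 for d in lengths)
        assert 1064 <= np.mean(lengths) <= 1074

    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        cfg = td.CohortConfig(n_intact=2, n_single_up=2, n_single_down=0,
                              n_no_is=1)
        p1 = td.simulate_cohort(cfg, seed=9).write(tmp_path / "a")
        p2 = td.simulate_cohort(cfg, seed=9).write(tmp_path / "b")
        for key in ("cohort", "empty_sites", "parents"):
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_empty_cohort_rejected(self):
        cfg = td.CohortConfig(n_intact=0, n_single_up=0, n_single_down=0,
                              n_no_is=0)
        with pytest.raises(ValueError):
            td.simulate_cohort(cfg, seed=0)

    def test_truth_consistency(self):
        cfg = td.CohortConfig(n_intact=1, n_single_up=2, n_single_down=1,
                              n_no_is=1)
        cohort = td.simulate_cohort(cfg, seed=3)
        for rec in cohort.records:
            excisions = [e for e in rec.truth.events if e["kind"] == "excision"]
            for ev in excisions:
                u, e0 = ev["removed_interval"]
                assert e0 - u == ev["deletion_len"]
                assert len(ev["joint_seq"]) == ev["joint_len"]
            if rec.parent_seq is not None:
                total = sum(e["deletion_len"] for e in excisions)
                assert len(rec.parent_seq) - len(rec.seq) == total
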