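import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import isoppi as ip
from isoppi.predict import (
    build_isoform_interactome,
    classify_edge_annotation,
    predict_edge_status_full,
    predict_edge_status_partial,
    validate_against_experiment,
)

domains = st.sets(st.sampled_from([f"d{i}" for i in range(8)]), max_size=6)


class TestFullRule:
    def test_lost_when_self_side_domain_absent(self):
        assert predict_edge_status_full({"PK"}, {"LB"}) == "lost"

    def test_identity_isoform_retains(self):
        ref = {"LB", "PK"}
        assert predict_edge_status_full({"PK"}, ref) == "retained"

    def test_empty_isoform_loses(self):
        assert predict_edge_status_full({"PK", "LB"}, set()) == "lost"

    def test_empty_instances_is_error(self):
        with pytest.raises(ValueError):
            predict_edge_status_full(set(), {"LB"})

    @given(st.sets(st.sampled_from([f"d{i}" for i in range(8)]), min_size=1), domains)
    @settings(max_examples=200, derandomize=True)
    def test_equals_intersection_test(self, self_side, iso):
        expected = "retained" if self_side & iso else "lost"
        assert predict_edge_status_full(self_side, iso) == expected

    @given(st.sets(st.sampled_from([f"d{i}" for i in range(8)]), min_size=1),
           domains, domains)
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_domain_content(self, self_side, small, extra):
        """A domain-richer isoform never loses an edge a poorer one retains."""
        big = small | extra
        if predict_edge_status_full(self_side, small) == "retained":
            assert predict_edge_status_full(self_side, big) == "retained"


class TestPartialRule:
    @pytest.mark.parametrize(
        "self_doms, iso_doms, expected",
        [({"d1", "d2"}, {"d2", "d9"}, "retained"), ({"d1"}, {"d3"}, "lost")],
    )
    def test_closed_form(self, self_doms, iso_doms, expected):
        assert predict_edge_status_partial(self_doms, iso_doms) == expected

    def test_empty_interacting_domains_is_error(self):
        with pytest.raises(ValueError):
            predict_edge_status_partial(set(), {"d1"})

    @given(st.sets(st.sampled_from([f"d{i}" for i in range(8)]), min_size=1), domains)
    @settings(max_examples=200, derandomize=True)
    def test_random_sets_equal_intersection_oracle(self, self_doms, iso):
        expected = "lost" if not (self_doms & iso) else "retained"
        assert predict_edge_status_partial(self_doms, iso) == expected


class TestClassifyAnnotation:
    def setup_method(self):
        self.ddis = ip.DDISet([("LB", "EGFd")])

    def test_full(self):
        profiles = ip.DomainProfileSet({"A": {"LB"}, "B": {"EGFd"}})
        assert classify_edge_annotation(("A", "B"), profiles, self.ddis, "A") == "full"

    def test_partial_on_multi_isoform_side(self):
        profiles = ip.DomainProfileSet({"A": {"LB"}, "B": {"x"}})
        assert classify_edge_annotation(("A", "B"), profiles, self.ddis, "A") == "partial"

    def test_none(self):
        profiles = ip.DomainProfileSet({"A": {"y"}, "B": {"x"}})
        assert classify_edge_annotation(("A", "B"), profiles, self.ddis, "A") == "none"

    def test_partial_requires_ddi_domain_on_named_side(self):
        profiles = ip.DomainProfileSet({"A": {"y"}, "B": {"LB"}})
        assert classify_edge_annotation(("A", "B"), profiles, self.ddis, "A") == "none"
        assert classify_edge_annotation(("A", "B"), profiles, self.ddis, "B") == "partial"


class TestBuildIsoformInteractome:
    def test_egfr_pattern(self, egfr_isonet):
        _, net = egfr_isonet
        for k in (2, 3, 4):
            iso = ip.IsoformId("P00533", k)
            assert net.status_of(iso, "P01133") == "retained"  # EGF via LB
            assert net.status_of(iso, "P62993") == "lost"      # GRB2 via PK

    def test_gene_without_alternatives_gives_reference_edges_only(self):
        dri = ip.DomainResolvedInteractome()
        dri.set_edge("A", "B", [ip.DDIInstance("a", "b")])
        gmap = ip.GeneIsoformMap({"A": [ip.IsoformId("A")], "B": [ip.IsoformId("B")]})
        profiles = ip.DomainProfileSet({"A": {"a"}, "B": {"b"}})
        net = build_isoform_interactome(dri, gmap, profiles)
        assert {e.status for e in net.edges} == {"reference"} and len(net) == 1

    def test_missing_isoform_profile_is_error(self):
        dri = ip.DomainResolvedInteractome()
        dri.set_edge("A", "B", [ip.DDIInstance("a", "b")])
        gmap = ip.GeneIsoformMap()
        gmap.add("A", ip.IsoformId("A", 2))
        gmap.add("B")
        profiles = ip.DomainProfileSet({"A": {"a"}, "B": {"b"}})
        with pytest.raises(ValueError, match="explicit domain profile"):
            build_isoform_interactome(dri, gmap, profiles)

    def test_exhaustiveness_over_alternative_isoforms(self):
        """#retained + #lost = sum over alternatives of parent DRI degree."""
        ds = ip.simulate_dataset(n_proteins=120, n_edges=360, seed=2)
        dri = ip.annotate_edges_with_ddis(ds.interactome, ds.profiles, ds.ddis)
        net = build_isoform_interactome(dri, ds.gmap, ds.profiles)
        n_predicted = sum(1 for e in net.edges if e.status != "reference")
        expected = sum(
            dri.degree(gene) * len(ds.gmap.alternatives(gene)) for gene in dri.nodes
        )
        assert n_predicted == expected

    def test_planted_ground_truth_recovered(self):
        ds = ip.simulate_dataset(n_proteins=150, n_edges=450, seed=5)
        dri = ip.annotate_edges_with_ddis(ds.interactome, ds.profiles, ds.ddis)
        net = build_isoform_interactome(dri, ds.gmap, ds.profiles)
        pred = {(e.isoform.render(), e.partner): e.status
                for e in net.edges if e.status != "reference"}
        assert pred == ds.ground_truth


class TestValidation:
    def test_all_lost_gives_tpr_one_and_nan_fpr(self):
        keys = [(f"I{i}-2", "P") for i in range(5)]
        pred = {k: "lost" for k in keys}
        counts = validate_against_experiment(pred, pred)
        assert counts.tpr == 1.0 and np.isnan(counts.fpr)

    def test_small_validation_counts(self):
        # 27 experimental losses of which 9 predicted; 15 retentions of which
        # 3 wrongly predicted lost -> TPR 1/3, FPR 0.2
        truth, pred = {}, {}
        for i in range(27):
            truth[(f"L{i}-2", "P")] = "lost"
            pred[(f"L{i}-2", "P")] = "lost" if i < 9 else "retained"
        for i in range(15):
            truth[(f"R{i}-2", "P")] = "retained"
            pred[(f"R{i}-2", "P")] = "lost" if i < 3 else "retained"
        counts = validate_against_experiment(pred, truth)
        assert counts.as_table() == [[9, 18], [3, 12]]
        assert counts.tpr == pytest.approx(1 / 3) and counts.fpr == pytest.approx(0.2)

    def test_random_labels_match_brute_force_tally(self):
        rng = np.random.default_rng(8)
        keys = [(f"I{i}-2", "P") for i in range(60)]
        pred = {k: ("lost" if rng.random() < 0.5 else "retained") for k in keys}
        truth = {k: ("lost" if rng.random() < 0.5 else "retained") for k in keys}
        counts = validate_against_experiment(pred, truth)
        tally = {(p, t): 0 for p in ("lost", "retained") for t in ("lost", "retained")}
        for k in keys:
            tally[(pred[k], truth[k])] += 1
        assert counts.tp == tally[("lost", "lost")]
        assert counts.fn == tally[("retained", "lost")]
        assert counts.fp == tally[("lost", "retained")]
        assert counts.tn == tally[("retained", "retained")]

    def test_empty_intersection_is_error(self):
        with pytest.raises(ValueError):
            validate_against_experiment({("A-2", "B"): "lost"}, {("C-2", "D"): "lost"})


class TestValidationModePredictions:
    def test_partial_rule_applied_where_full_unavailable(self):
        net = ip.Interactome.from_edges([("A", "B"), ("A", "C")])
        profiles = ip.DomainProfileSet({
            "A": {"d1", "d2"}, "B": {"e1"}, "C": {"x"},
            "A-2": {"d2"}, "A-3": set(),
        })
        ddis = ip.DDISet([("d1", "e1"), ("d2", "f9")])
        gmap = ip.GeneIsoformMap()
        gmap.add("A", ip.IsoformId("A", 2))
        gmap.add("A", ip.IsoformId("A", 3))
        preds = {}
        for edge in (frozenset(("A", "B")), frozenset(("A", "C"))):
            preds.update(ip.build_validation_predictions(
                net, gmap, profiles, ddis, {edge: "A"}))
        # (A,B) is fully annotated through d1-e1: A-2 keeps d2 but loses d1
        assert preds[("A-2", "B")] == "lost"
        # (A,C) is partially annotated (A holds d1,d2 which occur in DDIs)
        assert preds[("A-2", "C")] == "retained"
        assert preds[("A-3", "B")] == "lost" and preds[("A-3", "C")] == "lost"

    def test_partial_equals_full_when_partner_has_all_complements(self):
        """On fully complementary edges the two rules must agree."""
        rng = np.random.default_rng(4)
        doms = [f"d{i}" for i in range(6)]
        for trial in range(20):
            a_doms = set(rng.choice(doms, size=3, replace=False))
            ddis = ip.DDISet([(d, f"c_{d}") for d in a_doms])
            b_doms = {f"c_{d}" for d in a_doms}
            iso = {d for d in doms if rng.random() < 0.5}
            full_self = {d for d in a_doms if (d, f"c_{d}") in ddis}
            partial_self = a_doms & ddis.domains
            assert (predict_edge_status_full(full_self, iso)
                    == predict_edge_status_partial(partial_self, iso))
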