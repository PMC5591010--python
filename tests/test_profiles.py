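import pytest

import isoppi as ip
from isoppi.model import PairCategory
from isoppi.profiles import (
    PartnerPairLabel,
    classify_partner_pairs,
    gene_remodeling_summary,
    interaction_profiles,
    remodeling_ratio,
    sample_different_gene_pairs,
)


@pytest.fixture
def egfr_profiles(egfr_isonet):
    dri, net = egfr_isonet
    return dri, interaction_profiles(net)


class TestInteractionProfiles:
    def test_egfr_retention_sets(self, egfr_profiles):
        _, profiles = egfr_profiles
        by_iso = {p.isoform.render(): p.partners_retained for p in profiles}
        assert by_iso["P00533"] == {"P01133", "P62993"}
        for k in (2, 3, 4):
            assert by_iso[f"P00533-{k}"] == {"P01133"}

    def test_profiles_equal_planted_retention_sets(self):
        ds = ip.simulate_dataset(n_proteins=150, n_edges=450, seed=13)
        dri = ip.annotate_edges_with_ddis(ds.interactome, ds.profiles, ds.ddis)
        net = ip.build_isoform_interactome(dri, ds.gmap, ds.profiles)
        by_iso = {p.isoform.render(): p.partners_retained
                  for p in interaction_profiles(net)}
        expected = {}
        for (iso, partner), status in ds.ground_truth.items():
            expected.setdefault(iso, set())
            if status == "retained":
                expected[iso].add(partner)
        for iso, partners in expected.items():
            assert by_iso[iso] == partners

    def test_no_loss_gives_identical_profiles(self):
        ds = ip.simulate_dataset(n_proteins=60, n_edges=120, seed=3,
                                 domain_loss_prob=0.0)
        dri = ip.annotate_edges_with_ddis(ds.interactome, ds.profiles, ds.ddis)
        net = ip.build_isoform_interactome(dri, ds.gmap, ds.profiles)
        for p in interaction_profiles(net):
            ref = next(q for q in interaction_profiles(net)
                       if q.isoform == ip.IsoformId(p.isoform.parent))
            if p.isoform.parent in dri.nodes:
                assert p.partners_retained == ref.partners_retained


class TestRemodelingSummary:
    def test_egfr_alone(self, egfr_profiles):
        _, profiles = egfr_profiles
        s = gene_remodeling_summary(profiles)
        # only P00533 has >= 2 isoforms; it loses GRB2 on all alternatives
        assert s.n_genes == 1
        assert s.frac_genes_with_loss == 1.0
        # 6 isoform pairs: ref vs each of 3 alternatives differ, alt-alt same
        assert s.frac_isoform_pairs_different == pytest.approx(3 / 6)
        assert s.per_gene_frac_isoforms_losing == 1.0

    def test_all_identical_profiles_score_zero(self):
        profiles = [
            ip.InteractionProfile(ip.IsoformId("G"), frozenset({"X"})),
            ip.InteractionProfile(ip.IsoformId("G", 2), frozenset({"X"})),
        ]
        s = gene_remodeling_summary(profiles)
        assert s.frac_genes_with_loss == 0.0
        assert s.frac_isoform_pairs_different == 0.0

    def test_two_gene_mixture(self):
        profiles = [
            ip.InteractionProfile(ip.IsoformId("G1"), frozenset({"X"})),
            ip.InteractionProfile(ip.IsoformId("G1", 2), frozenset()),
            ip.InteractionProfile(ip.IsoformId("G2"), frozenset({"Y"})),
            ip.InteractionProfile(ip.IsoformId("G2", 2), frozenset({"Y"})),
        ]
        assert gene_remodeling_summary(profiles).frac_genes_with_loss == 0.5

    def test_no_eligible_genes_is_error(self):
        with pytest.raises(ValueError):
            gene_remodeling_summary(
                [ip.InteractionProfile(ip.IsoformId("G"), frozenset({"X"}))])


class TestClassifyPartnerPairs:
    def test_egfr_pair_is_different_subset(self, egfr_profiles):
        dri, profiles = egfr_profiles
        labels = classify_partner_pairs(profiles, dri)
        key = frozenset(("P01133", "P62993"))
        assert labels[key].category is PairCategory.DIFFERENT_SUBSET
        assert labels[key].target_genes == {"P00533"}

    def test_all_retained_partners_are_same_subset(self):
        ds = ip.simulate_dataset(n_proteins=80, n_edges=240, seed=21,
                                 domain_loss_prob=0.0, frac_edges_annotated=1.0)
        dri = ip.annotate_edges_with_ddis(ds.interactome, ds.profiles, ds.ddis)
        net = ip.build_isoform_interactome(dri, ds.gmap, ds.profiles)
        labels = classify_partner_pairs(interaction_profiles(net), dri)
        assert labels  # dense network: some gene has >= 2 partners
        assert all(v.category is PairCategory.SAME_SUBSET for v in labels.values())

    def test_conflicting_labels_across_genes_excluded(self):
        # x,y both partner genes g1 and g2; all isoforms of g1 retain both
        # (same subset) while only the reference of g2 retains y (different)
        profiles = [
            ip.InteractionProfile(ip.IsoformId("g1"), frozenset({"x", "y"})),
            ip.InteractionProfile(ip.IsoformId("g1", 2), frozenset({"x", "y"})),
            ip.InteractionProfile(ip.IsoformId("g2"), frozenset({"x", "y"})),
            ip.InteractionProfile(ip.IsoformId("g2", 2), frozenset({"x"})),
        ]
        dri = ip.DomainResolvedInteractome()
        for g in ("g1", "g2"):
            dri.set_edge(g, "x", [ip.DDIInstance("a", "b")])
            dri.set_edge(g, "y", [ip.DDIInstance("a", "b")])
        labels = classify_partner_pairs(profiles, dri)
        assert labels[frozenset(("x", "y"))].category is PairCategory.EXCLUDED_MIXED

    def test_reference_isoform_in_every_subset(self, egfr_profiles):
        dri, profiles = egfr_profiles
        by_iso = {p.isoform: p.partners_retained for p in profiles}
        for partner in dri.partners("P00533"):
            assert partner in by_iso[ip.IsoformId("P00533")]


class TestSampleDifferentGenePairs:
    def path_dri(self):
        dri = ip.DomainResolvedInteractome()
        dri.set_edge("A", "B", [ip.DDIInstance("a", "b")])
        dri.set_edge("B", "C", [ip.DDIInstance("a", "b")])
        return dri

    def test_shared_partner_ineligible(self):
        pairs = sample_different_gene_pairs(self.path_dri(), "all", seed=0)
        assert frozenset(("A", "C")) not in pairs  # both interact with B

    def test_disjoint_edges_all_cross_pairs_eligible(self):
        dri = ip.DomainResolvedInteractome()
        dri.set_edge("A", "B", [ip.DDIInstance("a", "b")])
        dri.set_edge("C", "D", [ip.DDIInstance("a", "b")])
        pairs = set(sample_different_gene_pairs(dri, "all", seed=0))
        assert pairs == {frozenset(p) for p in
                         (("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"))}

    def test_seeded_sampling_is_deterministic(self):
        ds = ip.simulate_dataset(n_proteins=60, n_edges=120, seed=1)
        dri = ip.annotate_edges_with_ddis(ds.interactome, ds.profiles, ds.ddis)
        s1 = sample_different_gene_pairs(dri, 10, seed=99)
        s2 = sample_different_gene_pairs(dri, 10, seed=99)
        assert s1 == s2 and len(s1) == 10

    def test_exclusion_respected(self):
        dri = self.path_dri()
        excl = {frozenset(("A", "B"))}
        pairs = sample_different_gene_pairs(dri, "all", seed=0, exclude=excl)
        assert not (set(pairs) & excl)


def make_label(cat, genes):
    label = PartnerPairLabel(cat)
    for g in genes:
        label.per_gene[g] = cat
    return label


class TestRemodelingRatio:
    def test_printed_ratio_values(self):
        # 63 different / 1437 same and 2669 / 20685
        cmap = {}
        for i in range(1437):
            cmap[frozenset((f"s{i}a", f"s{i}b"))] = make_label(
                PairCategory.SAME_SUBSET, [f"g{i}"])
        for i in range(63):
            cmap[frozenset((f"d{i}a", f"d{i}b"))] = make_label(
                PairCategory.DIFFERENT_SUBSET, [f"h{i}"])
        assert remodeling_ratio(cmap) == pytest.approx(63 / 1437)
        assert 63 / 1437 == pytest.approx(0.0438, abs=5e-4)
        assert 2669 / 20685 == pytest.approx(0.129, abs=5e-4)

    def test_all_same_subset_gives_zero(self):
        cmap = {frozenset(("a", "b")): make_label(PairCategory.SAME_SUBSET, ["g"]),
                frozenset(("c", "d")): make_label(PairCategory.SAME_SUBSET, ["g"])}
        assert remodeling_ratio(cmap) == 0.0

    def test_zero_same_subset_is_error(self):
        cmap = {frozenset(("a", "b")): make_label(PairCategory.DIFFERENT_SUBSET, ["g"])}
        with pytest.raises(ValueError):
            remodeling_ratio(cmap)

    def test_hub_filter_drops_pairs_of_hub_target_genes(self):
        net = ip.Interactome.from_edges(
            [("hub", f"n{i}") for i in range(8)] + [("g", "x"), ("g", "y")])
        cmap = {
            frozenset(("x", "y")): make_label(PairCategory.SAME_SUBSET, ["g"]),
            frozenset(("n0", "n1")): make_label(PairCategory.DIFFERENT_SUBSET, ["hub"]),
        }
        assert remodeling_ratio(cmap) == 1.0
        assert remodeling_ratio(cmap, hub_degree_cutoff=5, binary_net=net) == 0.0

    def test_order_invariance(self):
        cmap = {
            frozenset(("a", "b")): make_label(PairCategory.SAME_SUBSET, ["g1"]),
            frozenset(("c", "d")): make_label(PairCategory.DIFFERENT_SUBSET, ["g2"]),
        }
        reordered = dict(reversed(list(cmap.items())))
        assert remodeling_ratio(cmap) == remodeling_ratio(reordered)
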