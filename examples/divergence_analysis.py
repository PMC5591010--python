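"""Functional divergence of partner pairs with different isoform profiles.

Classifies pairs of proteins by whether they interact with the same or
different subsets of one gene's isoforms, then compares the two groups on
synthetic GO-style annotation sharing and tissue co-expression with a
two-sided bootstrap test. The annotations are generated with a planted
effect (same-subset pairs share terms more often), so the test should
report a positive mean difference with a small p-value.
"""

import numpy as np

import isoppi as ip

# pair categories from a predicted isoform interactome
ds = ip.simulate_dataset(n_proteins=600, n_edges=1800, frac_edges_annotated=0.4,
                         seed=7)
dri = ip.annotate_edges_with_ddis(ds.interactome, ds.profiles, ds.ddis)
net = ip.build_isoform_interactome(dri, ds.gmap, ds.profiles)
labels = ip.classify_partner_pairs(ip.interaction_profiles(net), dri)
cmap = {k: v.category for k, v in labels.items()
        if v.category in (ip.PairCategory.SAME_SUBSET,
                          ip.PairCategory.DIFFERENT_SUBSET)}
n_same = sum(1 for c in cmap.values() if c is ip.PairCategory.SAME_SUBSET)
n_diff = len(cmap) - n_same
print(f"partner pairs: {n_same} same-subset, {n_diff} different-subset, "
      f"ratio {n_diff / n_same:.3f}")

# planted annotation effect: same-subset pairs share terms more often
ann = ip.generate_annotations(cmap, same_subset_share_prob=0.8,
                              different_subset_share_prob=0.2, seed=7)
same_vals, diff_vals = [], []
for key, cat in cmap.items():
    x, y = sorted(key)
    value = ip.jaccard(ann.terms(x), ann.terms(y))
    (same_vals if cat is ip.PairCategory.SAME_SUBSET else diff_vals).append(value)
res = ip.bootstrap_mean_diff_test(same_vals, diff_vals, n_resamples=100_000, seed=7)
print(f"annotation similarity: same {np.mean(same_vals):.3f} vs "
      f"different {np.mean(diff_vals):.3f}; "
      f"bootstrap diff {res.observed_diff:+.3f}, p = {res.p_two_sided:.2g}")

# tissue co-expression with planted pair correlations; keep pairs with
# disjoint proteins so every pair's target correlation is honored
seen, disjoint = set(), {}
for key in sorted(cmap, key=lambda k: tuple(sorted(k))):
    if not (set(key) & seen):
        disjoint[key] = cmap[key]
        seen |= set(key)
rmap = {k: (0.7 if c is ip.PairCategory.SAME_SUBSET else 0.2)
        for k, c in disjoint.items()}
proteins = sorted(seen)
expr = ip.generate_expression(proteins, n_tissues=16, pair_correlation_map=rmap,
                              seed=7)
coex = ip.coexpression([tuple(sorted(k)) for k in disjoint], expr, min_tissues=8)
same_r = [v for k, v in coex.items() if disjoint[frozenset(k)] is ip.PairCategory.SAME_SUBSET]
diff_r = [v for k, v in coex.items() if disjoint[frozenset(k)] is ip.PairCategory.DIFFERENT_SUBSET]
res_r = ip.bootstrap_mean_diff_test(same_r, diff_r, n_resamples=100_000, seed=8)
print(f"tissue co-expression : same {np.mean(same_r):.3f} vs "
      f"different {np.mean(diff_r):.3f}; "
      f"bootstrap diff {res_r.observed_diff:+.3f}, p = {res_r.p_two_sided:.2g}")

print("\nSmall p-values confirm the planted divergence between the two pair "
      "categories\nis recovered by the bootstrap test.")
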