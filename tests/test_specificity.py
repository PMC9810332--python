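"""Specificity calling vs exhaustive interval oracles; clustering; categories."""

import numpy as np
import pandas as pd
import pytest

from regherit.io import GenomicInterval
from regherit.regnet import RegulatoryNetwork
from regherit.specificity import (
    ContextAtlas,
    build_categories,
    build_group_categories,
    call_specific_res,
    cluster_contexts,
    seg_t_statistics,
    specific_intervals,
)


def network_from_trs(context_id, pairs, values, res=()):
    trs = pd.DataFrame({"tf": [p[0] for p in pairs],
                        "tg": [p[1] for p in pairs],
                        "trs": values})
    intervals = {iv.id: iv for iv in res}
    return RegulatoryNetwork(
        context_id=context_id, trs_edges=trs,
        crs_edges=pd.DataFrame({"re": [iv.id for iv in res],
                                "tg": "g0", "crs": 1.0}),
        binding_edges=pd.DataFrame(columns=["tf", "re", "weight"]),
        tfs=set(trs["tf"]), res=set(intervals), tgs=set(trs["tg"]) | {"g0"},
        re_intervals=intervals)


def brute_force_specific(interval_sets, group_of, focal, cross=0.5, within=0.6):
    """Exhaustive all-pairs reimplementation of the two-tier overlap rule."""
    kept = []
    for iv in interval_sets[focal]:
        specific = True
        for other, ivs in interval_sets.items():
            if other == focal:
                continue
            thr = within if group_of[other] == group_of[focal] else cross
            for jv in ivs:
                if iv.overlap_bases(jv) / iv.length > thr:
                    specific = False
                    break
            if not specific:
                break
        if specific:
            kept.append(iv)
    return kept


def random_interval_sets(rng, n_contexts=5, n_per_context=200, genome=2_000_000):
    sets = {}
    for c in range(n_contexts):
        ivs = []
        for k in range(n_per_context):
            start = int(rng.integers(0, genome - 2000))
            ivs.append(GenomicInterval("1", start,
                                       start + int(rng.integers(200, 2000)),
                                       f"c{c}_re{k}"))
        sets[f"c{c}"] = ivs
    return sets


class TestClusterContexts:
    def _nets(self, vectors):
        pairs = [(f"tf{k}", f"g{k}") for k in range(len(next(iter(vectors.values()))))]
        return [network_from_trs(c, pairs, v) for c, v in vectors.items()]

    def test_identical_networks_share_group(self):
        nets = self._nets({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        groups = cluster_contexts(nets, n_groups=1)
        assert groups["a"] == groups["b"]

    def test_full_cut_gives_singletons(self, rng):
        vectors = {f"c{i}": rng.lognormal(0, 1, 50) for i in range(4)}
        groups = cluster_contexts(self._nets(vectors), n_groups=4)
        assert len(set(groups.values())) == 4

    def test_too_many_groups_rejected(self, rng):
        vectors = {f"c{i}": rng.lognormal(0, 1, 20) for i in range(3)}
        with pytest.raises(ValueError, match="n_groups"):
            cluster_contexts(self._nets(vectors), n_groups=5)

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_blocks_recovered(self, seed):
        # 12 contexts in 3 blocks; within-block TRS correlation 0.9, across 0
        rng = np.random.default_rng(1000 + seed)
        rho, p = 0.9, 300
        vectors, truth = {}, {}
        for g in range(3):
            template = rng.standard_normal(p)
            for m in range(4):
                ctx = f"g{g}m{m}"
                vectors[ctx] = 10 + (np.sqrt(rho) * template
                                     + np.sqrt(1 - rho) * rng.standard_normal(p))
                truth[ctx] = g
        groups = cluster_contexts(self._nets(vectors), n_groups=3)
        # perfect agreement up to label permutation
        mapping = {}
        for ctx, g in groups.items():
            mapping.setdefault(g, truth[ctx])
            assert mapping[g] == truth[ctx]


class TestSpecificRes:
    def test_exact_duplicate_in_other_group_not_specific(self):
        iv = GenomicInterval("1", 100, 600, "a_re")
        copy = GenomicInterval("1", 100, 600, "b_re")
        sets = {"a": [iv], "b": [copy]}
        kept = specific_intervals(sets, {"a": 1, "b": 2}, "a")
        assert kept == []

    def test_no_overlap_is_specific(self):
        sets = {"a": [GenomicInterval("1", 100, 600, "a_re")],
                "b": [GenomicInterval("1", 10_000, 10_500, "b_re")]}
        kept = specific_intervals(sets, {"a": 1, "b": 2}, "a")
        assert [iv.id for iv in kept] == ["a_re"]

    def test_two_tier_rule_boundaries(self):
        # 55% overlap: rejected cross-group, kept within-group (thr 0.6 strict)
        query = GenomicInterval("1", 0, 1000, "q")
        other = GenomicInterval("1", 450, 1450, "o")  # 550/1000 bases
        assert specific_intervals({"a": [query], "b": [other]},
                                  {"a": 1, "b": 2}, "a") == []
        assert [iv.id for iv in specific_intervals(
            {"a": [query], "b": [other]}, {"a": 1, "b": 1}, "a")] == ["q"]

    def test_matches_brute_force_oracle(self, rng):
        sets = random_interval_sets(rng)
        group_of = {"c0": 1, "c1": 1, "c2": 2, "c3": 2, "c4": 3}
        for focal in sets:
            fast = specific_intervals(sets, group_of, focal)
            slow = brute_force_specific(sets, group_of, focal)
            assert [iv.id for iv in fast] == [iv.id for iv in slow]

    def test_removing_context_never_shrinks_specific_sets(self, rng):
        sets = random_interval_sets(rng, n_contexts=4, n_per_context=100)
        group_of = {c: i + 1 for i, c in enumerate(sets)}
        before = {c: {iv.id for iv in specific_intervals(sets, group_of, c)}
                  for c in sets}
        smaller = {c: ivs for c, ivs in sets.items() if c != "c3"}
        for c in smaller:
            after = {iv.id for iv in specific_intervals(smaller, group_of, c)}
            assert before[c] <= after


def atlas_from_sets(sets, group_of):
    nets = []
    for c, ivs in sets.items():
        nets.append(network_from_trs(c, [("tf0", "g0")], [1.0], res=ivs))
    return ContextAtlas(nets, group_of)


class TestCategories:
    def test_specific_subset_of_res(self, rng):
        sets = random_interval_sets(rng, n_contexts=3, n_per_context=80)
        atlas = atlas_from_sets(sets, {"c0": 1, "c1": 1, "c2": 2})
        cat = call_specific_res(atlas, "c0")
        assert set(cat.source_re_ids) <= {iv.id for iv in sets["c0"]}
        covered_bp = sum(iv.length for iv in cat.regions)
        assert covered_bp <= sum(iv.length for iv in sets["c0"])

    def test_seg_top_fraction_and_window(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(20)]
        expr = pd.DataFrame(rng.lognormal(0, 0.3, (20, 3)), index=genes,
                            columns=["a", "b", "c"])
        expr.loc["g0", "a"] = 50.0   # strongly specific to context a
        gene_ivs = {g: GenomicInterval("chr1", 200_000 + 20_000 * i,
                                       210_000 + 20_000 * i, g)
                    for i, g in enumerate(genes)}
        sets = {c: [GenomicInterval("1", 0, 100, f"{c}_re")] for c in "abc"}
        atlas = atlas_from_sets(sets, {"a": 1, "b": 2, "c": 3})
        cats = build_categories(atlas, "seg", expression=expr,
                                gene_intervals=gene_ivs)
        by_ctx = {c.context_id: c for c in cats}
        # exactly top 10% of 20 genes = 2 genes per context
        assert all(len(c.source_re_ids) == 2 for c in cats)
        assert "g0" in by_ctx["a"].source_re_ids
        g0_region = [r for r in by_ctx["a"].regions
                     if r.start <= 200_000 - 100_000 + 1]
        assert any(r.start == 100_000 and r.end == 310_000
                   for r in by_ctx["a"].regions)

    def test_sap_identical_peaks_all_empty(self):
        peak = [GenomicInterval("1", 0, 500, "p")]
        sets = {"a": [GenomicInterval("1", 900, 1000)],
                "b": [GenomicInterval("1", 2900, 3000)]}
        atlas = atlas_from_sets(sets, {"a": 1, "b": 2})
        cats = build_categories(atlas, "sap", peaks={"a": peak, "b": peak})
        assert all(len(c.regions) == 0 for c in cats)

    def test_missing_aux_rejected(self, rng):
        sets = random_interval_sets(rng, n_contexts=2, n_per_context=5)
        atlas = atlas_from_sets(sets, {"c0": 1, "c1": 2})
        with pytest.raises(ValueError, match="peaks"):
            build_categories(atlas, "aap")

    def test_seg_t_statistic_definition(self):
        expr = pd.DataFrame([[10.0, 1.0, 2.0, 3.0]], index=["g"],
                            columns=list("abcd"))
        t = seg_t_statistics(expr)
        others = np.array([1.0, 2.0, 3.0])
        expected = (10 - others.mean()) / others.std(ddof=1)
        assert t.loc["g", "a"] == pytest.approx(expected, rel=1e-12)


class TestGroupCategories:
    def test_single_group_keeps_pool(self, rng):
        sets = random_interval_sets(rng, n_contexts=2, n_per_context=20)
        atlas = atlas_from_sets(sets, {"c0": 1, "c1": 1})
        (cat,) = build_group_categories(atlas, sets)
        assert len(cat.source_re_ids) == 40

    def test_verbatim_shared_between_groups_excluded(self):
        shared_a = GenomicInterval("1", 100, 600, "a_re")
        shared_b = GenomicInterval("1", 100, 600, "b_re")
        sets = {"a": [shared_a], "b": [shared_b]}
        atlas = atlas_from_sets(sets, {"a": 1, "b": 2})
        cats = build_group_categories(atlas, sets)
        assert all(len(c.regions) == 0 for c in cats)

    def test_matches_pooled_brute_force(self, rng):
        sets = random_interval_sets(rng, n_contexts=6, n_per_context=60)
        group_of = {"c0": 1, "c1": 1, "c2": 2, "c3": 2, "c4": 3, "c5": 3}
        atlas = atlas_from_sets(sets, group_of)
        cats = {c.context_id: c for c in build_group_categories(atlas, sets)}
        pooled = {}
        for ctx, ivs in sets.items():
            pooled.setdefault(group_of[ctx], []).extend(ivs)
        for g, ivs in pooled.items():
            slow = brute_force_specific(
                {**{f"grp{h}": v for h, v in pooled.items() if h != g},
                 "me": ivs},
                {**{f"grp{h}": h for h in pooled if h != g}, "me": g},
                "me", cross=0.5, within=0.5)
            assert set(cats[f"group{g}"].source_re_ids) == {iv.id for iv in slow}
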