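"""A-score arithmetic, Gaussian-FDR selection, and subnetwork extraction."""

import numpy as np
import pandas as pd
import pytest

from regherit.io import GenomicInterval
from regherit.regnet import RegulatoryNetwork
from regherit.subnetwork import (
    REAssociation,
    association_scores,
    extract_subnetwork,
    network_snp_universe,
    select_associated_res,
    shared_subnetwork,
)


def toy_network(res=None, crs_rows=None, trs_rows=None, bind_rows=None,
                context_id="ctx"):
    res = res or [GenomicInterval("1", 10_000, 12_000, "re0")]
    crs = pd.DataFrame(crs_rows or [("re0", "g0", 10.0)],
                       columns=["re", "tg", "crs"])
    trs = pd.DataFrame(trs_rows or [("tf0", "g0", 5.0)],
                       columns=["tf", "tg", "trs"])
    bind = pd.DataFrame(bind_rows or [("tf0", "re0", 1.0)],
                        columns=["tf", "re", "weight"])
    return RegulatoryNetwork(
        context_id=context_id, trs_edges=trs, crs_edges=crs,
        binding_edges=bind,
        tfs=set(trs["tf"]), res={iv.id for iv in res},
        tgs=set(trs["tg"]) | set(crs["tg"]),
        re_intervals={iv.id: iv for iv in res})


def sumstats(rows):
    df = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "pval"])
    df["n"] = 10_000
    df["chi2"] = 1.0
    return df


class TestAssociationScores:
    def test_hand_worked_two_snp_example(self):
        # SNP-A inside the RE (p=1e-4, w=0.5), SNP-B 5 kb away (p=1e-2, w=1)
        nw = toy_network()
        ss = sumstats([("a", "1", 11_000, 1e-4),
                       ("b", "1", 17_000, 1e-2)])
        weights = np.array([0.5, 1.0])
        (assoc,) = association_scores(nw, ss, weights, d0=5000.0)
        expected_s = (0.5 * 4 * 1.0 + 1.0 * 2 * np.exp(-1.0)) / 2
        assert assoc.S == pytest.approx(expected_s, abs=1e-12)
        assert assoc.A == pytest.approx(10 * expected_s, abs=1e-6)
        assert expected_s == pytest.approx(1.3679, abs=1e-4)
        assert assoc.A == pytest.approx(13.679, abs=1e-3)

    def test_distance_convention(self):
        nw = toy_network()
        ss = sumstats([("in_start", "1", 10_001, 0.5),
                       ("before", "1", 9_901, 0.5),
                       ("after", "1", 12_100, 0.5)])
        (assoc,) = association_scores(nw, ss, np.ones(3))
        d = dict(zip(assoc.snps["snp"], assoc.snps["dist"]))
        assert d["in_start"] == 0.0
        assert d["before"] == 100.0
        assert d["after"] == 100.0

    def test_no_snp_in_window_zero_scores(self):
        nw = toy_network()
        ss = sumstats([("far", "1", 10_000_000, 1e-8)])
        (assoc,) = association_scores(nw, ss, np.ones(1))
        assert assoc.S == 0.0 and assoc.A == 0.0

    def test_flat_pvalues_zero_signal(self):
        nw = toy_network()
        ss = sumstats([("a", "1", 11_000, 1.0), ("b", "1", 11_500, 1.0)])
        (assoc,) = association_scores(nw, ss, np.ones(2))
        assert assoc.S == 0.0

    def test_monotonicity(self):
        nw = toy_network()
        base = sumstats([("a", "1", 13_000, 1e-3)])
        (weak,) = association_scores(nw, base, np.ones(1))
        stronger_p = sumstats([("a", "1", 13_000, 1e-6)])
        (strong,) = association_scores(nw, stronger_p, np.ones(1))
        closer = sumstats([("a", "1", 12_100, 1e-3)])
        (near,) = association_scores(nw, closer, np.ones(1))
        assert strong.A > weak.A
        assert near.A > weak.A

    def test_dropping_below_mean_contribution_raises_s(self):
        nw = toy_network()
        both = sumstats([("big", "1", 11_000, 1e-6),
                         ("small", "1", 50_000, 0.5)])
        (s_both,) = association_scores(nw, both, np.ones(2))
        only = sumstats([("big", "1", 11_000, 1e-6)])
        (s_one,) = association_scores(nw, only, np.ones(1))
        assert s_one.S > s_both.S


class TestSelectAssociatedRes:
    def _assocs(self, values):
        return [REAssociation(f"re{i}", C=1.0, S=v, A=v,
                              snps=pd.DataFrame(columns=["snp", "dist",
                                                         "weight", "pval"]))
                for i, v in enumerate(values)]

    def test_all_equal_selects_nothing(self):
        assert select_associated_res(self._assocs([2.0] * 50)) == []

    def test_extreme_outlier_selected(self, rng):
        values = rng.normal(5, 1, 1000)
        values[7] = values.mean() + 6 * values.std()
        selected = select_associated_res(self._assocs(values))
        assert "re7" in {a.re_id for a in selected}

    def test_iid_gaussian_null_rate(self):
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            selected = select_associated_res(
                self._assocs(rng.normal(0, 1, 1000)), fdr=0.05)
            fracs.append(len(selected) / 1000)
        assert np.mean(fracs) <= 0.05


class TestExtractSubnetwork:
    def test_empty_selection_empty_subnetwork(self):
        nw = toy_network()
        sub = extract_subnetwork(nw, [])
        assert sub.res == sub.tfs == sub.tgs == sub.snps == set()

    def test_one_hop_counts(self):
        res = [GenomicInterval("1", 10_000, 12_000, "re0")]
        nw = toy_network(
            res=res,
            crs_rows=[("re0", "g0", 5.0), ("re0", "g1", 4.0)],
            trs_rows=[("tf0", "g0", 1.0), ("tf1", "g1", 1.0),
                      ("tf2", "g0", 1.0)],
            bind_rows=[("tf0", "re0", 1.0), ("tf1", "re0", 1.0),
                       ("tf2", "re0", 1.0)])
        snps = pd.DataFrame({"snp": [f"s{i}" for i in range(4)],
                             "dist": 0.0, "weight": 1.0, "pval": 1e-4})
        sel = [REAssociation("re0", C=5.0, S=1.0, A=5.0, snps=snps)]
        sub = extract_subnetwork(nw, sel)
        assert (len(sub.tfs), len(sub.res), len(sub.tgs), len(sub.snps)) == (
            3, 1, 2, 4)

    def test_matches_traversal_oracle_and_idempotent(self, rng):
        ivs = [GenomicInterval("1", 10_000 * k, 10_000 * k + 2000, f"re{k}")
               for k in range(10)]
        crs_rows = [(f"re{k}", f"g{rng.integers(6)}", float(rng.random()))
                    for k in range(10) for _ in range(2)]
        trs_rows = [(f"tf{i}", f"g{j}", 1.0) for i in range(5) for j in range(6)
                    if rng.random() < 0.5]
        bind_rows = [(f"tf{i}", f"re{k}", 1.0) for i in range(5)
                     for k in range(10) if rng.random() < 0.4]
        nw = toy_network(res=ivs, crs_rows=crs_rows, trs_rows=trs_rows,
                         bind_rows=bind_rows)
        empty = pd.DataFrame(columns=["snp", "dist", "weight", "pval"])
        sel = [REAssociation(f"re{k}", 1.0, 1.0, 1.0, snps=empty)
               for k in (0, 3, 7)]
        sub = extract_subnetwork(nw, sel)
        # brute-force one-hop traversal
        tgs = {r[1] for r in crs_rows if r[0] in {"re0", "re3", "re7"}}
        tfs = set()
        trs_pairs = {(t, g) for t, g, _ in trs_rows}
        for tf, re_, _ in bind_rows:
            if re_ in {"re0", "re3", "re7"}:
                my_tgs = {r[1] for r in crs_rows if r[0] == re_}
                if any((tf, g) in trs_pairs for g in my_tgs):
                    tfs.add(tf)
        assert sub.tgs == tgs and sub.tfs == tfs
        assert sub.tfs <= nw.tfs and sub.tgs <= nw.tgs and sub.res <= nw.res
        again = extract_subnetwork(nw, sel)
        assert (again.tfs, again.tgs, again.res) == (sub.tfs, sub.tgs, sub.res)


class TestSharedSubnetwork:
    def _sub(self, nw, re_ids, snp_ids=()):
        if snp_ids:
            snps = pd.DataFrame({"snp": list(snp_ids), "dist": 0.0,
                                 "weight": 1.0, "pval": 0.5})
        else:
            snps = pd.DataFrame(columns=["snp", "dist", "weight", "pval"])
        sel = [REAssociation(r, 1.0, 1.0, 1.0, snps=snps) for r in re_ids]
        return extract_subnetwork(nw, sel)

    def test_identical_subnetworks_minimal_p(self):
        ivs = [GenomicInterval("1", 10_000 * k, 10_000 * k + 2000, f"re{k}")
               for k in range(6)]
        crs_rows = [(f"re{k}", f"g{k}", 1.0) for k in range(6)]
        nw = toy_network(res=ivs, crs_rows=crs_rows,
                         trs_rows=[("tf0", "g0", 1.0)],
                         bind_rows=[("tf0", "re0", 1.0)])
        sub = self._sub(nw, ["re0", "re1"])
        rep = shared_subnetwork(sub, sub, nw).set_index("level")
        assert rep.loc["re", "overlap"] == 2
        assert rep.loc["re", "p"] < 0.1

    def test_disjoint_subnetworks_p_one(self):
        ivs = [GenomicInterval("1", 10_000 * k, 10_000 * k + 2000, f"re{k}")
               for k in range(6)]
        crs_rows = [(f"re{k}", f"g{k}", 1.0) for k in range(6)]
        nw = toy_network(res=ivs, crs_rows=crs_rows,
                         trs_rows=[("tfX", "gX", 1.0)],
                         bind_rows=[("tfX", "reX", 1.0)])
        a = self._sub(nw, ["re0", "re1"])
        b = self._sub(nw, ["re2", "re3"])
        rep = shared_subnetwork(a, b, nw).set_index("level")
        assert rep.loc["re", "overlap"] == 0
        assert rep.loc["re", "p"] == pytest.approx(1.0)
        assert rep.loc["tg", "p"] == pytest.approx(1.0)

    def test_context_mismatch_rejected(self):
        nw_a = toy_network(context_id="a")
        nw_b = toy_network(context_id="b")
        sub_a = self._sub(nw_a, ["re0"])
        sub_b = self._sub(nw_b, ["re0"])
        with pytest.raises(ValueError, match="context"):
            shared_subnetwork(sub_a, sub_b, nw_a)

    def test_random_subsets_hypergeometric_null(self, rng):
        ivs = [GenomicInterval("1", 10_000 * k, 10_000 * k + 2000, f"re{k}")
               for k in range(40)]
        crs_rows = [(f"re{k}", f"g{k}", 1.0) for k in range(40)]
        nw = toy_network(res=ivs, crs_rows=crs_rows,
                         trs_rows=[("tfX", "gX", 1.0)],
                         bind_rows=[("tfX", "reX", 1.0)])
        ps = []
        for _ in range(20):
            ids = [f"re{k}" for k in range(40)]
            a = self._sub(nw, list(rng.choice(ids, 10, replace=False)))
            b = self._sub(nw, list(rng.choice(ids, 10, replace=False)))
            ps.append(shared_subnetwork(a, b, nw).set_index("level")
                      .loc["re", "p"])
        # null p-values roughly uniform: mean near 0.5 and spread present
        assert 0.25 <= np.mean(ps) <= 0.85


class TestSnpUniverse:
    def test_window_membership(self):
        nw = toy_network()
        ss = sumstats([("near", "1", 40_000, 0.5),
                       ("far", "1", 200_000, 0.5)])
        assert network_snp_universe(nw, ss) == {"near"}
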