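"""SNP-associated regulatory subnetwork extraction via the A score.

Each RE of a context network is scored by A = C * S, where C is the RE's
maximal cis-regulatory score over its target genes and S is the mean GWAS
risk signal of nearby SNPs (within 50 kb), each SNP's -log10 p downweighted
by its LD score (weight = reciprocal of the floored LD score) and by an
exponential distance decay exp(-d / d0) with d0 = 5000 bp by default:

    C_k = max_j CRS_kj
    S_k = (1/|P_k|) * sum_{l in P_k} w_l * (-log10 p_l) * exp(-d_lk / d0)
    A_k = C_k * S_k

A scores across the scored universe are approximately Gaussian; REs in the
Benjamini-Hochberg-corrected upper tail (FDR <= 0.05) are selected, and the
subnetwork is their one-hop closure: bound upstream TFs with a retained trans
edge, downstream TGs on retained cis edges, and the nearby SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from regherit.regnet import RegulatoryNetwork

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 50_000
DEFAULT_D0 = 5_000.0


@dataclass
class REAssociation:
    """Per-RE association with a phenotype's GWAS signal."""

    re_id: str
    C: float
    S: float
    A: float
    snps: pd.DataFrame            # columns snp, dist, weight, pval
    d0: float = DEFAULT_D0
    p_gauss: float = float("nan")
    q: float = float("nan")


@dataclass
class SNPRegulatorySubnetwork:
    """One-hop closure of the selected REs: TFs, TGs and associated SNPs."""

    phenotype_id: str
    context_id: str
    res: set[str]
    tfs: set[str]
    tgs: set[str]
    snps: set[str]
    edges: pd.DataFrame           # columns src, dst, edge_type, weight
    snp_universe: frozenset[str] = field(default_factory=frozenset)

    def nodes_frame(self) -> pd.DataFrame:
        rows = [{"id": x, "type": t}
                for t, ids in (("tf", self.tfs), ("re", self.res),
                               ("tg", self.tgs), ("snp", self.snps))
                for x in sorted(ids)]
        return pd.DataFrame(rows, columns=["id", "type"])


def _snp_distances(interval, pos: np.ndarray) -> np.ndarray:
    """bp distance of 1-based SNP positions to a 0-based half-open interval.

    Zero inside the interval; otherwise distance to the nearest boundary base.
    """
    pos0 = pos - 1
    d = np.zeros(len(pos), dtype=float)
    left = pos0 < interval.start
    right = pos0 >= interval.end
    d[left] = interval.start - pos0[left]
    d[right] = pos0[right] - (interval.end - 1)
    return d


def association_scores(
    network: RegulatoryNetwork,
    ss: pd.DataFrame,
    snp_weights: np.ndarray,
    window_bp: int = DEFAULT_WINDOW_BP,
    d0: float = DEFAULT_D0,
) -> list[REAssociation]:
    """A scores for every RE of the network.

    ``snp_weights`` is the per-SNP LD weight aligned to ``ss`` rows (the
    reciprocal of the floored LD score).  SNPs strictly closer than
    ``window_bp`` to an RE contribute; an RE with no nearby SNP has S = A = 0.
    """
    if len(snp_weights) != len(ss):
        raise ValueError("snp_weights must align with sumstats rows")
    pos = ss["pos"].to_numpy()
    chroms = ss["chrom"].to_numpy()
    neglogp = -np.log10(np.maximum(ss["pval"].to_numpy(float), 1e-300))
    crs = network.crs_edges
    c_by_re = crs.groupby("re")["crs"].max() if len(crs) else pd.Series(dtype=float)

    out = []
    for rid in sorted(network.res):
        iv = network.re_intervals[rid]
        C = float(c_by_re.get(rid, np.nan))
        if np.isnan(C):
            logger.warning("association_scores: RE %s has no CRS edge; C = 0", rid)
            C = 0.0
        rows = np.flatnonzero(chroms == iv.chrom)
        d = _snp_distances(iv, pos[rows])
        near = d < window_bp
        rows, d = rows[near], d[near]
        if rows.size:
            contrib = snp_weights[rows] * neglogp[rows] * np.exp(-d / d0)
            S = float(contrib.mean())
            snps = pd.DataFrame({
                "snp": ss["snp"].to_numpy()[rows], "dist": d,
                "weight": snp_weights[rows],
                "pval": ss["pval"].to_numpy()[rows],
            })
        else:
            S = 0.0
            snps = pd.DataFrame(columns=["snp", "dist", "weight", "pval"])
        out.append(REAssociation(re_id=rid, C=C, S=S, A=C * S, snps=snps, d0=d0))
    return out


def select_associated_res(
    assocs: list[REAssociation], fdr: float = 0.05
) -> list[REAssociation]:
    """Gaussian upper-tail + BH selection of phenotype-associated REs.

    The Normal null is fit on the A scores of the whole scored universe
    (REs with A = 0 included; they shape the null).
    """
    if len(assocs) < 30:
        raise ValueError("select_associated_res requires >= 30 REs")
    A = np.array([a.A for a in assocs])
    mu, sd = A.mean(), A.std(ddof=1)
    if sd == 0:
        logger.warning("select_associated_res: zero variance in A scores")
        return []
    p = stats.norm.sf((A - mu) / sd)
    q = stats.false_discovery_control(p, method="bh")
    for a, pi, qi in zip(assocs, p, q):
        a.p_gauss, a.q = float(pi), float(qi)
    return [a for a, qi in zip(assocs, q) if qi <= fdr]


def extract_subnetwork(
    network: RegulatoryNetwork,
    selected: list[REAssociation],
    phenotype_id: str = "",
    snp_universe: frozenset[str] | None = None,
) -> SNPRegulatorySubnetwork:
    """One-hop closure of the selected REs.

    Per selected RE: its retained cis targets; the TFs bound on it (B > 0)
    having a retained trans edge to one of those targets; its nearby SNPs.
    """
    sel_ids = {a.re_id for a in selected}
    unknown = sel_ids - network.res
    if unknown:
        raise ValueError(f"selected REs not in network: {sorted(unknown)[:5]}")
    crs = network.crs_edges
    trs = network.trs_edges
    binding = network.binding_edges
    trs_pairs = set(zip(trs["tf"], trs["tg"])) if len(trs) else set()

    res: set[str] = set()
    tfs: set[str] = set()
    tgs: set[str] = set()
    snps: set[str] = set()
    edges = []
    for a in selected:
        rid = a.re_id
        res.add(rid)
        my_tgs = set(crs.loc[crs["re"] == rid, "tg"]) if len(crs) else set()
        for _, row in crs[crs["re"] == rid].iterrows():
            edges.append((rid, row["tg"], "cis", row["crs"]))
        tgs |= my_tgs
        bound = binding[binding["re"] == rid] if len(binding) else binding
        for _, row in bound.iterrows():
            tf = row["tf"]
            if any((tf, tg) in trs_pairs for tg in my_tgs):
                tfs.add(tf)
                edges.append((tf, rid, "trans", row["weight"]))
        for snp in a.snps["snp"]:
            snps.add(snp)
            edges.append((snp, rid, "snp", 0.0))
    edge_df = pd.DataFrame(edges, columns=["src", "dst", "edge_type", "weight"])
    return SNPRegulatorySubnetwork(
        phenotype_id=phenotype_id, context_id=network.context_id,
        res=res, tfs=tfs, tgs=tgs, snps=snps, edges=edge_df,
        snp_universe=snp_universe or frozenset(),
    )


def network_snp_universe(
    network: RegulatoryNetwork, ss: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> frozenset[str]:
    """SNPs within the window of any network RE (the SNP-level universe)."""
    pos = ss["pos"].to_numpy()
    chroms = ss["chrom"].to_numpy()
    hits: set[str] = set()
    for rid in network.res:
        iv = network.re_intervals[rid]
        rows = np.flatnonzero(chroms == iv.chrom)
        d = _snp_distances(iv, pos[rows])
        hits |= set(ss["snp"].to_numpy()[rows[d < window_bp]])
    return frozenset(hits)


def shared_subnetwork(
    sub_a: SNPRegulatorySubnetwork,
    sub_b: SNPRegulatorySubnetwork,
    universe: RegulatoryNetwork,
    snp_universe: frozenset[str] | None = None,
) -> pd.DataFrame:
    """Overlap of two phenotypes' subnetworks at SNP/RE/TG/TF level.

    Per level, the hypergeometric upper-tail p-value uses that node type's
    count in the context network as the population (for SNPs: all SNPs within
    window of any network RE).
    """
    if sub_a.context_id != sub_b.context_id:
        raise ValueError("subnetworks come from different contexts")
    if snp_universe is None:
        snp_universe = sub_a.snp_universe | sub_b.snp_universe
    levels = {
        "snp": (sub_a.snps, sub_b.snps, len(snp_universe)),
        "re": (sub_a.res, sub_b.res, len(universe.res)),
        "tg": (sub_a.tgs, sub_b.tgs, len(universe.tgs)),
        "tf": (sub_a.tfs, sub_b.tfs, len(universe.tfs)),
    }
    rows = []
    for level, (a, b, m) in levels.items():
        k = len(a & b)
        p = float(stats.hypergeom.sf(k - 1, m, len(a), len(b))) if m else 1.0
        rows.append({"level": level, "n_a": len(a), "n_b": len(b),
                     "overlap": k, "universe": m, "p": min(max(p, 0.0), 1.0)})
    return pd.DataFrame(rows)
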