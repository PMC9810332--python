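"""Relevance scores per context, fold-jackknife significance, tissue selection.

The relevance of a phenotype to a context combines the heritability-enrichment
magnitude of the context's regulatory category with its statistical
significance:

    R = enrichment * (-log10 p)

so a context scores high only when its category is both strongly and
confidently enriched.  Significance of R itself comes from a delete-one-fold
jackknife over the category's regions: the regions are split into ``n_folds``
random (seeded) folds, R is recomputed with each fold removed, the jackknife
SD of those values yields Z = R / SD ~ N(0, 1) one-sided, and q-values are
Benjamini-Hochberg across the contexts of one phenotype.  Relevant tissues
are those with R >= 100 and q <= 0.01.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from regherit.ldsc import (
    BASE_CATEGORY,
    DEFAULT_N_BLOCKS,
    DEFAULT_WINDOW_BP,
    P_FLOOR,
    AnnotationMatrix,
    LDReference,
    _block_starts,
    _wls_delete_one,
    compute_ld_scores,
    jackknife_se,
    region_membership,
)
from regherit.specificity import RegulatoryCategory

logger = logging.getLogger(__name__)

DEFAULT_N_FOLDS = 100
R_MIN = 100.0
Q_MAX = 0.01
LOG_BASE = 10.0


def relevance_score(enrichment_stat: float, p_value: float,
                    log_base: float = LOG_BASE) -> float:
    """R = statistic * (-log p); p is floored at 1e-300.

    Zero statistic or p = 1 gives R = 0 exactly.
    """
    if not 0 < p_value <= 1:
        raise ValueError(f"p_value must be in (0, 1], got {p_value}")
    p = max(p_value, P_FLOOR)
    return float(enrichment_stat) * (-math.log(p, log_base))


@dataclass
class RelevanceProfile:
    """Per-context relevance of one phenotype, with jackknife significance."""

    phenotype_id: str
    contexts: list[str]
    R: np.ndarray
    sd: np.ndarray
    z: np.ndarray
    p: np.ndarray
    q: np.ndarray
    n_folds: int
    enrichment: np.ndarray | None = None
    p_enr: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "context": self.contexts, "R": self.R, "sd": self.sd,
            "z": self.z, "p": self.p, "q": self.q,
        })
        out["selected"] = (out["R"] >= R_MIN) & (out["q"] <= Q_MAX)
        return out


def _context_fit(y, Nv, l_focal, l_base, w, starts, member, n, sizes):
    """Focal+base fit, enrichment and one-sided p, vectorized over blocks."""
    X = np.column_stack([Nv * l_focal, Nv * l_base, np.ones(len(y))])
    theta, theta_blocks = _wls_delete_one(y, X, w, starts)
    tau_f, tau_b = theta[0], theta[1]
    cnt = member.sum()
    num = cnt * (tau_f + tau_b)
    den = n * tau_b + cnt * tau_f
    E = np.nan if den <= 0 else (num / den) / (cnt / n)

    cnt_blocks = np.add.reduceat(member, starts)
    cnt_del = cnt - cnt_blocks
    n_del = n - sizes
    tf_b, tb_b = theta_blocks[:, 0], theta_blocks[:, 1]
    num_b = cnt_del * (tf_b + tb_b)
    den_b = n_del * tb_b + cnt_del * tf_b
    with np.errstate(divide="ignore", invalid="ignore"):
        E_blocks = (num_b / den_b) / (cnt_del / n_del)
    se = float(jackknife_se(E_blocks))
    if not np.isfinite(E):
        return E, np.nan, tau_f
    if se > 0:
        p = max(stats.norm.sf((E - 1.0) / se), P_FLOOR)
    else:
        p = P_FLOOR if E > 1 else 1.0
    return E, p, tau_f


def jackknife_relevance(
    category: RegulatoryCategory,
    ss: pd.DataFrame,
    ref: LDReference,
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 2023,
    window_bp: int = DEFAULT_WINDOW_BP,
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> dict:
    """R score of one category with delete-one-fold jackknife SD and p.

    Returns a dict with keys R, sd, z, p, enrichment, p_enr, fold_R.
    The fold partition is random but seed-fixed; if the category has fewer
    regions than folds, the fold count is reduced with a warning.
    """
    regions = category.regions
    if not ss["snp"].reset_index(drop=True).equals(
            ref.snps["snp"].reset_index(drop=True)):
        raise ValueError("sumstats must be aligned to the LD reference panel")
    n = len(ss)
    y = ss["chi2"].to_numpy(float)
    Nv = ss["n"].to_numpy(float)
    w = ref.weights
    l_base = ref.base_ld_scores
    starts = _block_starts(n, n_blocks)
    sizes = np.diff(np.append(starts, n)).astype(float)

    member = region_membership(ref.snps, regions)
    l_focal = _category_ld(ref, member, window_bp)
    E, p_enr, _ = _context_fit(y, Nv, l_focal, l_base, w, starts, member, n, sizes)
    R = 0.0 if not np.isfinite(E) else relevance_score(E, p_enr)

    g = min(n_folds, len(regions))
    if g < n_folds:
        logger.warning("jackknife_relevance: %d regions < %d folds; using %d",
                       len(regions), n_folds, g)
    if g < 2:
        raise ValueError("category needs >= 2 regions for the fold jackknife")
    rng = np.random.default_rng(seed)
    fold_of_region = rng.permuted(np.arange(len(regions)) % g)
    fold_of_snp = _snp_fold(ref.snps, regions, fold_of_region, member)
    L_parts = _fold_ld_contributions(ref, member, fold_of_snp, g, window_bp)

    fold_R = np.empty(g)
    for f in range(g):
        m_f = member * (fold_of_snp != f)
        l_f = l_focal - L_parts[:, f]
        E_f, p_f, _ = _context_fit(y, Nv, l_f, l_base, w, starts, m_f, n, sizes)
        fold_R[f] = 0.0 if not np.isfinite(E_f) else relevance_score(E_f, p_f)
    sd = float(jackknife_se(fold_R))
    if sd > 0:
        z = R / sd
        p = max(stats.norm.sf(z), P_FLOOR)
    else:
        z = np.inf if R > 0 else 0.0
        p = P_FLOOR if R > 0 else 1.0
    return {"R": R, "sd": sd, "z": z, "p": p,
            "enrichment": E, "p_enr": p_enr, "fold_R": fold_R, "n_folds": g}


def _snp_fold(snps, regions, fold_of_region, member):
    """Fold id per SNP (-1 outside the category); regions are merged/disjoint."""
    fold = np.full(len(snps), -1)
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for k, iv in enumerate(regions):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, fold_of_region[k]))
    pos_all = snps["pos"].to_numpy()
    for chrom, triples in by_chrom.items():
        triples.sort()
        starts = np.array([t[0] for t in triples])
        ends = np.array([t[1] for t in triples])
        folds = np.array([t[2] for t in triples])
        rows = np.flatnonzero((snps["chrom"] == chrom).to_numpy())
        pos0 = pos_all[rows] - 1
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
        fold[rows[ok]] = folds[idx[ok]]
    assert (fold >= 0).sum() == int(member.sum())
    return fold


def _fold_ld_contributions(ref, member, fold_of_snp, g, window_bp):
    """n x g matrix: LD-score contribution of each fold's SNPs to every SNP."""
    pos = ref.snps["pos"].to_numpy()
    L = np.zeros((len(pos), g))
    for b, idx in enumerate(ref.blocks):
        local_members = np.flatnonzero(fold_of_snp[idx] >= 0)
        if local_members.size == 0:
            continue
        r2 = ref.r_block(b) ** 2
        p = pos[idx]
        mask = np.abs(p[:, None] - p[None, local_members]) <= window_bp
        onehot = np.zeros((local_members.size, g))
        onehot[np.arange(local_members.size),
               fold_of_snp[idx][local_members]] = 1.0
        L[idx] += (r2[:, local_members] * mask) @ onehot
    return L


def _category_ld(ref, member, window_bp):
    annot = AnnotationMatrix(ref.snps, [BASE_CATEGORY, "focal"],
                             np.column_stack([np.ones(len(member)), member]))
    return compute_ld_scores(ref, annot, window_bp).ld[:, 1]


def relevance_profile(
    phenotype_id: str,
    categories: Sequence[RegulatoryCategory],
    ss: pd.DataFrame,
    ref: LDReference,
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 2023,
    window_bp: int = DEFAULT_WINDOW_BP,
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> RelevanceProfile:
    """Relevance of one phenotype to every context, with BH q-values."""
    contexts, R, sd, z, p, E, p_enr = [], [], [], [], [], [], []
    for k, cat in enumerate(categories):
        res = jackknife_relevance(cat, ss, ref, n_folds=n_folds,
                                  seed=seed + k, window_bp=window_bp,
                                  n_blocks=n_blocks)
        contexts.append(cat.context_id)
        R.append(res["R"]); sd.append(res["sd"]); z.append(res["z"])
        p.append(res["p"]); E.append(res["enrichment"]); p_enr.append(res["p_enr"])
    p = np.asarray(p)
    q = stats.false_discovery_control(p, method="bh")
    return RelevanceProfile(
        phenotype_id=phenotype_id, contexts=contexts,
        R=np.asarray(R), sd=np.asarray(sd), z=np.asarray(z), p=p, q=q,
        n_folds=n_folds, enrichment=np.asarray(E), p_enr=np.asarray(p_enr),
    )


def relevance_only(
    phenotype_id: str,
    categories: Sequence[RegulatoryCategory],
    ss: pd.DataFrame,
    ref: LDReference,
    window_bp: int = DEFAULT_WINDOW_BP,
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> pd.DataFrame:
    """R scores without the fold jackknife (for profile correlation work)."""
    rows = []
    n = len(ss)
    y = ss["chi2"].to_numpy(float)
    Nv = ss["n"].to_numpy(float)
    starts = _block_starts(n, n_blocks)
    sizes = np.diff(np.append(starts, n)).astype(float)
    for cat in categories:
        member = region_membership(ref.snps, cat.regions)
        l_focal = _category_ld(ref, member, window_bp)
        E, p_enr, _ = _context_fit(y, Nv, l_focal, ref.base_ld_scores,
                                   ref.weights, starts, member, n, sizes)
        R = 0.0 if not np.isfinite(E) else relevance_score(E, p_enr)
        rows.append({"context": cat.context_id, "R": R,
                     "enrichment": E, "p_enr": p_enr})
    return pd.DataFrame(rows)


def select_relevant_tissues(
    profile: RelevanceProfile, r_min: float = R_MIN, q_max: float = Q_MAX
) -> pd.DataFrame:
    """Contexts with R >= r_min and q <= q_max, sorted by R descending."""
    df = profile.to_frame()
    out = df[(df["R"] >= r_min) & (df["q"] <= q_max)]
    return out.sort_values("R", ascending=False).reset_index(drop=True)
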