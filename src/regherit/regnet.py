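"""Score and threshold TF->RE->TG regulatory networks for one cellular context.

The trans-regulatory score (TRS) of TF i on target gene j aggregates, over
regulatory elements k, the motif binding strength B_ik, the chromatin openness
O_k and a prior RE-TG interaction strength I_kj, modulated by the prior TF-TG
expression correlation R_ij and the geometric mean of the two expressions:

    TRS_ij = (sum_k B_ik * O_k * I_kj) * 2**R_ij * sqrt(TF_i * TG_j)

The cis-regulatory score (CRS) of RE k on gene j combines the TRS of the TFs
bound at k with the prior interaction and openness:

    CRS_kj = (sum_i B_ik * TRS_ij) * I_kj * O_k

Edges are thresholded empirically: TRS against a null of randomly re-paired
TF-TG combinations at a target FDR, CRS by an upper-tail test under a Normal
fit to log2(1 + CRS) over the candidate universe (pairs with I_kj > 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from regherit.io import GenomicInterval

logger = logging.getLogger(__name__)

DEFAULT_SEED = 2023


@dataclass
class ContextOmics:
    """Paired omics inputs for one context.

    ``motif_binding`` is TF x RE, ``prior_interaction`` RE x TG,
    ``prior_corr`` TF x TG with values in [-1, 1].  All expressions and
    openness values must be finite and non-negative.
    """

    context_id: str
    tf_expr: pd.Series
    tg_expr: pd.Series
    re_open: pd.Series
    motif_binding: pd.DataFrame
    prior_interaction: pd.DataFrame
    prior_corr: pd.DataFrame
    re_intervals: list[GenomicInterval] = field(default_factory=list)

    def validate(self) -> None:
        for name, values in (("tf_expr", self.tf_expr), ("tg_expr", self.tg_expr),
                             ("re_open", self.re_open),
                             ("motif_binding", self.motif_binding),
                             ("prior_interaction", self.prior_interaction)):
            arr = np.asarray(values, float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            if (arr < 0).any():
                raise ValueError(f"{name} contains negative values")
        known = set(self.re_open.index)
        for name, ids in (("motif_binding", self.motif_binding.columns),
                          ("prior_interaction", self.prior_interaction.index)):
            missing = set(ids) - known
            if missing:
                raise ValueError(f"{name} references unknown REs: {sorted(missing)[:5]}")
        interval_ids = {iv.id for iv in self.re_intervals}
        if self.re_intervals and not known <= interval_ids:
            raise ValueError("re_open contains REs without intervals")


@dataclass
class RegulatoryNetwork:
    """Thresholded regulatory network: TFs, REs (with intervals), TGs."""

    context_id: str
    trs_edges: pd.DataFrame      # columns tf, tg, trs
    crs_edges: pd.DataFrame      # columns re, tg, crs
    binding_edges: pd.DataFrame  # columns tf, re, weight (B_ik > 0, retained nodes)
    tfs: set[str]
    res: set[str]
    tgs: set[str]
    re_intervals: dict[str, GenomicInterval]


def _aligned_arrays(omics: ContextOmics):
    """Return (tfs, res, tgs, B, O, I, R, tf_expr, tg_expr) aligned ndarrays."""
    tfs = list(omics.motif_binding.index)
    res = list(omics.motif_binding.columns)
    tgs = list(omics.prior_interaction.columns)
    B = omics.motif_binding.to_numpy(float)
    O = omics.re_open.reindex(res).to_numpy(float)
    I = omics.prior_interaction.reindex(index=res, columns=tgs).fillna(0.0)
    I = I.to_numpy(float)
    R = omics.prior_corr.reindex(index=tfs, columns=tgs)
    n_missing = int(R.isna().to_numpy().sum())
    if n_missing:
        logger.warning(
            "prior_corr missing for %d TF-TG pairs; defaulting to 0", n_missing)
    R = R.fillna(0.0).to_numpy(float)
    tf_e = omics.tf_expr.reindex(tfs)
    tg_e = omics.tg_expr.reindex(tgs)
    if tf_e.isna().any() or tg_e.isna().any():
        raise ValueError("expression missing for some TFs/TGs in the priors")
    for name, arr in (("motif_binding", B), ("re_open", O),
                      ("prior_interaction", I),
                      ("tf_expr", tf_e.to_numpy()), ("tg_expr", tg_e.to_numpy())):
        if (np.asarray(arr) < 0).any():
            raise ValueError(f"{name} contains negative values")
    return tfs, res, tgs, B, O, I, R, tf_e.to_numpy(float), tg_e.to_numpy(float)


def _trs_matrix(omics: ContextOmics):
    tfs, res, tgs, B, O, I, R, tf_e, tg_e = _aligned_arrays(omics)
    S = (B * O[None, :]) @ I                       # sum_k B_ik O_k I_kj
    trs = S * np.exp2(R) * np.sqrt(np.outer(tf_e, tg_e))
    return tfs, tgs, trs, S


def compute_trs(omics: ContextOmics) -> pd.DataFrame:
    """Trans-regulatory scores; sparse output (zero-summation pairs omitted)."""
    tfs, tgs, trs, S = _trs_matrix(omics)
    ii, jj = np.nonzero(S > 0)
    return pd.DataFrame({
        "tf": np.asarray(tfs, object)[ii],
        "tg": np.asarray(tgs, object)[jj],
        "trs": trs[ii, jj],
    })


def select_trs_edges(
    omics: ContextOmics,
    trs: pd.DataFrame,
    n_background: int = 10_000,
    fdr: float = 0.001,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Threshold TRS edges against an empirical re-paired null at a target FDR.

    The null re-pairs each sampled candidate TF with a uniformly drawn
    *different* TG (its prior-interaction column, prior correlation and
    expression), breaking any genuine TF-TG coordination.  The threshold t* is
    the smallest observed TRS value t with

        [null fraction >= t] / [observed fraction >= t] <= fdr,

    and edges with TRS >= t* are kept.  Monotone: raising ``fdr`` never
    removes a previously selected edge.
    """
    if n_background < 1000:
        raise ValueError("n_background must be >= 1000")
    if trs.empty:
        return trs.copy()
    rng = np.random.default_rng(seed)
    tfs, tgs, trs_mat, S = _trs_matrix(omics)
    tf_pos = {t: i for i, t in enumerate(tfs)}
    tg_pos = {g: j for j, g in enumerate(tgs)}
    obs = np.sort(trs["trs"].to_numpy(float))
    cand_i = trs["tf"].map(tf_pos).to_numpy()
    cand_j = trs["tg"].map(tg_pos).to_numpy()

    pick = rng.integers(0, len(cand_i), size=n_background)
    null_i = cand_i[pick]
    # uniformly drawn TG different from the candidate's own
    shift = rng.integers(1, len(tgs), size=n_background)
    null_j = (cand_j[pick] + shift) % len(tgs)
    null = np.sort(trs_mat[null_i, null_j])
    if null.size and np.ptp(null) == 0:
        logger.warning("select_trs_edges: degenerate (constant) null distribution")

    thresholds = np.unique(obs)
    obs_tail = (obs.size - np.searchsorted(obs, thresholds, side="left")) / obs.size
    null_tail = (null.size - np.searchsorted(null, thresholds, side="left")) / null.size
    ok = null_tail / obs_tail <= fdr
    if not ok.any():
        logger.warning("select_trs_edges: no threshold reaches FDR %g", fdr)
        return trs.iloc[:0].copy()
    t_star = thresholds[np.argmax(ok)]
    out = trs[trs["trs"] >= t_star].reset_index(drop=True)
    out.attrs["threshold"] = float(t_star)
    return out


def compute_crs(omics: ContextOmics, trs: pd.DataFrame) -> pd.DataFrame:
    """Cis-regulatory scores for all (RE, TG) pairs with positive prior I_kj."""
    tfs, res, tgs, B, O, I, R, tf_e, tg_e = _aligned_arrays(omics)
    trs_mat = np.zeros((len(tfs), len(tgs)))
    tf_pos = {t: i for i, t in enumerate(tfs)}
    tg_pos = {g: j for j, g in enumerate(tgs)}
    ii = trs["tf"].map(tf_pos).to_numpy()
    jj = trs["tg"].map(tg_pos).to_numpy()
    trs_mat[ii, jj] = trs["trs"].to_numpy(float)
    crs = (B.T @ trs_mat) * I * O[:, None]
    kk, jj2 = np.nonzero(I > 0)
    return pd.DataFrame({
        "re": np.asarray(res, object)[kk],
        "tg": np.asarray(tgs, object)[jj2],
        "crs": crs[kk, jj2],
    })


def select_crs_edges(crs: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Keep RE-TG pairs in the Normal upper tail of log2(1 + CRS).

    The Normal is fit over the candidate universe (pairs with positive prior
    interaction); pairs with one-sided upper-tail p <= alpha are retained.
    """
    if len(crs) < 30:
        raise ValueError("select_crs_edges requires >= 30 candidate pairs")
    y = np.log2(1.0 + crs["crs"].to_numpy(float))
    mu, sd = y.mean(), y.std(ddof=1)
    if sd == 0:
        logger.warning("select_crs_edges: zero variance in log2(1+CRS)")
        return crs.iloc[:0].copy()
    p = stats.norm.sf((y - mu) / sd)
    out = crs[p <= alpha].reset_index(drop=True)
    out.attrs["mean_log2"] = float(mu)
    out.attrs["sd_log2"] = float(sd)
    return out


def build_network(
    omics: ContextOmics,
    trs_edges: pd.DataFrame,
    crs_edges: pd.DataFrame,
) -> RegulatoryNetwork:
    """Assemble the network whose nodes are exactly the retained edge endpoints."""
    tfs = set(trs_edges["tf"]) if len(trs_edges) else set()
    res = set(crs_edges["re"]) if len(crs_edges) else set()
    tgs = (set(trs_edges["tg"]) if len(trs_edges) else set()) | (
        set(crs_edges["tg"]) if len(crs_edges) else set())
    interval_map = {iv.id: iv for iv in omics.re_intervals}
    missing = res - set(interval_map)
    if missing:
        raise ValueError(
            f"CRS edges reference REs without intervals: {sorted(missing)[:5]}")
    b = omics.motif_binding
    sub = b.loc[b.index.intersection(sorted(tfs)), b.columns.intersection(sorted(res))]
    ii, kk = np.nonzero(sub.to_numpy(float) > 0)
    binding = pd.DataFrame({
        "tf": np.asarray(sub.index, object)[ii],
        "re": np.asarray(sub.columns, object)[kk],
        "weight": sub.to_numpy(float)[ii, kk],
    })
    return RegulatoryNetwork(
        context_id=omics.context_id,
        trs_edges=trs_edges.reset_index(drop=True),
        crs_edges=crs_edges.reset_index(drop=True),
        binding_edges=binding,
        tfs=tfs, res=res, tgs=tgs,
        re_intervals={rid: interval_map[rid] for rid in res},
    )


def infer_network(
    omics: ContextOmics,
    n_background: int = 10_000,
    trs_fdr: float = 0.001,
    crs_alpha: float = 0.05,
    seed: int = DEFAULT_SEED,
) -> RegulatoryNetwork:
    """Full per-context pipeline: score, threshold, assemble."""
    omics.validate()
    trs = compute_trs(omics)
    kept_trs = select_trs_edges(omics, trs, n_background=n_background,
                                fdr=trs_fdr, seed=seed)
    crs = compute_crs(omics, trs)
    kept_crs = select_crs_edges(crs, alpha=crs_alpha) if len(crs) >= 30 else crs.iloc[:0]
    return build_network(omics, kept_trs, kept_crs)
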