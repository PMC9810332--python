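"""Seeded generators: LD references, multi-context atlases, GWAS sumstats.

Everything is a pure function of (config, seed) and ships its ground truth, so
every stage of the pipeline is testable without external downloads.

The generative model for summary statistics is the marginal-z shortcut: each
SNP's z statistic is drawn independently with variance inflated to the
stratified polygenic expectation,

    z_j ~ Normal(0, sqrt(N * sum_i tau_i * l_{j,i} + N*a + 1)),   chi2_j = z_j^2,

which matches the regression model's expectation exactly while avoiding
individual-level genotypes.  The LD reference is block-diagonal with AR(1)
within-block correlation r^|i-j|.  The atlas plants, per context, a set of
REs unique to that context (placed in reserved genomic slots, so they are
context-specific by construction) alongside REs copied verbatim within a
group and across all contexts (which the specificity rule must reject).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from regherit.io import GenomicInterval
from regherit.ldsc import AnnotationMatrix, LDReference, LDScoreTable, compute_ld_scores
from regherit.regnet import ContextOmics, build_network, compute_crs, compute_trs
from regherit.specificity import ContextAtlas, RegulatoryCategory, call_specific_res

DEFAULT_SEED = 2023


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline.

    LD layout: ``n_snps`` SNPs at ``snp_spacing_bp`` on one chromosome, in
    ``n_blocks_ld`` equal blocks with AR(1) correlation ``block_r``.  Atlas
    layout: ``n_contexts`` contexts in ``n_groups`` groups, each with
    ``res_per_context`` REs of which ``planted_specific_fraction`` are unique
    to the context.  GWAS: sample size ``n_gwas``, per-SNP coefficient
    ``tau_base`` genome-wide plus ``tau_true`` extra inside the causal
    (planted-relevant) context's specific category, confounding ``intercept_a``.
    """

    seed: int = DEFAULT_SEED
    # LD layout
    n_snps: int = 50_000
    n_blocks_ld: int = 100
    block_r: float = 0.5
    ld_heterogeneity: float = 0.7
    snp_spacing_bp: int = 1_000
    # atlas layout
    n_contexts: int = 6
    n_groups: int = 3
    res_per_context: int = 240
    planted_specific_fraction: float = 0.5
    n_tfs: int = 10
    n_tgs: int = 30
    within_group_noise: float = 0.2
    # GWAS
    n_gwas: int = 50_000
    tau_true: float = 5e-5
    tau_base: float = 1e-6
    intercept_a: float = 0.0

    def __post_init__(self):
        for name in ("n_snps", "n_blocks_ld", "snp_spacing_bp", "n_contexts",
                     "n_groups", "res_per_context", "n_tfs", "n_tgs", "n_gwas"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not abs(self.block_r) < 1:
            raise ValueError("|block_r| must be < 1")
        if not 0 <= self.planted_specific_fraction <= 1:
            raise ValueError("planted_specific_fraction must be in [0, 1]")
        if self.n_groups > self.n_contexts:
            raise ValueError("n_groups cannot exceed n_contexts")


@dataclass
class GroundTruth:
    """What was planted: causal category, tau values, specific RE ids."""

    causal_categories: list[str]
    tau: dict[str, float]
    planted_relevant_context: str
    specific_re_ids: dict[str, list[str]] = field(default_factory=dict)
    intercept_a: float = 0.0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def simulate_ld_reference(cfg: SimulationConfig) -> LDReference:
    """Block-diagonal AR(1) LD reference on an evenly spaced SNP panel.

    Per-block decay rates are ``block_r`` scaled by a seeded multiplicative
    spread of ``ld_heterogeneity`` (real genomes have very unequal local LD;
    the resulting variation in total LD scores is also what identifies the
    base-category coefficient in the regression).  ``ld_heterogeneity=0``
    gives the homogeneous ``r = block_r**|i-j|`` layout in every block.
    """
    idx = np.arange(cfg.n_snps)
    snps = pd.DataFrame({
        "snp": [f"rs{i}" for i in idx],
        "chrom": "1",
        "pos": (idx + 1) * cfg.snp_spacing_bp,
    })
    bounds = (np.arange(cfg.n_blocks_ld + 1) * cfg.n_snps // cfg.n_blocks_ld)
    blocks = [np.arange(bounds[b], bounds[b + 1]) for b in range(cfg.n_blocks_ld)]
    rng = np.random.default_rng(cfg.seed)
    h = cfg.ld_heterogeneity
    decay = cfg.block_r * rng.uniform(1 - h, 1 + h, size=cfg.n_blocks_ld)
    decay = np.clip(decay, -0.95, 0.95)
    return LDReference(snps, blocks, decay=decay)


def _context_ids(cfg: SimulationConfig) -> list[str]:
    return [f"ctx{i}" for i in range(cfg.n_contexts)]


def _group_of(cfg: SimulationConfig) -> dict[str, int]:
    return {f"ctx{i}": 1 + i * cfg.n_groups // cfg.n_contexts
            for i in range(cfg.n_contexts)}


def simulate_atlas(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[ContextAtlas, dict[str, ContextOmics], GroundTruth]:
    """Multi-context atlas with planted context-specific REs.

    Specific REs occupy reserved, pairwise-disjoint genomic slots; shared REs
    are copied verbatim to every member context of their group (or to all
    contexts), so the specificity caller's ground truth is exact.  Slots are
    interleaved across the genome so each category spreads over LD blocks.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ctxs = _context_ids(cfg)
    group_of = _group_of(cfg)
    groups = sorted(set(group_of.values()))

    n_spec = round(cfg.planted_specific_fraction * cfg.res_per_context)
    n_rest = cfg.res_per_context - n_spec
    n_group_shared = n_rest // 2
    n_global = n_rest - n_group_shared

    # pools: one per (specific, ctx), one per (group-shared, group), one global
    pool_quota: list[tuple[str, str | int, int]] = (
        [("spec", c, n_spec) for c in ctxs]
        + [("group", g, n_group_shared) for g in groups]
        + [("glob", 0, n_global)]
    )
    slots: list[tuple[str, str | int]] = []
    remaining = {(kind, who): quota for kind, who, quota in pool_quota}
    while any(v > 0 for v in remaining.values()):
        for kind, who, _ in pool_quota:
            if remaining[(kind, who)] > 0:
                slots.append((kind, who))
                remaining[(kind, who)] -= 1

    genome_bp = cfg.n_snps * cfg.snp_spacing_bp
    stride = genome_bp // max(len(slots), 1)
    width_lo, width_hi = 1_500, 2_001
    slot_intervals = []
    for s, (kind, who) in enumerate(slots):
        width = int(rng.integers(width_lo, width_hi))
        margin = max(stride - width - 1, 1)
        start = s * stride + int(rng.integers(0, margin))
        slot_intervals.append((kind, who, start, start + width))

    # slot-level template values shared by every copy of a shared RE
    slot_open = rng.lognormal(0.0, 0.5, size=len(slots))
    slot_binding = (rng.random((len(slots), cfg.n_tfs)) < 0.3) * rng.uniform(
        0.5, 1.5, size=(len(slots), cfg.n_tfs))
    slot_prior = (rng.random((len(slots), cfg.n_tgs)) < 0.2) * rng.uniform(
        0.5, 1.5, size=(len(slots), cfg.n_tgs))
    # every RE regulates at least one gene so it survives network assembly
    none = slot_prior.sum(axis=1) == 0
    slot_prior[none, rng.integers(0, cfg.n_tgs, size=int(none.sum()))] = 1.0

    tf_ids = [f"tf{i}" for i in range(cfg.n_tfs)]
    tg_ids = [f"gene{j}" for j in range(cfg.n_tgs)]
    prior_corr = pd.DataFrame(rng.uniform(-1, 1, size=(cfg.n_tfs, cfg.n_tgs)),
                              index=tf_ids, columns=tg_ids)
    group_tf_expr = {g: rng.lognormal(0.0, 0.5, cfg.n_tfs) for g in groups}
    group_tg_expr = {g: rng.lognormal(0.0, 0.5, cfg.n_tgs) for g in groups}

    networks, omics_by_ctx = [], {}
    specific_ids: dict[str, list[str]] = {c: [] for c in ctxs}
    for c in ctxs:
        g = group_of[c]
        mine = [(s, kind) for s, (kind, who, *_rest) in enumerate(slot_intervals)
                if (kind == "spec" and who == c)
                or (kind == "group" and who == g) or kind == "glob"]
        re_ids, intervals = [], []
        for s, kind in mine:
            _, _, start, end = slot_intervals[s]
            rid = f"{c}_re{s}"
            re_ids.append(rid)
            intervals.append(GenomicInterval("1", start, end, rid))
            members = sum(1 for x in ctxs if group_of[x] == g)
            if kind == "spec" or (kind == "group" and members == 1):
                # group-shared REs of a singleton group are unique to it,
                # hence genuinely context-specific
                specific_ids[c].append(rid)
        noise = cfg.within_group_noise
        sel = [s for s, _ in mine]
        B = slot_binding[sel].T * rng.lognormal(0.0, noise,
                                                (cfg.n_tfs, len(sel)))
        I = slot_prior[sel] * rng.lognormal(0.0, noise, (len(sel), cfg.n_tgs))
        O = slot_open[sel] * rng.lognormal(0.0, noise, len(sel))
        omics = ContextOmics(
            context_id=c,
            tf_expr=pd.Series(group_tf_expr[g]
                              * rng.lognormal(0.0, noise, cfg.n_tfs),
                              index=tf_ids),
            tg_expr=pd.Series(group_tg_expr[g]
                              * rng.lognormal(0.0, noise, cfg.n_tgs),
                              index=tg_ids),
            re_open=pd.Series(O, index=re_ids),
            motif_binding=pd.DataFrame(B, index=tf_ids, columns=re_ids),
            prior_interaction=pd.DataFrame(I, index=re_ids, columns=tg_ids),
            prior_corr=prior_corr,
            re_intervals=intervals,
        )
        trs = compute_trs(omics)
        crs = compute_crs(omics, trs)
        networks.append(build_network(omics, trs, crs[crs["crs"] > 0]))
        omics_by_ctx[c] = omics

    atlas = ContextAtlas(networks, group_of)
    truth = GroundTruth(
        causal_categories=[ctxs[0]],
        tau={"base": cfg.tau_base, ctxs[0]: cfg.tau_true},
        planted_relevant_context=ctxs[0],
        specific_re_ids={c: sorted(set(specific_ids[c]) & nw.res)
                         for c, nw in zip(ctxs, networks)},
        intercept_a=cfg.intercept_a,
    )
    return atlas, omics_by_ctx, truth


def simulate_sumstats(
    cfg: SimulationConfig,
    ld: LDScoreTable,
    tau: Mapping[str, float],
    seed: int | None = None,
) -> pd.DataFrame:
    """Summary statistics under the stratified polygenic model.

    Per SNP, z ~ Normal(0, sqrt(N * sum_i tau_i l_{j,i} + N*a + 1)) and
    chi2 = z^2; categories absent from ``tau`` contribute 0.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    tau_vec = np.array([tau.get(name, 0.0) for name in ld.names])
    var = cfg.n_gwas * (ld.ld @ tau_vec) + cfg.n_gwas * cfg.intercept_a + 1.0
    if (var <= 0).any():
        raise ValueError("negative chi2 variance: invalid tau/a combination")
    z = rng.normal(0.0, np.sqrt(var))
    chi2 = z ** 2
    return pd.DataFrame({
        "snp": ld.snps["snp"].to_numpy(),
        "chrom": ld.snps["chrom"].to_numpy(),
        "pos": ld.snps["pos"].to_numpy(),
        "n": cfg.n_gwas,
        "chi2": chi2,
        "pval": stats.chi2.sf(chi2, df=1),
    })


@dataclass
class SimulatedStudy:
    """A self-contained synthetic dataset: reference, atlas, categories, GWAS."""

    cfg: SimulationConfig
    ref: LDReference
    atlas: ContextAtlas
    omics: dict[str, ContextOmics]
    categories: list[RegulatoryCategory]
    annot: AnnotationMatrix
    ld: LDScoreTable
    sumstats: pd.DataFrame
    truth: GroundTruth


def simulate_study(cfg: SimulationConfig, seed: int | None = None) -> SimulatedStudy:
    """Full pipeline fixture: LD, atlas, specific categories, causal GWAS."""
    seed = cfg.seed if seed is None else seed
    ref = simulate_ld_reference(cfg)
    atlas, omics, truth = simulate_atlas(cfg, seed=seed)
    categories = [call_specific_res(atlas, c) for c in atlas.context_ids]
    annot = AnnotationMatrix.from_regions(
        ref.snps, {cat.context_id: cat.regions for cat in categories})
    ld = compute_ld_scores(ref, annot)
    ss = simulate_sumstats(cfg, ld, truth.tau, seed=seed + 1)
    return SimulatedStudy(cfg, ref, atlas, omics, categories, annot, ld, ss, truth)


def simulate_phenotype_pair(
    cfg: SimulationConfig, shared: bool, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth, SimulatedStudy]:
    """Two phenotypes with shared or disjoint causal categories.

    ``shared=True``: both draw their category enrichment from the planted
    relevant context (independent GWAS noise).  ``shared=False``: the second
    phenotype's causal category is a different context.
    """
    seed = cfg.seed if seed is None else seed
    study = simulate_study(cfg, seed=seed)
    ctxs = study.atlas.context_ids
    ctx_a = study.truth.planted_relevant_context
    ctx_b = ctx_a if shared else ctxs[(ctxs.index(ctx_a) + 1) % len(ctxs)]
    tau_p = {"base": cfg.tau_base, ctx_a: cfg.tau_true}
    tau_q = {"base": cfg.tau_base, ctx_b: cfg.tau_true}
    ss_p = simulate_sumstats(cfg, study.ld, tau_p, seed=seed + 11)
    ss_q = simulate_sumstats(cfg, study.ld, tau_q, seed=seed + 12)
    truth = GroundTruth(
        causal_categories=sorted({ctx_a, ctx_b}),
        tau={"base": cfg.tau_base, ctx_a: cfg.tau_true, ctx_b: cfg.tau_true},
        planted_relevant_context=ctx_a,
        specific_re_ids=study.truth.specific_re_ids,
        intercept_a=cfg.intercept_a,
    )
    return ss_p, ss_q, truth, study
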