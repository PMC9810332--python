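"""Per-category LD scores, stratified LD-score regression, block jackknife.

The polygenic model: for SNP j with marginal association chi2_j from a GWAS of
N samples,

    E[chi2_j] = N * sum_i tau_i * l_{j,i} + N*a + 1

where l_{j,i} = sum_{k in C_i} r_{jk}^2 is the LD score of SNP j in category
C_i (genotype correlations r within a window), tau_i is the per-SNP
heritability coefficient of the category, and a absorbs confounding.  The fit
is a single-step weighted least squares of chi2 on {N*l_i} with a free
intercept and weights 1/max(l_base, 1); standard errors come from a
delete-one-block jackknife over contiguous, equal-SNP-count genomic blocks.

Heritability enrichment of a category is the proportion of total per-SNP
heritability its SNPs carry divided by the proportion of SNPs it contains;
its standard error and one-sided p (enrichment > 1) are jackknifed from the
same blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import toeplitz

from regherit.io import GenomicInterval, merge_intervals

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_N_BLOCKS = 200
BASE_CATEGORY = "base"
P_FLOOR = 1e-300


class PanelMismatchError(ValueError):
    """SNP panels of two inputs disagree."""


class SingularDesignError(np.linalg.LinAlgError):
    """Rank-deficient regression design (e.g. duplicate categories)."""


@dataclass
class LDReference:
    """SNP panel with block-structured pairwise genotype correlations.

    ``blocks`` partitions SNP row indices into contiguous runs; correlations
    across blocks are zero.  Within a block the correlation matrix is either
    stored explicitly (``r_blocks``) or generated as an AR(1) decay
    ``r = decay**|i-j|`` in panel order.
    """

    snps: pd.DataFrame                       # columns snp, chrom, pos; sorted
    blocks: list[np.ndarray]
    r_blocks: list[np.ndarray] | None = None
    decay: float | np.ndarray | None = None  # scalar or per-block AR(1) rate

    def __post_init__(self):
        if (self.r_blocks is None) == (self.decay is None):
            raise ValueError("provide exactly one of r_blocks or decay")
        if self.decay is not None:
            if np.ndim(self.decay) not in (0, 1):
                raise ValueError("decay must be a scalar or per-block vector")
            if not np.all(np.abs(self.decay) < 1):
                raise ValueError("|decay| must be < 1")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def r_block(self, b: int) -> np.ndarray:
        if self.r_blocks is not None:
            return self.r_blocks[b]
        k = len(self.blocks[b])
        rho = self.decay if np.ndim(self.decay) == 0 else self.decay[b]
        return toeplitz(rho ** np.arange(k))

    @cached_property
    def base_ld_scores(self) -> np.ndarray:
        """Total (all-SNP) LD scores at the default window."""
        annot = AnnotationMatrix(self.snps, [BASE_CATEGORY],
                                 np.ones((self.n_snps, 1)))
        return compute_ld_scores(self, annot, DEFAULT_WINDOW_BP).ld[:, 0]

    @cached_property
    def weights(self) -> np.ndarray:
        """Regression weights: reciprocal of the (floored) total LD score."""
        return 1.0 / np.maximum(self.base_ld_scores, 1.0)


@dataclass
class AnnotationMatrix:
    """Binary SNP x category membership; the all-SNP base category is first."""

    snps: pd.DataFrame
    names: list[str]
    M: np.ndarray                 # n_snps x n_categories, 0/1

    def __post_init__(self):
        self.M = np.asarray(self.M, float)
        if self.M.shape != (len(self.snps), len(self.names)):
            raise ValueError("membership shape does not match snps/names")
        if not np.isin(self.M, (0.0, 1.0)).all():
            raise ValueError("membership entries must be 0/1")
        if BASE_CATEGORY not in self.names:
            self.names = [BASE_CATEGORY] + list(self.names)
            self.M = np.column_stack([np.ones(len(self.snps)), self.M])

    @property
    def counts(self) -> np.ndarray:
        return self.M.sum(axis=0)

    @classmethod
    def from_regions(
        cls,
        snps: pd.DataFrame,
        regions: Mapping[str, Sequence[GenomicInterval]],
    ) -> "AnnotationMatrix":
        """Membership by position: 1-based SNP pos inside a 0-based half-open region."""
        names = list(regions)
        M = np.zeros((len(snps), len(names)))
        for c, name in enumerate(names):
            M[:, c] = region_membership(snps, regions[name])
        return cls(snps, names, M)


def region_membership(
    snps: pd.DataFrame, regions: Sequence[GenomicInterval]
) -> np.ndarray:
    """0/1 vector: SNP falls inside one of the (merged) regions."""
    member = np.zeros(len(snps))
    merged = merge_intervals(regions)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by_chrom.items():
        starts = np.array([iv.start for iv in ivs])
        ends = np.array([iv.end for iv in ivs])
        rows = np.flatnonzero((snps["chrom"] == chrom).to_numpy())
        pos0 = snps["pos"].to_numpy()[rows] - 1       # to 0-based
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
        member[rows[ok]] = 1.0
    return member


@dataclass
class LDScoreTable:
    """Per-SNP, per-category LD scores."""

    snps: pd.DataFrame
    names: list[str]
    ld: np.ndarray                # n_snps x n_categories
    window_bp: int

    def column(self, name: str) -> np.ndarray:
        return self.ld[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        out = self.snps[["snp", "chrom", "pos"]].copy()
        for c, name in enumerate(self.names):
            out[f"L2_{name}"] = self.ld[:, c]
        return out


def compute_ld_scores(
    ref: LDReference,
    annot: AnnotationMatrix,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> LDScoreTable:
    """l_{j,i} = sum over category-i SNPs k within the window of r_{jk}^2.

    The self term (k = j) is included whenever SNP j belongs to the category.
    """
    if not ref.snps["snp"].equals(annot.snps["snp"]):
        raise PanelMismatchError("LD reference and annotation SNP panels differ")
    pos = ref.snps["pos"].to_numpy()
    L = np.zeros_like(annot.M, dtype=float)
    for b, idx in enumerate(ref.blocks):
        r2 = ref.r_block(b) ** 2
        p = pos[idx]
        mask = np.abs(p[:, None] - p[None, :]) <= window_bp
        L[idx] = (r2 * mask) @ annot.M[idx]
    return LDScoreTable(ref.snps, list(annot.names), L, window_bp)


@dataclass
class StratifiedFit:
    """Stratified-LDSC fit: per-category tau with jackknife inference."""

    names: list[str]
    tau: np.ndarray
    se_tau: np.ndarray
    p_tau: np.ndarray
    intercept: float
    se_intercept: float
    n_blocks: int
    theta_blocks: np.ndarray = field(repr=False)   # n_blocks x (C+1) delete-one
    block_starts: np.ndarray = field(repr=False)
    snp_ids: pd.Index = field(repr=False)
    enrichment: np.ndarray | None = None
    se_enr: np.ndarray | None = None
    p_enr: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"category": self.names, "tau": self.tau,
                            "se": self.se_tau, "p_tau": self.p_tau})
        if self.enrichment is not None:
            out["enrichment"] = self.enrichment
            out["se_enr"] = self.se_enr
            out["p_enr"] = self.p_enr
        return out


def _block_starts(n: int, n_blocks: int) -> np.ndarray:
    return (np.arange(n_blocks) * n // n_blocks).astype(np.intp)


def _wls_delete_one(y, X, w, starts):
    """Full WLS solution plus delete-one-block solutions.

    Returns (theta, theta_blocks); uses per-block sufficient statistics so a
    delete-one refit is a small linear solve.
    """
    n, p = X.shape
    iu, ju = np.triu_indices(p)
    prods = X[:, iu] * X[:, ju] * w[:, None]
    a_blocks = np.add.reduceat(prods, starts, axis=0)      # g x p(p+1)/2
    c_blocks = np.add.reduceat(X * (w * y)[:, None], starts, axis=0)
    a_full = a_blocks.sum(axis=0)
    c_full = c_blocks.sum(axis=0)

    def unpack(flat):
        A = np.zeros(flat.shape[:-1] + (p, p))
        A[..., iu, ju] = flat
        A[..., ju, iu] = flat
        return A

    A = unpack(a_full)
    try:
        theta = np.linalg.solve(A, c_full)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError(str(exc)) from exc
    A_del = unpack(a_full[None, :] - a_blocks)
    c_del = c_full[None, :] - c_blocks
    theta_blocks = np.linalg.solve(A_del, c_del[..., None])[..., 0]
    return theta, theta_blocks


def jackknife_se(values: np.ndarray) -> np.ndarray:
    """Delete-one-group jackknife SE from the g leave-one-out statistics."""
    values = np.asarray(values, float)
    g = values.shape[0]
    dev = values - values.mean(axis=0)
    return np.sqrt((g - 1) / g * (dev ** 2).sum(axis=0))


def fit_stratified(
    ss: pd.DataFrame,
    ld: LDScoreTable,
    n_blocks: int = DEFAULT_N_BLOCKS,
    weights: np.ndarray | None = None,
) -> StratifiedFit:
    """Weighted least squares of chi2 on {N * l_i} with a free intercept.

    ``ss`` must be aligned to ``ld.snps`` (same SNPs, same order); p-values
    for tau are two-sided normal on the jackknife z.
    """
    if not ss["snp"].reset_index(drop=True).equals(
            ld.snps["snp"].reset_index(drop=True)):
        raise PanelMismatchError("sumstats and LD score table SNP panels differ")
    n = len(ss)
    names = list(ld.names)
    C = len(names)
    if n < 10 * (C + 1):
        raise ValueError(f"need >= {10 * (C + 1)} SNPs for {C} categories")
    if n_blocks < 2 or n_blocks > n // 10:
        raise ValueError("n_blocks must be in [2, n_snps/10]")
    # duplicate-category guard, named for the caller
    for i in range(C):
        for j in range(i + 1, C):
            if np.array_equal(ld.ld[:, i], ld.ld[:, j]):
                raise SingularDesignError(
                    f"duplicate categories in design: {names[i]!r} and {names[j]!r}")

    y = ss["chi2"].to_numpy(float)
    Nv = ss["n"].to_numpy(float)
    X = np.column_stack([Nv[:, None] * ld.ld, np.ones(n)])
    if weights is None:
        weights = 1.0 / np.maximum(ld.column(BASE_CATEGORY), 1.0)
    starts = _block_starts(n, n_blocks)
    theta, theta_blocks = _wls_delete_one(y, X, weights, starts)
    se = jackknife_se(theta_blocks)
    z = np.divide(theta, se, out=np.zeros_like(theta), where=se > 0)
    p = np.maximum(2 * stats.norm.sf(np.abs(z)), P_FLOOR)
    return StratifiedFit(
        names=names, tau=theta[:C], se_tau=se[:C], p_tau=p[:C],
        intercept=float(theta[C]), se_intercept=float(se[C]),
        n_blocks=n_blocks, theta_blocks=theta_blocks, block_starts=starts,
        snp_ids=pd.Index(ss["snp"]),
    )


def enrichment_summary(
    fit: StratifiedFit,
    annot: AnnotationMatrix,
) -> pd.DataFrame:
    """Per-category heritability enrichment with jackknife SE and one-sided p.

    Per-SNP heritability h_j = sum_i tau_i * 1{j in C_i}; enrichment
    E_i = (share of total h in C_i) / (share of SNPs in C_i).  The jackknife
    recomputes E_i with each block's SNPs (and its delete-one tau) removed; p
    tests E_i > 1 so depletion is never rewarded.  Results are attached to
    ``fit`` and returned as a table.
    """
    if len(annot.names) != len(fit.names) or list(annot.names) != list(fit.names):
        raise PanelMismatchError("annotation categories differ from fit categories")
    M = annot.M
    n, C = M.shape
    starts = fit.block_starts
    bounds = np.append(starts, n)
    g = fit.n_blocks
    # per-block category cross-products and counts
    G_blocks = np.empty((g, C, C))
    for b in range(g):
        Mb = M[bounds[b]:bounds[b + 1]]
        G_blocks[b] = Mb.T @ Mb
    G = G_blocks.sum(axis=0)
    cnt = np.diag(G).copy()
    sizes = np.diff(bounds).astype(float)

    tau = fit.tau
    total_h = float(cnt @ tau)
    if total_h <= 0:
        logger.warning("enrichment_summary: total heritability <= 0; "
                       "enrichment undefined")
        E = np.full(C, np.nan)
        fit.enrichment, fit.se_enr, fit.p_enr = E, np.full(C, np.nan), np.full(C, np.nan)
        return fit.to_frame()
    with np.errstate(divide="ignore", invalid="ignore"):
        E = (G @ tau / total_h) / (cnt / n)

    tau_b = fit.theta_blocks[:, :C]                       # g x C
    G_del = G[None] - G_blocks                            # g x C x C
    cnt_del = cnt[None, :] - np.einsum("bii->bi", G_blocks)
    n_del = (n - sizes)[:, None]
    num = np.einsum("bij,bj->bi", G_del, tau_b)
    den = np.einsum("bi,bi->b", cnt_del, tau_b)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        E_blocks = (num / den) / (cnt_del / n_del)
    se = jackknife_se(E_blocks)
    p = np.empty(C)
    for i in range(C):
        if not np.isfinite(E[i]):
            p[i] = np.nan
        elif se[i] > 0:
            p[i] = max(stats.norm.sf((E[i] - 1.0) / se[i]), P_FLOOR)
        else:
            p[i] = P_FLOOR if E[i] > 1 else 1.0
    fit.enrichment, fit.se_enr, fit.p_enr = E, se, p
    return fit.to_frame()


def fit_category_enrichment(
    ss: pd.DataFrame,
    ref: LDReference,
    regions: Sequence[GenomicInterval],
    name: str = "focal",
    window_bp: int = DEFAULT_WINDOW_BP,
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> StratifiedFit:
    """Convenience: fit one focal category (plus base) and its enrichment."""
    annot = AnnotationMatrix.from_regions(ref.snps, {name: regions})
    ld = compute_ld_scores(ref, annot, window_bp)
    fit = fit_stratified(ss, ld, n_blocks=n_blocks, weights=ref.weights)
    enrichment_summary(fit, annot)
    return fit


def read_ld_scores(path) -> LDScoreTable:
    """Read a TSV written by :meth:`LDScoreTable.to_frame`."""
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "chrom": str})
    names = [c[3:] for c in df.columns if c.startswith("L2_")]
    ld = df[[f"L2_{n}" for n in names]].to_numpy(float)
    return LDScoreTable(df[["snp", "chrom", "pos"]], names, ld,
                        window_bp=DEFAULT_WINDOW_BP)


def read_pairwise_r(panel: pd.DataFrame, pairs: pd.DataFrame) -> LDReference:
    """Build an LDReference from a panel table and (snp_a, snp_b, r) pairs.

    SNPs are grouped into blocks by connected components of the pair graph
    (in panel order); unlisted pairs have r = 0, diagonal r = 1.
    """
    panel = panel.reset_index(drop=True)
    index = {s: i for i, s in enumerate(panel["snp"])}
    parent = np.arange(len(panel))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in zip(pairs["snp_a"], pairs["snp_b"]):
        ra, rb = find(index[a]), find(index[b])
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    roots = np.array([find(i) for i in range(len(panel))])
    blocks, r_blocks = [], []
    for root in np.unique(roots):
        idx = np.flatnonzero(roots == root)
        local = {int(i): k for k, i in enumerate(idx)}
        r = np.eye(len(idx))
        sub = pairs[pairs["snp_a"].map(index).isin(idx)]
        for a, b, v in zip(sub["snp_a"], sub["snp_b"], sub["r"]):
            if abs(v) > 1:
                raise ValueError(f"|r| > 1 for pair ({a}, {b})")
            i, j = local[index[a]], local[index[b]]
            r[i, j] = r[j, i] = v
        blocks.append(idx)
        r_blocks.append(r)
    return LDReference(panel, blocks, r_blocks=r_blocks)
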