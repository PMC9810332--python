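"""Shared fixtures: tiny omics instances, atlases and LD references."""

import numpy as np
import pandas as pd
import pytest

from regherit.io import GenomicInterval
from regherit.ldsc import LDReference
from regherit.regnet import ContextOmics


def random_omics(rng, n_tfs=10, n_res=20, n_tgs=15, context_id="ctx",
                 genome_bp=1_000_000):
    """Random dense ContextOmics with disjoint RE intervals."""
    tfs = [f"tf{i}" for i in range(n_tfs)]
    res = [f"re{k}" for k in range(n_res)]
    tgs = [f"g{j}" for j in range(n_tgs)]
    stride = genome_bp // n_res
    intervals = [GenomicInterval("1", k * stride, k * stride + 500, res[k])
                 for k in range(n_res)]
    return ContextOmics(
        context_id=context_id,
        tf_expr=pd.Series(rng.lognormal(0, 0.5, n_tfs), index=tfs),
        tg_expr=pd.Series(rng.lognormal(0, 0.5, n_tgs), index=tgs),
        re_open=pd.Series(rng.lognormal(0, 0.5, n_res), index=res),
        motif_binding=pd.DataFrame(
            (rng.random((n_tfs, n_res)) < 0.4) * rng.uniform(0.2, 2, (n_tfs, n_res)),
            index=tfs, columns=res),
        prior_interaction=pd.DataFrame(
            (rng.random((n_res, n_tgs)) < 0.3) * rng.uniform(0.2, 2, (n_res, n_tgs)),
            index=res, columns=tgs),
        prior_corr=pd.DataFrame(rng.uniform(-1, 1, (n_tfs, n_tgs)),
                                index=tfs, columns=tgs),
        re_intervals=intervals,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


@pytest.fixture
def omics(rng):
    return random_omics(rng)


def tiny_ld_reference(r_matrix, positions=None, chrom="1"):
    """Single-block LDReference with an explicit correlation matrix."""
    k = len(r_matrix)
    if positions is None:
        positions = (np.arange(k) + 1) * 1000
    snps = pd.DataFrame({"snp": [f"s{i}" for i in range(k)],
                         "chrom": chrom, "pos": positions})
    return LDReference(snps, [np.arange(k)], r_blocks=[np.asarray(r_matrix, float)])
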