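# regherit

**Which tissues does a GWAS phenotype act through — and which regulations
carry the signal?**

`regherit` builds context-specific TF → RE → TG regulatory networks from
paired gene-expression and chromatin-accessibility inputs, turns each
context's *specific* regulatory elements into a genome annotation category,
estimates how strongly a phenotype's SNP-heritability is enriched in each
category by stratified LD-score regression on GWAS summary statistics, and
ranks contexts by a relevance score with block-jackknife significance.
On top of that it correlates relevance profiles between phenotypes (a proxy
for phenotypic correlation) and extracts the SNP-associated regulatory
subnetwork that explains a context's relevance. A seeded synthetic-data
module generates LD references, multi-context atlases with planted specific
REs, and summary statistics with known stratified-heritability ground truth,
so the whole pipeline is testable without external downloads.

It is aimed at statistical geneticists and regulatory genomicists doing
post-GWAS interpretation with paired multi-omics resources.

## The model in brief

Regulatory scoring per context (B = motif binding, O = openness, I = prior
RE–gene interaction, R = prior TF–gene correlation):

    TRS_ij = (Σ_k B_ik·O_k·I_kj) · 2^{R_ij} · √(TF_i·TG_j)
    CRS_kj = (Σ_i B_ik·TRS_ij) · I_kj · O_k

Edges are kept by an empirical re-pairing FDR (0.001) for TRS and a Normal
upper tail on log2(1+CRS) (α = 0.05) for CRS. An RE is *context-specific*
when no other context's RE overlaps more than 50% of its bases (60% within
the same context group); the merged specific REs form the context's genome
category C_i.

Heritability side, for SNP j with GWAS χ² and sample size N:

    E[χ²_j] = N·Σ_i τ_i·l_{j,i} + N·a + 1,       l_{j,i} = Σ_{k∈C_i} r²_{jk}

fit by weighted least squares with delete-one-block jackknife SEs; category
enrichment E_i = (share of heritability)/(share of SNPs); relevance
R_i = E_i·(−log₁₀ p_i), with significance from a 100-fold jackknife over the
category's REs and BH correction across contexts. Relevant tissues:
R ≥ 100 and FDR q ≤ 0.01. See `docs/methods.md` for the full account.

## Worked example

```python
from regherit import (SimulationConfig, relevance_profile,
                      select_relevant_tissues)
from regherit.synthetic import simulate_study

study = simulate_study(SimulationConfig(), seed=11)   # 50k SNPs, 6 contexts
prof = relevance_profile("my_phenotype", study.categories,
                         study.sumstats, study.ref, seed=5)
print(prof.to_frame().round(3))
print("planted:", study.truth.planted_relevant_context)
```

prints (numbers from this exact call):

```
  context        R      sd      z      p      q  selected
0    ctx0  487.123  85.168  5.720  0.000  0.000      True
1    ctx1    0.368   0.819  0.450  0.326  0.606     False
2    ctx2   -0.033   0.019 -1.708  0.956  0.956     False
3    ctx3    0.372   0.808  0.461  0.323  0.606     False
4    ctx4   -0.018   0.024 -0.740  0.770  0.924     False
5    ctx5    0.079   0.324  0.243  0.404  0.606     False
planted: ctx0
```

The planted causal context (`ctx0`) is the only one passing the R ≥ 100,
q ≤ 0.01 selection — its specific regulatory category carries the simulated
heritability (estimated enrichment 47.4 with one-sided enrichment
p ≈ 5e-11, hence R = 47.4 × 10.3 ≈ 487), while the five null contexts hover
around R ≈ 0.
`select_relevant_tissues(prof)` returns that one-row table.

The same pipeline is scriptable from the shell:

```bash
regherit --seed 11 simulate --out-dir study/
regherit relevance --study-dir study/ --sumstats study/sumstats.tsv \
         --out relevance.tsv
regherit enrich --sumstats study/sumstats.tsv --ldscores study/ldscore.tsv \
         --beds-dir study/categories --out enrichment.tsv
```

Other subcommands: `network` (per-context edge scoring), `specific` /
`categories` (genome categories by any of the five methods), `ldscore`,
`correlate` (pairwise relevance correlation + benchmark metrics), and
`subnetwork` (A-score SNP-associated subnetworks).

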