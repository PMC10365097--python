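"""Genome-scale scan: recover a planted differential-slope gene and score
the hit list against a reference set.

Simulates 300 samples, one causal SNP and 60 genes, of which one gene's
expression-biomarker slope depends on genotype (0.5 / 0.5 / 3.0).  Scans
every gene with the stratified Chow test, ranks by p, and evaluates the
hypergeometric enrichment of the significant genes against a small
reference list containing the causal gene.
"""

from fedchow import (
    ScanConfig,
    SimulationSpec,
    enrich_selection,
    scan_genes,
    select_genes,
    simulate_trio_dataset,
    stratify_by_genotype,
)

spec = SimulationSpec(
    n_samples=300, n_genes=60, n_causal_genes=1, n_snps=1, n_causal_snps=1,
    group_slopes=(0.5, 0.5, 3.0), noise_sd=0.2, balanced_groups=True, seed=7,
)
genotypes, expression, biomarker, truth = simulate_trio_dataset(spec)
print(f"planted causal pair: {truth['snp_id'][0]} -> {truth['gene_id'][0]}")

stratifier = stratify_by_genotype(genotypes, truth["snp_id"][0])
records = scan_genes(
    stratifier, biomarker, expression,
    ScanConfig(solver="federated", n_sites=3, seed=7),
)

top = sorted(records, key=lambda r: (r.p_value, r.gene_id))[:3]
print("\ntop three genes by Chow-test p-value:")
for r in top:
    print(f"  {r.gene_id}  F={r.f_value:9.2f}  p={r.p_value:.3e}  "
          f"q={r.q_value:.3e}")

selected = select_genes(records, alpha=0.05)
reference = [truth["gene_id"][0], "GENE00011", "GENE00012"]
enr = enrich_selection(selected, reference, expression.gene_ids)
print(f"\n{len(selected)} genes selected at p<0.05; "
      f"{enr.overlap} of {enr.reference_size} reference genes hit")
print(f"enrichment p (upper tail) = {enr.p_value:.4f}")
print()
print("The planted gene tops the ranking by many orders of magnitude, and")
print("the selection is enriched for the reference list that contains it.")
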