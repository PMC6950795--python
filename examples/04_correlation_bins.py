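"""Correlate probe methylation with expression on matched samples.

Uses a matched cohort (methylation and expression measured on the same
samples), computes the Pearson r of every probe against its gene, and
summarises the 11 correlation bins. Genes planted with positive coupling
(UPUP-like) should concentrate in positive bins, negative coupling
(UPDOWN-like) in negative bins.
"""

from methexpr import CohortSpec, SimConfig, correlate_group, simulate_dataset
from methexpr.correlation import modal_bin

config = SimConfig(
    seed=4,
    n_genes=60,
    probes_per_gene_sparse=2,
    probes_per_gene_dense=8,
    cohorts=[CohortSpec("Matched", 100, 100, "dense")],
    group_fractions={"UPUP": 0.5, "UPDOWN": 0.5, "DOWNUP": 0,
                     "DOWNDOWN": 0, "NULL": 0},
    expr_coupling=0.3,
    frac_inconsistent=0.0,
)
ds = simulate_dataset(config)
meth = ds.cohorts["Matched"][0]

for group in ("UPUP", "UPDOWN"):
    genes = list(ds.truth.genes.loc[ds.truth.genes["group"] == group, "gene"])
    records, summary = correlate_group(meth, ds.expression, ds.annotation, genes)
    print(f"\n{group}-coupled genes ({len(genes)} genes, "
          f"{len(records)} probe-gene pairs):")
    populated = summary.loc[summary["n_probes"] > 0]
    for row in populated.itertuples(index=False):
        print(f"  {row.bin:25s} {row.n_probes:4d} probes "
              f"({row.pct_probes:5.1f}%) across {row.n_genes} genes")
    print(f"  modal bin: {modal_bin(summary)}")

print("\nAt coupling 0.3 the mode sits in the intermediate bins (|r| in "
      "0.2-0.4],\nwith the sign following the planted direction.")
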